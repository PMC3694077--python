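"""Forward simulation of a two-line divergent selection experiment.

The generator emulates a residual-feed-intake (RFI) selection population:
founders in linkage equilibrium are split into a LOW and a HIGH line at
generation 0; the LOW line is truncation-selected for decreased RFI every
generation, while the HIGH line mates at random until a configurable
generation (default 5) and is then selected for increased RFI.  Gametes
recombine with Poisson crossover counts per chromosome, so linkage
disequilibrium accumulates by drift and selection rather than from a
coalescent backstory.

A sparse QTL architecture (a configurable fraction of SNPs, default 0.5%,
mirroring a whole-genome-regression mixture fraction of 0.995) drives a
polygenic RFI breeding value, with correlated breeding values for growth
(ADG), backfat (BF) and loin muscle area (LMA).  Raw records are produced
the way a test station would: biweekly weights on a per-animal growth
line, daily feed intakes on a per-animal quadratic curve, off-test
ultrasound traits, and per-SNP chip quality scores with a configurable
failure fraction.  Every downstream stage therefore has a known ground
truth to recover.

Sex chromosomes are simulated as autosomal (flagged in metadata); the
default desk scale is hundreds of SNPs and animals, full chip scale is
supported but slow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix, MarkerMap, MISSING, write_ped_map, write_pedigree

__all__ = ["SimConfig", "TruthSet", "SimulatedDataset", "simulate_founders",
           "simulate_lines", "simulate_records", "simulate_dataset"]


@dataclass
class SimConfig:
    """Study-design knobs for the divergent-line generator.

    Defaults give a desk-scale version of a 9-generation (G0-G8) two-line
    design: uniform founder MAF on [0.05, 0.5], heritability 0.4 for the
    selection trait, truncation selection of the best 20% per line, HIGH
    line random-mated before generation 5.
    """

    n_founders: int = 200
    n_per_line_per_gen: int = 100
    n_generations: int = 9          # G0..G8
    n_snps: int = 2000
    n_chroms: int = 18
    chrom_length_bp: int = 100_000_000
    founder_maf_low: float = 0.05
    founder_maf_high: float = 0.5
    qtl_fraction: float = 0.005     # 1 - pi of the mixture architecture
    h2_target: float = 0.4
    selection_fraction: float = 0.2
    high_line_selection_start_gen: int = 5
    select_low: bool = True         # truncation selection in the LOW line
    recomb_rate_per_bp: float = 1e-8
    genotype_missing_rate: float = 0.0
    # record-generation noise (kg / mm / cm^2 scales)
    weight_measurement_sd: float = 0.8
    intake_daily_sd: float = 0.35
    test_days: int = 98
    weigh_interval_days: int = 14
    sex_effect_sd: float = 0.08
    pen_group_effect_sd: float = 0.06
    dam_effect_sd: float = 0.05
    pen_size: int = 16
    qc_fail_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.qtl_fraction < 1:
            raise ValueError("qtl_fraction must be in (0, 1)")
        if not 0 < self.h2_target < 1:
            raise ValueError("h2_target must be in (0, 1)")
        if not 0 < self.selection_fraction <= 1:
            raise ValueError("selection_fraction must be in (0, 1]")
        if self.n_snps < self.n_chroms:
            raise ValueError("need at least one SNP per chromosome")


@dataclass
class TruthSet:
    """Ground truth of a simulated dataset."""

    qtl_indices: np.ndarray
    qtl_effects: dict            # trait -> effect vector over qtl_indices
    breeding_values: pd.DataFrame  # animal_id + one column per trait
    variance_components: dict    # genetic/dam/pen/residual for the RFI trait

    def to_json(self, path) -> None:
        payload = {
            "qtl_indices": self.qtl_indices.tolist(),
            "qtl_effects": {k: v.tolist() for k, v in self.qtl_effects.items()},
            "breeding_values": self.breeding_values.to_dict(orient="list"),
            "variance_components": self.variance_components,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SimulatedDataset:
    config: SimConfig
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    pedigree: pd.DataFrame
    truth: TruthSet
    weights: pd.DataFrame
    intakes: pd.DataFrame
    traits: pd.DataFrame
    snp_quality: pd.DataFrame
    haplotypes: np.ndarray | None = None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_ped_map(outdir / "genotypes", self.genotypes, self.marker_map, self.pedigree)
        write_pedigree(outdir / "pedigree.tsv", self.pedigree)
        self.weights.to_csv(outdir / "weights.tsv", sep="\t", index=False)
        self.intakes.to_csv(outdir / "intakes.tsv", sep="\t", index=False)
        self.traits.to_csv(outdir / "traits.tsv", sep="\t", index=False)
        self.snp_quality.to_csv(outdir / "snp_quality.tsv", sep="\t", index=False)
        self.truth.to_json(outdir / "truth.json")


# genetic correlations of the companion traits with the selection trait
_TRAIT_CORR = {"RFI": 1.0, "ADG": 0.2, "BF": 0.35, "LMA": -0.15}


def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None):
    """Founder genotypes in linkage equilibrium plus a sorted physical map.

    Returns ``(GenotypeMatrix, MarkerMap)``; the genotype object carries a
    ``haplotypes`` attribute (2, n, k) consumed by :func:`simulate_lines`.
    """
    rng = rng or np.random.default_rng(config.seed)
    k = config.n_snps
    maf = rng.uniform(config.founder_maf_low, config.founder_maf_high, size=k)
    haps = (rng.random((2, config.n_founders, k)) < maf).astype(np.int8)

    per = np.full(config.n_chroms, k // config.n_chroms)
    per[: k % config.n_chroms] += 1
    chroms = np.concatenate([np.full(c, i + 1) for i, c in enumerate(per)])
    pos = np.concatenate(
        [np.sort(rng.choice(np.arange(1, config.chrom_length_bp + 1), size=c, replace=False)) for c in per]
    )
    table = pd.DataFrame(
        {
            "snp_id": [f"SNP{j:06d}" for j in range(k)],
            "chrom": chroms.astype(str),
            "pos_bp": pos.astype(int),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    gm = GenotypeMatrix(haps.sum(axis=0, dtype=np.int8))
    gm.haplotypes = haps  # type: ignore[attr-defined]
    gm.founder_maf = maf  # type: ignore[attr-defined]
    return gm, MarkerMap(table)


def _chrom_bounds(marker_map: MarkerMap) -> list[tuple[int, int]]:
    chroms = marker_map.chrom
    bounds = []
    start = 0
    for j in range(1, len(chroms) + 1):
        if j == len(chroms) or chroms[j] != chroms[start]:
            bounds.append((start, j))
            start = j
    return bounds


def _gamete(hap_pair: np.ndarray, marker_map: MarkerMap, bounds, rate: float,
            chrom_len: int, rng: np.random.Generator) -> np.ndarray:
    """Recombine one parent's haplotype pair into a gamete."""
    k = hap_pair.shape[1]
    out = np.empty(k, dtype=np.int8)
    pos = marker_map.pos_bp
    for (a, b) in bounds:
        current = rng.integers(0, 2)
        n_x = rng.poisson(rate * chrom_len)
        if n_x == 0:
            out[a:b] = hap_pair[current, a:b]
            continue
        xpos = np.sort(rng.integers(1, chrom_len + 1, size=n_x))
        seg = current + np.searchsorted(xpos, pos[a:b], side="left")
        out[a:b] = hap_pair[seg % 2, np.arange(a, b)]
    return out


def simulate_lines(config: SimConfig, founders) -> tuple[pd.DataFrame, GenotypeMatrix, TruthSet]:
    """Run the two-line design forward from founders.

    ``founders`` is the ``(GenotypeMatrix, MarkerMap)`` pair from
    :func:`simulate_founders`.  Selection truncates on the simulated RFI
    phenotype (breeding value plus environmental noise), not on the true
    breeding value, as a breeding program would.
    """
    gm0, marker_map = founders
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    haps0 = getattr(gm0, "haplotypes", None)
    if haps0 is None:
        raise ValueError("founders must come from simulate_founders (haplotypes attached)")
    n0, k = gm0.codes.shape
    bounds = _chrom_bounds(marker_map)

    # sparse QTL architecture scaled to hit h2_target in the founders
    n_qtl = max(1, int(round(config.qtl_fraction * k)))
    qtl_idx = np.sort(rng.choice(k, size=n_qtl, replace=False))
    raw = rng.normal(size=n_qtl)
    bv_raw = gm0.codes[:, qtl_idx].astype(float) @ raw
    sd = bv_raw.std()
    if sd == 0:
        sd = 1.0
    scale = np.sqrt(config.h2_target) / sd
    effects = {"RFI": raw * scale}
    bv = {"RFI": bv_raw * scale}
    for trait, rho in _TRAIT_CORR.items():
        if trait == "RFI":
            continue
        indep = rng.normal(size=n_qtl)
        eff = rho * effects["RFI"] + np.sqrt(1 - rho**2) * indep * scale
        effects[trait] = eff
        bv[trait] = gm0.codes[:, qtl_idx].astype(float) @ eff
    # express breeding values as deviations from the founder mean
    bv_center = {t: float(bv[t].mean()) for t in bv}
    bv = {t: bv[t] - bv_center[t] for t in bv}

    env_sd = np.sqrt(1.0 - config.h2_target)

    half = n0 // 2
    lines = np.array(["LOW"] * half + ["HIGH"] * (n0 - half))
    sexes = np.array(["M", "F"] * ((n0 + 1) // 2))[:n0]

    all_haps = [haps0[:, i, :].copy() for i in range(n0)]
    ped_rows = []
    ids = [f"G0_{i:04d}" for i in range(n0)]
    for i in range(n0):
        ped_rows.append(
            dict(animal_id=ids[i], sire_id="0", dam_id="0", generation=0, line=lines[i],
                 sex=sexes[i], parity=1, pen=f"P{(i % 12) + 1:02d}", group="G0A",
                 age_on_test=int(rng.normal(90, 4)))
        )
    sel_phen_all = {ids[i]: bv["RFI"][i] + rng.normal(0, env_sd) for i in range(n0)}

    by_line = {ln: [i for i in range(n0) if lines[i] == ln] for ln in ("LOW", "HIGH")}
    prev_ids = {ln: [ids[i] for i in by_line[ln]] for ln in ("LOW", "HIGH")}
    prev_haps = {ln: [all_haps[i] for i in by_line[ln]] for ln in ("LOW", "HIGH")}
    prev_sex = {ln: [sexes[i] for i in by_line[ln]] for ln in ("LOW", "HIGH")}

    counter = n0
    for gen in range(1, config.n_generations):
        new_ids = {}
        new_haps = {}
        new_sex = {}
        for ln in ("LOW", "HIGH"):
            cand = np.arange(len(prev_ids[ln]))
            phen = np.array([sel_phen_all[prev_ids[ln][i]] for i in cand])
            selecting = (ln == "LOW" and config.select_low) or (
                ln == "HIGH" and gen >= config.high_line_selection_start_gen and config.select_low
            )
            # truncation within each sex so both sexes stay represented
            sires, dams = [], []
            for sex_label, out in (("M", sires), ("F", dams)):
                pool = [int(i) for i in cand if prev_sex[ln][i] == sex_label]
                if selecting and config.selection_fraction < 1:
                    order = np.argsort(phen[pool])
                    if ln == "HIGH":
                        order = order[::-1]
                    n_sel = max(2, int(round(config.selection_fraction * len(pool))))
                    out.extend(pool[i] for i in order[:n_sel])
                else:
                    out.extend(pool)
            if len(sires) < 2 or len(dams) < 2:
                raise ValueError(f"line {ln} generation {gen}: fewer than 2 selected parents of a sex")

            ids_g, haps_g, sex_g = [], [], []
            groups = ["A", "B"]
            for off in range(config.n_per_line_per_gen):
                s = sires[rng.integers(len(sires))]
                d = dams[rng.integers(len(dams))]
                g1 = _gamete(prev_haps[ln][s], marker_map, bounds,
                             config.recomb_rate_per_bp, config.chrom_length_bp, rng)
                g2 = _gamete(prev_haps[ln][d], marker_map, bounds,
                             config.recomb_rate_per_bp, config.chrom_length_bp, rng)
                hp = np.stack([g1, g2])
                aid = f"G{gen}_{counter:05d}"
                counter += 1
                sex = "M" if off % 2 == 0 else "F"
                grp = f"G{gen}{groups[off * 2 // config.n_per_line_per_gen]}"
                ped_rows.append(
                    dict(animal_id=aid, sire_id=prev_ids[ln][s], dam_id=prev_ids[ln][d],
                         generation=gen, line=ln, sex=sex,
                         parity=1 + (off % 2), pen=f"P{(off // config.pen_size) % 12 + 1:02d}",
                         group=grp, age_on_test=int(rng.normal(90, 4)))
                )
                code = hp.sum(axis=0).astype(float)
                bvals = {t: code[qtl_idx] @ effects[t] - bv_center[t] for t in effects}
                for t in effects:
                    bv[t] = np.append(bv[t], bvals[t])
                sel_phen_all[aid] = bvals["RFI"] + rng.normal(0, env_sd)
                ids_g.append(aid)
                haps_g.append(hp)
                sex_g.append(sex)
                all_haps.append(hp)
                ids.append(aid)
            new_ids[ln] = ids_g
            new_haps[ln] = haps_g
            new_sex[ln] = sex_g
        prev_ids, prev_haps, prev_sex = new_ids, new_haps, new_sex

    pedigree = pd.DataFrame(ped_rows)
    codes = np.stack([h.sum(axis=0) for h in all_haps]).astype(np.int8)
    if config.genotype_missing_rate > 0:
        miss = rng.random(codes.shape) < config.genotype_missing_rate
        codes = np.where(miss, MISSING, codes).astype(np.int8)
    gm = GenotypeMatrix(codes, ids)
    gm.haplotypes = np.stack(all_haps).transpose(1, 0, 2)  # type: ignore[attr-defined]

    bv_table = pd.DataFrame({"animal_id": ids, **{t: bv[t] for t in effects}})
    truth = TruthSet(
        qtl_indices=qtl_idx,
        qtl_effects=effects,
        breeding_values=bv_table,
        variance_components={
            "genetic": float(config.h2_target),
            "dam": float(config.dam_effect_sd**2),
            "pen": float(config.pen_group_effect_sd**2),
            "residual": float(1.0 - config.h2_target),
        },
    )
    return pedigree, gm, truth


def simulate_records(config: SimConfig, pedigree: pd.DataFrame, truth: TruthSet,
                     rng: np.random.Generator | None = None):
    """Raw station records for every pedigree animal.

    Returns (weights, intakes, traits, snp_quality) DataFrames.  Weights
    follow an individual growth line (intercept ~40 kg, slope = the
    animal's true ADG); daily intake follows a mild quadratic whose window
    mean equals the animal's true ADFI, which itself carries the RFI
    breeding value plus sex, pen-by-group and dam effects.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    bvs = truth.breeding_values.set_index("animal_id")
    days_w = np.arange(0, config.test_days + 1, config.weigh_interval_days)
    days_i = np.arange(0, config.test_days + 1)

    pen_group_levels = sorted(set(pedigree["pen"].astype(str) + "|" + pedigree["group"].astype(str)))
    pen_eff = dict(zip(pen_group_levels, rng.normal(0, config.pen_group_effect_sd, len(pen_group_levels))))
    dams = sorted(set(pedigree["dam_id"].astype(str)))
    dam_eff = dict(zip(dams, rng.normal(0, config.dam_effect_sd, len(dams))))
    dam_eff["0"] = 0.0
    sex_eff = {"M": config.sex_effect_sd, "F": -config.sex_effect_sd}

    w_rows, i_rows, t_rows = [], [], []
    for row in pedigree.itertuples(index=False):
        aid = str(row.animal_id)
        adg_true = 0.9 + 0.10 * float(bvs.loc[aid, "ADG"]) + rng.normal(0, 0.03)
        onwt = 40.0 + rng.normal(0, 2.0)
        wts = onwt + adg_true * days_w + rng.normal(0, config.weight_measurement_sd, days_w.size)
        for d, w in zip(days_w, wts):
            w_rows.append((aid, int(d), float(w)))

        pg = f"{row.pen}|{row.group}"
        adfi_true = (
            2.2
            + 0.8 * adg_true
            + float(bvs.loc[aid, "RFI"])
            + sex_eff[str(row.sex)]
            + pen_eff[pg]
            + dam_eff[str(row.dam_id)]
            + 0.002 * (float(row.age_on_test) - 90.0)
            + rng.normal(0, np.sqrt(truth.variance_components["residual"]) * 0.3)
        )
        c1, c2 = 0.004, -2e-5  # gentle rise then plateau over the window
        shape = c1 * days_i + c2 * days_i**2
        intake = adfi_true - shape.mean() + shape + rng.normal(0, config.intake_daily_sd, days_i.size)
        for d, v in zip(days_i, intake):
            i_rows.append((aid, int(d), float(v)))

        bf = 15.0 + 2.0 * float(bvs.loc[aid, "BF"]) + 0.05 * (wts[-1] - 115.0) + rng.normal(0, 1.0)
        lma = 42.0 + 3.0 * float(bvs.loc[aid, "LMA"]) + rng.normal(0, 1.5)
        t_rows.append((aid, float(bf), float(lma)))

    weights = pd.DataFrame(w_rows, columns=["animal_id", "day", "weight_kg"])
    intakes = pd.DataFrame(i_rows, columns=["animal_id", "day", "intake_kg"])
    traits = pd.DataFrame(t_rows, columns=["animal_id", "BF", "LMA"])

    k = config.n_snps
    fail = rng.random(k) < config.qc_fail_fraction
    which = rng.integers(0, 3, size=k)
    call_rate = np.clip(rng.uniform(0.92, 1.0, k), 0, 1)
    quality = np.clip(rng.uniform(0.6, 0.95, k), 0, 1)
    hwe_p = rng.uniform(0.05, 1.0, k)
    call_rate[fail & (which == 0)] = rng.uniform(0.3, 0.8, int((fail & (which == 0)).sum()))
    quality[fail & (which == 1)] = rng.uniform(0.0, 0.4, int((fail & (which == 1)).sum()))
    hwe_p[fail & (which == 2)] = rng.uniform(0.0, 1e-4, int((fail & (which == 2)).sum()))
    snp_quality = pd.DataFrame({"call_rate": call_rate, "quality_score": quality, "hwe_p": hwe_p})
    return weights, intakes, traits, snp_quality


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Convenience wrapper: founders -> lines -> records, deterministic in seed."""
    founders = simulate_founders(config)
    pedigree, genotypes, truth = simulate_lines(config, founders)
    weights, intakes, traits, quality = simulate_records(config, pedigree, truth)
    return SimulatedDataset(
        config=config,
        genotypes=genotypes,
        marker_map=founders[1],
        pedigree=pedigree,
        truth=truth,
        weights=weights,
        intakes=intakes,
        traits=traits,
        snp_quality=quality,
        haplotypes=getattr(genotypes, "haplotypes", None),
    )
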