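"""End-to-end orchestration: simulate -> phenotypes -> QC -> scans/WGAS.

One global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([global_seed, stage_index])`` so stages can be
rerun independently yet the whole run is byte-deterministic.  Stages
communicate only through the files they write (PED/MAP, TSV tables,
JSON manifest).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import bayesb as bayesb_mod
from . import divscan as divscan_mod
from . import geno_io
from . import pheno as pheno_mod
from . import simlines

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

TRAITS = ("RFI", "ADFI", "ADG", "BF", "LMA")
_STAGES = {"simulate": 0, "pheno": 1, "qc": 2, "divscan": 3, "bayesb": 4, "assoc": 5}


def stage_seed(global_seed: int, stage: str) -> int:
    """Documented fan-out: SeedSequence([global_seed, stage_index]) -> uint32."""
    ss = np.random.SeedSequence([int(global_seed), _STAGES[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


@dataclass
class RunConfig:
    outdir: str = "run"
    traits: tuple = ("RFI",)
    seed: int = 0
    sim: simlines.SimConfig = field(default_factory=lambda: simlines.SimConfig(
        n_founders=80, n_per_line_per_gen=40, n_generations=3, n_snps=500, n_chroms=5))
    bayesb: bayesb_mod.BayesBConfig = field(default_factory=lambda: bayesb_mod.BayesBConfig(
        n_iter=2000, burn_in=500, thin=10, expected_h2=0.4))
    variance_ratios: dict = field(default_factory=lambda: {"animal": 1.5, "dam": 20.0, "pen": 20.0})
    focal_generation: int | None = None  # default: last simulated generation
    gc_threshold: float = 0.01
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not self.traits:
            raise ValueError("trait list must be non-empty")
        unknown = set(self.traits) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown traits: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = simlines.SimConfig(**raw.pop("sim", {}))
        bb = bayesb_mod.BayesBConfig(**raw.pop("bayesb", {}))
        if "traits" in raw:
            raw["traits"] = tuple(raw["traits"])
        return cls(sim=sim, bayesb=bb, **raw)


def _config_hash(config: RunConfig) -> str:
    fields = {**asdict(config), "sim": asdict(config.sim), "bayesb": asdict(config.bayesb)}
    fields.pop("outdir", None)  # fingerprint the science, not the destination
    payload = json.dumps(fields, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage for every configured trait; returns the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate -----------------------------------------------------
    sim_cfg = simlines.SimConfig(**{**asdict(config.sim), "seed": stage_seed(config.seed, "simulate")})
    data = simlines.simulate_dataset(sim_cfg)
    data.write(out / "data")

    # --- phenotypes ---------------------------------------------------
    tab = pheno_mod.derive_phenotypes(data.weights, data.intakes, data.traits, data.pedigree)
    spec = pheno_mod.RfiModelSpec(variance_ratios=dict(config.variance_ratios))
    tab = pheno_mod.compute_rfi(tab, data.pedigree, spec)
    tab.to_csv(out / "phenotypes.tsv", sep="\t", index=False)

    # --- QC -----------------------------------------------------------
    quality = geno_io.SnpQuality(
        call_rate=data.snp_quality["call_rate"].to_numpy(),
        quality_score=data.snp_quality["quality_score"].to_numpy(),
        hwe_p=data.snp_quality["hwe_p"].to_numpy(),
    )
    kept, report = geno_io.qc_filter(data.genotypes, quality)
    kept_map = geno_io.MarkerMap(data.marker_map.table.loc[report.kept_mask].reset_index(drop=True))
    pd.DataFrame([{
        "n_input": report.n_input, "n_kept": report.n_kept,
        "fail_call_rate": report.n_fail_call_rate, "fail_quality": report.n_fail_quality,
        "fail_hwe": report.n_fail_hwe,
    }]).to_csv(out / "qc_report.tsv", sep="\t", index=False)

    # --- divergence scan ----------------------------------------------
    focal = config.focal_generation if config.focal_generation is not None else sim_cfg.n_generations - 1
    scan = divscan_mod.divergence_scan(kept, data.pedigree, kept_map, focal_generation=focal)
    scan.to_csv(out / "divscan.tsv", sep="\t", index=False, float_format="%.6g")

    # --- per-trait WGAS -----------------------------------------------
    order = {str(a): i for i, a in enumerate(kept.sample_ids)}
    tab_g = tab[tab["animal_id"].astype(str).isin(order)].copy()
    rows = [order[a] for a in tab_g["animal_id"].astype(str)]
    geno_sub = geno_io.GenotypeMatrix(kept.codes[rows], list(tab_g["animal_id"].astype(str)))
    Z = geno_io.encode_centered(geno_sub)
    tab_g["pen_group"] = tab_g["pen"].astype(str) + "|" + tab_g["group"].astype(str)
    tab_g["line_parity"] = tab_g["line"].astype(str) + "x" + tab_g["parity"].astype(str)
    X, _ = pheno_mod.build_design(
        tab_g, factors=["sex", "pen_group"], interactions=[("age_on_test", "line_parity")]
    )

    windows = bayesb_mod.make_windows(kept_map)
    manifest_traits = {}
    for t_idx, trait in enumerate(config.traits):
        y = tab_g[trait].to_numpy(float)
        ok = np.isfinite(y)
        bb_cfg = bayesb_mod.BayesBConfig(**{**asdict(config.bayesb),
                                            "seed": stage_seed(config.seed, "bayesb") + t_idx})
        samples = bayesb_mod.fit_bayesb(y[ok], X[ok], Z[ok], bb_cfg)
        wins = bayesb_mod.summarize_windows(samples, windows, kept_map)
        wins.to_csv(out / f"bayesb_windows_{trait}.tsv", sep="\t", index=False, float_format="%.6g")
        h2 = bayesb_mod.genomic_heritability(samples)

        res, summary = assoc_mod.association_pipeline(
            y[ok], tab_g.loc[ok], geno_io.GenotypeMatrix(geno_sub.codes[ok]),
            gc_threshold=config.gc_threshold, fdr_threshold=config.fdr_threshold,
        )
        res.insert(0, "snp_id", kept_map.snp_ids)
        res.insert(1, "chrom", kept_map.chrom)
        res.insert(2, "pos_bp", kept_map.pos_bp)
        res.to_csv(out / f"assoc_{trait}.tsv", sep="\t", index=False, float_format="%.6g")
        manifest_traits[trait] = {
            "genomic_h2": h2["mean"],
            "lambda": summary["lambda"],
            "n_candidate_windows": int(wins["candidate"].sum()),
            "n_sig_gc": summary["n_sig_gc"],
        }

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "thresholds": {
            "gc": config.gc_threshold,
            "fdr": config.fdr_threshold,
            "qc_call_rate": 0.80,
            "qc_quality": 0.40,
            "qc_hwe_alpha": 1e-4,
            "window_candidate_multiplier": 5.0,
        },
        "n_windows": windows.n_windows,
        "expected_window_share_pct": bayesb_mod.expected_window_share(windows.n_windows),
        "traits": manifest_traits,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
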