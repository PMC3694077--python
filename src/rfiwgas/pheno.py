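"""Derivation of growth and feed-efficiency phenotypes.

Average daily gain (ADG) is the least-squares slope of biweekly body
weights on days on test.  Average daily feed intake (ADFI) is the mean of
a per-animal quadratic least-squares fit of daily intake over the animal's
own on-test window.  Residual feed intake (RFI) is ADFI minus the intake
predicted by a single-trait animal model with fixed effects of line,
on-test group and sex, generation-by-line-specific slopes for six
covariates (onwt-40, age at on-test-90, offwt-115, metabolic mid-weight,
adjusted ADG, adjusted off-test backfat), and random animal (pedigree),
dam and pen-within-group effects.  The genetic deviation is deliberately
left inside RFI: only the fixed-effect and covariate predictions are
subtracted, so RFI remains a selectable trait rather than a pure residual.

The mixed-model machinery (Henderson's mixed-model equations, the inverse
numerator relationship matrix with Meuwissen-Luo inbreeding) lives here
too because the RFI definition depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "compute_adg",
    "compute_adfi",
    "inbreeding_coefficients",
    "build_a_inverse",
    "tabular_a",
    "build_design",
    "solve_mme",
    "MmeSolution",
    "RfiModelSpec",
    "derive_phenotypes",
    "compute_rfi",
    "em_reml_ratios",
]


# ---------------------------------------------------------------------------
# Per-animal regressions

def compute_adg(days, weights) -> float:
    """OLS slope of weight (kg) on days on test."""
    d = np.asarray(days, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.unique(d).size < 2:
        raise ValueError("ADG needs at least 2 distinct days")
    dc = d - d.mean()
    return float((dc @ (w - w.mean())) / (dc @ dc))


def compute_adfi(days, intakes) -> float:
    """Mean of a quadratic least-squares intake curve over the test window.

    Fit intake = c0 + c1*day + c2*day^2, then average the fitted curve over
    the integer days from the first to the last observed day inclusive.
    """
    d = np.asarray(days, dtype=float)
    y = np.asarray(intakes, dtype=float)
    if np.unique(d).size < 3:
        raise ValueError("ADFI needs at least 3 distinct days")
    X = np.column_stack([np.ones_like(d), d, d * d])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    grid = np.arange(int(np.floor(d.min())), int(np.ceil(d.max())) + 1, dtype=float)
    fitted = coef[0] + coef[1] * grid + coef[2] * grid * grid
    return float(fitted.mean())


# ---------------------------------------------------------------------------
# Pedigree relationship machinery

def _parent_indices(pedigree: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    ids = [str(a) for a in pedigree["animal_id"]]
    index = {a: i for i, a in enumerate(ids)}
    sire = np.full(len(ids), -1, dtype=int)
    dam = np.full(len(ids), -1, dtype=int)
    for i, row in enumerate(pedigree.itertuples(index=False)):
        for arr, pid in ((sire, str(row.sire_id)), (dam, str(row.dam_id))):
            if pid in ("0", "nan", "None", ""):
                continue
            if pid not in index:
                raise ValueError(f"unknown parent {pid}")
            j = index[pid]
            if j >= i:
                raise ValueError(f"pedigree not topologically ordered at {ids[i]} (parent {pid})")
            arr[i] = j
    return sire, dam, ids


def inbreeding_coefficients(pedigree: pd.DataFrame) -> np.ndarray:
    """Meuwissen-Luo inbreeding: F_i = a(sire_i, dam_i) / 2 via memoised kinship."""
    sire, dam, _ = _parent_indices(pedigree)
    n = len(sire)
    F = np.zeros(n)
    memo: dict[tuple[int, int], float] = {}

    def rel(i: int, j: int) -> float:
        # additive relationship a_ij, iterative over the younger animal
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        if i == j:
            val = 1.0 + 0.5 * rel(sire[i], dam[i])
        else:
            val = 0.5 * (rel(i, sire[j]) + rel(i, dam[j]))
        memo[key] = val
        return val

    for i in range(n):
        if sire[i] >= 0 and dam[i] >= 0:
            F[i] = 0.5 * rel(sire[i], dam[i])
    return F


def tabular_a(pedigree: pd.DataFrame) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method."""
    sire, dam, _ = _parent_indices(pedigree)
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        for j in range(i):
            aij = 0.0
            if s >= 0:
                aij += 0.5 * A[j, s]
            if d >= 0:
                aij += 0.5 * A[j, d]
            A[i, j] = A[j, i] = aij
    return A


def build_a_inverse(pedigree: pd.DataFrame) -> sparse.csr_matrix:
    """Sparse A-inverse by Henderson's rules with inbreeding accounted for.

    Mendelian sampling variance d_i is 0.5 - 0.25(F_s + F_d) with both
    parents known, 0.75 - 0.25 F_p with one, 1 with none.
    """
    sire, dam, ids = _parent_indices(pedigree)
    F = inbreeding_coefficients(pedigree)
    n = len(ids)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            di = 0.75 - 0.25 * F[p]
        else:
            di = 1.0
        alpha = 1.0 / di
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -alpha / 2)
                add(p, i, -alpha / 2)
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    add(p, q, alpha / 4)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


# ---------------------------------------------------------------------------
# Design matrices and Henderson's MME

def build_design(df: pd.DataFrame, factors: list[str] | None = None,
                 covariates: list[str] | None = None,
                 interactions: list[tuple[str, str]] | None = None,
                 intercept: bool = True) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design with corner constraints.

    Each factor contributes indicator columns for all levels but the first
    (sorted order), so the first level of every factor is the reference.
    ``interactions`` pairs a covariate with a factor: one slope column per
    factor level (no reference drop — there is no main covariate term).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    n = len(df)
    if intercept:
        cols.append(np.ones(n))
        names.append("intercept")
    for f in factors or []:
        levels = sorted(df[f].astype(str).unique())
        for lev in levels[1:]:
            cols.append((df[f].astype(str) == lev).to_numpy(float))
            names.append(f"{f}[{lev}]")
    for c in covariates or []:
        cols.append(df[c].to_numpy(float))
        names.append(c)
    for cov, fac in interactions or []:
        x = df[cov].to_numpy(float)
        for lev in sorted(df[fac].astype(str).unique()):
            cols.append(x * (df[fac].astype(str) == lev).to_numpy(float))
            names.append(f"{cov}:{fac}[{lev}]")
    return np.column_stack(cols), names


def factor_incidence(labels) -> tuple[np.ndarray, list[str]]:
    """Full 0/1 incidence matrix for a random factor (no reference drop)."""
    lab = np.asarray([str(x) for x in labels])
    levels = sorted(set(lab))
    Z = np.zeros((lab.size, len(levels)))
    for k, lev in enumerate(levels):
        Z[lab == lev, k] = 1.0
    return Z, levels


@dataclass
class MmeSolution:
    fixed: np.ndarray
    fixed_names: list[str]
    random: list[np.ndarray]
    residuals: np.ndarray
    coefficient_inverse: np.ndarray | None = None


def solve_mme(y, X, random_terms=None, ratios=None, return_inverse: bool = False,
              fixed_names: list[str] | None = None) -> MmeSolution:
    """Solve Henderson's mixed-model equations.

    ``random_terms`` is a list of (Z, Kinv) with Kinv = None meaning the
    identity; ``ratios`` the matching list of lambda = sigma2_e / sigma2_u
    added to each random block.  A ratio of 0/None/inf drops the term (its
    predictions are zero), so with no surviving terms the solution is OLS.
    A singular system falls back to the minimum-norm least-squares solution.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y are non-conformable")
    terms = []
    for (Z, Kinv), lam in zip(random_terms or [], ratios or []):
        if lam is None or lam == 0 or np.isinf(lam):
            terms.append(None)
            continue
        Z = np.asarray(Z, dtype=float)
        if Z.shape[0] != y.shape[0]:
            raise ValueError("random design non-conformable with y")
        terms.append((Z, Kinv, float(lam)))

    blocks = [X] + [t[0] for t in terms if t is not None]
    W = np.hstack(blocks)
    C = W.T @ W
    rhs = W.T @ y
    ofs = X.shape[1]
    for t in terms:
        if t is None:
            continue
        Z, Kinv, lam = t
        q = Z.shape[1]
        K = np.eye(q) if Kinv is None else (Kinv.toarray() if sparse.issparse(Kinv) else np.asarray(Kinv))
        C[ofs:ofs + q, ofs:ofs + q] += lam * K
        ofs += q

    Cinv = None
    try:
        if return_inverse:
            Cinv = np.linalg.inv(C)
            sol = Cinv @ rhs
        else:
            sol = np.linalg.solve(C, rhs)
        scale = max(float(np.abs(rhs).max()), 1.0)
        if not np.allclose(C @ sol, rhs, atol=1e-7 * scale):
            raise np.linalg.LinAlgError  # ill-conditioned; use min-norm SVD solve
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(C, rhs, rcond=None)[0]
        if return_inverse:
            Cinv = np.linalg.pinv(C)

    b = sol[:X.shape[1]]
    random_sols: list[np.ndarray] = []
    fitted = X @ b
    ofs = X.shape[1]
    for t in terms:
        if t is None:
            random_sols.append(np.zeros(0))
            continue
        Z, _, _ = t
        u = sol[ofs:ofs + Z.shape[1]]
        random_sols.append(u)
        fitted = fitted + Z @ u
        ofs += Z.shape[1]
    return MmeSolution(
        fixed=b,
        fixed_names=fixed_names or [f"b{i}" for i in range(X.shape[1])],
        random=random_sols,
        residuals=y - fitted,
        coefficient_inverse=Cinv,
    )


def em_reml_ratios(y, X, random_terms, start_ratios, n_iter: int = 50, tol: float = 1e-4):
    """Crude EM-REML for the variance ratios of the given random terms.

    Standard Henderson EM updates on the MME: sigma2_u = (u'K u +
    sigma2_e tr(K C_uu)) / q.  Dense; intended for modest data sizes.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    ratios = [float(r) for r in start_ratios]
    for _ in range(n_iter):
        sol = solve_mme(y, X, random_terms, ratios, return_inverse=True)
        e = sol.residuals
        p = X.shape[1]
        sigma2_e = float(e @ y) / (n - p)  # REML-style quadratic form
        new_ratios = []
        ofs = X.shape[1]
        for (Z, Kinv), lam, u in zip(random_terms, ratios, sol.random):
            q = Z.shape[1]
            K = np.eye(q) if Kinv is None else (Kinv.toarray() if sparse.issparse(Kinv) else np.asarray(Kinv))
            Cuu = sol.coefficient_inverse[ofs:ofs + q, ofs:ofs + q]
            sigma2_u = (u @ (K @ u) + sigma2_e * np.trace(K @ Cuu)) / q
            new_ratios.append(sigma2_e / max(sigma2_u, 1e-12))
            ofs += q
        if all(abs(a - b) / max(b, 1e-9) < tol for a, b in zip(new_ratios, ratios)):
            ratios = new_ratios
            break
        ratios = new_ratios
    return ratios


# ---------------------------------------------------------------------------
# Phenotype table and RFI

RFI_COVARIATES = ["onwt_dev", "age_dev", "offwt_dev", "metamidwt", "adga", "offbfa"]


@dataclass
class RfiModelSpec:
    """Model layout for the RFI animal model.

    ``variance_ratios`` maps effect name -> lambda = sigma2_e / sigma2_u;
    0 or absent drops the effect.  ``subtract_random`` controls whether
    animal/dam/pen predictions are removed from RFI; ``subtract_line``
    controls whether the line-related (generation-by-line) intercepts are.
    Both default to False so RFI keeps the genetic deviation and the
    between-line selection response — subtracting either would erase the
    realized line difference the trait is selected on.
    """

    # gen_line cell intercepts absorb the line main effect and make RFI
    # exactly mean-zero and covariate-orthogonal within every cell
    fixed_factors: list[str] = field(default_factory=lambda: ["gen_line", "group", "sex"])
    covariates: list[str] = field(default_factory=lambda: list(RFI_COVARIATES))
    cell_factor: str = "gen_line"
    variance_ratios: dict = field(default_factory=dict)
    subtract_random: bool = False
    subtract_line: bool = False


def _pooled_within_group_slope(y: np.ndarray, x: np.ndarray, groups) -> float:
    """Slope of y on x pooling within-group (de-meaned) cross-products."""
    g = np.asarray([str(v) for v in groups])
    num = 0.0
    den = 0.0
    for lev in np.unique(g):
        m = g == lev
        if m.sum() < 2:
            continue
        xc = x[m] - x[m].mean()
        num += float(xc @ (y[m] - y[m].mean()))
        den += float(xc @ xc)
    return num / den if den > 0 else 0.0


def derive_phenotypes(weights: pd.DataFrame, intakes: pd.DataFrame,
                      traits: pd.DataFrame, pedigree: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-animal phenotype table from raw records.

    weights: animal_id, day, weight_kg (biweekly); intakes: animal_id, day,
    intake_kg (daily); traits: animal_id, BF, LMA (off-test ultrasound).
    Returns one row per pedigree animal with ADG/ADFI, on/off-test weights,
    metabolic mid-weight and the adjusted covariates adga and offbfa.

    adga adjusts ADG to the reference 90-180 day test window and offbfa
    adjusts BF to 115 kg off-test weight, both by pooled within-group
    linear corrections with slopes estimated from the data.
    """
    rows = []
    wg = dict(tuple(weights.groupby("animal_id")))
    ig = dict(tuple(intakes.groupby("animal_id")))
    tr = traits.set_index(traits["animal_id"].astype(str))
    for row in pedigree.itertuples(index=False):
        aid = str(row.animal_id)
        if aid not in wg or aid not in ig:
            continue
        w = wg[aid].sort_values("day")
        it = ig[aid].sort_values("day")
        adg = compute_adg(w["day"], w["weight_kg"])
        adfi = compute_adfi(it["day"], it["intake_kg"])
        onwt = float(w["weight_kg"].iloc[0])
        offwt = float(w["weight_kg"].iloc[-1])
        midwt = float(w["weight_kg"].mean())
        last_day = float(w["day"].iloc[-1])
        rec = {
            "animal_id": aid,
            "onwt": onwt,
            "offwt": offwt,
            "age_on_test": float(row.age_on_test),
            "mid_age": float(row.age_on_test) + last_day / 2.0,
            "metamidwt": midwt ** 0.75,
            "ADG": adg,
            "ADFI": adfi,
            "BF": float(tr.loc[aid, "BF"]) if aid in tr.index else np.nan,
            "LMA": float(tr.loc[aid, "LMA"]) if aid in tr.index else np.nan,
            "line": row.line,
            "group": row.group,
            "sex": row.sex,
            "pen": row.pen,
            "generation": row.generation,
            "parity": row.parity,
        }
        rows.append(rec)
    tab = pd.DataFrame(rows)
    if tab.empty:
        raise ValueError("no animal has both weight and intake records")
    # reference test window 90-180 days of age has midpoint 135
    b_age = _pooled_within_group_slope(tab["ADG"].to_numpy(), tab["mid_age"].to_numpy(), tab["group"])
    tab["adga"] = tab["ADG"] - b_age * (tab["mid_age"] - 135.0)
    ok = tab["BF"].notna()
    b_bf = _pooled_within_group_slope(
        tab.loc[ok, "BF"].to_numpy(), tab.loc[ok, "offwt"].to_numpy(), tab.loc[ok, "group"]
    )
    tab["offbfa"] = tab["BF"] - b_bf * (tab["offwt"] - 115.0)
    tab["onwt_dev"] = tab["onwt"] - 40.0
    tab["age_dev"] = tab["age_on_test"] - 90.0
    tab["offwt_dev"] = tab["offwt"] - 115.0
    tab["gen_line"] = tab["generation"].astype(str) + "x" + tab["line"].astype(str)
    return tab


def compute_rfi(phenotypes: pd.DataFrame, pedigree: pd.DataFrame,
                spec: RfiModelSpec | None = None) -> pd.DataFrame:
    """Fit the ADFI animal model and attach the RFI column.

    RFI = observed ADFI minus the nuisance fixed effects (group, sex) and
    the per-generation-by-line covariate contributions.  The
    generation-by-line intercepts are estimated (so covariate slopes are
    unbiased by line differences) but subtracted only when
    ``spec.subtract_line`` is set, and random animal/dam/pen predictions
    only when ``spec.subtract_random`` is set: by default the genetic
    deviation and the selection response both remain inside RFI.
    """
    spec = spec or RfiModelSpec()
    tab = phenotypes.copy()
    need = spec.covariates + ["ADFI"]
    complete = tab[need].notna().all(axis=1)
    tab = tab.loc[complete].reset_index(drop=True)

    # centre covariates so level shifts live in the intercept terms, not in
    # the covariate contributions subtracted from RFI
    for cov in spec.covariates:
        tab[cov] = tab[cov] - tab[cov].mean()

    for cell, sub in tab.groupby(spec.cell_factor):
        if len(sub) <= len(spec.covariates):
            raise ValueError(
                f"generation-by-line cell {cell!r} has {len(sub)} animals for {len(spec.covariates)} covariates"
            )

    X, names = build_design(
        tab,
        factors=spec.fixed_factors,
        interactions=[(c, spec.cell_factor) for c in spec.covariates],
    )
    y = tab["ADFI"].to_numpy(float)

    random_terms = []
    ratios = []
    labels = {}
    lam_a = spec.variance_ratios.get("animal", 0)
    if lam_a:
        ped_ids = [str(a) for a in pedigree["animal_id"]]
        idx = {a: i for i, a in enumerate(ped_ids)}
        Za = np.zeros((len(tab), len(ped_ids)))
        for r, aid in enumerate(tab["animal_id"].astype(str)):
            Za[r, idx[aid]] = 1.0
        random_terms.append((Za, build_a_inverse(pedigree)))
        ratios.append(lam_a)
        labels["animal"] = len(random_terms) - 1
    lam_d = spec.variance_ratios.get("dam", 0)
    if lam_d:
        dam_of = dict(zip(pedigree["animal_id"].astype(str), pedigree["dam_id"].astype(str)))
        Zd, _ = factor_incidence([dam_of.get(a, "0") for a in tab["animal_id"].astype(str)])
        random_terms.append((Zd, None))
        ratios.append(lam_d)
        labels["dam"] = len(random_terms) - 1
    lam_p = spec.variance_ratios.get("pen", 0)
    if lam_p:
        Zp, _ = factor_incidence(tab["pen"].astype(str) + "|" + tab["group"].astype(str))
        random_terms.append((Zp, None))
        ratios.append(lam_p)
        labels["pen"] = len(random_terms) - 1

    sol = solve_mme(y, X, random_terms, ratios, fixed_names=names)
    if spec.subtract_line:
        prediction = X @ sol.fixed
    else:
        # keep the within-generation line contrast of the cell intercepts in
        # RFI; the generation-level component is confounded with on-test
        # group (nested in generation) and is subtracted with the nuisance
        keep = np.array([not nm.startswith(f"{spec.cell_factor}[") for nm in names])
        cell_part = X[:, ~keep] @ sol.fixed[~keep]
        gen_mean = pd.Series(cell_part).groupby(tab["generation"].to_numpy()).transform("mean")
        prediction = X[:, keep] @ sol.fixed[keep] + gen_mean.to_numpy()
    if spec.subtract_random:
        for (Z, _), u in zip(random_terms, sol.random):
            if u.size:
                prediction = prediction + Z @ u
    rfi = y - prediction

    out = phenotypes.copy()
    out["RFI"] = np.nan
    out.loc[out.index[complete], "RFI"] = rfi
    out.attrs["rfi_fixed_solutions"] = dict(zip(names, sol.fixed))
    return out
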