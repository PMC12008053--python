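"""Phylogenetic-eigenvector commonality partitioning of trait variance.

The trait (record-level log10 SLA) is regressed on three classes of
explanatory variables: P, phylogenetic eigenvectors (PCoA axes of the
patristic distance matrix, broadcast from species to records); C, climate
variables; S, soil variables.  All seven non-empty class subsets are
fitted as OLS models (AIC-parsimonious forward selection within each),
and the seven R^2 values are decomposed by commonality analysis into
unique and shared components.  Intraspecific variation is then estimated
from the full model's residuals: regressing them on species identities
gives R^2_R, and the intraspecific share is (1 - R^2_PCS)(1 - R^2_R).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import MatchedDataset
from .phylo_numerics import PCoABasis, patristic_matrix, pcoa

SUBSETS = ("P", "C", "S", "PC", "PS", "CS", "PCS")

DEFAULT_CLIMATE = ("par", "mtcm", "mthm", "map", "mi", "alpha")
DEFAULT_SOIL = ("sand_frac", "silt_frac", "clay_frac", "ph", "tn", "tp")


@dataclass
class VariableClasses:
    """Membership and term flags of the three predictor classes."""

    climate: tuple[str, ...] = DEFAULT_CLIMATE
    soil: tuple[str, ...] = DEFAULT_SOIL
    quad_flags: dict[str, bool] = field(default_factory=dict)
    interactions: bool = False

    def __post_init__(self):
        if set(self.climate) & set(self.soil):
            raise ValueError("climate and soil classes must be disjoint")
        members = set(self.climate) | set(self.soil)
        stray = set(k for k, v in self.quad_flags.items() if v) - members
        if stray:
            raise ValueError(f"quadratic flags for non-members: {sorted(stray)}")


def eigenvector_pool(basis: PCoABasis, cum_threshold: float = 0.95) -> int:
    """Number of leading axes whose eigenvalues reach the given fraction
    of the total positive eigenvalue mass."""
    if not 0.0 < cum_threshold <= 1.0:
        raise ValueError("cum_threshold must be in (0, 1]")
    if basis.n_axes == 0:
        raise ValueError("empty eigenbasis")
    cum = np.cumsum(basis.eigenvalues) / basis.eigenvalues.sum()
    return int(np.searchsorted(cum, cum_threshold - 1e-12) + 1)


def build_candidates(
    classes: VariableClasses, subset: str, n_axes: int
) -> list[str]:
    """Candidate term names for one class subset.

    Eigenvector terms are 'pc1'..'pcK' (never squared, never interacted);
    environment terms are centered variable names, with '<var>^2' for
    quadratic-flagged members; in the interaction variant, every
    climate x soil product '<cvar>:<svar>' joins subsets containing both
    C and S.
    """
    if not subset or any(ch not in "PCS" for ch in subset):
        raise ValueError(f"bad subset: {subset!r}")
    terms: list[str] = []
    if "P" in subset:
        terms += [f"pc{k + 1}" for k in range(n_axes)]
    if "C" in subset:
        for v in classes.climate:
            terms.append(v)
            if classes.quad_flags.get(v, False):
                terms.append(f"{v}^2")
    if "S" in subset:
        for v in classes.soil:
            terms.append(v)
            if classes.quad_flags.get(v, False):
                terms.append(f"{v}^2")
    if classes.interactions and "C" in subset and "S" in subset:
        for cv in classes.climate:
            for sv in classes.soil:
                terms.append(f"{cv}:{sv}")
    return terms


def build_design(
    dataset: MatchedDataset,
    basis: PCoABasis,
    classes: VariableClasses,
    n_axes: int,
) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Record-level design columns for every candidate term.

    Applies listwise deletion on the union of all class variables (the
    same rows for all seven models, so AICs are comparable), centers
    environment variables before squaring or interacting, and broadcasts
    species-level eigenvector coordinates to records.

    Returns (design frame, response vector, species labels).
    """
    env_vars = list(classes.climate) + list(classes.soil)
    cols = ["log_sla", "species"] + env_vars
    data = dataset.records.dropna(subset=[c for c in cols if c in dataset.records]).copy()
    missing = [v for v in env_vars if v not in dataset.records.columns]
    if missing:
        raise ValueError(f"records lack environment column(s): {missing}")

    sp_idx = data["species"].map(dataset.species_index).to_numpy()
    X = pd.DataFrame(index=data.index)
    for k in range(n_axes):
        X[f"pc{k + 1}"] = basis.axes[sp_idx, k]
    centered = {}
    for v in env_vars:
        c = data[v].to_numpy(dtype=float)
        c = c - c.mean()
        centered[v] = c
        X[v] = c
        if classes.quad_flags.get(v, False):
            X[f"{v}^2"] = c * c
    if classes.interactions:
        for cv in classes.climate:
            for sv in classes.soil:
                X[f"{cv}:{sv}"] = centered[cv] * centered[sv]
    y = data["log_sla"].to_numpy(dtype=float)
    return X, y, data["species"]


@dataclass
class ModelFit:
    """One OLS fit of a class subset."""

    subset: str
    terms: list[str]
    r2: float
    aic: float
    n: int
    residuals: np.ndarray = field(repr=False, default=None)
    warnings: list[str] = field(default_factory=list)


def _ols(y: np.ndarray, M: np.ndarray) -> tuple[float, np.ndarray, int]:
    """RSS, residuals, and rank of an OLS fit (M includes the intercept)."""
    beta, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ beta
    return float(resid @ resid), resid, int(rank)


def _aic(n: int, rss: float, n_params: int, rss_floor: float = 1e-300) -> float:
    # Gaussian OLS AIC up to an additive constant; +1 for sigma^2.  RSS is
    # floored so numerically perfect fits compare by parameter count alone
    # instead of by rounding noise.
    rss = max(rss, rss_floor)
    return n * np.log(rss / n) + 2.0 * (n_params + 1)


def stepwise_aic(
    y: np.ndarray,
    X: pd.DataFrame,
    candidates: Sequence[str],
    subset: str = "",
) -> ModelFit:
    """Forward AIC selection from the intercept-only model.

    At each step the term giving the largest AIC decrease is added (ties
    broken toward the earlier candidate, i.e. eigenvectors by eigenvalue
    rank then variables in class order); selection stops when no addition
    lowers AIC.  Terms making the design rank-deficient are skipped.
    """
    n = len(y)
    if n <= len(candidates) + 2:
        warnings.warn(
            f"subset {subset or '?'}: n = {n} close to candidate count; "
            "selection may be unstable"
        )
    selected: list[str] = []
    notes: list[str] = []
    M = np.ones((n, 1))
    rss, resid, _ = _ols(y, M)
    floor = rss * 1e-12 + 1e-300
    aic_cur = _aic(n, rss, 1, floor)
    remaining = list(candidates)
    while remaining:
        best = None
        for term in remaining:
            Mt = np.column_stack([M, X[term].to_numpy()])
            rss_t, _, rank = _ols(y, Mt)
            if rank < Mt.shape[1]:
                continue
            aic_t = _aic(n, rss_t, Mt.shape[1], floor)
            if aic_t < aic_cur - 1e-10 and (best is None or aic_t < best[0] - 1e-10):
                best = (aic_t, term)
        if best is None:
            break
        aic_cur, term = best
        selected.append(term)
        remaining.remove(term)
        M = np.column_stack([M, X[term].to_numpy()])
    rss, resid, rank = _ols(y, M)
    if rank < M.shape[1]:
        notes.append("final design rank-deficient")
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return ModelFit(
        subset=subset,
        terms=selected,
        r2=r2,
        aic=aic_cur,
        n=n,
        residuals=resid,
        warnings=notes,
    )


def full_fit(
    y: np.ndarray, X: pd.DataFrame, terms: Sequence[str], subset: str = ""
) -> ModelFit:
    """OLS fit with the complete term set (no selection); used for the
    exact commonality sum identity."""
    n = len(y)
    M = np.column_stack([np.ones(n)] + [X[t].to_numpy() for t in terms])
    rss, resid, rank = _ols(y, M)
    tss = float(np.sum((y - y.mean()) ** 2))
    return ModelFit(
        subset=subset,
        terms=list(terms),
        r2=1.0 - rss / tss if tss > 0 else 0.0,
        aic=_aic(n, rss, M.shape[1]),
        n=n,
        residuals=resid,
        warnings=[] if rank == M.shape[1] else ["rank-deficient"],
    )


def commonality(r2: dict[str, float]) -> dict[str, float]:
    """Unique and shared R^2 components of the three classes.

    U_P = R_PCS - R_CS (cyclic); C_PCS = R_P + R_C + R_S - R_PC - R_PS
    - R_CS + R_PCS; C_PC = R_P + R_C - R_PC - C_PCS (cyclic).  Negative
    components are reported as-is (suppressor structure).  With full
    (non-parsimonious) term sets the seven components sum to R_PCS.
    """
    for s in SUBSETS:
        if s not in r2:
            raise ValueError(f"missing R^2 for subset {s}")
    c_pcs = (
        r2["P"] + r2["C"] + r2["S"]
        - r2["PC"] - r2["PS"] - r2["CS"]
        + r2["PCS"]
    )
    return {
        "U_P": r2["PCS"] - r2["CS"],
        "U_C": r2["PCS"] - r2["PS"],
        "U_S": r2["PCS"] - r2["PC"],
        "C_PC": r2["P"] + r2["C"] - r2["PC"] - c_pcs,
        "C_PS": r2["P"] + r2["S"] - r2["PS"] - c_pcs,
        "C_CS": r2["C"] + r2["S"] - r2["CS"] - c_pcs,
        "C_PCS": c_pcs,
    }


def intraspecific_contribution(
    pcs_fit: ModelFit, species: pd.Series
) -> tuple[float, float]:
    """Residual-based intraspecific share: (1 - R^2_PCS)(1 - R^2_R).

    Model R regresses the full model's residuals on species indicators;
    its R^2 is computed from the within-/total-species sum of squares
    (identical to the OLS dummy fit).  With one record per species the
    indicator model is saturated, R^2_R = 1 and the share is 0.
    """
    resid = np.asarray(pcs_fit.residuals, dtype=float)
    grp = pd.Series(resid).groupby(species.to_numpy())
    within = float(sum(((g - g.mean()) ** 2).sum() for _, g in grp))
    tss = float(np.sum((resid - resid.mean()) ** 2))
    r2_r = 1.0 if tss == 0 else 1.0 - within / tss
    return (1.0 - pcs_fit.r2) * (1.0 - r2_r), r2_r


@dataclass
class PartitionResult:
    """The seven fits, commonality components, class totals, and the
    intraspecific contribution."""

    fits: dict[str, ModelFit]
    components: dict[str, float]
    totals: dict[str, float]          # total_P = R^2_P etc.
    intraspecific: float
    r2_r: float
    unexplained: float                # (1 - R^2_PCS) * R^2_R
    variant: str
    n_axes: int
    n_records: int

    def percentages(self) -> dict[str, float]:
        """All shares on the percent scale, rounded to two decimals."""
        out = {f"total_{k}": v * 100 for k, v in self.totals.items()}
        out |= {k: v * 100 for k, v in self.components.items()}
        out["intraspecific"] = self.intraspecific * 100
        out["unexplained"] = self.unexplained * 100
        return {k: round(v, 2) for k, v in out.items()}


def partition_pipeline(
    dataset: MatchedDataset,
    classes: VariableClasses | None = None,
    variant: str = "plain",
    eigvec_threshold: float = 0.95,
    n_axes: int | None = None,
    stepwise: bool = True,
) -> PartitionResult:
    """Run the seven-model commonality partition on a matched dataset.

    ``variant`` is 'plain' or 'interactions' (adds all climate x soil
    products to the CS and PCS candidate sets).  The eigenvector pool is
    the smallest leading set of PCoA axes reaching ``eigvec_threshold``
    of the positive eigenvalue mass, unless ``n_axes`` is given.  With
    ``stepwise=False`` every model keeps its full term set (used for the
    exact commonality identity).
    """
    if variant not in ("plain", "interactions"):
        raise ValueError("variant must be 'plain' or 'interactions'")
    classes = classes or VariableClasses()
    classes = VariableClasses(
        climate=tuple(classes.climate),
        soil=tuple(classes.soil),
        quad_flags=dict(classes.quad_flags),
        interactions=(variant == "interactions"),
    )
    d, order = patristic_matrix(dataset.tree)
    basis = pcoa(d, tip_order=order)
    k = n_axes if n_axes is not None else eigenvector_pool(basis, eigvec_threshold)
    X, y, species = build_design(dataset, basis, classes, k)

    fits: dict[str, ModelFit] = {}
    for subset in SUBSETS:
        cands = build_candidates(classes, subset, k)
        if stepwise:
            fits[subset] = stepwise_aic(y, X, cands, subset=subset)
        else:
            fits[subset] = full_fit(y, X, cands, subset=subset)

    r2 = {s: f.r2 for s, f in fits.items()}
    comps = commonality(r2)
    intra, r2_r = intraspecific_contribution(fits["PCS"], species)
    return PartitionResult(
        fits=fits,
        components=comps,
        totals={"P": r2["P"], "C": r2["C"], "S": r2["S"]},
        intraspecific=intra,
        r2_r=r2_r,
        unexplained=(1.0 - r2["PCS"]) * r2_r,
        variant=variant,
        n_axes=k,
        n_records=len(y),
    )
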