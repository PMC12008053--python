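"""Synthetic trees, traits, sites, and record tables with known ground truth.

The generator emulates the statistical structure the analyses assume: an
ultrametric phylogeny with one deep two-clade split (a small conifer-like
clade against a large angiosperm-like clade), species trait values from
lambda-rescaled Brownian motion plus clade mean offsets, correlated
site-level climate/soil gradients acting linearly or quadratically on the
trait, and record-level intraspecific Gaussian noise.  Every component of
each record's log10 SLA is stored, so the realized phylogenetic /
environmental / intraspecific variance fractions are known exactly and any
pipeline stage has a recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_model import CLIMATE_VARS, SOIL_VARS, ENV_VARS, tip_labels
from .phylo_numerics import bm_covariance

#: baseline log10 SLA (cm^2 g^-1); ~205 cm^2/g, a typical regional mean
BASE_LOG_SLA = 2.31

# affine maps latent N(0,1) -> plausible variable ranges: (center, scale,
# lower clip, upper clip)
_AFFINE = {
    "par": (6000.0, 1500.0, 100.0, None),
    "mat": (12.0, 7.0, None, None),
    "mtcm": (-2.0, 10.0, None, None),
    "mthm": (None, None, None, None),  # mtcm + positive gap, see below
    "map": (900.0, 450.0, 10.0, None),
    "mi": (0.8, 0.3, 0.01, None),
    "alpha": (0.7, 0.25, 0.01, 1.6),
    "precip_seasonality": (70.0, 25.0, 1.0, None),
    "sand_frac": (0.40, 0.15, 0.01, 0.98),
    "silt_frac": (0.35, 0.12, 0.01, 0.98),
    "clay_frac": (0.25, 0.10, 0.01, 0.98),
    "ph": (6.5, 1.0, 3.6, 9.4),
    "org_c": (15.0, 6.0, 0.5, None),
    "cec": (18.0, 7.0, 1.0, None),
    "tn": (2.0, 0.8, 0.05, None),
    "tp": (0.8, 0.3, 0.02, None),
}


def simulate_tree(
    n_tips: int,
    seed: int,
    root_depth: float = 325.0,
    split_fraction: float = 0.4,
    minor_clade_fraction: float = 0.1,
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Ultrametric tree with one deep two-clade split.

    The root (depth 0) splits into two clade stems reaching
    ``split_fraction * root_depth``; within each clade the topology is
    pure-birth with node times rescaled so all tips sit at ``root_depth``.
    The minor clade holds ``ceil(minor_clade_fraction * n_tips)`` tips.

    Returns the tree and a species -> clade-label map (minor clade
    'gymnosperm', major clade 'eudicot', echoing the conifer/angiosperm
    contrast the deep split emulates).
    """
    if n_tips < 4:
        raise ValueError("need n_tips >= 4")
    rng = np.random.default_rng(seed)
    n_minor = int(np.ceil(minor_clade_fraction * n_tips))
    n_major = n_tips - n_minor
    crown = split_fraction * root_depth

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    clade_map: dict[str, str] = {}

    counter = [0]

    def _make_clade(k: int, prefix: str) -> dendropy.Node:
        """Clade stem node (child of root); tips at root_depth."""
        stem = dendropy.Node()
        stem.edge.length = crown if k > 1 else root_depth
        if k == 1:
            counter[0] += 1
            label = f"{prefix}{counter[0]:04d}"
            stem.taxon = taxa.new_taxon(label)
            return stem
        # pure-birth event sequence among active lineages
        birth_depth = {id(stem): crown}
        children: dict[int, dendropy.Node] = {}
        active = []
        for _ in range(2):
            nd = dendropy.Node()
            stem.add_child(nd)
            active.append(nd)
            birth_depth[id(nd)] = crown
        sim_t = 0.0
        events = []  # (sim time, node that splits, children)
        while len(active) < k:
            sim_t += rng.exponential(1.0 / len(active))
            node = active.pop(rng.integers(len(active)))
            kids = [dendropy.Node(), dendropy.Node()]
            events.append((sim_t, node, kids))
            active.extend(kids)
        sim_end = sim_t + rng.exponential(1.0 / k)
        scale = (root_depth - crown) / sim_end
        for t, node, kids in events:
            depth = crown + t * scale
            node.edge.length = depth - birth_depth[id(node)]
            for kid in kids:
                node.add_child(kid)
                birth_depth[id(kid)] = depth
        for nd in active:
            counter[0] += 1
            label = f"{prefix}{counter[0]:04d}"
            nd.taxon = taxa.new_taxon(label)
            nd.edge.length = root_depth - birth_depth[id(nd)]
        return stem

    minor = _make_clade(n_minor, "sp")
    major = _make_clade(n_major, "sp")
    tree.seed_node.add_child(minor)
    tree.seed_node.add_child(major)
    for nd, lab in ((minor, "gymnosperm"), (major, "eudicot")):
        for leaf in (nd.leaf_iter() if not nd.is_leaf() else [nd]):
            clade_map[leaf.taxon.label] = lab
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree, clade_map


def lambda_rescale(V: np.ndarray, lam: float) -> np.ndarray:
    """Multiply the off-diagonal of a BM covariance by lambda."""
    Vl = V * lam
    np.fill_diagonal(Vl, np.diag(V))
    return Vl


def simulate_species_trait(
    tree: dendropy.Tree,
    sigma2: float,
    lam: float,
    clade_offsets: Mapping[str, float],
    clade_map: Mapping[str, str],
    seed: int,
) -> np.ndarray:
    """Species-level trait: MVN(clade offsets, sigma2 * V(lambda)).

    ``sigma2`` is the Brownian rate per Myr; ``lam`` in [0, 1] rescales
    the off-diagonal covariances (0 = independent tips, 1 = pure BM).
    Returned vector is aligned to tip order.
    """
    rng = np.random.default_rng(seed)
    labels = tip_labels(tree)
    mean = np.array([clade_offsets.get(clade_map.get(sp, ""), 0.0) for sp in labels])
    if sigma2 == 0.0:
        return mean
    V, _ = bm_covariance(tree)
    C = sigma2 * lambda_rescale(V, lam)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("lambda-rescaled covariance not positive definite") from exc
    return mean + L @ rng.standard_normal(len(labels))


@dataclass
class SiteTable:
    """Per-site environment: observed variables and the standardized
    latent gradients they are affine images of."""

    env: pd.DataFrame      # site_id + canonical environment columns
    latents: pd.DataFrame  # site_id + z_<var> standardized gradients
    env_corr: float


def simulate_sites(n_sites: int, env_corr: float, seed: int) -> SiteTable:
    """Correlated site-level climate and soil gradients.

    All 16 variables load on one common latent gradient with loading
    sqrt(env_corr), so every pairwise correlation equals ``env_corr``
    (guaranteed positive semidefinite).  Latents are standard normal;
    observed variables are affine images clipped to plausible ranges
    (MTHM is built as MTCM plus a positive gap so MTCM <= MTHM holds).
    """
    if n_sites < 2:
        raise ValueError("need n_sites >= 2")
    if not 0.0 <= env_corr <= 1.0:
        raise ValueError("env_corr must be in [0, 1] (factor-model construction)")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(n_sites)
    z = {}
    for var in ENV_VARS:
        e = rng.standard_normal(n_sites)
        z[var] = np.sqrt(env_corr) * g + np.sqrt(1.0 - env_corr) * e
    env = {}
    for var in ENV_VARS:
        if var == "mthm":
            continue
        c, s, lo, hi = _AFFINE[var]
        vals = c + s * z[var]
        env[var] = np.clip(vals, lo, hi)
    gap = np.clip(15.0 + 3.0 * z["mthm"], 1.0, None)
    env["mthm"] = env["mtcm"] + gap
    site_ids = [f"site{i + 1:03d}" for i in range(n_sites)]
    env_df = pd.DataFrame({"site_id": site_ids} | {v: env[v] for v in ENV_VARS})
    lat_df = pd.DataFrame(
        {"site_id": site_ids} | {f"z_{v}": z[v] for v in ENV_VARS}
    )
    return SiteTable(env=env_df, latents=lat_df, env_corr=env_corr)


@dataclass
class SyntheticTruth:
    """Ground truth for one generated record table.

    ``fractions`` are realized marginal variance fractions, recomputed
    from the stored latent components (species trait per record,
    environmental contribution, noise draw), not from the summed records.
    """

    seed: int
    tree_params: dict
    trait_params: dict
    env_params: dict
    tau: float
    components: pd.DataFrame = field(repr=False)
    fractions: dict[str, float] = field(default_factory=dict)

    @staticmethod
    def _fractions(components: pd.DataFrame) -> dict[str, float]:
        v = {
            name: float(np.var(components[name], ddof=1))
            for name in ("phylogenetic", "environmental", "intraspecific")
        }
        total = sum(v.values())
        return {k: val / total for k, val in v.items()}


def simulate_records(
    tree: dendropy.Tree,
    trait: np.ndarray,
    sites: SiteTable,
    betas: Mapping[str, float],
    quad_betas: Mapping[str, float],
    tau: float,
    occupancy: tuple[int, int] = (1, 4),
    seed: int = 0,
    clade_map: Mapping[str, str] | None = None,
    phenology_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Record table: one row per observation of a species at a site.

    log10 SLA = baseline + species trait + sum(beta * z_var(site))
    + sum(quad_beta * (z_var^2 - 1)/sqrt(2)) + Normal(0, tau^2).
    Effects act on the standardized latent gradients, so linear effects
    stay linear in the observed variables and quadratic effects are
    quadratic in them.  Records per species ~ uniform over ``occupancy``.
    """
    rng = np.random.default_rng(seed)
    labels = tip_labels(tree)
    n_sites = len(sites.env)
    lat = sites.latents

    rows = []
    comp = {"phylogenetic": [], "environmental": [], "intraspecific": []}
    lo, hi = occupancy
    for sp, x_sp in zip(labels, trait):
        n_rec = int(rng.integers(lo, hi + 1))
        for _ in range(n_rec):
            s = int(rng.integers(n_sites))
            env_eff = 0.0
            for var, b in betas.items():
                env_eff += b * lat[f"z_{var}"].iloc[s]
            for var, b in quad_betas.items():
                zv = lat[f"z_{var}"].iloc[s]
                env_eff += b * (zv * zv - 1.0) / np.sqrt(2.0)
            eps = tau * rng.standard_normal()
            log_sla = BASE_LOG_SLA + x_sp + env_eff + eps
            row = {
                "species": sp,
                "site_id": sites.env["site_id"].iloc[s],
                "sla": 10.0 ** log_sla,
                "log_sla": log_sla,
            }
            for var in ENV_VARS:
                row[var] = sites.env[var].iloc[s]
            if clade_map is not None:
                row["clade"] = clade_map.get(sp, "eudicot")
            if phenology_map is not None:
                row["phenology"] = phenology_map.get(sp, "unknown")
            row["woody"] = True
            rows.append(row)
            comp["phylogenetic"].append(x_sp)
            comp["environmental"].append(env_eff)
            comp["intraspecific"].append(eps)

    records = pd.DataFrame(rows)
    components = pd.DataFrame(comp)
    truth = SyntheticTruth(
        seed=seed,
        tree_params={"n_tips": len(labels)},
        trait_params={},
        env_params={"betas": dict(betas), "quad_betas": dict(quad_betas)},
        tau=tau,
        components=components,
        fractions=SyntheticTruth._fractions(components),
    )
    return records, truth


def expected_bm_tip_variance(V: np.ndarray) -> float:
    """E[sample variance across tips] of one MVN(0, V) draw."""
    n = V.shape[0]
    return (np.trace(V) - V.sum() / n) / (n - 1)


@dataclass
class Scenario:
    """A fully generated dataset plus its ground truth."""

    records: pd.DataFrame
    tree: dendropy.Tree
    clade_map: dict[str, str]
    truth: SyntheticTruth
    trait: np.ndarray
    params: dict


def default_scenario(
    seed: int,
    n_species: int = 300,
    n_sites: int = 40,
    fractions: Sequence[float] = (0.5, 0.3, 0.2),
    total_var: float = 0.06,
    lam: float = 1.0,
    env_corr: float = 0.5,
    offset_share: float = 0.4,
) -> Scenario:
    """The default study conditions: deep two-clade tree, lambda-BM trait
    with a clade offset, three true environmental effects (PAR linear, MI
    quadratic, TN linear) among 16 candidate gradients, and intraspecific
    noise, calibrated analytically so the expected phylogenetic /
    environmental / intraspecific variance fractions equal ``fractions``
    (default 0.5/0.3/0.2 of a total log10-SLA variance of 0.06).
    """
    f_phy, f_env, f_intra = fractions
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)

    tree, clade_map = simulate_tree(n_species, seed=int(seeds[0]))
    labels = tip_labels(tree)
    n_minor = sum(1 for sp in labels if clade_map[sp] == "gymnosperm")
    p = n_minor / len(labels)

    # clade offset: binary contrast with variance p(1-p)*d^2 across tips
    target_phy = f_phy * total_var
    d = np.sqrt(offset_share * target_phy / (p * (1.0 - p)))
    offsets = {"gymnosperm": -d * (1 - p), "eudicot": d * p}  # mean-zero

    V, _ = bm_covariance(tree)
    c_bm = expected_bm_tip_variance(lambda_rescale(V, lam))
    sigma2 = (1.0 - offset_share) * target_phy / c_bm

    trait = simulate_species_trait(
        tree, sigma2, lam, offsets, clade_map, seed=int(seeds[1])
    )
    # calibrate to the realized draw: one deep-split BM realization has a
    # highly variable across-tip variance (the clade-mean contrast is a
    # single random variable), so rescale the centered draw to the exact
    # target so the ground-truth fractions are sharp
    trait = trait - trait.mean()
    trait *= np.sqrt(target_phy / np.var(trait, ddof=1))

    sites = simulate_sites(n_sites, env_corr=env_corr, seed=int(seeds[2]))
    # effect pattern: PAR linear, TN linear (correlated rho), MI quadratic
    target_env = f_env * total_var
    w_par, w_tn, w_mi = 1.0, 0.8, 0.7
    var_unit = (
        w_par**2 + w_tn**2 + 2.0 * env_corr * w_par * w_tn + w_mi**2
    )
    s = np.sqrt(target_env / var_unit)
    betas = {"par": w_par * s, "tn": w_tn * s}
    quad_betas = {"mi": w_mi * s}
    # same calibration for the realized site-effect variance
    lat = sites.latents
    site_eff = sum(b * lat[f"z_{v}"].to_numpy() for v, b in betas.items())
    site_eff = site_eff + sum(
        b * (lat[f"z_{v}"].to_numpy() ** 2 - 1.0) / np.sqrt(2.0)
        for v, b in quad_betas.items()
    )
    realized = np.var(site_eff, ddof=1)
    adj = np.sqrt(target_env / realized) if realized > 0 else 0.0
    betas = {v: b * adj for v, b in betas.items()}
    quad_betas = {v: b * adj for v, b in quad_betas.items()}

    tau = np.sqrt(f_intra * total_var)

    phen_rng = np.random.default_rng(int(seeds[3]))
    phenology_map = {
        sp: ("evergreen" if phen_rng.random() < 0.5 else "deciduous")
        for sp in labels
    }

    records, truth = simulate_records(
        tree,
        trait,
        sites,
        betas,
        quad_betas,
        tau,
        seed=int(seeds[3]),
        clade_map=clade_map,
        phenology_map=phenology_map,
    )
    truth.trait_params = {
        "sigma2": sigma2,
        "lambda": lam,
        "clade_offsets": offsets,
    }
    truth.tree_params = {
        "n_tips": n_species,
        "root_depth": 325.0,
        "split_fraction": 0.4,
        "minor_clade_fraction": 0.1,
    }
    params = {
        "n_species": n_species,
        "n_sites": n_sites,
        "target_fractions": tuple(fractions),
        "total_var": total_var,
        "lambda": lam,
        "env_corr": env_corr,
    }
    return Scenario(
        records=records,
        tree=tree,
        clade_map=clade_map,
        truth=truth,
        trait=trait,
        params=params,
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Write the CSV + Newick + truth JSON that io_model reads back."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "records.csv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
    }
    scenario.records.to_csv(paths["records"], index=False)
    scenario.tree.write(path=str(paths["tree"]), schema="newick",
                        suppress_rooting=True, unquoted_underscores=True)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "fractions": scenario.truth.fractions,
                "params": scenario.params,
                "trait_params": {
                    k: v for k, v in scenario.truth.trait_params.items()
                },
            },
            fh,
            indent=2,
        )
    return paths
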