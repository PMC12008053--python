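"""Orchestration: run the full analysis sequence from one configuration.

Stages, in dependency order: harmonize -> phylogenetic signals -> nested
variance decompositions -> per-variable environment screens (with an
optional two-group slope contrast) -> seven-model commonality partitions
(plain and interaction variants, plus an optional evergreen/deciduous
contrast within woody angiosperms) -> node contribution report.  Stage
failures are isolated: the bundle records the error and the remaining
stages still run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_model import MatchedDataset, harmonize, read_trait_table, read_tree
from .mixed_models import (
    NestingSpec,
    env_screen,
    group_interaction_test,
    variance_decomposition,
)
from .node_contribution import aot_report
from .phylo_signal import signal_table, species_trait
from .pvr_partition import VariableClasses, partition_pipeline

# fixed per-stage seed offsets, so a stage can be re-run in isolation
STAGE_SEEDS = {"signals": 11, "aot": 23, "partition": 37}


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    trait_table: str | None = None
    tree_file: str | None = None
    column_map: dict[str, str] = field(default_factory=dict)
    clade_filter: list[str] | None = None
    species_agg: str = "mean"
    nestings: list[dict] = field(
        default_factory=lambda: [{"factors": ["site_id", "species"], "label": "spatial"}]
    )
    screen_vars: list[str] = field(default_factory=list)
    screen_group_col: str | None = None
    climate: list[str] | None = None
    soil: list[str] | None = None
    quad_from_screens: bool = True
    eigvec_threshold: float = 0.95
    variants: list[str] = field(default_factory=lambda: ["plain", "interactions"])
    phenology_contrast: bool = False
    min_group: int = 30
    ci_floor: float = 0.005
    n_perm: int = 999
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: [
            "signals",
            "variance",
            "screens",
            "partition",
            "aot",
        ]
    )
    outdir: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class ResultsBundle:
    """All stage outputs plus provenance (config echo, seeds, counts)."""

    signals: pd.DataFrame | None = None
    variance: dict[str, Any] = field(default_factory=dict)
    screens: pd.DataFrame | None = None
    partitions: dict[str, Any] = field(default_factory=dict)
    node_contributions: pd.DataFrame | None = None
    drop_report: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)


def _run_screens(dataset: MatchedDataset, config: RunConfig):
    rows = []
    quad_flags: dict[str, bool] = {}
    variables = config.screen_vars or [
        v
        for v in (list(config.climate or []) + list(config.soil or []))
        if v in dataset.records.columns
    ]
    for var in variables:
        res = env_screen(dataset.records, var)
        quad_flags[var] = res.degree == 2
        row = {
            "variable": var,
            "degree": res.degree,
            "aic_linear": res.aic.get(1, np.nan),
            "aic_quadratic": res.aic.get(2, np.nan),
            "marginal_r2": res.marginal_r2,
            "n": res.n,
            "interaction_p": np.nan,
        }
        if config.screen_group_col:
            try:
                row["interaction_p"] = group_interaction_test(
                    dataset.records,
                    var,
                    config.screen_group_col,
                    degree=res.degree,
                )
            except ValueError as exc:
                row["interaction_note"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows), quad_flags


def _partition_stage(dataset, config, quad_flags):
    classes = VariableClasses(
        climate=tuple(config.climate) if config.climate else VariableClasses().climate,
        soil=tuple(config.soil) if config.soil else VariableClasses().soil,
        quad_flags=quad_flags if config.quad_from_screens else {},
    )
    out: dict[str, Any] = {}
    for variant in config.variants:
        res = partition_pipeline(
            dataset,
            classes=classes,
            variant=variant,
            eigvec_threshold=config.eigvec_threshold,
        )
        out[variant] = res
    if config.phenology_contrast:
        out["phenology"] = phenology_contrast(dataset, config, classes)
    return out


def phenology_contrast(
    dataset: MatchedDataset,
    config: RunConfig,
    classes: VariableClasses | None = None,
) -> dict[str, Any]:
    """Interaction-variant partition run separately for evergreen and
    deciduous woody angiosperm records (tree re-pruned per group).

    A group below ``config.min_group`` records is skipped with a note,
    mirroring the exclusion of tiny groups from grouped analyses.
    """
    out: dict[str, Any] = {}
    rec = dataset.records
    if "phenology" not in rec.columns:
        raise ValueError("phenology contrast requested but no 'phenology' column")
    woody = rec["woody"] if "woody" in rec.columns else pd.Series(True, index=rec.index)
    angio = (
        rec["clade"] != "gymnosperm"
        if "clade" in rec.columns
        else pd.Series(True, index=rec.index)
    )
    base = rec[woody.astype(bool) & angio]
    for phen in ("evergreen", "deciduous"):
        sub = base[base["phenology"] == phen]
        if len(sub) < config.min_group or sub["species"].nunique() < 3:
            out[phen] = f"skipped: {len(sub)} records below minimum {config.min_group}"
            continue
        ds = harmonize(sub, dataset.tree)
        out[phen] = partition_pipeline(
            ds,
            classes=classes,
            variant="interactions",
            eigvec_threshold=config.eigvec_threshold,
        )
    return out


def run_full_analysis(
    config: RunConfig, dataset: MatchedDataset | None = None
) -> ResultsBundle:
    """Execute all requested stages; see the module docstring.

    Either pass a prepared ``dataset`` or set ``trait_table`` and
    ``tree_file`` in the config.
    """
    bundle = ResultsBundle()
    if dataset is None:
        if not (config.trait_table and config.tree_file):
            raise ValueError("config must give trait_table and tree_file")
        records = read_trait_table(config.trait_table, config.column_map)
        tree = read_tree(config.tree_file)
        dataset = harmonize(records, tree, clade_filter=config.clade_filter)
    bundle.drop_report = dict(dataset.drop_report)
    bundle.provenance = {
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "n_records": dataset.n_records,
        "n_species": dataset.n_species,
        "stages": list(config.stages),
    }

    quad_flags: dict[str, bool] = {}
    if "signals" in config.stages:
        try:
            bundle.signals = signal_table(
                dataset,
                n_perm=config.n_perm,
                seed=config.seed + STAGE_SEEDS["signals"],
                agg=config.species_agg,
            )
        except Exception as exc:  # noqa: BLE001 - stage isolation
            bundle.errors["signals"] = f"{type(exc).__name__}: {exc}"
    if "variance" in config.stages:
        for spec in config.nestings:
            label = spec.get("label") or "/".join(spec["factors"])
            try:
                vc = variance_decomposition(
                    dataset.records, NestingSpec(list(spec["factors"]), label)
                )
                bundle.variance[label] = vc
            except Exception as exc:  # noqa: BLE001
                bundle.errors[f"variance:{label}"] = f"{type(exc).__name__}: {exc}"
    if "screens" in config.stages:
        try:
            bundle.screens, quad_flags = _run_screens(dataset, config)
        except Exception as exc:  # noqa: BLE001
            bundle.errors["screens"] = f"{type(exc).__name__}: {exc}"
    if "partition" in config.stages:
        try:
            bundle.partitions = _partition_stage(dataset, config, quad_flags)
        except Exception as exc:  # noqa: BLE001
            bundle.errors["partition"] = f"{type(exc).__name__}: {exc}"
    if "aot" in config.stages:
        try:
            x = species_trait(dataset, agg=config.species_agg)
            rep = aot_report(
                dataset.tree,
                x,
                n_perm=config.n_perm,
                seed=config.seed + STAGE_SEEDS["aot"],
                ci_floor=config.ci_floor,
            )
            bundle.node_contributions = rep.table
        except Exception as exc:  # noqa: BLE001
            bundle.errors["aot"] = f"{type(exc).__name__}: {exc}"

    if config.outdir:
        write_bundle(bundle, config)
    return bundle


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if hasattr(obj, "__dataclass_fields__"):
        return {
            k: _jsonable(v)
            for k, v in asdict(obj).items()
            if k != "residuals"
        }
    if isinstance(obj, dict):
        return {
            str(k): _jsonable(v) for k, v in obj.items() if k != "residuals"
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_bundle(bundle: ResultsBundle, config: RunConfig) -> Path:
    """Write the bundle as TSVs plus one JSON summary in config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if bundle.signals is not None:
        bundle.signals.to_csv(outdir / "signals.tsv", sep="\t", index=False)
    if bundle.screens is not None:
        bundle.screens.to_csv(outdir / "env_screens.tsv", sep="\t", index=False)
    if bundle.node_contributions is not None:
        bundle.node_contributions.to_csv(
            outdir / "node_contributions.tsv", sep="\t", index=False
        )
    for label, vc in bundle.variance.items():
        pd.DataFrame(
            {
                "level": list(vc.fractions),
                "variance": [vc.components[k] for k in vc.fractions],
                "fraction": list(vc.fractions.values()),
            }
        ).to_csv(outdir / f"variance_{label.replace('/', '-')}.tsv",
                 sep="\t", index=False)
    for variant, res in bundle.partitions.items():
        if hasattr(res, "percentages"):
            pd.Series(res.percentages(), name="percent").rename_axis(
                "component"
            ).to_csv(outdir / f"partition_{variant}.tsv", sep="\t")
    summary = {
        "provenance": bundle.provenance,
        "drop_report": bundle.drop_report,
        "errors": bundle.errors,
        "variance": _jsonable(bundle.variance),
        "partitions": _jsonable(
            {
                k: (v.percentages() if hasattr(v, "percentages") else _jsonable(v))
                for k, v in bundle.partitions.items()
            }
        ),
        "config": _jsonable(asdict(config)),
    }
    with open(outdir / "results.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return outdir
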