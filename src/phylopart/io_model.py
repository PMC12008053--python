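"""Reading, validation, and joining of trait tables and phylogenies.

The analyses downstream all consume a :class:`MatchedDataset`: a record-level
trait table (one row per SLA observation, with site-level climate and soil
descriptors) joined to a phylogeny pruned to exactly the species present in
the table.  SLA is analysed on the log10 scale throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

#: canonical climate columns (units: PAR mol m-2 yr-1; temperatures degC;
#: MAP mm; MI, alpha, precipitation seasonality dimensionless)
CLIMATE_VARS = (
    "par",
    "mat",
    "mtcm",
    "mthm",
    "map",
    "mi",
    "alpha",
    "precip_seasonality",
)

#: canonical soil columns (fractions in [0,1]; pH units; org C g kg-1;
#: CEC cmol kg-1; TN, TP g kg-1)
SOIL_VARS = (
    "sand_frac",
    "silt_frac",
    "clay_frac",
    "ph",
    "org_c",
    "cec",
    "tn",
    "tp",
)

ENV_VARS = CLIMATE_VARS + SOIL_VARS

#: mandatory identifying columns of a trait table
MANDATORY_COLS = ("species", "site_id", "sla")

CLADES = ("gymnosperm", "magnoliid", "monocot", "eudicot")


class TraitTableError(ValueError):
    """Raised for malformed trait tables (bad SLA, missing columns)."""


class TreeError(ValueError):
    """Raised for malformed phylogenies."""


def normalize_species(name: str) -> str:
    """Underscore-normalize a binomial: 'Genus species' -> 'Genus_species'."""
    return "_".join(str(name).strip().split())


def read_trait_table(
    path: str | Path | io.IOBase,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a CSV/TSV trait table into the canonical record frame.

    Parameters
    ----------
    path:
        File path (``.tsv``/``.txt`` are read tab-separated) or file-like.
    column_map:
        Optional mapping from canonical names (``species``, ``site_id``,
        ``sla``, climate and soil names, ``clade``, ``phenology``,
        ``woody``) to the source file's headers.

    Returns
    -------
    DataFrame with the mandatory columns, ``log_sla``, any environment or
    label columns present in the source, and the original row number in
    ``source_row``.  Missing numeric cells stay ``NaN``.

    Raises
    ------
    TraitTableError
        If a mandatory column is absent, a species name is empty, or any
        SLA value is non-positive (offending row numbers are listed).
    """
    sep = None
    if isinstance(path, (str, Path)):
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, engine="python")

    column_map = dict(column_map or {})
    rename = {src: canon for canon, src in column_map.items() if src in raw.columns}
    df = raw.rename(columns=rename)

    missing = [c for c in MANDATORY_COLS if c not in df.columns]
    if missing:
        raise TraitTableError(f"missing mandatory column(s): {', '.join(missing)}")

    keep = [c for c in (MANDATORY_COLS + ENV_VARS + ("clade", "phenology", "woody"))
            if c in df.columns]
    df = df[keep].copy()
    df["source_row"] = np.arange(len(df)) + 2  # 1-based, after the header line

    df["species"] = df["species"].map(normalize_species)
    empty = df.index[df["species"] == ""]
    if len(empty):
        raise TraitTableError(
            f"empty species name in row(s): {list(df.loc[empty, 'source_row'])}"
        )

    for col in ("sla",) + tuple(c for c in ENV_VARS if c in df.columns):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    bad = df.index[df["sla"].notna() & (df["sla"] <= 0)]
    if len(bad):
        raise TraitTableError(
            f"non-positive SLA in row(s): {list(df.loc[bad, 'source_row'])}"
        )
    df["log_sla"] = np.log10(df["sla"])

    if "woody" in df.columns:
        df["woody"] = df["woody"].map(
            lambda v: bool(v) if not isinstance(v, str)
            else v.strip().lower() in ("1", "true", "yes", "woody")
        )
    return df.reset_index(drop=True)


def _validate_tree(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if any(lbl is None for lbl in labels):
        raise TreeError("tree has unlabeled tips")
    norm = [normalize_species(lbl) for lbl in labels]
    if len(set(norm)) != len(norm):
        dupes = sorted({l for l in norm if norm.count(l) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            path = "/".join(
                str(nd.taxon.label if nd.taxon else id(nd))
                for nd in edge.head_node.ancestor_iter(inclusive=True)
            )
            raise TreeError(f"negative branch length at node path {path}")


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick phylogeny with branch lengths in Myr."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except dendropy.utility.error.DataParseError as exc:
        raise TreeError(f"duplicate tip labels or malformed Newick: {exc}") from exc
    tree.is_rooted = True
    _validate_tree(tree)
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    """Parse a Newick string into a validated rooted tree."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except dendropy.utility.error.DataParseError as exc:
        raise TreeError(f"duplicate tip labels or malformed Newick: {exc}") from exc
    tree.is_rooted = True
    _validate_tree(tree)
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Underscore-normalized tip labels in the tree's leaf-iteration order."""
    return [normalize_species(leaf.taxon.label) for leaf in tree.leaf_node_iter()]


@dataclass
class MatchedDataset:
    """Trait records joined to a pruned phylogeny.

    Invariants: every record's species is a tip of ``tree``; every tip has
    at least one record; ``drop_report`` accounts for every removal.
    """

    records: pd.DataFrame
    tree: dendropy.Tree
    species_index: dict[str, int] = field(default_factory=dict)
    drop_report: dict[str, int] = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_species(self) -> int:
        return len(self.species_index)

    def species_order(self) -> list[str]:
        """Species in tip order (the alignment used by all tree matrices)."""
        return tip_labels(self.tree)


def harmonize(
    records: pd.DataFrame,
    tree: dendropy.Tree,
    clade_filter: Iterable[str] | None = None,
) -> MatchedDataset:
    """Join records to the tree: prune unmatched tips, drop unmatched records.

    Matching is exact on underscore-normalized binomials.  An optional
    ``clade_filter`` retains only records whose ``clade`` label is in the
    given set (applied before matching).  Raises :class:`TraitTableError`
    if fewer than two species are shared.
    """
    records = records.copy()
    n_input = len(records)
    dropped_clade = 0
    if clade_filter is not None:
        clade_filter = set(clade_filter)
        if "clade" not in records.columns:
            raise TraitTableError("clade_filter given but no 'clade' column")
        keep = records["clade"].isin(clade_filter)
        dropped_clade = int((~keep).sum())
        records = records[keep]

    tree = tree.clone(depth=1)
    tree_species = set(tip_labels(tree))
    rec_species = set(records["species"])
    shared = tree_species & rec_species
    if len(shared) < 2:
        raise TraitTableError(
            f"only {len(shared)} species shared between records and tree"
        )

    dropped_records = int((~records["species"].isin(shared)).sum())
    records = records[records["species"].isin(shared)].reset_index(drop=True)

    dropped_tips = len(tree_species) - len(shared)
    if dropped_tips:
        taxa = [
            t for t in tree.taxon_namespace
            if normalize_species(t.label) in shared
        ]
        tree.retain_taxa(taxa)

    order = tip_labels(tree)
    species_index = {sp: i for i, sp in enumerate(order)}
    dataset = MatchedDataset(
        records=records,
        tree=tree,
        species_index=species_index,
        drop_report={
            "input_records": n_input,
            "dropped_clade_filter": dropped_clade,
            "dropped_unmatched_records": dropped_records,
            "retained_records": len(records),
            "dropped_tips": dropped_tips,
            "retained_tips": len(shared),
        },
    )
    return dataset
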