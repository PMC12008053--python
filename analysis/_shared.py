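"""Shared loader for the analysis drivers: read the dataset written by
01_simulate_dataset.py and join it to the tree."""

from pathlib import Path

from phylopart.io_model import MatchedDataset, harmonize, read_trait_table, read_tree


def load_dataset(outdir: Path) -> MatchedDataset:
    data = outdir / "data"
    records_path = data / "records.csv"
    tree_path = data / "tree.nwk"
    if not records_path.exists() or not tree_path.exists():
        raise SystemExit(
            f"no dataset under {data}; run analysis/01_simulate_dataset.py first"
        )
    records = read_trait_table(records_path)
    tree = read_tree(tree_path)
    return harmonize(records, tree)
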