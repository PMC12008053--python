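import numpy as np
import pytest

from phylopart.io_model import harmonize, tree_from_string
from phylopart.phylo_numerics import bm_covariance
from phylopart.synthetic_data import default_scenario, simulate_tree


@pytest.fixture
def balanced4():
    return tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def tree200():
    """Fixed 200-tip ultrametric tree shared by the signal calibrations."""
    tree, clade_map = simulate_tree(200, seed=42)
    return tree, clade_map


@pytest.fixture(scope="session")
def V200(tree200):
    V, labels = bm_covariance(tree200[0])
    return V, labels


@pytest.fixture(scope="session")
def scenario_small():
    """A small default-conditions synthetic dataset for pipeline tests."""
    return default_scenario(11, n_species=100, n_sites=25)


@pytest.fixture(scope="session")
def dataset_small(scenario_small):
    return harmonize(scenario_small.records, scenario_small.tree)


@pytest.fixture
def trait_csv(tmp_path):
    """12-row trait table; rows 5 and 9 have a missing TN value."""
    lines = ["species,site_id,sla,par,tn,clade"]
    rng = np.random.default_rng(0)
    for i in range(12):
        sp = f"Genus_sp{i % 8}"
        tn = "" if i in (3, 7) else f"{1 + 0.1 * i:.2f}"
        lines.append(
            f"{sp},site{i % 3},{100 + 10 * i},{5000 + 100 * i},{tn},eudicot"
        )
    path = tmp_path / "traits.csv"
    path.write_text("\n".join(lines) + "\n")
    return path
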