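import numpy as np
import pandas as pd
import pytest

from phylopart.io_model import harmonize
from phylopart.phylo_numerics import PCoABasis, patristic_matrix, pcoa
from phylopart.pvr_partition import (
    ModelFit,
    VariableClasses,
    build_candidates,
    commonality,
    eigenvector_pool,
    full_fit,
    intraspecific_contribution,
    partition_pipeline,
    stepwise_aic,
)
from phylopart.synthetic_data import default_scenario, simulate_tree


def _basis(eigvals):
    eig = np.asarray(eigvals, dtype=float)
    return PCoABasis(
        eigenvalues=eig,
        axes=np.zeros((len(eig) + 1, len(eig))),
        tip_order=[],
        n_discarded=0,
    )


class TestEigenvectorPool:
    def test_threshold_examples(self):
        assert eigenvector_pool(_basis([6, 3, 1]), 0.9) == 2
        assert eigenvector_pool(_basis([6, 3, 1]), 1.0) == 3

    def test_cumulative_sum_oracle(self):
        tree, _ = simulate_tree(50, seed=21)
        d, order = patristic_matrix(tree)
        basis = pcoa(d, order)
        k = eigenvector_pool(basis, 0.95)
        cum = np.cumsum(basis.eigenvalues) / basis.eigenvalues.sum()
        expect = int(np.argmax(cum >= 0.95)) + 1
        assert k == expect

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            eigenvector_pool(_basis([1.0]), 0.0)


class TestBuildCandidates:
    def test_climate_with_quadratic_flag(self):
        classes = VariableClasses(quad_flags={"map": True})
        terms = build_candidates(classes, "C", n_axes=0)
        assert terms == ["par", "mtcm", "mthm", "map", "map^2", "mi", "alpha"]

    def test_interaction_terms_count(self):
        classes = VariableClasses(interactions=True)
        terms = build_candidates(classes, "CS", n_axes=0)
        assert sum(":" in t for t in terms) == 36

    def test_eigenvectors_never_squared_or_interacted(self):
        classes = VariableClasses(interactions=True, quad_flags={"mi": True})
        terms = build_candidates(classes, "P", n_axes=4)
        assert terms == ["pc1", "pc2", "pc3", "pc4"]


class TestStepwiseAic:
    def test_exact_candidate_selected(self):
        rng = np.random.default_rng(22)
        X = pd.DataFrame({"a": rng.standard_normal(60), "b": rng.standard_normal(60)})
        y = X["a"].to_numpy()
        fit = stepwise_aic(y, X, ["a", "b"])
        assert fit.terms == ["a"]
        assert fit.r2 == pytest.approx(1.0)

    def test_true_predictor_beats_decoys(self):
        chosen_true, noise_counts = 0, []
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(300 + seed)
            n = 200
            X = pd.DataFrame(
                {f"n{k}": rng.standard_normal(n) for k in range(10)}
            )
            X["signal"] = rng.standard_normal(n)
            y = X["signal"].to_numpy() + 0.1 * rng.standard_normal(n)
            fit = stepwise_aic(y, X, list(X.columns))
            chosen_true += "signal" in fit.terms
            noise_counts.append(len([t for t in fit.terms if t != "signal"]))
        assert chosen_true == n_rep
        assert np.mean(noise_counts) < 3.0  # decoys enter only occasionally

    def test_all_noise_rarely_selects(self):
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            n = 500
            X = pd.DataFrame({f"n{k}": rng.standard_normal(n) for k in range(8)})
            y = rng.standard_normal(n)
            counts.append(len(stepwise_aic(y, X, list(X.columns)).terms))
        assert np.mean(counts) < 1.5

    def test_duplicate_column_skipped(self):
        rng = np.random.default_rng(23)
        a = rng.standard_normal(50)
        X = pd.DataFrame({"a": a, "dup": a})
        y = a + 0.01 * rng.standard_normal(50)
        fit = stepwise_aic(y, X, ["a", "dup"])
        assert fit.terms == ["a"]  # the collinear duplicate never enters


class TestCommonality:
    @staticmethod
    def _r2(y, M):
        ones = np.ones((len(y), 1))
        X = np.hstack([ones, M]) if M.size else ones
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return 1 - (r @ r) / np.sum((y - y.mean()) ** 2)

    def test_orthogonal_blocks_have_no_shared_component(self):
        """Constructed orthogonal predictor blocks: every shared component
        vanishes and each unique component equals the block's own R^2."""
        n = 64
        t = np.arange(n)
        P = np.column_stack([np.where(t % 2 == 0, 1.0, -1.0)])
        C = np.column_stack([np.where((t // 2) % 2 == 0, 1.0, -1.0)])
        S = np.column_stack([np.where((t // 4) % 2 == 0, 1.0, -1.0)])
        y = 1.0 * P[:, 0] + 0.5 * C[:, 0] + 0.25 * S[:, 0]
        blocks = {"P": P, "C": C, "S": S}
        r2 = {}
        for name in ("P", "C", "S", "PC", "PS", "CS", "PCS"):
            M = np.hstack([blocks[ch] for ch in name])
            r2[name] = self._r2(y, M)
        comp = commonality(r2)
        for k in ("C_PC", "C_PS", "C_CS", "C_PCS"):
            assert comp[k] == pytest.approx(0.0, abs=1e-10)
        assert comp["U_P"] == pytest.approx(r2["P"], abs=1e-10)
        assert comp["U_C"] == pytest.approx(r2["C"], abs=1e-10)
        assert comp["U_S"] == pytest.approx(r2["S"], abs=1e-10)

    def test_duplicated_block_is_pure_common(self):
        rng = np.random.default_rng(24)
        n = 80
        P = rng.standard_normal((n, 2))
        C = rng.standard_normal((n, 2))
        S = C.copy()  # soil duplicates climate exactly
        y = C @ np.array([1.0, -0.5]) + 0.1 * rng.standard_normal(n)
        blocks = {"P": P, "C": C, "S": S}
        r2 = {}
        for name in ("P", "C", "S", "PC", "PS", "CS", "PCS"):
            M = np.hstack([blocks[ch] for ch in name])
            r2[name] = self._r2(y, M)
        comp = commonality(r2)
        assert comp["U_C"] == pytest.approx(0.0, abs=1e-10)
        assert comp["U_S"] == pytest.approx(0.0, abs=1e-10)
        assert comp["C_CS"] + comp["C_PCS"] == pytest.approx(r2["C"], abs=1e-8)

    def test_missing_subset_fatal(self):
        with pytest.raises(ValueError, match="missing"):
            commonality({"P": 0.1})


class TestIntraspecific:
    def test_one_record_per_species_gives_zero(self):
        resid = np.array([0.3, -0.2, 0.1, -0.4])
        fit = ModelFit("PCS", [], r2=0.5, aic=0.0, n=4, residuals=resid)
        species = pd.Series(["a", "b", "c", "d"])
        value, r2_r = intraspecific_contribution(fit, species)
        assert r2_r == 1.0
        assert value == 0.0

    def test_pure_within_species_noise(self):
        """Residuals independent of species: contribution ~ (1 - R2_PCS)."""
        rng = np.random.default_rng(25)
        n, n_sp = 2000, 100
        species = pd.Series(rng.integers(0, n_sp, n).astype(str))
        resid = rng.standard_normal(n)
        fit = ModelFit("PCS", [], r2=0.6, aic=0.0, n=n, residuals=resid)
        value, r2_r = intraspecific_contribution(fit, species)
        assert r2_r < 0.15
        assert value == pytest.approx(1 - 0.6, abs=0.1)


class TestPartitionPipeline:
    @pytest.fixture(scope="class")
    def partition(self, dataset_small):
        return partition_pipeline(dataset_small, variant="plain")

    def test_same_rows_for_all_seven_fits(self, partition):
        ns = {f.n for f in partition.fits.values()}
        assert len(ns) == 1

    def test_components_reconstruct_published_style_totals(self, partition):
        comp = partition.components
        r2 = {s: f.r2 for s, f in partition.fits.items()}
        assert comp["U_P"] == pytest.approx(r2["PCS"] - r2["CS"], abs=1e-12)
        assert partition.totals["P"] == r2["P"]

    def test_full_term_sum_identity(self, dataset_small):
        res = partition_pipeline(dataset_small, variant="plain", stepwise=False)
        total = sum(res.components.values())
        assert total == pytest.approx(res.fits["PCS"].r2, abs=1e-8)

    def test_interaction_variant_only_changes_cs_and_pcs(self, dataset_small):
        plain = partition_pipeline(dataset_small, variant="plain", stepwise=False)
        inter = partition_pipeline(
            dataset_small, variant="interactions", stepwise=False
        )
        for s in ("P", "C", "S", "PC", "PS"):
            assert inter.fits[s].r2 == pytest.approx(plain.fits[s].r2, abs=1e-10)
        assert inter.fits["CS"].r2 >= plain.fits["CS"].r2 - 1e-10
        assert inter.fits["PCS"].r2 >= plain.fits["PCS"].r2 - 1e-10

    def test_selected_r2_bounded_by_full_fit(self, dataset_small):
        sel = partition_pipeline(dataset_small, variant="plain", stepwise=True)
        full = partition_pipeline(dataset_small, variant="plain", stepwise=False)
        for s in sel.fits:
            assert sel.fits[s].r2 <= full.fits[s].r2 + 1e-10

    def test_recovery_of_generating_fractions(self, scenario_small, dataset_small):
        res = partition_pipeline(dataset_small, variant="plain")
        truth = scenario_small.truth.fractions
        assert res.totals["P"] == pytest.approx(truth["phylogenetic"], abs=0.12)
        assert res.intraspecific == pytest.approx(truth["intraspecific"], abs=0.12)

    def test_environment_free_generation_yields_small_env_totals(self):
        hits = 0
        for seed in (31, 32, 33, 34, 35):
            sc = default_scenario(
                seed, n_species=150, n_sites=40, fractions=(0.7, 0.0, 0.3)
            )
            ds = harmonize(sc.records, sc.tree)
            res = partition_pipeline(ds, variant="plain")
            hits += res.totals["C"] < 0.05 and res.totals["S"] < 0.05
        assert hits >= 4

    def test_percentages_rounding(self, partition):
        pct = partition.percentages()
        assert pct["total_P"] == round(partition.totals["P"] * 100, 2)
        assert "intraspecific" in pct
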