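"""DE callers, BH FDR and the consensus intersection rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressdeg.de_consensus import (benjamini_hochberg, call_de, consensus,
                                    normalize_library_sizes)
from stressdeg.io_model import ValidationError

from conftest import make_count_matrix


class TestBenjaminiHochberg:
    def test_single_value_identity(self):
        assert benjamini_hochberg([0.05]) == pytest.approx([0.05])

    def test_hand_computed_step_up(self):
        # p_(i) * m / i = (.04, .04, .04, .04) after the step-up minimum
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.5])

    @staticmethod
    def _oracle(p):
        """Direct evaluation of the step-up definition."""
        p = np.asarray(p, float)
        m = len(p)
        adj = np.empty(m)
        for i in range(m):
            candidates = [p[j] * m / (np.sum(p <= p[j]))
                          for j in range(m) if p[j] >= p[i]]
            adj[i] = min(1.0, min(candidates))
        return adj

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_brute_force_oracle(self, pvals):
        np.testing.assert_allclose(benjamini_hochberg(pvals),
                                   self._oracle(pvals), rtol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests
        _, expected, _, _ = multipletests(pvals, method="fdr_bh")
        np.testing.assert_allclose(benjamini_hochberg(pvals), expected,
                                   rtol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_in_sorted_order(self, pvals):
        p = np.sort(np.asarray(pvals))
        adj = benjamini_hochberg(p)
        assert (np.diff(adj) >= -1e-15).all()


class TestNormalization:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [3, 5, 9], "b": [3, 5, 9]})
        for method in ("median_of_ratios", "total_count"):
            np.testing.assert_allclose(normalize_library_sizes(df, method),
                                       [1.0, 1.0])

    def test_total_count_arithmetic(self):
        df = pd.DataFrame({"a": [50, 50], "b": [200, 100]})
        np.testing.assert_allclose(
            normalize_library_sizes(df, "total_count"), [0.5, 1.5])

    def test_median_of_ratios_hand_computation(self):
        # geometric means (sqrt8, sqrt18, sqrt200); all column-1 ratios 1/sqrt2
        df = pd.DataFrame([[2, 4], [3, 6], [10, 20]], columns=["a", "b"])
        np.testing.assert_allclose(
            normalize_library_sizes(df, "median_of_ratios"),
            [1 / np.sqrt(2), np.sqrt(2)])

    def test_median_of_ratios_needs_all_positive_gene(self):
        df = pd.DataFrame([[0, 4], [3, 0]], columns=["a", "b"])
        with pytest.raises(ValidationError):
            normalize_library_sizes(df, "median_of_ratios")


class TestCallDe:
    def _matrix(self, rng, n_genes=80, n=4, shift_gene=None, fold=4.0):
        base = rng.integers(50, 500, size=n_genes).astype(float)
        mu = np.tile(base[:, None], (1, 2 * n))
        if shift_gene is not None:
            mu[shift_gene, n:] *= fold
        return make_count_matrix(rng.poisson(mu), n_reps=n)

    @pytest.mark.parametrize("caller", ["nb_wald", "lm_moderated"])
    def test_identical_groups_null_identity(self, caller):
        counts = np.tile(np.array([[10], [100], [7]]), (1, 8))
        cm = make_count_matrix(counts, n_reps=4)
        res = call_de(cm, "Ba12", "leaf", (35, 15), caller=caller)
        np.testing.assert_allclose(res["lfc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["pvalue"], 1.0)

    @pytest.mark.parametrize("caller", ["nb_wald", "lm_moderated"])
    def test_antisymmetry_under_group_swap(self, caller):
        rng = np.random.default_rng(5)
        cm = self._matrix(rng, shift_gene=3)
        fwd = call_de(cm, "Ba12", "leaf", (35, 15), caller=caller)
        rev = call_de(cm, "Ba12", "leaf", (15, 35), caller=caller)
        np.testing.assert_allclose(fwd["lfc"], -rev["lfc"], atol=1e-10)
        np.testing.assert_allclose(fwd["pvalue"], rev["pvalue"], atol=1e-10)

    def test_large_sample_lfc_consistency(self):
        """Poisson-like counts with a true 4-fold shift, n=50 per side."""
        rng = np.random.default_rng(0)
        n = 50
        mu = np.full((1, 2 * n), 100.0)
        mu[0, n:] = 400.0
        extra = np.tile(rng.integers(50, 200, size=30).astype(float)[:, None],
                        (1, 2 * n))
        counts = rng.poisson(np.vstack([mu, extra]))
        cm = make_count_matrix(counts, n_reps=n)
        res = call_de(cm, "Ba12", "leaf", (35, 15), caller="nb_wald")
        lfc = res.set_index("gene_id").loc["g0", "lfc"]
        assert abs(lfc - 2.0) < 0.1

    def test_too_few_replicates_rejected(self, small_experiment):
        _, cm, _ = small_experiment
        sub = cm.subset("Ba12", "leaf", (35, 15))
        drop = [s for s in sub.samples
                if not (s.ewc == 15 and s.replicate > 1)]
        from stressdeg.io_model import CountMatrix
        sub2 = CountMatrix(sub.gene_ids, drop,
                           sub.counts[[s.sample_id for s in drop]])
        with pytest.raises(ValidationError):
            call_de(sub2, "Ba12", "leaf", (35, 15))


def _caller_table(lfcs, fdrs, genes=None):
    genes = genes or [f"g{i}" for i in range(len(lfcs))]
    return pd.DataFrame({
        "gene_id": genes, "genotype": "Ba12", "tissue": "leaf",
        "scheme": "AR", "comparison": "35/15", "caller": "x",
        "lfc": lfcs, "pvalue": fdrs, "fdr": fdrs,
    })


class TestConsensus:
    def test_all_callers_pass_up(self):
        tables = [_caller_table([1.5], [0.001]), _caller_table([1.6], [0.005]),
                  _caller_table([1.4], [0.009])]
        assert consensus(tables)["direction"].tolist() == ["up"]

    def test_one_caller_fails_lfc(self):
        tables = [_caller_table([1.5], [0.001]), _caller_table([1.5], [0.001]),
                  _caller_table([1.0], [0.001])]
        assert consensus(tables)["direction"].tolist() == ["ns"]

    def test_sign_disagreement_is_ns(self):
        tables = [_caller_table([1.5], [0.001]), _caller_table([-1.5], [0.001])]
        assert consensus(tables)["direction"].tolist() == ["ns"]

    def test_down_needs_negative_lfc_everywhere(self):
        tables = [_caller_table([-1.5], [0.001]), _caller_table([-2.0], [0.0001])]
        assert consensus(tables)["direction"].tolist() == ["down"]

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValidationError):
            consensus([_caller_table([1.5], [0.001], genes=["a"]),
                       _caller_table([1.5], [0.001], genes=["b"])])

    def test_monotone_in_thresholds_and_callers(self, small_de):
        results, _ = small_de
        groups = [g for _, g in results.groupby("caller")]

        def n_degs(tables, lfc=1.2, fdr=0.01):
            c = consensus(tables, lfc, fdr)
            return (c["direction"] != "ns").sum()

        base = n_degs(groups)
        assert n_degs(groups, lfc=1.5) <= base
        assert n_degs(groups, fdr=0.001) <= base
        assert base <= n_degs(groups[:1])  # adding a caller never enlarges


def test_callers_agree_in_sign_on_strong_shifts(small_experiment, small_de):
    _, _, truth = small_experiment
    results, _ = small_de
    tr = truth[truth["tissue"] == "leaf"].set_index(["gene_id", "genotype"])
    ar = results[(results["scheme"] == "AR") & (results["comparison"] == "35/1")]
    piv = ar.pivot_table(index=["gene_id", "genotype"], columns="caller",
                         values="lfc")
    shifts = pd.Series({k: tr.loc[k, "shift_1"] for k in piv.index})
    strong = piv[shifts.abs() >= 2.0]
    assert (np.sign(strong["nb_wald"]) == np.sign(strong["lm_moderated"])).all()


def test_null_simulation_false_call_rate():
    """On unplanted data the consensus miscall rate stays below 2 %."""
    from stressdeg.de_consensus import de_analysis
    from stressdeg.synthetic_data import null_config, simulate_experiment
    rates = []
    for seed in range(3):
        cm, _ = simulate_experiment(
            null_config(n_genes=300, tissues=("leaf",), seed=50 + seed))
        _, calls = de_analysis(cm)
        rates.append((calls["direction"] != "ns").mean())
    assert np.mean(rates) < 0.02
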