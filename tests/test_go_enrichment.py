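"""Fisher over-representation, direction partitions and sharing statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressdeg.go_enrichment import (_pairwise_pct, fisher_enrich,
                                     partitioned_enrichment, sharing)
from stressdeg.io_model import GOAnnotationMap, ValidationError


def _anno(mapping, meta=None):
    return GOAnnotationMap({g: frozenset(ts) for g, ts in mapping.items()},
                           meta or {})


def _hyper_tail(a, N, K, n):
    """Upper-tail P(X >= a) by direct enumeration of hypergeometric masses."""
    total = 0.0
    for x in range(a, min(K, n) + 1):
        total += (math.comb(K, x) * math.comb(N - K, n - x)) / math.comb(N, n)
    return total


class TestFisherEnrich:
    def test_term_on_every_background_gene_p_one(self):
        bg = [f"g{i}" for i in range(20)]
        anno = _anno({g: {"GO:0000001"} for g in bg})
        df = fisher_enrich(bg[:5], bg, anno)
        assert df["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_hypergeometric_enumeration_example(self):
        # background 50, term frequency 5, study 10, a = 3
        bg = [f"g{i}" for i in range(50)]
        term_genes = bg[:5]
        anno = _anno({g: {"GO:0000001"} for g in term_genes})
        study = term_genes[:3] + bg[5:12]
        df = fisher_enrich(study, bg, anno)
        assert df["pvalue"].iloc[0] == pytest.approx(_hyper_tail(3, 50, 5, 10))
        assert (df[["a", "b", "c", "d"]].iloc[0] == [3, 7, 2, 38]).all()

    def test_more_hits_never_increase_p(self):
        bg = [f"g{i}" for i in range(40)]
        anno = _anno({g: {"GO:0000001"} for g in bg[:10]})
        p3 = fisher_enrich(bg[:3] + bg[10:17], bg, anno)["pvalue"].iloc[0]
        p6 = fisher_enrich(bg[:6] + bg[10:14], bg, anno)["pvalue"].iloc[0]
        assert p6 <= p3

    def test_empty_study_rejected(self):
        anno = _anno({"g1": {"GO:0000001"}})
        with pytest.raises(ValidationError):
            fisher_enrich([], ["g1"], anno)

    def test_study_outside_background_rejected(self):
        anno = _anno({"g1": {"GO:0000001"}})
        with pytest.raises(ValidationError):
            fisher_enrich(["g2"], ["g1"], anno)

    def test_exhaustive_against_enumeration_small_universes(self):
        """Fisher p equals the enumerated hypergeometric tail for every
        2x2 table with N <= 25 (the full sweep to 60 runs in acceptance)."""
        from scipy.stats import hypergeom
        for N in range(2, 26):
            for K in range(0, N + 1):
                for n in range(1, N + 1):
                    a_vals = np.arange(1, min(K, n) + 1)
                    if a_vals.size == 0:
                        continue
                    sf = hypergeom.sf(a_vals - 1, N, K, n)
                    orc = [_hyper_tail(a, N, K, n) for a in a_vals]
                    np.testing.assert_allclose(sf, orc, rtol=1e-9, atol=1e-12)

    def test_fdr_order_invariant(self):
        rng = np.random.default_rng(1)
        bg = [f"g{i}" for i in range(60)]
        mapping = {}
        for t in range(8):
            term = f"GO:{t:07d}"
            for g in rng.choice(bg, size=10, replace=False):
                mapping.setdefault(g, set()).add(term)
        anno = _anno(mapping)
        study = list(rng.choice(bg, size=15, replace=False))
        df1 = fisher_enrich(study, bg, anno).set_index("term_id")["fdr"]
        df2 = fisher_enrich(study[::-1], list(reversed(bg)), anno
                            ).set_index("term_id")["fdr"]
        pd.testing.assert_series_equal(df1.sort_index(), df2.sort_index())


class TestPartitionedEnrichment:
    def _sets(self):
        # core: c1 (u), c2 (d), c3 (m); trend for genotype A
        return {
            "trend": {"A": {"c1", "c2", "c3", "t1"}},
            "core": {"c1", "c2", "c3"},
            "core_class": {"c1": "u", "c2": "d", "c3": "m"},
            "net_class": {("c1", "A"): "u_deg", ("c2", "A"): "d_deg",
                          ("c3", "A"): "i_deg", ("t1", "A"): "u_deg"},
        }

    def test_term_may_enrich_both_directions(self):
        bg = ["c1", "c2", "c3", "t1"] + [f"b{i}" for i in range(6)]
        anno = _anno({g: {"GO:0000009"} for g in ["c1", "c2"]})
        enr, _ = partitioned_enrichment(self._sets(), None, anno, bg, "core")
        assert set(enr["direction"]) >= {"U", "D"}

    def test_empty_m_partition_absent(self):
        sets = self._sets()
        sets["core"] = {"c1", "c2"}
        sets["core_class"] = {"c1": "u", "c2": "d"}
        bg = ["c1", "c2", "t1", "b1", "b2"]
        anno = _anno({g: {"GO:0000009"} for g in bg})
        enr, _ = partitioned_enrichment(sets, None, anno, bg, "core")
        assert "M" not in set(enr["direction"])

    def test_group_rollup_counts_union_not_sum(self):
        # two significant terms in one group share gene c1
        sets = {
            "trend": {"A": set()}, "core": {"c1", "c2"},
            "core_class": {"c1": "u", "c2": "u"}, "net_class": {},
        }
        bg = ["c1", "c2"] + [f"b{i}" for i in range(30)]
        anno = _anno({
            "c1": {"GO:0000001", "GO:0000002"},
            "c2": {"GO:0000001", "GO:0000002"},
            **{f"b{i}": {"GO:0000009"} for i in range(30)},
        })
        groups = {"GO:0000001": "grp", "GO:0000002": "grp"}
        _, rollup = partitioned_enrichment(sets, None, anno, bg, "core",
                                           groups=groups)
        row = rollup.iloc[0]
        assert row["n_terms"] == 2
        assert row["n_degs"] == 2  # |{c1, c2}| as a union, not 3

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValidationError):
            partitioned_enrichment(self._sets(), None, _anno({"g": {"GO:0000001"}}),
                                   ["g"], "nonsense")


class TestSharing:
    def test_identical_sets_all_hundred(self):
        sets = {g: {"a", "b", "c"} for g in "wxyz"}
        res = sharing(sets)
        assert all(v == 100.0 for v in res["pairwise"].values())
        assert res["all4"] == 100.0

    def test_disjoint_sets_all_zero(self):
        sets = {g: {f"{g}{i}" for i in range(3)} for g in "wxyz"}
        res = sharing(sets)
        assert all(v == 0.0 for v in res["pairwise"].values())
        assert res["all4"] == 0.0

    def test_mean_size_denominator_hand_arithmetic(self):
        a, b = {"g1", "g2", "g3"}, {"g2", "g3", "g4", "g5"}
        assert _pairwise_pct(frozenset(a), frozenset(b), "mean_size") == \
            pytest.approx(100 * 2 / 3.5)

    def test_denominator_conventions(self):
        a, b = frozenset({"1", "2"}), frozenset({"2", "3", "4"})
        assert _pairwise_pct(a, b, "union") == pytest.approx(25.0)
        assert _pairwise_pct(a, b, "min_size") == pytest.approx(50.0)

    def test_all_empty_rejected(self):
        with pytest.raises(ValidationError):
            sharing({g: set() for g in "wxyz"})

    @given(st.lists(st.sets(st.integers(0, 15)), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_symmetry_and_fourway_bound(self, sets):
        named = {f"G{i}": {str(x) for x in s} for i, s in enumerate(sets)}
        if all(len(s) == 0 for s in named.values()):
            return
        res = sharing(named)
        for (g1, g2), v in res["pairwise"].items():
            assert v == pytest.approx(
                _pairwise_pct(frozenset(named[g1]), frozenset(named[g2]),
                              "mean_size"))
            assert 0.0 <= v <= 100.0
        assert res["all4"] <= min(res["pairwise"].values()) + 1e-9


def test_obo_ancestor_propagation(tmp_path):
    obo = tmp_path / "mini.obo"
    obo.write_text("""\
format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: mid process
namespace: biological_process
is_a: GO:0000001 ! root process

[Term]
id: GO:0000003
name: leaf process
namespace: biological_process
is_a: GO:0000002 ! mid process
""")
    from stressdeg.go_enrichment import propagate_annotations
    anno = _anno({"g1": {"GO:0000003"}})
    prop = propagate_annotations(anno, str(obo))
    assert prop.terms_for("g1") == {"GO:0000001", "GO:0000002", "GO:0000003"}
    assert prop.term_meta["GO:0000001"]["namespace"] == "BP"
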