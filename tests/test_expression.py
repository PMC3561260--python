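import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mecp2screen import (
    bh_qvalues,
    collapse_probes_to_genes,
    detection_prefilter,
    differential_expression,
    normalize_log2,
)
from mecp2screen.expression import fallback_detection_calls, quantile_normalize


def brute_force_bh(pvals):
    """Step-up BH by direct enumeration: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * n / j for j in range(rank_pos, n + 1)]
        q[idx] = min(1.0, min(candidates))
    return q


def make_groups(n=3):
    samples = [f"WT_{i}" for i in range(n)] + [f"KO_{i}" for i in range(n)]
    return pd.Series(["WT"] * n + ["KO"] * n, index=samples)


def make_matrix(rows, n=3):
    groups = make_groups(n)
    return pd.DataFrame(rows).T.set_axis(groups.index, axis=1), groups


class TestPrefilter:
    def _calls(self, ko_calls):
        groups = make_groups()
        data = {s: ["present"] for s in groups.index[groups == "WT"]}
        for s, c in zip(groups.index[groups == "KO"], ko_calls):
            data[s] = [c]
        return pd.DataFrame(data, index=["p1"]), groups

    def test_single_detection_excluded(self):
        calls, groups = self._calls(["present", "absent", "absent"])
        assert detection_prefilter(calls, groups, "KO") == []

    def test_marginal_counts_toward_detection(self):
        calls, groups = self._calls(["present", "marginal", "absent"])
        assert detection_prefilter(calls, groups, "KO") == ["p1"]

    def test_all_present_saturates_both_lists(self):
        groups = make_groups()
        calls = pd.DataFrame("present", index=["p1", "p2"], columns=groups.index)
        assert detection_prefilter(calls, groups, "KO") == ["p1", "p2"]
        assert detection_prefilter(calls, groups, "WT") == ["p1", "p2"]

    def test_min_detected_larger_than_group_errors(self):
        calls, groups = self._calls(["present"] * 3)
        with pytest.raises(ValueError, match="exceeds group size"):
            detection_prefilter(calls, groups, "KO", min_detected=4)

    def test_fallback_calls_threshold_rule(self):
        m = pd.DataFrame({"s1": [1.0, 10.0, 100.0, 1000.0]}, index=list("abcd"))
        calls = fallback_detection_calls(m, background_quantile=0.5)
        assert calls["s1"].tolist() == ["absent", "absent", "present", "present"]


class TestNormalization:
    def test_identical_samples_are_fixed_point(self):
        m = pd.DataFrame({"s1": [1.0, 4.0, 16.0], "s2": [1.0, 4.0, 16.0]}, index=list("abc"))
        out = normalize_log2(m, "quantile_log2")
        assert np.allclose(out, np.log2(m))

    def test_single_probe_reduces_to_log2(self):
        m = pd.DataFrame({"s1": [4.0], "s2": [16.0]}, index=["p"])
        out = normalize_log2(m, "quantile_log2")
        assert out.values.tolist() == [[2.0, 4.0]]

    def test_column_means_equal_after_quantile(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.lognormal(5, 1, (200, 4)), columns=list("abcd"))
        out = quantile_normalize(m)
        assert np.allclose(out.mean(axis=0), out.mean(axis=0).iloc[0])

    def test_nonpositive_intensity_rejected(self):
        m = pd.DataFrame({"s1": [1.0, -2.0], "s2": [1.0, 3.0]})
        with pytest.raises(ValueError, match="positive"):
            normalize_log2(m, "quantile_log2")

    def test_passthrough_is_identity(self):
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0]})
        assert normalize_log2(m, "passthrough") is m


class TestBenjaminiHochberg:
    def test_worked_four_value_example(self):
        q = bh_qvalues(np.array([0.001, 0.02, 0.04, 0.9]))
        assert np.allclose(q, [0.004, 0.04, 0.04 * 4 / 3, 0.9])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_enumeration(self, pvals):
        assert np.allclose(bh_qvalues(np.array(pvals)), brute_force_bh(pvals))

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_q_at_least_p_and_within_unit_interval(self, pvals):
        q = bh_qvalues(np.array(pvals))
        assert (q >= np.array(pvals) - 1e-15).all() and (q <= 1.0).all()


class TestDifferentialExpression:
    def test_identical_groups_fail_with_unit_fold(self):
        m, groups = make_matrix({"p1": [5.0, 5.1, 4.9, 5.0, 5.1, 4.9]})
        res = differential_expression(m, groups)
        row = res.probes.loc["p1"]
        assert row["fold_change"] == 1.0
        assert row["p_value"] == pytest.approx(1.0)
        assert not row["passes"]

    def test_fold_change_gate_at_1p2(self):
        # log2 diff 0.30 -> fold 2**0.30 = 1.2311 > 1.2
        m, groups = make_matrix({"p1": [5.0, 5.01, 4.99, 5.3, 5.31, 5.29]})
        res = differential_expression(m, groups, mode="rawp", fc_cutoff=1.2)
        row = res.probes.loc["p1"]
        assert row["fold_change"] == pytest.approx(2 ** 0.30, rel=1e-6)
        assert row["direction"] == "up_in_KO"
        assert bool(row["passes"])

    def test_zero_variance_probe_untestable(self):
        m, groups = make_matrix({"p1": [5.0] * 6, "p2": [1, 2, 3, 4, 5, 6.0]})
        res = differential_expression(m, groups)
        assert res.untestable == ["p1"]
        assert "p1" not in res.probes.index

    def test_direction_must_match_prefiltered_list(self):
        m, groups = make_matrix({"p1": [5.0, 5.01, 4.99, 6.0, 6.01, 5.99]})  # up in KO
        res = differential_expression(m, groups, ko_prefiltered=[], wt_prefiltered=["p1"])
        assert not res.probes.loc["p1", "passes"]
        res2 = differential_expression(m, groups, ko_prefiltered=["p1"], wt_prefiltered=[])
        assert bool(res2.probes.loc["p1", "passes"])

    def test_label_swap_flips_direction_keeps_pass_set(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(
            rng.normal(8, 0.2, (50, 6)) + np.r_[np.zeros(3), np.full(3, 0.5)],
            index=[f"p{i}" for i in range(50)],
            columns=make_groups().index,
        )
        groups = make_groups()
        res = differential_expression(m, groups)
        swapped = groups.map({"WT": "KO", "KO": "WT"})
        res_swap = differential_expression(m, swapped)
        passing = set(res.probes.index[res.probes["passes"]])
        passing_swap = set(res_swap.probes.index[res_swap.probes["passes"]])
        assert passing == passing_swap
        for p in passing:
            d1 = res.probes.loc[p, "direction"]
            d2 = res_swap.probes.loc[p, "direction"]
            assert {d1, d2} == {"up_in_KO", "down_in_KO"}

    def test_fc_monotonicity(self):
        rng = np.random.default_rng(11)
        effects = rng.choice([0.0, 0.3, 0.7], 200)
        m = pd.DataFrame(
            rng.normal(7, 0.1, (200, 6)) + np.outer(effects, np.r_[np.zeros(3), np.ones(3)]),
            index=[f"p{i}" for i in range(200)],
            columns=make_groups().index,
        )
        groups = make_groups()
        loose = differential_expression(m, groups, fc_cutoff=1.2)
        strict = differential_expression(m, groups, fc_cutoff=1.5)
        assert set(strict.probes.index[strict.probes["passes"]]) <= set(
            loose.probes.index[loose.probes["passes"]]
        )
        assert loose.probes["passes"].sum() > 0

    def test_fdr_mode_uses_bh_within_list(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(8, 0.2, (100, 6)), index=[f"p{i}" for i in range(100)],
                         columns=make_groups().index)
        m.iloc[:5, 3:] += 2.0  # strong up effects
        res = differential_expression(m, make_groups(), mode="fdr")
        assert res.probes["passes"].sum() >= 5
        assert (res.probes.loc[res.probes["passes"], "bh_q_up"] < 0.05).all()


class TestCollapse:
    def _result(self, probe_rows):
        m, groups = make_matrix(probe_rows)
        return differential_expression(m, groups)

    def test_any_probe_rule_and_representative(self):
        res = self._result({
            "p1": [5.0, 5.02, 4.98, 6.0, 6.02, 5.98],   # passes
            "p2": [5.0, 5.5, 4.5, 5.1, 5.6, 4.6],       # fails
        })
        genes = collapse_probes_to_genes(res, pd.Series({"p1": "geneA", "p2": "geneA"})).genes
        assert list(genes.index) == ["geneA"]
        assert genes.loc["geneA", "representative_probe"] == "p1"
        assert genes.loc["geneA", "n_passing_probes"] == 1
        assert not genes.loc["geneA", "discordant"]

    def test_discordant_directions_flagged_and_kept(self):
        res = self._result({
            "p1": [5.0, 5.01, 4.99, 6.0, 6.01, 5.99],   # up, very small p
            "p2": [6.0, 6.02, 5.98, 5.0, 5.02, 4.98],   # down
        })
        genes = collapse_probes_to_genes(res, pd.Series({"p1": "geneA", "p2": "geneA"})).genes
        assert bool(genes.loc["geneA", "discordant"])
        assert genes.loc["geneA", "direction"] in ("up_in_KO", "down_in_KO")

    def test_unannotated_passing_probe_reported(self):
        res = self._result({"p1": [5.0, 5.01, 4.99, 6.0, 6.01, 5.99]})
        out = collapse_probes_to_genes(res, pd.Series({"other": "geneB"}))
        assert out.unannotated == ["p1"]
        assert len(out.genes) == 0

    def test_no_passing_probes_empty_gene_list(self):
        res = self._result({"p1": [5.0, 5.5, 4.5, 5.0, 5.5, 4.5]})
        out = collapse_probes_to_genes(res, pd.Series({"p1": "geneA"}))
        assert len(out.genes) == 0

    def test_many_probes_collapse_to_fewer_genes(self):
        # 142-probe / 118-gene style structure: extra probes share genes
        rng = np.random.default_rng(9)
        n_genes, n_probes = 118, 142
        gene_ids = [f"gene{i:03d}" for i in range(n_genes)]
        probe_gene = gene_ids + list(rng.choice(gene_ids, n_probes - n_genes, replace=False))
        rows = {}
        for i in range(n_probes):
            base = rng.normal(7, 0.5)
            rows[f"p{i:03d}"] = np.r_[base + rng.normal(0, 0.02, 3), base + 0.8 + rng.normal(0, 0.02, 3)]
        m, groups = make_matrix(rows)
        res = differential_expression(m, groups)
        assert res.probes["passes"].all()
        out = collapse_probes_to_genes(res, pd.Series(probe_gene, index=list(rows)))
        assert len(out.genes) == n_genes
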