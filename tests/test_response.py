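"""Target-set enrichment and the regulatory-effect score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import coldmir as cm
from oracles import fisher_two_sided_exact, re_score_brute


def _background(n):
    return [f"g{i}" for i in range(n)]


class TestFisherEnrichment:
    def test_tf_style_depletion_on_large_margins(self):
        """46 differential targets of 796, in 626 of 7356: depleted, p<0.01."""
        bg = _background(7356)
        targets = bg[:796]
        diff = bg[750:1376]  # overlap 46
        res = cm.fisher_target_enrichment(targets, diff, bg)
        assert res["n_overlap"] == 46
        assert res["p_value"] < 0.01
        assert res["direction"] == "depleted"
        assert res["p_value"] == pytest.approx(
            fisher_two_sided_exact(46, 7356, 796, 626), rel=1e-9
        )

    def test_targets_equal_background_is_uninformative(self):
        bg = _background(10)
        res = cm.fisher_target_enrichment(bg, bg[:5], bg)
        assert res["p_value"] == pytest.approx(1.0)

    def test_small_table_matches_exhaustive_enumeration(self):
        bg = _background(10)
        res = cm.fisher_target_enrichment(bg[:3], bg[:5], bg)
        assert res["n_overlap"] == 3
        assert res["p_value"] == pytest.approx(fisher_two_sided_exact(3, 10, 3, 5), rel=1e-12)

    def test_agrees_with_enumeration_over_margin_grid(self):
        """p equals exact rational enumeration for all tables with N <= 12."""
        for n in range(2, 13):
            bg = _background(n)
            for k in range(0, n + 1):
                for c in range(0, n + 1):
                    lo = max(0, c - (n - k))
                    for x in range(lo, min(k, c) + 1):
                        targets = bg[:k]
                        # overlap-x configuration: x from targets, c-x outside
                        diff = bg[:x] + bg[k : k + (c - x)]
                        if len(diff) != c:
                            continue
                        res = cm.fisher_target_enrichment(targets, diff, bg)
                        assert res["p_value"] == pytest.approx(
                            fisher_two_sided_exact(x, n, k, c), rel=1e-9, abs=1e-12
                        ), (n, k, c, x)

    def test_empty_background_errors(self):
        with pytest.raises(ValueError):
            cm.fisher_target_enrichment(["a"], [], [])


class TestBHFDR:
    def test_step_up_hand_example(self):
        assert cm.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged_and_all_ones(self):
        assert cm.bh_fdr([0.2]) == pytest.approx([0.2])
        assert cm.bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cm.bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_permutation_equivariance_and_dominance(self, ps):
        """Reordering inputs reorders outputs identically; q >= p."""
        q = cm.bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ps))
        q_perm = cm.bh_fdr(np.asarray(ps)[perm])
        assert q_perm == pytest.approx(q[perm])


class TestREScore:
    def test_hand_example_two_lowest_targets(self):
        expr = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        assert cm.re_score_per_sample(expr, ["a", "b"]) == pytest.approx(0.5)

    def test_identical_values_give_zero(self):
        expr = {g: 5.0 for g in "abcdef"}
        assert cm.re_score_per_sample(expr, ["a", "b"]) == pytest.approx(0.0)

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(size=30)
        expr = {f"g{i}": v for i, v in enumerate(vals)}
        targets = [f"g{i}" for i in range(0, 30, 3)]
        base = cm.re_score_per_sample(expr, targets)
        warped = {g: np.exp(3 * v) for g, v in expr.items()}
        assert cm.re_score_per_sample(warped, targets) == pytest.approx(base)

    def test_matches_brute_force_and_complement_antisymmetry(self, rng):
        """On random 6-gene samples the score matches the direct definition
        and swapping target/non-target roles exactly negates it."""
        for _ in range(50):
            vals = rng.integers(0, 5, size=6).astype(float)  # ties likely
            expr = {f"g{i}": v for i, v in enumerate(vals)}
            k = int(rng.integers(1, 6))
            targets = [f"g{i}" for i in rng.choice(6, size=k, replace=False)]
            mask = np.array([f"g{i}" in targets for i in range(6)])
            got = cm.re_score_per_sample(expr, targets)
            assert got == pytest.approx(re_score_brute(vals, mask))
            comp = [g for g in expr if g not in targets]
            assert got == pytest.approx(-cm.re_score_per_sample(expr, comp))

    def test_degenerate_target_sets_error(self):
        expr = {"a": 1.0, "b": 2.0}
        with pytest.raises(ValueError):
            cm.re_score_per_sample(expr, [])
        with pytest.raises(ValueError):
            cm.re_score_per_sample(expr, ["a", "b"])


class TestREScoreTest:
    @staticmethod
    def _cond(expr):
        return {c: ("NC" if c.startswith("NC") else "WC") for c in expr.columns}

    def test_identical_conditions_give_t0_p1(self):
        genes = [f"g{i}" for i in range(20)]
        rng = np.random.default_rng(1)
        col = rng.normal(size=20)
        expr = pd.DataFrame(
            {"NC1": col, "NC2": col + 0.1, "NC3": col - 0.1,
             "WC1": col, "WC2": col + 0.1, "WC3": col - 0.1},
            index=genes,
        )
        tm = cm.TargetMap.from_pairs([("m1", g) for g in genes[:5]])
        res = cm.re_score_test(expr, tm, self._cond(expr))
        assert res["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_too_few_samples_error(self):
        expr = pd.DataFrame({"NC1": [1.0, 2.0], "WC1": [1.0, 2.0]}, index=["a", "b"])
        tm = cm.TargetMap.from_pairs([("m1", "a")])
        with pytest.raises(ValueError):
            cm.re_score_test(expr, tm, self._cond(expr))

    def test_suppressed_targets_attain_smallest_p(self):
        """A miRNA whose targets drop by 2·noise_sd in WC is top-ranked in
        >= 90% of replicates."""
        noise_sd = 0.3
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            genes = [f"g{i}" for i in range(200)]
            base = rng.normal(8, 1.5, size=200)
            expr = pd.DataFrame(
                {c: base + rng.normal(0, noise_sd, 200) for c in
                 ["NC1", "NC2", "NC3", "WC1", "WC2", "WC3"]},
                index=genes,
            )
            pairs = []
            for m in range(20):
                tg = rng.choice(200, size=10, replace=False)
                pairs.extend((f"m{m}", genes[j]) for j in tg)
            tm = cm.TargetMap.from_pairs(sorted(set(pairs)))
            suppressed = list(tm.targets("m0"))
            for c in ["WC1", "WC2", "WC3"]:
                expr.loc[suppressed, c] -= 2 * noise_sd
            res = cm.re_score_test(expr, tm, self._cond(expr))
            if res.loc[res["p_value"].idxmin(), "mirna_id"] == "m0":
                hits += 1
        assert hits >= 0.9 * n_rep
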