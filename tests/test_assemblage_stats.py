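"""Exact r×c test against closed-form and Monte-Carlo oracles; suite plumbing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from otolith_origin.assemblage_stats import (
    bonferroni,
    build_contingency,
    fisher_exact_rxc,
    harmonize_external_prey,
    run_comparison_suite,
)
from otolith_origin.errors import ComparisonError


class TestFisherExact:
    def test_worked_2x2_diagonal(self):
        # margins (2,2)/(2,2): three tables, the observed one has p=1/6,
        # the anti-diagonal 1/6, the mixed table 2/3 -> two-sided p = 1/3
        r = fisher_exact_rxc([[2, 0], [0, 2]])
        assert r.p_value == pytest.approx(1 / 3, abs=1e-12)
        assert r.method == "enumeration"
        assert r.n_tables_or_reps == 3

    def test_single_row_is_degenerate(self):
        r = fisher_exact_rxc([[3, 4, 5]])
        assert r.p_value == 1.0
        assert r.method == "degenerate"

    def test_matches_classical_2x2_hypergeometric(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        checked = 0
        while checked < 1000:
            t = rng.integers(0, 12, (2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            ours = fisher_exact_rxc(t).p_value
            scipy_p = fisher_exact(t).pvalue
            worst = max(worst, abs(ours - scipy_p))
            checked += 1
        assert worst < 1e-12

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_enumeration_and_monte_carlo_agree(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 5, (3, 4))
        t[0, 0] += 2  # avoid empty tables
        reps = 30_000
        e = fisher_exact_rxc(t, method="enumeration")
        m = fisher_exact_rxc(t, method="monte_carlo", seed=seed * 7, n_reps=reps)
        se = np.sqrt(max(e.p_value * (1 - e.p_value), 1e-6) / reps)
        assert abs(e.p_value - m.p_value) <= 3 * se

    def test_invariant_to_row_and_column_permutations(self):
        t = np.array([[3, 1, 4], [2, 5, 0], [1, 1, 6]])
        p0 = fisher_exact_rxc(t).p_value
        for rp in itertools.permutations(range(3)):
            for cp in itertools.permutations(range(3)):
                assert fisher_exact_rxc(t[list(rp)][:, list(cp)]).p_value == (
                    pytest.approx(p0, rel=1e-9)
                )

    def test_monte_carlo_requires_seed(self):
        with pytest.raises(ComparisonError):
            fisher_exact_rxc([[5, 1], [1, 5]], method="monte_carlo", seed=None)

    def test_p_value_never_exceeds_one_nor_zero(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            t = rng.integers(0, 8, (2, 3))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            p = fisher_exact_rxc(t).p_value
            assert 0 < p <= 1


class TestBonferroni:
    def test_formula(self):
        assert bonferroni(0.05, 10) == pytest.approx(0.005)
        assert bonferroni(0.05, 1) == pytest.approx(0.05)

    def test_zero_tests_rejected(self):
        with pytest.raises(ComparisonError):
            bonferroni(0.05, 0)

    def test_adjusted_never_exceeds_nominal(self):
        for n in range(1, 30):
            assert bonferroni(0.05, n) <= 0.05


def _assign(groups_cats):
    rows = []
    for i, (g, cat) in enumerate(groups_cats):
        rows.append(dict(fish_id=f"f{i}", group=g, refined=cat))
    return pd.DataFrame(rows)


class TestBuildContingency:
    def test_small_groups_removed(self):
        df = _assign([("A", "x")] * 4 + [("B", "x")] * 6 + [("C", "y")] * 6)
        ct = build_contingency(df, "group")
        assert ct.row_labels == ("B", "C")

    def test_identical_vectors_give_valid_table(self):
        df = _assign([("A", "x")] * 5 + [("A", "y")] * 5
                     + [("B", "x")] * 5 + [("B", "y")] * 5)
        ct = build_contingency(df, "group")
        assert ct.counts.tolist() == [[5, 5], [5, 5]]

    def test_empty_category_column_pruned(self):
        df = _assign([("A", "x")] * 5 + [("B", "x")] * 5)
        ct = build_contingency(df, "group")
        assert ct.col_labels == ("x",)

    def test_single_surviving_group_skips(self):
        df = _assign([("A", "x")] * 5 + [("B", "x")] * 3)
        assert build_contingency(df, "group") is None


class TestHarmonization:
    def _ext(self):
        return pd.DataFrame({
            "fish_id": ["e1", "e2", "e3"],
            "family": "Leuciscidae",
            "refined": ["Upper Iowa or Wisconsin", "MN", "unclassifiable_above"],
            "coarse": ["tributary", "tributary", "unclassifiable_above"],
        })

    def test_label_remapping(self):
        out, counts = harmonize_external_prey(
            self._ext(),
            {"Upper Iowa or Wisconsin": "small tributary or Wisconsin River"},
        )
        assert out["refined"].iloc[0] == "small tributary or Wisconsin River"

    def test_out_of_limits_records_dropped(self):
        out, counts = harmonize_external_prey(self._ext())
        assert counts["removed_out_of_limits"] == 1
        assert "unclassifiable_above" not in set(out["coarse"])

    def test_identity_map_keeps_labels(self):
        out, _ = harmonize_external_prey(self._ext(), {}, drop_out_of_limits=False)
        assert out["refined"].tolist() == self._ext()["refined"].tolist()

    def test_strict_mode_reports_unmapped(self):
        with pytest.raises(ComparisonError):
            harmonize_external_prey(self._ext(), {"MN": "MN"}, strict=True)


def _suite_frame(rng, n_per_group=30, p=None, species=("bass", "bowfin")):
    p = p or {"UMR": 0.5, "MN": 0.3, "TRIB": 0.2}
    cats, probs = list(p), np.array(list(p.values()))
    rows = []
    i = 0
    for sp in species:
        for pool in ("P4", "P8"):
            for _ in range(n_per_group):
                rows.append(dict(
                    fish_id=f"f{i}", species=sp, family="Centrarchidae",
                    role="predator", source="sampled", pool=pool,
                    year=2019 + (i % 2),
                    coarse="tributary",
                    refined=cats[rng.choice(len(cats), p=probs)],
                    excluded_vaterite=False, error="",
                ))
                i += 1
    return pd.DataFrame(rows)


class TestComparisonSuite:
    def test_deterministic_given_seed(self):
        df = _suite_frame(np.random.default_rng(1))
        a = run_comparison_suite(df, seed=5)
        b = run_comparison_suite(df, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_alpha_adjusts_by_executed_tests_only(self):
        df = _suite_frame(np.random.default_rng(2))
        # starve one pool of one species so its comparisons skip
        df = df[~((df.species == "bowfin") & (df.pool == "P8"))].reset_index(drop=True)
        out = run_comparison_suite(df, seed=1)
        run = out[~out.skipped]
        n_run = len(run)
        assert run["alpha_adjusted"].unique().tolist() == [
            pytest.approx(0.05 / n_run)
        ]

    def test_skips_reported_not_dropped(self):
        df = _suite_frame(np.random.default_rng(3), n_per_group=3)
        out = run_comparison_suite(df, seed=1)
        assert out["skipped"].all()
        assert (out.loc[out.skipped, "reason"] != "").all()

    def test_null_groups_rarely_significant(self):
        rng = np.random.default_rng(7)
        rejections = 0
        trials = 40
        for _ in range(trials):
            df = _suite_frame(rng, n_per_group=25, species=("bass", "bowfin"))
            out = run_comparison_suite(df, alpha=0.05, seed=int(rng.integers(2**31)))
            run = out[~out.skipped]
            rejections += int((run["p_value"] < 0.05).any())
        assert rejections <= trials * 0.5  # family-wise, far below under the null
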