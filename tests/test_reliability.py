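"""Transition tables, agreement, weighted kappa, bootstrap CI, imbalance."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from delphiscales import (
    TransitionTable,
    UndefinedStatisticError,
    class_imbalance,
    interpret_kappa,
    kappa_ci,
    percent_agreement,
    percent_changes,
    quadratic_weights,
    reliability_report,
    simulate_panel,
    transition_table,
    weighted_kappa,
)

from conftest import make_panel, single_goal_config

THREE = ("NONE", "SECONDARY", "MAIN")

# frozen with an exact-fraction direct-formula oracle: kappa = 4148/5801
EXAMPLE_COUNTS = np.array([[50, 4, 1], [6, 18, 2], [0, 3, 3]])
EXAMPLE_KAPPA = 4148 / 5801


def table(counts, categories=THREE):
    return TransitionTable(categories=categories, counts=np.asarray(counts))


class TestTransitionTable:
    def test_two_participants_one_goal(self, tiny_three_panel):
        t = transition_table(tiny_three_panel, "three_point", goal="pain")
        # rows/cols in scale order no goal < secondary goal < main goal
        assert t.categories == ("no goal", "secondary goal", "main goal")
        expected = np.zeros((3, 3), dtype=int)
        expected[2, 2] = 1  # main -> main
        expected[2, 1] = 1  # main -> secondary
        assert (t.counts == expected).all()
        assert t.n == 2

    def test_overall_pools_participants_times_goals(self):
        cfg = single_goal_config(n=87)
        cfg = type(cfg)(**{**cfg.__dict__, "goal_effects": {f"g{i}": 0.0 for i in range(19)}})
        panel = simulate_panel(cfg)
        t = transition_table(panel, "three_point")
        assert t.n == 87 * 19

    def test_transformed_slice_collapses_to_three_levels(self):
        panel = simulate_panel(single_goal_config(n=30, seed=4))
        t9 = transition_table(panel, "nine_point", transformed=True)
        assert t9.K == 3
        assert t9.categories == THREE
        assert t9.n == 30

    def test_matches_brute_force_pairing(self):
        panel = simulate_panel(single_goal_config(n=25, seed=8))
        t = transition_table(panel, "nine_point")
        seen = {}
        for rec in panel.records():
            if rec.scale_id == "nine_point":
                seen.setdefault((rec.participant_id, rec.goal_id), {})[rec.round] = rec.rating
        brute = np.zeros((9, 9), dtype=int)
        for pair in seen.values():
            brute[int(pair[1]) - 1, int(pair[2]) - 1] += 1
        assert (t.counts == brute).all()

    def test_unpaired_records_are_excluded(self):
        rows = [
            ("p1", 1, "pain", "three_point", "main goal"),
            ("p1", 2, "pain", "three_point", "main goal"),
            ("p2", 1, "pain", "three_point", "no goal"),  # no round 2
        ]
        t = transition_table(make_panel(rows, goals=["pain"]), "three_point")
        assert t.n == 1
        assert t.excluded == 1

    def test_fully_unpaired_slice_is_an_error(self):
        rows = [("p1", 1, "pain", "three_point", "main goal")]
        with pytest.raises(UndefinedStatisticError, match="no paired"):
            transition_table(make_panel(rows, goals=["pain"]), "three_point")


class TestAgreement:
    def test_diagonal_table_is_full_agreement(self):
        assert percent_agreement(table(np.diag([5, 3, 2]))) == 100.0
        assert percent_changes(table(np.diag([5, 3, 2]))) == 0.0

    def test_example_table_arithmetic(self):
        t = table(EXAMPLE_COUNTS)
        assert t.n == 87
        assert percent_agreement(t) == pytest.approx(100 * 71 / 87)
        assert percent_changes(t) == pytest.approx(100 * 16 / 87)

    def test_off_diagonal_only_table(self):
        assert percent_changes(table([[0, 5, 0], [0, 0, 5], [0, 0, 0]])) == 100.0

    @given(
        counts=st.lists(
            st.lists(st.integers(min_value=0, max_value=20), min_size=3, max_size=3),
            min_size=3,
            max_size=3,
        ).filter(lambda c: sum(map(sum, c)) > 0)
    )
    def test_agreement_and_changes_are_exact_complements(self, counts):
        t = table(counts)
        assert percent_agreement(t) + percent_changes(t) == pytest.approx(100.0, abs=1e-12)


class TestQuadraticWeights:
    @pytest.mark.parametrize(
        "K,i,j,expected",
        [(3, 0, 2, 1.0), (3, 0, 1, 0.25), (3, 1, 1, 0.0), (9, 3, 5, 0.0625), (9, 0, 8, 1.0)],
    )
    def test_weight_values(self, K, i, j, expected):
        assert quadratic_weights(K)[i, j] == expected

    def test_rejects_degenerate_category_count(self):
        with pytest.raises(ValueError, match="K=1"):
            quadratic_weights(1)


class TestWeightedKappa:
    def test_perfect_agreement_is_one(self):
        assert weighted_kappa(table(np.diag([10, 5, 7]))) == 1.0

    def test_example_table_matches_frozen_oracle_value(self):
        assert weighted_kappa(table(EXAMPLE_COUNTS)) == pytest.approx(EXAMPLE_KAPPA, abs=1e-12)

    def test_statistical_independence_is_zero(self):
        # rows proportional to the column marginals: p = outer((.5,.25,.25))
        counts = np.array([[16, 8, 8], [8, 4, 4], [8, 4, 4]])
        assert weighted_kappa(table(counts)) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_single_category_returns_one_by_convention(self):
        t = table([[7, 0, 0], [0, 0, 0], [0, 0, 0]])
        assert weighted_kappa(t) == 1.0

    def test_single_pair_rejected(self):
        t = table([[0, 0, 0], [0, 1, 0], [0, 0, 0]])
        with pytest.raises(UndefinedStatisticError, match="at least 2"):
            weighted_kappa(t)

    def test_cross_checked_against_sklearn_on_random_tables(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        for K in (3, 5, 9):
            for _ in range(20):
                counts = rng.integers(0, 12, size=(K, K))
                y1 = np.repeat(np.arange(K * K) // K, counts.ravel())
                y2 = np.repeat(np.arange(K * K) % K, counts.ravel())
                if len(np.unique(y1)) < 2 or len(np.unique(y2)) < 2:
                    continue
                ours = weighted_kappa(table(counts, categories=tuple(map(str, range(K)))))
                theirs = sk.cohen_kappa_score(y1, y2, labels=np.arange(K), weights="quadratic")
                assert ours == pytest.approx(theirs, abs=1e-10)


class TestKappaCI:
    def test_identity_panel_gives_degenerate_interval_at_one(self):
        rows = []
        ratings = ["main goal", "secondary goal", "no goal"]
        for i in range(12):
            for r in (1, 2):
                rows.append((f"p{i}", r, "pain", "three_point", ratings[i % 3]))
        panel = make_panel(rows, goals=["pain"])
        assert kappa_ci(panel, "three_point", B=200, seed=0) == (1.0, 1.0)

    def test_same_seed_same_interval(self):
        panel = simulate_panel(single_goal_config(n=60, seed=13))
        a = kappa_ci(panel, "three_point", B=300, seed=42)
        b = kappa_ci(panel, "three_point", B=300, seed=42)
        assert a == b
        c = kappa_ci(panel, "three_point", B=300, seed=43)
        assert a != c

    def test_interval_brackets_the_point_estimate(self):
        panel = simulate_panel(single_goal_config(n=200, seed=1))
        lo, hi = kappa_ci(panel, "three_point", B=500, seed=7)
        k = weighted_kappa(transition_table(panel, "three_point"))
        assert lo <= k <= hi

    def test_too_few_replicates_rejected(self, tiny_three_panel):
        with pytest.raises(ValueError, match="B="):
            kappa_ci(tiny_three_panel, "three_point", B=50)


class TestClassImbalance:
    def test_seventy_nine_eleven_ten(self):
        rows = []
        for i in range(100):
            rating = "main goal" if i < 79 else ("secondary goal" if i < 90 else "no goal")
            rows.append((f"p{i}", 1, "pain", "three_point", rating))
        panel = make_panel(rows, goals=["pain"])
        assert class_imbalance(panel, "three_point", 1) == pytest.approx(79.0)

    def test_uniform_three_categories(self):
        rows = [
            (f"p{i}", 1, "pain", "three_point", r)
            for i, r in enumerate(["main goal", "secondary goal", "no goal"] * 4)
        ]
        panel = make_panel(rows, goals=["pain"])
        assert class_imbalance(panel, "three_point", 1) == pytest.approx(100 / 3)

    def test_single_category_is_hundred(self):
        rows = [(f"p{i}", 1, "pain", "nine_point", "9") for i in range(5)]
        assert class_imbalance(make_panel(rows, goals=["pain"]), "nine_point", 1) == 100.0

    def test_transformed_pools_the_top_band(self):
        rows = [
            ("p1", 1, "pain", "nine_point", "9"),
            ("p2", 1, "pain", "nine_point", "8"),
            ("p3", 1, "pain", "nine_point", "7"),
            ("p4", 1, "pain", "nine_point", "2"),
        ]
        panel = make_panel(rows, goals=["pain"])
        assert class_imbalance(panel, "nine_point", 1) == pytest.approx(25.0)
        assert class_imbalance(panel, "nine_point", 1, transformed=True) == pytest.approx(75.0)


class TestInterpretKappa:
    @pytest.mark.parametrize(
        "k,label",
        [
            (0.63, "substantial"),
            (0.47, "moderate"),
            (0.78, "substantial"),
            (-0.1, "poor"),
            (0.0, "slight"),
            (0.20, "slight"),
            (0.40, "fair"),
            (0.60, "moderate"),
            (0.80, "substantial"),
            (0.81, "almost perfect"),
            (1.0, "almost perfect"),
        ],
    )
    def test_band_labels(self, k, label):
        assert interpret_kappa(k) == label


class TestReliabilityReport:
    def test_degenerate_config_all_perfect(self):
        cfg = single_goal_config(rho=1.0, tau=(0.0, 0.0, 0.0), n=40, seed=2)
        report = reliability_report(simulate_panel(cfg), B=150, seed=0)
        assert set(report.variants) == {
            "three_point", "five_point", "nine_point", "five_point*", "nine_point*"
        }
        assert (report.overall.loc["agreement_pct"] == 100.0).all()
        assert (report.overall.loc["changes_pct"] == 0.0).all()
        assert (report.overall.loc["weighted_kappa"] == 1.0).all()

    def test_per_goal_values_lie_inside_summary_range(self):
        cfg = single_goal_config(n=50, seed=6)
        cfg = type(cfg)(**{**cfg.__dict__, "goal_effects": {"pain": 0.3, "strength": -0.4, "sex_life": -1.2}})
        report = reliability_report(simulate_panel(cfg), B=150, seed=0)
        for metric in ("agreement_pct", "changes_pct", "weighted_kappa"):
            pg = report.per_goal[metric]
            lo = report.summary.loc[f"{metric}_min"]
            hi = report.summary.loc[f"{metric}_max"]
            assert ((pg >= lo) & (pg <= hi) | pg.isna()).all().all()

    def test_coarsening_never_increases_changes_single_panel(self):
        panel = simulate_panel(single_goal_config(n=80, seed=10))
        for sid in ("five_point", "nine_point"):
            raw = percent_changes(transition_table(panel, sid))
            coarse = percent_changes(transition_table(panel, sid, transformed=True))
            assert coarse <= raw + 1e-12

    def test_same_seed_reproduces_the_report(self):
        panel = simulate_panel(single_goal_config(n=40, seed=5))
        r1 = reliability_report(panel, B=150, seed=9)
        r2 = reliability_report(panel, B=150, seed=9)
        assert r1.overall.equals(r2.overall)
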