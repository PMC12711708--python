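import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lesionctx import audit as au
from lesionctx import phantoms as ph


def brute_force_tau_b(x, y):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    n = len(x)
    nc = nd = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                nc += 1
            else:
                nd += 1
    n0 = n * (n - 1) / 2
    return (nc - nd) / math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))


def _tie_term(v):
    _, counts = np.unique(v, return_counts=True)
    return sum(c * (c - 1) / 2 for c in counts)


def brute_force_violation_rate(x, y, direction):
    ux = np.unique(x)
    if len(ux) < 2:
        return 0.0
    means = [np.mean([yy for xx, yy in zip(x, y) if xx == v]) for v in ux]
    viol = sum(
        1 for a, b in zip(means, means[1:]) if (b - a) * direction < 0
    )
    return viol / (len(ux) - 1)


class TestKendallTau:
    def test_perfect_agreement_and_reversal(self):
        tau, _, und = au.kendall_tau(np.array([1, 2, 3]), np.array([1, 2, 3]), B=10)
        assert tau == 1.0 and not und
        tau, _, _ = au.kendall_tau(np.array([1, 2, 3]), np.array([3, 2, 1]), B=10)
        assert tau == -1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_pair_counting_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 10, 80).astype(float)
        y = rng.integers(0, 10, 80).astype(float)
        tau, _, _ = au.kendall_tau(x, y, B=0)
        assert tau == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)

    def test_all_tied_flagged_undefined(self):
        tau, _, und = au.kendall_tau(np.ones(10), np.arange(10.0), B=10)
        assert und and math.isnan(tau)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        y = x + rng.normal(scale=0.8, size=100)
        tau, (lo, hi), _ = au.kendall_tau(x, y, B=300, seed=2)
        assert lo <= tau <= hi

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            au.kendall_tau(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestIsotonicViolationRate:
    def test_monotone_extremes(self):
        x = np.arange(20.0)
        y = np.sqrt(x)
        assert au.isotonic_violation_rate(x, y, +1) == 0.0
        assert au.isotonic_violation_rate(x, y, -1) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 15, 60).astype(float)
        y = x * 0.5 + rng.normal(size=60)
        for d in (+1, -1):
            assert au.isotonic_violation_rate(x, y, d) == pytest.approx(
                brute_force_violation_rate(x, y, d), abs=1e-12
            )

    def test_exact_zero_change_not_a_violation(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([5.0, 5.0, 6.0])
        assert au.isotonic_violation_rate(x, y, +1) == 0.0

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError):
            au.isotonic_violation_rate(np.arange(5.0), np.arange(5.0), 0)


class TestHolm:
    def test_single_p_unchanged(self):
        assert au.holm_adjust([0.03]) == pytest.approx([0.03])

    def test_two_p_step_down(self):
        assert au.holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_all_ones(self):
        assert au.holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_never_decreases_and_preserves_order(self, ps):
        p = np.asarray(ps)
        adj = au.holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            au.holm_adjust([0.5, 1.5])


class TestSubgroupInvariance:
    def _table(self, beta_by_group, n=200, seed=0, noise=0.5):
        rng = np.random.default_rng(seed)
        rows = []
        for g, beta in beta_by_group.items():
            x = rng.normal(size=n)
            eta = 0.2 + beta * x + rng.normal(scale=noise, size=n)
            rows.append(
                pd.DataFrame(
                    {
                        "min_pleura_distance_mm": x,
                        "risk_pneumothorax": 1 / (1 + np.exp(-eta)),
                        "sex": g,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_null_is_stable(self):
        t = self._table({"M": -0.8, "F": -0.8}, seed=3)
        res = au.subgroup_invariance(
            t, [("min_pleura_distance_mm", "pneumothorax", -1)], stratifiers=("sex",)
        )
        assert len(res) == 1
        r = res[0]
        assert r.direction_stable
        assert r.holm_p > 0.05
        assert r.max_abs_delta_beta < 0.2

    def test_planted_interaction_detected(self):
        t = self._table({"M": -0.3, "F": -1.3}, seed=4)
        r = au.subgroup_invariance(
            t, [("min_pleura_distance_mm", "pneumothorax", -1)], stratifiers=("sex",)
        )[0]
        assert r.holm_p < 0.05
        assert r.max_abs_delta_beta > 0.5

    def test_single_subgroup_delta_zero(self):
        t = self._table({"M": -0.8}, seed=5)
        r = au.subgroup_invariance(
            t, [("min_pleura_distance_mm", "pneumothorax", -1)], stratifiers=("sex",)
        )[0]
        assert r.max_abs_delta_beta == 0.0

    def test_small_subgroups_skipped(self):
        t = self._table({"M": -0.8, "F": -0.8}, n=3, seed=6)
        r = au.subgroup_invariance(
            t, [("min_pleura_distance_mm", "pneumothorax", -1)], stratifiers=("sex",)
        )[0]
        assert set(r.skipped_subgroups) == {"M", "F"}


class TestICC:
    def test_identical_raters_give_one(self):
        col = np.arange(10.0)
        icc, _ = au.icc_two_way_random(np.column_stack([col, col, col]))
        assert icc == pytest.approx(1.0)

    def test_matches_mean_squares_oracle_3x6(self):
        rng = np.random.default_rng(7)
        R = rng.normal(size=(6, 3)) + rng.normal(scale=2.0, size=(6, 1))
        icc, _ = au.icc_two_way_random(R)
        n, k = R.shape
        grand = R.mean()
        msr = k * ((R.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((R.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (((R - R.mean(1, keepdims=True) - R.mean(0, keepdims=True) + grand) ** 2).sum()
               / ((n - 1) * (k - 1)))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        R = rng.normal(0, 1, (10, 4)) + rng.normal(0, 2, (10, 1))
        icc, ci = au.icc_two_way_random(R)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 4),
                "rater": np.tile(np.arange(4), 10),
                "score": R.ravel(),
            }
        )
        res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        row = res[res["Type"] == "ICC(A,1)"].iloc[0]
        assert icc == pytest.approx(float(row["ICC"]), abs=1e-9)
        assert ci == pytest.approx(tuple(row["CI95"]), abs=0.01)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(11)
        icc, _ = au.icc_two_way_random(rng.normal(size=(100, 3)))
        assert -0.2 <= icc <= 0.2

    def test_missing_cells_rejected(self):
        R = np.ones((5, 3))
        R[0, 0] = np.nan
        with pytest.raises(ValueError):
            au.icc_two_way_random(R)
        with pytest.raises(ValueError):
            au.icc_two_way_random(np.ones((2, 3)))


class _ConstantModel:
    def predict(self, vol):
        return {r: 0.42 for r in ph.RISK_NAMES}


@pytest.fixture(scope="module")
def edit_cohort():
    ranges = ph.SpecRanges(
        tumor_radius_mm=(7.5, 9.0), pleura_distance_mm=(1.0, 5.0), vessel_distance_mm=(4.0, 7.0)
    )
    return ph.sample_cohort(16, ranges=ranges, seed=31)


class TestCounterfactualSensitivity:
    def test_surrogate_fully_consistent(self, edit_cohort):
        model = edit_cohort.model()
        res = au.counterfactual_sensitivity(
            model, edit_cohort.cases, "pleura_distance", "pneumothorax", -1, {"delta_mm": 5.0}
        )
        assert res.direction_consistency == 100.0
        assert res.mean_delta_risk < 0

    def test_constant_model_all_zero_deltas(self, edit_cohort):
        res = au.counterfactual_sensitivity(
            _ConstantModel(), edit_cohort.cases, "pleura_distance", "pneumothorax", -1,
            {"delta_mm": 5.0},
        )
        assert res.direction_consistency == 0.0
        assert res.mean_delta_risk == 0.0

    def test_zero_valid_edits_rejected(self, juxtapleural_phantom):
        class Case:
            volume = juxtapleural_phantom

        with pytest.raises(ValueError, match="zero valid"):
            au.counterfactual_sensitivity(
                _ConstantModel(), [Case()], "vessel_proximity", "hemorrhage", +1,
                {"delta_mm": -30.0},
            )


class TestRunAudit:
    def test_planted_signs_recovered(self, small_cohort):
        report = au.run_audit(
            small_cohort.model(), small_cohort, edit_cases=12, use_model_risks=False, B=100, seed=0
        )
        for m in report.monotonicity:
            assert m.direction_consistent
            assert m.violation_rate < 0.05
        for c in report.counterfactual:
            assert c.direction_consistency == 100.0

    def test_report_round_trips_serialization(self, small_cohort):
        report = au.run_audit(
            small_cohort.model(), small_cohort, edit_cases=6, use_model_risks=False, B=50, seed=0
        )
        back = au.AuditReport.from_dict(report.to_dict())
        assert back.to_json() == report.to_json()

    def test_shuffled_risks_kill_association(self, small_cohort):
        rng = np.random.default_rng(0)
        t = small_cohort.table
        x = t["min_pleura_distance_mm"].to_numpy()
        taus = []
        for _ in range(20):
            y = rng.permutation(t["risk_pneumothorax"].to_numpy())
            tau, _, _ = au.kendall_tau(x, y, B=0)
            taus.append(abs(tau))
        assert np.mean(taus) < 0.15
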