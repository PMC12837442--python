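"""Step pairing and the agreement statistics toolbox."""
import numpy as np
import pytest
from scipy import stats

from gaitdp.agreement import (
    PairedSteps,
    absolute_error,
    agreement_report,
    bland_altman,
    correlation_regression,
    group_report,
    mdae_iqr,
    nonparametric_tests,
    pair_steps,
    percent_error,
)


def _pairs(est, ref, **kw):
    return PairedSteps(est=np.asarray(est, float), ref=np.asarray(ref, float), **kw)


class TestPairing:
    def test_identical_timestamps_all_matched(self):
        t = np.arange(10) * 0.55
        L = np.full(10, 0.6)
        p = pair_steps(t, L, t, L)
        assert p.n == 10 and p.n_unmatched_est == 0 and p.n_unmatched_ref == 0

    def test_global_shift_absorbed_by_first_contact_alignment(self):
        t = np.arange(10) * 0.55
        L = np.linspace(0.5, 0.7, 10)
        p = pair_steps(t + 0.05, L, t, L, align="first_contact")
        assert p.n == 10
        np.testing.assert_array_equal(p.est, p.ref)

    def test_spurious_step_unmatched(self):
        t_ref = np.array([0.0, 0.55, 1.10])
        t_est = np.array([0.0, 0.27, 0.55, 1.10])  # extra step between two true ones
        p = pair_steps(t_est, np.full(4, 0.6), t_ref, np.full(3, 0.6), tol=0.1)
        assert p.n == 3 and p.n_unmatched_est == 1

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            pair_steps(np.array([]), np.array([]), np.array([0.0]), np.array([0.6]))

    def test_shared_clock_mode(self):
        # est running 0.4 s late on a 0.5 s grid: without re-alignment each
        # estimate matches the *next* reference step, not its own
        t = np.arange(6) * 0.5
        p = pair_steps(t + 0.4, np.full(6, 0.6), t, np.full(6, 0.6), tol=0.25, align="none")
        assert np.all(p.ref_idx == p.est_idx + 1)


class TestErrors:
    def test_absolute_error_examples(self):
        assert absolute_error(0.60, 0.60) == 0.0
        assert absolute_error(0.60, 0.55) == pytest.approx(0.05)

    def test_mdae_by_enumeration(self):
        mdae, lo, hi = mdae_iqr(np.array([0.01, 0.03, 0.05]))
        assert mdae == pytest.approx(0.03)
        assert lo <= mdae <= hi

    def test_percent_error_examples(self):
        assert percent_error(1.00, 1.05) == pytest.approx(5.0)
        assert percent_error(0.7, 0.7) == 0.0
        assert percent_error(0.50, 0.45) == pytest.approx(-10.0)

    def test_percent_error_zero_reference(self):
        with pytest.raises(ZeroDivisionError):
            percent_error(np.array([0.0]), np.array([0.5]))


class TestBlandAltman:
    def test_identical_arrays(self):
        bias, ci, loa = bland_altman(_pairs([0.6, 0.62, 0.58], [0.6, 0.62, 0.58]))
        assert bias == 0.0 and loa == (0.0, 0.0)

    def test_hand_computed_two_sided(self):
        # differences +0.01 and -0.01 (padded with zeros for n >= 3):
        # recompute by hand on exactly the two-point example
        d = np.array([0.01, -0.01])
        sd = d.std(ddof=1)
        assert sd == pytest.approx(0.0141421356, abs=1e-9)
        p = _pairs([0.61, 0.59, 0.60], [0.60, 0.60, 0.60])
        bias, ci, loa = bland_altman(p)
        assert bias == pytest.approx(0.0, abs=1e-12)
        assert loa[1] == pytest.approx(1.96 * np.std([0.01, -0.01, 0.0], ddof=1), abs=1e-12)

    def test_constant_offset(self):
        p = _pairs([0.62, 0.62, 0.62], [0.60, 0.60, 0.60])
        bias, ci, loa = bland_altman(p)
        assert bias == pytest.approx(0.02)
        assert loa[1] - loa[0] == pytest.approx(0.0, abs=1e-12)

    def test_bias_equals_mean_difference(self):
        rng = np.random.default_rng(0)
        est = rng.uniform(0.4, 0.8, 100)
        ref = rng.uniform(0.4, 0.8, 100)
        bias, _, _ = bland_altman(_pairs(est, ref))
        assert bias == pytest.approx(est.mean() - ref.mean(), abs=1e-15)

    def test_loa_coverage_large_normal_sample(self):
        rng = np.random.default_rng(42)
        ref = np.full(10_000, 0.6)
        est = ref + rng.normal(0, 0.02, ref.size)
        bias, _, loa = bland_altman(_pairs(est, ref))
        d = est - ref
        frac = np.mean((d >= loa[0]) & (d <= loa[1]))
        assert frac >= 0.93

    def test_insufficient_pairs(self):
        with pytest.raises(ValueError):
            bland_altman(_pairs([0.6], [0.6]))


class TestCorrelation:
    def test_perfect_agreement(self):
        ref = np.linspace(0.4, 0.8, 20)
        r, r2, slope, intercept = correlation_regression(_pairs(ref, ref))
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_doubling_slope(self):
        ref = np.linspace(0.4, 0.8, 20)
        r, r2, slope, _ = correlation_regression(_pairs(2 * ref, ref))
        assert r == pytest.approx(1.0) and slope == pytest.approx(2.0)

    def test_anticorrelation(self):
        ref = np.linspace(0.4, 0.8, 20)
        r, *_ = correlation_regression(_pairs(-ref + 1.0, ref))
        assert r == pytest.approx(-1.0)

    def test_r2_identity(self):
        rng = np.random.default_rng(1)
        ref = np.linspace(0.4, 0.8, 50)
        est = ref + rng.normal(0, 0.05, 50)
        r, r2, *_ = correlation_regression(_pairs(est, ref))
        assert r2 == pytest.approx(r * r, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_regression(_pairs(np.ones(5), np.ones(5)))


class TestNonparametric:
    def test_all_zero_differences_flagged(self):
        p = _pairs(np.full(10, 0.6), np.full(10, 0.6))
        with pytest.warns(UserWarning, match="degenerate"):
            out = nonparametric_tests(p)
        assert np.isnan(out["wilcoxon_p"])

    def test_normal_errors_pass_shapiro(self):
        # errors drawn from a normal distribution: Shapiro should accept
        # normality in the vast majority of replicates
        rng = np.random.default_rng(2024)
        accept = 0
        for _ in range(50):
            ref = np.full(200, 0.6)
            est = ref + rng.normal(0, 0.02, 200)
            out = nonparametric_tests(_pairs(est, ref))
            accept += out["shapiro_p"] > 0.05
        assert accept >= 45

    def test_heavy_tailed_errors_fail_shapiro(self):
        rng = np.random.default_rng(7)
        reject = 0
        for _ in range(50):
            ref = np.full(200, 0.6)
            mix = np.where(rng.uniform(size=200) < 0.15, rng.normal(0, 0.2, 200), rng.normal(0, 0.01, 200))
            out = nonparametric_tests(_pairs(ref + mix, ref))
            reject += out["shapiro_p"] < 0.05
        assert reject >= 45

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            nonparametric_tests(_pairs(np.ones(5) * 0.6, np.ones(5) * 0.61))


class TestGroupReport:
    def test_single_subject_grand_median(self):
        p = _pairs([0.6, 0.64, 0.58], [0.62, 0.60, 0.60], subject_id="S0",
                   side=np.array(["left", "left", "left"]))
        df = group_report([p])
        grand = df[df.subject_id == "Grand Median"]
        subj = df[df.subject_id == "S0"]
        assert grand["mdae"].iloc[0] == pytest.approx(subj["mdae"].iloc[0])

    def test_grand_median_of_subject_medians(self):
        subjects = []
        for sid, err in zip("ABC", (0.02, 0.03, 0.04)):
            ref = np.full(9, 0.6)
            subjects.append(
                _pairs(ref + err, ref, subject_id=sid, side=np.array(["left"] * 9))
            )
        df = group_report(subjects)
        grand = df[(df.subject_id == "Grand Median") & (df.side == "left")]
        assert grand["mdae"].iloc[0] == pytest.approx(0.03)

    def test_invariant_to_subject_order(self):
        rng = np.random.default_rng(3)
        subjects = []
        for sid in "ABCD":
            ref = rng.uniform(0.5, 0.7, 12)
            est = ref + rng.normal(0, 0.03, 12)
            side = np.array(["left", "right"] * 6)
            subjects.append(_pairs(est, ref, subject_id=sid, side=side))
        a = group_report(subjects)
        b = group_report(subjects[::-1])
        ga = a[a.subject_id == "Grand Median"].sort_values("side")["mdae"].to_numpy()
        gb = b[b.subject_id == "Grand Median"].sort_values("side")["mdae"].to_numpy()
        np.testing.assert_allclose(ga, gb)


def test_full_report_fields_consistent():
    rng = np.random.default_rng(9)
    ref = rng.uniform(0.5, 0.7, 60)
    est = ref + rng.normal(0.005, 0.02, 60)
    rep = agreement_report(_pairs(est, ref))
    assert rep.loa_lo < rep.bias < rep.loa_hi
    assert -1 <= rep.r <= 1
    assert rep.r2 == pytest.approx(rep.r**2, abs=1e-12)
    assert rep.iqr_lo <= rep.mdae <= rep.iqr_hi
    assert rep.n == 60
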