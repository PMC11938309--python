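import numpy as np
import pandas as pd
import pytest

import survcea as sc
from survcea.synthetic_data import fp_power


def star_network(d0, d1, p, n_per_arm, n_trials=6, seed=0, eps=1.0,
                 rate=0.08, cutoff=30.0):
    """Multi-trial star network vs a shared chemotherapy-style reference;
    three treatments, two trials each."""
    frames = []
    children = np.random.SeedSequence(seed).spawn(n_trials)
    for i, child in enumerate(children):
        spec = sc.TrialSpec(
            f"t{i}", n_per_arm, ((0.0,), (rate,)), contrast_truth=(d0, d1, p),
            accrual_months=6.0, cutoff_months=cutoff, dropout_rate=0.01,
            seed=int(child.generate_state(1)[0] % 2**31),
            arms=("control", f"drug{i % 3}"), eps_floor=eps,
        )
        frames.append(sc.simulate_trial(spec))
    return pd.concat(frames, ignore_index=True)


RECOVERY_BREAKS = np.unique(
    np.concatenate([np.arange(0, 4.01, 0.25), np.arange(4.0, 31.0, 1.0)])
)


class TestIntervalCountsFromIPD:
    def test_hand_counts(self):
        ipd = pd.DataFrame(
            {"trial": "a", "arm": "x", "time": [1.0, 2.0, 3.0], "event": 1}
        )
        out = sc.interval_counts_from_ipd(ipd, [0, 2, 4])
        assert list(out["n_at_risk"]) == [3, 2]
        assert list(out["events"]) == [1, 2]

    def test_event_conservation(self, dropout_trial):
        _, ipd = dropout_trial
        out = sc.interval_counts_from_ipd(ipd, sc.default_breaks(ipd, cutoff=30))
        assert out["events"].sum() == ipd["event"].sum()
        assert out["censored"].sum() == (ipd["event"] == 0).sum()

    def test_interval_hazard_tracks_truth(self):
        """With fine breaks, r/(n*dt) approximates the constant hazard
        within 20% at n = 10,000."""
        spec = sc.TrialSpec(
            "h", 10000, ((0.0,), (0.1,)), accrual_months=0.0,
            cutoff_months=200.0, seed=14,
        )
        ipd = sc.simulate_trial(spec)
        ipd = ipd[ipd["arm"] == "control"]
        out = sc.interval_counts_from_ipd(ipd, np.arange(0.0, 15.0, 0.5))
        out = out[np.isfinite(out["end"]) & (out["n_at_risk"] > 500)]
        dt = out["end"] - out["start"]
        haz = out["events"] / (out["n_at_risk"] * dt)
        assert np.all(np.abs(haz - 0.1) / 0.1 < 0.2)


class TestIntervalCountsFromSurvival:
    def test_closed_form_expected_events(self):
        out = sc.interval_counts_from_survival(
            lambda t: np.exp(-0.1 * np.asarray(t)), 100, [0, 1]
        )
        assert out["events"][0] == pytest.approx(100 * (1 - np.exp(-0.1)), abs=1e-9)

    def test_at_risk_non_increasing(self):
        breaks = np.linspace(0, 24, 25)
        out = sc.interval_counts_from_survival(
            lambda t: np.exp(-0.08 * np.asarray(t) ** 1.2), 500, breaks,
            cutoff=20.0, accrual_months=8.0,
        )
        assert np.all(np.diff(out["n_at_risk"]) <= 1e-9)

    def test_constant_hazard_in_constant_interval_hazard_out(self):
        h = 0.05
        dt = 0.5
        breaks = np.arange(0.0, 12.1, dt)
        out = sc.interval_counts_from_survival(
            lambda t: np.exp(-h * np.asarray(t)), 1000, breaks
        )
        ivh = out["events"] / (out["n_at_risk"] * dt)
        # relative discretization error is bounded by ~dt*h/2
        assert np.all(np.abs(ivh - h) / h <= dt * h / 2 + 1e-9)

    def test_rising_survival_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            sc.interval_counts_from_survival(
                np.array([1.0, 0.8, 0.9]), 100, [0, 1, 2]
            )


class TestFitFP:
    def test_identical_arms_recover_null(self):
        spec = sc.TrialSpec(
            "null", 3000, ((0.0,), (0.1,)), contrast_truth=(0.0, 0.0, -2.0),
            cutoff_months=30.0, seed=3, arms=("control", "trt"),
        )
        ipd = sc.simulate_trial(spec)
        counts = sc.interval_counts_from_ipd(ipd, sc.default_breaks(ipd, cutoff=30))
        fit = sc.fit_fp1(counts, -2.0, reference="control")
        c = fit.contrasts[0]
        assert abs(c.d0) < 3 * c.d0_se
        assert abs(c.d1) < 3 * c.d1_se

    def test_loglik_improves_on_null(self):
        ipd = star_network(-0.6, 0.8, -2.0, 500, seed=9)
        counts = sc.interval_counts_from_ipd(ipd, RECOVERY_BREAKS)
        fit = sc.fit_fp1(counts, -2.0, reference="control", eps=1.0)
        assert fit.loglik >= fit.loglik_null

    def test_published_contrast_round_trip(self):
        """Expected counts generated from a toripalimab-style PFS contrast
        (d0 = -0.91, d1 = 2.76, p = -2) refit to d0 within 0.05."""
        d0, d1, p, eps = -0.91, 2.76, -2.0, 1.0
        breaks = RECOVERY_BREAKS
        tgrid = np.linspace(0, breaks[-1], 60001)
        h_trt = 0.08 * np.exp(d0 + d1 * fp_power(tgrid, p, eps=eps))
        H = np.concatenate(
            [[0.0], np.cumsum(0.5 * (h_trt[1:] + h_trt[:-1]) * np.diff(tgrid))]
        )
        counts = pd.concat(
            [
                sc.interval_counts_from_survival(
                    lambda t: np.exp(-0.08 * np.asarray(t)), 1e5, breaks,
                    trial="t", arm="control",
                ),
                sc.interval_counts_from_survival(
                    lambda t: np.exp(-np.interp(t, tgrid, H)), 1e5, breaks,
                    trial="t", arm="toripalimab",
                ),
            ],
            ignore_index=True,
        )
        fit = sc.fit_fp1(counts, p, reference="control", eps=eps)
        assert fit.contrasts[0].d0 == pytest.approx(d0, abs=0.05)

    def test_armless_events_raise(self):
        counts = pd.DataFrame(
            {
                "trial": "t", "arm": ["control"] * 2 + ["drug"] * 2,
                "start": [0.0, 1.0] * 2, "end": [1.0, 2.0] * 2,
                "n_at_risk": [100.0, 90.0, 100.0, 100.0],
                "events": [10.0, 9.0, 0.0, 0.0],
                "censored": 0.0,
            }
        )
        with pytest.raises(sc.NMAError, match="no events"):
            sc.fit_fp1(counts, -2.0, reference="control")

    def test_order0_matches_cox(self, const_hazard_trial):
        """The order-0 (proportional hazards) special case agrees with the
        Cox partial-likelihood HR within 10% at n = 5000/arm."""
        _, ipd = const_hazard_trial
        counts = sc.interval_counts_from_ipd(ipd, sc.default_breaks(ipd, cutoff=30))
        fit = sc.fit_fp(counts, (), reference="control")
        hr_fp = np.exp(fit.contrasts[0].d0)
        hr_cox = sc.cox_hr(ipd, treatment_arm="treatment").hr_point
        assert abs(hr_fp - hr_cox) / hr_cox < 0.10


class TestScanPowers:
    @pytest.fixture(scope="class")
    def scan_counts(self):
        ipd = star_network(-0.6, 0.8, -2.0, 2000, n_trials=6, seed=17)
        return sc.interval_counts_from_ipd(ipd, RECOVERY_BREAKS)

    def test_true_power_ranked_first(self, scan_counts):
        selected, ranking = sc.scan_powers(
            scan_counts, power_grid=(-2.0, -1.0), reference="control", eps=1.0
        )
        assert selected.powers == (-2.0,)

    def test_single_cell_grid(self, scan_counts):
        selected, ranking = sc.scan_powers(
            scan_counts, power_grid=(1.0,), reference="control"
        )
        assert selected.powers == (1.0,)
        assert len(ranking) == 1

    def test_one_row_per_cell(self, scan_counts):
        _, ranking = sc.scan_powers(
            scan_counts, power_grid=(-2.0, 0.0, 1.0), orders=(1,),
            reference="control", eps=1.0,
        )
        assert len(ranking) == 3
        ok = ranking.dropna(subset=["aic"])
        assert np.all(np.diff(ok["aic"]) >= 0)

    def test_second_order_cells_accepted(self, scan_counts):
        fit = sc.fit_fp(scan_counts, (-2.0, 1.0), reference="control", eps=1.0)
        assert fit.order == 2
        assert np.isfinite(fit.aic)


class TestHRCurve:
    def test_null_contrast_unit_hr(self):
        c = sc.FPContrast("x", -2.0, 0.0, (0.0, 0.0), 0.0, (0.0, 0.0))
        assert np.allclose(sc.hr_curve(c, np.linspace(0.5, 30, 50)), 1.0)

    def test_published_os_contrast_asymptote(self):
        """A sintilimab-style OS contrast (d0=-0.45, d1=-0.56, p=-1) tends
        to exp(-0.45) ~ 0.6376 as t grows."""
        c = sc.FPContrast(
            "sintilimab", -1.0, -0.45, (-0.82, -0.08), -0.56, (-2.40, 1.29), "os"
        )
        assert sc.hr_curve(c, [1e9])[0] == pytest.approx(np.exp(-0.45), rel=1e-6)

    def test_monotone_decay_for_negative_power_positive_slope(self):
        c = sc.FPContrast("x", -2.0, -0.3, (-0.4, -0.2), 1.5, (1.0, 2.0))
        t = np.linspace(1.0, 40.0, 100)
        hr = sc.hr_curve(c, t)
        assert np.all(np.diff(hr) < 0)
        assert hr[-1] == pytest.approx(np.exp(-0.3), rel=1e-3)

    def test_nonpositive_times_rejected(self):
        c = sc.FPContrast("x", -2.0, 0.0, (0.0, 0.0), 0.0, (0.0, 0.0))
        with pytest.raises(ValueError):
            sc.hr_curve(c, [0.0, 1.0])


class _ConstHazardFit:
    def __init__(self, lam):
        self.lam = lam

    def hazard(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.lam)


class TestApplyContrast:
    def test_null_contrast_is_identity(self):
        c = sc.FPContrast("x", -2.0, 0.0, (0.0, 0.0), 0.0, (0.0, 0.0))
        grid = np.linspace(0, 60, 121)
        S = sc.apply_contrast(_ConstHazardFit(0.1), c, grid)
        assert np.max(np.abs(S - np.exp(-0.1 * grid))) < 1e-8

    def test_constant_hr_closed_form(self):
        c = sc.FPContrast(
            "x", -2.0, np.log(0.5), (np.log(0.5),) * 2, 0.0, (0.0, 0.0)
        )
        grid = np.linspace(0, 10, 21)
        S = sc.apply_contrast(_ConstHazardFit(0.1), c, grid)
        assert S[-1] == pytest.approx(np.exp(-0.5), abs=1e-10)

    def test_quadrature_matches_refined_trapezoid(self):
        c = sc.FPContrast("x", -1.0, -0.4, (-0.5, -0.3), 0.7, (0.4, 1.0))
        grid = np.linspace(0, 24, 49)
        S = sc.apply_contrast(_ConstHazardFit(0.09), c, grid, eps=0.5)
        fine = np.linspace(0, 24, 480001)
        integ = 0.09 * np.exp(-0.4 + 0.7 * fp_power(fine, -1.0, eps=0.5))
        H = np.concatenate(
            [[0.0], np.cumsum(0.5 * (integ[1:] + integ[:-1]) * np.diff(fine))]
        )
        S_tr = np.exp(-np.interp(grid, fine, H))
        assert np.max(np.abs(S - S_tr)) < 1e-5

    def test_output_is_valid_survival(self):
        c = sc.FPContrast("x", -2.0, -0.9, (-1.0, -0.8), 2.76, (2.0, 3.5))
        grid = np.linspace(0, 60, 200)
        S = sc.apply_contrast(_ConstHazardFit(0.08), c, grid, eps=1.0)
        assert S[0] == 1.0
        assert np.all((S >= 0) & (S <= 1))
        assert np.all(np.diff(S) <= 1e-12)


class TestHeterogeneity:
    def _expected_count_network(self, inflate_trial=None):
        breaks = np.arange(0.0, 25.0, 1.0)
        frames = []
        for i in range(3):
            for arm, lam in (("control", 0.10), ("drug", 0.06)):
                ic = sc.interval_counts_from_survival(
                    lambda t: np.exp(-lam * np.asarray(t)), 2000, breaks,
                    trial=f"t{i}", arm=arm,
                )
                if inflate_trial is not None and i == inflate_trial and arm == "drug":
                    ic["events"] *= 2.0
                frames.append(ic)
        return pd.concat(frames, ignore_index=True)

    def test_homogeneous_expected_counts_give_zero(self):
        counts = self._expected_count_network()
        fit = sc.fit_fp1(counts, 1.0, reference="control")
        assert fit.i_squared == pytest.approx(0.0, abs=1e-6)

    def test_bounded_and_raised_by_induced_heterogeneity(self):
        base = sc.fit_fp1(self._expected_count_network(), 1.0, reference="control")
        infl = sc.fit_fp1(
            self._expected_count_network(inflate_trial=1), 1.0, reference="control"
        )
        assert 0.0 <= base.i_squared <= 100.0
        assert 0.0 <= infl.i_squared <= 100.0
        assert infl.i_squared > base.i_squared

    def test_contrast_csv_round_trip(self, tmp_path):
        from survcea.fp_nma import contrasts_from_csv, contrasts_to_csv

        cs = [
            sc.FPContrast("a", -2.0, -0.5, (-0.7, -0.3), 1.0, (0.5, 1.5), "pfs"),
            sc.FPContrast("b", -1.0, -0.2, (-0.4, 0.0), -0.1, (-0.6, 0.4), "os"),
        ]
        path = tmp_path / "contrasts.csv"
        contrasts_to_csv(cs, path)
        back = contrasts_from_csv(path)
        assert [c.treatment for c in back] == ["a", "b"]
        assert back[0].d0 == pytest.approx(-0.5)
        assert back[1].d1_ci == (pytest.approx(-0.6), pytest.approx(0.4))
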