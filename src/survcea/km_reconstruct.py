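"""Individual-patient-data reconstruction from digitized Kaplan-Meier curves.

Implements the Guyot iterative algorithm: given survival probabilities read
off a published KM plot and the numbers-at-risk table printed beneath it,
solve for event and censoring counts in each inter-risk-time interval such
that the KM estimate of the output matches the digitized steps and the
at-risk counts match the table.  Censoring times are spread uniformly within
each interval (the standard convention when censoring times are unobserved).

Also provides the product-limit estimator, a Cox proportional-hazards
validation of reconstruction quality, and the non-proportional-hazards
diagnostics used before fractional-polynomial modelling: log-cumulative-hazard
curves per arm and Epanechnikov kernel-smoothed hazards, with a crossing flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

#: digitization jitter up to this size is repaired by isotonic clipping;
#: larger monotonicity violations raise
JITTER_TOL = 0.005


class ReconstructionError(ValueError):
    """Raised when curve/risk inputs are infeasible."""


@dataclass
class HRValidation:
    hr_point: float
    ci_low: float
    ci_high: float
    overlaps_reported: bool | None = None


# ---------------------------------------------------------------------------
# input validation


def _clean_curve(curve: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(curve["time"], dtype=float)
    s = np.asarray(curve["survival"], dtype=float)
    if len(t) == 0:
        raise ReconstructionError("empty curve")
    if np.any(np.diff(t) <= 0):
        raise ReconstructionError("curve times must be strictly increasing")
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    if np.any(s < -JITTER_TOL) or np.any(s > 1 + JITTER_TOL):
        raise ReconstructionError("survival outside [0, 1]")
    s = np.clip(s, 0.0, 1.0)
    # isotonic clip of small digitization jitter; big rises are errors
    rise = np.diff(s)
    if np.any(rise > JITTER_TOL):
        k = int(np.argmax(rise > JITTER_TOL))
        raise ReconstructionError(
            f"survival rises by {rise[k]:.4f} between t={t[k]:g} and "
            f"t={t[k + 1]:g} (exceeds jitter tolerance {JITTER_TOL})"
        )
    s = np.minimum.accumulate(s)
    return t, s


def _clean_risk(risk: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    rt = np.asarray(risk["time"], dtype=float)
    rn = np.asarray(risk["n_at_risk"], dtype=float)
    if len(rt) == 0 or rn[0] < 1:
        raise ReconstructionError("risk table needs an initial cohort size >= 1")
    if np.any(np.diff(rt) <= 0):
        raise ReconstructionError("risk-table times must be strictly increasing")
    if np.any(np.diff(rn) > 0):
        raise ReconstructionError("numbers at risk must be non-increasing")
    return rt, rn


# ---------------------------------------------------------------------------
# Guyot reconstruction


def reconstruct_ipd(
    curve: pd.DataFrame,
    risk: pd.DataFrame,
    total_events: int | None = None,
    trial: str = "trial",
    arm: str = "arm",
) -> pd.DataFrame:
    """Reconstruct IPD from a digitized curve and an at-risk table.

    Within each interval between consecutive risk-table times the censoring
    count is iterated until the implied number entering the next interval
    matches the printed at-risk count; event counts then follow from the KM
    steps.  If ``total_events`` is given, censoring in the final interval is
    adjusted so the cumulative event count matches it; otherwise the final
    interval is treated as censoring-free.
    """
    t, s = _clean_curve(curve)
    rt, rn = _clean_risk(risk)
    K = len(t)
    # lower[i]: first curve index at/after risk time i; upper[i]: last index
    # before risk time i+1
    nint = len(rt)
    lower = np.searchsorted(t, rt, side="left")
    if lower[0] > 0:
        lower[0] = 0
    upper = np.empty(nint, dtype=int)
    upper[:-1] = np.searchsorted(t, rt[1:], side="left") - 1
    upper[-1] = K - 1

    d = np.zeros(K, dtype=int)
    km = np.ones(K)
    interval_cens: list[np.ndarray] = [np.empty(0)] * nint

    def _run_interval(i: int, n_cen_i: int, n_start: float):
        """Distribute n_cen_i censorings uniformly over interval i, derive
        event counts from the KM steps; returns arrays and n at interval end."""
        lo, up = lower[i], upper[i]
        t_end = rt[i + 1] if i + 1 < nint else max(t[-1], rt[i]) + 1e-9
        if n_cen_i > 0:
            ct = rt[i] + (np.arange(1, n_cen_i + 1)) * (t_end - rt[i]) / (n_cen_i + 1)
        else:
            ct = np.empty(0)
        d_i = np.zeros(K, dtype=int)
        n = n_start
        km_prev = km[lo - 1] if 0 < lo <= K else (km[-1] if lo > K else 1.0)
        km_i = km.copy()
        if lo > up:
            # no curve points fall in this interval: censoring only
            return d_i, ct, km_i, n - len(ct)
        for k in range(lo, up + 1):
            bin_lo = rt[i] if k == lo else t[k]
            t_next = t[k + 1] if k + 1 <= up else t_end
            n_cen_k = int(((ct >= bin_lo) & (ct < t_next)).sum())
            if t[k] == 0:
                dk = 0
            else:
                dk = int(round(n * (1 - s[k] / km_prev))) if km_prev > 0 else 0
                dk = max(0, min(dk, int(n)))
            d_i[k] = dk
            if n > 0 and dk < n:
                km_prev = km_prev * (1 - dk / n)
            elif dk >= n > 0:
                km_prev = 0.0
            km_i[k] = km_prev
            n = n - dk - n_cen_k
            if n < 0:
                n = 0
        return d_i, ct, km_i, n

    n_start = float(rn[0])
    for i in range(nint):
        lo, up = lower[i], upper[i]
        last = i == nint - 1
        if not last:
            s_lo = s[min(lo, K - 1)]
            s_next = s[min(lower[i + 1], K - 1)]
            guess = int(round(n_start * s_next / max(s_lo, 1e-12) - rn[i + 1]))
            guess = max(0, guess)
        else:
            guess = 0
        for _ in range(60):
            d_i, ct_i, km_i, n_end = _run_interval(i, guess, n_start)
            if last:
                if total_events is not None:
                    ev_so_far = int(d[:max(lo, 0)].sum()) + int(d_i.sum())
                    # too many events -> censor earlier in the interval
                    if ev_so_far > total_events and guess < n_start:
                        guess += max(1, ev_so_far - total_events)
                        continue
                break
            diff = n_end - rn[i + 1]
            if diff == 0:
                break
            guess += int(round(diff))
            if guess < 0:
                guess = 0
                d_i, ct_i, km_i, n_end = _run_interval(i, 0, n_start)
                break
        if lo <= up:
            d[lo : up + 1] = d_i[lo : up + 1]
            km[lo : up + 1] = km_i[lo : up + 1]
        interval_cens[i] = ct_i
        # carry the computed count forward (not the table value): when the
        # censoring iteration cannot reconcile an interval exactly, later
        # intervals absorb the drift instead of compounding it
        n_start = n_end

    n_cen_total = sum(len(c) for c in interval_cens)
    if int(d.sum()) + n_cen_total > rn[0]:
        raise ReconstructionError("implied events+censorings exceed cohort size")

    times, events = [], []
    for k in range(K):
        if d[k] > 0:
            times.extend([t[k]] * d[k])
            events.extend([1] * d[k])
    for ct in interval_cens:
        times.extend(list(ct))
        events.extend([0] * len(ct))
    # patients never resolved on the curve: administratively censored at the end
    n_left = int(rn[0]) - len(times)
    if n_left > 0:
        times.extend([t[-1]] * n_left)
        events.extend([0] * n_left)
    out = pd.DataFrame(
        {"trial": trial, "arm": arm, "time": times, "event": events}
    ).sort_values("time", kind="stable", ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# estimation / diagnostics


def km_estimate(ipd: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit estimate; returns (step times, survival) with S before
    the first event implicitly 1 (times start at the first observed time)."""
    if len(ipd) == 0:
        raise ValueError("empty IPD")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd["time"], ipd["event"])
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def km_at(times_grid, step_times, step_surv) -> np.ndarray:
    """Evaluate a KM step function on an arbitrary grid."""
    times_grid = np.asarray(times_grid, dtype=float)
    idx = np.searchsorted(step_times, times_grid, side="right") - 1
    out = np.where(idx >= 0, step_surv[np.clip(idx, 0, None)], 1.0)
    return out


def cox_hr(
    ipd: pd.DataFrame,
    treatment_arm: str | None = None,
    reported_interval: tuple[float, float] | None = None,
) -> HRValidation:
    """Cox partial-likelihood HR (treatment vs the other arm), Efron ties,
    Wald 95% CI; used to validate reconstruction fidelity against a trial's
    reported hazard ratio."""
    arms = sorted(ipd["arm"].unique())
    if len(arms) != 2:
        raise ValueError("cox_hr needs exactly two arms")
    if treatment_arm is None:
        treatment_arm = arms[1]
    for a in arms:
        if ipd.loc[ipd["arm"] == a, "event"].sum() < 1:
            raise ValueError(f"arm {a!r} has no events")
    df = pd.DataFrame(
        {
            "time": ipd["time"].to_numpy(dtype=float),
            "event": ipd["event"].to_numpy(dtype=int),
            "treat": (ipd["arm"] == treatment_arm).astype(int).to_numpy(),
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["treat"])
    se = float(cph.standard_errors_["treat"])
    hr = float(np.exp(beta))
    lo, hi = float(np.exp(beta - 1.959963984540054 * se)), float(
        np.exp(beta + 1.959963984540054 * se)
    )
    overlaps = None
    if reported_interval is not None:
        r_lo, r_hi = reported_interval
        overlaps = not (hi < r_lo or lo > r_hi)
    return HRValidation(hr_point=hr, ci_low=lo, ci_high=hi, overlaps_reported=overlaps)


def _epanechnikov_hazard(event_times, increments, grid, bandwidth):
    """Kernel-smoothed hazard from Nelson-Aalen increments d_i / Y(t_i)."""
    grid = np.asarray(grid, dtype=float)
    u = (grid[:, None] - event_times[None, :]) / bandwidth
    k = np.where(np.abs(u) <= 1, 0.75 * (1 - u**2), 0.0) / bandwidth
    return k @ increments


def ph_diagnostics(
    ipd: pd.DataFrame,
    n_grid: int = 100,
    bandwidth: float | None = None,
    band: float = 0.05,
    skip_fraction: float = 0.10,
) -> dict:
    """Proportional-hazards diagnostics for a two-arm dataset.

    Computes log(-log S(t)) per arm from the KM estimate on a shared grid and
    an Epanechnikov-kernel smoothed hazard per arm.  The crossing flag is set
    when, after the first ``skip_fraction`` of event times, the between-arm
    log-cumulative-hazard difference exceeds +``band`` somewhere and falls
    below -``band`` somewhere else (a sign change beyond the noise band).
    """
    arms = sorted(ipd["arm"].unique())
    if len(arms) != 2:
        raise ValueError("ph_diagnostics needs exactly two arms")
    per_arm = {}
    all_event_times = np.sort(
        ipd.loc[ipd["event"] == 1, "time"].to_numpy(dtype=float)
    )
    for a in arms:
        sub = ipd[ipd["arm"] == a]
        if sub["event"].sum() < 5:
            raise ValueError(f"arm {a!r} has fewer than 5 events")
        per_arm[a] = km_estimate(sub)
    t_lo = np.quantile(all_event_times, 0.02)
    t_hi = np.quantile(all_event_times, 0.98)
    grid = np.linspace(t_lo, t_hi, n_grid)
    loglog = {}
    for a in arms:
        s = km_at(grid, *per_arm[a])
        s = np.clip(s, 1e-10, 1 - 1e-10)
        loglog[a] = np.log(-np.log(s))
    diff = loglog[arms[1]] - loglog[arms[0]]
    t_skip = np.quantile(all_event_times, skip_fraction)
    mask = grid >= t_skip
    crossing = bool(np.any(diff[mask] > band) and np.any(diff[mask] < -band))

    if bandwidth is None:
        bandwidth = max((t_hi - t_lo) / 8.0, 1e-6)
    hazards = {}
    for a in arms:
        sub = ipd[ipd["arm"] == a]
        tt = sub["time"].to_numpy(dtype=float)
        ev = sub["event"].to_numpy(dtype=int)
        et = np.sort(np.unique(tt[ev == 1]))
        at_risk = np.array([(tt >= x).sum() for x in et], dtype=float)
        d_cnt = np.array([((tt == x) & (ev == 1)).sum() for x in et], dtype=float)
        hazards[a] = _epanechnikov_hazard(et, d_cnt / at_risk, grid, bandwidth)

    return {
        "grid": grid,
        "log_cumhaz": loglog,
        "log_cumhaz_diff": diff,
        "smoothed_hazard": hazards,
        "bandwidth": bandwidth,
        "crossing": crossing,
    }


# ---------------------------------------------------------------------------
# I/O


def read_curve_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_risk_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_ipd_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
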