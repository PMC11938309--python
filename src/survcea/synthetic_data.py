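"""Synthetic two-arm oncology trials with time-varying hazard-ratio truth.

Generates individual patient data (IPD) from a piecewise-constant reference
hazard modulated, in the treatment arm, by a first-order fractional-polynomial
log hazard ratio ``d0 + d1 * t**p``.  Also produces digitization-style
Kaplan-Meier artifacts (a coarsened survival curve plus a numbers-at-risk
table) so the downstream reconstruction, fitting and meta-analysis stages can
be exercised against known truth without any external data.

Time unit is months throughout.  For negative powers ``t**p`` is evaluated as
``max(t, EPS_MONTHS)**p`` to avoid the singularity at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: floor applied to t before raising to a negative fractional-polynomial power
EPS_MONTHS: float = 0.01


def fp_power(t, p, eps: float = EPS_MONTHS):
    """Evaluate the fractional-polynomial basis t**p with the p=0 -> log t
    convention and an epsilon floor near t=0."""
    t = np.maximum(np.asarray(t, dtype=float), eps)
    if p == 0:
        return np.log(t)
    return t ** p


@dataclass(frozen=True)
class TrialSpec:
    """Specification of one simulated two-arm trial.

    The control arm follows the piecewise-constant ``reference_hazard``;
    the treatment arm hazard is the reference hazard times
    ``exp(d0 + d1 * t**p)`` where ``(d0, d1, p)`` is ``contrast_truth``.
    """

    trial_id: str
    n_per_arm: int
    reference_hazard: tuple  # ((breakpoints ascending, starting 0), (rates))
    contrast_truth: tuple = (0.0, 0.0, -2.0)  # (d0, d1, p)
    accrual_months: float = 12.0
    cutoff_months: float = 24.0
    dropout_rate: float = 0.0
    seed: int = 0
    arms: tuple = ("control", "treatment")
    #: floor for t**p in the treatment-arm hazard; raise it (e.g. to the
    #: first interval midpoint) for strongly negative powers with d1 != 0,
    #: where exp(d1 * t**p) is astronomically large near t = 0
    eps_floor: float = EPS_MONTHS

    def __post_init__(self):
        breaks, rates = self.reference_hazard
        breaks = np.asarray(breaks, dtype=float)
        rates = np.asarray(rates, dtype=float)
        if breaks[0] != 0 or np.any(np.diff(breaks) <= 0):
            raise ValueError("hazard breakpoints must start at 0 and increase")
        if len(rates) != len(breaks):
            raise ValueError("need one rate per breakpoint segment")
        if np.any(rates <= 0):
            raise ValueError("all hazard rates must be > 0")
        if self.cutoff_months <= 0:
            raise ValueError("cutoff_months must be > 0")
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be >= 0")
        if self.accrual_months < 0:
            raise ValueError("accrual_months must be >= 0")

    def to_yaml(self, path) -> None:
        breaks, rates = self.reference_hazard
        doc = {
            "trial_id": self.trial_id,
            "n_per_arm": int(self.n_per_arm),
            "reference_hazard": {
                "breakpoints": [float(b) for b in np.asarray(breaks)],
                "rates": [float(r) for r in np.asarray(rates)],
            },
            "contrast_truth": {
                "d0": float(self.contrast_truth[0]),
                "d1": float(self.contrast_truth[1]),
                "p": float(self.contrast_truth[2]),
            },
            "accrual_months": float(self.accrual_months),
            "cutoff_months": float(self.cutoff_months),
            "dropout_rate": float(self.dropout_rate),
            "seed": int(self.seed),
            "arms": list(self.arms),
            "eps_floor": float(self.eps_floor),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrialSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        rh = doc["reference_hazard"]
        ct = doc["contrast_truth"]
        return cls(
            trial_id=doc["trial_id"],
            n_per_arm=doc["n_per_arm"],
            reference_hazard=(tuple(rh["breakpoints"]), tuple(rh["rates"])),
            contrast_truth=(ct["d0"], ct["d1"], ct["p"]),
            accrual_months=doc["accrual_months"],
            cutoff_months=doc["cutoff_months"],
            dropout_rate=doc["dropout_rate"],
            seed=doc["seed"],
            arms=tuple(doc.get("arms", ("control", "treatment"))),
            eps_floor=float(doc.get("eps_floor", EPS_MONTHS)),
        )


@dataclass
class TruthBundle:
    """True survival per arm and true HR(t) on a time grid."""

    spec: TrialSpec
    grid: np.ndarray
    survival: dict  # arm -> np.ndarray
    hr: np.ndarray  # treatment vs control


# ---------------------------------------------------------------------------
# hazard bookkeeping


def _reference_hazard_at(t, breaks, rates):
    idx = np.searchsorted(breaks, t, side="right") - 1
    idx = np.clip(idx, 0, len(rates) - 1)
    return rates[idx]


def _reference_cumhaz(t, breaks, rates):
    """Exact cumulative hazard of the piecewise-constant reference."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    ends = np.append(breaks[1:], np.inf)
    out = np.zeros_like(t)
    for a, b, r in zip(breaks, ends, rates):
        out += r * np.clip(t - a, 0.0, b - a)
    return out


def _arm_hazard(t, spec: TrialSpec, treated: bool):
    breaks, rates = (np.asarray(x, float) for x in spec.reference_hazard)
    h = _reference_hazard_at(np.asarray(t, float), breaks, rates)
    if treated:
        d0, d1, p = spec.contrast_truth
        expo = d0 + d1 * fp_power(t, p, eps=spec.eps_floor)
        if np.any(expo > 50):
            raise ValueError(
                "treatment-arm log-HR exceeds 50 near t=0; raise eps_floor "
                "for this (d1, p) combination"
            )
        h = h * np.exp(expo)
    return h


def _arm_cumhaz_grid(spec: TrialSpec, treated: bool, t_max: float, n_grid: int = 8193):
    """Cumulative hazard on a fine grid (trapezoid), exact when d1 == 0."""
    breaks, rates = (np.asarray(x, float) for x in spec.reference_hazard)
    d0, d1, p = spec.contrast_truth
    grid = np.linspace(0.0, t_max, n_grid)
    # include hazard breakpoints so piecewise jumps are sampled exactly
    grid = np.unique(np.concatenate([grid, breaks[breaks <= t_max]]))
    if not treated or d1 == 0.0:
        H = _reference_cumhaz(grid, breaks, rates)
        if treated:
            H = H * np.exp(d0)
        return grid, H
    h = _arm_hazard(grid, spec, treated=True)
    H = np.concatenate(
        [[0.0], np.cumsum(0.5 * (h[1:] + h[:-1]) * np.diff(grid))]
    )
    return grid, H


def _invert_cumhaz(e, grid, H):
    """Map Exp(1) draws to event times via the inverse cumulative hazard.

    Draws exceeding H(t_max) map to +inf (event beyond the simulated window;
    they are administratively censored downstream)."""
    t = np.interp(e, H, grid, right=np.inf)
    t[e > H[-1]] = np.inf
    return t


# ---------------------------------------------------------------------------
# operations


def simulate_trial(spec: TrialSpec) -> pd.DataFrame:
    """Simulate IPD for one two-arm trial.

    Returns a DataFrame with columns ``trial, arm, time, event``; observed
    time = min(event, dropout, administrative censoring at
    ``cutoff - entry``), entry uniform over the accrual window.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for arm_idx, arm in enumerate(spec.arms):
        treated = arm_idx == 1
        grid, H = _arm_cumhaz_grid(spec, treated, t_max=spec.cutoff_months)
        n = spec.n_per_arm
        e = rng.exponential(size=n)
        t_event = _invert_cumhaz(e, grid, H)
        entry = rng.uniform(0.0, spec.accrual_months, size=n) if spec.accrual_months > 0 else np.zeros(n)
        t_admin = np.maximum(spec.cutoff_months - entry, 1e-9)
        if spec.dropout_rate > 0:
            t_drop = rng.exponential(1.0 / spec.dropout_rate, size=n)
        else:
            t_drop = np.full(n, np.inf)
        t_cens = np.minimum(t_admin, t_drop)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        frames.append(
            pd.DataFrame(
                {"trial": spec.trial_id, "arm": arm, "time": time, "event": event}
            )
        )
    return pd.concat(frames, ignore_index=True)


def make_km_artifacts(ipd: pd.DataFrame, grid, coarsen: bool = True, risk_grid=None):
    """Digitization-style artifacts from IPD: a KM curve sampled on ``grid``
    (optionally rounded to 3 decimals, mimicking plot digitization) and a
    numbers-at-risk table at the grid times (or at ``risk_grid`` when the
    published at-risk table is sparser than the digitized curve).

    Returns ``(curve, risk)`` DataFrames with columns ``time, survival`` and
    ``time, n_at_risk``.
    """
    if len(ipd) == 0:
        raise ValueError("empty IPD")
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must increase from 0")
    risk_grid = grid if risk_grid is None else np.asarray(risk_grid, dtype=float)
    from .km_reconstruct import km_estimate

    times, surv = km_estimate(ipd)
    # step-function evaluation: S(t) = value at the largest step time <= t
    idx = np.searchsorted(times, grid, side="right") - 1
    s = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
    s = np.concatenate([[1.0], s[1:]])  # S(0)=1 by definition
    if coarsen:
        s = np.round(s, 3)
    t = np.asarray(ipd["time"], dtype=float)
    n_at_risk = np.array([(t >= g).sum() for g in risk_grid], dtype=int)
    curve = pd.DataFrame({"time": grid, "survival": s})
    risk = pd.DataFrame({"time": risk_grid, "n_at_risk": n_at_risk})
    return curve, risk


def truth_bundle(spec: TrialSpec, grid) -> TruthBundle:
    """Closed-form true survival per arm and true HR(t) on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    breaks, rates = (np.asarray(x, float) for x in spec.reference_hazard)
    d0, d1, p = spec.contrast_truth
    surv = {}
    g0, H0 = _arm_cumhaz_grid(spec, treated=False, t_max=max(grid[-1], 1e-9))
    surv[spec.arms[0]] = np.exp(-np.interp(grid, g0, H0))
    g1, H1 = _arm_cumhaz_grid(spec, treated=True, t_max=max(grid[-1], 1e-9))
    surv[spec.arms[1]] = np.exp(-np.interp(grid, g1, H1))
    hr = np.exp(d0 + d1 * fp_power(grid, p, eps=spec.eps_floor))
    return TruthBundle(spec=spec, grid=grid, survival=surv, hr=hr)


# ---------------------------------------------------------------------------
# I/O helpers (CSV conventions shared with km_reconstruct)


def write_ipd_csv(ipd: pd.DataFrame, path) -> None:
    ipd.to_csv(path, index=False, columns=["trial", "arm", "time", "event"])


def write_curve_csv(curve: pd.DataFrame, path) -> None:
    curve.to_csv(path, index=False, columns=["time", "survival"])


def write_risk_csv(risk: pd.DataFrame, path) -> None:
    risk.to_csv(path, index=False, columns=["time", "n_at_risk"])
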