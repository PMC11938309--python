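"""Reference-arm survival model fitting, selection and prediction.

Three model classes are supported, all fitted by maximum likelihood on
right-censored IPD:

* seven standard parametric families (exponential, gamma, gompertz, weibull,
  loglogistic, lognormal, generalized gamma);
* Royston-Parmar flexible parametric models: a restricted cubic spline in
  log time placed on the log cumulative hazard, log cumulative odds, or
  probit ("normal") survival scale, with 1-3 internal knots;
* restricted-cubic-spline log-hazard models (3-5 total knots) with the
  cumulative hazard obtained by Gauss-Legendre quadrature.

Model choice follows minimum AIC with BIC then parameter count as
tie-breakers.  Fitted objects expose survival and hazard predictors used by
the extrapolation and economic-model stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize, special, stats

PARAMETRIC_FAMILIES = (
    "exponential",
    "gamma",
    "gompertz",
    "weibull",
    "loglogistic",
    "lognormal",
    "generalized_gamma",
)
RP_SCALES = ("hazard", "odds", "normal")

_Z95 = 1.959963984540054


class FitError(RuntimeError):
    """Raised when an optimizer fails to converge or a fit is degenerate."""


@dataclass
class SurvivalFit:
    """A fitted survival model with its information criteria and predictors."""

    model_kind: str  # e.g. "parametric:weibull", "rp_spline:normal:3", "rcs_hazard:4"
    coefficients: np.ndarray
    loglik: float
    n_params: int
    n_obs: int
    n_events: int
    knot_locations: np.ndarray | None = None
    survival: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)
    hazard: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)
    converged: bool = True
    diagnostics: dict = field(default_factory=dict, repr=False)

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    @property
    def bic(self) -> float:
        # sample-size convention: number of subjects
        return self.n_params * np.log(self.n_obs) - 2 * self.loglik

    def to_json_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "coefficients": [float(c) for c in np.atleast_1d(self.coefficients)],
            "knot_locations": None
            if self.knot_locations is None
            else [float(k) for k in self.knot_locations],
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "n_params": int(self.n_params),
            "n_obs": int(self.n_obs),
            "n_events": int(self.n_events),
            "converged": bool(self.converged),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)


def _extract(ipd) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(ipd["time"], dtype=float)
    e = np.asarray(ipd["event"], dtype=int)
    if np.any(t <= 0):
        t = np.maximum(t, 1e-8)
    return t, e


# ---------------------------------------------------------------------------
# parametric families: log-density and log-survival, parameters transformed
# to an unconstrained scale for optimization


def _family_loglik(family: str):
    """Return (fn(theta, t, e) -> per-subject loglik, n_params, start_fn)."""

    def logmix(logf, logS, e):
        return np.where(e == 1, logf, logS)

    if family == "exponential":

        def ll(th, t, e):
            lam = np.exp(th[0])
            return logmix(th[0] - lam * t, -lam * t, e)

        def start(t, e):
            return np.array([np.log(max(e.sum(), 0.5) / t.sum())])

        return ll, 1, start

    if family == "weibull":

        def ll(th, t, e):
            k, lam = np.exp(th)
            z = (t / lam) ** k
            logf = np.log(k) - np.log(lam) + (k - 1) * (np.log(t) - np.log(lam)) - z
            return logmix(logf, -z, e)

        def start(t, e):
            lt = np.log(t[e == 1]) if e.sum() >= 2 else np.log(t)
            s = max(np.std(lt), 0.2)
            return np.array([np.log(1.2 / s), np.mean(lt)])

        return ll, 2, start

    if family == "gompertz":

        def ll(th, t, e):
            a = th[0]
            b = np.exp(th[1])
            if abs(a) > 1e-8:
                H = b / a * (np.exp(a * t) - 1.0)
            else:
                H = b * t * (1 + a * t / 2)
            return logmix(th[1] + a * t - H, -H, e)

        def start(t, e):
            return np.array([0.0, np.log(max(e.sum(), 0.5) / t.sum())])

        return ll, 2, start

    if family == "gamma":

        def ll(th, t, e):
            a, rate = np.exp(th)
            logf = stats.gamma.logpdf(t, a, scale=1.0 / rate)
            logS = stats.gamma.logsf(t, a, scale=1.0 / rate)
            return logmix(logf, logS, e)

        def start(t, e):
            return np.array([0.0, np.log(max(e.sum(), 0.5) / t.sum())])

        return ll, 2, start

    if family == "lognormal":

        def ll(th, t, e):
            mu, sig = th[0], np.exp(th[1])
            z = (np.log(t) - mu) / sig
            logf = stats.norm.logpdf(z) - np.log(sig * t)
            logS = stats.norm.logsf(z)
            return logmix(logf, logS, e)

        def start(t, e):
            lt = np.log(t[e == 1]) if e.sum() >= 2 else np.log(t)
            return np.array([np.mean(lt), np.log(max(np.std(lt), 0.2))])

        return ll, 2, start

    if family == "loglogistic":

        def ll(th, t, e):
            beta, alpha = np.exp(th)
            z = beta * (np.log(t) - np.log(alpha))
            logS = -np.logaddexp(0.0, z)
            logf = th[0] - np.log(t) + z + 2 * logS
            return logmix(logf, logS, e)

        def start(t, e):
            lt = np.log(t[e == 1]) if e.sum() >= 2 else np.log(t)
            s = max(np.std(lt), 0.2)
            return np.array([np.log(1.2 / s), np.mean(lt)])

        return ll, 2, start

    if family == "generalized_gamma":
        # flexsurv (mu, sigma, Q) parameterization; Q ~ 0 handled by the
        # lognormal branch for numerical stability
        def ll(th, t, e):
            mu, sig, q = th[0], np.exp(th[1]), th[2]
            w = (np.log(t) - mu) / sig
            if abs(q) < 1e-6:
                logf = stats.norm.logpdf(w) - np.log(sig * t)
                logS = stats.norm.logsf(w)
            else:
                a = q ** -2
                u = a * np.exp(np.clip(q * w, -700, 700))
                logf = (
                    np.log(abs(q))
                    - np.log(sig * t)
                    + a * np.log(a)
                    - special.gammaln(a)
                    + a * q * w
                    - u
                )
                if q > 0:
                    S = special.gammaincc(a, u)
                else:
                    S = special.gammainc(a, u)
                logS = np.log(np.clip(S, 1e-300, 1.0))
            return logmix(logf, logS, e)

        def start(t, e):
            lt = np.log(t[e == 1]) if e.sum() >= 2 else np.log(t)
            return np.array([np.mean(lt), np.log(max(np.std(lt), 0.2)), 0.5])

        return ll, 3, start

    raise ValueError(f"unknown family {family!r}")


def _optimize_loglik(negll, x0, rng, n_restarts=5, tol=1e-8):
    best = None
    starts = [x0] + [x0 + rng.normal(0, 0.25, size=len(x0)) for _ in range(n_restarts - 1)]
    for s in starts:
        try:
            res = optimize.minimize(
                negll, s, method="L-BFGS-B", options={"ftol": tol, "maxiter": 500}
            )
        except (ValueError, FloatingPointError):
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError("all optimizer restarts failed")
    return best


def fit_parametric(ipd, family: str) -> SurvivalFit:
    """Fit one of the seven standard parametric families by MLE."""
    if family not in PARAMETRIC_FAMILIES:
        raise ValueError(f"family must be one of {PARAMETRIC_FAMILIES}")
    t, e = _extract(ipd)
    if e.sum() < 3:
        raise ValueError("need at least 3 events")
    llfun, n_par, start = _family_loglik(family)

    def negll(th):
        with np.errstate(all="ignore"):
            v = llfun(th, t, e)
        if not np.all(np.isfinite(v)):
            return 1e10
        return -float(v.sum())

    rng = np.random.default_rng(12345)
    res = _optimize_loglik(negll, start(t, e), rng)
    if not res.success and res.fun >= 1e9:
        raise FitError(f"{family} fit did not converge: {res.message}")
    theta = res.x

    def survival(times, theta=theta, llfun=llfun):
        times = np.maximum(np.asarray(times, dtype=float), 1e-10)
        with np.errstate(all="ignore"):
            logS = llfun(theta, times, np.zeros_like(times, dtype=int))
        return np.exp(np.minimum(logS, 0.0))

    def hazard(times, theta=theta, llfun=llfun):
        times = np.maximum(np.asarray(times, dtype=float), 1e-10)
        with np.errstate(all="ignore"):
            logS = llfun(theta, times, np.zeros_like(times, dtype=int))
            logf = llfun(theta, times, np.ones_like(times, dtype=int))
        return np.exp(logf - logS)

    return SurvivalFit(
        model_kind=f"parametric:{family}",
        coefficients=theta,
        loglik=-res.fun,
        n_params=n_par,
        n_obs=len(t),
        n_events=int(e.sum()),
        survival=survival,
        hazard=hazard,
        converged=bool(res.success),
        diagnostics={"optimizer_message": str(res.message)},
    )


# ---------------------------------------------------------------------------
# restricted cubic spline basis (Royston-Parmar form)


def rcs_basis(x, knots) -> np.ndarray:
    """Basis [1, x, v_1..v_m] of a restricted cubic spline with the given
    knot vector (boundary knots first/last)."""
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    cols = [np.ones_like(x), x]
    for kj in knots[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        v = (
            np.clip(x - kj, 0, None) ** 3
            - lam * np.clip(x - kmin, 0, None) ** 3
            - (1 - lam) * np.clip(x - kmax, 0, None) ** 3
        )
        cols.append(v)
    return np.column_stack(cols)


def rcs_basis_deriv(x, knots) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    cols = [np.zeros_like(x), np.ones_like(x)]
    for kj in knots[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        v = (
            3 * np.clip(x - kj, 0, None) ** 2
            - 3 * lam * np.clip(x - kmin, 0, None) ** 2
            - 3 * (1 - lam) * np.clip(x - kmax, 0, None) ** 2
        )
        cols.append(v)
    return np.column_stack(cols)


def _rp_knots(t, e, internal_knots: int) -> np.ndarray:
    lt = np.log(t[e == 1])
    if len(np.unique(lt)) < internal_knots + 2:
        raise ValueError("too few distinct event times for the requested knots")
    centiles = np.linspace(0, 100, internal_knots + 2)
    return np.percentile(lt, centiles)


def _rp_transforms(scale: str):
    """g, its inverse, and per-subject loglik pieces for one RP scale."""
    if scale == "hazard":

        def g(S):
            return np.log(-np.log(np.clip(S, 1e-12, 1 - 1e-12)))

        def S_of_eta(eta):
            return np.exp(-np.exp(np.clip(eta, -700, 700)))

        def ll_event(eta, deta, logt):
            return eta + np.log(deta) - logt - np.exp(np.clip(eta, -700, 700))

        def ll_cens(eta):
            return -np.exp(np.clip(eta, -700, 700))

    elif scale == "odds":

        def g(S):
            S = np.clip(S, 1e-12, 1 - 1e-12)
            return np.log((1 - S) / S)

        def S_of_eta(eta):
            return special.expit(-eta)

        def ll_event(eta, deta, logt):
            return eta + np.log(deta) - logt - 2 * np.logaddexp(0.0, eta)

        def ll_cens(eta):
            return -np.logaddexp(0.0, eta)

    elif scale == "normal":

        def g(S):
            return -stats.norm.ppf(np.clip(S, 1e-12, 1 - 1e-12))

        def S_of_eta(eta):
            return stats.norm.sf(eta)

        def ll_event(eta, deta, logt):
            return stats.norm.logpdf(eta) + np.log(deta) - logt

        def ll_cens(eta):
            return stats.norm.logsf(eta)

    else:
        raise ValueError(f"scale must be one of {RP_SCALES}")
    return g, S_of_eta, ll_event, ll_cens


def fit_royston_parmar(ipd, scale: str, internal_knots: int) -> SurvivalFit:
    """Fit a Royston-Parmar spline model on the requested survival scale.

    ``g(S(t))`` is a restricted cubic spline in log t; boundary knots sit at
    the extreme uncensored log event times, internal knots at equally spaced
    event-time centiles.  Monotonicity of the fitted cumulative transform is
    enforced with a smooth penalty on negative spline slopes; a fit whose
    final slope is still negative anywhere at the event times raises.
    """
    if internal_knots not in (1, 2, 3):
        raise ValueError("internal_knots must be 1, 2 or 3")
    t, e = _extract(ipd)
    knots = _rp_knots(t, e, internal_knots)
    g, S_of_eta, ll_event, ll_cens = _rp_transforms(scale)
    logt = np.log(t)
    B = rcs_basis(logt, knots)
    dB = rcs_basis_deriv(logt, knots)
    ev = e == 1

    # starting values: regress g(KM) on the basis at event times
    from .km_reconstruct import km_at, km_estimate

    st, ss = km_estimate(ipd)
    S_ev = np.clip(km_at(t[ev], st, ss), 1e-6, 1 - 1e-6)
    gamma0, *_ = np.linalg.lstsq(B[ev], g(S_ev), rcond=None)

    def negll(gamma):
        eta = B @ gamma
        deta = dB @ gamma
        pen = 1e4 * np.sum(np.clip(1e-6 - deta[ev], 0, None) ** 2)
        de = np.clip(deta[ev], 1e-10, None)
        with np.errstate(all="ignore"):
            ll = ll_event(eta[ev], de, logt[ev]).sum() + ll_cens(eta[~ev]).sum()
        if not np.isfinite(ll):
            return 1e10
        return -ll + pen

    rng = np.random.default_rng(12345)
    res = _optimize_loglik(negll, gamma0, rng)
    gamma = res.x
    if np.any(dB[ev] @ gamma <= 0):
        raise FitError("fitted cumulative transform is non-monotone at event times")

    def survival(times, gamma=gamma, knots=knots):
        times = np.asarray(times, dtype=float)
        out = np.ones_like(times, dtype=float)
        pos = times > 0
        eta = rcs_basis(np.log(times[pos]), knots) @ gamma
        out[pos] = S_of_eta(eta)
        return np.clip(out, 0.0, 1.0)

    def hazard(times, gamma=gamma, knots=knots):
        times = np.maximum(np.asarray(times, dtype=float), 1e-10)
        x = np.log(times)
        eta = rcs_basis(x, knots) @ gamma
        deta = np.clip(rcs_basis_deriv(x, knots) @ gamma, 1e-12, None)
        S = np.clip(S_of_eta(eta), 1e-300, 1.0)
        with np.errstate(all="ignore"):
            lf = ll_event(eta, deta, x)  # log density
        return np.exp(lf - np.log(S))

    # report the pure loglik (without any active penalty)
    eta = B @ gamma
    deta = np.clip(dB @ gamma, 1e-10, None)
    ll = float(ll_event(eta[ev], deta[ev], logt[ev]).sum() + ll_cens(eta[~ev]).sum())
    return SurvivalFit(
        model_kind=f"rp_spline:{scale}:{internal_knots}",
        coefficients=gamma,
        loglik=ll,
        n_params=len(gamma),
        n_obs=len(t),
        n_events=int(e.sum()),
        knot_locations=knots,
        survival=survival,
        hazard=hazard,
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# restricted-cubic-spline log-hazard model


def _cumulative_from_loghaz(times, loghaz_fn, knots, n_nodes: int = 24):
    """Cumulative hazard of h(t)=exp(spline(t)) by composite Gauss-Legendre,
    splitting at the spline knots (h is piecewise-smooth between them)."""
    times = np.asarray(times, dtype=float)
    xg, wg = np.polynomial.legendre.leggauss(n_nodes)
    uniq = np.unique(np.concatenate([[0.0], times[times > 0]]))
    seg_pts = np.unique(np.concatenate([uniq, knots[(knots > 0) & (knots < uniq[-1])]]))
    a = seg_pts[:-1]
    b = seg_pts[1:]
    mid = 0.5 * (a + b)[:, None]
    half = 0.5 * (b - a)[:, None]
    nodes = mid + half * xg[None, :]
    vals = np.exp(loghaz_fn(nodes.ravel())).reshape(nodes.shape)
    seg_int = (vals * wg[None, :]).sum(axis=1) * half.ravel()
    cum = np.concatenate([[0.0], np.cumsum(seg_int)])
    return np.interp(times, seg_pts, cum)


def fit_rcs_hazard(ipd, knots: int) -> SurvivalFit:
    """Fit log h(t) = restricted cubic spline in t with ``knots`` total knots
    (boundary at the extreme event times, internal at event-time quantiles)."""
    if knots not in (3, 4, 5):
        raise ValueError("knots must be 3, 4 or 5")
    t, e = _extract(ipd)
    if e.sum() < knots:
        raise ValueError("too few events for the requested knots")
    et = t[e == 1]
    kv = np.percentile(et, np.linspace(0, 100, knots))
    if len(np.unique(kv)) < knots:
        raise ValueError("degenerate knot vector (tied event times)")
    ev = e == 1

    def loghaz_fn_maker(gamma):
        def fn(x):
            return rcs_basis(x, kv) @ gamma

        return fn

    def negll(gamma):
        fn = loghaz_fn_maker(gamma)
        with np.errstate(all="ignore"):
            s_ev = fn(t[ev])
            H = _cumulative_from_loghaz(t, fn, kv)
        ll = s_ev.sum() - H.sum()
        if not np.isfinite(ll):
            return 1e10
        return -float(ll)

    gamma0 = np.zeros(knots)
    gamma0[0] = np.log(max(e.sum(), 0.5) / t.sum())
    rng = np.random.default_rng(12345)
    res = _optimize_loglik(negll, gamma0, rng)
    gamma = res.x

    def survival(times, gamma=gamma):
        fn = loghaz_fn_maker(gamma)
        H = _cumulative_from_loghaz(np.asarray(times, dtype=float), fn, kv)
        return np.exp(-H)

    def hazard(times, gamma=gamma):
        return np.exp(rcs_basis(np.asarray(times, dtype=float), kv) @ gamma)

    return SurvivalFit(
        model_kind=f"rcs_hazard:{knots}",
        coefficients=gamma,
        loglik=-res.fun,
        n_params=knots,
        n_obs=len(t),
        n_events=int(e.sum()),
        knot_locations=kv,
        survival=survival,
        hazard=hazard,
        converged=bool(res.success),
    )


def cumulative_hazard_rcs(fit: SurvivalFit, times) -> np.ndarray:
    """Expose the quadrature cumulative hazard of an rcs_hazard fit."""
    if not fit.model_kind.startswith("rcs_hazard"):
        raise ValueError("fit is not an rcs_hazard model")
    kv = fit.knot_locations

    def fn(x):
        return rcs_basis(x, kv) @ fit.coefficients

    return _cumulative_from_loghaz(np.asarray(times, dtype=float), fn, kv)


# ---------------------------------------------------------------------------
# selection / prediction


def select_model(fits: list[SurvivalFit]):
    """Minimum-AIC model; ties broken by BIC then fewest parameters.

    Returns ``(winner, ranking)`` where ranking is a DataFrame sorted by
    the selection order."""
    import pandas as pd

    if not fits:
        raise ValueError("no candidate fits")
    rows = [
        {
            "model_kind": f.model_kind,
            "n_params": f.n_params,
            "loglik": f.loglik,
            "aic": f.aic,
            "bic": f.bic,
            "converged": f.converged,
        }
        for f in fits
    ]
    ranking = (
        pd.DataFrame(rows)
        .sort_values(["aic", "bic", "n_params"], kind="stable")
        .reset_index(drop=True)
    )
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic, fits[i].bic, fits[i].n_params))
    return fits[order[0]], ranking


def predict(fit: SurvivalFit, times) -> tuple[np.ndarray, np.ndarray]:
    """Survival and hazard on a grid; S(0) = 1 by construction."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    S = np.clip(fit.survival(times), 0.0, 1.0)
    S = np.minimum.accumulate(S) if len(S) > 1 else S
    h = fit.hazard(times)
    return S, h
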