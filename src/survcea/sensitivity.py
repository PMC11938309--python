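"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis perturbs each parameter alone over a low/high
range (default +/-20% around baseline; drug prices vary only downward to 80%
of baseline, list prices being the ceiling).  Probabilistic sensitivity
analysis draws all parameters jointly: gamma for costs and body weight
(moment-matched by shape = (mean/SE)^2, scale = SE^2/mean), beta for
utilities, BSA and the discount rate (moment-matched on the parameter's
support), independent normals for the fractional-polynomial contrast
coefficients (SE from the reported 95% CI half-width / 1.96), and a
Dirichlet for the post-progression treatment mixture.

Cost-effectiveness probabilities use the pairwise incremental net monetary
benefit rule vs the reference: a draw counts as cost-effective when
WTP * dQALY - dCost > 0 (strictly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_Z95 = 1.959963984540054

#: relative-SE floor below which a distribution is treated as degenerate
_DEGENERATE_CV = 1e-8


class PSAError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# nested-path helpers (dotted paths into an EconParams dict)


def get_path(d: dict, path: str):
    cur = d
    for part in path.split("."):
        cur = cur[part]
    return cur


def set_path(d: dict, path: str, value) -> None:
    parts = path.split(".")
    cur = d
    for part in parts[:-1]:
        cur = cur[part]
    cur[parts[-1]] = value


# ---------------------------------------------------------------------------
# deterministic (one-way)


@dataclass
class DSASpec:
    """Entries of (parameter path, low, high)."""

    entries: list  # of (path, low, high)

    def __post_init__(self):
        for path, low, high in self.entries:
            if low > high:
                raise ValueError(f"{path}: low > high")


def default_dsa_spec(params) -> DSASpec:
    """+/-20% ranges; drug prices go down to 80% of baseline only."""
    d = params.to_dict()
    entries = []
    for drug in d["unit_costs"]:
        base = d["unit_costs"][drug]["price"]
        entries.append((f"unit_costs.{drug}.price", 0.8 * base, base))
    for cat, base in d["per_cycle_costs"].items():
        entries.append((f"per_cycle_costs.{cat}", 0.8 * base, 1.2 * base))
    for ae, base in d["ae_costs"].items():
        entries.append((f"ae_costs.{ae}", 0.8 * base, 1.2 * base))
    for u, base in d["utilities"].items():
        entries.append((f"utilities.{u}", 0.8 * base, min(1.2 * base, 1.0)))
    for ae, base in d["ae_disutilities"].items():
        lo, hi = sorted((0.8 * base, 1.2 * base))
        entries.append((f"ae_disutilities.{ae}", lo, hi))
    entries.append(("body_weight", 0.8 * d["body_weight"], 1.2 * d["body_weight"]))
    entries.append(("bsa", 0.8 * d["bsa"], 1.2 * d["bsa"]))
    entries.append(("annual_discount", 0.0, 0.08))
    return DSASpec(entries=entries)


def one_way(model, spec: DSASpec, strategy: str, baseline_params) -> pd.DataFrame:
    """Tornado table for one strategy's ICER vs the model's reference.

    ``model`` is a callable mapping an EconParams to an icer_table frame.
    Perturbations that make the incremental QALY non-positive are recorded
    as dominated (NaN ICER) rather than raising.
    """
    base_tab = model(baseline_params)
    base_icer = float(base_tab.loc[strategy, "icer"])
    rows = []
    for path, low, high in spec.entries:
        icers = {}
        for which, value in (("low", low), ("high", high)):
            d = baseline_params.to_dict()
            set_path(d, path, value)
            try:
                tab = model(baseline_params.__class__.from_dict(d))
                icer = float(tab.loc[strategy, "icer"])
            except Exception:
                icer = np.nan
            icers[which] = icer
        span = (
            abs(icers["high"] - icers["low"])
            if np.isfinite(icers["low"]) and np.isfinite(icers["high"])
            else np.inf
        )
        rows.append(
            {
                "parameter": path,
                "low_value": low,
                "high_value": high,
                "icer_low": icers["low"],
                "icer_high": icers["high"],
                "span": span,
            }
        )
    out = pd.DataFrame(rows).sort_values("span", ascending=False, kind="stable")
    out.attrs["baseline_icer"] = base_icer
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# probabilistic: distributions


def gamma_draws(rng, mean, se, size):
    if se <= 0:
        raise ValueError("SE must be > 0")
    if se / max(abs(mean), 1e-300) < _DEGENERATE_CV:
        return np.full(size, mean)
    shape = (mean / se) ** 2
    scale = se**2 / mean
    return rng.gamma(shape, scale, size=size)


def beta_draws(rng, mean, se, size, support=(0.0, 1.0)):
    a, b = support
    if not (a < mean < b):
        raise ValueError(f"mean {mean} outside support ({a}, {b})")
    if se <= 0:
        raise ValueError("SE must be > 0")
    if se / (b - a) < _DEGENERATE_CV:
        return np.full(size, mean)
    m = (mean - a) / (b - a)
    v = (se / (b - a)) ** 2
    if v >= m * (1 - m):
        raise ValueError("SE too large for a beta on this support")
    nu = m * (1 - m) / v - 1
    return a + (b - a) * rng.beta(m * nu, (1 - m) * nu, size=size)


@dataclass
class PSASpec:
    """Joint parameter distribution for the PSA.

    ``entries`` maps a dotted parameter path to a distribution tuple:
    ``("gamma", mean, se)``, ``("beta", mean, se, low, high)`` or
    ``("normal", mean, se)``.  ``dirichlet`` maps a path prefix to
    concentration parameters for a simplex block (e.g. the PD treatment
    mixture).
    """

    n_draws: int = 1000
    seed: int = 0
    entries: dict = field(default_factory=dict)
    dirichlet: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


def default_psa_spec(params, n_draws: int = 1000, seed: int = 0,
                     contrasts=None) -> PSASpec:
    """Distributions per the stated conventions; SEs for costs/utilities are
    20% of baseline / 1.96 (the one-way range read as a 95% interval)."""
    d = params.to_dict()

    def se_of(mean):
        return 0.2 * abs(mean) / _Z95

    entries = {}
    for drug in d["unit_costs"]:
        base = d["unit_costs"][drug]["price"]
        entries[f"unit_costs.{drug}.price"] = ("gamma", base, se_of(base))
    for cat, base in d["per_cycle_costs"].items():
        entries[f"per_cycle_costs.{cat}"] = ("gamma", base, se_of(base))
    for ae, base in d["ae_costs"].items():
        entries[f"ae_costs.{ae}"] = ("gamma", base, se_of(base))
    for u, base in d["utilities"].items():
        entries[f"utilities.{u}"] = ("beta", base, se_of(base), 0.0, 1.0)
    entries["body_weight"] = ("gamma", d["body_weight"], se_of(d["body_weight"]))
    entries["bsa"] = (
        "beta",
        d["bsa"],
        se_of(d["bsa"]),
        0.8 * d["bsa"],
        1.2 * d["bsa"],
    )
    entries["annual_discount"] = (
        "beta",
        d["annual_discount"],
        se_of(d["annual_discount"]),
        0.0,
        0.08,
    )
    if contrasts:
        for c in contrasts:
            key = f"contrast.{c.endpoint}.{c.treatment}"
            entries[f"{key}.d0"] = ("normal", c.d0, max(c.d0_se, 1e-12))
            entries[f"{key}.d1"] = ("normal", c.d1, max(c.d1_se, 1e-12))
    mix = d["pd_treatment_mix"]
    dirichlet = {
        "pd_treatment_mix": {k: 100.0 * v for k, v in mix.items()}
    }
    return PSASpec(n_draws=n_draws, seed=seed, entries=entries, dirichlet=dirichlet)


def sample_params(spec: PSASpec) -> pd.DataFrame:
    """One row per Monte Carlo draw, one column per parameter path."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_draws
    cols = {}
    for path, dist in spec.entries.items():
        kind = dist[0]
        if kind == "gamma":
            _, mean, se = dist
            cols[path] = gamma_draws(rng, mean, se, n)
        elif kind == "beta":
            _, mean, se, low, high = dist
            # negative quantities (disutilities) are sampled on the positive
            # magnitude scale and negated
            if mean < 0:
                cols[path] = -beta_draws(rng, -mean, se, n, (-high, -low))
            else:
                cols[path] = beta_draws(rng, mean, se, n, (low, high))
        elif kind == "normal":
            _, mean, se = dist
            if se <= 0:
                raise ValueError(f"{path}: SE must be > 0")
            cols[path] = rng.normal(mean, se, size=n)
        else:
            raise ValueError(f"unknown distribution {kind!r} for {path}")
    for prefix, alphas in spec.dirichlet.items():
        keys = list(alphas)
        draws = rng.dirichlet([alphas[k] for k in keys], size=n)
        for i, k in enumerate(keys):
            cols[f"{prefix}.{k}"] = draws[:, i]
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# probabilistic: model evaluation


def apply_draw(params, row: pd.Series):
    """Return a copy of ``params`` with a draw's non-contrast entries set."""
    d = params.to_dict()
    for path, value in row.items():
        if path.startswith("contrast."):
            continue
        set_path(d, path, float(value))
    return params.__class__.from_dict(d)


def run_psa(
    model,
    draws: pd.DataFrame,
    reference: str,
    wtp: float,
    max_failure_fraction: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Re-evaluate the full model per draw and summarize cost-effectiveness.

    ``model`` is a callable mapping one draw row (a Series of parameter
    values) to a DataFrame indexed by strategy with ``cost`` and ``qaly``
    columns.  Returns the incremental scatter (per draw, per non-reference
    strategy) and a dict of probabilities that incremental NMB vs the
    reference is strictly positive at ``wtp``.  Failed draws are excluded
    and counted; more than ``max_failure_fraction`` failing aborts.
    """
    if len(draws) == 0:
        raise PSAError("no draws")
    records = []
    failures = 0
    for idx, row in draws.iterrows():
        try:
            res = model(row)
            ref_cost = float(res.loc[reference, "cost"])
            ref_qaly = float(res.loc[reference, "qaly"])
            for s in res.index:
                if s == reference:
                    continue
                records.append(
                    {
                        "draw": idx,
                        "strategy": s,
                        "inc_cost": float(res.loc[s, "cost"]) - ref_cost,
                        "inc_qaly": float(res.loc[s, "qaly"]) - ref_qaly,
                    }
                )
        except Exception:
            failures += 1
    if failures > max_failure_fraction * len(draws):
        raise PSAError(f"{failures}/{len(draws)} draws failed")
    scatter = pd.DataFrame(records)
    scatter.attrs["n_failures"] = failures
    probs = {}
    for s, grp in scatter.groupby("strategy"):
        nmb = wtp * grp["inc_qaly"] - grp["inc_cost"]
        probs[s] = float((nmb > 0).mean())
    return scatter, probs


def ceac(scatter: pd.DataFrame, wtp_grid, rule: str = "pairwise") -> pd.DataFrame:
    """Cost-effectiveness acceptability curves on a WTP grid.

    ``rule="pairwise"``: per strategy, fraction of draws with incremental NMB
    vs the reference strictly positive (a draw whose ICER equals the WTP is
    not cost-effective).  ``rule="best"``: fraction of draws where the
    strategy has the highest NMB among all strategies and the reference
    (probabilities then sum to at most 1 across strategies).
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if len(wtp_grid) == 0:
        raise ValueError("empty WTP grid")
    strategies = sorted(scatter["strategy"].unique())
    rows = []
    for w in wtp_grid:
        row = {"wtp": w}
        if rule == "pairwise":
            for s in strategies:
                grp = scatter[scatter["strategy"] == s]
                nmb = w * grp["inc_qaly"] - grp["inc_cost"]
                row[s] = float((nmb > 0).mean())
        elif rule == "best":
            wide_q = scatter.pivot(index="draw", columns="strategy", values="inc_qaly")
            wide_c = scatter.pivot(index="draw", columns="strategy", values="inc_cost")
            nmb = w * wide_q - wide_c
            nmb["__reference__"] = 0.0
            winner = nmb.idxmax(axis=1)
            for s in strategies:
                row[s] = float((winner == s).mean())
            row["reference"] = float((winner == "__reference__").mean())
        else:
            raise ValueError("rule must be 'pairwise' or 'best'")
        rows.append(row)
    return pd.DataFrame(rows)
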