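"""Three-state partitioned survival model and cost-effectiveness accounting.

State occupancy is read directly off the PFS and OS curves (PFS state =
S_PFS, progressed = S_OS - S_PFS, dead = 1 - S_OS) on a 21-day cycle grid
over a 5-year horizon, with a half-cycle correction (endpoint averaging) and
annual discounting at 5%.  Costs follow a Chinese healthcare-system
perspective: vial-level drug acquisition (no vial sharing), fixed per-cycle
management categories, one-off adverse-event costs and disutilities, and a
post-progression treatment mixture over chemotherapy / targeted therapy /
traditional herbal medicine / supportive care.  Outputs are discounted total
costs, QALYs and life years per strategy, and an ICER table against the
chemotherapy reference with ranking and a below-WTP count.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

DAYS_PER_YEAR = 365.25


class EconError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parameters


def default_unit_costs() -> dict:
    """Unit drug prices (USD per vial) and vial strengths (mg)."""
    return {
        "toripalimab": {"price": 299.07, "vial_mg": 240.0},
        "camrelizumab": {"price": 366.78, "vial_mg": 200.0},
        "pembrolizumab": {"price": 2550.63, "vial_mg": 100.0},
        "serplulimab": {"price": 795.45, "vial_mg": 100.0},
        "sintilimab": {"price": 153.74, "vial_mg": 200.0},
        "tislelizumab": {"price": 392.17, "vial_mg": 200.0},
        "fluorouracil": {"price": 4.59, "vial_mg": 250.0},
        "cisplatin": {"price": 3.99, "vial_mg": 50.0},
        "anlotinib": {"price": 5.21, "vial_mg": 10.0},
        "paclitaxel_liposome": {"price": 173.52, "vial_mg": 30.0},
    }


def default_ae_incidence() -> dict:
    """Grade >= 3 adverse-event probabilities per strategy.

    Synthetic defaults: the trial-level incidence table is not public, so
    these are plausible chemotherapy-backbone values shared across arms, with
    a small immune-related pneumonia increment for the PD-1 combinations.
    """
    base = {
        "anaemia": 0.12,
        "leukopenia": 0.10,
        "neutropenia": 0.30,
        "nausea": 0.07,
        "vomiting": 0.06,
        "hypokalaemia": 0.06,
        "pneumonia": 0.02,
    }
    strategies = [
        "chemotherapy",
        "toripalimab",
        "camrelizumab",
        "pembrolizumab",
        "serplulimab",
        "sintilimab",
        "tislelizumab",
    ]
    out = {}
    for s in strategies:
        inc = dict(base)
        if s != "chemotherapy":
            inc["pneumonia"] = 0.04
        out[s] = inc
    return out


@dataclass
class EconParams:
    """All economic model inputs (USD, 21-day cycles, months/years mixed as
    documented per field)."""

    cycle_days: float = 21.0
    horizon_years: float = 5.0
    annual_discount: float = 0.05
    wtp_per_qaly: float = 36598.19
    cny_to_usd: float = 0.14235
    body_weight: float = 65.0  # kg
    bsa: float = 1.72  # m2
    unit_costs: dict = field(default_factory=default_unit_costs)
    per_cycle_costs: dict = field(
        default_factory=lambda: {
            "routine_follow_up": 78.23,
            "administration": 1.95,
            "laboratory_radiology": 379.15,
            "supportive_care": 177.87,
            "hospitalization": 159.72,
            "tcm_herbal": 213.53,
        }
    )
    ae_costs: dict = field(
        default_factory=lambda: {
            "anaemia": 203.13,
            "leukopenia": 472.07,
            "neutropenia": 472.07,
            "nausea": 20.50,
            "vomiting": 20.50,
            "hypokalaemia": 17.04,
            "pneumonia": 706.82,
        }
    )
    utilities: dict = field(default_factory=lambda: {"pfs": 0.741, "pd": 0.581})
    ae_disutilities: dict = field(
        default_factory=lambda: {
            "anaemia": -0.074,
            "leukopenia": -0.090,
            "neutropenia": -0.090,
            "nausea": -0.048,
            "vomiting": -0.048,
            "hypokalaemia": -0.040,
            "pneumonia": -0.008,
        }
    )
    ae_incidence: dict = field(default_factory=default_ae_incidence)
    # post-progression treatment mixture (all patients in PD keep receiving
    # treatment); proportions are assumptions, not published values
    pd_treatment_mix: dict = field(
        default_factory=lambda: {
            "chemotherapy": 0.30,
            "targeted": 0.15,
            "tcm": 0.35,
            "supportive": 0.20,
        }
    )
    # PD-stage regimens behind the mixture components
    pd_chemo_dose_mg_m2: float = 135.0  # paclitaxel liposome q3w
    pd_targeted_daily_mg: float = 12.0  # anlotinib, 14 days on per cycle
    discount_lys: bool = True

    def validate(self) -> list[str]:
        problems = []
        for d, spec in self.unit_costs.items():
            if spec["price"] < 0:
                problems.append(f"unit_costs.{d}.price is negative")
            if spec["vial_mg"] <= 0:
                problems.append(f"unit_costs.{d}.vial_mg must be > 0")
        for cat in (
            "routine_follow_up",
            "administration",
            "laboratory_radiology",
            "supportive_care",
            "hospitalization",
            "tcm_herbal",
        ):
            if cat not in self.per_cycle_costs:
                problems.append(f"per_cycle_costs.{cat} missing")
            elif self.per_cycle_costs[cat] < 0:
                problems.append(f"per_cycle_costs.{cat} is negative")
        for ae in ("anaemia", "leukopenia", "neutropenia", "nausea", "vomiting",
                   "hypokalaemia", "pneumonia"):
            if ae not in self.ae_costs:
                problems.append(f"ae_costs.{ae} missing")
            if ae not in self.ae_disutilities:
                problems.append(f"ae_disutilities.{ae} missing")
            elif self.ae_disutilities[ae] > 0:
                problems.append(f"ae_disutilities.{ae} must be <= 0")
        for u in ("pfs", "pd"):
            if not (0 <= self.utilities.get(u, -1) <= 1):
                problems.append(f"utilities.{u} must be in [0, 1]")
        mix_sum = sum(self.pd_treatment_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            problems.append(f"pd_treatment_mix sums to {mix_sum:g}, not 1")
        if not (0 <= self.annual_discount <= 0.08):
            problems.append("annual_discount outside [0, 0.08]")
        if self.wtp_per_qaly <= 0:
            problems.append("wtp_per_qaly must be > 0")
        return problems

    def to_dict(self) -> dict:
        return copy.deepcopy(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "EconParams":
        return cls(**copy.deepcopy(d))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, currency: str = "usd") -> "EconParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        p = cls.from_dict(d)
        if currency == "cny":
            rate = p.cny_to_usd
            for spec in p.unit_costs.values():
                spec["price"] *= rate
            p.per_cycle_costs = {k: v * rate for k, v in p.per_cycle_costs.items()}
            p.ae_costs = {k: v * rate for k, v in p.ae_costs.items()}
        elif currency != "usd":
            raise ValueError("currency must be 'usd' or 'cny'")
        return p


@dataclass(frozen=True)
class StrategyDef:
    """A treatment strategy: drug components with dose rules and schedules."""

    name: str
    components: tuple  # of (drug, dose_rule, dose, interval_days)
    treatment_duration_rule: str = "until_progression"

    def __post_init__(self):
        for drug, rule, dose, interval in self.components:
            if rule not in ("flat_mg", "mg_per_kg", "mg_per_m2"):
                raise ValueError(f"unknown dose rule {rule!r} for {drug}")
            if interval not in (14, 21):
                raise ValueError("administration interval must be 14 or 21 days")
            if dose <= 0:
                raise ValueError(f"dose for {drug} must be > 0")


#: cisplatin 80 mg/m2 day 1 + 5-FU 800 mg/m2/day x 5 days, q3w (assumed
#: doses for the named comparator backbone; the published dosing table is
#: not public)
CHEMO_BACKBONE = (
    ("cisplatin", "mg_per_m2", 80.0, 21),
    ("fluorouracil", "mg_per_m2", 4000.0, 21),
)


def default_strategies() -> list[StrategyDef]:
    pd1_doses = {
        "toripalimab": ("flat_mg", 240.0, 21),
        "camrelizumab": ("flat_mg", 200.0, 21),
        "pembrolizumab": ("flat_mg", 200.0, 21),
        "serplulimab": ("mg_per_kg", 3.0, 14),
        "sintilimab": ("flat_mg", 200.0, 21),
        "tislelizumab": ("flat_mg", 200.0, 21),
    }
    out = [StrategyDef(name="chemotherapy", components=CHEMO_BACKBONE)]
    for drug, (rule, dose, interval) in pd1_doses.items():
        out.append(
            StrategyDef(
                name=drug, components=((drug, rule, dose, interval),) + CHEMO_BACKBONE
            )
        )
    return out


# ---------------------------------------------------------------------------
# trace construction


def cycle_grid_years(params: EconParams) -> np.ndarray:
    """Cycle-boundary times in years: 21-day cycles with a final fractional
    cycle landing exactly on the horizon."""
    cl = params.cycle_days / DAYS_PER_YEAR
    n_full = int(math.floor(params.horizon_years / cl + 1e-12))
    grid = [c * cl for c in range(n_full + 1)]
    if grid[-1] < params.horizon_years - 1e-12:
        grid.append(params.horizon_years)
    return np.asarray(grid)


def build_trace(S_pfs, S_os, params: EconParams) -> pd.DataFrame:
    """Partitioned-survival trace on the cycle grid.

    ``S_pfs`` and ``S_os`` are survival values at the cycle boundaries
    (``cycle_grid_years``).  Where S_PFS > S_OS the PFS membership is clamped
    to S_OS (PD = 0) so rows still sum to one; the clamp count is reported in
    ``trace.attrs["clamp_count"]``.
    """
    grid = cycle_grid_years(params)
    S_pfs = np.asarray(S_pfs, dtype=float)
    S_os = np.asarray(S_os, dtype=float)
    if len(S_pfs) != len(grid) or len(S_os) != len(grid):
        raise EconError(
            f"curves must be evaluated on the cycle grid ({len(grid)} points)"
        )
    clamp = S_pfs > S_os + 1e-12
    p_pfs_b = np.where(clamp, S_os, S_pfs)
    p_pd_b = np.clip(S_os - S_pfs, 0.0, None)
    p_death_b = 1.0 - S_os

    dt = np.diff(grid)
    mid = 0.5 * (grid[:-1] + grid[1:])
    disc = (1.0 + params.annual_discount) ** (-mid)
    trace = pd.DataFrame(
        {
            "cycle": np.arange(len(dt)),
            "t_start": grid[:-1],
            "dt_years": dt,
            "p_pfs": 0.5 * (p_pfs_b[:-1] + p_pfs_b[1:]),
            "p_pd": 0.5 * (p_pd_b[:-1] + p_pd_b[1:]),
            "p_death": 0.5 * (p_death_b[:-1] + p_death_b[1:]),
            "discount": disc,
        }
    )
    trace.attrs["clamp_count"] = int(clamp.sum())
    return trace


# ---------------------------------------------------------------------------
# costing


def _component_cost_per_admin(drug, rule, dose, params: EconParams) -> float:
    try:
        spec = params.unit_costs[drug]
    except KeyError:
        raise EconError(f"unknown drug {drug!r} in unit_costs") from None
    if spec["vial_mg"] <= 0:
        raise EconError(f"zero vial strength for {drug!r}")
    if rule == "flat_mg":
        mg = dose
    elif rule == "mg_per_kg":
        mg = dose * params.body_weight
    elif rule == "mg_per_m2":
        mg = dose * params.bsa
    else:
        raise EconError(f"unknown dose rule {rule!r}")
    vials = math.ceil(mg / spec["vial_mg"] - 1e-9)
    return vials * spec["price"]


def drug_cost_per_cycle(strategy: StrategyDef, params: EconParams) -> float:
    """Acquisition cost per 21-day model cycle (vial-level ceiling, no vial
    sharing; a 14-day schedule contributes 1.5 administrations per cycle)."""
    total = 0.0
    for drug, rule, dose, interval in strategy.components:
        per_admin = _component_cost_per_admin(drug, rule, dose, params)
        total += per_admin * (params.cycle_days / interval)
    return total


def pd_state_cost_per_cycle(params: EconParams) -> float:
    """Per-cycle cost of the post-progression treatment mixture."""
    mix = params.pd_treatment_mix
    chemo = _component_cost_per_admin(
        "paclitaxel_liposome", "mg_per_m2", params.pd_chemo_dose_mg_m2, params
    )
    anlo = params.unit_costs["anlotinib"]
    caps_per_day = math.ceil(params.pd_targeted_daily_mg / anlo["vial_mg"] - 1e-9)
    targeted = caps_per_day * anlo["price"] * 14.0
    for key in ("tcm", "supportive", "chemotherapy", "targeted"):
        if key not in mix:
            raise EconError(f"pd_treatment_mix.{key} missing")
    return (
        mix["chemotherapy"] * chemo
        + mix["targeted"] * targeted
        + mix["tcm"] * params.per_cycle_costs["tcm_herbal"]
        + mix["supportive"] * params.per_cycle_costs["supportive_care"]
    )


def accrue(
    trace: pd.DataFrame, strategy: StrategyDef, params: EconParams
) -> dict:
    """Discounted totals (cost, QALY, LY) for one strategy over the trace.

    PFS-state cycle cost = drug acquisition + administration + laboratory /
    radiology + supportive care + hospitalization + routine follow-up; the PD
    state accrues the post-progression mixture cost.  Adverse-event costs and
    disutilities are one-off, applied to the whole cohort at model start.
    """
    for cat in (
        "administration",
        "laboratory_radiology",
        "supportive_care",
        "hospitalization",
        "routine_follow_up",
    ):
        if cat not in params.per_cycle_costs:
            raise EconError(f"per_cycle_costs.{cat} missing")
    cycle_years = params.cycle_days / DAYS_PER_YEAR
    pfs_cost = drug_cost_per_cycle(strategy, params) + sum(
        params.per_cycle_costs[c]
        for c in (
            "administration",
            "laboratory_radiology",
            "supportive_care",
            "hospitalization",
            "routine_follow_up",
        )
    )
    pd_cost = pd_state_cost_per_cycle(params)
    u_pfs, u_pd = params.utilities["pfs"], params.utilities["pd"]

    scale = trace["dt_years"].to_numpy() / cycle_years  # fractional last cycle
    disc = trace["discount"].to_numpy()
    p_pfs = trace["p_pfs"].to_numpy()
    p_pd = trace["p_pd"].to_numpy()
    dt = trace["dt_years"].to_numpy()

    cost = float(((pfs_cost * p_pfs + pd_cost * p_pd) * scale * disc).sum())
    qaly = float(((u_pfs * p_pfs + u_pd * p_pd) * dt * disc).sum())
    ly_disc = disc if params.discount_lys else np.ones_like(disc)
    ly = float(((p_pfs + p_pd) * dt * ly_disc).sum())

    inc = params.ae_incidence.get(strategy.name, {})
    ae_cost = 0.0
    ae_dis = 0.0
    for ae, prob in inc.items():
        if ae not in params.ae_costs:
            raise EconError(f"ae_costs.{ae} missing")
        if ae not in params.ae_disutilities:
            raise EconError(f"ae_disutilities.{ae} missing")
        ae_cost += prob * params.ae_costs[ae]
        ae_dis += prob * params.ae_disutilities[ae]
    return {
        "strategy": strategy.name,
        "cost": cost + ae_cost,
        "qaly": qaly + ae_dis,
        "ly": ly,
    }


# ---------------------------------------------------------------------------
# ICER assembly


def icer_table(
    results: pd.DataFrame, reference: str, params: EconParams
) -> pd.DataFrame:
    """Incremental cost-effectiveness table vs the reference strategy.

    ``results`` needs columns ``strategy, cost, qaly`` (``ly`` optional).
    Strategies with non-positive incremental QALYs are flagged (dominated or
    equivalent) and excluded from the ICER ranking.  The returned frame
    carries ``attrs["n_below_wtp"]``.
    """
    df = results.set_index("strategy") if "strategy" in results.columns else results.copy()
    if reference not in df.index:
        raise EconError(f"reference {reference!r} not among strategies")
    ref = df.loc[reference]
    out = df.copy()
    out["inc_cost"] = df["cost"] - ref["cost"]
    out["inc_qaly"] = df["qaly"] - ref["qaly"]
    out["icer"] = np.nan
    out["flag"] = ""
    for s in out.index:
        if s == reference:
            out.loc[s, "flag"] = "reference"
            continue
        dq = out.loc[s, "inc_qaly"]
        dc = out.loc[s, "inc_cost"]
        if dq > 0:
            out.loc[s, "icer"] = dc / dq
            if dc < 0:
                out.loc[s, "flag"] = "dominant"
        elif dq == 0 and dc == 0:
            out.loc[s, "flag"] = "equivalent"
        else:
            out.loc[s, "flag"] = "dominated"
    rankable = out[(out.index != reference) & (out["inc_qaly"] > 0)]
    ranks = rankable["icer"].rank(method="min").astype(int)
    out["rank"] = pd.Series(ranks, index=rankable.index).reindex(out.index)
    out["below_wtp"] = (out["icer"] < params.wtp_per_qaly) & out["icer"].notna()
    # a dominant strategy (cheaper, more effective) is cost-effective a fortiori
    out.loc[out["flag"] == "dominant", "below_wtp"] = True
    out.attrs["n_below_wtp"] = int(out["below_wtp"].sum())
    return out
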