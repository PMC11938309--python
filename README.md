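# survcea

Cost-effectiveness analysis machinery for first-line PD-1 inhibitor plus
chemotherapy regimens in advanced oesophageal squamous cell carcinoma
(ESCC), built as a reusable, tested Python pipeline:

1. **KM reconstruction** — recover approximate individual patient data
   (IPD) from digitized Kaplan–Meier coordinates plus numbers-at-risk
   tables (the Guyot algorithm), with Cox-HR validation and
   non-proportional-hazards diagnostics (log-cumulative-hazard crossing,
   kernel-smoothed hazards).
2. **Survival fitting** — maximum-likelihood fits of seven standard
   parametric families, Royston–Parmar flexible parametric splines on the
   log-cumulative-hazard / log-odds / probit scales, and restricted-cubic-
   spline log-hazard models; minimum-AIC selection with BIC tie-breaks.
3. **Fractional-polynomial network meta-analysis** — time-varying log
   hazard ratios `ln HR(t) = d0 + d1·t^p` estimated over a star network of
   trials against a common chemotherapy reference, via a binomial
   interval-count likelihood with a complementary-log-log link
   (fixed effects, Wald CIs, I² heterogeneity).
4. **Partitioned survival model** — three states (progression-free,
   progressed, dead) read directly off the PFS/OS curves on a 21-day cycle
   grid over 5 years, half-cycle corrected, 5%/year discounting, Chinese
   healthcare-system costing (vial-level drug acquisition, per-cycle
   management categories, one-off adverse-event burden, post-progression
   treatment mixture), producing cost/QALY/LY totals and an ICER table
   against chemotherapy with a willingness-to-pay (WTP) threshold of
   $36,598.19 per QALY.
5. **Sensitivity analysis** — one-way (tornado) analysis with ±20% ranges
   (drug prices vary only downward to 80% of list), and probabilistic
   sensitivity analysis with gamma/beta/normal/Dirichlet parameter
   distributions, CE-plane scatter, and cost-effectiveness acceptability
   curves under a pairwise net-monetary-benefit rule.
6. **Synthetic trials** — a first-class generator of two-arm survival data
   with known time-varying hazard-ratio truth and digitization-style KM
   artifacts, so every stage can be validated end-to-end without any
   external data.

The intended users are health-economics and biostatistics practitioners
who need a scriptable, reproducible version of this analysis chain — for
re-analysis with updated prices, different WTP thresholds, new comparator
sets, or methodological experiments.

## Worked example

Reassemble the base-case incremental cost-effectiveness table from the
published per-strategy totals, and evaluate a time-varying hazard ratio:

```python
import survcea as sc
from survcea.published import base_case_totals, OS_CONTRASTS

params = sc.EconParams()                      # Table-2 style defaults, USD
tab = sc.icer_table(base_case_totals(), "chemotherapy", params)
print(tab[["cost", "qaly", "inc_cost", "inc_qaly", "icer", "rank",
           "below_wtp"]].round(2))
print("strategies below WTP:", tab.attrs["n_below_wtp"])

sint = next(c for c in OS_CONTRASTS if c.treatment == "sintilimab")
for t in (3, 6, 12, 24):
    print(f"HR_sintilimab_OS({t} mo) = {sc.hr_curve(sint, [t])[0]:.3f}")
```

prints

```
                   cost  qaly  inc_cost  inc_qaly       icer  rank  below_wtp
strategy
chemotherapy   14025.37  0.66      0.00      0.00        NaN   NaN      False
toripalimab    33743.55  1.27  19718.18      0.61   32324.89   2.0       True
camrelizumab   30594.67  1.00  16569.30      0.34   48733.24   4.0      False
pembrolizumab  96591.87  0.92  82566.50      0.26  317563.46   6.0      False
serplulimab    71012.44  1.13  56987.07      0.47  121249.09   5.0      False
sintilimab     26033.52  1.06  12008.15      0.40   30020.37   1.0       True
tislelizumab   28047.10  1.06  14021.73      0.40   35054.32   3.0       True
strategies below WTP: 3
HR_sintilimab_OS(3 mo) = 0.529
HR_sintilimab_OS(6 mo) = 0.581
HR_sintilimab_OS(12 mo) = 0.609
HR_sintilimab_OS(24 mo) = 0.623
```

Reading: each incremental cost is the strategy's discounted 5-year total
minus the chemotherapy total; the ICER divides it by the QALY gain.
Sintilimab, toripalimab and tislelizumab (ranks 1–3) fall below the WTP
threshold. The OS hazard ratio for sintilimab starts around 0.53 and decays
toward its long-run value `exp(d0) = exp(-0.45) ≈ 0.64` as `d1/t` vanishes.

## Command-line pipeline

The `survcea` entry point runs the whole chain on a YAML config of
synthetic trial specifications (see `tests/test_pipeline_cli.py` for a
minimal config):

```bash
survcea validate --config config.yaml
survcea run-all  --config config.yaml --seed 11 --out results/
```

Outputs: simulated and reconstructed IPD, a survival-model scan table, the
fitted contrast table, the ICER table, tornado, PSA scatter and CEAC CSVs,
plus a `manifest.json` with per-stage seeds and the config hash (also
stamped into every CSV header).

## Limitations

The reference-arm spline coefficients, trial-level adverse-event incidence
table and full dosing table of the source analysis are not public, so the
package ships documented assumptions for those inputs (see
`docs/methods.md`); absolute cost/QALY totals from the bundled defaults are
therefore illustrative, while the structural machinery (reconstruction,
NMA, PSM arithmetic, DSA/PSA) is exact and fully tested.
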