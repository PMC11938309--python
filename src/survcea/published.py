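"""Published reference inputs for the six first-line PD-1 + chemotherapy
regimens in advanced oesophageal squamous cell carcinoma.

Two tables from the source cost-effectiveness study are shipped as data so
worked examples and validation runs need no external files:

* first-order fractional-polynomial contrast estimates vs chemotherapy
  (d0, d1 with 95% CIs; PFS at power p = -2, OS at power p = -1);
* base-case totals (discounted cost, QALY, LY) per strategy, from which the
  incremental table can be reassembled.
"""

from __future__ import annotations

import pandas as pd

from .fp_nma import FPContrast

#: PFS contrasts, first-order fractional polynomial, p = -2
PFS_CONTRASTS = [
    FPContrast("toripalimab", -2.0, -0.91, (-1.30, -0.52), 2.76, (-0.08, 5.60), "pfs"),
    FPContrast("camrelizumab", -2.0, -0.69, (-0.95, -0.43), 1.19, (-1.08, 3.46), "pfs"),
    FPContrast("pembrolizumab", -2.0, -0.26, (-0.47, -0.05), 1.14, (-0.62, 2.90), "pfs"),
    FPContrast("serplulimab", -2.0, -0.62, (-0.95, -0.30), 0.85, (-1.50, 3.19), "pfs"),
    FPContrast("sintilimab", -2.0, -0.62, (-0.88, -0.36), -0.10, (-2.34, 2.16), "pfs"),
    FPContrast("tislelizumab", -2.0, -0.38, (-0.63, -0.14), -1.34, (-3.36, 0.69), "pfs"),
]

#: OS contrasts, first-order fractional polynomial, p = -1
OS_CONTRASTS = [
    FPContrast("toripalimab", -1.0, -1.00, (-1.59, -0.41), 1.71, (-0.86, 4.28), "os"),
    FPContrast("camrelizumab", -1.0, -0.41, (-0.82, 0.01), -0.01, (-2.18, 2.17), "os"),
    FPContrast("pembrolizumab", -1.0, -0.34, (-0.60, -0.08), 0.30, (-1.54, 0.94), "os"),
    FPContrast("serplulimab", -1.0, -0.73, (-1.13, -0.33), 0.67, (-1.28, 2.62), "os"),
    FPContrast("sintilimab", -1.0, -0.45, (-0.82, -0.08), -0.56, (-2.40, 1.29), "os"),
    FPContrast("tislelizumab", -1.0, -0.52, (-0.82, -0.23), -0.14, (-1.63, 1.36), "os"),
]


def base_case_totals() -> pd.DataFrame:
    """Published base-case discounted totals per strategy (USD, QALYs, LYs)."""
    rows = [
        ("chemotherapy", 14025.37, 0.66, 0.96),
        ("toripalimab", 33743.55, 1.27, 1.84),
        ("camrelizumab", 30594.67, 1.00, 1.41),
        ("pembrolizumab", 96591.87, 0.92, 1.37),
        ("serplulimab", 71012.44, 1.13, 1.62),
        ("sintilimab", 26033.52, 1.06, 1.52),
        ("tislelizumab", 28047.10, 1.06, 1.56),
    ]
    return pd.DataFrame(rows, columns=["strategy", "cost", "qaly", "ly"])
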