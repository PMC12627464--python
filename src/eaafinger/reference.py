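"""Published summary values from the germ-free / conventionalized mouse study.

These printed per-EAA offset summaries (mean ± SD per organ × group, Welch p
values) and the muscle group statistics are inputs for worked examples and
desk checks; the raw per-mouse data behind them are not redistributed here.

Known internal inconsistencies of the printed table, preserved as printed:
the kidney GF "Avg" cell prints 2.2 although its six per-EAA means average to
2.25; the muscle "Avg" cells (4.5 / 3.7) do not match either the per-EAA means
(4.23 / 3.63) or the group statistics quoted in the running text
(4.24 ± 0.31 vs 3.65 ± 0.25).  Analyses in this package always compute from
full-precision values and round only in reporting.
"""

from __future__ import annotations

import pandas as pd

from .io import EAA_PANEL

#: Per-organ, per-group printed offset summaries: {organ: {group: {aa: (mean, sd)}}}
TABLE1: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "brain": {
        "GF": {"Ile": (4.8, 0.2), "Leu": (4.0, 0.2), "Lys": (0.7, 0.3),
               "Phe": (2.9, 0.2), "Thr": (6.5, 0.3), "Val": (4.5, 0.2)},
        "CVZ": {"Ile": (4.7, 0.1), "Leu": (3.8, 0.1), "Lys": (0.8, 0.2),
                "Phe": (2.9, 0.2), "Thr": (6.1, 0.3), "Val": (4.4, 0.2)},
    },
    "kidney": {
        "GF": {"Ile": (2.5, 0.4), "Leu": (2.7, 0.1), "Lys": (0.5, 0.4),
               "Phe": (1.9, 0.1), "Thr": (3.1, 0.6), "Val": (2.8, 0.5)},
        "CVZ": {"Ile": (2.4, 1.0), "Leu": (2.4, 0.5), "Lys": (0.5, 1.2),
                "Phe": (1.6, 0.8), "Thr": (2.9, 1.3), "Val": (2.6, 0.8)},
    },
    "liver": {
        "GF": {"Ile": (1.7, 0.1), "Leu": (2.0, 0.2), "Lys": (0.4, 0.4),
               "Phe": (1.6, 0.1), "Thr": (5.3, 0.3), "Val": (2.0, 0.5)},
        "CVZ": {"Ile": (1.5, 0.1), "Leu": (1.7, 0.2), "Lys": (0.6, 0.6),
                "Phe": (1.3, 0.3), "Thr": (4.6, 0.7), "Val": (1.8, 0.3)},
    },
    "muscle": {
        "GF": {"Ile": (5.5, 0.1), "Leu": (4.7, 0.1), "Lys": (1.9, 0.9),
               "Phe": (4.8, 0.8), "Thr": (4.3, 0.4), "Val": (4.2, 0.3)},
        "CVZ": {"Ile": (5.3, 0.3), "Leu": (4.2, 0.2), "Lys": (1.5, 0.4),
                "Phe": (3.6, 0.8), "Thr": (3.7, 0.5), "Val": (3.5, 0.4)},
    },
}

#: Printed "Avg" cells as they appear (see module docstring for caveats).
TABLE1_AVG_PRINTED: dict[str, dict[str, float]] = {
    "brain": {"GF": 3.9, "CVZ": 3.8},
    "kidney": {"GF": 2.2, "CVZ": 2.1},
    "liver": {"GF": 2.2, "CVZ": 1.9},
    "muscle": {"GF": 4.5, "CVZ": 3.7},
}

#: Printed Welch p values per organ × EAA.
TABLE1_P: dict[str, dict[str, float]] = {
    "brain": {"Ile": 0.154, "Leu": 0.190, "Lys": 0.521, "Phe": 0.829,
              "Thr": 0.053, "Val": 0.149},
    "kidney": {"Ile": 0.736, "Leu": 0.231, "Lys": 0.968, "Phe": 0.465,
               "Thr": 0.786, "Val": 0.625},
    "liver": {"Ile": 0.027, "Leu": 0.037, "Lys": 0.439, "Phe": 0.050,
              "Thr": 0.099, "Val": 0.323},
    "muscle": {"Ile": 0.296, "Leu": 0.005, "Lys": 0.417, "Phe": 0.044,
               "Thr": 0.038, "Val": 0.013},
}

#: Muscle mean-offset group statistics from the running text: mean, SD, n.
MUSCLE_GROUP_STATS: dict[str, tuple[float, float, int]] = {
    "GF": (4.24, 0.31, 5),
    "CVZ": (3.65, 0.25, 5),
}

#: Organ carbon replacement over the 20-day feeding period.
ORGAN_TURNOVER: dict[str, float] = {
    "liver": 0.75,
    "kidney": 0.60,
    "muscle": 0.45,
    "brain": 0.30,
}

#: Stated analytical performance of the isotope measurements (‰).
ANALYTICAL_PRECISION = 0.2
ANALYTICAL_ACCURACY = 0.5

#: Classifier library sizes (reference organisms per class).
CLASSIFIER_N = {"bacteria": 12, "fungi": 9, "plants": 11}


def table1_frame() -> pd.DataFrame:
    """Tidy view of the printed summaries: organ, group, amino_acid, mean, sd, p."""
    rows = []
    for organ, groups in TABLE1.items():
        for group, cells in groups.items():
            for aa in EAA_PANEL:
                m, s = cells[aa]
                rows.append(
                    {"organ": organ, "group": group, "amino_acid": aa,
                     "mean": m, "sd": s, "p": TABLE1_P[organ][aa]}
                )
    return pd.DataFrame(rows)
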