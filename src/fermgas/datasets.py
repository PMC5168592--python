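"""Published reference datasets for *Thermotoga maritima* batch fermentations.

Typed-in mean values from a controlled batch-culture study of glucose dark
fermentation, comprising:

* a serum-bottle screen of sulfured nutriments (control, DMSO, elemental
  sulfur, methionine, thiosulfate, cysteine, sodium sulfide; 25 mM glucose,
  1 g/L yeast extract), sampled at 0, 14.5 and 22 h;
* bioreactor runs at four imposed hydrogen partial pressures (7.1 to
  606.9 mbar; 25 mM glucose), sampled at phase times t0/t1/t2/t3;
* bioreactor runs at seven initial thiosulfate concentrations (0 to
  0.24 mmol/L; 60 mM glucose, 1 g/L yeast extract, outlet H2 held at 5 %),
  sampled at t0/t1/t2/t3, including L-alanine and EPS assays for three
  conditions;
* the two-condition sulfur budget (cells and medium sulfur sources).

Concentrations are mmol/L, cells mg dry weight per L, times hours.  Only
reported means are typed in; the published uncertainties are not carried.
Accessors return :class:`~fermgas.accounting.FermentationRun` objects ready
for the accounting layer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .accounting import FermentationRun, PhaseMarkers

__all__ = [
    "serum_bottle_table",
    "ph2_series_table",
    "thiosulfate_series_table",
    "sulfur_budget_table",
    "serum_bottle_run",
    "ph2_run",
    "thiosulfate_run",
    "thiosulfate_yield_points",
]

_NA = float("nan")

# condition -> rows of (time_h, cells, glucose_consumed, lactate, acetate, h2)
_SERUM_BOTTLE = {
    "control": [
        (0.0, 4.8, 0.0, 0.0, 0.0, 0.0),
        (14.5, 108.2, 3.8, 0.5, 5.4, 9.3),
        (22.0, 158.2, 7.1, 0.8, 10.1, 21.3),
    ],
    "DMSO": [
        (0.0, 6.0, 0.0, 0.0, 0.0, 0.0),
        (14.5, 129.7, 5.2, 0.4, 7.4, 14.9),
        (22.0, 160.8, 9.2, 0.8, 13.3, 28.7),
    ],
    "sulfur": [
        (0.0, 5.9, 0.0, 0.0, 0.0, 0.0),
        (14.5, 191.8, 11.0, 1.3, 16.3, 28.0),
        (22.0, 158.2, 16.6, 3.4, 23.8, 46.1),
    ],
    "methionine": [
        (0.0, 5.1, 0.0, 0.0, 0.0, 0.0),
        (14.5, 217.7, 11.9, 1.1, 17.3, 30.0),
        (22.0, 227.8, 18.3, 3.1, 26.5, 53.3),
    ],
    "thiosulfate": [
        (0.0, 4.1, 0.0, 0.0, 0.0, 0.0),
        (14.5, 250.6, 15.4, 3.6, 22.0, 39.7),
        (22.0, 157.0, 17.5, 6.3, 24.1, 47.3),
    ],
    "cysteine": [
        (0.0, 4.7, 0.0, 0.0, 0.0, 0.0),
        (14.5, 300.6, 16.8, 2.2, 25.4, 45.0),
        (22.0, 158.2, 20.4, 4.1, 30.5, 58.5),
    ],
    "sulfide": [
        (0.0, 4.7, 0.0, 0.0, 0.0, 0.0),
        (14.5, 264.6, 20.4, 4.7, 28.1, 50.9),
        (22.0, 234.2, 20.4, 4.7, 30.7, 54.9),
    ],
}

# pH2 (mbar) -> rows of (phase, time_h, cells, glucose_consumed, lactate,
# acetate, h2, co2); H2 could not be quantified at 606.9 mbar.
_PH2_SERIES = {
    7.1: [
        ("t0", 0.0, 14.8, 0.0, 0.0, 0.0, 0.0, 0.0),
        ("t1", 6.7, 17.5, 0.3, 0.1, 0.6, 0.4, 0.4),
        ("t2", 41.7, 127.5, 18.5, 8.9, 23.6, 44.5, 22.5),
        ("t3", 49.8, 122.5, 19.8, 10.5, 25.0, 46.4, 23.3),
    ],
    71.4: [
        ("t0", 0.0, 14.7, 0.0, 0.0, 0.0, 0.0, 0.0),
        ("t1", 5.5, 19.1, 0.5, 0.2, 0.7, 1.4, 0.3),
        ("t2", 40.4, 123.6, 18.1, 8.8, 22.5, 43.0, 20.0),
        ("t3", 46.2, 118.2, 19.7, 11.0, 24.6, 48.0, 21.8),
    ],
    178.5: [
        ("t0", 0.0, 12.7, 0.0, 0.0, 0.0, 0.0, 0.0),
        ("t1", 5.5, 22.7, 0.2, 0.1, 0.2, 0.6, 0.3),
        ("t2", 38.2, 129.8, 16.9, 9.2, 19.9, 39.3, 19.2),
        ("t3", 39.0, 127.3, 17.2, 9.4, 20.1, 40.0, 19.5),
    ],
    606.9: [
        ("t0", 0.0, 18.9, 0.0, 0.0, 0.0, _NA, 0.0),
        ("t1", 4.4, 23.9, 1.0, 0.0, 0.0, _NA, 0.3),
        ("t2", 41.7, 96.4, 11.9, 8.9, 12.0, _NA, 11.1),
        ("t3", 48.5, 96.3, 13.4, 11.0, 13.0, _NA, 12.2),
    ],
}

# thiosulfate (mmol/L) -> rows of (phase, time_h, cells, glucose_consumed,
# lactate, acetate, co2, h2, alanine, eps_glucose_equiv)
_THIOSULFATE_SERIES = {
    0.0: [
        ("t0", 0.0, 19.3, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        ("t1", 4.8, 31.8, 1.3, 0.2, 0.5, 0.2, 0.3, _NA, _NA),
        ("t2", 29.5, 127.6, 16.4, 4.9, 11.8, 11.1, 23.2, 1.39, 4.7),
        ("t3", 30.6, 119.8, 17.7, 5.4, 12.8, 11.9, 25.0, _NA, _NA),
    ],
    0.01: [
        ("t0", 0.0, 16.8, 0.0, 0.0, 0.0, 0.0, 0.0, _NA, _NA),
        ("t1", 3.1, 22.8, 2.1, 0.1, 0.2, 0.2, 0.4, _NA, _NA),
        ("t2", 22.8, 178.0, 19.8, 10.0, 16.0, 15.0, 30.7, _NA, _NA),
        ("t3", 23.0, 177.4, 20.0, 10.2, 16.0, 15.0, 31.0, _NA, _NA),
    ],
    0.03: [
        ("t0", 0.0, 23.6, 0.0, 0.0, 0.0, 0.0, 0.0, _NA, _NA),
        ("t1", 6.7, 32.1, 0.0, 0.0, 0.0, 0.2, 0.3, _NA, _NA),
        ("t2", 24.1, 265.0, 25.2, 6.8, 27.5, 27.3, 53.5, _NA, _NA),
        ("t3", 27.5, 264.1, 28.0, 8.2, 30.6, 29.7, 57.9, _NA, _NA),
    ],
    0.06: [
        ("t0", 0.0, 26.1, 0.0, 0.0, 0.0, 0.0, 0.0, _NA, _NA),
        ("t1", 1.8, 33.7, 0.7, 0.0, 0.1, 0.1, 0.3, _NA, _NA),
        ("t2", 20.4, 353.5, 38.2, 18.0, 37.7, 35.7, 73.2, _NA, _NA),
        ("t3", 22.3, 352.3, 38.5, 18.1, 38.2, 35.8, 73.3, _NA, _NA),
    ],
    0.12: [
        ("t0", 0.0, 24.4, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        ("t1", 3.0, 34.1, 1.1, 0.0, 0.8, 0.3, 0.3, _NA, _NA),
        ("t2", 17.9, 404.0, 42.4, 15.9, 47.0, 44.2, 90.5, 3.8, 3.6),
        ("t3", 23.2, 396.6, 45.7, 15.4, 52.4, 51.9, 99.7, _NA, _NA),
    ],
    0.18: [
        ("t0", 0.0, 25.3, 0.0, 0.0, 0.0, 0.0, 0.0, _NA, _NA),
        ("t1", 1.2, 32.7, 0.3, 0.0, 0.0, 0.4, 0.4, _NA, _NA),
        ("t2", 16.8, 428.8, 45.0, 23.3, 44.5, 44.6, 86.7, _NA, _NA),
        ("t3", 17.0, 418.0, 45.4, 23.4, 45.0, 44.7, 86.9, _NA, _NA),
    ],
    0.24: [
        ("t0", 0.0, 27.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        ("t1", 2.1, 33.8, 0.9, 0.0, 0.0, 0.2, 0.5, _NA, _NA),
        ("t2", 17.0, 423.9, 41.7, 22.5, 43.4, 40.0, 84.0, 3.8, 2.9),
        ("t3", 22.8, 422.4, 43.8, 26.4, 46.1, 42.2, 88.6, _NA, _NA),
    ],
}

# (condition, s_yeast_extract, s_thiosulfate, cells, thiosulfate_initial)
_SULFUR_BUDGET = [
    ("yeast extract only", 0.07, 0.00, 128.0, 0.0),
    ("yeast extract + 0.06 mM thiosulfate", 0.07, 0.12, 354.0, 0.06),
]


def serum_bottle_table() -> pd.DataFrame:
    """Serum-bottle sulfured-nutriment screen as a tidy DataFrame."""
    rows = [
        {
            "condition": cond,
            "time_h": t,
            "cells_mg_L": c,
            "glucose_consumed_mM": g,
            "lactate_mM": lac,
            "acetate_mM": ac,
            "H2_mM": h2,
        }
        for cond, data in _SERUM_BOTTLE.items()
        for (t, c, g, lac, ac, h2) in data
    ]
    return pd.DataFrame(rows)


def ph2_series_table() -> pd.DataFrame:
    """Bioreactor runs at imposed hydrogen partial pressures, tidy DataFrame."""
    rows = [
        {
            "ph2_mbar": ph2,
            "phase": phase,
            "time_h": t,
            "cells_mg_L": c,
            "glucose_consumed_mM": g,
            "lactate_mM": lac,
            "acetate_mM": ac,
            "H2_mM": h2,
            "CO2_mM": co2,
        }
        for ph2, data in _PH2_SERIES.items()
        for (phase, t, c, g, lac, ac, h2, co2) in data
    ]
    return pd.DataFrame(rows)


def thiosulfate_series_table() -> pd.DataFrame:
    """Bioreactor thiosulfate-limitation runs, tidy DataFrame."""
    rows = [
        {
            "thiosulfate_mM": thio,
            "phase": phase,
            "time_h": t,
            "cells_mg_L": c,
            "glucose_consumed_mM": g,
            "lactate_mM": lac,
            "acetate_mM": ac,
            "CO2_mM": co2,
            "H2_mM": h2,
            "alanine_mM": ala,
            "eps_glcEq_mM": eps,
        }
        for thio, data in _THIOSULFATE_SERIES.items()
        for (phase, t, c, g, lac, ac, co2, h2, ala, eps) in data
    ]
    return pd.DataFrame(rows)


def sulfur_budget_table() -> pd.DataFrame:
    """Reported sulfur inventories for the two limiting growth conditions."""
    return pd.DataFrame(
        _SULFUR_BUDGET,
        columns=[
            "condition",
            "s_yeast_extract_mM",
            "s_thiosulfate_mM",
            "cells_mg_L",
            "thiosulfate_mM",
        ],
    )


def serum_bottle_run(condition: str) -> FermentationRun:
    """One serum-bottle condition as a FermentationRun (stoichiometric CO2)."""
    data = _SERUM_BOTTLE[condition]
    arr = np.array([row for row in data], dtype=float)
    return FermentationRun(
        time_h=arr[:, 0],
        cells=arr[:, 1],
        glucose_consumed=arr[:, 2],
        lactate=arr[:, 3],
        acetate=arr[:, 4],
        h2=arr[:, 5],
        co2=None,
        co2_mode="acetate_stoichiometric",
        yeast_extract_g_L=1.0,
        thiosulfate_initial_mM=0.3 / 2 if condition == "thiosulfate" else 0.0,
        label=f"serum bottle / {condition}",
    )


def ph2_run(ph2_mbar: float) -> FermentationRun:
    """One imposed-pH2 bioreactor run as a FermentationRun."""
    data = _PH2_SERIES[ph2_mbar]
    arr = np.array([row[1:] for row in data], dtype=float)
    return FermentationRun(
        time_h=arr[:, 0],
        cells=arr[:, 1],
        glucose_consumed=arr[:, 2],
        lactate=arr[:, 3],
        acetate=arr[:, 4],
        h2=arr[:, 5],
        co2=arr[:, 6],
        co2_mode="measured",
        phases=PhaseMarkers(*(row[1] for row in data)),
        label=f"bioreactor / pH2 {ph2_mbar} mbar",
    )


def thiosulfate_run(thiosulfate_mM: float) -> FermentationRun:
    """One thiosulfate-limitation bioreactor run as a FermentationRun."""
    data = _THIOSULFATE_SERIES[thiosulfate_mM]
    arr = np.array([row[1:] for row in data], dtype=float)
    has_side = np.isfinite(arr[:, 7]).any()
    return FermentationRun(
        time_h=arr[:, 0],
        cells=arr[:, 1],
        glucose_consumed=arr[:, 2],
        lactate=arr[:, 3],
        acetate=arr[:, 4],
        co2=arr[:, 5],
        h2=arr[:, 6],
        alanine=arr[:, 7] if has_side else None,
        eps_glucose_equiv=arr[:, 8] if has_side else None,
        co2_mode="measured",
        thiosulfate_initial_mM=thiosulfate_mM,
        yeast_extract_g_L=1.0,
        phases=PhaseMarkers(*(row[1] for row in data)),
        label=f"bioreactor / thiosulfate {thiosulfate_mM} mmol/L",
    )


def thiosulfate_concentrations() -> list[float]:
    """Initial thiosulfate levels of the limitation series, mmol/L."""
    return sorted(_THIOSULFATE_SERIES)


def thiosulfate_yield_points(max_thiosulfate_mM: float = 0.06) -> list[tuple[float, float]]:
    """(initial thiosulfate, maximum cell density at t2) pairs for the yield fit."""
    pts = []
    for thio, data in sorted(_THIOSULFATE_SERIES.items()):
        if thio <= max_thiosulfate_mM:
            t2_row = next(row for row in data if row[0] == "t2")
            pts.append((thio, t2_row[2]))
    return pts
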