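"""Method-agreement statistics for automated-versus-manual comparison.

Paired tables use the column names ``manual`` and ``macro`` — 'macro'
being the conventional label for the automated measurement in this
workflow.

Lin's concordance correlation coefficient (ccc) measures agreement of
two measurement series against the identity line, penalising both poor
correlation and location/scale shift:

    ccc = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)

with population (1/n) moments.  The 95% confidence interval is
computed on Fisher's z-transform of the ccc with Lin's asymptotic
standard error.

Percent deviation follows the convention (manual - macro)/manual*100,
so a macro value larger than manual is *negative*.

The per-object sensitivity/specificity pair implements
sensitivity = TP/(TP+FP) and specificity = TP/(TP+FN) as printed in
the source protocol this package follows; since these names are
nonstandard (they are conventionally precision and recall), the result
carries both namings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "ObjectAgreement",
    "concordance_correlation",
    "percent_deviation",
    "object_agreement",
    "agreement_table",
    "read_paired_table",
]


@dataclass
class PairedSeries:
    x: np.ndarray  # manual values
    y: np.ndarray  # macro values

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1D arrays of equal length")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class AgreementReport:
    ccc: float
    ccc_ci95: tuple[float, float]
    mean_pct_deviation: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None


@dataclass
class ObjectAgreement:
    sensitivity_pct: float  # TP/(TP+FP): conventionally 'precision'
    specificity_pct: float  # TP/(TP+FN): conventionally 'recall'

    @property
    def precision_pct(self) -> float:
        return self.sensitivity_pct

    @property
    def recall_pct(self) -> float:
        return self.specificity_pct


def concordance_correlation(s: PairedSeries) -> tuple[float, tuple[float, float]]:
    """Lin's ccc with 95% CI via the Fisher z-transform."""
    n = s.n
    if n < 3:
        raise ValueError("need at least 3 pairs")
    x, y = s.x, s.y
    mx, my = x.mean(), y.mean()
    sx2 = ((x - mx) ** 2).mean()
    sy2 = ((y - my) ** 2).mean()
    sxy = ((x - mx) * (y - my)).mean()
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("both series constant: ccc undefined")
    ccc = 2.0 * sxy / denom

    if sx2 == 0 or sy2 == 0:
        return float(ccc), (float(ccc), float(ccc))
    r = sxy / np.sqrt(sx2 * sy2)
    if abs(ccc) >= 1.0 - 1e-12 or r == 0:
        return float(ccc), (float(ccc), float(ccc))
    u = (mx - my) / (sx2 * sy2) ** 0.25
    one_m = 1.0 - ccc**2
    se_z2 = (
        (1.0 - r**2) * ccc**2 / (one_m * r**2)
        + 2.0 * ccc**3 * (1.0 - ccc) * u**2 / (r * one_m**2)
        - ccc**4 * u**4 / (2.0 * r**2 * one_m**2)
    ) / (n - 2)
    se_z = np.sqrt(max(se_z2, 0.0))
    z = np.arctanh(ccc)
    lo, hi = np.tanh(z - 1.959964 * se_z), np.tanh(z + 1.959964 * se_z)
    return float(ccc), (float(lo), float(hi))


def percent_deviation(manual: float, macro: float) -> float:
    """(manual - macro) / manual * 100; sign preserved."""
    if manual == 0:
        raise ValueError("manual value is zero: percent deviation undefined")
    return (manual - macro) / manual * 100.0


def object_agreement(tp: int, fp: int, fn: int) -> ObjectAgreement:
    """Per-object agreement percentages from pre-matched counts."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0 or tp + fn == 0:
        raise ValueError("zero denominator: agreement undefined")
    return ObjectAgreement(
        sensitivity_pct=100.0 * tp / (tp + fp),
        specificity_pct=100.0 * tp / (tp + fn),
    )


def read_paired_table(path) -> pd.DataFrame:
    """Read a delimited table with columns nmj_id, feature, manual, macro."""
    df = pd.read_csv(Path(path), sep=None, engine="python")
    required = {"nmj_id", "feature", "manual", "macro"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"paired table missing columns: {sorted(missing)}")
    return df


def agreement_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-feature agreement report (ccc, CI, mean % deviation)."""
    rows = []
    for feature, grp in df.groupby("feature", sort=True):
        s = PairedSeries(grp["manual"].to_numpy(), grp["macro"].to_numpy())
        ccc, (lo, hi) = concordance_correlation(s)
        devs = [
            percent_deviation(m, k) for m, k in zip(s.x, s.y) if m != 0
        ]
        rows.append(
            {
                "feature": feature,
                "n": s.n,
                "manual_mean": float(s.x.mean()),
                "macro_mean": float(s.y.mean()),
                "ccc": ccc,
                "ccc_ci95_lo": lo,
                "ccc_ci95_hi": hi,
                "mean_pct_deviation": float(np.mean(np.abs(devs))) if devs else np.nan,
            }
        )
    return pd.DataFrame(rows)
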