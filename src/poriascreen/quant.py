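"""HPLC calibration curves, LOD/LOQ, recovery, and between-part content tests.

Standard curves regress integrated peak area Y on standard concentration X
(ordinary least squares); R^2 is the squared Pearson correlation, flagged
against the conventional > 0.99 linearity criterion. LOD and LOQ are the
concentrations at signal-to-noise 3 and 10. Spike recovery is judged against
the pharmacopeia band of 85-110% (inclusive). Between-part content
comparisons use Welch's unequal-variance two-sample t-test per analyte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

R2_LINEARITY_MIN = 0.99
RECOVERY_BAND = (85.0, 110.0)


@dataclass
class CalibrationCurve:
    analyte: str
    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]  # ug/ml
    lod: float | None = None
    loq: float | None = None

    @property
    def linearity_ok(self) -> bool:
        return self.r_squared > R2_LINEARITY_MIN

    def concentration(self, area: np.ndarray) -> np.ndarray:
        """Invert the curve; see ``quantify_and_compare`` for range flags."""
        return (np.asarray(area, dtype=float) - self.intercept) / self.slope


@dataclass
class RecoveryResult:
    level: str  # low | medium | high
    recovery_percent: float
    passed: bool


def fit_calibration(conc: np.ndarray, area: np.ndarray, analyte: str = "") -> CalibrationCurve:
    """OLS standard curve Y = a X + b with R^2 = squared Pearson correlation."""
    x = np.asarray(conc, dtype=float).ravel()
    y = np.asarray(area, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 calibration levels")
    if np.any(np.diff(x) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    if np.allclose(x, x[0]):
        raise ValueError("zero concentration variance")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ssy = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ssy == 0 else 1.0 - float((resid**2).sum()) / ssy
    return CalibrationCurve(
        analyte=analyte,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        conc_range=(float(x[0]), float(x[-1])),
    )


def lod_loq(noise_sd: float, slope: float) -> tuple[float, float]:
    """LOD = 3 sigma / slope, LOQ = 10 sigma / slope (signal-to-noise 3 and 10).

    ``noise_sd`` is the standard deviation of blank-region baseline residuals,
    supplied by the caller in area units.
    """
    if slope <= 0:
        raise ValueError("slope must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    return 3.0 * noise_sd / slope, 10.0 * noise_sd / slope


def recovery(
    measured_spiked: float, base_amount: float, added_amount: float, level: str = ""
) -> RecoveryResult:
    """Spike recovery percent; pass iff within the 85-110% band, inclusive."""
    if added_amount <= 0:
        raise ValueError("added_amount must be > 0")
    pct = 100.0 * (measured_spiked - base_amount) / added_amount
    lo, hi = RECOVERY_BAND
    return RecoveryResult(level=level, recovery_percent=pct, passed=lo <= pct <= hi)


def rsd_percent(values: np.ndarray) -> float:
    """Relative standard deviation, 100 * sd / mean, over replicate injections."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0:
        raise ValueError("mean of replicate values is zero")
    return float(100.0 * v.std(ddof=1) / m)


def quantify_and_compare(
    curves: dict[str, CalibrationCurve],
    sample_areas: pd.DataFrame,
    part_labels: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Back-calculate contents per analyte and compare the two parts.

    ``sample_areas`` holds one column per analyte (peak areas per sample).
    Concentrations below the curve intercept are floored at 0 and flagged;
    values outside the validated range are flagged as extrapolated. Each
    analyte gets per-part means/sds, a Welch two-sample t-test, and the
    direction of the difference.
    """
    parts = np.asarray(part_labels).astype(str)
    uniq = sorted(set(parts))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 parts, got {uniq}")
    rows = []
    for analyte in sample_areas.columns:
        curve = curves[analyte]
        conc = curve.concentration(sample_areas[analyte].to_numpy())
        floored = int((conc < 0).sum())
        conc = np.maximum(conc, 0.0)
        lo, hi = curve.conc_range
        extrapolated = int(((conc < lo) | (conc > hi)).sum())
        a = conc[parts == uniq[0]]
        b = conc[parts == uniq[1]]
        t, p = stats.ttest_ind(a, b, equal_var=False)
        direction = (
            f"{uniq[0]} > {uniq[1]}" if a.mean() > b.mean() else f"{uniq[1]} > {uniq[0]}"
        )
        rows.append(
            {
                "analyte": analyte,
                f"mean_{uniq[0]}": a.mean(),
                f"sd_{uniq[0]}": a.std(ddof=1),
                f"mean_{uniq[1]}": b.mean(),
                f"sd_{uniq[1]}": b.std(ddof=1),
                "t_statistic": float(t),
                "p_value": float(p),
                "significant": bool(p < alpha),
                "direction": direction,
                "n_floored": floored,
                "n_extrapolated": extrapolated,
            }
        )
    return pd.DataFrame(rows)
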