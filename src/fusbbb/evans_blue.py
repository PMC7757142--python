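"""Evans-blue standard-curve calibration and ROI quantification.

Known quantities of Evans blue imaged on filter paper define a semi-log
standard curve: radiance is linear in log10(nanograms) over a limited range
and saturates at high loads. The calibration fits ordinary least squares on
the linear portion (given explicitly or selected automatically) and inverts
it to interpolate unknown ROI radiances to nanogram quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EBCalibration:
    """Semi-log standard-curve fit over its linear range.

    ``slope`` has units of radiance per decade of nanograms; ``linear_range``
    is the (start, stop) index span (stop exclusive) of the standards used;
    ``radiance_span`` bounds the calibrated radiances, outside which
    interpolation is extrapolation.
    """

    slope: float
    intercept: float
    r_squared: float
    linear_range: tuple[int, int]
    radiance_span: tuple[float, float]


def _validate_standards(standards: pd.DataFrame) -> pd.DataFrame:
    if not {"ng", "radiance"} <= set(standards.columns):
        raise ValueError("standards must have 'ng' and 'radiance' columns")
    ng = standards["ng"].to_numpy(dtype=float)
    if np.any(ng <= 0):
        raise ValueError("standard quantities must be positive")
    if np.any(np.diff(ng) <= 0):
        raise ValueError("standard quantities must be strictly ascending")
    if len(standards) < 4:
        raise ValueError("need at least 4 standards")
    return standards


def _ols_r2(log_ng: np.ndarray, radiance: np.ndarray) -> tuple[float, float, float]:
    fit = sps.linregress(log_ng, radiance)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def fit_semilog(
    standards: pd.DataFrame,
    linear_range: tuple[int, int] | None = None,
    min_points: int = 4,
) -> EBCalibration:
    """Fit radiance ~ log10(ng) over the linear portion of the standards.

    If ``linear_range`` (start, stop) is not given, the contiguous span of at
    least ``min_points`` standards maximizing R^2 is selected; ties prefer
    the longest span and then the lowest start index, so saturated top
    standards are excluded rather than trimming good low standards.
    """
    standards = _validate_standards(standards)
    log_ng = np.log10(standards["ng"].to_numpy(dtype=float))
    radiance = standards["radiance"].to_numpy(dtype=float)
    n = len(standards)

    if linear_range is not None:
        start, stop = linear_range
        if stop - start < min_points:
            raise ValueError(f"linear range must span >= {min_points} standards")
    else:
        best = None  # (r2, length, -start)
        start, stop = 0, n
        for length in range(min_points, n + 1):
            for s in range(0, n - length + 1):
                _, _, r2 = _ols_r2(log_ng[s : s + length], radiance[s : s + length])
                key = (round(r2, 12), length, -s)
                if best is None or key > best:
                    best = key
                    start, stop = s, s + length

    slope, intercept, r2 = _ols_r2(log_ng[start:stop], radiance[start:stop])
    rad_used = radiance[start:stop]
    return EBCalibration(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        linear_range=(start, stop),
        radiance_span=(float(rad_used.min()), float(rad_used.max())),
    )


def interpolate_ng(radiance: float, calibration: EBCalibration) -> tuple[float, bool]:
    """Invert the calibration: ng = 10 ** ((radiance - intercept) / slope).

    Returns ``(ng, extrapolated)``; a radiance outside the calibrated span is
    flagged extrapolated (and warned about) rather than rejected, since a
    heavily-opened brain can exceed the top standard.
    """
    if calibration.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    lo, hi = calibration.radiance_span
    extrapolated = not (lo <= radiance <= hi)
    if extrapolated:
        logger.warning(
            "radiance %g outside calibrated span [%g, %g]; extrapolating",
            radiance,
            lo,
            hi,
        )
    ng = 10.0 ** ((radiance - calibration.intercept) / calibration.slope)
    return float(ng), extrapolated


def quantify_regions(
    roi_radiances: pd.DataFrame, calibration: EBCalibration
) -> tuple[pd.DataFrame, float]:
    """Interpolate each region's radiance to nanograms and total them.

    ``roi_radiances`` needs a ``radiance`` column (a ``region`` column is
    carried through if present). Regions below the lowest calibrated
    radiance are reported as below detection: 0 ng, flagged. Returns the
    per-region table and the total nanograms.
    """
    if "radiance" not in roi_radiances.columns:
        raise ValueError("roi_radiances must have a 'radiance' column")
    lo = calibration.radiance_span[0]
    rows = []
    for _, row in roi_radiances.iterrows():
        rad = float(row["radiance"])
        if rad < lo:
            ng, flag = 0.0, "below_detection"
        else:
            ng, extrap = interpolate_ng(rad, calibration)
            flag = "extrapolated" if extrap else "ok"
        rows.append(
            {
                "region": row.get("region", len(rows)),
                "radiance": rad,
                "ng": ng,
                "flag": flag,
            }
        )
    out = pd.DataFrame(rows)
    return out, float(out["ng"].sum())
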