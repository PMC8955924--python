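"""Expression versus leaf-water-potential amplitude regression screen.

For each condition the diurnal amplitude of leaf water potential is

    delta_psi = max(psi) - min(psi)        [MPa]

and each transcript's expression across samples is regressed (ordinary least
squares, simple linear model) on the delta_psi of each sample's condition.
The coefficient of determination R^2 (the squared Pearson correlation of the
two vectors) is screened against thresholds, conventionally 0.90 and 0.99.

With a 2-treatment x 2-stage x 2-replicate design there are only 8 points
and 4 distinct amplitudes, so the screen is permissive; ``n_points`` and
``n_distinct_x`` are reported so users can judge the support of each fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError

R2_THRESHOLDS_DEFAULT = (0.90, 0.99)


def amplitude(psi_values) -> float:
    """Daily amplitude max - min of one condition's water-potential series."""
    arr = np.asarray(psi_values, dtype=float)
    if arr.size < 2:
        raise InputError("amplitude needs at least 2 measurements")
    return float(arr.max() - arr.min())


def amplitudes(psi: pd.DataFrame) -> pd.DataFrame:
    """Per-condition amplitude table from a psi series table.

    Input columns ``condition, time, psi_mpa``; output ``condition_id,
    delta_psi`` with delta_psi >= 0.
    """
    rows = [
        {"condition_id": cond, "delta_psi": amplitude(sub["psi_mpa"])}
        for cond, sub in psi.groupby("condition", sort=False)
    ]
    return pd.DataFrame(rows, columns=["condition_id", "delta_psi"])


def screen(
    expr: pd.DataFrame,
    amps: pd.DataFrame,
    design: pd.DataFrame,
    r2_thresholds: tuple[float, float] = R2_THRESHOLDS_DEFAULT,
    log_expression: bool = False,
) -> pd.DataFrame:
    """Per-transcript OLS regression of expression on condition delta_psi.

    Points are (delta_psi of the sample's condition, expression in the
    sample) across all samples including replicates.  Returns columns
    ``transcript_id, slope, intercept, r_squared, n_points, n_distinct_x,
    passes_090, passes_099`` (flag column names follow the two thresholds in
    ascending order).  Transcripts with zero expression variance have an
    undefined fit: NaN statistics and both flags False.  Fewer than 3 points
    is refused — a 2-point fit is always perfect and meaningless.
    """
    lo, hi = sorted(r2_thresholds)
    amp_map = amps.set_index("condition_id")["delta_psi"]
    missing = set(design["condition"]) - set(amp_map.index)
    if missing:
        raise InputError(f"no delta_psi for condition(s): {sorted(missing)}")
    samples = [s for s in design["sample_id"] if s in expr.columns]
    if len(samples) < len(design):
        absent = sorted(set(design["sample_id"]) - set(samples))
        raise InputError(f"expression matrix lacks sample column(s): {absent}")
    x = amp_map.loc[design.set_index("sample_id").loc[samples, "condition"]].to_numpy(float)
    n = len(x)
    if n < 3:
        raise InputError(f"regression needs >= 3 points, got {n}")
    if np.ptp(x) == 0:
        raise InputError("all samples share one delta_psi; regression undefined")

    y = expr[samples].to_numpy(float)
    if log_expression:
        y = np.log(np.where(y > 0, y, np.nan))

    xc = x - x.mean()
    ssx = float(np.sum(xc**2))
    ybar = np.nanmean(y, axis=1)
    yc = y - ybar[:, None]
    ssy = np.nansum(yc**2, axis=1)
    sxy = np.nansum(yc * xc, axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / ssx
        intercept = ybar - slope * x.mean()
        r2 = np.where(ssy > 0, sxy**2 / (ssx * ssy), np.nan)
    slope = np.where(ssy > 0, slope, np.nan)
    intercept = np.where(ssy > 0, intercept, np.nan)

    defined = ~np.isnan(r2)
    return pd.DataFrame(
        {
            "transcript_id": expr.index.astype(str),
            "slope": slope,
            "intercept": intercept,
            "r_squared": r2,
            "n_points": n,
            "n_distinct_x": len(np.unique(x)),
            "passes_090": defined & (r2 >= lo),
            "passes_099": defined & (r2 >= hi),
        }
    )
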