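"""Signed treatment/control expression ratio and DEG calling.

The differential-expression statistic is a plain RPKM ratio with a sign
convention that makes downregulation legible: for treatment expression *t*
and control expression *c* (both > 0),

    ratio_raw    = t / c
    ratio_signed = ratio_raw          if ratio_raw >= 1
                 = -1 / ratio_raw     if ratio_raw <  1

so the signed value never enters the open interval (-1, 1): a transcript
halved under treatment reads -2, one doubled reads +2, and equality reads
exactly +1.  A transcript is called significantly regulated when
``|ratio_signed| > cutoff`` (default 1.5, strict inequality).

Zero expression on either side cannot form a ratio; such transcripts are
given a sentinel status (exclusive to treatment, exclusive to control, or
undefined when both are zero) and are never called significant here — the
set-partition analysis is where exclusive expression belongs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import InputError
from .io_tables import condition_id

RATIO_CUTOFF_DEFAULT = 1.5
DEFAULT_HIST_EDGES = (-5.0, -4.0, -3.0, -2.0, -1.5, 1.5, 2.0, 3.0, 4.0, 5.0)


class RatioStatus(str, Enum):
    """Outcome of a ratio computation for one transcript."""

    FINITE = "finite"
    EXCLUSIVE_TREATMENT = "exclusive_treatment"  # control = 0 < treatment
    EXCLUSIVE_CONTROL = "exclusive_control"      # treatment = 0 < control
    UNDEFINED = "undefined"                      # both zero


def signed_ratio(rpkm_treatment: float, rpkm_control: float) -> float | RatioStatus:
    """Signed ratio for one transcript; a :class:`RatioStatus` when zeros occur."""
    if rpkm_treatment < 0 or rpkm_control < 0:
        raise InputError("expression values must be non-negative")
    if rpkm_treatment == 0 and rpkm_control == 0:
        return RatioStatus.UNDEFINED
    if rpkm_control == 0:
        return RatioStatus.EXCLUSIVE_TREATMENT
    if rpkm_treatment == 0:
        return RatioStatus.EXCLUSIVE_CONTROL
    raw = rpkm_treatment / rpkm_control
    return raw if raw >= 1 else -1.0 / raw


def call_degs(
    merged_expr: pd.DataFrame,
    stage: str,
    cutoff: float = RATIO_CUTOFF_DEFAULT,
    treatment: str = "RDI",
    control: str = "SDI",
) -> pd.DataFrame:
    """Per-transcript ratio table for one developmental stage.

    ``merged_expr`` must carry the replicate-merged condition columns for the
    stage (e.g. ``RV`` and ``SV``).  Returns one row per transcript with
    columns ``transcript_id, stage, rpkm_treatment, rpkm_control, ratio_raw,
    ratio_signed, status, significant, direction``; sentinel rows have NaN
    ratios and are never significant.
    """
    t_col = condition_id(treatment, stage)
    c_col = condition_id(control, stage)
    for col in (t_col, c_col):
        if col not in merged_expr.columns:
            raise InputError(f"merged expression lacks condition column {col!r}")
    if cutoff <= 1:
        raise InputError("ratio cutoff must exceed 1")
    t = merged_expr[t_col].to_numpy(float)
    c = merged_expr[c_col].to_numpy(float)
    if (t < 0).any() or (c < 0).any():
        raise InputError("expression values must be non-negative")

    raw = np.full_like(t, np.nan)
    signed = np.full_like(t, np.nan)
    status = np.full(t.shape, RatioStatus.FINITE.value, dtype=object)
    both_pos = (t > 0) & (c > 0)
    raw[both_pos] = t[both_pos] / c[both_pos]
    signed[both_pos] = np.where(raw[both_pos] >= 1, raw[both_pos], -1.0 / raw[both_pos])
    status[(c == 0) & (t > 0)] = RatioStatus.EXCLUSIVE_TREATMENT.value
    status[(t == 0) & (c > 0)] = RatioStatus.EXCLUSIVE_CONTROL.value
    status[(t == 0) & (c == 0)] = RatioStatus.UNDEFINED.value

    significant = both_pos & (np.abs(signed) > cutoff)
    direction = np.where(significant & (signed > 0), "up",
                         np.where(significant & (signed < 0), "down", "none"))
    return pd.DataFrame(
        {
            "transcript_id": merged_expr.index.astype(str),
            "stage": stage,
            "rpkm_treatment": t,
            "rpkm_control": c,
            "ratio_raw": raw,
            "ratio_signed": signed,
            "status": status,
            "significant": significant,
            "direction": direction,
        }
    )


@dataclass(frozen=True)
class RatioHistogram:
    """Signed-ratio interval counts plus the excluded sentinel tallies."""

    bins: pd.DataFrame            # label, lo, hi, count, open_ended
    sentinel_counts: dict[str, int]

    @property
    def total_finite(self) -> int:
        return int(self.bins["count"].sum())


def ratio_histogram(
    ratios: pd.DataFrame,
    edges: tuple[float, ...] = DEFAULT_HIST_EDGES,
) -> RatioHistogram:
    """Count transcripts per signed-ratio interval.

    ``edges`` must be strictly increasing and sign-symmetric (the default is
    ±{1.5, 2, 3, 4, 5}).  Binning is by magnitude: ``|x| <= inner_edge`` is the
    central unregulated bin (so ±cutoff exactly is central, consistent with
    strict-``>`` significance); otherwise ``|x|`` in (lo, hi] maps to the bin
    on x's side, with open-ended outer bins beyond the largest edge.
    Sentinel rows are excluded from the bins and reported separately, so
    bin counts + sentinel counts = row count.
    """
    edges_arr = np.asarray(edges, dtype=float)
    if not np.all(np.diff(edges_arr) > 0):
        raise InputError("histogram edges must be strictly increasing")
    pos = edges_arr[edges_arr > 0]
    neg = edges_arr[edges_arr < 0]
    if len(pos) == 0 or len(neg) != len(pos) or not np.allclose(-neg[::-1], pos):
        raise InputError("histogram edges must be symmetric about zero")
    if pos[0] <= 1:
        raise InputError("inner histogram edge must exceed 1 (signed ratios avoid (-1, 1))")

    finite = ratios.loc[ratios["status"] == RatioStatus.FINITE.value, "ratio_signed"]
    x = finite.to_numpy(float)
    mag = np.abs(x)

    central = mag <= pos[0]

    labels, counts, open_ended, los, his = [], [], [], [], []
    # negative outer bin first
    n_outer_neg = int(((x < 0) & (mag > pos[-1])).sum())
    labels.append(f"<= {-pos[-1]:g}")
    counts.append(n_outer_neg)
    open_ended.append(True)
    los.append(-np.inf)
    his.append(-pos[-1])
    for i in range(len(pos) - 1, 0, -1):
        sel = (x < 0) & (mag > pos[i - 1]) & (mag <= pos[i])
        labels.append(f"({-pos[i]:g}, {-pos[i - 1]:g}]")
        counts.append(int(sel.sum()))
        open_ended.append(False)
        los.append(-pos[i])
        his.append(-pos[i - 1])
    labels.append(f"[{-pos[0]:g}, {pos[0]:g}]")
    counts.append(int(central.sum()))
    open_ended.append(False)
    los.append(-pos[0])
    his.append(pos[0])
    for i in range(1, len(pos)):
        sel = (x > 0) & (mag > pos[i - 1]) & (mag <= pos[i])
        labels.append(f"({pos[i - 1]:g}, {pos[i]:g}]")
        counts.append(int(sel.sum()))
        open_ended.append(False)
        los.append(pos[i - 1])
        his.append(pos[i])
    n_outer_pos = int(((x > 0) & (mag > pos[-1])).sum())
    labels.append(f">= {pos[-1]:g}")
    counts.append(n_outer_pos)
    open_ended.append(True)
    los.append(pos[-1])
    his.append(np.inf)

    bins = pd.DataFrame(
        {"label": labels, "lo": los, "hi": his, "count": counts, "open_ended": open_ended}
    )
    sentinels = {
        s.value: int((ratios["status"] == s.value).sum())
        for s in (RatioStatus.EXCLUSIVE_TREATMENT, RatioStatus.EXCLUSIVE_CONTROL,
                  RatioStatus.UNDEFINED)
    }
    return RatioHistogram(bins=bins, sentinel_counts=sentinels)


def top_k(ratios: pd.DataFrame, k: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The k most up- and most downregulated transcripts by signed ratio.

    Ties are broken by lexicographic transcript_id so the ranking is
    deterministic; sentinel rows are excluded.  When fewer than k finite
    ratios exist, all are returned with a warning.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    finite = ratios[ratios["status"] == RatioStatus.FINITE.value]
    if len(finite) < k:
        warnings.warn(
            f"only {len(finite)} finite ratios available for top-{k} ranking",
            stacklevel=2,
        )
    up = finite.sort_values(
        ["ratio_signed", "transcript_id"], ascending=[False, True]
    ).head(k)
    down = finite.sort_values(
        ["ratio_signed", "transcript_id"], ascending=[True, True]
    ).head(k)
    return up.reset_index(drop=True), down.reset_index(drop=True)
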