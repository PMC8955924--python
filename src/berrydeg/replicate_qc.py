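"""Biological-replicate validation and merging.

Replicates of the same (treatment, stage) condition are validated by the
Pearson correlation of their natural-log expression.  ln(0) is undefined, so
cells where either replicate has RPKM = 0 are excluded as incomplete
observations (the pairwise-complete convention once -inf is coded missing);
an optional pseudo-offset mode computes ln(RPKM + eps) on all cells instead.

After validation, replicates are merged by the arithmetic mean on the RPKM
scale (not the log scale) into one column per condition.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)


def _condition_groups(design: pd.DataFrame) -> dict[str, list[str]]:
    """Condition -> ordered sample_id list (by replicate number), design order."""
    groups: dict[str, list[str]] = {}
    for cond, sub in design.groupby("condition", sort=False):
        groups[cond] = sub.sort_values("replicate")["sample_id"].tolist()
    return groups


def _pair_r(x: np.ndarray, y: np.ndarray, log_transform: bool,
            pseudo_offset: float | None) -> tuple[float, float, int]:
    if log_transform:
        if pseudo_offset is not None:
            x = np.log(x + pseudo_offset)
            y = np.log(y + pseudo_offset)
        else:
            keep = (x > 0) & (y > 0)
            x, y = np.log(x[keep]), np.log(y[keep])
    n = len(x)
    if n < 3:
        raise InputError(f"fewer than 3 usable transcript pairs (got {n})")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance in a replicate column; r undefined")
        return np.nan, np.nan, n
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def replicate_correlation(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    log_transform: bool = True,
    *,
    pseudo_offset: float | None = None,
    allow_multi: bool = False,
) -> pd.DataFrame:
    """Pearson correlation between biological replicates per condition.

    Returns a table with columns ``condition_id, r, p_value, n_pairs``.  Each
    condition must have exactly two replicates; with ``allow_multi`` the mean
    pairwise r over all replicate pairs is reported (p_value NaN).
    """
    rows = []
    for cond, samples in _condition_groups(design).items():
        if len(samples) < 2:
            continue
        if len(samples) != 2 and not allow_multi:
            raise InputError(
                f"condition {cond!r} has {len(samples)} replicates; expected 2 "
                "(pass allow_multi=True for mean pairwise correlation)"
            )
        if len(samples) == 2:
            a, b = samples
            r, p, n = _pair_r(expr[a].to_numpy(float), expr[b].to_numpy(float),
                              log_transform, pseudo_offset)
        else:
            rs, ns = [], []
            for a, b in itertools.combinations(samples, 2):
                r_i, _, n_i = _pair_r(expr[a].to_numpy(float), expr[b].to_numpy(float),
                                      log_transform, pseudo_offset)
                rs.append(r_i)
                ns.append(n_i)
            r, p, n = float(np.mean(rs)), np.nan, min(ns)
        rows.append({"condition_id": cond, "r": r, "p_value": p, "n_pairs": n})
    return pd.DataFrame(rows, columns=["condition_id", "r", "p_value", "n_pairs"])


def merge_replicates(expr: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Merge replicate columns into one column per condition by arithmetic mean.

    A single-replicate condition passes through unchanged.  With balanced
    replicate counts the matrix-wide total expression is preserved up to the
    replicate factor.
    """
    groups = _condition_groups(design)
    merged = {cond: expr[samples].mean(axis=1) for cond, samples in groups.items()}
    out = pd.DataFrame(merged, index=expr.index)
    out.index.name = expr.index.name
    return out
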