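"""RPKM quantification and the activity filters.

RPKM (reads per kilobase of transcript per million mapped reads) for
transcript *t* in sample *s*:

    rpkm[t, s] = counts[t, s] / (library_size[s] / 1e6) / (length_bp[t] / 1e3)

A transcript is *active* in a sample when its annotated length is at least
``length_min`` (default 150 bp, an assembly-quality filter) and its RPKM is at
least ``rpkm_min`` (default 1).  Both thresholds are inclusive.  The active
universe defined here feeds every downstream stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

LENGTH_MIN_DEFAULT = 150
RPKM_MIN_DEFAULT = 1.0


def library_sizes(counts: pd.DataFrame, design: pd.DataFrame | None = None) -> pd.Series:
    """Total mapped reads per sample.

    Uses the sample sheet's ``library_size`` when present for every sample,
    otherwise falls back to the column sums of the count matrix; the choice is
    logged because it changes the RPKM denominator.
    """
    if design is not None and "library_size" in design.columns:
        sizes = design.set_index("sample_id")["library_size"]
        if sizes.reindex(counts.columns).notna().all():
            logger.info("library sizes taken from the sample sheet")
            return sizes.reindex(counts.columns).astype(float)
    logger.info("library sizes taken as count-matrix column sums")
    return counts.sum(axis=0).astype(float)


def compute_rpkm(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    design: pd.DataFrame | None = None,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Normalise a count matrix to RPKM.

    Parameters
    ----------
    counts
        Transcripts x samples matrix of non-negative counts.
    annotation
        Annotation table indexed by transcript_id with ``length_bp``; must
        cover every transcript in ``counts``.
    design
        Optional sample sheet supplying ``library_size`` per sample.
    lib_sizes
        Explicit per-sample totals; overrides both other sources.
    """
    missing = counts.index.difference(annotation.index)
    if len(missing):
        raise InputError(f"transcript(s) without annotation: {missing.tolist()[:5]}")
    if lib_sizes is None:
        lib_sizes = library_sizes(counts, design)
    lib_sizes = lib_sizes.reindex(counts.columns)
    if (lib_sizes <= 0).any() or lib_sizes.isna().any():
        bad = lib_sizes.index[(lib_sizes <= 0) | lib_sizes.isna()].tolist()
        raise InputError(f"library size must be positive; offending sample(s): {bad}")
    lengths = annotation.loc[counts.index, "length_bp"].astype(float)
    rpkm = counts.div(lib_sizes / 1e6, axis=1).div(lengths / 1e3, axis=0)
    return rpkm.astype(float)


def activity_mask(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    length_min: int = LENGTH_MIN_DEFAULT,
    rpkm_min: float = RPKM_MIN_DEFAULT,
) -> pd.DataFrame:
    """Boolean transcripts x samples matrix of the activity filter.

    ``active = (length_bp >= length_min) & (rpkm >= rpkm_min)``; thresholds
    are inclusive.  Columns may be samples or replicate-merged conditions.
    """
    missing = expr.index.difference(annotation.index)
    if len(missing):
        raise InputError(f"transcript(s) without annotation: {missing.tolist()[:5]}")
    long_enough = annotation.loc[expr.index, "length_bp"] >= length_min
    return expr.ge(rpkm_min).mul(long_enough, axis=0)


@dataclass(frozen=True)
class UniverseSummary:
    """Counts of transcripts by activity pattern across all columns."""

    n_transcripts: int
    active_in_all: int
    active_in_none: int
    active_in_some: int


def universe_summary(mask: pd.DataFrame) -> UniverseSummary:
    """Summarise an activity mask into all / none / some counts.

    The three counts always sum to the number of transcripts.
    """
    per_row = mask.sum(axis=1)
    n_cols = mask.shape[1]
    in_all = int((per_row == n_cols).sum())
    in_none = int((per_row == 0).sum())
    return UniverseSummary(
        n_transcripts=mask.shape[0],
        active_in_all=in_all,
        active_in_none=in_none,
        active_in_some=mask.shape[0] - in_all - in_none,
    )
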