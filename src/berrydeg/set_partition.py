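"""Shared and condition-exclusive active-transcript sets (Venn analysis).

Given per-condition activity, the condition active sets are partitioned into
the 2**n - 1 disjoint subset-signature regions (exclusive to one condition,
shared by a pair, ..., common to all).  Region sizes always sum to the size
of the union of the condition sets; the exclusive regions are the
"sample-specific transcripts" highlighted in a classic Venn diagram.
"""

from __future__ import annotations

import itertools

import pandas as pd

from .errors import InputError
from .quantify import LENGTH_MIN_DEFAULT, RPKM_MIN_DEFAULT, activity_mask

MAX_CONDITIONS = 6


def condition_activity(
    merged_expr: pd.DataFrame,
    annotation: pd.DataFrame,
    length_min: int = LENGTH_MIN_DEFAULT,
    rpkm_min: float = RPKM_MIN_DEFAULT,
) -> pd.DataFrame:
    """Condition-level activity from a replicate-merged expression matrix.

    A transcript is active in a condition when its merged RPKM passes the
    activity filter — the merged-matrix convention used throughout.  For the
    stricter alternative (active in every replicate), apply
    :func:`berrydeg.quantify.activity_mask` to the per-sample matrix and use
    :func:`activity_all_replicates`.
    """
    return activity_mask(merged_expr, annotation, length_min, rpkm_min)


def activity_all_replicates(sample_mask: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Condition-level activity requiring every replicate to be active."""
    out = {}
    for cond, sub in design.groupby("condition", sort=False):
        out[cond] = sample_mask[sub["sample_id"].tolist()].all(axis=1)
    return pd.DataFrame(out, index=sample_mask.index)


def active_sets(mask: pd.DataFrame, conditions: list[str]) -> dict[str, set[str]]:
    """Per-condition sets of active transcript ids from a boolean mask."""
    unknown = [c for c in conditions if c not in mask.columns]
    if unknown:
        raise InputError(f"unknown condition(s): {unknown}")
    return {c: set(mask.index[mask[c].astype(bool)].astype(str)) for c in conditions}


def partition(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Disjoint subset-signature regions of the condition active sets.

    Returns one row per non-empty signature (all 2**n - 1 of them, including
    zero-size regions) with columns ``region_label`` (conditions joined by
    ``&`` in input order), ``conditions`` (tuple), ``size`` and ``member_ids``
    (sorted tuple).  Exclusive regions are the singleton signatures.
    """
    names = list(sets)
    if len(names) < 2:
        raise InputError("partition needs at least 2 condition sets")
    if len(names) > MAX_CONDITIONS:
        raise InputError(f"partition supports at most {MAX_CONDITIONS} conditions")
    universe = set().union(*sets.values())
    membership: dict[frozenset[str], set[str]] = {}
    for tx in universe:
        sig = frozenset(c for c in names if tx in sets[c])
        membership.setdefault(sig, set()).add(tx)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            sig = frozenset(combo)
            members = tuple(sorted(membership.get(sig, set())))
            rows.append(
                {
                    "region_label": "&".join(combo),
                    "conditions": combo,
                    "size": len(members),
                    "member_ids": members,
                }
            )
    return pd.DataFrame(rows, columns=["region_label", "conditions", "size", "member_ids"])


def exclusive_counts(part: pd.DataFrame) -> dict[str, int]:
    """Sizes of the singleton regions — the condition-exclusive transcripts."""
    singles = part[part["conditions"].map(len) == 1]
    return {row["conditions"][0]: int(row["size"]) for _, row in singles.iterrows()}
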