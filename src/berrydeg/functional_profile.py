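"""Functional-category profiling of active transcripts and called DEGs.

Two views:

* per (condition, category) the percentage of that category's transcripts
  that are active — normalising by category size so small categories are
  comparable with large ones;
* per (comparison, direction, category[, sub_category]) the count of
  significantly regulated transcripts, which partitions the significant DEG
  set exactly.
"""

from __future__ import annotations

import pandas as pd

from .errors import InputError


def profile_active(
    mask: pd.DataFrame,
    annotation: pd.DataFrame,
    conditions: list[str] | None = None,
) -> pd.DataFrame:
    """Percent of each functional category active per condition.

    Returns columns ``condition_id, functional_category, n_active, n_total,
    percent_active``.  ``n_total`` is the category size within the mask's
    transcript universe (i.e. after any upstream filtering), so duplicating
    every transcript of a category leaves the percentage unchanged.
    """
    missing = mask.index.difference(annotation.index)
    if len(missing):
        raise InputError(f"transcript(s) without annotation: {missing.tolist()[:5]}")
    if conditions is None:
        conditions = list(mask.columns)
    unknown = [c for c in conditions if c not in mask.columns]
    if unknown:
        raise InputError(f"unknown condition(s): {unknown}")
    cats = annotation.loc[mask.index, "functional_category"]
    totals = cats.value_counts()
    rows = []
    for cond in conditions:
        active_by_cat = cats[mask[cond].astype(bool)].value_counts()
        for cat, n_total in totals.items():
            n_active = int(active_by_cat.get(cat, 0))
            rows.append(
                {
                    "condition_id": cond,
                    "functional_category": cat,
                    "n_active": n_active,
                    "n_total": int(n_total),
                    "percent_active": 100.0 * n_active / int(n_total),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["condition_id", "functional_category", "n_active", "n_total",
                 "percent_active"],
    )


def breakdown_degs(
    ratios: pd.DataFrame,
    annotation: pd.DataFrame,
    comparison_id: str | None = None,
) -> pd.DataFrame:
    """Count significant DEGs per direction x category (and sub-category).

    Per comparison and direction the category counts sum exactly to the
    number of significant calls.  Returns columns ``comparison_id, direction,
    functional_category, sub_category, n_degs``; empty when nothing is
    significant.
    """
    sig = ratios[ratios["significant"]].copy()
    if comparison_id is None:
        stages = sig["stage"].unique()
        comparison_id = f"stage-{stages[0]}" if len(stages) == 1 else "comparison"
    if sig.empty:
        return pd.DataFrame(
            columns=["comparison_id", "direction", "functional_category",
                     "sub_category", "n_degs"]
        )
    missing = set(sig["transcript_id"]) - set(annotation.index.astype(str))
    if missing:
        raise InputError(f"significant transcript(s) without annotation: {sorted(missing)[:5]}")
    ann = annotation.loc[sig["transcript_id"], ["functional_category", "sub_category"]]
    sig["functional_category"] = ann["functional_category"].to_numpy()
    sig["sub_category"] = ann["sub_category"].to_numpy()
    grouped = (
        sig.groupby(["direction", "functional_category", "sub_category"], dropna=False)
        .size()
        .reset_index(name="n_degs")
    )
    grouped.insert(0, "comparison_id", comparison_id)
    return grouped.sort_values(
        ["direction", "functional_category", "sub_category"], na_position="last"
    ).reset_index(drop=True)
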