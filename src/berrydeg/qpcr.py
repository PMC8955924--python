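"""Relative gene expression from RT-qPCR Cq values by the ddCq method.

Per biological replicate of each sample, technical replicates are averaged
to one Cq per gene, and the target is normalised against the arithmetic mean
Cq of the reference genes (equivalent, at 100 % amplification efficiency, to
the geometric mean of their quantities):

    dCq  = Cq_target - mean(Cq_references)
    ddCq = mean dCq(treatment) - mean dCq(control)

    relative_expression = 2 ** (-ddCq)       log2_expression = -ddCq

Amplification efficiency is fixed at 2 per cycle (the classical assumption).
A call is flagged by magnitude when ``|log2_expression| > 2`` (strict) and by
a two-sided Student t-test on the per-biological-replicate dCq values at
``p < 0.05``.  Three stably expressed reference genes (canonically ACT, TIF
and TIF-GTP for water-stressed grapevine) are expected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_REFERENCES = ("ACT", "TIF", "TIF-GTP")
LOG2_CUTOFF_DEFAULT = 2.0
ALPHA_DEFAULT = 0.05


def normalize_cq(plate: pd.DataFrame, reference_genes=DEFAULT_REFERENCES) -> pd.DataFrame:
    """Per-biological-replicate dCq table from a raw Cq plate.

    Technical replicates are averaged first; every sample must carry every
    reference gene in each biological replicate.  Returns columns
    ``sample_id, gene_id, bio_rep, delta_cq`` for target genes only.
    """
    reference_genes = list(reference_genes)
    if not reference_genes:
        raise InputError("at least one reference gene is required")
    if "bio_rep" not in plate.columns:
        raise InputError("plate must carry a 'bio_rep' column (biological replicate id)")
    plate = plate.copy()
    averaged = (
        plate.groupby(["sample", "gene", "bio_rep"], sort=False)["cq"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "cq"})
    )
    single = averaged["count"] == 1
    if single.any():
        logger.warning(
            "%d (sample, gene, bio_rep) well group(s) have a single technical replicate",
            int(single.sum()),
        )

    roles = plate.drop_duplicates("gene").set_index("gene")["role"]
    ref_set = set(reference_genes)
    declared_refs = set(roles[roles == "reference"].index)
    if not ref_set <= set(roles.index):
        raise InputError(f"reference gene(s) absent from plate: {sorted(ref_set - set(roles.index))}")
    if declared_refs - ref_set:
        logger.warning("plate declares extra reference gene(s) %s; using %s",
                       sorted(declared_refs - ref_set), reference_genes)

    rows = []
    for (sample, bio_rep), sub in averaged.groupby(["sample", "bio_rep"], sort=False):
        cqs = sub.set_index("gene")["cq"]
        missing = ref_set - set(cqs.index)
        if missing:
            raise InputError(
                f"reference gene(s) {sorted(missing)} missing in sample {sample!r}, "
                f"biological replicate {bio_rep!r}"
            )
        ref_mean = float(cqs.loc[reference_genes].mean())
        for gene, cq in cqs.items():
            if gene in ref_set:
                continue
            rows.append(
                {"sample_id": sample, "gene_id": gene, "bio_rep": bio_rep,
                 "delta_cq": float(cq) - ref_mean}
            )
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "bio_rep", "delta_cq"])


def ddcq(
    delta_cq_treatment: pd.DataFrame,
    delta_cq_control: pd.DataFrame,
    comparison_id: str = "treatment-vs-control",
    log2_cutoff: float = LOG2_CUTOFF_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    equal_var: bool = True,
) -> pd.DataFrame:
    """ddCq relative expression per gene between two dCq tables.

    Genes present on only one side are skipped with a warning.  The t-test
    (Student's by default; Welch via ``equal_var=False``) runs on the
    per-biological-replicate dCq values; with fewer than 2 replicates on a
    side the p-value is NaN and the test flag False.
    """
    rows = []
    genes_t = set(delta_cq_treatment["gene_id"])
    genes_c = set(delta_cq_control["gene_id"])
    for gene in sorted(genes_t ^ genes_c):
        logger.warning("gene %r present on only one side; skipped", gene)
    for gene in sorted(genes_t & genes_c):
        dt = delta_cq_treatment.loc[
            delta_cq_treatment["gene_id"] == gene, "delta_cq"
        ].to_numpy(float)
        dc = delta_cq_control.loc[
            delta_cq_control["gene_id"] == gene, "delta_cq"
        ].to_numpy(float)
        dd = float(dt.mean() - dc.mean())
        log2_expr = -dd
        if len(dt) >= 2 and len(dc) >= 2:
            if np.ptp(dt) == 0 and np.ptp(dc) == 0:
                p = 0.0 if dt.mean() != dc.mean() else 1.0
            else:
                p = float(stats.ttest_ind(dt, dc, equal_var=equal_var).pvalue)
        else:
            p = np.nan
        rows.append(
            {
                "gene_id": gene,
                "comparison_id": comparison_id,
                "ddcq": dd,
                "log2_expression": log2_expr,
                "relative_expression": float(2.0 ** log2_expr),
                "significant_magnitude": abs(log2_expr) > log2_cutoff,
                "p_value": p,
                "significant_test": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "comparison_id", "ddcq", "log2_expression",
                 "relative_expression", "significant_magnitude", "p_value",
                 "significant_test"],
    )


def relative_expression(
    plate: pd.DataFrame,
    treatment_sample: str,
    control_sample: str,
    reference_genes=DEFAULT_REFERENCES,
    **ddcq_kwargs,
) -> pd.DataFrame:
    """Convenience wrapper: plate -> dCq per side -> ddCq result table."""
    dcq = normalize_cq(plate, reference_genes)
    dt = dcq[dcq["sample_id"] == treatment_sample]
    dc = dcq[dcq["sample_id"] == control_sample]
    if dt.empty or dc.empty:
        raise InputError(
            f"no wells for sample {treatment_sample if dt.empty else control_sample!r}"
        )
    return ddcq(dt, dc,
                comparison_id=f"{treatment_sample}-vs-{control_sample}",
                **ddcq_kwargs)
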