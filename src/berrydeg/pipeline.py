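"""End-to-end orchestration: quantify -> QC -> merge -> DEG -> partition ->
profile -> psi screen (-> qPCR), with a manifest recording every effective
setting so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .deg_ratio import RATIO_CUTOFF_DEFAULT, call_degs, ratio_histogram, top_k
from .errors import InputError
from .functional_profile import breakdown_degs, profile_active
from .io_tables import (
    read_annotation,
    read_count_matrix,
    read_cq,
    read_expression_matrix,
    read_psi,
    read_sample_sheet,
    write_table,
)
from .psi_correlation import R2_THRESHOLDS_DEFAULT, amplitudes, screen
from .qpcr import ALPHA_DEFAULT, DEFAULT_REFERENCES, LOG2_CUTOFF_DEFAULT, relative_expression
from .quantify import (
    LENGTH_MIN_DEFAULT,
    RPKM_MIN_DEFAULT,
    activity_mask,
    compute_rpkm,
    universe_summary,
)
from .replicate_qc import merge_replicates, replicate_correlation
from .set_partition import active_sets, condition_activity, partition

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds of one full pipeline run.

    Exactly one of ``counts`` / ``rpkm`` must be given: ``counts`` runs RPKM
    quantification, ``rpkm`` accepts precomputed expression (the mode is
    recorded in the manifest).  Every threshold default is the conventional
    value: 150 bp length filter, RPKM >= 1 activity, signed-ratio cutoff 1.5,
    R^2 thresholds 0.90/0.99, |log2| > 2 and alpha = 0.05 for qPCR.
    """

    design: str = ""
    annotation: str = ""
    counts: str | None = None
    rpkm: str | None = None
    psi: str | None = None
    qpcr_plate: str | None = None
    out_dir: str = "berrydeg_run"

    length_min: int = LENGTH_MIN_DEFAULT
    rpkm_min: float = RPKM_MIN_DEFAULT
    ratio_cutoff: float = RATIO_CUTOFF_DEFAULT
    r2_thresholds: tuple[float, float] = R2_THRESHOLDS_DEFAULT
    log2_cutoff: float = LOG2_CUTOFF_DEFAULT
    alpha: float = ALPHA_DEFAULT
    treatment: str = "RDI"
    control: str = "SDI"
    stages: tuple[str, ...] = ("V", "M")
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCES
    qpcr_treatment_sample: str = "RM"
    qpcr_control_sample: str = "SM"

    # mode flags (module design decisions, paper-faithful defaults)
    log_transform_qc: bool = True
    qc_pseudo_offset: float | None = None
    activity_mode: str = "merged"  # or "all_replicates"
    equal_var_ttest: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("r2_thresholds", "stages", "reference_genes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute every stage and write all result tables plus a manifest.

    Returns the output directory.  Reruns with identical inputs and config
    produce byte-identical outputs (no timestamps are written).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("read inputs")
        design = read_sample_sheet(config.design)
        annotation = read_annotation(config.annotation)
        if (config.counts is None) == (config.rpkm is None):
            raise InputError("exactly one of 'counts' or 'rpkm' must be configured")
        if config.counts is not None:
            counts = read_count_matrix(config.counts, design)
            stage("quantify")
            expr = compute_rpkm(counts, annotation, design)
            expression_mode = "computed_from_counts"
        else:
            expr = read_expression_matrix(config.rpkm, design)
            expression_mode = "precomputed_rpkm"
        write_table(expr, out / "rpkm.tsv")

        stage("activity filter")
        mask = activity_mask(expr, annotation, config.length_min, config.rpkm_min)
        summary = universe_summary(mask)
        write_table(mask.astype(int), out / "activity_mask.tsv")

        stage("replicate qc")
        qc = replicate_correlation(
            expr, design, config.log_transform_qc, pseudo_offset=config.qc_pseudo_offset
        )
        write_table(qc, out / "qc_report.tsv")

        stage("merge replicates")
        merged = merge_replicates(expr, design)
        write_table(merged, out / "merged.tsv")

        stage("deg")
        n_significant = {}
        for st in config.stages:
            ratios = call_degs(merged, st, config.ratio_cutoff,
                               config.treatment, config.control)
            n_significant[st] = int(ratios["significant"].sum())
            write_table(ratios, out / f"ratios_{st}.tsv")
            hist = ratio_histogram(ratios)
            write_table(hist.bins, out / f"ratio_hist_{st}.tsv")
            up, down = top_k(ratios)
            write_table(up, out / f"top_up_{st}.tsv")
            write_table(down, out / f"top_down_{st}.tsv")
            bk = breakdown_degs(ratios, annotation, comparison_id=f"{config.treatment}-vs-{config.control}@{st}")
            write_table(bk, out / f"deg_breakdown_{st}.tsv")

        stage("set partition")
        if config.activity_mode == "merged":
            cond_mask = condition_activity(merged, annotation,
                                           config.length_min, config.rpkm_min)
        else:
            from .set_partition import activity_all_replicates

            cond_mask = activity_all_replicates(mask, design)
        conditions = list(dict.fromkeys(design["condition"]))
        sets = active_sets(cond_mask, conditions)
        part = partition(sets)
        part_out = part.drop(columns="conditions").copy()
        part_out["member_ids"] = part_out["member_ids"].map(",".join)
        write_table(part_out, out / "partition.tsv")

        stage("functional profile")
        prof = profile_active(cond_mask, annotation, conditions)
        write_table(prof, out / "profile.tsv")

        psi_screened = None
        if config.psi is not None:
            stage("psi screen")
            psi = read_psi(config.psi)
            amps = amplitudes(psi)
            screened = screen(expr, amps, design, config.r2_thresholds)
            write_table(screened, out / "psi_screen.tsv")
            psi_screened = {
                "passes_090": int(screened["passes_090"].sum()),
                "passes_099": int(screened["passes_099"].sum()),
            }

        qpcr_summary = None
        if config.qpcr_plate is not None:
            stage("qpcr")
            plate = read_cq(config.qpcr_plate)
            result = relative_expression(
                plate,
                config.qpcr_treatment_sample,
                config.qpcr_control_sample,
                config.reference_genes,
                log2_cutoff=config.log2_cutoff,
                alpha=config.alpha,
                equal_var=config.equal_var_ttest,
            )
            write_table(result, out / "ddcq.tsv")
            qpcr_summary = {"n_genes": int(len(result)),
                            "n_significant_magnitude": int(result["significant_magnitude"].sum())}
    except InputError as err:
        raise InputError(f"pipeline aborted: {err}") from err

    manifest = {
        "berrydeg_version": __version__,
        "config": asdict(config),
        "config_sha256": _config_hash(config),
        "expression_mode": expression_mode,
        "universe": {
            "n_transcripts": summary.n_transcripts,
            "active_in_all": summary.active_in_all,
            "active_in_none": summary.active_in_none,
            "active_in_some": summary.active_in_some,
        },
        "n_significant_degs": n_significant,
        "psi_screen": psi_screened,
        "qpcr": qpcr_summary,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out
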