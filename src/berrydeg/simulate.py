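"""Synthetic data generator with construction-known ground truth.

Emulates the study design every stage of the pipeline expects: two deficit
irrigation treatments (SDI control, RDI stronger restriction) x two
RNA-seq developmental stages (veraison V, maturation M) x two biological
replicates, with planted differentially expressed transcripts, planted
water-potential-linked transcripts, sub-150-bp "short" transcripts,
sub-threshold "inactive" transcripts, diurnal leaf-water-potential curves,
and RT-qPCR Cq plates with three stable reference genes.

Baseline expression is log-normal on the RPKM scale (a heavy right tail,
matching the marginal shape of bulk RNA-seq expression); replicate noise is
multiplicative log-normal.  Expression is converted to expected read counts
through transcript length and a nominal library size, then rounded, so that
RPKM quantification approximately inverts the construction instead of being
bypassed.  All randomness flows from a single seeded
:class:`numpy.random.Generator`, making runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .io_tables import validate_annotation, validate_design

PSI_TIMES = ("8h", "11h", "14h", "17h", "19h")
#: diurnal shape: fraction of the daily amplitude below the morning maximum
PSI_SHAPE = (0.0, 0.6, 1.0, 0.7, 0.3)

DEFAULT_CATEGORIES = (
    ("PM—photosynthesis", 0.08),
    ("PM—miscellaneous", 0.16),
    ("PM—amino acid metabolism", 0.06),
    ("PM—protein metabolism and modification", 0.10),
    ("SM—miscellaneous", 0.06),
    ("RS—abiotic stress response", 0.05),
    ("RS—biotic stress response", 0.04),
    ("RT—transcription factors", 0.06),
    ("signaling", 0.07),
    ("cellular process", 0.07),
    ("transport overview", 0.05),
    ("Unknown", 0.20),
)

#: daily water-potential amplitudes (MPa) per condition; the stronger deficit
#: (RDI) swings wider, and maturation (later, drier season) wider than veraison
DEFAULT_PSI_AMPLITUDES = {"SV": 0.4, "RV": 0.8, "SM": 0.5, "RM": 1.0}


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions.

    ``n_up``/``n_down`` transcripts are planted per RNA-seq stage (V and M,
    disjoint sets) at ``fold_change`` in the RDI columns.  ``psi_noise_sd``
    is the relative (fraction-of-signal) noise on the water-potential-linked
    transcripts; ``replicate_noise_sd`` is the log-scale sd of the
    between-replicate multiplicative noise.
    """

    n_transcripts: int = 2000
    n_up: int = 20
    n_down: int = 20
    fold_change: float = 4.0
    n_psi_linked: int = 20
    n_short: int = 50
    n_inactive: int = 200
    psi_noise_sd: float = 0.01
    replicate_noise_sd: float = 0.05
    length_range: tuple[int, int] = (200, 5000)
    short_length_range: tuple[int, int] = (50, 149)
    category_vocabulary: tuple = DEFAULT_CATEGORIES
    library_size: int = 20_000_000
    psi_amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_PSI_AMPLITUDES))
    psi_base: float = -0.2
    qpcr_fold_changes: dict = field(
        default_factory=lambda: {"HSP22": 8.0, "APX1": 4.0, "ERF105": 0.25, "AUX22": 1.0}
    )
    cq_noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        planted = 2 * (self.n_up + self.n_down) + self.n_psi_linked
        if planted + self.n_short + self.n_inactive > self.n_transcripts:
            raise InputError(
                "infeasible config: planted + short + inactive transcript counts "
                f"({planted + self.n_short + self.n_inactive}) exceed n_transcripts "
                f"({self.n_transcripts})"
            )
        if self.fold_change <= 1:
            raise InputError("fold_change must exceed 1")
        if self.n_transcripts < 0:
            raise InputError("n_transcripts must be non-negative")


def default_design() -> pd.DataFrame:
    """The 2 treatment x 2 stage x 2 replicate RNA-seq sample sheet."""
    rows = []
    for treatment in ("SDI", "RDI"):
        for stage in ("V", "M"):
            for rep in (1, 2):
                rows.append(
                    {
                        "sample_id": f"{treatment[0]}{stage}{rep}",
                        "treatment": treatment,
                        "stage": stage,
                        "replicate": rep,
                    }
                )
    return validate_design(pd.DataFrame(rows))


def simulate_counts(config: SimulationConfig):
    """Counts, annotation, design and ground truth for one simulated study.

    Returns ``(counts, annotation, design, truth)``.  ``truth`` has one row
    per transcript with a ``label`` in {up, down, null, psi_linked, short,
    inactive}, the planted ``stage`` for DEG labels, and the per-condition
    true expression used for construction is recoverable from the labels and
    the config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    design = default_design()
    ids = np.array([f"tx{i:05d}" for i in range(n)])

    if n == 0:
        counts = pd.DataFrame(
            np.empty((0, len(design)), dtype=np.int64),
            index=pd.Index([], name="transcript_id"),
            columns=design["sample_id"].tolist(),
        )
        annotation = pd.DataFrame(
            {"length_bp": pd.Series(dtype=np.int64),
             "functional_category": pd.Series(dtype=str),
             "sub_category": pd.Series(dtype=object)},
            index=pd.Index([], name="transcript_id"),
        )
        truth = pd.DataFrame(
            {"label": pd.Series(dtype=str), "stage": pd.Series(dtype=object)},
            index=pd.Index([], name="transcript_id"),
        )
        return counts, annotation, design, truth

    # --- assign roles to disjoint transcript blocks (shuffled for realism)
    order = rng.permutation(n)
    labels = np.full(n, "null", dtype=object)
    stages_planted = np.full(n, None, dtype=object)
    cursor = 0

    def take(k):
        nonlocal cursor
        block = order[cursor:cursor + k]
        cursor += k
        return block

    planted_idx = {}
    for stage in ("V", "M"):
        up = take(config.n_up)
        down = take(config.n_down)
        labels[up], labels[down] = "up", "down"
        stages_planted[up], stages_planted[down] = stage, stage
        planted_idx[(stage, "up")], planted_idx[(stage, "down")] = up, down
    psi_idx = take(config.n_psi_linked)
    labels[psi_idx] = "psi_linked"
    short_idx = take(config.n_short)
    labels[short_idx] = "short"
    inactive_idx = take(config.n_inactive)
    labels[inactive_idx] = "inactive"

    # --- annotation
    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, size=n)
    lengths[short_idx] = rng.integers(
        config.short_length_range[0], config.short_length_range[1] + 1,
        size=len(short_idx),
    )
    cats = [c for c, _ in config.category_vocabulary]
    weights = np.array([w for _, w in config.category_vocabulary], dtype=float)
    weights /= weights.sum()
    categories = rng.choice(cats, size=n, p=weights)
    annotation = validate_annotation(
        pd.DataFrame(
            {"transcript_id": ids, "length_bp": lengths, "functional_category": categories}
        )
    )

    # --- baseline condition-level RPKM
    base = np.exp(rng.normal(2.0, 1.5, size=n))  # lognormal, heavy right tail
    planted_any = np.isin(labels, ("up", "down", "psi_linked"))
    base[planted_any] = np.maximum(base[planted_any], 5.0)  # keep planted transcripts active
    base[inactive_idx] = rng.uniform(0.01, 0.3, size=len(inactive_idx))

    amps = config.psi_amplitudes
    cond_expr = {}
    for cond in design["condition"].unique():
        treatment = "RDI" if cond[0] == "R" else "SDI"
        stage = cond[1]
        e = base.copy()
        if treatment == "RDI":
            e[planted_idx[(stage, "up")]] *= config.fold_change
            e[planted_idx[(stage, "down")]] /= config.fold_change
        # psi-linked: expression proportional to the condition's daily amplitude
        scale = amps[cond] / np.mean(list(amps.values()))
        e[psi_idx] = base[psi_idx] * scale
        cond_expr[cond] = e

    # --- replicate realisation -> expected counts -> integer counts
    counts = {}
    for _, row in design.iterrows():
        e = cond_expr[row["condition"]].copy()
        if config.replicate_noise_sd > 0:
            noise = np.exp(rng.normal(0.0, config.replicate_noise_sd, size=n))
            noise[psi_idx] = 1.0  # psi-linked noise is governed by psi_noise_sd alone
            e = e * noise
        if config.psi_noise_sd > 0 and len(psi_idx):
            e[psi_idx] *= 1.0 + rng.normal(0.0, config.psi_noise_sd, size=len(psi_idx))
        e = np.maximum(e, 0.0)
        expected = e * (lengths / 1e3) * (config.library_size / 1e6)
        counts[row["sample_id"]] = np.rint(expected).astype(np.int64)
    counts = pd.DataFrame(counts, index=pd.Index(ids, name="transcript_id"))

    truth = pd.DataFrame(
        {"label": labels, "stage": stages_planted},
        index=pd.Index(ids, name="transcript_id"),
    )
    return counts, annotation, design, truth


def simulate_psi(config: SimulationConfig, design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Diurnal leaf-water-potential series per condition.

    Each condition's curve is its base potential minus the configured daily
    amplitude times a fixed diurnal shape (pre-dawn high, mid-afternoon low),
    so ``max - min`` recovers the configured amplitude exactly.
    """
    if design is None:
        design = default_design()
    rows = []
    for cond in design["condition"].unique():
        amp = config.psi_amplitudes[cond]
        for t, frac in zip(PSI_TIMES, PSI_SHAPE):
            rows.append(
                {"condition": cond, "time": t, "psi_mpa": config.psi_base - amp * frac}
            )
    return pd.DataFrame(rows, columns=["condition", "time", "psi_mpa"])


def simulate_qpcr(
    config: SimulationConfig,
    treatment_sample: str = "RM",
    control_sample: str = "SM",
) -> pd.DataFrame:
    """Cq plate for a treatment-vs-control comparison with known fold changes.

    Reference genes (ACT, TIF, TIF-GTP) sit at fixed Cq in every sample;
    each target's Cq in the treatment sample is shifted by ``-log2(fold)``
    relative to control, the 100 %-efficiency encoding of a fold change.
    2 biological x 2 technical replicates per well group; Gaussian Cq noise
    of sd ``cq_noise_sd`` cycles.
    """
    if not config.qpcr_fold_changes:
        raise InputError("qpcr_fold_changes must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9417]))
    ref_cq = {"ACT": 20.0, "TIF": 21.0, "TIF-GTP": 22.0}
    base_cq = 24.0
    rows = []
    for sample in (control_sample, treatment_sample):
        for gene, fold in config.qpcr_fold_changes.items():
            shift = -np.log2(fold) if sample == treatment_sample else 0.0
            for bio in (1, 2):
                for tech in (1, 2):
                    rows.append(
                        {
                            "gene": gene, "sample": sample, "role": "target",
                            "cq": base_cq + shift + rng.normal(0, config.cq_noise_sd),
                            "bio_rep": bio, "tech_rep": tech,
                        }
                    )
        for gene, cq in ref_cq.items():
            for bio in (1, 2):
                for tech in (1, 2):
                    rows.append(
                        {
                            "gene": gene, "sample": sample, "role": "reference",
                            "cq": cq + rng.normal(0, config.cq_noise_sd),
                            "bio_rep": bio, "tech_rep": tech,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["gene", "sample", "role", "cq", "bio_rep", "tech_rep"]
    )
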