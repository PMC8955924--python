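"""Tabular I/O and the shared data model.

Every stage of the pipeline exchanges plain :class:`pandas.DataFrame` objects
with documented schemas; this module owns reading, validation and writing of
those tables.

Conventions
-----------
* A *count matrix* / *expression matrix* is a DataFrame indexed by
  ``transcript_id`` with one column per ``sample_id`` (or per condition after
  replicate merging).  Counts are non-negative integers (a permissive mode
  accepts non-negative reals for estimated counts); expression values are
  non-negative RPKM.
* An *annotation table* is indexed by ``transcript_id`` with columns
  ``length_bp`` (int, >= 1), ``functional_category`` (never empty; missing
  cells become ``"Unclassified"``) and optional ``sub_category``.
* A *sample sheet* (design) has columns ``sample_id``, ``treatment``
  (``SDI`` control / ``RDI`` stronger deficit), ``stage`` (``G`` pea size,
  ``V`` veraison, ``M`` maturation), ``replicate`` and optional
  ``library_size``; a derived ``condition`` column holds the treatment-initial
  plus stage label (``RV``, ``SM``, ...).
* A *psi table* has columns ``condition``, ``time``, ``psi_mpa`` — leaf water
  potential in MPa per time of day.
* A *Cq table* has columns ``gene``, ``sample``, ``role`` (target/reference),
  ``cq``, ``bio_rep`` and ``tech_rep`` — every well is one technical
  replicate nested in one biological replicate, so both indices are explicit.

Matrices and annotation are tab-separated; psi and Cq tables are
comma-separated.  Delimiters are fixed per table kind (no sniffing) so that
outputs are predictable and round-trips are exact to the rendered precision.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

TREATMENTS = ("SDI", "RDI")
STAGES = ("G", "V", "M")

#: label used when an annotation row has no functional category
UNCLASSIFIED = "Unclassified"

#: decimal places used when rendering floats to disk
FLOAT_DECIMALS = 6

_SAMPLE_ID_RE = re.compile(r"^([SR])([GVM])(\d+)$")


def condition_id(treatment: str, stage: str) -> str:
    """Condition label for a (treatment, stage) pair, e.g. ``RV`` or ``SM``."""
    if treatment not in TREATMENTS:
        raise InputError(f"unknown treatment {treatment!r}; expected one of {TREATMENTS}")
    if stage not in STAGES:
        raise InputError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return treatment[0] + stage


def parse_sample_id(sample_id: str) -> tuple[str, str, int]:
    """Parse the default ``<treatment letter><stage letter><replicate>`` naming.

    ``RV1`` -> ``("RDI", "V", 1)``.  The sample sheet always overrides this
    convention; the parser exists for convenience when no sheet is given.
    """
    m = _SAMPLE_ID_RE.match(sample_id)
    if m is None:
        raise InputError(
            f"sample id {sample_id!r} does not follow the "
            "'<treatment letter><stage letter><replicate>' convention"
        )
    treat = {"S": "SDI", "R": "RDI"}[m.group(1)]
    return treat, m.group(2), int(m.group(3))


# ---------------------------------------------------------------------------
# sample sheet


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet and attach the derived ``condition`` column."""
    required = {"sample_id", "treatment", "stage", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise InputError(f"sample sheet lacks required column(s): {sorted(missing)}")
    design = design.copy()
    bad_treat = set(design["treatment"]) - set(TREATMENTS)
    if bad_treat:
        raise InputError(f"unknown treatment value(s) {sorted(bad_treat)} in sample sheet")
    bad_stage = set(design["stage"]) - set(STAGES)
    if bad_stage:
        raise InputError(f"unknown stage value(s) {sorted(bad_stage)} in sample sheet")
    design["replicate"] = design["replicate"].astype(int)
    if (design["replicate"] < 1).any():
        raise InputError("replicate numbers must be positive integers")
    key = design[["treatment", "stage", "replicate"]].apply(tuple, axis=1)
    dup = key[key.duplicated()]
    if not dup.empty:
        raise InputError(f"duplicate (treatment, stage, replicate) row(s): {sorted(dup)}")
    if design["sample_id"].duplicated().any():
        dups = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise InputError(f"duplicate sample_id(s): {dups}")
    if "library_size" in design.columns:
        sizes = design["library_size"]
        if sizes.notna().any() and (sizes.dropna() <= 0).any():
            raise InputError("library_size must be positive when given")
    design["condition"] = [
        condition_id(t, s) for t, s in zip(design["treatment"], design["stage"])
    ]
    return design


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet CSV and validate it."""
    design = pd.read_csv(path)
    return validate_design(design)


# ---------------------------------------------------------------------------
# matrices


def _read_matrix(path: str | Path) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    mat.index.name = "transcript_id"
    if mat.index.duplicated().any():
        dups = mat.index[mat.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate transcript_id(s) in matrix: {dups}")
    return mat


def _restrict_to_design(mat: pd.DataFrame, design: pd.DataFrame | None) -> pd.DataFrame:
    if design is None:
        return mat
    wanted = list(design["sample_id"])
    missing = [s for s in wanted if s not in mat.columns]
    if missing:
        raise InputError(f"matrix is missing sample column(s) declared in design: {missing}")
    return mat[wanted]


def read_count_matrix(
    path: str | Path,
    design: pd.DataFrame | None = None,
    *,
    allow_real: bool = False,
) -> pd.DataFrame:
    """Read a transcripts x samples count matrix (TSV).

    Columns are restricted to, and ordered as, the design's ``sample_id`` list
    when a design is given.  Counts must be non-negative integers unless
    ``allow_real`` is set (estimated counts from upstream quantifiers may be
    fractional).
    """
    mat = _read_matrix(path)
    mat = _restrict_to_design(mat, design)
    for col in mat.columns:
        vals = pd.to_numeric(mat[col], errors="coerce")
        bad = vals.isna() | np.isinf(vals)
        if bad.any():
            row = mat.index[bad.to_numpy().nonzero()[0][0]]
            raise InputError(f"unparseable count at transcript {row!r}, sample {col!r}")
        if (vals < 0).any():
            row = mat.index[(vals < 0).to_numpy().nonzero()[0][0]]
            raise InputError(f"negative count at transcript {row!r}, sample {col!r}")
        if not allow_real and not np.allclose(vals, np.round(vals), atol=0, rtol=0):
            off = vals[vals != np.round(vals)]
            raise InputError(
                f"non-integer count at transcript {off.index[0]!r}, sample {col!r} "
                "(pass allow_real=True for estimated counts)"
            )
        mat[col] = vals if allow_real else vals.astype(np.int64)
    return mat


def read_expression_matrix(
    path: str | Path, design: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Read a transcripts x samples (or x conditions) RPKM matrix (TSV)."""
    mat = _read_matrix(path)
    mat = _restrict_to_design(mat, design)
    arr = mat.apply(pd.to_numeric, errors="coerce")
    if arr.isna().any().any():
        r, c = next(zip(*np.where(arr.isna())))
        raise InputError(
            f"unparseable expression value at transcript {arr.index[r]!r}, "
            f"column {arr.columns[c]!r}"
        )
    if (arr < 0).any().any():
        r, c = next(zip(*np.where(arr < 0)))
        raise InputError(
            f"negative expression value at transcript {arr.index[r]!r}, "
            f"column {arr.columns[c]!r}"
        )
    return arr.astype(float)


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a transcript annotation TSV (id, length_bp, functional_category[, sub_category]).

    Missing or empty category cells map to :data:`UNCLASSIFIED`; duplicate ids
    and non-positive lengths are rejected.
    """
    ann = pd.read_csv(path, sep="\t", dtype={0: str})
    return validate_annotation(ann)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory annotation table; returns it indexed by transcript_id."""
    ann = ann.copy()
    if ann.index.name != "transcript_id":
        first = ann.columns[0]
        id_col = "transcript_id" if "transcript_id" in ann.columns else first
        ann = ann.rename(columns={id_col: "transcript_id"}).set_index("transcript_id")
    ann.index = ann.index.astype(str)
    if "length_bp" not in ann.columns or "functional_category" not in ann.columns:
        raise InputError("annotation needs 'length_bp' and 'functional_category' columns")
    if ann.index.duplicated().any():
        dups = ann.index[ann.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate transcript_id(s) in annotation: {dups}")
    ann["length_bp"] = pd.to_numeric(ann["length_bp"], errors="raise").astype(np.int64)
    if (ann["length_bp"] < 1).any():
        bad = ann.index[ann["length_bp"] < 1].tolist()
        raise InputError(f"length_bp must be >= 1; offending transcript(s): {bad}")
    cat = ann["functional_category"].astype("object")
    blank = cat.isna() | (cat.astype(str).str.strip() == "")
    if blank.any():
        logger.info("annotation: %d transcript(s) without category -> %s",
                    int(blank.sum()), UNCLASSIFIED)
    ann["functional_category"] = cat.where(~blank, UNCLASSIFIED).astype(str)
    if "sub_category" not in ann.columns:
        ann["sub_category"] = pd.NA
    return ann


# ---------------------------------------------------------------------------
# water potential and qPCR tables


def read_psi(path: str | Path) -> pd.DataFrame:
    """Read a leaf water potential CSV with columns condition, time, psi_mpa."""
    psi = pd.read_csv(path)
    required = {"condition", "time", "psi_mpa"}
    missing = required - set(psi.columns)
    if missing:
        raise InputError(f"psi table lacks column(s): {sorted(missing)}")
    psi["psi_mpa"] = pd.to_numeric(psi["psi_mpa"], errors="raise")
    counts = psi.groupby("condition")["psi_mpa"].count()
    few = counts[counts < 2]
    if not few.empty:
        raise InputError(
            f"psi amplitude needs >= 2 measurements per condition; too few for: "
            f"{sorted(few.index)}"
        )
    return psi


def read_cq(path: str | Path) -> pd.DataFrame:
    """Read an RT-qPCR Cq plate CSV.

    Missing Cq cells are treated as failed wells: dropped with a logged
    warning rather than rejected, mirroring bench reality.
    """
    plate = pd.read_csv(path)
    required = {"gene", "sample", "role", "cq", "bio_rep", "tech_rep"}
    missing = required - set(plate.columns)
    if missing:
        raise InputError(f"Cq table lacks column(s): {sorted(missing)}")
    plate["cq"] = pd.to_numeric(plate["cq"], errors="coerce")
    failed = plate["cq"].isna()
    if failed.any():
        logger.warning("dropping %d failed well(s) with missing Cq", int(failed.sum()))
        plate = plate.loc[~failed].copy()
    if (plate["cq"] <= 0).any():
        raise InputError("Cq values must be finite and > 0")
    bad_role = set(plate["role"]) - {"target", "reference"}
    if bad_role:
        raise InputError(f"unknown role value(s) {sorted(bad_role)}; expected target/reference")
    return plate


# ---------------------------------------------------------------------------
# writing


def write_table(table: pd.DataFrame, path: str | Path, *, index: bool | None = None) -> None:
    """Write a result table with stable column order and fixed float precision.

    Tab-separated unless the path ends in ``.csv``.  Matrices (indexed by
    ``transcript_id``) keep their index; plain record tables do not.  An empty
    table produces a header-only file.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    if index is None:
        index = table.index.name is not None
    table.to_csv(path, sep=sep, index=index, float_format=f"%.{FLOAT_DECIMALS}g")
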