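"""Readers and writers for every external table the pipeline touches.

All parsing and validation happens here so the analysis modules only ever
see validated in-memory containers:

* expression tables (TSV/CSV, miRNAs x samples, counts or cpm),
* mature-miRNA annotation tables (with optional miRBase-style GFF3 as an
  alternative source of the arm -> locus map),
* dual-luciferase reporter plate tables,
* the audit report (TSV and JSON, with a shipped JSON schema).

cpm columns must sum to 1e6 within a configurable relative tolerance
(public exports are rounded); matrices declared "prefiltered" (a subset of
miRNAs) only need column sums <= 1e6 plus tolerance.
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_seed import MirnaAnnotation
from .errors import ValidationError

CPM_TOTAL = 1_000_000.0
SAMPLE_CLASSES = ("cell_line", "tissue", "other")

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f"}
_MISSING = {"", "na", "nan", "none", "unknown", "null"}


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class TableDialect:
    """How to interpret an expression table on disk.

    orientation: "mirnas_by_samples" (canonical), "samples_by_mirnas"
    (transposed on read), or "auto" (pick the orientation whose column sums
    look like cpm totals; falls back to canonical).
    """

    sep: str = "\t"
    unit: str = "cpm"  # "cpm" | "counts"
    orientation: str = "mirnas_by_samples"
    prefiltered: bool = False
    dataset: str | None = None
    cpm_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.unit not in ("cpm", "counts"):
            raise ValidationError(f"unit must be 'cpm' or 'counts', got {self.unit!r}")
        if self.orientation not in ("mirnas_by_samples", "samples_by_mirnas", "auto"):
            raise ValidationError(f"unknown orientation {self.orientation!r}")


@dataclass
class ExpressionMatrix:
    """A validated nonnegative expression matrix, miRNAs x samples.

    ``values`` is indexed by mature miRNA id with sample ids as columns.
    ``sample_meta`` is indexed by sample id and carries ``dataset``,
    ``tissue_or_cell`` and ``sample_class`` per column.
    """

    values: pd.DataFrame
    unit: str = "cpm"
    sample_meta: pd.DataFrame | None = None
    prefiltered: bool = False
    name: str = "dataset"
    cpm_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(
                {
                    "dataset": self.name,
                    "tissue_or_cell": "unknown",
                    "sample_class": "other",
                },
                index=self.values.columns,
            )
        self.validate()

    # -- introspection ------------------------------------------------------
    @property
    def mature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_mirnas(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        vals = self.values
        if vals.size == 0:
            raise ValidationError(f"{self.name}: empty expression matrix")
        dup_rows = vals.index[vals.index.duplicated()].unique().tolist()
        if dup_rows:
            raise ValidationError(f"{self.name}: duplicate miRNA ids {dup_rows}")
        dup_cols = vals.columns[vals.columns.duplicated()].unique().tolist()
        if dup_cols:
            raise ValidationError(f"{self.name}: duplicate sample ids {dup_cols}")
        arr = vals.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"{self.name}: non-finite value at (row={vals.index[r]!r}, "
                f"col={vals.columns[c]!r})"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"{self.name}: negative value {arr[r, c]} at "
                f"(row={vals.index[r]!r}, col={vals.columns[c]!r})"
            )
        if self.unit == "cpm":
            sums = arr.sum(axis=0)
            tol = self.cpm_tolerance * CPM_TOTAL
            if self.prefiltered:
                bad = np.flatnonzero(sums > CPM_TOTAL + tol)
            else:
                bad = np.flatnonzero(np.abs(sums - CPM_TOTAL) > tol)
            if bad.size:
                j = bad[0]
                raise ValidationError(
                    f"{self.name}: cpm column {vals.columns[j]!r} sums to "
                    f"{sums[j]:.6g}, outside tolerance of {CPM_TOTAL:g}"
                    + (" (prefiltered: must be <=)" if self.prefiltered else "")
                )
        meta = self.sample_meta
        if not meta.index.equals(vals.columns):
            raise ValidationError(
                f"{self.name}: sample_meta index does not match matrix columns"
            )
        for col in ("dataset", "tissue_or_cell", "sample_class"):
            if col not in meta.columns:
                raise ValidationError(f"{self.name}: sample_meta lacks {col!r}")
        bad_class = set(meta["sample_class"]) - set(SAMPLE_CLASSES)
        if bad_class:
            raise ValidationError(
                f"{self.name}: unknown sample_class values {sorted(bad_class)}"
            )


@dataclass(frozen=True)
class SampleSetSummary:
    """Headline sizes of a collection of expression matrices."""

    n_samples: int
    n_mirnas: int
    n_datasets: int
    samples_per_class: dict[str, int]


def summarize_sample_set(matrices: Sequence[ExpressionMatrix]) -> SampleSetSummary:
    matures: set[str] = set()
    datasets: set[str] = set()
    per_class: dict[str, int] = {}
    n_samples = 0
    for m in matrices:
        matures.update(m.mature_ids)
        datasets.update(m.sample_meta["dataset"])
        n_samples += m.n_samples
        for cls, cnt in m.sample_meta["sample_class"].value_counts().items():
            per_class[cls] = per_class.get(cls, 0) + int(cnt)
    return SampleSetSummary(
        n_samples=n_samples,
        n_mirnas=len(matures),
        n_datasets=len(datasets),
        samples_per_class=per_class,
    )


def _looks_like_cpm(sums: np.ndarray, tol: float, prefiltered: bool) -> bool:
    if prefiltered:
        return bool((sums <= CPM_TOTAL * (1 + tol)).all())
    return bool((np.abs(sums - CPM_TOTAL) <= tol * CPM_TOTAL).all())


def read_expression_table(
    path: str | Path,
    dialect: TableDialect | None = None,
    sample_meta: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Read a TSV/CSV expression table into a validated ``ExpressionMatrix``.

    The first column holds miRNA identifiers (or sample identifiers when the
    table is transposed); a header row is required. Non-numeric and negative
    cells are hard errors reported with their coordinates.
    """
    path = Path(path)
    dialect = dialect or TableDialect()
    if not path.exists():
        raise ValidationError(f"expression table not found: {path}")
    raw = pd.read_csv(path, sep=dialect.sep, index_col=0, comment="#", dtype=str)
    if raw.empty or raw.shape[1] == 0:
        raise ValidationError(f"{path}: empty expression table")
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell {raw.iat[r, c]!r} at "
            f"(row={raw.index[r]!r}, col={raw.columns[c]!r})"
        )
    numeric = numeric.fillna(0.0).astype(float)

    orientation = dialect.orientation
    if orientation == "auto":
        if dialect.unit == "cpm":
            as_is = _looks_like_cpm(
                numeric.to_numpy().sum(axis=0), dialect.cpm_tolerance,
                dialect.prefiltered,
            )
            flipped = _looks_like_cpm(
                numeric.to_numpy().sum(axis=1), dialect.cpm_tolerance,
                dialect.prefiltered,
            )
            orientation = (
                "samples_by_mirnas" if (flipped and not as_is) else "mirnas_by_samples"
            )
        else:
            orientation = "mirnas_by_samples"
    if orientation == "samples_by_mirnas":
        numeric = numeric.T
    numeric.index.name = None
    numeric.columns.name = None

    name = dialect.dataset or path.stem
    return ExpressionMatrix(
        values=numeric,
        unit=dialect.unit,
        sample_meta=sample_meta,
        prefiltered=dialect.prefiltered,
        name=name,
        cpm_tolerance=dialect.cpm_tolerance,
    )


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, sep: str = "\t"
) -> None:
    matrix.values.to_csv(Path(path), sep=sep, index_label="mature_id",
                         float_format="%.10g")


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

_REQUIRED_ANN_COLS = ("mature_id", "locus_id", "arm", "sequence")


def _parse_optional_bool(value: object) -> bool | None:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    if s in _MISSING:
        return None
    raise ValidationError(f"cannot parse boolean flag {value!r}")


def _parse_optional_float(value: object) -> float | None:
    s = str(value).strip().lower()
    if s in _MISSING:
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise ValidationError(f"cannot parse number {value!r}") from exc


def read_annotation_table(path: str | Path, sep: str = "\t") -> list[MirnaAnnotation]:
    """Read a mature-miRNA annotation table.

    Required columns: mature_id, locus_id, arm, sequence. Optional:
    mirgenedb_member, taxon_node, taxon_age_mya, drosha_class (missing
    values become "unknown"/None). The same mature_id may appear on several
    rows (paralogous loci producing an identical mature) but only with an
    identical sequence; conflicting sequences are a hard error. Arm values
    are case-folded ("3P" -> "3p").
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"annotation table not found: {path}")
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#").fillna("")
    missing = [c for c in _REQUIRED_ANN_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")

    annotations: list[MirnaAnnotation] = []
    seq_by_mature: dict[str, str] = {}
    for _, row in df.iterrows():
        mature = str(row["mature_id"]).strip()
        arm = str(row["arm"]).strip().lower()
        if arm in ("", *(_MISSING - {""})):
            arm = "unknown"
        ann = MirnaAnnotation(
            mature_id=mature,
            locus_id=str(row["locus_id"]).strip(),
            arm=arm,
            sequence=str(row["sequence"]),
            mirgenedb_member=_parse_optional_bool(row.get("mirgenedb_member", "")),
            taxon_node=(str(row.get("taxon_node", "")).strip() or "unknown"),
            taxon_age_mya=_parse_optional_float(row.get("taxon_age_mya", "")),
            drosha_class=(
                str(row.get("drosha_class", "")).strip().lower() or "unknown"
            ),
        )
        prev = seq_by_mature.get(mature)
        if prev is not None and prev != ann.sequence:
            raise ValidationError(
                f"{path}: mature_id {mature!r} appears with conflicting sequences"
            )
        seq_by_mature[mature] = ann.sequence
        annotations.append(ann)
    if not annotations:
        raise ValidationError(f"{path}: empty annotation table")
    return annotations


def write_annotation_table(
    annotations: Iterable[MirnaAnnotation], path: str | Path, sep: str = "\t"
) -> None:
    rows = [
        {
            "mature_id": a.mature_id,
            "locus_id": a.locus_id,
            "arm": a.arm,
            "sequence": a.sequence,
            "mirgenedb_member": (
                "" if a.mirgenedb_member is None else str(a.mirgenedb_member).lower()
            ),
            "taxon_node": a.taxon_node,
            "taxon_age_mya": "" if a.taxon_age_mya is None else f"{a.taxon_age_mya:g}",
            "drosha_class": a.drosha_class,
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(Path(path), sep=sep, index=False)


# ---------------------------------------------------------------------------
# miRBase-style GFF3
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GffLocusMap:
    """Mature miRNA -> primary transcript (hairpin) map from a GFF3 file.

    Keys are mature accessions and names (both mapped when present);
    ``n_skipped`` counts miRNA features that lacked a usable Derives_from
    parent and were dropped with a warning. Coordinates in the source file
    are 1-based inclusive per the GFF3 standard; no coordinate arithmetic is
    performed here beyond parentage.
    """

    mature_to_locus: dict[str, str]
    n_skipped: int
    n_mirna_features: int


def read_mirbase_gff3(path: str | Path) -> GffLocusMap:
    """Extract the mature -> hairpin map from a miRBase-style GFF3."""
    import gffutils

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"GFF3 file not found: {path}")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    primary_ids = {
        f.id for f in db.features_of_type("miRNA_primary_transcript")
    }
    mapping: dict[str, str] = {}
    n_skipped = 0
    n_features = 0
    for feat in db.features_of_type("miRNA"):
        n_features += 1
        parents = feat.attributes.get("Derives_from", [])
        parent = next((p for p in parents if p in primary_ids), None)
        if parent is None:
            n_skipped += 1
            warnings.warn(
                f"miRNA feature {feat.id!r} has no Derives_from parent; skipped",
                stacklevel=2,
            )
            continue
        for key_attr in ("ID", "Name"):
            for key in feat.attributes.get(key_attr, []):
                mapping[key] = parent
    return GffLocusMap(
        mature_to_locus=mapping, n_skipped=n_skipped, n_mirna_features=n_features
    )


# ---------------------------------------------------------------------------
# reporter plates
# ---------------------------------------------------------------------------

EMPTY_VECTOR = "EMPTY_VECTOR"
_PLATE_COLS = ("reporter_id", "target_mirna", "bio_rep", "tech_rep",
               "firefly", "renilla")


@dataclass
class ReporterDataset:
    """Raw dual-luciferase plate readings.

    One row per well: reporter identity, the mature miRNA the reporter was
    designed against (or ``EMPTY_VECTOR`` for the unmodified control
    vector), biological and technical replicate indices, and the Firefly /
    Renilla luminescence readings. Firefly is the internal transfection
    control and must be positive (it is a divisor).
    """

    measurements: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.measurements
        missing = [c for c in _PLATE_COLS if c not in df.columns]
        if missing:
            raise ValidationError(f"reporter plate lacks columns {missing}")
        if df.empty:
            raise ValidationError("reporter plate has no rows")
        ff = df["firefly"].to_numpy(dtype=float)
        rn = df["renilla"].to_numpy(dtype=float)
        if not (np.isfinite(ff).all() and np.isfinite(rn).all()):
            raise ValidationError("reporter plate contains non-finite readings")
        if (ff <= 0).any():
            i = int(np.flatnonzero(ff <= 0)[0])
            raise ValidationError(
                f"firefly reading must be > 0 (row {i}, reporter "
                f"{df['reporter_id'].iloc[i]!r})"
            )
        if (rn < 0).any():
            i = int(np.flatnonzero(rn < 0)[0])
            raise ValidationError(f"negative renilla reading at row {i}")
        for col in ("bio_rep", "tech_rep"):
            reps = df[col].to_numpy()
            if not np.issubdtype(np.asarray(reps).dtype, np.integer):
                raise ValidationError(f"{col} must be integer replicate indices")
            if (reps < 1).any():
                raise ValidationError(f"{col} indices must be positive")
        if not (df["target_mirna"] == EMPTY_VECTOR).any():
            raise ValidationError(
                f"reporter plate lacks the {EMPTY_VECTOR} control reporter"
            )

    @property
    def reporter_ids(self) -> list[str]:
        return sorted(self.measurements["reporter_id"].unique())


def read_reporter_plate(path: str | Path, sep: str = ",") -> ReporterDataset:
    """Read a reporter plate CSV into a validated ``ReporterDataset``."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"reporter plate not found: {path}")
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in _PLATE_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df = df.astype(
        {"reporter_id": str, "target_mirna": str, "bio_rep": int,
         "tech_rep": int, "firefly": float, "renilla": float}
    )
    return ReporterDataset(measurements=df)


def write_reporter_plate(
    dataset: ReporterDataset, path: str | Path, sep: str = ","
) -> None:
    dataset.measurements.to_csv(Path(path), sep=sep, index=False,
                                float_format="%.10g")


# ---------------------------------------------------------------------------
# audit reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "mature_id", "max_cpm", "argmax_sample", "argmax_dataset", "bin",
    "not_detected",
)
REPORT_SCHEMA_VERSION = 1


def _sorted_report(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REPORT_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"audit report lacks columns {missing}")
    out = records.loc[:, list(REPORT_COLUMNS)].copy()
    return out.sort_values(["max_cpm", "mature_id"], kind="stable").reset_index(
        drop=True
    )


def write_audit_report(
    records: pd.DataFrame,
    path: str | Path,
    fmt: str = "tsv",
    manifest_hash: str | None = None,
) -> None:
    """Write the per-miRNA max-expression report, TSV or JSON.

    Rows are sorted by (max_cpm ascending, mature_id) for stable output;
    numbers are serialized with enough digits to round-trip through
    ``read_audit_report`` without loss.
    """
    path = Path(path)
    out = _sorted_report(records)
    if fmt == "tsv":
        with open(path, "w") as fh:
            if manifest_hash:
                fh.write(f"# manifest: {manifest_hash}\n")
            out.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    elif fmt == "json":
        payload = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "manifest": manifest_hash,
            "records": [
                {
                    "mature_id": r.mature_id,
                    "max_cpm": float(r.max_cpm),
                    "argmax_sample": r.argmax_sample,
                    "argmax_dataset": r.argmax_dataset,
                    "bin": r.bin,
                    "not_detected": bool(r.not_detected),
                }
                for r in out.itertuples(index=False)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise ValidationError(f"unknown report format {fmt!r}")


def read_audit_report(path: str | Path) -> pd.DataFrame:
    """Read back a TSV or JSON audit report (format inferred from suffix)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"audit report not found: {path}")
    if path.suffix == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        validate_report_json(payload)
        df = pd.DataFrame(payload["records"], columns=list(REPORT_COLUMNS))
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    df = df.astype({"max_cpm": float, "not_detected": bool})
    return _sorted_report(df)


def report_json_schema() -> dict:
    """The shipped JSON schema for the audit report."""
    text = (
        resources.files("miraudit") / "schemas" / "audit_report.schema.json"
    ).read_text()
    return json.loads(text)


def validate_report_json(payload: dict) -> None:
    """Validate a JSON report payload against the report model."""
    from .report_schema import AuditReport

    AuditReport.model_validate(payload)


__all__ = [
    "CPM_TOTAL", "EMPTY_VECTOR", "ExpressionMatrix", "GffLocusMap",
    "ReporterDataset", "SampleSetSummary", "TableDialect",
    "read_annotation_table", "read_audit_report", "read_expression_table",
    "read_mirbase_gff3", "read_reporter_plate", "report_json_schema",
    "summarize_sample_set", "validate_report_json", "write_annotation_table",
    "write_audit_report", "write_expression_table", "write_reporter_plate",
]
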