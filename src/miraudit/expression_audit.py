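"""The core audit: maximal miRNA expression, threshold bins, locus counts.

For every annotated mature miRNA the audit asks a single question: across
every sample of every dataset available, what is the highest cpm it ever
reaches? A miRNA "fails" a threshold T when its maximum never exceeds T
(strictly: failing means max <= T). Maxima are then aggregated to the locus
(hairpin) level — a locus is as expressed as its best arm — binned at
10/100/1000 cpm, accumulated into cumulative locus counts, and stratified
by curation status (miRGeneDB membership) or by the taxonomic age of the
locus.

Datasets from different resources are never merged cell-wise; only the
per-miRNA maxima are combined, so resources with different sample sets and
normalisation provenance stay independent.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_seed import MirnaAnnotation
from .errors import ValidationError
from .io_formats import CPM_TOTAL, ExpressionMatrix

DEFAULT_THRESHOLDS = (10.0, 100.0, 1000.0)

LOCUS_COLUMNS = (
    "locus_id", "max_cpm", "contributing_mature", "contributing_arm", "bin",
    "multi_locus_credit",
)


# ---------------------------------------------------------------------------
# cpm arithmetic
# ---------------------------------------------------------------------------

def counts_to_cpm(counts: np.ndarray | pd.Series, sample: str = "sample"):
    """Scale raw counts to counts-per-million: c_i * 1e6 / sum(c).

    Raises on an all-zero column, naming the offending sample.
    """
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValidationError(f"{sample}: negative counts")
    total = arr.sum()
    if total <= 0:
        raise ValidationError(f"{sample}: all-zero count column, cannot scale to cpm")
    cpm = arr * CPM_TOTAL / total
    if isinstance(counts, pd.Series):
        return pd.Series(cpm, index=counts.index, name=counts.name)
    return cpm


def matrix_counts_to_cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert a counts matrix to cpm column by column."""
    if matrix.unit == "cpm":
        return matrix
    cols = {
        c: counts_to_cpm(matrix.values[c], sample=str(c)) for c in matrix.values
    }
    return ExpressionMatrix(
        values=pd.DataFrame(cols, index=matrix.values.index),
        unit="cpm",
        sample_meta=matrix.sample_meta.copy(),
        prefiltered=matrix.prefiltered,
        name=matrix.name,
        cpm_tolerance=matrix.cpm_tolerance,
    )


def cpm_to_fraction(cpm: float) -> float:
    """Fraction of the total small-RNA pool at a given cpm (200 -> 0.0002)."""
    return cpm / CPM_TOTAL


def cpm_to_percent(cpm: float) -> float:
    """Percent of the total pool at a given cpm (200 -> 0.02)."""
    return 100.0 * cpm / CPM_TOTAL


# ---------------------------------------------------------------------------
# threshold bins
# ---------------------------------------------------------------------------

def bin_labels(thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> list[str]:
    """Ordered bin labels for a strictly increasing threshold list.

    For thresholds (10, 100, 1000): ``<=10``, ``(10,100]``, ``(100,1000]``,
    ``>1000``. Upper bounds are inclusive: a maximum of exactly 100 cpm
    *fails* the 100 cpm threshold ("never expressed above 100 cpm").
    """
    ts = [float(t) for t in thresholds]
    if len(ts) == 0 or any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValidationError("thresholds must be a non-empty strictly increasing list")
    labels = [f"<={ts[0]:g}"]
    labels += [f"({a:g},{b:g}]" for a, b in zip(ts, ts[1:])]
    labels.append(f">{ts[-1]:g}")
    return labels


def classify_threshold(
    max_cpm: float, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> str:
    """Bin a single maximal cpm value (inclusive upper bounds)."""
    if max_cpm < 0 or not np.isfinite(max_cpm):
        raise ValidationError(f"max_cpm must be finite and >= 0, got {max_cpm}")
    return classify_bins([max_cpm], thresholds)[0]


def classify_bins(
    max_cpm: Sequence[float] | np.ndarray,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[str]:
    """Vectorised threshold binning."""
    labels = bin_labels(thresholds)
    arr = np.asarray(max_cpm, dtype=float)
    if arr.size and ((arr < 0) | ~np.isfinite(arr)).any():
        raise ValidationError("max_cpm values must be finite and >= 0")
    idx = np.searchsorted(np.asarray(thresholds, dtype=float), arr, side="left")
    return [labels[i] for i in idx]


# ---------------------------------------------------------------------------
# per-miRNA maxima
# ---------------------------------------------------------------------------

def max_expression(
    matrices: Sequence[ExpressionMatrix],
    annotations: Iterable[MirnaAnnotation] | None = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-miRNA maximal cpm across every column of every matrix.

    Returns one row per distinct mature id with columns ``mature_id``,
    ``max_cpm``, ``argmax_sample``, ``argmax_dataset``, ``bin`` and
    ``not_detected``. Ties are broken first-seen (dataset order as given,
    then column order) for the argmax provenance. When ``annotations`` is
    supplied, annotated matures absent from every matrix are appended with
    ``max_cpm = 0`` and ``not_detected = True`` — absence from a cpm export
    is treated as evidence of non-detection while preserving the
    distinction.
    """
    if not matrices:
        raise ValidationError("max_expression needs at least one matrix")
    for m in matrices:
        if m.unit != "cpm":
            raise ValidationError(
                f"matrix {m.name!r} is in counts; convert with matrix_counts_to_cpm"
            )
    parts = []
    for m in matrices:
        vals = m.values
        row_max = vals.max(axis=1)
        arg_sample = vals.idxmax(axis=1)  # first column attaining the max
        datasets = m.sample_meta["dataset"]
        parts.append(
            pd.DataFrame(
                {
                    "mature_id": vals.index,
                    "max_cpm": row_max.to_numpy(dtype=float),
                    "argmax_sample": arg_sample.to_numpy(),
                    "argmax_dataset": datasets.loc[arg_sample].to_numpy(),
                }
            )
        )
    combined = pd.concat(parts, ignore_index=True)
    # idxmax returns the first occurrence of the max; concat order preserves
    # dataset-then-column precedence, so ties resolve first-seen.
    best = combined.loc[combined.groupby("mature_id")["max_cpm"].idxmax()]
    best = best.sort_values("mature_id", kind="stable").reset_index(drop=True)
    best["not_detected"] = False

    if annotations is not None:
        seen = set(best["mature_id"])
        missing = sorted(
            {a.mature_id for a in annotations if a.mature_id not in seen}
        )
        if missing:
            extra = pd.DataFrame(
                {
                    "mature_id": missing,
                    "max_cpm": 0.0,
                    "argmax_sample": "none",
                    "argmax_dataset": "none",
                    "not_detected": True,
                }
            )
            best = pd.concat([best, extra], ignore_index=True)
            best = best.sort_values("mature_id", kind="stable").reset_index(drop=True)
    best["bin"] = classify_bins(best["max_cpm"].to_numpy(), thresholds)
    return best.loc[:, ["mature_id", "max_cpm", "argmax_sample",
                        "argmax_dataset", "bin", "not_detected"]]


# ---------------------------------------------------------------------------
# locus aggregation
# ---------------------------------------------------------------------------

def _mature_locus_map(
    annotations: Iterable[MirnaAnnotation], multilocus: str
) -> pd.DataFrame:
    if multilocus not in ("all", "first"):
        raise ValidationError("multilocus must be 'all' or 'first'")
    rows, seen_pairs, seen_mature = [], set(), set()
    locus_count: dict[str, int] = {}
    for a in annotations:
        locus_count[a.mature_id] = locus_count.get(a.mature_id, 0)
    for a in annotations:
        pair = (a.mature_id, a.locus_id)
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        locus_count[a.mature_id] += 1
        if multilocus == "first" and a.mature_id in seen_mature:
            continue
        seen_mature.add(a.mature_id)
        rows.append({"mature_id": a.mature_id, "locus_id": a.locus_id,
                     "arm": a.arm})
    df = pd.DataFrame(rows, columns=["mature_id", "locus_id", "arm"])
    df["multi_locus"] = df["mature_id"].map(lambda m: locus_count[m] > 1)
    return df


def locus_aggregate(
    records: pd.DataFrame,
    annotations: Iterable[MirnaAnnotation],
    multilocus: str = "all",
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-miRNA maxima to the locus (hairpin) level.

    A locus's maximum is the maximum over its mature arms. Matures mapping
    to several loci are credited to every parent locus by default
    (``multilocus='all'``, the conservative, function-favouring choice —
    such loci are flagged via ``multi_locus_credit``) or only to their
    first-listed locus (``multilocus='first'``).

    Returns ``(locus_records, unmapped)`` where ``unmapped`` lists matures
    observed in the expression data but absent from the annotation; they are
    excluded from locus counts, never silently dropped.
    """
    anns = list(annotations)
    mapping = _mature_locus_map(anns, multilocus)
    merged = records.merge(mapping, on="mature_id", how="left")
    unmapped = (
        merged[merged["locus_id"].isna()]
        .loc[:, ["mature_id", "max_cpm", "argmax_sample", "argmax_dataset"]]
        .drop_duplicates("mature_id")
        .reset_index(drop=True)
    )
    mapped = merged.dropna(subset=["locus_id"])
    if mapped.empty:
        locus = pd.DataFrame(columns=list(LOCUS_COLUMNS))
        return locus, unmapped
    best = mapped.loc[mapped.groupby("locus_id")["max_cpm"].idxmax()]
    locus = pd.DataFrame(
        {
            "locus_id": best["locus_id"].to_numpy(),
            "max_cpm": best["max_cpm"].to_numpy(dtype=float),
            "contributing_mature": best["mature_id"].to_numpy(),
            "contributing_arm": best["arm"].to_numpy(),
            "multi_locus_credit": best["multi_locus"].to_numpy(dtype=bool),
        }
    )
    locus["bin"] = classify_bins(locus["max_cpm"].to_numpy(), thresholds)
    locus = locus.sort_values("locus_id", kind="stable").reset_index(drop=True)
    return locus.loc[:, list(LOCUS_COLUMNS)], unmapped


def cumulative_locus_counts(
    locus_records: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Cumulative count of loci whose maximum is <= T, for each threshold.

    The table ends with T = inf, whose count equals the total locus number;
    counts are monotone nondecreasing in T by construction.
    """
    maxima = locus_records["max_cpm"].to_numpy(dtype=float)
    ts = [float(t) for t in thresholds] + [np.inf]
    rows = [
        {"threshold": t, "n_loci_le": int((maxima <= t).sum())} for t in ts
    ]
    out = pd.DataFrame(rows)
    out["total_loci"] = len(maxima)
    return out


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def locus_annotation_table(annotations: Iterable[MirnaAnnotation]) -> pd.DataFrame:
    """Locus-level curation/taxon annotation (first arm's values per locus)."""
    rows: dict[str, dict] = {}
    for a in annotations:
        if a.locus_id not in rows:
            rows[a.locus_id] = {
                "locus_id": a.locus_id,
                "mirgenedb_member": a.mirgenedb_member,
                "taxon_node": a.taxon_node,
                "taxon_age_mya": a.taxon_age_mya,
                "drosha_class": a.drosha_class,
            }
    return pd.DataFrame(rows.values())


@dataclass
class StratifiedSummary:
    """Per-stratum locus counts and percentages by threshold bin.

    ``table`` has one row per (non-empty) stratum with ``n_loci``, a count
    column ``n {bin}`` and a percentage column ``pct {bin}`` per bin;
    percentages within a stratum sum to 100 up to float rounding.
    ``empty_strata`` lists annotation strata with no audited locus, omitted
    from the table.
    """

    key: str
    table: pd.DataFrame
    empty_strata: list[str]


def stratify(
    locus_records: pd.DataFrame,
    annotations: Iterable[MirnaAnnotation],
    key: str = "taxon_node",
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> StratifiedSummary:
    """Stratify locus maxima by curation status or taxonomic node.

    ``key`` is ``'mirgenedb_member'`` or ``'taxon_node'``. Loci whose
    annotation lacks the key form their own ``'unknown'`` stratum. Taxon
    strata are ordered oldest first (descending ``taxon_age_mya``),
    matching the conventional presentation of evolutionary age.
    """
    if key not in ("mirgenedb_member", "taxon_node"):
        raise ValidationError(f"unsupported stratification key {key!r}")
    ann_table = locus_annotation_table(annotations)
    merged = locus_records.merge(ann_table, on="locus_id", how="left")

    if key == "mirgenedb_member":
        strata = merged["mirgenedb_member"].map(
            {True: "miRGeneDB", False: "not_miRGeneDB"}
        ).fillna("unknown")
        order = ["miRGeneDB", "not_miRGeneDB", "unknown"]
        all_strata = order
    else:
        strata = merged["taxon_node"].fillna("unknown").replace("", "unknown")
        ages = (
            ann_table.assign(
                taxon_node=ann_table["taxon_node"].fillna("unknown")
            )
            .groupby("taxon_node")["taxon_age_mya"]
            .max()
        )
        all_strata = sorted(
            ages.index,
            key=lambda n: (-(ages[n] if pd.notna(ages[n]) else -1.0), n),
        )
        order = all_strata

    labels = bin_labels(thresholds)
    merged = merged.assign(stratum=strata)
    rows = []
    present = []
    for stratum in order:
        sub = merged[merged["stratum"] == stratum]
        if sub.empty:
            continue
        present.append(stratum)
        n = len(sub)
        counts = sub["bin"].value_counts()
        row: dict[str, object] = {"stratum": stratum, "n_loci": n}
        for lab in labels:
            c = int(counts.get(lab, 0))
            row[f"n {lab}"] = c
            row[f"pct {lab}"] = 100.0 * c / n
        rows.append(row)
    empty = [s for s in all_strata if s not in present]
    table = pd.DataFrame(rows)
    return StratifiedSummary(key=key, table=table, empty_strata=empty)


# ---------------------------------------------------------------------------
# low-expression resource list
# ---------------------------------------------------------------------------

def low_expression_list(
    records: pd.DataFrame,
    annotations: Iterable[MirnaAnnotation],
    threshold: float = 100.0,
) -> pd.DataFrame:
    """Resource table of matures whose maximum never exceeds ``threshold``.

    One row per mature, joined to its locus (or loci, semicolon-separated),
    taxonomic origin, curation flag and DROSHA processing class; sorted by
    (max_cpm ascending, mature_id).
    """
    anns = list(annotations)
    meta: dict[str, dict] = {}
    for a in anns:
        entry = meta.setdefault(
            a.mature_id,
            {
                "locus_ids": [],
                "mirgenedb_member": a.mirgenedb_member,
                "taxon_node": a.taxon_node,
                "taxon_age_mya": a.taxon_age_mya,
                "drosha_class": a.drosha_class,
            },
        )
        if a.locus_id not in entry["locus_ids"]:
            entry["locus_ids"].append(a.locus_id)

    low = records[records["max_cpm"] <= threshold].copy()
    low["locus_ids"] = low["mature_id"].map(
        lambda m: ";".join(meta[m]["locus_ids"]) if m in meta else ""
    )
    for col in ("mirgenedb_member", "taxon_node", "taxon_age_mya", "drosha_class"):
        low[col] = low["mature_id"].map(
            lambda m, c=col: meta[m][c] if m in meta else None
        )
    low = low.sort_values(["max_cpm", "mature_id"], kind="stable").reset_index(
        drop=True
    )
    cols = [
        "mature_id", "max_cpm", "argmax_sample", "argmax_dataset", "bin",
        "not_detected", "locus_ids", "mirgenedb_member", "taxon_node",
        "taxon_age_mya", "drosha_class",
    ]
    return low.loc[:, cols]


__all__ = [
    "DEFAULT_THRESHOLDS", "StratifiedSummary", "bin_labels", "classify_bins",
    "classify_threshold", "counts_to_cpm", "cpm_to_fraction", "cpm_to_percent",
    "cumulative_locus_counts", "locus_aggregate", "locus_annotation_table",
    "low_expression_list", "matrix_counts_to_cpm", "max_expression", "stratify",
]
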