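"""End-to-end orchestration: simulate -> audit -> reporters -> report.

Each run writes its outputs plus a reproducibility manifest (tool version,
config hash, input digests, seed, output inventory). Every output table
carries a ``# manifest: <hash>`` header comment; the manifest hash is a
digest of the run's configuration, inputs and seed, so two runs with
identical inputs produce identical table bytes (timestamps live only in
the manifest file itself, outside the hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation_seed import seed_family_expression
from . import expression_audit as ea
from . import io_formats as io
from . import reporter_assay as ra
from . import synthetic_data as syn

log = logging.getLogger("miraudit")


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _sha256_obj(obj: object) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    stage: str
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    rng_seed: int | None = None
    outputs: dict[str, str] = field(default_factory=dict)
    tool_version: str = __version__

    @property
    def hash(self) -> str:
        return _sha256_obj(
            {
                "tool_version": self.tool_version,
                "stage": self.stage,
                "config": self.config,
                "inputs": self.input_digests,
                "seed": self.rng_seed,
            }
        )

    def write(self, path: Path) -> None:
        payload = {
            "manifest_hash": self.hash,
            "tool_version": self.tool_version,
            "stage": self.stage,
            "config": self.config,
            "input_digests": self.input_digests,
            "rng_seed": self.rng_seed,
            "outputs": self.outputs,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)
            fh.write("\n")


def _write_tsv(df: pd.DataFrame, path: Path, manifest_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest: {manifest_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _inventory(manifest: RunManifest, out_dir: Path, names: Sequence[str]) -> None:
    for name in names:
        manifest.outputs[name] = _sha256_file(out_dir / name)
    manifest.write(out_dir / "manifest.json")


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulation(
    config: syn.SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Generate annotation, expression matrices, plates and ground truth.

    All randomness flows from ``config.rng_seed`` through a single
    generator, so identical seeds give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()

    annotations, truth = syn.generate_annotation(config, rng)
    log.info("simulate: %d loci -> %d matures", len(truth.loci), len(annotations))
    matrices = syn.generate_expression(annotations, truth, config, rng)
    # assay profile: first sample of the first dataset plays the cell line
    profile = matrices[0].values.iloc[:, [0]]
    plates, rep_truth = syn.generate_reporter_plates(
        annotations, profile.iloc[:, 0], config, rng=rng
    )
    truth.reporters = rep_truth
    profile_matrix = io.ExpressionMatrix(
        values=profile, unit="cpm", name="assay_cells",
        sample_meta=matrices[0].sample_meta.iloc[[0]],
    )

    manifest = RunManifest(
        stage="simulate", config=config.to_dict(), rng_seed=config.rng_seed
    )
    outputs: dict[str, Path] = {}
    io.write_annotation_table(annotations, out_dir / "annotation.tsv")
    outputs["annotation.tsv"] = out_dir / "annotation.tsv"
    for i, m in enumerate(matrices, start=1):
        name = f"expr_dataset{i}.tsv"
        io.write_expression_table(m, out_dir / name)
        outputs[name] = out_dir / name
    io.write_reporter_plate(plates, out_dir / "plates.csv")
    outputs["plates.csv"] = out_dir / "plates.csv"
    io.write_expression_table(profile_matrix, out_dir / "cell_profile.tsv")
    outputs["cell_profile.tsv"] = out_dir / "cell_profile.tsv"
    truth.to_json(out_dir / "truth.json")
    outputs["truth.json"] = out_dir / "truth.json"
    _inventory(manifest, out_dir, list(outputs))
    log.info("simulate: wrote %d files to %s", len(outputs), out_dir)
    return outputs


# ---------------------------------------------------------------------------
# audit
# ---------------------------------------------------------------------------

@dataclass
class AuditResult:
    """In-memory bundle of the full expression audit."""

    records: pd.DataFrame
    locus_records: pd.DataFrame
    unmapped: pd.DataFrame
    cumulative: pd.DataFrame
    strata_mirgenedb: ea.StratifiedSummary
    strata_taxon: ea.StratifiedSummary
    low_expression: pd.DataFrame
    summary: io.SampleSetSummary


def full_audit(
    matrices: Sequence[io.ExpressionMatrix],
    annotations: Sequence,
    thresholds: Sequence[float] = ea.DEFAULT_THRESHOLDS,
    multilocus: str = "all",
    low_threshold: float = 100.0,
) -> AuditResult:
    """Run every audit stage on in-memory inputs."""
    matrices = [ea.matrix_counts_to_cpm(m) for m in matrices]
    records = ea.max_expression(matrices, annotations, thresholds)
    log.info("audit: %d matures audited across %d matrices",
             len(records), len(matrices))
    locus, unmapped = ea.locus_aggregate(records, annotations, multilocus,
                                         thresholds)
    log.info("audit: %d loci, %d unmapped matures", len(locus), len(unmapped))
    return AuditResult(
        records=records,
        locus_records=locus,
        unmapped=unmapped,
        cumulative=ea.cumulative_locus_counts(locus, thresholds),
        strata_mirgenedb=ea.stratify(locus, annotations, "mirgenedb_member",
                                     thresholds),
        strata_taxon=ea.stratify(locus, annotations, "taxon_node", thresholds),
        low_expression=ea.low_expression_list(records, annotations,
                                              low_threshold),
        summary=io.summarize_sample_set(matrices),
    )


def run_full_audit(
    expression_paths: Sequence[str | Path],
    annotation_path: str | Path,
    out_dir: str | Path,
    thresholds: Sequence[float] = ea.DEFAULT_THRESHOLDS,
    multilocus: str = "all",
    low_threshold: float = 100.0,
    dialect: io.TableDialect | None = None,
) -> AuditResult:
    """File-to-file audit: read, audit, write the report bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotations = io.read_annotation_table(annotation_path)
    matrices = [io.read_expression_table(p, dialect) for p in expression_paths]
    result = full_audit(matrices, annotations, thresholds, multilocus,
                        low_threshold)

    manifest = RunManifest(
        stage="audit",
        config={
            "thresholds": list(thresholds), "multilocus": multilocus,
            "low_threshold": low_threshold,
        },
        # keyed by file name, not path, so relocating inputs does not
        # change the manifest hash (content digests still pin identity)
        input_digests={
            Path(p).name: _sha256_file(Path(p))
            for p in [*expression_paths, annotation_path]
        },
    )
    h = manifest.hash
    io.write_audit_report(result.records, out_dir / "report.tsv", "tsv", h)
    io.write_audit_report(result.records, out_dir / "report.json", "json", h)
    _write_tsv(result.locus_records, out_dir / "locus.tsv", h)
    _write_tsv(result.cumulative, out_dir / "cumulative.tsv", h)
    _write_tsv(result.strata_mirgenedb.table, out_dir / "strata_mirgenedb.tsv", h)
    _write_tsv(result.strata_taxon.table, out_dir / "strata_taxon.tsv", h)
    _write_tsv(result.low_expression, out_dir / "low_expression.tsv", h)
    _write_tsv(result.unmapped, out_dir / "unmapped.tsv", h)
    _inventory(
        manifest, out_dir,
        ["report.tsv", "report.json", "locus.tsv", "cumulative.tsv",
         "strata_mirgenedb.tsv", "strata_taxon.tsv", "low_expression.tsv",
         "unmapped.tsv"],
    )
    return result


# ---------------------------------------------------------------------------
# reporters
# ---------------------------------------------------------------------------

@dataclass
class ReporterResult:
    activities: ra.ReporterActivities
    band: ra.GroupControlBand
    calls: pd.DataFrame
    detection: ra.DetectionSummary


def reporter_analysis(
    plates: io.ReporterDataset,
    annotations: Sequence,
    profile: Mapping[str, float],
    cutoff: float = ra.GROUP_CONTROL_CUTOFF_CPM,
    pooling: str = "bio_means",
    welch: bool = False,
    bonferroni: bool = False,
    exclude_from_control: Sequence[str] = (),
) -> ReporterResult:
    """Full reporter pipeline on in-memory inputs.

    ``profile`` is the expression of the assayed cells (mature id -> cpm);
    Exact/Seed columns are attached from the annotation's seed families.
    """
    activities = ra.relative_activity(plates)
    target_cpm = {a.mature_id: float(profile.get(a.mature_id, 0.0))
                  for a in annotations}
    for t in activities.summary["target_mirna"]:
        if t != io.EMPTY_VECTOR and t not in target_cpm and t in profile:
            target_cpm[t] = float(profile[t])
    band = ra.build_group_control(
        activities, target_cpm, cutoff, pooling, exclude=exclude_from_control
    )
    ann_ids = {a.mature_id for a in annotations}
    seed_table = {}
    for row in activities.summary.itertuples(index=False):
        target = row.target_mirna
        if target == io.EMPTY_VECTOR:
            continue
        if target in ann_ids:
            exact, seed = seed_family_expression(target, annotations, profile)
        else:
            exact = float(profile.get(target, 0.0))
            seed = exact
        seed_table[row.reporter_id] = (exact, seed)
    calls = ra.call_repression(activities, band, seed_table, welch=welch,
                               bonferroni=bonferroni)
    log.info("reporters: %d calls from %d reporters (%d in group control)",
             len(calls), len(activities.summary), len(band.member_ids))
    return ReporterResult(
        activities=activities,
        band=band,
        calls=calls,
        detection=ra.detection_vs_expression(calls),
    )


def run_reporter_analysis(
    plates_path: str | Path,
    expression_path: str | Path,
    annotation_path: str | Path,
    out_dir: str | Path,
    cutoff: float = ra.GROUP_CONTROL_CUTOFF_CPM,
    pooling: str = "bio_means",
    welch: bool = False,
    dialect: io.TableDialect | None = None,
) -> ReporterResult:
    """File-to-file reporter analysis; writes calls, band and summary.

    The expression table provides the assay cells' profile; with several
    columns, the per-miRNA maximum over its columns is used.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plates = io.read_reporter_plate(plates_path)
    annotations = io.read_annotation_table(annotation_path)
    expr = io.read_expression_table(expression_path, dialect)
    profile = expr.values.max(axis=1)
    result = reporter_analysis(plates, annotations, profile, cutoff, pooling,
                               welch)

    manifest = RunManifest(
        stage="reporters",
        config={"cutoff": cutoff, "pooling": pooling, "welch": welch},
        input_digests={
            Path(p).name: _sha256_file(Path(p))
            for p in (plates_path, expression_path, annotation_path)
        },
    )
    h = manifest.hash
    _write_tsv(result.calls, out_dir / "calls.tsv", h)
    _write_tsv(result.detection.table, out_dir / "detection_summary.tsv", h)
    with open(out_dir / "band.json", "w") as fh:
        json.dump(
            {
                "manifest": h,
                "members": list(result.band.member_ids),
                "lower": result.band.lower,
                "upper": result.band.upper,
                "cutoff_cpm": result.band.cutoff_cpm,
                "pooling": result.band.pooling,
                "pooled_n": int(result.band.pooled.size),
                "min_detected_dose": (
                    None
                    if not np.isfinite(result.detection.min_detected_dose)
                    else result.detection.min_detected_dose
                ),
            },
            fh, indent=1,
        )
        fh.write("\n")
    _inventory(manifest, out_dir,
               ["calls.tsv", "detection_summary.tsv", "band.json"])
    return result


# ---------------------------------------------------------------------------
# repeated-screen experiments
# ---------------------------------------------------------------------------

def run_reporter_screen(
    doses: Sequence[float],
    config: syn.SimulationConfig,
    n_repetitions: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate and analyse a dose-spanning screen ``n_repetitions`` times.

    Each repetition draws fresh plates from the generator, runs the full
    reporter pipeline (normalisation, group control, t tests) and keeps the
    dose-reporter calls merged with their ground truth. Returns the
    concatenated calls with a ``repetition`` column; group-control
    reporters are excluded (they are the null, not calls).
    """
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    out = []
    for rep in range(n_repetitions):
        plates, truth, profile = syn.simulate_reporter_screen(
            doses, config, rng
        )
        activities = ra.relative_activity(plates)
        # dose reporters are the tested conditions, never the null — keep
        # them out of the group control even when their dose is < 20 cpm
        dose_reporters = [
            r.reporter_id for r in truth.itertuples(index=False)
            if r.target_mirna.startswith("dose-")
        ]
        band = ra.build_group_control(
            activities, profile, cutoff=20.0, exclude=dose_reporters
        )
        seed_table = {
            r.reporter_id: (r.exact_cpm, r.seed_cpm)
            for r in truth.itertuples(index=False)
        }
        calls = ra.call_repression(activities, band, seed_table)
        merged = calls.merge(
            truth.loc[:, ["reporter_id", "dose", "true_activity"]],
            on="reporter_id",
        )
        merged["repetition"] = rep
        out.append(merged)
    return pd.concat(out, ignore_index=True)


__all__ = [
    "AuditResult", "ReporterResult", "RunManifest", "full_audit",
    "reporter_analysis", "run_full_audit", "run_reporter_analysis",
    "run_reporter_screen", "run_simulation",
]
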