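"""Dual-luciferase reporter analysis.

The measured quantity per well is the Renilla/Firefly ratio (Firefly is an
internal transfection control expressed from the same vector). Within each
biological replicate, each reporter's technical-replicate mean ratio is
divided by the same replicate's empty-vector mean ratio, giving one
*relative luciferase activity* per (reporter, biological replicate); 1
means no repression. The unit of statistical analysis is the biological
replicate (technical replicates are averaged first).

Because reporters show intrinsic variability even without a cognate miRNA,
the null distribution is empirical: the *group control* pools the relative
activities of all reporters whose target miRNA is expressed below a cutoff
(20 cpm by default) in the assayed cells. Each remaining reporter is tested
against this pooled sample with an unpaired two-tailed Student's t test
(pooled variance; Welch optionally), significance is star-coded with
inclusive boundaries (p <= 0.05 -> *, <= 0.01 -> **, <= 0.001 -> ***,
<= 0.0001 -> ****), and repression is *detected* only when the test is
significant AND the mean activity lies below the lower bound of the group
control band — significant departures above the band are not repression.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import EMPTY_VECTOR, ReporterDataset

STAR_LEVELS = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)
STAR_ORDER = {"NS": 0, "*": 1, "**": 2, "***": 3, "****": 4}

GROUP_CONTROL_CUTOFF_CPM = 20.0


# ---------------------------------------------------------------------------
# relative activity
# ---------------------------------------------------------------------------

@dataclass
class ReporterActivities:
    """Relative luciferase activities at three granularities.

    per_well: one row per well with its control-normalised ratio.
    per_bio:  one relative activity per (reporter, biological replicate).
    summary:  per reporter mean, SEM (NaN when fewer than 2 biological
              replicates; downstream tests are then disabled) and n_bio.
    """

    per_well: pd.DataFrame
    per_bio: pd.DataFrame
    summary: pd.DataFrame

    def bio_activities(self, reporter_id: str) -> np.ndarray:
        sel = self.per_bio["reporter_id"] == reporter_id
        return self.per_bio.loc[sel, "activity"].to_numpy(dtype=float)

    def target_of(self, reporter_id: str) -> str:
        sel = self.summary["reporter_id"] == reporter_id
        if not sel.any():
            raise ValidationError(f"unknown reporter {reporter_id!r}")
        return str(self.summary.loc[sel, "target_mirna"].iloc[0])


def relative_activity(dataset: ReporterDataset) -> ReporterActivities:
    """Normalise plate readings to empty-vector relative activities.

    Every biological replicate must contain empty-vector wells (its
    normaliser); a replicate without them is a hard error. The empty vector
    itself is carried through with relative activity exactly 1 in every
    biological replicate, by construction.
    """
    df = dataset.measurements.copy()
    df["ratio"] = df["renilla"] / df["firefly"]

    tech_mean = (
        df.groupby(["reporter_id", "target_mirna", "bio_rep"], sort=True)["ratio"]
        .mean()
        .reset_index()
    )
    is_ev = tech_mean["target_mirna"] == EMPTY_VECTOR
    control = tech_mean[is_ev].set_index("bio_rep")["ratio"]
    bio_reps = sorted(df["bio_rep"].unique())
    missing = [int(b) for b in bio_reps if b not in control.index]
    if missing:
        raise ValidationError(
            f"biological replicate(s) {missing} lack {EMPTY_VECTOR} control wells"
        )

    tech_mean["activity"] = (
        tech_mean["ratio"] / control.loc[tech_mean["bio_rep"]].to_numpy()
    )
    per_bio = tech_mean.loc[:, ["reporter_id", "target_mirna", "bio_rep",
                                "activity"]]

    well = df.copy()
    well["rel_ratio"] = well["ratio"] / control.loc[well["bio_rep"]].to_numpy()
    per_well = well.loc[:, ["reporter_id", "target_mirna", "bio_rep",
                            "tech_rep", "rel_ratio"]]

    grp = per_bio.groupby(["reporter_id", "target_mirna"], sort=True)["activity"]
    summary = grp.agg(["mean", "count"]).reset_index()
    sd = grp.std(ddof=1).reset_index(drop=True)
    summary = summary.rename(columns={"mean": "mean_activity", "count": "n_bio"})
    with np.errstate(invalid="ignore"):
        summary["sem"] = sd.to_numpy() / np.sqrt(summary["n_bio"].to_numpy())
    summary.loc[summary["n_bio"] < 2, "sem"] = np.nan
    return ReporterActivities(per_well=per_well, per_bio=per_bio, summary=summary)


# ---------------------------------------------------------------------------
# group control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupControlBand:
    """The pooled null for reporters of sub-threshold miRNAs.

    ``lower``/``upper`` bound the band spanned by member reporter *means*
    (reporter-level activities, not raw wells, so one noisy well does not
    widen the band artifactually); ``pooled`` is the null sample used in
    the t tests.
    """

    member_ids: tuple[str, ...]
    pooled: np.ndarray
    lower: float
    upper: float
    cutoff_cpm: float
    pooling: str


def build_group_control(
    activities: ReporterActivities,
    target_cpm: Mapping[str, float],
    cutoff: float = GROUP_CONTROL_CUTOFF_CPM,
    pooling: str = "bio_means",
    exclude: Sequence[str] = (),
) -> GroupControlBand:
    """Pool reporters whose target is expressed below ``cutoff`` cpm.

    ``target_cpm`` maps mature miRNA ids to their expression in the assayed
    cells (a single-sample profile or a per-miRNA maximum vector); targets
    absent from it are treated as 0 cpm with a warning. ``pooling`` selects
    the null sample: ``'bio_means'`` pools one activity per member and
    biological replicate (default), ``'wells'`` pools every
    control-normalised well.
    """
    if pooling not in ("bio_means", "wells"):
        raise ValidationError(f"unknown pooling mode {pooling!r}")
    summary = activities.summary
    members = []
    for row in summary.itertuples(index=False):
        if row.target_mirna == EMPTY_VECTOR or row.reporter_id in exclude:
            continue
        if row.target_mirna in target_cpm:
            cpm = float(target_cpm[row.target_mirna])
        else:
            warnings.warn(
                f"target {row.target_mirna!r} absent from expression profile; "
                "treated as 0 cpm",
                stacklevel=2,
            )
            cpm = 0.0
        if cpm < cutoff:
            members.append(row.reporter_id)
    if len(members) < 2:
        raise ValidationError(
            f"group control not constructible: {len(members)} reporter(s) with "
            f"target < {cutoff:g} cpm (need >= 2)"
        )
    source = activities.per_bio if pooling == "bio_means" else activities.per_well
    col = "activity" if pooling == "bio_means" else "rel_ratio"
    pooled = source.loc[
        source["reporter_id"].isin(members), col
    ].to_numpy(dtype=float)
    means = summary.loc[
        summary["reporter_id"].isin(members), "mean_activity"
    ].to_numpy(dtype=float)
    return GroupControlBand(
        member_ids=tuple(members),
        pooled=pooled,
        lower=float(means.min()),
        upper=float(means.max()),
        cutoff_cpm=float(cutoff),
        pooling=pooling,
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def students_t_unpaired(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    welch: bool = False,
) -> tuple[float, float, float]:
    """Unpaired two-tailed Student's t test; returns (t, df, p).

    Pooled-variance by default (df = n_a + n_b - 2); ``welch=True`` uses
    the Welch unequal-variance form. Degenerate zero-variance inputs are
    resolved by the limit: equal means -> p = 1, unequal means -> p = 0
    (with a warning), rather than NaN.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("samples must be finite")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        warnings.warn(
            "zero pooled variance with unequal means; p set to 0", stacklevel=2
        )
        return float(np.inf * np.sign(a.mean() - b.mean())), float(
            a.size + b.size - 2
        ), 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def star_code(p: float) -> str:
    """GraphPad-style significance stars with inclusive boundaries."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p-value must lie in [0, 1], got {p}")
    for cut, stars in STAR_LEVELS:
        if p <= cut:
            return stars
    return "NS"


# ---------------------------------------------------------------------------
# repression calls
# ---------------------------------------------------------------------------

CALL_COLUMNS = (
    "reporter_id", "target_mirna", "exact_cpm", "seed_cpm", "n_bio",
    "mean_activity", "sem", "t", "p_value", "stars", "detected",
)


def call_repression(
    activities: ReporterActivities,
    band: GroupControlBand,
    seed_table: Mapping[str, tuple[float, float]] | None = None,
    alpha: float = 0.05,
    welch: bool = False,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Test every non-control reporter against the group control.

    ``seed_table`` maps reporter ids to their (exact_cpm, seed_cpm) columns
    (target-only and seed-family-summed expression); missing entries become
    NaN. ``detected`` requires p <= alpha AND mean activity below the
    band's lower bound. ``bonferroni=True`` multiplies p-values by the
    number of tested reporters first (off by default). Reporters with fewer
    than 2 biological replicates are reported with tests disabled
    (p = NaN, stars = 'NS', detected = False).
    """
    summary = activities.summary
    skip = set(band.member_ids)
    rows = []
    testable = [
        r for r in summary.itertuples(index=False)
        if r.target_mirna != EMPTY_VECTOR and r.reporter_id not in skip
    ]
    n_tests = sum(1 for r in testable if r.n_bio >= 2)
    for row in testable:
        exact, seed = (np.nan, np.nan)
        if seed_table is not None and row.reporter_id in seed_table:
            exact, seed = seed_table[row.reporter_id]
        if row.n_bio < 2:
            t = p = np.nan
            stars_, det = "NS", False
        else:
            sample = activities.bio_activities(row.reporter_id)
            t, _, p = students_t_unpaired(sample, band.pooled, welch=welch)
            if bonferroni and n_tests:
                p = min(1.0, p * n_tests)
            stars_ = star_code(p)
            det = bool(p <= alpha and row.mean_activity < band.lower)
        rows.append(
            {
                "reporter_id": row.reporter_id,
                "target_mirna": row.target_mirna,
                "exact_cpm": exact,
                "seed_cpm": seed,
                "n_bio": int(row.n_bio),
                "mean_activity": float(row.mean_activity),
                "sem": float(row.sem) if np.isfinite(row.sem) else np.nan,
                "t": t,
                "p_value": p,
                "stars": stars_,
                "detected": det,
            }
        )
    return pd.DataFrame(rows, columns=list(CALL_COLUMNS))


@dataclass
class DetectionSummary:
    """Detection rate per effective-dose band, plus the minimum detected dose.

    ``table`` has one row per band with n, n_detected and detection_rate;
    ``min_detected_dose`` is the smallest dose among detected reporters
    (NaN when nothing was detected).
    """

    table: pd.DataFrame
    min_detected_dose: float
    dose_column: str


def detection_vs_expression(
    calls: pd.DataFrame,
    band_edges: Sequence[float] = (200.0, 1000.0),
    dose_column: str = "seed_cpm",
) -> DetectionSummary:
    """Summarise detection as a function of effective miRNA dose.

    The dose axis defaults to the seed-family-summed cpm, because family
    members sharing the seed also repress the reporter (the miR-99a/miR-99b
    situation). Bands for the default edges are ``<200``, ``[200,1000]``
    and ``>1000``.
    """
    edges = [float(e) for e in band_edges]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("band edges must be strictly increasing")
    labels = [f"<{edges[0]:g}"]
    labels += [f"[{a:g},{b:g}]" for a, b in zip(edges, edges[1:])]
    labels.append(f">{edges[-1]:g}")
    if calls.empty:
        return DetectionSummary(
            table=pd.DataFrame(
                columns=["band", "n", "n_detected", "detection_rate"]
            ),
            min_detected_dose=float("nan"),
            dose_column=dose_column,
        )
    dose = calls[dose_column].to_numpy(dtype=float)
    detected = calls["detected"].to_numpy(dtype=bool)
    # outer bands are open (< lower edge, > upper edge); interior bands
    # close both ends, so a dose exactly on an edge sits in the interior.
    rows = []
    for i, lab in enumerate(labels):
        if i == 0:
            sel = dose < edges[0]
        elif i == len(labels) - 1:
            sel = dose > edges[-1]
        else:
            sel = (dose >= edges[i - 1]) & (dose <= edges[i])
        n = int(sel.sum())
        nd = int((sel & detected).sum())
        rows.append(
            {
                "band": lab,
                "n": n,
                "n_detected": nd,
                "detection_rate": (nd / n) if n else np.nan,
            }
        )
    min_dose = float(dose[detected].min()) if detected.any() else float("nan")
    return DetectionSummary(
        table=pd.DataFrame(rows), min_detected_dose=min_dose,
        dose_column=dose_column,
    )


__all__ = [
    "CALL_COLUMNS", "DetectionSummary", "GroupControlBand",
    "GROUP_CONTROL_CUTOFF_CPM", "ReporterActivities", "build_group_control",
    "call_repression", "detection_vs_expression", "relative_activity",
    "star_code", "students_t_unpaired",
]
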