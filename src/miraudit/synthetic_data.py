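"""Synthetic annotation, expression and reporter-plate generator.

The generator emits data with the statistical structure the audit assumes,
together with exported ground truth, so every stage of the pipeline runs
and can be checked for parameter recovery without any download.

Expression model
----------------
Each locus draws a taxonomic node, a curation (miRGeneDB-like membership)
flag whose probability depends on the node (older lineages are more often
curated), and a latent low/high expression label whose probability depends
on the joint (membership, node) stratum. Mature basal abundances are
log10-normal within the low or high component; the basal vector is scaled
to sum to 1e6 so cpm compositionality holds, then per-(miRNA, sample)
multiplicative log-normal noise is applied and every column renormalised
to exactly 1e6 — one miRNA's rise depresses the others, as in real cpm.

Repression model
----------------
The dose–response of a perfectly complementary reporter is a Hill curve
with a floor: a(E) = floor + (1 - floor) / (1 + (E/K)^h), where the
effective dose E = exact_cpm + w * (seed_cpm - exact_cpm) blends the
target's own expression with its seed family's. Defaults (K = 2000 cpm,
h = 1.3, floor = 0.02, w = 0.05) put the simulated detection threshold
between 200 and 1000 cpm. Well readings are log-normal around a plate
mean for Firefly, with Renilla = Firefly x a(E) x control ratio x noise,
so the Firefly component cancels exactly in the per-well ratio.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .annotation_seed import MirnaAnnotation, seed_family_expression
from .errors import ValidationError
from .io_formats import CPM_TOTAL, EMPTY_VECTOR, ExpressionMatrix, \
    ReporterDataset

_NTS = np.array(list("ACGU"))

DEFAULT_TAXON_NODES = (
    "Bilateria", "Vertebrata", "Mammalia", "Primates", "Homo sapiens",
)
DEFAULT_TAXON_AGES = (650.0, 530.0, 180.0, 75.0, 0.0)
DEFAULT_TAXON_PROBS = (0.15, 0.20, 0.25, 0.20, 0.20)
# probability a locus at each node is miRGeneDB-curated: ancient loci are
# almost always curated, recent ones rarely
DEFAULT_MEMBER_PROB_BY_NODE = (0.80, 0.60, 0.30, 0.15, 0.08)
# probability a locus is in the "low" expression component, by the joint
# (curated, node) stratum: curated ancient loci are essentially never low,
# 20% of curated human-specific loci are; uncurated loci are mostly low
DEFAULT_LOW_PROB_MEMBER = (0.00, 0.02, 0.08, 0.12, 0.20)
DEFAULT_LOW_PROB_NONMEMBER = (0.30, 0.45, 0.60, 0.70, 0.85)

DEFAULT_DATASET_NAMES = (
    "sim_microRNAome", "sim_miTED_cells", "sim_miTED_tissues",
)


@dataclass
class SimulationConfig:
    """All knobs of the generator, with defaults encoding the study design.

    Expression: 1,744 loci (the annotated human complement), ~1.6 matures
    per locus, three datasets mimicking the public resources. Reporter
    plates: 4 technical x 3 biological replicates per condition. The
    log10-cpm component means/sds and the per-sample noise are set so the
    low and high components are well separated around the 100 cpm line
    after compositional renormalisation.
    """

    rng_seed: int = 0
    # annotation
    n_loci: int = 1744
    two_arm_fraction: float = 0.62
    taxon_nodes: tuple[str, ...] = DEFAULT_TAXON_NODES
    taxon_ages_mya: tuple[float, ...] = DEFAULT_TAXON_AGES
    taxon_node_probabilities: tuple[float, ...] = DEFAULT_TAXON_PROBS
    member_prob_by_node: tuple[float, ...] = DEFAULT_MEMBER_PROB_BY_NODE
    low_prob_member: tuple[float, ...] = DEFAULT_LOW_PROB_MEMBER
    low_prob_nonmember: tuple[float, ...] = DEFAULT_LOW_PROB_NONMEMBER
    mirgenedb_fraction: float | None = None  # scalar override of the node map
    seed_pool_size: int = 400
    # expression
    mu_log10_low: float = 1.0
    sigma_log10_low: float = 0.45
    mu_log10_high: float = 3.0
    sigma_log10_high: float = 0.45
    n_datasets: int = 3
    samples_per_dataset: int = 40
    sample_noise_sd_log: float = 0.35  # natural-log sd of per-cell noise
    dataset_names: tuple[str, ...] = DEFAULT_DATASET_NAMES
    # repression / plates
    K: float = 2000.0
    h: float = 1.3
    w: float = 0.05
    floor: float = 0.02
    n_bio: int = 3
    n_tech: int = 4
    measurement_cv: float = 0.15   # ln-sd of the per-well ratio noise
    bio_cv: float = 0.08           # ln-sd of the per-(reporter, bio) factor
    firefly_mean: float = 10000.0
    firefly_cv: float = 0.10
    control_ratio: float = 2.0
    repression_off: bool = False   # force true activity 1 everywhere
    mimic_repression: float = 0.1  # forced activity for exogenous mimics

    def __post_init__(self) -> None:
        k = len(self.taxon_nodes)
        for name in ("taxon_ages_mya", "taxon_node_probabilities",
                     "member_prob_by_node", "low_prob_member",
                     "low_prob_nonmember"):
            if len(getattr(self, name)) != k:
                raise ValidationError(f"{name} must have {k} entries")
        probs = np.asarray(self.taxon_node_probabilities, dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValidationError("taxon_node_probabilities must sum to 1")
        if not (0.0 <= self.two_arm_fraction <= 1.0):
            raise ValidationError("two_arm_fraction must lie in [0, 1]")
        if self.K <= 0 or self.h <= 0:
            raise ValidationError("K and h must be positive")
        if not (0.0 <= self.floor < 1.0):
            raise ValidationError("floor must lie in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests.

    ``loci``: locus_id, taxon_node, taxon_age_mya, mirgenedb_member, low,
    n_arms. ``matures``: mature_id, locus_id, arm, low, basal_cpm (filled
    by ``generate_expression``). ``reporters``: per-reporter target, dose
    and true activity (filled by the plate generators).
    """

    loci: pd.DataFrame
    matures: pd.DataFrame
    reporters: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "loci": self.loci.to_dict(orient="list"),
            "matures": self.matures.to_dict(orient="list"),
            "reporters": (
                None if self.reporters is None
                else self.reporters.to_dict(orient="list")
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            loci=pd.DataFrame(payload["loci"]),
            matures=pd.DataFrame(payload["matures"]),
            reporters=(
                None if payload.get("reporters") is None
                else pd.DataFrame(payload["reporters"])
            ),
        )


def hill_activity(dose: float | np.ndarray, K: float, h: float,
                  floor: float) -> float | np.ndarray:
    """Hill-type relative activity with a floor; a(0) = 1, a(K) = (1+floor)/2."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        act = floor + (1.0 - floor) / (1.0 + (dose / K) ** h)
    return float(act) if act.ndim == 0 else act


def expected_low_fraction_by_node(config: SimulationConfig) -> dict[str, float]:
    """The marginal P(low | node) implied by the config's joint strata."""
    out = {}
    for i, node in enumerate(config.taxon_nodes):
        pm = (
            config.mirgenedb_fraction
            if config.mirgenedb_fraction is not None
            else config.member_prob_by_node[i]
        )
        out[node] = (
            pm * config.low_prob_member[i]
            + (1 - pm) * config.low_prob_nonmember[i]
        )
    return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _random_seed_pool(rng: np.random.Generator, size: int) -> list[str]:
    if not (1 <= size <= 4096):
        raise ValidationError("seed_pool_size must be in 1..4096")
    codes = rng.choice(4096, size=size, replace=False)
    pool = []
    for code in codes:
        s, chars = int(code), []
        for _ in range(6):
            chars.append("ACGU"[s % 4])
            s //= 4
        pool.append("".join(chars))
    return pool


def _random_sequence(rng: np.random.Generator, seed6: str, length: int = 22) -> str:
    head = _NTS[rng.integers(0, 4)]
    tail = "".join(_NTS[rng.integers(0, 4, size=length - 7)])
    return head + seed6 + tail


def generate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[MirnaAnnotation], GroundTruth]:
    """Draw loci, strata, arms and sequences; return annotations + truth.

    Seeds (nt 2–7) are drawn from a finite pool so seed families of size
    > 1 exist; sequences are otherwise uniform over {A,C,G,U} with no
    attempt at realistic composition.
    """
    rng = rng if rng is not None else config.rng()
    n = config.n_loci
    node_idx = rng.choice(len(config.taxon_nodes), size=n,
                          p=np.asarray(config.taxon_node_probabilities))
    if config.mirgenedb_fraction is not None:
        member = rng.random(n) < config.mirgenedb_fraction
    else:
        pm = np.asarray(config.member_prob_by_node)[node_idx]
        member = rng.random(n) < pm
    p_low = np.where(
        member,
        np.asarray(config.low_prob_member)[node_idx],
        np.asarray(config.low_prob_nonmember)[node_idx],
    )
    low = rng.random(n) < p_low
    two_arm = rng.random(n) < config.two_arm_fraction
    # DROSHA processing class correlates with the low label (pass-through
    # annotation in real data; simulated here only so the resource list has
    # realistic structure)
    p_poor = np.where(low, 0.6, 0.15)
    drosha = np.where(rng.random(n) < p_poor, "poor", "good")
    drosha = np.where(rng.random(n) < 0.1, "unknown", drosha)

    pool = _random_seed_pool(rng, config.seed_pool_size)
    annotations: list[MirnaAnnotation] = []
    mature_rows = []
    loci_rows = []
    for i in range(n):
        locus = f"syn-mir-{i + 1:04d}"
        node = config.taxon_nodes[node_idx[i]]
        age = config.taxon_ages_mya[node_idx[i]]
        arms = ("5p", "3p") if two_arm[i] else (("5p",) if rng.random() < 0.5
                                                else ("3p",))
        loci_rows.append(
            {
                "locus_id": locus, "taxon_node": node, "taxon_age_mya": age,
                "mirgenedb_member": bool(member[i]), "low": bool(low[i]),
                "n_arms": len(arms), "drosha_class": str(drosha[i]),
            }
        )
        for arm in arms:
            seed6 = pool[rng.integers(0, len(pool))]
            mature = f"syn-miR-{i + 1:04d}-{arm}"
            annotations.append(
                MirnaAnnotation(
                    mature_id=mature,
                    locus_id=locus,
                    arm=arm,
                    sequence=_random_sequence(rng, seed6),
                    mirgenedb_member=bool(member[i]),
                    taxon_node=node,
                    taxon_age_mya=age,
                    drosha_class=str(drosha[i]),
                )
            )
            mature_rows.append(
                {
                    "mature_id": mature, "locus_id": locus, "arm": arm,
                    "low": bool(low[i]), "basal_cpm": np.nan,
                }
            )
    truth = GroundTruth(
        loci=pd.DataFrame(loci_rows), matures=pd.DataFrame(mature_rows)
    )
    return annotations, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    annotations: Sequence[MirnaAnnotation],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[ExpressionMatrix]:
    """Multi-dataset cpm matrices from the bimodal basal model.

    Fills ``truth.matures['basal_cpm']`` (the scaled basal vector, summing
    to 1e6) in place and returns one validated ``ExpressionMatrix`` per
    dataset, every column summing to exactly 1e6.
    """
    rng = rng if rng is not None else config.rng()
    matures = truth.matures
    n_mat = len(matures)
    low = matures["low"].to_numpy(dtype=bool)
    mu = np.where(low, config.mu_log10_low, config.mu_log10_high)
    sigma = np.where(low, config.sigma_log10_low, config.sigma_log10_high)
    basal = 10.0 ** rng.normal(mu, sigma)
    basal *= CPM_TOTAL / basal.sum()
    truth.matures["basal_cpm"] = basal

    names = list(config.dataset_names)
    while len(names) < config.n_datasets:
        names.append(f"sim_ds{len(names) + 1}")
    matrices = []
    ids = matures["mature_id"].to_numpy()
    for d in range(config.n_datasets):
        name = names[d]
        n_s = config.samples_per_dataset
        noise = np.exp(
            rng.normal(0.0, config.sample_noise_sd_log, size=(n_mat, n_s))
        )
        vals = basal[:, None] * noise
        vals *= CPM_TOTAL / vals.sum(axis=0, keepdims=True)
        cols = [f"{name}_s{j + 1:03d}" for j in range(n_s)]
        sample_class = "cell_line" if "cell" in name else "tissue"
        meta = pd.DataFrame(
            {
                "dataset": name,
                "tissue_or_cell": [f"context_{j % 8 + 1}" for j in range(n_s)],
                "sample_class": sample_class,
            },
            index=pd.Index(cols),
        )
        matrices.append(
            ExpressionMatrix(
                values=pd.DataFrame(vals, index=ids, columns=cols),
                unit="cpm",
                sample_meta=meta,
                name=name,
            )
        )
    return matrices


# ---------------------------------------------------------------------------
# reporter plates
# ---------------------------------------------------------------------------

def _plate_rows(
    rng: np.random.Generator,
    config: SimulationConfig,
    reporters: Sequence[tuple[str, str, float]],  # (reporter_id, target, activity)
) -> pd.DataFrame:
    rows = []
    for bio in range(1, config.n_bio + 1):
        for rep_id, target, act in [
            ("EMPTY_VECTOR_rep", EMPTY_VECTOR, 1.0), *reporters
        ]:
            bio_factor = float(np.exp(rng.normal(0.0, config.bio_cv)))
            for tech in range(1, config.n_tech + 1):
                firefly = config.firefly_mean * float(
                    np.exp(rng.normal(0.0, config.firefly_cv))
                )
                renilla = (
                    firefly * act * config.control_ratio * bio_factor
                    * float(np.exp(rng.normal(0.0, config.measurement_cv)))
                )
                rows.append(
                    {
                        "reporter_id": rep_id, "target_mirna": target,
                        "bio_rep": bio, "tech_rep": tech,
                        "firefly": firefly, "renilla": renilla,
                    }
                )
    return pd.DataFrame(rows)


def generate_reporter_plates(
    annotations: Sequence[MirnaAnnotation],
    profile: Mapping[str, float],
    config: SimulationConfig,
    targets: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ReporterDataset, pd.DataFrame]:
    """Simulate a dual-luciferase screen against targets of one cell profile.

    ``profile`` maps mature ids to cpm in the simulated assay cells. When
    ``targets`` is not given, reporters are designed against a spread of
    expression levels plus at least four sub-20-cpm targets so a group
    control is always constructible. Returns the plate dataset and a
    per-reporter truth table (dose, true activity).
    """
    rng = rng if rng is not None else config.rng()
    prof = pd.Series(dict(profile), dtype=float)
    ann_ids = [a.mature_id for a in annotations]
    if targets is None:
        in_prof = [m for m in ann_ids if m in prof.index]
        ordered = sorted(in_prof, key=lambda m: prof[m])
        lows = [m for m in ordered if prof[m] < 20.0][:4]
        if len(lows) < 2:
            raise ValidationError(
                "profile has fewer than 2 sub-20-cpm annotated targets; "
                "cannot place a group control"
            )
        qs = np.linspace(0.05, 0.995, 12)
        spread = [ordered[int(q * (len(ordered) - 1))] for q in qs]
        targets = list(dict.fromkeys(lows + spread))

    truth_rows = []
    reporters = []
    for target in targets:
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            exact, seed = seed_family_expression(target, annotations, prof)
        dose = exact + config.w * (seed - exact)
        act = 1.0 if config.repression_off else float(
            hill_activity(dose, config.K, config.h, config.floor)
        )
        rep_id = f"rep-{target}"
        reporters.append((rep_id, target, act))
        truth_rows.append(
            {
                "reporter_id": rep_id, "target_mirna": target,
                "exact_cpm": exact, "seed_cpm": seed, "dose": dose,
                "true_activity": act, "mimic": False,
            }
        )
    plate = _plate_rows(rng, config, reporters)
    return ReporterDataset(measurements=plate), pd.DataFrame(truth_rows)


def scenario_artificial_mimic(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    mimic_on: bool = True,
) -> tuple[ReporterDataset, pd.DataFrame]:
    """Reporters against non-genomic sequences co-transfected with mimics.

    Four reporters target 21-nt sequences absent from the genome (zero
    endogenous dose). With the mimic on, their true activity is forced to
    ``config.mimic_repression`` — demonstrating that over-expression
    repression carries no information about endogenous function. Four
    sub-threshold endogenous-style reporters are included so the group
    control is constructible downstream.
    """
    rng = rng if rng is not None else config.rng()
    reporters = []
    truth_rows = []
    for i in range(1, 5):
        target = f"NG{i}"
        act = config.mimic_repression if mimic_on else 1.0
        rep = f"rep-{target}"
        reporters.append((rep, target, float(act)))
        truth_rows.append(
            {
                "reporter_id": rep, "target_mirna": target,
                "exact_cpm": 0.0, "seed_cpm": 0.0, "dose": 0.0,
                "true_activity": float(act), "mimic": mimic_on,
            }
        )
    for i in range(1, 5):
        target = f"lowctrl-miR-{i}"
        rep = f"rep-{target}"
        reporters.append((rep, target, 1.0))
        truth_rows.append(
            {
                "reporter_id": rep, "target_mirna": target,
                "exact_cpm": 5.0, "seed_cpm": 5.0, "dose": 5.0,
                "true_activity": 1.0, "mimic": False,
            }
        )
    plate = _plate_rows(rng, config, reporters)
    return ReporterDataset(measurements=plate), pd.DataFrame(truth_rows)


def simulate_reporter_screen(
    doses: Sequence[float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ReporterDataset, pd.DataFrame, pd.Series]:
    """A minimal screen with one reporter per requested effective dose.

    Builds pseudo-targets expressed at exactly the requested cpm (each in
    its own seed family, so dose == exact == seed cpm), four sub-20-cpm
    group-control targets, and empty-vector wells. Returns the plates, the
    reporter truth table and the cell-profile series used downstream.
    """
    rng = rng if rng is not None else config.rng()
    reporters = []
    truth_rows = []
    profile = {}
    for i, dose in enumerate(doses, start=1):
        target = f"dose-miR-{i}"
        profile[target] = float(dose)
        act = 1.0 if config.repression_off else float(
            hill_activity(dose, config.K, config.h, config.floor)
        )
        rep = f"rep-{target}"
        reporters.append((rep, target, act))
        truth_rows.append(
            {
                "reporter_id": rep, "target_mirna": target,
                "exact_cpm": float(dose), "seed_cpm": float(dose),
                "dose": float(dose), "true_activity": act, "mimic": False,
            }
        )
    for i in range(1, 5):
        target = f"lowctrl-miR-{i}"
        cpm = float(rng.uniform(2.0, 15.0))
        profile[target] = cpm
        rep = f"rep-{target}"
        reporters.append((rep, target, 1.0))
        truth_rows.append(
            {
                "reporter_id": rep, "target_mirna": target,
                "exact_cpm": cpm, "seed_cpm": cpm, "dose": cpm,
                "true_activity": 1.0, "mimic": False,
            }
        )
    plate = _plate_rows(rng, config, reporters)
    return (
        ReporterDataset(measurements=plate),
        pd.DataFrame(truth_rows),
        pd.Series(profile, dtype=float),
    )


__all__ = [
    "GroundTruth", "SimulationConfig", "expected_low_fraction_by_node",
    "generate_annotation", "generate_expression", "generate_reporter_plates",
    "hill_activity", "scenario_artificial_mimic", "simulate_reporter_screen",
]
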