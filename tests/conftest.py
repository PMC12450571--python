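import numpy as np
import pandas as pd
import pytest

from miraudit.annotation_seed import MirnaAnnotation
from miraudit.io_formats import ExpressionMatrix, ReporterDataset
from miraudit.synthetic_data import SimulationConfig


def _seq(seed6: str, tail: str = "AAGUUUGCAGGUUUG") -> str:
    # 22-nt mature with a chosen nt 2-7 seed
    return "U" + seed6 + tail


@pytest.fixture
def annotations() -> list[MirnaAnnotation]:
    """Four loci, five matures, two sharing a seed family."""
    return [
        MirnaAnnotation("miR-A-5p", "mir-A", "5p", _seq("AGCAUA"),
                        mirgenedb_member=True, taxon_node="Bilateria",
                        taxon_age_mya=650.0, drosha_class="good"),
        MirnaAnnotation("miR-A-3p", "mir-A", "3p", _seq("CCGUAA"),
                        mirgenedb_member=True, taxon_node="Bilateria",
                        taxon_age_mya=650.0),
        MirnaAnnotation("miR-B-5p", "mir-B", "5p", _seq("AGCAUA"),
                        mirgenedb_member=False, taxon_node="Homo sapiens",
                        taxon_age_mya=0.0, drosha_class="poor"),
        MirnaAnnotation("miR-C-3p", "mir-C", "3p", _seq("GGGUUU"),
                        mirgenedb_member=False),
        MirnaAnnotation("miR-D-5p", "mir-D", "5p", _seq("UUUAAA"),
                        mirgenedb_member=True, taxon_node="Primates",
                        taxon_age_mya=75.0),
    ]


def make_cpm_matrix(values: dict[str, list[float]], mature_ids: list[str],
                    name: str = "ds", **kwargs) -> ExpressionMatrix:
    """Columns are scaled so each sums to 1e6 unless prefiltered."""
    df = pd.DataFrame(values, index=mature_ids, dtype=float)
    if not kwargs.get("prefiltered", False):
        df = df * (1e6 / df.sum(axis=0))
    return ExpressionMatrix(values=df, unit="cpm", name=name, **kwargs)


@pytest.fixture
def cpm_matrix(annotations) -> ExpressionMatrix:
    ids = [a.mature_id for a in annotations]
    # after per-column cpm scaling, miR-A-5p peaks in the (10,100] bin and
    # miR-C-3p stays <=10 while the others are high
    return make_cpm_matrix(
        {"s1": [0.5, 400, 9000, 0.05, 120], "s2": [0.8, 90, 20000, 0.02, 1500]},
        ids, name="dsA",
    )


def make_plate(activities: dict[str, tuple[str, float]], n_bio: int = 3,
               n_tech: int = 4, control_ratio: float = 2.0,
               rng: np.random.Generator | None = None,
               noise: float = 0.0) -> ReporterDataset:
    """Deterministic plate: renilla/firefly = control_ratio * activity."""
    rng = rng or np.random.default_rng(0)
    rows = []
    entries = [("EMPTY_VECTOR_rep", ("EMPTY_VECTOR", 1.0)), *activities.items()]
    for rep_id, (target, act) in entries:
        for bio in range(1, n_bio + 1):
            for tech in range(1, n_tech + 1):
                firefly = 10000.0 * (1 + 0.01 * bio)
                factor = float(np.exp(rng.normal(0, noise))) if noise else 1.0
                rows.append(
                    {"reporter_id": rep_id, "target_mirna": target,
                     "bio_rep": bio, "tech_rep": tech, "firefly": firefly,
                     "renilla": firefly * control_ratio * act * factor}
                )
    return ReporterDataset(measurements=pd.DataFrame(rows))


@pytest.fixture
def tiny_sim_config() -> SimulationConfig:
    return SimulationConfig(rng_seed=11, n_loci=60, n_datasets=2,
                            samples_per_dataset=6, seed_pool_size=30)
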