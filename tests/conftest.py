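"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ripenet.core_model import (
    AbundanceTable,
    DesignMap,
    FeatureDescriptor,
    SampleDescriptor,
)
from ripenet.synthetic_data import PlantedModule, SimulationConfig
from ripenet.core_model import PathwayMap


def make_features(n: int, kind: str = "metabolite", prefix: str = "F") -> list[FeatureDescriptor]:
    return [FeatureDescriptor(f"{prefix}{i}", f"feature {i}", kind, "CAR") for i in range(n)]


def make_samples(
    genotypes: dict[str, str],
    stages: tuple[str, ...] = ("MG",),
    reps: int = 3,
) -> list[SampleDescriptor]:
    """genotypes maps genotype -> background."""
    out = []
    for g, bg in genotypes.items():
        for st in stages:
            for r in range(1, reps + 1):
                out.append(SampleDescriptor(f"{g}_{st}_{r}", g, bg, st, r))
    return out


def make_table(
    values: np.ndarray,
    features: list[FeatureDescriptor] | None = None,
    samples: list[SampleDescriptor] | None = None,
    detected: np.ndarray | None = None,
) -> AbundanceTable:
    values = np.asarray(values, dtype=float)
    n_f, n_s = values.shape
    if features is None:
        features = make_features(n_f)
    if samples is None:
        samples = [
            SampleDescriptor(f"S{j}", "AC", "AC", "MG", j + 1) for j in range(n_s)
        ]
    if detected is None:
        detected = np.ones_like(values, dtype=bool)
    return AbundanceTable(features, samples, values, detected)


def two_group_table(
    mutant_values: dict[str, list[float]],
    wildtype_values: dict[str, list[float]],
    stage: str = "MG",
) -> tuple[AbundanceTable, DesignMap]:
    """Table with mutant 'm' vs wild type 'w'; dict maps feature_id -> replicates.

    NaN entries in the replicate lists become ND cells.
    """
    fids = list(mutant_values)
    n_m = len(next(iter(mutant_values.values())))
    n_w = len(next(iter(wildtype_values.values())))
    features = [FeatureDescriptor(f, f, "metabolite", "CAR") for f in fids]
    samples = [
        *(SampleDescriptor(f"m_{stage}_{r}", "m", "w", stage, r) for r in range(1, n_m + 1)),
        *(SampleDescriptor(f"w_{stage}_{r}", "w", "w", stage, r) for r in range(1, n_w + 1)),
    ]
    values = np.array(
        [[*mutant_values[f], *wildtype_values[f]] for f in fids], dtype=float
    )
    detected = np.isfinite(values)
    values = np.where(detected, values, 0.0)
    table = AbundanceTable(features, samples, values, detected)
    return table, DesignMap({"m": "w"})


def flat_panel_config(
    n_transcripts: int,
    modules: list[PlantedModule],
    n_replicates: int = 21,
    stages: tuple[str, ...] = ("MG",),
    noise_sigma: float = 0.25,
    lod: float = 0.0,
    seed: int = 0,
) -> SimulationConfig:
    """Single wild-type genotype with flat transcript means: the only
    cross-feature structure is what the planted modules induce."""
    features = make_features(n_transcripts, kind="transcript", prefix="T")
    return SimulationConfig(
        features=features,
        pathway_map=PathwayMap(nodes=[], edges=[]),
        design=DesignMap({}),
        mutations=[],
        genotypes=["AC"],
        stages=list(stages),
        n_replicates=n_replicates,
        stage_activity={st: 1.0 for st in stages},
        noise_sigma=noise_sigma,
        lod=lod,
        transcript_coupling=modules,
        seed=seed,
    )


@pytest.fixture(scope="session")
def default_dataset():
    from ripenet.synthetic_data import default_simulation_config, generate_dataset

    cfg = default_simulation_config(seed=11)
    table, truth = generate_dataset(cfg)
    return cfg, table, truth
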