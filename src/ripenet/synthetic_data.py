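"""Synthetic mutant-panel data with known ground truth.

Noiseless feature means come from a steady-state multiplicative flux model on
the pathway DAG (mutation-driven redistribution, stage-dependent input) plus
baseline tables for off-pathway metabolites and transcripts.  Replicate noise
is log-normal multiplicative; planted modules share a per-sample latent factor
on the log scale so that the expected pairwise Pearson correlation within a
module equals ``rho_plant``; values falling below the detection limit are
censored to ND.  The generator returns the truth record needed by recovery
tests: expected means, planted modules and genotype groupings implied by
shared mutation effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_model import (
    AbundanceTable,
    DesignMap,
    FeatureDescriptor,
    PathwayMap,
    SampleDescriptor,
    ValidationError,
)
from . import defaults

__all__ = [
    "MutationSpec",
    "PlantedModule",
    "SimulationConfig",
    "SyntheticTruth",
    "propagate_flux",
    "simulate_transcripts",
    "generate_dataset",
    "default_mutation_specs",
    "default_simulation_config",
]


@dataclass(frozen=True)
class MutationSpec:
    """One mutation: loss of function (leaky block) or gain of function.

    lof: a fraction ``leakiness`` (lambda) of flux passes the mutated step and
    the immediate substrate of each blocked edge accumulates by a factor
    ``1 + (1 - lambda) * backlog``.  gof: the branch fractions of the mutated
    gene's edges are multiplied by ``gain`` before per-node renormalization.
    """

    genotype: str
    target_gene: str
    effect: str  # "lof" | "gof"
    leakiness: float = 1.0
    gain: float = 1.0
    backlog: float = 0.0

    def __post_init__(self) -> None:
        if self.effect not in ("lof", "gof"):
            raise ValidationError(f"effect must be 'lof' or 'gof', got {self.effect!r}")
        if not 0.0 <= self.leakiness <= 1.0:
            raise ValidationError("leakiness must lie in [0, 1]")
        if self.gain < 1.0:
            raise ValidationError("gain must be >= 1")
        if self.backlog < 0.0:
            raise ValidationError("backlog must be >= 0")


@dataclass(frozen=True)
class PlantedModule:
    """Features sharing a latent factor; expected within-module Pearson = rho.

    ``stages`` restricts the coupling to samples of those stages (None = all
    stages), which lets recovery tests plant a module at one stage only.
    """

    members: tuple[str, ...]
    rho: float
    stages: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValidationError("rho_plant must lie in [0, 1]")
        if len(self.members) < 2:
            raise ValidationError("a planted module needs >= 2 members")


@dataclass
class SimulationConfig:
    features: list[FeatureDescriptor]
    pathway_map: PathwayMap
    design: DesignMap
    mutations: list[MutationSpec]
    genotypes: list[str]
    stages: list[str]
    n_replicates: int = 3
    stage_activity: Mapping[str, float] = field(
        default_factory=lambda: {"MG": 1.0, "Br": 2.5, "FR": 5.0}
    )
    base_flux: float = 100.0
    noise_sigma: float = 0.25
    lod: float = 2.0
    transcript_base: Mapping[str, float | Mapping[str, float]] = field(default_factory=dict)
    default_transcript_base: float = 100.0
    metabolite_base: Mapping[str, float] = field(default_factory=dict)
    default_metabolite_base: float = 100.0
    transcript_modifiers: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    transcript_coupling: list[PlantedModule] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.lod < 0:
            raise ValidationError("lod must be >= 0")
        catalog_ids = {f.feature_id for f in self.features}
        transcript_ids = {f.feature_id for f in self.features if f.kind == "transcript"}
        self.pathway_map.check_genes(transcript_ids)
        for st in self.stages:
            if st not in self.stage_activity:
                raise ValidationError(f"stage {st!r} missing from stage_activity")
        seen: set[str] = set()
        for mod in self.transcript_coupling:
            for m in mod.members:
                if m not in catalog_ids:
                    raise ValidationError(f"planted module references unknown feature {m!r}")
                if m in seen:
                    raise ValidationError(f"feature {m!r} belongs to more than one module")
                seen.add(m)
        for spec in self.mutations:
            if spec.target_gene not in self.pathway_map.genes():
                raise ValidationError(
                    f"mutation for {spec.genotype!r} targets gene "
                    f"{spec.target_gene!r} absent from the pathway map"
                )

    def samples(self) -> list[SampleDescriptor]:
        out = []
        for g in self.genotypes:
            background = g if g not in self.design.mutant_to_wildtype else self.design.wildtype_of(g)
            for stage in self.stages:
                for rep in range(1, self.n_replicates + 1):
                    out.append(
                        SampleDescriptor(
                            sample_id=f"{g}_{stage}_{rep}",
                            genotype=g,
                            background=background,
                            stage=stage,
                            replicate=rep,
                        )
                    )
        return out


@dataclass
class SyntheticTruth:
    """Ground truth: noiseless means per feature x (genotype, stage), planted
    modules, genotype groupings implied by shared effects, and the mutation
    specs used."""

    expected_means: dict[tuple[str, str, str], float]  # (feature, genotype, stage)
    planted_modules: list[PlantedModule]
    planted_genotype_pairs: list[tuple[str, ...]]
    mutation_specs: list[MutationSpec]


# ---------------------------------------------------------------------------
# noiseless flux propagation
# ---------------------------------------------------------------------------

def propagate_flux(
    pmap: PathwayMap,
    mutations: Sequence[MutationSpec],
    stage_input: float,
) -> dict[str, float]:
    """Noiseless steady-state means for one genotype at one stage activity.

    Entry nodes receive ``stage_input``; each product receives the sum over
    incoming edges of substrate mean x branch fraction x edge transmission
    (transmission = leakiness for lof-mutated genes, else 1).  gof mutations
    rescale their gene's branch fractions by ``gain`` with per-node
    renormalization.  Finally each lof-blocked edge multiplies its substrate's
    reported mean by ``1 + (1 - leakiness) * backlog`` without propagating the
    backlog downstream.
    """
    if stage_input <= 0:
        raise ValidationError("stage_input must be > 0")
    map_genes = pmap.genes()
    for spec in mutations:
        if spec.target_gene not in map_genes:
            raise ValidationError(
                f"mutation targets gene {spec.target_gene!r} absent from the pathway map"
            )
    lof = {s.target_gene: s for s in mutations if s.effect == "lof"}
    gof = {s.target_gene: s for s in mutations if s.effect == "gof"}

    # effective branch fractions after gof rescaling + renormalization
    out_by_node: dict[str, list] = {}
    for e in pmap.edges:
        out_by_node.setdefault(e.substrate, []).append(e)
    frac: dict[tuple[str, str], float] = {}
    for node, outs in out_by_node.items():
        raw = {}
        for e in outs:
            f = pmap.effective_fraction(e.substrate, e.product)
            if e.gene in gof:
                f *= gof[e.gene].gain
            raw[e.product] = f
        total = sum(raw.values())
        for prod, f in raw.items():
            frac[(node, prod)] = f / total

    import networkx as nx

    g = pmap.to_graph()
    mean: dict[str, float] = {}
    entries = set(pmap.entry_nodes())
    for node in nx.topological_sort(g):
        if node in entries:
            mean[node] = float(stage_input)
            continue
        total = 0.0
        for e in pmap.in_edges(node):
            trans = lof[e.gene].leakiness if e.gene in lof else 1.0
            total += mean[e.substrate] * frac[(e.substrate, e.product)] * trans
        mean[node] = total

    # substrate backlog of blocked steps (reported, not propagated)
    final = dict(mean)
    for e in pmap.edges:
        if e.gene in lof:
            spec = lof[e.gene]
            final[e.substrate] = final[e.substrate] * (
                1.0 + (1.0 - spec.leakiness) * spec.backlog
            )
    return final


# ---------------------------------------------------------------------------
# transcript means and planted latent factors
# ---------------------------------------------------------------------------

def _base_of(table: Mapping, key: str, stage: str, default: float) -> float:
    v = table.get(key, default)
    if isinstance(v, Mapping):
        return float(v.get(stage, default))
    return float(v)


def simulate_transcripts(
    config: SimulationConfig,
    samples: Sequence[SampleDescriptor],
    rng: np.random.Generator,
) -> tuple[dict[tuple[str, str], float], np.ndarray]:
    """Noiseless transcript means per (gene, sample_id) plus module latent factors.

    Returns ``(means, latents)`` where ``latents`` has one row per planted
    module and one column per sample (standard-normal draws shared by the
    module's members on the log scale).
    """
    transcript_ids = [f.feature_id for f in config.features if f.kind == "transcript"]
    tset = set(transcript_ids)
    for mod in config.transcript_coupling:
        for m in mod.members:
            if m not in {f.feature_id for f in config.features}:
                raise ValidationError(f"planted module references unknown feature {m!r}")
    means: dict[tuple[str, str], float] = {}
    for gene in transcript_ids:
        for s in samples:
            base = _base_of(config.transcript_base, gene, s.stage, config.default_transcript_base)
            mod = config.transcript_modifiers.get(s.genotype, {}).get(gene, 1.0)
            means[(gene, s.sample_id)] = base * mod
    latents = rng.standard_normal((len(config.transcript_coupling), len(samples)))
    return means, latents


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def _expected_means(config: SimulationConfig) -> dict[tuple[str, str, str], float]:
    """Noiseless mean per (feature_id, genotype, stage)."""
    by_genotype: dict[str, list[MutationSpec]] = {}
    for spec in config.mutations:
        by_genotype.setdefault(spec.genotype, []).append(spec)
    node_set = set(config.pathway_map.nodes)
    out: dict[tuple[str, str, str], float] = {}
    for g in config.genotypes:
        muts = by_genotype.get(g, [])
        for stage in config.stages:
            inflow = config.base_flux * float(config.stage_activity[stage])
            flux = propagate_flux(config.pathway_map, muts, inflow)
            for f in config.features:
                if f.kind == "transcript":
                    base = _base_of(
                        config.transcript_base, f.feature_id, stage,
                        config.default_transcript_base,
                    )
                    mod = config.transcript_modifiers.get(g, {}).get(f.feature_id, 1.0)
                    out[(f.feature_id, g, stage)] = base * mod
                elif f.feature_id in node_set:
                    out[(f.feature_id, g, stage)] = flux[f.feature_id]
                else:
                    out[(f.feature_id, g, stage)] = _base_of(
                        config.metabolite_base, f.feature_id, stage,
                        config.default_metabolite_base,
                    )
    return out


def _planted_genotype_pairs(
    config: SimulationConfig, expected: dict[tuple[str, str, str], float]
) -> list[tuple[str, ...]]:
    """Group mutants whose noiseless effect signatures are near-identical.

    The signature is the log-ratio of mutant to matched wild-type means over
    all metabolite features and stages (with a small pseudocount so full
    blocks stay finite); mutants whose signatures correlate at or above 0.9
    fall in the same group (connected components).
    """
    mutants = [g for g in config.genotypes if g in config.design.mutant_to_wildtype]
    if len(mutants) < 2:
        return [(m,) for m in mutants]
    met_ids = [f.feature_id for f in config.features if f.kind == "metabolite"]
    all_means = [expected[k] for k in expected]
    pseudo = 1e-6 * (max(all_means) if all_means else 1.0) + 1e-30
    sig = {}
    for m in mutants:
        wt = config.design.wildtype_of(m)
        vec = []
        for fid in met_ids:
            for stage in config.stages:
                mv = expected[(fid, m, stage)]
                wv = expected[(fid, wt, stage)]
                vec.append(math.log2((mv + pseudo) / (wv + pseudo)))
        sig[m] = np.asarray(vec)
    # union-find over high-correlation pairs
    parent = {m: m for m in mutants}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(mutants):
        for b in mutants[i + 1:]:
            va, vb = sig[a], sig[b]
            if np.std(va) == 0 or np.std(vb) == 0:
                continue
            r = float(np.corrcoef(va, vb)[0, 1])
            if r >= 0.9:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for m in mutants:
        groups.setdefault(find(m), []).append(m)
    return [tuple(sorted(g)) for g in sorted(groups.values())]


def generate_dataset(config: SimulationConfig) -> tuple[AbundanceTable, SyntheticTruth]:
    """Generate the replicate-level table and its ground truth.

    Replicate value = noiseless mean x exp(sigma * eta) where eta is standard
    normal, shared through the module latent factor for planted members
    (loading sqrt(rho) on the factor, sqrt(1-rho) on the residual, so the
    expected within-module log-scale Pearson correlation is rho).  Values
    below ``lod`` are censored to ND.  Identical config + seed gives
    bit-identical output.
    """
    samples = config.samples()
    rng = np.random.default_rng(config.seed)
    expected = _expected_means(config)
    _, latents = simulate_transcripts(config, samples, rng)

    feature_ids = [f.feature_id for f in config.features]
    module_of: dict[str, int] = {}
    for k, mod in enumerate(config.transcript_coupling):
        for m in mod.members:
            module_of[m] = k

    n_f, n_s = len(feature_ids), len(samples)
    residuals = rng.standard_normal((n_f, n_s))
    eta = np.empty((n_f, n_s))
    stage_of = np.array([s.stage for s in samples])
    for i, fid in enumerate(feature_ids):
        k = module_of.get(fid)
        if k is None:
            eta[i] = residuals[i]
        else:
            mod = config.transcript_coupling[k]
            coupled = (
                np.ones(n_s, dtype=bool)
                if mod.stages is None
                else np.isin(stage_of, mod.stages)
            )
            mixed = math.sqrt(mod.rho) * latents[k] + math.sqrt(1.0 - mod.rho) * residuals[i]
            eta[i] = np.where(coupled, mixed, residuals[i])

    means = np.empty((n_f, n_s))
    for i, fid in enumerate(feature_ids):
        for j, s in enumerate(samples):
            means[i, j] = expected[(fid, s.genotype, s.stage)]
    values = means * np.exp(config.noise_sigma * eta)
    detected = values >= config.lod

    table = AbundanceTable(
        features=config.features, samples=samples, values=values, detected=detected
    )
    truth = SyntheticTruth(
        expected_means=expected,
        planted_modules=list(config.transcript_coupling),
        planted_genotype_pairs=_planted_genotype_pairs(config, expected),
        mutation_specs=list(config.mutations),
    )
    return table, truth


# ---------------------------------------------------------------------------
# presets mirroring the default mutant panel
# ---------------------------------------------------------------------------

def default_mutation_specs() -> list[MutationSpec]:
    """Illustrative allele strengths for the default panel (not measured)."""
    return [
        MutationSpec("at", "IDI1", "lof", leakiness=0.0, backlog=0.5),
        MutationSpec("r", "PSY1", "lof", leakiness=0.0, backlog=1.0),
        MutationSpec("t", "CrtISO1", "lof", leakiness=0.05, backlog=1.0),
        MutationSpec("B", "CYC-b", "gof", gain=5.0),
        MutationSpec("Del", "LCY-e", "gof", gain=5.0),
    ]


def default_simulation_config(seed: int = 0, n_replicates: int = 3) -> SimulationConfig:
    features = defaults.default_feature_catalog()
    return SimulationConfig(
        features=features,
        pathway_map=defaults.default_pathway_map(),
        design=defaults.default_design_map(),
        mutations=default_mutation_specs(),
        genotypes=list(defaults.WILDTYPES) + list(defaults.MUTANT_ORDER),
        stages=list(defaults.STAGE_ORDER),
        n_replicates=n_replicates,
        transcript_coupling=[
            PlantedModule(("CYC-b", "CHY1", "CHY2", "LUT5", "NCED"), rho=0.9),
            PlantedModule(("PSY1", "PDS", "ZDS", "CrtISO1"), rho=0.85),
        ],
        seed=seed,
    )
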