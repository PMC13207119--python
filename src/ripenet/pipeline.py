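"""Configuration-driven orchestration: simulate -> differential -> clustering
-> correlation -> hub networks, with provenance and stage-granular logging.

A single flat config (YAML or JSON) drives an end-to-end run into a
deterministic directory layout::

    outdir/
      inputs/        abundance.tsv samples.tsv features.tsv design.json pathway_map.json truth.json
      differential/  diff_<stage>.tsv
      clustering/    hcl_<stage>.nwk  hcl_<stage>_merges.tsv
      correlation/   corr_<stage>.tsv (+ .npairs.tsv)
      networks/      <hub>_<stage>.graphml / .edges.tsv, summary.tsv, trajectories.tsv
      provenance.json run.log

Identical config + inputs + seed gives byte-identical outputs apart from the
timestamped provenance.json and run.log.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .core_model import (
    ValidationError,
    read_abundance_table,
    read_design_map,
    read_feature_table,
    read_pathway_map,
    read_sample_table,
    validate_design,
    write_abundance_table,
    write_design_map,
    write_feature_table,
    write_pathway_map,
    write_sample_table,
)
from .correlation_networks import (
    DEFAULT_MIN_PAIRS,
    DEFAULT_TAU,
    export_network,
    hub_network,
    network_summary,
    pearson_matrix,
    write_correlation_matrix,
)
from .defaults import MUTANT_GENES, MUTANT_ORDER, STAGE_ORDER
from .differential import differential_table, export_heatmap_table
from .stage_clustering import build_profiles, hcl, to_newick
from .synthetic_data import default_simulation_config, generate_dataset

__all__ = ["RunConfig", "load_run_config", "run_all", "summarize_trajectories"]


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    simulate: bool = True
    n_replicates: int = 3
    # input paths (used when simulate is False)
    table_path: str | None = None
    samples_path: str | None = None
    features_path: str | None = None
    design_path: str | None = None
    pathway_map_path: str | None = None
    # analysis options
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    corr_pathway_classes: list[str] | None = None  # None = all features
    hubs: list[str] = field(default_factory=lambda: [MUTANT_GENES[m] for m in MUTANT_ORDER])
    tau: float = DEFAULT_TAU
    min_pairs: int = DEFAULT_MIN_PAIRS
    on_log_scale: bool = True
    welch: bool = False
    sample_unit: str = "replicate"
    include_neighbor_edges: bool = False
    clustering_mode: str = "log2fc"
    clustering_distance: str = "one_minus_pearson"
    clustering_linkage: str = "average"

    def validate(self) -> None:
        if not self.stages:
            raise ValidationError("stages must be nonempty")
        if not self.simulate:
            for name in ("table_path", "samples_path", "features_path", "design_path"):
                if getattr(self, name) is None:
                    raise ValidationError(f"{name} required when simulate is false")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run config (YAML is a JSON superset here)."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_logger(outdir: Path) -> logging.Logger:
    logger = logging.getLogger(f"ripenet.run.{outdir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.propagate = False
    return logger


def summarize_trajectories(summaries: Sequence[Mapping[str, Any]],
                           stage_order: Sequence[str]) -> list[dict[str, Any]]:
    """Per-hub stage trajectory of connectivity with delta-sign labels.

    Labels are descriptive, not inferential: "expanding" when edge-count
    deltas are all >= 0 with at least one > 0, "contracting" for the mirror
    case, "stable" when all deltas are 0, "rewired" otherwise.
    """
    by_hub: dict[str, dict[str, Mapping[str, Any]]] = {}
    for s in summaries:
        by_hub.setdefault(s["hub"], {})[s["stage"]] = s
    rows = []
    for hub in sorted(by_hub):
        stages = [st for st in stage_order if st in by_hub[hub]]
        if len(stages) < 2:
            continue
        counts = [by_hub[hub][st]["n_edges"] for st in stages]
        deltas = [b - a for a, b in zip(counts, counts[1:])]
        if all(d == 0 for d in deltas):
            label = "stable"
        elif all(d >= 0 for d in deltas):
            label = "expanding"
        elif all(d <= 0 for d in deltas):
            label = "contracting"
        else:
            label = "rewired"
        row: dict[str, Any] = {"hub": hub, "label": label}
        for st in stages:
            s = by_hub[hub][st]
            row[f"n_edges_{st}"] = s["n_edges"]
            row[f"n_positive_{st}"] = s["n_positive"]
            row[f"n_negative_{st}"] = s["n_negative"]
            row[f"ns_hub_{st}"] = s["ns_hub"]
        for st_a, st_b, d in zip(stages, stages[1:], deltas):
            row[f"delta_{st_a}_{st_b}"] = d
        rows.append(row)
    return rows


def _write_dict_rows(rows: Sequence[Mapping[str, Any]], path: Path) -> None:
    cols: list[str] = []
    for r in rows:
        for k in r:
            if k not in cols:
                cols.append(k)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for r in rows:
            w.writerow(["" if r.get(c) is None else r.get(c, "") for c in cols])


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sub in ("inputs", "differential", "clustering", "correlation", "networks"):
        (outdir / sub).mkdir(exist_ok=True)
    logger = _setup_logger(outdir)
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()

    # ---- inputs ----------------------------------------------------------
    if config.simulate:
        sim = default_simulation_config(seed=config.seed, n_replicates=config.n_replicates)
        table, truth = generate_dataset(sim)
        design = sim.design
        catalog = sim.features
        pmap = sim.pathway_map
        inputs = outdir / "inputs"
        write_abundance_table(table, inputs / "abundance.tsv")
        write_sample_table(table.samples, inputs / "samples.tsv")
        write_feature_table(catalog, inputs / "features.tsv")
        write_design_map(design, inputs / "design.json")
        write_pathway_map(pmap, inputs / "pathway_map.json")
        with (inputs / "truth.json").open("w") as fh:
            json.dump(
                {
                    "planted_modules": [
                        {"members": list(m.members), "rho": m.rho,
                         "stages": list(m.stages) if m.stages else None}
                        for m in truth.planted_modules
                    ],
                    "planted_genotype_pairs": [list(g) for g in truth.planted_genotype_pairs],
                    "mutation_specs": [dataclasses.asdict(m) for m in truth.mutation_specs],
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
        logger.info("simulated dataset: %d features x %d samples (seed=%d)",
                    len(table.features), len(table.samples), config.seed)
    else:
        catalog = read_feature_table(config.features_path)
        samples = read_sample_table(config.samples_path)
        table = read_abundance_table(config.table_path, catalog, samples)
        design = read_design_map(config.design_path)
        pmap = (
            read_pathway_map(config.pathway_map_path)
            if config.pathway_map_path
            else None
        )
        logger.info("loaded dataset: %d features x %d samples",
                    len(table.features), len(table.samples))

    # ---- validation before any computation -------------------------------
    transcript_ids = {f.feature_id for f in table.features if f.kind == "transcript"}
    for hub in config.hubs:
        if hub not in transcript_ids:
            raise ValidationError(f"hub gene {hub!r} absent from the transcript catalog")
    for st in config.stages:
        if st not in table.stages():
            raise ValidationError(f"configured stage {st!r} absent from the table")
    report = validate_design(table.samples, design)
    if report.unmatched_mutants:
        raise ValidationError(f"unmatched mutants in design: {report.unmatched_mutants}")
    for m, st, n in report.low_replicate_cells:
        logger.warning("low replicate count: %s at %s has %d replicates", m, st, n)

    corr_features = None
    if config.corr_pathway_classes is not None:
        wanted = set(config.corr_pathway_classes)
        corr_features = [f.feature_id for f in table.features if f.pathway_class in wanted]

    # ---- per-stage analyses ---------------------------------------------
    summaries: list[dict[str, Any]] = []
    for stage in config.stages:
        logger.info("stage %s: differential", stage)
        results = differential_table(
            table, design, stages=[stage],
            on_log_scale=config.on_log_scale, welch=config.welch,
        )
        nd_only = sum(1 for r in results if r.status.startswith("nd"))
        logger.info("stage %s: %d differential cells (%d ND)", stage, len(results), nd_only)
        export_heatmap_table(results, table.features, outdir / "differential" / f"diff_{stage}.tsv")

        logger.info("stage %s: clustering (%s/%s/%s)", stage, config.clustering_mode,
                    config.clustering_distance, config.clustering_linkage)
        profiles = build_profiles(table, design, stage, mode=config.clustering_mode)
        dend = hcl(profiles, distance=config.clustering_distance,
                   linkage=config.clustering_linkage)
        (outdir / "clustering" / f"hcl_{stage}.nwk").write_text(to_newick(dend) + "\n")
        with (outdir / "clustering" / f"hcl_{stage}_merges.tsv").open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["cluster_a", "cluster_b", "height", "new_cluster", "members"])
            members = dend.members()
            for a, b, h, new in dend.merges:
                w.writerow([a, b, repr(h), new, ";".join(members[new])])

        logger.info("stage %s: correlation matrix", stage)
        matrix = pearson_matrix(
            table, stage, features=corr_features,
            sample_unit=config.sample_unit, on_log_scale=config.on_log_scale,
            min_pairs=config.min_pairs,
        )
        write_correlation_matrix(matrix, outdir / "correlation" / f"corr_{stage}.tsv")

        for hub in config.hubs:
            net = hub_network(matrix, hub, tau=config.tau,
                              include_neighbor_edges=config.include_neighbor_edges)
            if net.warning:
                logger.warning("%s", net.warning)
            base = outdir / "networks" / f"{hub}_{stage}"
            export_network(net, base.with_suffix(".graphml"), "graphml", catalog=table.features)
            export_network(net, Path(str(base) + ".edges.tsv"), "edge_tsv")
            summaries.append(network_summary(net))
            logger.info("stage %s: hub %s -> %d edges", stage, hub, len(net.edges))

    _write_dict_rows(summaries, outdir / "networks" / "summary.tsv")
    trajectories = summarize_trajectories(summaries, config.stages)
    _write_dict_rows(trajectories, outdir / "networks" / "trajectories.tsv")

    # ---- provenance ------------------------------------------------------
    digests = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name not in ("provenance.json", "run.log"):
            digests[str(p.relative_to(outdir))] = _sha256(p)
    provenance = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "started": started,
        "finished": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "output_digests": digests,
    }
    with (outdir / "provenance.json").open("w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %d output files", len(digests))
    for h in logger.handlers:
        h.close()
    return outdir
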