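"""Domain types and I/O for abundance tables, sample/feature metadata and pathway maps.

The single data currency of the pipeline is the :class:`AbundanceTable`: a
features-in-rows, samples-in-columns matrix of nonnegative abundances with an
explicit parallel "detected" mask.  Not-detected (ND) is a first-class flag —
distinct from a measured zero and from a missing number — and must survive I/O
round trips.  All tabular interchange is plain TSV; the pathway map is JSON.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "ValidationError",
    "FeatureDescriptor",
    "SampleDescriptor",
    "DesignMap",
    "AbundanceTable",
    "PathwayMap",
    "PathwayEdge",
    "DesignReport",
    "ND_SENTINEL",
    "PATHWAY_CLASSES",
    "FEATURE_KINDS",
    "read_abundance_table",
    "write_abundance_table",
    "read_sample_table",
    "write_sample_table",
    "read_feature_table",
    "write_feature_table",
    "read_design_map",
    "write_design_map",
    "validate_design",
    "read_pathway_map",
    "write_pathway_map",
]

ND_SENTINEL = "ND"
FEATURE_KINDS = frozenset({"metabolite", "transcript"})
PATHWAY_CLASSES = frozenset({"CAR", "ABA", "MEP", "MVA", "CHL", "TOC", "QUI"})


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class FeatureDescriptor:
    """One measured feature (metabolite or transcript) in the catalog.

    ``branch_id``/``step_index`` locate pathway-positioned features along a
    named branch (0-based from the branch entry); both are None for features
    without a pathway position (e.g. isomers quantified off the map).
    """

    feature_id: str
    display_name: str
    kind: str
    pathway_class: str
    branch_id: str | None = None
    step_index: int | None = None

    def __post_init__(self) -> None:
        if not self.feature_id:
            raise ValidationError("feature_id must be non-empty")
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(
                f"feature {self.feature_id!r}: kind must be one of "
                f"{sorted(FEATURE_KINDS)}, got {self.kind!r}"
            )
        if self.pathway_class not in PATHWAY_CLASSES:
            raise ValidationError(
                f"feature {self.feature_id!r}: pathway_class must be one of "
                f"{sorted(PATHWAY_CLASSES)}, got {self.pathway_class!r}"
            )
        if (self.branch_id is None) != (self.step_index is None):
            raise ValidationError(
                f"feature {self.feature_id!r}: step_index present iff branch_id present"
            )
        if self.step_index is not None and self.step_index < 0:
            raise ValidationError(f"feature {self.feature_id!r}: step_index must be >= 0")


@dataclass(frozen=True)
class SampleDescriptor:
    """One biological-replicate sample.

    Genotype and stage vocabularies are open (the default mutant panel is just
    a shipped catalog); the structural constraint is that wild-type genotypes
    have ``background`` equal to themselves.
    """

    sample_id: str
    genotype: str
    background: str
    stage: str
    replicate: int

    def __post_init__(self) -> None:
        for attr in ("sample_id", "genotype", "background", "stage"):
            if not getattr(self, attr):
                raise ValidationError(f"sample field {attr!r} must be non-empty")
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )

    @property
    def is_wildtype(self) -> bool:
        return self.genotype == self.background


@dataclass(frozen=True)
class DesignMap:
    """Mutant genotype -> matched wild-type genotype."""

    mutant_to_wildtype: Mapping[str, str]

    def wildtype_of(self, mutant: str) -> str:
        try:
            return self.mutant_to_wildtype[mutant]
        except KeyError:
            raise ValidationError(f"no matched wild type for mutant {mutant!r}") from None

    @property
    def mutants(self) -> list[str]:
        return list(self.mutant_to_wildtype)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} {i!r}")
        seen.add(i)


class AbundanceTable:
    """Features x samples abundance matrix with an explicit detected mask.

    ``values[i, j]`` is meaningful only where ``detected[i, j]`` is True; ND
    cells store NaN internally so they can never silently leak into statistics.
    """

    def __init__(
        self,
        features: Sequence[FeatureDescriptor],
        samples: Sequence[SampleDescriptor],
        values: np.ndarray,
        detected: np.ndarray,
    ) -> None:
        self.features = list(features)
        self.samples = list(samples)
        values = np.asarray(values, dtype=float)
        detected = np.asarray(detected, dtype=bool)
        if values.shape != (len(self.features), len(self.samples)):
            raise ValidationError(
                f"values shape {values.shape} != "
                f"({len(self.features)} features, {len(self.samples)} samples)"
            )
        if detected.shape != values.shape:
            raise ValidationError("detected mask shape must equal values shape")
        det_vals = values[detected]
        if det_vals.size and (not np.all(np.isfinite(det_vals)) or np.any(det_vals < 0)):
            raise ValidationError("detected values must be finite and >= 0")
        # ND cells carry no usable numeric value
        values = values.copy()
        values[~detected] = np.nan
        self.values = values
        self.detected = detected
        _check_unique([f.feature_id for f in self.features], "feature_id")
        _check_unique([s.sample_id for s in self.samples], "sample_id")
        _check_unique(
            [f"{s.genotype}/{s.stage}/{s.replicate}" for s in self.samples],
            "(genotype, stage, replicate)",
        )
        for s in self.samples:
            if s.genotype == s.background:
                continue
        self._fidx = {f.feature_id: i for i, f in enumerate(self.features)}
        self._sidx = {s.sample_id: j for j, s in enumerate(self.samples)}

    # -- lookup helpers -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def feature_index(self, feature_id: str) -> int:
        try:
            return self._fidx[feature_id]
        except KeyError:
            raise ValidationError(f"unknown feature {feature_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sidx[sample_id]
        except KeyError:
            raise ValidationError(f"unknown sample {sample_id!r}") from None

    def samples_where(self, **conditions: str) -> list[int]:
        """Column indices of samples matching all given attribute values."""
        out = []
        for j, s in enumerate(self.samples):
            if all(getattr(s, k) == v for k, v in conditions.items()):
                out.append(j)
        return out

    def group_values(self, feature_id: str, sample_cols: Sequence[int]) -> np.ndarray:
        """Detected values of one feature over the given sample columns."""
        i = self.feature_index(feature_id)
        cols = np.asarray(sample_cols, dtype=int)
        det = self.detected[i, cols]
        return self.values[i, cols][det]

    def masked_values(self) -> np.ndarray:
        """Copy of the matrix with NaN at ND cells (features x samples)."""
        return self.values.copy()

    def stages(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.stage, None)
        return list(seen)

    def genotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.genotype, None)
        return list(seen)


class PathwayEdge(NamedTuple):
    substrate: str
    product: str
    gene: str


@dataclass
class PathwayMap:
    """Directed acyclic reaction graph: metabolite nodes, gene-labeled edges.

    ``branch_fractions[node][product]`` gives the fractional flux routed to
    each outgoing edge of a branching node; nodes with a single outgoing edge
    implicitly route fraction 1.
    """

    nodes: list[str]
    edges: list[PathwayEdge]
    branch_fractions: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = [PathwayEdge(*e) for e in self.edges]
        _check_unique(self.nodes, "pathway node")
        node_set = set(self.nodes)
        for e in self.edges:
            for endpoint in (e.substrate, e.product):
                if endpoint not in node_set:
                    raise ValidationError(f"edge endpoint {endpoint!r} not among nodes")
        g = self.to_graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
            raise ValidationError(f"pathway map contains a cycle: {path}")
        out_by_node: dict[str, list[PathwayEdge]] = {}
        for e in self.edges:
            out_by_node.setdefault(e.substrate, []).append(e)
        for node, outs in out_by_node.items():
            fr = self.branch_fractions.get(node)
            if len(outs) > 1 or fr is not None:
                if fr is None:
                    raise ValidationError(
                        f"branching node {node!r} requires branch_fractions"
                    )
                if set(fr) != {e.product for e in outs}:
                    raise ValidationError(
                        f"branch_fractions at {node!r} must name exactly its products"
                    )
                total = sum(fr.values())
                if not math.isclose(total, 1.0, abs_tol=1e-9):
                    raise ValidationError(
                        f"branch fractions at node {node!r} sum to {total!r}, not 1"
                    )

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.substrate, e.product, gene=e.gene)
        return g

    def entry_nodes(self) -> list[str]:
        targets = {e.product for e in self.edges}
        return [n for n in self.nodes if n not in targets]

    def out_edges(self, node: str) -> list[PathwayEdge]:
        return [e for e in self.edges if e.substrate == node]

    def in_edges(self, node: str) -> list[PathwayEdge]:
        return [e for e in self.edges if e.product == node]

    def genes(self) -> set[str]:
        return {e.gene for e in self.edges}

    def effective_fraction(self, substrate: str, product: str) -> float:
        fr = self.branch_fractions.get(substrate)
        if fr is not None:
            return fr[product]
        return 1.0

    def check_genes(self, transcript_ids: Iterable[str]) -> None:
        known = set(transcript_ids)
        for e in self.edges:
            if e.gene not in known:
                raise ValidationError(
                    f"edge gene {e.gene!r} ({e.substrate} -> {e.product}) "
                    f"absent from the transcript catalog"
                )


# ---------------------------------------------------------------------------
# abundance matrix I/O
# ---------------------------------------------------------------------------

def _format_value(v: float) -> str:
    # repr() of a Python float round-trips bit-identically
    return repr(float(v))


def read_abundance_table(
    path: str | Path,
    catalog: Sequence[FeatureDescriptor],
    samples: Sequence[SampleDescriptor],
    nd_sentinel: str = ND_SENTINEL,
) -> AbundanceTable:
    """Read a TSV abundance matrix (row 1 = sample ids, column 1 = feature ids).

    The catalog and sample metadata act as the vocabulary: every id in the
    file must be declared there.  Row/column order is preserved from the file;
    the transpose orientation (features in the header) is rejected, not
    guessed.
    """
    path = Path(path)
    by_fid = {f.feature_id: f for f in catalog}
    by_sid = {s.sample_id: s for s in samples}
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValidationError(f"{path}: empty file")
    header = rows[0]
    sample_ids = header[1:]
    for sid in sample_ids:
        if sid not in by_sid:
            hint = ""
            if sid in by_fid:
                hint = " (looks like a feature id: is the matrix transposed?)"
            raise ValidationError(f"{path}: unknown sample id {sid!r} in header{hint}")
    _check_unique(sample_ids, "sample id in header")
    feature_ids: list[str] = []
    values: list[list[float]] = []
    detected: list[list[bool]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0]):
            continue
        fid = row[0]
        if fid not in by_fid:
            raise ValidationError(f"{path}:{lineno}: unknown feature id {fid!r}")
        if fid in feature_ids:
            raise ValidationError(f"{path}:{lineno}: duplicate row for feature {fid!r}")
        if len(row) != len(header):
            raise ValidationError(
                f"{path}:{lineno}: expected {len(header) - 1} values, got {len(row) - 1}"
            )
        vrow: list[float] = []
        drow: list[bool] = []
        for sid, tok in zip(sample_ids, row[1:]):
            if tok == nd_sentinel:
                vrow.append(np.nan)
                drow.append(False)
                continue
            try:
                v = float(tok)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: cell for sample {sid!r} is neither a number "
                    f"nor the ND sentinel: {tok!r}"
                ) from None
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{path}:{lineno}: negative or non-finite abundance {tok!r} "
                    f"for feature {fid!r}, sample {sid!r}"
                )
            vrow.append(v)
            drow.append(True)
        feature_ids.append(fid)
        values.append(vrow)
        detected.append(drow)
    return AbundanceTable(
        features=[by_fid[f] for f in feature_ids],
        samples=[by_sid[s] for s in sample_ids],
        values=np.array(values, dtype=float).reshape(len(feature_ids), len(sample_ids)),
        detected=np.array(detected, dtype=bool).reshape(len(feature_ids), len(sample_ids)),
    )


def write_abundance_table(
    table: AbundanceTable, path: str | Path, nd_sentinel: str = ND_SENTINEL
) -> None:
    """Write the TSV dialect accepted by :func:`read_abundance_table`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["feature_id", *table.sample_ids])
        for i, f in enumerate(table.features):
            row: list[str] = [f.feature_id]
            for j in range(len(table.samples)):
                if table.detected[i, j]:
                    row.append(_format_value(table.values[i, j]))
                else:
                    row.append(nd_sentinel)
            w.writerow(row)


# ---------------------------------------------------------------------------
# metadata I/O (sidecar TSVs)
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> list[SampleDescriptor]:
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        out = []
        for row in reader:
            out.append(
                SampleDescriptor(
                    sample_id=row["sample_id"],
                    genotype=row["genotype"],
                    background=row["background"],
                    stage=row["stage"],
                    replicate=int(row["replicate"]),
                )
            )
    _check_unique([s.sample_id for s in out], "sample_id")
    return out


def write_sample_table(samples: Sequence[SampleDescriptor], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "genotype", "background", "stage", "replicate"])
        for s in samples:
            w.writerow([s.sample_id, s.genotype, s.background, s.stage, s.replicate])


def read_feature_table(path: str | Path) -> list[FeatureDescriptor]:
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        out = []
        for row in reader:
            branch = row.get("branch_id") or None
            step = row.get("step_index") or None
            out.append(
                FeatureDescriptor(
                    feature_id=row["feature_id"],
                    display_name=row["display_name"],
                    kind=row["kind"],
                    pathway_class=row["pathway_class"],
                    branch_id=branch,
                    step_index=int(step) if step is not None else None,
                )
            )
    _check_unique([f.feature_id for f in out], "feature_id")
    return out


def write_feature_table(features: Sequence[FeatureDescriptor], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["feature_id", "display_name", "kind", "pathway_class", "branch_id", "step_index"]
        )
        for f in features:
            w.writerow(
                [
                    f.feature_id,
                    f.display_name,
                    f.kind,
                    f.pathway_class,
                    f.branch_id or "",
                    "" if f.step_index is None else f.step_index,
                ]
            )


def read_design_map(path: str | Path) -> DesignMap:
    with Path(path).open() as fh:
        data = json.load(fh)
    return DesignMap(mutant_to_wildtype=dict(data["mutant_to_wildtype"]))


def write_design_map(design: DesignMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump({"mutant_to_wildtype": dict(design.mutant_to_wildtype)}, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# design validation (report-only, never raises)
# ---------------------------------------------------------------------------

@dataclass
class DesignReport:
    """Replicate accounting per (genotype, stage) with design flags."""

    replicate_counts: dict[tuple[str, str], int]
    low_replicate_cells: list[tuple[str, str, int]]
    unmatched_mutants: list[str]

    @property
    def ok(self) -> bool:
        return not self.low_replicate_cells and not self.unmatched_mutants


def validate_design(
    samples: Sequence[SampleDescriptor], design: DesignMap
) -> DesignReport:
    """Report replicate counts per (genotype, stage) and design problems.

    Flags every mutant x stage cell with fewer than 2 replicates (a t-test is
    impossible there) and every mutant lacking a matched wild type among the
    sample genotypes.  Total: never raises.
    """
    counts: dict[tuple[str, str], int] = {}
    for s in samples:
        counts[(s.genotype, s.stage)] = counts.get((s.genotype, s.stage), 0) + 1
    genotypes = {s.genotype for s in samples}
    mutants = sorted({s.genotype for s in samples if s.genotype != s.background})
    unmatched = []
    for m in mutants:
        wt = design.mutant_to_wildtype.get(m)
        if wt is None or wt not in genotypes:
            unmatched.append(m)
    stages = sorted({s.stage for s in samples})
    low = []
    for m in mutants:
        for st in stages:
            n = counts.get((m, st), 0)
            if n < 2:
                low.append((m, st, n))
    return DesignReport(
        replicate_counts=counts,
        low_replicate_cells=low,
        unmatched_mutants=unmatched,
    )


# ---------------------------------------------------------------------------
# pathway map I/O
# ---------------------------------------------------------------------------

def read_pathway_map(
    path: str | Path, transcript_ids: Iterable[str] | None = None
) -> PathwayMap:
    """Load a pathway map JSON document and enforce its invariants.

    If ``transcript_ids`` is given, every edge gene must appear in it.
    """
    with Path(path).open() as fh:
        data = json.load(fh)
    pm = PathwayMap(
        nodes=list(data["nodes"]),
        edges=[PathwayEdge(e["substrate"], e["product"], e["gene"]) for e in data["edges"]],
        branch_fractions={
            node: {prod: float(fr) for prod, fr in fracs.items()}
            for node, fracs in data.get("branch_fractions", {}).items()
        },
    )
    if transcript_ids is not None:
        pm.check_genes(transcript_ids)
    return pm


def write_pathway_map(pmap: PathwayMap, path: str | Path) -> None:
    data = {
        "nodes": pmap.nodes,
        "edges": [
            {"substrate": e.substrate, "product": e.product, "gene": e.gene}
            for e in pmap.edges
        ],
        "branch_fractions": pmap.branch_fractions,
    }
    with Path(path).open("w") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")
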