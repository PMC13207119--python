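"""Stage-specific Pearson correlation matrices and hub-centered networks.

Correlations are pairwise-complete over the stage's samples (ND cells are
excluded per pair, the per-pair sample count is recorded, and pairs with fewer
than ``min_pairs`` shared samples or a constant variable are undefined).
Hub networks keep every feature whose correlation with the hub transcript
passes ``|r| >= tau`` (default 0.88); node strength is the sum of absolute
correlation weights over incident retained edges.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_model import AbundanceTable, FeatureDescriptor, ValidationError

__all__ = [
    "CorrelationMatrix",
    "HubNetwork",
    "pearson_matrix",
    "hub_network",
    "network_summary",
    "export_network",
    "read_edge_tsv",
    "write_correlation_matrix",
    "read_correlation_matrix",
]

DEFAULT_TAU = 0.88
DEFAULT_MIN_PAIRS = 4


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix (NaN = undefined) with per-pair sample counts."""

    feature_ids: list[str]
    r: np.ndarray
    n_pairs: np.ndarray
    stage: str

    def __post_init__(self) -> None:
        k = len(self.feature_ids)
        self.r = np.asarray(self.r, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if self.r.shape != (k, k) or self.n_pairs.shape != (k, k):
            raise ValidationError("correlation matrix shape mismatch")
        defined = np.isfinite(self.r)
        if not np.allclose(self.r[defined], self.r.T[defined.T], atol=1e-12):
            raise ValidationError("correlation matrix must be symmetric")
        if defined.any() and (
            np.any(self.r[defined] > 1 + 1e-12) or np.any(self.r[defined] < -1 - 1e-12)
        ):
            raise ValidationError("correlation values must lie in [-1, 1]")
        self._idx = {f: i for i, f in enumerate(self.feature_ids)}

    def index(self, feature_id: str) -> int:
        try:
            return self._idx[feature_id]
        except KeyError:
            raise ValidationError(f"feature {feature_id!r} absent from matrix") from None

    def value(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)])


def pearson_matrix(
    table: AbundanceTable,
    stage: str,
    features: Sequence[str] | None = None,
    sample_unit: str = "replicate",
    on_log_scale: bool = True,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson matrix over the stage's samples.

    ``sample_unit`` is ``replicate`` (default, one column per biological
    replicate) or ``genotype_mean`` (one column per genotype, means of
    detected replicates).  With ``on_log_scale`` values are log2-transformed;
    nonpositive values cannot be transformed and count as missing.
    """
    if min_pairs < 3:
        raise ValidationError("min_pairs must be >= 3")
    if sample_unit not in ("replicate", "genotype_mean"):
        raise ValidationError(f"unknown sample_unit {sample_unit!r}")
    fids = list(features) if features is not None else table.feature_ids
    rows = [table.feature_index(f) for f in fids]

    cols = table.samples_where(stage=stage)
    if not cols:
        raise ValidationError(f"no samples at stage {stage!r}")
    x = table.values[np.ix_(rows, cols)]  # NaN at ND

    if sample_unit == "genotype_mean":
        genos = []
        seen = set()
        for j in cols:
            g = table.samples[j].genotype
            if g not in seen:
                seen.add(g)
                genos.append(g)
        agg = np.full((len(rows), len(genos)), np.nan)
        stage_samples = [table.samples[j] for j in cols]
        for gi, g in enumerate(genos):
            sel = [k for k, s in enumerate(stage_samples) if s.genotype == g]
            sub = x[:, sel]
            cnt = np.sum(np.isfinite(sub), axis=1)
            sums = np.nansum(np.where(np.isfinite(sub), sub, 0.0), axis=1)
            agg[:, gi] = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
        x = agg
    if x.shape[1] < min_pairs:
        raise ValidationError(
            f"stage {stage!r} has {x.shape[1]} sample columns, fewer than "
            f"min_pairs = {min_pairs}"
        )
    if on_log_scale:
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.where(x > 0, np.log2(x), np.nan)

    df = pd.DataFrame(x.T, columns=fids)
    r = df.corr(method="pearson", min_periods=min_pairs).to_numpy()
    notna = np.isfinite(x).astype(int)
    n_pairs = notna @ notna.T
    # clip numerical overshoot from the library path
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(feature_ids=fids, r=r, n_pairs=n_pairs, stage=stage)


@dataclass
class HubNetwork:
    """Star network around one hub transcript (neighbor edges optional)."""

    hub: str
    stage: str
    tau: float
    edges: list[tuple[str, float]]  # (partner, r with hub)
    neighbor_edges: list[tuple[str, str, float]] = field(default_factory=list)
    warning: str | None = None

    @property
    def node_strength(self) -> dict[str, float]:
        ns: dict[str, float] = {self.hub: 0.0}
        for partner, r in self.edges:
            ns[self.hub] += abs(r)
            ns[partner] = ns.get(partner, 0.0) + abs(r)
        for a, b, r in self.neighbor_edges:
            ns[a] = ns.get(a, 0.0) + abs(r)
            ns[b] = ns.get(b, 0.0) + abs(r)
        return ns

    @property
    def nodes(self) -> list[str]:
        out = [self.hub]
        for partner, _ in self.edges:
            out.append(partner)
        return out


def hub_network(
    matrix: CorrelationMatrix,
    hub: str,
    tau: float = DEFAULT_TAU,
    include_neighbor_edges: bool = False,
) -> HubNetwork:
    """Thresholded hub-centered network from one row of the matrix.

    Default mode keeps exactly the hub row filtered at ``|r| >= tau``; the
    optional neighbor mode additionally keeps partner-partner edges passing
    the same threshold.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValidationError(f"tau must lie in [0, 1], got {tau!r}")
    hi = matrix.index(hub)
    row = matrix.r[hi]
    edges = []
    for j, fid in enumerate(matrix.feature_ids):
        if j == hi:
            continue
        r = row[j]
        if math.isfinite(r) and abs(r) >= tau:
            edges.append((fid, float(r)))
    warning = None
    defined = np.isfinite(np.delete(row, hi))
    if not defined.any():
        warning = f"hub {hub!r}: all correlations undefined at stage {matrix.stage!r}"
    neighbor_edges = []
    if include_neighbor_edges:
        partners = [f for f, _ in edges]
        for i, a in enumerate(partners):
            for b in partners[i + 1:]:
                r = matrix.value(a, b)
                if math.isfinite(r) and abs(r) >= tau:
                    neighbor_edges.append((a, b, float(r)))
    return HubNetwork(
        hub=hub, stage=matrix.stage, tau=tau, edges=edges,
        neighbor_edges=neighbor_edges, warning=warning,
    )


def network_summary(net: HubNetwork) -> dict:
    """Edge counts, sign split, mean |r| and hub strength of one network."""
    n_pos = sum(1 for _, r in net.edges if r > 0)
    n_neg = sum(1 for _, r in net.edges if r < 0)
    abs_r = [abs(r) for _, r in net.edges]
    return {
        "hub": net.hub,
        "stage": net.stage,
        "tau": net.tau,
        "n_edges": len(net.edges),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "mean_abs_r": float(np.mean(abs_r)) if abs_r else None,
        "ns_hub": float(sum(abs_r)),
    }


def export_network(
    net: HubNetwork,
    path: str | Path,
    fmt: str = "graphml",
    catalog: Sequence[FeatureDescriptor] | None = None,
) -> None:
    """Write the network as GraphML or an edge TSV (both round-trip parseable)."""
    by_fid = {f.feature_id: f for f in catalog} if catalog else {}
    ns = net.node_strength
    if fmt == "graphml":
        g = nx.Graph()
        for node in net.nodes:
            f = by_fid.get(node)
            g.add_node(
                node,
                kind=f.kind if f else "",
                pathway_class=f.pathway_class if f else "",
                ns=ns.get(node, 0.0),
                is_hub=node == net.hub,
            )
        for partner, r in net.edges:
            g.add_edge(net.hub, partner, r=r, sign="positive" if r > 0 else "negative",
                       abs_r=abs(r))
        for a, b, r in net.neighbor_edges:
            g.add_edge(a, b, r=r, sign="positive" if r > 0 else "negative", abs_r=abs(r))
        nx.write_graphml(g, str(path))
    elif fmt == "edge_tsv":
        with Path(path).open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["source", "target", "r", "sign", "abs_r"])
            for partner, r in net.edges:
                w.writerow([net.hub, partner, repr(r),
                            "positive" if r > 0 else "negative", repr(abs(r))])
            for a, b, r in net.neighbor_edges:
                w.writerow([a, b, repr(r),
                            "positive" if r > 0 else "negative", repr(abs(r))])
    else:
        raise ValidationError(f"unknown export format {fmt!r}")


def read_edge_tsv(path: str | Path, hub: str, stage: str, tau: float) -> HubNetwork:
    """Parse an edge TSV back into a HubNetwork (hub edges + neighbor edges)."""
    edges: list[tuple[str, float]] = []
    neighbor: list[tuple[str, str, float]] = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            r = float(row["r"])
            if row["source"] == hub:
                edges.append((row["target"], r))
            elif row["target"] == hub:
                edges.append((row["source"], r))
            else:
                neighbor.append((row["source"], row["target"], r))
    return HubNetwork(hub=hub, stage=stage, tau=tau, edges=edges, neighbor_edges=neighbor)


def write_correlation_matrix(matrix: CorrelationMatrix, path: str | Path) -> None:
    """Matrix TSV: NA for undefined cells; a parallel .npairs.tsv is written."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["feature_id", *matrix.feature_ids])
        for i, fid in enumerate(matrix.feature_ids):
            row = [fid]
            for j in range(len(matrix.feature_ids)):
                v = matrix.r[i, j]
                row.append("NA" if not math.isfinite(v) else repr(float(v)))
            w.writerow(row)
    npath = path.with_suffix(".npairs.tsv")
    with npath.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["feature_id", *matrix.feature_ids])
        for i, fid in enumerate(matrix.feature_ids):
            w.writerow([fid, *(int(matrix.n_pairs[i, j]) for j in range(len(matrix.feature_ids)))])


def read_correlation_matrix(path: str | Path, stage: str) -> CorrelationMatrix:
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    fids = rows[0][1:]
    r = np.full((len(fids), len(fids)), np.nan)
    for i, row in enumerate(rows[1:]):
        for j, tok in enumerate(row[1:]):
            if tok != "NA":
                r[i, j] = float(tok)
    npath = path.with_suffix(".npairs.tsv")
    n_pairs = np.zeros((len(fids), len(fids)), dtype=int)
    if npath.exists():
        with npath.open(newline="") as fh:
            nrows = list(csv.reader(fh, delimiter="\t"))
        for i, row in enumerate(nrows[1:]):
            n_pairs[i] = [int(t) for t in row[1:]]
    return CorrelationMatrix(feature_ids=fids, r=r, n_pairs=n_pairs, stage=stage)
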