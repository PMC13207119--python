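"""Stage-specific hierarchical clustering of genotypes in the joint
metabolite + transcript space.

Profiles are either log2 fold changes versus the matched wild type (mutants
only) or z-scored genotype means (all genotypes); ND entries are masked and
pairwise distances use mutually unmasked entries only.  The agglomerator is
implemented directly (Lance-Williams updates) so tie-breaking is deterministic
by lexicographic leaf label, independent of input order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_model import AbundanceTable, DesignMap, ValidationError

__all__ = [
    "GenotypeProfile",
    "Dendrogram",
    "build_profiles",
    "profile_distance",
    "hcl",
    "cut_clusters",
    "to_newick",
]

DISTANCES = ("one_minus_pearson", "euclidean")
LINKAGES = ("average", "complete", "ward")


@dataclass
class GenotypeProfile:
    genotype: str
    stage: str
    feature_ids: list[str]
    values: np.ndarray  # NaN where masked

    @property
    def mask(self) -> np.ndarray:
        """True where the entry is usable."""
        return np.isfinite(self.values)


def build_profiles(
    table: AbundanceTable,
    design: DesignMap,
    stage: str,
    mode: str = "log2fc",
) -> list[GenotypeProfile]:
    """One profile per genotype at the given stage.

    ``log2fc`` mode: mutants only, per-feature log2 ratio of raw-scale group
    means versus the matched wild type (masked when either group is all-ND or
    a mean is zero).  ``zscore`` mode: every genotype, per-feature z-score of
    the genotype mean across genotypes (population sd over unmasked entries).
    """
    if stage not in table.stages():
        raise ValidationError(f"stage {stage!r} not present in table")
    if mode not in ("log2fc", "zscore"):
        raise ValidationError(f"unknown profile mode {mode!r}")
    fids = table.feature_ids
    present = set(table.genotypes())

    def group_mean(genotype: str, fid: str) -> float:
        cols = table.samples_where(genotype=genotype, stage=stage)
        vals = table.group_values(fid, cols)
        return float(np.mean(vals)) if len(vals) else np.nan

    if mode == "log2fc":
        mutants = [m for m in design.mutants if m in present]
        for m in mutants:
            if design.wildtype_of(m) not in present:
                raise ValidationError(f"mutant {m!r} has no matched wild type in table")
        profiles = []
        for m in mutants:
            wt = design.wildtype_of(m)
            vec = np.full(len(fids), np.nan)
            for i, fid in enumerate(fids):
                mv, wv = group_mean(m, fid), group_mean(wt, fid)
                if math.isnan(mv) or math.isnan(wv) or mv <= 0 or wv <= 0:
                    continue
                vec[i] = math.log2(mv / wv)
            profiles.append(GenotypeProfile(m, stage, list(fids), vec))
        return profiles

    genotypes = table.genotypes()
    raw = np.full((len(genotypes), len(fids)), np.nan)
    for gi, g in enumerate(genotypes):
        for i, fid in enumerate(fids):
            raw[gi, i] = group_mean(g, fid)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(raw, axis=0)
        sd = np.nanstd(raw, axis=0)
    z = np.full_like(raw, np.nan)
    ok = sd > 0
    z[:, ok] = (raw[:, ok] - mu[ok]) / sd[ok]
    return [
        GenotypeProfile(g, stage, list(fids), z[gi]) for gi, g in enumerate(genotypes)
    ]


def profile_distance(
    a: GenotypeProfile, b: GenotypeProfile, distance: str = "one_minus_pearson"
) -> float:
    """Distance on mutually unmasked entries; needs >= 3 shared entries."""
    if distance not in DISTANCES:
        raise ValidationError(f"unknown distance {distance!r}")
    shared = a.mask & b.mask
    n = int(shared.sum())
    if n < 3:
        raise ValidationError(
            f"profiles {a.genotype!r}/{b.genotype!r} share only {n} unmasked entries"
        )
    x, y = a.values[shared], b.values[shared]
    if distance == "euclidean":
        return float(np.sqrt(np.sum((x - y) ** 2)))
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        if sx == 0 and sy == 0 and np.allclose(x, y):
            return 0.0
        raise ValidationError(
            f"correlation distance undefined: profile "
            f"{(a if sx == 0 else b).genotype!r} is constant on shared entries"
        )
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


@dataclass
class Dendrogram:
    """Agglomeration record: leaves 0..n-1, new clusters n..2n-2.

    Each merge is (cluster_a, cluster_b, height, new_id) with a < b by id and
    n-1 merges for n leaves; heights are non-decreasing for the supported
    linkages.
    """

    leaf_labels: list[str]
    merges: list[tuple[int, int, float, int]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def members(self) -> dict[int, tuple[str, ...]]:
        """Sorted leaf-label tuple of every cluster id."""
        out: dict[int, tuple[str, ...]] = {
            i: (lbl,) for i, lbl in enumerate(self.leaf_labels)
        }
        for a, b, _, new in self.merges:
            out[new] = tuple(sorted(out[a] + out[b]))
        return out


def hcl(
    profiles: Sequence[GenotypeProfile],
    distance: str = "one_minus_pearson",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering with deterministic lexicographic tie-breaking.

    Cluster-cluster distances follow the Lance-Williams recurrences (ward on
    squared distances); among equidistant candidate pairs the one whose sorted
    leaf-label tuples compare lexicographically smallest merges first.
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"unknown linkage {linkage!r}")
    if len(profiles) < 2:
        raise ValidationError("need at least 2 profiles to cluster")
    labels = [p.genotype for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate profile labels")
    # canonical leaf order: lexicographic, so input order cannot matter
    order = sorted(range(len(profiles)), key=lambda i: labels[i])
    profiles = [profiles[i] for i in order]
    labels = [labels[i] for i in order]
    n = len(profiles)

    d: dict[frozenset[int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((i, j))] = profile_distance(profiles[i], profiles[j], distance)

    members: dict[int, tuple[str, ...]] = {i: (labels[i],) for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    squared = linkage == "ward"
    if squared:
        d = {k: v * v for k, v in d.items()}

    while len(active) > 1:
        best = None
        for key, dist in d.items():
            i, j = sorted(key)
            if i not in active or j not in active:
                continue
            tie_key = tuple(sorted((members[i], members[j])))
            cand = (dist, tie_key, i, j)
            if best is None or cand < best:
                best = cand
        dist, _, i, j = best
        height = math.sqrt(dist) if squared else dist
        merges.append((i, j, height, next_id))
        members[next_id] = tuple(sorted(members[i] + members[j]))
        sizes[next_id] = sizes[i] + sizes[j]
        active.discard(i)
        active.discard(j)
        for k in list(active):
            dki = d[frozenset((k, i))]
            dkj = d[frozenset((k, j))]
            if linkage == "average":
                new = (sizes[i] * dki + sizes[j] * dkj) / (sizes[i] + sizes[j])
            elif linkage == "complete":
                new = max(dki, dkj)
            else:  # ward, on squared distances
                tot = sizes[k] + sizes[i] + sizes[j]
                new = (
                    (sizes[k] + sizes[i]) * dki
                    + (sizes[k] + sizes[j]) * dkj
                    - sizes[k] * d[frozenset((i, j))]
                ) / tot
            d[frozenset((k, next_id))] = new
        active.add(next_id)
        next_id += 1
    return Dendrogram(leaf_labels=labels, merges=merges)


def cut_clusters(dendrogram: Dendrogram, k: int) -> list[tuple[str, ...]]:
    """Partition into k groups by withholding the k-1 highest (last) merges."""
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k must lie in [1, {n}], got {k}")
    members: dict[int, tuple[str, ...]] = {
        i: (lbl,) for i, lbl in enumerate(dendrogram.leaf_labels)
    }
    alive = set(members)
    for a, b, _, new in dendrogram.merges[: n - k]:
        members[new] = tuple(sorted(members[a] + members[b]))
        alive.discard(a)
        alive.discard(b)
        alive.add(new)
    return sorted(members[c] for c in alive)


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick string with merge heights as node heights (branch length =
    parent height minus child height; leaves sit at height 0)."""
    heights: dict[int, float] = {i: 0.0 for i in range(dendrogram.n_leaves)}
    children: dict[int, tuple[int, int]] = {}
    for a, b, h, new in dendrogram.merges:
        heights[new] = h
        children[new] = (a, b)
    root = dendrogram.merges[-1][3] if dendrogram.merges else 0

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - heights[node]
        if node < dendrogram.n_leaves:
            return f"{dendrogram.leaf_labels[node]}:{bl:.10g}"
        a, b = children[node]
        inner = ",".join(render(c, heights[node]) for c in (a, b))
        return f"({inner}):{bl:.10g}"

    if not dendrogram.merges:
        return f"{dendrogram.leaf_labels[0]}:0;"
    a, b = children[root]
    inner = ",".join(render(c, heights[root]) for c in (a, b))
    return f"({inner});"
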