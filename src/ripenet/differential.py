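"""Per-mutant differential tables: log2 fold change vs matched wild type with
significance stars, ND propagation, and ANOVA/Tukey comparisons across
genotypes.

ND handling rules: replicate-level ND values are excluded from group means
(never zero-filled); a group whose replicates are all ND makes the whole cell
ND; one-sided ND (or a zero group mean) yields a signed-infinity sentinel,
never a silent imputation.  Group means are arithmetic on the raw scale;
significance tests run on log2-transformed values by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import AbundanceTable, DesignMap, FeatureDescriptor, ValidationError
from .defaults import MUTANT_ORDER, STAGE_ORDER

__all__ = [
    "DifferentialResult",
    "AnovaResult",
    "stars_for",
    "log2_fold_change",
    "student_t_test",
    "anova_tukey",
    "differential_table",
    "export_heatmap_table",
]

_CLASS_ORDER = {c: i for i, c in enumerate(["MEP", "MVA", "CAR", "ABA", "CHL", "TOC", "QUI"])}


def stars_for(p: float | None) -> str:
    """Star code as a pure function of p (boundaries inclusive)."""
    if p is None or not math.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class DifferentialResult:
    feature_id: str
    genotype: str
    stage: str
    log2fc: float | None  # None when ND; +/-inf sentinels allowed
    p_value: float | None
    status: str  # ok | nd_both | nd_mutant_only | nd_wildtype_only | insufficient_replicates

    @property
    def stars(self) -> str:
        return stars_for(self.p_value)


def student_t_test(
    mutant_values: Sequence[float],
    wildtype_values: Sequence[float],
    on_log_scale: bool = True,
    welch: bool = False,
) -> tuple[float, float] | None:
    """Two-tailed Student's t-test (pooled variance unless ``welch``).

    Returns ``(t, p)``, or None when either group has < 2 usable values.
    With ``on_log_scale`` the test runs on log2 values; nonpositive values
    cannot be log-transformed and are dropped from the test.
    """
    x = np.asarray(mutant_values, dtype=float)
    y = np.asarray(wildtype_values, dtype=float)
    if on_log_scale:
        x = np.log2(x[x > 0])
        y = np.log2(y[y > 0])
    if len(x) < 2 or len(y) < 2:
        return None
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and np.mean(x) == np.mean(y):
        return 0.0, 1.0  # identical constant groups: no evidence, p = 1
    import warnings

    with warnings.catch_warnings():
        # constant groups trigger a precision-loss RuntimeWarning; the
        # resulting +/-inf statistic (p = 0) is the intended answer
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def log2_fold_change(
    table: AbundanceTable,
    design: DesignMap,
    mutant: str,
    stage: str,
    feature_id: str,
    on_log_scale: bool = True,
    welch: bool = False,
) -> DifferentialResult:
    """Fold change of one mutant vs its matched wild type at one stage.

    log2fc = log2(raw-scale mean of detected mutant replicates / raw-scale
    mean of detected wild-type replicates).  Status precedence: ND groups
    first, then insufficient replicates (< 2 detected in either group), then
    ok with the t-test p-value attached.
    """
    wt = design.wildtype_of(mutant)
    mut_cols = table.samples_where(genotype=mutant, stage=stage)
    wt_cols = table.samples_where(genotype=wt, stage=stage)
    if not mut_cols or not wt_cols:
        raise ValidationError(
            f"no samples for {mutant!r}/{wt!r} at stage {stage!r}"
        )
    mut_vals = table.group_values(feature_id, mut_cols)
    wt_vals = table.group_values(feature_id, wt_cols)

    mut_nd = len(mut_vals) == 0
    wt_nd = len(wt_vals) == 0
    if mut_nd and wt_nd:
        return DifferentialResult(feature_id, mutant, stage, None, None, "nd_both")
    if mut_nd:
        return DifferentialResult(feature_id, mutant, stage, None, None, "nd_mutant_only")
    if wt_nd:
        return DifferentialResult(feature_id, mutant, stage, None, None, "nd_wildtype_only")
    if len(mut_vals) < 2 or len(wt_vals) < 2:
        return DifferentialResult(
            feature_id, mutant, stage, None, None, "insufficient_replicates"
        )
    m_mean = float(np.mean(mut_vals))
    w_mean = float(np.mean(wt_vals))
    if w_mean == 0 and m_mean == 0:
        fc = 0.0  # both groups detected at zero: no change
    elif w_mean == 0:
        fc = math.inf
    elif m_mean == 0:
        fc = -math.inf
    else:
        fc = math.log2(m_mean / w_mean)
    tp = student_t_test(mut_vals, wt_vals, on_log_scale=on_log_scale, welch=welch)
    p = tp[1] if tp is not None else None
    return DifferentialResult(feature_id, mutant, stage, fc, p, "ok")


@dataclass
class AnovaResult:
    feature_id: str
    stage: str
    f_statistic: float | None
    p_value: float | None
    pairwise: dict[tuple[str, str], float]  # Tukey HSD adjusted p per genotype pair
    status: str  # ok | no_variance | insufficient_groups
    groups: list[str]


def anova_tukey(
    table: AbundanceTable,
    feature_id: str,
    stage: str,
    on_log_scale: bool = True,
    min_replicates: int = 2,
) -> AnovaResult:
    """One-way ANOVA across genotypes followed by Tukey's HSD.

    Only genotypes with >= ``min_replicates`` detected replicates enter; Tukey
    adjusted p-values use the studentized-range distribution.
    """
    groups: dict[str, np.ndarray] = {}
    for g in table.genotypes():
        cols = table.samples_where(genotype=g, stage=stage)
        vals = table.group_values(feature_id, cols)
        if on_log_scale:
            vals = np.log2(vals[vals > 0])
        if len(vals) >= min_replicates:
            groups[g] = vals
    names = list(groups)
    if len(names) < 2:
        return AnovaResult(feature_id, stage, None, None, {}, "insufficient_groups", names)
    arrays = [groups[g] for g in names]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return AnovaResult(feature_id, stage, None, None, {}, "no_variance", names)
    f, p = stats.f_oneway(*arrays)
    tk = stats.tukey_hsd(*arrays)
    pairwise = {}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            pairwise[(a, names[j])] = float(tk.pvalue[i, j])
    return AnovaResult(feature_id, stage, float(f), float(p), pairwise, "ok", names)


def differential_table(
    table: AbundanceTable,
    design: DesignMap,
    stages: Iterable[str] | None = None,
    mutants: Iterable[str] | None = None,
    features: Iterable[str] | None = None,
    on_log_scale: bool = True,
    welch: bool = False,
) -> list[DifferentialResult]:
    """All mutant x stage x feature differential results."""
    stages = list(stages) if stages is not None else table.stages()
    present = set(table.genotypes())
    if mutants is None:
        mutants = [m for m in design.mutants if m in present]
    fids = list(features) if features is not None else table.feature_ids
    out = []
    for fid in fids:
        for m in mutants:
            for st in stages:
                out.append(
                    log2_fold_change(
                        table, design, m, st, fid, on_log_scale=on_log_scale, welch=welch
                    )
                )
    return out


def _bh_adjust(pvals: list[float | None]) -> list[float | None]:
    """Benjamini-Hochberg adjusted p-values (None entries pass through)."""
    idx = [i for i, p in enumerate(pvals) if p is not None and math.isfinite(p)]
    m = len(idx)
    out: list[float | None] = [None] * len(pvals)
    if m == 0:
        return out
    order = sorted(idx, key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        adj[rank - 1] = val
        prev = val
    for rank, i in enumerate(order):
        out[i] = adj[rank]
    return out


def _fc_token(r: DifferentialResult) -> str:
    if r.log2fc is None:
        return "ND"
    if r.log2fc == math.inf:
        return "+Inf"
    if r.log2fc == -math.inf:
        return "-Inf"
    return repr(r.log2fc)


def export_heatmap_table(
    results: Sequence[DifferentialResult],
    catalog: Sequence[FeatureDescriptor],
    path: str | Path | None = None,
    mutant_order: Sequence[str] = MUTANT_ORDER,
    stage_order: Sequence[str] = STAGE_ORDER,
) -> pd.DataFrame:
    """Long-format heatmap table.

    Rows are ordered by pathway position (class, branch, step) then by the
    display mutant order; metabolites export glyph "square", transcripts
    "circle".  A BH-adjusted p column is included for convenience but never
    drives the stars.
    """
    by_fid = {f.feature_id: f for f in catalog}
    mrank = {m: i for i, m in enumerate(mutant_order)}
    srank = {s: i for i, s in enumerate(stage_order)}

    def feature_key(fid: str):
        f = by_fid[fid]
        return (
            _CLASS_ORDER.get(f.pathway_class, len(_CLASS_ORDER)),
            0 if f.branch_id is not None else 1,
            f.branch_id or "",
            f.step_index if f.step_index is not None else 0,
            fid,
        )

    ordered = sorted(
        results,
        key=lambda r: (
            feature_key(r.feature_id),
            srank.get(r.stage, len(srank)),
            mrank.get(r.genotype, len(mrank)),
            r.genotype,
        ),
    )
    p_adj = _bh_adjust([r.p_value for r in ordered])
    rows = []
    for r, padj in zip(ordered, p_adj):
        f = by_fid[r.feature_id]
        rows.append(
            {
                "feature_id": r.feature_id,
                "glyph": "square" if f.kind == "metabolite" else "circle",
                "pathway_class": f.pathway_class,
                "branch_id": f.branch_id or "",
                "step_index": "" if f.step_index is None else f.step_index,
                "mutant": r.genotype,
                "stage": r.stage,
                "log2fc": _fc_token(r),
                "p_value": "" if r.p_value is None else repr(r.p_value),
                "p_adj_bh": "" if padj is None else repr(padj),
                "stars": r.stars,
                "status": r.status,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "feature_id", "glyph", "pathway_class", "branch_id", "step_index",
            "mutant", "stage", "log2fc", "p_value", "p_adj_bh", "stars", "status",
        ],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return df
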