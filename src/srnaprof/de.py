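"""Consensus differential expression for small RNA count matrices.

Assembles a features x samples count matrix (features keyed
``mature:precursor`` so multi-copy miRNAs stay distinct), normalizes to
counts per million (CPM), and tests for differential expression with an
internal Welch t-test on log2(CPM+1) plus pluggable external backends
(edgeR, DESeq2, ...).  Per-method significant sets are intersected into
consensus tables and UpSet-style membership matrices.

Fold changes are log2((mean_A + 1)/(mean_B + 1)) on normalized values; the
+1 pseudocount avoids division by zero and damps spurious large fold changes
at very low expression.  "Up" means higher in the first listed group.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiler import ExpressionRecord

__all__ = [
    "ExpressionMatrix", "DEResult", "ConsensusSummary",
    "DuplicateSample", "DegenerateGroup", "BackendUnavailable", "EmptyColumn",
    "build_matrix", "normalize_cpm", "log2fc", "ttest_de", "run_backend",
    "consensus",
]


class DuplicateSample(ValueError):
    pass


class DegenerateGroup(ValueError):
    """A group has fewer than 2 samples; no within-group variance."""


class BackendUnavailable(RuntimeError):
    """External DE backend not usable; consensus proceeds without it."""


class EmptyColumn(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Features x samples counts with per-sample group labels."""

    counts: pd.DataFrame                  # features x samples
    groups: dict[str, str]                # sample -> group label
    mm_mode: str = "adjusted"

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


@dataclass
class DEResult:
    """One method's per-feature statistics in the common shape."""

    method: str
    table: pd.DataFrame   # index=features; log2fc, pvalue, padj, significant, direction
    alpha: float = 0.05

    def significant_features(self, direction: str | None = None) -> set[str]:
        t = self.table[self.table["significant"]]
        if direction is not None:
            t = t[t["direction"] == direction]
        return set(t.index)


@dataclass
class ConsensusSummary:
    """Per-method membership and intersection counts (UpSet input)."""

    membership: pd.DataFrame          # features x methods, boolean
    membership_up: pd.DataFrame
    membership_down: pd.DataFrame
    fc_membership: pd.Series          # |log2fc| >= threshold
    intersections: dict[frozenset[str], int]
    consensus_features: set[str]


def build_matrix(
    samples: Mapping[str, Iterable[ExpressionRecord]],
    groups: Mapping[str, str],
    mm_mode: str = "adjusted",
) -> ExpressionMatrix:
    """Assemble the expression matrix from per-sample profiling records.

    Features are the union across samples (missing -> 0); counts are taken
    from the requested multiple-mapping mode's column (``adjusted`` by
    default).
    """
    cols: dict[str, dict[str, float]] = {}
    for sample, records in samples.items():
        if sample in cols:
            raise DuplicateSample(sample)
        cols[sample] = {
            f"{r.mature_name}:{r.precursor_name}": r.count(mm_mode)
            for r in records
        }
    df = pd.DataFrame(cols).fillna(0.0)
    df = df.sort_index()
    df = df[list(samples.keys())]
    return ExpressionMatrix(counts=df, groups=dict(groups), mm_mode=mm_mode)


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale every column to one million total counts."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise EmptyColumn(f"zero-total columns: {bad}")
    return counts / totals * 1e6


def log2fc(
    counts: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    normalized: bool = False,
) -> pd.Series:
    """Per-feature log2((mean_A + 1)/(mean_B + 1)) over normalized values."""
    if not len(samples_a) or not len(samples_b):
        raise ValueError("both groups must be non-empty")
    norm = counts if normalized else normalize_cpm(counts)
    mean_a = norm[list(samples_a)].mean(axis=1)
    mean_b = norm[list(samples_b)].mean(axis=1)
    # difference of logs, not log of ratio: keeps swap-antisymmetry exact
    return np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)


def _direction(fc: pd.Series, significant: pd.Series) -> pd.Series:
    d = pd.Series("ns", index=fc.index)
    d[significant & (fc > 0)] = "up"
    d[significant & (fc < 0)] = "down"
    return d


def ttest_de(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> DEResult:
    """Welch t-test per feature on log2(CPM+1), BH-adjusted.

    Zero-variance features get p = 1 when the group means agree (no
    evidence) and p = 0 when they differ (infinite t in the limit).
    """
    sa, sb = matrix.samples_of(group_a), matrix.samples_of(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise DegenerateGroup("need >= 2 samples per group")
    norm = normalize_cpm(matrix.counts)
    log = np.log2(norm + 1.0)
    a, b = log[sa].to_numpy(), log[sb].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    same_mean = np.isclose(a.mean(axis=1), b.mean(axis=1))
    pvals = np.where(zero_var & same_mean, 1.0, pvals)
    pvals = np.where(zero_var & ~same_mean, 0.0, pvals)
    pvals = np.nan_to_num(pvals, nan=1.0)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    fc = log2fc(norm, sa, sb, normalized=True)
    sig = pd.Series(padj < alpha, index=fc.index)
    table = pd.DataFrame({
        "log2fc": fc,
        "pvalue": pd.Series(pvals, index=fc.index),
        "padj": pd.Series(padj, index=fc.index),
        "significant": sig,
        "direction": _direction(fc, sig),
    })
    return DEResult(method="ttest", table=table, alpha=alpha)


_EDGER_SCRIPT = """\
suppressMessages(library(edgeR))
counts <- read.delim("{counts}", row.names = 1, check.names = FALSE)
groups <- factor(scan("{groups}", what = character(), quiet = TRUE),
                 levels = c("{gb}", "{ga}"))
y <- DGEList(counts = counts, group = groups)
y <- calcNormFactors(y)
y <- estimateDisp(y)
et <- exactTest(y, pair = c("{gb}", "{ga}"))
tab <- topTags(et, n = Inf, sort.by = "none")$table
write.table(data.frame(feature = rownames(tab), log2fc = tab$logFC,
                       pvalue = tab$PValue, padj = tab$FDR),
            "{out}", sep = "\\t", quote = FALSE, row.names = FALSE)
"""


def _run_edger(matrix: ExpressionMatrix, group_a: str, group_b: str,
               alpha: float) -> DEResult:
    if shutil.which("Rscript") is None:
        raise BackendUnavailable("Rscript not on PATH")
    sa, sb = matrix.samples_of(group_a), matrix.samples_of(group_b)
    counts = matrix.counts[sa + sb].round().astype(int)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        counts.to_csv(tmp / "counts.tsv", sep="\t")
        (tmp / "groups.txt").write_text(
            "\n".join([group_a] * len(sa) + [group_b] * len(sb)) + "\n")
        script = _EDGER_SCRIPT.format(
            counts=tmp / "counts.tsv", groups=tmp / "groups.txt",
            ga=group_a, gb=group_b, out=tmp / "out.tsv")
        (tmp / "run.R").write_text(script)
        proc = subprocess.run(
            ["Rscript", str(tmp / "run.R")], capture_output=True, text=True)
        if proc.returncode != 0 or not (tmp / "out.tsv").exists():
            raise BackendUnavailable(f"edgeR failed: {proc.stderr[-500:]}")
        tab = pd.read_csv(tmp / "out.tsv", sep="\t", index_col="feature")
    tab = tab.reindex(matrix.counts.index)
    sig = tab["padj"] < alpha
    table = pd.DataFrame({
        "log2fc": tab["log2fc"], "pvalue": tab["pvalue"], "padj": tab["padj"],
        "significant": sig.fillna(False),
        "direction": _direction(tab["log2fc"], sig.fillna(False)),
    })
    return DEResult(method="edgeR", table=table, alpha=alpha)


def _run_deseq2(matrix: ExpressionMatrix, group_a: str, group_b: str,
                alpha: float) -> DEResult:
    try:
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats
    except ImportError as exc:
        raise BackendUnavailable(f"pydeseq2 not importable: {exc}") from exc
    sa, sb = matrix.samples_of(group_a), matrix.samples_of(group_b)
    counts = matrix.counts[sa + sb].round().astype(int).T
    meta = pd.DataFrame(
        {"condition": [group_a] * len(sa) + [group_b] * len(sb)},
        index=counts.index)
    try:
        dds = DeseqDataSet(counts=counts, metadata=meta,
                           design="~condition", quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", group_a, group_b],
                        quiet=True)
        ds.summary()
        res = ds.results_df
    except Exception as exc:  # backend internals out of our control
        raise BackendUnavailable(f"DESeq2 failed: {exc}") from exc
    res = res.reindex(matrix.counts.index)
    sig = (res["padj"] < alpha).fillna(False)
    table = pd.DataFrame({
        "log2fc": res["log2FoldChange"],
        "pvalue": res["pvalue"],
        "padj": res["padj"],
        "significant": sig,
        "direction": _direction(res["log2FoldChange"], sig),
    })
    return DEResult(method="DESeq2", table=table, alpha=alpha)


#: External backend registry.  Backends absent from the runtime raise
#: BackendUnavailable; the pipeline records the omission and continues.
_BACKENDS: dict[str, Callable[[ExpressionMatrix, str, str, float], DEResult]] = {
    "edgeR": _run_edger,
    "DESeq2": _run_deseq2,
}


def run_backend(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    backend: str,
    alpha: float = 0.05,
) -> DEResult:
    """Run one external DE backend on raw counts.

    Backends normalize internally, so they receive the unnormalized matrix.
    NOISeq-style posterior probabilities would map to significance via
    prob >= 1 - alpha; no such backend is currently registered.
    """
    if backend not in {"edgeR", "DESeq", "DESeq2", "NOISeq"}:
        raise ValueError(f"unknown backend {backend!r}")
    fn = _BACKENDS.get(backend)
    if fn is None:
        raise BackendUnavailable(f"no runtime provides backend {backend!r}")
    return fn(matrix, group_a, group_b, alpha)


def consensus(
    results: Sequence[DEResult],
    fc: pd.Series,
    fc_threshold: float = 1.0,
) -> ConsensusSummary:
    """Intersect per-method significant sets and build UpSet membership.

    The consensus set is the intersection over all supplied methods;
    ``intersections`` counts, for every non-empty method subset, the features
    significant in exactly that subset (UpSet semantics).
    """
    if not results:
        raise ValueError("need at least one DE result")
    methods = [r.method for r in results]
    features = sorted(set().union(*(set(r.table.index) for r in results)))

    def member_frame(direction: str | None) -> pd.DataFrame:
        return pd.DataFrame(
            {r.method: [f in r.significant_features(direction) for f in features]
             for r in results},
            index=features,
        )

    membership = member_frame(None)
    inter: dict[frozenset[str], int] = {}
    for k in range(1, len(methods) + 1):
        for subset in combinations(methods, k):
            s = frozenset(subset)
            mask = membership[list(subset)].all(axis=1)
            others = [m for m in methods if m not in s]
            if others:
                mask &= ~membership[others].any(axis=1)
            inter[s] = int(mask.sum())
    consensus_features = set(features)
    for r in results:
        consensus_features &= r.significant_features()
    return ConsensusSummary(
        membership=membership,
        membership_up=member_frame("up"),
        membership_down=member_frame("down"),
        fc_membership=fc.abs() >= fc_threshold,
        intersections=inter,
        consensus_features=consensus_features,
    )
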