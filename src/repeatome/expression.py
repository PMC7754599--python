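"""Recent-TE expression: annotation filtering, counting, normalization, bias.

The workflow mirrors a recent-TE expression survey: keep only annotated
copies with K2P < 5% from their consensus (likely still-active elements),
count aligned RNA-seq reads per TE subfamily with fractional assignment of
reads overlapping several subfamilies, normalize libraries with
median-of-ratios size factors, and label subfamilies whose expression
differs between males and females (MBTE: log2FC > 0 and adjusted P < 0.05;
FBTE: log2FC < 0 and adjusted P < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy import stats

from .formats import AlignedCopy

log = logging.getLogger(__name__)


def filter_recent_annotation(
    copies: Sequence[AlignedCopy], max_k2p: float = 0.05
) -> list[AlignedCopy]:
    """Keep copies strictly below ``max_k2p`` (default 5%) divergence.

    Saturated (undefined) K2P never qualifies.  Retained/dropped counts are
    logged.
    """
    kept = [c for c in copies if c.k2p is not None and c.k2p < max_k2p]
    log.info(
        "recent-annotation filter: kept %d / %d copies (< %.1f%% K2P)",
        len(kept),
        len(copies),
        max_k2p * 100,
    )
    return kept


class AnnotationIndex:
    """Interval index of annotated repeat copies, keyed by reference name."""

    def __init__(self, copies: Sequence[AlignedCopy]):
        self.trees: dict[str, IntervalTree] = {}
        for c in copies:
            self.trees.setdefault(c.query_id, IntervalTree()).addi(
                c.start, c.end, c.consensus_name
            )

    def overlapping_subfamilies(self, ref: str, start: int, end: int, min_overlap: int) -> set[str]:
        tree = self.trees.get(ref)
        if tree is None:
            return set()
        out = set()
        for iv in tree.overlap(start, end):
            if min(end, iv.end) - max(start, iv.begin) >= min_overlap:
                out.add(iv.data)
        return out


def count_reads_per_subfamily(
    sam_path: str,
    annotation: Sequence[AlignedCopy],
    min_overlap_bp: int = 20,
) -> tuple[dict[str, float], int]:
    """Fractional per-subfamily read counts from a SAM/BAM alignment file.

    A read overlapping copies of exactly one subfamily (by at least
    ``min_overlap_bp``) contributes 1 to it; a read overlapping k subfamilies
    contributes 1/k to each; reads overlapping nothing are tallied as
    unassigned.  Total assigned mass + unassigned equals the number of
    aligned reads.

    Returns (counts, n_unassigned).
    """
    index = AnnotationIndex(annotation)
    counts: dict[str, float] = {}
    unassigned = 0
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            subs = index.overlapping_subfamilies(
                aln.reference_name, aln.reference_start, aln.reference_end, min_overlap_bp
            )
            if not subs:
                unassigned += 1
                continue
            w = 1.0 / len(subs)
            for s in subs:
                counts[s] = counts.get(s, 0.0) + w
    return counts, unassigned


@dataclass
class CountsMatrix:
    """Subfamilies x samples count matrix with per-column size factors."""

    counts: pd.DataFrame  # rows: subfamilies, columns: samples
    size_factors: pd.Series | None = None

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("size factors not computed")
        return self.counts / self.size_factors


def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the standard RNA-seq normalization):
    per column, the median over all-positive subfamilies of count /
    geometric-mean-across-columns."""
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no subfamily with all-positive counts; cannot compute size factors")
    log_geomean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geomean, axis=0)
    return np.exp(ratios.median(axis=0))


def normalize_and_fc(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_total: int = 10,
) -> pd.DataFrame:
    """Normalize counts and compute the A-vs-B log2 fold-change.

    Subfamilies with total raw count below ``min_total`` are removed
    (low-count filtering); size factors come from :func:`median_of_ratios`
    over the retained subfamilies; log2FC = log2((mean normalized A + 0.5) /
    (mean normalized B + 0.5)).
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one column")
    kept = counts[counts.sum(axis=1) >= min_total]
    sf = median_of_ratios(kept)
    norm = kept / sf
    mean_a = norm[list(group_a)].mean(axis=1)
    mean_b = norm[list(group_b)].mean(axis=1)
    return pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2FC": np.log2((mean_a + 0.5) / (mean_b + 0.5)),
        }
    )


def rank_sum_pvalues(
    counts: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.Series:
    """Two-sided exact Mann-Whitney rank-sum p per subfamily across replicates.

    A stand-in for a count-model Wald test; externally computed p-values may
    be supplied to :func:`classify_bias` instead.
    """
    pvals = {}
    for sub, row in counts.iterrows():
        a = row[list(group_a)].to_numpy(dtype=float)
        b = row[list(group_b)].to_numpy(dtype=float)
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[sub] = 1.0
            continue
        try:
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        except ValueError:
            p = 1.0
        pvals[sub] = p
    return pd.Series(pvals)


@dataclass
class BiasCall:
    subfamily: str
    log2FC: float
    padj: float
    label: str  # MBTE / FBTE / unbiased


def classify_bias(
    log2fc: Mapping[str, float],
    p_values: Mapping[str, float],
    alpha: float = 0.05,
) -> tuple[list[BiasCall], dict]:
    """Label subfamilies as MBTE / FBTE / unbiased.

    Benjamini-Hochberg adjustment is applied over all tested subfamilies;
    MBTE requires log2FC > 0 and padj < alpha, FBTE log2FC < 0 and padj <
    alpha (log2FC exactly 0 is never biased).  Returns the calls plus a
    summary (n_expressed, n_SBTE, n_MBTE, n_FBTE and percentages of
    expressed subfamilies).
    """
    if set(log2fc) != set(p_values):
        raise ValueError("log2FC and p-value subfamily sets differ")
    subs = sorted(log2fc)
    raw = np.array([p_values[s] for s in subs])
    padj = stats.false_discovery_control(raw, method="bh")
    calls = []
    for s, fc, pa in zip(subs, (log2fc[s] for s in subs), padj):
        if pa < alpha and fc > 0:
            label = "MBTE"
        elif pa < alpha and fc < 0:
            label = "FBTE"
        else:
            label = "unbiased"
        calls.append(BiasCall(s, float(fc), float(pa), label))
    n = len(calls)
    n_m = sum(1 for c in calls if c.label == "MBTE")
    n_f = sum(1 for c in calls if c.label == "FBTE")
    summary = {
        "n_expressed": n,
        "n_SBTE": n_m + n_f,
        "n_MBTE": n_m,
        "n_FBTE": n_f,
        "pct_SBTE": 100.0 * (n_m + n_f) / n if n else 0.0,
        "pct_MBTE": 100.0 * n_m / n if n else 0.0,
        "pct_FBTE": 100.0 * n_f / n if n else 0.0,
    }
    return calls, summary
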