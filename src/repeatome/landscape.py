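"""Kimura 2-parameter distances and repeat divergence landscapes.

A repeat landscape is a histogram of repeat-derived base pairs binned by the
K2P distance of each copy from its consensus.  Low-divergence bins indicate
recently active elements; here copies below 5% divergence are treated as
"recent" and copies below 1% as "very recent", the presets used throughout
the comparative analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formats import AlignedCopy, SubstitutionCounts

N_BINS = 51  # half-open 1% bins [0,1), ..., [50,51)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_ACGT = frozenset("ACGT")


def count_substitutions(gapped_a: str, gapped_b: str) -> SubstitutionCounts:
    """Count transitions and transversions between two gapped sequences.

    Columns containing a gap or a non-ACGT symbol in either sequence are
    excluded from ``n_sites``; A<->G and C<->T count as transitions, every
    other mismatch as a transversion.  P and Q are proportions of
    ``n_sites``.
    """
    if len(gapped_a) != len(gapped_b):
        raise ValueError(
            f"gapped lengths differ: {len(gapped_a)} vs {len(gapped_b)}"
        )
    n = ts = tv = 0
    for a, b in zip(gapped_a.upper(), gapped_b.upper()):
        if a not in _ACGT or b not in _ACGT:
            continue
        n += 1
        if a != b:
            if (a, b) in TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        return SubstitutionCounts(0.0, 0.0, 0)
    return SubstitutionCounts(ts / n, tv / n, n)


def k2p_distance(s: SubstitutionCounts) -> float | None:
    """Kimura 2-parameter distance K = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).

    Corrects the raw substitution proportions for multiple hits assuming
    equal base frequencies and homogeneous rates across sites.  Returns
    ``None`` (saturated) when either log argument is non-positive.
    """
    w1 = 1.0 - 2.0 * s.P - s.Q
    w2 = 1.0 - 2.0 * s.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_from_alignment(gapped_a: str, gapped_b: str) -> float | None:
    return k2p_distance(count_substitutions(gapped_a, gapped_b))


@dataclass
class Landscape:
    """Per-group bp totals in 1% K2P bins plus an overflow bucket.

    ``group_key`` is ``(repeat_class, superfamily)`` or a family name.
    ``overflow_bp`` holds copies at K2P >= 51% or with saturated distance;
    they are excluded from the 0-50% plot but kept for bp conservation.
    """

    group_key: tuple[str, str] | str
    denominator_bp: int
    bp_per_bin: list[int] = field(default_factory=lambda: [0] * N_BINS)
    overflow_bp: int = 0

    @property
    def total_bp(self) -> int:
        return sum(self.bp_per_bin) + self.overflow_bp

    def proportion_per_bin(self) -> list[float]:
        return [b / self.denominator_bp for b in self.bp_per_bin]


def build_landscape(
    copies: Iterable[AlignedCopy],
    group_by: str = "superfamily",
    denominator_bp: int = 0,
    classification: dict[str, tuple[str, str]] | None = None,
) -> list[Landscape]:
    """Bin repeat copies into per-group divergence landscapes.

    Each copy contributes its full ``bp`` to the single bin
    ``[floor(100*k2p), floor(100*k2p)+1)``; saturated copies and copies at
    or beyond 51% go to the overflow bucket.  ``group_by`` is either
    ``"superfamily"`` (requires ``classification`` mapping consensus name ->
    (class, superfamily)) or ``"family"`` (groups by consensus name).
    """
    if denominator_bp <= 0:
        raise ValueError(f"denominator_bp must be positive, got {denominator_bp}")
    if group_by not in ("superfamily", "family"):
        raise ValueError(f"group_by must be 'superfamily' or 'family', got {group_by!r}")

    out: dict = {}
    for copy in copies:
        if group_by == "family":
            key = copy.consensus_name
        else:
            if classification is None or copy.consensus_name not in classification:
                key = ("Unknown", "")
            else:
                key = classification[copy.consensus_name]
        ls = out.get(key)
        if ls is None:
            ls = out[key] = Landscape(key, denominator_bp)
        if copy.k2p is None:
            ls.overflow_bp += copy.bp
            continue
        b = math.floor(copy.k2p * 100.0)
        if b >= N_BINS:
            ls.overflow_bp += copy.bp
        else:
            ls.bp_per_bin[b] += copy.bp
    return [out[k] for k in sorted(out, key=str)]


def recent_accumulation(
    landscapes: Sequence[Landscape], threshold_pct: float = 5.0
) -> list[dict]:
    """Sum bp in divergence bins strictly below ``threshold_pct``.

    The presets mirror the study: 5% for recent copies, 1% for very recent
    copies (those that accumulated during or after race divergence).  Returns
    one row per group with total bp and genome proportion.
    """
    if not (0.0 < threshold_pct <= 50.0):
        raise ValueError(f"threshold_pct must be in (0, 50], got {threshold_pct}")
    # a bin [i, i+1) lies entirely below t iff i+1 <= t, so include floor(t)
    # full bins; a copy at exactly t sits in bin [t, t+1) and is excluded
    n_full = int(math.floor(threshold_pct))
    denominators = {ls.denominator_bp for ls in landscapes}
    if len(denominators) > 1:
        raise ValueError("landscapes must share one denominator")
    rows = []
    for ls in landscapes:
        total = sum(ls.bp_per_bin[:n_full])
        key = ls.group_key
        rows.append(
            {
                "group": "/".join(key) if isinstance(key, tuple) else key,
                "total_bp": total,
                "genome_proportion": total / ls.denominator_bp,
            }
        )
    return rows


def landscape_table(landscapes: Sequence[Landscape]) -> list[dict]:
    """Flatten landscapes to one row per group x bin (TSV-friendly)."""
    rows = []
    for ls in landscapes:
        key = ls.group_key
        name = "/".join(key) if isinstance(key, tuple) else key
        for i, bp in enumerate(ls.bp_per_bin):
            rows.append(
                {
                    "group": name,
                    "bin_lo_pct": i,
                    "bp": bp,
                    "genome_proportion": bp / ls.denominator_bp,
                }
            )
        rows.append(
            {
                "group": name,
                "bin_lo_pct": "overflow",
                "bp": ls.overflow_bp,
                "genome_proportion": ls.overflow_bp / ls.denominator_bp,
            }
        )
    return rows


def plot_landscape(
    landscapes: Sequence[Landscape],
    path: str,
    max_pct: int = 50,
    title: str = "",
) -> None:
    """Stacked-bar divergence landscape (bp share per 1% K2P bin)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    x = np.arange(max_pct)
    bottom = np.zeros(max_pct)
    fig, ax = plt.subplots(figsize=(9, 4))
    for ls in landscapes:
        y = np.array(ls.proportion_per_bin()[:max_pct]) * 100.0
        key = ls.group_key
        name = "/".join(key) if isinstance(key, tuple) else key
        ax.bar(x, y, bottom=bottom, width=0.9, label=name)
        bottom += y
    ax.set_xlabel("K2P distance to consensus (%)")
    ax.set_ylabel("genome proportion (%)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
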