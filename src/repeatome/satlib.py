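"""Cross-sample satellite DNA families and the library hypothesis.

Satellite monomers have arbitrary phase and strand, so all comparisons are
rotation- and reverse-complement-invariant.  Families follow the 80-80-80
homology rule (>=80% identity over >=80% of the shorter monomer, >=80 bp
aligned — relaxed to 0.8x the shorter monomer for short monomers) with
single-linkage merging across samples.  The library hypothesis is assessed
from the resulting presence/absence matrix, the coefficient of variation of
genome proportions across samples (cv > 80% flags differential
amplification), and Kruskal-Wallis tests on divergence profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from scipy import stats

from .formats import revcomp
from .landscape import N_BINS
from .quantify import MaskHit


def canonicalize_monomer(sequence: str) -> str:
    """Lexicographically minimal rotation over the sequence and its reverse
    complement: a phase- and strand-free identifier for a tandem monomer."""
    s = sequence.upper()
    if not s:
        raise ValueError("empty monomer sequence")
    best = None
    for variant in (s, revcomp(s)):
        doubled = variant + variant
        for i in range(len(variant)):
            cand = doubled[i : i + len(variant)]
            if best is None or cand < best:
                best = cand
    return best


@dataclass
class SatMonomer:
    """A satellite monomer consensus from one sample (e.g. VvP24X0-6)."""

    source_sample: str
    local_name: str
    sequence: str
    canonical_form: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 5:
            raise ValueError(f"monomer {self.local_name!r} shorter than 5 bp")
        if not self.canonical_form:
            self.canonical_form = canonicalize_monomer(self.sequence)

    @property
    def qualified_name(self) -> str:
        return f"{self.source_sample}|{self.local_name}"


@dataclass
class HomologyEdge:
    a: str  # qualified names
    b: str
    identity: float
    coverage: float
    aligned_len: int


def pairwise_homology(a: SatMonomer, b: SatMonomer, circular: bool = True) -> HomologyEdge:
    """Best alignment of the shorter monomer against the longer.

    The shorter monomer (and its reverse complement) is aligned end-to-end
    against the longer monomer doubled, so any rotation phase is captured;
    ``circular=False`` disables the doubling (linear redundancy merging).
    Identity is matches over alignment columns; coverage is aligned columns
    over the shorter monomer length.
    """
    if len(a.sequence) < len(b.sequence):
        pairings = [(a, b)]
    elif len(b.sequence) < len(a.sequence):
        pairings = [(b, a)]
    else:
        # equal lengths: evaluate both roles so the edge is symmetric
        pairings = [(a, b), (b, a)]
    best: tuple[float, float, int] | None = None
    for short, long_ in pairings:
        target = long_.sequence + long_.sequence if circular else long_.sequence
        for query in (short.sequence, revcomp(short.sequence)):
            res = edlib.align(query, target, mode="HW", task="path")
            if res["editDistance"] < 0:
                continue
            nice = edlib.getNiceAlignment(res, query, target)
            gq, gt = nice["query_aligned"], nice["target_aligned"]
            matches = sum(1 for x, y in zip(gq, gt) if x == y and x != "-")
            identity = matches / len(gq)
            coverage = min(1.0, len(gq) / len(short.sequence))
            if best is None or (identity, coverage, len(gq)) > best:
                best = (identity, coverage, len(gq))
    if best is None:
        return HomologyEdge(a.qualified_name, b.qualified_name, 0.0, 0.0, 0)
    return HomologyEdge(a.qualified_name, b.qualified_name, best[0], best[1], best[2])


def _edge_passes(
    edge: HomologyEdge,
    shorter_len: int,
    min_identity: float,
    min_coverage: float,
    min_aligned_bp: int,
) -> bool:
    need_bp = min(min_aligned_bp, 0.8 * shorter_len)
    return (
        edge.identity >= min_identity
        and edge.coverage >= min_coverage
        and edge.aligned_len >= need_bp
    )


def cluster_families(
    monomers: Sequence[SatMonomer],
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
    min_aligned_bp: int = 80,
) -> list[list[SatMonomer]]:
    """Single-linkage clustering of monomers under the 80-80-80 rule.

    An edge joins two monomers when identity >= ``min_identity``, coverage >=
    ``min_coverage`` and aligned length >= ``min(min_aligned_bp, 0.8 x
    shorter monomer)``; families are the connected components.  Output order
    is deterministic (by smallest member name) and invariant to input
    permutation, rotation, and reverse complement.
    """
    if not monomers:
        raise ValueError("no monomers to cluster")
    order = sorted(range(len(monomers)), key=lambda i: monomers[i].qualified_name)
    parent = list(range(len(monomers)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ii in range(len(order)):
        for jj in range(ii + 1, len(order)):
            i, j = order[ii], order[jj]
            if find(i) == find(j):
                continue
            mi, mj = monomers[i], monomers[j]
            edge = pairwise_homology(mi, mj, circular=True)
            shorter = min(len(mi.sequence), len(mj.sequence))
            if _edge_passes(edge, shorter, min_identity, min_coverage, min_aligned_bp):
                parent[find(i)] = find(j)

    comps: dict[int, list[SatMonomer]] = {}
    for i in range(len(monomers)):
        comps.setdefault(find(i), []).append(monomers[i])
    clusters = [sorted(c, key=lambda m: m.qualified_name) for c in comps.values()]
    clusters.sort(key=lambda c: c[0].qualified_name)
    return clusters


def call_presence(gp: float, min_gp: float = 1e-5) -> bool:
    """Presence call from genome proportion.

    The default threshold (0.001% of sampled bp) sits below the ~0.01%
    de novo detection limit of read-clustering approaches but above masking
    noise, so low-abundance relic families still register.
    """
    if gp < 0:
        raise ValueError("GP must be non-negative")
    return gp >= min_gp


@dataclass
class FamilyRecord:
    name: str  # satDNA-<k>
    members: list[SatMonomer]
    gp: dict[str, float]  # per sample
    present: dict[str, bool]
    mean_k2p: dict[str, float | None]
    profile: dict[str, np.ndarray]  # per sample, 51-bin bp vector


@dataclass
class LibraryMatrix:
    """Cross-sample satDNA family matrix plus sharing summary."""

    samples: list[str]
    families: list[FamilyRecord]
    totals: dict[str, int] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return len(self.families)

    @property
    def n_shared_all(self) -> int:
        return sum(1 for f in self.families if all(f.present[s] for s in self.samples))

    @property
    def n_not_shared(self) -> int:
        return self.n_total - self.n_shared_all

    def unique_counts(self) -> dict[str, int]:
        """Families present in exactly one sample, per sample."""
        out = {s: 0 for s in self.samples}
        for f in self.families:
            present = [s for s in self.samples if f.present[s]]
            if len(present) == 1:
                out[present[0]] += 1
        return out

    def summary(self) -> dict[str, int]:
        d = {
            "n_total": self.n_total,
            "n_shared_all": self.n_shared_all,
            "n_not_shared": self.n_not_shared,
        }
        for s, n in self.unique_counts().items():
            d[f"unique_{s}"] = n
        return d

    def to_rows(self) -> list[dict]:
        rows = []
        for f in self.families:
            row: dict = {"family": f.name, "members": ",".join(m.qualified_name for m in f.members)}
            for s in self.samples:
                row[f"present_{s}"] = "+" if f.present[s] else "-"
                row[f"GP_{s}"] = f.gp[s]
            rows.append(row)
        return rows


def build_library_matrix(
    clusters: Sequence[Sequence[SatMonomer]],
    hits_per_sample: Mapping[str, Iterable[MaskHit]],
    totals: Mapping[str, int],
    min_gp: float = 1e-5,
) -> LibraryMatrix:
    """Assemble the family x sample matrix from per-sample masking hits.

    Family GP in a sample is the summed masked bp of all member monomers
    divided by the sample's total sampled bp; within-race consensus variants
    that joined one cross-race family therefore pool their abundance.
    Families are named satDNA-1, satDNA-2, ... in descending pooled GP (ties
    by member name).
    """
    samples = list(totals)
    by_monomer: dict[str, int] = {}
    for ci, cluster in enumerate(clusters):
        for m in cluster:
            by_monomer[m.qualified_name] = ci

    n = len(clusters)
    bp = {s: np.zeros(n, dtype=np.int64) for s in samples}
    k2p_wsum = {s: np.zeros(n) for s in samples}
    profiles = {s: np.zeros((n, N_BINS), dtype=np.int64) for s in samples}
    for s in samples:
        for h in hits_per_sample.get(s, []):
            ci = by_monomer.get(h.consensus_name)
            if ci is None:
                raise ValueError(f"hit names unclustered monomer {h.consensus_name!r}")
            bp[s][ci] += h.bp
            if h.k2p is not None:
                k2p_wsum[s][ci] += h.k2p * h.bp
                b = min(int(math.floor(h.k2p * 100.0)), N_BINS - 1)
                profiles[s][ci, b] += h.bp

    pooled_total = sum(totals.values())
    pooled_gp = sum(bp[s] for s in samples) / pooled_total
    cluster_key = [c[0].qualified_name if c else "" for c in
                   [sorted(c, key=lambda m: m.qualified_name) for c in clusters]]
    rank = sorted(range(n), key=lambda i: (-pooled_gp[i], cluster_key[i]))

    families = []
    for out_i, ci in enumerate(rank, start=1):
        gp = {s: bp[s][ci] / totals[s] for s in samples}
        families.append(
            FamilyRecord(
                name=f"satDNA-{out_i}",
                members=sorted(clusters[ci], key=lambda m: m.qualified_name),
                gp=gp,
                present={s: call_presence(gp[s], min_gp) for s in samples},
                mean_k2p={
                    s: (k2p_wsum[s][ci] / bp[s][ci]) if bp[s][ci] > 0 else None
                    for s in samples
                },
                profile={s: profiles[s][ci].copy() for s in samples},
            )
        )
    return LibraryMatrix(samples=samples, families=families, totals=dict(totals))


def coefficient_of_variation(values: Sequence[float], ddof: int = 1) -> float | None:
    """cv = sd / mean x 100 (sample sd by default); None when the mean is 0."""
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean == 0:
        return None
    return float(arr.std(ddof=ddof) / mean * 100.0)


@dataclass
class FamilyStats:
    family: str
    mean_gp: float
    cv: float | None
    differential: bool
    H: float
    p: float


def kw_divergence_test(
    profiles: Sequence[np.ndarray],
    totals: Sequence[int] | None = None,
    permutation: bool = False,
    n_perm: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Kruskal-Wallis test across samples on abundance-by-divergence profiles.

    Groups are samples; observations are the per-bin GP values over the 51
    K2P bins (bp vectors are converted to GP when ``totals`` is given).  Ties
    are corrected; p comes from the chi-square approximation with
    ``n_groups - 1`` df, or from a seeded permutation of group labels when
    ``permutation`` is set.  Identical observations in all groups give
    (H=0, p=1).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two samples")
    groups = []
    for i, prof in enumerate(profiles):
        v = np.asarray(prof, dtype=float)
        if totals is not None:
            v = v / totals[i]
        groups.append(v)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    if permutation:
        rng = np.random.default_rng(seed)
        sizes = [len(g) for g in groups]
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            if np.all(perm == perm[0]):
                hp = 0.0
            else:
                try:
                    hp, _ = stats.kruskal(*parts)
                except ValueError:
                    hp = 0.0
            if hp >= H - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
    return float(H), float(p)


def differential_amplification(
    matrix: LibraryMatrix,
    cv_threshold: float = 80.0,
    ddof: int = 1,
    shared_only: bool = True,
) -> list[FamilyStats]:
    """Flag differentially amplified families (cv of GP across samples > 80%).

    Restricted to families present in all samples by default (the shared
    "library"); cv uses the sample standard deviation (ddof=1).  The
    Kruskal-Wallis statistic compares each family's divergence profiles
    across samples.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least two samples")
    out = []
    for fam in matrix.families:
        if shared_only and not all(fam.present[s] for s in matrix.samples):
            continue
        gps = [fam.gp[s] for s in matrix.samples]
        cv = coefficient_of_variation(gps, ddof=ddof)
        if cv is None:
            continue  # mean GP 0: cv undefined, excluded
        H, p = kw_divergence_test(
            [fam.profile[s] for s in matrix.samples],
            totals=[matrix.totals[s] for s in matrix.samples] if matrix.totals else None,
        )
        out.append(
            FamilyStats(
                family=fam.name,
                mean_gp=float(np.mean(gps)),
                cv=cv,
                differential=cv > cv_threshold,
                H=H,
                p=p,
            )
        )
    return out
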