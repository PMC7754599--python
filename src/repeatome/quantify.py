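"""Read-based repeat quantification.

Mirrors the read-based estimation of repeat abundance used for grasshopper
repeatomes: subsample read pairs, mask them against a combined repeat
library, and report genome proportions (GP, masked bp / total sampled bp)
per family with roll-ups to superfamily and class.

The masker is a seed-and-extend homology search: k-mer seeds grouped by
diagonal, ungapped extension (match +1 / mismatch -1) to the best-scoring
segment, adjacent-diagonal merging refined by a gapped (edit-distance)
realignment, and best-score-per-base overlap resolution.  It trades the
sensitivity machinery of a production masker for determinism and speed at
simulation scale; externally produced RepeatMasker annotations can be
supplied instead for genome-scale runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .formats import RepeatConsensus, SequenceRecord, revcomp
from .landscape import count_substitutions, k2p_distance

log = logging.getLogger(__name__)

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lower case


def encode(seq: str) -> np.ndarray:
    """Encode DNA as uint8 codes A=0 C=1 G=2 T=3, 255 for anything else."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling k-mer integer codes; -1 where the window contains a non-ACGT base."""
    n = codes.shape[-1]
    if n < k:
        return np.full(codes.shape[:-1] + (0,), -1, dtype=np.int64)
    out = np.zeros(codes.shape[:-1] + (n - k + 1,), dtype=np.int64)
    bad = np.zeros(out.shape, dtype=bool)
    for j in range(k):
        window = codes[..., j : n - k + 1 + j]
        out = out * 4 + window
        bad |= window > 3
    out[bad] = -1
    return out


@dataclass
class MaskHit:
    """One resolved repeat hit on a read (0-based half-open read interval)."""

    read_id: str
    start: int
    end: int
    strand: str
    consensus_name: str
    identity: float
    score: int
    k2p: float | None

    @property
    def bp(self) -> int:
        return self.end - self.start


class _Target:
    """One oriented library sequence prepared for seeding/extension."""

    __slots__ = ("name", "strand", "codes")

    def __init__(self, name: str, strand: str, seq: str):
        self.name = name
        self.strand = strand
        self.codes = encode(seq)


class RepeatMasker:
    """Seed-and-extend masker over a repeat library.

    Tandem-repeat monomers (``is_monomer``) are expanded to concatemers of at
    least ``max(2 * monomer, 400)`` bp so that any read phase aligns on a
    single diagonal, mirroring the dimer/concatemer masking references used
    for satDNA read mapping.
    """

    def __init__(
        self,
        library: Sequence[RepeatConsensus],
        min_identity: float = 0.7,
        min_hit_bp: int = 30,
        seed_kmer: int = 11,
    ):
        if not library:
            raise ValueError("repeat library is empty")
        self.min_identity = min_identity
        self.min_hit_bp = min_hit_bp
        self.k = seed_kmer
        self.targets: list[_Target] = []
        self.index: dict[int, list[tuple[int, int]]] = {}
        for cons in library:
            seq = cons.sequence.upper()
            if cons.is_monomer:
                n_copies = max(2, -(-400 // len(seq)))
                seq = seq * n_copies
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                tid = len(self.targets)
                self.targets.append(_Target(cons.name, strand, s))
                for pos, code in enumerate(_kmer_codes(encode(s), self.k)):
                    if code >= 0:
                        self.index.setdefault(int(code), []).append((tid, pos))
        self._lib_codes = np.fromiter(self.index.keys(), dtype=np.int64)
        self._lib_codes.sort()

    # -- per-read machinery ---------------------------------------------------

    def _seed_groups(self, kmers: np.ndarray, hit_pos: np.ndarray | None = None):
        """Group seed matches by (target, diagonal)."""
        if hit_pos is None:
            hit_pos = np.nonzero(np.isin(kmers, self._lib_codes, kind="sort"))[0]
        groups: dict[tuple[int, int], list[int]] = {}
        for p in hit_pos:
            for tid, tpos in self.index[int(kmers[p])]:
                diag = int(p) - tpos
                groups.setdefault((tid, diag), []).append(int(p))
        return groups

    def _extend(self, read_codes: np.ndarray, tid: int, diag: int):
        """Best-scoring ungapped segment on one diagonal (Kadane on +1/-1)."""
        tcodes = self.targets[tid].codes
        r0 = max(0, diag)
        r1 = min(len(read_codes), diag + len(tcodes))
        if r1 - r0 < self.min_hit_bp:
            return None
        a = read_codes[r0:r1]
        b = tcodes[r0 - diag : r1 - diag]
        eq = (a == b) & (a <= 3)
        scores = np.where(eq, 1, -1).astype(np.int64)
        prefix = np.concatenate(([0], np.cumsum(scores)))
        runmin = np.minimum.accumulate(prefix[:-1])
        gains = prefix[1:] - runmin
        score = int(gains.max())
        # among max-score segments take the longest (ties resolved toward the
        # earliest strict running-minimum start), keeping masked bp invariant
        # under reverse complementation of the read
        strict_new_min = prefix[:-1] < np.concatenate(([np.iinfo(np.int64).max], runmin[:-1]))
        start_idx = np.maximum.accumulate(np.where(strict_new_min, np.arange(len(runmin)), 0))
        js = np.nonzero(gains == score)[0]
        lengths = js + 1 - start_idx[js]
        jj = int(js[np.argmax(lengths)])
        i = int(start_idx[jj])
        j = jj
        seg_eq = eq[i : j + 1]
        length = j + 1 - i
        if length < self.min_hit_bp:
            return None
        identity = float(np.mean(seg_eq))
        if identity < self.min_identity:
            return None
        return (r0 + i, r0 + j + 1, score, identity, seg_eq, a[i : j + 1], b[i : j + 1])

    @staticmethod
    def _k2p_from_codes(a: np.ndarray, b: np.ndarray) -> float | None:
        valid = (a <= 3) & (b <= 3)
        n = int(valid.sum())
        if n == 0:
            return None
        diff = valid & (a != b)
        ts = int((diff & (np.abs(a.astype(np.int16) - b) == 2)).sum())
        tv = int(diff.sum()) - ts
        from .formats import SubstitutionCounts

        return k2p_distance(SubstitutionCounts(ts / n, tv / n, n))

    def mask_read(self, read: SequenceRecord) -> list[MaskHit]:
        if not read.residues:
            log.info("skipping empty sequence %s", read.id)
            return []
        codes = encode(read.residues)
        kmers = _kmer_codes(codes, self.k)
        return self._mask_coded(read.id, codes, kmers)

    def _mask_coded(
        self,
        read_id: str,
        codes: np.ndarray,
        kmers: np.ndarray,
        hit_pos: np.ndarray | None = None,
    ) -> list[MaskHit]:
        groups = self._seed_groups(kmers, hit_pos)
        raw: list[tuple] = []
        for (tid, diag), _seeds in groups.items():
            ext = self._extend(codes, tid, diag)
            if ext is not None:
                raw.append((tid, diag) + ext)
        raw = self._merge_adjacent(codes, raw)
        hits = [
            MaskHit(
                read_id,
                start,
                end,
                self.targets[tid].strand,
                self.targets[tid].name,
                identity,
                score,
                self._k2p_from_codes(acodes, bcodes),
            )
            for tid, _diag, start, end, score, identity, _eq, acodes, bcodes in raw
        ]
        return resolve_overlaps(hits, self.min_hit_bp)

    def _merge_adjacent(self, read_codes: np.ndarray, raw: list[tuple]) -> list[tuple]:
        """Merge same-target hits on nearby diagonals (small indels) and
        realign the merged read interval with a gapped aligner."""
        by_tid: dict[int, list[tuple]] = {}
        for item in raw:
            by_tid.setdefault(item[0], []).append(item)
        merged: list[tuple] = []
        for tid, items in by_tid.items():
            items.sort(key=lambda it: it[2])
            cur = items[0]
            for nxt in items[1:]:
                gap = nxt[2] - cur[3]
                joined = None
                if abs(nxt[1] - cur[1]) <= 10 and -10 <= gap <= 5:
                    joined = self._gapped_merge(read_codes, tid, cur, nxt)
                if joined is not None:
                    cur = joined
                else:
                    merged.append(cur)
                    cur = nxt
            merged.append(cur)
        return merged

    def _gapped_merge(self, read_codes: np.ndarray, tid: int, a: tuple, b: tuple):
        tcodes = self.targets[tid].codes
        r0, r1 = a[2], b[3]
        t0 = max(0, r0 - a[1] - 5)
        t1 = min(len(tcodes), r1 - b[1] + 5)
        if r1 - r0 < self.min_hit_bp or t1 <= t0:
            return None
        query = _decode(read_codes[r0:r1])
        target = _decode(tcodes[t0:t1])
        res = edlib.align(query, target, mode="HW", task="path")
        if res["editDistance"] < 0:
            return None
        nice = edlib.getNiceAlignment(res, query, target)
        gq, gt = nice["query_aligned"], nice["target_aligned"]
        matches = sum(1 for x, y in zip(gq, gt) if x == y and x != "-")
        identity = matches / len(gq)
        if identity < self.min_identity:
            return None
        subst = count_substitutions(gq, gt)
        k2p = k2p_distance(subst)
        score = matches - (len(gq) - matches)
        aeq = np.zeros(0, dtype=bool)
        acodes = encode(gq.replace("-", ""))
        bcodes = encode(gt.replace("-", ""))[: len(acodes)]
        if len(bcodes) < len(acodes):
            bcodes = np.pad(bcodes, (0, len(acodes) - len(bcodes)), constant_values=255)
        return (tid, a[1], r0, r1, score, identity, aeq, acodes, bcodes)

    # -- batch path -----------------------------------------------------------

    def mask_sequences(self, sequences: Sequence[SequenceRecord]) -> list[MaskHit]:
        """Mask a batch of sequences; equal-length batches take a fast path."""
        nonempty = []
        for rec in sequences:
            if rec.residues:
                nonempty.append(rec)
            else:
                log.info("skipping empty sequence %s", rec.id)
        if not nonempty:
            return []
        lengths = {len(r.residues) for r in nonempty}
        hits: list[MaskHit] = []
        if len(lengths) == 1 and len(nonempty) > 1:
            chunk = 32768  # bounds the (reads x positions) kmer matrix
            for lo in range(0, len(nonempty), chunk):
                block = nonempty[lo : lo + chunk]
                mat = np.vstack([encode(r.residues) for r in block])
                kmat = _kmer_codes(mat, self.k)
                cand = np.isin(kmat, self._lib_codes, kind="sort")
                for i in np.nonzero(cand.any(axis=1))[0]:
                    hits.extend(
                        self._mask_coded(
                            block[i].id, mat[i], kmat[i], np.nonzero(cand[i])[0]
                        )
                    )
        else:
            for rec in nonempty:
                hits.extend(self.mask_read(rec))
        return hits


def _decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[min(int(c), 4)] for c in codes)


def resolve_overlaps(hits: list[MaskHit], min_hit_bp: int = 30) -> list[MaskHit]:
    """Keep the best-scoring hit per read base.

    Hits are taken in order of score, then length, then consensus name; each
    is trimmed to its longest run of still-unclaimed bases and dropped if the
    run falls below both ``min_hit_bp`` and half its original span.
    """
    if len(hits) <= 1:
        return list(hits)
    hits = sorted(hits, key=lambda h: (-h.score, -(h.end - h.start), h.consensus_name))
    span = max(h.end for h in hits)
    taken = np.zeros(span, dtype=bool)
    kept: list[MaskHit] = []
    for h in hits:
        free = ~taken[h.start : h.end]
        n_free = int(free.sum())
        if n_free == 0:
            continue
        # longest free run within the hit interval
        padded = np.concatenate(([False], free, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        runs = ends - starts
        best = int(np.argmax(runs))
        run_len = int(runs[best])
        if run_len < min(min_hit_bp, max(1, (h.end - h.start) // 2)):
            continue
        s, e = h.start + int(starts[best]), h.start + int(ends[best])
        taken[s:e] = True
        kept.append(
            MaskHit(h.read_id, s, e, h.strand, h.consensus_name, h.identity, h.score, h.k2p)
        )
    kept.sort(key=lambda h: (h.read_id, h.start))
    return kept


def mask_sequences(
    sequences: Sequence[SequenceRecord],
    library: Sequence[RepeatConsensus],
    min_identity: float = 0.7,
    min_hit_bp: int = 30,
    seed_kmer: int = 11,
) -> list[MaskHit]:
    """Convenience wrapper: build a :class:`RepeatMasker` and mask ``sequences``."""
    masker = RepeatMasker(library, min_identity, min_hit_bp, seed_kmer)
    return masker.mask_sequences(sequences)


def sample_read_pairs(
    reads1: Sequence[SequenceRecord],
    reads2: Sequence[SequenceRecord],
    n_pairs: int,
    seed: int,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Uniform sample of read pairs without replacement (mate pairing kept).

    ``n_pairs`` of 4,000,000 mirrors the study's per-library subsample; desk
    runs use far fewer.
    """
    if len(reads1) != len(reads2):
        raise ValueError("read files have different numbers of reads")
    available = len(reads1)
    if n_pairs > available:
        raise ValueError(f"requested {n_pairs} pairs but only {available} available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(available, size=n_pairs, replace=False)
    return [reads1[i] for i in idx], [reads2[i] for i in idx]


def summarize_genome_proportion(
    hits: Iterable[MaskHit],
    total_sampled_bp: int,
    classification: dict[str, tuple[str, str]],
) -> list[dict]:
    """Per-family masked bp and GP with superfamily/class/Total roll-ups.

    Returns rows with keys ``level`` (family, superfamily, class, total),
    ``name``, ``masked_bp`` and ``GP``; class rows sum their members exactly
    and the Total row sums the classes.
    """
    if total_sampled_bp <= 0:
        raise ValueError("total_sampled_bp must be positive")
    fam_bp: dict[str, int] = {}
    for h in hits:
        if h.consensus_name not in classification:
            raise ValueError(f"hit names unknown consensus {h.consensus_name!r}")
        fam_bp[h.consensus_name] = fam_bp.get(h.consensus_name, 0) + h.bp
    sup_bp: dict[tuple[str, str], int] = {}
    cls_bp: dict[str, int] = {}
    for name, bp in fam_bp.items():
        cls, sup = classification[name]
        sup_bp[(cls, sup)] = sup_bp.get((cls, sup), 0) + bp
        cls_bp[cls] = cls_bp.get(cls, 0) + bp
    rows = []
    for name in sorted(fam_bp):
        rows.append(_row("family", name, fam_bp[name], total_sampled_bp))
    for (cls, sup) in sorted(sup_bp):
        rows.append(_row("superfamily", f"{cls}/{sup}" if sup else cls, sup_bp[(cls, sup)], total_sampled_bp))
    for cls in sorted(cls_bp):
        rows.append(_row("class", cls, cls_bp[cls], total_sampled_bp))
    rows.append(_row("total", "Total", sum(cls_bp.values()), total_sampled_bp))
    return rows


def _row(level: str, name: str, bp: int, denom: int) -> dict:
    return {"level": level, "name": name, "masked_bp": bp, "GP": bp / denom}
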