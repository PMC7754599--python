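"""Tandem-repeat structure: monomer period, arrays, HORs, dotplots, naming.

A tandem array is characterized by its fundamental monomer period (the
smallest self-alignment lag with high identity), the maximum number of
consecutive monomer copies per contig, and an optional higher-order repeat
(HOR) multiple — a super-period formed by a recurring block of divergent
monomer variants, visible as a stronger self-identity at an integer multiple
of the fundamental lag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .formats import RepeatConsensus, SequenceRecord
from .quantify import RepeatMasker, encode
from .satlib import SatMonomer, pairwise_homology


@dataclass
class TandemArray:
    contig_id: str
    monomer_len: int
    n_copies: int
    hor_multiple: int = 1


def _lag_identity(codes: np.ndarray, lag: int) -> float:
    a, b = codes[:-lag], codes[lag:]
    valid = (a <= 3) & (b <= 3)
    n = int(valid.sum())
    if n == 0:
        return 0.0
    return float((valid & (a == b)).sum() / n)


def estimate_monomer_period(
    sequence: str,
    min_period: int = 5,
    max_period: int = 2000,
    min_identity: float = 0.7,
) -> tuple[int, float] | None:
    """Fundamental tandem period by self-alignment lag identity.

    Returns the smallest lag whose mean per-position identity between the
    sequence and itself shifted by the lag reaches ``min_identity`` (with its
    identity score), or ``None`` when no lag qualifies.  The smallest
    qualifying lag is the fundamental period even when a HOR super-period
    scores higher; see :func:`detect_hor`.
    """
    if len(sequence) < 2 * min_period:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than 2 x min_period {min_period}"
        )
    codes = encode(sequence.upper())
    hi = min(max_period, len(sequence) // 2)
    for lag in range(min_period, hi + 1):
        ident = _lag_identity(codes, lag)
        if ident >= min_identity:
            return lag, ident
    return None


def detect_hor(sequence: str, period: int, delta: float = 0.05, max_multiple: int = 12) -> int:
    """Smallest integer multiple of ``period`` whose lag identity exceeds the
    fundamental's by at least ``delta`` (HOR super-period); 1 when none."""
    codes = encode(sequence.upper())
    base = _lag_identity(codes, period)
    for m in range(2, max_multiple + 1):
        lag = m * period
        if lag > len(sequence) // 2:
            break
        if _lag_identity(codes, lag) >= base + delta:
            return m
    return 1


def count_tandem_array(
    contig: SequenceRecord,
    monomer: SatMonomer,
    min_identity: float = 0.8,
) -> TandemArray:
    """Maximum run of consecutive monomer copies on a contig.

    The contig is tiled with best-phase monomer alignments (strand-aware,
    phase re-estimated via a concatemer reference, so the result is invariant
    to rotating the monomer).  Hits separated by gaps of at most 0.2 x the
    monomer length form a run; copies per run are counted as full monomer
    spans, with a terminal partial copy counted iff at least half the monomer
    aligns.  A contig without the monomer yields ``n_copies=0``.
    """
    m = len(monomer.sequence)
    ref = RepeatConsensus(
        name=monomer.qualified_name,
        repeat_class="TR",
        superfamily="satDNA",
        sequence=monomer.sequence,
        is_monomer=True,
    )
    masker = RepeatMasker(
        [ref],
        min_identity=min_identity,
        min_hit_bp=min(max(10, m // 2), 30),
        seed_kmer=min(11, max(5, m // 2)),
    )
    hits = sorted(masker.mask_read(contig), key=lambda h: h.start)
    if not hits:
        return TandemArray(contig.id, m, 0, 1)

    max_gap = 0.2 * m
    best_len = 0
    best_span: tuple[int, int] | None = None
    run_start, run_end = hits[0].start, hits[0].end
    for h in hits[1:]:
        if h.start - run_end <= max_gap:
            run_end = max(run_end, h.end)
        else:
            if run_end - run_start > best_len:
                best_len, best_span = run_end - run_start, (run_start, run_end)
            run_start, run_end = h.start, h.end
    if run_end - run_start > best_len:
        best_len, best_span = run_end - run_start, (run_start, run_end)

    full, rem = divmod(best_len, m)
    n_copies = full + (1 if rem >= 0.5 * m else 0)
    hor = 1
    if n_copies >= 4 and best_span is not None:
        region = contig.residues[best_span[0] : best_span[1]]
        hor = detect_hor(region, m)
    return TandemArray(contig.id, m, max(n_copies, 1 if best_len else 0), hor)


def dotplot_matrix(
    a: str, b: str, window: int = 10, min_matches: int = 8
) -> np.ndarray:
    """Boolean dotplot: cell (i, j) is true when the ``window``-length words
    at a[i:] and b[j:] match in at least ``min_matches`` positions."""
    if window < min_matches:
        raise ValueError("window must be >= min_matches")
    if window > min(len(a), len(b)):
        raise ValueError("window exceeds sequence length")
    ca, cb = encode(a.upper()), encode(b.upper())
    na, nb = len(a) - window + 1, len(b) - window + 1
    counts = np.zeros((na, nb), dtype=np.int16)
    for w in range(window):
        counts += (ca[w : w + na, None] == cb[None, w : w + nb]) & (
            ca[w : w + na, None] <= 3
        )
    return counts >= min_matches


def build_masking_reference(monomer: SatMonomer, target_len: int = 150) -> str:
    """Concatemer masking reference: at least a dimer, and for short monomers
    enough copies to reach roughly ``target_len`` bp of array."""
    m = len(monomer.sequence)
    k = max(2, math.ceil(target_len / m))
    return monomer.sequence * k


def classify_and_name_tr(
    monomers: Sequence[SatMonomer],
    seed_db: Sequence[tuple[str, str]],
    sample_label: str,
    gps: Sequence[float],
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
) -> list[tuple[str, str]]:
    """Classify tandem repeats against labeled seeds and name the satDNAs.

    ``seed_db`` is a list of (label, sequence) references — the insect
    telomere repeat (TTAGG)n, rRNA/snRNA/histone multigene seeds, etc.  A
    monomer matching a seed at >= 80% identity and coverage takes the seed's
    label; the rest are satDNAs named ``Vv<sample>-<rank>`` in descending
    genome proportion (ties by monomer name).

    Returns (name, label) per monomer, in input order.
    """
    if len(monomers) != len(gps):
        raise ValueError("monomers and gps length mismatch")
    labels = []
    for mono in monomers:
        label = "satDNA"
        best_ident = 0.0
        for seed_label, seed_seq in seed_db:
            seed = SatMonomer("seed", seed_label, seed_seq)
            edge = pairwise_homology(mono, seed, circular=True)
            if (
                edge.identity >= min_identity
                and edge.coverage >= min_coverage
                and edge.identity > best_ident
            ):
                label = seed_label
                best_ident = edge.identity
        labels.append(label)

    sat_idx = [i for i, lab in enumerate(labels) if lab == "satDNA"]
    sat_idx.sort(key=lambda i: (-gps[i], monomers[i].local_name))
    names: dict[int, str] = {}
    for rank, i in enumerate(sat_idx, start=1):
        names[i] = f"Vv{sample_label}-{rank}"
    out = []
    for i, mono in enumerate(monomers):
        name = names.get(i, f"{labels[i]}_{mono.local_name}")
        out.append((name, labels[i]))
    assert len({n for n, _ in out}) == len(out), "duplicate output names"
    return out
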