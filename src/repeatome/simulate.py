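"""Ground-truthed synthetic repeatomes.

Generates the statistical structure the comparative analysis assumes: a
shared ancestral library of TE consensus sequences and satDNA monomers,
per-race copy proliferation with controlled K2P divergence and
transition/transversion bias, tandem arrays with optional higher-order
structure, differential per-race amplification, and 150 bp paired-end
reads.  Every planted copy is recorded in a truth table so parameter
recovery can be tested end to end.

The substitution process is the K2P model itself: each site mutates at most
once, to a transition with odds kappa : 1 over a transversion, with the
per-site probabilities solved so the expected K2P distance equals the
requested target.  Concerted evolution is modeled only as low intra-race
divergence of satDNA copies; there is no rate heterogeneity across sites
and no sequencing error by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .formats import RepeatConsensus, SequenceRecord, revcomp
from .landscape import count_substitutions, k2p_distance
from .satlib import SatMonomer

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def solve_site_rates(target_k2p: float, kappa: float) -> tuple[float, float]:
    """Per-site transition (p_ts) and transversion (p_tv) probabilities whose
    expected K2P distance equals ``target_k2p``, with p_ts = kappa x p_tv."""
    if target_k2p < 0:
        raise ValueError("target K2P must be non-negative")
    if target_k2p == 0:
        return 0.0, 0.0
    if target_k2p >= 0.45:
        raise ValueError(f"target K2P {target_k2p} is beyond the saturation guard (0.45)")
    if kappa <= 0:
        raise ValueError("kappa must be positive")

    def f(q: float) -> float:
        p = kappa * q
        return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q) - target_k2p

    q_max = (1.0 / (2 * kappa + 1)) * (1 - 1e-9)
    q_max = min(q_max, 0.5 * (1 - 1e-9))
    q = brentq(f, 1e-15, q_max)
    return kappa * q, q


def mutate_codes(
    codes: np.ndarray,
    p_ts: float,
    p_tv: float,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
) -> np.ndarray:
    """Apply one round of per-site substitutions (and optional 1 bp indels).

    Transitions are code XOR 2 (A<->G, C<->T); the two transversion targets
    are code XOR 1 and XOR 3, chosen uniformly.
    """
    r = rng.random(len(codes))
    ts = r < p_ts
    tv = (r >= p_ts) & (r < p_ts + p_tv)
    flip = np.zeros(len(codes), dtype=np.uint8)
    flip[ts] = 2
    tv_choice = rng.random(int(tv.sum())) < 0.5
    flip[tv] = np.where(tv_choice, 1, 3)
    out = codes ^ flip
    if indel_rate > 0:
        keep = rng.random(len(out)) >= indel_rate / 2
        out = out[keep]
        n_ins = rng.binomial(len(codes), indel_rate / 2)
        if n_ins:
            pos = np.sort(rng.integers(0, len(out) + 1, size=n_ins))
            out = np.insert(out, pos, rng.integers(0, 4, size=n_ins, dtype=np.uint8))
    return out


def evolve_copies(
    consensus: str,
    n_copies: int,
    target_k2p: float,
    kappa: float = 2.0,
    indel_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[list[str], list[float | None]]:
    """Mutated copies of a consensus with known expected K2P.

    Returns the copies and their realized K2P distances, recomputed through
    the same substitution-counting route the analysis uses (a closed loop:
    generator and estimator share only the K2P formula).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p_ts, p_tv = solve_site_rates(target_k2p, kappa)
    codes = _encode(consensus)
    copies, realized = [], []
    for _ in range(n_copies):
        mut = mutate_codes(codes, p_ts, p_tv, rng, indel_rate)
        seq = _decode(mut)
        copies.append(seq)
        if indel_rate == 0:
            realized.append(k2p_distance(count_substitutions(seq, consensus)))
        else:
            # an equal-length copy can still hide a deletion+insertion pair,
            # so always realign when indels are possible
            realized.append(_aligned_k2p(seq, consensus))
    return copies, realized


def _aligned_k2p(a: str, b: str) -> float | None:
    import edlib

    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    return k2p_distance(count_substitutions(nice["query_aligned"], nice["target_aligned"]))


# --- configuration and truth -------------------------------------------------

@dataclass
class SatFamilyConfig:
    """Per-family simulation parameters."""

    name: str
    monomer_len: int
    target_gp: float  # of genome_len, before amplification
    divergence: float  # mean K2P of copies from the race consensus
    present_in: tuple[int, ...]  # race indices
    fold_per_race: dict[int, float] = field(default_factory=dict)
    hor_multiple: int = 1
    array_copies: int = 30  # monomer copies per planted array


@dataclass
class SimConfig:
    """Study-shaped defaults: four races, 150 bp paired reads, kappa 2.

    ``monomer_len_range`` spans the printed monomer range of the study
    system (7-1740 bp); desk-scale runs draw from a narrower slice via
    ``sat_families``.
    """

    seed: int = 0
    n_races: int = 4
    n_te_families: int = 0
    n_sat_families: int = 12
    monomer_len_range: tuple[int, int] = (7, 1740)
    te_len_range: tuple[int, int] = (400, 3000)
    te_target_gp: float = 0.02
    te_divergence: float = 0.08
    kappa: float = 2.0
    indel_rate: float = 0.0
    shared_fraction: float = 0.75
    race_consensus_divergence: float = 0.02
    genome_len: int = 1_000_000
    read_len: int = 150
    n_pairs: int = 50_000
    insert_mean: int = 400
    insert_sd: int = 25
    error_rate: float = 0.0
    sat_families: list[SatFamilyConfig] | None = None

    def race_names(self) -> list[str]:
        return [f"race{i + 1}" for i in range(self.n_races)]


@dataclass
class PlantedCopy:
    race: str
    family: str
    start: int
    end: int
    strand: str
    realized_k2p: float | None
    copy_index: int = 0
    array_id: int = -1
    hor_multiple: int = 1


@dataclass
class SyntheticTruth:
    copies: list[PlantedCopy] = field(default_factory=list)
    planted_gp: dict[tuple[str, str], float] = field(default_factory=dict)  # (race, family)
    presence: dict[tuple[str, str], bool] = field(default_factory=dict)

    def family_bp(self, race: str, family: str) -> int:
        return sum(c.end - c.start for c in self.copies if c.race == race and c.family == family)


@dataclass
class RaceData:
    name: str
    genome: SequenceRecord
    reads1: list[SequenceRecord]
    reads2: list[SequenceRecord]
    monomers: list[SatMonomer]  # race-level satDNA consensus variants


# --- library and genome assembly ---------------------------------------------

def default_sat_families(config: SimConfig, rng: np.random.Generator) -> list[SatFamilyConfig]:
    """Family layout used by the closed-loop recovery experiments.

    ``shared_fraction`` of families are present in all races; the remainder
    alternate between absent-in-one-race and private-to-one-race patterns.
    Family 1 is amplified 5-fold in race 1 at 2% divergence (the planted
    differential-amplification signal); the other families draw divergence
    uniformly in [2%, 12%].
    """
    n = config.n_sat_families
    n_shared = int(round(config.shared_fraction * n))
    lo, hi = config.monomer_len_range
    fams = []
    for i in range(n):
        if i < n_shared:
            present = tuple(range(config.n_races))
        else:
            j = i - n_shared
            race = j % config.n_races
            if j % 2 == 0:
                present = tuple(r for r in range(config.n_races) if r != race)
            else:
                present = (race,)
        fams.append(
            SatFamilyConfig(
                name=f"satfam{i + 1}",
                monomer_len=int(rng.integers(lo, hi + 1)),
                target_gp=0.004,
                divergence=0.02 if i == 0 else float(rng.uniform(0.02, 0.12)),
                present_in=present,
                fold_per_race={0: 5.0} if i == 0 else {},
            )
        )
    return fams


def generate_repeat_library(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[RepeatConsensus], list[SatFamilyConfig]]:
    """Ancestral library: i.i.d. random TE consensus and satDNA monomers."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.monomer_len_range
    if lo < 5 or hi < lo:
        raise ValueError(f"invalid monomer_len_range {config.monomer_len_range}")
    sat_configs = config.sat_families or default_sat_families(config, rng)
    library = []
    for fam in sat_configs:
        library.append(
            RepeatConsensus(
                name=fam.name,
                repeat_class="TR",
                superfamily="satDNA",
                sequence=_decode(_random_seq_codes(rng, fam.monomer_len)),
                is_monomer=True,
            )
        )
    tlo, thi = config.te_len_range
    for i in range(config.n_te_families):
        library.append(
            RepeatConsensus(
                name=f"tefam{i + 1}",
                repeat_class="DNA",
                superfamily="TcMar",
                sequence=_decode(_random_seq_codes(rng, int(rng.integers(tlo, thi + 1)))),
                is_monomer=False,
            )
        )
    return library, sat_configs


def assemble_genome(
    config: SimConfig,
    race_index: int,
    library: Sequence[RepeatConsensus],
    sat_configs: Sequence[SatFamilyConfig],
    rng: np.random.Generator,
    truth: SyntheticTruth,
) -> tuple[SequenceRecord, list[SatMonomer]]:
    """One race genome: random background with planted arrays and TE copies.

    satDNA copies are placed as tandem arrays of per-copy mutated monomers
    (optionally interleaving two variant monomers as a HOR block); TE copies
    are dispersed at uniform non-overlapping positions on random strands.
    Returns the genome and the race-level monomer consensus variants (the
    sequences a per-race repeat-discovery step would report).
    """
    race = config.race_names()[race_index]
    genome = _random_seq_codes(rng, config.genome_len)
    claimed = np.zeros(config.genome_len, dtype=bool)
    monomers: list[SatMonomer] = []
    sat_by_name = {c.name: c for c in library if c.is_monomer}
    te_by_name = {c.name: c for c in library if not c.is_monomer}

    segments: list[tuple[str, list[tuple[str, float | None]], int, int]] = []
    # (family, [(copy_seq, realized_k2p)...], array_id, hor_multiple)
    array_id = 0
    for fam in sat_configs:
        ancestral = sat_by_name[fam.name].sequence
        (race_cons,), _ = evolve_copies(
            ancestral, 1, config.race_consensus_divergence, config.kappa, 0.0, rng=rng
        )
        present = race_index in fam.present_in
        truth.presence[(race, fam.name)] = present
        if present:
            monomers.append(SatMonomer(race, fam.name, race_cons))
        fold = fam.fold_per_race.get(race_index, 1.0)
        gp = fam.target_gp * fold if present else 0.0
        if not present:
            truth.planted_gp[(race, fam.name)] = 0.0
            continue
        variants = [race_cons]
        if fam.hor_multiple > 1:
            for _ in range(fam.hor_multiple - 1):
                (v,), _ = evolve_copies(race_cons, 1, 0.10, config.kappa, 0.0, rng=rng)
                variants.append(v)
        n_copies_total = max(4, int(round(gp * config.genome_len / fam.monomer_len)))
        placed = 0
        while placed < n_copies_total:
            n_arr = min(fam.array_copies, n_copies_total - placed)
            copies: list[tuple[str, float | None]] = []
            for ci in range(n_arr):
                base = variants[ci % len(variants)]
                (seq,), (rk,) = evolve_copies(
                    base, 1, fam.divergence, config.kappa, config.indel_rate, rng=rng
                )
                copies.append((seq, rk))
            segments.append((fam.name, copies, array_id, fam.hor_multiple))
            array_id += 1
            placed += n_arr

    for te_name, cons in te_by_name.items():
        n_copies = int(round(config.te_target_gp * config.genome_len / len(cons.sequence)))
        seqs, rks = evolve_copies(
            cons.sequence, n_copies, config.te_divergence, config.kappa, config.indel_rate, rng=rng
        )
        for seq, rk in zip(seqs, rks):
            segments.append((te_name, [(seq, rk)], -1, 1))

    total_planted = sum(sum(len(s) for s, _ in copies) for _, copies, _, _ in segments)
    if total_planted > 0.9 * config.genome_len:
        raise ValueError(
            f"planted bp {total_planted} exceeds 90% of genome_len; increase genome_len"
        )

    order = rng.permutation(len(segments))
    segments = [segments[i] for i in order]
    for family, copies, arr_id, hor in segments:
        seg = "".join(s for s, _ in copies)
        strand = "+" if rng.random() < 0.5 else "-"
        placed_seq = seg if strand == "+" else revcomp(seg)
        start = _place(rng, claimed, len(placed_seq), config.genome_len)
        genome[start : start + len(placed_seq)] = _encode(placed_seq)
        offset = start
        # on the minus strand the last copy of the array comes first in
        # genome coordinates
        ordered = copies if strand == "+" else list(reversed(copies))
        for ci, (seq, rk) in enumerate(ordered):
            truth.copies.append(
                PlantedCopy(
                    race=race,
                    family=family,
                    start=offset,
                    end=offset + len(seq),
                    strand=strand,
                    realized_k2p=rk,
                    copy_index=ci,
                    array_id=arr_id,
                    hor_multiple=hor,
                )
            )
            offset += len(seq)

    for fam in sat_configs:
        truth.planted_gp[(race, fam.name)] = (
            truth.family_bp(race, fam.name) / config.genome_len
        )
    return SequenceRecord(race, "synthetic genome", _decode(genome)), monomers


def _place(
    rng: np.random.Generator, claimed: np.ndarray, length: int, genome_len: int, retries: int = 200
) -> int:
    if length > genome_len:
        raise ValueError("segment longer than genome")
    for _ in range(retries):
        start = int(rng.integers(0, genome_len - length + 1))
        if not claimed[start : start + length].any():
            claimed[start : start + length] = True
            return start
    raise ValueError("placement failed after bounded retries; increase genome_len")


def simulate_reads(
    genome: SequenceRecord,
    n_pairs: int,
    read_len: int = 150,
    insert_mean: int = 400,
    insert_sd: int = 25,
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Uniform paired-end reads (second mate reverse-complemented)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    L = len(genome.residues)
    if L < max(insert_mean, 2 * read_len):
        raise ValueError("genome shorter than the insert size")
    inserts = np.clip(
        np.round(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int),
        2 * read_len,
        L,
    )
    starts = (rng.random(n_pairs) * (L - inserts + 1)).astype(int)
    r1, r2 = [], []
    seq = genome.residues
    for i in range(n_pairs):
        s, ins = int(starts[i]), int(inserts[i])
        frag = seq[s : s + ins]
        a = frag[:read_len]
        b = revcomp(frag[-read_len:])
        if error_rate > 0:
            a = _add_errors(a, error_rate, rng)
            b = _add_errors(b, error_rate, rng)
        r1.append(SequenceRecord(f"{genome.id}_p{i}/1", "", a))
        r2.append(SequenceRecord(f"{genome.id}_p{i}/2", "", b))
    return r1, r2


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    codes = _encode(seq)
    err = rng.random(len(codes)) < rate
    if err.any():
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        codes[err] = (codes[err] + shift) % 4
    return _decode(codes)


def simulate_race_panel(config: SimConfig) -> tuple[list[RaceData], SyntheticTruth, list[RepeatConsensus], list[SatFamilyConfig]]:
    """Full multi-race simulation: genomes, reads, monomers, and truth."""
    rng = np.random.default_rng(config.seed)
    library, sat_configs = generate_repeat_library(config, rng)
    truth = SyntheticTruth()
    races = []
    for ri in range(config.n_races):
        genome, monomers = assemble_genome(config, ri, library, sat_configs, rng, truth)
        r1, r2 = simulate_reads(
            genome,
            config.n_pairs,
            config.read_len,
            config.insert_mean,
            config.insert_sd,
            config.error_rate,
            rng=rng,
        )
        races.append(RaceData(genome.id, genome, r1, r2, monomers))
    return races, truth, library, sat_configs
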