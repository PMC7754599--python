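import numpy as np
import pytest

from conftest import point_mutate, random_dna
from repeatome.formats import RepeatConsensus, SequenceRecord, revcomp
from repeatome.quantify import (
    MaskHit,
    mask_sequences,
    resolve_overlaps,
    sample_read_pairs,
    summarize_genome_proportion,
)


def _lib(name, seq, cls="DNA", sup="TcMar", monomer=False):
    return RepeatConsensus(name, cls, sup, seq, is_monomer=monomer)


class TestMasker:
    def test_exact_substring_hit(self, rng):
        cons = random_dna(rng, 60)
        read = SequenceRecord("r", "", random_dna(rng, 40) + cons + random_dna(rng, 50))
        (hit,) = mask_sequences([read], [_lib("fam", cons)])
        assert (hit.start, hit.end) == (40, 100)
        assert hit.identity == 1.0
        assert hit.k2p == pytest.approx(0.0)

    def test_minus_strand_hit(self, rng):
        cons = random_dna(rng, 80)
        read = SequenceRecord("r", "", random_dna(rng, 30) + revcomp(cons) + random_dna(rng, 30))
        (hit,) = mask_sequences([read], [_lib("fam", cons)])
        assert hit.strand == "-"
        assert (hit.start, hit.end) == (30, 110)

    def test_diverged_copy_k2p_recovered(self, rng):
        """A ~15%-planted copy is found with k2p within 3 percentage points."""
        from repeatome.simulate import evolve_copies

        cons = random_dna(rng, 120)
        (mut,), (realized,) = evolve_copies(cons, 1, 0.15, kappa=2.0, rng=rng)
        read = SequenceRecord("r", "", random_dna(rng, 20) + mut + random_dna(rng, 20))
        hits = mask_sequences([read], [_lib("fam", cons)])
        assert hits, "diverged copy missed"
        best = max(hits, key=lambda h: h.bp)
        assert best.k2p == pytest.approx(realized, abs=0.03)

    def test_overlap_resolution_keeps_best_per_base(self, rng):
        cons_a = random_dna(rng, 70)
        cons_b = point_mutate(rng, cons_a, 0.25)  # related, worse match to the read
        read = SequenceRecord("r", "", random_dna(rng, 10) + cons_a + random_dna(rng, 10))
        hits = mask_sequences([read], [_lib("A", cons_a), _lib("B", cons_b)])
        covered = np.zeros(len(read.residues), dtype=int)
        for h in hits:
            covered[h.start : h.end] += 1
        assert covered.max() <= 1  # disjoint after resolution
        assert {h.consensus_name for h in hits if h.bp > 50} == {"A"}

    def test_strand_symmetry(self, rng):
        """Reverse-complementing every read leaves per-family masked bp unchanged."""
        cons = random_dna(rng, 100)
        reads = []
        for i in range(30):
            copy = point_mutate(rng, cons, 0.05)
            reads.append(SequenceRecord(f"r{i}", "", random_dna(rng, 15) + copy + random_dna(rng, 15)))
        lib = [_lib("fam", cons)]
        fwd = mask_sequences(reads, lib)
        rc_reads = [SequenceRecord(r.id, "", revcomp(r.residues)) for r in reads]
        rev = mask_sequences(rc_reads, lib)
        assert sum(h.bp for h in fwd) == sum(h.bp for h in rev)

    def test_monomer_reference_masks_any_phase(self, rng):
        monomer = random_dna(rng, 50)
        # read starts mid-monomer inside a long array
        array = monomer * 10
        read = SequenceRecord("r", "", array[23 : 23 + 150])
        (hit,) = mask_sequences([read], [_lib("sat", monomer, cls="TR", sup="satDNA", monomer=True)])
        assert hit.bp == 150

    def test_empty_sequence_skipped(self, rng):
        cons = random_dna(rng, 60)
        hits = mask_sequences([SequenceRecord("r", "", "")], [_lib("fam", cons)])
        assert hits == []

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            mask_sequences([SequenceRecord("r", "", "ACGT")], [])


class TestResolveOverlaps:
    def test_disjoint_after_resolution(self):
        hits = [
            MaskHit("r", 0, 100, "+", "A", 0.95, 90, 0.02),
            MaskHit("r", 50, 150, "+", "B", 0.90, 70, 0.05),
        ]
        out = resolve_overlaps(hits, min_hit_bp=30)
        assert [(h.consensus_name, h.start, h.end) for h in out] == [
            ("A", 0, 100),
            ("B", 100, 150),
        ]

    def test_tie_broken_by_length_then_name(self):
        hits = [
            MaskHit("r", 0, 50, "+", "B", 1.0, 50, 0.0),
            MaskHit("r", 0, 50, "+", "A", 1.0, 50, 0.0),
        ]
        out = resolve_overlaps(hits, min_hit_bp=10)
        assert len(out) == 1 and out[0].consensus_name == "A"


class TestSampling:
    def _pairs(self, rng, n):
        r1 = [SequenceRecord(f"p{i}/1", "", random_dna(rng, 20)) for i in range(n)]
        r2 = [SequenceRecord(f"p{i}/2", "", random_dna(rng, 20)) for i in range(n)]
        return r1, r2

    def test_deterministic_and_mate_preserving(self, rng):
        r1, r2 = self._pairs(rng, 50)
        a1, a2 = sample_read_pairs(r1, r2, 20, seed=5)
        b1, b2 = sample_read_pairs(r1, r2, 20, seed=5)
        assert [r.id for r in a1] == [r.id for r in b1]
        for m1, m2 in zip(a1, a2):
            assert m1.id.split("/")[0] == m2.id.split("/")[0]

    def test_all_pairs_returned_when_n_equals_available(self, rng):
        r1, r2 = self._pairs(rng, 10)
        a1, _ = sample_read_pairs(r1, r2, 10, seed=0)
        assert sorted(r.id for r in a1) == sorted(r.id for r in r1)

    def test_oversampling_raises_with_both_counts(self, rng):
        r1, r2 = self._pairs(rng, 5)
        with pytest.raises(ValueError, match="10.*5|5.*10"):
            sample_read_pairs(r1, r2, 10, seed=0)


class TestSummarize:
    CLS = {"A": ("DNA", "TcMar"), "B": ("LINE", "L2"), "C": ("DNA", "hAT")}

    def test_total_gp(self):
        hits = [MaskHit("r1", 0, 75, "+", "A", 1.0, 75, 0.0)]
        rows = summarize_genome_proportion(hits, 300, self.CLS)
        total = next(r for r in rows if r["level"] == "total")
        assert total["GP"] == pytest.approx(0.25)

    def test_class_rows_sum_to_total(self, rng):
        hits = []
        pos = 0
        for i in range(50):
            name = "ABC"[int(rng.integers(3))]
            bp = int(rng.integers(10, 100))
            hits.append(MaskHit(f"r{i}", 0, bp, "+", name, 1.0, bp, 0.0))
        rows = summarize_genome_proportion(hits, 10**6, self.CLS)
        cls_sum = sum(r["masked_bp"] for r in rows if r["level"] == "class")
        fam_sum = sum(r["masked_bp"] for r in rows if r["level"] == "family")
        total = next(r for r in rows if r["level"] == "total")["masked_bp"]
        assert cls_sum == fam_sum == total

    def test_unknown_consensus_raises(self):
        hits = [MaskHit("r", 0, 10, "+", "Z", 1.0, 10, 0.0)]
        with pytest.raises(ValueError, match="Z"):
            summarize_genome_proportion(hits, 100, self.CLS)


def test_gp_recovery_from_planted_families(rng):
    """Planted GPs of 5% and 1% are recovered within 0.5 percentage points."""
    from repeatome.simulate import SatFamilyConfig, SimConfig, simulate_race_panel

    config = SimConfig(
        seed=11,
        n_races=1,
        genome_len=300_000,
        n_pairs=12_000,
        sat_families=[
            SatFamilyConfig("famA", 100, 0.05, 0.02, (0,)),
            SatFamilyConfig("famB", 80, 0.01, 0.02, (0,)),
        ],
    )
    races, truth, library, _ = simulate_race_panel(config)
    race = races[0]
    reads = race.reads1 + race.reads2
    lib = [
        RepeatConsensus(m.qualified_name, "TR", "satDNA", m.sequence, is_monomer=True)
        for m in race.monomers
    ]
    hits = mask_sequences(reads, lib, min_identity=0.8, min_hit_bp=40)
    total_bp = sum(len(r.residues) for r in reads)
    classification = {c.name: ("TR", "satDNA") for c in lib}
    rows = summarize_genome_proportion(hits, total_bp, classification)
    by_name = {r["name"]: r["GP"] for r in rows if r["level"] == "family"}
    for fam in ("famA", "famB"):
        planted = truth.planted_gp[(race.name, fam)]
        measured = by_name.get(f"{race.name}|{fam}", 0.0)
        assert measured == pytest.approx(planted, abs=0.005)
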