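import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import point_mutate, random_dna
from repeatome.formats import revcomp
from repeatome.quantify import MaskHit
from repeatome.satlib import (
    SatMonomer,
    build_library_matrix,
    call_presence,
    canonicalize_monomer,
    cluster_families,
    coefficient_of_variation,
    kw_divergence_test,
    pairwise_homology,
)

DNA = st.text(alphabet="ACGT", min_size=5, max_size=40)


class TestCanonicalize:
    def test_brute_force_example(self):
        # min over all rotations of TTAGG and of its reverse complement CCTAA
        cands = []
        for s in ("TTAGG", "CCTAA"):
            for i in range(5):
                cands.append(s[i:] + s[:i])
        assert canonicalize_monomer("TTAGG") == min(cands) == "AACCT"

    @given(DNA, st.integers(0, 39))
    def test_rotation_and_strand_invariance(self, s, k):
        k = k % len(s)
        rot = s[k:] + s[:k]
        assert canonicalize_monomer(rot) == canonicalize_monomer(s)
        assert canonicalize_monomer(revcomp(s)) == canonicalize_monomer(s)

    @given(DNA)
    def test_idempotent(self, s):
        c = canonicalize_monomer(s)
        assert canonicalize_monomer(c) == c

    def test_homopolymer_fixed_point(self):
        assert canonicalize_monomer("AAAA") == "AAAA"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            canonicalize_monomer("")


class TestPairwiseHomology:
    def test_identical(self, rng):
        s = random_dna(rng, 60)
        a = SatMonomer("s1", "a", s)
        b = SatMonomer("s2", "b", s)
        e = pairwise_homology(a, b)
        assert e.identity == 1.0 and e.coverage == 1.0

    def test_rotation_needs_circular(self, rng):
        s = random_dna(rng, 60)
        rot = s[7:] + s[:7]
        a, b = SatMonomer("s1", "a", s), SatMonomer("s2", "b", rot)
        circ = pairwise_homology(a, b, circular=True)
        assert circ.identity == 1.0 and circ.coverage == 1.0
        lin = pairwise_homology(a, b, circular=False)
        assert lin.identity < 1.0

    def test_ten_percent_mutations(self, rng):
        """~10 of 100 positions mutated: identity close to 0.90."""
        s = random_dna(rng, 100)
        idx = rng.choice(100, size=10, replace=False)
        mutated = list(s)
        for i in idx:
            mutated[i] = "ACGT"[("ACGT".index(s[i]) + 1) % 4]
        e = pairwise_homology(SatMonomer("s1", "a", s), SatMonomer("s2", "b", "".join(mutated)))
        assert e.identity == pytest.approx(0.90, abs=0.02)

    def test_agrees_with_biopython_aligner(self, rng):
        """Independent aligner oracle: identity of a linear pair."""
        from Bio import Align

        s = random_dna(rng, 80)
        t = point_mutate(rng, s, 0.06)
        e = pairwise_homology(
            SatMonomer("s1", "a", s), SatMonomer("s2", "b", t), circular=False
        )
        aligner = Align.PairwiseAligner(
            mode="global", match_score=1, mismatch_score=-1,
            open_gap_score=-2, extend_gap_score=-2,
        )
        aln = aligner.align(s, t)[0]
        cols = list(zip(str(aln[0]), str(aln[1])))
        matches = sum(1 for x, y in cols if x == y and x != "-")
        oracle_identity = matches / len(cols)
        assert e.identity == pytest.approx(oracle_identity, abs=0.03)


class TestClustering:
    def test_rotation_joins_unrelated_stays(self, rng):
        base = random_dna(rng, 60)
        mons = [
            SatMonomer("s1", "A", base),
            SatMonomer("s2", "Arot", base[11:] + base[:11]),
            SatMonomer("s3", "C", random_dna(rng, 60)),
        ]
        clusters = cluster_families(mons)
        sizes = sorted(len(c) for c in clusters)
        assert sizes == [1, 2]

    def test_single_linkage_chain(self, rng):
        """A-B and B-C each ~85% similar while A-C is below threshold: one family."""
        a = random_dna(rng, 100)
        b = point_mutate(rng, a, 0.10)
        c = point_mutate(rng, b, 0.10)
        mons = [SatMonomer("s1", "A", a), SatMonomer("s2", "B", b), SatMonomer("s3", "C", c)]
        ab = pairwise_homology(mons[0], mons[1]).identity
        bc = pairwise_homology(mons[1], mons[2]).identity
        assert ab >= 0.8 and bc >= 0.8
        clusters = cluster_families(mons)
        assert len(clusters) == 1

    def test_order_and_orientation_invariance(self, rng):
        base = random_dna(rng, 80)
        mons = [
            SatMonomer("s1", "A", base),
            SatMonomer("s2", "B", point_mutate(rng, base, 0.05)),
            SatMonomer("s3", "C", random_dna(rng, 80)),
            SatMonomer("s4", "D", random_dna(rng, 40)),
        ]

        def partition(monomers):
            return sorted(
                tuple(sorted(m.local_name for m in c)) for c in cluster_families(monomers)
            )

        ref = partition(mons)
        shuffled = [mons[i] for i in rng.permutation(len(mons))]
        assert partition(shuffled) == ref
        twisted = [
            SatMonomer(m.source_sample, m.local_name, revcomp(m.sequence[13 % len(m.sequence):] + m.sequence[: 13 % len(m.sequence)]))
            for m in mons
        ]
        assert partition(twisted) == ref

    def test_short_monomer_rule_relaxed(self, rng):
        """Monomers far below 80 bp can still satisfy the aligned-bp rule."""
        s = random_dna(rng, 21)
        mons = [SatMonomer("s1", "A", s), SatMonomer("s2", "B", s)]
        assert len(cluster_families(mons)) == 1


class TestPresenceAndCV:
    def test_presence_thresholds(self):
        assert call_presence(0.0002)
        assert not call_presence(1e-6)
        assert not call_presence(0.0)

    @pytest.mark.parametrize(
        "values,expected",
        [
            ((0.5, 0.5, 0.5, 0.5), 0.0),
            ((1, 1, 1, 3), 66.6667),
            ((0.1, 0.5), 94.2809),
        ],
    )
    def test_cv_worked_examples(self, values, expected):
        assert coefficient_of_variation(values) == pytest.approx(expected, abs=1e-3)

    def test_cv_zero_mean_undefined(self):
        assert coefficient_of_variation([0, 0, 0]) is None

    @given(st.floats(0.1, 100.0))
    def test_cv_scale_invariant(self, scale):
        base = [0.1, 0.4, 0.2, 0.9]
        assert coefficient_of_variation(
            [v * scale for v in base]
        ) == pytest.approx(coefficient_of_variation(base), rel=1e-9)


class TestKruskalWallis:
    def test_identical_profiles(self):
        p = np.array([1.0, 2.0, 3.0])
        assert kw_divergence_test([p, p, p]) == (0.0, 1.0)

    def test_two_group_hand_oracle(self):
        H, p = kw_divergence_test([np.array([1, 2, 3]), np.array([4, 5, 6])])
        assert H == pytest.approx(3.857142857, abs=1e-6)
        assert p == pytest.approx(0.0495, abs=1e-3)

    def test_permutation_agrees_with_chi2(self):
        g1 = np.array([1, 2, 3, 10, 4, 2], dtype=float)
        g2 = np.array([8, 9, 12, 11, 7, 14], dtype=float)
        _, p_chi2 = kw_divergence_test([g1, g2])
        _, p_perm = kw_divergence_test([g1, g2], permutation=True, n_perm=4000, seed=1)
        assert p_perm == pytest.approx(p_chi2, abs=0.02)


class TestLibraryMatrix:
    def _hit(self, name, bp, k2p=0.02):
        return MaskHit("r", 0, bp, "+", name, 0.95, bp, k2p)

    def test_sharing_summary(self, rng):
        mons = {
            "A": SatMonomer("s1", "A", random_dna(rng, 60)),
            "B": SatMonomer("s1", "B", random_dna(rng, 60)),
            "C": SatMonomer("s1", "C", random_dna(rng, 60)),
        }
        clusters = [[mons["A"]], [mons["B"]], [mons["C"]]]
        hits = {
            "x": [self._hit("s1|A", 500), self._hit("s1|B", 300), self._hit("s1|C", 100)],
            "y": [self._hit("s1|A", 500), self._hit("s1|C", 90)],  # B absent in y
        }
        m = build_library_matrix(clusters, hits, {"x": 10**6, "y": 10**6})
        assert m.summary()["n_total"] == 3
        assert m.summary()["n_shared_all"] == 2
        assert m.summary()["n_not_shared"] == 1
        # naming by descending pooled GP
        assert m.families[0].members[0].local_name == "A"
        assert m.families[0].name == "satDNA-1"

    def test_unclustered_hit_raises(self, rng):
        mono = SatMonomer("s1", "A", random_dna(rng, 60))
        with pytest.raises(ValueError, match="unclustered"):
            build_library_matrix([[mono]], {"x": [self._hit("s1|Z", 10)]}, {"x": 100})
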