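import math

import numpy as np
import pytest

from repeatome.formats import revcomp
from repeatome.landscape import TRANSITIONS, count_substitutions
from repeatome.simulate import (
    SatFamilyConfig,
    SimConfig,
    evolve_copies,
    generate_repeat_library,
    simulate_race_panel,
    simulate_reads,
    solve_site_rates,
)


class TestSiteRates:
    def test_zero_target(self):
        assert solve_site_rates(0.0, 2.0) == (0.0, 0.0)

    def test_beyond_saturation_raises(self):
        with pytest.raises(ValueError):
            solve_site_rates(0.5, 2.0)

    @pytest.mark.parametrize("target,kappa", [(0.02, 2.0), (0.10, 2.0), (0.10, 0.5), (0.30, 4.0)])
    def test_inverts_k2p_formula(self, target, kappa):
        p, q = solve_site_rates(target, kappa)
        assert p == pytest.approx(kappa * q, rel=1e-9)
        k = -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)
        assert k == pytest.approx(target, rel=1e-9)


class TestEvolveCopies:
    def test_zero_target_is_identity(self, rng):
        cons = "ACGT" * 100
        seqs, realized = evolve_copies(cons, 5, 0.0, rng=rng)
        assert all(s == cons for s in seqs)
        assert all(r == 0.0 for r in realized)

    def test_mean_realized_k2p(self, rng):
        cons = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        _, realized = evolve_copies(cons, 2000, 0.10, kappa=2.0, rng=rng)
        vals = np.array(realized, dtype=float)
        assert 0.095 <= vals.mean() <= 0.105

    def test_no_indels_preserve_length(self, rng):
        cons = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        seqs, _ = evolve_copies(cons, 20, 0.1, indel_rate=0.0, rng=rng)
        assert all(len(s) == 300 for s in seqs)

    def test_indels_change_length(self, rng):
        cons = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        seqs, realized = evolve_copies(cons, 30, 0.05, indel_rate=0.01, rng=rng)
        assert any(len(s) != 500 for s in seqs)
        assert all(r is None or r < 0.12 for r in realized)

    def test_transition_transversion_ratio_converges(self, rng):
        """Simulated ts/tv count ratio converges to kappa (3 se)."""
        kappa = 2.0
        cons = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        seqs, _ = evolve_copies(cons, 200, 0.10, kappa=kappa, rng=rng)
        ts = tv = 0
        for s in seqs:
            for a, b in zip(cons, s):
                if a != b:
                    if (a, b) in TRANSITIONS:
                        ts += 1
                    else:
                        tv += 1
        ratio = ts / tv
        se = ratio * math.sqrt(1 / ts + 1 / tv)
        assert abs(ratio - kappa) < 3 * se


class TestLibraryGeneration:
    def test_lengths_and_determinism(self):
        cfg = SimConfig(seed=3, n_sat_families=5, monomer_len_range=(50, 200))
        lib1, _ = generate_repeat_library(cfg)
        lib2, _ = generate_repeat_library(cfg)
        sats = [c for c in lib1 if c.is_monomer]
        assert len(sats) == 5
        assert all(50 <= len(c.sequence) <= 200 for c in sats)
        assert [c.sequence for c in lib1] == [c.sequence for c in lib2]

    def test_invalid_range_raises(self):
        with pytest.raises(ValueError):
            generate_repeat_library(SimConfig(monomer_len_range=(10, 4)))


class TestGenomeAssembly:
    def test_truth_intervals_disjoint_and_gp_close(self, small_sim_config):
        races, truth, _, sat_configs = simulate_race_panel(small_sim_config)
        race = races[0].name
        ivals = sorted(
            (c.start, c.end) for c in truth.copies if c.race == race
        )
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            assert e1 <= s2, "planted intervals overlap"
        for fam in sat_configs:
            planted = truth.planted_gp[(race, fam.name)]
            if truth.presence[(race, fam.name)]:
                target = fam.target_gp * fam.fold_per_race.get(0, 1.0)
                assert planted == pytest.approx(target, rel=0.35, abs=0.001)
            else:
                assert planted == 0.0

    def test_hor_arrays_alternate_variants(self, rng):
        cfg = SimConfig(
            seed=5,
            n_races=1,
            genome_len=100_000,
            n_pairs=100,
            sat_families=[
                SatFamilyConfig("h", 60, 0.01, 0.01, (0,), hor_multiple=2, array_copies=8)
            ],
        )
        races, truth, _, _ = simulate_race_panel(cfg)
        arr_ids = {c.array_id for c in truth.copies}
        assert all(c.hor_multiple == 2 for c in truth.copies)
        from repeatome.trstruct import detect_hor, estimate_monomer_period

        genome = races[0].genome.residues
        one_array = [c for c in truth.copies if c.array_id == next(iter(arr_ids))]
        one_array.sort(key=lambda c: c.start)
        region = genome[one_array[0].start : one_array[-1].end]
        period = estimate_monomer_period(region, min_period=10)
        assert period is not None and period[0] == 60
        assert detect_hor(region, 60) == 2

    def test_overfull_genome_raises(self):
        cfg = SimConfig(
            seed=1,
            n_races=1,
            genome_len=20_000,
            sat_families=[SatFamilyConfig("x", 100, 0.95, 0.01, (0,))],
        )
        with pytest.raises(ValueError, match="90%|genome_len"):
            simulate_race_panel(cfg)


class TestReads:
    def _genome(self, rng, n=30_000):
        from repeatome.formats import SequenceRecord

        return SequenceRecord("g", "", "".join("ACGT"[i] for i in rng.integers(0, 4, n)))

    def test_shapes_and_determinism(self, rng):
        g = self._genome(rng)
        a1, a2 = simulate_reads(g, 500, seed=9)
        b1, b2 = simulate_reads(g, 500, seed=9)
        assert len(a1) == len(a2) == 500
        assert all(len(r.residues) == 150 for r in a1 + a2)
        assert [r.residues for r in a1] == [r.residues for r in b1]

    def test_mate_is_reverse_complement_of_fragment_end(self, rng):
        g = self._genome(rng)
        r1, r2 = simulate_reads(g, 200, seed=4)
        found = 0
        for m2 in r2[:50]:
            if revcomp(m2.residues) in g.residues:
                found += 1
        assert found == 50

    def test_coverage_expectation(self, rng):
        g = self._genome(rng, n=20_000)
        n_pairs = 2000
        r1, r2 = simulate_reads(g, n_pairs, seed=2)
        total = sum(len(r.residues) for r in r1 + r2)
        assert total == 2 * n_pairs * 150

    def test_short_genome_raises(self, rng):
        g = self._genome(rng, n=200)
        with pytest.raises(ValueError):
            simulate_reads(g, 10, insert_mean=400, seed=0)


def test_small_closed_loop_recovers_structure(small_sim_config):
    """Down-scaled end-to-end run: family count and sharing recovered."""
    from repeatome.pipeline import run_closed_loop

    report, result, truth = run_closed_loop(small_sim_config.seed, small_sim_config)
    assert report.n_families == report.planted_n_families
    assert report.n_shared == report.planted_n_shared
    assert report.amplified_flagged
    assert report.modal_bin_amplified == report.planted_divergence_bin
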