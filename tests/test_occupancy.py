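"""Fragment-size estimation, density imputation, mappability, correlation."""

import numpy as np
import pytest

from netdecay.homology import ChainMap, filter_one_to_one, revcomp
from netdecay.occupancy import (
    EstimationError,
    MappabilityTrack,
    StartSiteDensity,
    correlate_profiles,
    estimate_fragment_size,
    impute_density,
    mappability_track,
    merge_replicates,
    normalize_density,
    start_site_density,
    transfer_to_reference,
)
from netdecay.synthdata import random_genome, simulate_chip_reads
from tests.test_homology import make_chain


def delta_train_density(positions, offset, n=20_000):
    plus = np.zeros(n, dtype=np.int64)
    minus = np.zeros(n, dtype=np.int64)
    for p in positions:
        plus[p] += 1
        minus[p + offset] += 1
    return StartSiteDensity(plus={"chr1": plus}, minus={"chr1": minus})


class TestFragmentSize:
    def test_exact_offset_delta_trains(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(500, 18_000, size=200)
        k0 = 180
        starts = delta_train_density(pos, k0)
        est = estimate_fragment_size(starts, max_offset=400)
        assert est.L == k0
        assert est.cross_correlation[k0] == pytest.approx(1.0)

    def test_recovery_within_10bp_over_20_seeds(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sites = [
                ("chr1", int(p), 1.0)
                for p in rng.integers(1000, 49_000, size=40)
            ]
            reads = simulate_chip_reads(
                sites, {"chr1": 50_000}, 2000, rng,
                fragment_size=200, read_length=36, background_fraction=0.1,
            )
            starts = start_site_density(reads, {"chr1": 50_000})
            est = estimate_fragment_size(starts, max_offset=400, min_offset=37)
            assert abs(est.L - 200) <= 10

    def test_matches_smoothed_curve_argmax_oracle(self):
        from scipy.ndimage import gaussian_filter1d

        rng = np.random.default_rng(3)
        sites = [("chr1", int(p), 1.0) for p in rng.integers(1000, 39_000, 30)]
        reads = simulate_chip_reads(
            sites, {"chr1": 40_000}, 1500, rng, fragment_size=150,
            read_length=36, background_fraction=0.3,
        )
        starts = start_site_density(reads, {"chr1": 40_000})
        est = estimate_fragment_size(starts, max_offset=400, min_offset=37)
        # oracle: smooth r(k) itself and take its global maximum; for a
        # unimodal curve the first prominent downward zero-crossing of the
        # smoothed derivative is the same peak
        smooth_r = gaussian_filter1d(est.cross_correlation, sigma=10,
                                     truncate=4.0)
        oracle = int(np.argmax(smooth_r[37:])) + 37
        assert abs(est.L - oracle) <= 5

    def test_no_zero_crossing_raises(self):
        starts = delta_train_density([100, 5000, 9000], 500, n=20_000)
        with pytest.raises(EstimationError, match="max_offset"):
            estimate_fragment_size(starts, max_offset=100)


class TestImputeDensity:
    def test_plus_read_covers_L_positions(self):
        prof = impute_density(
            [("chr1", 100, 136, "N", 0, "+")], 5, {"chr1": 1000}
        )
        assert prof.plus["chr1"][100:105].tolist() == [1] * 5
        assert prof.plus["chr1"].sum() == 5

    def test_minus_read_extends_leftward(self):
        prof = impute_density(
            [("chr1", 100, 136, "N", 0, "-")], 10, {"chr1": 1000}
        )
        # 3' start site is position 135; extension covers [126, 136)
        assert prof.minus["chr1"][126:136].tolist() == [1] * 10
        assert prof.minus["chr1"].sum() == 10

    def test_mass_conservation_and_truncation(self, rng):
        reads = [
            ("chr1", int(s), int(s) + 36, "N", 0, "+")
            for s in rng.integers(0, 990, size=50)
        ]
        prof = impute_density(reads, 50, {"chr1": 1000})
        starts = {r[1] for r in reads}  # dedup collapses shared start sites
        assert prof.plus["chr1"].sum() == sum(
            min(50, 1000 - s) for s in starts
        )
        assert prof.n_truncated == sum(1 for s in starts if s + 50 > 1000)

    def test_replicate_merge_equals_concatenation(self, rng):
        r1 = [("chr1", int(s), int(s) + 36, "N", 0, "+")
              for s in rng.integers(0, 900, 30)]
        r2 = [("chr1", int(s), int(s) + 36, "N", 0, "-")
              for s in rng.integers(40, 900, 30)]
        sizes = {"chr1": 1000}
        merged = merge_replicates(
            [impute_density(r1, 20, sizes), impute_density(r2, 20, sizes)]
        )
        both = impute_density(r1 + r2, 20, sizes)
        assert np.array_equal(merged.plus["chr1"], both.plus["chr1"])
        assert np.array_equal(merged.minus["chr1"], both.minus["chr1"])


class TestMappability:
    def test_distinct_kmers_mappable_unless_strand_collision(self):
        track = mappability_track({"chr1": "ACGTAG"}, 3)
        # forward k-mers ACG CGT GTA TAG are distinct, but ACG and CGT
        # also occur on the reverse strand (CTACGT), so they are not unique
        assert track.plus["chr1"].tolist() == [False, False, True, True,
                                               False, False]
        assert track.minus["chr1"].tolist() == [False, False, False, False,
                                                True, True]

    def test_homopolymer_never_unique(self):
        track = mappability_track({"chr1": "AAAAAA"}, 3)
        assert not track.plus["chr1"].any()
        assert not track.minus["chr1"].any()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        seq = random_genome(3000, rng)
        # plant a duplication so some positions are non-unique
        seq = seq[:1000] + seq[500:700] + seq[1000:]
        k = 20
        track = mappability_track({"chr1": seq}, k)
        rc = revcomp(seq)

        def occurrences(kmer):
            count = 0
            for s in (seq, rc):
                i = s.find(kmer)
                while i != -1:
                    count += 1
                    i = s.find(kmer, i + 1)
            return count

        for p in range(0, len(seq) - k + 1, 7):
            assert track.plus["chr1"][p] == (occurrences(seq[p : p + k]) == 1)
        for p in range(k - 1, len(seq), 7):
            kmer = revcomp(seq[p - k + 1 : p + 1])
            assert track.minus["chr1"][p] == (occurrences(kmer) == 1)


class TestNormalize:
    def test_identity_on_fully_mappable_genome(self, rng):
        seq = random_genome(2000, rng)
        sizes = {"chr1": 2000}
        reads = [("chr1", int(s), int(s) + 36, "N", 0, "+")
                 for s in rng.integers(0, 1900, 40)]
        L = 30
        prof = impute_density(reads, L, sizes)
        track = mappability_track({"chr1": seq}, 36)
        norm = normalize_density(prof, track)
        interior = slice(L, 2000 - L)
        if track.plus["chr1"].all() and track.minus["chr1"].all():
            expect = prof.plus["chr1"] + prof.minus["chr1"]
            assert np.allclose(norm.combined["chr1"][interior],
                               expect[interior])

    def test_half_mappable_window_doubles_density(self):
        sizes = {"chr1": 400}
        reads = [("chr1", 200, 236, "N", 0, "+")]
        L = 20
        prof = impute_density(reads, L, sizes)
        plus = np.zeros(400, dtype=bool)
        plus[::2] = True  # every other start mappable
        minus = np.ones(400, dtype=bool)
        track = MappabilityTrack(plus={"chr1": plus},
                                 minus={"chr1": minus}, read_length=36)
        norm = normalize_density(prof, track)
        assert norm.combined["chr1"][210] == pytest.approx(2.0)

    def test_dead_windows_masked_by_window_count_oracle(self, rng):
        seq = random_genome(1500, rng)
        seq = seq[:400] + seq[100:300] + seq[400:]  # duplicated 200 bp
        sizes = {"chr1": len(seq)}
        track = mappability_track({"chr1": seq}, 24)
        reads = [("chr1", int(s), int(s) + 24, "N", 0, "+")
                 for s in rng.integers(0, 1500, 30)]
        L = 25
        prof = impute_density(reads, L, sizes)
        norm = normalize_density(prof, track)
        for p in range(L, len(seq) - L, 11):
            wp = track.plus["chr1"][p - L + 1 : p + 1].sum()
            wm = track.minus["chr1"][p : p + L].sum()
            assert norm.mask["chr1"][p] == (wp > 0 and wm > 0)

    def test_mismatched_L_rejected(self, rng):
        seq = random_genome(500, rng)
        prof = impute_density([], 20, {"chr1": 500})
        track = mappability_track({"chr1": seq}, 36)
        with pytest.raises(ValueError, match="differs"):
            normalize_density(prof, track, L=30)


class TestCorrelate:
    def _normed(self, reads, genome, L=50):
        sizes = {c: len(s) for c, s in genome.items()}
        prof = impute_density(reads, L, sizes)
        track = mappability_track(genome, 36)
        return normalize_density(prof, track)

    def test_profile_vs_itself_identity_map(self, rng):
        genome = {"chr1": random_genome(5000, rng)}
        reads = [("chr1", int(s), int(s) + 36, "N", 0, "+")
                 for s in rng.integers(0, 4900, 200)]
        prof = self._normed(reads, genome)
        ident = ChainMap(chains=[
            make_chain(1, 5000.0, [(0, 0, 5000)], t_size=5000, q_size=5000)
        ])
        on_ref = transfer_to_reference(prof, ident, {"chr1": 5000})
        assert correlate_profiles(prof, on_ref) == pytest.approx(1.0)

    def test_independent_backgrounds_uncorrelated(self):
        # fragment-length autocorrelation leaves ~n/L effective samples, so
        # the null correlation is only zero to ~1/sqrt(n/L)
        rng = np.random.default_rng(11)
        n = 100_000
        genome = {"chr1": random_genome(n, rng)}
        profs = []
        for _ in range(2):
            reads = simulate_chip_reads(
                [], {"chr1": n}, 5000, rng, fragment_size=100,
                read_length=36, background_fraction=1.0,
            )
            profs.append(self._normed(reads, genome, L=100))
        ident = ChainMap(chains=[
            make_chain(1, 1.0, [(0, 0, n)], t_size=n, q_size=n)
        ])
        on_ref = transfer_to_reference(profs[1], ident, {"chr1": n})
        assert abs(correlate_profiles(profs[0], on_ref)) < 0.1

    def test_correlation_monotone_in_shared_site_fraction(self):
        rng = np.random.default_rng(12)
        genome = {"chr1": random_genome(30_000, rng)}
        base_sites = [("chr1", int(p), 1.0)
                      for p in rng.integers(1000, 29_000, 30)]
        ident = ChainMap(chains=[
            make_chain(1, 1.0, [(0, 0, 30_000)], t_size=30_000, q_size=30_000)
        ])

        def profile_with_shared(frac):
            n_keep = int(30 * frac)
            sites = base_sites[:n_keep] + [
                ("chr1", int(p), 1.0)
                for p in rng.integers(1000, 29_000, 30 - n_keep)
            ]
            reads = simulate_chip_reads(
                sites, {"chr1": 30_000}, 6000, rng, fragment_size=100,
                read_length=36,
            )
            return self._normed(reads, genome, L=100)

        ref_reads = simulate_chip_reads(
            base_sites, {"chr1": 30_000}, 6000, rng, fragment_size=100,
            read_length=36,
        )
        ref = self._normed(ref_reads, genome, L=100)
        rs = []
        for frac in (0.0, 0.5, 1.0):
            prof = profile_with_shared(frac)
            on_ref = transfer_to_reference(prof, ident, {"chr1": 30_000})
            rs.append(correlate_profiles(ref, on_ref))
        assert rs[0] < rs[1] < rs[2]
        assert rs[2] > 0.8 and rs[0] < 0.3

    def test_resampled_replicate_beats_independent_simulation(self):
        rng = np.random.default_rng(13)
        genome = {"chr1": random_genome(20_000, rng)}
        sites = [("chr1", int(p), 1.0) for p in rng.integers(1000, 19_000, 20)]

        def prof(site_list):
            reads = simulate_chip_reads(
                site_list, {"chr1": 20_000}, 4000, rng, fragment_size=100,
                read_length=36,
            )
            return self._normed(reads, genome, L=100)

        ident = ChainMap(chains=[
            make_chain(1, 1.0, [(0, 0, 20_000)], t_size=20_000, q_size=20_000)
        ])
        ref = prof(sites)
        same = transfer_to_reference(prof(sites), ident, {"chr1": 20_000})
        other_sites = [("chr1", int(p), 1.0)
                       for p in rng.integers(1000, 19_000, 20)]
        other = transfer_to_reference(prof(other_sites), ident,
                                      {"chr1": 20_000})
        assert correlate_profiles(ref, same) > correlate_profiles(ref, other)

    def test_zero_variance_rejected(self):
        import pytest as _pytest

        flat = self._normed([], {"chr1": "ACGT" * 500})
        ident = ChainMap(chains=[
            make_chain(1, 1.0, [(0, 0, 2000)], t_size=2000, q_size=2000)
        ])
        on_ref = transfer_to_reference(flat, ident, {"chr1": 2000})
        with _pytest.raises(ValueError):
            correlate_profiles(flat, on_ref)
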