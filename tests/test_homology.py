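"""Chain I/O, one-to-one filtering, lifting, retention, alignment identity."""

import numpy as np
import pytest

from netdecay.homology import (
    BoundsError,
    Chain,
    ChainMap,
    ChainParseError,
    LiftParams,
    extract_lifted_sequences,
    filter_one_to_one,
    lift_interval,
    read_chain,
    revcomp,
    sample_retention,
    sw_align,
    ungapped_identity,
    write_chain,
)

# ---------------------------------------------------------------------------
# oracles


def sw_oracle(a: str, b: str, match=5.0, mismatch=-4.0, open_=10.0, ext=0.5):
    """Gotoh local alignment; a gap of length k costs open_ + k * ext."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consuming b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consuming a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - (open_ + ext), E[i][j - 1] - ext)
            F[i][j] = max(H[i - 1][j] - (open_ + ext), F[i - 1][j] - ext)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def best_chain_per_base(chains, axis: str, length: int):
    """Per-position best-scoring chain id over one genome axis, or None."""
    best = [None] * length
    key = [(-np.inf, 0)] * length
    for c in chains:
        for t0, q0, size in c.blocks:
            if axis == "target":
                span = range(t0, t0 + size)
            else:
                if c.q_strand == "-":
                    span = range(c.q_size - (q0 + size), c.q_size - q0)
                else:
                    span = range(q0, q0 + size)
            for p in span:
                k = (c.score, -c.chain_id)
                if k > key[p]:
                    key[p] = k
                    best[p] = c.chain_id
    return best


def q_forward_of(chain, t_pos):
    q = chain.q_forward(t_pos)
    assert q is not None
    return q


def make_chain(cid, score, blocks, t_size=1000, q_size=1000, q_strand="+",
               t_name="chr1", q_name="chr1"):
    blocks = tuple(sorted(blocks))
    return Chain(
        score=score, t_name=t_name, t_size=t_size,
        t_start=blocks[0][0], t_end=blocks[-1][0] + blocks[-1][2],
        q_name=q_name, q_size=q_size, q_strand=q_strand,
        q_start=blocks[0][1], q_end=blocks[-1][1] + blocks[-1][2],
        chain_id=cid, blocks=blocks,
    )


# ---------------------------------------------------------------------------


class TestChainIO:
    def test_single_block_chain(self, tmp_path):
        p = tmp_path / "one.chain"
        p.write_text("chain 500 chr1 1000 + 100 200 chr2 800 + 50 150 1\n100\n\n")
        cm = read_chain(p)
        (chain,) = cm.chains
        assert chain.blocks == ((100, 50, 100),)
        assert chain.t_end - chain.t_start == chain.q_end - chain.q_start == 100

    def test_minus_strand_reflection(self, tmp_path):
        p = tmp_path / "neg.chain"
        p.write_text("chain 500 chr1 1000 + 100 200 chr2 800 - 50 150 1\n100\n\n")
        (chain,) = read_chain(p).chains
        # target 100 aligns to raw 50 -> forward 800 - 1 - 50 = 749
        assert chain.q_forward(100) == 749
        assert chain.q_forward(199) == 650

    def test_block_sum_mismatch_reports_line(self, tmp_path):
        p = tmp_path / "bad.chain"
        p.write_text("chain 500 chr1 1000 + 100 200 chr2 800 + 50 150 1\n90\n\n")
        with pytest.raises(ChainParseError, match="line"):
            read_chain(p)

    def test_round_trip_fuzz_byte_identical(self, tmp_path):
        rng = np.random.default_rng(42)
        chains = []
        for cid in range(1, 101):
            t = int(rng.integers(0, 5000))
            q = int(rng.integers(0, 5000))
            blocks = []
            for _ in range(int(rng.integers(1, 6))):
                size = int(rng.integers(1, 200))
                blocks.append((t, q, size))
                t += size + int(rng.integers(0, 50))
                q += size + int(rng.integers(0, 50))
            chains.append(
                make_chain(cid, float(rng.integers(1, 10_000)), blocks,
                           t_size=20_000, q_size=20_000,
                           q_strand="-" if rng.random() < 0.5 else "+")
            )
        p1, p2 = tmp_path / "a.chain", tmp_path / "b.chain"
        write_chain(ChainMap(chains=chains), p1)
        write_chain(read_chain(p1), p2)
        assert p1.read_text() == p2.read_text()


class TestFilterOneToOne:
    def test_disjoint_chains_unchanged(self):
        cm = ChainMap(chains=[
            make_chain(1, 1000, [(0, 0, 100)]),
            make_chain(2, 500, [(200, 200, 100)]),
        ])
        out = filter_one_to_one(cm)
        assert {c.chain_id: c.blocks for c in out.chains} == {
            1: ((0, 0, 100),), 2: ((200, 200, 100),)
        }

    def test_overlap_goes_to_higher_score(self):
        cm = ChainMap(chains=[
            make_chain(1, 1000, [(0, 0, 100)]),
            make_chain(2, 500, [(50, 500, 100)]),  # target overlap [50,100)
        ])
        out = filter_one_to_one(cm)
        by_id = {c.chain_id: c for c in out.chains}
        assert by_id[1].blocks == ((0, 0, 100),)
        assert by_id[2].blocks == ((100, 550, 50),)

    def test_query_side_conflicts_also_resolved(self):
        # both chains map distinct target regions onto query [0, 100)
        cm = ChainMap(chains=[
            make_chain(1, 1000, [(0, 0, 100)]),
            make_chain(2, 900, [(500, 0, 100)]),
        ])
        out = filter_one_to_one(cm)
        by_id = {c.chain_id: c for c in out.chains}
        assert by_id[1].blocks == ((0, 0, 100),)
        assert 2 not in by_id

    @pytest.mark.parametrize("seed", range(5))
    def test_random_sets_match_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chains = []
        for cid in range(1, 9):
            t = int(rng.integers(0, 600))
            q = int(rng.integers(0, 600))
            blocks = []
            for _ in range(int(rng.integers(1, 4))):
                size = int(rng.integers(5, 80))
                blocks.append((t, q, size))
                t += size + int(rng.integers(0, 30))
                q += size + int(rng.integers(0, 30))
            chains.append(
                make_chain(cid, float(rng.integers(10, 1000)), blocks,
                           q_strand="-" if rng.random() < 0.3 else "+")
            )
        cm = ChainMap(chains=chains)
        out = filter_one_to_one(cm)
        t_owner = best_chain_per_base(chains, "target", 1000)
        q_owner = best_chain_per_base(chains, "query", 1000)
        # oracle: an aligned base survives iff its chain owns both positions
        expected = set()
        for c in chains:
            for t0, _q0, size in c.blocks:
                for tp in range(t0, t0 + size):
                    qp = q_forward_of(c, tp)
                    if t_owner[tp] == c.chain_id and q_owner[qp] == c.chain_id:
                        expected.add((c.chain_id, tp, qp))
        actual = set()
        for c in out.chains:
            for t0, q0, size in c.blocks:
                for i in range(size):
                    tp = t0 + i
                    raw = q0 + i
                    qp = c.q_size - 1 - raw if c.q_strand == "-" else raw
                    actual.add((c.chain_id, tp, qp))
        assert actual == expected
        # and the result is one-to-one on both genomes
        assert len({t for _c, t, _q in actual}) == len(actual)
        assert len({q for _c, _t, q in actual}) == len(actual)


class TestLiftInterval:
    def setup_method(self):
        self.cm = ChainMap(chains=[
            make_chain(1, 1000, [(100, 100, 40), (180, 200, 40)]),
        ])

    def test_interval_inside_block_lifts_exactly(self):
        res = lift_interval(("chr1", 110, 130), self.cm,
                            LiftParams(min_match=0.95))
        assert res.ok and (res.start, res.end) == (110, 130)

    def test_min_match_arithmetic(self):
        # 75 bp interval [105, 180): 35 aligned bases -> 35/75 = 0.467
        res_l = lift_interval(("chr1", 105, 180), self.cm,
                              LiftParams(min_match=0.4))
        res_s = lift_interval(("chr1", 105, 180), self.cm,
                              LiftParams(min_match=0.95))
        assert res_l.ok and res_l.aligned_bases == 35
        assert not res_s.ok and res_s.reason == "minmatch"

    def test_span_rule(self):
        cm = ChainMap(chains=[
            make_chain(1, 1000, [(0, 0, 50), (60, 1500, 50)], q_size=2000)
        ])
        res = lift_interval(("chr1", 0, 110), cm,
                            LiftParams(min_match=0.5, max_target_span=1000))
        assert not res.ok and res.reason == "span"
        res2 = lift_interval(("chr1", 0, 110), cm,
                             LiftParams(min_match=0.5, max_target_span=2000))
        assert res2.ok and (res2.start, res2.end) == (0, 1550)

    def test_off_chromosome_is_bounds_error(self):
        with pytest.raises(BoundsError):
            lift_interval(("chr1", 900, 1100), self.cm)

    def test_minus_strand_lift(self):
        cm = ChainMap(chains=[
            make_chain(1, 1000, [(100, 100, 50)], q_strand="-", q_size=400)
        ])
        res = lift_interval(("chr1", 110, 120), cm)
        # raw [110, 120) -> forward [400-120, 400-110)
        assert res.ok and (res.start, res.end) == (280, 290)
        assert res.strand == "-"


class TestSampleRetention:
    def test_identity_chain_full_retention(self, small_clade):
        res = sample_retention(
            [("chr1", 0, 200_000)], small_clade.chains["sp0"],
            n_segments=200, segment_length=75, n_trials=3,
            rng=np.random.default_rng(0),
        )
        assert res.fraction_retained == 1.0
        assert all(f == 1.0 for f in res.per_trial)

    def test_known_hazard_recovered(self, small_clade):
        # uniform hazard 0.009/Myr; at t = 100 expected survival exp(-0.9)
        res = sample_retention(
            [("chr1", 0, 200_000)], small_clade.chains["sp100"],
            n_segments=500, segment_length=75, n_trials=5,
            rng=np.random.default_rng(1),
        )
        assert res.fraction_retained == pytest.approx(np.exp(-0.9), abs=0.06)

    def test_variant_parameters_preserve_ordering(self, small_clade):
        # longer segments / stricter min_match must preserve the time ordering
        for length, mm in ((150, 0.001), (75, 0.5)):
            fracs = []
            for sp in ("sp50", "sp100"):
                res = sample_retention(
                    [("chr1", 0, 200_000)], small_clade.chains[sp],
                    n_segments=300, segment_length=length, n_trials=2,
                    params=LiftParams(min_match=mm),
                    rng=np.random.default_rng(2),
                )
                fracs.append(res.fraction_retained)
            assert fracs[0] > fracs[1]

    def test_retention_monotone_in_time(self, small_clade):
        fracs = [
            sample_retention(
                [("chr1", 0, 200_000)], small_clade.chains[sp],
                n_segments=300, segment_length=75, n_trials=2,
                rng=np.random.default_rng(3),
            ).fraction_retained
            for sp in ("sp0", "sp50", "sp100")
        ]
        assert fracs[0] >= fracs[1] >= fracs[2]

    def test_insufficient_space_raises(self, small_clade):
        with pytest.raises(ValueError):
            sample_retention(
                [("chr1", 0, 1000)], small_clade.chains["sp0"],
                n_segments=100, segment_length=75, n_trials=1,
                rng=np.random.default_rng(4),
            )


class TestSmithWaterman:
    def test_identical_sequences_full_identity(self):
        score, ident, cols = sw_align("ACGTACGTACGT", "ACGTACGTACGT")
        assert ident == 100.0 and cols == 12

    def test_single_mismatch_example(self):
        score, ident, cols = sw_align("ACGTACGT", "ACGAACGT")
        assert score == sw_oracle("ACGTACGT", "ACGAACGT")
        assert ident == pytest.approx(87.5)

    def test_matches_dp_oracle_on_500_random_pairs(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for _ in range(500):
            a = "".join(rng.choice(bases, size=rng.integers(3, 21)))
            b = "".join(rng.choice(bases, size=rng.integers(3, 21)))
            assert sw_align(a, b)[0] == pytest.approx(sw_oracle(a, b))

    def test_generator_ground_truth_identity(self, rng):
        from netdecay.synthdata import EvolParams, evolve_clade

        params = EvolParams(sub_rate=0.001, indel_rate=0.0, loss_rate=0.0)
        clade = evolve_clade(150_000, {"sp": 50.0}, params, rng)
        result, pairs = sample_retention(
            [("chr1", 0, 150_000)], clade.chains["sp"],
            n_segments=200, segment_length=75, n_trials=2,
            rng=np.random.default_rng(6), return_segments=True,
        )
        seqs = extract_lifted_sequences(
            pairs, clade.reference, clade.descendants["sp"]
        )
        mean_ident, excluded = ungapped_identity(seqs)
        assert mean_ident == pytest.approx(95.0, abs=1.0)
        assert excluded == 0

    def test_unalignable_pairs_counted(self):
        mean_ident, excluded = ungapped_identity(
            [("AAAAAAAA", "AAAAAAAA"), ("AAAA", "TTTT")]
        )
        assert excluded == 1 and mean_ident == 100.0
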