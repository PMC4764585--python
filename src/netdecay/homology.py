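"""Chain-based homology: coordinate lifting, retention sampling, segment identity.

Implements the genome-sequence divergence layer: UCSC chain file reading and
writing, filtering of chain sets to one-to-one (per-base best-scoring)
correspondences, liftOver-style interval mapping with a ``minMatch``
fraction and a maximum target-span rule, the random-segment retention
procedure (by default 5000 non-overlapping 75 bp segments, 20 trials,
minMatch 0.001, segments mapping to regions longer than 1000 bp excluded),
and Smith-Waterman ungapped percent identity of retained segments (EMBOSS
water defaults: gap open 10, gap extend 0.5, EDNAFULL scoring).

Coordinates are 0-based half-open (BED convention) on the forward strand of
the target genome; query coordinates of minus-strand chains follow the UCSC
chain convention (counted from the reverse-strand origin) and are reflected
to forward coordinates on output.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_MIN_MATCH = 0.001
DEFAULT_MAX_TARGET_SPAN = 1000
DEFAULT_N_SEGMENTS = 5000
DEFAULT_SEGMENT_LENGTH = 75
DEFAULT_N_TRIALS = 20

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ChainParseError(ValueError):
    """Malformed chain file (reported with the offending line number)."""


class BoundsError(ValueError):
    """Interval lies outside the chromosome it names."""


@dataclass(frozen=True)
class Chain:
    """One scored chain of ungapped aligned blocks between two genomes.

    ``blocks`` holds ``(t_start, q_start, size)`` triples; target starts are
    forward-strand coordinates, query starts are in chain-strand coordinates
    (reversed origin when ``q_strand == "-"``), exactly as in the file format.
    """

    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    blocks: tuple[tuple[int, int, int], ...]

    def q_forward(self, t_pos: int) -> int | None:
        """Forward-strand query coordinate aligned to target position, or None."""
        for t0, q0, size in self.blocks:
            if t0 <= t_pos < t0 + size:
                raw = q0 + (t_pos - t0)
                if self.q_strand == "-":
                    return self.q_size - 1 - raw
                return raw
        return None

    def aligned_in(self, start: int, end: int) -> int:
        """Number of target bases of [start, end) inside aligned blocks."""
        total = 0
        for t0, _q0, size in self.blocks:
            total += max(0, min(end, t0 + size) - max(start, t0))
        return total


@dataclass
class ChainMap:
    """A set of chains between one target genome and one query genome."""

    chains: list[Chain] = field(default_factory=list)

    def for_target(self, t_name: str) -> list[Chain]:
        return [c for c in self.chains if c.t_name == t_name]

    def overlapping_target(self, t_name: str, start: int, end: int) -> list[Chain]:
        """Chains whose target span intersects [start, end), via a cached index."""
        idx = getattr(self, "_index", None)
        if idx is None:
            idx = {}
            for c in self.chains:
                idx.setdefault(c.t_name, []).append(c)
            for name, cs in idx.items():
                cs.sort(key=lambda c: c.t_start)
                idx[name] = (
                    np.array([c.t_start for c in cs]),
                    np.array([c.t_end for c in cs]),
                    cs,
                )
            object.__setattr__(self, "_index", idx)
        if t_name not in idx:
            return []
        starts, ends, cs = idx[t_name]
        hit = np.nonzero((starts < end) & (ends > start))[0]
        return [cs[i] for i in hit]

    def __len__(self) -> int:
        return len(self.chains)


# ---------------------------------------------------------------------------
# chain file I/O (UCSC chain format)


def read_chain(path) -> ChainMap:
    """Parse a UCSC chain file, validating block sums against header spans."""
    chains: list[Chain] = []
    header = None
    blocks: list[tuple[int, int, int]] = []
    t_cursor = q_cursor = 0
    expect_more = False

    def finish(lineno: int) -> None:
        nonlocal header, blocks
        if header is None:
            return
        if expect_more:
            raise ChainParseError(f"line {lineno}: chain truncated (no final block)")
        if t_cursor != header["t_end"] or q_cursor != header["q_end"]:
            raise ChainParseError(
                f"line {lineno}: block sums ({t_cursor}, {q_cursor}) do not match "
                f"header spans ({header['t_end']}, {header['q_end']})"
            )
        chains.append(Chain(blocks=tuple(blocks), **header))
        header, blocks = None, []

    lineno = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                finish(lineno)
                f = line.split()
                if len(f) != 13:
                    raise ChainParseError(f"line {lineno}: chain header needs 13 fields")
                if f[4] != "+":
                    raise ChainParseError(f"line {lineno}: target strand must be '+'")
                if f[9] not in "+-":
                    raise ChainParseError(f"line {lineno}: bad query strand {f[9]!r}")
                header = dict(
                    score=float(f[1]),
                    t_name=f[2],
                    t_size=int(f[3]),
                    t_start=int(f[5]),
                    t_end=int(f[6]),
                    q_name=f[7],
                    q_size=int(f[8]),
                    q_strand=f[9],
                    q_start=int(f[10]),
                    q_end=int(f[11]),
                    chain_id=int(f[12]),
                )
                t_cursor, q_cursor = header["t_start"], header["q_start"]
                expect_more = True
            else:
                if header is None:
                    raise ChainParseError(f"line {lineno}: block outside chain")
                f = line.split()
                size = int(f[0])
                blocks.append((t_cursor, q_cursor, size))
                t_cursor += size
                q_cursor += size
                if len(f) == 3:
                    t_cursor += int(f[1])
                    q_cursor += int(f[2])
                    expect_more = True
                elif len(f) == 1:
                    expect_more = False
                else:
                    raise ChainParseError(f"line {lineno}: block line needs 1 or 3 fields")
        finish(lineno)
    return ChainMap(chains=chains)


def write_chain(chain_map: ChainMap, path) -> None:
    """Write a ChainMap in canonical UCSC chain format."""
    with open(path, "w") as fh:
        for c in chain_map.chains:
            score = int(c.score) if float(c.score).is_integer() else c.score
            fh.write(
                f"chain {score} {c.t_name} {c.t_size} + {c.t_start} {c.t_end} "
                f"{c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for i, (t0, q0, size) in enumerate(c.blocks):
                if i + 1 < len(c.blocks):
                    t1, q1, _ = c.blocks[i + 1]
                    fh.write(f"{size} {t1 - (t0 + size)} {q1 - (q0 + size)}\n")
                else:
                    fh.write(f"{size}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# one-to-one filtering


def _q_forward_interval(c: Chain, t0: int, q0: int, size: int) -> tuple[int, int]:
    """Forward-strand query interval of one block."""
    if c.q_strand == "-":
        return (c.q_size - (q0 + size), c.q_size - q0)
    return (q0, q0 + size)


def _assign_best(intervals):
    """Per-base best-score assignment over [start, end, rank, payload] items.

    Sweep line over elementary intervals; within each, the item with the
    highest rank tuple wins.  Returns {payload: [(start, end), ...]} of the
    retained (possibly trimmed) pieces.
    """
    events = []
    for iv in intervals:
        start, end, rank, payload = iv
        events.append((start, 0, rank, payload))
        events.append((end, 1, rank, payload))
    points = sorted({e[0] for e in events})
    starts = sorted(intervals)
    out: dict = {}
    active: list = []
    idx = 0
    for i, p in enumerate(points[:-1]):
        while idx < len(starts) and starts[idx][0] <= p:
            active.append(starts[idx])
            idx += 1
        active = [iv for iv in active if iv[1] > p]
        if not active:
            continue
        best = max(active, key=lambda iv: iv[2])
        out.setdefault(best[3], []).append((p, points[i + 1]))
    return out


def filter_one_to_one(chain_map: ChainMap) -> ChainMap:
    """Retain, for every target and query position, only the best-scoring chain.

    For every position of either genome the best-scoring covering chain is
    determined (ties broken by chain id); a base of an alignment survives
    only if its chain wins on both its target and its query position.
    Surviving pieces are re-assembled into chains with recomputed spans.
    """
    by_id = {c.chain_id: c for c in chain_map.chains}

    # target-side ownership
    t_won: dict[int, list[tuple[int, int]]] = {}
    for t_name in sorted({c.t_name for c in chain_map.chains}):
        items = []
        for c in chain_map.chains:
            if c.t_name != t_name:
                continue
            for t0, _q0, size in c.blocks:
                items.append((t0, t0 + size, (c.score, -c.chain_id), c.chain_id))
        for cid, pieces in _assign_best(items).items():
            t_won.setdefault(cid, []).extend(pieces)

    # query-side ownership, expressed back in target coordinates
    q_won: dict[int, list[tuple[int, int]]] = {}
    for q_name in sorted({c.q_name for c in chain_map.chains}):
        items = []
        for c in chain_map.chains:
            if c.q_name != q_name:
                continue
            for t0, _q0, size in c.blocks:
                qs, qe = _t_to_q_interval(c, t0, t0 + size)
                items.append((qs, qe, (c.score, -c.chain_id), (c.chain_id, t0)))
        for (cid, _t0), q_pieces in _assign_best(items).items():
            c = by_id[cid]
            for qs, qe in q_pieces:
                q_won.setdefault(cid, []).append(_q_to_t_interval(c, qs, qe))

    kept = {
        cid: _intersect_intervals(
            sorted(t_won.get(cid, [])), sorted(q_won.get(cid, []))
        )
        for cid in by_id
    }

    out = []
    for c in chain_map.chains:
        pieces = kept[c.chain_id]
        if not pieces:
            continue
        # coalesce seamless neighbours (same block, contiguous on both sides)
        merged: list[list[int]] = []
        for s, e in sorted(pieces):
            if (
                merged
                and merged[-1][1] == s
                and _t_to_q_raw(c, s - 1) + 1 == _t_to_q_raw(c, s)
            ):
                merged[-1][1] = e
            else:
                merged.append([s, e])
        # raw (chain-strand) query coordinates are monotone in t, so trimmed
        # pieces re-assemble directly into blocks
        new_blocks = sorted((s, _t_to_q_raw(c, s), e - s) for s, e in merged)
        t_start, t_end = new_blocks[0][0], new_blocks[-1][0] + new_blocks[-1][2]
        out.append(
            replace(
                c,
                t_start=t_start,
                t_end=t_end,
                q_start=new_blocks[0][1],
                q_end=new_blocks[-1][1] + new_blocks[-1][2],
                blocks=tuple(new_blocks),
            )
        )
    return ChainMap(chains=out)


def _intersect_intervals(a, b):
    """Intersection of two sorted, disjoint interval lists."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _t_to_q_raw(c: Chain, t_pos: int) -> int:
    for t0, q0, size in c.blocks:
        if t0 <= t_pos < t0 + size:
            return q0 + (t_pos - t0)
    raise ValueError(f"target position {t_pos} not aligned in chain {c.chain_id}")


def _t_to_q_interval(c: Chain, s: int, e: int) -> tuple[int, int]:
    """Forward query interval of target piece [s, e) (must lie in one block)."""
    raw_s = _t_to_q_raw(c, s)
    raw_e = raw_s + (e - s)
    if c.q_strand == "-":
        return (c.q_size - raw_e, c.q_size - raw_s)
    return (raw_s, raw_e)


def _q_to_t_interval(c: Chain, qs: int, qe: int) -> tuple[int, int]:
    """Inverse of :func:`_t_to_q_interval` (piece within one block)."""
    if c.q_strand == "-":
        raw_s, raw_e = c.q_size - qe, c.q_size - qs
    else:
        raw_s, raw_e = qs, qe
    for t0, q0, size in c.blocks:
        if q0 <= raw_s < q0 + size:
            return (t0 + (raw_s - q0), t0 + (raw_e - q0))
    raise ValueError("query piece not aligned in chain")


# ---------------------------------------------------------------------------
# interval lifting


@dataclass(frozen=True)
class LiftParams:
    """liftOver-style thresholds: minMatch fraction and maximum query span."""

    min_match: float = DEFAULT_MIN_MATCH
    max_target_span: int = DEFAULT_MAX_TARGET_SPAN

    def __post_init__(self) -> None:
        if not (0 < self.min_match <= 1):
            raise ValueError("min_match must be in (0, 1]")


@dataclass(frozen=True)
class LiftResult:
    """Outcome of lifting one interval; ``ok`` False carries a ``reason``."""

    ok: bool
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    chain_id: int | None = None
    aligned_bases: int = 0
    reason: str | None = None


def lift_interval(
    interval: tuple[str, int, int],
    chain_map: ChainMap,
    params: LiftParams = LiftParams(),
) -> LiftResult:
    """Map a target interval to query coordinates through the best single chain.

    Succeeds iff at least ``min_match`` of the interval's bases are aligned
    within one chain (aligned bases are counted per chain, not pooled) and
    the spanning query interval is no longer than ``max_target_span``.
    """
    chrom, start, end = interval
    if end <= start:
        raise ValueError("empty interval")
    any_chain = next((c for c in chain_map.chains if c.t_name == chrom), None)
    if any_chain is not None and not (0 <= start and end <= any_chain.t_size):
        raise BoundsError(f"{chrom}:{start}-{end} outside chromosome of size "
                          f"{any_chain.t_size}")
    candidates = chain_map.overlapping_target(chrom, start, end)
    best, best_aligned = None, 0
    for c in candidates:
        a = c.aligned_in(start, end)
        if a > best_aligned or (a == best_aligned and best and c.score > best.score):
            best, best_aligned = c, a
    if best is None or best_aligned == 0:
        return LiftResult(ok=False, reason="deleted")
    if best_aligned / (end - start) < params.min_match:
        return LiftResult(ok=False, reason="minmatch", aligned_bases=best_aligned)
    q_lo, q_hi = None, None
    for t0, q0, size in best.blocks:
        lo = max(start, t0)
        hi = min(end, t0 + size)
        if lo < hi:
            qs, qe = _t_to_q_interval(best, lo, hi)
            q_lo = qs if q_lo is None else min(q_lo, qs)
            q_hi = qe if q_hi is None else max(q_hi, qe)
    span = q_hi - q_lo
    if span > params.max_target_span:
        return LiftResult(ok=False, reason="span", aligned_bases=best_aligned)
    return LiftResult(
        ok=True,
        chrom=best.q_name,
        start=q_lo,
        end=q_hi,
        strand=best.q_strand,
        chain_id=best.chain_id,
        aligned_bases=best_aligned,
    )


# ---------------------------------------------------------------------------
# segment retention


@dataclass(frozen=True)
class RetentionResult:
    """Mean and per-trial fractions of segments that lifted successfully."""

    fraction_retained: float
    per_trial: tuple[float, ...]
    n_segments: int
    segment_length: int
    n_trials: int

    def __post_init__(self) -> None:
        if any(not (0 <= f <= 1) for f in self.per_trial):
            raise ValueError("per-trial fractions must be in [0, 1]")
        if abs(self.fraction_retained - float(np.mean(self.per_trial))) > 1e-12:
            raise ValueError("mean inconsistent with per-trial values")


def sample_nonoverlapping_segments(
    regions: list[tuple[str, int, int]],
    n_segments: int,
    segment_length: int,
    rng: np.random.Generator,
    max_attempts_factor: int = 200,
) -> list[tuple[str, int, int]]:
    """Uniformly place non-overlapping fixed-length segments inside regions.

    Rejection sampling: a candidate start is drawn uniformly over all valid
    placements and rejected if it overlaps an already placed segment.
    """
    placements = [
        (chrom, start, end) for chrom, start, end in regions
        if end - start >= segment_length
    ]
    total = sum(end - start - segment_length + 1 for _c, start, end in placements)
    if total < n_segments:
        raise ValueError("regions cannot hold the requested segments")
    weights = np.array(
        [end - start - segment_length + 1 for _c, start, end in placements],
        dtype=float,
    )
    weights /= weights.sum()
    occupied: dict[str, list[int]] = {}
    segments: list[tuple[str, int, int]] = []
    attempts = 0
    budget = max_attempts_factor * n_segments
    while len(segments) < n_segments:
        attempts += 1
        if attempts > budget:
            raise ValueError(
                "rejection sampling budget exhausted; regions too crowded for "
                f"{n_segments} non-overlapping segments of {segment_length} bp"
            )
        ridx = rng.choice(len(placements), p=weights)
        chrom, rstart, rend = placements[ridx]
        s = int(rng.integers(rstart, rend - segment_length + 1))
        e = s + segment_length
        starts = occupied.setdefault(chrom, [])
        i = bisect.bisect_left(starts, s)
        if i > 0 and starts[i - 1] + segment_length > s:
            continue
        if i < len(starts) and starts[i] < e:
            continue
        starts.insert(i, s)
        segments.append((chrom, s, e))
    return segments


def sample_retention(
    regions: list[tuple[str, int, int]],
    chain_map: ChainMap,
    n_segments: int = DEFAULT_N_SEGMENTS,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    n_trials: int = DEFAULT_N_TRIALS,
    params: LiftParams = LiftParams(),
    rng: np.random.Generator | None = None,
    return_segments: bool = False,
):
    """Fraction of randomly placed segments that retain homology.

    Per trial, ``n_segments`` non-overlapping segments of ``segment_length``
    bp are placed uniformly within ``regions`` and lifted through
    ``chain_map``; the retained fraction (lift succeeded, span within
    bounds) is averaged over ``n_trials``.  With ``return_segments`` the
    successfully lifted (reference, query) segment pairs of every trial are
    returned as a second value, for downstream identity scoring.
    """
    rng = np.random.default_rng() if rng is None else rng
    fractions = []
    lifted_pairs = []
    for _ in range(n_trials):
        segments = sample_nonoverlapping_segments(
            regions, n_segments, segment_length, rng
        )
        ok = 0
        for seg in segments:
            res = lift_interval(seg, chain_map, params)
            if res.ok:
                ok += 1
                if return_segments:
                    lifted_pairs.append((seg, res))
        fractions.append(ok / n_segments)
    result = RetentionResult(
        fraction_retained=float(np.mean(fractions)),
        per_trial=tuple(fractions),
        n_segments=n_segments,
        segment_length=segment_length,
        n_trials=n_trials,
    )
    if return_segments:
        return result, lifted_pairs
    return result


# ---------------------------------------------------------------------------
# Smith-Waterman ungapped identity

_EDNAFULL = substitution_matrices.load("NUC.4.4")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _EDNAFULL
    # EMBOSS water accounting: a gap of length k costs open + k * extend
    aligner.open_gap_score = -10.5
    aligner.extend_gap_score = -0.5
    return aligner


def sw_align(ref_seq: str, query_seq: str) -> tuple[float, float, int]:
    """Best local alignment; returns (score, percent identity, aligned columns).

    Identity is matches over aligned (non-gap) columns of the best local
    alignment.  A score of 0 (no positive-scoring local alignment) returns
    ``(0.0, nan, 0)``.
    """
    aligner = _make_aligner()
    ref_seq, query_seq = ref_seq.upper(), query_seq.upper()
    score = aligner.score(ref_seq, query_seq)
    if score <= 0:
        return 0.0, float("nan"), 0
    aln = aligner.align(ref_seq, query_seq)[0]
    matches = 0
    cols = 0
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        cols += te - ts
        matches += sum(
            1 for a, b in zip(ref_seq[ts:te], query_seq[qs:qe]) if a == b
        )
    return float(score), 100.0 * matches / cols, cols


def ungapped_identity(pairs: list[tuple[str, str]]) -> tuple[float, int]:
    """Mean percent identity of the ungapped columns over segment pairs.

    Pairs whose local alignment has score 0 are excluded; the count of
    exclusions is returned alongside the mean.
    """
    idents = []
    excluded = 0
    for ref_seq, query_seq in pairs:
        _score, ident, cols = sw_align(ref_seq, query_seq)
        if cols == 0:
            excluded += 1
        else:
            idents.append(ident)
    if not idents:
        raise ValueError("no alignable segment pairs")
    return float(np.mean(idents)), excluded


def extract_lifted_sequences(
    lifted_pairs,
    ref_genome: dict[str, str],
    query_genome: dict[str, str],
) -> list[tuple[str, str]]:
    """Pull (reference, query) sequences for lifted segments; minus-strand
    query images are reverse-complemented into reference orientation."""
    out = []
    for (chrom, start, end), res in lifted_pairs:
        ref_seq = ref_genome[chrom][start:end]
        q_seq = query_genome[res.chrom][res.start : res.end]
        if res.strand == "-":
            q_seq = revcomp(q_seq)
        out.append((ref_seq, q_seq))
    return out
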