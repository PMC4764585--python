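"""Nucleotide-resolution TF occupancy profiles and their cross-species correlation.

The pipeline mirrors how deeply-sequenced ChIP experiments are compared
without peak calling:

1. the mean fragment size ``L`` is estimated by strand cross-correlation of
   5' read-start densities (the offset maximising the Pearson correlation
   between plus- and minus-strand start densities, located as the first
   downward zero-crossing of the Gaussian-smoothed finite-difference
   derivative of the correlation curve);
2. every read start is extended ``L`` bp in its 3' direction, giving an
   imputed-fragment density per strand (replicates merge by adding
   densities);
3. densities are adaptively normalized for mappability: each position is
   divided by the fraction of uniquely-mappable read-start positions in the
   ``L``-bp window upstream of it (strand-appropriate direction); windows
   with zero mappable starts are masked;
4. after per-strand normalization the strands are summed, the query profile
   is transferred onto reference coordinates through a one-to-one filtered
   chain map, and a single Pearson correlation is computed over all usable
   positions of the concatenated chromosomes.

Duplicate read starts (PCR duplicates) are collapsed by default before
density imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import pearsonr

from .homology import ChainMap

DEFAULT_SMOOTH_BANDWIDTH = 10.0
DEFAULT_MAX_OFFSET = 600


class EstimationError(RuntimeError):
    """Fragment-size estimation failed (no zero-crossing / no variance)."""


@dataclass
class StartSiteDensity:
    """Per-chromosome 5' read-start counts, one integer vector per strand."""

    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]

    @property
    def n_reads(self) -> tuple[int, int]:
        return (
            int(sum(v.sum() for v in self.plus.values())),
            int(sum(v.sum() for v in self.minus.values())),
        )


def start_site_density(
    records,
    chrom_sizes: dict[str, int],
    dedup: bool = True,
) -> StartSiteDensity:
    """Count 5' read starts per strand from tagAlign records.

    Plus-strand reads start at their ``start`` coordinate; minus-strand
    reads at ``end - 1``.  With ``dedup`` (default) multiple reads sharing a
    start site on the same strand are collapsed to one, the usual PCR
    duplicate heuristic.
    """
    plus = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    minus = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    seen = set()
    for chrom, start, end, _seq, _score, strand in records:
        pos = start if strand == "+" else end - 1
        if dedup:
            key = (chrom, pos, strand)
            if key in seen:
                continue
            seen.add(key)
        (plus if strand == "+" else minus)[chrom][pos] += 1
    return StartSiteDensity(plus=plus, minus=minus)


@dataclass(frozen=True)
class FragmentSizeEstimate:
    L: int
    cross_correlation: np.ndarray  # r(k), k = 0..max_offset
    smoothing_bandwidth: float
    zero_crossing_offset: int


def estimate_fragment_size(
    starts: StartSiteDensity,
    max_offset: int = DEFAULT_MAX_OFFSET,
    min_offset: int = 0,
    bandwidth: float = DEFAULT_SMOOTH_BANDWIDTH,
) -> FragmentSizeEstimate:
    """Estimate mean fragment size L from strand cross-correlation.

    ``r(k)`` is the Pearson correlation between the plus-strand start
    density and the minus-strand density shifted left by ``k``, pooled over
    chromosomes.  L is the offset of the first peak, found as the first
    downward zero-crossing of the Gaussian-smoothed (sd ``bandwidth``
    offsets) finite-difference derivative, searching from ``min_offset``.
    """
    chroms = sorted(starts.plus)
    if not chroms:
        raise ValueError("empty density")
    rs = np.empty(max_offset + 1)
    for k in range(max_offset + 1):
        xs, ys = [], []
        for c in chroms:
            p, m = starts.plus[c], starts.minus[c]
            if len(p) <= k:
                continue
            xs.append(p[: len(p) - k])
            ys.append(m[k:])
        x = np.concatenate(xs).astype(float)
        y = np.concatenate(ys).astype(float)
        if x.std() == 0 or y.std() == 0:
            raise EstimationError("constant start-site density; correlation undefined")
        rs[k] = np.corrcoef(x, y)[0, 1]
    deriv = np.diff(rs)
    smooth = gaussian_filter1d(deriv, sigma=bandwidth, truncate=4.0)
    # the same kernel applied to the curve itself gates out zero-crossings
    # of pure noise: a candidate must sit in the upper half of the smoothed
    # correlation's range
    smooth_r = gaussian_filter1d(rs, sigma=bandwidth, truncate=4.0)
    lo, hi = smooth_r[min_offset:].min(), smooth_r[min_offset:].max()
    prominence_floor = lo + 0.5 * (hi - lo)
    for k in range(max(min_offset, 1), len(smooth)):
        if smooth[k] <= 0 and smooth[k - 1] > 0 and smooth_r[k] >= prominence_floor:
            return FragmentSizeEstimate(
                L=k,
                cross_correlation=rs,
                smoothing_bandwidth=bandwidth,
                zero_crossing_offset=k,
            )
    raise EstimationError(
        "no downward zero-crossing found; increase max_offset"
    )


@dataclass
class OccupancyProfile:
    """Normalized (or raw) per-chromosome density with a validity mask."""

    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]  # True = usable
    L: int
    read_length: int | None = None
    combined: dict[str, np.ndarray] | None = None
    n_truncated: int = 0

    def chroms(self) -> list[str]:
        return sorted(self.plus)


def impute_density(
    records,
    L: int,
    chrom_sizes: dict[str, int],
    read_length: int | None = None,
    dedup: bool = True,
) -> OccupancyProfile:
    """Imputed-fragment density: each read start extended L bp 3'-ward.

    Plus-strand reads cover ``[start, start + L)``; minus-strand reads
    extend leftward from their 3'-end start, covering ``[end - L, end)``.
    Fragments crossing a chromosome boundary are truncated and counted.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    starts = start_site_density(records, chrom_sizes, dedup=dedup)
    out = {}
    truncated = 0
    for strand, src in (("+", starts.plus), ("-", starts.minus)):
        dens = {}
        for chrom, vec in src.items():
            n = len(vec)
            diff = np.zeros(n + 1)
            positions = np.nonzero(vec)[0]
            for pos in positions:
                count = vec[pos]
                if strand == "+":
                    lo, hi = pos, min(n, pos + L)
                    if pos + L > n:
                        truncated += count
                else:
                    lo, hi = max(0, pos + 1 - L), pos + 1
                    if pos + 1 - L < 0:
                        truncated += count
                diff[lo] += count
                diff[hi] -= count
            dens[chrom] = np.cumsum(diff[:-1])
        out[strand] = dens
    mask = {c: np.ones(n, dtype=bool) for c, n in chrom_sizes.items()}
    return OccupancyProfile(
        plus=out["+"],
        minus=out["-"],
        mask=mask,
        L=L,
        read_length=read_length,
        n_truncated=truncated,
    )


def merge_replicates(profiles: list[OccupancyProfile]) -> OccupancyProfile:
    """Replicates merge by adding their (unnormalized) density vectors."""
    first = profiles[0]
    if any(p.L != first.L for p in profiles):
        raise ValueError("replicates must share L")
    plus = {
        c: sum(p.plus[c] for p in profiles) for c in first.plus
    }
    minus = {
        c: sum(p.minus[c] for p in profiles) for c in first.minus
    }
    return OccupancyProfile(
        plus=plus,
        minus=minus,
        mask={c: m.copy() for c, m in first.mask.items()},
        L=first.L,
        read_length=first.read_length,
        n_truncated=sum(p.n_truncated for p in profiles),
    )


@dataclass
class MappabilityTrack:
    """Uniquely-mappable read-start positions per strand (True = unique)."""

    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]
    read_length: int


def mappability_track(genome: dict[str, str], read_length: int) -> MappabilityTrack:
    """Mark read-start positions whose error-free read maps uniquely.

    A plus-strand start at p is unique iff the k-mer ``genome[p:p+k]``
    occurs exactly once over both strands of the whole genome; a
    minus-strand start at p (the read's 3'-most genomic position) is unique
    iff the reverse complement of ``genome[p-k+1:p+1]`` does.  Equivalent
    to exhaustive error-free alignment of all possible reads.
    """
    k = read_length
    if k < 1:
        raise ValueError("read_length must be >= 1")
    from .homology import revcomp

    counts: dict[str, int] = {}
    for chrom, seq in genome.items():
        if k > len(seq):
            raise ValueError(f"read_length {k} exceeds chromosome {chrom}")
        seq = seq.upper()
        rc = revcomp(seq)
        for s in (seq, rc):
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                counts[kmer] = counts.get(kmer, 0) + 1
    plus, minus = {}, {}
    for chrom, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        p_track = np.zeros(n, dtype=bool)
        m_track = np.zeros(n, dtype=bool)
        for i in range(n - k + 1):
            kmer = seq[i : i + k]
            if counts.get(kmer, 0) == 1:
                p_track[i] = True
        for i in range(k - 1, n):
            kmer = revcomp(seq[i - k + 1 : i + 1])
            if counts.get(kmer, 0) == 1:
                m_track[i] = True
        plus[chrom] = p_track
        minus[chrom] = m_track
    return MappabilityTrack(plus=plus, minus=minus, read_length=k)


def _upstream_window_counts(track: np.ndarray, L: int, direction: str) -> np.ndarray:
    """Mappable-start counts in the L-window upstream of each position.

    For plus-strand density the window is [p-L+1, p] (fragments covering p
    start there); for minus-strand density it is [p, p+L-1].
    """
    cs = np.concatenate([[0], np.cumsum(track.astype(np.int64))])
    n = len(track)
    idx = np.arange(n)
    if direction == "+":
        lo = np.maximum(0, idx - L + 1)
        return cs[idx + 1] - cs[lo]
    hi = np.minimum(n, idx + L)
    return cs[hi] - cs[idx]


def normalize_density(
    profile: OccupancyProfile,
    track: MappabilityTrack,
    L: int | None = None,
    sum_before_normalize: bool = False,
) -> OccupancyProfile:
    """Mappability-normalize per strand, mask dead windows, then sum strands.

    Each position's density is divided by (mappable starts in its upstream
    L-window) / L; positions whose window holds zero mappable starts are
    masked.  ``sum_before_normalize`` switches to normalizing the
    strand-summed density by the combined window counts (sensitivity
    variant).
    """
    if L is None:
        L = profile.L
    if L != profile.L:
        raise ValueError(
            f"normalization L={L} differs from imputation L={profile.L}"
        )
    combined, mask = {}, {}
    for chrom in profile.chroms():
        wp = _upstream_window_counts(track.plus[chrom], L, "+")
        wm = _upstream_window_counts(track.minus[chrom], L, "-")
        if sum_before_normalize:
            w = wp + wm
            ok = w > 0
            dens = np.zeros_like(profile.plus[chrom])
            total = profile.plus[chrom] + profile.minus[chrom]
            dens[ok] = total[ok] / (w[ok] / (2.0 * L))
        else:
            ok = (wp > 0) & (wm > 0)
            dens = np.zeros_like(profile.plus[chrom])
            dens[ok] = profile.plus[chrom][ok] / (wp[ok] / L) + profile.minus[
                chrom
            ][ok] / (wm[ok] / L)
        combined[chrom] = dens
        mask[chrom] = ok & profile.mask[chrom]
    return OccupancyProfile(
        plus=profile.plus,
        minus=profile.minus,
        mask=mask,
        L=profile.L,
        read_length=track.read_length,
        combined=combined,
        n_truncated=profile.n_truncated,
    )


def transfer_to_reference(
    query_profile: OccupancyProfile,
    one_to_one: ChainMap,
    ref_chrom_sizes: dict[str, int],
) -> OccupancyProfile:
    """Project a query-coordinate profile onto reference coordinates.

    Every aligned block of the one-to-one chain map copies query values to
    their reference positions (minus-strand chains reverse the block).
    Unmapped reference positions stay masked.
    """
    if query_profile.combined is None:
        raise ValueError("normalize the profile before transfer")
    combined = {c: np.zeros(n) for c, n in ref_chrom_sizes.items()}
    mask = {c: np.zeros(n, dtype=bool) for c, n in ref_chrom_sizes.items()}
    for chain in one_to_one.chains:
        if chain.t_name not in combined:
            continue
        qvec = query_profile.combined.get(chain.q_name)
        qmask = query_profile.mask.get(chain.q_name)
        if qvec is None:
            continue
        for t0, q0, size in chain.blocks:
            if chain.q_strand == "+":
                vals = qvec[q0 : q0 + size]
                ok = qmask[q0 : q0 + size]
            else:
                lo = chain.q_size - (q0 + size)
                hi = chain.q_size - q0
                vals = qvec[lo:hi][::-1]
                ok = qmask[lo:hi][::-1]
            combined[chain.t_name][t0 : t0 + size] = vals
            mask[chain.t_name][t0 : t0 + size] = ok
    return OccupancyProfile(
        plus={},
        minus={},
        mask=mask,
        L=query_profile.L,
        read_length=query_profile.read_length,
        combined=combined,
    )


def correlate_profiles(
    profile_ref: OccupancyProfile,
    profile_query_on_ref: OccupancyProfile,
) -> float:
    """Pearson r over concatenated usable positions of both profiles."""
    xs, ys = [], []
    for chrom in profile_ref.chroms():
        if chrom not in profile_query_on_ref.mask:
            continue
        ok = profile_ref.mask[chrom] & profile_query_on_ref.mask[chrom]
        xs.append(profile_ref.combined[chrom][ok])
        ys.append(profile_query_on_ref.combined[chrom][ok])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 2:
        raise ValueError("fewer than 2 usable positions")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(pearsonr(x, y)[0])
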