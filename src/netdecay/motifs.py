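"""PWM scanning with exact p-value thresholds and the motif-retention statistic.

Motif matches are scored with a log-odds position weight matrix (counts
plus a pseudocount against a 0-order background).  The score cutoff for a
significance level alpha (default 1e-4, the conventional genome-scan
threshold) comes from the exact null score distribution, computed by
dynamic programming over positions with background-weighted base
probabilities; log-odds entries are rounded to a fixed decimal precision
so the distribution is exact over the discrete score lattice.

Cross-species motif retention: reference matches are lifted to the query
genome (minMatch 0.001), lifted loci are extended by 50 bp and re-scanned;
the same count on location-shuffled loci estimates the background, and

    F = (mapped_with_motif - shuffled_mapped_with_motif) / mapped * 100

is the percentage of loci retaining the motif in excess of background --
the similarity measure the rate framework consumes for this layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .homology import ChainMap, LiftParams, lift_interval, revcomp

ALPHABET = "ACGT"
DEFAULT_ALPHA = 1e-4
DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_EXTENSION = 50
#: decimal places of log-odds rounding (the exact-DP score lattice)
SCORE_DECIMALS = 3

_IDX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(ALPHABET):
    _IDX[ord(_b)] = _i
    _IDX[ord(_b.lower())] = _i


@dataclass(frozen=True)
class PWM:
    """Log-odds position weight matrix over {A, C, G, T}.

    ``log_odds`` has shape (length, 4); entries are rounded to
    ``SCORE_DECIMALS`` decimals.  ``probabilities`` are the pseudocounted
    column distributions used for sampling site sequences.
    """

    name: str
    log_odds: np.ndarray
    probabilities: np.ndarray
    background: tuple[float, float, float, float]

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.log_odds.argmax(axis=1))


def pwm_from_counts(
    counts: np.ndarray,
    name: str = "",
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PWM:
    """Build a log-odds PWM from a (length, 4) count matrix."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must be (length, 4)")
    bg = np.asarray(background, dtype=float)
    if not math.isclose(bg.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("background must sum to 1")
    probs = (counts + pseudocount) / (counts + pseudocount).sum(
        axis=1, keepdims=True
    )
    lo = np.round(np.log2(probs / bg), SCORE_DECIMALS)
    return PWM(
        name=name,
        log_odds=lo,
        probabilities=probs,
        background=tuple(bg),
    )


def read_jaspar(path, **kwargs) -> PWM:
    """Read a JASPAR .pfm / .jaspar count file (one motif, 4 base rows)."""
    name = ""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                continue
            tokens = line.replace("[", " ").replace("]", " ").split()
            if tokens and len(tokens[0]) == 1 and tokens[0] in ALPHABET:
                tokens = tokens[1:]
            rows.append([float(t) for t in tokens])
    if len(rows) != 4:
        raise ValueError(f"expected 4 base rows in {path}, got {len(rows)}")
    return pwm_from_counts(np.array(rows).T, name=name, **kwargs)


def read_meme(path, **kwargs) -> list[PWM]:
    """Read motifs from MEME minimal format (letter-probability matrices).

    Probability rows are rescaled by nsites (or 100 when absent) into
    pseudo-counts before log-odds conversion.
    """
    pwms = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i = 0
    while i < len(lines):
        if lines[i].startswith("MOTIF"):
            name = lines[i].split()[1]
            while i < len(lines) and not lines[i].startswith("letter-probability"):
                i += 1
            if i == len(lines):
                break
            tokens = lines[i].replace("=", " ").split()
            width = int(tokens[tokens.index("w") + 1]) if "w" in tokens else None
            nsites = (
                float(tokens[tokens.index("nsites") + 1])
                if "nsites" in tokens
                else 100.0
            )
            rows = []
            i += 1
            while i < len(lines) and len(rows) < (width or 10**9):
                if lines[i]:
                    rows.append([float(x) for x in lines[i].split()])
                i += 1
            pwms.append(
                pwm_from_counts(np.array(rows) * nsites, name=name, **kwargs)
            )
        else:
            i += 1
    return pwms


def genome_background(genome: dict[str, str]) -> tuple[float, float, float, float]:
    """0-order base composition of a genome (strand-symmetrized)."""
    counts = np.zeros(4)
    for seq in genome.values():
        idx = _IDX[np.frombuffer(seq.encode(), dtype=np.uint8)]
        valid = idx[idx >= 0]
        counts += np.bincount(valid, minlength=4)
    # strand symmetry: A<->T, C<->G
    counts = (counts + counts[::-1]) / 2.0
    return tuple(counts / counts.sum())


def pwm_pvalue_threshold(
    pwm: PWM, alpha: float = DEFAULT_ALPHA
) -> float:
    """Smallest score c with P(score >= c | background) < alpha, by exact DP.

    The null distribution of word scores is computed over the integer score
    lattice implied by the rounded log-odds entries, weighting each base by
    the PWM's background.  Returns the cutoff on the log-odds scale.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if pwm.length > 30:
        raise ValueError("PWM too long for exact DP (length > 30)")
    scale = 10**SCORE_DECIMALS
    ints = np.round(pwm.log_odds * scale).astype(np.int64)
    bg = np.asarray(pwm.background)
    offset = int(-ints.min(axis=1).sum())  # shift so all sums are >= 0
    span = int((ints.max(axis=1) - ints.min(axis=1)).sum()) + 1
    dist = np.zeros(span)
    dist[0] = 1.0
    floor_shift = 0
    for j in range(pwm.length):
        nxt = np.zeros(span)
        col_min = ints[j].min()
        for b in range(4):
            shift = int(ints[j, b] - col_min)
            if shift == 0:
                nxt += bg[b] * dist
            else:
                nxt[shift:] += bg[b] * dist[:-shift]
        dist = nxt
        floor_shift += int(col_min)
    # dist[i] = P(total integer score == i + floor_shift)
    reachable = dist > 0
    if alpha >= 1.0:  # every word passes, including the worst
        return (int(np.nonzero(reachable)[0][0]) + floor_shift) / scale
    tail = np.cumsum(dist[::-1])[::-1]
    passing = np.nonzero((tail < alpha) & reachable)[0]
    if len(passing) == 0:
        return float("inf")  # not even the best word reaches alpha
    return (int(passing[0]) + floor_shift) / scale


def scan_sequence(seq: str, pwm: PWM, cutoff: float):
    """All positions (both strands) scoring >= cutoff; 0-based half-open.

    Returns a list of (start, end, score, strand).
    """
    w = pwm.length
    n = len(seq)
    if n < w:
        return []
    idx = _IDX[np.frombuffer(seq.encode(), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    cols = np.arange(w)
    fwd = pwm.log_odds[cols, safe].sum(axis=1)
    # reverse strand: score of revcomp window = reversed complement matrix
    rc_matrix = pwm.log_odds[::-1, ::-1]
    rev = rc_matrix[cols, safe].sum(axis=1)
    hits = []
    tol = 10.0 ** (-SCORE_DECIMALS) / 2
    for strand, scores in (("+", fwd), ("-", rev)):
        ok = valid & (scores >= cutoff - tol)
        for p in np.nonzero(ok)[0]:
            hits.append((int(p), int(p) + w, float(scores[p]), strand))
    return sorted(hits)


def scan_genome(genome: dict[str, str], pwm: PWM, cutoff: float):
    """Scan every chromosome; returns (chrom, start, end, score, strand) hits."""
    out = []
    for chrom in sorted(genome):
        for start, end, score, strand in scan_sequence(genome[chrom], pwm, cutoff):
            out.append((chrom, start, end, score, strand))
    return out


@dataclass(frozen=True)
class MotifRetention:
    """Counts and the background-corrected retention percentage F."""

    mapped: int
    mapped_with_motif: int
    shuffled_mapped_with_motif: int
    F: float

    def __post_init__(self) -> None:
        if min(self.mapped, self.mapped_with_motif,
               self.shuffled_mapped_with_motif) < 0:
            raise ValueError("counts must be >= 0")
        if self.mapped_with_motif > self.mapped:
            raise ValueError("mapped_with_motif cannot exceed mapped")
        expected = retention_F(
            self.mapped, self.mapped_with_motif, self.shuffled_mapped_with_motif
        )
        if not math.isclose(self.F, expected, abs_tol=1e-9):
            raise ValueError("F inconsistent with counts")


def retention_F(mapped: int, mapped_with_motif: int, shuffled: int) -> float:
    """F = (mapped_with_motif - shuffled_mapped_with_motif) / mapped * 100."""
    if mapped == 0:
        raise ValueError("F undefined with zero mapped segments")
    return (mapped_with_motif - shuffled) / mapped * 100.0


def _contains_hit(seq: str, pwm: PWM, cutoff: float) -> bool:
    w = pwm.length
    n = len(seq)
    if n < w:
        return False
    idx = _IDX[np.frombuffer(seq.encode(), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return False
    safe = np.where(windows >= 0, windows, 0)
    cols = np.arange(w)
    tol = 10.0 ** (-SCORE_DECIMALS) / 2
    fwd = pwm.log_odds[cols, safe].sum(axis=1)
    if bool((valid & (fwd >= cutoff - tol)).any()):
        return True
    rc = pwm.log_odds[::-1, ::-1]
    rev = rc[cols, safe].sum(axis=1)
    return bool((valid & (rev >= cutoff - tol)).any())


def motif_retention(
    matches,
    chain_map: ChainMap,
    query_genome: dict[str, str],
    pwm: PWM,
    cutoff: float,
    rng: np.random.Generator,
    extension: int = DEFAULT_EXTENSION,
    two_sided: bool = True,
    lift_params: LiftParams | None = None,
) -> MotifRetention:
    """Cross-species motif retention with a shuffled-location background.

    ``matches`` are reference-genome scan hits.  Each is lifted through the
    chain map (minMatch 0.001 by default); successful lifts are extended by
    ``extension`` bp (both directions unless ``two_sided`` is False, then
    downstream only) and scanned for any motif occurrence.  The shuffled
    control re-places the lifted segments uniformly on the same query
    chromosome and re-scans.
    """
    params = lift_params if lift_params is not None else LiftParams()
    lifted = []
    for chrom, start, end, _score, _strand in matches:
        res = lift_interval((chrom, start, end), chain_map, params)
        if res.ok:
            lifted.append((res.chrom, res.start, res.end))
    mapped = len(lifted)
    if mapped == 0:
        raise ValueError("no matches lifted; F undefined")
    with_motif = 0
    shuffled_with_motif = 0
    for chrom, start, end in lifted:
        seq = query_genome[chrom]
        lo = max(0, start - (extension if two_sided else 0))
        hi = min(len(seq), end + extension)
        if _contains_hit(seq[lo:hi], pwm, cutoff):
            with_motif += 1
        seg_len = hi - lo
        s = int(rng.integers(0, len(seq) - seg_len + 1))
        if _contains_hit(seq[s : s + seg_len], pwm, cutoff):
            shuffled_with_motif += 1
    return MotifRetention(
        mapped=mapped,
        mapped_with_motif=with_motif,
        shuffled_mapped_with_motif=shuffled_with_motif,
        F=retention_F(mapped, with_motif, shuffled_with_motif),
    )
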