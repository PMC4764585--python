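"""Segment-resolution occupancy comparison across a grid of analysis pipelines.

Cross-species conservation of TF binding is notoriously sensitive to
analytical choices.  This module enumerates the full factorial grid of five
choice axes -- peak caller variant (2) x quality filter (3) x liftOver
minMatch (3) x reference subset (3) x overlap rule (2) = 108 pipelines --
and, for each pipeline, measures the fraction of reference-occupied
segments that retain occupancy in each other species; those fractions are
the similarity series fed to the rate-comparison framework.

External peak callers are deliberately not re-implemented.  A single
internal Poisson-enrichment caller with two window-size variants (the
caller axis) and lenient/stringent significance tiers stands in for them;
the stringent tier of variant B selects the top-scoring tie class of
windows rather than using a fixed cutoff, mirroring how q-value-saturated
callers behave.  The axis still changes results, which is what the grid is
probing.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from .homology import ChainMap, LiftParams, LiftResult, lift_interval
from .occupancy import OccupancyProfile
from .ratecomp import RateComparison, SimilarityObservation, compare_rates

logger = logging.getLogger(__name__)

PEAK_CALLERS = ("M", "S")  # window-size variants A/B of the stand-in caller
QUALITY_FILTERS = ("S", "L", "A")  # stringent / lenient / asymmetric
MIN_MATCH_LEVELS = {"S": 0.95, "L": 0.5, "N": 0.001}
REFERENCE_SUBSETS = ("A", "P", "S")  # all / pairwise-mappable / all-species
OVERLAP_RULES = ("L", "S")  # >=1 bp / reciprocal >=50%

CALLER_WINDOW = {"M": 150, "S": 75}
LENIENT_P = 1e-5
STRINGENT_P = 1e-22


@dataclass(frozen=True)
class PipelineChoice:
    """One cell of the 108-pipeline grid."""

    peak_caller: str
    quality: str
    min_match: str
    reference_subset: str
    overlap: str

    def __post_init__(self) -> None:
        if (
            self.peak_caller not in PEAK_CALLERS
            or self.quality not in QUALITY_FILTERS
            or self.min_match not in MIN_MATCH_LEVELS
            or self.reference_subset not in REFERENCE_SUBSETS
            or self.overlap not in OVERLAP_RULES
        ):
            raise ValueError(f"invalid pipeline choice {self}")

    def label(self) -> str:
        return "".join(
            [self.peak_caller, self.quality, self.min_match,
             self.reference_subset, self.overlap]
        )


def enumerate_pipelines() -> list[PipelineChoice]:
    """The full factorial grid (2 x 3 x 3 x 3 x 2 = 108 pipelines)."""
    return [
        PipelineChoice(*combo)
        for combo in itertools.product(
            PEAK_CALLERS, QUALITY_FILTERS, sorted(MIN_MATCH_LEVELS),
            REFERENCE_SUBSETS, OVERLAP_RULES,
        )
    ]


@dataclass
class PeakSet:
    """Sorted, non-overlapping scored intervals on one genome."""

    intervals: list[tuple[str, int, int, float]]  # chrom, start, end, score
    tier: str | None = None

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)
        for (c1, s1, e1, _), (c2, s2, e2, _) in zip(
            self.intervals, self.intervals[1:]
        ):
            if c1 == c2 and s2 < e1:
                raise ValueError("peak intervals overlap after merge")

    def __len__(self) -> int:
        return len(self.intervals)

    def as_tuples(self) -> list[tuple[str, int, int]]:
        return [(c, s, e) for c, s, e, _ in self.intervals]


def _merge_scored(windows: list[tuple[str, int, int, float]]):
    """Merge touching/overlapping windows, keeping the best score."""
    merged = []
    for chrom, start, end, score in sorted(windows):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            c, s, e, sc = merged[-1]
            merged[-1] = (c, s, max(e, end), max(sc, score))
        else:
            merged.append((chrom, start, end, score))
    return merged


def call_peaks_standin(
    profile: OccupancyProfile,
    control: OccupancyProfile | None,
    tier: str,
    caller: str = "M",
) -> PeakSet:
    """Poisson-enrichment peak calling on imputed-fragment density.

    Non-overlapping windows of the caller variant's width are tested for
    read-density enrichment against the (library-size scaled) control with
    a Poisson upper-tail p-value.  ``tier`` "lenient" uses p < 1e-5;
    "stringent" uses p < 1e-22, except for caller variant "S" where the
    stringent tier keeps the top-scoring tie class of windows.  Adjacent
    significant windows are merged.
    """
    if tier not in ("lenient", "stringent"):
        raise ValueError("tier must be 'lenient' or 'stringent'")
    w = CALLER_WINDOW[caller]
    windows = []  # (chrom, start, end, -log10 p)
    for chrom in profile.chroms():
        dens = profile.plus[chrom] + profile.minus[chrom]
        n = len(dens)
        n_win = n // w
        if n_win == 0:
            continue
        sig = dens[: n_win * w].reshape(n_win, w).sum(axis=1) / profile.L
        if control is not None and chrom in control.plus:
            ctl_dens = control.plus[chrom] + control.minus[chrom]
            ctl = ctl_dens[: n_win * w].reshape(n_win, w).sum(axis=1) / control.L
            scale = sig.sum() / max(ctl.sum(), 1e-9)
            lam = np.maximum(ctl * scale, sig.mean())
        else:
            logger.info("empty control; using global background rate")
            lam = np.full(n_win, max(sig.mean(), 1e-9))
        logp = -poisson.logsf(np.round(sig) - 1, lam) / math.log(10)
        for i in np.nonzero(logp > -math.log10(LENIENT_P))[0]:
            windows.append((chrom, int(i) * w, (int(i) + 1) * w, float(logp[i])))
    if tier == "stringent":
        if caller == "S" and windows:
            best = max(score for *_x, score in windows)
            windows = [v for v in windows if v[3] >= best - 1e-9]
        else:
            windows = [v for v in windows if v[3] > -math.log10(STRINGENT_P)]
    return PeakSet(intervals=_merge_scored(windows), tier=tier)


def combine_replicates(
    peaks_rep1: PeakSet, peaks_rep2: PeakSet, mode: str
) -> PeakSet:
    """Merge or intersect two replicate peak sets.

    ``merge`` is the interval union; ``intersect`` keeps merged segments
    supported by at least one segment in each original replicate.
    """
    if mode not in ("merge", "intersect"):
        raise ValueError("mode must be 'merge' or 'intersect'")
    union = _merge_scored(peaks_rep1.intervals + peaks_rep2.intervals)
    if mode == "merge":
        return PeakSet(intervals=union)
    kept = []
    for chrom, start, end, score in union:
        if _any_overlap(chrom, start, end, peaks_rep1) and _any_overlap(
            chrom, start, end, peaks_rep2
        ):
            kept.append((chrom, start, end, score))
    return PeakSet(intervals=kept)


def _any_overlap(chrom: str, start: int, end: int, peaks: PeakSet) -> bool:
    return any(
        c == chrom and s < end and start < e for c, s, e, _ in peaks.intervals
    )


def select_reference_subset(
    ref_peaks: PeakSet,
    lift_results: dict[str, list[LiftResult]],
    mode: str,
    pair_species: str | None = None,
) -> list[int]:
    """Indices of reference peaks kept under subset rule A / P / S.

    ``A`` keeps all; ``P`` keeps peaks mappable to the current pair's
    species (``pair_species``); ``S`` keeps peaks mappable to every species
    in ``lift_results``.
    """
    n = len(ref_peaks)
    if mode == "A":
        return list(range(n))
    if mode == "P":
        if pair_species is None:
            raise ValueError("mode P needs pair_species")
        return [i for i in range(n) if lift_results[pair_species][i].ok]
    if mode == "S":
        return [
            i
            for i in range(n)
            if all(res[i].ok for res in lift_results.values())
        ]
    raise ValueError(f"unknown subset mode {mode!r}")


def occupancy_overlap_fraction(
    projected: list[LiftResult],
    query_peaks: PeakSet,
    mode: str,
) -> float:
    """Fraction of projected reference segments overlapping a query peak.

    ``L`` requires >= 1 bp of overlap; ``S`` requires a reciprocal overlap
    of at least half of each segment's length.
    """
    if mode not in ("L", "S"):
        raise ValueError("mode must be 'L' or 'S'")
    usable = [r for r in projected if r.ok]
    if not usable:
        raise ValueError("empty reference subset")
    hits = 0
    for r in usable:
        seg_len = r.end - r.start
        for chrom, s, e, _score in query_peaks.intervals:
            if chrom != r.chrom:
                continue
            ov = min(e, r.end) - max(s, r.start)
            if ov <= 0:
                continue
            if mode == "L":
                hits += 1
                break
            if ov >= 0.5 * seg_len and ov >= 0.5 * (e - s):
                hits += 1
                break
    return hits / len(usable)


# ---------------------------------------------------------------------------
# grid orchestration


@dataclass
class SpeciesChip:
    """Per-species inputs to the grid: replicate profiles + control + chain."""

    replicates: list[OccupancyProfile]
    control: OccupancyProfile | None
    chain: ChainMap | None  # None for the reference species itself
    divergence_myr: float


def _peaks_for(
    species_data: SpeciesChip, caller: str, tier: str
) -> PeakSet:
    reps = [
        call_peaks_standin(p, species_data.control, tier, caller)
        for p in species_data.replicates
    ]
    if len(reps) == 1:
        return reps[0]
    mode = "merge" if tier == "lenient" else "intersect"
    out = reps[0]
    for nxt in reps[1:]:
        out = combine_replicates(out, nxt, mode)
    return out


def pipeline_similarities(
    lineage_data: dict[str, SpeciesChip],
    reference: str,
    choice: PipelineChoice,
) -> list[SimilarityObservation]:
    """Run one pipeline on one lineage; per-species retention fractions.

    The asymmetric quality filter calls reference peaks stringently and
    query peaks leniently; S/L use the same tier on both sides.
    """
    ref_tier = {"S": "stringent", "L": "lenient", "A": "stringent"}[choice.quality]
    qry_tier = {"S": "stringent", "L": "lenient", "A": "lenient"}[choice.quality]
    ref_peaks = _peaks_for(lineage_data[reference], choice.peak_caller, ref_tier)
    params = LiftParams(min_match=MIN_MATCH_LEVELS[choice.min_match])
    others = sorted(sp for sp in lineage_data if sp != reference)
    lifts = {
        sp: [
            lift_interval((c, s, e), lineage_data[sp].chain, params)
            for c, s, e in ref_peaks.as_tuples()
        ]
        for sp in others
    }
    obs = []
    for sp in others:
        idx = select_reference_subset(
            ref_peaks, lifts, choice.reference_subset, pair_species=sp
        )
        projected = [lifts[sp][i] for i in idx]
        q_peaks = _peaks_for(lineage_data[sp], choice.peak_caller, qry_tier)
        frac = occupancy_overlap_fraction(projected, q_peaks, choice.overlap)
        obs.append(
            SimilarityObservation(
                similarity=frac,
                divergence_myr=lineage_data[sp].divergence_myr,
                lineage="",
                pair_id=f"{reference}|{sp}",
            )
        )
    return obs


def run_grid(
    lineages: dict[str, tuple[str, dict[str, SpeciesChip]]],
    factor_pairs: list[tuple[str, str]] | None = None,
    choices: list[PipelineChoice] | None = None,
    **compare_kwargs,
):
    """Execute pipelines over lineage datasets and compare rates per pair.

    ``lineages`` maps a dataset key "lineage/factor" to (reference species,
    per-species data).  ``factor_pairs`` lists the dataset-key pairs to
    compare (defaults to all cross-lineage pairs).  Returns a list of dicts
    with the pipeline label, the pair, the similarity series, and the
    :class:`RateComparison` verdict.
    """
    if choices is None:
        choices = enumerate_pipelines()
    keys = sorted(lineages)
    if factor_pairs is None:
        factor_pairs = [
            (a, b)
            for i, a in enumerate(keys)
            for b in keys[i + 1 :]
            if a.split("/")[0] != b.split("/")[0]
        ]
    results = []
    for choice in choices:
        series = {}
        for key in keys:
            ref, data = lineages[key]
            try:
                series[key] = pipeline_similarities(data, ref, choice)
            except ValueError as exc:  # e.g. empty reference subset
                logger.warning("pipeline %s lineage %s failed: %s",
                               choice.label(), key, exc)
                series[key] = None
        for a, b in factor_pairs:
            if series[a] is None or series[b] is None:
                results.append(
                    {
                        "pipeline": choice.label(),
                        "choice": choice,
                        "pair": (a, b),
                        "observations": [],
                        "comparison": None,
                        "verdict": "unresolved",
                    }
                )
                continue
            obs = [
                SimilarityObservation(o.similarity, o.divergence_myr, a, o.pair_id)
                for o in series[a]
            ] + [
                SimilarityObservation(o.similarity, o.divergence_myr, b, o.pair_id)
                for o in series[b]
            ]
            try:
                cmp_res: RateComparison | None = compare_rates(obs, **compare_kwargs)
                verdict = cmp_res.verdict
            except Exception as exc:  # degenerate series stay unresolved
                logger.warning("pipeline %s pair %s|%s failed: %s",
                               choice.label(), a, b, exc)
                cmp_res, verdict = None, "unresolved"
            results.append(
                {
                    "pipeline": choice.label(),
                    "choice": choice,
                    "pair": (a, b),
                    "observations": obs,
                    "comparison": cmp_res,
                    "verdict": verdict,
                }
            )
    return results
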