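"""Statistical framework for comparing evolutionary divergence rates between lineages.

Cross-species similarity (a correlation, a retention fraction, a percent
identity ...) is modelled as an exponential decay over divergence time,
``s(t) = exp(a + b * t)``, fitted by ordinary least squares in log-linear
space.  Three nested model structures are fitted to the same observations:

* **naive** — one shared intercept and one shared slope for all lineages;
* **aware** — one shared intercept, one slope per lineage;
* **specific** — an independent (intercept, slope) pair per lineage.

The naive and aware models are compared with a likelihood-ratio test
(Gaussian errors, statistic ``n * log(RSS0 / RSS1)``, chi-square reference
with df equal to the difference in parameter counts; an F-test variant is
available).  The effect size is the largest predicted absolute difference in
similarity between any two lineages after a fixed horizon (100 Myrs by
default), expressed in percentage points.  Rates are declared *different*
only when the test is significant (p < alpha) AND the effect size exceeds
the threshold (5 percentage points by default); otherwise they are
*indistinguishable*.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: decision-rule defaults
DEFAULT_ALPHA = 0.05
DEFAULT_EFFECT_THRESHOLD_PCT = 5.0
DEFAULT_HORIZON_MYR = 100.0

MODEL_KINDS = ("naive", "aware", "specific")
VERDICT_DIFFERENT = "different"
VERDICT_INDISTINGUISHABLE = "indistinguishable"


class DegreesOfFreedomError(ValueError):
    """Too few observations for the number of free parameters requested."""


class EmptyInputError(ValueError):
    """No usable (strictly positive) similarity observations."""


class ContractViolationError(ValueError):
    """Model-comparison preconditions (nesting, identical data) violated."""


@dataclass(frozen=True)
class SimilarityObservation:
    """One cross-species similarity measurement.

    Parameters
    ----------
    similarity
        Pairwise cross-species similarity (correlation, fraction retained,
        identity ...); must be finite.  Only strictly positive values can
        enter the log-linear fit.
    divergence_myr
        Pairwise evolutionary distance in millions of years; nonnegative.
    lineage
        Categorical lineage label (e.g. ``"Mammalia"``).
    pair_id
        Free-text identifier of the species pair.
    """

    similarity: float
    divergence_myr: float
    lineage: str
    pair_id: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.similarity):
            raise ValueError(f"similarity must be finite, got {self.similarity}")
        if not (self.divergence_myr >= 0):
            raise ValueError(
                f"divergence_myr must be >= 0, got {self.divergence_myr}"
            )


@dataclass(frozen=True)
class DecayFit:
    """A fitted log-linear exponential-decay model.

    ``intercepts`` maps lineage -> intercept (identical values for the naive
    and aware structures, which share one intercept) and ``slopes`` maps
    lineage -> decay rate per Myr (identical values for the naive structure).
    ``rss`` is the residual sum of squares of log-similarity.
    """

    model_kind: str
    intercepts: dict[str, float]
    slopes: dict[str, float]
    rss: float
    n_obs: int
    n_params: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.rss < -1e-12:
            raise ValueError("rss must be nonnegative")
        if self.n_params >= self.n_obs:
            raise DegreesOfFreedomError(
                f"{self.n_params} parameters for {self.n_obs} observations"
            )

    @property
    def lineages(self) -> list[str]:
        return sorted(self.slopes)

    def predict(self, lineage: str, t: float) -> float:
        """Predicted similarity for ``lineage`` after ``t`` Myrs."""
        return math.exp(self.intercepts[lineage] + self.slopes[lineage] * t)


@dataclass(frozen=True)
class RateComparison:
    """Outcome of the full naive-vs-aware rate comparison."""

    p_value: float
    effect_size_pct: float
    verdict: str
    fits: dict[str, DecayFit]
    pairwise_effects_pct: dict[tuple[str, str], float] = field(default_factory=dict)
    alpha: float = DEFAULT_ALPHA
    effect_threshold_pct: float = DEFAULT_EFFECT_THRESHOLD_PCT
    horizon_myr: float = DEFAULT_HORIZON_MYR

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")
        if self.effect_size_pct < 0:
            raise ValueError("effect_size_pct must be >= 0")
        expected = (
            VERDICT_DIFFERENT
            if (self.p_value < self.alpha and self.effect_size_pct > self.effect_threshold_pct)
            else VERDICT_INDISTINGUISHABLE
        )
        if self.verdict != expected:
            raise ValueError(
                f"verdict {self.verdict!r} inconsistent with decision rule "
                f"(p={self.p_value}, effect={self.effect_size_pct})"
            )


def _usable_arrays(
    observations: list[SimilarityObservation],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Return (log_similarity, time, lineage labels) of strictly positive obs.

    Non-positive similarities cannot be log-transformed; they are dropped
    with a logged warning and their count is recorded on the fit.
    """
    if not observations:
        raise EmptyInputError("no observations")
    sims = np.array([o.similarity for o in observations], dtype=float)
    times = np.array([o.divergence_myr for o in observations], dtype=float)
    lineages = np.array([o.lineage for o in observations], dtype=object)
    keep = sims > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "dropping %d non-positive similarity observation(s) before log fit",
            n_dropped,
        )
    if not keep.any():
        raise EmptyInputError("all observations have non-positive similarity")
    return np.log(sims[keep]), times[keep], lineages[keep], n_dropped


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def fit_decay(
    observations: list[SimilarityObservation], model_kind: str = "naive"
) -> DecayFit:
    """Least-squares fit of ``log(similarity) = a + b*t`` under a sharing structure.

    ``model_kind`` selects how intercepts/slopes are shared across lineages
    (see module docstring).  Raises :class:`DegreesOfFreedomError` when there
    are fewer than 3 observations per free slope and
    :class:`EmptyInputError` when no strictly positive similarity remains.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    y, t, lin, n_dropped = _usable_arrays(observations)
    labels = sorted(set(lin))
    k = len(labels)
    n = y.size

    if model_kind == "aware" and k == 1:
        warnings.warn(
            "aware model requested with a single lineage; reducing to naive",
            stacklevel=2,
        )
        model_kind = "naive"

    n_slopes = 1 if model_kind == "naive" else k
    if n < 3 * n_slopes:
        raise DegreesOfFreedomError(
            f"{model_kind} model needs >= {3 * n_slopes} observations, got {n}"
        )

    if model_kind == "naive":
        X = np.column_stack([np.ones(n), t])
        beta, rss = _ols(X, y)
        intercepts = {lab: float(beta[0]) for lab in labels}
        slopes = {lab: float(beta[1]) for lab in labels}
        n_params = 2
    elif model_kind == "aware":
        cols = [np.ones(n)]
        for lab in labels:
            cols.append(np.where(lin == lab, t, 0.0))
        beta, rss = _ols(np.column_stack(cols), y)
        intercepts = {lab: float(beta[0]) for lab in labels}
        slopes = {lab: float(beta[1 + i]) for i, lab in enumerate(labels)}
        n_params = 1 + k
    else:  # specific
        intercepts, slopes, rss = {}, {}, 0.0
        for lab in labels:
            m = lin == lab
            if m.sum() < 3:
                raise DegreesOfFreedomError(
                    f"lineage {lab!r} has {int(m.sum())} observations; >= 3 needed"
                )
            beta, r = _ols(np.column_stack([np.ones(int(m.sum())), t[m]]), y[m])
            intercepts[lab] = float(beta[0])
            slopes[lab] = float(beta[1])
            rss += r
        n_params = 2 * k

    return DecayFit(
        model_kind=model_kind,
        intercepts=intercepts,
        slopes=slopes,
        rss=max(rss, 0.0),
        n_obs=n,
        n_params=n_params,
        n_dropped=n_dropped,
    )


def lrt_compare(fit_naive: DecayFit, fit_aware: DecayFit, method: str = "lrt") -> float:
    """p-value comparing a restricted (naive) against a richer (aware) fit.

    ``method="lrt"`` uses the Gaussian likelihood-ratio statistic
    ``n * log(RSS0 / RSS1)`` against a chi-square with df equal to the
    parameter-count difference; ``method="f"`` uses the standard nested-model
    F-test.  Both fits must be on the identical observation set.
    """
    if fit_naive.n_obs != fit_aware.n_obs or fit_naive.n_dropped != fit_aware.n_dropped:
        raise ContractViolationError("fits are not on the same observations")
    if fit_aware.n_params <= fit_naive.n_params:
        raise ContractViolationError("aware fit must have more parameters")
    if fit_aware.rss > fit_naive.rss + 1e-9 * max(1.0, fit_naive.rss):
        raise ContractViolationError("models are not nested (RSS1 > RSS0)")
    n = fit_naive.n_obs
    df = fit_aware.n_params - fit_naive.n_params
    rss0, rss1 = fit_naive.rss, fit_aware.rss
    if rss1 == 0.0:
        return 1.0 if rss0 == 0.0 else 0.0
    if method == "lrt":
        stat = n * math.log(rss0 / rss1)
        return float(stats.chi2.sf(stat, df))
    if method == "f":
        df2 = n - fit_aware.n_params
        if df2 <= 0:
            raise DegreesOfFreedomError("no residual degrees of freedom for F-test")
        f = ((rss0 - rss1) / df) / (rss1 / df2)
        return float(stats.f.sf(f, df, df2))
    raise ValueError(f"unknown method {method!r}")


def effect_size(
    specific_fit: DecayFit, horizon_myr: float = DEFAULT_HORIZON_MYR
) -> tuple[float, dict[tuple[str, str], float]]:
    """Predicted absolute similarity differences between lineage pairs at the horizon.

    Returns ``(max_pairwise_pct, all_pairwise_pct)`` where values are absolute
    differences in similarity units times 100 (percentage points).  The
    maximum over pairs is the decision-rule effect size: a difference is
    claimed if *any* pair of lineages is predicted to differ.
    """
    labs = specific_fit.lineages
    if len(labs) < 2:
        raise ValueError("effect size needs >= 2 lineages")
    preds = {lab: specific_fit.predict(lab, horizon_myr) for lab in labs}
    pairwise = {
        (a, b): abs(preds[a] - preds[b]) * 100.0
        for i, a in enumerate(labs)
        for b in labs[i + 1 :]
    }
    return max(pairwise.values()), pairwise


def compare_rates(
    observations: list[SimilarityObservation],
    alpha: float = DEFAULT_ALPHA,
    effect_threshold_pct: float = DEFAULT_EFFECT_THRESHOLD_PCT,
    horizon_myr: float = DEFAULT_HORIZON_MYR,
    method: str = "lrt",
) -> RateComparison:
    """Full decision pipeline: fit all three structures, test, gate, decide."""
    lineage_set = {o.lineage for o in observations}
    if len(lineage_set) < 2:
        raise ValueError("compare_rates needs >= 2 lineages")
    fit_n = fit_decay(observations, "naive")
    fit_a = fit_decay(observations, "aware")
    fit_s = fit_decay(observations, "specific")
    p = lrt_compare(fit_n, fit_a, method=method)
    eff, pairwise = effect_size(fit_s, horizon_myr)
    verdict = (
        VERDICT_DIFFERENT
        if (p < alpha and eff > effect_threshold_pct)
        else VERDICT_INDISTINGUISHABLE
    )
    return RateComparison(
        p_value=p,
        effect_size_pct=eff,
        verdict=verdict,
        fits={"naive": fit_n, "aware": fit_a, "specific": fit_s},
        pairwise_effects_pct=pairwise,
        alpha=alpha,
        effect_threshold_pct=effect_threshold_pct,
        horizon_myr=horizon_myr,
    )


# ---------------------------------------------------------------------------
# I/O helpers


def read_observations(path) -> list[SimilarityObservation]:
    """Read observations from a TSV with columns pair_id, lineage, divergence_myr, similarity."""
    df = pd.read_csv(path, sep="\t")
    required = {"pair_id", "lineage", "divergence_myr", "similarity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in {path}: {sorted(missing)}")
    return [
        SimilarityObservation(
            similarity=float(r.similarity),
            divergence_myr=float(r.divergence_myr),
            lineage=str(r.lineage),
            pair_id=str(r.pair_id),
        )
        for r in df.itertuples()
    ]


def comparison_report(result: RateComparison) -> dict:
    """JSON-serializable report of a :class:`RateComparison`."""
    return {
        "p_value": result.p_value,
        "effect_size_pct": result.effect_size_pct,
        "verdict": result.verdict,
        "alpha": result.alpha,
        "effect_threshold_pct": result.effect_threshold_pct,
        "horizon_myr": result.horizon_myr,
        "pairwise_effects_pct": {
            f"{a}|{b}": v for (a, b), v in result.pairwise_effects_pct.items()
        },
        "fits": {
            kind: {
                "intercepts": f.intercepts,
                "slopes": f.slopes,
                "rss": f.rss,
                "n_obs": f.n_obs,
                "n_params": f.n_params,
                "n_dropped": f.n_dropped,
            }
            for kind, f in result.fits.items()
        },
    }
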