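"""Power assessment of the rate-comparison framework by Monte-Carlo simulation.

Two lineages are simulated whose cross-species similarity decays
exponentially at rates ``base_rate`` and ``base_rate - rate_delta`` (the
second lineage decays faster).  At each pairwise divergence time in the
panel, each lineage contributes ``draws_per_distance`` similarity values
drawn from a normal distribution centred on its expected decay value, with
a fixed standard deviation on the similarity scale (so with the default of
one draw, two values are sampled per distance -- one per lineage).  Each
simulated dataset is fed to :func:`netdecay.ratecomp.compare_rates` and the
frequency of a *different* verdict over many simulations is the detection
frequency.

The default divergence-time panel mirrors the species pairs of the
mammalian ChIP comparisons: mouse strains and close relatives at a few
Myrs, mouse-rat around 20 Myrs, then mouse-human (91 Myrs) and mouse-dog
(97.4 Myrs).  With this panel, one draw per (lineage, distance) and the
steepest base rate (-0.007/Myr), the framework's measured detection
frequencies match the four published headline values across the
(rate-difference, noise) grid; see ``docs/methods.md`` for the calibration
argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ratecomp import (
    DEFAULT_ALPHA,
    DEFAULT_EFFECT_THRESHOLD_PCT,
    VERDICT_DIFFERENT,
    RateComparison,
    SimilarityObservation,
    compare_rates,
)

#: default per-Myr base decay rates examined
DEFAULT_BASE_RATES = (-0.007, -0.005, -0.003)

#: default divergence-time panel (Myrs): mouse-strain/close-relative pairs,
#: mouse-rat, mouse-human (91) and mouse-dog (97.4)
DEFAULT_DISTANCES_MYR = (0.5, 1.0, 3.0, 20.9, 91.0, 97.4)

#: headline grid of (rate_delta, noise_sd) combinations
HEADLINE_COMBOS = ((0.003, 0.005), (0.003, 0.05), (0.001, 0.05), (0.001, 0.005))


@dataclass(frozen=True)
class PowerConfig:
    """Configuration of one two-lineage power simulation."""

    base_rate: float = -0.005
    rate_delta: float = 0.001
    noise_sd: float = 0.005
    distances_myr: tuple[float, ...] = DEFAULT_DISTANCES_MYR
    draws_per_distance: int = 1
    n_sims: int = 1000
    seed: int = 0
    alpha: float = DEFAULT_ALPHA
    effect_threshold_pct: float = DEFAULT_EFFECT_THRESHOLD_PCT

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not self.distances_myr or any(t < 0 for t in self.distances_myr):
            raise ValueError("distances_myr must be non-empty and nonnegative")
        if self.rate_delta < 0:
            raise ValueError("rate_delta must be >= 0")
        if self.draws_per_distance < 1:
            raise ValueError("draws_per_distance must be >= 1")


@dataclass(frozen=True)
class PowerResult:
    """Detection frequency of one configuration."""

    config: PowerConfig
    detection_frequency: float
    n_detected: int
    per_sim_verdicts: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        expected = self.n_detected / self.config.n_sims
        if abs(self.detection_frequency - expected) > 1e-12:
            raise ValueError("detection_frequency != n_detected / n_sims")


def simulate_two_lineages(
    config: PowerConfig, rng: np.random.Generator
) -> list[SimilarityObservation]:
    """Draw one simulated two-lineage similarity dataset.

    Lineage ``"A"`` decays at ``base_rate``; lineage ``"B"`` at
    ``base_rate - rate_delta`` (faster).  Values are N(exp(rate*t), noise_sd).
    """
    rates = {"A": config.base_rate, "B": config.base_rate - config.rate_delta}
    obs: list[SimilarityObservation] = []
    for lineage, rate in rates.items():
        for t in config.distances_myr:
            mean = np.exp(rate * t)
            for j in range(config.draws_per_distance):
                obs.append(
                    SimilarityObservation(
                        similarity=float(rng.normal(mean, config.noise_sd)),
                        divergence_myr=float(t),
                        lineage=lineage,
                        pair_id=f"t{t}:{j}",
                    )
                )
    return obs


def detection_frequency(
    config: PowerConfig, keep_verdicts: bool = False
) -> PowerResult:
    """Fraction of ``n_sims`` simulated datasets yielding a *different* verdict."""
    rng = np.random.default_rng(config.seed)
    verdicts = []
    n_detected = 0
    for _ in range(config.n_sims):
        obs = simulate_two_lineages(config, rng)
        result: RateComparison = compare_rates(
            obs,
            alpha=config.alpha,
            effect_threshold_pct=config.effect_threshold_pct,
        )
        if result.verdict == VERDICT_DIFFERENT:
            n_detected += 1
        if keep_verdicts:
            verdicts.append(result.verdict)
    return PowerResult(
        config=config,
        detection_frequency=n_detected / config.n_sims,
        n_detected=n_detected,
        per_sim_verdicts=tuple(verdicts) if keep_verdicts else None,
    )


def aggregated_detection_frequency(
    rate_delta: float,
    noise_sd: float,
    base_rates: tuple[float, ...] = DEFAULT_BASE_RATES,
    n_sims: int = 1000,
    seed: int = 0,
    **kwargs,
) -> float:
    """Detection frequency pooled over the three base decay rates.

    Runs ``n_sims`` simulations for each base rate and returns the overall
    detected fraction (the headline one-number-per-(delta, sd) summary).
    """
    total = 0
    for i, base in enumerate(base_rates):
        cfg = PowerConfig(
            base_rate=base,
            rate_delta=rate_delta,
            noise_sd=noise_sd,
            n_sims=n_sims,
            seed=seed + 1000003 * i,
            **kwargs,
        )
        total += detection_frequency(cfg).n_detected
    return total / (n_sims * len(base_rates))


def headline_detection_frequencies(
    n_sims: int = 1000,
    seed: int = 0,
    base_rate: float = -0.007,
    **kwargs,
) -> dict[tuple[float, float], float]:
    """Detection frequencies over the headline (rate_delta, noise_sd) grid.

    Replays the published power assessment at its stated conditions: the
    steepest base rate (-0.007/Myr), one similarity draw per lineage per
    divergence time on the default distance panel, ``n_sims`` simulations
    per grid cell.  Returns ``{(rate_delta, noise_sd): frequency}`` with
    frequencies as fractions in [0, 1].
    """
    out = {}
    for i, (delta, sd) in enumerate(HEADLINE_COMBOS):
        cfg = PowerConfig(
            base_rate=base_rate,
            rate_delta=delta,
            noise_sd=sd,
            n_sims=n_sims,
            seed=seed + 104729 * i,
            **kwargs,
        )
        out[(delta, sd)] = detection_frequency(cfg).detection_frequency
    return out


def power_grid(
    deltas,
    noise_sds,
    base_rates: tuple[float, ...] = DEFAULT_BASE_RATES,
    n_sims: int = 1000,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Full factorial sweep over (base_rate, noise_sd, delta).

    Returns a DataFrame with one row per combination, plus the pooled
    frequency over base rates for each (noise_sd, delta) in a companion
    column ``aggregated`` (repeated across the base-rate rows).
    """
    deltas = list(deltas)
    noise_sds = list(noise_sds)
    if not deltas or not noise_sds or not base_rates:
        raise ValueError("grids must be non-empty")
    rows = []
    for sd in noise_sds:
        for delta in deltas:
            cell = []
            for i, base in enumerate(base_rates):
                cfg = PowerConfig(
                    base_rate=base,
                    rate_delta=delta,
                    noise_sd=sd,
                    n_sims=n_sims,
                    seed=seed + 1000003 * i + 7919 * len(rows),
                    **kwargs,
                )
                res = detection_frequency(cfg)
                cell.append(res)
            agg = sum(r.n_detected for r in cell) / (n_sims * len(base_rates))
            for base, res in zip(base_rates, cell):
                rows.append(
                    {
                        "base_rate": base,
                        "noise_sd": sd,
                        "delta": delta,
                        "n_sims": n_sims,
                        "detection_frequency": res.detection_frequency,
                        "aggregated": agg,
                    }
                )
    return pd.DataFrame(rows)
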