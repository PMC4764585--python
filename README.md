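# netdecay

Do transcriptional networks evolve faster in mammals than in birds or
insects?  Answering that requires comparing *rates of divergence* of very
different data layers — genome sequence retention, transcription-factor
(TF) occupancy, *cis*-regulatory motifs, mRNA expression — across lineages
whose species pairs sit at different evolutionary distances.  `netdecay`
is a toolkit for exactly this comparison: it implements the full
measurement pipeline for each layer, a common statistical framework that
decides whether lineages diverge at the same or different rates, and a
synthetic-clade generator with known ground truth so the entire machinery
can be exercised and validated without any external genomes or sequencing
archives.

It is aimed at comparative and regulatory genomicists who want to measure
cross-species similarity decay on their own data, or to study how robust
such conclusions are to analytical choices.

## The statistical core

Every layer reduces to observations *(s, t, ℓ)*: a cross-species
similarity *s* (a correlation, a retention fraction, a percent identity),
a divergence time *t* in millions of years (Myrs), and a lineage label
*ℓ*.  Divergence is modelled as exponential decay in log-linear space,

&nbsp;&nbsp;&nbsp;&nbsp;log *s* = *a* + *b·t*,

fitted by ordinary least squares under three nested structures: a
**lineage-naïve** model (one shared intercept and slope), a
**lineage-aware** model (shared intercept, per-lineage slopes *b<sub>ℓ</sub>*),
and **lineage-specific** models (independent *a<sub>ℓ</sub>*, *b<sub>ℓ</sub>*).
The naïve and aware models are compared with a likelihood-ratio test
(statistic *n*·log(RSS₀/RSS₁), χ² reference; an exact nested-model F-test
is available as a variant).  The effect size is the largest predicted
absolute difference in similarity between any two lineages after 100 Myrs,
from the lineage-specific fits.  Rates are declared **different** only
when *p* < 0.05 **and** the effect size exceeds 5 percentage points;
otherwise they are **indistinguishable**.

## The layers

| module | similarity measure |
| --- | --- |
| `homology` | fraction of random 75 bp segments that lift to another genome through UCSC chain files (minMatch 0.001, ≤1 kb target span), and Smith–Waterman ungapped identity of retained segments (EDNAFULL, gap 10/0.5) |
| `occupancy` | genome-wide Pearson correlation of nucleotide-resolution TF occupancy: strand cross-correlation fragment-size estimation, imputed-fragment densities, adaptive mappability masking, one-to-one chain transfer |
| `chipgrid` | fraction of reference-occupied segments retaining occupancy, across a full factorial grid of 108 analysis pipelines (caller variant × quality filter × minMatch × reference subset × overlap rule) |
| `motifs` | motif retention *F* = (Mapped<sub>with&nbsp;motif</sub> − Shuffled<sub>with&nbsp;motif</sub>)/Mapped × 100, with exact-DP PWM p-value thresholds (*P* < 10⁻⁴) and 50 bp locus extension |
| `exprcorr` | Spearman/Kendall/Pearson-log₂ correlation of one-to-one ortholog TPMs, >5 TPM filter |
| `powersim` | Monte-Carlo power of the framework itself at configurable rate differences and noise levels |
| `synthdata` | synthetic clades: substitutions, indels, class-specific segment loss, ground-truth chains, ChIP read sets, expression tables, implanted motifs |
| `pipeline` | end-to-end replay of all layers on two synthetic lineages, with per-layer verdicts |

## Worked example

```python
import numpy as np
from netdecay import SimilarityObservation, compare_rates

rng = np.random.default_rng(0)
obs = [
    SimilarityObservation(
        similarity=float(np.exp(rate * t) + rng.normal(0, 0.02)),
        divergence_myr=t,
        lineage=lineage,
        pair_id=f"ref-vs-sp{t}",
    )
    for lineage, rate in [("Mammalia", -0.0125), ("Insecta", -0.0075)]
    for t in (2, 7, 13, 25, 45, 60, 91, 97.4)
]
result = compare_rates(obs)
print("verdict:     ", result.verdict)
print("p-value:     ", f"{result.p_value:.2e}")
print("effect size: ", f"{result.effect_size_pct:.1f} percentage points at 100 Myrs")
print("slopes:      ", {k: round(v, 4) for k, v in result.fits["aware"].slopes.items()})
```

prints

```
verdict:      different
p-value:      8.18e-14
effect size:  14.9 percentage points at 100 Myrs
slopes:       {'Insecta': -0.0078, 'Mammalia': -0.0118}
```

The two lineages were simulated with true decay rates −0.0125 and
−0.0075 per Myr and 2% similarity noise; the aware fit recovers both
slopes, the likelihood-ratio test rejects a shared rate, and the predicted
similarity gap at 100 Myrs (≈15 points) clears the 5-point gate, so the
rates are called different.

The same decision logic is available from the shell:

```bash
netdecay ratecomp --input observations.tsv --alpha 0.05 --effect-threshold 5
netdecay replay --seed 1 --out report.json     # full multi-layer synthetic replay
netdecay powersim --delta 0.003 --sd 0.05 --n-sims 1000 --seed 17
```

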