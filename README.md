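# thermopanel

Quantitative dissection of a polygenic temperature-specialization tradeoff
from a combinatorial allele-replacement strain panel.

## The problem

A thermotolerant yeast species owes its trait to variants at many unlinked
loci. Swapping the orthologous alleles of a set of candidate genes — one at
a time, and stacked stepwise until all are replaced — into a thermosensitive
sister species asks three quantitative questions of the resulting panel:

1. **How much of the trait do the loci reconstitute?** Growth efficiency
   (ΔOD₆₀₀ over a fixed incubation) of the fully stacked transgenic,
   expressed as a fold change over the recipient wild type and as the
   *recapitulation fraction* of the interspecies divergence,
   `100 · (x̄_trans − x̄_rec) / (x̄_donor − x̄_rec)`.
2. **Do the loci interact?** Under independence, the joint effect of all
   L swaps (vs the recipient wild type) equals the sum of the single-swap
   marginal effects. The deviation `ε = observed − Σ effects` is tested
   with a replicate-level bootstrap: each strain's replicate pool is
   resampled with replacement, the wild-type reference draw is shared
   across all terms of one test, and the p-value is the smoothed fraction
   of iterates on the null side of zero. Per-locus background dependence
   (alone vs on top of the stacking path) is classified as magnitude,
   masking, or sign epistasis from bootstrap CIs, and the directional
   consistency of the path is scored with an exact binomial tail.
3. **At what cost?** Cold (4 °C) timecourses are summarized by a bounded
   logistic fit `OD(t) = K / (1 + exp(−R(t − x₀)))`, and viability by
   CFU/mL per OD from the densest countable spot of a 1:10 dilution
   series — revealing antagonistic pleiotropy of the swapped alleles.

No raw panel data are distributed; a ground-truth-known synthetic
generator emulates the full measurement campaign (replicate structure,
noise, interaction regimes, Poisson dilution series), so every estimator
is verifiable end to end. See `docs/methods.md` for model details and the
calibration rationale.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic panel (eight loci, magnitude damping placing the joint truth at
60 % of the additive sum) and write tables under `results/`:

```sh
python analysis/01_simulate_panel.py
python analysis/02_heat_growth_effects.py
python analysis/03_epistasis.py
```

`analysis/03_epistasis.py` prints:

```
Observed joint effect:  +0.7369 dOD
Additive expectation:   +1.3818 dOD
epsilon = -0.6449, p = 9.999e-05, label = negative_magnitude
Per-locus background dependence: {'DYN1': 'none', 'MYO1': 'none',
 'SCC2': 'negative_magnitude', 'APC1': 'negative_magnitude',
 'CEP3': 'negative_magnitude', 'ESP1': 'negative_magnitude',
 'TAF2': 'masking', 'AFG2': 'negative_magnitude'}
Path trend: 8/8 beneficial steps, binomial p = 0.003906
```

The stacked strain gains 0.74 ΔOD over the recipient wild type — far below
the 1.38 ΔOD the single-swap effects would predict additively — so the
panel is labeled negative (magnitude) epistasis at p ≈ 1e-4; yet every one
of the eight stacking steps is beneficial (binomial p = 0.0039): the loci
damp one another without ever hurting. `02` reports the same panel's
headline ratios (fold change 2.95×, recapitulation 45.8 % of the
wild-type divergence), and `04`–`06` cover the cold tradeoff, viability,
and the operating characteristics of the test (measured type-I error
0.061 at nominal 0.05 over 1,000 additive panels; power 0.98 against the
60 % damping regime).

A thin CLI wraps the same pipeline: `thermopanel run-all --config cfg.yaml
--out results/run --seed 11`.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch at a given seed — the simulate → effects → epistasis pipeline at
n_boot = 10,000, a noiseless logistic-recovery check, and a viability
estimator recovery — and writes its JSON output to `--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
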