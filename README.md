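# symdet

Computational model of mirror-symmetry detection in noise-masked
random-dot displays: stimulus generation, a multi-channel divisive-
inhibition response model with a max-rule decision stage, TvD
(threshold-versus-masker-density) prediction and fitting, rival baseline
predictions (Gaussian max uncertainty, weight-of-evidence), and a
model-driven synthetic observer for end-to-end validation.

## What's inside

| module | contents |
| --- | --- |
| `symdet.stimuli` | mirror-symmetric dot patterns, count-matched random controls, noise superposition, the 8-aperture viewing mask (high/low axial salience), reverse-mapping symmetry counts, PGM/PNG export |
| `symdet.model` | channel excitation, divisive-inhibition response, fourth-power pooling over monitored channels, d', threshold solving, TvD curves and log-log slopes; canonical per-observer parameter sets |
| `symdet.baselines` | SD of the max of m Gaussians (quadrature + Monte Carlo), uncertainty-model intensity ratios, weight-of-evidence factors, unit-slope null comparison |
| `symdet.fitting` | ML Weibull psychometric thresholds with bootstrap SEs, 9-free-parameter model fits (S_et anchor = 1000), goodness of fit, nested F comparison against the uncertainty-only reduction, slope reports |
| `symdet.synthetic` | constant-stimulus experiment designs (2x2 conditions, 7-9 levels in 0.15-log steps), trial-level yes/no observer simulation (true max rule or the model's pooled Gaussian abstraction), parameter-recovery suites |
| `symdet.cli` | `symdet` command line: `simulate`, `fit`, `predict`, `baselines`, `render`, `recover` |

## CLI examples

```bash
# rival-account table (m, sd_ratio, intensity_ratio)
symdet baselines --ms 1,2,4,8

# model TvD curves for a canonical observer, optionally ablated
symdet predict --observer CC --out tvd.csv --plot tvd.png
symdet predict --observer CC --ablate z_prime --out tvd_noz.csv

# simulate a synthetic observer and fit the model to its trials
symdet simulate --observer CC --trials-per-level 100 --seed 1 \
    --out-trials trials.csv --out-design design.yaml
symdet fit --trials trials.csv --out-fit fit.json \
    --out-residuals resid.csv --out-thresholds thresholds.csv

# fit a threshold table directly; --reduced collapses the cue effect
symdet fit --thresholds thresholds.csv --reduced \
    --out-fit fit_reduced.json --out-residuals resid_reduced.csv

# render a masked stimulus (PGM + PNG + JSON sidecar)
symdet render --salience low --axis 45 --seed 7 --out-prefix stim

# parameter-recovery study
symdet recover --observer CC --noise-sd-log 0.08 --out recovery.json
```

## File formats

Trial tables and TvD tables are CSV (densities stored in linear units;
log views are computed, never stored). Model parameters are JSON with
fixed values flagged. Designs are YAML or JSON. Stimulus images are
plain PGM (P2) or PNG with a JSON metadata sidecar. Every CLI artifact
gets a `.meta.json` sidecar recording the package version, seed, and a
config hash.
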