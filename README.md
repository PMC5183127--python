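# sadcompare

Likelihood-based comparison of species-abundance distribution (SAD) models.

Fits four zero-truncated discrete distributions — the log-series, the
Poisson lognormal, the negative binomial, and the Zipf (zeta) distribution —
to per-site abundance vectors by maximum likelihood, and compares them with
AICc weights. Includes a synthetic-community generator with recorded ground
truth, so every stage (generation → fitting → model selection → summary
tables) can be exercised and validated without any external data.

## Layout

| module | contents |
|---|---|
| `sadcompare.distributions` | the four families on support {1, 2, ...}: `pmf`, `logpmf`, `cdf`, `sample`, analytic `tail_mass`. The Poisson lognormal is evaluated by mode-centred Gauss–Hermite quadrature (128 nodes) in log-rate space. |
| `sadcompare.fitting` | `Community`, `ModelFit`, `fit_logseries` / `fit_zipf` / `fit_neg_binom` / `fit_poisson_lognormal` / `fit_all`. Degenerate inputs return flagged fits, never exceptions. |
| `sadcompare.model_selection` | `aicc` (sample size = species richness), `akaike_weights`, `best_model` (ties → fewer parameters, then fixed order), `loglik_deviation`, `compare_site`. |
| `sadcompare.pipeline` | `read_communities` (long CSV: `site_id, species_id, abundance[, dataset_id]`), `run_comparison`, `summarize_best_models`; writes per-site and summary CSVs plus a metadata sidecar. |
| `sadcompare.synthetic_data` | `SyntheticSpec`, `generate_collection` (per-site counter sub-seeds, ground-truth table), `recovery_experiment`. |

## CLI

Generate a synthetic collection with known ground truth:

```sh
sadcompare simulate --output communities.csv --truth truth.csv \
    --seed 7 --n-sites 100 --families logseries,zipf
# or drive it from a TOML spec:
sadcompare simulate --spec spec.toml --output communities.csv
```

Fit and compare all four models on every site of a community table:

```sh
sadcompare run --input communities.csv --output outdir --seed 42 \
    --min-richness 4 --families logseries,pln,negbin,zipf
```

`outdir/` then contains `results_per_site.csv` (one row per site × family:
parameters, log-likelihood, AICc, ΔAICc, Akaike weight, best-model flag,
convergence/boundary flags), `summary_best_models.csv` (best-model counts and
proportions per dataset and overall), `loglik_deviations.csv` (per-site
deviation from the across-model mean log-likelihood), `exclusions.csv`
(excluded sites with reason codes) and `run_metadata.json`.

Sites with fewer than `--min-richness` species (default 4) cannot receive an
AICc for the two-parameter models and are excluded from model selection with
reason `low_richness`.

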