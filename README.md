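# exportkinetics

Kinetic inference of mRNA chromatin-to-cytoplasm transport from
subcellular-fraction RNA-seq time courses.

## The problem

When cells are stimulated (e.g. macrophages responding to endotoxin),
hundreds of genes are induced within minutes. How quickly an mRNA appears
in the cytoplasm — and how abundant it gets — depends not only on
transcription and cytoplasmic decay but on the rarely measured steps in
between: release from chromatin, nucleoplasmic transit, and export. Given
RNA-seq time courses of the chromatin-associated, nucleoplasmic and
cytoplasmic fractions, this package infers per-gene rate constants for
those steps, with confidence intervals that honestly report which
parameters the data can and cannot pin down.

## The model

The measured chromatin signal x(t) (caFPKM) drives two linear compartments:

    dy/dt = k1' x(t) − k2 y          (nucleoplasm, npFPKM)
    dz/dt = k2' y    − k_cyto_deg z  (cytoplasm, cytoFPKM)

* `k1'` — fractional chromatin→nucleoplasm appearance rate ((npFPKM/caFPKM)/min)
* `k2` — total disappearance rate from the nucleoplasm (export + decay, 1/min)
* `k2'` — fractional nucleoplasm→cytoplasm appearance rate ((cytoFPKM/npFPKM)/min)
* `k_cyto_deg` — cytoplasmic decay rate (1/min); half-life = ln2/k_cyto_deg

Because FPKM is a relative unit, the absolute copy-number rates are not
identifiable; the fraction-normalisation factors are deliberately folded
into `k1'` and `k2'`. The composites `k1'/k2` (chromatin-release
efficiency), `k2'/k2` (export efficiency) and `k1'k2'/k2` (effective
transport rate) are first-class quantities: the model can be rewritten with
each of them as a coordinate, which is how their profile likelihoods are
computed.

Observed counts follow a log-normal × Poisson (≈ Gamma–Poisson = negative
binomial) error model with log-scale variance
`σ_total² = σ_b² + slope²·σ_t²` — biological scatter plus timepoint-sampling
jitter amplified by the local trajectory slope. Fitting minimises the
negative log-likelihood of all three fractions (the chromatin prediction is
a weighted smoothing spline) plus priors regularising the nuisance
parameters (spar, σ_t, σ_b), using 100–1000 random multi-starts of L-BFGS-B
in log10 parameter space. Confidence intervals come from profile
likelihoods thresholded at icdf(χ²₁, 0.95)/2 = 1.9207, searched up to
1000-fold from the optimum.

Also included: an actinomycin-D half-life estimator (spike-in median-ratio
normalization, regression-window search maximising adjusted R², shared
slope across replicates, HL = −1/slope in log2/min), percent-intron /
splicing-probability metrics from junction counts, responsiveness
simulations, and a synthetic-data generator that produces all of the above
with known ground truth.

## Worked example

The numbered scripts under `analysis/` run the study end to end on
synthetic data. `python analysis/01_simulate_cohort.py` followed by
`python analysis/02_fit_cohort.py` prints:

```
simulated 20 genes -> results/analysis/counts.tsv
selection: 19/20 pass the inducibility filters
  gene0014 fails: induction < 10-fold within 40 min
fitted 20 genes (60 starts each) -> results/analysis/fits.tsv
effective transport within 2-fold of truth: 95% of genes
median |log2 error| of effective transport: 0.26 log2 units
half-life within 2-fold of truth: 85% of genes
fit quality: 18 good, 1 moderate, 1 poor
```

19 of 20 simulated genes pass the inducibility filters (≥32 fragments,
FPKM ≥ 1 in 3 samples, ≥10-fold induction within 40 min); after fitting,
the effective transport rate is recovered within the 2-fold
reproducibility window for 95% of genes, and the fit-quality metric
(|lag-1 autocorrelation| × mean|residual|/range, in log2 FPKM) flags the
hard-to-fit genes. `analysis/03_identifiability.py` reproduces the
characteristic identifiability pattern — for a gene whose nucleoplasmic
signal tracks chromatin, `k1'` and `k2` are only bounded from below while
their ratio stays identifiable within ~1.2-fold:

```
np_tracks_ca  k1_prime                      5  3.568  0.882    NaN  lower_bound_only
np_tracks_ca  k2                            5  3.341  0.8142   NaN  lower_bound_only
np_tracks_ca  chromatin_release_efficiency  1  1.068  0.9717  1.175 identifiable
```

`04_actd_halflives.py` (ActD round trip, worst error 1.7%),
`05_splicing.py` (PI(8,4,4) = 0.3333, SP = 0.4444) and
`06_responsiveness.py` (time-to-half-induction is set by the mRNA
half-life, not by transport, across a 10-fold transport range) complete
the picture.

The same stages are exposed as a CLI
(`exportkinetics simulate|select|fit|profile|quality|actd|splice|respond|pipeline`)
for tab-separated count tables.

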