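# Methods

## Model and estimation

The observation model is linear: the read count of genomic element j in
sample i is D_ij = N_i Σ_k g_ik l_jk, with g the per-sample taxon relative
abundances (rows summing to 1), l_jk the element's prevalence in taxon k's
genome in nucleotides, and N_i an unknown per-sample sequencing scale.
Normalizing each count by the count of a constant genomic element of known
combined length l_C gives the response y_ij = D_ij·l_C/D_iC = Σ_k g_ik l_jk,
one ordinary linear system per element over the samples. The model assumes
(i) reads land on elements in proportion to encoded nucleotides, (ii) the
constant element really is single-prevalence in every community member,
and (iii) the taxon profile and the count table describe the same
underlying community. Nothing is assumed about genome sizes: they cancel.

Solvers: plain least squares (numpy `lstsq`, SVD-based; negative
prevalences are reported as-is and fall out as "absent" in calling),
non-negative least squares (`scipy.optimize.nnls`), and lasso.  Lasso uses
the LARS path (`sklearn.LassoLarsCV`) with the penalty chosen by 5-fold
cross-validated MSE over the exact path knots, folds seeded at 0 for
determinism; LARS rather than coordinate descent because the path is
computed exactly — at the near-zero penalties CV selects on consistent
systems, coordinate descent stalls around 1e-2 relative error on these
ill-conditioned designs while the path solution is exact to ~1e-9.
`positive=True` combines the L1 penalty with non-negativity.  Exact
solvers require n_samples ≥ n_taxa and a full-rank design; rank deficiency
raises an error carrying the condition number, and condition numbers above
1e8 are logged. Elements are solved independently, so results are
invariant to execution order and per-element method choices are possible.

Filters mirror common practice for this kind of data: taxa must be present
in at least half the samples (and optionally exceed a peak-abundance
floor, e.g. 5%, for genus-level work); elements must have a mean count
above 0.1% of the top element's mean, optionally be present in a minimum
fraction of samples, and — when a reference-genome catalog is supplied —
be neither near-universal core genes (≥75% of reference genomes) nor
likely-spurious annotations (<1%). After the taxon filter, retained rows
are renormalized to sum to 1 so the constant-element form of the system
still applies; a sample left without any retained taxon is dropped with a
logged warning, as is any sample with zero constant-element counts.

Presence calling divides each predicted prevalence by the element's
average sequenced-ortholog length; the ratio is an implied copy number and
the call is present when it meets the threshold (inclusive, so threshold
1.0 accepts exact-length predictions). The convoluted null assigns every
taxon one shared genome whose element lengths are the per-sample relative
abundances averaged over samples, scaled by the constant element's length
and average relative abundance. Constant-element selection keeps catalog
candidates with presence ≥ 98% of genomes and length CV strictly below the
anchor (16S) CV, pooling their counts and summing their mean lengths.

## The synthetic-community generator

The generator emulates an abstract, sequence-free model of shotgun
sequencing; its defaults are the study conditions of the headline
experiment.

* Catalog of `n_elements` orthology groups (default 100), the last being a
  1500-nt single-copy constant gene carried by every species. Variable
  genes get integer lengths uniform on [400, 500] nt, shared across all
  carriers (species-specific lengths are out of scope).
* Each variable gene is assigned to a uniformly drawn 20–80% subset of the
  `n_species` species (default 60); species are topped up to a minimum of
  10 variable genes. Carried genes have copy number c with probability
  ∝ 0.05^(c−1) — a 5% duplication chance with geometrically decreasing
  higher-copy rates.
* Typical species abundances c_k are i.i.d. Exponential(mean 1). Sample
  profiles are a_ik = c_k·exp(ν·r_ik) with r_ik ~ N(0,1) i.i.d.; ν = 0
  gives identical profiles across samples and the per-species CV across
  samples is sqrt(exp(ν²)−1). The published description of this noise law
  is not fully legible in our source material; this form satisfies every
  stated property and is the package's single largest reconstruction
  assumption. Default ν = 0.10.
* Reads are multinomial at fixed depth (default 5×10⁶ per sample) with
  element weights ∝ Σ_k a_ik·copies_kj·length_j. Species below 0.5% of the
  sample's most abundant species are treated as undetectable: removed from
  read generation and zeroed in the observed profile, which is then
  renormalized (keeping their reads while zeroing the profile is available
  as `cutoff_affects_reads=False` for sensitivity analysis). The observed
  profile is otherwise error-free, standing in for an idealized 16S
  measurement.
* `expected_counts` returns the multinomial expectation (fractional
  counts): a consistent, noise-free system on which all three solvers
  recover the true prevalences exactly — the test suite's strongest
  oracle.

What the generator does *not* emulate: sequence-level error, read
annotation mistakes and fractional tied annotations, 16S copy-number bias,
phylogenetic correlation among genomes, and compositional noise in the
taxon profile. Passing tests on these simulations therefore demonstrate
the correctness of the estimator and its software, not robustness to
annotation error on real data.

## Numerical and design choices

* TSV is the interchange format (tab-separated, header row, row ids first,
  `%.10g` floats); missing cells are errors rather than zeros, because a
  silent zero-fill would bias the regression. BIOM input is a feature flag
  that requires the optional `biom-format` package.
* Sample alignment between taxon and element tables is by id,
  order-insensitive, and fails loudly on disjoint id sets.
* Presence thresholds are inclusive (≥). Truth presence for simulated
  genomes is copy number ≥ 1; for annotated reference genomes, copy number
  ≥ 0.1.
* ROC curves sweep the predicted/reference ratio directly over all
  distinct scores; AUC is trapezoidal and equals the pairwise probability
  P(score_present > score_absent) + ½·P(tie).
* Per-element relative error averages |predicted − true|/true over
  carrying taxa only (truth > 0); the constant gene is excluded from
  error-vs-variation summaries because it is the normalization anchor, not
  a reconstructed gene. CVs use ddof = 1.
* Empty-vs-empty Jaccard comparisons are undefined and excluded from genus
  means rather than scored as 1, to avoid rewarding trivial emptiness.
* Undefined correlations in the naive baseline (constant vectors) are
  called absent with a warning.
* All randomness flows through numpy `SeedSequence` spawning, so every
  recipe is bit-reproducible from one integer seed.

## Scale of the shipped experiments and noise analysis

The headline recipe runs at full stated scale (100 samples × 60 species ×
100 elements, 5M reads/sample) in well under a minute; smaller communities
(≈10–12 species, 25–30 samples) are used for the noise-free recovery and
property tests.

At ν = 0.10 the inter-sample abundance variation is ~10%, and the
regression design is highly collinear: sqrt of the largest diagonal of
(GᵀG)⁻¹ reaches ~3×10³ for the rarest retained species (relative
abundance ~5×10⁻⁴ after the detection cutoff). Multinomial counting noise
at 5M reads contributes ~1 nt of response noise per observation, so
predicted prevalences for the rarest species carry errors of order 10³ nt
— matching closed-form least-squares error propagation — and their
presence calls are unreliable at any threshold. Accuracy pooled over all
pairs is ~85–89% across seeds, improves steeply with ν (≈99.9% near ν = 1)
and in the noise-free limit is exactly 100% at every threshold between
0.2 and 0.8. The error-vs-variation correlations (≈ −0.5 across samples,
≈ −0.6 across species) quantify the same phenomenon per gene.

## Known limitations

* Unweighted regression: heteroscedastic count noise (variance ∝ count) is
  not modeled; abundant elements dominate neither more nor less than the
  model form implies, but rare-taxon estimates are noise-limited as
  analyzed above.
* The externally published three-strain benchmark with sequencing and
  annotation error can be re-analyzed through `recipes.strain_benchmark`
  once its tables are converted to TSV (see `tests/test_acceptance.py`
  for the expected layout); the tables are an external download and are
  not redistributed with the package.
* No 16S copy-number correction is applied to taxon profiles.
* Genus-level deconvolution interprets a reconstructed genus as the
  abundance-weighted average genome of its members; genes variable within
  a genus are intrinsically ambiguous at that resolution.
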