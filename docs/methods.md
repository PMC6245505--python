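# Methods

This note records the models, the defaults and why they were chosen,
what the synthetic generator does and does not emulate, and the places
where the design was genuinely open.

## Complexity metrics

All three signal classes reduce to a weighted categorical distribution
and are scored with richness (categories with positive weight) and
diversity, the order-1 Hill number `D = exp(−Σ pᵢ ln pᵢ)`. Natural log
throughout; `D` is base-free. Shannon-based diversity is used because it
weights categories by their actual usage, remains meaningful under
unequal weights, and has the doubling interpretation (a display with
`D = 2x` behaves like one with twice as many equally used elements as
one with `D = x`). Invariants enforced and tested: `1 ≤ D ≤ richness`,
equality exactly at uniform weights.

### Sliding windows

Recording effort varies wildly across species, so per-individual scores
come from the single fixed-length window of maximal complexity rather
than from whole corpora. Windows start at offsets 0, step, 2·step, …
inside each clip and never span clip boundaries; clips shorter than the
window are scored once whole rather than discarded (dropping them would
silently remove rarely filmed species). Defaults: 50 s window for
behavior, 10 s for sound, 1 s step (the step is not a scientifically
stated quantity; 1 s is fine-grained relative to both windows).
Richness and diversity maxima are searched independently; a
`single_window_by` switch restores the coupled reading in which one
best window supplies both numbers. Ties break deterministically:
earliest clip, then earliest offset. Instantaneous events enter the
weight distribution with a nominal duration (`event_weight_s`, default
1 s) so that counts and state durations are commensurate; for acoustic
notes, which are all near-instantaneous relative to a 10 s window, this
reduces to count weighting. Species scores are unweighted means over
individuals; individuals with no scorable window propagate as missing.
Window-size robustness sweeps (10–60 s behavioral, 5–50 s acoustic) are
available through `window_sweep` and the `--sweep` CLI flag.

## Color

### Visual model

Receptor-noise-limited discrimination in the log form: for catches
`q`, `f = ln q`, channel noise `ωᵢ = ν·√(n_ref/nᵢ)` with `ν` the Weber
fraction of the most abundant cone class and `nᵢ` relative cone
densities. The chromatic distance for `n` channels is

    ΔS² = Σ_{i<j} (Π_{k∉{i,j}} ω_k)² (Δf_i − Δf_j)²
          ─────────────────────────────────────────
          Σ_i (Π_{k≠i} ω_k)²

which reduces to the familiar di-/tri-/tetrachromatic quotients; the
achromatic distance is `ΔL = |Δ ln q_L| / ω_L`. ΔS is zero on uniform
intensity scalings (only pairwise log-catch differences enter) and
symmetric — both property-tested. Defaults model a violet-sensitive
tetrachromat with relative densities (1, 2, 2, 4) for (vs, sws, mws,
lws), `ν = 0.1`, `ω_L = 0.1` — pigeon-like VS values appropriate for
birds-of-paradise; all configurable, since published noise estimates
vary by species and method.

### Clustering

Each foreground pixel starts as a cluster. Per pass: clusters with any
two pixels within the current Chebyshev radius are neighbors; each
cluster picks its nearest neighbor by the composite distance
`√[(ΔS/T_c)² + (ΔL/T_l)²]` between cluster mean catches (ties to the
lowest cluster index); the merge is accepted only when *both*
components are sub-threshold (`ΔS < T_c` and `ΔL < T_l`); accepted
merges chain transitively within the pass via union–find; means are
then recomputed as area-weighted means and the radius grows by one
pixel. The process runs over n + 2 dimensions (n receptor channels plus
x, y) and stops when a pass merges nothing while the radius already
spans the image, or at `max_passes` (warning + partial result).
Defaults: `T_c = T_l = 3` JND — a conventional supra-threshold cut for
discriminability under uncontrolled viewing (threshold values are a
declared choice, not derived); initial radius 1, increment 1 per pass;
3×3 median blur first to remove aberrant pixels (dust, dead pixels),
restricted to the foreground so background values never leak in.
Tested invariants: areas always partition the foreground, per-channel
catch mass `Σ area·mean` is conserved every pass, vanishing thresholds
recover the count of distinct pixel values, infinite thresholds give
one cluster, identical inputs give identical partitions. A
`min_area_fraction` filter (default 0 = off) can drop specks before
scoring. Richness/diversity per view; views (dorsal, ventral, angled)
average to specimens and specimens to species.

## Acoustics

Features are z-scored and decomposed by correlation-matrix PCA
(zero-variance features dropped with a warning; components capped at
rank; signs fixed so each component's largest-magnitude loading is
positive). Partial note identity comes from agglomerative clustering
(Ward default; average/complete configurable) on Euclidean distances in
the top-3 PC space. The cluster count can be given explicitly;
automatic selection evaluates candidate cuts 2..20 of the same
dendrogram by mean silhouette and keeps the best, declaring a single
type when no cut reaches 0.5. A merge-height-gap rule was tried first
and rejected: Ward heights grow with cluster size, so the gap between
the last within-type and the first between-type merge is only ~1.7× on
realistic mixtures — indistinguishable from noise — whereas silhouette
separates these cases cleanly. Full identity is the pair (cluster,
4-bit qualitative code from frequency-modulation / nonharmonic /
impulsive / stochastic flags, high to low bit). Windowed complexity
then reuses the behavioral machinery (10 s default).

## Phylogenetic analysis

`Phylogeny` wraps an ultrametric Newick tree (branch lengths in My;
ultrametricity checked to 1e-6 relative tolerance, warning-only mode
available; polytomies fine). The OU working correlation is the
Martins–Hansen form on patristic distances, `C_ij = exp(−α d_ij)`, used
as a correlation with σ² profiled out. GLS estimates are
`β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y` via Cholesky solves; standard errors use
`σ̂² = RSS_C/(n−p)`; p values from t on n − p df. α is estimated by
profiled **REML** (log-spaced bracketing grid on [1e-4, 50]/tree-height,
then bounded scalar refinement). REML rather than ML is the default
deliberately: it is the default of the standard gls machinery this
construction mirrors, and in 40-tip null simulations with the full
7-term design it brings the slope test's type-I error to ~0.06–0.07
versus ~0.08 under ML profiling. ML remains available
(`method="ML"`, `PipelineConfig.pgls_method`). Residual mild inflation
above the nominal 5% is a known property of plug-in-α phylogenetic GLS
and is reported by the validation experiments rather than corrected ad
hoc.

Each mPGLS regresses one log-transformed measure on the two same-class
measures of the other modalities (richness with richness, diversity
with diversity) plus dummy-coded display height (reference: ground) and
display proximity (reference: solitary); category levels absent from a
data set drop out of the design. Log transforms are natural log and
raise on nonpositive values rather than offsetting.

### Imputation

Per trait, four covariance families are fitted by ML on observed tips —
BM (shared path lengths), OU (stationary `exp(−α d)`), early-burst
(`(e^{rs} − 1)/r` on shared paths, r < 0) and Pagel's λ (off-diagonal
scaling) — each with mean and scale profiled and the shape parameter
optimized by bounded scalar search. The AIC winner supplies the joint
multivariate normal whose conditional expectation fills the missing
tips. The pipeline imputes on the log scale (the scale of all
downstream analyses) and exponentiates back. Exactness checks: on a
star tree under BM the imputed value is exactly the observed mean; a
missing tip at zero phylogenetic distance from an observed tip takes
that tip's value. The multivariate-trait OU variant is out of scope;
imputation is univariate per trait. Complete-case analysis (drop
unsampled species and prune the tree) is available as a switch.

### Composite diversity

Each modality's diversity is min–max scaled to [0, 1] across species
and the three scaled scores are summed (0–3); a constant column scales
to 0 with a warning.

## Synthetic data

The generator emulates the study conditions: 40 species on a pure-birth
tree rescaled to 25 My height, 80% of species sampled for behavior and
sound, 3 individuals × 6 clips (log-normal clip durations averaging
~1 min) for behavior, 3 × 3 longer clips (140 s) of ~25 notes for
sound, 2 specimens × 3 views for color. Ground truth is explicit:
per-species repertoire sizes (3–12, ~30% instantaneous events), true
patch counts (2–8, pairwise ≥ 8 chromatic JND, log-normal pixel noise
sd 0.01 in log-catch space so within-patch JNDs are distribution-
stable), and true note-mixture components (1–8). Note types live in a
3-D latent acoustic space — means on a rotated integer lattice at 10σ
pairwise separation, each latent dimension loading a block of five
measured features — because real spectrogram variables covary in
groups, which is exactly what lets three principal components carry the
type separation; flag patterns are fixed per component (independent
Bernoulli(0.3) bits drawn once), so the true full-identity count equals
the component count. All streams are independent per (stage, species)
via seeded `SeedSequence`s: regenerating with more species leaves
existing species' data byte-identical.

What the generator does **not** emulate: plumage texture, iridescence
and view-to-view variation (all three views share one patch count);
behavioral syntax (states are i.i.d. draws, not Markov sequences);
acoustic temporal structure (onsets are uniform); observation and
measurement error in feature extraction. Passing tests therefore
demonstrate that the pipeline recovers known structure under realistic
sizes and noise — not that any particular empirical conclusion about
real specimens is correct.

## Numerical choices and problem sizes

Tolerances: GLS vs dense oracle 1e-8; ultrametricity 1e-6 relative;
diversity tie-breaks use a 1e-12 slack so exact ties resolve to the
earliest window. Cholesky factorization everywhere a covariance is
solved; eigendecomposition square roots for simulation (PSD-clipped).
Validation experiment sizes are chosen to keep the full suite and the
acceptance script each around a minute on one core: 1,000 null
replicates and 200 power replicates for mPGLS calibration at 40 tips,
100 replicates for imputation leave-one-out and AIC recovery, patch
recovery on 20×20 images for k = 1..8, window-oracle agreement on 40
random multi-clip sequence sets. The default end-to-end pipeline (40
species) runs in about a minute.

## Known limitations

- The clustering's pass structure makes cluster shapes mildly
  order-dependent in principle; determinism is guaranteed (fixed
  iteration order, lowest-index tie-breaks) but the partition is not a
  global optimum of any single objective.
- Automatic note-cluster counts cap at 20 and assume roughly convex,
  separated types; heavily overlapping repertoires need an explicit k.
- OU correlation uses tip distances only (stationary form); non-
  ultrametric trees are accepted in warning mode but the form is then an
  approximation.
- p values condition on the estimated α; mild anti-conservatism at
  small n is measured and reported by `signaldiv.experiments`.
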