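# Methods

`glytrace` implements the computational layer of a glycine-supplemented
hepatocyte-maturation experiment: LC-MS feature-table normalization,
multivariate condition ranking, stable-isotope-resolved metabolomics
(SIRM) with natural-abundance correction and an atom-fate model of
glycine routing, and qPCR relative quantification.  A synthetic-data
generator with known ground truth stands in for the wet-lab inputs.

## Normalization (preprocess)

The carbon-source challenge compares four cell systems (HepG2, mHepG2,
day-22 and day-44 hepatocyte-like cells) exposed for 2 h to a single
carbon source.  Each analyte intensity is divided by the co-measured
fully ¹³C-labeled yeast internal standard (IS) for the same metabolite
and sample, then by the mean IS-ratio of the carbon-source-free HBSS
control wells of the same cell system:

    R[m, s] = (I[m, s] / IS[m, s]) / mean_{c in controls(model(s))} (I[m, c] / IS[m, c])

Control aggregation defaults to the arithmetic mean over replicates
(median available).  The differentiation comparison (AA3, 1.5 mM glycine
vs AAGly, 268 mM glycine) divides raw intensities by each well's total
DNA (µg) instead.  Missingness is first-class: empty CSV cells are NaN
in memory, never zero, because the completeness filter removes exactly
the metabolites unobserved in some condition × cell-model group — the
stricter condition × model grouping is the default (per-condition
grouping is available).  The added carbon sources themselves are
excluded before multivariate analysis to avoid multicollinearity.
Spare mitochondrial capacity is mean(maximal OCR) − mean(basal OCR),
reported signed (a negative value warns but is not clipped).

## Condition-importance ranking (multivariate)

The ranking asks which medium condition best separates the cell systems.
Observations are (metabolite, replicate) pairs labeled by cell model;
features are conditions; values are control-normalized abundances.
Replicates are paired across conditions by their index — deterministic,
and consistent with independently processed wells of one batch.  Fisher
LDA solves S_b v = λ S_w v; coefficients are scaled to unit pooled
within-class variance and sign-fixed (largest-magnitude entry positive).
The proportion of trace λ_k/Σλ gives each discriminant's share of
discriminatory power.  A condition's importance is the trace-weighted
sum of its squared coefficients (unweighted mode available; with one
dominant discriminant both agree).  Metabolite importance averages each
metabolite's discriminant coordinates and applies the same weighting.
Rankings treat scores equal within 1e-6 relative as ties, broken
lexicographically, so degenerate designs are reproducible.  A singular
within-class scatter gets a logged ridge of 1e-8·tr(S_w)/p.

PCA is a plain SVD of the (optionally log10-transformed, centered,
scaled with ddof = 1) sample × feature matrix, with the same sign
convention; the log-vs-none transform accompanying centering is exposed
as config and defaults to none.

## SIRM (sirm)

The tracer is glycine labeled at the alpha carbon — written
NH₂¹³CH₂COOH — so the glycine MID support is {M+0, M+1}.

**Natural-abundance correction.**  A molecule carrying j tracer labels
among n carbons appears at M+i with probability Binom(n−j, p13) of i−j
natural hits (p13 = 0.0107 for ¹³C; other elements and
resolution-dependent overlap are out of scope).  These binomials form a
lower-triangular matrix C and the tracer-only MID is recovered by
non-negative least squares min‖Ca − x‖₂, a ≥ 0, renormalized to
fractions.  NNLS rather than back-substitution keeps noisy inputs from
producing negative fractions.  When only M+0..M+k of an n-carbon
metabolite is measured (e.g. the 15-carbon SAM measured to M+2), the
observed rows of C are used and the label support is capped at the
tracer-reachable maximum (1 for single-transfer products, 2 for PBG).

**Atom-fate forward model.**  Six pool-level parameters in [0, 1]:
g (glycine M+1 enrichment), f (5,10-CH₂-THF one-carbon pool enrichment,
fed by the glycine cleavage system), s (serine fraction newly made via
SHMT), m (methionine fraction remethylated via 5-CH₃-THF), q (SAM
turnover), a (ALA fraction newly made).  Predicted MIDs:

    glycine    (1−g, g)
    serine     s·((1−g)(1−f), g(1−f)+(1−g)f, g·f) + (1−s)·(1, 0, 0)
    methionine (1−m·f, m·f)
    SAM        (1−q·m·f, q·m·f)
    SAH        (1, 0)
    ALA        (1−a·g, a·g)
    PBG        ALA ⊗ ALA

Model assumptions: the glycine carboxyl carbon is lost in the ALAS
decarboxylation and succinyl-CoA is unlabeled, so ALA is at most M+1 and
PBG — two ALA condensing — is the ALA self-convolution; the labeled
methyl departs during transmethylation, leaving SAH unlabeled;
homocysteine, adenosyl and medium serine pools are treated as unlabeled
over the 24 h window.  These are steady-state enrichment parameters, not
fluxes; no kinetics are modeled.

**Estimation.**  Bounded trust-region least squares of predicted vs
observed fractions over θ ∈ [0,1]⁶, 16 seeded multistarts, ties broken
by lowest cost then lexicographically smallest θ.  Parameters whose
estimate lands within 1e-3 of a bound are snapped onto the bound and the
rest refit (kept only if the cost does not degrade), then flagged
`at_bound`; parameters with a flat residual profile (finite-difference
Jacobian column below 1e-7 of the largest) are flagged `flat_profile`.
Flagged parameters are reported as not identified and pinned to 0 for
determinism.  With an unlabeled one-carbon pool (f = 0), m and q are
structurally unidentifiable and are flagged, not guessed.

## qPCR (qpcr)

Relative expression is 2^(−Ct_gene)/2^(−Ct_hk).  When the two genes ran
on different plates, each side's 2^(−Ct) is first divided by the mean
2^(−Ct) of its plate's calibrator wells (shared cDNA amplified with the
housekeeping primer); calibrating both sides makes a constant cycle
offset on either plate cancel exactly, and reproduces the worked
cross-plate value 0.25 (gene Ct 22 on a plate calibrated at 20,
housekeeping Ct 20 elsewhere).  The calibrator mean is taken on the
2^(−Ct) scale; technical replicates are averaged on the Ct scale before
transformation (both choices configurable).  A plate needed for a
cross-plate pair without calibrator wells is a hard error.

## Synthetic data (synthdata)

Intensity noise is multiplicative (log-normal, default 0.1 log10 units —
typical LC-MS peak-area repeatability), with the IS channel at half that.
Default design constants mirror the study: 4 cell models, HBSS + 5
carbon sources × {5, 20} mM, N = 3 (carbon-source design) or N = 5
(AA3/AAGly and tracing designs), 64 metabolites with the key panel named
and generic fillers.  The carbon-source preset embeds a +1 log10 effect
on all metabolites for one (cell model, condition) cell — day-44 HLCs
under 20 mM glycine — leaving every other condition pure noise, so rank
recovery has an unambiguous truth.  Tracer presets ("AA3-like",
"AAGly-like-HLC", "AAGly-like-mHepG2") live in config, not in test
assertions; tracing data are multinomial draws at 10⁴ ions by default
(analytic mode at infinite ions available), with the instrument
reporting isotopologues to M+2.  Ct values are
ct_hk − log2(true ratio) + plate offset + N(0, σ²) with replicated
calibrator wells per plate.  Everything regenerates bit-identically from
(config, seed).

The generator does not emulate chromatographic drift, batch effects,
correlated metabolite covariance, missing-not-at-random dropout, or
isotopologue overlap at finite mass resolution — so passing tests
demonstrate correctness of the computations under the stated error
model, not robustness to every artifact of real LC-MS data.

## Problem sizes and numerics

The bundled studies use 50 seeds × 10⁴ ions for parameter recovery and
100 seeds for LDA rank recovery — sizes at which the Monte-Carlo error
of the reported rates is well below the margins being checked, while the
whole suite stays interactive.  Round-trip identities are asserted at
1e-6 (correction), 1e-9 (PCA reconstruction) and 1e-12 (plate
cancellation).  Degenerate inputs fail loudly: all-zero isotopologue
vectors, constant rows under min-max scaling (configurable to map to
0.5), missing values entering PCA, and missing calibrators are all hard
errors rather than silent repairs.

## Known limitations

The atom-fate model is deliberately coarse: one enrichment per pool, no
compartment split between cytosolic and mitochondrial serine/one-carbon
pools, no time dependence.  Parameters are only as identified as the
measured metabolite set allows, and the fit report says which ones are
not.  The LDA observation layout (metabolite × replicate rows,
condition features) is one of two defensible readings of a
condition-ranking analysis; it is the one under which per-condition
importance is directly defined, and the alternative (per-condition LDAs
over metabolite features) can be built on the same design function.
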