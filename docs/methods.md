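# Methods

This note documents the models implemented in `stoichproteo`, the choices
made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Elemental content and sequence properties

The elemental content of a protein for element `e ∈ {C, N, O, S}` is the
mean number of side-chain atoms of `e` per residue:
`(1/L) Σ_i w_ie n_i`, with `n_i` residue counts and `w_ie` the side-chain
heavy-atom counts (residue molecular formula minus one C2H3NO backbone
unit). A `per_100_residues` scale (×100 exactly) is offered because the
quantity is sometimes printed per 100 residues; all defaults are per
residue, matching the units in which per-protein values are usually
discussed (e.g. an O content of ~0.5 atoms/residue).

Residue classes are configurable; the defaults are standard
hydropathy/charge groupings: hydrophobic {A,C,F,I,L,M,V,W}, polar
{G,N,Q,S,T,Y}, positive {H,K,R}, negative {D,E}, aromatic {F,W,Y}.
Charge is deliberately kept separate from hydropathy and aromatic
overlaps hydrophobic, so the five fractions do not sum to 1. Histidine's
placement among the positives is a convention, not a fact about
physiological pKa; change the sets if your use case differs.

Ambiguous residues (X, B, Z, U): the default policy drops the whole
protein (and logs it) rather than inventing atom counts; a `mask` policy
instead removes the offending residues from numerator and denominator.
The initiator methionine is kept by default; `drop_initial_met=True`
removes it before all statistics, a robustness variant because Met
contributes a constant S atom to every protein. GC content is computed
over the supplied CDS with ambiguity codes excluded from both numerator
and denominator; whether the CDS includes the stop codon is a reader
flag and does not affect GC.

The universal-ortholog filter keeps families with at least one member in
every species and resolves paralog ties deterministically (longest
protein, then smallest id).

## Standing variation

PCA is computed on z-scored variables (the correlation matrix) because
the ten variables mix atoms/residue, percent and residue counts;
component signs are fixed by making the largest-magnitude loading
positive, which makes the decomposition bit-reproducible. Eight
components are retained by default (configurable).

The MANOVA is two-way crossed (species × category) with interaction,
using Pillai's trace and type-II sums of squares: each main effect is
tested adjusted for the other main effect, the interaction against the
additive model; the error SSCP comes from the full model. The F
approximation is the standard Pillai one. Type II was chosen because the
synthetic designs are near-balanced and main effects are the scientific
focus; with heavily unbalanced real data the type choice matters and is
worth revisiting.

Group summaries report median, IQR, and the boxplot-notch 95% CI of the
median, `median ± 1.58·IQR/√n`.

## Comparative methods

All comparative methods condition on a known, rooted tree with strictly
positive branch lengths (not necessarily ultrametric) and assume
Brownian motion (BM) for continuous characters.

*Ancestral states.* The BM log-likelihood of a complete assignment of
node states is `−½ Σ_edges (x_child − x_parent)²/b` up to constants; its
maximizer over internal states is the solution of the tree-Laplacian
linear system with tip values as boundary conditions, solved densely.
The root estimate coincides with the GLS phylogenetic mean. Divergence
since the most recent ancestor is the tip value minus the ML state of
its parent, i.e. ancestral values standardized at the origin.

*Independent contrasts.* Felsenstein pruning: contrast
`(x_L − x_R)/√(b_L + b_R)` at each internal node, nodal value the
branch-length-weighted average, parent branch augmented by
`b_L b_R/(b_L + b_R)`. Because pruning is linear in the tip data the
package precomputes the contrast matrix once per tree and contrasts
whole per-family matrices in a single product. Polytomies must be
resolved first (`resolve_polytomies`, ε = 1e-8 × tree depth on new
branches).

*Evolutionary PCA.* Contrasts have expectation zero by construction, so
the PCA of pooled contrasts is computed through the origin (no
centering) after scaling each column to unit root-mean-square, i.e. on
the correlation structure of evolutionary change.

*PGLS.* GLS of raw species values with error covariance proportional to
the Brownian matrix V (shared root-to-MRCA branch length). No Pagel's λ
or other transformation is estimated — the error structure is pure BM by
design. Slope inference uses t with n−2 df. The per-family sweep
vectorizes thousands of GLS fits through one Cholesky factorization, so
a full sweep of 4934 families is a single matrix operation per axis. The
sweep reports the count of raw p < 0.01 calls against the analytic null
expectation α·N and against a deliberately conservative threshold of 4×
that expectation; an optional Benjamini–Hochberg mode is available for
modern use, but raw-p counting is the default because the conservative
threshold, not per-test error control, is the decision rule. Diet
breadth enters as a numeric 0/1/2 ordinal code — the minimal assumption
for a single ordered trait; the output metadata flags it.

Bias tests on the significant fits: exact two-sided binomial on the
positive/negative slope split, and Pearson χ² (no continuity correction)
on the category × sign table with a single-pass pooling of categories
whose expected count falls below 1 into "other".

## Expression analysis

The piecewise model is a continuous hinge
`y = β0 + β1 x + β2 (x − c)+` reported as below-slope β1 and above-slope
β1+β2 with SEs from the OLS covariance. A disjoint mode (independent
segments, separate intercepts) exists for sensitivity analysis; the
continuous hinge is the default because a single curve broken at a point
is the natural reading of segmented regression on a bimodal abundance
distribution. AIC is Gaussian, `n·log(RSS/n) + 2k` with k counting the
error variance, so an unused hinge term costs exactly 2 units.

Degenerate breakpoints: when one side of the breakpoint is empty the
hinge term is unidentifiable and the fit collapses to the plain linear
regression (flagged `degenerate`); a side with one or two points raises
an error naming the side. Breakpoint selection minimizes AIC over a
candidate grid (default 3.0–8.0 by 0.25), breaking ties toward the grid
median; if no candidate beats the straight-line AIC by at least 2 the
data carry essentially no evidence of a breakpoint and a flat-profile
warning is emitted. The default breakpoint of 5.5 log2 units is the
conventional split between the low- and high-expression clusters of
FlyAtlas-style data and can be re-derived on any dataset with
`select_breakpoint`.

The linear-vs-piecewise comparison is the nested F test
`F = ((RSS_lin − RSS_pw)/Δdf)/(RSS_pw/df_pw)`. The tissue sweep ranks
tissues ascending by above-breakpoint slope (strongest nutrient
conservation first) with ties broken by tissue name, and attaches
significance stars at 0.05/0.01/0.001.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
not any real organism's biology.

*Compositional drift.* Each family draws a root amino-acid frequency
vector around a eukaryote-average baseline (logit-space jitter, sd 0.30
across families) plus its category's logit offsets, then evolves
elementwise-logit frequencies by BM along the tree (σ² = 1e-3 per unit
branch; the bundled tree is 63 units deep, giving tip-level logit sds
near 0.25) and back-transforms with a 1e-6 floor and renormalization.
Logit-BM rather than Dirichlet jumps keeps frequencies valid while
giving tips the shared-branch-length covariance that PIC and PGLS
assume, so calibration tests are meaningful. Category offsets plant
biochemical signatures, e.g. +0.5 logits on K and R for
nucleic-acid-binding-like proteins (elevated N, the positive charge of
DNA binders); membrane categories get hydrophobic offsets.

*Lengths, GC, sequences.* Root lengths are gamma (mean 400, shape 4)
with lognormal BM across species; species GC level is BM around 52%
(clipped 40–62). Realized sequences are i.i.d. draws from the tip
frequency vectors with an initiator Met; codons are sampled with a
per-species GC bias so realized CDS GC tracks the planted level. The
sequence-free "analytic" composition mode evaluates the composition
variables exactly from the frequency vectors — the infinite-length
limit — and is used for calibration studies, because finite-sequence
multinomial noise is iid across tips and would sit on top of the
Brownian covariance those studies isolate.

*Traits.* Each trait evolves by BM and is mapped into a realistic
published range (genome size 130–364 Mb, intron percent 19.6–24.0, and
so on), with diet breadth cut from a latent BM character into an ordinal
0/1/2. Planted effects replace a trait by slope × (a species-level
composition signal) + BM noise.

*Expression.* Per gene and tissue, log2 abundance is a two-component
Gaussian mixture (means 2.5 and 7.5, sds 1, weight 0.5). The planted
per-tissue high-expression slopes (defaults −0.007, −0.002, 0, +0.0036 N
atoms/residue per log2 unit for gut-, brain-, ovary- and testis-like
tissues) are installed by tilting each gene's N content once by
`Σ_t slope_t (abundance_t − 5.5)+`. Within a tissue this plants a
continuous hinge with below-slope exactly 0 and above-slope exactly the
tissue's target (cross-tissue terms are independent noise), so the
estimator being validated is correctly specified.

What the generator does **not** emulate: real codon usage, introns,
probe-level expression artifacts, gene families gained or lost on the
tree, or correlated evolution between traits and composition beyond the
planted linear effects. Passing tests therefore demonstrate the
correctness and calibration of the methods under their own assumptions,
not that real proteomes satisfy those assumptions.

## Calibration studies and problem sizes

The test suite and acceptance script fix these study conditions:

- **Null sweep at full scale**: 4934 families on the 12-taxon tree,
  analytic composition mode, one null BM trait; the observed count of
  p < 0.01 calls on PC1 is compared with the exact binomial 99% interval
  around α·N = 49. PC1 is the reference axis because it is dominated by
  the genuinely evolving compositional variables. Axes dominated by the
  GC column are not binomially calibratable by construction: species GC
  is a single shared vector entering every family identically, so those
  4934 tests are fully dependent (their count collapses toward 0 or
  extremes). This is a property of any design with species-level
  covariates, not an implementation artifact.
- **PGLS null calibration**: 2000 vectorized replicates at α = 0.01.
- **PIC/PGLS identity**: 100 random 12-taxon trees, agreement to 1e-8.
- **Ancestral-state oracle**: 3-taxon trees against a nested grid search
  of the BM likelihood, agreement to 1e-4.
- **Breakpoint selection**: 200 replicates, n = 2000, residual sd 0.1,
  grid 4.0–7.0 by 0.5, generating hinge +0.05/−0.10 at 5.5 (a clear
  break; the slopes are the generator's declared condition).
- **Slope coverage**: 500 replicates, n = 4000, residual sd 0.15,
  generating slopes +0.0005 below and −0.007 above; 95% CI coverage of
  the above-slope must be ≥ 93%.
- **End-to-end**: a realized 500-family scenario (category N enrichment,
  null-sweep calibration) plus the 4000-gene expression condition. At
  n = 4000 the above-slope SE is ≈0.0015, so the planted −0.002 and 0
  tissues differ by about one SE; the sweep is therefore validated on
  sign and significance calls and on the extreme ranks (gut-like
  steepest negative, testis-like the only significant positive), which
  is what the planted effect sizes can support.

The full suite runs in well under a minute; the acceptance script in
about half a minute.

## Known limitations

- PGLS assumes pure BM errors; measurement noise (e.g. finite sequence
  length) makes the tests conservative to miscalibrated depending on the
  noise-to-signal ratio. A λ-style error model is out of scope.
- The MANOVA F approximation for Pillai's trace is asymptotic; very
  small groups give only approximate p-values.
- The hinge and disjoint piecewise variants answer slightly different
  questions when the true relation is discontinuous at the breakpoint;
  the reported SEs assume the chosen variant is correct.
- Ordinal diet breadth as numeric 0/1/2 assumes equal spacing between
  levels.
- `filter_universal_orthologs` trusts the ortholog map; paralog
  tie-breaking by length is a convention, not an orthology inference.
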