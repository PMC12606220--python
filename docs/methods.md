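# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `collagenphylo`, and what the synthetic-data validation does and does
not establish.

## In-silico digestion and peptide masses

Trypsin is modelled with the classic Keil rule: cleavage C-terminal to K or
R, suppressed when the next residue is proline. Peptides with 0..`max_missed`
internal missed cleavages are generated per chain (COL1A1 and COL1A2 are
digested as separate mature chains; default `max_missed = 1`). Monoisotopic
masses are the sum of residue masses (6-decimal standard values shipped in
`constants.py`) plus water (18.010565 Da); modifications add 15.994915 Da per
hydroxylation (proline by default, optionally lysine) and 0.984016 Da per
deamidation (N/Q sites). m/z assumes positive protonation, (M + z·1.007276)/z,
with the MALDI singly-charged convention as default. The theoretical
fingerprint enumerates modification variants inside an m/z window (default
800–3600 Da, the usual ZooMS MALDI range) with a per-peptide hydroxylation cap
(default 6) to bound the combinatorics — collagen's Gly-X-Y repeat makes
higher counts chemically implausible for tryptic-sized peptides.

The worked example used throughout the package is the 33-residue peptide
GLTGPIGPPGPAGPSGDKGESGPSGPAGPTGAR (one internal missed cleavage). With a
single hydroxyproline its neutral mass is 2868.400 Da and its [M+H]+ is
2869.41 — the diagnostic high-mass marker peak. One hydroxylation is
mass-consistent with the nominal m/z 2869 assignment; the exact
hydroxylation count behind that assignment is not otherwise constrained, so
the package notes rather than asserts it.

## Fingerprint screening

Observed and theoretical peaks are matched greedily by nearest |Δm/z| with a
one-to-one constraint, tolerance 0.2 Da by default (typical
externally calibrated MALDI-ToF accuracy). Marker panels map taxa to
diagnostic m/z sets. Because bone collagen is highly conserved, panels built
from theoretical fingerprints default to the *full* fingerprint per taxon:
identification then rests on the joint peak pattern ("collectively unique"
markers), which is robust where single unique peaks are rare. Taxa whose
fingerprints are mutually indistinguishable at the matching tolerance form
ambiguity groups and are reported under a joint label (e.g. `T7/T8`) rather
than as a single taxon. Assignment requires the top score to reach
`min_markers` (default 2) and to beat every taxon outside the winner's
ambiguity group; all other outcomes are "indeterminate" — conservative by
design.

Preservation is scored from high-mass peak visibility: "good" requires at
least `min_high_peaks` (2) peaks above `high_mz_threshold` (2400 Da) at
≥ `min_relative_intensity` (10%) of the base peak. Collagen degradation is
indexed by the raw height ratio of the nominal 1105.58/1106.56 peak pair;
lower ratios mean more deamidation. When either peak is absent the index is
undefined (`None`), never zero. The thresholds are declared configuration,
not inferred from data; the peptide identity behind the 1105/1106 pair is
not modelled — the index is defined purely on nominal m/z.

## Sequence assembly

Collagen I chains are assumed indel-free across the ingroup, so recovered
peptides are placed by coordinate on the concatenated COL1A1+COL1A2 frame of
a reference taxon — no gap-admitting alignment. Unknown positions are `X`.
Overlapping peptides that disagree are resolved by majority peptide support;
ties become `X`, and every conflict is logged (taxon, chain, position,
vote counts). Coverage is reported per taxon as % non-X to one decimal.

## Likelihood model

The substitution model is a reversible empirical amino-acid model
(mtMAM or mtREV24 exchangeabilities with their published frequencies;
`+F` replaces frequencies with observed counts, pseudocount 0.5). The rate
matrix is Q = S·diag(π) normalized so −Σ πᵢQᵢᵢ = 1. Rate heterogeneity
combines a proportion of invariant sites p_inv (`+I`) with a two-category
free-rate mixture (`+R2`): weights (w₁, w₂) and rates (r₁, r₂) with
Σwₖ = 1 and the mean-rate constraint (1 − p_inv)·Σwₖrₖ = 1, so branch
lengths remain on the expected-substitutions scale. r₂ is always solved from
the constraint, leaving (w₁, r₁) free.

Site likelihoods use Felsenstein pruning on unique column patterns, `X`
treated as fully missing (tip partial of ones), with per-pattern rescaling
against underflow. The invariant class contributes p_inv·π_a for columns
whose observed residues all equal a (and p_inv·1 for all-missing columns).
Transition matrices come from the symmetric eigendecomposition of Q;
negative round-off entries are clipped and rows renormalized. The pruning
path is validated against an exhaustive enumeration oracle (sum over all
internal-state assignments) to 1e-10 relative tolerance on small instances.

## Optimization and tree search

Branch lengths are optimized by exact coordinate ascent: a recursive
traversal maintains conditional likelihoods below each node and outside each
edge, so each per-edge Brent line search (bounds [1e-8, 10], xatol 1e-7)
costs one transition matrix and one (patterns × 20) product. Model
parameters (p_inv ∈ [0, 0.95], w₁ ∈ [0.02, 0.98], r₁ bounded to keep r₂
feasible) are fitted by bounded scalar searches interleaved with
branch-length rounds; iteration stops when a full round gains < 1e-6 logL.
Only improving steps are accepted, so the objective is monotone.

Tree search is NNI hill climbing with seeded random restarts (perturbed
starts), each neighbour evaluated by branch-length re-optimization;
the winner gets a final high-round polish. Support values use standard
nonparametric column-resampling bootstrap with a cheap NNI re-search per
replicate. This is deliberately *not* the UFBoot approximation: supports
are comparable in meaning but not numerically identical to IQ-TREE's, and
the package's validation targets properties (degenerate-signal clades at
100%, support growth with alignment length) rather than third-party
numbers.

Model selection fits each candidate {matrix} × {+F} × {+I} × {+R2} on a
fixed topology and ranks by AIC (default) or BIC. Parameter counts:
2n−3 branch lengths, +F = 19, +I = 1, +R2 = 2.

## Topology testing

The AU test resamples per-site log-likelihood vectors (RELL — no
re-optimization) at scales r ∈ {0.5, …, 1.4} (default), B = 10 000
replicates per scale, ties broken uniformly at random (seeded). For each
topology the bootstrap proportions BP(r) are probit-transformed and fitted
by weighted least squares to d·√r + c/√r; p_AU = 1 − Φ(d − c). Scales at
which BP is degenerate (0 or 1) are dropped; if fewer than two usable
scales remain the p-value is clamped to 0/1 and flagged. With a single
scale r = 1 the procedure reduces to the plain RELL proportion, which is
checked against an independent resampling implementation.

## Divergence dating

Node dating runs on a fixed rooted topology (by default the ML tree rooted
on the designated outgroup). The model:

* uniform fossil calibrations on clade ages, attached to the *stem* node
  (parent of the MRCA) by default — whether a named calibration means stem
  or crown is genuinely ambiguous in such designs, so both are supported
  via a per-calibration switch and the default is declared, not guessed;
* a birth-death node-age prior conditioned on the root age (conditioned
  birth-death density, each non-root internal age iid on [0, t_root]),
  with exponential hyperpriors on birth and death rates;
* a strict clock or an uncorrelated lognormal relaxed clock — per-branch
  multipliers m with log m ~ Normal(−σ²/2, σ²) (mean-1 parameterization),
  clock mean with a broad lognormal prior, σ exponential;
* likelihood = pruning likelihood at branch lengths clock_mean·m·duration.

Sampling is Metropolis-Hastings with operator weights 40% node ages / 30%
rate multipliers / 30% scalars. Node-age proposals draw uniformly in the
feasible window [max(children, calibration min), min(parent, calibration
max)] — symmetric, and exact Gibbs sampling in prior-only mode. Scale moves
are lognormal random walks with the standard Hastings correction.
`use_likelihood=False` and `use_tree_prior=False` switches support
prior-sampling validation; note that uniform *marginals* at calibrated
nodes are only guaranteed when order constraints do not truncate the
calibrated window (a free intermediate node between a calibrated node and
the root makes the joint-uniform marginal provably non-uniform — a property
of the age polytope, not an implementation artifact). The validation
therefore calibrates a node directly under a much older root.

Summaries: shortest-interval HPD (the minimal-width window containing
⌈mass·n⌉ sorted samples); ESS by Geyer's initial-positive-sequence rule
(paired autocorrelations summed while positive; pathologically
anticorrelated chains report ESS > n and are flagged); the MCC tree
maximizes the product of clade posterior frequencies over sampled
topologies (trivially the fixed topology here), annotated with mean ages
and 95% HPDs. Desk-scale defaults are 3 chains × 200 000 steps sampling
every 100; production-scale settings (e.g. 10M steps) are plain
configuration.

Topology is *fixed* during dating; co-estimation of topology and ages is
not implemented. This is the main known limitation of the dating module:
posterior clade supports from dating runs are meaningful only relative to
the fixed tree.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, with
defaults chosen as the study conditions:

* birth-death time tree (birth 0.15/Ma, death 0.05/Ma) conditioned on
  n_taxa = 8, root age 50 Ma — a small diprotodontian-like radiation; tip
  edges are extended by the exponential waiting time to the next event so
  the youngest node age is positive;
* collagen sequences of 2000 residues (split 50/50 into chains) evolved
  under mtMAM at clock mean 0.002 substitutions/site/Ma (strict clock by
  default; lognormal σ configurable), giving root-to-tip lengths ~0.1 —
  the slow, conserved regime of collagen;
* per-taxon coverage drawn U(0.74, 0.84) and imposed either as
  peptide-level recovery subsets or as geometric blocks of X (mean block
  15 residues — tryptic-peptide-shaped missingness, not iid cells);
* spectra from the 0-missed-cleavage, ≤1-hydroxylation fingerprint with
  Gaussian m/z jitter (σ 0.02 Da), lognormal intensities (σ 0.5), 10% peak
  dropout, an injected 1105.58/1106.56 pair whose height ratio follows a
  logistic age map onto [0.58, 0.77] (midpoint 50 ka, width 20 ka — the
  observed ratio range anchors the endpoints; the kinetic form is a
  modelling choice), and a "poor" mode that scales peaks above 2400 Da to
  5% of base;
* one master seed drives all randomness; identical seeds give
  byte-identical bundles.

What the generator does **not** emulate: isotope envelopes and peak shape,
chemical noise and matrix clusters, mass-calibration drift, inter-taxon
length variation/indels, site-specific hydroxylation preferences, and
non-collagenous protein contamination. Passing the synthetic recovery
tests therefore shows internal consistency of the pipeline under its own
generative assumptions — not field performance on real spectra.

## Problem sizes used in validation

Validation runs are sized for a desk machine: pruning-oracle checks use
≤4 taxa × ≤10 columns × 100 instances; parameter recovery uses 4–6 taxa at
800–5000 columns; topology recovery uses the 8-taxon, 2000-column bundle;
prior-sampling checks use 60 000-step chains; HPD-coverage uses 20
replicates of 6 taxa × 600 columns × 10 000-step chains with the true root
age drawn from the calibration window (so Bayesian coverage is exactly
calibrated by construction). Bootstrap and AU replicate counts in tests are
reduced from the production defaults (which remain 1000 bootstrap
replicates and B = 10 000 AU resamples).

## Numerical choices and degenerate inputs

Branch lengths clamped to [1e-8, 10]; rates to [1e-4, 100]; p_inv < 0.95;
+F pseudocount 0.5 avoids zero frequencies; per-pattern rescaling in the
pruning recursion; probit WLS in the AU fit drops degenerate scales;
deamidation index is undefined (not 0) when a peak is missing; empty peak
lists classify as "poor"; empty alignments, inconsistent calibrations,
zero-length chains, profile-mode spectra and spans beyond the reference all
raise immediately with context.
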