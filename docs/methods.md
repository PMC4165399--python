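# Methods

## Scope and model

netprio re-implements, as a tested library, the standard network-knowledge
workflow for characterizing the transcriptional footprint of a perturbation:
fold-change DEG screening, integration of public PPI edge lists into one
parent interactome, first-neighbor subnetwork construction around the DEGs,
scale-free topology analysis of those subnetworks, random-walk-with-restart
(RWR) prioritization of DEGs relative to a seed protein, and enrichment-chart
comparison between two contrasts. All graphs are undirected, unweighted and
simple; all gene identifiers are uppercased symbols sharing one namespace
(no identifier-mapping service is built in; an optional two-column alias map
can be applied at read time).

## DEG screening

Inputs are assumed normalized, gene-level, linear-scale intensities, one
profile per condition. The screen is a pure ratio filter: up if
case/control ≥ t, down if ≤ 1/t. Choices that the ratio convention leaves
open are fixed as contracts: the threshold is applied symmetrically on the
ratio scale, the boundary is inclusive, and fold changes are computed on
linear intensities (a `--log2-input` CLI flag exponentiates first). No
replicate statistics or p-values are computed — with one profile per
condition nothing else is estimable, and the fold-change-only design is
exactly what the screen models. Raising the threshold can only shrink the
DEG set (anti-monotonicity), which the property tests assert.

## Network integration and subnetworks

Readers handle a generic two-column TSV, a BioGRID-TAB-style file (symbol
columns located by header name; the header row may carry the conventional
leading `#`) and an HPRD-flat-style file (positional columns, default
(0, 3)). Self-loops are dropped at read time because they distort degrees
and the RWR column normalization; duplicate unordered pairs are collapsed,
making `integrate` a plain union that is commutative, associative and
idempotent.

"First neighbor" extraction returns the *induced* subgraph on
seeds ∪ neighbors — neighbor–neighbor edges included — matching the
Cytoscape select-first-neighbors operation; the DEG–DEG subnetwork is the
induced subgraph on the DEGs alone, with zero-degree DEGs retained and
flagged rather than silently dropped. Unmapped DEG symbols are reported,
not fatal: microarray symbol sets routinely exceed PPI namespaces.

## Topology

The degree histogram uses raw (k, count) points without logarithmic binning
or cumulative transformation, mirroring NetworkAnalyzer's direct linearized
fit. The fit is OLS of ln(count) on ln(k); natural logs are used internally
(the exponent and R² are base-independent). Degenerate zero-residual fits
(including constant counts) define R² = 1, the perfect-fit limit that keeps
R² ∈ [0, 1]. The "correlation" statistic is the Pearson r between observed
and fitted counts on the original scale, NetworkAnalyzer's convention; when
either vector is constant, Pearson r is undefined and the value is reported
as 1 for an exact fit and 0 otherwise. Centralization requires N ≥ 3,
density N ≥ 2; smaller inputs raise an undefined-metric error instead of
returning a number.

## Random walk with restart

The walk iterates p⁽ᵗ⁺¹⁾ = (1−r)Wp⁽ᵗ⁾ + r p⁰ with W[i,j] = A[i,j]/deg(j)
(column-stochastic) and p⁰ uniform over the seeds. Components containing no
seed are excluded with score 0 (label "unreached"), so the total probability
over included nodes is exactly 1 at every iteration; the residual decays
geometrically with ratio ≤ 1−r, making the defaults (L1 tolerance 1e-10,
max 10 000 iterations) cheap. Defaults: r = 0.7, the standard choice in the
RWR gene-prioritization literature; the restart probability of any given
published run is rarely recoverable, so r is an explicit parameter
everywhere. A dense closed-form solver p = r(I − (1−r)W)⁻¹p⁰ — valid
because the spectral radius of (1−r)W is below 1 for r > 0 — is shipped as
an exact oracle for graphs up to a few hundred nodes and is never used as
the production path.

Layer binning: seeds are layer A regardless of score; a non-seed node with
⌊−log10 p⌋ = b gets the b-th letter (2 → B, 3 → C, …). A non-seed score
above 10⁻² has no published precedent in this scheme; it is clamped to B
with a logged warning.

## Enrichment

The chart tests a gene list against every set of a GMT collection with the
one-sided hypergeometric upper tail P(X ≥ k) (Fisher exact), or the EASE
variant P(X ≥ k−1), DAVID's conservative score, which is row-wise ≥ the
Fisher p-value. Gene lists and sets are intersected with the background
first; query genes outside the background are dropped with a log message
rather than raising, matching how annotation services treat unannotated
input. The default background is the union of collection members (the
"annotated universe"), intersected with the expression universe in the
synthetic pipeline. The significance filter is a strict raw P < α cut
(α = 0.05 by default); Benjamini–Hochberg is available behind a flag but is
not applied by default. Term–term edges use the overlap coefficient
|A∩B|/min(|A|,|B|) with cutoff 0.6, Enrichment Map's default metric, and
node tables carry −log10 p as a size attribute.

## Synthetic data: what it emulates and what it does not

* Networks: Barabási–Albert preferential attachment, which guarantees a
  connected simple graph with a heavy-tailed degree distribution — the
  property the topology stage is designed to detect. Fitted exponents on
  n = 2000, m = 2 networks land around −1.8 to −2.0 with R² > 0.8.
  Real interactomes additionally show date-hub structure, study bias and
  modularity that the generator does not model.
* Expression: control intensities are log-normal (log2 mean 7, sd 1.5),
  the positive right-skewed range RMA-normalized arrays produce. Planted
  fold changes are uniform in [fc_low, fc_high] for up-genes and reciprocal
  for down-genes; noise is multiplicative on the linear scale (additive
  Normal(0, sd) in log2), the standard microarray error model. One profile
  per condition is emitted, matching the fold-change-only screen; replicate
  structure is deliberately out of scope. Passing tests therefore shows the
  pipeline's arithmetic and recovery behavior under this error model, not
  robustness to probe effects, batch effects or correlated noise.
* Gene sets: uniform random subsets with uniform sizes. Real annotation
  categories are hierarchical and correlated; term-graph results on
  synthetic sets exercise the mechanics, not GO-like redundancy.

Default demo conditions (50 up / 50 down planted at FC ∈ [1.8, 3.0], log2
noise sd 0.3, threshold 1.5): recovery sensitivity is ≥ 0.9 by construction
of the signal-to-threshold margin (log2 1.8 ≈ 0.85 vs log2 1.5 ≈ 0.585,
noise sd 0.3), and the shipped seeds realize 0.97–1.0. Noise also produces
false-positive DEG calls at this sd — intentional, since the screen has no
error control.

## Numerical choices

* RWR convergence: L1 residual < 1e-10 or 10 000 iterations; conservation
  is exact to float rounding (≈ 2e-16 observed).
* Iterative vs closed-form agreement on ≤ 200-node graphs is required to
  1e-8 in L∞ and observed around 1e-11.
* Power-law OLS matches the closed-form normal equations to 1e-10.
* Hypergeometric tails match exhaustive enumeration to 1e-12 for all
  N ≤ 60 (observed error ≈ 1e-16).
* Ties everywhere break lexicographically by symbol (DEG ordering at equal
  |log2 FC|, RWR ranking at equal score, largest-component selection at
  equal size), so every output is deterministic.
* All RNGs are explicit numpy Generators seeded by required arguments; the
  pipeline derives per-stage seeds (master+1 … master+3) from one master
  seed, and re-running a config reproduces byte-identical files (verified
  by sha256 in the manifest).

## Problem sizes

Tests and the acceptance script use 2000-node generated networks for
topology claims, 10–200-node random connected graphs for RWR oracle
equivalence, N ≤ 60 universes for exhaustive hypergeometric enumeration and
a 600–1500-node end-to-end pipeline — sizes at which the closed-form and
brute-force oracles are exact and fast while the asymptotic properties
(heavy tails, geometric convergence) are already clearly expressed.

## Known limitations

* No identifier mapping, interaction-type filtering or confidence scoring
  on PPI input; rows are trusted as given.
* Single-profile contrasts only; no moderated statistics or FDR on the DEG
  screen.
* The power-law fit is the linearized least-squares convention, chosen for
  fidelity to the NetworkAnalyzer-style workflow; it is known to be biased
  relative to maximum-likelihood (Clauset-style) estimation, which is
  deliberately out of scope.
* Enrichment results depend entirely on the user-supplied GMT content; no
  annotation databases ship with the package.
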