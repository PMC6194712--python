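# Methods

This note records the statistical models, conventions and design choices
behind `cofracbench`, in the order the pipeline applies them.

## Chromatogram conventions

A chromatogram is a protein's SILAC ratio over ordered fractions, with
explicit missing values. Two global preprocessing rules apply to every
pairwise comparison:

* **zero-filling** — missing values are replaced by zeros before computing
  either similarity metric. A missing SILAC ratio in a fraction is treated
  as evidence of absence there, not as ignorable; this makes profiles with
  disjoint quantified regions (which cannot be co-eluting) strongly
  dissimilar rather than incomparable.
* **min–max normalization** — for Euclidean distance only, each zero-filled
  chromatogram is scaled to min 0 / max 1. Zero-filling precedes
  normalization: it is a statement about the raw measurements, not the
  normalized shape.

Profiles constant after zero-filling (including all-missing profiles) have
no defined correlation and a degenerate normalization; such pairs are
excluded from both metrics and counted (`table.attrs["n_excluded"]`), never
imputed or given a sentinel value. Profiles quantified in fewer than
`min_fractions` fractions (default 5) are dropped before any analysis.
Pearson uses the standard product-moment formula; implementation and test
oracles agree to 1e-12.

The anti-correlated fraction (share of pairs with R strictly below a
threshold, default 0) is reported both pooled over datasets and
per-dataset (mean ± sd), since the two summaries answer slightly different
questions and the pooled one is dominated by the largest datasets.

## Complex-level permutation test

Per complex: the mean pairwise R over all within-complex profile pairs,
pooled **flat** across datasets — each comparison weighs equally, so a
complex quantified in many datasets is summarized by many comparisons, not
by a mean of per-dataset means. Internally all profiles are centered and
scaled to unit norm, making the sum of pairwise correlations of a member
set computable from one vector norm (‖Σzᵢ‖² − m)/2; this is what makes
thousands of permutations cheap.

The null resamples **protein identities, not fractions**: each permutation
draws, from every dataset, a random set of the same size as the complex's
observed membership in that dataset, and records the identically pooled
mean. This preserves each dataset's marginal profile statistics (the
"chance" co-elution level, which is substantially positive in real data)
and the complex's per-dataset pooling weights. P-values use the add-one
rule, p_high = (1 + #{null ≥ obs})/(1 + n_perm), and symmetrically p_low,
so no finite-permutation p is ever zero; the two one-sided families are BH
corrected separately across complexes, and a complex is *enriched* if
q_high < α, *depleted* if q_low < α (α = 0.05 default, n_perm = 1000
default). Because p_high + p_low ≥ 1 + 1/(1+n_perm), both calls can never
fire together in practice; a tie-break on the smaller p exists for
completeness.

Housekeeping complexes follow the per-tissue variant: a complex qualifies
iff its uncorrected p_high < α in **every** tissue — a conjunction over
tissues is already a multiplicity control, so no BH is applied there.

A generic `permutation_null(datasets, n_members, ...)` with a single set
size is also exposed; the significance path uses the per-dataset matched
variant above because under missingness the observed membership differs by
dataset, and mismatched null sizes would break calibration.

## Interactome enrichment

For one interactome and one complex with n possible within-complex pairs
(both members observed in the interactome) of which k are edges, against
database totals N and K over all observed complexes, the enrichment p is
the hypergeometric upper tail P(X ≥ k), X ~ Hypergeom(N, K, n). The
universe is deliberately restricted to within-complex pair slots over
observed proteins, so "enriched" means denser than the catalogue-wide
within-complex edge rate of that interactome; the degenerate single-complex
case (n = N) then gives p = 1 explicitly instead of a spurious signal. The
alternative universe (all pairs among observed proteins) would conflate
catalogue coverage with complex-level signal.

Technique-specific complexes: predicted (≥ 1 within-complex edge) in at
least ⌈2·t/3⌉ of a technique's t interactomes (4 of 6, 2 of 3) and in at
most 1 interactome of each other technique. The chance model permutes,
independently per interactome, *which* complexes carry the predicted flag —
preserving each interactome's number of predicted complexes, the only
margin the observed count should be judged against — and reports the
add-one bootstrap p of the observed count.

Detectability ("could-be-predicted") controls are technique-specific: CF
requires ≥ 2 complex members in the quantified raw-data roster; AP-MS under
the matrix model requires ≥ 2 members among interactome proteins; Y2H
requires ≥ 1 member among the baits.

## Gold-standard subsets

The CF-specific subset at threshold t contains the complexes with
enrichment p < t in **all** chosen held-out interactomes (the conjunction
reading; an any-k-of-n mode exists but is off by default). At t = 1 this
reduces to "≥ 1 within-complex edge in each". Subsets therefore nest along
the threshold ladder 1, 10⁻², 10⁻⁶, 10⁻¹⁰, and each subset's pair set is
the union of within-complex pairs of its complexes. Random control subsets
are drawn uniformly without replacement over unique gold *pairs* (not
complexes), size-matched to the subset under test — the control for the
fact that shrinking any gold standard inflates precision estimates (FP
label pairs grow quadratically with roster size, TP pairs linearly).

## Expression consistency

Gini is computed per protein across tissues from the sorted closed form
G = (2Σᵢ i·x₍ᵢ₎)/(nΣx) − (n+1)/n (equal to the mean-absolute-difference
form to 1e-12 in tests), over non-missing values only — expression
matrices, unlike chromatograms, carry no zero-fill convention. Undefined
rows (< 2 values, or all zero) are skipped and logged. The unit of analysis
is the protein; group comparison (CF-specific complex members vs other
complex members, shared proteins assigned to the CF-specific side) uses the
Welch unequal-variance t-test. Overlap of complex sets is the same
hypergeometric upper tail, with the universe defaulting to the number of
observed complexes.

## Interactome prediction

Features per candidate pair: zero-fill Pearson R, min–max Euclidean
distance, and co-apex distance (absolute difference of peak fractions),
averaged over the datasets where the pair is computable. The classifier is
Gaussian Naive Bayes (per-class feature means/variances, variance floor
1e-9). Labeled pairs (TP = within-complex in the chosen gold standard,
FP = both proteins in the gold roster but never co-complexed) are scored
out-of-fold under stratified k-fold CV (10 folds by default, shrunk to the
minority-class count when needed, shuffled under the seed); unlabeled pairs
are scored by the model fit on all labeled pairs. Pairs are ranked by
descending posterior P(TP), ties broken by canonical pair order for
determinism. Precision is cumulative over labeled pairs down the ranking
(the alternative — thresholded-set precision — differs only by where the
curve is read); the interactome at target precision is the deepest prefix
whose cumulative precision meets the target, and its size counts unlabeled
pairs too, since those are the discoveries.

## Synthetic data: what it emulates, and what it does not

Chromatograms are sums of 1–2 Gaussian elution peaks (σ = `peak_width`,
default 3 fractions; height ~ U(0.5, 1.5) × `peak_height`, default 10) plus
zero-truncated Gaussian noise (default sd 1 = a tenth of the peak height)
and uniform missingness (default 20%). Elution centers for ordinary
proteins are drawn from a shared mid-axis envelope (Normal, sd
`envelope_sd`, default n_fractions/8): real chromatograms concentrate most
complexes in a central elution range, which makes *chance* pairwise
correlation substantially positive — without this feature a depleted
complex could never score below chance, because m mutually anti-correlated
vectors are bounded at mean R = −1/(m−1). Planted classes:

* **coeluting** — members share one peak center per dataset, jittered by at
  most `coelution_jitter` (default peak_width/4);
* **disrupted** — members get anti-phased centers spread evenly across the
  whole fraction axis (the strongest mutually-anti-correlated arrangement),
  redrawn per dataset;
* **neutral** — independent envelope draws, statistically exchangeable with
  chance.

Complex memberships are disjoint, sizes uniform on `complex_size_range`
(default 2–10); the default study is 500 proteins, 50 fractions, 60
complexes, 3 replicate datasets — sized so the full pipeline runs in well
under a minute. Synthetic interactomes sample within-complex edges of each
technique's detectable complexes (co-eluting complexes for CF; the others
split between AP-MS and Y2H) at `detect_prob_within` = 0.8, plus uniform
background edges at `detect_prob_cross` = 0.01 per pair — background
density an order of magnitude above published interactomes, so that small
simulated universes still get realistic catalogue coverage. Expression is
lognormal around a per-protein abundance with across-tissue CV 0.2 for
housekeeping proteins (members of co-eluting complexes) and 1.0 otherwise.

What the generator does **not** emulate: multi-complex membership and
moonlighting proteins, correlated (structured) missingness, fraction-shift
miscalibration between replicates, intensity-dependent noise, shared
subunits between complexes, or any sequence-level identity structure.
Passing parameter-recovery tests therefore demonstrates the statistics
behave as designed under the stated generative model — not that real data
meet that model's assumptions.

## Numerical and degenerate-input policy

Correlations are clipped to [−1, 1] against rounding; oracle comparisons in
tests use 1e-12 absolute tolerance. Small complexes are the systematic
power limit of the permutation test: a size-2 complex contributes one
comparison per dataset, and with 3 datasets neither tail can reach extreme
p-values, so a minority of size-2/3 planted complexes land in "neither" —
visible in the recovery tests' sensitivity just above 0.9. Degenerate
cases raise (empty tables, zero tissues, oversized random subsets, missing
rosters) or are excluded-and-counted (constant profiles, undefined Gini),
never silently imputed. All randomness flows through
`numpy.random.Generator` objects or integer seeds; the pipeline derives
per-stage seeds from the master seed via `SeedSequence`, and re-running a
config reproduces byte-identical outputs (verified by SHA-256 in tests).

## Known limitations

* The hypergeometric universe choice (within-complex slots) is one of two
  defensible readings; the alternative is noted above and would shift
  absolute p-values but not the subset-nesting structure.
* The permutation and bootstrap chance models condition on the margins
  described; other exchangeability assumptions (e.g. degree-preserving edge
  rewiring) are not implemented.
* Protein groups collapse to their first accession on load; no attempt is
  made to resolve shared peptides or isoform-level evidence.
* The predictor implements the classifier/evaluation core only — no
  Gaussian-mixture profile fitting or complex reconstruction.
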