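# Methods

## The network model

The cytokine GRN is a bipartite simple graph: TFs on one side, cytokine
genes on the other, one edge per distinct curated (TF, cytokine) pair
within a species. Duplicate literature reports of the same pair are merged
at read time — assay categories and article ids are unioned, and
conflicting activity annotations (activating in one report, repressing in
another) become *bifunctional* — so degree always counts distinct
partners, never citations. Randomized networks produced by the null model
carry topology only; statistics that need curation metadata (activity and
evidence fractions) refuse to run on them.

Evidence classification is a pure function of the assay-category set:
*high* requires a functional assay (reporter, knockdown, ...) together
with a direct-binding assay (ChIP or in vitro binding). The conjunction is
applied literally, so ChIP + in vitro binding without any functional
read-out is still *low*: two binding modalities show occupancy, not
regulation.

Cross-species overlap uses case-insensitive symbol identity as the default
ortholog map, with an optional user-supplied two-column mapping; genes
without a counterpart stay species-specific. Degree-rank coverage (the
minimal fraction of top-degree nodes accounting for more than a target
share of edges) breaks degree ties lexicographically so the reported
fraction is reproducible.

## Scores

**TSPS.** TSPS = Σ pᵢ log₂(pᵢ/p) with p = 1/T, i.e. the Kullback–Leibler
divergence from uniform, equivalently log₂ T minus the Shannon entropy of
the shares (both identities are property-tested). The 0·log 0 := 0
convention is used. The score is invariant to positive rescaling of the
profile, and undefined (an error) for all-zero profiles — such genes are
excluded from TS classification rather than silently scored 0. The TS
threshold defaults to 0.7 bits. The tissue panel is an input; the
generator uses 34 tissues.

**EES.** The pseudocount of 1 is added to every expression value *before*
both the numerator and the per-gene mean, so a gene's tissue-count-weighted
mean enrichment is exactly 1 — a useful internal check, asserted in the
tests. Immune/non-immune flags must cover every tissue; the generator
flags 5 of 32-scaled tissues immune, mirroring typical bulk-tissue panels
(lymph node, bone marrow, spleen, tonsil, appendix).

**Inflammatory score.** Computed on the fraction scale, so it lives in
[−1, 1] and the ±0.5 bands apply directly. The default pro list has the
10 canonical pro-inflammatory cytokines (IL1A, IL1B, IL12A, IL12B, IL18,
TNF, IFNG, CSF2, CXCL8, IL6) and the anti list 13 (IL10, IL11, IL13,
IL19, IL1RN, IL24, IL37, IL4, IL5, CXCL17, TGFB1, TGFB2, TGFB3); both are
arguments, and the synthetic world supplies its own disjoint lists.

**Degree bins.** Degree-stratified summaries default to bins
{0, 1, 2–4, 5–9, ≥10}; the bin edges are configurable since any choice is
somewhat arbitrary, and the degree-0 bin is populated from an explicitly
supplied TF universe (a network cannot name its absent nodes).

## Association tests

Cell-type enrichment compares, per (TF, cell type), the TF's share of
targets expressed in the cell type against the share among all other TFs'
target instances, with a pooled two-proportion z-test. The pooled-z
variant (rather than chi-square with continuity correction) was chosen for
its direct interpretation as a signed enrichment statistic; the choice is
recorded here and in the output metadata. TFs with fewer than two targets
are skipped — a one-target proportion is degenerate. Degenerate pooled
proportions (0 or 1) return p = 1 with a warning rather than NaN.

Disease enrichment builds, per (TF, disease), a 2×2 table over the full
configured cytokine universe (not only cytokines with PDIs — absence of
any interaction is informative), and applies a one-sided (greater)
Fisher's exact test, since the question is enrichment; a two-sided variant
is available. BH adjustment is applied jointly across the full TF × context
family in both analyses, the most conservative reading of an unstated
family structure, with significance at adjusted p < 0.1.

Fisher's exact test and BH adjustment delegate to scipy and statsmodels
respectively; the test suite cross-checks them against an independent
hypergeometric enumeration oracle and a hand-computed step-up example.

## The degree-preserving null

Randomization is by double edge swaps constrained to the bipartite
structure: (TF1–C1, TF2–C2) → (TF1–C2, TF2–C1), rejecting degenerate
picks and swaps that would duplicate an edge. Every node keeps its exact
degree by construction. The swap-attempt budget is 10× the edge count per
replicate (configurable); on a toy network where the degree-preserving
support can be enumerated exhaustively, 3000 such randomizations are
statistically indistinguishable from uniform over the support.

The test statistic counts (TF, cytokine, disease) triples — an interacting
pair sharing k diseases contributes k; a pair-level variant (≥ 1 shared
disease) is available by flag. Significance is a z-score against the
null moments with an upper-tail normal p; the empirical tail fraction
(1 + #{null ≥ observed})/(n + 1) is always reported alongside, and becomes
the p-value when the null is degenerate (sd = 0, e.g. when annotations are
dense enough to make the statistic a function of degrees alone). With
annotations drawn independently of topology the z > 1.645 rejection rate
measures ≈ 5% over 200 synthetic nulls, asserted in the acceptance tests.

## Motif scanning

PWMs are per-position base-probability matrices over A, C, G, T; CIS-BP
tab layout and MEME minimal format are both read, with a load-time
pseudocount (default 0.01) to avoid −∞ log-odds from zero cells while
preserving stringency. A window scores Σᵢ log₂(pᵢ(bᵢ)/q(bᵢ)) in bits with
a uniform background q = 0.25 by default (both base and background are
configurable and recorded). Both strands are scanned; minus-strand hits
report the forward-strand start of the window, so coordinates are always
promoter-relative (offset 0 = the 5′ end of the supplied 2 kb region,
i.e. −2000 relative to the TSS; windows are half-open). Any window
containing N is skipped: an ambiguous base has no defined likelihood. The
site threshold defaults to 10 bits — stringent relative to the ~27-bit
consensus score of the information-rich 14-mer synthetic motifs, for which
fewer than ~2% of random 2 kb promoters contain any passing window.

## Prediction

The co-expression provider contract is "query gene set → ranked gene
list". The default provider ranks candidates by the Fisher-z average of
their Pearson correlations to each query gene across the supplied
compendium (joint query). Per-query mean-rank aggregation is available by
flag, since rank aggregation is a defensible alternative when query genes
have very different dynamic ranges. Zero-variance genes correlate 0 with
everything; ties break by symbol so rankings are deterministic.

Candidates are the members of the configured cytokine universe among the
top-100 ranked genes that are not already targets of the TF; a retained
prediction needs at least one motif site. In the tier rule, "fewer than
two sites with mouse evidence" can only mean exactly one site, because
zero-site candidates are filtered out before tiering. The mouse-evidence
enrichment 2×2 is built over all testable (TF, cytokine) pairs minus known
human PDIs, with a chi-square test without continuity correction (the
correction is available by flag).

## The synthetic world

The generator emulates the *shape* of the real inputs, not their biology:
gene identities are synthetic labels, TF degrees follow a truncated power
law (exponent 2 by default) with rank-weighted cytokine attractiveness so
both margins are heavy-tailed, activity labels are activating with
probability 0.8, tissue expression is log-normal with planted TS genes
concentrated (95% share) in one home tissue, co-expression modules share a
latent factor (loading 3 over unit noise), promoters are i.i.d. uniform
with consensus sites planted at recorded non-overlapping offsets on random
strands, and the abstract corpus embeds planted TF + cytokine + assay
co-mentions in a lexicon-free word soup. The mouse network is a thinned
copy of the human one (shared core, 50%) plus random mouse-specific edges
and the planted orthologous edges. A master seed fans out to fixed child
seeds per sub-generator, so each piece can be regenerated independently
and the whole world is byte-identical under reseeding.

Because all structure is planted, passing recovery tests demonstrates that
the pipeline's logic is faithful — not that real cytokine regulation is
this clean. Real curation tables carry symbol drift and assay ambiguity;
real co-expression signal is far weaker than a loading-3 module; real
promoters have repeat structure and GC heterogeneity that raise motif
false-positive rates. The default problem sizes (40 TFs × 60 cytokines,
~140 PDIs, 34 tissues, 60-sample compendium, 2 kb promoters, 1000 null
replicates, 200 calibration nulls) keep every analysis script and the
full test suite in the minutes range on one CPU while leaving enough
events for the statistical checks to be non-trivial.

## Known limitations

- The literature triage is co-mention only; it deliberately performs no
  relation extraction, so precision on real abstracts depends entirely on
  lexicon quality.
- Alias expansion covers hyphen/space/fused separators and Greek-letter ↔
  spelled-name substitutions; it does not generate Latin single-letter
  abbreviations (NF-kB, IFN-g), which should be listed as explicit aliases
  when needed.
- Symbol-identity orthology slightly overstates species specificity for
  genes without a same-name counterpart (e.g. human CXCL8); a curated
  two-column mapping can be supplied.
- The normal approximation behind the triplet z-test is only as good as
  the null spread; for sparse annotations prefer the empirical tail, which
  is always reported.
- BH adjustment is not idempotent (re-adjusting adjusted values inflates
  them); adjusted p-values are reported once, per test family.
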