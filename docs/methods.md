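# Methods

This note documents the statistical procedures `mitodiag` implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Data model

An alignment is a taxa × sites character matrix over DNA, RY or amino-acid
alphabets, with per-site (gene, codon position) annotation derived from a
RAxML-style partition file ("DNA, ND2 = 1-1023", 1-based inclusive in the
file, 0-based half-open internally; "a-b\3" stride lines annotate single
codon positions). Gap `-` and `?` are treated identically as missing by
every stage. Derived datasets follow the standard mito-phylogenomic
constructions: codon-position subsets, RY recoding (A,G→R; C,T→Y;
ambiguity codes spanning both classes become `?`, since two-state coding
cannot resolve them), and translation under NCBI genetic code 5
(invertebrate mitochondrial; selectable), with codons containing missing
data rendered `X` and internal stops warned about and written `*`.

## Compositional heterogeneity

Three complementary readouts:

1. **Per-taxon composition** over non-missing characters, with AT content
   for DNA.
2. **Chi-squared homogeneity**: the R×C contingency statistic
   Σ(O−E)²/E on the taxon × state count table, E from row/column margins,
   df = (R−1)(C−1), no continuity correction; all-zero state columns and
   empty taxon rows are dropped with df adjusted. Run per gene ×
   {all,1,2,3} codon positions plus whole-dataset rows, and re-run on
   RY-recoded positions (2-state tables). P < 0.05 is reported as
   heterogeneous, uncorrected — matching the conventional presentation of
   such tables — with a clearly-labelled Benjamini–Hochberg column as an
   extra. When an outgroup is declared the test defaults to ingroup-only.
   The plain contingency test is implemented; no tree-conditioned variant.
3. **Permutation Z-score** per taxon: d_t = Σ_states |f_t − f̄| against a
   null built by permuting characters within each alignment column across
   taxa. The null preserves per-site composition while destroying
   lineage-specific composition, so Z_t = (d_t − mean₀)/sd₀ > 2 flags a
   lineage-specific compositional signal. This is a desk-scale analogue of
   the posterior-predictive compositional check usually run with CAT+GTR in
   PhyloBayes; outputs are labelled `permutation_z` so the two are never
   conflated. sd₀ = 0 yields Z = 0 by convention; at least 100 replicates
   are required, and the replicate count and seed are recorded.

## Distances and saturation

Transitions are A↔G and C↔T; any cross-class difference is a transversion;
sites with a non-concrete base in either taxon are skipped pairwise, never
fractionally counted. K2P is undefined (and excluded from fits, with the
exclusion counted) when 1−2P−Q ≤ 0 or 1−2Q ≤ 0 — itself a saturation
symptom. Patristic distances are path-length sums on a user-supplied tree
with branch lengths; in practice that tree comes from a model-based
analysis of the same data, and the report header records its provenance.
Saturation regressions are ordinary least squares (slope, intercept, r²)
of S or V proportions on K2P, and of observed p-distance on patristic
distance; the output names both axes explicitly rather than relying on an
implied orientation. OLS, not reduced major axis, because the readout is a
regression slope, and shallower slope = more saturation.

## Ka/Ks (NG86)

The Nei–Gojobori (1986) counting method: per-codon synonymous-site
fractions (synonymous single-nucleotide changes / 3 per position, averaged
over the two sequences; changes that would create a stop count as
nonsynonymous, which preserves N + S = 3 × codons); observed differences
resolved by equal-weight averaging over all minimal substitution pathways,
excluding pathways through stop codons (codons whose every pathway hits a
stop are skipped and counted); Jukes–Cantor correction
d = −¾ ln(1 − 4/3 p), undefined at p ≥ 3/4; ω = Ka/Ks, undefined when Ks
is 0 or undefined. NG86 with JC correction is the classic DnaSP-style
default for this kind of per-gene screen. Because the per-gene statistic
can be defined against a designated reference taxon or over all pairs,
both modes are provided (`reference` / `all_pairs`), pooling Nd, Sd, N, S
over pairs before correction. Known bias, documented rather than patched:
under strong transition bias (κ ≫ 1) NG86 underestimates ω (transitions
saturate synonymous sites first), so the neutral-calibration test runs at
κ = 1 where the estimator is unbiased; the ordering of estimates across
true ω values is robust to κ.

"Branch length of a clade" has no single definition, so three candidate
summaries are emitted side by side — stem branch above the MRCA (0 at the
root), mean terminal branch, mean MRCA-to-tip path — with a monophyly flag
(non-monophyletic taxon sets are flagged but still summarised).

## Parsimony signal and CI filtering

For each site, m = max(0, distinct unambiguous states − 1) is the minimum
conceivable number of changes, and s is the parsimony step count on the
reference topology computed by generalised Fitch (Hartigan's count at each
internal node: steps += children − max number of children sharing a
state), which is exact on multifurcating trees and invariant to root
placement; the engine is verified against an independent exact-minimisation
oracle in the test suite. Missing or ambiguous leaves contribute the full
state set and can never force a step, so alignment gaps cannot manufacture
homoplasy. CI = m/s when s > 0; invariant sites (s = 0, hence always
m = 0) take CI = 1 and are always retained — removing signal-free but
harmless sites would distort the removal arithmetic. Sites with CI below
the threshold (default 0.3, the conventional homoplasy cut-off) are
removed; only the step *count* matters for CI, so ACCTRAN/DELTRAN-style
placement of changes on branches is irrelevant and not implemented.
Filtering is monotone in the threshold and idempotent at a fixed threshold
and tree. Removal summaries report both codon-level conventions — codons
with all three positions removed ("complete amino acids") and codons with
at least one position removed — because the two differ and neither is
canonical.

The reference topology is an input by design: the method asks "which sites
disagree with this tree", so it requires an a priori tree and inherits
that tree's assumptions. That is the method's stated limitation, not a
defect of the implementation.

## Neighbor joining and monophyly checks

NJ is included only as a fast, deterministic recovery check (full ML/BI
inference is out of scope). Ties in the Q criterion resolve
lexicographically by taxon label; negative branch-length estimates are
clamped to 0 (topology unaffected). The pipeline's pre/post-filter check
uses K2P distances, substituting the uncorrected p-distance for pairs
whose K2P is undefined so that heavily saturated replicates remain
scorable; the substitution is noted in the output header. Monophyly of a
taxon set is tested after rooting on the declared outgroup as the
existence of a node whose descendant leaf set equals the set exactly.

## Synthetic data

The simulator is a test harness, not a method claim, which is why the
kernel is HKY rather than full GTR: two parameters generate exactly the
two bias axes the diagnostics target — AT enrichment via equilibrium
frequencies and saturation via rate multipliers — while keeping every
transition matrix a directly checkable matrix exponential. Composition
shifts attach to the branch above a designated clade and are inherited by
the whole subtree (a single nonstationary regime change, mirroring the
clade-level AT contrast between a fast AT-rich family and its relatives in
heteropteran mitochondrial data). Rates multiply per codon position and
per site-rate class, with truth labels retained per site so downstream
removal decisions can be joined to the generating rate class exactly.
Codon mode evolves whole codons under the CTMC whose generator multiplies
nonsynonymous single-nucleotide HKY rates by ω and zeroes stop-codon
rates (table 5; 62 sense codons); ω = 1 reduces to HKY restricted to
sense codons, ω = 0 permits no amino-acid change. All randomness flows
from the declared seed through one generator; regeneration is
byte-identical.

Canned benchmarks (fixed conditions, chosen once by pilot calibration of
effect sizes and then frozen):

- `homogeneous`: 30 taxa, 2 × 600 sites, stationary HKY (κ = 4,
  AT = 0.70), codon-position rates 1/0.5/3 — the calm null.
- `shifted_clade`: 60 taxa, 2 × 900 sites, a genuine 12-taxon clade
  switched to AT = 0.82 — positive control for the composition tests.
- `lba_with_fast_sites`: 30 ingroup taxa + outgroup, 3,000 sites, 30% of
  sites at 10× rate, two unrelated terminals stretched 6× and both shifted
  to AT = 0.82 (convergent composition), short internal edges — the
  long-branch-attraction test bed for the end-to-end filter benefit.
- `two_gene_rates`: two 600-site genes at a 5× rate contrast — the
  per-gene removal-ratio pattern.

What passing these benchmarks shows: the diagnostics detect the biases
they were built for at realistic effect sizes, and CI filtering removes
predominantly fast, homoplastic sites and measurably improves
distance-based clade recovery under the simulated long-branch-attraction
regime. What it does not show: performance on real data, which adds
alignment error, indels, among-gene tree discordance, covarion-like rate
shifts and annotation noise that the simulator deliberately omits; nor
anything about likelihood/Bayesian inference, which the package does not
perform.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: simulations of
1,200–3,000 sites and 6–60 taxa, 20–50 replicates per property, chosen as
the smallest sizes at which the properties are stable. Z-score nulls use
200 permutation replicates by default (minimum 100 enforced). The Fitch
engine operates on state-set bitmasks vectorised across sites. OLS fits
exclude undefined pairs and require ≥ 3 points and non-constant x. All
table output is TSV with `#` header comments carrying parameter
provenance; every pipeline run writes a JSON manifest (input SHA-256
digests, parameters, seeds, output digests) sufficient to replay the run
and verify byte-identical outputs.
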