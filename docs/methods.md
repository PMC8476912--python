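# Methods

This note records the models, conventions and numerical choices behind
`mirvar`, in the order the pipeline runs.

## Duplex model and expectation score

A target site is an mRNA region complementary to a mature miRNA
(18–25 nt). The duplex is antiparallel: miRNA position 1 (its 5′ end)
pairs the 3′-most base of the site. In-site positions are numbered
1..site_length along the mRNA 5′→3′, so in an ungapped duplex the
target position *i* pairs miRNA position L−i+1. Cross-referencing
in-site labels from sources that number along the miRNA instead may
require reversing the coordinate.

The expectation score is the seed-weighted penalty sum described in the
README. Parameters live in `ScoringConfig` and are deliberately
explicit rather than hidden in code: mismatch 1.0, G:U wobble 0.5,
bulged nucleotide 2.0, seed region = miRNA positions 2–13 with
multiplier 2, retention cutoff 3.5. These follow the convention of
plant-miRNA target predictors run "with default parameters"; tools of
that family do not publish a closed formula, so the table here is the
package's pinned definition, exposed for adjustment.

Bulge handling: at most **one** bulge per duplex. This keeps the
window enumeration exact, and confines site lengths to {L−1, L, L+1} —
matching the observed 20–22 nt range for 21-nt plant miRNAs, where
about 97% of real target sites fall. A target-strand bulge (one extra
mRNA base) is *anchored* at the miRNA position 5′-adjacent to it on the
miRNA and its 2.0 penalty takes that anchor's seed weight; for a
miRNA-strand bulge the unpaired miRNA base is its own anchor. The
anchor convention makes seed weighting of gaps deterministic.

`find_sites` enumerates every ungapped window of length L plus every
single-bulge variant (all anchors, all offsets), scores each with early
termination once the running penalty exceeds the cutoff, and reports
*all* hits at E ≤ cutoff sorted by (E, position) — overlapping hits are
not collapsed, so a planted perfect site is typically accompanied by
bulged "shoulder" variants that also clear the cutoff.

Inhibition mode: a mismatch or bulge anchored at miRNA positions 9–11
predicts translational repression; otherwise cleavage. Wobbles in the
central window do **not** trigger the switch — central G:U pairing
still supports cleavage. This is the explicit form of the
central-complementarity rule; whether published site counts used a
wobble-inclusive rule is not decidable from the outside, so the
stricter variant was chosen and fixed.

## Accessibility proxy

True target-accessibility energies (UPE, kcal/mol) come from partition
function folding and are specific to the tool computing them; they are
not reproduced here. Instead the package defines a transparent
stand-in: maximum-weight nested folding (Nussinov DP) of the site plus
50 nt of flank on each side, pair weights G:C = 3, A:U = 2, G:U = 1,
minimum hairpin loop of 3 unpaired bases. The proxy is the summed
weight of pairs with at least one endpoint in the site — the cost to
open the site. It is monotone in the intuitive direction (paired sites
score high, unstructured contexts score 0) and is reported in score
units. Co-optimal structures are resolved by a canonical traceback:
prefer pairing the window ends (the diagonal move), then the
bifurcation with the smallest split point; this makes the reported
value deterministic.

## Allele re-scoring

Edits are expressed in in-site coordinates on the mRNA strand and
applied jointly (the two-SNPs-in-one-site pattern) after validating
every reference base — a mismatch raises an error carrying the position
and both bases, which catches coordinate-convention bugs early. The
miRNA is then re-aligned against the edited sequence over every
admissible single-bulge geometry implied by the edited length, and
ΔE = E_alt − E_ref: positive = impaired binding, negative = enhanced,
`site_destroyed` when E_alt exceeds the retention cutoff (including
length changes beyond ±1, which no single-bulge duplex can absorb).
An indel whose reference span sticks out past the site boundary is
applied as a deletion of its in-site bases only; an insertion anchored
outside the site leaves the site sequence unchanged. For minus-strand
sites, genomic alleles are reverse-complemented before application.

## Genome mapping and annotation

Sites are localized primarily by exact projection through the exon
chain of their source transcript (1-based inclusive coordinates
throughout, the GFF3/VCF convention — kept internally as well, so there
is no 0-based conversion layer to get wrong). Sites spanning splice
junctions become multi-block locations and are retained. A secondary
near-exact scanner (`find_site_occurrences`) re-locates a site sequence
anywhere in the genome allowing substitutions only (localizing an
already-predicted site needs tolerance for reference/transcript
discrepancies, not alignment); multi-mapping sequences are all
reported so callers can flag them.

The region annotator classifies a position against every overlapping
transcript with fixed precedence exonic(CDS) > 5′UTR > 3′UTR >
intronic > upstream1kb > downstream1kb > intergenic, with
upstream/downstream measured from the strand-aware TSS/TTS.

## Variant statistics and profiles

Dosage is the alt-allele count (0/1/2; NaN missing). The panel is
assumed selfed ≥ 5 generations, so the simulator emits only {0, 2};
heterozygous calls in real VCFs are retained in the frequency
arithmetic. Boundaries are inclusive exactly as defined: integrity
exactly 0.7 passes, MAF exactly 0.05 is rare and *not*
analysis-eligible. A variant inside two overlapping sites yields one
record per site (association de-duplicates by variant key).
Substitution classes are the six unordered base pairs, normalized to
the mRNA strand of the site (a genomic G>A under a minus-strand site
reports as C-T), consistent with the biological reading that C↔T(U)
and A↔G changes can preserve partial pairing through G:U wobbles.

## Association

The "general linear model" here is OLS of phenotype on additive dosage
with an intercept — identical to one-way ANOVA for two-genotype inbred
data (F = t², a tested invariant). Missing phenotypes or genotypes are
dropped pairwise per test; markers monomorphic after deletion are
flagged untestable rather than aborting a scan. The scan threshold is
1/M at full precision (display rounds to 3 decimals; M = 199 displays
as 0.005); no further multiple-testing correction is applied, by
design. Replicate phenotype rows are averaged to one value per
(accession, trait, year) at load. Wilcoxon rank-sum P-values are exact
(full enumeration) for pooled n ≤ 20 without ties, otherwise the
normal approximation with tie and continuity corrections. Trait
summaries use the sample SD (n−1) and CV = SD/mean, rounded to two
decimals only in tabular output.

## Synthetic cohorts

The generator emulates the study design, not its data: 210 selfed
accessions, three trial years, 21-nt miRNAs, 12 transcripts of 600 nt
each carrying one planted site (cycling through perfect / one-wobble /
one-mismatch defects, E = 0 / 0.5 / 1.0), gene models including
spliced and minus-strand genes, SNPs at chosen in-site positions
(cycling 1/10/15/20, some sites with a second SNP at 13 and a 1-nt
deletion at 5), ~150 off-site variants, a rare/common MAF mixture with
a 33.5% target rare fraction, 3% missingness, and one causal variant
per trait planted at marginal R² = 0.15 — the scale of the strongest
multi-year marker effects reported for such panels. Year effects
default to (0, +0.5, −0.3) residual-SD units, giving some but not all
traits a detectable environment effect. Effect sizes are parameterized
as marginal R² and converted to slopes through the realized dosage
variance (β_c = √(r_c σ²_tot / Var g_c) with σ²_tot = σ²/(1 − Σr)), so
the planted variance explained is exact in expectation regardless of
allele frequency. Each output stream has its own generator spawned
from the master seed; one seed fixes every output file byte for byte.

What the simulator does **not** emulate: linkage disequilibrium
structure between markers, population stratification and kinship,
selection, genotype-calling error profiles, or sequence-composition
biases. Passing tests therefore demonstrate the pipeline's arithmetic
and calibration under the stated generative model, not robustness to
confounding in real panels (where a mixed model with kinship would be
the appropriate scan — deliberately out of scope here, as is genome-
scale annotation, GO enrichment, and degradome validation).

## Problem sizes and tolerances

Default test/acceptance problem sizes were chosen so the whole suite
exercises every stage at statistically meaningful scale: scoring
oracles on 10³ random duplexes and 200 folding windows ≤ 14 nt
(exhaustive enumeration stays exact there); null calibration with
~200 eligible markers × 3 traits × 3 years × 12 replicates (≈ 21,600
tests, binomial 3-SE band around 1/M); planted-effect recovery with
500 replicates at n = 210 (co-detection > 90%, R̂² bias ≤ 0.02 — the
expected small-sample inflation of R̂² is ≈ (1−R²)/n ≈ 0.004, well
inside the band). Percentage profiles must sum to 100 within 1e−9;
floating-point comparisons elsewhere use pytest's default relative
tolerance.
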