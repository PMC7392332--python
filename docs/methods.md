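# Methods

## Dosage model

Amplicon sequencing of a tetraploid carrying *d* copies of a derived
haplotype (d ∈ {0..4}) yields the derived base at each diagnostic SNP with
probability

    p_d = (d/4)(1 − ε) + (1 − d/4)(ε/3)

under a symmetric substitution error model in which a read reports each of
the three wrong bases with probability ε/3 (default ε = 0.01, a conservative
short-read substitution rate after quality trimming). Sites are treated as
independent — amplicon phasing is out of scope — and the dosage call is

    argmax_d Σ_i log Binomial(k_i; n_i, p_d)

over the usable diagnostic sites, which generalizes frequency-based
("haplotype proportion") genotyping and yields per-call log-likelihoods as a
confidence measure. How to reconcile conflicting per-SNP proportions within a
gene is genuinely open; the summed log-likelihood is this package's choice.
Ties (numerically equal maxima within 1e-9 relative) break toward the
heterozygous dosage nearest 2 and are flagged `ambiguous`.

QC defaults: sites with depth < 50 are excluded (`low_depth`); at least 2
usable sites are required per call; sites whose minor-base fraction is below
0.25 get an informational `below_min_variant_freq` flag matching the SNP
caller settings used to build such count tables. That threshold is *not*
applied as a filter: a dosage-1 genotype has an expected derived fraction of
exactly 0.25, and a hard filter would erase exactly the signal the model must
see.

Relabelling derived ↔ ancestral maps d → 4 − d exactly at ε = 0; with ε > 0
the derived and ancestral base fractions are not complementary (each wrong
base absorbs ε/3), so the symmetry is only approximate, and ties break toward
the HET side by design.

## Chimera detection

Gene-converted/chimeric alleles are segmented over the *diagnostic columns* —
alignment positions where the two parental references differ and no sequence
has a gap or N. Each segmentation with 0, 1 or 2 breakpoints placed between
adjacent diagnostic sites is scored as

    (mismatches of each segment to its best parent) + λ × (breakpoints)

and minimized exhaustively (ties: fewer, then earlier, breakpoints). The
penalty default λ = 2 diagnostic sites per breakpoint keeps isolated
back-mutations from being "explained" by extra breakpoints while still
detecting real tracts; λ ≥ the number of diagnostic sites provably forces a
single segment. Breakpoints are reported as the 1-based position of the last
diagnostic site assigned to the left segment, so a conversion of the first
740 coding bases reads off as breakpoint 740. Per-segment difference counts
against both parents ("7 vs 21 SNPs") are emitted. Whether real breakpoints
in such data were historically placed by eye or by rule is unknowable from
summaries alone; the parsimony objective is this package's formalization.

## Structural-variant detection

Tandem duplications and deletions are located by longest-common-prefix and
-suffix comparison of an unaligned reference/alternate pair. This is valid
for a *single clean event*: alleles additionally carrying point differences
are out of scope and return `none` with diagnostics (the synthetic presets
therefore expose a clean ND/TD or ND/DEL pair alongside the SNP-marked
derived allele). Rotationally equivalent placements of a repeat unit resolve
to the leftmost unit start. A duplication must insert an exact tandem copy of
the adjacent reference block; any clean contiguous loss qualifies as a
deletion. Junction microhomology is the longest exact match between the unit
and the sequence flanking it (both sides checked, longer side reported), and
is only reported at ≥ 3 bp — shorter matches arise by chance 1/64 of the
time per side and carry no mechanistic signal. Frame status is unit length
mod 3. Translation uses the standard genetic code (table 1) only; an
internal stop flags the call and counting stops there.

## Cytology statistics

A metaphase-I nucleus is *stable* iff 16 individual bivalents are scored and
no multivalent is present; per-plant stability is the percentage of stable
nuclei. A bivalent is a *ring* iff both arms carry ≥ 1 chiasma. Chiasma
frequency is the sum of zone counts (distal, interstitial, proximal) over
both arms. Scoreable bivalents from unstable cells are shuffled (seeded) into
pseudo-nuclei of 16; remainder bivalents are dropped and counted — the
source analyses are silent on remainder handling and any alternative changes
only ⌊n/16⌋ vs n/16.

The rDNA FISH representation test compares observed bivalent counts in the
four probe classes (none, 5S, 45S, 5S+45S) against the karyotype composition
7:5:2:2 of 16 with a Pearson χ² (df 3). Expected counts are computed
**unrounded** (total × k_j/16). This matters: with observed (46, 21, 6, 4)
the unrounded expecteds (33.6875, 24.0625, 9.625, 9.625) give χ² = 9.54,
whereas pre-rounded expecteds (34, 24, 9.5, 9.5) give ≈ 9.08 — the rounded
convention cannot reproduce the reference statistic, so the unrounded one is
adopted, and the discrepancy is asserted in the tests.

HEI10 focus means are reported per cell and per bivalent (mean/16), with
decimal rounding half-away-from-zero at the report precision: 20.4/16 =
1.275 → 1.28 (2 dp) and 22.5/16 = 1.40625 → 1.4 (1 dp).

## Association testing

Stability percentages are compared between genotype classes per gene with
two-sided Mann–Whitney–Wilcoxon tests: exact enumeration when n₁+n₂ ≤ 16
with no ties, otherwise the normal approximation with midranks, tie
correction and continuity correction. Sidedness is not stated in the source
analyses; two-sided is the conservative default. Medians and IQRs use
linear-interpolation quantiles (the R `stats` default convention — IQR values
are convention-dependent, so this is configurable in principle via numpy's
quantile methods). The Bonferroni family defaults to the total number of
pairwise tests across all testable genes in the run, the most conservative
reading of "Bonferroni corrected pairwise" testing; it is configurable.
Genes with a single observed class are skipped with a logged reason rather
than erroring, since an all-heterozygous gene is an expected study outcome.

## Synthetic-data generator

The generator emulates the study conditions; its defaults are the study's
where stated and fixed calibrated choices otherwise.

**Alleles.** Per gene, a random stop-free CDS backbone (lyrata reference), an
arenosa reference diverged at a fraction 0.02 of sites, and a derived
tetraploid allele carrying n diagnostic SNPs (default 10) at positions where
the diploids agree. Structural presets:

- `ASY3_TD` / `ASY3_DEL`: the backbone contains a 78 bp serine-rich unit
  (26 codons, 7 serines) that begins with AGAGA and is followed by AGAGA, so
  the duplication/deletion junctions carry exactly 5 bp of microhomology; the
  TD allele duplicates the unit in tandem (region then encodes 14 serines),
  the DEL allele removes it. Marked-derived diagnostic SNPs sit 5′ of the
  event so the lesion region stays clean.
- `ZYP1b_GC`: a paralog pair with forced divergent sites straddling the
  junction; the derived allele's terminal 1474 bp are replaced by the
  paralog.
- `PRD3_chimera`: 28 diploid-divergent sites in the first 740 bp (one at
  740) and 29 after (one at 741); the query takes the arenosa state first,
  lyrata after, with 7 and 5 isolated back-flips placed away from the
  junction so the parsimony optimum is unique and reproduces the 7-vs-21 and
  5-vs-24 segment counts.

**Population.** 52 plants by default. Genotype-class frequencies per gene
default to (41/52, 11/52, 0) for *ASY3* — the study's observed split — all-HET
for *ZYP1b*, and mostly-fixed derived classes for the rest (invented but
realistic for loci under strong selection). HET dosages are uniform on
{1,2,3}. Per-plant stability π is logit-normal by the causal gene's class:
medians 0.889 (HOM_DERIVED) and 0.66 (HET) with logit scales 0.8 and 1.5,
calibrated to the reported group medians and IQR spread; HOM_ANCESTRAL
plants (rare) get median 0.5 at the HET scale.

**Reads.** Multinomial base counts at fixed depth (default 2000×): derived
base p_d, ancestral base the mirror, ε/3 to each other base; counts always
sum to depth, and depth 0 yields all-zero rows.

**Cytology.** Each cell is stable with probability π. Stable cells carry the
fixed 7:5:2:2 rDNA karyotype over 16 bivalents, each with one obligate distal
chiasma plus independent Bernoulli extras per zone. Extra-chiasma rates
(second-distal, interstitial, proximal) default to (0.20, 0.20, 0.12)
diploid, (0.08, 0.03, 0.01) stable-4n, (0.12, 0.09, 0.05) unstable-4n —
chosen so group means are ≈ 1.52 / 1.12 / 1.26 chiasmata per bivalent and
the zone shift from proximal/interstitial toward distal in stable tetraploids
is qualitatively right. Note the per-bivalent SD this produces (≈ 0.3–0.7)
is the model's, not a fitted quantity: an integer count with mean 1.5 cannot
have arbitrary dispersion. Unstable cells expose 1–11 scoreable bivalents
with 45S-bearing classes' odds divided by ρ = 2.5 (only the direction of the
45S bias is established; ρ is a fixed invented magnitude) and carry a
multivalent. HEI10 foci per cell are 16 + Poisson(16 μ) with μ = 0.275
(→ 20.4 foci/cell) for plants with π ≥ 0.5 and μ = 0.40625 (→ 22.5) below;
the 0.5 threshold is a simple grouping convenience. Cells per plant default
to 50 (unstated in the source; a realistic scoring effort per slide set).

**Randomness.** Everything flows from one integer seed through named
`numpy.random.Generator` streams with deterministic per-plant substreams;
fixed seed ⇒ byte-identical outputs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linked reads across sites (sites are independent
given dosage), PCR/mapping bias and depth variation across amplicons,
alignment and SNP-calling errors upstream of the count table, more than two
allele groups segregating per gene, multivalent geometry beyond scoreable-set
bias, population structure, and female meiosis.

## Problem sizes and test design

Monte-Carlo checks use: 1000 plant×gene dosage calls at depth 2000 for the
≥ 99% recovery bound; 500 end-to-end replicates of the 52-plant single-gene
study for the ≥ 80% power bound plus 1000 null replicates for type-I
calibration; 312/960/590 bivalents (the study's group sizes) for the chiasma
calibration means within 3 standard errors; and 100–150 fuzz cases per
structural round-trip property. These sizes give binomial standard errors
comfortably inside the asserted margins while keeping the default suite
around a minute.

## Known limitations

- The SV detectors handle one clean event per pair; multi-event or
  SNP-contaminated pairs return `none` with diagnostics rather than a call.
- Origin assignment is nearest-reference Hamming distance, a deliberate proxy
  for phylogenetic placement; it has no support values and ties go to
  `unknown`.
- The dosage model resolves one derived-vs-ancestral contrast per gene;
  three or more simultaneous allele groups are out of scope.
- The association module fits no covariates (population structure, admixture
  proportion); at n ≈ 52 a mixed model is not identifiable anyway.
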