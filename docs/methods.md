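# Methods

## Duplex scoring model

Recognition of a plant miRNA target is modelled as a purely positional
mismatch count over the antiparallel duplex: miRNA position *i* (1-based
from the 5' end) faces site position *L − i + 1* on the mRNA read 5'→3'.
Watson–Crick pairs cost 0, pairs in a configurable half-penalty class cost
0.5, all other juxtapositions cost 1.  No thermodynamic (ΔG) term, bulge,
or gap is modelled: target sites in this analysis class are fixed-length
and indel-free.

Two rules gate acceptance:

* **Total cut-off** — total ≤ 4.0, inclusive.  The inclusive reading is
  deliberate: a known functional target class carries exactly four
  mismatches, so an exclusive "< 4" rule would reject a validated target.
  Configurable (`max_total`, `total_inclusive`).
* **Critical region** — score over miRNA positions 2–8 strictly < 1.0, so
  one wobble is tolerated there but any full mismatch rejects.  This
  region nucleates recognition and spans the slicing site.  Configurable
  (`critical_region`, `critical_max`, `critical_strict`).

### The wobble-class question

The half-penalty class defaults to **G:U**, the standard RNA wobble pair.
Some printed descriptions of this rule say "U:U pairs" instead; because a
U:U juxtaposition is not a stable base pair, we read that as a
typographical variant of G:U but ship both: `ScoringParams.standard()`
(G:U) and `ScoringParams.literal_paper()` (U:U).  The mode is recorded in
every output row.  Supporting the G:U reading: the documented C/T allele
at miRNA position 13 of one rice target site forms exactly a G:U pair
against the miRNA and scores 0.5 under the standard mode.

### Site reconstruction

Worked examples are often given only as printed mismatch positions.
`reconstruct_site` starts from the exact reverse complement and
substitutes deterministically: for a full mismatch, the first base in
fixed order A, C, G, U that is neither complementary nor in the wobble
class; for a half penalty, the first base forming a wobble pair (which
requires the miRNA base to be G or U — requesting a wobble opposite A or C
raises).  The round trip `score(reconstruct(F, H))` returns exactly the
planted position sets; this is a tested invariant, not an assumption.

## Scanning

Every window of miRNA length on the sense strand of each supplied
transcript is scored and kept iff accepted; overlapping hits are all
reported with 1-based inclusive coordinates.  The O(N·L) loop is ample at
ORF/cDNA scale; a test verifies exact agreement with an independently
written brute-force enumerator over 10⁴ windows.  Only the given strand is
scanned (targets are mRNAs).  Region labels (CDS/UTR) come from an
optional user interval table; a site must be fully contained in an
interval to inherit its label.

## Conservation and SNP impact

Panels are assumed pre-aligned and trimmed to the L-nt site (amplicon
alignment is upstream of this package; varieties are inbred, one sequence
each, heterozygosity not modelled).  Positions are reported in miRNA
coordinates throughout, since that is how target-site SNPs are described
in the field.

* Profile: per-position base counts/frequencies and information content
  IC = 2 + Σ f·log₂f bits (0·log 0 := 0), the sequence-logo letter-height
  statistic.  No small-sample correction by default: panel sizes here
  (~120–160) make it negligible and uncorrected heights match the common
  logo-viewer convention.  `plot_logo` draws the logo directly with
  matplotlib.
* SNP calling: any position with ≥2 observed alleles; minimum minor-allele
  count 1 (a single-landrace haplotype must be callable), configurable.
* Impact: each variety's site is re-scored against the miRNA with the
  configured mode; `RETAINED` iff the acceptance rule passes.  Consistency
  with `accept_site` is cross-checked by a property test rather than
  assumed.

## Cleavage mapping

A RACE clone's 5' end is the first base of the 3' cleavage fragment.  The
reported cleavage position is the miRNA position paired to that base,
p = site.end − coordinate + 1.  Under canonical slicing between the bases
paired to miRNA nt 10 and 11, this convention yields 10, which is the
number quoted in degradome/RACE work, so figures are directly
reproducible.  Modal ties break to the smallest position and the tie set
is reported.  Off-site clones are tallied separately and excluded from the
mode.

## Expression analysis

The two-line rule: a gene is UP iff its OE/WT ratio is ≥ fold (default 2)
in *every* independent transgenic line, DOWN iff ≤ 1/fold in every line.
The default ratio uses replicate means per line against the WT replicate
mean; the original description does not state whether averaging or
per-replicate comparison was used, so a stricter `per_replicate` mode is
provided as well.  Thresholds are inclusive ("2-fold change" read as
attaining 2-fold).  Signals are floored at 1.0 (signal scale) before
ratios to avoid division blow-ups on background probes; the floor is
recorded in output headers.

Venn analysis enumerates all exclusive regions of the named call sets
(inclusion–exclusion is a tested invariant).  The drought cross-tab
counts {OE-UP, OE-DOWN} × {drought-UP, drought-DOWN, NONE} per genotype;
the reversal fraction is (OE-UP ∩ drought-DOWN + OE-DOWN ∩ drought-UP)
over called-and-annotated genes, with unannotated genes treated as NONE.
Functional categorisation is a plain cross-tab against any user-supplied
gene→category table; no enrichment p-values are computed.  Promoter
analysis is an exact IUPAC match on both strands of user-supplied
upstream sequences; motif patterns (e.g. NAC recognition sequences) are
user-supplied configuration, not packaged data.

## Synthetic data

The generators emulate the study design the package targets: a 21-nt
guide, germplasm panels of 122–158 varieties, 24 RACE clones, and a
two-line / two-replicate overexpressor microarray design with a planted
common core (defaults in the `simulate` command: 79 common down, 11
common up across four genotypes, 135-variety panel segregating a G/U SNP
at miRNA position 20 with the substitution in the majority).

Choices worth knowing:

* One integer seed; one `numpy` Generator per generator module seeded as
  `default_rng([stream, seed])` with fixed stream indices (transcriptome
  0, panel 1, RACE 2, expression 3), so generators are mutually
  independent and adding one cannot perturb another.
* Transcript backbones are uniform random (25% each base).  Planted SNP
  carrier counts are binomial at the requested frequency, clipped to
  [1, n−1] so a planted position is guaranteed polymorphic.
* RACE canonical mode places exactly round(purity·n) clones at the
  canonical product start and the rest uniformly in-site, so the planted
  histogram is recoverable without sampling noise in the canonical count.
* Expression noise is lognormal and multiplicative (σ on the log scale,
  default 0.1); planted fold changes are applied to both lines equally.
  Planted direction is global per gene so one drought annotation is
  coherent across genotypes; planted DE genes get the opposite drought
  sign with the stated reversal probability, others NONE.

What the simulations do **not** emulate: microarray probe effects,
normalisation artefacts, linkage among varieties, partial-cleavage RACE
artefacts, indels in target sites, and expression-level correlation
structure.  Passing recovery tests therefore demonstrates the pipeline's
correctness on its own model of the data, not performance on raw
instrument output.

## Problem sizes

The test suite runs the scanner/oracle comparison at 10⁴ random windows
plus planted sites, the large acceptance-rule scan at 10⁵ windows, SNP
recovery over 200 seeded 50-variety panels, and DE recovery on 2 000-gene
matrices — sizes chosen so the full suite completes in well under a
minute on one CPU while keeping the statistical assertions meaningful.

## Known limitations

* No thermodynamic scoring or translational-inhibition prediction; the
  mismatch rule is the whole model.
* No multiple alignment: panel inputs must already be trimmed to the site.
* The scanner does not splice or search reverse strands.
* DE calling is a threshold rule, not a statistical test; with two
  replicates per line that matches the original design but offers no
  error control.
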