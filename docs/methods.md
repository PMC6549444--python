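# Methods

## Markers and classification model

Fall armyworm host strains cannot be separated morphologically; strain
identity is inferred from single-nucleotide markers on two unlinked loci:

* **COIB** — a 603-bp amplicon of the maternally inherited mitochondrial
  *COI* gene. Site mCOI1164D is strain-diagnostic (T → rice-strain
  *COI*-RS; A or G → corn-strain *COI*-CS; C is unobserved in the
  species). Together with mCOI1287R it defines the four corn-strain
  configurations h1 = A/A, h2 = A/G, h3 = G/A, h4 = G/G used to separate
  Western Hemisphere source populations. Five further sites
  (mCOI1125Y … mCOI1216W) are strain-biased and, with the two diagnostic
  sites, define the COIB haplotypes (CSa1, CSa2, RSa1–RSa4).
* **TpiE4 / TpiI4** — the fourth exon and adjacent fourth-intron segment
  of the Z-linked *Triosephosphate isomerase* gene. gTpi183Y is
  strain-diagnostic (C → TpiC, T → TpiR). Because males are ZZ, a male
  can be heterozygous (TpiH), visible in a Sanger consensus as an IUPAC
  ambiguity code. The African panel has three exon haplotypes (TpiCa1,
  TpiCa2 — differing at gTpi192Y and gTpi198Y — and TpiRa1) and six
  intron haplotypes (Ca1a, Ca1b = Ca1a plus a 200-bp insertion, Ca2a–c,
  Ra1a).

Classification is strictly panel-driven. Site coordinates are 1-based
from each segment's biological origin (COI translational start, 5' exon
start, 5' intron start) and are located on a query by gap-aware pairwise
alignment, never by absolute offset, so reads starting at internal primer
positions and indel-bearing introns are handled uniformly. A site falling
in a query gap fails for that site only.

Heterozygote resolution is an exact combinatorial decode: an observed
TpiE4 allele vector containing ambiguity codes is matched against the
site-wise IUPAC union of every unordered pair of panel haplotypes; on the
three-haplotype African panel this mapping is a bijection (verified
exhaustively in the tests), giving C-YY = Ca1/Ca2, H-CC = Ca1/Ra1,
H-YY = Ca2/Ra1. Vectors consistent with no single haplotype and no pair
are reported ambiguous rather than forced.

For the intron, the poor-signal site gTpiI4[131]R is forced to its
consensus G before matching (the published description gives both "131"
and "G_128"; position 131 is taken as authoritative and the position is
configurable in the panel). Any remaining in-core ambiguity, or indel
evidence incompatible with a single panel haplotype, is reported as
heterozygous and excluded from unambiguous-haplotype counts. The core
window is intron positions 10–171 inclusive: the source text gives "a
162-bp fragment from intron nucleotide 10 to 172", whose endpoints span
163 nt; the printed length was honored.

## Sex-linkage adjustment

Let m = 2 for all-male pheromone-trap collections and
m = 2r + (1 − r) for larval collections with assumed male fraction r
(default r = 0.5, giving the 1.5 multiplier). Chromosome counts are

```
n(Ca1) = m·Ca1 + C-YY + H-CC
n(Ca2) = m·Ca2 + C-YY + H-YY
n(Ra1) = m·Ra1 + H-CC + H-YY
```

Raw (real-valued) counts are kept for frequency computation; reported
integers use round-half-up, which is the only rounding rule consistent
with every half-valued cell in the published table (58.5→59, 12.5→13,
45.5→46, 70.5→71, 30.5→31, 34.5→35, 17.5→18, 8.5→9, 64.5→65). The
adjustment is linear in the count vector and conserves chromosomes:
totals equal m·(unambiguous specimens) + 2·(heterozygotes).

Mean frequencies across collections are **unweighted** (each collection
is one unit); this reproduces the published mean-frequency rows, which a
specimen-weighted pooled mean does not. The pooled share is exposed
separately for the "99% of the corn-strain group" style statements.

## Regional comparison

The published figures compare Togo + São Tomé & Príncipe against the rest
of the continent by a two-tailed t-test without naming the flavor. The
default here is Welch's unequal-variance t with the Welch–Satterthwaite
df (group sizes 3 vs 10 and very different variances make pooled variance
hard to defend); a pooled-variance Student's t is available via an option
flag. α = 0.05; identical degenerate groups report t = 0, p = 1. No
multiple-testing correction is applied, matching the single per-quantity
tests in the source analysis.

## Intron tree

The published figure uses an externally computed maximum-likelihood tree
(Tamura–Nei model). This package deliberately substitutes TN93 distances
plus Saitou–Nei neighbor-joining — both methods the same analysis also
invokes — because the goal is the figure's qualitative claim (the African
rice-intron haplotype falls in a 100% rice-annotated clade), not the
external program's output; ML optimization and its log-likelihood are out
of scope.

TN93 uses empirical base frequencies from the pooled pair, distinct
A↔G and C↔T transition rates and a common transversion rate. Gapped or
ambiguous columns are deleted pair by pair (complete deletion would erase
the Ca1b insertion region for every pair). Fewer than 20 comparable sites
is an undefined distance (error); saturation (non-positive log argument)
returns infinity. The implementation was cross-checked against
`ape::dist.dna(model = "TN93")` (agreement to 13 significant digits on a
fixed 100-bp pair; the value is frozen in the tests) and against the
closed-form transversion-only limit d = −½ln(1−Q) − ¼ln(1−2Q).

Neighbor-joining is delegated to scikit-bio with negative branch-length
estimates clamped to zero and the deficit shifted to the adjacent branch;
tip ids are sorted before matrix construction so tie-breaking is
deterministic. Duplicate sequences are collapsed to unique haplotypes
before tree building. Clade composition walks outward from the focal tip
through its ancestors on the rooted representation of the NJ tree; the
headline metric is the class composition (focal tip excluded) of the
smallest non-trivial containing clade.

## Alignment anchoring

Scoring: match +1, mismatch −1, affine gaps (open −5, extend −0.5);
ambiguity codes match any base they admit. End gaps are asymmetric: a
query covering only part of the segment is free, while query overhang
beyond the reference pays −0.5 per base. The asymmetry is load-bearing:
with fully free end gaps the optimal alignment of a Ca1b-type query
absorbs the 200-bp insertion into end gaps (32 trailing reference
positions re-align as mismatches), and the insertion is never reported.
An 80% identity floor over aligned columns rejects non-target sequences.
Same-length, high-identity queries take a column-comparison fast path
with no dynamic programming. Insertion features match a panel haplotype's
declared indel within ±5 bp of position and ±10 bp of length, absorbing
alignment placement ambiguity at repeat boundaries.

## Synthetic data

The generator emulates the sampling scheme of the African surveys: a
collection has a label, size, source type, COIB haplotype and Tpi allele
frequency vectors, a mito–nuclear coupling mode, sex ratio, per-marker
sequencing-failure probability and per-site error rate. Sexes are drawn
from the sex ratio (pheromone traps are all-male); each Z chromosome
draws an allele independently (random mating); male heterozygotes are
emitted as one consensus with IUPAC codes at differing sites; each
specimen carries one mitochondrial haplotype. Coupling is a single
discordance probability (the specimen's COI strain equals the strain of
its first-drawn Tpi allele, flipped with that probability); the default
is fully independent draws, which is what the continental African data
effectively look like. Default frequencies are the fixture-derived
continental values (Tpi: Ca1 0.59 / Ca2 0.31 / Ra1 0.10 on a chromosome
basis; COIB: CSa1 0.33, RSa1 0.62, minor haplotypes the remainder), the
sex ratio is 1:1 and the per-marker failure rate 5%.

Sequences are built by editing the panel's reference segments at
diagnostic sites plus declared indels — no sequence evolution, PCR error
model, or chromatogram signal is simulated, and intron heterozygotes with
indel-differing alleles are merged only over their shared prefix. A green
end-to-end test therefore establishes that classification, tabulation and
adjustment invert the generative model exactly under clean or mildly
noisy signal; it says nothing about base-calling quality, alignment of
highly diverged non-target species, or real chromatogram artifacts.

Documented estimator properties (tested): the adjusted-count frequency
estimator is unbiased on all-male collections; on larval collections it
is consistent when the true sex ratio is 0.5 and predictably biased
otherwise (homozygotes are underweighted relative to heterozygotes, e.g.
all-male larvae at minor-allele frequency 0.3 inflate the estimate by
~+0.025).

## Known limitations

* The default panel's backbone sequences and the exact distinguishing
  states of the rare COIB haplotypes (RSa2–RSa4) are synthetic stand-ins:
  the deposited amplicon sequences and the supplementary alignment figure
  are not redistributed. Every decision the classifier makes depends only
  on the documented diagnostic sites, which follow the published
  definitions; users with the real references can drop them into the
  panel YAML unchanged.
* Packaged count fixtures inherit the source tables' internal
  inconsistencies (pooled specimen totals differ slightly from the prose;
  the rice-allele column sums to 12 specimens vs 11 in the text). The
  tables are treated as authoritative and no reconciliation is forced.
* Chromatogram (.ab1) processing, base quality, multiple alignment, ML
  tree inference and bootstrap support are out of scope.
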