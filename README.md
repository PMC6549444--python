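# fawhap

Diagnostic-SNP strain and haplotype analysis of invasive fall armyworm
(*Spodoptera frugiperda*) marker sequences.

Fall armyworm comprises two morphologically identical host strains — the
"corn-strain" (maize/sorghum) and the "rice-strain" (turf and pasture
grasses) — distinguishable only by molecular markers: a diagnostic SNP in
the mitochondrial *COI* gene (site mCOI1164D: T = rice-strain *COI*-RS,
A/G = corn-strain *COI*-CS) and one in the fourth exon of the Z-linked
*Triosephosphate isomerase* gene (gTpi183Y: C = TpiC, T = TpiR, an
overlapping C/T signal = male heterozygote TpiH). This package gives
entomologists and molecular ecologists surveying the African invasion a
tested pipeline for:

- **per-specimen classification** of COIB / TpiE4 / TpiI4 Sanger consensus
  sequences against a configurable marker panel: COI strain, COIB
  haplotype and h1–h4 configuration, TpiE4 genotype with exact IUPAC-union
  decoding of the three heterozygote classes (C-YY = Ca1/Ca2,
  H-CC = Ca1/Ra1, H-YY = Ca2/Ra1), TpiI4 intron haplotype, and a COIB
  species check;
- **sex-linkage-adjusted allele frequencies**: because *Tpi* is Z-linked
  (males ZZ, females ZW hemizygous), specimen counts are converted to
  chromosome counts as `n(a) = m·(unambiguous a specimens) + (each
  heterozygote class containing a)`, with m = 2 for all-male pheromone-trap
  collections and m = 1.5 for unknown-sex larvae under a 1:1 sex ratio;
- **frequency summaries and regional comparison**: unweighted means ± sd
  across collections, specimen-weighted pooled shares, and a two-sided
  Welch t-test between collection groups;
- **intron phylogenetics**: Tamura–Nei (TN93) distances, neighbor-joining,
  and clade-composition reports against host-plant / COI-strain
  annotations;
- **a synthetic-data generator** that emulates field collections (Z-linked
  inheritance, random mating, configurable mito–nuclear discordance,
  sequencing failure), so the whole pipeline is testable without the
  deposited sequences.

Observed genotype-class and haplotype count tables for 13 African
collection sets (11 nations, 2016–2017) are packaged as fixtures; the
default marker panel encodes the published site and haplotype definitions
on synthetic backbone sequences (clearly labelled — the deposited
amplicons are not redistributed).

## Worked example

```python
from fawhap.popfreq import (adjust_tpi_counts, frequency_summary,
                            load_coib_counts, load_tpie4_counts,
                            compare_regions, pooled_shares)

counts = load_tpie4_counts()          # packaged African TpiE4 counts
adj = adjust_tpi_counts(counts["TOGb"])
print("TOGb adjusted chromosome counts:", adj.reported,
      f"(multiplier {adj.multiplier})")

adjusted = {lab: adjust_tpi_counts(c).raw for lab, c in counts.items()}
for allele in ("Ca1", "Ca2", "Ra1"):
    s = frequency_summary(adjusted, allele)
    print(f"Tpi{allele} adjusted frequency: mean {s.mean:.2f} +/- {s.sd:.2f}")

coib = load_coib_counts()
s = frequency_summary(coib, ["CSa1", "CSa2"], quantity="COI-CS")
cmp = compare_regions(s, ("TOGa", "TOGb", "STP"),
                      tuple(k for k in coib if k not in ("TOGa", "TOGb", "STP")))
print(f"COI-CS, Togo+Sao Tome vs rest: t={cmp.t:.2f}, df={cmp.df:.1f}, "
      f"p={cmp.p:.4f}")
print("CSa1 share of the COI-CS pool: %d%%" %
      pooled_shares(coib, "CSa1", ["CSa1", "CSa2"])[1])
```

prints

```
TOGb adjusted chromosome counts: {'Ca1': 212, 'Ca2': 162, 'Ra1': 28} (multiplier 2.0)
TpiCa1 adjusted frequency: mean 0.59 +/- 0.10
TpiCa2 adjusted frequency: mean 0.31 +/- 0.08
TpiRa1 adjusted frequency: mean 0.10 +/- 0.05
COI-CS, Togo+Sao Tome vs rest: t=8.04, df=10.8, p=0.0000
CSa1 share of the COI-CS pool: 99%
```

The TOGb row shows the all-male pheromone-trap adjustment (70 Ca1
specimens ×2 plus 59 C-YY and 13 H-CC heterozygotes = 212 Ca1
chromosomes, and so on); the means are the published continental picture —
corn-strain Tpi alleles dominate everywhere (~90% combined) while the
corn-strain *COI* marker is significantly more frequent in Togo and
São Tomé & Príncipe than in the rest of the continent.

## Command line

```sh
fawhap simulate --seed 7 --n 200 --out sim/          # synthetic collection
fawhap run-all --coib sim/COIB.fasta --tpie4 sim/TpiE4.fasta \
       --tpii4 sim/TpiI4.fasta --metadata sim/metadata.tsv --out results/
fawhap frequencies --out freqs.tsv                   # packaged fixtures
fawhap tree --fasta introns.fasta --focal TpiI4Ra1a --out tree/
```

`run-all` chains classify → tabulate → adjust → frequencies → compare and
writes plain TSV/newick artifacts plus a `run.json` option log.

## Acceptance script

`scripts/acceptance.py` recomputes the headline chromosome-basis summary
from scratch: it loads the packaged observed TpiE4 genotype-class counts,
applies the sex-linkage adjustment equations per collection, and reports
the unweighted mean adjusted frequency of the rice-strain TpiR allele
across the 13 collections as a rounded percentage:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
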