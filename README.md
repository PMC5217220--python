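# plexprimer

Genome-aware multiplex PCR primer design for targeted resequencing.

Targeted resequencing — validating GWAS loci, screening candidate genes in
hundreds of samples — often relies on multiplex PCR on microfluidic platforms
(e.g., 48×48 Access Array chips) followed by short-read sequencing.  The hard
part is primer design at scale: every primer must anneal to a *single* place
in the genome, avoid known variant sites and repeats, and be grouped with
other primer pairs into pools whose members do not interact in one reaction.
`plexprimer` automates the whole path from a BED file of targets to
order-ready primer pools.

## What it computes

**Genome uniqueness via a hashed genome.**  A k-mer index (default k = 15)
counts every k-length window of the reference over both strands.  Each
surviving primer gets a *quality score*

> score = mean over the primer's k-windows of genome occurrence count,
> × P₃ (default 100) if the 3′-terminal k-mer is not unique,

so a score of 1 means every constituent k-mer occurs exactly once in the
genome, and a repeated 3′ end — the dominant mispriming risk — is effectively
disqualifying.  Primers above a configurable score threshold are dropped.

**Seven exclusion filters.**  Every window of every allowed length (default
17–26 bp) on both strands around each target is examined and rejected if it
(1) forms a hairpin, (2) self-dimerizes, (3) has Tm outside the window,
(4) has GC outside the window, (5) overlaps a soft-masked (lowercase) repeat,
(6) overlaps a known SNP at or above a minor-allele-frequency cutoff, or
(7) — checked at pairing time — its last 7 bases anneal within the amplified
product.  Tm is a nearest-neighbor calculation (unified ΔH/ΔS parameters,
entropic salt correction):

> Tm = ΔH / (ΔS + 0.368 (N−1) ln[Na⁺] + R ln(Cₜ/4)) − 273.15

**Pairing and tiling.**  All forward/reverse combinations with amplicon size
in range (default 247–300 bp) form candidate pairs; a greedy interval cover
tiles each target with amplicons, allowing multiple overlapping amplicons per
region.

**Compatibility pooling.**  Pairs A and B may share a reaction iff: no cross
combination of their primers dimerizes; all four Tm's lie within 2 °C; their
amplicons do not overlap; and |len(A) − len(B)| ≤ 20 % of the *maximum
allowable* amplicon size (for a 400 bp maximum, an 80 bp threshold) — so no
short product dominates the kinetics.  Additionally (default on), no primer's
3′ word may anneal inside a pool-mate's amplicon.  Pools are grown greedily
from the most- (or least-) connected pair in the compatibility matrix.

**Iterative loosening.**  If coverage is incomplete, the Tm window widens by
1 °C per side and the maximum amplicon size by 25 bp per iteration (up to 3
extra iterations by default), redesigning only still-uncovered bases; primers
from stringent iterations are never discarded.

**In-silico PCR.**  An internal simulator (3′-terminal k-mer must match
exactly; optional 5′ mismatches) enumerates every predicted product of a pair
or pool, verifying one product per pair and zero cross-pair products.

## Worked example

The package bundles a deterministic synthetic-genome generator, so no
downloads are needed:

```python
from plexprimer.fixtures import standard_spec, generate
from plexprimer import DesignConfig, run_design, write_outputs

paths, manifest = generate(standard_spec(seed=7, n_targets=3), "fixture/")
result = run_design(DesignConfig(), paths["bed"], paths["fasta"], paths["snps"])
write_outputs(result, "out/")
print("\n".join(result.log))
```

prints

```
[iter 0] Tm 57.0-63.0 amp 247-300: 3 new pairs, coverage 840/840 bp
done: 3 pairs in 3 pools, 840/840 target bp covered
```

i.e., all three 280 bp targets were covered at the stringent iteration, one
primer pair each.  `out/primers.txt` then holds the designs:

```
pool  pair  fwd_seq            rev_seq            chrom  amp_start  amp_end  fwd_tm  rev_tm  fwd_len  rev_len  amp_len
1     P1    TGTTTCGCACCGGCCGA  TCGGCCGGTACGCTCTT  chr1   900        1180     59.21   57.56   17       17       280
2     P2    ACGCCCAACAACGCTCG  TGGGATTGCGCGCCGTT  chr1   2900       3180     57.95   60.02   17       17       280
3     P3    TGCCGTGCCGGTTGATG  AGGAGCGCTTCTGCCGA  chr1   4900       5180     57.59   57.88   17       17       280
```

Four artifacts are written per run: `primers.txt` (designs, one pair per
line), `primers.ispcr.txt` (`id fwd rev` triples for in-silico PCR tools),
`order_sheet.csv` (96-well plate layout, column-major fill, forward primers
on odd plates and their mates in the same wells of the sibling even plate,
adapters prepended when configured), and `coverage.tsv` (per-region covered
bases, fraction, and total amplified bases including flanks).

The same run from a shell:

```bash
plexprimer --bed fixture/targets.bed --fasta fixture/genome.fa \
           --snps fixture/snps.tsv --out-dir out/
```

SNP file dialect: 3-column TSV `chrom  pos  freq` with 0-based positions;
frequencies above 0.5 are folded to the minor allele (1 − f) on read.

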