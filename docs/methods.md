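# Methods

This note documents the models, parameter choices and numerical conventions
behind `plexprimer`, and what the bundled synthetic fixtures do and do not
demonstrate.

## Coordinates and formats

All coordinates are 0-based half-open (BED convention), internally and in
every output file.  The reference FASTA is expected soft-masked: lowercase
runs are treated as repeat intervals and any primer window intersecting one
is rejected.  Known variants come from a minimal 3-column TSV
(`chrom  pos  freq`); frequencies above 0.5 are interpreted as major-allele
frequencies and folded to 1 − f, so downstream logic always sees a
minor-allele frequency in [0, 0.5].  The "Excel upload" artifact is written
as a CSV plate sheet: bit-exact, vendor-neutral, and diffable.

## The k-mer genome index

The index stores canonical k-mers (lexicographic minimum of a k-mer and its
reverse complement), mapping each to its two-strand occurrence count;
palindromic k-mers count twice per genomic window since both strands read
them.  Windows containing N are excluded.  One k (default 15) is used rather
than a range of sizes: a single table keeps memory proportional to genome
size and the score semantics sharp.  k is configurable in [8, 16] for
file-based builds; the in-memory constructor accepts k ≥ 2 so that tiny toy
genomes can be checked against exhaustive scans.

The quality score of a primer is the arithmetic mean of the counts of its
k-length windows, multiplied by a penalty factor P₃ (default 100) when the
3′-terminal window is not unique.  This reproduces the intended boundary
semantics — exactly 1 iff every window is genome-unique; near 1 when most
are; catastrophic when the 3′ end is repeated — while staying monotone under
genome duplication.  The retention threshold (default 2.0) therefore
tolerates a primer with a few duplicated interior k-mers but never a
non-unique 3′ terminus.  Candidates failing the threshold carry the rejection
code `quality`, complementing the six per-window codes
(`hairpin`, `self_dimer`, `tm`, `gc`, `masked`, `snp`).

## Thermodynamics

Melting temperatures use unified nearest-neighbor ΔH/ΔS parameters with
duplex initiation and per-terminal-AT corrections, an entropic monovalent
salt term 0.368 (N−1) ln[Na⁺], and the two-state formula with R ln(Cₜ/4) for
non-self-complementary duplexes.  Defaults are 50 mM monovalent cation and
250 nM total primer — ordinary PCR practice; both are configurable.  The
implementation agrees with an independent nearest-neighbor implementation
(Biopython's, at identical parameters and conditions) to numerical precision;
the test suite asserts agreement within 0.5 °C on random oligos.

Secondary-structure screens are deterministic ungapped complementary-run
heuristics rather than free-energy minimization: a hairpin requires a
reverse-complementary stem of ≥ 4 bp separated by a loop of ≥ 3 nt (scanning
minimal stems suffices, since any longer stem contains one); two primers
dimerize when they share an antiparallel complementary run of ≥ 8 bp
anywhere, or ≥ 5 bp touching either 3′-terminal base.  Run-length screens
are exact, fast, and independently re-checkable by brute-force dynamic scans
(`max_complementary_run`), which the pool validator and the property tests
use as the oracle.  The 3′-anneal check (filter 7) searches the amplicon
interior — the product minus both binding sites — for the primer's last 7
bases in either orientation; because the "amplified product" only exists
once a pair is formed, this filter is evaluated at pairing time even though
it is conceptually a per-primer exclusion.

## Candidate search, pairing, tiling

Primers may bind up to one maximum-amplicon-size outside the target
(flank = `amp_max`), so amplicons may overhang targets; coverage reports
both on-target and total amplified bases for this reason.  Filters are
attributed in the fixed order hairpin → self-dimer → Tm → GC → masked → SNP:
the first failure names the rejection, which makes planted-defect tests
unambiguous.  Windows containing N yield no candidate at all — an N-window is
not a primer, and inventing a rejection code for it would imply otherwise.

Pairing forms every forward × reverse combination whose amplicon length lies
in [amp_min, amp_max] with non-overlapping binding sites.  Tiling is a greedy
interval cover: repeatedly take the pair covering the leftmost uncovered
target base that reaches furthest right; ties break on lower combined quality
score, then leftmost start.  Greedy cover is optimal for interval covering
and makes the selection order-independent and deterministic.

## Pooling

The compatibility matrix applies, per unordered pair of primer pairs:
no cross-dimer among the four primer combinations; all four Tm's within
2 °C; non-overlapping amplicons; amplicon lengths within 20 % of the maximum
allowable amplicon size of one another.  The size rule deliberately scales
with the configured maximum (80 bp at a 400 bp maximum) rather than with a
pool average: the threshold is then a design-time constant rather than a
function of pool membership.  When loosening has raised `amp_max`, the
loosest value actually used sets the threshold, since retained amplicons may
be that large.  A fifth, config-switchable rule (default on) forbids any
primer's 3′ word from annealing inside a pool-mate's amplicon interior —
amplicon–amplicon interaction is the failure mode that minimum-separation
heuristics try to avoid, and checking annealing directly subsumes them, so no
fixed 5 kb separation is enforced.

Pool assembly is greedy: seed with the unpooled pair of highest ("most") or
lowest ("least") static degree in the matrix, then repeatedly admit the
extreme-degree pair compatible with every current member; a closed pool is
maximal.  Degrees are static properties of the full matrix (a dynamic,
recompute-on-removal variant sits behind `dynamic_degrees`).  All ties break
on (combined quality score, chrom, start, end), making pooling — and hence
entire runs — bit-reproducible.  An independent validator re-checks every
emitted pool through the brute-force run scanner; builder and validator share
no screening code.

## Iterative loosening

Iteration 0 runs at the configured stringency.  Each later iteration widens
the Tm window symmetrically by `tm_step` (default 1 °C) and raises `amp_max`
by `amp_step` (default 25 bp), up to `max_iterations` (default 3), and
designs only over still-uncovered bases, so earlier designs are never
revisited and coverage is monotone by construction.  Pooling runs once at the
end over all retained pairs, letting pairs from different iterations share
pools.  An undesignable target is a *result* (zero coverage in the report),
not an error.

## In-silico PCR

Binding requires the primer's 3′-terminal k-mer to match the template
exactly (k = the index k-mer size, which always covers the critical last 5
bases); up to 2 mismatches are tolerated in the 5′ remainder.  Sites are
found by string-scanning for the seed on both strands and verified by direct
comparison.  Products are all plus-site × minus-site combinations on a
chromosome within `max_product` (default 4 × `amp_max`), including cross-pair
combinations within a pool.  The default mismatch tolerance for the
end-to-end uniqueness guarantee is 0.  No amplification-efficiency model is
attempted; the simulator answers "could this pool make this product", not
"how much".

## Synthetic fixtures

The generator is a pure function of its seed.  Its central construction, the
*island target*, plants two primer-length uppercase islands at the ends of an
intended amplicon inside a soft-masked buffer wider than any reachable
amplicon size.  Island sequences are rejection-sampled with the package's own
Tm model to sit inside a requested Tm band, inside the GC window, free of
hairpins and self-dimers, and verified genome-unique after assembly; the
amplicon interior is resampled if it happens to contain either primer's 3′
word.  Consequently each island target has exactly one valid primer pair, and
the manifest records it — the manifest is the test oracle.

Tm-marginal targets (for exercising the loosening loop) use a band just
*below* the stringent window (56.2–56.8 °C against a 57–63 °C window): at
17 bp, a primer just above the window's high side would need a GC fraction
above the 0.70 filter ceiling, so low-side marginality is the construction
that isolates the Tm-loosening mechanism from the GC filter.

Default study conditions used by tests and the acceptance script: 280 bp
amplicons, 17 bp island primers, loci on a 2 kb pitch (so no cross-locus
product fits under the in-silico PCR ceiling), genomes of 5–100 kb, 2–50
targets.  These sizes keep every brute-force oracle (full-genome scans,
exhaustive partition search) exact and fast.  What passing these fixtures
shows: the algorithmic contracts hold — filters are sound, designed pairs are
genome-unique, pools are valid, loosening is monotone, runs are
deterministic.  What they do not show: primer performance against real
repeat structure, extreme GC, or polymerase behavior in actual reactions.

## Known limitations

- Dimer/hairpin screens are run-length heuristics; thermodynamically weak
  but long complementary runs and strong but short ones are treated by
  length alone.
- The quality score weights all k-mer windows equally apart from the 3′
  penalty; no positional decay toward the 5′ end.
- Greedy pooling does not minimize pool count globally; it matches the
  exhaustive optimum on small instances but carries no general guarantee.
- The SNP table is positional only; allele identity is not used to, e.g.,
  permit primers over variants fixed in the study population.
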