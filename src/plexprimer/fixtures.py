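"""Deterministic synthetic genomes with planted, verifiable design structure.

The generator emulates what the design engine actually consumes: a
soft-masked reference FASTA, a SNP frequency table and a BED of targets.  Its
flagship construction is the *island target*: a locus whose amplicon ends are
two uppercase primer-length "islands" engineered to pass every primer filter
(Tm sampled inside a requested band using the package's own thermodynamic
model, GC inside the filter window, no hairpin, no self-dimer, genome-unique),
embedded in a soft-masked buffer wide enough that no amplicon overlapping the
target can be primed outside the islands.  By construction such a locus has
exactly one valid primer pair, which makes end-to-end outcomes (coverage,
uniqueness, pooling) predictable and recorded in the manifest.

Everything derives from one seeded ``random.Random``; the same spec always
produces byte-identical files.  What these fixtures do *not* emulate: real
repeat families, GC-skewed isochores, or sequencing error — they validate the
algorithmic contracts, not wet-lab performance.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .seq import revcomp
from . import thermo


class FixtureError(Exception):
    """Planted features collide or an engineered guarantee failed verification."""


@dataclass(frozen=True)
class IslandTarget:
    """An engineered locus with exactly one valid primer pair.

    ``start`` is the left edge of the soft-masked buffer; the amplicon spans
    [start + buffer, start + buffer + amplicon_length).  ``buffer`` must be at
    least the largest amplicon size the design may reach, so that no primer
    pair outside the islands can amplify across the target.
    """

    chrom: str
    start: int
    tm_band: tuple[float, float] = (57.5, 62.5)
    amplicon_length: int = 280
    primer_length: int = 17
    buffer: int = 400
    label: str = ""


@dataclass(frozen=True)
class SequencePlant:
    """A sequence inserted at a known copy number (for k-mer / binding-site oracles)."""

    sequence: str | None = None  # None: random non-palindromic sequence of `length`
    length: int = 15
    copies: int = 1
    chrom: str | None = None     # None: first chromosome
    positions: tuple[int, ...] | None = None  # explicit starts; None: random free spots
    soft_mask: bool = False


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    chrom_lengths: Mapping[str, int]
    gc: float = 0.5
    island_targets: Sequence[IslandTarget] = ()
    plain_targets: Sequence[tuple[str, int, int, str]] = ()  # (chrom, start, end, label)
    snps: Sequence[tuple[str, int, float]] = ()
    masked_intervals: Sequence[tuple[str, int, int]] = ()
    plants: Sequence[SequencePlant] = ()
    gc_range: tuple[float, float] = (0.35, 0.68)  # sampling window for island primers
    line_width: int = 60


def sample_primer_site(
    rng: random.Random,
    length: int,
    tm_band: tuple[float, float],
    gc_range: tuple[float, float] = (0.35, 0.68),
    cond: thermo.ThermoConditions | None = None,
    sp: thermo.StructureParams | None = None,
    max_tries: int = 200_000,
) -> str:
    """Rejection-sample a primer sequence inside a Tm band that passes the structure screens."""
    cond = cond or thermo.DEFAULT_CONDITIONS
    sp = sp or thermo.DEFAULT_STRUCTURE
    lo, hi = tm_band
    for _ in range(max_tries):
        p_gc = rng.uniform(*gc_range)
        seq = "".join(
            rng.choice("GC") if rng.random() < p_gc else rng.choice("AT")
            for _ in range(length)
        )
        gc = thermo.gc_fraction(seq)
        if not gc_range[0] <= gc <= gc_range[1]:
            continue
        if not lo <= thermo.melting_temperature(seq, cond) <= hi:
            continue
        if thermo.forms_hairpin(seq, sp) or thermo.dimerizes(seq, seq, sp):
            continue
        return seq
    raise FixtureError(f"no {length}-mer found with Tm in {tm_band} and GC in {gc_range}")


def _count_both_strands(chrom_seqs: Mapping[str, str], seq: str) -> int:
    total = 0
    rc = revcomp(seq)
    probes = [seq] if seq == rc else [seq, rc]
    for s in chrom_seqs.values():
        up = s.upper()
        for probe in probes:
            i = up.find(probe)
            while i != -1:
                total += 1
                i = up.find(probe, i + 1)
    return total


class _Builder:
    def __init__(self, spec: FixtureSpec):
        self.spec = spec
        self.rng = random.Random(spec.seed)
        self.genome: dict[str, list[str]] = {}
        self.reserved: dict[str, list[tuple[int, int]]] = {}
        self.bed: list[tuple[str, int, int, str]] = []
        self.manifest: dict = {
            "seed": spec.seed,
            "chroms": dict(spec.chrom_lengths),
            "targets": [],
            "snps": [],
            "masked": [],
            "plants": [],
        }

    def _reserve(self, chrom: str, start: int, end: int, what: str) -> None:
        if chrom not in self.genome:
            raise FixtureError(f"{what}: unknown chromosome {chrom!r}")
        if start < 0 or end > len(self.genome[chrom]):
            raise FixtureError(f"{what}: [{start},{end}) outside {chrom}")
        for s, e in self.reserved[chrom]:
            if start < e and s < end:
                raise FixtureError(f"{what}: collides with reserved [{s},{e}) on {chrom}")
        self.reserved[chrom].append((start, end))

    def _random_bases(self, n: int) -> list[str]:
        gc = self.spec.gc
        rng = self.rng
        return [rng.choice("GC") if rng.random() < gc else rng.choice("AT")
                for _ in range(n)]

    def build(self) -> dict[str, str]:
        for name, length in self.spec.chrom_lengths.items():
            self.genome[name] = self._random_bases(length)
            self.reserved[name] = []
        for t in self.spec.island_targets:
            self._plant_island_target(t)
        for chrom, start, end, label in self.spec.plain_targets:
            if chrom not in self.genome or start < 0 or end > len(self.genome[chrom]) or start >= end:
                raise FixtureError(f"plain target {chrom}:{start}-{end} invalid")
            self.bed.append((chrom, start, end, label))
            self.manifest["targets"].append({
                "chrom": chrom, "start": start, "end": end,
                "label": label, "kind": "plain",
            })
        for plant in self.spec.plants:
            self._plant_sequence(plant)
        for chrom, start, end in self.spec.masked_intervals:
            self._reserve(chrom, start, end, "masked interval")
            seg = self.genome[chrom]
            for i in range(start, end):
                seg[i] = seg[i].lower()
            self.manifest["masked"].append([chrom, start, end])
        for chrom, pos, freq in self.spec.snps:
            if chrom not in self.genome or not 0 <= pos < len(self.genome[chrom]):
                raise FixtureError(f"SNP {chrom}:{pos} outside genome")
            self.manifest["snps"].append([chrom, pos, freq])

        seqs = {name: "".join(bases) for name, bases in self.genome.items()}
        self._verify(seqs)
        return seqs

    def _plant_island_target(self, t: IslandTarget) -> None:
        L = t.primer_length
        amp = t.amplicon_length
        if amp < 2 * L:
            raise FixtureError("amplicon shorter than two primers")
        foot_end = t.start + amp + 2 * t.buffer
        self._reserve(t.chrom, t.start, foot_end, f"island target {t.label or t.start}")
        amp_start = t.start + t.buffer
        amp_end = amp_start + amp
        seg = self.genome[t.chrom]

        fwd = sample_primer_site(self.rng, L, t.tm_band, self.spec.gc_range)
        rev = sample_primer_site(self.rng, L, t.tm_band, self.spec.gc_range)
        seg[amp_start:amp_start + L] = list(fwd)
        seg[amp_end - L:amp_end] = list(revcomp(rev))

        # the amplicon interior must not capture either primer's 3' word
        for _ in range(50):
            interior = "".join(seg[amp_start + L:amp_end - L]).upper()
            if not (thermo.three_prime_anneals_within(fwd, interior)
                    or thermo.three_prime_anneals_within(rev, interior)):
                break
            seg[amp_start + L:amp_end - L] = self._random_bases(amp - 2 * L)
        else:
            raise FixtureError("could not build a clean amplicon interior")

        # soft-mask the buffer and interior, leaving only the two islands designable
        for s, e in ((t.start, amp_start), (amp_start + L, amp_end - L), (amp_end, foot_end)):
            for i in range(s, e):
                seg[i] = seg[i].lower()

        self.bed.append((t.chrom, amp_start, amp_end, t.label))
        self.manifest["targets"].append({
            "chrom": t.chrom, "start": amp_start, "end": amp_end,
            "label": t.label, "kind": "island",
            "expected": {
                "amplicon": [amp_start, amp_end],
                "amplicon_length": amp,
                "fwd_seq": fwd, "rev_seq": rev,
                "fwd_tm": round(thermo.melting_temperature(fwd), 3),
                "rev_tm": round(thermo.melting_temperature(rev), 3),
                "tm_band": list(t.tm_band),
                "n_valid_pairs": 1,
            },
        })

    def _plant_sequence(self, plant: SequencePlant) -> None:
        rng = self.rng
        if plant.sequence is not None:
            seq = plant.sequence.upper()
        else:
            while True:
                seq = "".join(rng.choice("ACGT") for _ in range(plant.length))
                if seq != revcomp(seq):
                    break
        chrom = plant.chrom or next(iter(self.genome))
        seg = self.genome[chrom]
        if plant.positions is not None:
            if len(plant.positions) != plant.copies:
                raise FixtureError("positions/copies mismatch")
            positions = list(plant.positions)
            for pos in positions:
                self._reserve(chrom, pos, pos + len(seq), f"plant {seq[:8]}...")
        else:
            positions = []
            for _ in range(plant.copies):
                for _try in range(10_000):
                    pos = rng.randrange(0, len(seg) - len(seq))
                    try:
                        self._reserve(chrom, pos, pos + len(seq), "plant")
                    except FixtureError:
                        continue
                    positions.append(pos)
                    break
                else:
                    raise FixtureError("no free position for plant")
        text = seq.lower() if plant.soft_mask else seq
        for pos in positions:
            seg[pos:pos + len(seq)] = list(text)
        self.manifest["plants"].append({
            "sequence": seq,
            "positions": [[chrom, p] for p in sorted(positions)],
            "copies": plant.copies,
            "soft_mask": plant.soft_mask,
        })

    def _verify(self, seqs: Mapping[str, str]) -> None:
        for entry in self.manifest["targets"]:
            if entry["kind"] != "island":
                continue
            exp = entry["expected"]
            for primer in (exp["fwd_seq"], exp["rev_seq"]):
                n = _count_both_strands(seqs, primer)
                if n != 1:
                    raise FixtureError(
                        f"island primer {primer} occurs {n} times (expected 1); "
                        "choose a different seed")
        for plant in self.manifest["plants"]:
            n = _count_both_strands(seqs, plant["sequence"])
            if n != plant["copies"]:
                raise FixtureError(
                    f"plant {plant['sequence']} occurs {n} times "
                    f"(expected {plant['copies']}); choose a different seed")


def build(spec: FixtureSpec) -> tuple[dict[str, str], dict]:
    """Assemble the genome in memory; returns (chrom -> sequence, manifest)."""
    builder = _Builder(spec)
    seqs = builder.build()
    builder.manifest["bed"] = [list(b) for b in builder.bed]
    return seqs, builder.manifest


def generate(spec: FixtureSpec, out_dir) -> tuple[dict[str, Path], dict]:
    """Write genome.fa, snps.tsv, targets.bed and manifest.json; returns (paths, manifest)."""
    seqs, manifest = build(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "snps": out / "snps.tsv",
        "bed": out / "targets.bed",
        "manifest": out / "manifest.json",
    }
    with open(paths["fasta"], "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), spec.line_width):
                fh.write(seq[i:i + spec.line_width] + "\n")
    with open(paths["snps"], "w") as fh:
        for chrom, pos, freq in sorted(manifest["snps"]):
            fh.write(f"{chrom}\t{pos}\t{freq}\n")
    with open(paths["bed"], "w") as fh:
        for chrom, start, end, label in manifest["bed"]:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths, manifest


def standard_spec(
    seed: int,
    n_targets: int = 4,
    chrom: str = "chr1",
    tm_band: tuple[float, float] = (57.5, 62.5),
    amplicon_length: int = 280,
    pitch: int = 2000,
    buffer: int = 400,
    n_marginal: int = 0,
    marginal_band: tuple[float, float] = (56.2, 56.8),
) -> FixtureSpec:
    """A ready-made design fixture: island targets spaced widely on one chromosome.

    The pitch keeps loci far enough apart that no cross-locus amplicon fits
    under the in-silico PCR product ceiling.  The last ``n_marginal`` targets
    get primers whose Tm sits just below the stringent window, so they become
    designable only after one loosening step.
    """
    if n_marginal > n_targets:
        raise ValueError("n_marginal > n_targets")
    length = n_targets * pitch + 1000
    targets = []
    for i in range(n_targets):
        band = marginal_band if i >= n_targets - n_marginal else tm_band
        targets.append(IslandTarget(
            chrom=chrom,
            start=500 + i * pitch,
            tm_band=band,
            amplicon_length=amplicon_length,
            buffer=buffer,
            label=f"T{i + 1}",
        ))
    return FixtureSpec(seed=seed, chrom_lengths={chrom: length}, island_targets=targets)
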