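"""Input parsing (BED targets, SNP tables) and the four design output files.

Coordinate convention: BED-style 0-based half-open throughout the package.

The SNP flat file is a minimal 3-column TSV dialect: ``chrom  pos  freq``
with pos 0-based and freq an allele frequency in [0, 1]; frequencies above
0.5 are folded to the minor-allele frequency (1 - f) on read.

Output artifacts of a completed design:

``primers.txt``
    one primer pair per line with pool id, pair id, sequences, amplicon
    coordinates, Tm's and sizes (TSV with header);
``primers.ispcr.txt``
    ``id fwd rev`` per line, space-separated — the classic in-silico-PCR
    input format;
``order_sheet.csv``
    96-well plate layout for bulk oligo synthesis, column-major fill
    (A1, B1, ... H1, A2, ...); forward primers sit on odd-numbered plates and
    their reverse mates occupy the same well coordinate on the sibling
    even-numbered plate; configured adapters are prepended here and only here;
``coverage.tsv``
    per sanitized target region: bases covered, fraction, total amplified
    bases (flanking bases included) and the covering pair ids.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


@dataclass(frozen=True)
class TargetRegion:
    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SnpRecord:
    chrom: str
    pos: int
    freq: float  # minor-allele frequency

    def __post_init__(self) -> None:
        if not 0.0 <= self.freq <= 0.5:
            raise ValueError(f"minor-allele frequency {self.freq} outside [0, 0.5]")


@dataclass
class CoverageReport:
    region: TargetRegion
    covered_bp: int
    fraction: float
    amplified_bp: int  # union of covering amplicons, flanking bases included
    pair_ids: list[str] = field(default_factory=list)
    uncovered: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0 or self.covered_bp > len(self.region):
            raise ValueError("inconsistent coverage report")


# --- readers ----------------------------------------------------------------

def read_bed(path) -> list[TargetRegion]:
    """Parse a BED file (>=3 tab-separated columns) into target regions."""
    regions = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom, s, e = parts[0], parts[1], parts[2]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates {s!r}, {e!r}") from None
            if start < 0 or start >= end:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            label = parts[3] if len(parts) > 3 else ""
            regions.append(TargetRegion(chrom, start, end, label))
    return regions


def sanitize_regions(regions: Iterable[TargetRegion]) -> list[TargetRegion]:
    """Sort by (chrom, start) and merge overlapping or book-ended intervals."""
    merged: list[TargetRegion] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            prev = merged[-1]
            labels = [x for x in (prev.label, r.label) if x]
            label = ";".join(dict.fromkeys(labels))
            merged[-1] = TargetRegion(prev.chrom, prev.start, max(prev.end, r.end), label)
        else:
            merged.append(r)
    return merged


def read_snp_table(path) -> list[SnpRecord]:
    """Parse the 3-column TSV SNP dialect; returns records sorted by (chrom, pos)."""
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated columns")
            try:
                pos = int(parts[1])
                freq = float(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad position or frequency") from None
            if pos < 0:
                raise ParseError(f"{path}:{lineno}: negative position")
            if not 0.0 <= freq <= 1.0:
                raise ParseError(f"{path}:{lineno}: frequency {freq} outside [0, 1]")
            if freq > 0.5:  # fold major-allele frequency to MAF
                freq = 1.0 - freq
            records.append(SnpRecord(parts[0], pos, freq))
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def read_ispcr(path) -> list[tuple[str, str, str]]:
    """Read an in-silico-PCR primer file back as (id, fwd, rev) triples."""
    triples = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 'id fwd rev'")
            triples.append((parts[0], parts[1], parts[2]))
    return triples


# --- writers ----------------------------------------------------------------

WELLS_PER_PLATE = 96
_ROWS = "ABCDEFGH"


def well_coordinate(i: int) -> str:
    """Column-major well coordinate within one 96-well plate (0 -> A1, 1 -> B1, ... 8 -> A2)."""
    if not 0 <= i < WELLS_PER_PLATE:
        raise ValueError(f"well index {i} outside plate")
    return f"{_ROWS[i % 8]}{i // 8 + 1}"


def plate_rows(primer_names_seqs: Sequence[tuple[str, str, str]]) -> list[tuple[int, str, str, str]]:
    """Lay out (name, sequence, orientation) triples onto 96-well plates.

    Forward primers fill odd plates and reverse primers the sibling even plate
    at the same well coordinate, so a pair can be cherry-picked from matching
    wells.  Returns (plate, well, name, sequence) rows in fill order.
    """
    rows = []
    counters = {"F": 0, "R": 0}
    for name, seq, orient in primer_names_seqs:
        idx = counters[orient]
        counters[orient] += 1
        plate_pair = idx // WELLS_PER_PLATE
        plate = 2 * plate_pair + (1 if orient == "F" else 2)
        rows.append((plate, well_coordinate(idx % WELLS_PER_PLATE), name, seq))
    rows.sort(key=lambda r: (r[0], _ROWS.index(r[1][0]) + 8 * (int(r[1][1:]) - 1)))
    return rows


def write_outputs(result, out_dir) -> dict[str, Path]:
    """Write the four design artifacts; returns the path of each by short name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    paths = {
        "primers": out / "primers.txt",
        "ispcr": out / "primers.ispcr.txt",
        "order_sheet": out / "order_sheet.csv",
        "coverage": out / "coverage.tsv",
    }

    pool_of = {}
    for pool in result.pools:
        for pair in pool.members:
            pool_of[pair.pair_id] = pool.pool_id

    with open(paths["primers"], "w") as fh:
        fh.write("pool\tpair\tfwd_seq\trev_seq\tchrom\tamp_start\tamp_end\t"
                 "fwd_tm\trev_tm\tfwd_len\trev_len\tamp_len\n")
        for pair in result.pairs:
            fh.write("\t".join(map(str, (
                pool_of.get(pair.pair_id, "NA"), pair.pair_id,
                pair.fwd.sequence, pair.rev.sequence, pair.chrom,
                pair.start, pair.end,
                f"{pair.fwd.tm:.2f}", f"{pair.rev.tm:.2f}",
                len(pair.fwd.sequence), len(pair.rev.sequence), pair.length,
            ))) + "\n")

    with open(paths["ispcr"], "w") as fh:
        for pair in result.pairs:
            fh.write(f"{pair.pair_id} {pair.fwd.sequence} {pair.rev.sequence}\n")

    primer_rows = []
    for pair in result.pairs:
        primer_rows.append((f"{pair.pair_id}_F", cfg.adapter_fwd + pair.fwd.sequence, "F"))
        primer_rows.append((f"{pair.pair_id}_R", cfg.adapter_rev + pair.rev.sequence, "R"))
    with open(paths["order_sheet"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plate", "well", "name", "sequence"])
        for plate, well, name, seq in plate_rows(primer_rows):
            writer.writerow([plate, well, name, seq])

    with open(paths["coverage"], "w") as fh:
        fh.write("chrom\tstart\tend\tlabel\tregion_bp\tcovered_bp\tfraction\t"
                 "amplified_bp\tn_pairs\tpair_ids\n")
        for rep in result.coverage:
            r = rep.region
            fh.write("\t".join(map(str, (
                r.chrom, r.start, r.end, r.label, len(r),
                rep.covered_bp, f"{rep.fraction:.4f}", rep.amplified_bp,
                len(rep.pair_ids), ",".join(rep.pair_ids),
            ))) + "\n")

    return paths
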