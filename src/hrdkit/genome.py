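"""Chromosome/arm coordinate model shared by all genomic scoring.

A genome build is an ordered set of chromosomes, each with a length and a
single centromeric interval.  The p arm is ``[0, cen_start)``, the q arm
``[cen_end, length)``; the centromeric gap belongs to neither arm and is
excised from every interval that touches it.  All coordinates are 0-based,
half-open base pairs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path


class GenomeError(ValueError):
    """Raised for malformed genome tables or invalid intervals."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GenomeError(f"chromosome {self.name}: length must be > 0")
        if not (0 < self.cen_start < self.cen_end < self.length):
            raise GenomeError(
                f"chromosome {self.name}: need 0 < cen_start < cen_end < length, "
                f"got cen=[{self.cen_start},{self.cen_end}) length={self.length}"
            )


@dataclass(frozen=True)
class GenomeBuild:
    name: str
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise GenomeError("duplicate chromosome names in genome build")

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise GenomeError(f"chromosome {name!r} not in genome build {self.name!r}")

    def has_chromosome(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def arms(self) -> list[tuple[str, "GenomicInterval"]]:
        """All (arm id, interval) pairs in genome order, p before q."""
        out = []
        for c in self.chromosomes:
            out.append((f"{c.name}p", GenomicInterval(c.name, 0, c.cen_start)))
            out.append((f"{c.name}q", GenomicInterval(c.name, c.cen_end, c.length)))
        return out


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GenomeError(
                f"interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def _toy3() -> GenomeBuild:
    chroms = tuple(
        Chromosome(str(i), 200_000_000, 95_000_000, 105_000_000) for i in (1, 2, 3)
    )
    return GenomeBuild("toy3", chroms)


def _read_genome_tsv(lines, name: str) -> GenomeBuild:
    header = None
    chroms = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            expected = ["chrom", "length", "cen_start", "cen_end"]
            if header != expected:
                raise GenomeError(
                    f"genome table header must be {expected!r}, got {header!r}"
                )
            continue
        if len(fields) != 4:
            raise GenomeError(f"genome table row {lineno}: expected 4 columns")
        try:
            chrom = Chromosome(fields[0], int(fields[1]), int(fields[2]), int(fields[3]))
        except GenomeError as exc:
            raise GenomeError(f"genome table row {lineno}: {exc}") from exc
        except ValueError as exc:
            raise GenomeError(f"genome table row {lineno}: non-integer field") from exc
        if any(c.name == chrom.name for c in chroms):
            raise GenomeError(f"genome table row {lineno}: duplicate chromosome {chrom.name}")
        chroms.append(chrom)
    if header is None or not chroms:
        raise GenomeError("genome table is empty")
    return GenomeBuild(name, tuple(chroms))


def load_genome(path_or_builtin: str | Path) -> GenomeBuild:
    """Load a genome build from a TSV path or by built-in name.

    Built-ins: ``"hg19"`` (autosomes + X, arm boundaries from the standard
    cytoband table) and ``"toy3"`` (3 chromosomes of 200 Mb, centromere at
    95-105 Mb) — both bundled, no network access.
    """
    if str(path_or_builtin) == "toy3":
        return _toy3()
    if str(path_or_builtin) == "hg19":
        ref = importlib.resources.files("hrdkit.data").joinpath("hg19_arms.tsv")
        with ref.open("r") as fh:
            return _read_genome_tsv(fh, "hg19")
    path = Path(path_or_builtin)
    with open(path) as fh:
        return _read_genome_tsv(fh, path.stem)


def split_by_arm(
    interval: GenomicInterval, genome: GenomeBuild
) -> list[tuple[str, GenomicInterval]]:
    """Split an interval into its p/q arm parts, excising the centromere.

    Returns 0, 1 or 2 labelled sub-intervals; an interval entirely inside
    the centromeric gap yields an empty list.
    """
    chrom = genome.chromosome(interval.chrom)
    if interval.end > chrom.length:
        raise GenomeError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
            f"chromosome length {chrom.length}"
        )
    out: list[tuple[str, GenomicInterval]] = []
    p_end = min(interval.end, chrom.cen_start)
    if interval.start < p_end:
        out.append((f"{chrom.name}p", GenomicInterval(interval.chrom, interval.start, p_end)))
    q_start = max(interval.start, chrom.cen_end)
    if q_start < interval.end:
        out.append((f"{chrom.name}q", GenomicInterval(interval.chrom, q_start, interval.end)))
    return out
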