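"""BED interval handling (0-based, half-open) shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

__all__ = ["BedFormatError", "NamedRegion", "read_bed", "read_named_bed", "build_trees", "point_in_regions"]


class BedFormatError(ValueError):
    """A BED line could not be parsed; the message carries the line number."""


@dataclass(frozen=True)
class NamedRegion:
    """One BED interval with its name column (0-based half-open)."""

    contig: str
    start: int
    end: int
    name: str = "."


def read_named_bed(path) -> list[NamedRegion]:
    """Parse a BED3+ file into :class:`NamedRegion` records.

    Raises :class:`BedFormatError` naming the offending line for short rows,
    non-integer coordinates or empty intervals.  The name column defaults to
    ``"."`` for BED3 input.
    """
    regions: list[NamedRegion] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: expected at least 3 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates {fields[1]!r}/{fields[2]!r}") from None
            if end <= start or start < 0:
                raise BedFormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            regions.append(NamedRegion(fields[0], start, end, name))
    return regions


def build_trees(regions: list[NamedRegion]) -> dict[str, IntervalTree]:
    """Index regions per contig for point/overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for region in regions:
        trees.setdefault(region.contig, IntervalTree()).addi(region.start, region.end, region.name)
    return trees


def read_bed(path) -> dict[str, IntervalTree]:
    """Read a BED file straight into per-contig interval trees."""
    return build_trees(read_named_bed(path))


def point_in_regions(trees: dict[str, IntervalTree], contig: str, pos0: int) -> bool:
    """True iff the 0-based position falls inside some interval."""
    tree = trees.get(contig)
    return bool(tree is not None and tree[pos0])
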