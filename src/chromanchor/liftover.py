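"""Invertible coordinate translation between scaffold and chromonome space.

A :class:`CoordinateTransform` is built from the placements of a chromonome:
each placed fragment contributes one entry mapping a scaffold interval onto
a chromosome interval, forward or reverse-complemented.  Every placed base
has exactly one image; spacer bases map to nothing; scaffolds that were
never placed stay in their own coordinate system.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .formats_io import Feature, FeatureSet
from .integrate import Chromonome, Placement

__all__ = [
    "CoordinateTransform",
    "LiftedInterval",
    "LiftReport",
    "build_transform",
    "transform_from_agp",
    "lift_interval",
    "lift_position",
    "unlift_position",
    "lift_gff",
]


@dataclass(frozen=True)
class LiftedInterval:
    """Result of lifting one (piece of an) interval.  1-based inclusive."""

    seqid: str
    start: int
    end: int
    strand: str
    placed: bool = True
    truncated: bool = False


@dataclass
class CoordinateTransform:
    """Bidirectional scaffold <-> chromosome interval index."""

    # per source scaffold: placements sorted by source_start
    forward: dict[str, list[Placement]] = field(default_factory=dict)
    # per chromosome: placements sorted by chrom_start
    reverse: dict[str, list[Placement]] = field(default_factory=dict)

    def is_placed(self, scaffold_id: str) -> bool:
        return scaffold_id in self.forward


def build_transform(chromonome: Chromonome) -> CoordinateTransform:
    """Index a chromonome's placements for O(log n) interval lookup."""
    t = CoordinateTransform()
    for p in chromonome.placements:
        t.forward.setdefault(p.scaffold_id, []).append(p)
        t.reverse.setdefault(p.chrom, []).append(p)
    for plist in t.forward.values():
        plist.sort(key=lambda p: p.source_start)
        last = 0
        for p in plist:
            if p.source_start <= last:
                raise ValueError(
                    f"overlapping placements on scaffold {p.scaffold_id!r}"
                )
            last = p.source_end
    for plist in t.reverse.values():
        plist.sort(key=lambda p: p.chrom_start)
        last = 0
        for p in plist:
            if p.chrom_start <= last:
                raise ValueError(f"overlapping placements on chromosome {p.chrom!r}")
            last = p.chrom_end
    return t


def transform_from_agp(layout) -> CoordinateTransform:
    """Rebuild a transform from a chromonome AGP.

    Every W row places a component interval on an object, so the chromonome
    AGP doubles as the serialized transform.  Unplaced scaffolds carried
    through the AGP keep contig-level component ids that no annotation
    references, so their features fall back to the unplaced path.
    """
    from .formats_io import ContigRow

    chromonome = Chromonome(chromosomes={}, spacer_gap=0, unplaced=[])
    for obj in layout.scaffolds.values():
        placements = []
        for row in obj.rows:
            if not isinstance(row, ContigRow):
                continue
            placements.append(
                Placement(
                    chrom=obj.id,
                    chrom_start=row.start + 1,
                    chrom_end=row.end,
                    fragment_id=row.component_id,
                    scaffold_id=row.component_id,
                    source_start=row.component_beg,
                    source_end=row.component_end,
                    orientation=row.orientation if row.orientation in ("+", "-") else "+",
                    orientation_known=True,
                )
            )
        if placements:
            chromonome.chromosomes[obj.id] = placements
    return build_transform(chromonome)


def _flip(strand: str) -> str:
    return {"+": "-", "-": "+"}.get(strand, strand)


def _lift_within(p: Placement, start: int, end: int, strand: str) -> LiftedInterval:
    """Lift [start, end] known to lie within placement ``p``."""
    offset = p.chrom_start - 1
    a = start - p.source_start + 1  # 1-based within the fragment
    b = end - p.source_start + 1
    L = p.source_end - p.source_start + 1
    if p.orientation == "+":
        return LiftedInterval(p.chrom, offset + a, offset + b, strand)
    return LiftedInterval(p.chrom, offset + (L - b + 1), offset + (L - a + 1), _flip(strand))


def lift_interval(
    t: CoordinateTransform, scaffold_id: str, start: int, end: int, strand: str = "+"
) -> list[LiftedInterval]:
    """Translate a scaffold interval (1-based inclusive) to chromosome space.

    Returns one piece per overlapped fragment, in scaffold order.  Pieces
    are flagged ``truncated`` when the interval crosses a split boundary or
    overhangs sequence dropped at a cut; an interval on an unplaced scaffold
    comes back unchanged with ``placed=False``.
    """
    if end < start:
        raise ValueError(f"interval end {end} < start {start}")
    if start < 1:
        raise ValueError("interval start must be >= 1")
    plist = t.forward.get(scaffold_id)
    if not plist:
        return [LiftedInterval(scaffold_id, start, end, strand, placed=False)]
    if end > plist[-1].source_end and start > plist[-1].source_end:
        raise ValueError(
            f"interval [{start}, {end}] lies beyond the placed extent of "
            f"scaffold {scaffold_id!r}"
        )
    pieces: list[LiftedInterval] = []
    covered = 0
    starts = [p.source_start for p in plist]
    i = max(0, bisect.bisect_right(starts, start) - 1)
    for p in plist[i:]:
        if p.source_start > end:
            break
        a, b = max(start, p.source_start), min(end, p.source_end)
        if b < a:
            continue
        pieces.append(_lift_within(p, a, b, strand))
        covered += b - a + 1
    if not pieces:
        # interval falls entirely in a region dropped at a split cut
        return [LiftedInterval(scaffold_id, start, end, strand, placed=False)]
    if len(pieces) > 1 or covered < end - start + 1:
        pieces = [
            LiftedInterval(x.seqid, x.start, x.end, x.strand, True, True) for x in pieces
        ]
    return pieces


def lift_position(t: CoordinateTransform, scaffold_id: str, pos: int) -> LiftedInterval:
    """Lift a single base; convenience wrapper over :func:`lift_interval`."""
    return lift_interval(t, scaffold_id, pos, pos)[0]


def unlift_position(
    t: CoordinateTransform, chrom: str, pos: int
) -> tuple[str, int, str] | None:
    """Map a chromosome base back to (scaffold, position, orientation).

    Returns ``None`` for spacer bases (and for coordinates outside every
    placement), which have no source.
    """
    plist = t.reverse.get(chrom)
    if not plist:
        return None
    starts = [p.chrom_start for p in plist]
    i = bisect.bisect_right(starts, pos) - 1
    if i < 0:
        return None
    p = plist[i]
    if pos > p.chrom_end:
        return None
    q = pos - p.chrom_start + 1
    L = p.source_end - p.source_start + 1
    if p.orientation == "+":
        return (p.scaffold_id, p.source_start + q - 1, "+")
    return (p.scaffold_id, p.source_start + (L - q), "-")


@dataclass
class LiftReport:
    """Bookkeeping for an annotation lift: conservation must hold as
    ``lifted_intact + unplaced + sum(parts per split feature) == output``
    and ``lifted_intact + unplaced + split == input``."""

    input_count: int = 0
    lifted_intact: int = 0
    unplaced: int = 0
    split: int = 0
    split_parts: int = 0
    truncated_cds: int = 0


def lift_gff(t: CoordinateTransform, features: FeatureSet) -> tuple[FeatureSet, LiftReport]:
    """Translate a feature set onto the chromonome.

    Parent/child attributes pass through untouched.  Features crossing a
    split cut are emitted as parts sharing a ``split_of`` tag; a truncated
    CDS gets phase "." since its frame can no longer be trusted.  Features
    on unplaced scaffolds are emitted unchanged under their original seqid.
    """
    report = LiftReport(input_count=len(features))
    out: list[Feature] = []
    for f in features.features:
        pieces = lift_interval(t, f.seqid, f.start, f.end, f.strand)
        if not pieces[0].placed:
            report.unplaced += 1
            out.append(f)
            continue
        multi = len(pieces) > 1
        if multi:
            report.split += 1
            report.split_parts += len(pieces)
        else:
            report.lifted_intact += 1
        fid = f.attr("ID")
        for k, piece in enumerate(pieces, start=1):
            phase = f.phase
            if piece.truncated and f.type == "CDS" and f.phase != ".":
                phase = "."
                report.truncated_cds += 1
            g = Feature(
                seqid=piece.seqid,
                source=f.source,
                type=f.type,
                start=piece.start,
                end=piece.end,
                score=f.score,
                strand=piece.strand,
                phase=phase,
                attributes=[(a, v) for a, v in f.attributes],
            )
            if multi:
                tag = fid if fid is not None else f"{f.seqid}:{f.start}-{f.end}"
                if fid is not None:
                    g.set_attr("ID", f"{fid}_part{k}")
                g.set_attr("split_of", tag)
                g.set_attr("split_part", f"{k}/{len(pieces)}")
            out.append(g)
    return FeatureSet(out), report
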