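"""Readers and writers for the file formats the anchoring pipeline touches.

Formats handled: AGP v2.0 (scaffold layout), FASTA, GFF3, SAM or TSV marker
alignments, and a tab-separated genetic-map table.  All external coordinates
are 1-based inclusive (the AGP/GFF/SAM convention); internal interval
arithmetic elsewhere in the package is 0-based half-open and converted at
this boundary.

Round trips are semantic identities: ``read(write(x)) == x`` for every valid
object, and writing is canonical, so a second write is byte-identical.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Marker",
    "GeneticMap",
    "ContigRow",
    "GapRow",
    "ScaffoldLayout",
    "AssemblyLayout",
    "MarkerAlignment",
    "Feature",
    "FeatureSet",
    "FormatError",
    "read_genetic_map",
    "write_genetic_map",
    "read_agp",
    "write_agp",
    "read_alignments",
    "write_alignments_tsv",
    "read_gff",
    "write_gff",
    "read_fasta",
    "write_fasta",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Marker:
    """One mapped marker: an id, a linkage group, and a cM position."""

    id: str
    lg: str
    cm: float


@dataclass
class GeneticMap:
    """A genetic linkage map: markers grouped into linkage groups.

    Markers keep input order for provenance; ``linkage_groups`` lists group
    ids in order of first appearance.
    """

    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.markers:
            if m.id in seen:
                raise FormatError(f"duplicate marker id {m.id!r} in genetic map")
            seen.add(m.id)
            if not (m.cm >= 0.0 and m.cm == m.cm and m.cm != float("inf")):
                raise FormatError(
                    f"marker {m.id!r} has non-finite or negative cM position {m.cm!r}"
                )

    @property
    def linkage_groups(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for m in self.markers:
            if m.lg not in seen:
                seen.add(m.lg)
                out.append(m.lg)
        return out

    def by_id(self) -> dict[str, Marker]:
        return {m.id: m for m in self.markers}

    def __len__(self) -> int:
        return len(self.markers)


MAP_HEADER = ("marker", "lg", "cM")


def read_genetic_map(path: PathLike) -> GeneticMap:
    """Parse a genetic-map table (tab-separated: marker, lg, cM)."""
    markers: list[Marker] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if [c.strip() for c in cols[:3]] != list(MAP_HEADER):
            raise FormatError(
                f"{path}: expected header columns {MAP_HEADER}, got {cols[:3]}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            mid, lg, cm_s = parts[0], parts[1], parts[2]
            try:
                cm = float(cm_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cM value {cm_s!r} for marker {mid!r}"
                ) from None
            markers.append(Marker(mid, lg, cm))
    return GeneticMap(markers)


def write_genetic_map(gmap: GeneticMap, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MAP_HEADER) + "\n")
        for m in gmap.markers:
            fh.write(f"{m.id}\t{m.lg}\t{_fmt_num(m.cm)}\n")


def _fmt_num(x: float) -> str:
    """Canonical number formatting: integers without a trailing .0."""
    return repr(round(float(x), 6)).removesuffix(".0")


# ---------------------------------------------------------------------------
# AGP v2.0
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContigRow:
    """A W component row: a contig placed on the object.

    ``start``/``end`` are 0-based half-open on the object; component
    coordinates stay 1-based inclusive as AGP prints them.
    """

    start: int
    end: int
    component_id: str
    component_beg: int
    component_end: int
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"contig row {self.component_id!r} has zero/negative length")
        if self.component_end - self.component_beg + 1 != self.end - self.start:
            raise FormatError(
                f"contig row {self.component_id!r}: object span and component span differ"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GapRow:
    """An N or U gap row on the object (0-based half-open object span)."""

    start: int
    end: int
    component_type: str = "N"  # N = known length, U = unknown (100 by convention)
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "paired-ends"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError("gap row must have positive length")
        if self.component_type not in ("N", "U"):
            raise FormatError(f"gap component_type must be N or U, got {self.component_type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


Row = Union[ContigRow, GapRow]


@dataclass
class ScaffoldLayout:
    """One AGP object: an id, a length, and rows tiling [0, length)."""

    id: str
    length: int
    rows: list[Row] = field(default_factory=list)

    def validate(self) -> None:
        pos = 0
        for i, row in enumerate(self.rows, start=1):
            if row.start != pos:
                raise FormatError(
                    f"object {self.id!r}: row {i} starts at {row.start + 1}, "
                    f"expected {pos + 1} (rows must tile the object)"
                )
            pos = row.end
        if pos != self.length:
            raise FormatError(
                f"object {self.id!r}: rows cover {pos} bp but object length is {self.length}"
            )

    @property
    def gap_rows(self) -> list[GapRow]:
        return [r for r in self.rows if isinstance(r, GapRow)]

    @property
    def gap_length(self) -> int:
        return sum(r.length for r in self.gap_rows)


@dataclass
class AssemblyLayout:
    """An AGP file in memory: ordered scaffold (object) layouts."""

    scaffolds: dict[str, ScaffoldLayout] = field(default_factory=dict)

    def validate(self) -> None:
        for s in self.scaffolds.values():
            s.validate()

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self.scaffolds

    def __getitem__(self, scaffold_id: str) -> ScaffoldLayout:
        return self.scaffolds[scaffold_id]

    def __len__(self) -> int:
        return len(self.scaffolds)


def read_agp(path: PathLike) -> AssemblyLayout:
    """Parse an AGP v2.0 file into an :class:`AssemblyLayout` (validated)."""
    per_object: dict[str, list[Row]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise FormatError(f"{path}:{lineno}: AGP row has {len(f)} columns, need >= 8")
            obj, beg_s, end_s, _part, ctype = f[0], f[1], f[2], f[3], f[4]
            try:
                beg, end = int(beg_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer object coordinates") from None
            start0, end0 = beg - 1, end
            if ctype in ("N", "U"):
                gap_len = int(f[5])
                if gap_len != end0 - start0:
                    raise FormatError(
                        f"{path}:{lineno}: gap length {gap_len} does not match span"
                    )
                if ctype == "U" and gap_len != 100:
                    raise FormatError(f"{path}:{lineno}: U gaps must have length 100")
                row: Row = GapRow(
                    start0, end0, ctype, f[6], f[7], f[8] if len(f) > 8 else "na"
                )
            elif ctype == "W":
                if len(f) < 9:
                    raise FormatError(f"{path}:{lineno}: W row needs 9 columns")
                row = ContigRow(start0, end0, f[5], int(f[6]), int(f[7]), f[8])
            else:
                raise FormatError(
                    f"{path}:{lineno}: unsupported component_type {ctype!r}"
                )
            per_object.setdefault(obj, []).append(row)

    layout = AssemblyLayout(
        {
            obj: ScaffoldLayout(obj, rows[-1].end if rows else 0, rows)
            for obj, rows in per_object.items()
        }
    )
    layout.validate()
    return layout


def write_agp(layout: AssemblyLayout, path_or_fh: Union[PathLike, TextIO]) -> None:
    """Write a canonical AGP v2.0 file (tiling is validated first)."""
    layout.validate()
    own = not hasattr(path_or_fh, "write")
    fh: TextIO = open(path_or_fh, "w") if own else path_or_fh  # type: ignore[arg-type]
    try:
        fh.write("##agp-version\t2.0\n")
        for s in layout.scaffolds.values():
            for part, row in enumerate(s.rows, start=1):
                beg, end = row.start + 1, row.end
                if isinstance(row, GapRow):
                    fh.write(
                        f"{s.id}\t{beg}\t{end}\t{part}\t{row.component_type}\t"
                        f"{row.length}\t{row.gap_type}\t{row.linkage}\t{row.evidence}\n"
                    )
                else:
                    fh.write(
                        f"{s.id}\t{beg}\t{end}\t{part}\tW\t{row.component_id}\t"
                        f"{row.component_beg}\t{row.component_end}\t{row.orientation}\n"
                    )
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Marker alignments (SAM or TSV)
# ---------------------------------------------------------------------------

@dataclass
class MarkerAlignment:
    """A marker's physical placement on a scaffold.

    ``position`` is the 1-based start of the alignment; ``coverage`` is the
    fraction of the marker's length that aligned; ``is_unique`` is False when
    the marker has more than one retained alignment record.
    """

    marker_id: str
    scaffold_id: str
    position: int
    strand: str
    mismatches: int
    gap_opens: int
    coverage: float
    is_unique: bool = True

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"alignment of {self.marker_id!r}: position must be >= 1")
        if not 0.0 <= self.coverage <= 1.0:
            raise FormatError(
                f"alignment of {self.marker_id!r}: coverage {self.coverage} outside [0, 1]"
            )
        if self.mismatches < 0 or self.gap_opens < 0:
            raise FormatError(
                f"alignment of {self.marker_id!r}: negative mismatch/gap count"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"alignment of {self.marker_id!r}: strand must be + or -")


ALN_HEADER = ("marker", "scaffold", "pos", "strand", "mismatches", "gap_opens", "coverage")


def read_alignments(
    path: PathLike,
    dialect: str | None = None,
    layout: AssemblyLayout | None = None,
) -> list[MarkerAlignment]:
    """Read marker alignments from SAM or TSV.

    Secondary and supplementary SAM records are excluded.  Any marker with
    more than one retained record gets ``is_unique = False`` on all of its
    records.  If ``layout`` is given, alignments to scaffolds absent from it
    (or beyond scaffold length) are errors.
    """
    if dialect is None:
        dialect = "sam" if str(path).endswith(".sam") else "tsv"
    if dialect == "sam":
        alns = _read_sam(path)
    elif dialect == "tsv":
        alns = _read_aln_tsv(path)
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")

    counts: dict[str, int] = {}
    for a in alns:
        counts[a.marker_id] = counts.get(a.marker_id, 0) + 1
    for a in alns:
        a.is_unique = counts[a.marker_id] == 1

    if layout is not None:
        for a in alns:
            if a.scaffold_id not in layout:
                raise FormatError(
                    f"alignment of {a.marker_id!r} references unknown scaffold "
                    f"{a.scaffold_id!r}"
                )
            if a.position > layout[a.scaffold_id].length:
                raise FormatError(
                    f"alignment of {a.marker_id!r} at {a.position} exceeds "
                    f"scaffold {a.scaffold_id!r} length {layout[a.scaffold_id].length}"
                )
    return alns


def _read_sam(path: PathLike) -> list[MarkerAlignment]:
    alns: list[MarkerAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            qlen = rec.query_length or rec.infer_read_length() or 0
            aligned = sum(l for op, l in (rec.cigartuples or []) if op == 0)  # M
            ins = sum(l for op, l in (rec.cigartuples or []) if op == 1)
            dele = sum(l for op, l in (rec.cigartuples or []) if op == 2)
            gap_opens = sum(1 for op, _ in (rec.cigartuples or []) if op in (1, 2))
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            # NM counts gap bases as edits; subtract them to keep substitutions only
            mism = max(0, int(nm) - ins - dele)
            cov = (aligned + ins) / qlen if qlen else 0.0
            alns.append(
                MarkerAlignment(
                    marker_id=rec.query_name,
                    scaffold_id=rec.reference_name,
                    position=rec.reference_start + 1,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=mism,
                    gap_opens=gap_opens,
                    coverage=min(1.0, cov),
                )
            )
    return alns


def _read_aln_tsv(path: PathLike) -> list[MarkerAlignment]:
    alns: list[MarkerAlignment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [c.strip() for c in header[:7]] != list(ALN_HEADER):
            raise FormatError(f"{path}: expected header columns {ALN_HEADER}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(f)}")
            try:
                alns.append(
                    MarkerAlignment(f[0], f[1], int(f[2]), f[3], int(f[4]), int(f[5]), float(f[6]))
                )
            except FormatError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed numeric field") from None
    return alns


def write_alignments_tsv(alns: Sequence[MarkerAlignment], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALN_HEADER) + "\n")
        for a in alns:
            fh.write(
                f"{a.marker_id}\t{a.scaffold_id}\t{a.position}\t{a.strand}\t"
                f"{a.mismatches}\t{a.gap_opens}\t{_fmt_num(a.coverage)}\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

@dataclass
class Feature:
    """One GFF3 record; attributes kept as an ordered list of (key, value)."""

    seqid: str
    source: str
    type: str
    start: int  # 1-based inclusive
    end: int
    score: str
    strand: str
    phase: str
    attributes: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(
                f"feature {self.attr('ID') or self.type} has end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-", ".", "?"):
            raise FormatError(f"invalid strand {self.strand!r}")

    def attr(self, key: str) -> str | None:
        for k, v in self.attributes:
            if k == key:
                return v
        return None

    def set_attr(self, key: str, value: str) -> None:
        for i, (k, _) in enumerate(self.attributes):
            if k == key:
                self.attributes[i] = (key, value)
                return
        self.attributes.append((key, value))

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes)
        return "\t".join(
            [
                self.seqid,
                self.source,
                self.type,
                str(self.start),
                str(self.end),
                self.score,
                self.strand,
                self.phase,
                attrs,
            ]
        )


@dataclass
class FeatureSet:
    """An ordered GFF3 feature collection with parent/child bookkeeping."""

    features: list[Feature] = field(default_factory=list)

    def by_id(self) -> dict[str, Feature]:
        out: dict[str, Feature] = {}
        for f in self.features:
            fid = f.attr("ID")
            if fid is not None:
                out[fid] = f
        return out

    def children(self, parent_id: str) -> list[Feature]:
        return [
            f
            for f in self.features
            if parent_id in (f.attr("Parent") or "").split(",")
        ]

    def check_hierarchy(self) -> list[str]:
        """Return warnings for children that escape their parent's bounds."""
        warnings_out: list[str] = []
        idx = self.by_id()
        for f in self.features:
            for pid in (f.attr("Parent") or "").split(","):
                if not pid:
                    continue
                p = idx.get(pid)
                if p is None:
                    warnings_out.append(f"feature {f.attr('ID') or f.type}: unknown Parent {pid}")
                elif f.seqid != p.seqid or f.start < p.start or f.end > p.end:
                    warnings_out.append(
                        f"feature {f.attr('ID') or f.type} [{f.start}-{f.end}] "
                        f"escapes parent {pid} [{p.start}-{p.end}]"
                    )
        return warnings_out

    def __len__(self) -> int:
        return len(self.features)


def _parse_attributes(s: str) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    for part in s.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out.append((k, v))
        else:
            out.append((part, ""))
    return out


def read_gff(path: PathLike, strict_hierarchy: bool = False) -> FeatureSet:
    """Parse GFF3.  Hierarchy violations warn (or raise if strict)."""
    feats: list[Feature] = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##gff-version"):
            raise FormatError(f"{path}: missing ##gff-version directive on line 1")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(f)}")
            try:
                feats.append(
                    Feature(
                        f[0], f[1], f[2], int(f[3]), int(f[4]), f[5], f[6], f[7],
                        _parse_attributes(f[8]),
                    )
                )
            except FormatError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
    fs = FeatureSet(feats)
    for w in fs.check_hierarchy():
        if strict_hierarchy:
            raise FormatError(w)
        warnings.warn(w, stacklevel=2)
    return fs


def write_gff(features: FeatureSet, path_or_fh: Union[PathLike, TextIO]) -> None:
    own = not hasattr(path_or_fh, "write")
    fh: TextIO = open(path_or_fh, "w") if own else path_or_fh  # type: ignore[arg-type]
    try:
        fh.write("##gff-version 3\n")
        for f in features.features:
            fh.write(f.to_line() + "\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: PathLike, width: int = 60) -> None:
    """Write sequences wrapped at ``width`` columns."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
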