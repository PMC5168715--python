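"""Linkage-map-guided anchoring of assembly scaffolds into chromosomes.

The pipeline mirrors how chromonome builders reconcile a genetic map with a
draft assembly:

1. filter marker alignments (uniqueness, mismatch score, coverage);
2. assign each scaffold to the linkage group with majority marker support;
3. per scaffold, keep a maximum set of markers whose cM positions are
   monotone in physical (bp) order — out-of-order markers are discarded,
   but a scaffold's last marker is never dropped;
4. orient each scaffold from the direction of the cM trend (two or more
   distinct map positions are required; otherwise orientation is unknown
   and the scaffold is emitted forward);
5. order scaffolds along each linkage group by mean cM;
6. split scaffolds whose markers interleave with other scaffolds in the map
   (chimeric joins), cutting at the largest assembly gap between the
   bracketing markers;
7. concatenate ordered, oriented fragments into chromosome sequences with
   fixed-length N spacers between joins, and emit FASTA/AGP plus a full
   marker accounting.

Coordinates on scaffolds and chromosomes are 1-based inclusive at this
module's surface, matching the AGP convention used for output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formats_io import (
    AssemblyLayout,
    ContigRow,
    FormatError,
    GapRow,
    GeneticMap,
    MarkerAlignment,
    ScaffoldLayout,
)

__all__ = [
    "IntegrationParams",
    "PlacedMarker",
    "AnchoredScaffold",
    "Placement",
    "SplitRequest",
    "SplitRecord",
    "Chromonome",
    "IntegrationResult",
    "filter_alignments",
    "assign_linkage_groups",
    "select_consistent_markers",
    "orient_scaffold",
    "order_scaffolds",
    "detect_interleavings",
    "split_scaffold",
    "build_chromonome",
    "run_integration",
    "reverse_complement",
]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class IntegrationParams:
    """Tunable thresholds of the anchoring pipeline.

    ``max_mismatch_score`` caps mismatches + ``gap_penalty`` x gap opens per
    alignment; ``min_coverage`` is the fraction of the marker that must
    align; ``spacer_gap`` is the N run placed between joined fragments;
    ``min_orient_positions`` is the number of distinct cM positions needed
    to call an orientation.
    """

    max_mismatch_score: int = 5
    gap_penalty: int = 4
    min_coverage: float = 0.99
    spacer_gap: int = 100
    min_orient_positions: int = 2
    allow_splits: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatch_score < 0 or self.gap_penalty < 0 or self.spacer_gap < 0:
            raise ValueError("integration parameters must be non-negative")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError("min_coverage must be in [0, 1]")
        if self.min_orient_positions < 2:
            raise ValueError("min_orient_positions must be >= 2")


@dataclass(frozen=True)
class PlacedMarker:
    """A mapped marker placed on a scaffold: id, 1-based bp, cM position."""

    marker_id: str
    bp: int
    cm: float


@dataclass
class AnchoredScaffold:
    """A scaffold (or split fragment) anchored to one linkage group.

    ``retained`` markers are sorted by bp and their cM sequence is monotone;
    ``source_start``/``source_end`` give the fragment's 1-based interval on
    the root scaffold (``parent_id``), identity for unsplit scaffolds.
    """

    scaffold_id: str
    lg_id: str
    length: int
    retained: list[PlacedMarker]
    excluded: list[tuple[PlacedMarker, str]] = field(default_factory=list)
    orientation: str = "unknown"  # '+', '-', or 'unknown'
    parent_id: str = ""
    source_start: int = 1
    source_end: int = 0
    layout: ScaffoldLayout | None = None

    def __post_init__(self) -> None:
        if not self.retained:
            raise ValueError(f"anchored scaffold {self.scaffold_id!r} has no retained markers")
        if not self.parent_id:
            self.parent_id = self.scaffold_id
        if self.source_end == 0:
            self.source_end = self.length

    @property
    def mean_cm(self) -> float:
        return sum(m.cm for m in self.retained) / len(self.retained)

    @property
    def map_span(self) -> tuple[float, float]:
        cms = [m.cm for m in self.retained]
        return (min(cms), max(cms))


@dataclass(frozen=True)
class Placement:
    """One fragment's location in the chromonome (1-based inclusive)."""

    chrom: str
    chrom_start: int
    chrom_end: int
    fragment_id: str
    scaffold_id: str  # root scaffold the sequence comes from
    source_start: int
    source_end: int
    orientation: str  # '+' or '-'
    orientation_known: bool

    @property
    def length(self) -> int:
        return self.chrom_end - self.chrom_start + 1


@dataclass(frozen=True)
class SplitRequest:
    """An interleaving that can only be reconciled by cutting the host."""

    host_id: str
    left_marker: PlacedMarker
    right_marker: PlacedMarker
    guests: tuple[str, ...]


@dataclass(frozen=True)
class SplitRecord:
    """Provenance of one scaffold cut."""

    parent_id: str          # scaffold/fragment that was cut
    root_id: str            # original input scaffold
    cut_start: int          # 1-based interval dropped from the root scaffold
    cut_end: int            # (zero-length midpoint cuts have cut_end = cut_start - 1)
    gap_dropped: int        # bp of gap sequence removed at the cut
    low_confidence: bool    # True when no assembly gap existed and a midpoint was used
    left_marker: str
    right_marker: str
    guests: tuple[str, ...]
    fragment_ids: tuple[str, str]


@dataclass
class Chromonome:
    """Ordered, oriented scaffold fragments per chromosome plus leftovers."""

    chromosomes: dict[str, list[Placement]]
    spacer_gap: int
    unplaced: list[str]
    splits: list[SplitRecord] = field(default_factory=list)

    def chromosome_length(self, chrom: str) -> int:
        placements = self.chromosomes[chrom]
        return sum(p.length for p in placements) + self.spacer_gap * (len(placements) - 1)

    @property
    def placements(self) -> list[Placement]:
        return [p for ps in self.chromosomes.values() for p in ps]


# ---------------------------------------------------------------------------
# Stage 1: alignment filtering
# ---------------------------------------------------------------------------

def filter_alignments(
    alignments: Sequence[MarkerAlignment], params: IntegrationParams
) -> tuple[list[MarkerAlignment], list[tuple[MarkerAlignment, str]]]:
    """Keep unique alignments within the mismatch-score and coverage limits.

    The mismatch score is ``mismatches + gap_penalty * gap_opens``.  Each
    rejected alignment carries the first failing criterion, tested in the
    order unique, score, coverage.
    """
    kept: list[MarkerAlignment] = []
    rejected: list[tuple[MarkerAlignment, str]] = []
    for a in alignments:
        if not a.is_unique:
            rejected.append((a, "non-unique"))
        elif a.mismatches + params.gap_penalty * a.gap_opens > params.max_mismatch_score:
            rejected.append((a, "mismatch-score"))
        elif a.coverage < params.min_coverage:
            rejected.append((a, "low-coverage"))
        else:
            kept.append(a)
    return kept, rejected


# ---------------------------------------------------------------------------
# Stage 2: linkage-group assignment
# ---------------------------------------------------------------------------

def assign_linkage_groups(
    gmap: GeneticMap, kept: Sequence[MarkerAlignment]
) -> tuple[dict[str, str], dict[str, list[PlacedMarker]], list[tuple[str, str, str]]]:
    """Vote each scaffold into the linkage group with most marker support.

    Returns ``(assignment, scaffold_markers, excluded)`` where ``assignment``
    maps scaffold id to lg id (scaffolds with an exact tie are absent),
    ``scaffold_markers`` holds the surviving markers per scaffold sorted by
    bp, and ``excluded`` lists (marker_id, scaffold_id, reason) for markers
    lost to lg conflicts or ties.
    """
    by_id = gmap.by_id()
    per_scaffold: dict[str, list[MarkerAlignment]] = {}
    for a in kept:
        if a.marker_id not in by_id:
            raise KeyError(f"aligned marker {a.marker_id!r} is not in the genetic map")
        per_scaffold.setdefault(a.scaffold_id, []).append(a)

    assignment: dict[str, str] = {}
    scaffold_markers: dict[str, list[PlacedMarker]] = {}
    excluded: list[tuple[str, str, str]] = []
    for scaffold_id, alns in per_scaffold.items():
        votes: dict[str, int] = {}
        for a in alns:
            votes[by_id[a.marker_id].lg] = votes.get(by_id[a.marker_id].lg, 0) + 1
        best = max(votes.values())
        winners = sorted(lg for lg, n in votes.items() if n == best)
        if len(winners) > 1:
            for a in alns:
                excluded.append((a.marker_id, scaffold_id, "lg-tie"))
            continue
        lg = winners[0]
        assignment[scaffold_id] = lg
        markers: list[PlacedMarker] = []
        for a in alns:
            m = by_id[a.marker_id]
            if m.lg == lg:
                markers.append(PlacedMarker(a.marker_id, a.position, m.cm))
            else:
                excluded.append((a.marker_id, scaffold_id, "lg-conflict"))
        markers.sort(key=lambda m: (m.bp, m.marker_id))
        scaffold_markers[scaffold_id] = markers
    return assignment, scaffold_markers, excluded


# ---------------------------------------------------------------------------
# Stage 3: within-scaffold marker consistency
# ---------------------------------------------------------------------------

def _longest_monotone(cms: Sequence[float], nondecreasing: bool) -> list[int]:
    """Indices of the maximum monotone subsequence, lexicographically
    smallest among optima (so earlier-bp markers win ties)."""
    n = len(cms)
    ok = (lambda a, b: a <= b) if nondecreasing else (lambda a, b: a >= b)
    f = [1] * n
    for i in range(n - 2, -1, -1):
        best = 0
        for j in range(i + 1, n):
            if ok(cms[i], cms[j]) and f[j] > best:
                best = f[j]
        f[i] = 1 + best
    target = max(f, default=0)
    idxs: list[int] = []
    need, prev = target, -1
    for i in range(n):
        if f[i] == need and (prev < 0 or ok(cms[prev], cms[i])):
            idxs.append(i)
            prev = i
            need -= 1
            if need == 0:
                break
    return idxs


def select_consistent_markers(
    markers: Sequence[PlacedMarker],
) -> tuple[list[PlacedMarker], str, list[tuple[PlacedMarker, str]]]:
    """Retain a maximum subset of markers with cM monotone in bp order.

    The longest non-decreasing subsequence is tested against the longest
    non-increasing one; the larger wins and sets the orientation hint
    ('+', '-', or 'tie').  Among equal-size optima the earlier-bp markers
    are kept.  A scaffold never loses its final marker: if selection would
    leave nothing, the marker nearest the median bp is retained.
    """
    if not markers:
        raise ValueError("select_consistent_markers: empty marker list")
    ms = sorted(markers, key=lambda m: (m.bp, m.marker_id))
    cms = [m.cm for m in ms]
    up = _longest_monotone(cms, nondecreasing=True)
    down = _longest_monotone(cms, nondecreasing=False)
    if len(up) > len(down):
        chosen, hint = up, "+"
    elif len(down) > len(up):
        chosen, hint = down, "-"
    else:
        chosen, hint = up, "tie"
    if not chosen:  # defensive; a non-empty input always yields >= 1
        median_bp = ms[len(ms) // 2].bp
        keep = min(range(len(ms)), key=lambda i: (abs(ms[i].bp - median_bp), i))
        chosen = [keep]
    chosen_set = set(chosen)
    retained = [ms[i] for i in chosen]
    excluded = [(ms[i], "order-conflict") for i in range(len(ms)) if i not in chosen_set]
    return retained, hint, excluded


def orient_scaffold(anchored: AnchoredScaffold, params: IntegrationParams, hint: str) -> str:
    """Call '+' or '-' from the cM trend; 'unknown' without enough positions."""
    distinct = len({m.cm for m in anchored.retained})
    if hint in ("+", "-") and distinct >= params.min_orient_positions:
        return hint
    return "unknown"


# ---------------------------------------------------------------------------
# Stage 4: ordering and interleaving detection
# ---------------------------------------------------------------------------

def order_scaffolds(lg_scaffolds: Iterable[AnchoredScaffold]) -> list[AnchoredScaffold]:
    """Order scaffolds along a linkage group by mean cM of retained markers;
    ties go to the longer scaffold, then lexical id."""
    return sorted(lg_scaffolds, key=lambda s: (s.mean_cm, -s.length, s.scaffold_id))


def detect_interleavings(ordered: Sequence[AnchoredScaffold]) -> list[SplitRequest]:
    """Find scaffolds whose map span falls strictly between two successive
    retained markers of another scaffold.

    Such a guest cannot be placed before or after the host without breaking
    map order, so the host must be split between the bracketing markers.
    One request is emitted per (host, bracketing pair), listing all guests.
    """
    requests: list[SplitRequest] = []
    for host in ordered:
        for a, b in zip(host.retained, host.retained[1:]):
            lo, hi = min(a.cm, b.cm), max(a.cm, b.cm)
            if lo == hi:
                continue
            guests = tuple(
                g.scaffold_id
                for g in ordered
                if g.scaffold_id != host.scaffold_id
                and lo < g.map_span[0]
                and g.map_span[1] < hi
            )
            if guests:
                requests.append(SplitRequest(host.scaffold_id, a, b, guests))
    return requests


# ---------------------------------------------------------------------------
# Stage 5: splitting
# ---------------------------------------------------------------------------

def _slice_layout(src: ScaffoldLayout, start0: int, end0: int, new_id: str) -> ScaffoldLayout:
    """Clip and rebase AGP rows of ``src`` to the 0-based window [start0, end0)."""
    rows: list = []
    for row in src.rows:
        a, b = max(row.start, start0), min(row.end, end0)
        if b <= a:
            continue
        if isinstance(row, GapRow):
            ctype = row.component_type
            if ctype == "U" and b - a != 100:  # clipped U gap loses its fixed length
                ctype = "N"
            rows.append(GapRow(a - start0, b - start0, ctype, row.gap_type, row.linkage, row.evidence))
        else:
            lcut, rcut = a - row.start, row.end - b
            if row.orientation == "-":
                cb, ce = row.component_beg + rcut, row.component_end - lcut
            else:
                cb, ce = row.component_beg + lcut, row.component_end - rcut
            rows.append(ContigRow(a - start0, b - start0, row.component_id, cb, ce, row.orientation))
    out = ScaffoldLayout(new_id, end0 - start0, rows)
    out.validate()
    return out


def split_scaffold(
    host: AnchoredScaffold,
    request: SplitRequest,
    params: IntegrationParams | None = None,
) -> tuple[AnchoredScaffold, AnchoredScaffold, SplitRecord]:
    """Cut the host at the largest assembly gap between the bracketing
    markers; fall back to the marker midpoint (flagged) if no gap exists.

    Fragments are named ``<host>_1`` and ``<host>_2`` in bp order; markers
    (retained and excluded) are partitioned and rebased onto the fragments.
    The dropped gap's bases vanish from the chromonome; their length is
    recorded in the split provenance.
    """
    params = params or IntegrationParams()
    if host.layout is None:
        raise ValueError(f"host {host.scaffold_id!r} has no layout to split")
    left_bp = min(request.left_marker.bp, request.right_marker.bp)
    right_bp = max(request.left_marker.bp, request.right_marker.bp)
    host_bps = {m.bp for m in host.retained}
    if request.left_marker.bp not in host_bps or request.right_marker.bp not in host_bps:
        raise ValueError(
            f"split request markers are not retained on host {host.scaffold_id!r}"
        )

    gaps = [
        g
        for g in host.layout.gap_rows
        if g.start + 1 > left_bp and g.end < right_bp  # strictly between markers
    ]
    if gaps:
        gap = max(gaps, key=lambda g: (g.length, -g.start))
        cut_a, cut_b = gap.start, gap.end  # 0-based half-open window dropped
        gap_dropped = gap.length
        low_confidence = False
    else:
        mid = (left_bp + right_bp) // 2
        cut_a = cut_b = mid  # 0-based: fragment 1 ends at bp mid (1-based)
        gap_dropped = 0
        low_confidence = True

    f1_id, f2_id = f"{host.scaffold_id}_1", f"{host.scaffold_id}_2"
    lay1 = _slice_layout(host.layout, 0, cut_a, f1_id)
    lay2 = _slice_layout(host.layout, cut_b, host.length, f2_id)

    def _partition(markers, lo0, hi0, shift):
        return [
            PlacedMarker(m.marker_id, m.bp - shift, m.cm)
            for m in markers
            if lo0 < m.bp <= hi0
        ]

    r1 = _partition(host.retained, 0, cut_a, 0)
    r2 = _partition(host.retained, cut_b, host.length, cut_b)
    e1 = [
        (PlacedMarker(m.marker_id, m.bp, m.cm), why)
        for m, why in host.excluded
        if m.bp <= cut_a
    ]
    e2 = [
        (PlacedMarker(m.marker_id, m.bp - cut_b, m.cm), why)
        for m, why in host.excluded
        if m.bp > cut_b
    ]

    frags = []
    for fid, lay, retained, excl, off in (
        (f1_id, lay1, r1, e1, 0),
        (f2_id, lay2, r2, e2, cut_b),
    ):
        retained2, hint, more_excl = select_consistent_markers(retained)
        frag = AnchoredScaffold(
            scaffold_id=fid,
            lg_id=host.lg_id,
            length=lay.length,
            retained=retained2,
            excluded=excl + more_excl,
            parent_id=host.parent_id,
            source_start=host.source_start + off,
            source_end=host.source_start + off + lay.length - 1,
            layout=lay,
        )
        frag.orientation = orient_scaffold(frag, params, hint)
        frags.append(frag)

    record = SplitRecord(
        parent_id=host.scaffold_id,
        root_id=host.parent_id,
        cut_start=host.source_start + cut_a,
        cut_end=host.source_start + cut_b - 1,
        gap_dropped=gap_dropped,
        low_confidence=low_confidence,
        left_marker=request.left_marker.marker_id,
        right_marker=request.right_marker.marker_id,
        guests=request.guests,
        fragment_ids=(f1_id, f2_id),
    )
    return frags[0], frags[1], record


def _resolve_interleavings(
    ordered: list[AnchoredScaffold], params: IntegrationParams
) -> tuple[list[AnchoredScaffold], list[SplitRecord]]:
    """Iteratively split hosts until the linkage group is interleaving-free."""
    splits: list[SplitRecord] = []
    max_rounds = 2 * len(ordered) + 4
    for _ in range(max_rounds):
        requests = detect_interleavings(ordered)
        if not requests or not params.allow_splits:
            break
        req = requests[0]
        idx = next(i for i, s in enumerate(ordered) if s.scaffold_id == req.host_id)
        f1, f2, rec = split_scaffold(ordered[idx], req, params)
        splits.append(rec)
        ordered = ordered[:idx] + [f1, f2] + ordered[idx + 1 :]
        ordered = order_scaffolds(ordered)
    return ordered, splits


# ---------------------------------------------------------------------------
# Stage 6: chromonome construction
# ---------------------------------------------------------------------------

def build_chromonome(
    per_lg: dict[str, list[AnchoredScaffold]],
    layout: AssemblyLayout,
    sequences: dict[str, str],
    params: IntegrationParams,
    splits: Sequence[SplitRecord] = (),
    lg_order: Sequence[str] | None = None,
) -> tuple[Chromonome, dict[str, str], AssemblyLayout]:
    """Concatenate ordered, oriented fragments into chromosome sequences.

    Fragments are joined with ``params.spacer_gap`` N bases; '-' fragments
    are reverse-complemented; scaffolds never anchored are carried through
    unchanged.  Returns the chromonome, a {chromosome: sequence} dict, and
    the chromonome AGP (spacers as U gaps with map evidence; unplaced
    scaffolds keep their original rows).
    """
    for lg, scaffolds in per_lg.items():
        for s in scaffolds:
            if s.parent_id not in sequences:
                raise KeyError(f"no sequence for scaffold {s.parent_id!r}")

    lgs = [lg for lg in (lg_order or sorted(per_lg)) if per_lg.get(lg)]
    chromosomes: dict[str, list[Placement]] = {}
    chrom_seqs: dict[str, str] = {}
    agp = AssemblyLayout({})
    placed_roots: set[str] = set()

    for lg in lgs:
        parts: list[str] = []
        placements: list[Placement] = []
        rows: list = []
        pos = 0  # 0-based cursor on the chromosome
        for i, frag in enumerate(per_lg[lg]):
            if i > 0 and params.spacer_gap:
                rows.append(
                    GapRow(pos, pos + params.spacer_gap, "U", "contig", "yes", "map")
                )
                parts.append("N" * params.spacer_gap)
                pos += params.spacer_gap
            seq = sequences[frag.parent_id][frag.source_start - 1 : frag.source_end]
            orientation = frag.orientation if frag.orientation in ("+", "-") else "+"
            if orientation == "-":
                seq = reverse_complement(seq)
            parts.append(seq)
            placements.append(
                Placement(
                    chrom=lg,
                    chrom_start=pos + 1,
                    chrom_end=pos + len(seq),
                    fragment_id=frag.scaffold_id,
                    scaffold_id=frag.parent_id,
                    source_start=frag.source_start,
                    source_end=frag.source_end,
                    orientation=orientation,
                    orientation_known=frag.orientation != "unknown",
                )
            )
            rows.append(
                ContigRow(
                    pos,
                    pos + len(seq),
                    frag.parent_id,
                    frag.source_start,
                    frag.source_end,
                    orientation,
                )
            )
            placed_roots.add(frag.parent_id)
            pos += len(seq)
        chromosomes[lg] = placements
        chrom_seqs[lg] = "".join(parts)
        agp.scaffolds[lg] = ScaffoldLayout(lg, pos, rows)

    unplaced = [sid for sid in layout.scaffolds if sid not in placed_roots]
    for sid in unplaced:
        src = layout[sid]
        agp.scaffolds[sid] = ScaffoldLayout(sid, src.length, list(src.rows))
    agp.validate()
    chromonome = Chromonome(chromosomes, params.spacer_gap, unplaced, list(splits))
    return chromonome, chrom_seqs, agp


# ---------------------------------------------------------------------------
# Stage 7: end-to-end driver
# ---------------------------------------------------------------------------

@dataclass
class IntegrationResult:
    chromonome: Chromonome
    chromosome_sequences: dict[str, str]
    chromonome_agp: AssemblyLayout
    anchored: dict[str, list[AnchoredScaffold]]
    retained_markers: list[tuple[str, str, int, float]]  # marker, fragment, bp, cM
    excluded_markers: list[tuple[str, str, str]]         # marker, scaffold, reason
    splits: list[SplitRecord]
    lifted_features: "object | None" = None
    lift_report: "object | None" = None

    @property
    def n_markers_retained(self) -> int:
        return len(self.retained_markers)

    @property
    def n_markers_excluded(self) -> int:
        return len(self.excluded_markers)


def run_integration(
    gmap: GeneticMap,
    layout: AssemblyLayout,
    alignments: Sequence[MarkerAlignment],
    sequences: dict[str, str],
    features=None,
    params: IntegrationParams | None = None,
) -> IntegrationResult:
    """Run the full map/assembly integration and return every artefact.

    Marker accounting is conserved: each uniquely-aligned map marker ends up
    exactly once in ``retained_markers`` or ``excluded_markers``.
    """
    params = params or IntegrationParams()
    by_id = gmap.by_id()

    mapped = [a for a in alignments if a.marker_id in by_id]
    kept, rejected = filter_alignments(mapped, params)
    excluded: list[tuple[str, str, str]] = []
    seen_rejected: set[str] = set()
    for a, why in rejected:
        if a.marker_id not in seen_rejected:  # one accounting entry per marker
            excluded.append((a.marker_id, a.scaffold_id, why))
            seen_rejected.add(a.marker_id)

    assignment, scaffold_markers, lg_excluded = assign_linkage_groups(gmap, kept)
    excluded.extend(lg_excluded)

    per_lg: dict[str, list[AnchoredScaffold]] = {}
    for scaffold_id, markers in scaffold_markers.items():
        lg = assignment[scaffold_id]
        retained, hint, order_excl = select_consistent_markers(markers)
        anchored = AnchoredScaffold(
            scaffold_id=scaffold_id,
            lg_id=lg,
            length=layout[scaffold_id].length,
            retained=retained,
            excluded=order_excl,
            layout=layout[scaffold_id],
        )
        anchored.orientation = orient_scaffold(anchored, params, hint)
        per_lg.setdefault(lg, []).append(anchored)

    all_splits: list[SplitRecord] = []
    for lg in list(per_lg):
        ordered = order_scaffolds(per_lg[lg])
        ordered, splits = _resolve_interleavings(ordered, params)
        per_lg[lg] = ordered
        all_splits.extend(splits)

    chromonome, chrom_seqs, agp = build_chromonome(
        per_lg, layout, sequences, params, all_splits, lg_order=gmap.linkage_groups
    )

    retained_markers: list[tuple[str, str, int, float]] = []
    for scaffolds in per_lg.values():
        for s in scaffolds:
            for m in s.retained:
                retained_markers.append((m.marker_id, s.scaffold_id, m.bp, m.cm))
            for m, why in s.excluded:
                excluded.append((m.marker_id, s.scaffold_id, why))

    result = IntegrationResult(
        chromonome=chromonome,
        chromosome_sequences=chrom_seqs,
        chromonome_agp=agp,
        anchored=per_lg,
        retained_markers=retained_markers,
        excluded_markers=excluded,
        splits=all_splits,
    )

    if features is not None:
        from .liftover import build_transform, lift_gff

        transform = build_transform(chromonome)
        result.lifted_features, result.lift_report = lift_gff(transform, features)
    return result
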