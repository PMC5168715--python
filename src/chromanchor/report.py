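"""Assembly statistics, integration summaries, and the RAD-capture
genome-size estimator."""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .formats_io import AssemblyLayout, GapRow
from .integrate import Chromonome, IntegrationResult

__all__ = [
    "AssemblyStats",
    "SizeEstimate",
    "assembly_stats",
    "integration_stats",
    "estimate_genome_size",
    "n50",
]


def n50(lengths: list[int]) -> int:
    """Length of the shortest piece in the smallest set of longest pieces
    covering at least half the total length."""
    if not lengths:
        raise ValueError("n50 of an empty length list")
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if 2 * acc >= total:
            return L
    return min(lengths)  # unreachable


@dataclass(frozen=True)
class AssemblyStats:
    n_scaffolds: int
    total_length: int
    gap_fraction: float
    contig_n50: int
    scaffold_n50: int
    max_scaffold: int


def assembly_stats(layout: AssemblyLayout, min_length: int = 1000) -> AssemblyStats:
    """Scaffold- and contig-level summary over scaffolds >= ``min_length``.

    Contig N50 breaks scaffolds at their AGP gap rows, so it reflects
    gap-free sequence only.
    """
    scaffolds = [s for s in layout.scaffolds.values() if s.length >= min_length]
    if not scaffolds:
        raise ValueError("no scaffolds at or above the minimum length")
    lengths = [s.length for s in scaffolds]
    contig_lengths = [
        r.length for s in scaffolds for r in s.rows if not isinstance(r, GapRow)
    ]
    gap_bp = sum(s.gap_length for s in scaffolds)
    total = sum(lengths)
    return AssemblyStats(
        n_scaffolds=len(scaffolds),
        total_length=total,
        gap_fraction=gap_bp / total,
        contig_n50=n50(contig_lengths),
        scaffold_n50=n50(lengths),
        max_scaffold=max(lengths),
    )


def integration_stats(
    chromonome: Chromonome,
    assembly_length: int,
    n_markers_retained: int,
    n_markers_excluded: int,
) -> dict:
    """Summary of an integration run.

    ``anchored_percent`` is the headline figure, rounded to the nearest
    integer; ``anchored_percent_exact`` keeps full precision.  Anchored bp
    counts chromosome length including spacer gaps, matching how chromonome
    sizes are conventionally reported.
    """
    anchored_bp = sum(chromonome.chromosome_length(c) for c in chromonome.chromosomes)
    sequence_bp = sum(p.length for p in chromonome.placements)
    pct = 100.0 * anchored_bp / assembly_length if assembly_length else 0.0
    placements = chromonome.placements
    return {
        "n_chromosomes": len(chromonome.chromosomes),
        "anchored_bp": anchored_bp,
        "anchored_sequence_bp": sequence_bp,
        "spacer_bp": anchored_bp - sequence_bp,
        "anchored_percent": round(pct),
        "anchored_percent_exact": pct,
        "scaffolds_placed": len({p.scaffold_id for p in placements}),
        "fragments_placed": len(placements),
        "scaffolds_oriented": len(
            {p.scaffold_id for p in placements if p.orientation_known}
        ),
        "scaffolds_split": len({r.root_id for r in chromonome.splits}),
        "n_splits": len(chromonome.splits),
        "scaffolds_unplaced": len(chromonome.unplaced),
        "markers_retained": n_markers_retained,
        "markers_excluded": n_markers_excluded,
    }


@dataclass(frozen=True)
class SizeEstimate:
    """Capture-ratio genome-size estimate from RAD-marker recovery.

    With ``M_total`` mapped markers of which ``M_aligned`` land on the
    assembly, and assuming markers sample the genome uniformly, the
    assembly of length ``A`` captures a fraction ``M_aligned / M_total`` of
    the genome, so ``G_hat = A * M_total / M_aligned`` (a mark-recapture
    style estimator).
    """

    assembly_length: int
    markers_total: int
    markers_aligned: int
    genome_size_estimate: float
    missing_estimate: float
    missing_fraction: float


def estimate_genome_size(
    assembly_length: int, markers_total: int, markers_aligned: int
) -> SizeEstimate:
    if markers_aligned < 1:
        raise ValueError("no aligned markers: the capture ratio is undefined")
    if markers_aligned > markers_total:
        raise ValueError("markers_aligned cannot exceed markers_total")
    g_hat = assembly_length * markers_total / markers_aligned
    missing = g_hat - assembly_length
    return SizeEstimate(
        assembly_length=assembly_length,
        markers_total=markers_total,
        markers_aligned=markers_aligned,
        genome_size_estimate=g_hat,
        missing_estimate=missing,
        missing_fraction=missing / g_hat,
    )
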