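"""Synthetic genomes, scaffolds, RAD markers and genetic maps with truth.

The generator emulates the inputs a map-integration run consumes: a
multi-chromosome genome is fragmented into scaffolds of log-normal length
(draft assemblies have strongly skewed scaffold sizes), scaffolds carry
internal assembly gaps and may be flipped, RAD markers sit on restriction
sites (SbfI by default, whose CCTGCAGG recognition sequence is palindromic,
so a site survives reverse complementation), and cM positions derive
linearly from physical position with optional jitter mimicking genotyping
error.  Chimeric scaffolds are built by fusing two distant loci of the same
chromosome across a junction gap, the misassembly mode that interleaving
detection must find and cut.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .formats_io import (
    AssemblyLayout,
    ContigRow,
    Feature,
    FeatureSet,
    GapRow,
    GeneticMap,
    Marker,
    MarkerAlignment,
    ScaffoldLayout,
    write_agp,
    write_alignments_tsv,
    write_fasta,
    write_genetic_map,
    write_gff,
)
from .integrate import Chromonome, reverse_complement

__all__ = [
    "SimulationParams",
    "TruthSegment",
    "TruthMarker",
    "TruthSet",
    "ReconstructionScore",
    "scan_restriction_sites",
    "simulate_genome",
    "write_inputs",
    "score_reconstruction",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study system.

    Defaults give 3 chromosomes x 2 Mb cut into ~60 scaffolds carrying
    ~300 SbfI-anchored markers, a scale at which every pipeline stage is
    exercised in seconds.
    """

    n_chromosomes: int = 3
    chromosome_length: int = 2_000_000
    scaffold_mean_length: int = 100_000
    scaffold_sigma: float = 0.5       # log-normal shape of scaffold lengths
    min_scaffold_length: int = 5_000
    internal_gap_rate: float = 2.0    # mean assembly gaps per scaffold (Poisson)
    internal_gap_min: int = 20
    internal_gap_max: int = 80
    restriction_motif: str = "CCTGCAGG"
    site_spacing: int = 25_000        # mean distance between planted sites
    cM_per_Mb: float = 25.0
    marker_noise_rate: float = 0.0    # fraction of markers with jittered cM
    chimera_rate: float = 0.0         # fraction of scaffolds fused across loci
    junction_gap: int = 100           # gap placed at a chimeric fusion point
    flip_rate: float = 0.5            # probability a scaffold is reverse-complemented
    genes_per_scaffold: float = 1.0
    seed: int = 42

    def __post_init__(self) -> None:
        for r in (self.marker_noise_rate, self.chimera_rate, self.flip_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if min(self.n_chromosomes, self.chromosome_length, self.scaffold_mean_length) <= 0:
            raise ValueError("counts and lengths must be positive")
        if not self.restriction_motif or set(self.restriction_motif) - set("ACGT"):
            raise ValueError("restriction motif must be non-empty uppercase ACGT")


@dataclass(frozen=True)
class TruthSegment:
    """One true locus of a scaffold (chimeras have two)."""

    chrom: str
    chrom_start: int  # 1-based inclusive on the true chromosome
    chrom_end: int
    scaf_start: int   # 1-based inclusive on the scaffold
    scaf_end: int
    flipped: bool


@dataclass(frozen=True)
class TruthMarker:
    id: str
    scaffold: str
    scaffold_bp: int
    chrom: str
    chrom_bp: int
    true_cm: float
    observed_cm: float
    perturbed: bool


@dataclass
class TruthSet:
    """Ground truth plus the emitted inputs of one simulated study."""

    params: SimulationParams
    chromosome_sequences: dict[str, str]
    scaffold_sequences: dict[str, str]
    scaffold_segments: dict[str, list[TruthSegment]]
    markers: list[TruthMarker]
    chimera_junctions: list[tuple[str, int, int]]  # scaffold, gap start/end (1-based)
    genetic_map: GeneticMap = None  # type: ignore[assignment]
    layout: AssemblyLayout = None   # type: ignore[assignment]
    alignments: list[MarkerAlignment] = field(default_factory=list)
    features: FeatureSet = field(default_factory=FeatureSet)

    def lg_of_chrom(self, chrom: str) -> str:
        return "LG" + chrom.removeprefix("chr")


def scan_restriction_sites(seq: str, motif: str) -> list[int]:
    """1-based start positions of exact motif matches on the forward strand.

    Ambiguity codes never match.  For a palindromic motif (SbfI's CCTGCAGG)
    the forward-strand scan already counts both strands' sites.
    """
    if not motif:
        raise ValueError("restriction motif must be non-empty")
    out: list[int] = []
    i = seq.find(motif)
    while i != -1:
        out.append(i + 1)
        i = seq.find(motif, i + 1)
    return out


def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _make_chromosome(rng: np.random.Generator, p: SimulationParams) -> str:
    """Random chromosome with restriction sites planted at ~site_spacing."""
    arr = _random_sequence(rng, p.chromosome_length)
    motif = np.frombuffer(p.restriction_motif.encode(), dtype=np.uint8)
    pos = int(rng.integers(p.site_spacing // 2, p.site_spacing))
    while pos + len(motif) < p.chromosome_length:
        arr[pos : pos + len(motif)] = motif
        pos += int(rng.integers(p.site_spacing // 2, p.site_spacing * 3 // 2))
    return arr.tobytes().decode()


def _scaffold_lengths(rng: np.random.Generator, p: SimulationParams) -> list[int]:
    """Log-normal scaffold lengths tiling one chromosome."""
    mu = np.log(p.scaffold_mean_length) - p.scaffold_sigma**2 / 2
    lengths: list[int] = []
    total = 0
    while total < p.chromosome_length:
        L = int(rng.lognormal(mu, p.scaffold_sigma))
        L = max(L, p.min_scaffold_length)
        L = min(L, p.chromosome_length - total)
        lengths.append(L)
        total += L
    # avoid a terminal sliver shorter than the minimum
    if len(lengths) > 1 and lengths[-1] < p.min_scaffold_length:
        lengths[-2] += lengths.pop()
    return lengths


def _insert_gaps(rng: np.random.Generator, seq: list[str], p: SimulationParams) -> None:
    """Replace a few interior stretches with N runs (assembly gaps)."""
    n = int(rng.poisson(p.internal_gap_rate))
    L = len(seq)
    margin = 500
    if L <= 2 * margin:
        return
    taken: list[tuple[int, int]] = []
    for _ in range(n):
        glen = int(rng.integers(p.internal_gap_min, p.internal_gap_max + 1))
        start = int(rng.integers(margin, L - margin - glen))
        if any(start < e + 10 and s - 10 < start + glen for s, e in taken):
            continue
        seq[start : start + glen] = ["N"] * glen
        taken.append((start, start + glen))


def _layout_from_sequence(scaffold_id: str, seq: str) -> ScaffoldLayout:
    """Derive AGP rows by run-length scanning the N gaps of a sequence."""
    rows: list = []
    n_ctg = 0
    i = 0
    L = len(seq)
    while i < L:
        if seq[i] == "N":
            j = i
            while j < L and seq[j] == "N":
                j += 1
            glen = j - i
            ctype = "U" if glen == 100 else "N"
            rows.append(GapRow(i, j, ctype, "scaffold", "yes", "paired-ends"))
            i = j
        else:
            j = i
            while j < L and seq[j] != "N":
                j += 1
            n_ctg += 1
            rows.append(ContigRow(i, j, f"{scaffold_id}_ctg{n_ctg}", 1, j - i, "+"))
            i = j
    lay = ScaffoldLayout(scaffold_id, L, rows)
    lay.validate()
    return lay


def simulate_genome(params: SimulationParams | None = None) -> TruthSet:
    """Generate a full input bundle (map, AGP, alignments, FASTA, GFF3)
    together with the ground truth needed to score a reconstruction."""
    p = params or SimulationParams()
    rng = np.random.default_rng(p.seed)
    m = len(p.restriction_motif)

    chroms = {f"chr{i + 1}": _make_chromosome(rng, p) for i in range(p.n_chromosomes)}

    # ---- cut chromosomes into scaffolds -------------------------------
    raw: list[dict] = []  # per scaffold: chrom, start0, end0, flipped, seq(list)
    per_chrom_index: dict[str, list[int]] = {c: [] for c in chroms}
    for chrom, seq in chroms.items():
        pos = 0
        for L in _scaffold_lengths(rng, p):
            flipped = bool(rng.random() < p.flip_rate)
            raw.append({"chrom": chrom, "start0": pos, "end0": pos + L, "flipped": flipped})
            per_chrom_index[chrom].append(len(raw) - 1)
            pos += L

    # ---- choose chimeric fusions --------------------------------------
    n_chim = int(round(p.chimera_rate * len(raw)))
    fused_pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    chrom_cycle = sorted(per_chrom_index, key=lambda c: -len(per_chrom_index[c]))
    attempts = 0
    while len(fused_pairs) < n_chim and attempts < 10 * max(1, n_chim):
        attempts += 1
        chrom = chrom_cycle[attempts % len(chrom_cycle)]
        idxs = [i for i in per_chrom_index[chrom] if i not in used]
        if len(idxs) < 4:
            continue
        ai = int(rng.integers(0, len(idxs) - 2))
        bi = int(rng.integers(ai + 2, len(idxs)))
        a, b = idxs[ai], idxs[bi]
        fused_pairs.append((a, b))
        used.update((a, b))

    # ---- materialise scaffold sequences -------------------------------
    scaffold_sequences: dict[str, str] = {}
    scaffold_segments: dict[str, list[TruthSegment]] = {}
    chimera_junctions: list[tuple[str, int, int]] = []

    def _piece(i: int, force_forward: bool = False) -> tuple[list[str], TruthSegment]:
        r = raw[i]
        flipped = r["flipped"] and not force_forward
        s = chroms[r["chrom"]][r["start0"] : r["end0"]]
        if flipped:
            s = reverse_complement(s)
        seg = TruthSegment(r["chrom"], r["start0"] + 1, r["end0"], 1, len(s), flipped)
        return list(s), seg

    fused_members = {i for pair in fused_pairs for i in pair}
    counter = 0
    for i, r in enumerate(raw):
        if i in fused_members:
            continue
        counter += 1
        sid = f"scaffold{counter}"
        seq, seg = _piece(i)
        _insert_gaps(rng, seq, p)
        scaffold_sequences[sid] = "".join(seq)
        scaffold_segments[sid] = [seg]
    for k, (a, b) in enumerate(fused_pairs, start=1):
        sid = f"chimera{k}"
        seq_a, seg_a = _piece(a, force_forward=True)
        seq_b, seg_b = _piece(b, force_forward=True)
        _insert_gaps(rng, seq_a, p)
        _insert_gaps(rng, seq_b, p)
        la = len(seq_a)
        seq = "".join(seq_a) + "N" * p.junction_gap + "".join(seq_b)
        off = la + p.junction_gap
        scaffold_sequences[sid] = seq
        scaffold_segments[sid] = [
            TruthSegment(seg_a.chrom, seg_a.chrom_start, seg_a.chrom_end, 1, la, False),
            TruthSegment(
                seg_b.chrom, seg_b.chrom_start, seg_b.chrom_end,
                off + 1, off + len(seq_b), False,
            ),
        ]
        chimera_junctions.append((sid, la + 1, la + p.junction_gap))

    layout = AssemblyLayout(
        {sid: _layout_from_sequence(sid, s) for sid, s in scaffold_sequences.items()}
    )
    layout.validate()

    # ---- markers at restriction sites ---------------------------------
    chrom_cm_span = (p.chromosome_length - 1) * p.cM_per_Mb / 1e6
    markers: list[TruthMarker] = []
    mid = 0
    for sid in scaffold_sequences:
        seq = scaffold_sequences[sid]
        for pos in scan_restriction_sites(seq, p.restriction_motif):
            seg = next(
                (g for g in scaffold_segments[sid] if g.scaf_start <= pos <= g.scaf_end),
                None,
            )
            if seg is None or pos + m - 1 > seg.scaf_end:
                continue
            if seg.flipped:
                chrom_bp = seg.chrom_end - (pos - seg.scaf_start) - (m - 1)
            else:
                chrom_bp = seg.chrom_start + (pos - seg.scaf_start)
            true_cm = round((chrom_bp - 1) * p.cM_per_Mb / 1e6, 4)
            perturbed = bool(rng.random() < p.marker_noise_rate)
            observed = round(float(rng.uniform(0.0, chrom_cm_span)), 4) if perturbed else true_cm
            mid += 1
            markers.append(
                TruthMarker(f"mk{mid:05d}", sid, pos, seg.chrom, chrom_bp, true_cm, observed, perturbed)
            )

    gmap = GeneticMap(
        [Marker(t.id, "LG" + t.chrom.removeprefix("chr"), t.observed_cm) for t in markers]
    )
    alignments = [
        MarkerAlignment(t.id, t.scaffold, t.scaffold_bp, "+", 0, 0, 1.0) for t in markers
    ]

    # ---- toy annotations for liftover testing -------------------------
    feats: list[Feature] = []
    gn = 0
    for sid, seq in scaffold_sequences.items():
        L = len(seq)
        n_genes = int(rng.poisson(p.genes_per_scaffold))
        for _ in range(n_genes):
            if L < 2_000:
                break
            g0 = int(rng.integers(1, L - 1_000))
            gn += 1
            gid = f"gene{gn}"
            feats.append(
                Feature(sid, "sim", "gene", g0, g0 + 999, ".", "+", ".", [("ID", gid)])
            )
            feats.append(
                Feature(sid, "sim", "mRNA", g0, g0 + 999, ".", "+", ".",
                        [("ID", f"{gid}.t1"), ("Parent", gid)])
            )
            for e, (a, b) in enumerate(((g0, g0 + 399), (g0 + 600, g0 + 999)), start=1):
                feats.append(
                    Feature(sid, "sim", "exon", a, b, ".", "+", ".",
                            [("ID", f"{gid}.t1.e{e}"), ("Parent", f"{gid}.t1")])
                )
    features = FeatureSet(feats)

    return TruthSet(
        params=p,
        chromosome_sequences=chroms,
        scaffold_sequences=scaffold_sequences,
        scaffold_segments=scaffold_segments,
        markers=markers,
        chimera_junctions=chimera_junctions,
        genetic_map=gmap,
        layout=layout,
        alignments=alignments,
        features=features,
    )


def write_inputs(truth: TruthSet, out_dir) -> dict[str, Path]:
    """Emit the simulated input bundle (plus truth.json) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "map": out / "map.tsv",
        "agp": out / "scaffolds.agp",
        "fasta": out / "scaffolds.fa",
        "alignments": out / "markers.tsv",
        "gff": out / "genes.gff3",
        "truth": out / "truth.json",
    }
    write_genetic_map(truth.genetic_map, paths["map"])
    write_agp(truth.layout, paths["agp"])
    write_fasta(truth.scaffold_sequences, paths["fasta"])
    write_alignments_tsv(truth.alignments, paths["alignments"])
    write_gff(truth.features, paths["gff"])
    blob = {
        "params": asdict(truth.params),
        "scaffold_segments": {
            sid: [asdict(s) for s in segs] for sid, segs in truth.scaffold_segments.items()
        },
        "markers": [asdict(t) for t in truth.markers],
        "chimera_junctions": truth.chimera_junctions,
    }
    paths["truth"].write_text(json.dumps(blob, indent=1))
    return paths


# ---------------------------------------------------------------------------
# Scoring a reconstruction against the truth
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionScore:
    anchored_fraction: float
    order_correlation_mean: float
    order_correlation_min: float
    orientation_accuracy: float
    n_orientable: int
    n_true_junctions: int
    n_cuts_in_junction_gap: int
    split_distances: list[float]


def _true_position(truth: TruthSet, scaffold_id: str, lo: int, hi: int) -> float | None:
    """Mean true chromosome bp of truth markers inside [lo, hi] on a scaffold."""
    pos = [t.chrom_bp for t in truth.markers if t.scaffold == scaffold_id and lo <= t.scaffold_bp <= hi]
    return float(np.mean(pos)) if pos else None


def score_reconstruction(truth: TruthSet, chromonome: Chromonome) -> ReconstructionScore:
    """Compare an integration result with the simulation's ground truth.

    Order is scored as the Spearman correlation, per chromosome, between
    placement rank and the placements' true physical positions; orientation
    accuracy is taken over placements whose markers span at least two
    distinct observed cM positions (the orientable ones); each true chimera
    junction is checked for a cut inside its junction gap.
    """
    truth_ids = set(truth.scaffold_sequences)
    seen = {p.scaffold_id for p in chromonome.placements} | set(chromonome.unplaced)
    if not seen <= truth_ids:
        raise ValueError("reconstruction references scaffolds outside the simulated universe")

    total_bp = sum(len(s) for s in truth.scaffold_sequences.values())
    anchored_bp = sum(p.source_end - p.source_start + 1 for p in chromonome.placements)

    cors: list[float] = []
    for chrom, placements in chromonome.chromosomes.items():
        pos = [
            _true_position(truth, p.scaffold_id, p.source_start, p.source_end)
            for p in placements
        ]
        pos = [x for x in pos if x is not None]
        if len(pos) < 3:
            continue
        rho = sps.spearmanr(range(len(pos)), pos).statistic
        cors.append(float(rho))
    order_mean = float(np.mean(cors)) if cors else float("nan")
    order_min = float(np.min(cors)) if cors else float("nan")

    n_orient = 0
    n_correct = 0
    for p in chromonome.placements:
        mks = [
            t
            for t in truth.markers
            if t.scaffold == p.scaffold_id and p.source_start <= t.scaffold_bp <= p.source_end
        ]
        if len({t.observed_cm for t in mks}) < 2:
            continue
        segs = [
            s
            for s in truth.scaffold_segments[p.scaffold_id]
            if s.scaf_start <= p.source_start and p.source_end <= s.scaf_end
        ]
        if not segs:
            continue
        n_orient += 1
        if (p.orientation == "-") == segs[0].flipped:
            n_correct += 1
    orientation_accuracy = n_correct / n_orient if n_orient else float("nan")

    dists: list[float] = []
    n_in_gap = 0
    for sid, gs, ge in truth.chimera_junctions:
        cuts = [r for r in chromonome.splits if r.root_id == sid]
        if not cuts:
            dists.append(float("inf"))
            continue
        best = float("inf")
        for r in cuts:
            if r.cut_start <= ge and r.cut_end >= gs:
                best = 0.0
                break
            mid = (r.cut_start + r.cut_end) / 2
            best = min(best, min(abs(mid - gs), abs(mid - ge)))
        if best == 0.0:
            n_in_gap += 1
        dists.append(best)

    return ReconstructionScore(
        anchored_fraction=anchored_bp / total_bp if total_bp else 0.0,
        order_correlation_mean=order_mean,
        order_correlation_min=order_min,
        orientation_accuracy=orientation_accuracy,
        n_orientable=n_orient,
        n_true_junctions=len(truth.chimera_junctions),
        n_cuts_in_junction_gap=n_in_gap,
        split_distances=dists,
    )
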