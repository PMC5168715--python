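# Methods

## Model and assumptions

The integration treats a genetic linkage map as an ordering oracle for
assembly scaffolds. Its assumptions are the standard ones for map-guided
anchoring:

- a linkage group corresponds to one chromosome, and cM position increases
  monotonically along it (the map may be noisy marker-by-marker, but its
  large-scale order is trusted over the assembly's joins);
- markers identify unique genomic sites: multi-mapping markers carry no
  placement information and are discarded rather than arbitrated;
- co-segregating markers legitimately share a cM position (an F1 map has
  finite resolution), so monotonicity is tested as non-decreasing, not
  strictly increasing;
- a within-scaffold conflict between bp order and cM order is genotyping
  or mapping error when isolated (the marker is dropped), and a
  misassembly when a *different* scaffold maps inside the gap (the
  scaffold is split).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_mismatch_score` | 5 | mismatch budget per marker alignment |
| `gap_penalty` | 4 | mismatch-equivalents charged per gap open |
| `min_coverage` | 0.99 | fraction of the marker that must align |
| `spacer_gap` | 100 bp | N run placed between joined fragments (emitted as AGP `U` gaps, `gap_type contig`, `linkage yes`, `evidence map`) |
| `min_orient_positions` | 2 | distinct cM positions required to call orientation |

The alignment thresholds are the conventional short-read RAD-tag settings
for this task; the 100 bp spacer is the standard unknown-size join.

## Algorithmic choices

**Marker selection.** The maximum monotone subsequence is found by an
O(n²) dynamic program over markers in bp order (scaffolds carry tens of
markers, so asymptotics are irrelevant; the property suite checks the DP
against exhaustive enumeration up to 12 markers). Two deliberate
tie-breaks make the output deterministic: among equal-size optima the
lexicographically earliest index set is retained (earlier-bp markers win),
and when the non-decreasing and non-increasing optima tie in size the
non-decreasing set is kept with orientation left unknown. A scaffold's
final marker is never excluded — with nothing retained the scaffold would
silently fall out of the map — and if selection could ever return an empty
set the marker nearest the median bp is kept as the anchor of last resort.

**Linkage-group conflicts.** Majority vote per scaffold; an exact tie
leaves the scaffold unplaced rather than guessing. Resolving such ties
properly needs outside evidence (e.g. conserved synteny), which is out of
scope, so the tool fails safe.

**Ordering.** Scaffolds are ordered by the mean cM of retained markers —
robust to one residual misplaced marker, unlike min or first — with ties
broken by descending length then id, so identical inputs always produce
identical output.

**Interleaving and splitting.** A split is requested only when another
scaffold's entire map span falls strictly between two successive retained
markers of a host; a guest at the host's boundary cM is placed adjacent
instead. The cut goes through the largest AGP gap strictly between the
bracketing markers (gap bases are dropped and logged); with no gap
available the cut falls at the bp midpoint between the markers and the
split record carries a low-confidence flag. Splits are applied one per
round and re-detected, so nested interleavings resolve iteratively with a
hard round cap.

**Coordinates.** External formats are 1-based inclusive (AGP/GFF/SAM);
internal interval arithmetic is 0-based half-open and converted at the I/O
boundary, which keeps reverse-complement index algebra single-sourced in
one helper. Liftover of an interval on a `-` fragment of length L at
offset o maps [a, b] to [o + L − b + 1, o + L − a + 1] with the strand
flipped; `.` and `?` strands pass through. Features crossing a split cut
are emitted as parts sharing a `split_of` tag (lossless provenance) and a
truncated CDS has its phase cleared to `.` because the reading frame can
no longer be asserted.

## Synthetic data

The generator emulates the input bundle of a real map-integration run at
desk scale — defaults: 3 chromosomes × 2 Mb, log-normal scaffolds of mean
100 kb (draft assemblies' scaffold lengths are strongly right-skewed),
0–few internal 20–80 bp assembly gaps per scaffold, restriction-site
markers planted every ~25 kb (SbfI motif CCTGCAGG, palindromic, so sites
survive reverse complementation) plus naturally occurring motif hits,
~330 markers in all. cM is linear in bp (constant cM/Mb, default 25 so a
2 Mb toy chromosome spans a realistic ~50 cM); recombination interference
adds nothing to testing order logic. Map noise replaces a marker's cM
with a uniform draw over its linkage group's span — deliberately
unambiguous misplacement. Chimeras fuse two distant segments of the same
chromosome across a 100 bp junction gap; internal gaps are drawn smaller
than the junction so the largest-gap rule is testable against a known
answer, and cross-linkage-group fusions are not generated because the
majority vote absorbs rather than splits them.

What the simulation does *not* model: alignment error (alignments are
emitted perfect and unique; the filter logic is tested separately at unit
level), repeat-induced multi-mapping, structured genotyping error (map
noise is independent per marker), marker density variation, and gap-length
misestimation. Passing recovery tests therefore demonstrates the
correctness of the ordering/orientation/splitting logic under the stated
noise model, not robustness to every pathology of real RAD data.

Problem sizes throughout (simulations, property-test depths, the 1000
random liftover intervals, exhaustive selector enumeration to 7 markers
with 3 cM levels plus randomized checks to 12) were chosen so the whole
suite completes in seconds while still exercising every code path,
including multi-fragment splits and reverse-complement placements.

## Genome-size estimator

With M_total mapped markers, M_aligned of which land on an assembly of
length A, uniform marker sampling gives the capture fraction
M_aligned/M_total, hence `G_hat = A · M_total / M_aligned` — a
mark-recapture estimator. The raw counts are exposed on the result object
so per-scaffold-density variants can be substituted. The estimator is
scale-invariant in A and undefined at zero captures (an error, not a
sentinel). Repetitive sequence invisible to both the markers and the
assembly is outside what the capture ratio can see, so the estimate bounds
non-repetitive missing sequence only.

## Known limitations

- Orientation of scaffolds with a single distinct map position is
  unknowable from the map; they are emitted forward and flagged, never
  counted as oriented.
- Scaffold order within a shared cM bin is length/id-determined, not
  biologically informed; synteny-aware tie-breaking would need orthology
  input the tool does not consume.
- The midpoint split fallback can cut through a contig; it is flagged
  low-confidence precisely because there is no assembly evidence for the
  breakpoint.
- GFF hierarchy violations warn rather than fail: liftover is per-feature
  and does not depend on a consistent gene tree.
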