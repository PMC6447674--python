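"""Chimeric-contig detection, breakpoint refinement, and contig breaking.

A contig carrying map markers from two or more linkage groups is a
chimera candidate.  The junction is narrowed with read-depth and
mate-pair clone-coverage evidence; candidates whose minority markers are
all repetitive are downgraded to false signals; confirmed contigs are
broken.  Whole-genome alignment against a trusted reference catches the
intra-chromosomal joins that linkage maps cannot see.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from statistics import median

import numpy as np
from intervaltree import IntervalTree

from .io import Track
from .model import (
    ContigSet,
    MarkerRecord,
    RepeatAnnotation,
    SegmentMap,
    SyntenyBlock,
    ValidationError,
)


@dataclass
class LgPartition:
    """Markers of one linkage group on one contig, spanning an interval."""

    lg: str
    marker_count: int
    span: tuple[int, int]  # (min marker pos, max marker pos)
    marker_ids: tuple[str, ...] = ()


@dataclass
class ChimeraCandidate:
    """A contig whose markers split across >= 2 linkage groups.

    ``partitions`` are ordered by median marker position along the contig;
    ``junction_search_intervals`` holds one bp interval per adjacent
    partition pair (a single interval for the common two-partition case,
    exposed as ``junction_search_interval``).
    """

    contig: str
    partitions: list[LgPartition]
    junction_search_intervals: list[tuple[int, int]]
    status: str = "candidate"  # candidate | confirmed | repeat_false_signal | unresolved

    @property
    def junction_search_interval(self) -> tuple[int, int]:
        return self.junction_search_intervals[0]

    @property
    def lgs(self) -> list[str]:
        return [p.lg for p in self.partitions]


@dataclass(frozen=True)
class Breakpoint:
    contig: str
    position: int
    evidence: frozenset = frozenset()
    flagged: bool = False  # True when only the midpoint fallback was available


def detect_chimeric_contigs(
    markers: list[MarkerRecord], min_markers_per_lg: int = 1
) -> list[ChimeraCandidate]:
    """One candidate per contig with >= 2 linkage groups each supported by
    >= ``min_markers_per_lg`` markers.  Output is invariant to marker row
    order; contigs come back sorted by name.
    """
    by_contig: dict[str, list[MarkerRecord]] = {}
    for m in markers:
        by_contig.setdefault(m.contig, []).append(m)
    candidates: list[ChimeraCandidate] = []
    for contig in sorted(by_contig):
        ms = sorted(by_contig[contig], key=lambda m: (m.contig_pos, m.marker_id))
        by_lg: dict[str, list[MarkerRecord]] = {}
        for m in ms:
            by_lg.setdefault(m.lg, []).append(m)
        kept = {lg: v for lg, v in by_lg.items() if len(v) >= min_markers_per_lg}
        if len(kept) < 2:
            continue
        parts = [
            LgPartition(
                lg=lg,
                marker_count=len(v),
                span=(v[0].contig_pos, v[-1].contig_pos),
                marker_ids=tuple(m.marker_id for m in v),
            )
            for lg, v in kept.items()
        ]
        parts.sort(key=lambda p: (median(s for s in p.span), p.lg))
        intervals = []
        for left, right in zip(parts, parts[1:]):
            lo, hi = left.span[1], right.span[0]
            if hi <= lo:  # interleaved spans: fall back to the overlap bounds
                lo, hi = min(hi, lo), max(hi, lo) + 1
            intervals.append((lo, hi))
        candidates.append(
            ChimeraCandidate(contig=contig, partitions=parts, junction_search_intervals=intervals)
        )
    return candidates


def _zero_runs(vec: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zeros as (start_bin, end_bin) half-open."""
    iszero = np.concatenate(([0], (vec == 0).astype(np.int8), [0]))
    diff = np.diff(iszero)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts, ends))


def refine_breakpoint(
    candidate: ChimeraCandidate,
    depth: Track,
    clone: Track,
    dip_fraction: float = 0.5,
    min_clone_gap: int = 1_000,
) -> list[Breakpoint]:
    """Refine each junction interval to a breakpoint using evidence tracks.

    The depth-dip argmin wins when the minimum depth inside the interval
    is <= ``dip_fraction`` x the contig-median depth; otherwise a zero
    clone-coverage run of >= ``min_clone_gap`` bp overlapping the interval
    places the breakpoint at the run midpoint.  When neither fires the
    interval midpoint is returned flagged and the candidate is left
    unresolved.  Updates ``candidate.status``.
    """
    contig = candidate.contig
    if contig not in depth.data or contig not in clone.data:
        raise ValidationError(f"tracks do not cover contig {contig}")
    contig_bp = len(depth.data[contig]) * depth.bin_width
    breakpoints: list[Breakpoint] = []
    all_confirmed = True
    for lo, hi in candidate.junction_search_intervals:
        if not (0 <= lo < hi <= contig_bp):
            raise ValidationError(
                f"junction interval ({lo}, {hi}) outside contig {contig} (len {contig_bp})"
            )
        evidence = {"marker_partition"}
        dvec = depth.slice(contig, lo, hi)
        med = depth.median(contig)
        argmin = int(np.argmin(dvec))
        pos = None
        if dvec[argmin] <= dip_fraction * med:
            evidence.add("depth_dip")
            pos = lo // depth.bin_width * depth.bin_width + argmin * depth.bin_width
            pos += depth.bin_width // 2
        # clone gaps recorded as evidence even when depth positions the break
        cvec = clone.data[contig]
        bw = clone.bin_width
        for b0, b1 in _zero_runs(cvec):
            if (b1 - b0) * bw >= min_clone_gap and b0 * bw < hi and b1 * bw > lo:
                evidence.add("clone_gap")
                if pos is None:
                    pos = (b0 + b1) // 2 * bw + bw // 2
                break
        flagged = False
        if pos is None:
            pos = (lo + hi) // 2
            flagged = True
            all_confirmed = False
        breakpoints.append(
            Breakpoint(contig=contig, position=int(pos), evidence=frozenset(evidence), flagged=flagged)
        )
    candidate.status = "confirmed" if all_confirmed else "unresolved"
    return breakpoints


def classify_candidate(
    candidate: ChimeraCandidate,
    repeats: list[RepeatAnnotation],
    markers: list[MarkerRecord] | None = None,
) -> ChimeraCandidate:
    """Downgrade candidates whose minority markers are all repetitive.

    When every marker of every minority partition (all but the
    best-supported linkage group) lies inside a repeat annotation on the
    contig, or carries a non-unique placement flag, the signal is a
    repeat artifact and the status becomes ``repeat_false_signal``.
    Mixed evidence keeps the candidate (conservative).
    """
    tree = IntervalTree()
    for r in repeats:
        if r.chrom == candidate.contig:
            tree.addi(r.start, r.end)
    non_unique = {
        m.marker_id for m in (markers or []) if not m.unique_placement
    }
    marker_pos = {m.marker_id: m.contig_pos for m in (markers or []) if m.contig == candidate.contig}
    majority = max(candidate.partitions, key=lambda p: (p.marker_count, p.span[1] - p.span[0]))
    all_repetitive = True
    for part in candidate.partitions:
        if part is majority:
            continue
        for mid in part.marker_ids:
            if mid in non_unique:
                continue
            pos = marker_pos.get(mid)
            if pos is not None and tree.overlaps(pos, pos + 1):
                continue
            all_repetitive = False
    if all_repetitive:
        candidate.status = "repeat_false_signal"
    return candidate


def detect_alignment_misassembly(
    contig_blocks: list[SyntenyBlock], max_jump: int = 2_000_000
) -> list[ChimeraCandidate]:
    """Intra-chromosomal misassembly from alignment against a trusted reference.

    Blocks are taken in contig (query) order.  A candidate junction is
    emitted wherever consecutive blocks switch reference chromosome, jump
    more than ``max_jump`` on the reference, or violate within-strand
    monotonicity (forward runs must advance, reverse runs must retreat) —
    a clean single strand flip with collinear coordinates is an inversion,
    not a misassembly.
    """
    blocks = sorted(contig_blocks, key=lambda b: b.query_start)
    candidates: list[ChimeraCandidate] = []
    for left, right in zip(blocks, blocks[1:]):
        suspicious = False
        if left.ref_chrom != right.ref_chrom:
            suspicious = True
        else:
            separation = max(
                right.ref_start - left.ref_end, left.ref_start - right.ref_end, 0
            )
            if separation > max_jump:
                suspicious = True
            elif left.strand == right.strand:
                if left.strand == "+" and right.ref_mid < left.ref_mid - max_jump:
                    suspicious = True
                if left.strand == "-" and right.ref_mid > left.ref_mid + max_jump:
                    suspicious = True
        if suspicious:
            parts = [
                LgPartition(lg=left.ref_chrom, marker_count=1, span=(left.query_start, left.query_end)),
                LgPartition(lg=right.ref_chrom, marker_count=1, span=(right.query_start, right.query_end)),
            ]
            lo, hi = left.query_end, right.query_start
            if hi <= lo:
                lo, hi = min(lo, hi), max(lo, hi) + 1
            candidates.append(
                ChimeraCandidate(
                    contig=left.query_chrom,
                    partitions=parts,
                    junction_search_intervals=[(lo, hi)],
                )
            )
    return candidates


def break_contigs(
    contigs: ContigSet, breakpoints: list[Breakpoint]
) -> tuple[ContigSet, SegmentMap]:
    """Split contigs at confirmed breakpoints.

    Parts are named ``<id>_1, <id>_2, ...`` left to right; total bp is
    conserved.  The returned liftover maps old (contig, pos) to the new
    parts for markers and annotations.  Duplicate positions are collapsed
    with a warning.
    """
    by_contig: dict[str, list[int]] = {}
    for bp in breakpoints:
        if bp.contig not in contigs:
            raise ValidationError(f"breakpoint on unknown contig {bp.contig}")
        if not (0 < bp.position < contigs.lengths[bp.contig]):
            raise ValidationError(
                f"breakpoint {bp.position} outside contig {bp.contig}"
            )
        by_contig.setdefault(bp.contig, []).append(bp.position)

    lengths: dict[str, int] = {}
    sequences: dict[str, str] = {}
    have_seq = bool(contigs.sequences)
    liftover = SegmentMap()
    for contig, L in contigs.lengths.items():
        cuts = sorted(set(by_contig.get(contig, ())))
        if contig in by_contig and len(cuts) < len(by_contig[contig]):
            warnings.warn(f"duplicate breakpoints on {contig} collapsed", stacklevel=2)
        if not cuts:
            lengths[contig] = L
            if have_seq and contig in contigs.sequences:
                sequences[contig] = contigs.sequence(contig)
            liftover.add(contig, 0, L, contig, 0)
            continue
        bounds = [0, *cuts, L]
        for i, (s, e) in enumerate(zip(bounds, bounds[1:]), start=1):
            name = f"{contig}_{i}"
            lengths[name] = e - s
            if have_seq and contig in contigs.sequences:
                sequences[name] = contigs.sequence(contig)[s:e]
            liftover.add(contig, s, e, name, 0)
    out = ContigSet(sequences=sequences or None, lengths=lengths)
    assert out.total_bp == contigs.total_bp, "breaking must conserve bp"
    return out, liftover.freeze()
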