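"""Shared domain types.

All coordinates are 0-based half-open internally.  Dialects that use
1-based inclusive coordinates (AGP, nucmer show-coords) are converted at
the I/O boundary and never leak inward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class FormatError(ValueError):
    """A file does not parse under the expected dialect."""


@dataclass(frozen=True)
class MarkerRecord:
    """One genetic-map marker with its linkage-group and contig placement.

    ``pos_cM`` is the sex-averaged map position in centimorgans;
    ``female_cM``/``male_cM`` are optional sex-specific positions.
    ``contig_pos`` is the 0-based bp offset of the marker on ``contig``.
    ``unique_placement`` is False for markers whose flanking sequence
    aligned to multiple locations (repetitive markers).
    """

    marker_id: str
    lg: str
    pos_cM: float
    contig: str
    contig_pos: int
    strand: str = "?"
    female_cM: float | None = None
    male_cM: float | None = None
    unique_placement: bool = True

    def __post_init__(self) -> None:
        if self.pos_cM < 0:
            raise ValidationError(
                f"marker {self.marker_id}: pos_cM must be >= 0, got {self.pos_cM}"
            )
        if self.contig_pos < 0:
            raise ValidationError(
                f"marker {self.marker_id}: contig_pos must be >= 0"
            )
        if self.strand not in ("+", "-", "?"):
            raise ValidationError(
                f"marker {self.marker_id}: strand must be one of + - ?"
            )


class ContigSet:
    """A set of contig sequences, or length-only stubs for large genomes.

    ``sequences`` maps contig_id -> str for contigs with sequence; every
    contig has an entry in ``lengths``.
    """

    def __init__(
        self,
        sequences: Mapping[str, str] | None = None,
        lengths: Mapping[str, int] | None = None,
    ) -> None:
        self.sequences: dict[str, str] = dict(sequences or {})
        self.lengths: dict[str, int] = {k: len(v) for k, v in self.sequences.items()}
        if lengths:
            for cid, n in lengths.items():
                if cid in self.lengths and self.lengths[cid] != n:
                    raise ValidationError(
                        f"contig {cid}: sequence length {self.lengths[cid]} != stated {n}"
                    )
                self.lengths[cid] = int(n)
        for cid, n in self.lengths.items():
            if n <= 0:
                raise ValidationError(f"contig {cid}: length must be > 0")

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())

    def __len__(self) -> int:
        return len(self.lengths)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.lengths

    def __iter__(self):
        return iter(self.lengths)

    def sequence(self, contig_id: str) -> str:
        try:
            return self.sequences[contig_id]
        except KeyError:
            raise KeyError(f"contig {contig_id} has no stored sequence") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, ContigSet):
            return NotImplemented
        return self.lengths == other.lengths and self.sequences == other.sequences

    def __repr__(self) -> str:
        return f"ContigSet(n={len(self)}, total_bp={self.total_bp})"


@dataclass(frozen=True)
class AlignmentRecord:
    """One whole-genome alignment segment (reference always forward).

    Internal coordinates are 0-based half-open.  The strand is carried on
    the query interval: for '-' records the query interval is stored
    forward (start < end) and ``strand`` records the flip.
    """

    ref_chrom: str
    query_chrom: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    pct_identity: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (self.ref_start < self.ref_end and self.query_start < self.query_end):
            raise ValidationError("alignment intervals must be non-degenerate")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValidationError("pct_identity must lie in [0, 100]")
        if self.strand not in ("+", "-"):
            raise ValidationError("strand must be + or -")

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def query_len(self) -> int:
        return self.query_end - self.query_start


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repeat-masked interval with class/family and % divergence."""

    chrom: str
    start: int
    end: int
    family: str
    class_name: str
    divergence_pct: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"repeat {self.family}@{self.chrom}: end must exceed start"
            )
        if self.divergence_pct < 0:
            raise ValidationError("divergence_pct must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene with sorted, non-overlapping exons within [start, end)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValidationError(f"gene {self.gene_id}: exon outside gene body")
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start (0-based position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class AgpComponent:
    """One AGP v2.1 row: a contig or gap tiling part of an object.

    ``object_start``/``object_end`` follow the AGP convention (1-based
    inclusive) because the type mirrors the file row; conversion happens
    only when mapping onto internal intervals.
    """

    object_id: str
    object_start: int
    object_end: int
    part_number: int
    kind: str  # "contig" | "gap"
    component_id: str | None = None
    component_orientation: str = "?"
    gap_length: int | None = None
    gap_type: str = "scaffold"
    linkage_evidence: str = "paired-ends"

    def __post_init__(self) -> None:
        if self.kind not in ("contig", "gap"):
            raise ValidationError("AGP component kind must be 'contig' or 'gap'")
        if self.object_end < self.object_start:
            raise ValidationError("AGP object_end < object_start")
        if self.kind == "gap":
            expect = self.object_end - self.object_start + 1
            if self.gap_length != expect:
                raise ValidationError(
                    f"gap row length {self.gap_length} != span {expect}"
                )
        else:
            if self.component_id is None:
                raise ValidationError("contig row requires component_id")
            if self.component_orientation not in ("+", "-", "?"):
                raise ValidationError("orientation must be + - ?")

    @property
    def span(self) -> int:
        return self.object_end - self.object_start + 1


class AnchoredAssembly:
    """Ordered, oriented contigs per linkage group plus unanchored contigs.

    ``components`` maps LG id -> list of AgpComponent tiling that LG.
    """

    def __init__(
        self,
        components: Mapping[str, list[AgpComponent]],
        unanchored: Iterable[str] = (),
        gap_length: int = 100,
        total_bp: int | None = None,
    ) -> None:
        self.components: dict[str, list[AgpComponent]] = {
            lg: list(rows) for lg, rows in components.items()
        }
        self.unanchored: list[str] = list(unanchored)
        self.gap_length = gap_length
        self._validate()
        self.total_bp = total_bp

    def _validate(self) -> None:
        seen: set[str] = set()
        for lg, rows in self.components.items():
            pos = 0
            for row in rows:
                if row.object_start != pos + 1:
                    raise ValidationError(
                        f"{lg}: component part {row.part_number} does not tile "
                        f"(starts at {row.object_start}, expected {pos + 1})"
                    )
                pos = row.object_end
                if row.kind == "contig":
                    if row.component_id in seen:
                        raise ValidationError(
                            f"contig {row.component_id} placed more than once"
                        )
                    seen.add(row.component_id)

    def lg_length(self, lg: str) -> int:
        rows = self.components[lg]
        return rows[-1].object_end if rows else 0

    def contigs_of(self, lg: str) -> list[AgpComponent]:
        return [c for c in self.components[lg] if c.kind == "contig"]

    @property
    def total_anchored_bp(self) -> int:
        return sum(
            c.span for rows in self.components.values() for c in rows if c.kind == "contig"
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnchoredAssembly):
            return NotImplemented
        return (
            self.components == other.components
            and self.unanchored == other.unanchored
        )


class SegmentMap:
    """Piecewise-linear coordinate liftover between two coordinate systems.

    Each segment maps [src_start, src_end) on ``src`` forward onto ``dst``
    starting at ``dst_start``.  Used for genome->contig liftover after
    fragmentation and old->new liftover after contig breaking.
    """

    def __init__(self) -> None:
        self._by_src: dict[str, list[tuple[int, int, str, int]]] = {}

    def add(self, src: str, src_start: int, src_end: int, dst: str, dst_start: int) -> None:
        self._by_src.setdefault(src, []).append((src_start, src_end, dst, dst_start))

    def freeze(self) -> "SegmentMap":
        for segs in self._by_src.values():
            segs.sort()
        return self

    def lift(self, src: str, pos: int) -> tuple[str, int]:
        import bisect

        segs = self._by_src.get(src)
        if not segs:
            raise KeyError(f"no liftover segments for {src}")
        i = bisect.bisect_right(segs, (pos, float("inf"))) - 1
        if i < 0 or not (segs[i][0] <= pos < segs[i][1]):
            raise KeyError(f"position {src}:{pos} not covered by liftover")
        s0, _, dst, d0 = segs[i]
        return dst, d0 + (pos - s0)

    def segments(self, src: str) -> list[tuple[int, int, str, int]]:
        return list(self._by_src.get(src, []))

    def sources(self) -> list[str]:
        return list(self._by_src)


@dataclass(frozen=True)
class SyntenyBlock:
    """A chained run of alignments between two genomes, order/strand coherent."""

    ref_chrom: str
    query_chrom: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    strand: str
    aligned_bp: int
    mean_identity: float
    n_records: int = 1

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start or self.query_end <= self.query_start:
            raise ValidationError("synteny block intervals must be non-degenerate")
        if self.aligned_bp > min(
            self.ref_end - self.ref_start, self.query_end - self.query_start
        ):
            raise ValidationError("aligned_bp exceeds block interval length")

    @property
    def ref_mid(self) -> float:
        return 0.5 * (self.ref_start + self.ref_end)

    @property
    def query_mid(self) -> float:
        return 0.5 * (self.query_start + self.query_end)
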