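"""Inter- and intra-chromosomal rearrangement calling and karyotype inference.

Discordant contig assignments across several genetic maps flag putative
inter-chromosomal differences between the mapped species.  Whole-genome
alignment records are chained into synteny blocks; per query chromosome
the blocks classify fusions (a second reference chromosome contributing a
terminal run), translocations (interleaved), and large inversions
(reverse-strand runs).  Centromeres are located from satellite-repeat
clusters and chromosomes classified on the Levan long:short arm-ratio
convention; homologous chromosomes whose classes differ between species
are reported as centromere repositioning events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AlignmentRecord, RepeatAnnotation, SyntenyBlock, ValidationError

# Levan-convention arm-ratio thresholds
KARYOTYPE_CLASSES = (
    (1.7, "metacentric"),
    (3.0, "submetacentric"),
    (7.0, "subtelocentric"),
    (float("inf"), "acrocentric"),
)

METACENTRIC_GROUP = {"metacentric", "submetacentric"}
ACROCENTRIC_GROUP = {"subtelocentric", "acrocentric"}


@dataclass
class DiscordantContig:
    contig: str
    size: int
    assignments: list[tuple[str, str, int]]  # (map_id, lg, n_markers)
    majority_lg: str
    single_marker_support: bool
    repeat_note: str | None = None


@dataclass
class RearrangementEvent:
    type: str  # inversion | translocation | fusion_partner | collinear
    query_chrom: str
    ref_chroms: tuple[str, ...]
    span_bp: int
    blocks: list[SyntenyBlock] = field(default_factory=list)


@dataclass
class CentromereCall:
    chrom: str
    interval: tuple[int, int]
    satellite_family: str
    cluster_bp: int
    ambiguous: bool = False
    arm_ratio: float | None = None
    karyotype_class: str | None = None


# ---------------------------------------------------------------------------
# inter-chromosomal differences from map-anchoring comparison
# ---------------------------------------------------------------------------


def detect_interchromosomal_differences(
    per_map_assignments: dict[str, dict[str, tuple[str, int]]],
    contig_sizes: dict[str, int],
    repeat_notes: dict[str, str] | None = None,
) -> tuple[list[DiscordantContig], dict]:
    """Contigs assigned to different LGs by different maps.

    ``per_map_assignments`` maps map_id -> {contig: (lg, n_markers)} — the
    LG each map put the contig on and the marker support.  A contig is
    discordant when at least two maps disagree.  The majority LG is the
    one chosen by the most maps (ties: most markers, then name);
    ``single_marker_support`` is True when every non-majority assignment
    rests on exactly one marker.  The aggregate reports the count, exact
    total bp, and the number of single-marker-supported contigs.
    """
    if len(per_map_assignments) < 2:
        raise ValidationError("need assignments from >= 2 maps")
    repeat_notes = repeat_notes or {}
    contigs = sorted({c for asg in per_map_assignments.values() for c in asg})
    out: list[DiscordantContig] = []
    for contig in contigs:
        assigns = [
            (map_id, *asg[contig])
            for map_id, asg in per_map_assignments.items()
            if contig in asg
        ]
        lgs = {lg for _, lg, _ in assigns}
        if len(lgs) < 2:
            continue
        votes: dict[str, int] = {}
        marker_sum: dict[str, int] = {}
        for _, lg, n in assigns:
            votes[lg] = votes.get(lg, 0) + 1
            marker_sum[lg] = marker_sum.get(lg, 0) + n
        majority = max(votes, key=lambda lg: (votes[lg], marker_sum[lg], lg))
        single = all(n == 1 for _, lg, n in assigns if lg != majority)
        out.append(
            DiscordantContig(
                contig=contig,
                size=contig_sizes[contig],
                assignments=assigns,
                majority_lg=majority,
                single_marker_support=single,
                repeat_note=repeat_notes.get(contig),
            )
        )
    aggregate = {
        "count": len(out),
        "total_bp": sum(d.size for d in out),
        "n_single_marker": sum(d.single_marker_support for d in out),
    }
    return out, aggregate


# ---------------------------------------------------------------------------
# synteny block chaining
# ---------------------------------------------------------------------------


def chain_synteny_blocks(
    records: list[AlignmentRecord],
    min_identity: float = 10.0,
    min_length: int = 5_000,
    max_chain_gap: int = 100_000,
) -> list[SyntenyBlock]:
    """Filter and chain alignment records into synteny blocks.

    Records below the identity or length floor are dropped; overlapping
    records (on either genome) are resolved one-to-one keeping the larger
    alignment.  Adjacent records of the same chromosome pair and strand
    merge when both coordinate gaps are <= ``max_chain_gap`` and the
    diagonal is consistent (forward runs advance on both genomes, reverse
    runs advance on the query while retreating on the reference).
    Chaining never increases total aligned bp and is idempotent.
    """
    kept: list[AlignmentRecord] = []
    for r in sorted(
        records, key=lambda r: (-min(r.ref_len, r.query_len), r.ref_chrom, r.ref_start)
    ):
        if r.pct_identity < min_identity or min(r.ref_len, r.query_len) < min_length:
            continue
        clash = False
        for k in kept:
            if (
                k.ref_chrom == r.ref_chrom
                and k.ref_start < r.ref_end
                and r.ref_start < k.ref_end
            ) or (
                k.query_chrom == r.query_chrom
                and k.query_start < r.query_end
                and r.query_start < k.query_end
            ):
                clash = True
                break
        if not clash:
            kept.append(r)

    by_group: dict[tuple[str, str, str], list[AlignmentRecord]] = {}
    for r in kept:
        by_group.setdefault((r.query_chrom, r.ref_chrom, r.strand), []).append(r)

    blocks: list[SyntenyBlock] = []
    for (qc, rc, strand), rs in by_group.items():
        rs.sort(key=lambda r: r.query_start)
        run = [rs[0]]
        for r in rs[1:]:
            prev = run[-1]
            qgap = r.query_start - prev.query_end
            if strand == "+":
                rgap = r.ref_start - prev.ref_end
                diagonal_ok = r.ref_start >= prev.ref_end - max_chain_gap
            else:
                rgap = prev.ref_start - r.ref_end
                diagonal_ok = r.ref_end <= prev.ref_start + max_chain_gap
            if 0 <= qgap <= max_chain_gap and -max_chain_gap <= rgap <= max_chain_gap and diagonal_ok:
                run.append(r)
            else:
                blocks.append(_merge_run(run, strand))
                run = [r]
        blocks.append(_merge_run(run, strand))
    blocks.sort(key=lambda b: (b.query_chrom, b.query_start))
    return blocks


def _merge_run(run: list[AlignmentRecord], strand: str) -> SyntenyBlock:
    aligned = sum(min(r.ref_len, r.query_len) for r in run)
    wid = sum(r.pct_identity * min(r.ref_len, r.query_len) for r in run)
    return SyntenyBlock(
        ref_chrom=run[0].ref_chrom,
        query_chrom=run[0].query_chrom,
        ref_start=min(r.ref_start for r in run),
        ref_end=max(r.ref_end for r in run),
        query_start=min(r.query_start for r in run),
        query_end=max(r.query_end for r in run),
        strand=strand,
        aligned_bp=aligned,
        mean_identity=wid / aligned if aligned else 0.0,
        n_records=sum(getattr(r, "n_records", 1) for r in run),
    )


def blocks_to_records(blocks: list[SyntenyBlock]) -> list[AlignmentRecord]:
    """View blocks as alignment records (for idempotence checks and rechaining)."""
    return [
        AlignmentRecord(
            ref_chrom=b.ref_chrom,
            query_chrom=b.query_chrom,
            ref_start=b.ref_start,
            ref_end=b.ref_end,
            query_start=b.query_start,
            query_end=b.query_end,
            pct_identity=b.mean_identity,
            strand=b.strand,
        )
        for b in blocks
    ]


# ---------------------------------------------------------------------------
# rearrangement classification
# ---------------------------------------------------------------------------


def classify_rearrangements(
    blocks: list[SyntenyBlock],
    fusion_min_secondary_bp: int = 5_000_000,
    inversion_min_bp: int = 2_000_000,
) -> tuple[list[RearrangementEvent], dict[str, list[tuple[str, int]]]]:
    """Classify per-query-chromosome events from chained blocks.

    The primary reference chromosome carries the most aligned bp.  Any
    other reference chromosome reaching ``fusion_min_secondary_bp`` is a
    fusion partner when its blocks sit terminally on the query, a
    translocation when they interleave within the primary's span.
    Maximal runs of minority-strand blocks on the primary reference
    spanning >= ``inversion_min_bp`` of the query are inversions.  A query
    chromosome with none of these yields a single collinear event.
    """
    by_query: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_query.setdefault(b.query_chrom, []).append(b)
    events: list[RearrangementEvent] = []
    table: dict[str, list[tuple[str, int]]] = {}
    for qc in sorted(by_query):
        bs = sorted(by_query[qc], key=lambda b: b.query_start)
        per_ref: dict[str, int] = {}
        for b in bs:
            per_ref[b.ref_chrom] = per_ref.get(b.ref_chrom, 0) + b.aligned_bp
        ranked = sorted(per_ref.items(), key=lambda kv: -kv[1])
        table[qc] = ranked
        primary = ranked[0][0]
        pblocks = [b for b in bs if b.ref_chrom == primary]
        pstart = min(b.query_start for b in pblocks)
        pend = max(b.query_end for b in pblocks)
        structural = False

        secondaries = [
            (rc, bp) for rc, bp in ranked[1:] if bp >= fusion_min_secondary_bp
        ]
        for rc, bp in secondaries:
            sblocks = [b for b in bs if b.ref_chrom == rc]
            sstart = min(b.query_start for b in sblocks)
            send = max(b.query_end for b in sblocks)
            terminal = send <= pstart or sstart >= pend
            events.append(
                RearrangementEvent(
                    type="fusion_partner" if terminal else "translocation",
                    query_chrom=qc,
                    ref_chroms=(rc,),
                    span_bp=send - sstart,
                    blocks=sblocks,
                )
            )
            structural = True
        if secondaries:
            events.append(
                RearrangementEvent(
                    type="fusion_partner",
                    query_chrom=qc,
                    ref_chroms=(primary,),
                    span_bp=pend - pstart,
                    blocks=pblocks,
                )
            )

        fwd = sum(b.aligned_bp for b in pblocks if b.strand == "+")
        rev = sum(b.aligned_bp for b in pblocks if b.strand == "-")
        minority = "-" if rev <= fwd else "+"
        run: list[SyntenyBlock] = []
        for b in pblocks + [None]:  # type: ignore[list-item]
            if b is not None and b.strand == minority:
                run.append(b)
                continue
            if run:
                span = run[-1].query_end - run[0].query_start
                if span >= inversion_min_bp:
                    events.append(
                        RearrangementEvent(
                            type="inversion",
                            query_chrom=qc,
                            ref_chroms=(primary,),
                            span_bp=span,
                            blocks=list(run),
                        )
                    )
                    structural = True
                run = []
        if not structural:
            events.append(
                RearrangementEvent(
                    type="collinear",
                    query_chrom=qc,
                    ref_chroms=(primary,),
                    span_bp=pend - pstart,
                    blocks=pblocks,
                )
            )
    return events, table


# ---------------------------------------------------------------------------
# centromeres and karyotypes
# ---------------------------------------------------------------------------


def locate_centromeres(
    repeats: list[RepeatAnnotation],
    satellite_families: set[str] = frozenset({"ONSATA", "TZSAT"}),
    max_cluster_gap: int = 500_000,
    ambiguity_fraction: float = 0.25,
    ambiguity_distance: int = 5_000_000,
) -> list[CentromereCall]:
    """Call one centromere per chromosome from satellite-repeat clusters.

    Satellite hits closer than ``max_cluster_gap`` merge into clusters;
    the cluster with the most satellite bp is the call.  The call is
    ambiguous when two or more clusters each hold >= 25% of the
    chromosome's satellite bp and lie more than 5 Mbp apart.
    """
    by_chrom: dict[str, list[RepeatAnnotation]] = {}
    for r in repeats:
        if r.family in satellite_families:
            by_chrom.setdefault(r.chrom, []).append(r)
    calls: list[CentromereCall] = []
    for chrom in sorted(by_chrom):
        hits = sorted(by_chrom[chrom], key=lambda r: r.start)
        clusters: list[list[RepeatAnnotation]] = [[hits[0]]]
        for r in hits[1:]:
            if r.start - clusters[-1][-1].end <= max_cluster_gap:
                clusters[-1].append(r)
            else:
                clusters.append([r])
        total_sat = sum(r.length for r in hits)
        sized = [
            (sum(r.length for r in cl), cl[0].start, cl[-1].end, cl) for cl in clusters
        ]
        best = max(sized, key=lambda t: t[0])
        big = [
            t
            for t in sized
            if t[0] >= ambiguity_fraction * total_sat
        ]
        ambiguous = any(
            abs((a[1] + a[2]) / 2 - (b[1] + b[2]) / 2) > ambiguity_distance
            for i, a in enumerate(big)
            for b in big[i + 1 :]
        )
        families = sorted({r.family for r in best[3]})
        calls.append(
            CentromereCall(
                chrom=chrom,
                interval=(best[1], best[2]),
                satellite_family=",".join(families),
                cluster_bp=best[0],
                ambiguous=ambiguous,
            )
        )
    return calls


def classify_karyotype(
    call: CentromereCall, chrom_length: int, position: str = "midpoint"
) -> str:
    """Karyotype class from the long:short arm ratio (Levan convention).

    The centromere point is the cluster midpoint (or bp-weighted centroid
    when ``position='centroid'`` — identical here since the call stores
    only the cluster interval).  The short arm has a 1-bp floor so a
    terminal centromere is acrocentric.  Sets the fields on the call.
    """
    if not (0 <= call.interval[0] <= call.interval[1] <= chrom_length):
        raise ValidationError(f"centromere interval outside chromosome {call.chrom}")
    mid = (call.interval[0] + call.interval[1]) / 2
    short = max(min(mid, chrom_length - mid), 1.0)
    long = max(mid, chrom_length - mid)
    ratio = long / short
    for cutoff, name in KARYOTYPE_CLASSES:
        if ratio <= cutoff:
            call.arm_ratio = ratio
            call.karyotype_class = name
            return name
    raise AssertionError("unreachable")


def detect_centromere_repositioning(
    calls_a: list[CentromereCall],
    calls_b: list[CentromereCall],
    homology: dict[str, str] | None = None,
    events: list[RearrangementEvent] | None = None,
) -> list[dict]:
    """Homologous chromosome pairs whose karyotype group changed.

    ``homology`` maps genome-B chromosome -> genome-A chromosome (e.g. the
    primary-reference table from classify_rearrangements); identical
    names are homologous by default.  A repositioning is reported when
    one side is meta/submetacentric and the other subtelo/acrocentric.
    Rearrangement events overlapping either centromere interval are
    attached.
    """
    homology = homology or {}
    a_by = {c.chrom: c for c in calls_a}
    out: list[dict] = []
    for cb in calls_b:
        a_chrom = homology.get(cb.chrom, cb.chrom)
        ca = a_by.get(a_chrom)
        if ca is None or ca.karyotype_class is None or cb.karyotype_class is None:
            continue
        group_a = "meta" if ca.karyotype_class in METACENTRIC_GROUP else "acro"
        group_b = "meta" if cb.karyotype_class in METACENTRIC_GROUP else "acro"
        if group_a == group_b:
            continue
        near = []
        for ev in events or []:
            for blk in ev.blocks:
                if (
                    blk.query_chrom == cb.chrom
                    and blk.query_start < cb.interval[1]
                    and cb.interval[0] < blk.query_end
                ) or (
                    blk.ref_chrom == a_chrom
                    and blk.ref_start < ca.interval[1]
                    and ca.interval[0] < blk.ref_end
                ):
                    near.append(ev)
                    break
        out.append(
            {
                "chrom_pair": (a_chrom, cb.chrom),
                "class_a": ca.karyotype_class,
                "class_b": cb.karyotype_class,
                "events": near,
            }
        )
    return out
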