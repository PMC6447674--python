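"""Order, orient, and concatenate contigs into chromosomes per genetic map.

Each contig is assigned to the linkage group holding most of its markers,
ordered along the LG by the median cM of those markers, and oriented by
the rank correlation between marker bp offsets and cM.  Anchorings built
from several maps are integrated per LG (by collinearity against a
reference, or by explicit selection), with 100-bp gaps between contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import numpy as np
from scipy.stats import kendalltau

from .model import (
    AgpComponent,
    AnchoredAssembly,
    ContigSet,
    MarkerRecord,
    SyntenyBlock,
    ValidationError,
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ContigAssignment:
    contig: str
    lg: str
    n_markers: int
    order_key: float  # median cM of the assigned LG's markers on the contig
    orientation: str = "?"
    orientation_support: int = 0
    source_map: str = ""


@dataclass
class AnchoringSummary:
    per_lg_bp: dict[str, int]
    per_lg_contigs: dict[str, int]
    total_anchored_bp: int
    total_bp: int | None
    percent_anchored: float | None


def assign_contigs(
    markers: list[MarkerRecord], map_id: str = ""
) -> tuple[list[ContigAssignment], list[dict]]:
    """Assign each contig to the linkage group with the most markers.

    Markers flagged as non-unique placements (repetitive) are excluded
    from the vote but preserved in the discordance report.  Exact ties
    leave the contig unassigned (reported with a tie flag).  Returns the
    assignments and a per-contig report of all LG marker counts.
    """
    by_contig: dict[str, list[MarkerRecord]] = {}
    for m in markers:
        by_contig.setdefault(m.contig, []).append(m)
    assignments: list[ContigAssignment] = []
    report: list[dict] = []
    for contig in sorted(by_contig):
        ms = by_contig[contig]
        counts: dict[str, int] = {}
        flagged: dict[str, int] = {}
        for m in ms:
            if m.unique_placement:
                counts[m.lg] = counts.get(m.lg, 0) + 1
            else:
                flagged[m.lg] = flagged.get(m.lg, 0) + 1
        entry = {
            "contig": contig,
            "map_id": map_id,
            "lg_counts": dict(sorted(counts.items())),
            "repeat_flagged_counts": dict(sorted(flagged.items())),
            "assigned_lg": None,
            "tie": False,
        }
        if not counts:
            report.append(entry)
            continue
        best = max(counts.values())
        winners = [lg for lg, c in counts.items() if c == best]
        if len(winners) > 1:
            entry["tie"] = True
            report.append(entry)
            continue
        lg = winners[0]
        cms = [m.pos_cM for m in ms if m.lg == lg and m.unique_placement]
        entry["assigned_lg"] = lg
        report.append(entry)
        assignments.append(
            ContigAssignment(
                contig=contig,
                lg=lg,
                n_markers=best,
                order_key=float(median(cms)),
                source_map=map_id,
            )
        )
    return assignments, report


def order_and_orient(
    assignments: list[ContigAssignment], markers: list[MarkerRecord]
) -> dict[str, list[ContigAssignment]]:
    """Sort contigs within each LG and infer orientations.

    Order is (median cM, contig id) ascending — co-segregating contigs
    fall back to a deterministic lexicographic order.  Orientation is the
    sign of the Kendall correlation between marker bp offset and cM on
    the assigned LG; a zero correlation or a single informative cM bin
    gives '?' (placed as '+', counted as unoriented).
    """
    by_key: dict[tuple[str, str], list[MarkerRecord]] = {}
    for m in markers:
        if m.unique_placement:
            by_key.setdefault((m.contig, m.lg), []).append(m)
    ordered: dict[str, list[ContigAssignment]] = {}
    for a in assignments:
        ms = by_key.get((a.contig, a.lg), [])
        pos = [m.contig_pos for m in ms]
        cm = [m.pos_cM for m in ms]
        if len(set(cm)) < 2 or len(pos) < 2:
            a.orientation = "?"
            a.orientation_support = 0
        else:
            tau = kendalltau(pos, cm).statistic
            if tau > 0:
                a.orientation = "+"
            elif tau < 0:
                a.orientation = "-"
            else:
                a.orientation = "?"
            a.orientation_support = len(ms) if a.orientation != "?" else 0
        ordered.setdefault(a.lg, []).append(a)
    for lg in ordered:
        ordered[lg].sort(key=lambda a: (a.order_key, a.contig))
    return dict(sorted(ordered.items()))


def build_anchored_assembly(
    ordered: dict[str, list[ContigAssignment]],
    contigs: ContigSet,
    gap_length: int = 100,
) -> AnchoredAssembly:
    """Tile each LG with its ordered contigs separated by fixed gaps.

    LG sequence length is sum(contig lengths) + gap_length x (n - 1).
    Contigs absent from the anchoring are listed as unanchored.
    """
    components: dict[str, list[AgpComponent]] = {}
    anchored: set[str] = set()
    for lg, assigns in ordered.items():
        rows: list[AgpComponent] = []
        pos = 0
        part = 0
        for i, a in enumerate(assigns):
            if a.contig not in contigs:
                raise ValidationError(f"{lg}: contig {a.contig} not in contig set")
            if i > 0:
                part += 1
                rows.append(
                    AgpComponent(
                        object_id=lg,
                        object_start=pos + 1,
                        object_end=pos + gap_length,
                        part_number=part,
                        kind="gap",
                        gap_length=gap_length,
                    )
                )
                pos += gap_length
            n = contigs.lengths[a.contig]
            part += 1
            rows.append(
                AgpComponent(
                    object_id=lg,
                    object_start=pos + 1,
                    object_end=pos + n,
                    part_number=part,
                    kind="contig",
                    component_id=a.contig,
                    component_orientation=a.orientation,
                )
            )
            pos += n
            anchored.add(a.contig)
        components[lg] = rows
    unanchored = [c for c in sorted(contigs.lengths) if c not in anchored]
    return AnchoredAssembly(
        components, unanchored=unanchored, gap_length=gap_length, total_bp=contigs.total_bp
    )


def assembly_sequences(assembly: AnchoredAssembly, contigs: ContigSet) -> ContigSet:
    """Emit per-LG sequences; '-' contigs are reverse-complemented, gaps are N."""
    out: dict[str, str] = {}
    for lg, rows in assembly.components.items():
        parts: list[str] = []
        for row in rows:
            if row.kind == "gap":
                parts.append("N" * row.gap_length)
            else:
                seq = contigs.sequence(row.component_id)
                parts.append(reverse_complement(seq) if row.component_orientation == "-" else seq)
        out[lg] = "".join(parts)
    return ContigSet(sequences=out)


def collinearity_score(
    blocks: list[SyntenyBlock], orientation_agnostic: bool = True
) -> float | None:
    """Fraction of aligned bp in the best strictly increasing chain.

    Blocks are taken in order along the anchored LG (their query
    coordinate); the score is the maximum total weight (aligned bp) of a
    chain whose reference midpoints strictly increase, divided by the
    total aligned bp.  With ``orientation_agnostic`` the better of the
    forward and reversed readings is scored.  No blocks -> None.
    """
    if not blocks:
        return None
    bs = sorted(blocks, key=lambda b: b.query_mid)
    weights = np.array([b.aligned_bp for b in bs], dtype=float)
    mids = np.array([b.ref_mid for b in bs])
    total = weights.sum()

    def chain(values: np.ndarray) -> float:
        best = weights.copy()
        for i in range(len(values)):
            for j in range(i):
                if values[j] < values[i]:
                    best[i] = max(best[i], best[j] + weights[i])
        return float(best.max())

    score = chain(mids)
    if orientation_agnostic:
        score = max(score, chain(-mids))
    return score / total


def integrate_maps(
    anchorings: dict[str, AnchoredAssembly],
    assignments: dict[str, list[ContigAssignment]],
    selection: dict[str, str] | str = "auto",
    reference_blocks: dict[tuple[str, str], list[SyntenyBlock]] | None = None,
    precedence: list[str] | None = None,
    contigs: ContigSet | None = None,
    gap_length: int = 100,
) -> tuple[AnchoredAssembly, list[dict]]:
    """Combine per-map anchorings into one final assembly.

    ``selection`` maps LG -> map_id, or "auto" to pick per LG the map with
    the best collinearity against ``reference_blocks`` (ties: more
    anchored bp, then ``precedence`` order).  A contig claimed by two
    selected LGs stays where it has more markers; the loss is logged and
    the contig is dropped (to unanchored) elsewhere.
    """
    precedence = precedence or list(anchorings)
    lgs = sorted({lg for a in anchorings.values() for lg in a.components})
    n_markers: dict[str, dict[str, int]] = {
        map_id: {a.contig: a.n_markers for a in asg} for map_id, asg in assignments.items()
    }

    chosen: dict[str, str] = {}
    if selection == "auto":
        if reference_blocks is None:
            raise ValidationError("auto selection requires reference blocks")
        for lg in lgs:
            scored = []
            for map_id in precedence:
                if lg not in anchorings.get(map_id, AnchoredAssembly({})).components:
                    continue
                score = collinearity_score(reference_blocks.get((map_id, lg), []))
                bp = sum(c.span for c in anchorings[map_id].contigs_of(lg))
                scored.append((-1.0 if score is None else score, bp, -precedence.index(map_id), map_id))
            if scored:
                chosen[lg] = max(scored)[3]
    else:
        unknown = set(selection.values()) - set(anchorings)
        if unknown:
            raise ValidationError(f"selection names unknown maps: {sorted(unknown)}")
        chosen = dict(selection)

    # resolve contigs claimed by several selected LGs
    claims: dict[str, list[tuple[str, str]]] = {}
    for lg, map_id in chosen.items():
        for comp in anchorings[map_id].contigs_of(lg):
            claims.setdefault(comp.component_id, []).append((lg, map_id))
    dropped: dict[str, str] = {}  # contig -> winning lg
    log: list[dict] = []
    for contig, places in claims.items():
        if len(places) == 1:
            continue
        ranked = sorted(
            places,
            key=lambda p: (n_markers.get(p[1], {}).get(contig, 0), -precedence.index(p[1])),
            reverse=True,
        )
        winner = ranked[0]
        dropped[contig] = winner[0]
        log.append(
            {
                "contig": contig,
                "kept_lg": winner[0],
                "kept_map": winner[1],
                "dropped_from": [
                    {"lg": lg, "map": m} for lg, m in places if (lg, m) != winner
                ],
            }
        )

    components: dict[str, list[AgpComponent]] = {}
    anchored: set[str] = set()
    for lg in lgs:
        if lg not in chosen:
            continue
        map_id = chosen[lg]
        rows_in = anchorings[map_id].contigs_of(lg)
        rows: list[AgpComponent] = []
        pos = 0
        part = 0
        for comp in rows_in:
            cid = comp.component_id
            if cid in dropped and dropped[cid] != lg:
                continue
            n = comp.span if contigs is None else contigs.lengths[cid]
            if rows:
                part += 1
                rows.append(
                    AgpComponent(lg, pos + 1, pos + gap_length, part, "gap", gap_length=gap_length)
                )
                pos += gap_length
            part += 1
            rows.append(
                AgpComponent(
                    lg,
                    pos + 1,
                    pos + n,
                    part,
                    "contig",
                    component_id=cid,
                    component_orientation=comp.component_orientation,
                )
            )
            pos += n
            anchored.add(cid)
        components[lg] = rows

    all_contigs = (
        set(contigs.lengths)
        if contigs is not None
        else {
            c.component_id
            for a in anchorings.values()
            for lg in a.components
            for c in a.contigs_of(lg)
        } | {u for a in anchorings.values() for u in a.unanchored}
    )
    unanchored = sorted(all_contigs - anchored)
    total_bp = contigs.total_bp if contigs is not None else None
    return (
        AnchoredAssembly(components, unanchored=unanchored, gap_length=gap_length, total_bp=total_bp),
        log,
    )


def anchoring_summary(
    assembly: AnchoredAssembly | dict[str, int], total_bp: int | None = None
) -> AnchoringSummary:
    """Per-LG and total anchored bp with the percent of the assembly anchored.

    Accepts either a built assembly or a plain LG -> anchored-bp table
    (e.g. a published anchoring column).  Percent is rounded to one
    decimal.
    """
    if isinstance(assembly, AnchoredAssembly):
        per_lg = {
            lg: sum(c.span for c in assembly.contigs_of(lg)) for lg in assembly.components
        }
        per_n = {lg: len(assembly.contigs_of(lg)) for lg in assembly.components}
        if total_bp is None:
            total_bp = assembly.total_bp
    else:
        per_lg = dict(assembly)
        per_n = {}
    if not per_lg:
        return AnchoringSummary({}, {}, 0, total_bp, 0.0)
    total_anchored = sum(per_lg.values())
    pct = None
    if total_bp is not None:
        if total_bp < total_anchored:
            raise ValidationError("total_bp smaller than anchored bp")
        pct = round(100.0 * total_anchored / total_bp, 1)
    return AnchoringSummary(per_lg, per_n, total_anchored, total_bp, pct)
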