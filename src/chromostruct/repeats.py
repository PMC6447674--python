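"""Transposable-element landscape by divergence bin and genic context.

The repeat landscape bins masked repeat bp by sequence divergence from
the family consensus (a proxy for insertion age): per repeat class and
1%-divergence bin, the fraction of the genome covered.  "Recent"
insertions are summarized below 1% and 2% divergence.  TE genic context
assigns each insertion to exactly one of promoter, exon, intron, or
intergenic, with promoter defined as a strand-aware window upstream of
the transcription start (1 kbp or 15 kbp in the comparisons this
supports) and precedence promoter > exon > intron > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import GeneModel, RepeatAnnotation, ValidationError

CONTEXTS = ("promoter", "exon", "intron", "intergenic")


@dataclass
class RepeatLandscape:
    fractions: dict[tuple[str, int], float]  # (class_name, bin index) -> % of genome
    genome_size: int
    bin_width: float
    recent_thresholds: tuple[float, float] = (1.0, 2.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class_name": cls, "divergence_bin": b, "fraction_pct": f}
            for (cls, b), f in sorted(self.fractions.items())
        ]
        return pd.DataFrame(rows, columns=["class_name", "divergence_bin", "fraction_pct"])

    def recent_fraction(self, class_name: str | None = None, below_pct: float = 2.0) -> float:
        """Genome % in bins whose divergence is fully below ``below_pct``."""
        n_bins = int(round(below_pct / self.bin_width))
        return sum(
            f
            for (cls, b), f in self.fractions.items()
            if b < n_bins and (class_name is None or cls == class_name)
        )

    def class_total(self, class_name: str) -> float:
        return sum(f for (cls, _), f in self.fractions.items() if cls == class_name)

    @property
    def total_fraction(self) -> float:
        return sum(self.fractions.values())


@dataclass
class TEContextCounts:
    counts: dict[tuple[str, str], int]  # (superfamily, context) -> n insertions
    promoter_window: int
    overlap_policy: str = "any-overlap"  # recorded in output metadata

    def context_total(self, context: str) -> int:
        return sum(n for (_, c), n in self.counts.items() if c == context)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"superfamily": sf, "context": c, "count": n}
            for (sf, c), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["superfamily", "context", "count"])


def compute_repeat_landscape(
    repeats: list[RepeatAnnotation],
    genome_size: int,
    bin_width: float = 1.0,
    chrom_lengths: dict[str, int] | None = None,
) -> RepeatLandscape:
    """Genome fraction per (repeat class, divergence bin).

    Overlapping same-class annotations are merged before summation so
    nested or duplicated hits count once: annotations are processed in
    (start, divergence) order per class and chromosome, and only bp not
    already covered by an earlier same-class annotation accrue to an
    annotation's divergence bin.  The denominator is the full assembly
    size including gaps.
    """
    if genome_size <= 0:
        raise ValidationError("genome_size must be > 0")
    if chrom_lengths is not None:
        for r in repeats:
            if r.chrom in chrom_lengths and r.end > chrom_lengths[r.chrom]:
                raise ValidationError(
                    f"repeat beyond chromosome {r.chrom} length {chrom_lengths[r.chrom]}"
                )
    by_key: dict[tuple[str, str], list[RepeatAnnotation]] = {}
    for r in repeats:
        by_key.setdefault((r.class_name, r.chrom), []).append(r)
    fractions: dict[tuple[str, int], float] = {}
    for (cls, _), anns in sorted(by_key.items()):
        anns.sort(key=lambda r: (r.start, r.divergence_pct))
        covered = IntervalTree()
        for r in anns:
            new_bp = r.length
            for hit in covered.overlap(r.start, r.end):
                new_bp -= min(r.end, hit.end) - max(r.start, hit.begin)
            if new_bp <= 0:
                continue
            covered.addi(r.start, r.end)
            covered.merge_overlaps()
            b = int(r.divergence_pct // bin_width)
            key = (cls, b)
            fractions[key] = fractions.get(key, 0.0) + 100.0 * new_bp / genome_size
    return RepeatLandscape(fractions=fractions, genome_size=genome_size, bin_width=bin_width)


def classify_te_context(
    repeats: list[RepeatAnnotation],
    genes: list[GeneModel],
    promoter_window: int = 15_000,
) -> TEContextCounts:
    """Count TE insertions per (superfamily, genic context).

    Contexts with precedence promoter > exon > intron > intergenic; an
    annotation overlapping >= 1 bp of a category belongs to the highest
    one (any-overlap policy).  The promoter is the strand-aware
    ``promoter_window`` upstream of the transcription start, exclusive of
    the gene body; counts are of annotations, not bp.  Superfamily is the
    class/family label of each annotation.
    """
    promoters: dict[str, IntervalTree] = {}
    exons: dict[str, IntervalTree] = {}
    bodies: dict[str, IntervalTree] = {}
    for g in genes:
        if g.strand == "+":
            ps, pe = max(g.start - promoter_window, 0), g.start
        else:
            ps, pe = g.end, g.end + promoter_window
        if pe > ps:
            promoters.setdefault(g.chrom, IntervalTree()).addi(ps, pe)
        for s, e in g.exons:
            exons.setdefault(g.chrom, IntervalTree()).addi(s, e)
        bodies.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)

    counts: dict[tuple[str, str], int] = {}
    for r in repeats:
        sf = r.class_name if r.class_name == r.family else f"{r.class_name}/{r.family}"
        if r.chrom in promoters and promoters[r.chrom].overlaps(r.start, r.end):
            ctx = "promoter"
        elif r.chrom in exons and exons[r.chrom].overlaps(r.start, r.end):
            ctx = "exon"
        elif r.chrom in bodies and bodies[r.chrom].overlaps(r.start, r.end):
            ctx = "intron"
        else:
            ctx = "intergenic"
        counts[(sf, ctx)] = counts.get((sf, ctx), 0) + 1
    return TEContextCounts(counts=counts, promoter_window=promoter_window)
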