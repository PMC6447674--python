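"""Readers and writers for the external formats, plus basic assembly statistics.

Supported formats
-----------------
- marker tables: delimited text with a per-source column mapping
  (:class:`MarkerDialect`) because published linkage-map layouts vary
- alignments: headerless nucmer ``show-coords -T -H -l`` dialect, and PAF
- anchorings: AGP v2.1
- repeats: RepeatMasker ``.out`` and BED6+divergence
- gene models: GFF3 (gene/mRNA/exon) and BED12
- coverage/clone tracks: bedGraph
- sequences: FASTA (via Biopython)

Every reader emits the domain types of :mod:`chromostruct.model` with
0-based half-open coordinates; 1-based inclusive dialects (AGP,
show-coords) are converted here and nowhere else.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AgpComponent,
    AlignmentRecord,
    AnchoredAssembly,
    ContigSet,
    FormatError,
    GeneModel,
    MarkerRecord,
    RepeatAnnotation,
    ValidationError,
)

# ---------------------------------------------------------------------------
# marker tables
# ---------------------------------------------------------------------------


@dataclass
class MarkerDialect:
    """Column mapping for one marker-table layout.

    Values name the columns in the file; optional fields may be None when
    a source does not provide them.  ``delimiter`` defaults to tab.
    """

    marker_id: str = "marker_id"
    lg: str = "lg"
    pos_cM: str = "pos_cM"
    contig: str = "contig"
    contig_pos: str = "contig_pos"
    strand: str | None = "strand"
    female_cM: str | None = None
    male_cM: str | None = None
    unique_placement: str | None = None
    delimiter: str = "\t"


def read_marker_table(path, dialect: MarkerDialect | None = None) -> list[MarkerRecord]:
    """Read one genetic-map marker table under a column-mapping dialect.

    Rows missing the linkage group or the cM position are rejected with a
    :class:`FormatError` naming the line; duplicate marker ids raise a
    :class:`ValidationError`.
    """
    dialect = dialect or MarkerDialect()
    records: list[MarkerRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            return []
        for lineno, row in enumerate(reader, start=2):
            lg = (row.get(dialect.lg) or "").strip()
            raw_cm = (row.get(dialect.pos_cM) or "").strip()
            if not lg or not raw_cm:
                raise FormatError(f"{path}:{lineno}: missing lg or pos_cM")
            try:
                pos_cm = float(raw_cm)
                contig_pos = int(row[dialect.contig_pos])
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}:{lineno}: unparseable field ({exc})") from None
            marker_id = row[dialect.marker_id].strip()
            if marker_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate marker_id {marker_id}")
            seen.add(marker_id)

            def _opt(col: str | None) -> float | None:
                if col is None or not (row.get(col) or "").strip():
                    return None
                return float(row[col])

            unique = True
            if dialect.unique_placement is not None:
                raw = (row.get(dialect.unique_placement) or "").strip().lower()
                unique = raw not in ("0", "false", "no")
            records.append(
                MarkerRecord(
                    marker_id=marker_id,
                    lg=lg,
                    pos_cM=pos_cm,
                    contig=row[dialect.contig].strip(),
                    contig_pos=contig_pos,
                    strand=(row.get(dialect.strand) or "?").strip() or "?"
                    if dialect.strand
                    else "?",
                    female_cM=_opt(dialect.female_cM),
                    male_cM=_opt(dialect.male_cM),
                    unique_placement=unique,
                )
            )
    return records


def write_marker_table(markers: Sequence[MarkerRecord], path, dialect: MarkerDialect | None = None) -> None:
    dialect = dialect or MarkerDialect(
        female_cM="female_cM", male_cM="male_cM", unique_placement="unique_placement"
    )
    cols = [
        (dialect.marker_id, lambda m: m.marker_id),
        (dialect.lg, lambda m: m.lg),
        (dialect.pos_cM, lambda m: repr(m.pos_cM)),
        (dialect.contig, lambda m: m.contig),
        (dialect.contig_pos, lambda m: str(m.contig_pos)),
    ]
    if dialect.strand:
        cols.append((dialect.strand, lambda m: m.strand))
    if dialect.female_cM:
        cols.append((dialect.female_cM, lambda m: "" if m.female_cM is None else repr(m.female_cM)))
    if dialect.male_cM:
        cols.append((dialect.male_cM, lambda m: "" if m.male_cM is None else repr(m.male_cM)))
    if dialect.unique_placement:
        cols.append((dialect.unique_placement, lambda m: str(int(m.unique_placement))))
    with open(path, "w") as fh:
        fh.write(dialect.delimiter.join(name for name, _ in cols) + "\n")
        for m in markers:
            fh.write(dialect.delimiter.join(get(m) for _, get in cols) + "\n")


def validate_marker_placements(markers: Iterable[MarkerRecord], contigs: ContigSet) -> None:
    """Check that every marker's contig offset lies within the named contig."""
    for m in markers:
        if m.contig not in contigs:
            raise ValidationError(f"marker {m.marker_id}: unknown contig {m.contig}")
        if m.contig_pos >= contigs.lengths[m.contig]:
            raise ValidationError(
                f"marker {m.marker_id}: contig_pos {m.contig_pos} beyond "
                f"{m.contig} length {contigs.lengths[m.contig]}"
            )


# ---------------------------------------------------------------------------
# whole-genome alignment coordinates
# ---------------------------------------------------------------------------

_COORDS_NCOL = 11  # S1 E1 S2 E2 LEN1 LEN2 %IDY LENR LENQ REF QUERY


def read_alignment_coords(path) -> list[AlignmentRecord]:
    """Read the headerless tab dialect of nucmer ``show-coords -T -H -l``.

    Input coordinates are 1-based inclusive with the reference always
    forward; a query_start > query_end encodes a reverse-strand hit.  All
    records come back 0-based half-open with forward-stored intervals.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != _COORDS_NCOL:
                raise FormatError(
                    f"{path}:{lineno}: expected {_COORDS_NCOL} columns, got {len(parts)}"
                )
            s1, e1, s2, e2 = (int(parts[i]) for i in range(4))
            identity = float(parts[6])
            ref_chrom, query_chrom = parts[9], parts[10]
            strand = "+"
            if s2 > e2:
                strand = "-"
                s2, e2 = e2, s2
            records.append(
                AlignmentRecord(
                    ref_chrom=ref_chrom,
                    query_chrom=query_chrom,
                    ref_start=s1 - 1,
                    ref_end=e1,
                    query_start=s2 - 1,
                    query_end=e2,
                    pct_identity=identity,
                    strand=strand,
                )
            )
    return records


def write_alignment_coords(records: Sequence[AlignmentRecord], path) -> None:
    """Write records back to the show-coords tab dialect (inverse of reader)."""
    with open(path, "w") as fh:
        for r in records:
            if r.strand == "+":
                s2, e2 = r.query_start + 1, r.query_end
            else:
                s2, e2 = r.query_end, r.query_start + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.ref_start + 1,
                        r.ref_end,
                        s2,
                        e2,
                        r.ref_len,
                        r.query_len,
                        f"{r.pct_identity:.2f}",
                        0,
                        0,
                        r.ref_chrom,
                        r.query_chrom,
                    )
                )
                + "\n"
            )


def read_paf(path) -> list[AlignmentRecord]:
    """Read a PAF file into the same AlignmentRecord type.

    PAF is already 0-based half-open; the PAF query is mapped onto our
    query slot and the PAF target onto the reference.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}:{lineno}: PAF requires >= 12 columns")
            qname, _, qs, qe, strand, tname, _, ts, te, nmatch, alen = parts[:11]
            alen_i = int(alen)
            identity = 100.0 * int(nmatch) / alen_i if alen_i else 0.0
            records.append(
                AlignmentRecord(
                    ref_chrom=tname,
                    query_chrom=qname,
                    ref_start=int(ts),
                    ref_end=int(te),
                    query_start=int(qs),
                    query_end=int(qe),
                    pct_identity=min(identity, 100.0),
                    strand=strand,
                )
            )
    return records


# ---------------------------------------------------------------------------
# AGP
# ---------------------------------------------------------------------------


def write_agp(assembly: AnchoredAssembly, path) -> None:
    """Write an anchoring as AGP v2.1 (gap rows typed scaffold/paired-ends)."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for lg in assembly.components:
            for row in assembly.components[lg]:
                if row.kind == "contig":
                    fh.write(
                        "\t".join(
                            str(x)
                            for x in (
                                row.object_id,
                                row.object_start,
                                row.object_end,
                                row.part_number,
                                "W",
                                row.component_id,
                                1,
                                row.span,
                                row.component_orientation,
                            )
                        )
                        + "\n"
                    )
                else:
                    fh.write(
                        "\t".join(
                            str(x)
                            for x in (
                                row.object_id,
                                row.object_start,
                                row.object_end,
                                row.part_number,
                                "N",
                                row.gap_length,
                                row.gap_type,
                                "yes",
                                row.linkage_evidence,
                            )
                        )
                        + "\n"
                    )
        for i, contig in enumerate(assembly.unanchored, start=1):
            fh.write(f"#unanchored\t{contig}\n")


def read_agp(path) -> AnchoredAssembly:
    components: dict[str, list[AgpComponent]] = {}
    unanchored: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#unanchored\t"):
                unanchored.append(line.split("\t")[1])
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: AGP rows have 9 columns")
            obj, start, end, part, kind = parts[0], int(parts[1]), int(parts[2]), int(parts[3]), parts[4]
            rows = components.setdefault(obj, [])
            if kind in ("N", "U"):
                rows.append(
                    AgpComponent(
                        object_id=obj,
                        object_start=start,
                        object_end=end,
                        part_number=part,
                        kind="gap",
                        gap_length=int(parts[5]),
                        gap_type=parts[6],
                        linkage_evidence=parts[8],
                    )
                )
            else:
                rows.append(
                    AgpComponent(
                        object_id=obj,
                        object_start=start,
                        object_end=end,
                        part_number=part,
                        kind="contig",
                        component_id=parts[5],
                        component_orientation=parts[8],
                    )
                )
    return AnchoredAssembly(components, unanchored=unanchored)


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------


def _split_class_family(label: str) -> tuple[str, str]:
    if "/" in label:
        cls, fam = label.split("/", 1)
    else:
        cls, fam = label, label
    return cls, fam


def read_repeat_annotations(path, dialect: str = "auto") -> list[RepeatAnnotation]:
    """Read RepeatMasker ``.out``-style output or BED6+divergence.

    The ``.out`` dialect is whitespace-separated with two header lines and
    columns (score, div, del, ins, query, qstart, qend, qleft, strand,
    family, class/family, ...); coordinates are 1-based inclusive.  The
    BED dialect is ``chrom start end class/family score-or-div strand div``
    with 0-based half-open coordinates and the divergence in column 7
    (falling back to column 5).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    data = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith(("score", "SW", "#"))]
    if dialect == "auto":
        dialect = "bed" if data and "\t" in data[0] else "out"
    out: list[RepeatAnnotation] = []
    if dialect == "out":
        for ln in data:
            parts = ln.split()
            if len(parts) < 11:
                raise FormatError(f"{path}: short RepeatMasker row: {ln!r}")
            div = float(parts[1])
            chrom, qstart, qend = parts[4], int(parts[5]), int(parts[6])
            cls, fam = _split_class_family(parts[10])
            out.append(
                RepeatAnnotation(
                    chrom=chrom,
                    start=qstart - 1,
                    end=qend,
                    family=fam,
                    class_name=cls,
                    divergence_pct=div,
                )
            )
    elif dialect == "bed":
        for ln in data:
            parts = ln.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}: short BED+div row: {ln!r}")
            div = float(parts[6]) if len(parts) >= 7 else float(parts[4])
            cls, fam = _split_class_family(parts[3])
            out.append(
                RepeatAnnotation(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    family=fam,
                    class_name=cls,
                    divergence_pct=div,
                )
            )
    else:
        raise ValueError(f"unknown repeat dialect {dialect!r}")
    return out


def write_repeat_annotations(repeats: Sequence[RepeatAnnotation], path) -> None:
    """Write repeats as BED6+divergence (readable by read_repeat_annotations)."""
    with open(path, "w") as fh:
        for r in repeats:
            label = r.class_name if r.class_name == r.family else f"{r.class_name}/{r.family}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{label}\t0\t+\t{r.divergence_pct!r}\n"
            )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def read_gene_models(path, dialect: str = "auto") -> list[GeneModel]:
    """Read gene models from GFF3 (gene + exon features) or BED12."""
    path = Path(path)
    if dialect == "auto":
        dialect = "bed12" if path.suffix in (".bed", ".bed12") else "gff3"
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown gene-model dialect {dialect!r}")


def _read_gff3(path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: GFF3 rows have 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID", f"gene{len(genes)}")
                genes[gid] = {
                    "chrom": chrom,
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand,
                    "exons": [],
                }
                order.append(gid)
            elif ftype == "exon":
                parent = attr.get("Parent", "")
                gid = parent.split(".")[0] if parent else None
                if gid in genes:
                    genes[gid]["exons"].append((int(start) - 1, int(end)))
    out = []
    for gid in order:
        g = genes[gid]
        out.append(
            GeneModel(
                gene_id=gid,
                chrom=g["chrom"],
                start=g["start"],
                end=g["end"],
                strand=g["strand"],
                exons=tuple(sorted(g["exons"])),
            )
        )
    return out


def _read_bed12(path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 12:
                raise FormatError(f"{path}: BED12 rows have 12 columns")
            chrom, start, end, name, _, strand = p[0], int(p[1]), int(p[2]), p[3], p[4], p[5]
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            offsets = [int(x) for x in p[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            out.append(
                GeneModel(
                    gene_id=name, chrom=chrom, start=start, end=end, strand=strand, exons=exons
                )
            )
    return out


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene + exon rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tchromostruct\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tchromostruct\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> ContigSet:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return ContigSet(sequences=seqs)


def write_fasta(contigs: ContigSet, path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(contigs.sequence(cid)), id=cid, description="")
        for cid in contigs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# coverage tracks (bedGraph)
# ---------------------------------------------------------------------------


class Track:
    """Per-contig depth vectors at a fixed bin width.

    ``data`` maps contig -> float array; element i covers
    [i*bin_width, (i+1)*bin_width).  Gaps in the input are depth 0.
    """

    def __init__(self, data: dict[str, np.ndarray], bin_width: int = 1) -> None:
        self.data = data
        self.bin_width = bin_width

    def depth_at(self, contig: str, pos: int) -> float:
        return float(self.data[contig][pos // self.bin_width])

    def median(self, contig: str) -> float:
        return float(np.median(self.data[contig]))

    def slice(self, contig: str, start: int, end: int) -> np.ndarray:
        b0 = start // self.bin_width
        b1 = -(-end // self.bin_width)
        return self.data[contig][b0:b1]

    def bin_to_pos(self, bin_index: int) -> int:
        """Position of the center of a bin."""
        return bin_index * self.bin_width + self.bin_width // 2


def read_track(path, contigs: ContigSet | None = None, bin_width: int = 1) -> Track:
    """Read a bedGraph file into contiguous per-bin depth vectors.

    Intervals must not overlap; gaps between intervals read back as 0.
    When ``contigs`` is supplied, intervals beyond a contig's length are a
    validation error and vectors span the whole contig.
    """
    raw: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: bedGraph rows have 4 columns")
            chrom, start, end, depth = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if contigs is not None:
                if chrom not in contigs:
                    raise ValidationError(f"{path}:{lineno}: unknown contig {chrom}")
                if end > contigs.lengths[chrom]:
                    raise ValidationError(
                        f"{path}:{lineno}: interval beyond contig {chrom} length"
                    )
            raw.setdefault(chrom, []).append((start, end, depth))
    data: dict[str, np.ndarray] = {}
    for chrom, ivals in raw.items():
        ivals.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValidationError(f"{path}: overlapping intervals on {chrom}")
        length = contigs.lengths[chrom] if contigs is not None else ivals[-1][1]
        n_bins = -(-length // bin_width)
        vec = np.zeros(n_bins)
        for s, e, d in ivals:
            vec[s // bin_width : -(-e // bin_width)] = d
        data[chrom] = vec
    return Track(data, bin_width=bin_width)


def write_track(track: Track, path) -> None:
    """Write a track as bedGraph, merging equal-depth adjacent bins."""
    with open(path, "w") as fh:
        for chrom in track.data:
            vec = track.data[chrom]
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for b0, b1 in zip(starts, ends):
                fh.write(
                    f"{chrom}\t{b0 * track.bin_width}\t{b1 * track.bin_width}\t"
                    f"{vec[b0]:g}\n"
                )


# ---------------------------------------------------------------------------
# assembly statistics
# ---------------------------------------------------------------------------


def assembly_stats(contigs: ContigSet, genome_size: int | None = None) -> dict:
    """N50/L50 (and NG50/LG50 against an estimated genome size).

    N50 is the length of the smallest contig in the minimal set of longest
    contigs whose summed length reaches half the assembly; L50 is the size
    of that set.  NG50/LG50 use half of ``genome_size`` instead.
    """
    if len(contigs) == 0:
        raise ValidationError("assembly_stats requires a nonempty contig set")
    lengths = sorted(contigs.lengths.values(), reverse=True)
    total = sum(lengths)

    def _n50(target: float) -> tuple[int | None, int | None]:
        acc = 0
        for i, n in enumerate(lengths, start=1):
            acc += n
            if acc >= target:
                return n, i
        return None, None  # assembly smaller than target

    n50, l50 = _n50(total / 2)
    stats = {
        "n_contigs": len(lengths),
        "total_bp": total,
        "max": lengths[0],
        "mean": total / len(lengths),
        "N50": n50,
        "L50": l50,
    }
    if genome_size is not None:
        ng50, lg50 = _n50(genome_size / 2)
        stats["NG50"] = ng50
        stats["LG50"] = lg50
    return stats


def feature_count_delta(old: int, new: int) -> tuple[int, float]:
    """Annotation-report delta: absolute change and % change of a feature count."""
    delta = new - old
    pct = round(100.0 * delta / old, 1) if old else float("nan")
    return delta, pct
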