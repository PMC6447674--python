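"""Synthetic genomes, crosses, and evidence tracks with known ground truth.

The generator emulates the study system end to end: multi-chromosome
genomes carrying a centromeric satellite array and TE insertions with a
divergence distribution; fragmentation of those genomes into contigs with
planted chimeric joins; F2 intercross genetic maps with a configurable
along-chromosome crossover landscape (including recombination-suppressing
inversions heterozygous in a cross); a diverged second genome built from
planted fusion/translocation/inversion events, with the whole-genome
alignment coordinates between the pair emitted directly from the event
coordinates; and read-depth plus mate-pair clone-coverage tracks around
planted chimera junctions.

Everything is a pure function of (config, seed): repeated runs are
byte-identical.  Sequence synthesis is optional (``SimConfig.with_sequence``)
so that genome-scale runs can work with length-only contig stubs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import Track
from .model import (
    AlignmentRecord,
    ContigSet,
    GeneModel,
    MarkerRecord,
    RepeatAnnotation,
    SegmentMap,
)


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# configuration and truth types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TEFamily:
    """One TE family to plant: fixed-length copies, normal divergence."""

    name: str
    class_name: str
    copy_number: int
    length: int = 1500
    div_mean: float = 5.0
    div_sd: float = 0.0  # 0 => point mass at div_mean


@dataclass(frozen=True)
class SimConfig:
    """Genome-level simulation parameters.

    ``centromere_positions`` are fractions of each chromosome length; the
    satellite array is centered there.  Defaults model a compact version
    of a cichlid-like genome: mostly subtelo-acrocentric chromosomes
    (centromere fraction 0.1) with a tandem satellite array and a TE
    complement dominated by DNA transposons and LINEs.
    """

    chrom_lengths: tuple[int, ...] = (40_000_000, 35_000_000, 30_000_000)
    centromere_positions: tuple[float, ...] | None = None  # default 0.1 each
    satellite_unit: str = "TTAGGGATCCGGGCCCAATT"
    satellite_array_length: int = 200_000
    satellite_family: str = "ONSATA"
    te_families: tuple[TEFamily, ...] = (
        TEFamily("TcMar", "DNA", copy_number=300, div_mean=4.0, div_sd=3.0),
        TEFamily("hAT", "DNA", copy_number=150, div_mean=6.0, div_sd=4.0),
        TEFamily("Rex", "LINE", copy_number=200, length=3000, div_mean=8.0, div_sd=5.0),
    )
    n_genes: int = 300
    seed: int = 0
    with_sequence: bool = False

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths)

    def centromere_fraction(self, i: int) -> float:
        if self.centromere_positions is None:
            return 0.1
        return self.centromere_positions[i]

    def validate(self) -> None:
        if any(n <= 0 for n in self.chrom_lengths):
            raise ConfigError("chromosome lengths must be > 0")
        if self.centromere_positions is not None:
            if len(self.centromere_positions) != self.n_chromosomes:
                raise ConfigError("one centromere fraction per chromosome required")
            if any(not 0 <= f <= 1 for f in self.centromere_positions):
                raise ConfigError("centromere fractions must lie in [0, 1]")
        if self.satellite_array_length >= min(self.chrom_lengths):
            raise ConfigError("satellite array longer than shortest chromosome")


@dataclass(frozen=True)
class PlantedEvent:
    """One planted structural event; coordinates are on the source genome."""

    type: str  # inversion | fusion | translocation | centromere_move
    chroms: tuple[str, ...]
    intervals: tuple[tuple[int, int], ...] = ()
    detail: dict = field(default_factory=dict)


@dataclass
class TruthSet:
    """Ground truth accumulated across generator stages."""

    chimera_junctions: list[tuple[str, int]] = field(default_factory=list)
    planted_events: list[PlantedEvent] = field(default_factory=list)
    suppressed_intervals: list[tuple[str, int, int, tuple[str, ...]]] = field(
        default_factory=list
    )


@dataclass
class SimulatedGenome:
    contigs: ContigSet  # whole chromosomes
    repeats: list[RepeatAnnotation]
    genes: list[GeneModel]
    truth: TruthSet
    config: SimConfig


# ---------------------------------------------------------------------------
# genome synthesis
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def simulate_genome(config: SimConfig) -> SimulatedGenome:
    """Generate whole chromosomes with satellite arrays, TEs, and genes.

    Each chromosome carries exactly one satellite array centered at its
    configured centromere fraction (clipped into the chromosome); TE
    copies are placed uniformly outside the array with divergences drawn
    from the family's (truncated) normal distribution; genes are placed
    uniformly, avoiding the array, with 2-6 exons each.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    lengths = dict(zip(names, config.chrom_lengths))
    repeats: list[RepeatAnnotation] = []
    genes: list[GeneModel] = []
    sequences: dict[str, str] = {}
    sat_intervals: dict[str, tuple[int, int]] = {}

    for i, chrom in enumerate(names):
        L = lengths[chrom]
        half = config.satellite_array_length // 2
        mid = int(config.centromere_fraction(i) * L)
        start = min(max(mid - half, 0), L - config.satellite_array_length)
        end = start + config.satellite_array_length
        sat_intervals[chrom] = (start, end)
        repeats.append(
            RepeatAnnotation(
                chrom=chrom,
                start=start,
                end=end,
                family=config.satellite_family,
                class_name="Satellite",
                divergence_pct=float(rng.uniform(0.0, 2.0)),
            )
        )

    for i, chrom in enumerate(names):
        L = lengths[chrom]
        s0, e0 = sat_intervals[chrom]
        frac = L / sum(config.chrom_lengths)
        for fam in config.te_families:
            n_copies = int(round(fam.copy_number * frac))
            placed = 0
            while placed < n_copies:
                pos = int(rng.integers(0, max(L - fam.length, 1)))
                if s0 - fam.length < pos < e0:  # keep the array satellite-only
                    continue
                div = fam.div_mean
                if fam.div_sd > 0:
                    div = max(0.0, float(rng.normal(fam.div_mean, fam.div_sd)))
                repeats.append(
                    RepeatAnnotation(
                        chrom=chrom,
                        start=pos,
                        end=pos + fam.length,
                        family=fam.name,
                        class_name=fam.class_name,
                        divergence_pct=div,
                    )
                )
                placed += 1

    gene_counter = 0
    for i, chrom in enumerate(names):
        L = lengths[chrom]
        s0, e0 = sat_intervals[chrom]
        n_here = int(round(config.n_genes * L / sum(config.chrom_lengths)))
        for _ in range(n_here):
            glen = int(rng.integers(5_000, 20_000))
            gstart = int(rng.integers(0, max(L - glen, 1)))
            if s0 - glen < gstart < e0:
                gstart = (e0 + 1000) if e0 + glen + 1000 < L else max(s0 - glen - 1000, 0)
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 7))
            bounds = np.sort(rng.choice(np.arange(1, glen), size=2 * n_exons, replace=False))
            exons = tuple(
                (gstart + int(bounds[2 * k]), gstart + int(bounds[2 * k + 1]))
                for k in range(n_exons)
            )
            gene_counter += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{gene_counter:05d}",
                    chrom=chrom,
                    start=gstart,
                    end=gstart + glen,
                    strand=strand,
                    exons=exons,
                )
            )

    if config.with_sequence:
        unit = config.satellite_unit
        for chrom in names:
            seq = np.frombuffer(_random_sequence(rng, lengths[chrom]).encode(), dtype="S1").copy()
            s0, e0 = sat_intervals[chrom]
            reps = -(-(e0 - s0) // len(unit))
            array = (unit * reps)[: e0 - s0]
            seq[s0:e0] = np.frombuffer(array.encode(), dtype="S1")
            sequences[chrom] = seq.tobytes().decode()
        contigs = ContigSet(sequences=sequences)
    else:
        contigs = ContigSet(lengths=lengths)

    repeats.sort(key=lambda r: (r.chrom, r.start))
    return SimulatedGenome(
        contigs=contigs, repeats=repeats, genes=genes, truth=TruthSet(), config=config
    )


# ---------------------------------------------------------------------------
# fragmentation and chimera planting
# ---------------------------------------------------------------------------


@dataclass
class FragmentedAssembly:
    contigs: ContigSet
    liftover: SegmentMap  # chromosome coordinate -> (contig, offset)
    truth: TruthSet


def fragment_and_chimerize(
    genome: SimulatedGenome,
    target_N50: int,
    n_chimeras: int = 0,
    seed: int = 0,
    min_fragment: int | None = None,
) -> FragmentedAssembly:
    """Cut chromosomes into contigs; join ``n_chimeras`` cross-chromosome pairs.

    Fragment lengths are drawn uniformly in [0.5, 1.5] x target_N50, so the
    realized N50 is close to the target.  Each chimera concatenates two
    fragments from different chromosomes; the junction offset (the length
    of the first fragment) is recorded in the truth set.  The liftover maps
    every genome coordinate to its (contig, offset).
    """
    if target_N50 >= min(genome.contigs.lengths.values()):
        raise ConfigError("target_N50 must be smaller than the shortest chromosome")
    rng = np.random.default_rng(seed)
    min_fragment = min_fragment or max(target_N50 // 10, 1)

    fragments: list[tuple[str, int, int]] = []  # (chrom, start, end)
    for chrom, L in genome.contigs.lengths.items():
        pos = 0
        while pos < L:
            n = int(rng.integers(target_N50 // 2, 3 * target_N50 // 2 + 1))
            if L - pos - n < min_fragment:
                n = L - pos
            fragments.append((chrom, pos, pos + n))
            pos += n

    order = rng.permutation(len(fragments))
    by_chrom_frag: dict[int, str] = {i: fragments[i][0] for i in range(len(fragments))}

    # choose disjoint cross-chromosome fragment pairs for chimeras
    pool = list(order)
    pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    for i in pool:
        if len(pairs) == n_chimeras:
            break
        if i in used:
            continue
        for j in pool:
            if j == i or j in used:
                continue
            if by_chrom_frag[i] != by_chrom_frag[j]:
                pairs.append((i, j))
                used.update((i, j))
                break
    if len(pairs) < n_chimeras:
        raise ConfigError(
            f"cannot plant {n_chimeras} chimeras from {len(fragments)} fragments"
        )

    liftover = SegmentMap()
    truth = TruthSet(
        chimera_junctions=list(genome.truth.chimera_junctions),
        planted_events=list(genome.truth.planted_events),
        suppressed_intervals=list(genome.truth.suppressed_intervals),
    )
    lengths: dict[str, int] = {}
    sequences: dict[str, str] = {}
    have_seq = bool(genome.contigs.sequences)

    counter = 0

    def _next_name() -> str:
        nonlocal counter
        counter += 1
        return f"ctg{counter:05d}"

    paired = {i: j for i, j in pairs}
    consumed = set(used)
    for i in order:
        if i in consumed and i not in paired:
            continue  # second halves are emitted with their partner
        if i in paired:
            j = paired[i]
            name = _next_name()
            (c1, s1, e1), (c2, s2, e2) = fragments[i], fragments[j]
            junction = e1 - s1
            liftover.add(c1, s1, e1, name, 0)
            liftover.add(c2, s2, e2, name, junction)
            lengths[name] = (e1 - s1) + (e2 - s2)
            if have_seq:
                sequences[name] = (
                    genome.contigs.sequence(c1)[s1:e1] + genome.contigs.sequence(c2)[s2:e2]
                )
            truth.chimera_junctions.append((name, junction))
        else:
            name = _next_name()
            chrom, s, e = fragments[i]
            liftover.add(chrom, s, e, name, 0)
            lengths[name] = e - s
            if have_seq:
                sequences[name] = genome.contigs.sequence(chrom)[s:e]

    contigs = ContigSet(sequences=sequences or None, lengths=lengths)
    assert contigs.total_bp == genome.contigs.total_bp, "fragmentation must conserve bp"
    return FragmentedAssembly(contigs=contigs, liftover=liftover.freeze(), truth=truth)


# ---------------------------------------------------------------------------
# F2 crosses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossConfig:
    """One simulated F2 intercross producing a genetic map.

    ``genetic_length_cM`` gives the target map length per chromosome (in
    chromosome order); ``rate_shape`` is "uniform" or "sigmoidal" (low
    crossover density within ``low_end_bp`` of each chromosome end, the
    genome-wide norm in fish maps).  ``suppressed_intervals`` are
    (chrom, start, end) spans with zero crossovers in this cross, modeling
    an inversion heterozygous in the cross.  ``female_male_ratio`` scales
    sex-specific maps around the sex-averaged landscape when set.
    """

    map_id: str = "cross"
    n_F2: int = 200
    n_markers_per_chrom: int = 100
    mapping_function: str = "kosambi"
    genetic_length_cM: tuple[float, ...] = (50.0,)
    rate_shape: str = "sigmoidal"
    low_end_bp: int = 5_000_000
    low_end_factor: float = 0.15
    suppressed_intervals: tuple[tuple[str, int, int], ...] = ()
    female_male_ratio: float | None = None
    seed: int = 0

    def validate(self, n_chrom: int) -> None:
        if self.n_F2 < 2:
            raise ConfigError("n_F2 must be >= 2")
        if self.n_markers_per_chrom < 2:
            raise ConfigError("need >= 2 markers per chromosome")
        if len(self.genetic_length_cM) != n_chrom:
            raise ConfigError("one genetic length per chromosome required")
        if any(g <= 0 for g in self.genetic_length_cM):
            raise ConfigError("genetic lengths must be > 0")
        if self.mapping_function not in ("haldane", "kosambi"):
            raise ConfigError("mapping_function must be haldane or kosambi")


def haldane_d_to_r(d_cM: float) -> float:
    """Haldane mapping function: recombination fraction from map distance."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cM / 100.0))


def haldane_r_to_d(r: float) -> float:
    r = min(r, 0.4999)
    return -50.0 * math.log(1.0 - 2.0 * r)


def kosambi_d_to_r(d_cM: float) -> float:
    return 0.5 * math.tanh(2.0 * d_cM / 100.0)


def kosambi_r_to_d(r: float) -> float:
    r = min(r, 0.4999)
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


_MAPFUN = {
    "haldane": (haldane_d_to_r, haldane_r_to_d),
    "kosambi": (kosambi_d_to_r, kosambi_r_to_d),
}


def _crossover_cdf(L: int, cross: CrossConfig, chrom: str) -> "np.ufunc":
    """Cumulative crossover density on [0, L], normalized to 1 before
    suppression; suppressed intervals are zeroed afterwards (their map
    distance is lost, as in an inversion heterozygote)."""
    grid = np.linspace(0, L, 2049)
    if cross.rate_shape == "uniform":
        dens = np.ones_like(grid)
    elif cross.rate_shape == "sigmoidal":
        w = min(cross.low_end_bp, L // 3)
        k = 8.0 / max(w, 1)
        rise = 1.0 / (1.0 + np.exp(-k * (grid - w)))
        fall = 1.0 / (1.0 + np.exp(-k * ((L - grid) - w)))
        dens = cross.low_end_factor + (1.0 - cross.low_end_factor) * rise * fall
    else:
        raise ConfigError(f"unknown rate_shape {cross.rate_shape!r}")
    step = grid[1] - grid[0]
    total = np.sum(dens) * step
    dens = dens / total  # integrates to 1 over [0, L]
    for sc, s, e in cross.suppressed_intervals:
        if sc == chrom:
            dens[(grid >= s) & (grid < e)] = 0.0
    cum = np.concatenate(([0.0], np.cumsum(dens) * step))
    gridc = np.concatenate((grid, [L + step]))

    def cdf(x):
        return np.interp(x, gridc, cum)

    return cdf


def simulate_cross(
    genome: SimulatedGenome,
    cross: CrossConfig,
    liftover: SegmentMap | None = None,
) -> list[MarkerRecord]:
    """Simulate a genetic map from an F2 intercross over the genome.

    Marker cM positions are cumulative map distances obtained by sampling
    recombinant counts between adjacent markers from Binomial(2 n_F2, r)
    — two informative meioses per F2 — and inverting the chosen mapping
    function on the observed recombination fraction.  Markers inside a
    suppressed interval co-segregate (identical cM).  Contig placements
    come through ``liftover`` when given, else markers sit on the
    chromosomes themselves.
    """
    cross.validate(genome.config.n_chromosomes)
    rng = np.random.default_rng(cross.seed)
    d_to_r, r_to_d = _MAPFUN[cross.mapping_function]
    markers: list[MarkerRecord] = []

    chrom_names = list(genome.contigs.lengths)
    for ci, chrom in enumerate(chrom_names):
        L = genome.contigs.lengths[chrom]
        G = cross.genetic_length_cM[ci]
        cdf = _crossover_cdf(L, cross, chrom)
        want = cross.n_markers_per_chrom
        picks = np.unique(rng.integers(1, L, size=2 * want + 16))
        while len(picks) < want:  # collisions are rare for L >> n
            picks = np.unique(np.concatenate([picks, rng.integers(1, L, size=want)]))
        pos = np.sort(rng.permutation(picks)[:want])
        ratio = cross.female_male_ratio
        if ratio is None:
            scales = {"": 1.0}
        else:
            scales = {
                "": 1.0,
                "f": 2.0 * ratio / (1.0 + ratio),
                "m": 2.0 / (1.0 + ratio),
            }
        cm: dict[str, np.ndarray] = {}
        for key, scale in scales.items():
            cum = np.zeros(len(pos))
            frac = cdf(pos)
            for k in range(1, len(pos)):
                d_true = G * scale * (frac[k] - frac[k - 1])
                r = d_to_r(d_true)
                n_meioses = 2 * cross.n_F2
                k_rec = rng.binomial(n_meioses, r)
                cum[k] = cum[k - 1] + r_to_d(k_rec / n_meioses)
            cm[key] = cum
        for k in range(len(pos)):
            p = int(pos[k])
            if liftover is not None:
                contig, off = liftover.lift(chrom, p)
            else:
                contig, off = chrom, p
            markers.append(
                MarkerRecord(
                    marker_id=f"{cross.map_id}_{chrom}_m{k + 1:04d}",
                    lg=f"LG{ci + 1}",
                    pos_cM=round(float(cm[""][k]), 6),
                    contig=contig,
                    contig_pos=off,
                    strand="+",
                    female_cM=round(float(cm["f"][k]), 6) if ratio is not None else None,
                    male_cM=round(float(cm["m"][k]), 6) if ratio is not None else None,
                )
            )
    return markers


# ---------------------------------------------------------------------------
# species divergence
# ---------------------------------------------------------------------------


@dataclass
class SpeciesPair:
    query_contigs: ContigSet  # second-genome chromosomes (length stubs)
    alignments: list[AlignmentRecord]
    query_repeats: list[RepeatAnnotation]
    truth: TruthSet


def diverge_species(
    genome: SimulatedGenome,
    events: list[PlantedEvent],
    seed: int = 0,
    mean_identity: float = 90.0,
    identity_sd: float = 2.0,
) -> SpeciesPair:
    """Derive a second genome by applying planted structural events.

    Alignment records are synthesized directly from the event coordinates
    (no aligner): collinear runs give forward-strand records, inverted
    runs reverse-strand, fused chromosomes yield records to both reference
    chromosomes.  Satellite annotations are carried through so centromere
    repositioning is recoverable; ``centromere_move`` relocates the query
    satellite array without changing the alignment.
    """
    rng = np.random.default_rng(seed)
    # planted intervals must not collide on any source chromosome
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for ev in events:
        if ev.type == "inversion":
            by_chrom.setdefault(ev.chroms[0], []).append(ev.intervals[0])
        elif ev.type == "translocation":
            by_chrom.setdefault(ev.chroms[0], []).append(ev.intervals[0])
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 < b1:
                raise ConfigError(f"planted events overlap on {chrom}")

    # seg = (ref_chrom, start, end, strand) in query order
    layout: dict[str, list[tuple[str, int, int, str]]] = {
        c: [(c, 0, L, "+")] for c, L in genome.contigs.lengths.items()
    }
    query_names = {c: c for c in layout}
    sat_moves: dict[str, float] = {}
    truth = TruthSet(planted_events=list(events))

    for ev in events:
        if ev.type == "inversion":
            (chrom,) = ev.chroms
            (s, e), = ev.intervals
            segs = layout[chrom]
            new: list[tuple[str, int, int, str]] = []
            for rc, a, b, st in segs:
                if rc != chrom or b <= s or a >= e:
                    new.append((rc, a, b, st))
                    continue
                if a < s:
                    new.append((rc, a, s, st))
                inv_a, inv_b = max(a, s), min(b, e)
                new.append((rc, inv_a, inv_b, "-" if st == "+" else "+"))
                if b > e:
                    new.append((rc, e, b, st))
            layout[chrom] = new
        elif ev.type == "fusion":
            c1, c2 = ev.chroms
            fused = f"{c1}_{c2}"
            layout[fused] = layout.pop(c1) + layout.pop(c2)
            query_names[fused] = fused
        elif ev.type == "translocation":
            src, dst = ev.chroms
            (s, e), (ins, _) = ev.intervals
            moved: list[tuple[str, int, int, str]] = []
            kept: list[tuple[str, int, int, str]] = []
            for rc, a, b, st in layout[src]:
                if rc != src or b <= s or a >= e:
                    kept.append((rc, a, b, st))
                    continue
                if a < s:
                    kept.append((rc, a, s, st))
                moved.append((rc, max(a, s), min(b, e), st))
                if b > e:
                    kept.append((rc, e, b, st))
            layout[src] = kept
            out: list[tuple[str, int, int, str]] = []
            placed = False
            qpos = 0
            for rc, a, b, st in layout[dst]:
                if not placed and qpos + (b - a) > ins:
                    cut = ins - qpos
                    if cut > 0:
                        out.append((rc, a, a + cut, st))
                    out.extend(moved)
                    if cut < b - a:
                        out.append((rc, a + cut, b, st))
                    placed = True
                else:
                    out.append((rc, a, b, st))
                qpos += b - a
            if not placed:
                out.extend(moved)
            layout[dst] = out
        elif ev.type == "centromere_move":
            (chrom,) = ev.chroms
            sat_moves[chrom] = ev.detail.get("new_fraction", 0.5)
        else:
            raise ConfigError(f"unknown event type {ev.type!r}")

    # overlap check per reference chromosome (events must not collide)
    for qc, segs in layout.items():
        per_ref: dict[str, list[tuple[int, int]]] = {}
        for rc, a, b, _ in segs:
            per_ref.setdefault(rc, []).append((a, b))
        for rc, ivs in per_ref.items():
            ivs.sort()
            for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
                if a2 < b1:
                    raise ConfigError(f"planted events overlap on {rc}")

    alignments: list[AlignmentRecord] = []
    q_lengths: dict[str, int] = {}
    query_repeats: list[RepeatAnnotation] = []
    sats = [r for r in genome.repeats if r.class_name == "Satellite"]

    for qc, segs in layout.items():
        qpos = 0
        for rc, a, b, st in segs:
            ident = float(np.clip(rng.normal(mean_identity, identity_sd), 50.0, 100.0))
            alignments.append(
                AlignmentRecord(
                    ref_chrom=rc,
                    query_chrom=qc,
                    ref_start=a,
                    ref_end=b,
                    query_start=qpos,
                    query_end=qpos + (b - a),
                    pct_identity=ident,
                    strand=st,
                )
            )
            for sat in sats:
                if sat.chrom == rc and sat.start >= a and sat.end <= b:
                    if st == "+":
                        qs = qpos + (sat.start - a)
                    else:
                        qs = qpos + (b - sat.end)
                    query_repeats.append(replace(sat, chrom=qc, start=qs, end=qs + sat.length))
            qpos += b - a
        q_lengths[qc] = qpos

    # apply centromere moves on the query annotations
    moved_out: list[RepeatAnnotation] = []
    for r in query_repeats:
        if r.chrom in sat_moves:
            L = q_lengths[r.chrom]
            mid = int(sat_moves[r.chrom] * L)
            s = min(max(mid - r.length // 2, 0), L - r.length)
            moved_out.append(replace(r, start=s, end=s + r.length))
        else:
            moved_out.append(r)

    alignments.sort(key=lambda r: (r.query_chrom, r.query_start))
    return SpeciesPair(
        query_contigs=ContigSet(lengths=q_lengths),
        alignments=alignments,
        query_repeats=sorted(moved_out, key=lambda r: (r.chrom, r.start)),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# evidence tracks
# ---------------------------------------------------------------------------


def simulate_evidence_tracks(
    contigs: ContigSet,
    truth: TruthSet,
    depth_mean: float = 30.0,
    clone_span: int = 40_000,
    seed: int = 0,
    bin_width: int = 100,
    dip_fraction: float = 0.6,
    dip_width: int = 1_000,
    clone_mean: float = 20.0,
) -> tuple[Track, Track]:
    """Read-depth and mate-pair clone-coverage tracks around chimera junctions.

    Depth is Poisson noise around ``depth_mean`` with a ``dip_fraction``
    reduction over ``dip_width`` centered on each junction; clone coverage
    drops to zero over a ``clone_span`` window there (no clone spans a
    chimeric join).
    """
    if depth_mean <= 0:
        raise ConfigError("depth_mean must be > 0")
    if clone_span >= min(contigs.lengths.values()):
        raise ConfigError("clone_span must be shorter than every contig")
    rng = np.random.default_rng(seed)
    junctions: dict[str, list[int]] = {}
    for contig, pos in truth.chimera_junctions:
        junctions.setdefault(contig, []).append(pos)

    depth_data: dict[str, np.ndarray] = {}
    clone_data: dict[str, np.ndarray] = {}
    for contig, L in contigs.lengths.items():
        n_bins = -(-L // bin_width)
        depth = rng.poisson(depth_mean, size=n_bins).astype(float)
        clone = rng.poisson(clone_mean, size=n_bins).astype(float)
        clone[clone == 0] = 1.0  # baseline clone coverage never 0 off-junction
        for j in junctions.get(contig, ()):
            d0 = max((j - dip_width // 2) // bin_width, 0)
            d1 = min(-(-(j + dip_width // 2) // bin_width), n_bins)
            depth[d0:d1] = np.floor(depth[d0:d1] * (1.0 - dip_fraction))
            c0 = max((j - clone_span // 2) // bin_width, 0)
            c1 = min(-(-(j + clone_span // 2) // bin_width), n_bins)
            clone[c0:c1] = 0.0
        depth_data[contig] = depth
        clone_data[contig] = clone
    return Track(depth_data, bin_width), Track(clone_data, bin_width)
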