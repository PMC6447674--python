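"""Marey maps, smoothed recombination-rate curves, suppression regions, LD.

A Marey map plots genetic position (cM) against physical position (bp)
for the markers of one chromosome; its slope is the local recombination
rate.  The smoother is locally weighted quadratic regression (LOESS,
tri-cube weights over the span-fraction nearest markers, degree 2), the
convention of the plotting routines used for such curves; degree-2 local
fits reproduce any quadratic Marey map exactly, so linear maps give a
constant rate and quadratic maps a linear one.  The rate is the central
finite difference of the fitted cM per Mbp, clipped at zero for
reporting (raw values retained).

Recombination-suppressed candidate inversions are grid runs where at
least one cross shows (near-)zero rate while another recombines freely;
run boundaries are refined by the extent of the suppressed crosses' flat
cM plateau, which locates the edges more sharply than the smoothed-rate
threshold crossing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MarkerRecord, ValidationError


@dataclass
class MareyMap:
    chrom: str
    map_id: str
    bp: np.ndarray  # strictly increasing after dedup
    cm: np.ndarray
    out_of_order_flags: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.bp)


@dataclass
class RecombinationCurve:
    chrom: str
    map_id: str
    grid: np.ndarray  # bp
    fitted_cM: np.ndarray
    rate_cM_per_Mbp: np.ndarray  # clipped at 0
    rate_raw: np.ndarray
    span: float
    interval_Mbp: float

    @property
    def total_cM(self) -> float:
        return float(self.fitted_cM[-1] - self.fitted_cM[0])


@dataclass
class SuppressionRegion:
    chrom: str
    interval: tuple[int, int]
    suppressed_in: list[str]
    active_in: list[str]
    mean_rates: dict[str, float]
    terminal: bool = False


def build_marey_map(
    markers: list[MarkerRecord],
    map_id: str = "",
    chrom: str | None = None,
    tolerance_cM: float = 0.0,
    sex: str | None = None,
) -> MareyMap:
    """Marey map from markers anchored to one chromosome.

    Markers must carry chromosome coordinates in ``contig``/``contig_pos``
    (i.e. after anchoring).  Exact-duplicate bp positions collapse to
    their median cM; indices where cM then decreases by more than
    ``tolerance_cM`` are flagged, not removed.  ``sex`` selects the
    female_cM/male_cM column instead of the sex-averaged one.
    """
    ms = [m for m in markers if chrom is None or m.contig == chrom]
    if chrom is None and ms:
        chroms = {m.contig for m in ms}
        if len(chroms) > 1:
            raise ValidationError("markers span several chromosomes; pass chrom=")
        chrom = next(iter(chroms))
    if len(ms) < 2:
        raise ValidationError("a Marey map needs >= 2 markers")

    def _cm(m: MarkerRecord) -> float:
        if sex == "female":
            if m.female_cM is None:
                raise ValidationError(f"marker {m.marker_id} lacks female_cM")
            return m.female_cM
        if sex == "male":
            if m.male_cM is None:
                raise ValidationError(f"marker {m.marker_id} lacks male_cM")
            return m.male_cM
        return m.pos_cM

    pairs = sorted((m.contig_pos, _cm(m)) for m in ms)
    bp: list[int] = []
    cm: list[float] = []
    i = 0
    while i < len(pairs):
        j = i
        while j < len(pairs) and pairs[j][0] == pairs[i][0]:
            j += 1
        bp.append(pairs[i][0])
        cm.append(float(np.median([p[1] for p in pairs[i:j]])))
        i = j
    flags = [k for k in range(1, len(cm)) if cm[k] < cm[k - 1] - tolerance_cM]
    return MareyMap(
        chrom=chrom or "", map_id=map_id, bp=np.array(bp, float), cm=np.array(cm), out_of_order_flags=flags
    )


def _loess_fit(x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float) -> np.ndarray:
    """Local quadratic regression with tri-cube weights at each grid point.

    The neighborhood is the ``ceil(span * n)`` nearest markers; the
    bandwidth is the distance to the farthest of them.  Exact for
    polynomials of degree <= 2 by construction.
    """
    n = len(x)
    q = max(int(math.ceil(span * n)), 4)
    q = min(q, n)
    fitted = np.empty(len(grid))
    for gi, x0 in enumerate(grid):
        d = np.abs(x - x0)
        idx = np.argpartition(d, q - 1)[:q]
        h = d[idx].max()
        if h == 0:
            fitted[gi] = y[idx].mean()
            continue
        u = d[idx] / h
        w = np.clip(1.0 - u**3, 0.0, None) ** 3
        w[u >= 1.0] = 0.0
        if np.count_nonzero(w) < 3:  # keep the quadratic solvable
            w = np.maximum(w, 1e-9)
        t = (x[idx] - x0) / h  # scale for conditioning
        X = np.column_stack((np.ones_like(t), t, t * t))
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[idx] * sw, rcond=None)
        fitted[gi] = beta[0]
    return fitted


def smooth_recombination_rate(
    marey: MareyMap, span: float = 0.17, interval_Mbp: float = 0.1
) -> RecombinationCurve:
    """LOESS-smoothed Marey curve and its derivative in cM/Mbp.

    The fitted curve is evaluated on a bp grid at ``interval_Mbp`` spacing
    covering [first marker, last marker]; the rate is the central finite
    difference of the fitted cM (one-sided at the ends), clipped at zero
    for the reported track with the raw derivative retained.
    """
    n = marey.n
    minimum = max(4, int(math.ceil(span * n)))
    if n < minimum:
        raise ValidationError(f"need >= {minimum} markers for span {span}, got {n}")
    step = interval_Mbp * 1e6
    grid = np.arange(marey.bp[0], marey.bp[-1] + step / 2, step)
    fitted = _loess_fit(marey.bp, marey.cm, grid, span)
    raw = np.gradient(fitted, grid) * 1e6  # cM per Mbp
    return RecombinationCurve(
        chrom=marey.chrom,
        map_id=marey.map_id,
        grid=grid,
        fitted_cM=fitted,
        rate_cM_per_Mbp=np.clip(raw, 0.0, None),
        rate_raw=raw,
        span=span,
        interval_Mbp=interval_Mbp,
    )


def compare_maps(curves: list[RecombinationCurve]) -> tuple[pd.DataFrame, dict[str, float]]:
    """Align rate curves from several maps on one chromosome.

    Rates are re-gridded to the union grid (restricted to the region the
    grids jointly cover is NOT required — linear interpolation within each
    curve's own grid, NaN outside).  Per-map total map length is the
    fitted cM difference between curve ends.
    """
    chroms = {c.chrom for c in curves}
    if len(chroms) > 1:
        raise ValidationError("curves must share one chromosome")
    lo = max(c.grid[0] for c in curves)
    hi = min(c.grid[-1] for c in curves)
    if hi <= lo:
        raise ValidationError("curve grids do not overlap")
    union = np.unique(np.concatenate([c.grid for c in curves]))
    cols = {"bp": union}
    totals: dict[str, float] = {}
    for c in curves:
        cols[c.map_id] = np.interp(union, c.grid, c.rate_cM_per_Mbp, left=np.nan, right=np.nan)
        totals[c.map_id] = c.total_cM
    return pd.DataFrame(cols), totals


def compare_sex_maps(
    female: MareyMap, male: MareyMap, span: float = 0.17, interval_Mbp: float = 0.1
) -> dict:
    """Female:male rate ratio along one chromosome, plus map totals.

    Returns the grid, the two rate tracks, their ratio (NaN where the
    male rate is zero), total female and male map lengths, and the grid
    intervals where the male rate exceeds the female rate.
    """
    if female.chrom != male.chrom:
        raise ValidationError("sex maps must be on one chromosome")
    cf = smooth_recombination_rate(female, span=span, interval_Mbp=interval_Mbp)
    cm_ = smooth_recombination_rate(male, span=span, interval_Mbp=interval_Mbp)
    table, _ = compare_maps(
        [
            RecombinationCurve(cf.chrom, "female", cf.grid, cf.fitted_cM, cf.rate_cM_per_Mbp, cf.rate_raw, span, interval_Mbp),
            RecombinationCurve(cm_.chrom, "male", cm_.grid, cm_.fitted_cM, cm_.rate_cM_per_Mbp, cm_.rate_raw, span, interval_Mbp),
        ]
    )
    f = table["female"].to_numpy()
    m = table["male"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(m > 0, f / m, np.nan)
    male_excess = m > f
    bp = table["bp"].to_numpy()
    flagged: list[tuple[int, int]] = []
    start = None
    for i, hot in enumerate(male_excess):
        if hot and start is None:
            start = i
        if (not hot or i == len(male_excess) - 1) and start is not None:
            end = i if not hot else i + 1
            flagged.append((int(bp[start]), int(bp[min(end, len(bp) - 1)])))
            start = None
    return {
        "bp": bp,
        "female_rate": f,
        "male_rate": m,
        "ratio": ratio,
        "total_female_cM": cf.total_cM,
        "total_male_cM": cm_.total_cM,
        "male_gt_female_intervals": flagged,
    }


def detect_suppression_regions(
    curves: list[RecombinationCurve],
    suppressed_rate: float = 0.1,
    active_rate: float = 1.0,
    min_length: int = 5_000_000,
    refine_plateau_tol_cM: float = 1.0,
) -> list[SuppressionRegion]:
    """Candidate inversions: regions suppressed in some crosses, active in others.

    A region is a maximal grid run of >= ``min_length`` where at least one
    map's rate is <= ``suppressed_rate`` while at least one other map's is
    >= ``active_rate`` (suppression shared by every map is the common
    landscape, not an event).  Each run's boundaries are then refined to
    the extent of the suppressed maps' flat cM plateau (within
    ``refine_plateau_tol_cM`` of the run's median fitted cM), which
    undoes the inward bias of the smoothed-rate threshold.  Runs within
    min_length/2 of the chromosome ends are annotated terminal, since
    chromosome-end suppression is the genome-wide norm.
    """
    if len(curves) < 2:
        raise ValidationError("need >= 2 curves")
    union = np.unique(np.concatenate([c.grid for c in curves]))
    rates = {
        c.map_id: np.interp(union, c.grid, c.rate_cM_per_Mbp) for c in curves
    }
    fitted = {c.map_id: np.interp(union, c.grid, c.fitted_cM) for c in curves}
    mat = np.vstack(list(rates.values()))
    mask = (mat.min(axis=0) <= suppressed_rate) & (mat.max(axis=0) >= active_rate)

    regions: list[SuppressionRegion] = []
    i = 0
    n = len(union)
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        start_bp, end_bp = union[i], union[j - 1]
        sel = slice(i, j)
        means = {mid: float(np.mean(r[sel])) for mid, r in rates.items()}
        suppressed_in = sorted(m for m, v in means.items() if v <= suppressed_rate)
        active_in = sorted(m for m, v in means.items() if v >= active_rate)
        if suppressed_in and active_in:
            # intersect the suppressed maps' plateau extents, then hull
            # with the rate run so refinement never loses the detection
            lo_ext, hi_ext = [], []
            for mid in suppressed_in:
                plateau = float(np.median(fitted[mid][sel]))
                ok = np.abs(fitted[mid] - plateau) <= refine_plateau_tol_cM
                a, b = i, j - 1
                while a > 0 and ok[a - 1]:
                    a -= 1
                while b < n - 1 and ok[b + 1]:
                    b += 1
                lo_ext.append(union[a])
                hi_ext.append(union[b])
            lo = min(max(lo_ext), start_bp)
            hi = max(min(hi_ext), end_bp)
            if hi - lo >= min_length:
                terminal = lo - union[0] < min_length / 2 or union[-1] - hi < min_length / 2
                regions.append(
                    SuppressionRegion(
                        chrom=curves[0].chrom,
                        interval=(int(lo), int(hi)),
                        suppressed_in=suppressed_in,
                        active_in=active_in,
                        mean_rates=means,
                        terminal=terminal,
                    )
                )
        i = j
    return regions


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


class GenotypeMatrix:
    """Allele-dosage genotypes: individuals x loci, values {0, 1, 2, NaN}."""

    def __init__(
        self,
        dosages: np.ndarray,
        positions: list[tuple[str, int]],
        locus_ids: list[str] | None = None,
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValidationError("dosage matrix must be individuals x loci")
        if dosages.shape[0] < 2:
            raise ValidationError("LD needs >= 2 individuals")
        if dosages.shape[1] != len(positions):
            raise ValidationError("one position per locus required")
        valid = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValidationError("dosages must be 0, 1, 2, or missing")
        self.dosages = dosages
        self.positions = list(positions)
        self.locus_ids = locus_ids or [f"locus{i}" for i in range(len(positions))]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]


def compute_ld_r2(
    genotypes: GenotypeMatrix,
    max_pair_distance: int | None = None,
    r2_report_threshold: float = 0.97,
) -> tuple[pd.DataFrame, dict]:
    """Pairwise LD as the squared Pearson correlation of allele dosages.

    Pairs are same-chromosome loci within ``max_pair_distance`` (all pairs
    when None).  Individuals missing either locus are excluded per pair;
    monomorphic loci (zero variance among shared individuals) are
    skipped.  ``flagged`` marks r² above the reporting threshold.
    """
    rows = []
    log = {"n_pairs": 0, "n_skipped_monomorphic": 0, "n_skipped_missing": 0}
    D = genotypes.dosages
    for i in range(genotypes.n_loci):
        ci, bi = genotypes.positions[i]
        for j in range(i + 1, genotypes.n_loci):
            cj, bj = genotypes.positions[j]
            if ci != cj:
                continue
            dist = abs(bj - bi)
            if max_pair_distance is not None and dist > max_pair_distance:
                continue
            ok = ~(np.isnan(D[:, i]) | np.isnan(D[:, j]))
            if ok.sum() < 2:
                log["n_skipped_missing"] += 1
                continue
            a, b = D[ok, i], D[ok, j]
            if a.std() == 0 or b.std() == 0:
                log["n_skipped_monomorphic"] += 1
                continue
            r = np.corrcoef(a, b)[0, 1]
            r2 = float(r * r)
            log["n_pairs"] += 1
            rows.append(
                {
                    "locus_i": genotypes.locus_ids[i],
                    "locus_j": genotypes.locus_ids[j],
                    "chrom": ci,
                    "distance_bp": dist,
                    "n": int(ok.sum()),
                    "r2": r2,
                    "flagged": r2 > r2_report_threshold,
                }
            )
    return pd.DataFrame(rows), log
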