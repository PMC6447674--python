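"""Marey maps, LOESS smoothing, sex/cross comparison, suppression, LD."""

import itertools
import subprocess

import numpy as np
import pytest

from chromostruct.model import MarkerRecord, ValidationError
from chromostruct.recombination import (
    GenotypeMatrix,
    MareyMap,
    build_marey_map,
    compare_maps,
    compare_sex_maps,
    compute_ld_r2,
    detect_suppression_regions,
    smooth_recombination_rate,
)


def _markers(points, chrom="chr1", female=None, male=None):
    out = []
    for i, (bp, cm) in enumerate(points):
        out.append(
            MarkerRecord(
                f"m{i}", "LG1", cm, chrom, bp,
                female_cM=None if female is None else female[i],
                male_cM=None if male is None else male[i],
            )
        )
    return out


class TestBuildMareyMap:
    def test_monotone_map_no_flags(self):
        mm = build_marey_map(_markers([(i * 1000, i * 0.5) for i in range(10)]))
        assert mm.out_of_order_flags == []
        assert mm.n == 10

    def test_out_of_order_marker_flagged_not_removed(self):
        pts = [(0, 0.0), (1000, 1.0), (2000, 0.4), (3000, 2.0)]
        mm = build_marey_map(_markers(pts))
        assert mm.out_of_order_flags == [2]
        assert mm.n == 4

    def test_duplicate_bp_collapsed_to_median(self):
        pts = [(0, 0.0), (1000, 5.0), (1000, 7.0), (2000, 8.0)]
        mm = build_marey_map(_markers(pts))
        assert mm.n == 3
        assert mm.cm[1] == 6.0

    def test_fewer_than_two_markers_rejected(self):
        with pytest.raises(ValidationError):
            build_marey_map(_markers([(0, 0.0)]))


class TestLoessSmoothing:
    def test_linear_marey_map_constant_rate(self):
        bp = np.linspace(0, 30e6, 120)
        curve = smooth_recombination_rate(MareyMap("c", "t", bp, 2 * bp / 1e6))
        interior = slice(2, -2)
        assert np.abs(curve.rate_cM_per_Mbp[interior] - 2.0).max() < 1e-6

    def test_quadratic_marey_map_linear_rate(self):
        a = 0.05
        bp = np.linspace(0, 30e6, 120)
        curve = smooth_recombination_rate(MareyMap("c", "t", bp, a * (bp / 1e6) ** 2))
        interior = slice(2, -2)
        expected = 2 * a * (curve.grid / 1e6)
        assert np.abs(curve.rate_raw[interior] - expected[interior]).max() < 1e-6

    def test_plateau_region_near_zero_rate(self):
        bp = np.linspace(0, 30e6, 200)
        cm = np.where(bp < 15e6, 2 * bp / 1e6, 30.0)  # slope 2 then plateau
        curve = smooth_recombination_rate(MareyMap("c", "t", bp, cm))
        deep = curve.grid > 22e6  # well inside the plateau
        assert np.abs(curve.rate_cM_per_Mbp[deep]).max() < 0.1

    def test_negative_rates_clipped_with_raw_retained(self):
        rng = np.random.default_rng(2)
        bp = np.linspace(0, 10e6, 60)
        cm = np.sort(rng.uniform(0, 20, 60))
        cm[30] = cm[29]  # local flatness encourages negative fit slopes
        curve = smooth_recombination_rate(MareyMap("c", "t", bp, cm))
        assert (curve.rate_cM_per_Mbp >= 0).all()
        assert len(curve.rate_raw) == len(curve.grid)

    def test_total_cm_invariant_under_bp_rescaling(self):
        rng = np.random.default_rng(3)
        bp = np.sort(rng.choice(np.arange(1, 10**7), 80, replace=False)).astype(float)
        cm = np.maximum.accumulate(rng.uniform(0, 1, 80)).cumsum()
        c1 = smooth_recombination_rate(MareyMap("c", "t", bp, cm), interval_Mbp=0.1)
        c2 = smooth_recombination_rate(
            MareyMap("c", "t", bp * 10, cm), interval_Mbp=1.0
        )
        assert c1.total_cM == pytest.approx(c2.total_cM, abs=1e-6)

    def test_insufficient_markers_rejected_naming_minimum(self):
        bp = np.array([0.0, 1e6, 2e6])
        with pytest.raises(ValidationError, match="4"):
            smooth_recombination_rate(MareyMap("c", "t", bp, bp / 1e6))

    def test_matches_independent_r_loess(self, tmp_path):
        # cross-check the local quadratic tri-cube fit against R's loess
        # (degree=2, surface="direct") on a noisy sigmoidal Marey map
        rng = np.random.default_rng(4)
        bp = np.sort(rng.choice(np.arange(1, 30_000_000), 150, replace=False)).astype(float)
        cm = 60 * (bp / 3e7) ** 2 + rng.normal(0, 0.8, len(bp)).cumsum() * 0.05
        cm = np.maximum.accumulate(cm)
        curve = smooth_recombination_rate(MareyMap("c", "t", bp, cm))
        xy, grid_f, out = tmp_path / "xy.tsv", tmp_path / "grid.tsv", tmp_path / "fit.tsv"
        np.savetxt(xy, np.column_stack([bp, cm]), delimiter="\t")
        np.savetxt(grid_f, curve.grid, delimiter="\t")
        r_code = (
            f'd <- read.table("{xy}"); g <- scan("{grid_f}"); '
            'fit <- loess(V2 ~ V1, data=d, span=0.17, degree=2, '
            'family="gaussian", surface="direct"); '
            'p <- predict(fit, newdata=data.frame(V1=g)); '
            f'write(p, "{out}", ncolumns=1)'
        )
        subprocess.run(["Rscript", "-e", r_code], check=True, capture_output=True)
        rfit = np.loadtxt(out)
        assert np.abs(rfit - curve.fitted_cM).max() < 0.05


class TestCompareMaps:
    def _curve(self, map_id, slope=2.0, n=80, L=20e6):
        bp = np.linspace(0, L, n)
        mm = MareyMap("chr1", map_id, bp, slope * bp / 1e6)
        return smooth_recombination_rate(mm)

    def test_identical_curves_zero_difference(self):
        c1, c2 = self._curve("a"), self._curve("b")
        table, totals = compare_maps([c1, c2])
        diff = (table["a"] - table["b"]).abs().max()
        assert diff == 0.0
        assert totals["a"] == totals["b"]

    def test_single_curve_identity(self):
        c = self._curve("a")
        table, totals = compare_maps([c])
        assert np.allclose(table["a"].to_numpy(), c.rate_cM_per_Mbp)
        assert totals["a"] == c.total_cM

    def test_two_to_one_crossover_density_ratio(self):
        from chromostruct.simulate import CrossConfig, SimConfig, simulate_cross, simulate_genome

        g = simulate_genome(SimConfig(chrom_lengths=(20_000_000,), seed=71))
        curves = []
        for map_id, length in (("hot", 80.0), ("cold", 40.0)):
            cross = CrossConfig(
                map_id=map_id, n_F2=500, n_markers_per_chrom=120,
                genetic_length_cM=(length,), rate_shape="uniform", seed=72,
            )
            mk = simulate_cross(g, cross)
            curves.append(smooth_recombination_rate(build_marey_map(mk, map_id=map_id)))
        _, totals = compare_maps(curves)
        assert totals["hot"] / totals["cold"] == pytest.approx(2.0, rel=0.10)

    def test_disjoint_grids_rejected(self):
        bp1 = np.linspace(0, 5e6, 50)
        bp2 = np.linspace(10e6, 15e6, 50)
        c1 = smooth_recombination_rate(MareyMap("c", "a", bp1, bp1 / 1e6))
        c2 = smooth_recombination_rate(MareyMap("c", "b", bp2, bp2 / 1e6))
        with pytest.raises(ValidationError):
            compare_maps([c1, c2])


class TestCompareSexMaps:
    def test_identical_maps_unit_ratio(self):
        bp = np.linspace(0, 20e6, 100)
        cm = 2 * bp / 1e6
        f = MareyMap("chr1", "f", bp, cm)
        m = MareyMap("chr1", "m", bp, cm.copy())
        out = compare_sex_maps(f, m)
        interior = ~np.isnan(out["ratio"])
        assert np.allclose(out["ratio"][interior], 1.0)
        assert out["male_gt_female_intervals"] == []

    def test_female_scaled_ratio_recovered(self):
        from chromostruct.simulate import CrossConfig, SimConfig, simulate_cross, simulate_genome

        g = simulate_genome(SimConfig(chrom_lengths=(20_000_000,), seed=73))
        cross = CrossConfig(
            n_F2=800, n_markers_per_chrom=120, genetic_length_cM=(60.0,),
            rate_shape="uniform", female_male_ratio=1.24, seed=74,
        )
        mk = simulate_cross(g, cross)
        f = build_marey_map(mk, map_id="f", sex="female")
        m = build_marey_map(mk, map_id="m", sex="male")
        out = compare_sex_maps(f, m)
        assert out["total_female_cM"] / out["total_male_cM"] == pytest.approx(1.24, rel=0.05)

    def test_male_excess_region_flagged(self):
        bp = np.linspace(0, 20e6, 100)
        f_cm = np.where(bp < 10e6, 2 * bp / 1e6, 20.0)       # female plateau after 10 Mbp
        m_cm = 1.5 * bp / 1e6                                 # male keeps recombining
        out = compare_sex_maps(MareyMap("c", "f", bp, f_cm), MareyMap("c", "m", bp, m_cm))
        assert out["male_gt_female_intervals"]
        lo, hi = out["male_gt_female_intervals"][-1]
        assert hi > 15e6  # the male-excess tail is recovered


class TestDetectSuppressionRegions:
    def _curves_with_suppression(self, seed, suppressed_maps=2):
        from chromostruct.simulate import CrossConfig, SimConfig, simulate_cross, simulate_genome

        L = 32_000_000
        g = simulate_genome(SimConfig(chrom_lengths=(L,), seed=11))
        interval = ("chr1", 9_000_000, 24_000_000)
        curves = []
        for k in range(4):
            cross = CrossConfig(
                map_id=f"m{k}", n_F2=300, n_markers_per_chrom=150,
                genetic_length_cM=(55.0,), rate_shape="sigmoidal",
                suppressed_intervals=(interval,) if k < suppressed_maps else (),
                seed=seed * 10 + k,
            )
            mk = simulate_cross(g, cross)
            curves.append(smooth_recombination_rate(build_marey_map(mk, map_id=f"m{k}")))
        return curves, (interval[1], interval[2])

    def test_planted_region_recovered_with_reciprocal_overlap(self):
        curves, (s, e) = self._curves_with_suppression(seed=1)
        regions = [r for r in detect_suppression_regions(curves) if not r.terminal]
        assert regions
        best = max(
            min(
                (min(r.interval[1], e) - max(r.interval[0], s)) / (e - s),
                (min(r.interval[1], e) - max(r.interval[0], s))
                / (r.interval[1] - r.interval[0]),
            )
            for r in regions
        )
        assert best >= 0.8
        assert regions[0].suppressed_in == ["m0", "m1"]

    def test_suppression_in_all_maps_is_no_event(self):
        curves, _ = self._curves_with_suppression(seed=2, suppressed_maps=4)
        assert [r for r in detect_suppression_regions(curves) if not r.terminal] == []

    def test_homogeneous_landscape_no_candidates(self):
        curves, _ = self._curves_with_suppression(seed=3, suppressed_maps=0)
        assert [r for r in detect_suppression_regions(curves) if not r.terminal] == []

    def test_single_curve_rejected(self):
        curves, _ = self._curves_with_suppression(seed=4, suppressed_maps=0)
        with pytest.raises(ValidationError):
            detect_suppression_regions(curves[:1])


class TestComputeLdR2:
    def _gm(self, cols, positions=None):
        arr = np.array(cols, float).T
        pos = positions or [("c", i * 1000) for i in range(arr.shape[1])]
        return GenotypeMatrix(arr, pos)

    def test_duplicated_locus_r2_one(self):
        v = [0, 0, 1, 1, 2, 2]
        df, _ = compute_ld_r2(self._gm([v, v]))
        assert df.r2.iloc[0] == pytest.approx(1.0)
        assert bool(df.flagged.iloc[0])

    def test_perfect_negative_association_r2_one(self):
        df, _ = compute_ld_r2(self._gm([[0, 0, 1, 1, 2, 2], [2, 2, 1, 1, 0, 0]]))
        assert df.r2.iloc[0] == pytest.approx(1.0)

    def test_single_recombinant_hand_oracle(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [0, 1, 1, 1, 2, 2]  # one individual changed
        df, _ = compute_ld_r2(self._gm([a, b]))
        # direct-summation oracle
        x, y = np.array(a, float), np.array(b, float)
        n = len(x)
        num = (n * (x * y).sum() - x.sum() * y.sum()) ** 2
        den = (n * (x * x).sum() - x.sum() ** 2) * (n * (y * y).sum() - y.sum() ** 2)
        assert df.r2.iloc[0] == pytest.approx(num / den)

    def test_exhaustive_three_individual_tables_match_oracle(self):
        for a in itertools.product((0, 1, 2), repeat=3):
            for b in itertools.product((0, 1, 2), repeat=3):
                x, y = np.array(a, float), np.array(b, float)
                if x.std() == 0 or y.std() == 0:
                    continue
                df, _ = compute_ld_r2(self._gm([list(a), list(b)]))
                n = 3
                num = (n * (x * y).sum() - x.sum() * y.sum()) ** 2
                den = (n * (x * x).sum() - x.sum() ** 2) * (
                    n * (y * y).sum() - y.sum() ** 2
                )
                assert df.r2.iloc[0] == pytest.approx(num / den, abs=1e-12)

    def test_monomorphic_locus_skipped(self):
        df, log = compute_ld_r2(self._gm([[1, 1, 1, 1], [0, 1, 2, 1]]))
        assert df.empty and log["n_skipped_monomorphic"] == 1

    def test_missing_individuals_excluded_pairwise(self):
        a = [0, 1, 2, np.nan]
        b = [0, 1, 2, 2]
        df, _ = compute_ld_r2(self._gm([a, b]))
        assert df.n.iloc[0] == 3 and df.r2.iloc[0] == pytest.approx(1.0)

    def test_max_pair_distance_filter(self):
        gm = self._gm(
            [[0, 1, 2], [0, 1, 2], [0, 1, 2]],
            positions=[("c", 0), ("c", 500), ("c", 10_000)],
        )
        df, _ = compute_ld_r2(gm, max_pair_distance=1_000)
        assert len(df) == 1
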