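"""dSTORM pipeline: IO, filtering, merging, homogenization, DBSCAN,
cluster measurement and stratified summaries."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from dolinekit.smlm import (PipelineConfig, cluster_dbscan,
                            filter_localizations, homogenize_density,
                            measure_clusters, merge_consecutive,
                            read_localizations, run_pipeline,
                            stratify_and_summarize, write_localizations)

from conftest import make_table


def dbscan_union_find(points, eps, minpts):
    """Independent DBSCAN oracle via pairwise distances and union-find,
    with the same published semantics (self-counting cores, border points
    to the lowest cluster id)."""
    pts = np.asarray(points, float)
    m = len(pts)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    adj = d2 <= eps * eps
    core = adj.sum(1) >= minpts
    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(m):
        if not core[i]:
            continue
        for j in range(i + 1, m):
            if core[j] and adj[i, j]:
                parent[find(i)] = find(j)
    roots = {}
    labels = np.full(m, -1, int)
    for i in range(m):
        if core[i]:
            r = find(i)
            if r not in roots:
                roots[r] = None
    # number components by smallest member index
    comp_min = {}
    for i in range(m):
        if core[i]:
            r = find(i)
            comp_min[r] = min(comp_min.get(r, i), i)
    order = sorted(comp_min, key=lambda r: comp_min[r])
    ids = {r: k for k, r in enumerate(order)}
    for i in range(m):
        if core[i]:
            labels[i] = ids[find(i)]
    for i in range(m):
        if not core[i]:
            cands = [labels[j] for j in range(m) if core[j] and adj[i, j]]
            if cands:
                labels[i] = min(cands)
    return labels


THUNDERSTORM_CSV = """\
"frame","x [nm]","y [nm]","sigma [nm]","intensity [photon]","uncertainty [nm]"
1,100.5,200.25,150.0,1200.0,12.5
2,101.0,201.0,140.0,900.0,18.0
5,3000.0,4000.0,160.0,2500.0,9.0
"""


class TestIO:
    def test_read_write_roundtrip(self, tmp_path):
        p = tmp_path / "locs.csv"
        p.write_text(THUNDERSTORM_CSV)
        t = read_localizations(p, roi_area=1e6)
        assert len(t) == 3
        assert t.df.loc[0, "x"] == 100.5
        assert t.df.loc[1, "uncertainty"] == 18.0
        q = tmp_path / "out.csv"
        write_localizations(t, q)
        t2 = read_localizations(q, roi_area=1e6)
        pd.testing.assert_frame_equal(t.df, t2.df)

    def test_bare_header_aliases(self, tmp_path):
        p = tmp_path / "locs.csv"
        p.write_text("frame,x,y,sigma,intensity,uncertainty\n1,0,0,100,500,10\n")
        t = read_localizations(p, roi_area=1e4)
        assert t.df.loc[0, "intensity"] == 500

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "locs.csv"
        p.write_text("frame,x [nm],y [nm],sigma [nm],intensity [photon],"
                     "uncertainty [nm]\n")
        t = read_localizations(p, roi_area=1e4)
        assert len(t) == 0

    def test_missing_column(self, tmp_path):
        p = tmp_path / "locs.csv"
        p.write_text("frame,x [nm],y [nm]\n1,0,0\n")
        with pytest.raises(ValueError, match="missing"):
            read_localizations(p, roi_area=1e4)

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "locs.csv"
        p.write_text("frame,x,y,sigma,intensity,uncertainty\n"
                     "1,0,0,100,500,10\n1,oops,0,100,500,10\n")
        with pytest.raises(ValueError, match=r"line\(s\) \[3\]"):
            read_localizations(p, roi_area=1e4)

    def test_frames_must_start_at_one(self):
        with pytest.raises(ValueError, match="frames"):
            make_table([0, 1], [0, 1], [0, 1])

    def test_roi_polygon_area_consistency(self):
        with pytest.raises(ValueError, match="inconsistent"):
            make_table([1], [5.0], [5.0], roi_area=999.0,
                       roi_polygon=[(0, 0), (10, 0), (10, 10), (0, 10)])


class TestFilter:
    def test_boundary_is_strict(self):
        t = make_table([1], [0.0], [0.0], intensity=[300.0],
                       uncertainty=[10.0], sigma=[100.0])
        assert len(filter_localizations(t)) == 0

    def test_just_inside_window_kept(self):
        t = make_table([1], [0.0], [0.0], intensity=[301.0],
                       uncertainty=[34.9], sigma=[299.0])
        assert len(filter_localizations(t)) == 1

    def test_one_survivor_of_five(self):
        t = make_table([1, 2, 3, 4, 5], np.arange(5.0), np.zeros(5),
                       intensity=[299.0, 5001.0, 1000.0, 1000.0, 1000.0],
                       uncertainty=[10.0, 10.0, 36.0, 10.0, 10.0],
                       sigma=[100.0, 100.0, 100.0, 310.0, 100.0])
        out = filter_localizations(t)
        assert len(out) == 1
        assert out.df.loc[0, "frame"] == 5


class TestMerge:
    def test_coincident_chain_collapses(self):
        t = make_table([1, 2, 3], [50.0] * 3, [60.0] * 3,
                       intensity=[400.0, 500.0, 600.0],
                       uncertainty=[12.0, 8.0, 20.0], sigma=[100, 120, 140])
        out = merge_consecutive(t)
        assert len(out) == 1
        row = out.df.iloc[0]
        assert row["frame"] == 1
        assert row["x"] == 50.0 and row["y"] == 60.0
        assert row["intensity"] == 1500.0        # summed
        assert row["uncertainty"] == 8.0         # min
        assert row["sigma"] == pytest.approx(120.0)   # mean

    def test_beyond_radius_not_merged(self):
        t = make_table([1, 2], [0.0, 30.0], [0.0, 0.0])
        assert len(merge_consecutive(t)) == 2

    def test_mean_position_of_chain(self):
        t = make_table([1, 2], [0.0, 10.0], [0.0, 0.0])
        out = merge_consecutive(t)
        assert len(out) == 1
        assert out.df.loc[0, "x"] == pytest.approx(5.0)

    def test_gap_frame_breaks_chain(self):
        t = make_table([1, 3], [0.0, 0.0], [0.0, 0.0])
        assert len(merge_consecutive(t)) == 2

    def test_empty_table(self):
        t = make_table([], [], [])
        assert len(merge_consecutive(t)) == 0


class TestHomogenize:
    def test_uniform_fixture_truncates_to_k2(self):
        # 1000 blinks spread 100 per frame over 10 frames in a 1e6 nm^2
        # ROI; target 2e-4 blinks/nm^2 = 200 blinks => k = 2 exactly
        frames = np.repeat(np.arange(1, 11), 100)
        t = make_table(frames, np.arange(1000.0) % 977,
                       np.arange(1000.0) % 983, roi_area=1e6)
        out, k, dens = homogenize_density(t)
        assert k == 2
        assert len(out) == 200
        assert dens == pytest.approx(2e-4)

    def test_exact_hit_in_first_frame(self):
        t = make_table(np.ones(200, int), np.arange(200.0), np.zeros(200),
                       roi_area=1e6)
        out, k, dens = homogenize_density(t)
        assert k == 1 and dens == pytest.approx(2e-4)

    def test_tie_prefers_smaller_k(self):
        # 150 blinks in frame 1 and 100 in frame 2: |150-200| = |250-200|
        frames = np.r_[np.ones(150, int), np.full(100, 2)]
        t = make_table(frames, np.arange(250.0), np.zeros(250), roi_area=1e6)
        _, k, _ = homogenize_density(t)
        assert k == 1

    def test_sparse_sample_warns_and_keeps_all(self):
        t = make_table([1, 2, 3], [0.0, 1.0, 2.0], [0.0, 0.0, 0.0],
                       roi_area=1e6)
        with pytest.warns(UserWarning, match="target density"):
            out, k, _ = homogenize_density(t)
        assert k == 3 and len(out) == 3


class TestDBSCAN:
    def test_29_coincident_points_are_noise(self):
        pts = np.zeros((29, 2))
        assert (cluster_dbscan(pts, 20.0, 30) == -1).all()

    def test_30_coincident_points_form_cluster(self):
        pts = np.zeros((30, 2))
        labels = cluster_dbscan(pts, 20.0, 30)
        assert (labels == 0).all()

    def test_two_blobs_match_oracles(self):
        rng = np.random.default_rng(11)
        pts = np.vstack([rng.normal(0, 3, (50, 2)),
                         rng.normal([200, 0], 3, (50, 2))])
        labels = cluster_dbscan(pts, 20.0, 30)
        assert set(labels) == {0, 1}
        assert (labels == dbscan_union_find(pts, 20.0, 30)).all()
        sk = pytest.importorskip("sklearn.cluster")
        ref = sk.DBSCAN(eps=20.0, min_samples=30).fit_predict(pts)
        # same partition up to label permutation
        for lab in (0, 1):
            ref_labs = set(ref[labels == lab])
            assert len(ref_labs) == 1 and -1 not in ref_labs

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 5)
        pts = np.vstack([rng.normal(rng.uniform(0, 500, 2), rng.uniform(2, 8),
                                    (rng.integers(10, 60), 2))
                         for _ in range(k)]
                        + [rng.uniform(0, 500, (40, 2))])
        eps, minpts = 15.0, rng.integers(5, 25)
        assert (cluster_dbscan(pts, eps, minpts)
                == dbscan_union_find(pts, eps, minpts)).all()

    def test_order_independence(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 4, (40, 2)),
                         rng.normal([100, 100], 4, (40, 2))])
        perm = rng.permutation(len(pts))
        l1 = cluster_dbscan(pts, 20.0, 10)[perm]
        l2 = cluster_dbscan(pts[perm], 20.0, 10)
        # identical partitions up to label permutation; noise maps to noise
        assert ((l1 == -1) == (l2 == -1)).all()
        pairs = {(a, b) for a, b in zip(l1, l2) if a != -1}
        assert len({a for a, _ in pairs}) == len(pairs)
        assert len({b for _, b in pairs}) == len(pairs)


class TestMeasure:
    def test_right_triangle_hull_area(self):
        cfg = PipelineConfig(minpts=3)
        t = make_table([1, 1, 1], [0.0, 10.0, 0.0], [0.0, 0.0, 10.0])
        labels = np.zeros(3, int)
        cs = measure_clusters(t, labels, cfg)
        assert cs.clusters[0].hull_area == pytest.approx(50.0)
        assert cs.clusters[0].blink_density == pytest.approx(3 / 50.0)

    def test_feret_is_max_pairwise_distance(self):
        t = make_table([1] * 4, [0.0, 3.0, 1.0, 2.0], [0.0, 4.0, 0.5, 3.0])
        cs = measure_clusters(t, np.zeros(4, int), PipelineConfig(minpts=3))
        assert cs.clusters[0].feret_diameter == pytest.approx(5.0)

    def test_degenerate_collinear_cluster_flagged(self):
        t = make_table([1] * 5, np.arange(5.0), np.zeros(5))
        cs = measure_clusters(t, np.zeros(5, int), PipelineConfig(minpts=3))
        assert cs.clusters[0].degenerate
        assert cs.measured == []

    def test_border_exclusion(self):
        poly = [(0.0, 0.0), (1000.0, 0.0), (1000.0, 1000.0), (0.0, 1000.0)]
        inside = np.array([[500 + dx, 500 + dy]
                           for dx, dy in [(0, 0), (20, 0), (0, 20), (20, 20)]])
        crossing = np.array([[995 + dx, 500 + dy]
                             for dx, dy in [(0, 0), (20, 0), (0, 20), (20, 20)]])
        pts = np.vstack([inside, crossing])
        t = make_table([1] * 8, pts[:, 0], pts[:, 1], roi_area=1e6,
                       roi_polygon=poly)
        labels = np.r_[np.zeros(4, int), np.ones(4, int)]
        cs = measure_clusters(t, labels, PipelineConfig(minpts=3))
        assert not cs.clusters[0].touches_border
        assert cs.clusters[1].touches_border
        assert [c.label for c in cs.measured] == [0]


class TestStratify:
    def _clusters(self, areas, densities):
        from dolinekit.smlm import Cluster, ClusterSet
        cfg = PipelineConfig()
        cl = []
        for i, (a, d) in enumerate(zip(areas, densities)):
            stratum = ("small" if a < cfg.a_small
                       else "medium" if a < cfg.a_large else "large")
            cl.append(Cluster(label=i, member_idx=np.arange(3), n_members=3,
                              hull_area=a, blink_density=d, feret_diameter=1.0,
                              stratum=stratum))
        return ClusterSet(clusters=cl, roi_area=1e8)

    def test_exact_small_bound_is_medium(self):
        a = 25.0**2 * math.pi
        cs = self._clusters([a], [1.0])
        s = stratify_and_summarize(cs)
        assert s.strata["medium"]["count"] == 1
        assert s.strata["small"]["count"] == 0

    def test_medians_and_counts(self):
        a_small, a_med, a_lg = 100.0, 3000.0, 9000.0
        cs = self._clusters([a_small] * 3 + [a_med] * 4 + [a_lg],
                            [1.0, 2.0, 3.0, 5.0, 7.0, 6.0, 8.0, 4.0])
        s = stratify_and_summarize(cs)
        assert s.strata["small"]["median_blink_density"] == 2.0
        assert s.strata["medium"]["median_blink_density"] == 6.5
        assert s.strata["large"]["median_blink_density"] == 4.0
        assert sum(b["count"] for b in s.strata.values()) == s.total_clusters
        assert s.strata["small"]["clusters_per_um2"] == pytest.approx(
            3 / 1e8 * 1e6)

    def test_empty_stratum_reports_missing(self):
        s = stratify_and_summarize(self._clusters([100.0], [1.0]))
        assert s.strata["large"]["median_blink_density"] is None
        assert s.strata["large"]["count"] == 0


class TestPipelineEndToEnd:
    def test_deterministic_rerun(self):
        from dolinekit.synthetic import BlinkParams, gen_blinks
        table, _ = gen_blinks(BlinkParams(n_clusters=5), seed=5)
        cs1, sum1, log1 = run_pipeline(table)
        cs2, sum2, log2 = run_pipeline(table)
        assert log1 == log2
        pd.testing.assert_frame_equal(cs1.to_frame(), cs2.to_frame())
        assert sum1.to_json() == sum2.to_json()

    def test_recovers_ground_truth_clusters(self):
        from dolinekit.synthetic import BlinkParams, gen_blinks
        table, truth = gen_blinks(BlinkParams(), seed=1)
        cs, summary, log = run_pipeline(table)
        k = len(cs.measured)
        assert abs(k - truth.centers.shape[0]) <= 1
        # each recovered cluster sits on a true centre
        from scipy.spatial.distance import cdist
        rec = np.array([c.centroid for c in cs.measured])
        d = cdist(rec, truth.centers).min(axis=1)
        assert (d < 3 * truth.sds.max()).all()

    def test_density_ranking_recovered(self):
        from scipy.stats import spearmanr
        from scipy.spatial.distance import cdist
        from dolinekit.synthetic import BlinkParams, gen_blinks
        p = BlinkParams(n_clusters=8,
                        blinks_per_cluster=(60, 80, 100, 120, 140, 160, 180, 200),
                        cluster_sd=(14, 13, 12, 11, 10, 9, 8, 7),
                        noise_fraction=0.05)
        table, truth = gen_blinks(p, seed=2)
        cs, _, _ = run_pipeline(table)
        rec = np.array([c.centroid for c in cs.measured])
        match = cdist(rec, truth.centers).argmin(axis=1)
        assert len(set(match)) == len(match)       # one-to-one
        rho = spearmanr(truth.true_densities[match],
                        [c.blink_density for c in cs.measured]).statistic
        assert rho > 0.9

    @pytest.mark.filterwarnings("ignore:sample never reaches")
    def test_osmotic_shock_series_orders_cluster_density(self):
        """Emulated iso-osmotic / mild / strong shocks (progressively fewer
        clusters in the generator) must come out ordered in summarized
        cluster density per ROI area."""
        from dolinekit.synthetic import BlinkParams, gen_blinks
        dens = []
        for n_cl, seed in ((14, 7), (9, 8), (4, 9)):
            p = BlinkParams(n_clusters=n_cl, roi_side=3000.0,
                            min_separation=200.0)
            table, _ = gen_blinks(p, seed=seed)
            _, summary, _ = run_pipeline(table)
            dens.append(sum(b["clusters_per_um2"]
                            for b in summary.strata.values()))
        assert dens[0] > dens[1] > dens[2]
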