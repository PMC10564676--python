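"""LD decay fitting, window growth, and interval clustering."""

import numpy as np
import pandas as pd
import pytest

import sogwas as sg
from sogwas.qtl import LDWindow, Qtl, _side_extent, cluster_qtls, merge_meta_qtls
from sogwas.config import RunConfig


class TestPairwiseR2:
    def test_self_is_one(self, diallel_panel):
        r2 = sg.pairwise_r2(diallel_panel, 0, np.array([0]))
        assert r2[0] == pytest.approx(1.0)

    def test_duplicated_column_is_one(self, diallel_panel):
        dose = diallel_panel.dosage().astype(float)
        dose[:, 1] = dose[:, 0]
        r2 = sg.pairwise_r2(diallel_panel, 0, np.array([1]), dose=dose)
        assert r2[0] == pytest.approx(1.0)

    def test_independent_markers_near_zero(self):
        rng = np.random.default_rng(0)
        n = 2000
        alleles = rng.integers(0, 2, size=(n, 2, 2)).astype(np.uint8)
        origins = rng.integers(0, 2, size=(n, 2, 2)).astype(np.uint8)
        panel = sg.PanelGenotypes(
            hybrids=[f"h{i}" for i in range(n)], markers=["a", "b"],
            alleles=alleles, origins=origins,
        )
        r2 = sg.pairwise_r2(panel, 0, np.array([1]))
        assert r2[0] < 0.01

    def test_zero_variance_focal_rejected(self):
        alleles = np.zeros((10, 1, 2), dtype=np.uint8)
        origins = np.zeros((10, 1, 2), dtype=np.uint8)
        panel = sg.PanelGenotypes(
            hybrids=[f"h{i}" for i in range(10)], markers=["a"],
            alleles=alleles, origins=origins,
        )
        with pytest.raises(ValueError, match="zero dosage variance"):
            sg.pairwise_r2(panel, 0, np.array([0]))


class TestLdDecayFit:
    def test_recovers_generating_curve_crossing(self):
        """r2 drawn from the expected-decay curve plus small noise: the
        fitted 0.1-crossing lands within 10% of the generating one."""
        rng = np.random.default_rng(1)
        n = 300
        rho_true = 40.0
        d = np.linspace(0.05, 6.0, 120)
        r2 = sg.hill_weir_expected_r2(d, rho_true, n) + rng.normal(0, 0.01, len(d))
        rho, extent = sg.fit_ld_decay(r2, d, n)

        def f(x):
            return sg.hill_weir_expected_r2(np.array([x]), rho_true, n)[0] - 0.1

        from scipy.optimize import brentq
        true_extent = brentq(f, 1e-6, 50.0)
        assert abs(extent - true_extent) / true_extent < 0.10

    def test_all_r2_below_threshold_gives_zero_extent(self):
        d = np.linspace(0.1, 5.0, 30)
        r2 = np.full(30, 0.02)
        rho, extent = sg.fit_ld_decay(r2, d, 300)
        assert extent == 0.0

    def test_flat_data_not_estimable(self):
        d = np.linspace(0.1, 5.0, 30)
        rho, extent = sg.fit_ld_decay(np.full(30, 0.5), d, 300)
        assert extent is None

    def test_too_few_pairs_not_estimable(self):
        rho, extent = sg.fit_ld_decay(np.array([0.5, 0.1]), np.array([0.1, 0.2]), 300)
        assert extent is None

    def test_extent_monotone_in_threshold(self):
        """Raising the r2 threshold never increases the estimated extent
        (the fitted decay curve is monotone decreasing)."""
        rng = np.random.default_rng(2)
        n = 300
        d = np.linspace(0.05, 6.0, 100)
        r2 = sg.hill_weir_expected_r2(d, 30.0, n) + rng.normal(0, 0.01, 100)
        extents = [
            sg.fit_ld_decay(r2, d, n, threshold=t)[1] for t in (0.05, 0.1, 0.2, 0.3)
        ]
        assert all(np.diff(extents) <= 1e-9)


def copying_ld_panel(n=300, m=200, span_cm=8.0, persistence_cm=2.0, seed=60):
    """Panel with distance-decaying LD built by a haplotype-copying walk:
    each gamete keeps its previous allele and redraws with a probability
    growing in map distance, so r2(d) is roughly exp(-2 d / persistence)."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.uniform(0, span_cm, m))
    gmap = sg.GeneticMap(pd.DataFrame(
        {"marker": [f"m{j:04d}" for j in range(m)], "chrom": "c1",
         "cm": pos, "bp": (pos * 1e6 + 1).astype(int)}
    ))
    alleles = np.empty((n, m, 2), dtype=np.uint8)
    for g in range(2):
        hap = rng.integers(0, 2, size=n)
        alleles[:, 0, g] = hap
        for j in range(1, m):
            p_new = 1.0 - np.exp(-(pos[j] - pos[j - 1]) / persistence_cm)
            redraw = rng.random(n) < p_new
            hap = np.where(redraw, rng.integers(0, 2, size=n), hap)
            alleles[:, j, g] = hap
    origins = rng.integers(0, 2, size=(n, m, 2)).astype(np.uint8)
    panel = sg.PanelGenotypes(
        hybrids=[f"h{i}" for i in range(n)], markers=gmap.markers,
        alleles=alleles, origins=origins,
    )
    return panel, gmap


@pytest.fixture(scope="module")
def dense_panel():
    return copying_ld_panel()


class TestWindows:

    def test_window_extends_beyond_initial_when_ld_is_long(self, dense_panel):
        """LD persisting over ~2 cM forces the window past its 0.5 cM
        start, and the final extent exceeds the initial window."""
        panel, gmap = dense_panel
        w = sg.ld_window(panel, gmap, gmap.markers[100])
        assert max(w.left_window, w.right_window) > 0.5
        assert max(w.left_extent, w.right_extent) > 0.5

    def test_boundary_truncation_at_chromosome_start(self, dense_panel):
        panel, gmap = dense_panel
        first = gmap.markers[0]
        w = sg.ld_window(panel, gmap, first)
        assert w.left_extent == pytest.approx(0.0, abs=1e-9)

    def test_unmapped_marker_rejected(self, dense_panel):
        panel, gmap = dense_panel
        with pytest.raises(ValueError, match="not mapped"):
            sg.ld_window(panel, gmap, "not_a_marker")

    def test_tight_ld_stays_in_initial_window(self):
        """Unlinked markers (independent columns): extent collapses to ~0
        within the very first 0.5 cM window."""
        rng = np.random.default_rng(3)
        n, m = 400, 300
        alleles = rng.integers(0, 2, (n, m, 2)).astype(np.uint8)
        origins = rng.integers(0, 2, (n, m, 2)).astype(np.uint8)
        gmap = sg.simulate_map(m, n_chrom=1, chrom_len_cm=3.0, seed=4)
        panel = sg.PanelGenotypes(
            hybrids=[f"h{i}" for i in range(n)], markers=gmap.markers,
            alleles=alleles, origins=origins,
        )
        w = sg.ld_window(panel, gmap, gmap.markers[150])
        assert w.left_window == pytest.approx(0.5)
        assert w.right_window == pytest.approx(0.5)
        assert w.left_extent < 0.5 and w.right_extent < 0.5


def make_window(marker, chrom, cm, left, right):
    return LDWindow(marker=marker, chrom=chrom, cm=cm, left_extent=left,
                    right_extent=right, left_window=0.5, right_window=0.5,
                    n_pairs_left=10, n_pairs_right=10)


def make_hits(specs):
    return pd.DataFrame(
        [
            {"marker": mk, "chrom": chrom, "contrast": con, "layer": lay,
             "p": p, "estimate": 1.0, "trait": "t"}
            for mk, chrom, con, lay, p in specs
        ]
    )


def brute_force_clusters(intervals):
    """O(n^2) transitive interval merging oracle."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a[0] <= b[1] and b[0] <= a[1]:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestClustering:
    def simple_map(self, markers, cms):
        return sg.GeneticMap(pd.DataFrame(
            {"marker": markers, "chrom": "c1", "cm": cms,
             "bp": (np.asarray(cms) * 1e6 + 1).astype(int)}
        ))

    def test_overlapping_windows_merge(self):
        wins = {"m1": make_window("m1", "c1", 10.0, 1.0, 1.0),
                "m2": make_window("m2", "c1", 11.0, 1.0, 1.0)}
        gmap = self.simple_map(["m1", "m2"], [10.0, 11.0])
        hits = make_hits([("m1", "c1", "a", "e1", 1e-6), ("m2", "c1", "a", "e1", 1e-5)])
        qtls = cluster_qtls(hits, wins, gmap)
        assert len(qtls) == 1
        assert qtls[0].start_cm == pytest.approx(9.0)
        assert qtls[0].end_cm == pytest.approx(12.0)
        assert qtls[0].peak_marker == "m1"

    def test_disjoint_windows_stay_separate(self):
        wins = {"m1": make_window("m1", "c1", 1.5, 0.5, 0.5),
                "m2": make_window("m2", "c1", 3.5, 0.5, 0.5)}
        gmap = self.simple_map(["m1", "m2"], [1.5, 3.5])
        hits = make_hits([("m1", "c1", "a", "e1", 1e-6), ("m2", "c1", "a", "e1", 1e-5)])
        assert len(cluster_qtls(hits, wins, gmap)) == 2

    def test_chain_transitive_closure(self):
        wins = {"m1": make_window("m1", "c1", 1.5, 0.5, 0.5),
                "m2": make_window("m2", "c1", 2.45, 0.55, 0.55),
                "m3": make_window("m3", "c1", 3.45, 0.55, 0.55)}
        gmap = self.simple_map(["m1", "m2", "m3"], [1.5, 2.45, 3.45])
        hits = make_hits([(f"m{i}", "c1", "a", "e1", 1e-5) for i in (1, 2, 3)])
        qtls = cluster_qtls(hits, wins, gmap)
        assert len(qtls) == 1 and len(qtls[0].members) == 3

    def test_single_marker_interval_is_its_window(self):
        wins = {"m1": make_window("m1", "c1", 5.0, 0.7, 0.3)}
        gmap = self.simple_map(["m1"], [5.0])
        hits = make_hits([("m1", "c1", "a", "e1", 1e-6)])
        q = cluster_qtls(hits, wins, gmap)[0]
        assert (q.start_cm, q.end_cm) == (pytest.approx(4.3), pytest.approx(5.3))

    def test_matches_brute_force_oracle_on_random_sets(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            k = int(rng.integers(2, 15))
            starts = rng.uniform(0, 20, k)
            lens = rng.uniform(0.1, 3.0, k)
            markers = [f"m{i}" for i in range(k)]
            cms = starts + lens / 2
            wins = {m: make_window(m, "c1", c, l / 2, l / 2)
                    for m, c, l in zip(markers, cms, lens)}
            gmap = self.simple_map(markers, sorted(cms) if False else cms)
            hits = make_hits([(m, "c1", "a", "e1", 1e-5) for m in markers])
            qtls = cluster_qtls(hits, wins, gmap)
            got = {frozenset(int(m[1:]) for m in q.members) for q in qtls}
            expect = brute_force_clusters(
                [(s, s + l) for s, l in zip(starts, lens)]
            )
            assert got == expect

    def test_order_invariance(self):
        rng = np.random.default_rng(10)
        k = 10
        starts = rng.uniform(0, 10, k)
        markers = [f"m{i}" for i in range(k)]
        cms = starts + 0.5
        wins = {m: make_window(m, "c1", c, 0.5, 0.5) for m, c in zip(markers, cms)}
        gmap = self.simple_map(markers, cms)
        hits = make_hits([(m, "c1", "a", "e1", 1e-5) for m in markers])
        q1 = cluster_qtls(hits, wins, gmap)
        q2 = cluster_qtls(hits.iloc[::-1].reset_index(drop=True), wins, gmap)
        assert {tuple(q.members) for q in q1} == {tuple(q.members) for q in q2}

    def test_every_marker_in_exactly_one_qtl(self):
        rng = np.random.default_rng(11)
        k = 12
        cms = rng.uniform(0, 15, k)
        markers = [f"m{i}" for i in range(k)]
        wins = {m: make_window(m, "c1", c, 0.4, 0.4) for m, c in zip(markers, cms)}
        gmap = self.simple_map(markers, cms)
        hits = make_hits([(m, "c1", "a", "e1", 1e-5) for m in markers])
        qtls = cluster_qtls(hits, wins, gmap)
        all_members = [m for q in qtls for m in q.members]
        assert sorted(all_members) == sorted(markers)


class TestMetaMerging:
    def qtl(self, contrast, family, start, end, layers=("e1",), trait="t"):
        return Qtl(chrom="c1", start_cm=start, end_cm=end,
                   start_bp=int(start * 1e6), end_bp=int(end * 1e6),
                   members=["m"], contrast=contrast, family=family,
                   layers=list(layers), peak_marker="m", peak_p=1e-6,
                   peak_estimate=1.0, trait=trait)

    def test_same_qtl_across_environments_merges_with_provenance(self):
        a1 = self.qtl("a_DF", "additive", 1.0, 2.0, layers=("e1",))
        a2 = self.qtl("a", "additive", 1.5, 2.5, layers=("e2",))
        merged = merge_meta_qtls([a1, a2])
        assert len(merged) == 1
        assert merged[0].layers == ["e1", "e2"]

    def test_additive_and_dominance_never_merge(self):
        a = self.qtl("a", "additive", 1.0, 2.0)
        d = self.qtl("d", "dominance", 1.5, 2.5)
        o = self.qtl("o_a", "origin", 1.2, 2.2)
        merged = merge_meta_qtls([a, d, o])
        assert len(merged) == 3

    def test_non_overlapping_same_family_stay_separate(self):
        a1 = self.qtl("a", "additive", 1.0, 2.0)
        a2 = self.qtl("a", "additive", 5.0, 6.0)
        assert len(merge_meta_qtls([a1, a2])) == 2

    def test_touching_endpoints_merge(self):
        a1 = self.qtl("a", "additive", 1.0, 2.0)
        a2 = self.qtl("a", "additive", 2.0, 3.0)
        assert len(merge_meta_qtls([a1, a2])) == 1
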