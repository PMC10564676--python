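"""Gso/Gad marker tests: contrast algebra, filters, GLS oracle, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import sogwas as sg
from sogwas.gwas import test_marker_gad as gad_test  # noqa: E402
from sogwas.gwas import test_marker_gso as gso_test
from sogwas.gwas import (
    CONTRASTS,
    NullModel,
    bh_fdr,
    classify_dominance,
    evaluate_contrasts,
    minor_class_filter_gad,
)
from sogwas.panel import SO_CLASSES, SO_INDEX


def beta_vec(**kw):
    b = np.zeros(10)
    for name, v in kw.items():
        key = name.replace("b_", "")
        b[SO_INDEX[key]] = v
    return b


class TestContrastAlgebra:
    def test_all_equal_class_effects_give_zero(self):
        vals = evaluate_contrasts(np.full(10, 3.7))
        assert all(abs(v) < 1e-12 for v in vals.values())

    def test_a_dd_half_difference(self):
        vals = evaluate_contrasts(beta_vec(b_1D1D=2.0, b_0D0D=0.0))
        assert vals["a_DD"] == pytest.approx(1.0)

    def test_homogeneous_additivity_aggregation(self):
        b = beta_vec(b_1D1D=1.0, b_0D0D=-1.0, b_1F1F=1.0, b_0F0F=-1.0,
                     b_1D1F=1.0, b_0D0F=-1.0)
        vals = evaluate_contrasts(b)
        assert vals["a"] == pytest.approx(1.0)
        assert vals["s_a"] == pytest.approx(0.0)
        assert vals["t_a"] == pytest.approx(0.0)

    def test_delta_ld_printed_definition(self):
        vals = evaluate_contrasts(beta_vec(b_0D1F=1.0, b_1D0F=-1.0))
        assert vals["delta_ld"] == pytest.approx(2.0)

    def test_origin_contrasts_printed_definitions(self):
        vals = evaluate_contrasts(beta_vec(b_0D0D=1.0, b_0F0F=-1.0, b_0D0F=0.0))
        assert vals["o_a00"] == pytest.approx(1.0)
        assert vals["o_d00"] == pytest.approx(0.0)

    def test_scalar_contrast_rows_sum_to_zero(self):
        for spec in CONTRASTS.values():
            assert np.allclose(spec.matrix.sum(axis=1), 0.0)

    def test_invariance_to_constant_shift(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=10)
        v1 = evaluate_contrasts(b)
        v2 = evaluate_contrasts(b + 11.3)
        for k in v1:
            assert v1[k] == pytest.approx(v2[k], abs=1e-9)

    def test_global_tests_degrees_of_freedom(self):
        assert CONTRASTS["g_shared"].df == 3
        assert CONTRASTS["g_all"].df == 9


class TestFiltering:
    def make_panel(self, class_list):
        """Panel with one marker whose SO classes are given explicitly."""
        inv = []
        for name in class_list:
            i = SO_CLASSES.index(name)
            # decode canonical name back to gametes
            a1, o1, a2, o2 = name[0], name[1], name[2], name[3]
            inv.append(((int(a1), 0 if o1 == "D" else 1), (int(a2), 0 if o2 == "D" else 1)))
        n = len(inv)
        alleles = np.zeros((n, 1, 2), dtype=np.uint8)
        origins = np.zeros((n, 1, 2), dtype=np.uint8)
        for i, (g1, g2) in enumerate(inv):
            alleles[i, 0] = [g1[0], g2[0]]
            origins[i, 0] = [g1[1], g2[1]]
        return sg.PanelGenotypes(
            hybrids=[f"h{i}" for i in range(n)], markers=["m0"],
            alleles=alleles, origins=origins,
        )

    def test_minor_class_rule_is_per_contrast(self):
        # 4 carriers of 1D1D: a_DD blocked, a_FF still eligible
        classes = (["1D1D"] * 4 + ["0D0D"] * 8 + ["1F1F"] * 8 + ["0F0F"] * 8
                   + ["1D0D"] * 8 + ["1F0F"] * 4)
        panel = self.make_panel(classes)
        assert not sg.filter_markers(panel, CONTRASTS["a_DD"], maf_threshold=0.0)[0]
        assert sg.filter_markers(panel, CONTRASTS["a_FF"], maf_threshold=0.0)[0]

    def test_low_maf_blocks_every_contrast(self):
        classes = ["1D1D"] * 1 + ["0D0D"] * 40
        panel = self.make_panel(classes)
        assert panel.maf()[0] < 0.05
        for name in ("a_DD", "a", "g_all"):
            assert not sg.filter_markers(panel, CONTRASTS[name])[0]

    def test_gad_minor_dosage_class_rule(self):
        dosage = np.array([[2]] * 4 + [[0]] * 20 + [[1]] * 20)
        assert not minor_class_filter_gad(dosage, 5)[0]
        dosage2 = np.array([[2]] * 5 + [[0]] * 20 + [[1]] * 20)
        assert minor_class_filter_gad(dosage2, 5)[0]

    def test_negative_threshold_rejected(self, diallel_panel):
        with pytest.raises(ValueError):
            sg.filter_markers(diallel_panel, CONTRASTS["a"], maf_threshold=-1)


def dense_gso_oracle(y, vi, so, x_extra, spec):
    """Brute-force GLS + Wald for one contrast, independent matrix algebra."""
    present = np.unique(so)
    C = (so[:, None] == present[None, :]).astype(float)
    X = np.hstack([C, x_extra]) if x_extra.size else C
    xtvx = X.T @ vi @ X
    beta = np.linalg.solve(xtvx, X.T @ vi @ y)
    r = y - X @ beta
    s2 = (r @ vi @ r) / (len(y) - X.shape[1])
    cov = s2 * np.linalg.inv(xtvx)
    pos = {int(c): j for j, c in enumerate(present)}
    if any(int(c) not in pos for c in spec.classes):
        return None
    L = np.zeros((spec.df, X.shape[1]))
    for i in range(spec.df):
        for c in spec.classes:
            L[i, pos[int(c)]] = spec.matrix[i, c]
    est = L @ beta
    v = L @ cov @ L.T
    if spec.df == 1:
        return float(est[0]), float(np.sqrt(v[0, 0])), float(est[0] ** 2 / v[0, 0])
    return np.nan, np.nan, float(est @ np.linalg.solve(v, est))


def random_null(rng, n, with_extra=False):
    A = rng.normal(size=(n, n))
    V = A @ A.T / n + np.eye(n)
    vi = np.linalg.inv(V)
    y = rng.normal(size=n)
    x_extra = rng.normal(size=(n, 2)) if with_extra else np.empty((n, 0))
    return NullModel(layer="env1", y=y, hybrid_idx=np.arange(n),
                     x_extra=x_extra, vi=vi, varcomp=None, excluded_chrom="none")


class TestGlsOracle:
    @pytest.mark.parametrize("with_extra", [False, True])
    def test_gso_matches_dense_oracle(self, with_extra):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(18, 31))
            null = random_null(rng, n, with_extra)
            so = rng.integers(0, 10, size=n)
            res = gso_test(null, so, list(CONTRASTS))
            for r in res:
                spec = CONTRASTS[r["contrast"]]
                oracle = dense_gso_oracle(null.y, null.vi, so, null.x_extra, spec)
                if r["skipped"]:
                    continue
                assert oracle is not None
                est, se, wald = oracle
                if spec.df == 1:
                    assert r["estimate"] == pytest.approx(est, abs=1e-8)
                    assert r["se"] == pytest.approx(se, abs=1e-8)
                assert r["wald"] == pytest.approx(wald, abs=1e-8)

    def test_gad_matches_dense_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(18, 31))
            null = random_null(rng, n)
            dose = rng.integers(0, 3, size=n)
            het = (dose == 1).astype(int)
            res = {r["contrast"]: r for r in gad_test(null, dose, het)}
            X = np.column_stack([np.ones(n), dose, het])
            xtvx = X.T @ null.vi @ X
            beta = np.linalg.solve(xtvx, X.T @ null.vi @ null.y)
            r0 = null.y - X @ beta
            s2 = (r0 @ null.vi @ r0) / (n - 3)
            cov = s2 * np.linalg.inv(xtvx)
            assert res["alpha"]["estimate"] == pytest.approx(beta[1], abs=1e-8)
            assert res["alpha"]["wald"] == pytest.approx(beta[1] ** 2 / cov[1, 1], abs=1e-8)
            assert res["delta"]["estimate"] == pytest.approx(beta[2], abs=1e-8)

    def test_gad_linear_class_means_zero_delta(self):
        """Noise-free phenotypes exactly linear in dosage: delta = 0 and
        alpha equals the per-allele slope."""
        n = 30
        dose = np.repeat([0, 1, 2], 10)
        het = (dose == 1).astype(int)
        y = 1.0 + 0.5 * dose.astype(float)
        null = NullModel(layer="e", y=y, hybrid_idx=np.arange(n),
                         x_extra=np.empty((n, 0)), vi=np.eye(n),
                         varcomp=None, excluded_chrom="none")
        res = {r["contrast"]: r for r in gad_test(null, dose, het)}
        assert res["alpha"]["estimate"] == pytest.approx(0.5, abs=1e-10)
        assert res["delta"]["estimate"] == pytest.approx(0.0, abs=1e-10)

    def test_missing_class_skipped_with_reason(self):
        rng = np.random.default_rng(7)
        null = random_null(rng, 20)
        so = np.full(20, SO_INDEX["0D0F"])
        so[:10] = SO_INDEX["1D1F"]
        res = gso_test(null, so, ["a_DF", "a_DD"])
        by = {r["contrast"]: r for r in res}
        assert by["a_DF"]["skipped"] == ""
        assert by["a_DD"]["skipped"] == "missing SO class"


class TestNullModelPlumbing:
    def test_null_components_equal_fit_mono(self, diallel_panel, diallel_kinships):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(
            {"hybrid": diallel_panel.hybrids, "env": "env1",
             "value": rng.normal(size=diallel_panel.n_hybrids)}
        )
        null = sg.fit_null_model(data, diallel_kinships, diallel_panel.hybrids, "env1")
        direct = sg.fit_mono(data, diallel_kinships, diallel_panel.hybrids)
        for k, v in direct.sigma2.items():
            assert null.varcomp.sigma2[k] == pytest.approx(v, abs=1e-10)

    def test_loco_key_mismatch_rejected(self, diallel_panel, small_map):
        loco = sg.loco_kinships(diallel_panel, small_map)
        chroms = small_map.chromosomes
        swapped = {chroms[0]: loco[chroms[1]], chroms[1]: loco[chroms[0]]}
        rng = np.random.default_rng(2)
        data = pd.DataFrame(
            {"hybrid": diallel_panel.hybrids, "env": "env1",
             "value": rng.normal(size=diallel_panel.n_hybrids)}
        )
        with pytest.raises(ValueError, match="LOCO key mismatch"):
            sg.run_gwas(diallel_panel, small_map, data, swapped,
                        model="gso", layers=["env1"], contrasts=["a"])


class TestBH:
    def test_step_up_worked_example(self):
        df = pd.DataFrame(
            {"p": [0.01, 0.02, 0.03, 0.5], "contrast": "a", "panel": "x",
             "model": "gso", "trait": "t"}
        )
        q = bh_fdr(df)["q"].to_numpy()
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_all_ones(self):
        df = pd.DataFrame(
            {"p": [1.0, 1.0], "contrast": "a", "panel": "x", "model": "gso",
             "trait": "t"}
        )
        assert (bh_fdr(df)["q"] == 1.0).all()

    def test_families_separate_but_environments_pooled(self):
        df = pd.DataFrame(
            {
                "p": [0.01, 0.01, 0.5, 0.5],
                "contrast": ["a", "a", "d", "d"],
                "layer": ["env1", "env2", "env1", "env2"],
                "panel": "x", "model": "gso", "trait": "t",
            }
        )
        out = bh_fdr(df)
        # within the "a" family both environments' p-values are pooled (m=2)
        assert np.allclose(out.loc[out["contrast"] == "a", "q"], 0.01)
        assert np.allclose(out.loc[out["contrast"] == "d", "q"], 0.5)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30))
    def test_q_monotone_in_p(self, ps):
        df = pd.DataFrame(
            {"p": ps, "contrast": "a", "panel": "x", "model": "gso", "trait": "t"}
        )
        out = bh_fdr(df).sort_values("p")
        q = out["q"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()
        assert (q >= out["p"].to_numpy() - 1e-12).all()


class TestDominanceClassification:
    @pytest.mark.parametrize(
        "a,d,expect",
        [
            (1.0, 2.5, "overdominant"),
            (1.0, 0.5, "partial dominance"),
            (1.0, 0.0, "additive"),
            (0.0, 1.0, "overdominant (a=0)"),
            (-1.0, 1.5, "overdominant"),
        ],
    )
    def test_categories(self, a, d, expect):
        assert classify_dominance(a, d) == expect
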