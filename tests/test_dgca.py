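"""Differential co-expression: Fisher z, FDR, classes, hubs."""

import numpy as np
import pandas as pd
import pytest

from coexnet import dgca


class TestFisherZ:
    def test_equal_correlations_zero(self):
        dz, p = dgca.fisher_z_diff(0.6, 20, 0.6, 35)
        assert dz == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_value(self):
        # atanh(0.9)/sqrt(1/4 + 1/4) = 1.4722/0.7071
        dz, p = dgca.fisher_z_diff(0.9, 7, 0.0, 7)
        assert dz == pytest.approx(np.arctanh(0.9) / np.sqrt(0.5), rel=1e-12)
        assert dz == pytest.approx(2.082, abs=1e-3)
        assert p == pytest.approx(0.0374, abs=1e-3)

    def test_swap_antisymmetry(self):
        a = dgca.fisher_z_diff(0.7, 12, -0.2, 30)
        b = dgca.fisher_z_diff(-0.2, 30, 0.7, 12)
        assert a[0] == pytest.approx(-b[0])
        assert a[1] == pytest.approx(b[1])

    def test_perfect_correlation_clamped(self):
        dz, p = dgca.fisher_z_diff(1.0, 10, 0.0, 10)
        assert np.isfinite(dz) and 0 <= p <= 1

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            dgca.fisher_z_diff(0.5, 3, 0.5, 10)


class TestFDR:
    def test_all_ones(self):
        assert dgca.adjust_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_single_p(self):
        assert dgca.adjust_fdr([0.03]) == pytest.approx([0.03])

    def test_textbook_step_up(self):
        # sorted p = (.01,.02,.03,.04,.25); q_i = min_{j>=i} p_j * 5/j
        p = [0.25, 0.01, 0.04, 0.03, 0.02]
        q = dgca.adjust_fdr(p)
        expected = {0.01: 0.05, 0.02: 0.05, 0.03: 0.05, 0.04: 0.05, 0.25: 0.25}
        for pi, qi in zip(p, q):
            assert qi == pytest.approx(expected[pi])

    def test_monotone_and_dominates_p(self, rng):
        p = rng.uniform(size=200)
        q = dgca.adjust_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            dgca.adjust_fdr([0.5, 1.5])


class TestClasses:
    def _pairs(self, r_con, p_con, r_res, p_res):
        return pd.DataFrame({"r_con": r_con, "p_con": p_con,
                             "r_res": r_res, "p_res": p_res})

    @pytest.mark.parametrize("rc,pc,rr,pr,label", [
        (0.9, 0.001, -0.8, 0.002, "+/-"),
        (0.5, 0.3, 0.5, 0.3, "0/0"),
        (0.2, 0.8, 0.7, 0.01, "0/+"),
        (-0.9, 0.001, -0.85, 0.004, "-/-"),
        (-0.6, 0.02, 0.1, 0.9, "-/0"),
    ])
    def test_labels(self, rc, pc, rr, pr, label):
        got = dgca.classify_pair(self._pairs([rc], [pc], [rr], [pr]))
        assert got.iloc[0] == label

    def test_class_consistent_with_signs(self, rng):
        n = 500
        pairs = self._pairs(rng.uniform(-1, 1, n), rng.uniform(size=n),
                            rng.uniform(-1, 1, n), rng.uniform(size=n))
        labels = dgca.classify_pair(pairs, alpha_within=0.05)
        for (_, row), lab in zip(pairs.iterrows(), labels):
            con, res = lab.split("/")
            for code, r, p in ((con, row.r_con, row.p_con),
                               (res, row.r_res, row.p_res)):
                if p <= 0.05 and r > 0:
                    assert code == "+"
                elif p <= 0.05 and r < 0:
                    assert code == "-"
                else:
                    assert code == "0"


class TestPairCorrelations:
    @staticmethod
    def _toy(rng, n_genes=6, n=8):
        cols = [f"c{i}" for i in range(n)] + [f"r{i}" for i in range(n)]
        norm = pd.DataFrame(rng.standard_normal((n_genes, 2 * n)),
                            index=[f"g{i}" for i in range(n_genes)], columns=cols)
        meta = pd.DataFrame({"tissue": "t", "condition": ["CON"] * n + ["RES"] * n,
                             "sex": "M"}, index=cols)
        return norm, meta

    def test_pair_count(self, rng):
        norm, meta = self._toy(rng)
        out = dgca.condition_pair_correlations(norm, meta)
        assert len(out) == 6 * 5 // 2

    def test_identical_genes_r_one(self, rng):
        norm, meta = self._toy(rng)
        norm.loc["g1"] = norm.loc["g0"]
        out = dgca.condition_pair_correlations(norm, meta)
        row = out[(out.geneA == "g0") & (out.geneB == "g1")].iloc[0]
        assert row.r_con == pytest.approx(1.0)
        assert row.r_res == pytest.approx(1.0)

    def test_hand_pearson_and_p(self, rng):
        norm, meta = self._toy(rng)
        out = dgca.condition_pair_correlations(norm, meta)
        row = out.iloc[0]
        a = norm.loc[row.geneA, meta.index[meta.condition == "CON"]]
        b = norm.loc[row.geneB, meta.index[meta.condition == "CON"]]
        from scipy import stats as ss

        r_ref, p_ref = ss.pearsonr(a, b)
        assert row.r_con == pytest.approx(r_ref)
        assert row.p_con == pytest.approx(p_ref, rel=1e-6)

    def test_touching_restriction(self, rng):
        norm, meta = self._toy(rng)
        out = dgca.condition_pair_correlations(norm, meta, touching={"g0"})
        assert ((out.geneA == "g0") | (out.geneB == "g0")).all()
        assert len(out) == 5

    def test_missing_condition_errors(self, rng):
        norm, meta = self._toy(rng)
        meta["condition"] = "CON"
        with pytest.raises(ValueError, match="RES"):
            dgca.condition_pair_correlations(norm, meta)


def _two_condition_dataset(rng, rho_con, rho_res, n_pairs, n):
    """Independent gene pairs with given within-condition correlations."""
    rows, names = [], []
    for k in range(n_pairs):
        for rho, half in ((rho_con, 0), (rho_res, 1)):
            cov = np.array([[1, rho], [rho, 1]])
            xy = rng.multivariate_normal([0, 0], cov, size=n).T
            if half == 0:
                block_con = xy
            else:
                block_res = xy
        rows.append(np.hstack([block_con[0], block_res[0]]))
        rows.append(np.hstack([block_con[1], block_res[1]]))
        names += [f"p{k}a", f"p{k}b"]
    cols = [f"c{i}" for i in range(n)] + [f"r{i}" for i in range(n)]
    norm = pd.DataFrame(rows, index=names, columns=cols)
    meta = pd.DataFrame({"tissue": "t", "condition": ["CON"] * n + ["RES"] * n,
                         "sex": "M"}, index=cols)
    return norm, meta


def test_power_on_sign_flipped_pairs(rng):
    """Planted delta r = (0.8, -0.8) at n = 30: nearly all pairs at q <= 0.05."""
    norm, meta = _two_condition_dataset(rng, 0.8, -0.8, n_pairs=60, n=30)
    out = dgca.dc_analysis(norm, meta)
    planted = out[out.geneA.str[:-1] == out.geneB.str[:-1]]
    assert len(planted) == 60
    assert (planted.q_diff <= 0.05).mean() >= 0.8
    assert (planted.loc[planted.q_diff <= 0.05, "class"] == "+/-").mean() >= 0.9


def test_permutation_mode_agrees_with_analytic(rng):
    norm, meta = _two_condition_dataset(rng, 0.8, -0.8, n_pairs=10, n=30)
    ana = dgca.dc_analysis(norm, meta)
    per = dgca.dc_analysis(norm, meta, permutations=99, seed=4)
    planted_a = ana[ana.geneA.str[:-1] == ana.geneB.str[:-1]]
    planted_p = per[per.geneA.str[:-1] == per.geneB.str[:-1]]
    # strong signals are extreme under both null models
    assert (planted_a.p_diff < 0.05).all()
    assert (planted_p.p_diff <= 2 / 100).all()
    # permutation p-values are reproducible under the same seed
    per2 = dgca.dc_analysis(norm, meta, permutations=99, seed=4)
    assert np.allclose(per.p_diff, per2.p_diff)


def test_dc_hubs_unique_hub(rng):
    pairs = pd.DataFrame({
        "geneA": ["hub"] * 12 + ["x1"],
        "geneB": [f"g{i}" for i in range(12)] + ["x2"],
        "q_diff": [0.01] * 13,
    })
    out = dgca.dc_hubs(pairs)
    assert out["is_hub"].sum() == 1
    assert out.index[out["is_hub"]][0] == "hub"


def test_dc_hubs_uniform_degrees_none():
    pairs = pd.DataFrame({"geneA": ["a", "c"], "geneB": ["b", "d"],
                          "q_diff": [0.01, 0.01]})
    out = dgca.dc_hubs(pairs)
    assert out["is_hub"].sum() == 0
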