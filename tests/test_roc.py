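import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

import gwasroc as g
from gwasroc.roc import delong_components, delong_from_components


def brute_force_auc(scores, labels):
    """O(m*n) Mann-Whitney oracle over all case-control pairs."""
    x = scores[labels]
    y = scores[~labels]
    total = 0.0
    for xi in x:
        for yj in y:
            total += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return total / (len(x) * len(y))


def brute_force_delong(s1, s2, labels):
    """Direct-summation DeLong oracle (structural components and 2x2 cov)."""
    comps = []
    for s in (s1, s2):
        x, y = s[labels], s[~labels]
        m, n = len(x), len(y)
        psi = (x[:, None] > y[None, :]) + 0.5 * (x[:, None] == y[None, :])
        comps.append((psi.mean(), psi.mean(axis=1), psi.mean(axis=0), m, n))
    auc = [c[0] for c in comps]
    m, n = comps[0][3], comps[0][4]
    v10 = np.vstack([comps[0][1], comps[1][1]])
    v01 = np.vstack([comps[0][2], comps[1][2]])
    s10 = np.cov(v10, ddof=1)
    s01 = np.cov(v01, ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    z = (auc[0] - auc[1]) / np.sqrt(var_diff) if var_diff > 0 else 0.0
    return auc, cov, z


def random_input(rng, m=20, n=80, ties=False):
    scores = rng.integers(0, 15, size=m + n).astype(float) if ties \
        else rng.standard_normal(m + n)
    labels = np.zeros(m + n, dtype=bool)
    labels[rng.choice(m + n, size=m, replace=False)] = True
    return g.RocInput(scores=scores, labels=labels)


class TestAucMidrank:
    def test_small_tied_example(self):
        inp = g.RocInput(scores=[2.0, 1.0, 2.0, 0.0],
                         labels=[True, True, False, False])
        assert g.auc_midrank(inp) == pytest.approx(0.625)

    def test_perfect_separation(self):
        inp = g.RocInput(scores=[5.0, 1.0], labels=[True, False])
        assert g.auc_midrank(inp) == 1.0

    def test_matches_double_loop_with_ties(self):
        rng = np.random.default_rng(61)
        inp = random_input(rng, m=100, n=400, ties=True)
        assert g.auc_midrank(inp) == brute_force_auc(inp.scores, inp.labels)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(62)
        inp = random_input(rng, m=30, n=120, ties=True)
        assert g.auc_midrank(inp) == pytest.approx(
            roc_auc_score(inp.labels, inp.scores), abs=1e-12
        )

    def test_one_class_empty_raises(self):
        with pytest.raises(ValueError):
            g.RocInput(scores=[1.0, 2.0], labels=[True, True])


class TestEmpiricalRoc:
    def test_perfect_curve_passes_through_corner(self):
        inp = g.RocInput(scores=[3.0, 2.0, 1.0, 0.0],
                         labels=[True, True, False, False])
        curve = g.empirical_roc(inp)
        assert curve.auc == 1.0
        corner = (curve.specificity == 1.0) & (curve.sensitivity == 1.0)
        assert corner.any()

    def test_constant_scores_collapse_to_diagonal(self):
        inp = g.RocInput(scores=np.ones(10),
                         labels=[True] * 3 + [False] * 7)
        curve = g.empirical_roc(inp)
        pts = set(zip(1 - curve.specificity, curve.sensitivity))
        assert pts == {(0.0, 0.0), (1.0, 1.0)}
        assert curve.auc == 0.5

    def test_matches_threshold_sweep_oracle(self):
        rng = np.random.default_rng(63)
        inp = random_input(rng, m=20, n=80, ties=True)
        curve = g.empirical_roc(inp)
        cases, controls = inp.scores[inp.labels], inp.scores[~inp.labels]
        for thr, sens, spec in zip(curve.thresholds, curve.sensitivity,
                                   curve.specificity):
            assert sens == pytest.approx((cases >= thr).mean())
            assert spec == pytest.approx((controls < thr).mean())
        # every distinct finite score appears as a threshold
        assert set(np.unique(inp.scores)) <= set(curve.thresholds)

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(64)
        curve = g.empirical_roc(random_input(rng, ties=True))
        assert (np.diff(curve.sensitivity) >= 0).all()
        assert (np.diff(1 - curve.specificity) >= 0).all()
        assert curve.sensitivity[0] == 0 and 1 - curve.specificity[0] == 0
        assert curve.sensitivity[-1] == 1 and curve.specificity[-1] == 0

    def test_auc_equals_trapezoid_area(self):
        rng = np.random.default_rng(65)
        for ties in (False, True):
            curve = g.empirical_roc(random_input(rng, m=25, n=75, ties=ties))
            fpr = 1 - curve.specificity
            area = np.trapezoid(curve.sensitivity, fpr)
            assert curve.auc == pytest.approx(area, abs=1e-12)


@given(st.integers(0, 2**32 - 1))
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    inp = random_input(rng, m=10, n=30, ties=True)
    base = g.auc_midrank(inp)
    shifted = g.RocInput(scores=np.exp(inp.scores / 5.0), labels=inp.labels)
    assert g.auc_midrank(shifted) == pytest.approx(base, abs=1e-12)


class TestMeanRoc:
    def test_identical_curves_average_to_themselves(self):
        rng = np.random.default_rng(66)
        curve = g.empirical_roc(random_input(rng))
        mean = g.mean_roc([curve] * 10)
        single = g.mean_roc([curve])
        np.testing.assert_allclose(mean.sensitivity, single.sensitivity)

    def test_midpoint_of_perfect_and_diagonal(self):
        perfect = g.empirical_roc(
            g.RocInput(scores=[3.0, 2.0, 1.0, 0.0],
                       labels=[True, True, False, False])
        )
        diag = g.empirical_roc(
            g.RocInput(scores=np.ones(4), labels=[True, True, False, False])
        )
        mean = g.mean_roc([perfect, diag])
        i = np.argmin(np.abs(mean.specificity - 1.0))
        p1 = g.mean_roc([perfect]).sensitivity[i]
        p2 = g.mean_roc([diag]).sensitivity[i]
        assert mean.sensitivity[i] == pytest.approx((p1 + p2) / 2)

    def test_mean_of_aucs_close_to_auc_of_mean(self):
        rng = np.random.default_rng(67)
        curves = [g.empirical_roc(random_input(rng, m=40, n=160))
                  for _ in range(8)]
        grid_aucs = [g.mean_roc([c]).auc for c in curves]
        assert g.mean_roc(curves).auc == pytest.approx(
            np.mean(grid_aucs), abs=0.005
        )

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            g.mean_roc([])


class TestDelongPaired:
    def test_self_comparison_degenerate_zero(self):
        rng = np.random.default_rng(68)
        inp = random_input(rng)
        res = g.delong_paired_test(inp, inp)
        assert res.z == 0.0
        assert res.degenerate
        assert res.auc1 == res.auc2

    def test_antisymmetric_in_argument_order(self):
        rng = np.random.default_rng(69)
        inp1 = random_input(rng, m=15, n=60)
        inp2 = g.RocInput(scores=rng.standard_normal(75), labels=inp1.labels)
        fwd = g.delong_paired_test(inp1, inp2)
        rev = g.delong_paired_test(inp2, inp1)
        assert fwd.z == pytest.approx(-rev.z, abs=1e-12)

    def test_components_match_direct_summation(self):
        rng = np.random.default_rng(70)
        labels = np.array([True] * 5 + [False] * 8)
        s1 = rng.standard_normal(13)
        s2 = rng.standard_normal(13)
        res = g.delong_paired_test(
            g.RocInput(s1, labels), g.RocInput(s2, labels)
        )
        aucs, cov, z = brute_force_delong(s1, s2, labels)
        assert res.auc1 == pytest.approx(aucs[0], abs=1e-12)
        assert res.auc2 == pytest.approx(aucs[1], abs=1e-12)
        assert res.var1 == pytest.approx(cov[0, 0], abs=1e-12)
        assert res.var2 == pytest.approx(cov[1, 1], abs=1e-12)
        assert res.cov12 == pytest.approx(cov[0, 1], abs=1e-12)
        assert res.z == pytest.approx(z, abs=1e-10)

    def test_components_match_oracle_with_ties(self):
        rng = np.random.default_rng(71)
        labels = np.zeros(60, dtype=bool)
        labels[:12] = True
        s1 = rng.integers(0, 6, 60).astype(float)
        s2 = rng.integers(0, 6, 60).astype(float)
        res = g.delong_paired_test(g.RocInput(s1, labels), g.RocInput(s2, labels))
        aucs, cov, z = brute_force_delong(s1, s2, labels)
        assert res.var1 == pytest.approx(cov[0, 0], abs=1e-12)
        assert res.cov12 == pytest.approx(cov[0, 1], abs=1e-12)

    def test_mismatched_labels_raise(self):
        rng = np.random.default_rng(72)
        inp1 = random_input(rng, m=10, n=20)
        labels2 = np.roll(inp1.labels, 1)
        inp2 = g.RocInput(scores=rng.standard_normal(30), labels=labels2)
        with pytest.raises(ValueError):
            g.delong_paired_test(inp1, inp2)

    def test_variance_close_to_bootstrap(self):
        # single-curve DeLong variance vs a case/control bootstrap
        rng = np.random.default_rng(73)
        m, n = 40, 150
        labels = np.array([True] * m + [False] * n)
        scores = np.concatenate([rng.normal(1.0, 1.0, m), rng.normal(0.0, 1.0, n)])
        comp = delong_components(g.RocInput(scores, labels))
        var_delong = np.var(comp.v10, ddof=1) / m + np.var(comp.v01, ddof=1) / n
        x, y = scores[:m], scores[m:]
        psi = (x[:, None] > y[None, :]) + 0.5 * (x[:, None] == y[None, :])
        boots = np.empty(2000)
        for b in range(2000):
            bi = rng.integers(0, m, m)
            bj = rng.integers(0, n, n)
            boots[b] = psi[np.ix_(bi, bj)].mean()
        assert var_delong == pytest.approx(boots.var(ddof=1), rel=0.15)
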