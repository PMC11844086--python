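import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwescan.ordination import (
    RDA,
    adjusted_r2,
    fit_rda,
    forward_select,
    geodesic_distance,
    pcoa,
    permutation_test,
    varpart,
)


def ols_inertia_oracle(Y, X):
    """Per-response-column OLS explained sum of squares, summed."""
    Yc = Y - Y.mean(axis=0)
    Xc = np.column_stack([np.ones(len(X)), X])
    total = 0.0
    for j in range(Yc.shape[1]):
        beta, *_ = np.linalg.lstsq(Xc, Yc[:, j], rcond=None)
        fitted = Xc @ beta
        total += float(np.sum((fitted - fitted.mean()) ** 2))
    return total


class TestRda:
    def test_self_regression_is_perfect(self, rng):
        x = rng.standard_normal(30)
        r = fit_rda(x[:, None], x[:, None])
        assert r.r2_ == pytest.approx(1.0)
        assert len(r.eigenvalues_) == 1

    def test_null_adjusted_r2_near_zero(self):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((200, 40))
        X = rng.standard_normal((200, 1))
        r = fit_rda(Y, X)
        assert abs(r.adj_r2_) < 0.02

    @pytest.mark.parametrize("seed", range(3))
    def test_constrained_inertia_matches_ols_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Y = rng.standard_normal((20, 50))
        X = rng.standard_normal((20, 3))
        r = fit_rda(Y, X)
        assert r.constrained_inertia_ == pytest.approx(
            ols_inertia_oracle(Y, X), abs=1e-8
        )
        # eigenvalue/total identity
        full = fit_rda(Y, X)
        assert np.sum(full.eigenvalues_) / full.total_inertia_ == pytest.approx(
            full.r2_, abs=1e-10
        )

    def test_collinear_predictors_named(self, rng):
        X = rng.standard_normal((30, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])
        Y = rng.standard_normal((30, 5))
        with pytest.raises(ValueError, match="collinear"):
            fit_rda(Y, X)

    def test_condition_removes_covariate_signal(self, rng):
        z = rng.standard_normal((40, 1))
        Y = z @ rng.standard_normal((1, 10)) + 0.1 * rng.standard_normal((40, 10))
        r_cond = fit_rda(Y, rng.standard_normal((40, 2)), condition=z)
        assert r_cond.r2_ < 0.2


class TestAdjustedR2:
    @pytest.mark.parametrize(
        "r2, n, p, expected",
        [
            (0.5, 11, 1, 1 - 0.5 * 10 / 9),
            (1.0, 50, 5, 1.0),
            (0.0, 100, 10, -10 / 89),
        ],
    )
    def test_closed_form(self, r2, n, p, expected):
        assert adjusted_r2(r2, n, p) == pytest.approx(expected, abs=1e-12)

    def test_saturated_design_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 5, 4)

    def test_never_exceeds_r2(self, rng):
        for _ in range(20):
            r2 = rng.random()
            n = int(rng.integers(10, 200))
            p = int(rng.integers(1, n - 2))
            assert adjusted_r2(r2, n, p) <= r2 + 1e-12


class TestPermutationTest:
    def test_perfect_fit_attains_minimum_p(self, rng):
        x = rng.standard_normal(30)
        f, p = permutation_test(x[:, None], x[:, None], n_perm=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_p_always_in_bounds(self, rng):
        Y = rng.standard_normal((25, 8))
        X = rng.standard_normal((25, 2))
        _, p = permutation_test(Y, X, n_perm=99, seed=1)
        assert 1 / 100 <= p <= 1.0

    def test_null_p_uniform(self):
        master = np.random.default_rng(7)
        ps = []
        for _ in range(500):
            Y = master.standard_normal((20, 3))
            X = master.standard_normal((20, 1))
            _, p = permutation_test(Y, X, n_perm=99, rng=master)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


def make_collinear_candidates(seed=5, n=150, n_candidates=15, n_informative=3):
    """Y driven by 3 variables; 12 decoys collinear with the informative set."""
    rng = np.random.default_rng(seed)
    informative = rng.standard_normal((n, n_informative))
    decoys = (
        informative[:, rng.integers(n_informative, size=n_candidates - n_informative)]
        + 0.8 * rng.standard_normal((n, n_candidates - n_informative))
    )
    X = pd.DataFrame(
        np.column_stack([informative, decoys]),
        columns=[f"v{i}" for i in range(n_candidates)],
    )
    Y = (
        informative @ rng.standard_normal((n_informative, 60))
        + 2.0 * rng.standard_normal((n, 60))
    )
    return Y, X, [f"v{i}" for i in range(n_informative)]


class TestForwardSelection:
    def test_recovers_planted_variables_first(self):
        Y, X, informative = make_collinear_candidates(seed=5)
        res = forward_select(Y, X, alpha=0.05, n_perm=199, seed=5)
        assert set(res.selected[:3]) == set(informative)
        cum = [s["cum_adj_r2"] for s in res.steps]
        assert all(b > a for a, b in zip(cum, cum[1:]))

    def test_stops_when_nothing_passes_alpha(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((60, 20))
        X = pd.DataFrame({"a": rng.standard_normal(60)})
        res = forward_select(Y, X, alpha=0.01, n_perm=199, seed=0)
        assert res.selected == []
        assert res.stopping_reason == "alpha"

    def test_null_multicandidate_selects_nothing(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((60, 20))
        X = pd.DataFrame(rng.standard_normal((60, 5)), columns=list("abcde"))
        res = forward_select(Y, X, alpha=0.01, n_perm=199, seed=0)
        assert res.selected == []

    def test_duplicate_candidate_never_selected_twice(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(80)
        Y = np.outer(x, rng.standard_normal(10)) + 0.5 * rng.standard_normal((80, 10))
        X = pd.DataFrame({"a": x, "a_copy": x.copy(), "noise": rng.standard_normal(80)})
        res = forward_select(Y, X, n_perm=199, seed=3)
        assert len({"a", "a_copy"} & set(res.selected)) <= 1

    def test_ceiling_respected(self):
        Y, X, _ = make_collinear_candidates(seed=8)
        res = forward_select(Y, X, n_perm=199, seed=8)
        full = fit_rda(Y, X).adj_r2_
        for step in res.steps:
            assert step["cum_adj_r2"] <= full + 1e-10


class TestVarpart:
    def test_duplicate_blocks_share_everything(self, rng):
        Y = rng.standard_normal((100, 20))
        X = rng.standard_normal((100, 3))
        vp = varpart(Y, X, X.copy())
        assert abs(vp.a) < 1e-8 and abs(vp.c) < 1e-8
        assert vp.b == pytest.approx(vp.adj_r2_full, abs=1e-8)

    def test_orthogonal_blocks_have_no_shared_fraction(self):
        rng = np.random.default_rng(2)
        basis = np.linalg.qr(rng.standard_normal((200, 6)))[0]
        X1, X2 = basis[:, :3], basis[:, 3:]
        Y = (
            X1 @ rng.standard_normal((3, 30))
            + X2 @ rng.standard_normal((3, 30))
            + rng.standard_normal((200, 30))
        )
        vp = varpart(Y, X1, X2)
        assert abs(vp.b) < 0.02

    def test_fractions_sum_to_one(self, rng):
        Y = rng.standard_normal((50, 10))
        vp = varpart(Y, rng.standard_normal((50, 2)), rng.standard_normal((50, 3)))
        assert vp.a + vp.b + vp.c + vp.d == pytest.approx(1.0, abs=1e-10)

    def test_empty_block_rejected(self, rng):
        with pytest.raises(ValueError):
            varpart(rng.standard_normal((20, 5)), np.empty((20, 0)),
                    rng.standard_normal((20, 2)))


# distVincentyEllipsoid (WGS-84) reference distances, meters
GEOSPHERE_ORACLE = [
    (149.33017565868795, -7.18389803776518, 145.4512994270772, 40.3912550210953, 5282403.03256608),
    (157.34714878723025, 37.24908278090879, -130.0643396191299, 52.8793740156107, 5709039.43202200),
    (-76.98976747691631, 73.89428201597184, 176.0010224115103, -19.0215919213369, 12545689.09878068),
    (118.96114538423717, -41.57709986204281, 160.8005637209862, 31.4788539987057, 9157265.94788942),
    (51.02838680148125, -6.41022016759962, -150.3224790841341, -84.3287824047729, 9883434.55844321),
    (6.87454168684781, 74.80246886843815, 5.1162423659116, 56.5957336430438, 2031385.44138496),
    (85.17179327085614, 81.29849282559007, -39.5267518423498, -83.7531950301491, 19193921.65077290),
    (-131.52002499438822, -65.02714851871133, 146.0657271277159, -49.6979746199213, 4833765.80855425),
    (56.51722454465926, -4.25049613462761, -19.0909338835627, 69.1222393256612, 9877443.52861049),
    (73.82332225330174, 10.25656686164439, 120.9615335986018, 19.0023693861440, 5154247.37928099),
]


class TestGeodesy:
    def test_identical_points(self):
        assert geodesic_distance(45.0, 10.0, 45.0, 10.0) == 0.0

    def test_symmetry(self, rng):
        for _ in range(10):
            lon1, lon2 = rng.uniform(-180, 180, 2)
            lat1, lat2 = rng.uniform(-85, 85, 2)
            assert geodesic_distance(lon1, lat1, lon2, lat2) == pytest.approx(
                geodesic_distance(lon2, lat2, lon1, lat1), abs=1e-9
            )

    @pytest.mark.parametrize("lon1,lat1,lon2,lat2,expected", GEOSPHERE_ORACLE)
    def test_matches_independent_geodesic_oracle(self, lon1, lat1, lon2, lat2, expected):
        assert geodesic_distance(lon1, lat1, lon2, lat2) == pytest.approx(
            expected, abs=1e-3
        )

    def test_pcoa_recovers_planar_configuration(self, rng):
        pts = rng.standard_normal((15, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords, vals = pcoa(D, 2)
        # Procrustes: align by orthogonal transform and compare
        A = pts - pts.mean(axis=0)
        B = coords - coords.mean(axis=0)
        U, _, Vt = np.linalg.svd(B.T @ A)
        rms = np.sqrt(np.mean((B @ (U @ Vt) - A) ** 2))
        assert rms < 1e-8

    def test_pcoa_oracle_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.standard_normal((12, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ours, _ = pcoa(D, 3)
        theirs = skbio.stats.ordination.pcoa(D, number_of_dimensions=3).samples.to_numpy()
        for k in range(3):
            assert (
                np.allclose(ours[:, k], theirs[:, k], atol=1e-6)
                or np.allclose(ours[:, k], -theirs[:, k], atol=1e-6)
            )
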