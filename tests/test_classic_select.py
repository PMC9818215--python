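"""SPA and CARS selection: projection oracles, criterion curves, schedules."""

import warnings

import numpy as np
import pytest

from specseed.classic_select import (
    SelectionResult,
    cars_schedule,
    cars_select,
    rmsecv,
    spa_chain,
    spa_select,
)
from specseed.dataset import SpectraDataset
from specseed.grid import WavelengthGrid

from conftest import make_dataset


def gram_schmidt_oracle(X: np.ndarray, start: int, k: int) -> list[int]:
    """Exhaustive projection: orthogonal complement via pseudoinverse."""
    Xc = X - X.mean(axis=0)
    chain = [start]
    for _ in range(k - 1):
        S = Xc[:, chain]
        P = np.eye(X.shape[0]) - S @ np.linalg.pinv(S)
        norms = np.linalg.norm(P @ Xc, axis=0)
        norms[chain] = -1.0
        chain.append(int(np.argmax(norms)))
    return chain


class TestSpaChain:
    def test_k1_returns_start_index(self, rng):
        X = rng.normal(0, 1, (8, 5))
        assert spa_chain(X, 3, 1) == [3]

    def test_orthogonal_design_picks_largest_norms_in_order(self):
        X = np.zeros((6, 4))
        for j, scale in enumerate([1.0, 4.0, 3.0, 2.0]):
            X[j, j] = scale  # orthogonal columns of distinct norms
        chain = spa_chain(X, 0, 4)
        assert chain == [0, 1, 2, 3]  # then descending residual norm

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_projection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(4, 13))
        L = int(rng.integers(2, 9))
        X = rng.normal(0, 1, (N, L))
        k = int(rng.integers(1, min(N - 1, L) + 1))
        start = int(rng.integers(0, L))
        assert spa_chain(X, start, k) == gram_schmidt_oracle(X, start, k)

    def test_no_duplicates_and_linear_independence(self, rng):
        X = rng.normal(0, 1, (12, 8))
        chain = spa_chain(X, 0, 6)
        assert len(set(chain)) == len(chain)
        Xc = X - X.mean(axis=0)
        sv = np.linalg.svd(Xc[:, chain], compute_uv=False)
        assert sv[-1] > 1e-10

    def test_rank_exhaustion_returns_short_chain(self):
        X = np.zeros((6, 5))
        X[:, 0] = [1, 2, 3, 4, 5, 6]
        X[:, 1] = X[:, 0] * 2  # rank 1 overall
        with pytest.warns(UserWarning, match="rank exhausted"):
            chain = spa_chain(X, 0, 4)
        assert len(chain) < 4


class TestSpaSelect:
    def _planted(self, seed=3):
        rng = np.random.default_rng(seed)
        N, L = 60, 15
        y = np.repeat([0, 1], N // 2)
        X = rng.normal(0, 1, (N, L))
        X[:, 6] = 2.0 * y - 1.0  # exact linear carrier of the class signal
        labels = np.where(y == 1, "defective", "healthy")
        return make_dataset(X, labels), y

    def test_noise_free_signal_rmse_curve_flat_after_recovery(self):
        ds, _ = self._planted()
        res = spa_select(ds, max_vars=6, seed=0)
        assert 6 in res.indices
        assert res.n_selected <= 5
        assert res.best_value < 1e-6
        k_star = res.n_selected
        assert np.all(np.diff(res.criterion_curve[: k_star + 1]) <= 1e-6)

    def test_max_vars_one_exhaustive_scan(self):
        ds, _ = self._planted()
        res = spa_select(ds, max_vars=1, seed=0)
        assert res.n_selected == 1 and res.indices[0] == 6

    def test_indices_sorted_unique_and_fraction(self):
        ds, _ = self._planted()
        res = spa_select(ds, max_vars=5, seed=0)
        assert np.all(np.diff(res.indices) > 0)
        expected = round(100.0 * res.n_selected / 15, 2)
        assert res.fraction_of() == expected

    def test_max_vars_precondition(self):
        ds, _ = self._planted()
        tiny = ds.select_rows(np.arange(10))  # min(N-1, L) = 9
        with pytest.raises(ValueError):
            spa_select(tiny, max_vars=10, seed=0)


class TestRmsecv:
    def test_exact_linear_fit_near_zero(self, rng):
        N = 40
        y = np.repeat([0.0, 1.0], N // 2)
        X = (2 * y - 1)[:, None]
        assert rmsecv(X, y, folds=5) < 1e-8

    def test_pure_noise_rmsecv_near_sd_y(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (200, 5))
        y = rng.normal(0, 1, 200)
        v = rmsecv(X, y, folds=5, n_components=3)
        assert abs(v - y.std()) / y.std() < 0.2

    def test_loo_matches_explicit_oracle(self):
        rng = np.random.default_rng(4)
        N, p, nc = 14, 3, 2
        X = rng.normal(0, 1, (N, p))
        y = rng.normal(0, 1, N)
        got = rmsecv(X, y, folds=N, n_components=nc)
        from sklearn.cross_decomposition import PLSRegression

        sse = 0.0
        for i in range(N):
            tr = np.setdiff1d(np.arange(N), [i])
            pls = PLSRegression(n_components=nc, scale=False).fit(X[tr], y[tr])
            sse += float((y[i] - pls.predict(X[[i]]).ravel()[0]) ** 2)
        assert np.isclose(got, np.sqrt(sse / N), atol=1e-10)

    def test_preconditions(self, rng):
        X = rng.normal(0, 1, (10, 2))
        y = rng.normal(0, 1, 10)
        with pytest.raises(ValueError):
            rmsecv(X, y, folds=1)
        with pytest.raises(ValueError):
            rmsecv(X[:, :0], y, folds=5)


class TestCars:
    def _planted(self, seed, L=30, N=80):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], N // 2)
        X = rng.normal(0, 1, (N, L))
        X[:, 13] = 2.0 * y + rng.normal(0, 0.1, N)
        labels = np.where(y == 1, "defective", "healthy")
        return make_dataset(X, labels)

    def test_schedule_endpoints(self):
        sch = cars_schedule(245, 50)
        assert sch[0] == 245 and sch[-1] == 2 and len(sch) == 50
        assert np.all(np.diff(sch) <= 0)

    def test_curve_length_counts_follow_schedule(self):
        ds = self._planted(1)
        res = cars_select(ds, n_mc=50, folds=5, seed=1)
        assert len(res.criterion_curve) == 50
        counts = np.array(res.meta["retained_counts"])
        sched = np.array(res.meta["schedule"])
        assert np.all(np.diff(counts) <= 0)
        assert np.all(np.abs(counts - sched) <= 1)

    def test_fixed_seed_bit_reproducible(self):
        ds = self._planted(2)
        a = cars_select(ds, n_mc=20, seed=5)
        b = cars_select(ds, n_mc=20, seed=5)
        assert np.array_equal(a.indices, b.indices)
        assert np.array_equal(a.criterion_curve, b.criterion_curve)

    def test_planted_band_survives_to_argmin_subset(self):
        hits = sum(
            13 in cars_select(self._planted(seed), n_mc=30, seed=seed).indices
            for seed in range(1, 6)
        )
        assert hits >= 4

    def test_best_value_is_curve_minimum(self):
        ds = self._planted(3)
        res = cars_select(ds, n_mc=20, seed=3)
        assert np.isclose(res.best_value, res.criterion_curve.min())

    def test_n_mc_precondition(self):
        with pytest.raises(ValueError):
            cars_select(self._planted(1), n_mc=1)


class TestSelectionResultIO:
    def test_json_roundtrip(self, tmp_path):
        res = SelectionResult(
            indices=np.array([1, 5, 9]),
            wavelengths_nm=np.array([910.0, 950.0, 990.0]),
            criterion_curve=np.array([0.5, 0.3, 0.4]),
            best_value=0.3,
            meta={"algorithm": "spa", "n_bands_total": 20},
        )
        path = tmp_path / "sel.json"
        res.to_json(path)
        back = SelectionResult.from_json(path)
        assert np.array_equal(back.indices, res.indices)
        assert back.fraction_of() == 15.0
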