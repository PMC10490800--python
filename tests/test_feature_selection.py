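import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pellspec import synthetic
from pellspec.core import ReferenceTable, SpectraSet, WavelengthGrid
from pellspec.feature_selection import (
    CarsConfig,
    cars_select,
    coefficient_weights,
    edf_ratio,
    selected_fraction_pct,
    spa_chain,
    spa_select,
)


class TestEdfRatio:
    @given(st.integers(3, 3000), st.integers(2, 100))
    @settings(max_examples=60, deadline=None)
    def test_closed_form_and_endpoints(self, n, N):
        assert edf_ratio(1, n, N) == pytest.approx(1.0, abs=1e-12)
        assert edf_ratio(N, n, N) == pytest.approx(2.0 / n, rel=1e-12)
        i = max(1, min(N, N // 2))
        direct = (n / 2.0) ** ((1.0 - i) / (N - 1))
        assert edf_ratio(i, n, N) == pytest.approx(direct, rel=1e-12)

    def test_strictly_decreasing_trace(self):
        trace = [edf_ratio(i, 244, 40) for i in range(1, 41)]
        assert all(a > b for a, b in zip(trace, trace[1:]))

    def test_published_schedule_point(self):
        # run 17 of 40 on the 244-band grid
        assert edf_ratio(17, 244, 40) == pytest.approx(
            (122.0) ** (-16.0 / 39.0), rel=1e-12
        )
        assert edf_ratio(17, 244, 40) == pytest.approx(0.139334, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            edf_ratio(0, 244, 40)
        with pytest.raises(ValueError):
            edf_ratio(41, 244, 40)
        with pytest.raises(ValueError):
            edf_ratio(1, 2, 40)
        with pytest.raises(ValueError):
            edf_ratio(1, 244, 1)


class TestWeights:
    def test_examples(self):
        np.testing.assert_allclose(
            coefficient_weights(np.array([1.0, 1.0, 2.0])), [0.25, 0.25, 0.5]
        )
        np.testing.assert_allclose(
            coefficient_weights(np.array([-3.0, 1.0])), [0.75, 0.25]
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_normalization(self, seed):
        B = np.random.default_rng(seed).normal(size=8)
        if np.all(B == 0):
            return
        assert coefficient_weights(B).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            coefficient_weights(np.zeros(4))


class TestSelectedFraction:
    def test_printed_percentage(self):
        assert selected_fraction_pct(34, 244) == 13.9

    def test_bounds(self):
        with pytest.raises(ValueError):
            selected_fraction_pct(5, 0)
        with pytest.raises(ValueError):
            selected_fraction_pct(10, 5)


def _spa_bruteforce(X, k0, N):
    """Independent oracle: argmax residual norm after least-squares
    projection onto the span of all previously selected columns."""
    X = X - X.mean(axis=0)
    chain = [k0]
    for _ in range(N - 1):
        S = X[:, chain]
        best, best_norm = None, -1.0
        for j in range(X.shape[1]):
            if j in chain:
                continue
            coef, *_ = np.linalg.lstsq(S, X[:, j], rcond=None)
            resid = X[:, j] - S @ coef
            nrm = np.linalg.norm(resid)
            if nrm > best_norm:
                best, best_norm = j, nrm
        chain.append(best)
    return np.array(chain)


class TestSpaChain:
    def test_orthogonal_columns_ranked_by_norm(self):
        # orthogonal columns with norms 3, 1, 2 (already centered)
        X = np.zeros((6, 3))
        X[:2, 0] = [3.0 / np.sqrt(2), -3.0 / np.sqrt(2)]
        X[2:4, 1] = [1.0 / np.sqrt(2), -1.0 / np.sqrt(2)]
        X[4:6, 2] = [2.0 / np.sqrt(2), -2.0 / np.sqrt(2)]
        chain = spa_chain(X, 0, 3)
        np.testing.assert_array_equal(chain, [0, 2, 1])

    def test_duplicate_column_never_follows_twin(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 5))
        X[:, 3] = X[:, 1]  # exact twin
        with pytest.warns(UserWarning):
            chain = spa_chain(X, 1, 5)
        assert 3 not in chain[1:3]

    def test_matches_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            X = rng.normal(size=(6, 6))
            k0 = int(rng.integers(6))
            np.testing.assert_array_equal(
                spa_chain(X, k0, 5), _spa_bruteforce(X, k0, 5)
            )

    def test_bounds_validation(self):
        X = np.random.default_rng(2).normal(size=(6, 6))
        with pytest.raises(ValueError):
            spa_chain(X, 6, 3)
        with pytest.raises(ValueError):
            spa_chain(X, 0, 6)  # > samples - 1


def _table(X):
    ids = [f"s{i:02d}" for i in range(X.shape[0])]
    grid = WavelengthGrid(np.arange(X.shape[1]) * 10.0 + 1000.0)
    return SpectraSet(X, grid, ids), ids


class TestSpaSelect:
    def test_finds_minimal_sufficient_set(self):
        # orthogonal design whose three large-norm columns carry all of y:
        # the projection chain ranks them first and CV error vanishes at N=3
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.normal(size=(40, 8)))
        scales = np.array([3.0, 2.8, 2.6, 0.5, 0.4, 0.3, 0.2, 0.1])
        X = Q * scales
        y = 11.0 + 2 * X[:, 0] - 3 * X[:, 1] + X[:, 2]  # noiseless
        s, ids = _table(X)
        refs = ReferenceTable(ids, y)
        res = spa_select(s, refs, n_min=1, n_max=6, cv_folds=5, seed=0)
        assert res.chosen == 3
        assert set(res.selected_indices) == {0, 1, 2}

    def test_selected_wavelengths_sorted_unique(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 10))
        y = 11 + X[:, 2] + 0.1 * rng.normal(size=30)
        s, ids = _table(X)
        res = spa_select(s, ReferenceTable(ids, y), n_min=2, n_max=5, cv_folds=5, seed=0)
        wl = res.selected_wavelengths
        assert np.all(np.diff(wl) > 0)
        assert len(set(res.selected_indices.tolist())) == res.n_selected

    def test_invalid_range_rejected(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 6))
        s, ids = _table(X)
        refs = ReferenceTable(ids, np.full(20, 11.0) + rng.normal(size=20))
        with pytest.raises(ValueError):
            spa_select(s, refs, n_min=5, n_max=3)


class TestCars:
    @pytest.fixture(scope="class")
    def sparse(self):
        return synthetic.generate_sparse_dataset(seed=1)

    def test_recovers_informative_variables(self, sparse):
        X, y, info = sparse
        res = cars_select(X, y, CarsConfig(seed=1, pls_components=5))
        assert set(info).issubset(set(res.selected_indices.tolist()))
        assert 5 <= res.n_selected < X.n_bands

    def test_chosen_run_beats_full_spectrum(self, sparse):
        X, y, _ = sparse
        res = cars_select(X, y, CarsConfig(seed=2, pls_components=5))
        assert res.rmsecv_trace[res.chosen - 1] <= res.rmsecv_trace[0] + 1e-12

    def test_retained_counts_follow_schedule(self, sparse):
        X, y, _ = sparse
        res = cars_select(X, y, CarsConfig(seed=3, pls_components=5))
        counts = res.retained_counts
        assert np.all(np.diff(counts) <= 0)
        assert counts[0] == X.n_bands  # r_1 = 1: full spectrum baseline
        assert counts[-1] == 2

    def test_invariant_to_sample_order(self, sparse):
        X, y, _ = sparse
        perm = np.random.default_rng(9).permutation(X.n_samples)
        Xp = X.subset_rows(perm)
        a = cars_select(X, y, CarsConfig(seed=4, pls_components=5))
        b = cars_select(Xp, y, CarsConfig(seed=4, pls_components=5))
        np.testing.assert_array_equal(a.selected_indices, b.selected_indices)

    def test_ars_mode_runs_and_shrinks_faster(self, sparse):
        X, y, _ = sparse
        res = cars_select(X, y, CarsConfig(seed=5, pls_components=5, use_ars=True))
        assert res.retained_counts[5] < X.n_bands * edf_ratio(6, X.n_bands, 40)

    def test_result_json_round_trip(self, sparse, tmp_path):
        import json

        X, y, _ = sparse
        res = cars_select(X, y, CarsConfig(seed=6, pls_components=5))
        res.to_json(tmp_path / "sel.json")
        d = json.loads((tmp_path / "sel.json").read_text())
        assert d["method"] == "CARS"
        assert d["n_selected"] == res.n_selected
        assert d["selected_fraction_pct"] == res.selected_fraction_pct
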