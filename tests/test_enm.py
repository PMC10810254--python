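import warnings

import numpy as np
import pytest

from genosdm import (EnvGrid, MaxentNicheModel, OccurrenceSet, auc,
                     fit_niche_model, max_sss_threshold, sample_background)


def gradient_grid(n=20, n_layers=2, seed=0):
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    layers = [cc / (n - 1), rr / (n - 1)][:n_layers]
    layers += [rng.random((n, n)) for _ in range(n_layers - len(layers))]
    return EnvGrid([f"env{i+1}" for i in range(n_layers)], np.stack(layers),
                   np.ones((n, n), bool), 0.0, float(n), 1.0)


class TestSampleBackground:
    def test_zero_buffer_excludes_only_presence_cells(self):
        grid = gradient_grid(6)
        pres = OccurrenceSet.from_arrays([0.5, 1.5], [5.5, 5.5])
        bg = sample_background(grid, pres, n=34, buffer_radius=0.0, seed=0)
        assert len(bg) == 34  # all 36 cells minus the 2 presence cells
        pres_cells = {(0, 0), (0, 1)}
        bg_cells = set(zip(*grid.cell_of(bg.x, bg.y)))
        assert not pres_cells & bg_cells

    def test_presence_everywhere_warns_and_returns_empty(self):
        grid = gradient_grid(3)
        rr, cc = np.nonzero(grid.mask)
        x, y = grid.cell_center(rr, cc)
        pres = OccurrenceSet.from_arrays(x, y)
        with pytest.warns(UserWarning):
            bg = sample_background(grid, pres, n=5, seed=0)
        assert len(bg) == 0

    def test_eligible_count_matches_brute_force_distance_scan(self):
        grid = gradient_grid(10)
        pres = OccurrenceSet.from_arrays([4.5], [5.5])
        radius = 2.5
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # must not warn: enough cells
            bg = sample_background(grid, pres, n=10, buffer_radius=radius,
                                   seed=1)
        # brute force: count cells whose centre is farther than the radius
        eligible = 0
        for r in range(10):
            for c in range(10):
                x, y = grid.cell_center(r, c)
                if np.hypot(x - 4.5, y - 5.5) > radius:
                    eligible += 1
        big = sample_background(grid, pres, n=10_000, buffer_radius=radius,
                                seed=1)
        assert len(big) == eligible

    def test_sampling_is_seeded(self):
        grid = gradient_grid(8)
        pres = OccurrenceSet.from_arrays([1.5], [6.5])
        a = sample_background(grid, pres, 20, seed=5)
        b = sample_background(grid, pres, 20, seed=5)
        assert np.array_equal(a.coords(), b.coords())


class TestFit:
    def planted_fit(self, betamultiplier=1.0, n=60, seed=0, **kwargs):
        """Presences concentrated where env1 is high, uniform background."""
        grid = gradient_grid(n, seed=seed)
        rng = np.random.default_rng(seed)
        # presence cells biased toward high env1 (right-hand columns)
        cols = rng.integers(int(0.7 * n), n, size=100)
        rows = rng.integers(0, n, size=100)
        px, py = grid.cell_center(rows, cols)
        pres = OccurrenceSet.from_arrays(px, py)
        bg = sample_background(grid, pres, 300, seed=seed + 1)
        return fit_niche_model(pres, bg, grid,
                               betamultiplier=betamultiplier, **kwargs), grid

    def test_planted_gradient_coefficient_sign(self):
        model, _ = self.planted_fit()
        coef = dict(zip(model.feature_defs_, model.coef_))
        assert coef[("env1", "linear")] > 0

    def test_huge_betamultiplier_shrinks_to_constant(self):
        model, grid = self.planted_fit(betamultiplier=1e6)
        assert np.allclose(model.coef_, 0.0)
        pred = model.predict_grid(grid)
        assert np.ptp(pred.valid_values()) < 1e-9

    def test_duplicated_presences_with_renormalized_weights_match(self):
        grid = gradient_grid(20)
        rng = np.random.default_rng(2)
        px = rng.uniform(10, 20, 30)
        py = rng.uniform(0, 20, 30)
        bgx = rng.uniform(0, 20, 100)
        bgy = rng.uniform(0, 20, 100)
        Xp = grid.extract(px, py)
        Xb = grid.extract(bgx, bgy)
        X1 = np.vstack([Xp, Xb])
        y1 = np.r_[np.ones(30), np.zeros(100)]
        X2 = np.vstack([Xp, Xp, Xb])
        y2 = np.r_[np.ones(60), np.zeros(100)]
        w2 = np.r_[np.full(60, 0.5), np.ones(100)]
        lam = 1.0 / 30
        m1 = MaxentNicheModel(lam=lam).fit(X1, y1)
        m2 = MaxentNicheModel(lam=lam).fit(X2, y2, sample_weight=w2)
        assert np.allclose(m1.coef_, m2.coef_, atol=1e-4)

    def test_constant_layer_dropped_with_warning(self):
        grid = gradient_grid(10)
        grid.values[1][:] = 0.7  # flatten env2
        pres = OccurrenceSet.from_arrays([7.5, 8.5, 9.5], [5.5, 5.5, 4.5])
        bg = sample_background(grid, pres, 50, seed=0)
        with pytest.warns(UserWarning):
            model = fit_niche_model(pres, bg, grid)
        assert all(layer != "env2" for layer, _ in model.feature_defs_)

    def test_too_few_presences_rejected(self):
        with pytest.raises(ValueError):
            MaxentNicheModel().fit(np.ones((3, 2)), [1, 0, 0])

    def test_training_deviance_monotone_in_betamultiplier(self):
        grid = gradient_grid(30)
        rng = np.random.default_rng(3)
        cols = rng.integers(20, 30, size=50)
        rows = rng.integers(0, 30, size=50)
        px, py = grid.cell_center(rows, cols)
        pres = OccurrenceSet.from_arrays(px, py)
        bg = sample_background(grid, pres, 200, seed=4)
        X = np.vstack([grid.extract(pres.x, pres.y),
                       grid.extract(bg.x, bg.y)])
        y = np.r_[np.ones(len(pres)), np.zeros(len(bg))]
        devs = []
        for beta in (0.01, 1.0, 5.0, 10.0):
            m = MaxentNicheModel(betamultiplier=beta).fit(
                X, y, layer_names=grid.layer_names)
            p = np.clip(m.predict_points(X, grid.layer_names), 1e-12,
                        1 - 1e-12)
            devs.append(-2 * np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
        assert all(d2 >= d1 - 1e-6 for d1, d2 in zip(devs, devs[1:]))


class TestPredict:
    def test_prediction_reproduces_training_cell_scores(self):
        grid = gradient_grid(15)
        pres = OccurrenceSet.from_arrays([12.5, 13.5, 14.5], [7.5, 6.5, 5.5])
        bg = sample_background(grid, pres, 80, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_niche_model(pres, bg, grid)
        surf = model.predict_grid(grid)
        r, c = grid.cell_of(pres.x, pres.y)
        direct = model.predict_points(grid.extract(pres.x, pres.y))
        assert np.allclose(surf.values[r, c], direct)

    def test_monotone_in_positive_coefficient_layer(self):
        grid = gradient_grid(20)
        rng = np.random.default_rng(5)
        cols = rng.integers(14, 20, size=40)
        rows = rng.integers(0, 20, size=40)
        px, py = grid.cell_center(rows, cols)
        pres = OccurrenceSet.from_arrays(px, py)
        bg = sample_background(grid, pres, 150, seed=6)
        model = fit_niche_model(pres, bg, grid, quadratic=False)
        coef = dict(zip(model.feature_defs_, model.coef_))
        assert coef[("env1", "linear")] > 0
        X = grid.extract(bg.x, bg.y)
        X_up = X.copy()
        lo, hi = model.feature_ranges_["env1"]
        X = np.clip(X, lo, hi)  # stay inside the clamp range
        X_up = X.copy()
        X_up[:, 0] = np.minimum(X_up[:, 0] + 0.05, hi)
        assert (model.predict_points(X_up) >= model.predict_points(X) - 1e-12
                ).all()

    def test_missing_layer_rejected(self):
        grid = gradient_grid(10)
        pres = OccurrenceSet.from_arrays([7.5, 8.5, 6.5], [5.5, 5.5, 4.5])
        bg = sample_background(grid, pres, 40, seed=0)
        model = fit_niche_model(pres, bg, grid)
        other = EnvGrid(["env1"], grid.values[:1].copy(), grid.mask.copy(),
                        0.0, 10.0, 1.0)
        with pytest.raises(ValueError):
            model.predict_grid(other)

    def test_json_round_trip_preserves_predictions(self):
        grid = gradient_grid(12)
        pres = OccurrenceSet.from_arrays([9.5, 10.5, 11.5], [5.5, 5.5, 4.5])
        bg = sample_background(grid, pres, 60, seed=0)
        model = fit_niche_model(pres, bg, grid)
        back = MaxentNicheModel.from_json(model.to_json())
        assert np.allclose(back.predict_grid(grid).values,
                           model.predict_grid(grid).values)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_all_tied_scores(self):
        assert auc([0.5] * 10, [0.5] * 7) == 0.5

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        pres = rng.random(50)
        bg = rng.random(50)
        total = 0.0
        for p in pres:
            for b in bg:
                total += 1.0 if p > b else (0.5 if p == b else 0.0)
        assert auc(pres, bg) == pytest.approx(total / 2500, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        pres, bg = rng.random(30), rng.random(40)
        assert auc(pres, bg) == pytest.approx(auc(np.exp(pres), np.exp(bg)),
                                              abs=1e-12)


class TestMaxSSS:
    def test_separated_sets_pick_presence_score(self):
        assert max_sss_threshold([0.9] * 5, [0.1] * 5) == 0.9

    def test_identical_sets_return_smallest_candidate(self):
        scores = [0.2, 0.5, 0.8]
        assert max_sss_threshold(scores, scores) == 0.2

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(2)
        pres = rng.random(30)
        bg = rng.random(30)
        best_t, best_v = None, -np.inf
        for t in sorted(np.unique(np.r_[pres, bg])):
            v = np.mean(pres >= t) + np.mean(bg < t)
            if v > best_v + 1e-12:
                best_v, best_t = v, t
        assert max_sss_threshold(pres, bg) == pytest.approx(best_t)
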