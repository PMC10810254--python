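import itertools

import numpy as np
import pytest

from genosdm import (EnvGrid, OccurrenceSet, SuitabilityMap, mantel_test,
                     niche_breadth_pca, schoener_d, similarity_test,
                     welch_pairwise)


def make_map(values, mask=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if mask is None:
        mask = np.ones(values.shape, bool)
    return SuitabilityMap(values, mask, 0.0, float(values.shape[0]), 1.0)


class TestSchoenerD:
    def test_identical_maps_give_one(self):
        rng = np.random.default_rng(0)
        m = make_map(rng.random((5, 5)))
        assert schoener_d(m, m) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_support_gives_zero(self):
        assert schoener_d(make_map([[1.0, 0.0]]),
                          make_map([[0.0, 1.0]])) == pytest.approx(0.0,
                                                                   abs=1e-12)

    def test_two_cell_hand_computed_case(self):
        # after scaling: (0.5, 0.5) vs (0.25, 0.75) -> 1 - 0.5*(0.25+0.25)
        d = schoener_d(make_map([[0.5, 0.5]]), make_map([[0.25, 0.75]]))
        assert d == pytest.approx(0.75, abs=1e-12)

    def test_symmetric_and_scale_invariant(self):
        rng = np.random.default_rng(1)
        a, b = make_map(rng.random((4, 6))), make_map(rng.random((4, 6)))
        assert schoener_d(a, b) == pytest.approx(schoener_d(b, a), abs=1e-12)
        scaled = make_map(a.values * 0.37)
        assert schoener_d(scaled, b) == pytest.approx(schoener_d(a, b),
                                                      abs=1e-12)

    def test_geometry_mismatch_and_zero_map_rejected(self):
        with pytest.raises(ValueError):
            schoener_d(make_map([[0.5, 0.5]]), make_map([[0.5], [0.5]]))
        with pytest.raises(ValueError):
            schoener_d(make_map([[0.0, 0.0]]), make_map([[0.5, 0.5]]))


@pytest.fixture(scope="module")
def similarity_setup():
    from genosdm import ScenarioSpec, generate_scenario

    spec = ScenarioSpec(grid_size=(25, 25), n_env_layers=3, n_snps=100,
                        n_individuals_per_range=50, niche_sd=0.15, seed=9)
    data = generate_scenario(spec)
    return data


class TestSimilarityTest:
    def test_null_count_contract(self, similarity_setup):
        data = similarity_setup
        gA = data.grids["native"]
        gB = data.grids["invaded_old"]
        res = similarity_test(data.occurrences["native"],
                              data.occurrences["invaded_old"], gA, gB,
                              data.grids["invaded_new"], n_reps=1, seed=0,
                              n_background=200)
        assert len(res.null_values) + res.n_failed == 2

    def test_self_comparison_is_significantly_similar(self, similarity_setup):
        data = similarity_setup
        gA = data.grids["native"]
        recs = data.occurrences["native"]
        res = similarity_test(recs, recs, gA, gA, data.grids["invaded_new"],
                              n_reps=10, seed=1, n_background=200)
        assert res.D >= res.percentile_high
        assert res.significant

    def test_null_values_in_unit_interval_and_reproducible(self,
                                                           similarity_setup):
        data = similarity_setup
        args = (data.occurrences["native"], data.occurrences["invaded_old"],
                data.grids["native"], data.grids["invaded_old"],
                data.grids["invaded_new"])
        r1 = similarity_test(*args, n_reps=3, seed=7, n_background=200)
        r2 = similarity_test(*args, n_reps=3, seed=7, n_background=200)
        assert all(0.0 <= v <= 1.0 for v in r1.null_values)
        assert r1.null_values == r2.null_values
        assert r1.D == r2.D


def shoelace(points):
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestNicheBreadth:
    def grid_and_records(self):
        rng = np.random.default_rng(3)
        n = 20
        vals = np.stack([rng.random((n, n)) for _ in range(3)])
        grid = EnvGrid(["e1", "e2", "e3"], vals, np.ones((n, n), bool),
                       0.0, float(n), 1.0)
        rr = rng.integers(0, n, 60)
        cc = rng.integers(0, n, 60)
        x, y = grid.cell_center(rr, cc)
        return grid, x, y

    def test_subset_hull_not_larger_than_global(self):
        grid, x, y = self.grid_and_records()
        all_recs = OccurrenceSet.from_arrays(x, y, range_label="all")
        sub = OccurrenceSet.from_arrays(x[:20], y[:20], range_label="sub")
        nb = niche_breadth_pca({"all": all_recs, "sub": sub},
                               {"all": grid, "sub": grid})
        assert nb.pct_of_global["global"] == pytest.approx(100.0)
        assert nb.pct_of_global["sub"] <= 100.0 + 1e-9

    def test_hull_area_matches_shoelace_on_pc_scores(self):
        grid, x, y = self.grid_and_records()
        recs = OccurrenceSet.from_arrays(x[:4], y[:4], range_label="r")
        nb = niche_breadth_pca({"r": recs}, {"r": grid})
        pts = nb.pc_scores[["PC1", "PC2"]].to_numpy()
        from scipy.spatial import ConvexHull

        hull_pts = pts[ConvexHull(pts).vertices]
        assert nb.hull_area_by_range["r"] == pytest.approx(
            shoelace(hull_pts), abs=1e-12)

    def test_duplicated_records_leave_area_unchanged(self):
        grid, x, y = self.grid_and_records()
        recs = OccurrenceSet.from_arrays(x[:10], y[:10], range_label="r")
        dup = OccurrenceSet.from_arrays(np.r_[x[:10], x[:10]],
                                        np.r_[y[:10], y[:10]],
                                        range_label="r")
        a1 = niche_breadth_pca({"r": recs}, {"r": grid})
        a2 = niche_breadth_pca({"r": dup}, {"r": grid})
        assert a1.hull_area_by_range["r"] == pytest.approx(
            a2.hull_area_by_range["r"], rel=1e-9)

    def test_collinear_records_warn_with_zero_area(self):
        grid, x, y = self.grid_and_records()
        recs = OccurrenceSet.from_arrays(x[:2], y[:2], range_label="r")
        with pytest.warns(UserWarning):
            nb = niche_breadth_pca({"r": recs}, {"r": grid})
        assert nb.hull_area_by_range["r"] == 0.0


def welch_oracle(a, b):
    import scipy.stats as st

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * st.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_groups_give_null_result(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        out = welch_pairwise({"a": vals, "b": vals.copy()})
        assert out.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p"] == pytest.approx(1.0, abs=1e-12)

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(0)
        out = welch_pairwise({"a": rng.normal(0, 1e-4, 6),
                              "b": 1 + rng.normal(0, 1e-4, 6)})
        assert out.loc[0, "p"] < 1e-10

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1.5, 15)
        out = welch_pairwise({"a": a, "b": b})
        t, df, p = welch_oracle(a, b)
        assert out.loc[0, "t"] == pytest.approx(t, abs=1e-10)
        assert out.loc[0, "df"] == pytest.approx(df, abs=1e-10)
        assert out.loc[0, "p"] == pytest.approx(p, abs=1e-10)

    def test_zero_variance_pair_reports_nan_with_warning(self):
        with pytest.warns(UserWarning):
            out = welch_pairwise({"a": np.ones(4), "b": np.full(4, 2.0)})
        assert np.isnan(out.loc[0, "t"])

    def test_all_pairs_reported(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(size=5) for k in "abcd"}
        assert len(welch_pairwise(groups)) == 6


def sym(m):
    m = np.triu(m, 1)
    return m + m.T


class TestMantel:
    def test_identity_gives_r_one(self):
        rng = np.random.default_rng(0)
        m = sym(rng.random((5, 5)))
        r, p = mantel_test(m, m.copy(), n_perm=99, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_affine_transform_preserves_r(self):
        rng = np.random.default_rng(1)
        m = sym(rng.random((6, 6)))
        r, _ = mantel_test(m, 3.0 * m + sym(np.full((6, 6), 2.0)),
                           n_perm=99, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        m1, m2 = sym(rng.random((5, 5))), sym(rng.random((5, 5)))
        r_obs, p = mantel_test(m1, m2, n_perm=120)
        iu = np.triu_indices(5, 1)
        count = 0
        for perm in itertools.permutations(range(5)):
            mp = m2[np.ix_(perm, perm)]
            rp = np.corrcoef(m1[iu], mp[iu])[0, 1]
            if abs(rp) >= abs(r_obs) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 120, abs=1e-12)

    def test_zero_variance_rejected(self):
        m = sym(np.full((4, 4), 1.0))
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            mantel_test(m, sym(rng.random((4, 4))), n_perm=9)

    def test_asymmetric_input_rejected(self):
        rng = np.random.default_rng(4)
        bad = rng.random((4, 4))
        with pytest.raises(ValueError):
            mantel_test(bad, bad, n_perm=9)
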