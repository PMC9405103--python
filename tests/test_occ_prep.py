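"""Cleaning cascade: thinning, Mahalanobis outliers, overlap balancing."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from nichetransfer.containers import OccurrenceSet
from nichetransfer.errors import DataError
from nichetransfer.occ_prep import (
    balance_by_overlap,
    clean_cascade,
    ellipsoid_overlap,
    remove_env_outliers,
    thin_to_cells,
)
from tests.conftest import make_env


def occ_from(points, period="historical", species="sp"):
    return OccurrenceSet(
        pd.DataFrame(
            [
                {"species": species, "x": x, "y": y, "period": period, "source": "t"}
                for y, x in points
            ]
        )
    )


class TestThinToCells:
    def test_duplicate_cell_keeps_first(self):
        env = make_env(np.zeros((1, 10, 10)))
        occ = occ_from([(2, 2), (2, 2)])
        assert len(thin_to_cells(occ, env)) == 1

    def test_masked_cell_dropped(self):
        mask = np.ones((10, 10), dtype=bool)
        mask[3, 3] = False
        env = make_env(np.zeros((1, 10, 10)), mask=mask)
        occ = occ_from([(3, 3)])
        assert len(thin_to_cells(occ, env)) == 0

    def test_toy_enumeration(self):
        mask = np.ones((10, 10), dtype=bool)
        mask[5, 5] = False
        env = make_env(np.zeros((1, 10, 10)), mask=mask)
        occ = occ_from([(1, 1), (1, 1), (2, 2), (5, 5), (4, 4)])
        assert len(thin_to_cells(occ, env)) == 3

    def test_periods_thinned_separately(self):
        env = make_env(np.zeros((1, 10, 10)))
        occ = OccurrenceSet.concat(
            [occ_from([(2, 2)], period="historical"), occ_from([(2, 2)], period="modern")]
        )
        assert len(thin_to_cells(occ, env)) == 2


def _cloud_env_and_occ(X, shape=(40, 40), period="historical"):
    """Place each row of X in its own grid cell of a 2-layer stack."""
    n, L = X.shape
    layers = np.zeros((L, *shape))
    pts = []
    for i in range(n):
        y, x = divmod(i, shape[1])
        layers[:, y, x] = X[i]
        pts.append((y, x))
    return make_env(layers), occ_from(pts, period=period)


class TestRemoveEnvOutliers:
    def test_centroid_record_never_dropped(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 2))
        X[0] = X.mean(axis=0)  # approximately the centroid
        X[0] = np.vstack([X[1:]]).reshape(-1, 2).mean(axis=0)
        env, occ = _cloud_env_and_occ(X)
        kept = remove_env_outliers(occ, env)
        first = (occ.records.y[0], occ.records.x[0])
        assert first in set(zip(kept.ys.tolist(), kept.xs.tolist()))

    def test_planted_outlier_is_dropped(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(size=(500, 2)), [[10.0, 10.0]]])
        env, occ = _cloud_env_and_occ(X, shape=(30, 30))
        kept = thin_to_cells(occ, env)  # all cells distinct by construction
        kept = remove_env_outliers(kept, env, level=0.975)
        dropped = len(occ) - len(kept)
        outlier_cell = (occ.records.y.iloc[-1], occ.records.x.iloc[-1])
        assert outlier_cell not in set(zip(kept.ys.tolist(), kept.xs.tolist()))
        assert dropped >= 1

    def test_chi2_coverage_under_normality(self):
        """Expected drop fraction ~ 1 - level within 99% binomial bounds."""
        rng = np.random.default_rng(2)
        n, level = 2000, 0.975
        X = rng.normal(size=(n, 2))
        env, occ = _cloud_env_and_occ(X, shape=(50, 50))
        kept = remove_env_outliers(occ, env, level=level)
        dropped = n - len(kept)
        p = 1 - level
        bound = 2.576 * np.sqrt(p * (1 - p) * n)
        assert abs(dropped - p * n) < bound + 5  # slack for estimated (mu, cov)

    def test_too_few_records_raise(self):
        env, occ = _cloud_env_and_occ(np.random.default_rng(0).normal(size=(3, 2)))
        with pytest.raises(DataError):
            remove_env_outliers(occ, env)


class TestEllipsoidOverlap:
    def test_identical_point_sets(self):
        X = np.random.default_rng(0).normal(size=(60, 2))
        assert ellipsoid_overlap(X, X.copy(), seed=1) == pytest.approx(1.0, abs=0.01)

    def test_far_separated_clouds(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(60, 2))
        B = rng.normal(size=(60, 2)) + 100.0
        assert ellipsoid_overlap(A, B, seed=1) == pytest.approx(0.0, abs=0.005)

    def test_unit_circles_offset_by_one_match_lens_area(self):
        """Two unit-radius disks at distance 1: Jaccard from the lens-area
        closed form (intersection 2*pi/3 - sqrt(3)/2)."""
        c = chi2.ppf(0.975, df=2)
        # 4 points with sample mean 0 and sample covariance I/c -> the
        # level-0.975 ellipsoid is exactly the unit disk
        r = np.sqrt(3.0 / 2.0 / c)
        base = np.array([[r, 0], [-r, 0], [0, r], [0, -r]])
        inter = 2 * np.arccos(0.5) - 0.5 * np.sqrt(3)
        union = 2 * np.pi - inter
        expected = inter / union
        got = ellipsoid_overlap(base, base + [1.0, 0.0], n_points=200_000, seed=3)
        assert got == pytest.approx(expected, abs=0.01)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        A, B = rng.normal(size=(40, 2)), rng.normal(size=(40, 2)) + 0.5
        assert ellipsoid_overlap(A, B, seed=9) == ellipsoid_overlap(A, B, seed=9)


class TestBalanceByOverlap:
    def _setup(self, n_hist=30, n_mod=35, planted=0, seed=0):
        rng = np.random.default_rng(seed)
        XH = rng.normal(size=(n_hist, 2))
        XM = rng.normal(size=(n_mod - planted, 2))
        if planted:
            XM = np.vstack([XM, rng.normal(size=(planted, 2)) + 8.0])
        envH, occH = _cloud_env_and_occ(XH, period="historical")
        envM, occM = _cloud_env_and_occ(XM, period="modern")
        return occH, occM, envH, envM, XH, XM

    def test_already_balanced_is_identity(self):
        occH, occM, envH, envM, *_ = self._setup(30, 30)
        h, m, test, _ = balance_by_overlap(occH, occM, envH, envM, seed=1)
        assert h.records.equals(occH.records)
        assert m.records.equals(occM.records)
        assert len(test) == 0

    def test_planted_distant_records_removed_first(self):
        occH, occM, envH, envM, _, XM = self._setup(30, 35, planted=5, seed=2)
        h, m, test, _ = balance_by_overlap(occH, occM, envH, envM, seed=1)
        planted_cells = set(
            zip(occM.ys[-5:].tolist(), occM.xs[-5:].tolist())
        )
        test_cells = set(zip(test.ys.tolist(), test.xs.tolist()))
        assert planted_cells == test_cells

    def test_output_sizes_equal_minimum(self):
        occH, occM, envH, envM, *_ = self._setup(28, 40, seed=3)
        h, m, test, rep = balance_by_overlap(occH, occM, envH, envM, seed=1)
        assert len(h) == len(m) == 28
        assert len(test) == 12
        assert rep.n_after_balancing == {"historical": 28, "modern": 28}

    def test_greedy_beats_random_deletion(self):
        """Greedy deletion never yields lower final overlap than deleting
        uniformly random records, over seeded trials on the planted fixture."""
        occH, occM, envH, envM, XH, XM = self._setup(30, 36, planted=6, seed=4)
        h, m, _, _ = balance_by_overlap(occH, occM, envH, envM, seed=1)
        XM_kept = envM.values_at(m.ys, m.xs)
        greedy_ov = ellipsoid_overlap(XH, XM_kept, seed=123)
        rng = np.random.default_rng(7)
        worse = 0
        for _ in range(20):
            idx = rng.choice(len(XM), size=30, replace=False)
            rand_ov = ellipsoid_overlap(XH, XM[idx], seed=123)
            if greedy_ov < rand_ov - 0.02:
                worse += 1
        assert worse == 0


class TestCleanCascade:
    def test_counts_are_monotone_and_balanced(self, small_scenario):
        from nichetransfer.env_prep import derive_bioclim, select_apriori, tailor_study_area

        sp = small_scenario.species_ids[0]
        occ = small_scenario.occurrences.for_species(sp)
        envs = {
            p: select_apriori(derive_bioclim(small_scenario.climates[p]))
            for p in ("historical", "modern")
        }
        envH = tailor_study_area(envs["historical"], occ, 8)
        envM = tailor_study_area(envs["modern"], occ, 8)
        h, m, test, rep = clean_cascade(occ, envH, envM, seed=2)
        for period in ("historical", "modern"):
            assert (
                rep.n_input[period]
                >= rep.n_after_thinning[period]
                >= rep.n_after_outliers[period]
                >= rep.n_after_balancing[period]
            )
        assert len(h) == len(m)
        assert len(test) == rep.n_after_outliers["modern"] - rep.n_after_balancing["modern"]
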