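"""Trait-scape geometry: standardisation, PCA, centroid shifts, correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qpa.errors import DecompositionError, InvalidInputError
from qpa.traitscape import (
    centroids,
    pca,
    shift_metric,
    standardize,
    trait_correlation_matrix,
    traitscape_correspondence,
)

coord = st.floats(min_value=-100, max_value=100, allow_nan=False)
point = st.tuples(coord, coord)


def random_frame(rng, n=20, p=5):
    return pd.DataFrame(rng.normal(size=(n, p)), columns=[f"t{i}" for i in range(p)])


class TestStandardize:
    def test_zero_mean_unit_sample_sd(self, rng):
        z = standardize(random_frame(rng))
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_affine_transformed_column_standardises_identically(self, rng):
        df = random_frame(rng, p=2)
        df2 = df.copy()
        df2["t0"] = 3.5 * df2["t0"] - 7.0
        np.testing.assert_allclose(standardize(df), standardize(df2), atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(InvalidInputError):
            standardize(pd.DataFrame({"a": [1.0]}))

    def test_zero_variance_column_named(self, rng):
        df = random_frame(rng, p=2)
        df["dead"] = 1.0
        with pytest.raises(InvalidInputError, match="dead"):
            standardize(df)


class TestPca:
    def test_perfectly_correlated_traits_pc1_explains_all(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        scape = pca(standardize(df))
        assert scape.var_explained[0] == pytest.approx(100.0, abs=1e-9)

    def test_variance_explained_sums_to_100(self, rng):
        scape = pca(standardize(random_frame(rng)))
        assert scape.var_explained.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(scape.var_explained) <= 1e-9)  # nonincreasing

    def test_scores_match_independent_svd_oracle_up_to_sign(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        z = standardize(random_frame(rng, n=25, p=6))
        scape = pca(z)
        ref = SkPCA().fit_transform(np.asarray(z))
        for j in range(ref.shape[1]):
            ours = scape.scores.iloc[:, j].to_numpy()
            sign = np.sign(np.dot(ours, ref[:, j]))
            np.testing.assert_allclose(ours, sign * ref[:, j], atol=1e-8)

    def test_row_permutation_permutes_scores(self, rng):
        z = standardize(random_frame(rng))
        perm = rng.permutation(len(z))
        a = pca(z)
        b = pca(z.iloc[perm])
        np.testing.assert_allclose(
            a.scores.to_numpy()[perm], b.scores.to_numpy(), atol=1e-9
        )

    def test_var_explained_invariant_under_orthogonal_rotation(self, rng):
        z = standardize(random_frame(rng, n=30, p=4))
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        rotated = pd.DataFrame(np.asarray(z) @ q, columns=z.columns)
        np.testing.assert_allclose(
            pca(z).var_explained, pca(rotated).var_explained, atol=1e-8
        )

    def test_zero_rank_input_rejected(self):
        with pytest.raises(DecompositionError):
            pca(pd.DataFrame(np.zeros((5, 3))))

    def test_components_orthonormal(self, rng):
        scape = pca(standardize(random_frame(rng)))
        v = scape.loadings.to_numpy()
        np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-9)


class TestCentroidsAndShift:
    def test_centroids_hand_computed(self, rng):
        z = standardize(random_frame(rng, n=4, p=3))
        scape = pca(z)
        groups = ["g1", "g1", "g2", "g2"]
        cents = centroids(scape, groups)
        s = scape.scores
        assert cents["g1"][0] == pytest.approx(s.iloc[:2, 0].mean())
        assert cents["g2"][1] == pytest.approx(s.iloc[2:, 1].mean())

    def test_single_member_group_is_its_own_score(self, rng):
        scape = pca(standardize(random_frame(rng, n=5)))
        cents = centroids(scape, ["a", "b", "b", "b", "b"])
        assert cents["a"] == (
            pytest.approx(scape.scores.iloc[0, 0]),
            pytest.approx(scape.scores.iloc[0, 1]),
        )

    def test_unit_diagonal_shift(self):
        m = shift_metric((0.0, 0.0), (1.0, 1.0))
        assert m.distance == pytest.approx(math.sqrt(2))
        assert m.direction_deg == pytest.approx(45.0)

    def test_3_4_5_shift(self):
        m = shift_metric((0.0, 0.0), (3.0, 4.0))
        assert m.distance == pytest.approx(5.0)
        assert m.direction_deg == pytest.approx(53.13, abs=0.01)

    def test_identical_points_undefined_direction(self):
        m = shift_metric((1.0, 2.0), (1.0, 2.0))
        assert m.distance == 0.0
        assert m.direction_deg is None

    def test_quadrant_resolution(self):
        assert shift_metric((0, 0), (-1.0, -1.0)).direction_deg == pytest.approx(-135.0)
        assert shift_metric((0, 0), (-1.0, 0.0)).direction_deg == pytest.approx(180.0)

    @given(a=point, b=point, c=point)
    def test_distance_is_a_metric(self, a, b, c):
        dab = shift_metric(a, b).distance
        dba = shift_metric(b, a).distance
        assert dab >= 0
        assert dab == pytest.approx(dba, rel=1e-12, abs=1e-12)
        assert dab <= shift_metric(a, c).distance + shift_metric(c, b).distance + 1e-9


class TestCorrespondence:
    def _scape_pair(self, rng, transform):
        z = standardize(random_frame(rng, n=18, p=4))
        scape_a = pca(z)
        groups = [f"g{i % 6}" for i in range(18)]
        scores_b = scape_a.scores.copy()
        scores_b.iloc[:, :2] = transform(scores_b.iloc[:, :2].to_numpy())
        scape_b = type(scape_a)(
            scores=scores_b, loadings=scape_a.loadings, var_explained=scape_a.var_explained
        )
        return scape_a, scape_b, groups

    def test_rigid_rotation_gives_r2_1_slope_1(self, rng):
        th = 0.7
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        a, b, groups = self._scape_pair(rng, lambda s: s @ rot.T)
        res = traitscape_correspondence(a, b, groups, groups)
        assert res["r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert res["slope"] == pytest.approx(1.0, rel=1e-9)

    def test_uniform_scaling_gives_r2_1_slope_2(self, rng):
        a, b, groups = self._scape_pair(rng, lambda s: 2.0 * s)
        res = traitscape_correspondence(a, b, groups, groups)
        assert res["r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert res["slope"] == pytest.approx(2.0, rel=1e-9)

    def test_matches_closed_form_regression_oracle(self, rng):
        z1 = standardize(random_frame(rng, n=12, p=3))
        z2 = standardize(random_frame(rng, n=12, p=3))
        groups = [f"g{i % 4}" for i in range(12)]
        res = traitscape_correspondence(pca(z1), pca(z2), groups, groups)
        ca = centroids(pca(z1), groups)
        cb = centroids(pca(z2), groups)
        names = sorted(ca)
        da, db = [], []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                da.append(math.dist(ca[names[i]], ca[names[j]]))
                db.append(math.dist(cb[names[i]], cb[names[j]]))
        da, db = np.array(da), np.array(db)
        slope = ((da - da.mean()) * (db - db.mean())).sum() / ((da - da.mean()) ** 2).sum()
        r2 = (
            ((da - da.mean()) * (db - db.mean())).sum() ** 2
            / (((da - da.mean()) ** 2).sum() * ((db - db.mean()) ** 2).sum())
        )
        assert res["slope"] == pytest.approx(slope, rel=1e-9)
        assert res["r_squared"] == pytest.approx(r2, rel=1e-9)

    def test_too_few_groups_rejected(self, rng):
        z = standardize(random_frame(rng, n=8, p=3))
        scape = pca(z)
        groups = ["a", "a", "a", "a", "b", "b", "b", "b"]
        with pytest.raises(InvalidInputError):
            traitscape_correspondence(scape, scape, groups, groups)


class TestCorrelationMatrix:
    def test_self_correlation_shown(self, rng):
        df = random_frame(rng, p=3)
        cm = trait_correlation_matrix(df)
        assert cm.r.loc["t0", "t0"] == 1.0
        assert bool(cm.shown.loc["t0", "t0"])

    def test_anticorrelated_pair(self, rng):
        x = rng.normal(size=30)
        cm = trait_correlation_matrix(pd.DataFrame({"a": x, "b": -x}))
        assert cm.r.loc["a", "b"] == pytest.approx(-1.0)
        assert bool(cm.shown.loc["a", "b"])

    def test_constant_column_masked_not_shown(self, rng):
        df = random_frame(rng, p=2)
        df["flat"] = 5.0
        cm = trait_correlation_matrix(pd.DataFrame(df))
        assert np.isnan(cm.r.loc["flat", "t0"])
        assert not bool(cm.shown.loc["flat", "t0"])

    def test_type_i_shown_fraction_near_alpha(self, rng):
        # independent noise: off-diagonal shown fraction should be ~5%
        shown, total = 0, 0
        for _ in range(150):
            cm = trait_correlation_matrix(random_frame(rng, n=20, p=5), alpha=0.05)
            off = ~np.eye(5, dtype=bool)
            shown += int(cm.shown.to_numpy()[off].sum()) // 2
            total += 10
        assert 0.02 <= shown / total <= 0.08
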