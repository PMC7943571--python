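"""GPA, mirroring, imputation, trait-table assembly, and sex assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from skelevol.morphodata import (
    LandmarkConfiguration,
    SpecimenRecord,
    assign_sex_lda,
    build_trait_table,
    centroid_size,
    gpa_align,
    impute_limb_lengths,
    mirror_to_left,
    procrustes_distance,
    reflect_axis,
)
from skelevol.synthdata import default_template


def _config(coords, sid="s1", structure="pelvic", side="left"):
    return LandmarkConfiguration(
        specimen_id=sid, structure=structure, side=side, coords=coords
    )


def _rotation_z(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


class TestGpa:
    def test_identical_up_to_similarity_transform(self, rng):
        base = default_template(8)
        moved = base @ _rotation_z(np.deg2rad(37)).T + np.array([5.0, -2.0, 9.0])
        res = gpa_align([_config(base, "a"), _config(moved, "b")])
        d = procrustes_distance(res.aligned[0], res.aligned[1], align=False)
        assert d < 1e-8

    def test_unit_square_centroid_size(self):
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        assert centroid_size(square) == pytest.approx(np.sqrt(2.0))

    def test_mean_shape_matches_pairwise_opa_oracle(self, rng):
        # 20 specimens = known mean + isotropic noise; the GPA mean must
        # agree with brute-force ordinary-Procrustes superimposition of
        # each specimen onto the known mean
        template = default_template(10)
        template = template / centroid_size(template)
        noise = 0.01
        configs = []
        for i in range(20):
            c = template + rng.standard_normal(template.shape) * noise
            c = c @ _rotation_z(rng.uniform(0, 2 * np.pi)).T + rng.uniform(-3, 3, 3)
            configs.append(_config(c, f"s{i}"))
        res = gpa_align(configs)
        # oracle: align each raw specimen to the template by OPA, average
        from skelevol.morphodata import _center_scale, _optimal_rotation

        aligned = []
        for c in configs:
            s, _ = _center_scale(c.coords)
            aligned.append(s @ _optimal_rotation(s, template))
        oracle_mean = np.mean(aligned, axis=0)
        oracle_mean /= centroid_size(oracle_mean)
        assert procrustes_distance(res.mean_shape, oracle_mean) < 5 * noise

    def test_invariant_to_input_similarity_transform(self, rng):
        template = default_template(9)
        configs = [
            _config(template + rng.standard_normal(template.shape) * 0.2, f"s{i}")
            for i in range(6)
        ]
        res1 = gpa_align(configs)
        R = _rotation_z(1.1)
        moved = [
            _config(c.coords @ R.T * 3.7 + np.array([1.0, 2.0, 3.0]), c.specimen_id)
            for c in configs
        ]
        res2 = gpa_align(moved)
        for a, b in zip(res1.aligned, res2.aligned):
            assert procrustes_distance(a, b) < 1e-8

    def test_residual_sum_monotone_nonincreasing(self, rng):
        template = default_template(12)
        configs = [
            _config(template + rng.standard_normal(template.shape) * 1.0, f"s{i}")
            for i in range(15)
        ]
        res = gpa_align(configs)
        ss = np.array(res.ss_history)
        assert (np.diff(ss) <= 1e-10).all()

    def test_degenerate_configuration_names_specimen(self):
        with pytest.raises(ValueError, match="bad_specimen"):
            _config(np.ones((5, 3)), sid="bad_specimen")

    def test_needs_two_configs(self):
        with pytest.raises(ValueError, match="at least 2"):
            gpa_align([_config(default_template(5))])


class TestMirroring:
    def test_reflection_is_involution(self, rng):
        coords = rng.standard_normal((18, 3))
        assert np.array_equal(reflect_axis(reflect_axis(coords, "y"), "y"), coords)

    def test_mirrored_matches_true_left(self, rng):
        left = default_template(18)
        right = _config(reflect_axis(left, "x"), side="right")
        mirrored = mirror_to_left(right, axis="x")
        assert mirrored.side.value == "left"
        assert procrustes_distance(mirrored.coords, left) < 1e-8
        assert mirrored.centroid_size == pytest.approx(
            right.centroid_size, rel=1e-12
        )

    def test_left_input_rejected(self):
        with pytest.raises(ValueError, match="already left"):
            mirror_to_left(_config(default_template(18), side="left"))

    def test_mirrored_specimens_not_outliers_in_gpa(self, rng):
        template = default_template(18)
        noise = 0.02 * centroid_size(template)
        configs = []
        for i in range(100):
            c = template + rng.standard_normal(template.shape) * noise / np.sqrt(54)
            c = c @ _rotation_z(rng.uniform(0, 2 * np.pi)).T
            if i < 19:  # "damaged-left" specimens digitized on the right
                c = reflect_axis(c, "x")
                configs.append(
                    mirror_to_left(_config(c, f"s{i}", side="right"), axis="x")
                )
            else:
                configs.append(_config(c, f"s{i}"))
        res = gpa_align(configs)
        d = np.array(
            [procrustes_distance(a, res.mean_shape, align=False) for a in res.aligned]
        )
        lim = d.mean() + 3 * d.std()
        assert (d[:19] < lim).all()


class TestImputation:
    def test_complete_table_returned_unchanged(self, rng):
        X = rng.uniform(1, 10, (20, 5))
        out, conv = impute_limb_lengths(X)
        assert out is X or np.array_equal(np.asarray(out), X)
        assert conv

    def test_rank_one_exact_recovery(self, rng):
        species = rng.uniform(1, 4, (40, 1))
        element = rng.uniform(0.5, 3, (1, 15))
        X = species @ element
        mask = rng.random(X.shape) < 0.05
        Xm = X.copy()
        Xm[mask] = np.nan
        out, conv = impute_limb_lengths(Xm, n_components=1, tol=1e-12)
        assert conv
        rel = np.abs(out[mask] - X[mask]) / X[mask]
        assert rel.max() < 1e-6

    def test_beats_column_mean_on_correlated_lengths(self, rng):
        # two-factor model with study-scale missingness (~0.45%)
        n, p = 300, 15
        F = rng.standard_normal((n, 2))
        L = rng.standard_normal((2, p))
        X = np.exp(0.5 * (F @ L) + rng.standard_normal((n, p)) * 0.1 + 2)
        mask = rng.random(X.shape) < 0.0045
        Xm = X.copy()
        Xm[mask] = np.nan
        out, _ = impute_limb_lengths(Xm, n_components=2)
        rmse = np.sqrt(np.mean((out[mask] - X[mask]) ** 2))
        col_mean = np.nanmean(Xm, axis=0)
        naive = np.take(col_mean, np.where(mask)[1])
        rmse_naive = np.sqrt(np.mean((naive - X[mask]) ** 2))
        assert rmse < rmse_naive

    def test_observed_cells_bit_identical(self, rng):
        X = rng.uniform(1, 10, (30, 8))
        mask = rng.random(X.shape) < 0.1
        Xm = X.copy()
        Xm[mask] = np.nan
        out, _ = impute_limb_lengths(Xm, n_components=2)
        assert np.array_equal(out[~mask], X[~mask])

    def test_excess_missingness_rejected(self, rng):
        X = rng.uniform(1, 10, (10, 4))
        X[np.unravel_index(np.arange(22), X.shape)] = np.nan
        with pytest.raises(ValueError, match="50%"):
            impute_limb_lengths(X)


def _make_specimens(rng, n_species=3, n_spec=2, sex="male"):
    template = default_template(18)
    specimens, pec_cfgs, pel_cfgs = [], [], []
    for s in range(n_species):
        dev = rng.standard_normal(template.shape) * 0.3
        for i in range(n_spec):
            sid = f"sp{s}_i{i}"
            pec = LandmarkConfiguration(sid, "pectoral", "left", template + dev)
            pel = LandmarkConfiguration(
                sid, "pelvic", "left", (template + dev) * (1 + 0.1 * s)
            )
            pec_cfgs.append(pec)
            pel_cfgs.append(pel)
            specimens.append(
                SpecimenRecord(
                    specimen_id=sid,
                    species_id=f"sp{s}",
                    group="GreaterAntilles",
                    sex=sex,
                    limb_lengths={
                        e: float(v)
                        for e, v in zip(
                            specimens_vocab(), rng.uniform(1, 30, 15)
                        )
                    },
                    pectoral=pec,
                    pelvic=pel,
                )
            )
    return specimens, pec_cfgs, pel_cfgs


def specimens_vocab():
    from skelevol.morphodata import LIMB_ELEMENTS

    return LIMB_ELEMENTS


class TestTraitTable:
    def test_identical_specimens_give_their_values(self, rng):
        template = default_template(18)
        specimens, pec, pel = [], [], []
        lengths = dict(zip(specimens_vocab(), rng.uniform(5, 20, 15)))
        for i in range(2):
            sid = f"a_i{i}"
            p1 = LandmarkConfiguration(sid, "pectoral", "left", template)
            p2 = LandmarkConfiguration(sid, "pelvic", "left", template * 2)
            pec.append(p1)
            pel.append(p2)
            specimens.append(
                SpecimenRecord(sid, "a", "GreaterAntilles", sex="male",
                               limb_lengths=dict(lengths), pectoral=p1, pelvic=p2)
            )
        gp = gpa_align(pec)
        gl = gpa_align(pel)
        tt = build_trait_table(specimens, gp, gl, standardize=False)
        assert tt.values.shape == (1, 124)
        row = tt.values.iloc[0]
        cs = gl.centroid_sizes[0]
        assert row["centroid_size"] == pytest.approx(cs)
        assert row["humerus"] == pytest.approx(lengths["humerus"] / cs)
        expected_pec = gp.aligned[0].ravel()
        assert np.allclose(row[[c for c in tt.values.columns
                                if c.startswith("pec_")]].to_numpy(), expected_pec)

    def test_standardized_columns(self, rng):
        specimens, pec, pel = _make_specimens(rng, n_species=5)
        tt = build_trait_table(specimens, gpa_align(pec), gpa_align(pel),
                               standardize=True)
        v = tt.values
        assert np.abs(v.mean(axis=0)).max() < 1e-10
        assert np.abs(v.std(axis=0, ddof=1) - 1).max() < 1e-10
        # idempotence and total-variance identity
        again = tt.standardize()
        assert np.allclose(again.values, v, atol=1e-10)
        assert v.var(axis=0, ddof=1).sum() == pytest.approx(tt.n_traits)

    def test_block_structure_counts(self, rng):
        specimens, pec, pel = _make_specimens(rng, n_species=4)
        tt = build_trait_table(specimens, gpa_align(pec), gpa_align(pel),
                               standardize=False)
        counts = pd.Series(tt.block_of).value_counts()
        assert tt.n_traits == 124
        assert counts["pectoral_shape"] == 54
        assert counts["pelvic_shape"] == 54
        assert counts["forelimb"] == 7
        assert counts["hindlimb"] == 8
        assert counts["size"] == 1

    def test_females_and_girdle_less_specimens_excluded(self, rng):
        specimens, pec, pel = _make_specimens(rng, n_species=3)
        specimens[0].sex = "female"
        specimens[1].sex = "female"  # species sp0 has no usable males
        with pytest.warns(UserWarning, match="sp0"):
            tt = build_trait_table(specimens, gpa_align(pec), gpa_align(pel),
                                   standardize=False)
        assert "sp0" not in tt.species


class TestSexLda:
    def test_well_separated_classes(self, rng):
        n = 40
        X = np.vstack([
            rng.standard_normal((n, 6)),
            rng.standard_normal((n, 6)) + np.array([10, 0, 0, 0, 0, 0]),
        ])
        sex = pd.Series(["male"] * n + ["female"] * n)
        sex_obs = sex.copy()
        sex_obs.iloc[::5] = "unknown"
        res = assign_sex_lda(pd.DataFrame(X), sex_obs, seed=0)
        assert res.validation_accuracy == 1.0
        unknown = sex_obs == "unknown"
        assert (res.posteriors[unknown] >= 0.8).all()
        assert (res.calls[unknown] == sex[unknown]).all()

    def test_accuracy_near_bayes_rate(self, rng):
        # univariate equal-variance mixture with Bayes error 20%:
        # means ±delta, delta = sigma * z_{0.80}
        delta = norm.ppf(0.80)
        n = 500
        X = np.concatenate([
            rng.standard_normal(n) - delta,
            rng.standard_normal(n) + delta,
        ])[:, None]
        sex = pd.Series(["male"] * n + ["female"] * n)
        res = assign_sex_lda(pd.DataFrame(X), sex, reduce_dims=False, seed=2)
        assert abs(res.validation_accuracy - 0.80) < 0.05

    def test_threshold_boundaries(self, rng):
        n = 20
        X = np.vstack([
            rng.standard_normal((n, 3)),
            rng.standard_normal((n, 3)) + 8,
        ])
        sex = pd.Series(["male"] * n + ["female"] * n)
        sex.iloc[:5] = "unknown"
        hi = assign_sex_lda(pd.DataFrame(X), sex, posterior_threshold=1.0, seed=0)
        assert (hi.calls[sex == "unknown"] == "unassigned").all()
        lo = assign_sex_lda(pd.DataFrame(X), sex, posterior_threshold=1e-12, seed=0)
        assert (lo.calls[sex == "unknown"] != "unassigned").all()

    def test_singular_covariance_requires_reduction(self, rng):
        X = rng.standard_normal((10, 54))
        sex = pd.Series(["male"] * 5 + ["female"] * 5)
        with pytest.raises(ValueError, match="reduce_dims"):
            assign_sex_lda(pd.DataFrame(X), sex, reduce_dims=False, seed=0)
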