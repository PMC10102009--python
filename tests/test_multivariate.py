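import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cartiq import multivariate as mv
from cartiq.image_io import METRIC_COLUMNS


def make_table(n_per_group=6, groups=("control", "DMM"), seed=0, time_points=(1,)):
    rng = np.random.default_rng(seed)
    rows = []
    fid = 0
    for tp in time_points:
        for g in groups:
            for _ in range(n_per_group):
                rows.append(
                    {
                        "specimen": f"m{fid % 4}",
                        "group": g,
                        "time_point": tp,
                        "zone": "superficial",
                        "field_id": fid,
                        "variance": rng.uniform(0.2, 0.4),
                        "xlink_density": rng.uniform(1.0, 2.0),
                        "xlink_llif": rng.uniform(0.4, 0.6),
                        "redox_ratio": rng.uniform(0.3, 0.5),
                        "nadh_llif": rng.uniform(0.4, 0.6),
                        "beta": rng.uniform(1.5, 2.5),
                    }
                )
                fid += 1
    return pd.DataFrame(rows)


class TestNormalizeToControl:
    def test_control_means_become_one(self):
        table = make_table(seed=1)
        out = mv.normalize_to_control(table, {"group": "control"})
        ctrl = out[out.group == "control"]
        for m in METRIC_COLUMNS:
            assert ctrl[m].mean() == pytest.approx(1.0)

    def test_simple_ratio(self):
        table = make_table(n_per_group=2, seed=2)
        table.loc[table.group == "control", "variance"] = 0.4
        table.loc[table.group == "DMM", "variance"] = 0.8
        out = mv.normalize_to_control(table, {"group": "control"})
        assert np.allclose(out.loc[out.group == "DMM", "variance"], 2.0)

    def test_missing_control_stratum_rejected(self):
        table = make_table(time_points=(1, 2))
        table = table[~((table.group == "control") & (table.time_point == 2))]
        with pytest.raises(ValueError, match="stratum"):
            mv.normalize_to_control(table, {"group": "control"}, by=("time_point",))

    def test_no_control_rows_rejected(self):
        with pytest.raises(ValueError, match="no control rows"):
            mv.normalize_to_control(make_table(), {"group": "sham"})

    def test_stratified_means(self):
        table = make_table(time_points=(1, 2), seed=3)
        out = mv.normalize_to_control(table, {"group": "control"}, by=("time_point",))
        for tp in (1, 2):
            sel = (out.group == "control") & (out.time_point == tp)
            assert out.loc[sel, "beta"].mean() == pytest.approx(1.0)


class TestCollinearityScreen:
    def test_duplicated_column_flagged(self):
        table = make_table(seed=4)
        table["beta"] = table["variance"]
        r, flagged = mv.collinearity_screen(table)
        assert r.loc["variance", "beta"] == pytest.approx(1.0)
        assert ("variance", "beta") in flagged

    def test_independent_columns_uncorrelated(self):
        rng = np.random.default_rng(5)
        table = make_table(n_per_group=250, seed=5)
        for m in METRIC_COLUMNS:
            table[m] = rng.normal(size=len(table))
        r, flagged = mv.collinearity_screen(table)
        off = r.to_numpy()[~np.eye(len(METRIC_COLUMNS), dtype=bool)]
        assert np.all(np.abs(off) < 0.2)
        assert not flagged

    def test_matrix_symmetric_unit_diagonal(self):
        r, _ = mv.collinearity_screen(make_table(seed=6))
        arr = r.to_numpy()
        np.testing.assert_allclose(arr, arr.T)
        np.testing.assert_allclose(np.diag(arr), 1.0)

    def test_constant_column_flagged_nan(self):
        table = make_table(seed=7)
        table["beta"] = 2.0
        r, flagged = mv.collinearity_screen(table)
        assert np.isnan(r.loc["beta", "variance"])
        assert any("beta" in pair for pair in flagged)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="3 rows"):
            mv.collinearity_screen(make_table(n_per_group=1, groups=("a",)))


class TestLda:
    def test_perfect_separation(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 1, (100, 6)), rng.normal(10, 1, (100, 6))])
        y = np.array(["a"] * 100 + ["b"] * 100)
        rep = mv.lda_classify(X, y)
        assert rep.oca == 100.0 and rep.cvca == 100.0

    def test_null_accuracy_near_chance(self):
        rng = np.random.default_rng(9)
        n = 200
        X = rng.normal(size=(n, 4))
        y = np.array(["a", "b"] * (n // 2))
        rep = mv.lda_classify(X, y)
        sigma = 100 * np.sqrt(0.25 / n)
        assert abs(rep.cvca - 50.0) <= 3 * sigma + 1e-9

    def test_cross_validation_not_optimistic(self):
        rng = np.random.default_rng(10)
        wins = 0
        n_sims = 50
        for _ in range(n_sims):
            X = rng.normal(size=(30, 3))
            X[15:] += 0.5
            y = np.array(["a"] * 15 + ["b"] * 15)
            rep = mv.lda_classify(X, y)
            wins += rep.cvca <= rep.oca
        assert wins >= 0.9 * n_sims

    def test_decisions_invariant_to_feature_rescaling(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 3))
        X[30:, 0] += 1.0
        y = np.array(["a"] * 30 + ["b"] * 30)
        base = mv.fit_lda(X, y).predict(X)
        Xs = X.copy()
        Xs[:, 1] = Xs[:, 1] * 1000.0 + 5.0
        scaled = mv.fit_lda(Xs, y).predict(Xs)
        np.testing.assert_array_equal(base, scaled)

    def test_singular_covariance_ridged_and_flagged(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 3))
        X[:, 2] = X[:, 1]  # exactly collinear features
        y = np.array(["a"] * 20 + ["b"] * 20)
        model = mv.fit_lda(X, y)
        assert model.ridged
        rep = mv.lda_classify(X, y)
        assert "ridged" in " ".join(rep.flags)

    def test_small_class_rejected(self):
        X = np.random.default_rng(13).normal(size=(8, 6))
        y = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError, match="rows"):
            mv.fit_lda(X, y)


def make_reference(seed=0, n=200):
    rng = np.random.default_rng(seed)
    frames = []
    for cls, mu in (("glycolysis", (0.5, 0.1, -0.2)), ("uncoupling", (-0.4, 0.3, 0.6))):
        frames.append(
            pd.DataFrame(
                {
                    "class": cls,
                    "d_redox_ratio": rng.normal(mu[0], 0.1, n),
                    "d_nadh_llif": rng.normal(mu[1], 0.1, n),
                    "d_beta": rng.normal(mu[2], 0.1, n),
                }
            )
        )
    return mv.PerturbationReference(pd.concat(frames, ignore_index=True))


class TestMetabolicDelta:
    def test_control_deltas_average_zero(self):
        table = make_table(seed=14)
        out = mv.metabolic_delta(table, {"group": "control"})
        ctrl = out[out.group == "control"]
        for m in mv.METABOLIC_COLUMNS:
            assert ctrl[f"d_{m}"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_sample_at_centroid_has_zero_distance(self):
        ref = make_reference()
        mu, _ = ref.class_stats()["glycolysis"]
        cls, d = ref.nearest_class(mu)
        assert cls == "glycolysis"
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_ellipsoid_coverage_near_75pct(self):
        ref = make_reference(seed=15, n=500)
        mu, cov = ref.class_stats()["uncoupling"]
        rng = np.random.default_rng(16)
        draws = rng.multivariate_normal(mu, cov, 5000)
        inv = np.linalg.inv(cov)
        d2 = np.einsum("ij,jk,ik->i", draws - mu, inv, draws - mu)
        frac = (d2 <= ref.ellipsoid_radius_sq()).mean()
        assert frac == pytest.approx(0.75, abs=0.03)

    def test_small_class_skipped_with_flag(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame(
            {
                "class": ["tiny"] * 3 + ["big"] * 10,
                "d_redox_ratio": rng.normal(size=13),
                "d_nadh_llif": rng.normal(size=13),
                "d_beta": rng.normal(size=13),
            }
        )
        ref = mv.PerturbationReference(df)
        assert "tiny" not in ref.class_stats()
        assert any("tiny" in f for f in ref.flags)

    def test_nearest_class_assigned_per_row(self):
        table = make_table(seed=18)
        ref = make_reference()
        out = mv.metabolic_delta(table, {"group": "control"}, reference=ref)
        assert set(out["nearest_class"]) <= {"glycolysis", "uncoupling"}
        assert np.isfinite(out["mahalanobis"]).all()
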