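import numpy as np
import pandas as pd
import pytest

from turbomap import (ImputeParams, IntensityMatrix, RegressSpec,
                      SampleDesign, bait_normalize, bootstrap_regress,
                      filter_by_missingness, impute_missing,
                      median_polish_normalize)


def _matrix(vals, mask=None):
    vals = np.asarray(vals, dtype=float)
    if mask is None:
        mask = np.ones_like(vals, dtype=bool)
    return IntensityMatrix([f"P{i}" for i in range(vals.shape[0])],
                           [f"s{j}" for j in range(vals.shape[1])],
                           vals, np.asarray(mask, bool))


class TestFilter:
    def test_exactly_half_missing_is_dropped(self):
        mask = np.ones((2, 4), bool)
        mask[0, :2] = False  # P0 missing in exactly 50%
        m = filter_by_missingness(_matrix(np.full((2, 4), 20.0), mask))
        assert m.protein_ids == ["P1"]

    def test_fully_observed_kept_in_both_modes(self, two_group_design):
        m = _matrix(np.full((1, 4), 20.0))
        assert filter_by_missingness(m).n_proteins == 1
        assert filter_by_missingness(m, two_group_design,
                                     mode="groupwise").n_proteins == 1

    def test_groupwise_keeps_one_group_fully_observed(self):
        d = SampleDesign(pd.DataFrame(
            {"group": ["A"] * 4 + ["B"] * 4},
            index=pd.Index([f"s{j}" for j in range(8)], name="sample_id")))
        mask = np.ones((1, 8), bool)
        mask[0, 4:] = False  # observed 4/4 in A, 0/4 in B
        m = _matrix(np.full((1, 8), 20.0), mask)
        assert filter_by_missingness(m, d, mode="groupwise").n_proteins == 1
        with pytest.raises(ValueError):  # dropped globally -> empty result
            filter_by_missingness(m, d, mode="global")

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        mask = rng.random((50, 6)) > 0.3
        mask[:, 0] = True
        m = _matrix(rng.normal(20, 1, (50, 6)), mask)
        once = filter_by_missingness(m)
        twice = filter_by_missingness(once)
        assert once.protein_ids == twice.protein_ids


class TestImpute:
    def test_complete_matrix_returned_unchanged(self, tiny_matrix):
        out = impute_missing(tiny_matrix, ImputeParams(seed=1))
        np.testing.assert_array_equal(out.values, tiny_matrix.values)

    def test_downshift_and_width_recovered(self):
        """Monte Carlo: imputed cells follow Normal(mu - 1.8 sd, (0.3 sd)^2)."""
        rng = np.random.default_rng(42)
        n_obs, n_miss = 1000, 100_000
        vals = np.zeros((n_obs + n_miss, 1))
        vals[:n_obs, 0] = rng.normal(20, 1, n_obs)
        mask = np.zeros_like(vals, bool)
        mask[:n_obs] = True
        m = IntensityMatrix([f"P{i}" for i in range(len(vals))], ["s1"],
                            vals, mask)
        out = impute_missing(m, ImputeParams(seed=7))
        obs = vals[:n_obs, 0]
        imput = out.values[n_obs:, 0]
        shift = (imput.mean() - obs.mean()) / obs.std(ddof=1)
        width = imput.std(ddof=1) / obs.std(ddof=1)
        assert shift == pytest.approx(-1.8, abs=0.018)
        assert width == pytest.approx(0.3, abs=0.003)

    def test_observed_cells_untouched_and_seeded(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(20, 1, (30, 4))
        mask = rng.random((30, 4)) > 0.3
        m = _matrix(vals, mask)
        a = impute_missing(m, ImputeParams(seed=5))
        b = impute_missing(m, ImputeParams(seed=5))
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.values[mask], vals[mask])
        assert a.mask.all()

    def test_too_few_observed_errors_with_sample_name(self):
        mask = np.zeros((5, 1), bool)
        mask[:2] = True
        m = _matrix(np.full((5, 1), 20.0), mask)
        with pytest.raises(ValueError, match="s0"):
            impute_missing(m)


class TestBaitNormalize:
    def test_constant_bait_rows_leave_matrix_unchanged(self):
        vals = np.vstack([np.full(4, 25.0), np.full(4, 24.0),
                          np.arange(4, dtype=float) + 20])
        m = _matrix(vals)
        out = bait_normalize(m, ["P0", "P1"])
        np.testing.assert_allclose(out.values, vals)

    def test_sample_shifted_by_bait_offset(self):
        vals = np.full((3, 2), 20.0)
        vals[:, 1] += 1.0  # sample s1 one unit high, including baits
        m = _matrix(vals)
        out = bait_normalize(m, ["P0"])
        # the +1 offset of s1 is removed entirely (bait carried the shift)
        np.testing.assert_allclose(out.values[:, 1], out.values[:, 0])
        # scale preserved: grand bait mean unchanged
        assert out.values[0].mean() == pytest.approx(20.5)
        # bait-mean SD across samples is 0 afterwards
        assert out.values[0].std() < 1e-12

    def test_missing_bait_observation_errors(self):
        mask = np.ones((2, 2), bool)
        mask[0, 1] = False
        m = _matrix(np.full((2, 2), 20.0), mask)
        with pytest.raises(ValueError, match="unobserved"):
            bait_normalize(m, ["P0"])


def _two_batch_design(n_per_batch=3, gis=True):
    rows, idx = [], []
    for b in ("b1", "b2"):
        for i in range(n_per_batch):
            idx.append(f"{b}_s{i}")
            rows.append({"group": "CTL", "batch": b, "is_gis": False})
        if gis:
            idx.append(f"{b}_gis")
            rows.append({"group": "GIS", "batch": b, "is_gis": True})
    return SampleDesign(pd.DataFrame(rows, index=pd.Index(idx, name="sample_id")))


class TestMedianPolish:
    def test_batch_offset_removed_and_gis_at_zero(self):
        rng = np.random.default_rng(2)
        d = _two_batch_design()
        base = rng.normal(0, 1, size=(200, 1))
        vals = base + rng.normal(0, 0.1, size=(200, 8))
        vals[:, 4:] += 1.0  # batch b2 offset
        vals[:, 3] = base[:, 0] + 0.0   # b1 GIS: noiseless
        vals[:, 7] = base[:, 0] + 1.0   # b2 GIS: noiseless + offset
        m = IntensityMatrix([f"P{i}" for i in range(200)], d.sample_ids,
                            vals, np.ones_like(vals, bool))
        out = median_polish_normalize(m, d)
        gis_cols = d.table["is_gis"].to_numpy()
        assert abs(np.median(out.values[:, gis_cols])) < 1e-6
        # batch median difference removed
        b1 = out.values[:, :4].mean()
        b2 = out.values[:, 4:].mean()
        assert abs(b1 - b2) < 0.05

    def test_fixed_point_input_unchanged(self):
        d = _two_batch_design(n_per_batch=2)
        # symmetric values already centered: GIS = row center, sample medians 0
        vals = np.array([[0.5, -0.5, 0.0, 0.4, -0.4, 0.0],
                         [-0.5, 0.5, 0.0, -0.4, 0.4, 0.0],
                         [0.2, -0.2, 0.0, 0.1, -0.1, 0.0],
                         [-0.2, 0.2, 0.0, -0.1, 0.1, 0.0]])
        m = IntensityMatrix([f"P{i}" for i in range(4)], d.sample_ids, vals,
                            np.ones_like(vals, bool))
        out = median_polish_normalize(m, d)
        np.testing.assert_allclose(out.values, vals, atol=1e-8)

    def test_no_gis_falls_back_to_batch_median(self, caplog):
        d = _two_batch_design(gis=False)
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, size=(50, 6))
        m = IntensityMatrix([f"P{i}" for i in range(50)], d.sample_ids, vals,
                            np.ones_like(vals, bool))
        with caplog.at_level("WARNING", logger="turbomap"):
            median_polish_normalize(m, d)
        assert any("pseudo-GIS" in r.message for r in caplog.records)


class TestBootstrapRegress:
    def _design(self, n, rng):
        age = rng.uniform(55, 95, n)
        group = np.where(np.arange(n) % 2 == 0, "CTL", "AD")
        return SampleDesign(pd.DataFrame(
            {"group": group, "age": age},
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))), age

    def test_age_slope_removed(self):
        rng = np.random.default_rng(4)
        n = 120
        d, age = self._design(n, rng)
        vals = 0.1 * age[None, :] + rng.normal(0, 0.5, size=(40, n))
        m = IntensityMatrix([f"P{i}" for i in range(40)], d.sample_ids, vals,
                            np.ones_like(vals, bool))
        out = bootstrap_regress(m, d, RegressSpec(covariates=("age",),
                                                  n_boot=200, seed=1))
        for row in out.values:
            slope = np.polyfit(age, row, 1)[0]
            assert abs(slope) < 0.01

    def test_null_covariate_leaves_matrix_nearly_unchanged(self):
        rng = np.random.default_rng(5)
        n = 60
        d, age = self._design(n, rng)
        vals = rng.normal(0, 1, size=(30, n))
        m = IntensityMatrix([f"P{i}" for i in range(30)], d.sample_ids, vals,
                            np.ones_like(vals, bool))
        out = bootstrap_regress(m, d, RegressSpec(covariates=("age",),
                                                  n_boot=200, seed=2))
        se_slope = 1.0 / (age.std() * np.sqrt(n))
        rms = np.sqrt(((out.values - vals) ** 2).mean(axis=1))
        assert (rms < 3 * se_slope * age.std()).all()

    def test_protected_group_difference_preserved(self):
        rng = np.random.default_rng(6)
        n = 80
        d, age = self._design(n, rng)
        g = (d.table["group"] == "AD").to_numpy(float)
        vals = 2.0 * g[None, :] + rng.normal(0, 0.3, size=(20, n))
        m = IntensityMatrix([f"P{i}" for i in range(20)], d.sample_ids, vals,
                            np.ones_like(vals, bool))
        out = bootstrap_regress(m, d, RegressSpec(
            covariates=("age",), protected=("group",), n_boot=100, seed=3))
        diff = out.values[:, g == 1].mean(axis=1) - out.values[:, g == 0].mean(axis=1)
        np.testing.assert_allclose(diff, 2.0, atol=0.3)

    def test_protected_and_removed_must_not_overlap(self):
        with pytest.raises(ValueError, match="removed and protected"):
            RegressSpec(covariates=("age",), protected=("age",))
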