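import io

import numpy as np
import pytest

import biozscreen as bz
from biozscreen.features import attribute_columns
from biozscreen.io import write_feature_table
from biozscreen.predictor import fit_power_law
from biozscreen.synthetic import default_calibration_model, null_cohort


class TestCohortComposition:
    def test_default_counts_match_the_study(self, default_cohort):
        table, truth = default_cohort
        assert len(table) == 256
        assert table["subject_id"].nunique() == 53
        subj = truth.subjects
        assert (subj["sex"] == 0).sum() == 34
        assert (subj["sex"] == 1).sum() == 19
        assert subj["diabetic_true"].sum() == 20
        assert subj["age"].between(19, 76).all()

    def test_feature_schema(self, default_cohort):
        table, _ = default_cohort
        cols = attribute_columns(table)
        assert len(cols) == 20
        assert cols[-4:] == ["age", "weight", "sex", "height"]

    def test_measurement_allocation_hits_total_exactly(self):
        spec = bz.CohortSpec(rng_seed=1)
        table, truth = bz.generate_cohort(spec)
        counts = truth.subjects["n_measurements"]
        assert counts.sum() == spec.total_samples
        assert counts.max() - counts.min() <= 1  # near-even, ~5 per subject

    def test_determinism_byte_identical(self):
        buf1, buf2 = io.StringIO(), io.StringIO()
        write_feature_table(bz.generate_cohort(bz.CohortSpec(rng_seed=5))[0], buf1)
        write_feature_table(bz.generate_cohort(bz.CohortSpec(rng_seed=5))[0], buf2)
        assert buf1.getvalue() == buf2.getvalue()

    def test_different_seed_different_cohort(self):
        t1, _ = bz.generate_cohort(bz.CohortSpec(rng_seed=1))
        t2, _ = bz.generate_cohort(bz.CohortSpec(rng_seed=2))
        assert not np.allclose(t1["f10000_mag"], t2["f10000_mag"])

    def test_infeasible_allocation_rejected(self):
        with pytest.raises(ValueError):
            bz.CohortSpec(total_samples=10)

    def test_label_noise_flips_whole_subjects(self):
        table, truth = bz.generate_cohort(bz.CohortSpec(rng_seed=3, label_noise=0.15))
        subj = truth.subjects
        flipped = subj[subj["label"] != subj["diabetic_true"]]
        assert len(flipped) == round(0.15 * 53)
        # every measurement of a subject carries the same recorded label
        assert (table.groupby("subject_id")["label"].nunique() == 1).all()


class TestSpectraAndSignal:
    def test_noise_free_power_law_recovery(self):
        spec = bz.CohortSpec(rng_seed=2, noise_sd=0.0)
        table, truth = bz.generate_cohort(spec)
        freqs = np.array(spec.frequencies)
        mag_cols = [f"f{int(f)}_mag" for f in freqs]
        first = table.groupby("subject_id").first()
        for sid, row in first.iterrows():
            true = truth.subjects.set_index("subject_id").loc[sid]
            fit = fit_power_law(freqs, row[mag_cols].to_numpy(float))
            assert fit.a == pytest.approx(true["a"], rel=1e-9)
            assert fit.b == pytest.approx(true["b"], rel=1e-9)

    def test_diabetic_class_has_higher_impedance(self, default_cohort):
        table, truth = default_cohort
        merged = table.merge(truth.subjects[["subject_id", "diabetic_true"]], on="subject_id")
        mag_d = merged.loc[merged["diabetic_true"] == 1, "f10000_mag"].mean()
        mag_n = merged.loc[merged["diabetic_true"] == 0, "f10000_mag"].mean()
        assert mag_d > 1.3 * mag_n

    def test_null_cohort_is_at_chance(self):
        """No class effect, no biometric shift: CV accuracy ~ 0.5."""
        from sklearn.model_selection import cross_val_score
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import StandardScaler

        table, _ = bz.generate_cohort(null_cohort(bz.CohortSpec(rng_seed=4)))
        cols = attribute_columns(table)
        X = StandardScaler().fit_transform(table[cols].to_numpy(float))
        y = table["label"].to_numpy(int)
        acc = cross_val_score(LogisticRegression(max_iter=1000), X, y, cv=5).mean()
        assert abs(acc - 0.5) < 0.25  # wide band: repeated measures inflate variance

    def test_separable_cohort_is_learnable(self, default_cohort):
        table, _ = default_cohort
        rep = bz.compare_methods(table, repeats=1, folds=5, base_seed=0)
        assert rep.mean_traditional > 0.9


class TestRawEncoding:
    def test_round_trip_identity(self):
        model = default_calibration_model()
        rng = np.random.default_rng(6)
        s = bz.ImpedanceSpectrum(
            frequencies=model.frequencies,
            magnitude=rng.uniform(50, 400, model.frequencies.size),
            phase=rng.uniform(-0.4, 0.1, model.frequencies.size),
        )
        back = bz.apply_calibration(bz.encode_raw(s, model), model)
        np.testing.assert_allclose(back.magnitude, s.magnitude, rtol=1e-9)
        np.testing.assert_allclose(back.phase, s.phase, atol=1e-9)

    def test_calibration_resistor_encodes_to_calibration_magnitude(self):
        model = default_calibration_model()
        s = bz.ImpedanceSpectrum(
            frequencies=model.frequencies,
            magnitude=np.full(model.frequencies.size, model.calibration_resistance),
            phase=np.zeros(model.frequencies.size),
        )
        raw = bz.encode_raw(s, model)
        from biozscreen.calibration import raw_magnitude

        np.testing.assert_allclose(
            raw_magnitude(raw.rr, raw.ir),
            1.0 / (model.gain_factor * model.calibration_resistance),
            rtol=1e-12,
        )

    def test_doubling_magnitude_halves_raw_magnitude(self):
        model = default_calibration_model()
        n = model.frequencies.size
        s1 = bz.ImpedanceSpectrum(model.frequencies, np.full(n, 100.0), np.zeros(n))
        s2 = bz.ImpedanceSpectrum(model.frequencies, np.full(n, 200.0), np.zeros(n))
        from biozscreen.calibration import raw_magnitude

        r1 = bz.encode_raw(s1, model)
        r2 = bz.encode_raw(s2, model)
        np.testing.assert_allclose(
            raw_magnitude(r2.rr, r2.ir), raw_magnitude(r1.rr, r1.ir) / 2.0, rtol=1e-12
        )


class TestStabilitySeries:
    def test_default_noise_gives_about_two_percent_rsd(self):
        s = bz.stability_series(bz.CohortSpec(rng_seed=9), n_hours=12, per_hour=10)
        rsd = s.groupby("hour")["f10000_mag"].apply(lambda v: 100 * v.std() / v.mean())
        assert 1.0 < rsd.mean() < 3.0

    def test_zero_noise_gives_zero_rsd(self):
        s = bz.stability_series(bz.CohortSpec(rng_seed=9, noise_sd=0.0), n_hours=3, per_hour=5)
        rsd = s.groupby("hour")["f10000_mag"].std()
        assert np.allclose(rsd, 0.0)

    def test_rsd_scales_linearly_with_noise(self):
        """Delta method: RSD of a log-normal ~ sigma for small sigma."""
        rsds = []
        for sd in (0.01, 0.02, 0.04):
            s = bz.stability_series(
                bz.CohortSpec(rng_seed=10, noise_sd=sd), n_hours=20, per_hour=20
            )
            rsds.append(s["f10000_mag"].std() / s["f10000_mag"].mean())
        assert rsds[1] / rsds[0] == pytest.approx(2.0, rel=0.25)
        assert rsds[2] / rsds[1] == pytest.approx(2.0, rel=0.25)
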