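"""Cohort I/O, alignment and leakage-safe scaling."""

import numpy as np
import pandas as pd
import pytest

from tricoat import (CohortSpec, IntegrityError, SchemaError, apply_scaler,
                     fit_scaler, read_cohort, read_plink_raw, simulate_cohort,
                     write_cohort)


@pytest.fixture(scope="module")
def tiny_cohort():
    cohort, labels = simulate_cohort(
        CohortSpec(n_per_class=(5, 6, 3), n_roi=4, n_snp=5,
                   n_informative=(2, 3, 2), seed=2))
    return cohort, labels


class TestRoundTrip:
    def test_write_then_read_is_identity(self, tiny_cohort, tmp_path):
        cohort, _ = tiny_cohort
        write_cohort(cohort, tmp_path)
        back = read_cohort(tmp_path)
        pd.testing.assert_frame_equal(back.imaging, cohort.imaging,
                                      check_names=False, atol=1e-9)
        pd.testing.assert_frame_equal(back.clinical, cohort.clinical,
                                      check_names=False, atol=1e-9)
        assert (back.dosages.to_numpy() == cohort.dosages.to_numpy()).all()
        assert np.allclose(back.mmse.to_numpy(), cohort.mmse.to_numpy())

    def test_alignment_is_subject_intersection(self, tiny_cohort, tmp_path):
        cohort, _ = tiny_cohort
        write_cohort(cohort, tmp_path)
        # drop one subject from clinical only
        cli = pd.read_csv(tmp_path / "clinical.csv")
        cli.iloc[1:].to_csv(tmp_path / "clinical.csv", index=False)
        back = read_cohort(tmp_path)
        assert back.n_subjects == cohort.n_subjects - 1
        assert back.subjects.is_monotonic_increasing
        for tab in (back.dosages, back.clinical, back.mmse):
            assert tab.index.equals(back.subjects)

    def test_empty_intersection_is_fatal(self, tiny_cohort, tmp_path):
        cohort, _ = tiny_cohort
        write_cohort(cohort, tmp_path)
        cli = pd.read_csv(tmp_path / "clinical.csv")
        cli["subject_id"] = "ZZ" + cli["subject_id"]
        cli.to_csv(tmp_path / "clinical.csv", index=False)
        with pytest.raises(IntegrityError, match="no subject"):
            read_cohort(tmp_path)


class TestSchemaValidation:
    def test_missing_column_named_in_error(self, tiny_cohort, tmp_path):
        cohort, _ = tiny_cohort
        write_cohort(cohort, tmp_path)
        cli = pd.read_csv(tmp_path / "clinical.csv").drop(columns=["TRABSCOR"])
        cli.to_csv(tmp_path / "clinical.csv", index=False)
        with pytest.raises(SchemaError, match="TRABSCOR"):
            read_cohort(tmp_path)

    def test_bad_dosage_names_subject_and_snp(self, tiny_cohort, tmp_path):
        cohort, _ = tiny_cohort
        write_cohort(cohort, tmp_path)
        dos = pd.read_csv(tmp_path / "genotype_dosages.csv")
        dos.loc[3, "dosage"] = 3
        dos.to_csv(tmp_path / "genotype_dosages.csv", index=False)
        with pytest.raises(IntegrityError) as exc:
            read_cohort(tmp_path)
        assert str(dos.loc[3, "snp_id"]) in str(exc.value)
        assert str(dos.loc[3, "subject_id"]) in str(exc.value)

    def test_duplicate_row_rejected(self, tiny_cohort, tmp_path):
        cohort, _ = tiny_cohort
        write_cohort(cohort, tmp_path)
        cli = pd.read_csv(tmp_path / "clinical.csv")
        pd.concat([cli, cli.iloc[[0]]]).to_csv(tmp_path / "clinical.csv",
                                               index=False)
        with pytest.raises(IntegrityError, match="duplicate"):
            read_cohort(tmp_path)

    def test_plink_raw_maps_to_dosage_schema(self, tmp_path):
        raw = pd.DataFrame({
            "FID": [1, 2], "IID": ["A", "B"], "PAT": 0, "MAT": 0, "SEX": 1,
            "PHENOTYPE": -9, "rs123_A": [0, 2], "rs456_T": [1, 0]})
        path = tmp_path / "geno.raw"
        raw.to_csv(path, sep=" ", index=False)
        out = read_plink_raw(path)
        assert list(out.columns) == ["subject_id", "snp_id", "dosage"]
        assert set(out["snp_id"]) == {"rs123", "rs456"}
        assert out.set_index(["subject_id", "snp_id"]).loc[("B", "rs123"),
                                                           "dosage"] == 2


class TestScaler:
    def test_train_stats_population_sd(self, tiny_cohort):
        cohort, _ = tiny_cohort
        train = cohort.subjects[:6]
        scaler = fit_scaler(cohort, train)
        col = cohort.clinical.columns[0]
        vals = cohort.clinical.loc[train, col]
        assert np.isclose(scaler.clinical_mean_[col], vals.mean())
        assert np.isclose(scaler.clinical_scale_[col], vals.std(ddof=0))

    def test_train_rows_scale_to_zero_mean_unit_sd(self, tiny_cohort):
        cohort, _ = tiny_cohort
        train = cohort.subjects[:8]
        scaled = apply_scaler(fit_scaler(cohort, train), cohort)
        sub = scaled.clinical.loc[train]
        assert np.abs(sub.mean()).max() < 1e-8
        assert np.abs(sub.std(ddof=0) - 1.0).max() < 1e-8
        sub_img = scaled.imaging.loc[train]
        assert np.abs(sub_img.mean()).max() < 1e-8

    def test_test_rows_not_centred_in_general(self, tiny_cohort):
        """Leakage probe: a scaler fit on fold-train rows does not zero-centre
        the held-out rows."""
        cohort, _ = tiny_cohort
        train = cohort.subjects[:7]
        test = cohort.subjects[7:]
        scaled = apply_scaler(fit_scaler(cohort, train), cohort)
        assert np.abs(scaled.clinical.loc[test].mean()).max() > 1e-6

    def test_apply_then_invert_recovers_values(self, tiny_cohort):
        cohort, _ = tiny_cohort
        scaler = fit_scaler(cohort, cohort.subjects)
        back = scaler.inverse_transform(scaler.transform(cohort))
        assert np.allclose(back.imaging.to_numpy(), cohort.imaging.to_numpy(),
                           rtol=1e-10)
        assert np.allclose(back.clinical.to_numpy(), cohort.clinical.to_numpy(),
                           rtol=1e-10)

    def test_genotype_left_unscaled(self, tiny_cohort):
        cohort, _ = tiny_cohort
        scaled = apply_scaler(fit_scaler(cohort, cohort.subjects), cohort)
        assert (scaled.dosages.to_numpy() == cohort.dosages.to_numpy()).all()
        assert scaled.snps.equals(cohort.snps)

    def test_constant_feature_gets_unit_scale_and_warning(self, tiny_cohort):
        cohort, _ = tiny_cohort
        cohort = cohort.copy()
        col = cohort.clinical.columns[2]
        cohort.clinical[col] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            scaler = fit_scaler(cohort, cohort.subjects)
        assert scaler.clinical_scale_[col] == 1.0

    def test_scaler_is_pure_function_of_training_rows(self, tiny_cohort):
        """Perturbing any non-training row leaves the scaler bit-identical."""
        cohort, _ = tiny_cohort
        train = cohort.subjects[:7]
        a = fit_scaler(cohort, train)
        perturbed = cohort.copy()
        perturbed.clinical.iloc[-1] += 100.0
        perturbed.imaging.iloc[-1] += 50.0
        b = fit_scaler(perturbed, train)
        assert (a.clinical_mean_ == b.clinical_mean_).all()
        assert (a.imaging_mean_ == b.imaging_mean_).all()
        assert (a.clinical_scale_ == b.clinical_scale_).all()

    def test_empty_train_ids_rejected(self, tiny_cohort):
        cohort, _ = tiny_cohort
        with pytest.raises(ValueError, match="empty"):
            fit_scaler(cohort, [])
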