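"""Conversion of an aligned cohort into the dense arrays the models consume."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Cohort


@dataclass
class ModalityArrays:
    """Dense per-modality arrays for a set of subjects, row-aligned.

    imaging : (n, M, 4) float — ROI x trait values.
    dosage : (n, N) float — allele dosages in {0,1,2}.
    snp_attrs : (N, 3) float — odds ratio, rare-allele frequency, intergenic.
    snp_chrom : (N,) int — chromosome index of each SNP.
    clinical : (n, B) float — cognitive scores.
    """

    imaging: np.ndarray
    dosage: np.ndarray
    snp_attrs: np.ndarray
    snp_chrom: np.ndarray
    clinical: np.ndarray
    subject_ids: pd.Index
    roi_names: list[str]
    snp_names: list[str]
    clinical_names: list[str]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def take(self, indices) -> "ModalityArrays":
        indices = np.asarray(indices)
        return ModalityArrays(
            imaging=self.imaging[indices],
            dosage=self.dosage[indices],
            snp_attrs=self.snp_attrs,
            snp_chrom=self.snp_chrom,
            clinical=self.clinical[indices],
            subject_ids=self.subject_ids[indices],
            roi_names=self.roi_names,
            snp_names=self.snp_names,
            clinical_names=self.clinical_names,
        )

    def loc(self, subject_ids) -> "ModalityArrays":
        pos = self.subject_ids.get_indexer(pd.Index(subject_ids))
        if (pos < 0).any():
            raise KeyError("unknown subject id(s) requested")
        return self.take(pos)

    def snp_tokens_input(self) -> np.ndarray:
        """(n, N, 4) per-SNP input: dosage + the three static attributes."""
        n = self.dosage.shape[0]
        attrs = np.broadcast_to(self.snp_attrs, (n, *self.snp_attrs.shape))
        return np.concatenate([self.dosage[:, :, None], attrs], axis=2)

    def flatten(self, modality: str) -> np.ndarray:
        """Flat per-subject feature vector for classical ML baselines.

        Genetics uses dosages only: the SNP static attributes are identical
        across subjects and carry no discriminative signal.
        """
        if modality == "imaging":
            return self.imaging.reshape(self.imaging.shape[0], -1)
        if modality == "genetics":
            return self.dosage
        if modality == "clinical":
            return self.clinical
        if modality == "all":
            return np.concatenate([self.flatten("imaging"),
                                   self.flatten("genetics"),
                                   self.flatten("clinical")], axis=1)
        raise ValueError(f"unknown modality {modality!r}")


def tensorize(cohort: Cohort) -> ModalityArrays:
    """Extract row-aligned dense arrays from an (already scaled) cohort."""
    rois = cohort.roi_names
    n = cohort.n_subjects
    imaging = cohort.imaging.to_numpy(dtype=float).reshape(n, len(rois), 4)
    snps = cohort.snps
    return ModalityArrays(
        imaging=imaging,
        dosage=cohort.dosages.to_numpy(dtype=float),
        snp_attrs=snps[["odds_ratio", "rare_allele_freq", "intergenic"]]
            .to_numpy(dtype=float),
        snp_chrom=snps["chromosome"].to_numpy(dtype=int),
        clinical=cohort.clinical.to_numpy(dtype=float),
        subject_ids=cohort.subjects,
        roi_names=rois,
        snp_names=cohort.snp_names,
        clinical_names=list(cohort.clinical.columns),
    )
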