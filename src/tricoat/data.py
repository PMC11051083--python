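"""Cohort data structures, CSV schemas and leakage-safe feature scaling.

A :class:`Cohort` aligns four per-subject tables on a common, lexicographically
sorted subject index:

* imaging  — 72 cortical ROIs x 4 FreeSurfer-derived traits per subject
  (cortical thickness average/SD, surface area, volume),
* genotype — allele dosages for 70 GWAS-selected SNPs plus per-SNP static
  attributes (chromosome, odds ratio, rare-allele frequency, intergenic flag),
* clinical — 7 cognitive scores,
* mmse     — MMSE at baseline and 6/12/24-month follow-ups.

Imaging and clinical features are z-scored with statistics estimated from a
declared training subset only (:class:`CohortScaler`); genotype dosages and
SNP attributes enter the model unscaled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

IMAGING_TRAITS = ["thickness_avg", "thickness_sd", "surface_area", "volume"]
CLINICAL_SCORES = [
    "LDELTOTAL", "DIGITSCOR", "TRABSCOR",
    "RAVLT_immediate", "RAVLT_learning", "RAVLT_forgetting",
    "RAVLT_perc_forgetting",
]
MMSE_VISITS = [0, 6, 12, 24]
SNP_ATTRS = ["chromosome", "odds_ratio", "rare_allele_freq", "intergenic"]
SUBTYPES = ["slow", "intermediate", "fast"]


class SchemaError(ValueError):
    """A CSV is missing required columns or has malformed values."""


class IntegrityError(ValueError):
    """Table contents violate a cohort invariant (duplicates, bad dosage...)."""


@dataclass
class Cohort:
    """Aligned multimodal cohort.

    Attributes
    ----------
    imaging : wide DataFrame, index subject_id, MultiIndex columns (roi, trait).
    dosages : DataFrame, index subject_id, one integer column per SNP.
    snps : DataFrame, index snp_id, columns chromosome/odds_ratio/
        rare_allele_freq/intergenic.
    clinical : DataFrame, index subject_id, one column per cognitive score.
    mmse : DataFrame, index subject_id, integer columns 0/6/12/24 (months);
        missing follow-ups are NaN.
    labels : optional Series of subtype labels covering all subjects.
    """

    imaging: pd.DataFrame
    dosages: pd.DataFrame
    snps: pd.DataFrame
    clinical: pd.DataFrame
    mmse: pd.DataFrame
    labels: pd.Series | None = field(default=None)

    @property
    def subjects(self) -> pd.Index:
        return self.imaging.index

    @property
    def roi_names(self) -> list[str]:
        return list(self.imaging.columns.get_level_values(0).unique())

    @property
    def snp_names(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.imaging)

    def validate(self) -> "Cohort":
        idx = self.imaging.index
        for name, tab in (("dosages", self.dosages), ("clinical", self.clinical),
                          ("mmse", self.mmse)):
            if not tab.index.equals(idx):
                raise IntegrityError(f"{name} subject index is not aligned with imaging")
        if not set(self.dosages.columns) <= set(self.snps.index):
            missing = sorted(set(self.dosages.columns) - set(self.snps.index))
            raise IntegrityError(f"dosage SNPs without static record: {missing}")
        bad = ~self.dosages.isin([0, 1, 2]).to_numpy()
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise IntegrityError(
                f"dosage outside {{0,1,2}} for subject {self.dosages.index[i]!r}, "
                f"snp {self.dosages.columns[j]!r}")
        for name, tab in (("imaging", self.imaging), ("clinical", self.clinical)):
            if tab.isna().to_numpy().any():
                raise IntegrityError(f"NaN values in {name} feature columns")
        if self.mmse[0].isna().any():
            raise IntegrityError("baseline MMSE missing for some subjects")
        if self.labels is not None and not self.labels.index.equals(idx):
            raise IntegrityError("labels do not cover the aligned subjects")
        return self

    def subset(self, subject_ids) -> "Cohort":
        ids = pd.Index(subject_ids)
        return Cohort(
            imaging=self.imaging.loc[ids],
            dosages=self.dosages.loc[ids],
            snps=self.snps,
            clinical=self.clinical.loc[ids],
            mmse=self.mmse.loc[ids],
            labels=None if self.labels is None else self.labels.loc[ids],
        )

    def copy(self) -> "Cohort":
        return Cohort(self.imaging.copy(), self.dosages.copy(), self.snps.copy(),
                      self.clinical.copy(), self.mmse.copy(),
                      None if self.labels is None else self.labels.copy())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def _check_duplicates(df: pd.DataFrame, keys: list[str], name: str) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        row = df.loc[dup, keys].iloc[0].to_dict()
        raise IntegrityError(f"{name}: duplicate row for {row}")


def read_cohort(directory: str | Path | None = None, *, imaging=None, dosages=None,
                snps=None, clinical=None, mmse=None) -> Cohort:
    """Read the five CSVs and align them on the subject-ID intersection.

    Either pass ``directory`` containing the standard file names
    (imaging.csv, genotype_dosages.csv, genotype_snps.csv, clinical.csv,
    mmse.csv) or the individual paths.  Subjects absent from any table are
    dropped and logged; an empty intersection is fatal.
    """
    if directory is not None:
        d = Path(directory)
        imaging = imaging or d / "imaging.csv"
        dosages = dosages or d / "genotype_dosages.csv"
        snps = snps or d / "genotype_snps.csv"
        clinical = clinical or d / "clinical.csv"
        mmse = mmse or d / "mmse.csv"

    img = pd.read_csv(imaging, dtype={"subject_id": str, "roi_id": str})
    _require_columns(img, ["subject_id", "roi_id", *IMAGING_TRAITS], "imaging.csv")
    _check_duplicates(img, ["subject_id", "roi_id"], "imaging.csv")

    dos = pd.read_csv(dosages, dtype={"subject_id": str, "snp_id": str})
    _require_columns(dos, ["subject_id", "snp_id", "dosage"], "genotype_dosages.csv")
    _check_duplicates(dos, ["subject_id", "snp_id"], "genotype_dosages.csv")

    snp = pd.read_csv(snps, dtype={"snp_id": str})
    _require_columns(snp, ["snp_id", *SNP_ATTRS], "genotype_snps.csv")
    _check_duplicates(snp, ["snp_id"], "genotype_snps.csv")

    cli = pd.read_csv(clinical, dtype={"subject_id": str})
    _require_columns(cli, ["subject_id", *CLINICAL_SCORES], "clinical.csv")
    _check_duplicates(cli, ["subject_id"], "clinical.csv")

    mm = pd.read_csv(mmse, dtype={"subject_id": str})
    _require_columns(mm, ["subject_id", "visit_month", "mmse"], "mmse.csv")
    _check_duplicates(mm, ["subject_id", "visit_month"], "mmse.csv")

    bad = ~dos["dosage"].isin([0, 1, 2])
    if bad.any():
        row = dos.loc[bad].iloc[0]
        raise IntegrityError(
            f"dosage outside {{0,1,2}}: subject {row['subject_id']!r}, "
            f"snp {row['snp_id']!r}, value {row['dosage']!r}")

    img_wide = img.pivot(index="subject_id", columns="roi_id", values=IMAGING_TRAITS)
    img_wide.columns = img_wide.columns.swaplevel(0, 1)  # (roi, trait)
    img_wide = img_wide.sort_index(axis=1)
    # preserve trait order inside each ROI
    rois = sorted(img_wide.columns.get_level_values(0).unique())
    img_wide = img_wide.loc[:, [(r, t) for r in rois for t in IMAGING_TRAITS]]
    if img_wide.isna().to_numpy().any():
        raise IntegrityError("imaging.csv: ROI set differs across subjects or NaN trait")

    dos_wide = dos.pivot(index="subject_id", columns="snp_id", values="dosage")
    if dos_wide.isna().to_numpy().any():
        raise IntegrityError("genotype_dosages.csv: SNP set differs across subjects")
    dos_wide = dos_wide.sort_index(axis=1).astype(np.int64)

    snp = snp.set_index("snp_id").loc[dos_wide.columns]
    cli = cli.set_index("subject_id")[CLINICAL_SCORES].astype(float)
    if cli.isna().to_numpy().any():
        raise IntegrityError("clinical.csv: NaN score values are not supported")

    mm_wide = mm.pivot(index="subject_id", columns="visit_month", values="mmse")
    mm_wide = mm_wide.reindex(columns=MMSE_VISITS)

    tables = {"imaging": img_wide, "dosages": dos_wide, "clinical": cli, "mmse": mm_wide}
    common = None
    for tab in tables.values():
        common = tab.index if common is None else common.intersection(tab.index)
    common = common.sort_values()
    if len(common) == 0:
        raise IntegrityError("no subject present in all tables")
    for name, tab in tables.items():
        dropped = tab.index.difference(common)
        if len(dropped):
            logger.info("read_cohort: dropping %d subject(s) absent from other tables "
                        "(first from %s): %s", len(dropped), name, list(dropped[:5]))
    cohort = Cohort(imaging=img_wide.loc[common], dosages=dos_wide.loc[common],
                    snps=snp, clinical=cli.loc[common], mmse=mm_wide.loc[common])
    return cohort.validate()


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort back to the five standard CSVs; returns the paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    img = cohort.imaging.stack(level=0, future_stack=True).reset_index()
    img.columns = ["subject_id", "roi_id", *cohort.imaging.columns.get_level_values(1).unique()]
    img = img[["subject_id", "roi_id", *IMAGING_TRAITS]]
    dos = cohort.dosages.stack().reset_index()
    dos.columns = ["subject_id", "snp_id", "dosage"]
    mm = cohort.mmse.stack().reset_index()
    mm.columns = ["subject_id", "visit_month", "mmse"]
    paths = {
        "imaging": d / "imaging.csv",
        "dosages": d / "genotype_dosages.csv",
        "snps": d / "genotype_snps.csv",
        "clinical": d / "clinical.csv",
        "mmse": d / "mmse.csv",
    }
    img.to_csv(paths["imaging"], index=False)
    dos.to_csv(paths["dosages"], index=False)
    cohort.snps.reset_index().to_csv(paths["snps"], index=False)
    cohort.clinical.reset_index().to_csv(paths["clinical"], index=False)
    mm.to_csv(paths["mmse"], index=False)
    if cohort.labels is not None:
        lab = cohort.labels.rename("subtype").rename_axis("subject_id")
        lab.reset_index().to_csv(d / "true_labels.csv", index=False)
        paths["labels"] = d / "true_labels.csv"
    return paths


def read_plink_raw(path: str | Path) -> pd.DataFrame:
    """Map a PLINK ``.raw`` additive-dosage export to the long dosage schema.

    Returns a DataFrame with columns subject_id, snp_id, dosage; the trailing
    ``_<allele>`` suffix PLINK appends to variant names is stripped.
    """
    raw = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    _require_columns(raw, meta, "plink .raw")
    snp_cols = [c for c in raw.columns if c not in meta]
    out = raw[["IID", *snp_cols]].melt(id_vars="IID", var_name="snp_id",
                                       value_name="dosage")
    out["snp_id"] = out["snp_id"].str.replace(r"_[ACGT]+$", "", regex=True)
    out = out.rename(columns={"IID": "subject_id"})
    out["subject_id"] = out["subject_id"].astype(str)
    return out[["subject_id", "snp_id", "dosage"]]


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

class CohortScaler(BaseEstimator, TransformerMixin):
    """Z-score imaging and clinical features from training-set statistics.

    Mean and population SD (denominator ``n``) are computed only from the
    subject IDs given to :meth:`fit`; genotype dosages and SNP static
    attributes pass through untouched.  Constant features get scale 1 and a
    warning so the transform stays invertible.
    """

    def __init__(self, scale_imaging: bool = True, scale_clinical: bool = True):
        self.scale_imaging = scale_imaging
        self.scale_clinical = scale_clinical

    def fit(self, cohort: Cohort, train_ids=None) -> "CohortScaler":
        if train_ids is None:
            train_ids = cohort.subjects
        train_ids = pd.Index(train_ids)
        if len(train_ids) == 0:
            raise ValueError("train_ids is empty")
        if not train_ids.isin(cohort.subjects).all():
            raise ValueError("train_ids contains subjects outside the cohort")
        self.imaging_mean_, self.imaging_scale_ = self._stats(
            cohort.imaging.loc[train_ids]) if self.scale_imaging else (None, None)
        self.clinical_mean_, self.clinical_scale_ = self._stats(
            cohort.clinical.loc[train_ids]) if self.scale_clinical else (None, None)
        return self

    @staticmethod
    def _stats(frame: pd.DataFrame):
        mean = frame.mean(axis=0)
        scale = frame.std(axis=0, ddof=0)
        const = scale <= 0.0
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant feature column(s); scale set to 1",
                UserWarning, stacklevel=3)
            scale = scale.mask(const, 1.0)
        return mean, scale

    def transform(self, cohort: Cohort) -> Cohort:
        out = cohort.copy()
        if self.scale_imaging:
            self._check(out.imaging.columns, self.imaging_mean_.index, "imaging")
            out.imaging = (out.imaging - self.imaging_mean_) / self.imaging_scale_
        if self.scale_clinical:
            self._check(out.clinical.columns, self.clinical_mean_.index, "clinical")
            out.clinical = (out.clinical - self.clinical_mean_) / self.clinical_scale_
        return out

    def inverse_transform(self, cohort: Cohort) -> Cohort:
        out = cohort.copy()
        if self.scale_imaging:
            out.imaging = out.imaging * self.imaging_scale_ + self.imaging_mean_
        if self.scale_clinical:
            out.clinical = out.clinical * self.clinical_scale_ + self.clinical_mean_
        return out

    @staticmethod
    def _check(cols, fitted, name):
        if not cols.equals(pd.Index(fitted) if not isinstance(fitted, pd.MultiIndex)
                           else fitted):
            unmatched = list(set(map(tuple if name == "imaging" else str, cols))
                             ^ set(map(tuple if name == "imaging" else str, fitted)))
            raise ValueError(f"{name} feature names do not match scaler: "
                             f"{unmatched[:5]}")


def fit_scaler(cohort: Cohort, train_ids) -> CohortScaler:
    """Fit a :class:`CohortScaler` on ``train_ids`` only (leakage-safe)."""
    return CohortScaler().fit(cohort, train_ids)


def apply_scaler(scaler: CohortScaler, cohort: Cohort) -> Cohort:
    """Apply a fitted scaler, returning a transformed copy of the cohort."""
    return scaler.transform(cohort)
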