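"""Nested stratified cross-testing harness.

The cohort is split into 10 stratified outer test folds; each outer training
set is further split into 5 stratified inner validation folds used only for
hyperparameter selection and best-epoch checkpointing.  Every outer test
fold is evaluated 5 times — once per inner split, with the hyperparameters
that split selected — giving 50 evaluations per method.  Feature scaling is
fit on the outer training set only, so no test statistic can leak into
training, selection or checkpointing.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .data import Cohort, fit_scaler
from .features import tensorize
from .metrics import auroc_ovo, null_auroc_se  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    """Outer test folds and nested inner validation folds, as subject IDs."""

    outer: list[dict]  # {"train": [ids], "test": [ids]}
    inner: list[list[dict]]  # per outer fold: [{"train": [...], "val": [...]}]
    seed: int
    n_outer: int
    n_inner: int

    def to_json(self, path: str | Path) -> None:
        payload = {"seed": self.seed, "n_outer": self.n_outer,
                   "n_inner": self.n_inner, "outer": self.outer,
                   "inner": self.inner}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        d = json.loads(Path(path).read_text())
        return cls(outer=d["outer"], inner=d["inner"], seed=d["seed"],
                   n_outer=d["n_outer"], n_inner=d["n_inner"])


def _stratified_split(ids: np.ndarray, y: np.ndarray, n_splits: int,
                      seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="The least populated class", category=UserWarning)
        counts = pd.Series(y).value_counts()
        if (counts < n_splits).any():
            small = counts[counts < n_splits]
            warnings.warn(
                f"class(es) {dict(small)} have fewer members than {n_splits} "
                "folds; best-effort stratification (some folds may lack them)",
                UserWarning, stacklevel=3)
        return [(ids[tr], ids[te]) for tr, te in skf.split(ids, y)]


def make_fold_plan(labels: pd.Series, seed: int = 0, n_outer: int = 10,
                   n_inner: int = 5) -> FoldPlan:
    """Build the nested outer/inner stratified fold plan over subject IDs.

    Subjects are ordered lexicographically by ID before splitting, so the
    plan is deterministic given (labels, seed).
    """
    labels = labels.sort_index()
    ids = labels.index.to_numpy()
    y = labels.to_numpy()
    outer, inner = [], []
    for k, (tr, te) in enumerate(_stratified_split(ids, y, n_outer, seed)):
        outer.append({"train": list(tr), "test": list(te)})
        y_tr = labels.loc[tr].to_numpy()
        inner_k = [{"train": list(itr), "val": list(iva)}
                   for itr, iva in _stratified_split(tr, y_tr, n_inner,
                                                     seed + 1000 + k)]
        inner.append(inner_k)
    return FoldPlan(outer=outer, inner=inner, seed=seed, n_outer=n_outer,
                    n_inner=n_inner)


@dataclass
class EvaluationReport:
    """Per-run AUROCs plus aggregate statistics.

    ``records`` has one row per (method, outer_fold, repeat) with the test
    AUROC and the hyperparameters the corresponding inner split selected.
    """

    records: pd.DataFrame
    n_outer: int = 10
    n_repeats: int = 5
    failures: list[dict] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean +/- sample SD (ddof=1) of AUROC over all runs per method."""
        g = self.records.groupby("method")["auroc"]
        out = pd.DataFrame({"mean_auroc": g.mean(), "sd_auroc": g.std(ddof=1),
                            "n_runs": g.count()})
        return out

    def ttest_matrix(self) -> pd.DataFrame:
        methods = sorted(self.records["method"].unique())
        mat = pd.DataFrame(np.nan, index=methods, columns=methods)
        for a, b in itertools.combinations(methods, 2):
            p = paired_ttest(self, a, b)
            mat.loc[a, b] = mat.loc[b, a] = p
        return mat


def paired_ttest(report: EvaluationReport, method_a: str, method_b: str) -> float:
    """Two-sided paired t-test on fold-and-repeat-matched AUROC differences.

    Degenerate conventions: identical vectors -> p = 1.0; a constant nonzero
    difference (zero variance) -> p = 0.0.
    """
    recs = report.records
    a = (recs[recs["method"] == method_a]
         .set_index(["outer_fold", "repeat"])["auroc"].sort_index())
    b = (recs[recs["method"] == method_b]
         .set_index(["outer_fold", "repeat"])["auroc"].sort_index())
    if not a.index.equals(b.index):
        raise ValueError(f"unmatched runs between {method_a!r} and {method_b!r}")
    d = a.to_numpy() - b.to_numpy()
    if np.allclose(d.std(ddof=1) if len(d) > 1 else 0.0, 0.0):
        return 1.0 if np.allclose(d, 0.0) else 0.0
    return float(stats.ttest_rel(a.to_numpy(), b.to_numpy()).pvalue)


def run_cross_testing(cohort: Cohort, labels: pd.Series, methods: dict,
                      plan: FoldPlan, grid: dict | None = None,
                      seed: int = 0) -> EvaluationReport:
    """Run the nested cross-testing protocol for every method.

    Parameters
    ----------
    methods : mapping method name -> prototype estimator (cloned per run).
    plan : nested fold plan over the cohort's subjects.
    grid : optional mapping method name -> list of parameter dicts searched
        by inner-CV mean validation AUROC.  Default: just the prototype's
        own parameters.

    For each outer fold the scaler is fit on the outer training subjects
    only.  For repeat r the estimator is trained on inner split r's training
    subjects with checkpoint selection on split r's validation subjects
    (using the grid point that split selected), then scored on the untouched
    outer test fold.
    """
    grid = grid or {}
    rows, failures = [], []
    rng = np.random.default_rng(seed)
    for k, fold in enumerate(plan.outer):
        train_ids = pd.Index(fold["train"])
        test_ids = pd.Index(fold["test"])
        scaler = fit_scaler(cohort, train_ids)
        arrays = tensorize(scaler.transform(cohort))
        X_test, y_test = arrays.loc(test_ids), labels.loc[test_ids].to_numpy()
        for name, proto in methods.items():
            param_grid = grid.get(name, [{}])
            for r, split in enumerate(plan.inner[k]):
                itr, iva = pd.Index(split["train"]), pd.Index(split["val"])
                X_itr, y_itr = arrays.loc(itr), labels.loc[itr].to_numpy()
                X_iva, y_iva = arrays.loc(iva), labels.loc[iva].to_numpy()
                best = (-np.inf, None, None)
                for params in param_grid:
                    est = clone(proto).set_params(
                        **params, random_state=int(rng.integers(2**31)))
                    try:
                        if getattr(est, "supports_validation", False):
                            est.fit(X_itr, y_itr, validation=(X_iva, y_iva))
                        else:
                            est.fit(X_itr, y_itr)
                        val_auc = auroc_ovo(y_iva, est.predict_proba(X_iva),
                                            classes=est.classes_)
                    except ValueError as exc:
                        failures.append({"method": name, "outer_fold": k,
                                         "repeat": r, "reason": str(exc)})
                        continue
                    if val_auc > best[0]:
                        best = (val_auc, est, params)
                if best[1] is None:
                    failures.append({"method": name, "outer_fold": k,
                                     "repeat": r,
                                     "reason": "no grid point succeeded"})
                    logger.warning("fold %d repeat %d (%s): AUROC missing",
                                   k, r, name)
                    continue
                try:
                    test_auc = auroc_ovo(y_test, best[1].predict_proba(X_test),
                                         classes=best[1].classes_)
                except ValueError as exc:
                    failures.append({"method": name, "outer_fold": k,
                                     "repeat": r, "reason": str(exc)})
                    continue
                rows.append({"method": name, "outer_fold": k, "repeat": r,
                             "auroc": test_auc, "val_auroc": best[0],
                             "params": json.dumps(best[2], sort_keys=True)})
    records = pd.DataFrame(rows, columns=["method", "outer_fold", "repeat",
                                          "auroc", "val_auroc", "params"])
    return EvaluationReport(records=records, n_outer=plan.n_outer,
                            n_repeats=plan.n_inner, failures=failures)
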