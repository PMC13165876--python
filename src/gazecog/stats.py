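"""Tabular baseline classifiers and group statistics.

Baselines (logistic regression, Gaussian naive Bayes, RBF-kernel SVM with a
small C grid) are fit on the 40-column feature table; group differences are
screened feature-by-feature with the two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import median_impute
from .model.mil import classification_metrics


@dataclass
class BaselineSpec:
    model: str = "LR"  # LR | GNB | SVM
    lr_C: float = 1.0            # inverse regularization (L2 penalty)
    svm_C_grid: tuple[float, ...] = (0.1, 0.4, 0.7, 1.0)
    svm_gamma: str = "scale"

    def __post_init__(self) -> None:
        if self.model not in ("LR", "GNB", "SVM"):
            raise ValueError(f"unknown baseline model {self.model!r}")
        if self.model == "SVM" and not self.svm_C_grid:
            raise ValueError("SVM grid must be nonempty")


@dataclass
class FittedBaseline:
    spec: BaselineSpec
    model: object
    scaler: StandardScaler
    columns: list[str]
    chosen_C: float | None
    metrics: dict[str, float]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = self.scaler.transform(table[self.columns].to_numpy(dtype=float))
        return self.model.predict(X)


def _make_estimator(spec: BaselineSpec, C: float | None = None):
    if spec.model == "LR":
        # the default penalty is L2; the argument spelling changed across
        # scikit-learn versions, so rely on the default
        return LogisticRegression(C=spec.lr_C, max_iter=2000)
    if spec.model == "GNB":
        return GaussianNB()
    return SVC(kernel="rbf", gamma=spec.svm_gamma, C=C if C is not None else 1.0)


def train_baseline(spec: BaselineSpec, table: pd.DataFrame,
                   train_index: pd.Index, val_index: pd.Index,
                   test_index: pd.Index) -> FittedBaseline:
    """Fit a tabular baseline on the training split and score the test split.

    Missing behavioral features are imputed with training-split medians;
    features are standardized with training statistics; the SVM selects its
    C from the configured grid by validation accuracy. Constant feature
    columns (zero training spread) are dropped with a warning.
    """
    filled = median_impute(table, train_index)
    cols = [c for c in filled.columns if c != "label"]
    tr = filled.loc[train_index]
    const = [c for c in cols if tr[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant feature column(s): {const}",
                      stacklevel=2)
        cols = [c for c in cols if c not in const]
    scaler = StandardScaler().fit(tr[cols].to_numpy(dtype=float))
    Xtr = scaler.transform(tr[cols].to_numpy(dtype=float))
    ytr = tr["label"].to_numpy(dtype=int)
    chosen_C = None
    if spec.model == "SVM":
        Xval = scaler.transform(filled.loc[val_index, cols].to_numpy(dtype=float))
        yval = filled.loc[val_index, "label"].to_numpy(dtype=int)
        best_acc = -1.0
        for C in spec.svm_C_grid:
            est = _make_estimator(spec, C).fit(Xtr, ytr)
            acc = float((est.predict(Xval) == yval).mean())
            if acc > best_acc:
                best_acc, chosen_C = acc, C
        model = _make_estimator(spec, chosen_C).fit(Xtr, ytr)
    else:
        model = _make_estimator(spec).fit(Xtr, ytr)
    Xte = scaler.transform(filled.loc[test_index, cols].to_numpy(dtype=float))
    yte = filled.loc[test_index, "label"].to_numpy(dtype=int)
    metrics = classification_metrics(yte, model.predict(Xte))
    return FittedBaseline(spec=spec, model=model, scaler=scaler, columns=cols,
                          chosen_C=chosen_C, metrics=metrics)


@dataclass
class StatResult:
    feature: str
    u_statistic: float
    p_value: float
    median_hc: float
    median_cd: float

    @property
    def direction(self) -> int:
        """+1 when the CD median exceeds the HC median, -1 when lower."""
        d = self.median_cd - self.median_hc
        return int(np.sign(d))


def mannwhitney_all(table: pd.DataFrame, labels: np.ndarray,
                    columns: list[str] | None = None) -> list[StatResult]:
    """Two-sided Mann-Whitney U test per feature, sorted by p-value.

    ``labels`` marks CD as 1. Uses the exact distribution for small
    samples without ties and the tie-corrected normal approximation
    otherwise (scipy's default policy). All-NaN or all-tied features get
    p = 1.
    """
    labels = np.asarray(labels, dtype=int)
    cols = columns or [c for c in table.columns if c != "label"]
    out: list[StatResult] = []
    for c in cols:
        x = table[c].to_numpy(dtype=float)
        hc, cd = x[labels == 0], x[labels == 1]
        hc, cd = hc[np.isfinite(hc)], cd[np.isfinite(cd)]
        if len(hc) < 3 or len(cd) < 3 or (np.ptp(np.concatenate([hc, cd])) == 0):
            out.append(StatResult(c, len(hc) * len(cd) / 2.0, 1.0,
                                  float(np.median(hc)) if len(hc) else np.nan,
                                  float(np.median(cd)) if len(cd) else np.nan))
            continue
        res = sps.mannwhitneyu(hc, cd, alternative="two-sided")
        out.append(StatResult(c, float(res.statistic),
                              float(min(1.0, res.pvalue)),
                              float(np.median(hc)), float(np.median(cd))))
    return sorted(out, key=lambda r: r.p_value)


def stats_table(results: list[StatResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature": r.feature, "U": r.u_statistic, "p": r.p_value,
        "median_hc": r.median_hc, "median_cd": r.median_cd,
        "direction": r.direction,
    } for r in results])
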