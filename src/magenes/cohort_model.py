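"""Disease-classification machinery: features, CV logistic regression, McNemar.

Feature variants mirror the seven model inputs evaluated on the
case/control cohort (1: Shannon diversity per gene type + gender,
2: blood lipid markers + gender, 3: abundance of the TMA-lyase/oxygenase
types only + gender, 4: every gene's abundance + gender, 5: abundance
summed per gene type + gender, 6: abundance summed per TMA role + gender,
7: variant 1 without gender).  Labels are 1 = disease, 0 = healthy;
gender is coded 1 = male, 0 = female.

Models are L2-penalized logistic regressions evaluated by stratified
10-fold cross-validation; per-fold ROC curves are vertically averaged on a
fixed false-positive-rate grid and the AUC of the mean curve is reported,
alongside per-fold AUCs.  Competing models are compared with McNemar's
test on their out-of-fold correctness at a 0.5 probability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .quant import NormalizedMatrix, aggregate
from .seq_io import gene_role

BLOOD_MARKERS = ("triglyceride_mmol_l", "ldl_mmol_l", "hdl_mmol_l")


def shannon_index(abundances: np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log); 0 if no signal."""
    a = np.asarray(abundances, dtype=float)
    total = a.sum()
    if total <= 0:
        return 0.0
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_by_type(
    norm: NormalizedMatrix | pd.DataFrame,
    typemap: dict[str, str],
    types: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-sample Shannon diversity within each gene type.

    ``typemap`` maps gene id -> gene type; proportions are renormalized
    within each type.  cntA and yeaW counts are already pooled under the
    single cntA_yeaW label upstream.  Returns samples x types.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    if types is None:
        types = sorted({t for t in typemap.values()})
    out = {}
    for t in types:
        genes = [g for g in values.index if typemap.get(g) == t]
        if not genes:
            raise ValueError(f"no genes mapped to type {t!r}")
        sub = values.loc[genes]
        out[t] = sub.apply(lambda col: shannon_index(col.values), axis=0)
    return pd.DataFrame(out)


@dataclass
class FeatureTable:
    X: pd.DataFrame  # samples x features
    y: pd.Series  # 1 = disease
    variant: int

    def __post_init__(self) -> None:
        if self.y.isna().any():
            raise ValueError("missing labels")
        if not set(self.y.unique()) <= {0, 1}:
            raise ValueError("labels must be 0/1")


def build_features(
    norm: NormalizedMatrix | pd.DataFrame,
    metadata: pd.DataFrame,
    typemap: dict[str, str],
    variant: int,
) -> FeatureTable:
    """Assemble the feature table for one model variant (1..7).

    ``metadata`` is indexed by sample id with columns ``label``, ``gender``
    and, for variant 2, the blood markers (triglyceride/LDL/HDL, mmol/L).
    Column order is deterministic.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    samples = [s for s in values.columns if s in metadata.index]
    if variant == 2:
        samples = list(metadata.index)
    meta = metadata.loc[samples]
    if "label" not in meta.columns or meta["label"].isna().any():
        raise ValueError("metadata must supply a complete 0/1 'label' column")

    def gender_col() -> pd.Series:
        if "gender" not in meta.columns or meta["gender"].isna().any():
            raise ValueError(f"variant {variant} requires a complete 'gender' column")
        return meta["gender"].astype(float)

    if variant in (1, 7):
        X = shannon_by_type(values[samples] if variant != 2 else values, typemap)
        X = X.loc[samples]
        if variant == 1:
            X["gender"] = gender_col()
    elif variant == 2:
        missing = [c for c in BLOOD_MARKERS if c not in meta.columns]
        if missing:
            raise ValueError(f"variant 2 requires blood marker columns {missing}")
        X = meta[list(BLOOD_MARKERS)].astype(float).copy()
        X["gender"] = gender_col()
    elif variant == 3:
        per_type = aggregate(values[samples], typemap)
        want = [t for t in ("cutC", "cntA_yeaW") if t in per_type.columns]
        if not want:
            raise ValueError("variant 3 requires cutC or cntA_yeaW genes")
        X = per_type[want].copy()
        X["gender"] = gender_col()
    elif variant == 4:
        X = values[samples].T.copy()
        X["gender"] = gender_col()
    elif variant == 5:
        X = aggregate(values[samples], typemap).copy()
        X["gender"] = gender_col()
    elif variant == 6:
        rolemap = {g: gene_role(t) for g, t in typemap.items()}
        X = aggregate(values[samples], rolemap).copy()
        X["gender"] = gender_col()
    else:
        raise ValueError(f"unknown feature variant {variant!r} (expected 1..7)")
    X = X.loc[samples]
    return FeatureTable(X=X, y=meta["label"].astype(int), variant=variant)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    l2_strength: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> tuple[np.ndarray, float]:
    """L2-penalized logistic regression on z-scored features.

    Minimizes -loglik + l2_strength/2 * ||w||^2 (intercept unpenalized);
    ``l2_strength=0`` fits unpenalized (iteration-capped under perfect
    separation).  Returns (weights, intercept) on the standardized scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    C = 1.0 / l2_strength if l2_strength > 0 else np.inf
    clf = LogisticRegression(C=C, tol=tol, max_iter=max_iter, solver="lbfgs")
    clf.fit(Xs, y)
    return clf.coef_.ravel(), float(clf.intercept_[0])


@dataclass
class CVResult:
    fold_assignments: np.ndarray  # fold index per sample
    fold_rocs: list[tuple[np.ndarray, np.ndarray]]  # (fpr, tpr) per fold
    fold_aucs: list[float]
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    auc: float  # AUC of the vertically averaged curve
    oof_scores: np.ndarray  # out-of-fold probability of class 1
    oof_correct: np.ndarray  # correctness at threshold 0.5


def cv_roc(
    table: FeatureTable,
    k: int = 10,
    seed: int = 0,
    grid_size: int = 101,
    l2_strength: float = 1.0,
) -> CVResult:
    """Stratified k-fold cross-validated mean ROC.

    Folds come from a seeded stratified shuffle; features are z-scored on
    each training fold only.  Per-fold ROC curves are interpolated onto a
    fixed FPR grid and vertically averaged; the reported AUC is the
    trapezoidal area under the mean curve.
    """
    X = table.X.values.astype(float)
    y = table.y.values.astype(int)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if min(n_pos, n_neg) < k:
        raise ValueError(f"each class must have >= k={k} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fpr_grid = np.linspace(0.0, 1.0, grid_size)
    fold_assignments = np.full(len(y), -1, dtype=int)
    oof_scores = np.zeros(len(y))
    fold_rocs, fold_aucs, tprs = [], [], []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        fold_assignments[te] = fold
        scaler = StandardScaler().fit(X[tr])
        C = 1.0 / l2_strength if l2_strength > 0 else np.inf
        clf = LogisticRegression(C=C, max_iter=2000)
        clf.fit(scaler.transform(X[tr]), y[tr])
        scores = clf.predict_proba(scaler.transform(X[te]))[:, 1]
        oof_scores[te] = scores
        fpr, tpr, _ = roc_curve(y[te], scores)
        fold_rocs.append((fpr, tpr))
        fold_aucs.append(float(sk_auc(fpr, tpr)))
        tprs.append(np.interp(fpr_grid, fpr, tpr))
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    mean_auc = float(np.trapezoid(mean_tpr, fpr_grid))
    return CVResult(
        fold_assignments=fold_assignments,
        fold_rocs=fold_rocs,
        fold_aucs=fold_aucs,
        fpr_grid=fpr_grid,
        mean_tpr=mean_tpr,
        auc=mean_auc,
        oof_scores=oof_scores,
        oof_correct=(oof_scores >= 0.5).astype(int) == y,
    )


@dataclass
class McNemarResult:
    b: int  # model A correct, model B wrong
    c: int  # model B correct, model A wrong
    statistic: float
    p_value: float
    method: Literal["exact", "chi2_cc"]


def mcnemar(correct_a: Sequence[bool], correct_b: Sequence[bool]) -> McNemarResult:
    """McNemar's test on paired correctness vectors.

    Exact two-sided binomial when the discordant count b+c < 25, otherwise
    chi-square with continuity correction.  Symmetric in its arguments.
    """
    a = np.asarray(correct_a, dtype=bool)
    b_vec = np.asarray(correct_b, dtype=bool)
    if a.shape != b_vec.shape:
        raise ValueError("correctness vectors must have equal length")
    b = int((a & ~b_vec).sum())
    c = int((~a & b_vec).sum())
    n = b + c
    if n == 0:
        return McNemarResult(b=b, c=c, statistic=0.0, p_value=1.0, method="exact")
    if n < 25:
        p = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5)))
        return McNemarResult(b=b, c=c, statistic=float(min(b, c)), p_value=p, method="exact")
    stat = (abs(b - c) - 1.0) ** 2 / n
    p = float(stats.chi2.sf(stat, df=1))
    return McNemarResult(b=b, c=c, statistic=float(stat), p_value=p, method="chi2_cc")
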