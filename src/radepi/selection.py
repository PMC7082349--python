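"""Feature normalization, univariate screening and the LASSO-logistic signature.

The signature workflow mirrors standard radiomics practice: z-score
normalization with training-cohort parameters, a univariate screen keeping
features with a two-sided Pearson-test p < 0.05 AND an oriented empirical
AUC > 0.6, then an L1-penalized logistic regression whose penalty is tuned
by leave-one-out cross-validated misclassification error (cut-off 0.5,
ties broken toward the larger, i.e. sparser, penalty). The signature of a
patient is the intercept-free linear combination of the selected
normalized features; the intercept is kept internally for probability
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import LeaveOneOut


@dataclass
class FeatureTable:
    """Patients x features matrix with binary labels (generalized = 1)."""

    patient_ids: list[str]
    features: pd.DataFrame  # index aligned with patient_ids
    labels: np.ndarray
    cohort: str = "train"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.patient_ids) != len(self.features) or len(self.labels) != len(self.features):
            raise ValueError("patient_ids, features and labels must have equal length")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def n(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class NormalizationParams:
    mean: pd.Series
    std: pd.Series
    dropped_constant: tuple[str, ...] = ()

    def apply(self, features: pd.DataFrame) -> pd.DataFrame:
        cols = self.mean.index
        return (features[cols] - self.mean) / self.std


@dataclass
class ScreenResult:
    table: pd.DataFrame  # columns: feature, pearson_p, auc, kept

    @property
    def kept(self) -> list[str]:
        return list(self.table.loc[self.table["kept"], "feature"])


@dataclass(frozen=True)
class LassoConfig:
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-4
    solver_tol: float = 1e-7
    max_iter: int = 10_000


@dataclass
class SignatureModel:
    feature_names: list[str]
    coefficients: np.ndarray  # aligned with feature_names, all nonzero
    intercept: float
    lambda_star: float
    lambda_grid: np.ndarray
    cv_error: np.ndarray  # LOOCV misclassification per grid lambda
    normalization: NormalizationParams
    all_candidates: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "coefficients": [float(c) for c in self.coefficients],
                "intercept": self.intercept,
                "lambda_star": self.lambda_star,
                "lambda_grid": [float(v) for v in self.lambda_grid],
                "cv_error": [float(v) for v in self.cv_error],
                "normalization_mean": {k: float(v) for k, v in self.normalization.mean.items()},
                "normalization_std": {k: float(v) for k, v in self.normalization.std.items()},
                "candidates": self.all_candidates,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            lambda_star=float(d["lambda_star"]),
            lambda_grid=np.asarray(d["lambda_grid"], dtype=float),
            cv_error=np.asarray(d["cv_error"], dtype=float),
            normalization=NormalizationParams(
                mean=pd.Series(d["normalization_mean"]),
                std=pd.Series(d["normalization_std"]),
            ),
            all_candidates=d.get("candidates", []),
        )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def zscore_fit_apply(
    train: FeatureTable, *others: FeatureTable
) -> tuple[list[FeatureTable], NormalizationParams]:
    """z-score features with training-cohort mean/SD, applied to every table.

    Features constant in the training cohort are excluded (and reported in
    the returned parameters) since their z-score is undefined.
    """
    if train.n < 2:
        raise ValueError("z-score normalization needs at least 2 training patients")
    mu = train.features.mean(axis=0)
    sd = train.features.std(axis=0, ddof=1)  # sample SD: [1,2,3] -> [-1,0,1]
    constant = tuple(sd.index[sd == 0])
    keep = sd.index[sd > 0]
    params = NormalizationParams(mean=mu[keep], std=sd[keep], dropped_constant=constant)
    out = []
    for t in (train, *others):
        out.append(
            FeatureTable(
                patient_ids=t.patient_ids,
                features=params.apply(t.features),
                labels=t.labels,
                cohort=t.cohort,
            )
        )
    return out, params


# ---------------------------------------------------------------------------
# Univariate screening
# ---------------------------------------------------------------------------

def _pearson_p(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Pearson-correlation p-values of each column of x against y."""
    n = len(y)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = xc.T @ yc / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    # t approximation, as in the classical Pearson test
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[~np.isfinite(t)] = 0.0  # |r| == 1
    return p


def _rank_auc(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Tie-corrected empirical AUC of each column of x for labels y (1 = positive)."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = stats.rankdata(x, axis=0)
    auc = (ranks[y == 1].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return auc


def univariate_screen(
    train: FeatureTable, p_threshold: float = 0.05, auc_threshold: float = 0.6
) -> ScreenResult:
    """Per-feature Pearson test and oriented AUC; kept = both criteria met.

    The AUC is oriented, ``max(AUC, 1 - AUC)``, because the screen measures
    discriminative power regardless of direction. Zero-variance features are
    dropped with p = 1 and AUC = 0.5.
    """
    y = train.labels
    if len(np.unique(y)) < 2:
        raise ValueError("screening requires both classes in the training cohort")
    x = train.features.to_numpy(dtype=float)
    p = _pearson_p(x, y.astype(float))
    auc = _rank_auc(x, y)
    auc = np.maximum(auc, 1.0 - auc)
    const = x.std(axis=0) == 0
    p[const] = 1.0
    auc[const] = 0.5
    kept = (p < p_threshold) & (auc > auc_threshold)
    table = pd.DataFrame(
        {
            "feature": train.features.columns,
            "pearson_p": p,
            "auc": auc,
            "kept": kept,
        }
    )
    return ScreenResult(table=table)


# ---------------------------------------------------------------------------
# LASSO-logistic with LOOCV lambda tuning
# ---------------------------------------------------------------------------

def _lambda_max(x: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty that shrinks every coefficient to zero (glmnet rule)."""
    resid = y - y.mean()
    return float(np.max(np.abs(x.T @ resid)) / len(y))


def _fit_l1(x: np.ndarray, y: np.ndarray, lam: float, cfg: LassoConfig) -> LogisticRegression:
    # sklearn's l1 objective is ||w||_1 + C * sum(loss); glmnet's is
    # mean(loss) + lam * ||w||_1, so C = 1 / (n * lam)
    c = 1.0 / (len(y) * lam)
    model = LogisticRegression(
        l1_ratio=1.0,  # pure L1 penalty
        C=c,
        solver="liblinear",
        tol=cfg.solver_tol,
        max_iter=cfg.max_iter,
        random_state=0,
    )
    model.fit(x, y)
    return model


def build_lambda_grid(x: np.ndarray, y: np.ndarray, cfg: LassoConfig) -> np.ndarray:
    """Decreasing log-spaced grid spanning [lambda_min_ratio * lmax, lmax]."""
    lmax = _lambda_max(x, y) * 1.05  # headroom so the top of the grid is fully shrinking
    return np.geomspace(lmax, lmax * cfg.lambda_min_ratio, cfg.n_lambdas)


def fit_lasso_loocv(
    train: FeatureTable, cfg: LassoConfig = LassoConfig(),
    normalization: NormalizationParams | None = None,
) -> SignatureModel:
    """L1-logistic signature with leave-one-out-tuned penalty.

    For each lambda on the grid the leave-one-out misclassification error at
    probability cut-off 0.5 is computed; lambda* minimizes the error with
    ties broken toward the larger lambda. The final model is refit on the
    full training cohort at lambda*; features with nonzero coefficients form
    the signature.
    """
    y = train.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are all one class; cannot fit")
    if train.features.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    if train.n < 10:
        raise ValueError(f"need at least 10 training patients, got {train.n}")
    if min(np.bincount(y)) < 2:
        raise ValueError("each class needs at least 2 training patients for LOOCV")
    x = train.features.to_numpy(dtype=float)
    grid = build_lambda_grid(x, y, cfg)

    # The LOOCV-over-grid loop is delegated to sklearn's LogisticRegressionCV:
    # accuracy scoring with predict() is exactly misclassification at the 0.5
    # probability cut-off, and with Cs ascending (= lambda descending) its
    # first-best tie rule matches "ties toward larger lambda".
    cs = 1.0 / (len(y) * grid[::-1])  # ascending C
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        cv = LogisticRegressionCV(
            Cs=cs,
            cv=LeaveOneOut(),
            penalty="l1",
            solver="liblinear",
            scoring="accuracy",
            tol=cfg.solver_tol,
            max_iter=cfg.max_iter,
            refit=False,
            random_state=0,
        )
        cv.fit(x, y)
    scores = next(iter(cv.scores_.values()))  # (n_folds, n_Cs), Cs ascending
    errors = (1.0 - scores.mean(axis=0))[::-1]  # align with the decreasing grid

    # ties toward larger lambda = first index in the decreasing grid
    best = int(np.flatnonzero(errors == errors.min())[0])
    lambda_star = float(grid[best])
    final = _fit_l1(x, y, lambda_star, cfg)
    coef = final.coef_.ravel()
    nz = np.flatnonzero(coef != 0.0)
    if len(nz) == 0:
        raise ValueError(
            "no feature survived the LASSO at the selected lambda; "
            "extend the grid toward smaller penalties (lambda_min_ratio)"
        )
    names = [train.features.columns[k] for k in nz]
    if normalization is None:
        normalization = NormalizationParams(
            mean=pd.Series(0.0, index=train.features.columns),
            std=pd.Series(1.0, index=train.features.columns),
        )
    return SignatureModel(
        feature_names=names,
        coefficients=coef[nz],
        intercept=float(final.intercept_[0]),
        lambda_star=lambda_star,
        lambda_grid=grid,
        cv_error=errors,
        normalization=normalization,
        all_candidates=list(train.features.columns),
    )


def compute_signature(model: SignatureModel, features: pd.DataFrame) -> np.ndarray:
    """Per-patient signature: the intercept-free linear weighting s = sum beta_k x_k.

    ``features`` must already be normalized with the model's parameters
    (as produced by :func:`zscore_fit_apply`).
    """
    missing = [f for f in model.feature_names if f not in features.columns]
    if missing:
        raise ValueError(f"feature table is missing selected features: {missing}")
    x = features[model.feature_names].to_numpy(dtype=float)
    s = x @ model.coefficients
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite signature value encountered")
    return s


def signature_probability(model: SignatureModel, features: pd.DataFrame) -> np.ndarray:
    """Predicted P(generalized) using the internally retained intercept."""
    return expit(compute_signature(model, features) + model.intercept)
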