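"""Model evaluation: discrimination, calibration, decision curves,
AIC-selected multivariable model, nomogram and cohort-comparison statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from scipy.special import expit


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong confidence interval
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_lower: float
    ci_upper: float
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Empirical AUC and its DeLong variance estimate."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # structural components (Sun & Xu fast DeLong)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return float(auc), float(var)


def roc_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    alpha: float = 0.05,
) -> RocResult:
    """AUC with a 95% DeLong CI plus accuracy/sensitivity/specificity at a cut-off.

    ``threshold`` is compared against the scores directly, so pass predicted
    probabilities when the conventional 0.5 cut-off is intended.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC analysis needs both classes present")
    auc, var = delong_auc_variance(scores, labels)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return RocResult(
        auc=auc,
        ci_lower=float(np.clip(auc - half, 0.0, 1.0)),
        ci_upper=float(np.clip(auc + half, 0.0, 1.0)),
        threshold=threshold,
        accuracy=(tp + tn) / len(labels),
        sensitivity=tp / int(np.sum(labels == 1)),
        specificity=tn / int(np.sum(labels == 0)),
    )


# ---------------------------------------------------------------------------
# Calibration: Hosmer-Lemeshow
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    bin_mean_predicted: np.ndarray
    bin_observed_frequency: np.ndarray
    bin_sizes: np.ndarray
    statistic: float
    dof: int
    p_value: float
    merged_bins: int = 0


def hosmer_lemeshow_calibration(
    probabilities: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> CalibrationResult:
    """Hosmer-Lemeshow test on equal-count bins of predicted risk.

    HL = sum over bins of (O - E)^2 / (E (1 - E/n_b)); p from chi-square with
    ``n_bins - 2`` degrees of freedom. Bins whose expected count is degenerate
    (E = 0 or E = n_b) are merged with their neighbor and the dof reduced.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0,1)")
    if len(p) < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} observations, got {len(p)}")
    order = np.argsort(p, kind="stable")
    groups = np.array_split(order, n_bins)

    bins = [(p[g].sum(), y[g].sum(), len(g), p[g].mean(), y[g].mean()) for g in groups]
    merged = 0
    i = 0
    while i < len(bins) and len(bins) > 1:
        e, o, nb, _, _ = bins[i]
        if e <= 0 or e >= nb:  # degenerate expectation; merge with neighbor
            j = i + 1 if i + 1 < len(bins) else i - 1
            e2, o2, nb2, _, _ = bins[j]
            tot = nb + nb2
            bins[min(i, j)] = (
                e + e2,
                o + o2,
                tot,
                (bins[i][3] * nb + bins[j][3] * nb2) / tot,
                (bins[i][4] * nb + bins[j][4] * nb2) / tot,
            )
            del bins[max(i, j)]
            merged += 1
        else:
            i += 1

    stat = 0.0
    for e, o, nb, _, _ in bins:
        stat += (o - e) ** 2 / (e * (1.0 - e / nb))
    dof = max(len(bins) - 2, 1)
    return CalibrationResult(
        bin_mean_predicted=np.array([b[3] for b in bins]),
        bin_observed_frequency=np.array([b[4] for b in bins]),
        bin_sizes=np.array([b[2] for b in bins]),
        statistic=float(stat),
        dof=dof,
        p_value=float(stats.chi2.sf(stat, dof)),
        merged_bins=merged,
    )


# ---------------------------------------------------------------------------
# Decision-curve analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_all: np.ndarray
    net_benefit_none: np.ndarray


def decision_curve(
    probabilities: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> DecisionCurve:
    """Net benefit of the model vs. treat-all and treat-none policies.

    net benefit = TP/N - (FP/N) * p_t/(1 - p_t), calling positive at
    probability >= p_t; treat-all = pi - (1 - pi) * p_t/(1 - p_t).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("threshold probabilities must lie strictly in (0,1)")
    n = len(y)
    prevalence = y.mean()
    odds = thresholds / (1.0 - thresholds)
    nb_model = np.empty_like(thresholds)
    for k, (t, o) in enumerate(zip(thresholds, odds)):
        called = p >= t
        tp = np.sum(called & (y == 1))
        fp = np.sum(called & (y == 0))
        nb_model[k] = tp / n - (fp / n) * o
    nb_all = prevalence - (1.0 - prevalence) * odds
    return DecisionCurve(
        thresholds=thresholds,
        net_benefit_model=nb_model,
        net_benefit_all=nb_all,
        net_benefit_none=np.zeros_like(thresholds),
    )


# ---------------------------------------------------------------------------
# AIC-selected multivariable model + nomogram
# ---------------------------------------------------------------------------

@dataclass
class NomogramModel:
    predictors: list[str]
    coefficients: dict[str, float]
    intercept: float
    aic: float
    elimination_trace: list[tuple[str, float]] = field(default_factory=list)
    # points scale, populated by build_nomogram
    point_scales: dict[str, dict[str, float]] = field(default_factory=dict)
    base_eta: float = float("nan")
    eta_per_point: float = float("nan")

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(data), self.intercept)
        for name in self.predictors:
            eta = eta + self.coefficients[name] * data[name].to_numpy(dtype=float)
        return eta

    def probability(self, data: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(data))

    def points(self, data: pd.DataFrame) -> pd.DataFrame:
        """Per-predictor and total nomogram points of each patient."""
        cols = {}
        for name, sc in self.point_scales.items():
            x = data[name].to_numpy(dtype=float)
            cols[name] = (x - sc["reference"]) * sc["points_per_unit"]
        out = pd.DataFrame(cols, index=data.index)
        out["total"] = out.sum(axis=1)
        return out

    def probability_from_points(self, total_points: np.ndarray) -> np.ndarray:
        return expit(self.base_eta + self.eta_per_point * np.asarray(total_points, dtype=float))


def _fit_logit(x: pd.DataFrame, y: np.ndarray) -> sm.Logit:
    model = sm.Logit(y, sm.add_constant(x, has_constant="add"))
    try:
        with np.errstate(divide="ignore", over="ignore"):
            res = model.fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        raise ValueError(
            f"logistic fit failed ({exc}); predictors likely separate the classes "
            "perfectly -- drop or regularize the offending predictor"
        ) from exc
    if not res.mle_retvals.get("converged", True) or np.any(np.abs(res.params) > 50):
        raise ValueError(
            "logistic fit did not converge (possible separation); "
            "check predictors for quasi-complete separation"
        )
    return res


def fit_multivariable_aic(data: pd.DataFrame, labels: np.ndarray,
                          candidates: list[str] | None = None) -> NomogramModel:
    """Backward elimination on AIC from the full logistic model.

    At each step the predictor whose removal lowers AIC the most is dropped;
    elimination stops when no removal lowers AIC. AIC = 2k - 2 log L.
    """
    y = np.asarray(labels, dtype=int)
    current = list(candidates) if candidates is not None else list(data.columns)
    if not current:
        raise ValueError("no candidate predictors supplied")
    res = _fit_logit(data[current], y)
    trace: list[tuple[str, float]] = [("<full>", res.aic)]
    while len(current) > 1:
        best_drop, best_aic = None, res.aic
        for name in current:
            reduced = [c for c in current if c != name]
            r = _fit_logit(data[reduced], y)
            if r.aic < best_aic:
                best_drop, best_aic = name, r.aic
        if best_drop is None:
            break
        current = [c for c in current if c != best_drop]
        res = _fit_logit(data[current], y)
        trace.append((best_drop, res.aic))
    params = res.params
    return NomogramModel(
        predictors=current,
        coefficients={c: float(params[c]) for c in current},
        intercept=float(params["const"]),
        aic=float(res.aic),
        elimination_trace=trace,
    )


def build_nomogram(model: NomogramModel, data: pd.DataFrame) -> NomogramModel:
    """Attach 0-100 point scales to a fitted multivariable model.

    Each predictor's scale is anchored at the value minimizing its
    contribution (0 points); the predictor with the widest effect
    |beta| * range spans exactly 100 points. The points path reproduces the
    direct logistic probability exactly because total points are an affine
    function of the linear predictor.
    """
    effects = {}
    refs = {}
    for name in model.predictors:
        x = data[name].to_numpy(dtype=float)
        beta = model.coefficients[name]
        lo, hi = float(x.min()), float(x.max())
        effects[name] = abs(beta) * (hi - lo)
        refs[name] = lo if beta >= 0 else hi  # contribution-minimizing anchor
    max_effect = max(effects.values())
    if max_effect <= 0:
        raise ValueError("all predictors have zero effect range; no point scale possible")
    scales = {}
    for name in model.predictors:
        if effects[name] == 0:
            continue  # zero-range predictor carries no points
        beta = model.coefficients[name]
        scales[name] = {
            "reference": refs[name],
            "points_per_unit": beta * 100.0 / max_effect,
            "max_points": effects[name] / max_effect * 100.0,
        }
    base_eta = model.intercept + sum(
        model.coefficients[n] * refs[n] for n in model.predictors
    )
    model.point_scales = scales
    model.base_eta = float(base_eta)
    model.eta_per_point = float(max_effect / 100.0)
    return model


def nomogram_lookup_table(model: NomogramModel, n: int = 101) -> pd.DataFrame:
    """Monotone total-points -> probability table over the achievable range."""
    max_total = sum(s["max_points"] for s in model.point_scales.values())
    pts = np.linspace(0.0, max_total, n)
    return pd.DataFrame(
        {"total_points": pts, "probability": model.probability_from_points(pts)}
    )


# ---------------------------------------------------------------------------
# Cohort comparison (Table-1-style statistics)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortComparison:
    table: pd.DataFrame  # variable, test, statistic, p_value


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]]."""
    if (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0):
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def compare_cohorts(records: pd.DataFrame, group_col: str = "epilepsy_type",
                    positive: str = "generalized") -> CohortComparison:
    """Table-1-style comparison between the two label groups.

    Continuous variables (age, signature) use a two-sided independent-samples
    t-test; gender and histopathology use two-sided Fisher's exact on the
    2x2 counts.
    """
    g = records[records[group_col] == positive]
    f = records[records[group_col] != positive]
    if len(g) == 0 or len(f) == 0:
        raise ValueError("both groups must be nonempty")
    rows = []
    for var in ("age", "signature"):
        if var not in records.columns:
            continue
        t, p = stats.ttest_ind(g[var], f[var], equal_var=True)
        if np.isnan(p):  # zero variance in both groups
            t, p = 0.0, 1.0
        rows.append({"variable": var, "test": "t-test", "statistic": float(t),
                     "p_value": float(p)})
    for var, level in (("gender", "male"), ("histopathology", "oligodendroglial")):
        if var not in records.columns:
            continue
        a = int((g[var] == level).sum())
        b = int((g[var] != level).sum())
        c = int((f[var] == level).sum())
        d = int((f[var] != level).sum())
        odds_p = fisher_2x2(a, b, c, d)
        rows.append({"variable": var, "test": "fisher", "statistic": float("nan"),
                     "p_value": odds_p})
    return CohortComparison(table=pd.DataFrame(rows))
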