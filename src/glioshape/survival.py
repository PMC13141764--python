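"""Survival estimation, risk-score models, and internal validation.

The two published progression-risk scores for insular glioma are linear
predictors over binary-coded adverse indicators:

    Risk_L = 0.78*Ki67 + 0.54*epilepsy - 0.77*TP53 - 0.90*1p/19q + 0.55*volume
    Risk_C = 0.04*Ki67 - 0.86*IDH1 + 1.31*age + 1.39*volume
             + 1.19*tortuosity - 1.70*1p/19q

where each "status" is 1 at the adverse level (Ki-67 index > 10%, epilepsy
present, TP53 mutant, 1p/19q co-deleted, tumor volume > 20.17 cm3, IDH1
mutant, age > 38 y, tortuosity above the cohort median).  Scores are mapped
to an integer points scale, dichotomized at a points threshold, and
validated internally by bootstrap optimism correction of Harrell's C and by
k-fold cross-validated C plus calibration (ICI / E50) at a fixed horizon.

Kaplan-Meier estimation, weighted log-rank tests, Cox partial-likelihood
fitting (Efron ties) and the concordance index are delegated to lifelines;
the model-building layer (stepwise Wald selection, points scale, threshold
search, optimism correction, cross-validated calibration) is implemented
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats

from .errors import SurvivalError

__all__ = [
    "CodingRule",
    "RiskModel",
    "RISK_L",
    "RISK_C",
    "KMEstimate",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "stepwise_wald",
    "code_covariates",
    "risk_score",
    "to_points",
    "threshold_search",
    "harrell_c",
    "bootstrap_validate",
    "crossvalidate",
    "calibration_error",
]

TIME_COL, EVENT_COL = "pfs_months", "event"


# --------------------------------------------------------------------------
# model description
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingRule:
    """Maps a raw cohort column to a 0/1 adverse indicator.

    op: ``gt``/``ge`` compare numerically against ``value``; ``eq`` tests
    string equality; ``identity`` passes an already-coded 0/1 column;
    ``gt-median`` compares against the in-cohort median of the column.
    """

    column: str
    op: str = "identity"
    value: object = None

    def apply(self, df: pd.DataFrame) -> pd.Series:
        if self.column not in df.columns:
            raise SurvivalError("missing-covariate",
                                f"cohort lacks column {self.column!r}")
        col = df[self.column]
        if self.op == "identity":
            out = col.astype(float)
        elif self.op == "gt":
            out = (pd.to_numeric(col) > self.value).astype(float)
        elif self.op == "ge":
            out = (pd.to_numeric(col) >= self.value).astype(float)
        elif self.op == "eq":
            out = (col == self.value).astype(float)
        elif self.op == "gt-median":
            num = pd.to_numeric(col)
            out = (num > num.median()).astype(float)
        else:
            raise SurvivalError("bad-coding", f"unknown op {self.op!r}")
        out[col.isna()] = np.nan
        return out


@dataclass
class RiskModel:
    """Named coefficient vector with its covariate coding and points scale."""

    name: str
    coefficients: dict[str, float]                 # indicator -> weight
    coding: dict[str, CodingRule]                  # indicator -> rule
    points_threshold: float | None = None          # published cut on the points scale
    points_scheme: str = "nomogram-100"
    recorded: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not all(np.isfinite(list(self.coefficients.values()))):
            raise SurvivalError("bad-model", "non-finite coefficient")
        missing = set(self.coefficients) - set(self.coding)
        if missing:
            raise SurvivalError("bad-model",
                                f"no coding rule for {sorted(missing)}")


#: published L-subgroup model; ``recorded`` carries the publication's own
#: patient-level validation metrics as metadata (not reproducible without
#: the original cohort).
RISK_L = RiskModel(
    name="Risk_L",
    coefficients={"ki67_high": 0.78, "epilepsy_yes": 0.54,
                  "tp53_mutant": -0.77, "chr1p19q_codel": -0.90,
                  "volume_high": 0.55},
    coding={
        "ki67_high": CodingRule("ki67_index", "gt", 0.10),
        "epilepsy_yes": CodingRule("epilepsy", "eq", "yes"),
        "tp53_mutant": CodingRule("tp53", "eq", "mutant"),
        "chr1p19q_codel": CodingRule("chr1p19q", "eq", "co-deleted"),
        "volume_high": CodingRule("volume", "gt", 20.17),
    },
    points_threshold=23,
    recorded={"bootstrap_c": 0.67, "cv_mean_c": 0.63,
              "ici": 0.008, "e50": 0.006, "logrank_p": 0.003},
)

#: published C-subgroup model
RISK_C = RiskModel(
    name="Risk_C",
    coefficients={"ki67_high": 0.04, "idh1_mutant": -0.86, "age_high": 1.31,
                  "volume_high": 1.39, "tortuosity_high": 1.19,
                  "chr1p19q_codel": -1.70},
    coding={
        "ki67_high": CodingRule("ki67_index", "gt", 0.10),
        "idh1_mutant": CodingRule("idh1", "eq", "mutant"),
        "age_high": CodingRule("age", "gt", 38.0),
        "volume_high": CodingRule("volume", "gt", 20.17),
        "tortuosity_high": CodingRule("tortuosity", "gt-median"),
        "chr1p19q_codel": CodingRule("chr1p19q", "eq", "co-deleted"),
    },
    points_threshold=41,
    recorded={"bootstrap_c": 0.84, "cv_mean_c": 0.81,
              "ici": 0.061, "e50": 0.021, "logrank_p": 0.001},
)


def code_covariates(model: RiskModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """Binary-coded design matrix for the model's covariates."""
    return pd.DataFrame({name: rule.apply(cohort)
                         for name, rule in model.coding.items()
                         if name in model.coefficients},
                        index=cohort.index)


def risk_score(model: RiskModel, cohort: pd.DataFrame) -> pd.Series:
    """Linear predictor: dot product of coded indicators with weights."""
    coded = code_covariates(model, cohort)
    if coded.isna().any().any():
        bad = coded.columns[coded.isna().any()].tolist()
        raise SurvivalError("missing-covariate",
                            f"unresolvable covariates: {bad}")
    beta = pd.Series(model.coefficients)
    return coded[beta.index] @ beta


def to_points(model: RiskModel, scale: str | float = "nomogram-100"
              ) -> dict[str, int]:
    """Integer points per covariate.

    Default ``nomogram-100``: points_j = round(100 |beta_j| / max|beta|),
    carrying the coefficient's sign (invariant under rescaling of all
    coefficients).  A numeric ``scale`` f instead gives round(f * beta_j).
    """
    beta = model.coefficients
    if not beta or max(abs(b) for b in beta.values()) == 0:
        raise SurvivalError("bad-model", "all coefficients zero")
    if scale == "nomogram-100":
        m = max(abs(b) for b in beta.values())
        return {k: int(round(100 * abs(b) / m)) * (1 if b >= 0 else -1)
                for k, b in beta.items()}
    factor = float(scale)
    return {k: int(round(factor * b)) for k, b in beta.items()}


# --------------------------------------------------------------------------
# estimation
# --------------------------------------------------------------------------

@dataclass
class KMEstimate:
    times: np.ndarray          # distinct event times
    survival: np.ndarray       # S(t) just after each time
    variance: np.ndarray       # Greenwood variance of S(t)
    median: float | None       # earliest t with S(t) <= 0.5; None if not reached

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_records(df: pd.DataFrame) -> pd.DataFrame:
    if len(df) == 0:
        raise SurvivalError("no-records", "empty record set")
    if (df[TIME_COL] < 0).any():
        raise SurvivalError("bad-time", "negative survival time")
    if not df[EVENT_COL].isin([0, 1]).all():
        raise SurvivalError("bad-event", "event must be 0 or 1")
    return df


def km_estimate(records: pd.DataFrame) -> KMEstimate:
    """Product-limit estimator with Greenwood variance and median."""
    df = _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df[TIME_COL], df[EVENT_COL])
    table = kmf.event_table[kmf.event_table["observed"] > 0]
    times = table.index.to_numpy(float)
    surv = np.array([kmf.predict(t) for t in times], dtype=float)
    # Greenwood: Var S(t) = S(t)^2 * sum_{ti<=t} d_i / (n_i (n_i - d_i))
    d = table["observed"].to_numpy(float)
    nrisk = table["at_risk"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(nrisk > d, d / (nrisk * (nrisk - d)), np.nan)
    var = surv ** 2 * np.cumsum(inc)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMEstimate(times=times, survival=surv, variance=var, median=median)


def logrank_test(groups: list[pd.DataFrame],
                 weighting: str = "mantel-cox") -> tuple[float, float]:
    """Weighted log-rank comparison of two or more groups.

    ``mantel-cox`` weights every event time equally; ``breslow-wilcoxon``
    (Gehan-Breslow) weights by the number at risk.  Chi-square reference
    with (groups - 1) degrees of freedom.
    """
    if len(groups) < 2:
        raise SurvivalError("bad-groups", "need >= 2 groups")
    for g in groups:
        if len(g) == 0:
            raise SurvivalError("empty-group", "a group has no subjects")
        _check_records(g)
    if sum(int(g[EVENT_COL].sum()) for g in groups) == 0:
        raise SurvivalError("no-events", "no events in any group")
    durations = np.concatenate([g[TIME_COL].to_numpy(float) for g in groups])
    events = np.concatenate([g[EVENT_COL].to_numpy(int) for g in groups])
    labels = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    kwargs = {}
    if weighting == "breslow-wilcoxon":
        kwargs["weightings"] = "wilcoxon"
    elif weighting != "mantel-cox":
        raise SurvivalError("bad-weighting", f"unknown weighting {weighting!r}")
    res = multivariate_logrank_test(durations, labels, events, **kwargs)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    params: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    log_likelihood: float
    converged: bool
    flags: list[str] = field(default_factory=list)

    def ci(self, alpha: float = 0.05) -> pd.DataFrame:
        zq = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({"low": self.params - zq * self.se,
                             "high": self.params + zq * self.se})


def _null_loglik(df: pd.DataFrame) -> float:
    """Efron partial log-likelihood of the covariate-free model."""
    t = df[TIME_COL].to_numpy(float)
    e = df[EVENT_COL].to_numpy(int)
    ll = 0.0
    for ti in np.unique(t[e == 1]):
        d = int(((t == ti) & (e == 1)).sum())
        n = int((t >= ti).sum())
        ll -= sum(np.log(n - l) for l in range(d))
    return ll


def _fit_cph(data: pd.DataFrame, covariates: list[str]
             ) -> tuple[CoxPHFitter, list[str]]:
    """Fit lifelines CoxPHFitter with a penalized fallback.

    Monotone likelihood (perfect separation) or a degenerate design makes
    the unpenalized Newton iteration diverge; a light ridge penalty caps
    the coefficients, and the result is flagged.
    """
    flags: list[str] = []
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data[[TIME_COL, EVENT_COL] + covariates],
                    TIME_COL, EVENT_COL)
    except ConvergenceError:
        flags.append("monotone-likelihood")
        cph = CoxPHFitter(penalizer=0.1)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(data[[TIME_COL, EVENT_COL] + covariates],
                        TIME_COL, EVENT_COL)
        except ConvergenceError as exc:
            raise SurvivalError("fit-failed",
                                f"Cox fit did not converge: {exc}") from exc
    return cph, flags


def cox_fit(records: pd.DataFrame, covariates: list[str]) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) via partial likelihood.

    Monotone likelihood (perfect separation) is flagged and the fit
    retried with a light ridge penalty so a capped coefficient is returned
    rather than a divergence.
    """
    df = _check_records(records)
    if int(df[EVENT_COL].sum()) == 0:
        raise SurvivalError("no-events", "need at least one event")
    if not covariates:
        empty = pd.Series(dtype=float)
        return CoxResult(params=empty, se=empty, z=empty, p=empty,
                         log_likelihood=_null_loglik(df), converged=True)
    data = df[[TIME_COL, EVENT_COL] + list(covariates)].dropna()
    cph, flags = _fit_cph(data, list(covariates))
    summ = cph.summary
    return CoxResult(params=cph.params_.copy(),
                     se=summ["se(coef)"].copy(),
                     z=summ["z"].copy(),
                     p=summ["p"].copy(),
                     log_likelihood=float(cph.log_likelihood_),
                     converged=not flags,
                     flags=flags)


def stepwise_wald(records: pd.DataFrame, candidates: list[str],
                  p_enter: float = 0.05, p_remove: float = 0.10
                  ) -> tuple[RiskModel, list[dict]]:
    """Forward-stepwise Cox selection with Wald entry/removal tests.

    At each forward step the candidate with the smallest Wald p (ties
    broken by declared order) enters if p < ``p_enter``; after each entry,
    included covariates with Wald p > ``p_remove`` are removed (worst
    first).  Returns the fitted model (identity coding over the selected
    columns) and the full selection path.
    """
    if p_enter > p_remove:
        raise SurvivalError("bad-thresholds", "need p_enter <= p_remove")
    included: list[str] = []
    path: list[dict] = []
    while True:
        remaining = [c for c in candidates if c not in included]
        best = None
        for cand in remaining:
            fit = cox_fit(records, included + [cand])
            p = float(fit.p[cand])
            if best is None or p < best[1] - 1e-15:
                best = (cand, p)
        if best is None or best[1] >= p_enter:
            break
        included.append(best[0])
        path.append({"step": "enter", "covariate": best[0], "p": best[1]})
        # backward sweep
        while len(included) > 1:
            fit = cox_fit(records, included)
            worst = fit.p[included].astype(float).idxmax()
            if float(fit.p[worst]) <= p_remove or worst == best[0]:
                break
            included.remove(worst)
            path.append({"step": "remove", "covariate": worst,
                         "p": float(fit.p[worst])})
    if not included:
        model = RiskModel(name="stepwise", coefficients={}, coding={})
        path.append({"step": "null-model", "covariate": None, "p": None})
        return model, path
    fit = cox_fit(records, included)
    model = RiskModel(
        name="stepwise",
        coefficients={c: float(fit.params[c]) for c in included},
        coding={c: CodingRule(c, "identity") for c in included},
    )
    return model, path


# --------------------------------------------------------------------------
# discrimination, thresholding, validation
# --------------------------------------------------------------------------

def harrell_c(records: pd.DataFrame, scores: np.ndarray | pd.Series) -> float:
    """Harrell's concordance of a *risk* score (higher = earlier event).

    Comparable pairs are those where the earlier time is an event; tied
    scores earn half credit.
    """
    df = _check_records(records)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(df):
        raise SurvivalError("bad-scores", "scores must align with records")
    try:
        return float(concordance_index(df[TIME_COL], -s, df[EVENT_COL]))
    except ZeroDivisionError:
        raise SurvivalError("no-comparable-pairs",
                            "no comparable pairs for concordance")


def threshold_search(scores: np.ndarray | pd.Series, records: pd.DataFrame,
                     min_group_fraction: float = 0.10
                     ) -> tuple[float, float, float]:
    """Best risk-score cut by Mantel-Cox separation.

    Scans the unique score values; a cut v splits low (score <= v) from
    high (score > v).  Admissible cuts leave at least
    ``min_group_fraction`` of patients on each side; among admissible cuts
    the one maximizing the Mantel-Cox statistic wins, ties going to the
    lower threshold.  Returns (threshold, statistic, p).
    """
    df = _check_records(records).reset_index(drop=True)
    s = np.asarray(scores, dtype=float)
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise SurvivalError("degenerate-scores", "need >= 2 distinct scores")
    n = len(df)
    best = None
    for v in uniq[:-1]:
        low = s <= v
        if low.sum() < min_group_fraction * n or \
                (~low).sum() < min_group_fraction * n:
            continue
        try:
            stat, p = logrank_test([df[low], df[~low]])
        except SurvivalError:
            continue
        if best is None or stat > best[1] + 1e-12:
            best = (float(v), float(stat), float(p))
    if best is None:
        raise SurvivalError("no-admissible-cut",
                            "no cut satisfies the group-size constraint")
    return best


def bootstrap_validate(records: pd.DataFrame, covariates: list[str],
                       B: int = 200, seed: int = 0) -> dict:
    """Harrell's bootstrap optimism correction of the C-index.

    For each resample: refit, evaluate C on the resample (C_boot) and on
    the original data (C_orig); optimism = mean(C_boot - C_orig);
    corrected C = apparent C - optimism.  Degenerate resamples (no events
    or failed fits) are skipped and counted.
    """
    if B < 1:
        raise SurvivalError("bad-b", "need B >= 1")
    df = _check_records(records).reset_index(drop=True)
    rng = np.random.default_rng(seed)

    def fit_scores(train: pd.DataFrame, test: pd.DataFrame) -> np.ndarray:
        if not covariates:
            return np.zeros(len(test))
        fit = cox_fit(train, covariates)
        return test[covariates].to_numpy(float) @ fit.params[covariates].to_numpy()

    apparent = harrell_c(df, fit_scores(df, df)) if covariates else 0.5
    optimisms = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, len(df), len(df))
        boot = df.iloc[idx].reset_index(drop=True)
        if boot[EVENT_COL].sum() == 0:
            skipped += 1
            continue
        try:
            sc_boot = fit_scores(boot, boot)
            sc_orig = fit_scores(boot, df)
            if covariates:
                c_boot = harrell_c(boot, sc_boot)
                c_orig = harrell_c(df, sc_orig)
            else:
                c_boot = c_orig = 0.5
        except SurvivalError:
            skipped += 1
            continue
        optimisms.append(c_boot - c_orig)
    if not optimisms:
        raise SurvivalError("degenerate-bootstrap", "all resamples degenerate")
    optimism = float(np.mean(optimisms))
    return {"apparent_c": float(apparent),
            "optimism": optimism,
            "corrected_c": float(apparent - optimism),
            "optimisms": [float(o) for o in optimisms],
            "replicates": len(optimisms),
            "skipped": skipped,
            "seed": seed}


def _censoring_survival(df: pd.DataFrame) -> KMEstimate:
    """KM of the censoring distribution (events and censorings swapped)."""
    cens = df.copy()
    cens[EVENT_COL] = 1 - cens[EVENT_COL]
    if cens[EVENT_COL].sum() == 0:
        # no censoring: G == 1 everywhere
        return KMEstimate(times=np.array([np.inf]), survival=np.array([1.0]),
                          variance=np.array([0.0]), median=None)
    return km_estimate(cens)


def _local_linear(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                  x0: np.ndarray, bandwidth: float) -> np.ndarray:
    """Weighted local-linear smooth of y on x, evaluated at x0."""
    out = np.empty(len(x0))
    for i, xi in enumerate(x0):
        k = w * np.exp(-0.5 * ((x - xi) / bandwidth) ** 2)
        sw = k.sum()
        if sw <= 0:
            out[i] = np.nan
            continue
        xm = (k * x).sum() / sw
        ym = (k * y).sum() / sw
        sxx = (k * (x - xm) ** 2).sum()
        if sxx < 1e-12:
            out[i] = ym
        else:
            slope = (k * (x - xm) * (y - ym)).sum() / sxx
            out[i] = ym + slope * (xi - xm)
    return out


def calibration_error(pred_prob: np.ndarray, records: pd.DataFrame,
                      horizon: float) -> tuple[float, float]:
    """ICI and E50 of predicted event probabilities at a horizon.

    The observed curve is a weighted local-linear smooth, over predicted
    probability, of inverse-censoring-weighted event indicators: subjects
    with an event by the horizon contribute 1 with weight 1/G(T-),
    subjects followed past the horizon contribute 0 with weight 1/G(h),
    and subjects censored before the horizon are excluded.  ICI is the
    mean and E50 the median absolute difference between predicted and
    smoothed observed probability.
    """
    df = _check_records(records).reset_index(drop=True)
    p = np.asarray(pred_prob, dtype=float)
    if len(p) != len(df):
        raise SurvivalError("bad-scores", "predictions must align with records")
    t = df[TIME_COL].to_numpy(float)
    e = df[EVENT_COL].to_numpy(int)
    G = _censoring_survival(df)
    y = np.zeros(len(df))
    w = np.zeros(len(df))
    for i in range(len(df)):
        if t[i] <= horizon and e[i] == 1:
            y[i] = 1.0
            w[i] = 1.0 / max(G.at(t[i] - 1e-9), 1e-6)
        elif t[i] > horizon:
            y[i] = 0.0
            w[i] = 1.0 / max(G.at(horizon), 1e-6)
    usable = w > 0
    if usable.sum() < 10:
        raise SurvivalError("too-few-usable", "not enough usable subjects")
    bw = max(0.9 * np.std(p[usable]) * usable.sum() ** (-0.2), 0.01)
    smoothed = _local_linear(p[usable], y[usable], w[usable], p[usable], bw)
    diff = np.abs(p[usable] - smoothed)
    diff = diff[np.isfinite(diff)]
    return float(np.mean(diff)), float(np.median(diff))


def _stratified_folds(df: pd.DataFrame, k: int, seed: int) -> np.ndarray:
    """Event-stratified fold assignment; fold sizes differ by <= 1."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(df), dtype=int)
    slots = []
    for val in (1, 0):
        idx = np.flatnonzero(df[EVENT_COL].to_numpy() == val)
        rng.shuffle(idx)
        slots.append(idx)
    counter = 0
    for idx in slots:
        for i in idx:
            fold[i] = counter % k
            counter += 1
    return fold


def crossvalidate(records: pd.DataFrame, covariates: list[str],
                  k: int = 5, horizon: float = 36.0, seed: int = 0) -> dict:
    """Event-stratified k-fold cross-validation of a Cox model.

    Per fold: fit on the training folds, score the held-out fold; C is
    averaged across folds.  Held-out predicted event probabilities at the
    horizon (from each fold model's baseline hazard) are pooled and
    compared with the smoothed observed probability to give ICI and E50.
    """
    if k < 2:
        raise SurvivalError("bad-k", "need k >= 2")
    df = _check_records(records).reset_index(drop=True).dropna(
        subset=[TIME_COL, EVENT_COL] + list(covariates)).reset_index(drop=True)
    fold = _stratified_folds(df, k, seed)
    cs = []
    pred = np.full(len(df), np.nan)
    for f in range(k):
        test = df[fold == f]
        train = df[fold != f]
        if test[EVENT_COL].sum() == 0 or train[EVENT_COL].sum() == 0:
            raise SurvivalError("fold-without-events",
                                "a fold has no events; use smaller k")
        cph, _ = _fit_cph(train, list(covariates))
        lp = test[covariates].to_numpy(float) @ cph.params_[covariates].to_numpy()
        cs.append(harrell_c(test, lp))
        sf = cph.predict_survival_function(test[covariates], times=[horizon])
        pred[fold == f] = 1.0 - sf.iloc[0].to_numpy(float)
    ici, e50 = calibration_error(pred, df, horizon)
    return {"mean_c": float(np.mean(cs)),
            "fold_c": [float(c) for c in cs],
            "ici": ici,
            "e50": e50,
            "horizon": horizon,
            "k": k,
            "seed": seed,
            "fold_sizes": [int((fold == f).sum()) for f in range(k)]}
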