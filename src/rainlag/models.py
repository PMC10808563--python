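"""Regularized model comparison: L1 logistic presence and L1 Poisson abundance.

Four model specifications are compared per outcome: an intercept-only null,
all 20 daily lags, daily lags plus the 10-day cumulative sum, and daily lags
plus the 20-day cumulative sum (cumulative-only variants are also available).
Sites (traps) are split 75/25 into training and testing so no trap
contributes to both; presence models are scored by AUC-ROC on the held-out
set, abundance models by RMSE of the Poisson mean on the count scale.

The L1 penalty is chosen by 5-fold cross-validation on the training set over
a log-spaced path.  Presence models fall back to an unpenalized fit when the
path does not improve validation loss.  Abundance predictors are centered
and scaled to unit variance before penalization so coefficients are
comparable; presence models are fit on raw inches.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .lags import LAG_COLUMNS

logger = logging.getLogger(__name__)

SPEC_PREDICTORS: dict[str, list[str]] = {
    "null": [],
    "daily": list(LAG_COLUMNS),
    "daily+cum10": list(LAG_COLUMNS) + ["cum10"],
    "daily+cum20": list(LAG_COLUMNS) + ["cum20"],
    "cum10-only": ["cum10"],
    "cum20-only": ["cum20"],
}

DEFAULT_SPECS = ("null", "daily", "daily+cum10", "daily+cum20")


@dataclasses.dataclass
class FittedSpec:
    spec: str
    outcome: str
    metric_name: str  # "AUC-ROC" or "RMSE"
    estimate: float
    n_train: int
    n_test: int
    penalty: float
    coefficients: dict[str, float]  # intercept + nonzero terms; zeros kept as 0.0


@dataclasses.dataclass
class CoefficientEstimate:
    term: str
    estimate: float
    ci_low: float
    ci_high: float
    replicates: int
    flag: str | None = None


def split_by_site(lagmatrix: pd.DataFrame, train_fraction: float = 0.75,
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign whole traps to train/test, targeting a 75% observation share.

    Traps are shuffled by the seed, then accumulated greedily into the
    training set; the final trap is kept or dropped, whichever lands the
    realized observation share closer to the target.  No trap appears in
    both sets.
    """
    traps = lagmatrix["trap_id"].astype(str)
    unique = np.array(sorted(traps.unique()))
    if unique.size < 2:
        raise ValueError("need at least 2 sites to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(unique.size)
    counts = traps.value_counts()
    total = len(lagmatrix)
    train_ids: list[str] = []
    acc = 0
    for idx in order:
        tid = unique[idx]
        c = int(counts[tid])
        if acc + c > train_fraction * total:
            # keep it only if including lands closer to the target share
            if abs((acc + c) / total - train_fraction) < abs(acc / total - train_fraction) \
                    and len(train_ids) < unique.size - 1:
                train_ids.append(tid)
                acc += c
            break
        train_ids.append(tid)
        acc += c
    if not train_ids:  # degenerate: first trap alone overshoots badly
        train_ids = [unique[order[0]]]
    train_set = set(train_ids)
    if len(train_set) == unique.size:
        train_set.discard(unique[order[-1]])
    mask = traps.isin(train_set).to_numpy()
    return lagmatrix[mask].reset_index(drop=True), lagmatrix[~mask].reset_index(drop=True)


def auc_roc(scores, labels) -> float:
    """AUC-ROC = P(score+ > score-) + 0.5 P(tie), by midranks.

    Exactly equals exhaustive pairwise concordance; ties (including an
    all-constant score vector) contribute one half, so an uninformative
    model scores 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both outcome classes")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def rmse(predicted, observed) -> float:
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("length mismatch")
    if predicted.size == 0:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


# ---------------------------------------------------------------------------
# fitting internals

_PRESENCE_C_PATH = np.logspace(-2, 2, 9)  # inverse penalty path for logistic
_ABUNDANCE_ALPHA_PATH = np.logspace(-4, 0, 5)  # L1 weight path for Poisson


def _check_design(X: np.ndarray, names: Sequence[str]) -> np.ndarray:
    """Mask of estimable (non-constant) columns.

    A fully dry lag day yields an all-zero column in arid data; such columns
    are inestimable and reported as eliminated (coefficient 0) rather than
    fatal.  Only a design with no varying predictor at all is an error.
    """
    varying = np.array([np.ptp(col) > 0.0 for col in X.T])
    if not varying.any():
        raise ValueError(f"constant predictor column(s): {list(names)}; "
                         "no varying predictors remain")
    dropped = [nm for nm, v in zip(names, varying) if not v]
    if dropped:
        logger.info("constant predictor column(s) eliminated: %s", dropped)
    return varying


def _kfold_indices(n: int, k: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    return np.array_split(idx, k)


def _fit_presence(X: np.ndarray, y: np.ndarray, seed: int,
                  k_folds: int = 5) -> tuple[float, np.ndarray, float]:
    """L1 logistic with CV-chosen penalty; returns (intercept, coefs, penalty).

    penalty is the L1 weight (0 means the unpenalized fallback won)."""
    if X.shape[1] == 0:
        p = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        return float(np.log(p / (1 - p))), np.zeros(0), 0.0
    rng = np.random.default_rng(seed)
    folds = _kfold_indices(len(y), k_folds, rng)
    losses = {}
    candidates = [0.0] + [1.0 / c for c in _PRESENCE_C_PATH]
    for pen in candidates:
        ll = 0.0
        ok = True
        for i in range(k_folds):
            val = folds[i]
            trn = np.concatenate([folds[j] for j in range(k_folds) if j != i])
            if y[trn].min() == y[trn].max():
                ok = False
                break
            mdl = _logit(X[trn], y[trn], pen)
            p = np.clip(mdl.predict_proba(X[val])[:, 1], 1e-12, 1 - 1e-12)
            ll += -np.sum(y[val] * np.log(p) + (1 - y[val]) * np.log(1 - p))
        losses[pen] = ll if ok else np.inf
    best_pen = min(candidates, key=lambda pen: (losses[pen], pen))
    if losses[best_pen] >= losses[0.0] - 1e-9:
        best_pen = 0.0  # regularization did not improve validation loss
    mdl = _logit(X, y, best_pen)
    return float(mdl.intercept_[0]), mdl.coef_[0].copy(), best_pen


def _logit(X, y, penalty: float) -> LogisticRegression:
    if penalty == 0.0:
        mdl = LogisticRegression(C=np.inf, max_iter=2000)
    else:
        mdl = LogisticRegression(l1_ratio=1.0, C=1.0 / penalty,
                                 solver="liblinear", max_iter=2000,
                                 random_state=0)
    return mdl.fit(X, y)


def _fit_abundance(X: np.ndarray, y: np.ndarray, seed: int,
                   k_folds: int = 5) -> tuple[float, np.ndarray, float]:
    """L1 Poisson GLM with CV-chosen penalty on standardized predictors.

    Returns (intercept, coefs, alpha) on the standardized scale used
    internally; callers receive predictions, not raw coefficients, unless
    they ask for the standardized ones.
    """
    if X.shape[1] == 0:
        return float(np.log(max(y.mean(), 1e-12))), np.zeros(0), 0.0
    rng = np.random.default_rng(seed)
    folds = _kfold_indices(len(y), k_folds, rng)
    devs = {}
    for alpha in _ABUNDANCE_ALPHA_PATH:
        dev = 0.0
        for i in range(k_folds):
            val = folds[i]
            trn = np.concatenate([folds[j] for j in range(k_folds) if j != i])
            params = _poisson_l1(X[trn], y[trn], alpha)
            mu = np.exp(np.clip(sm.add_constant(X[val], has_constant="add") @ params, -30, 30))
            dev += _poisson_deviance(y[val], mu)
        devs[alpha] = dev
    best_alpha = min(_ABUNDANCE_ALPHA_PATH, key=lambda a: (devs[a], a))
    params = _poisson_l1(X, y, best_alpha)
    return float(params[0]), params[1:].copy(), float(best_alpha)


def _poisson_l1(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    exog = sm.add_constant(X, has_constant="add")
    pen = np.full(exog.shape[1], alpha)
    pen[0] = 0.0  # never penalize the intercept
    model = sm.GLM(y, exog, family=sm.families.Poisson())
    res = model.fit_regularized(method="elastic_net", alpha=pen, L1_wt=1.0,
                                maxiter=200, cnvrg_tol=1e-7)
    return np.asarray(res.params, dtype=float)


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _standardize(train: np.ndarray, test: np.ndarray):
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (train - mean) / sd, (test - mean) / sd, mean, sd


def fit_model_suite(lagmatrix: pd.DataFrame, outcome: str,
                    specs: Sequence[str] = DEFAULT_SPECS,
                    seed: int = 0,
                    train_fraction: float = 0.75) -> list[FittedSpec]:
    """Fit and score every requested spec on a shared site-level split."""
    if outcome not in ("presence", "abundance"):
        raise ValueError("outcome must be 'presence' or 'abundance'")
    train, test = split_by_site(lagmatrix, train_fraction, seed)
    results = []
    for spec in specs:
        all_cols = SPEC_PREDICTORS[spec]
        if all_cols:
            mask = _check_design(train[all_cols].to_numpy(dtype=float), all_cols)
            cols = [c for c, v in zip(all_cols, mask) if v]
        else:
            cols = []
        Xtr = train[cols].to_numpy(dtype=float) if cols else np.empty((len(train), 0))
        Xte = test[cols].to_numpy(dtype=float) if cols else np.empty((len(test), 0))
        if outcome == "presence":
            y_tr = train["presence"].to_numpy(dtype=float)
            y_te = test["presence"].to_numpy(dtype=bool)
            b0, coefs, pen = _fit_presence(Xtr, y_tr, seed)
            scores = b0 + (Xte @ coefs if cols else np.zeros(len(test)))
            est = auc_roc(scores, y_te)
            metric = "AUC-ROC"
        else:
            y_tr = train["female_count"].to_numpy(dtype=float)
            y_te = test["female_count"].to_numpy(dtype=float)
            if cols:
                Xtr_s, Xte_s, _, _ = _standardize(Xtr, Xte)
            else:
                Xtr_s, Xte_s = Xtr, Xte
            b0, coefs, pen = _fit_abundance(Xtr_s, y_tr, seed)
            mu = np.exp(np.clip(b0 + (Xte_s @ coefs if cols else 0.0), -30, 30))
            mu = np.broadcast_to(mu, (len(test),))
            est = rmse(mu, y_te)
            metric = "RMSE"
        coef_map = {"intercept": b0}
        coef_map.update({nm: 0.0 for nm in all_cols})
        coef_map.update({nm: float(c) for nm, c in zip(cols, coefs)})
        results.append(FittedSpec(spec=spec, outcome=outcome, metric_name=metric,
                                  estimate=est, n_train=len(train),
                                  n_test=len(test), penalty=pen,
                                  coefficients=coef_map))
    return results


def nonzero_path_counts(lagmatrix: pd.DataFrame, spec: str = "daily",
                        penalties: Sequence[float] = (0.01, 0.1, 1.0, 10.0)) -> list[int]:
    """Nonzero-coefficient counts of the presence model along an L1 path."""
    cols = SPEC_PREDICTORS[spec]
    X = lagmatrix[cols].to_numpy(dtype=float)
    y = lagmatrix["presence"].to_numpy(dtype=float)
    return [int(np.sum(_logit(X, y, pen).coef_[0] != 0.0)) for pen in penalties]


def bootstrap_coefficients(lagmatrix: pd.DataFrame, spec: str = "daily",
                           outcome: str = "presence",
                           replicates: int = 1000, seed: int = 0,
                           cluster_by_site: bool = False) -> list[CoefficientEstimate]:
    """Percentile bootstrap CIs for the coefficients of one spec.

    The penalty is chosen once on the full data; each replicate resamples
    rows (or whole sites with ``cluster_by_site``) with replacement and
    refits at that penalty.  More than 10% failed replicates is an error.
    """
    cols = SPEC_PREDICTORS[spec]
    if not cols:
        raise ValueError("bootstrap needs a spec with predictors")
    mask = _check_design(lagmatrix[cols].to_numpy(dtype=float), cols)
    cols = [c for c, v in zip(cols, mask) if v]
    X = lagmatrix[cols].to_numpy(dtype=float)
    if outcome == "presence":
        y = lagmatrix["presence"].to_numpy(dtype=float)
        b0, coefs, pen = _fit_presence(X, y, seed)
    else:
        y = lagmatrix["female_count"].to_numpy(dtype=float)
        Xs, _, mean, sd = _standardize(X, X)
        b0, coefs, pen = _fit_abundance(Xs, y, seed)
        X = Xs
    point = np.concatenate([[b0], coefs])
    rng = np.random.default_rng(seed)
    n = len(y)
    site_ids = lagmatrix["trap_id"].to_numpy()
    sites = np.unique(site_ids)
    draws = np.empty((replicates, len(point)))
    failures = 0
    for r in range(replicates):
        if cluster_by_site:
            pick = rng.choice(sites, size=len(sites), replace=True)
            idx = np.concatenate([np.flatnonzero(site_ids == s) for s in pick])
        else:
            idx = rng.integers(0, n, size=n)
        try:
            if outcome == "presence":
                if y[idx].min() == y[idx].max():
                    raise ValueError("single class in replicate")
                mdl = _logit(X[idx], y[idx], pen)
                draws[r] = np.concatenate([[mdl.intercept_[0]], mdl.coef_[0]])
            else:
                params = _poisson_l1(X[idx], y[idx], pen)
                draws[r] = params
        except Exception:
            failures += 1
            draws[r] = np.nan
    if failures > 0.1 * replicates:
        raise RuntimeError(
            f"{failures}/{replicates} bootstrap replicates failed to converge")
    terms = ["intercept"] + list(cols)
    out = []
    degenerate = replicates < 2
    for j, term in enumerate(terms):
        col = draws[:, j]
        col = col[np.isfinite(col)]
        if degenerate or col.size < 2:
            out.append(CoefficientEstimate(term, float(point[j]), float(point[j]),
                                           float(point[j]), replicates,
                                           "degenerate"))
            continue
        lo, hi = np.percentile(col, [2.5, 97.5])
        out.append(CoefficientEstimate(term, float(point[j]), float(lo),
                                       float(hi), replicates))
    return out


def comparison_to_frame(results: list[FittedSpec]) -> pd.DataFrame:
    rows = [{"spec": r.spec, "outcome": r.outcome, "metric": r.metric_name,
             "estimate": r.estimate, "n_train": r.n_train, "n_test": r.n_test,
             "penalty": r.penalty} for r in results]
    return pd.DataFrame(rows)
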