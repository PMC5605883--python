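"""Ensemble estimation of cause-specific mortality with out-of-sample
predictive-validity weighting, plus a negative-binomial family for rare
causes.

The ensemble works on one cause (and sex) at a time.  A pool of candidate
regressions is enumerated systematically — every non-empty covariate subset
in each of two response spaces (log death rate, logit cause fraction).
Candidates must pass a screening rule: each coefficient carries its expected
sign and is significant at a configured level.  Survivors are scored by
cross-validation on held-out location-years, separately for *levels* (RMSE
of held-out log rates) and *trends* (RMSE of held-out year-on-year first
differences in log space), ranked on both, and combined with
rank-exponential weights.  Final estimates are draws: each draw picks a
model by weight, samples its coefficients from the fitted sampling
distribution, and adds observation noise (inflated where the source was
flagged non-representative).

Rare causes with very low counts use a negative-binomial count model on a
log-exposure offset instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .cube import DrawCube

RESPONSE_SPACES = ("log_rate", "logit_fraction")
LOGIT_EPS = 1e-6
RATE_FLOOR = 1e-12
DEFAULT_ALPHA = 0.05
DEFAULT_VARIANCE_INFLATION = 2.0


@dataclass(frozen=True)
class ModelSpec:
    """One candidate regression: covariate subset x response space."""

    covariates: tuple
    response: str = "log_rate"
    random_intercept: bool = False

    def __post_init__(self):
        if not self.covariates:
            raise ValueError("covariate subset must be non-empty")
        if self.response not in RESPONSE_SPACES:
            raise ValueError(f"unknown response space {self.response!r}")

    @property
    def model_id(self) -> str:
        tag = "re" if self.random_intercept else "fe"
        return f"{self.response}:{'+'.join(self.covariates)}:{tag}"


@dataclass
class FittedModel:
    spec: ModelSpec
    params: np.ndarray  # const + covariates
    cov_params: np.ndarray
    resid_var: float
    screen_ok: bool
    screen_reason: str = ""


@dataclass
class PVScore:
    """Out-of-sample predictive validity of one pool member."""

    model_id: str
    rmse_level: float
    rmse_trend: float
    combined_rank: float = np.nan
    weight: float = np.nan


def enumerate_models(covariates, max_models: int | None = None,
                     random_intercept: bool = False) -> list[ModelSpec]:
    """All non-empty covariate subsets crossed with both response spaces.

    Deterministic order: by subset size, then lexicographically, log-rate
    space first; capped at ``max_models`` if given.
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("need at least one covariate")
    subsets = chain.from_iterable(
        combinations(sorted(covariates), k) for k in range(1, len(covariates) + 1)
    )
    pool = [
        ModelSpec(sub, space, random_intercept)
        for sub in subsets
        for space in RESPONSE_SPACES
    ]
    pool.sort(key=lambda s: (len(s.covariates), s.covariates,
                             RESPONSE_SPACES.index(s.response)))
    return pool[:max_models] if max_models is not None else pool


def _response_vector(spec: ModelSpec, data: pd.DataFrame) -> np.ndarray:
    rate = np.maximum(data["deaths"].to_numpy(float)
                      / data["population"].to_numpy(float), RATE_FLOOR)
    if spec.response == "log_rate":
        return np.log(rate)
    if "envelope" not in data:
        raise ValueError("logit_fraction response needs an 'envelope' column")
    frac = data["deaths"].to_numpy(float) / data["envelope"].to_numpy(float)
    frac = np.clip(frac, LOGIT_EPS, 1.0 - LOGIT_EPS)
    return np.log(frac / (1.0 - frac))


def _design(spec: ModelSpec, data: pd.DataFrame) -> np.ndarray:
    return np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(float) for c in spec.covariates]
    )


def fit_model(spec: ModelSpec, data: pd.DataFrame,
              expected_signs: dict | None = None,
              alpha: float = DEFAULT_ALPHA) -> FittedModel:
    """Fit one candidate and apply the sign/significance screen.

    ``expected_signs`` maps covariate name -> +1/-1 (0 or absent = no
    constraint).  A model is retained only if every constrained coefficient
    has the expected sign and p < alpha.
    """
    y = _response_vector(spec, data)
    X = _design(spec, data)
    if spec.random_intercept and data["location"].nunique() > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, X, groups=data["location"].to_numpy()).fit(reml=False)
        params = np.asarray(res.fe_params)
        cov = np.asarray(res.cov_params())[: len(params), : len(params)]
        pvalues = np.asarray(res.pvalues)[: len(params)]
        resid_var = float(res.scale)
    else:
        res = sm.OLS(y, X).fit()
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        pvalues = np.asarray(res.pvalues)
        resid_var = float(res.mse_resid) if len(data) > X.shape[1] else 0.0

    ok, reason = True, ""
    expected_signs = expected_signs or {}
    for j, cname in enumerate(spec.covariates, start=1):
        want = expected_signs.get(cname, 0)
        if want == 0:
            continue
        if np.sign(params[j]) != np.sign(want):
            ok, reason = False, f"{cname}: wrong sign"
            break
        if pvalues[j] >= alpha:
            ok, reason = False, f"{cname}: not significant (p={pvalues[j]:.3g})"
            break
    return FittedModel(spec, params, cov, resid_var, ok, reason)


def predict_log_rate(fitted: FittedModel, data: pd.DataFrame,
                     params: np.ndarray | None = None) -> np.ndarray:
    """Point prediction on the log-rate scale (common scale for scoring)."""
    X = _design(fitted.spec, data)
    beta = fitted.params if params is None else params
    eta = X @ beta
    if fitted.spec.response == "log_rate":
        return eta
    frac = 1.0 / (1.0 + np.exp(-eta))
    rate = frac * data["envelope"].to_numpy(float) / data["population"].to_numpy(float)
    return np.log(np.maximum(rate, RATE_FLOOR))


def make_folds(data: pd.DataFrame, n_folds: int, seed: int) -> np.ndarray:
    """Random partition of location-years into folds (fold id per row)."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    ly = data[["location", "year"]].drop_duplicates().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ly))
    fold_of = np.empty(len(ly), dtype=int)
    fold_of[order] = np.arange(len(ly)) % n_folds
    ly = ly.assign(fold=fold_of)
    return data.merge(ly, on=["location", "year"], how="left")["fold"].to_numpy()


def _trend_errors(test: pd.DataFrame, y_obs: np.ndarray,
                  y_pred: np.ndarray) -> np.ndarray:
    """Observed-minus-predicted first differences for consecutive-year pairs
    within a location, both years held out."""
    df = test.assign(_obs=y_obs, _pred=y_pred).sort_values(["location", "year"])
    errs = []
    for _, g in df.groupby(["location"] + (["age"] if "age" in df else [])
                           + (["sex"] if "sex" in df else [])):
        yrs = g["year"].to_numpy()
        consec = np.flatnonzero(np.diff(yrs) == 1)
        if len(consec):
            d_obs = g["_obs"].to_numpy()[consec + 1] - g["_obs"].to_numpy()[consec]
            d_pred = g["_pred"].to_numpy()[consec + 1] - g["_pred"].to_numpy()[consec]
            errs.append(d_obs - d_pred)
    return np.concatenate(errs) if errs else np.array([])


def holdout_pv(pool, data: pd.DataFrame, n_folds: int, seed: int,
               expected_signs: dict | None = None,
               alpha: float = DEFAULT_ALPHA):
    """Score every pool member out of sample.

    Returns (scores, dropped) where ``scores`` is a list of
    :class:`PVScore` for models that passed screening on every training
    fold and ``dropped`` logs the rest.  Raises if nothing survives.
    """
    folds = make_folds(data, n_folds, seed)
    y_true = np.log(np.maximum(
        data["deaths"].to_numpy(float) / data["population"].to_numpy(float),
        RATE_FLOOR))
    scores, dropped = [], []
    for spec in pool:
        level_sq, trend_errs = [], []
        failed = None
        for f in range(n_folds):
            train, test = data[folds != f], data[folds == f]
            if not len(test):
                continue
            fitted = fit_model(spec, train, expected_signs, alpha)
            if not fitted.screen_ok:
                failed = fitted.screen_reason
                break
            pred = predict_log_rate(fitted, test)
            obs = y_true[folds == f]
            level_sq.append((pred - obs) ** 2)
            trend_errs.append(_trend_errors(test, obs, pred))
        if failed is not None:
            dropped.append({"model_id": spec.model_id, "reason": failed})
            continue
        lvl = float(np.sqrt(np.mean(np.concatenate(level_sq))))
        tre = np.concatenate(trend_errs)
        scores.append(PVScore(
            spec.model_id, lvl,
            float(np.sqrt(np.mean(tre**2))) if len(tre) else np.nan,
        ))
    if not scores:
        raise RuntimeError(
            "every candidate model failed the sign/significance screen; "
            "relax the expected-sign constraints or the significance level"
        )
    return scores, dropped


def ensemble_weights(scores, temperature: float = 1.0) -> np.ndarray:
    """Rank-exponential weights on the combined level/trend rank.

    Combined rank = mean of the level-RMSE rank and trend-RMSE rank
    (1 = best; missing trend scores rank worst); weight proportional to
    exp(-rank / temperature), normalised to sum to 1.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not scores:
        raise ValueError("no scored models")
    lvl = np.array([s.rmse_level for s in scores])
    tre = np.array([s.rmse_trend for s in scores])
    tre = np.where(np.isnan(tre), np.inf, tre)
    combined = (rankdata(lvl) + rankdata(tre)) / 2.0
    w = np.exp(-combined / temperature)
    w = w / w.sum()
    for s, r, wi in zip(scores, combined, w):
        s.combined_rank, s.weight = float(r), float(wi)
    return w


def predict_draws(fitted_models, weights, data: pd.DataFrame, n_draws: int,
                  seed: int, add_noise: bool = True,
                  variance_inflation: float = DEFAULT_VARIANCE_INFLATION,
                  cause: str = "cause") -> DrawCube:
    """Posterior draws of deaths for every row of ``data``.

    Each draw samples a model by ensemble weight, coefficients from the
    fitted sampling distribution, and (optionally) observation noise with
    the residual variance — inflated by ``variance_inflation`` for rows
    whose ``non_representative`` flag is set.
    """
    if n_draws < 2:
        raise ValueError("need at least 2 draws")
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
        raise ValueError("weights must be a probability vector")
    rng = np.random.default_rng(seed)
    choice = rng.choice(len(fitted_models), size=n_draws, p=weights)
    pop = data["population"].to_numpy(float)
    infl = np.ones(len(data))
    if "non_representative" in data:
        infl = np.where(data["non_representative"].to_numpy(bool),
                        variance_inflation, 1.0)
    out = np.empty((len(data), n_draws))
    for m, fitted in enumerate(fitted_models):
        cols = np.flatnonzero(choice == m)
        if not len(cols):
            continue
        betas = rng.multivariate_normal(
            fitted.params, fitted.cov_params, size=len(cols),
            check_valid="ignore", method="svd",
        )
        X = _design(fitted.spec, data)
        eta = X @ betas.T  # (n_cells, n_model_draws)
        if add_noise and fitted.resid_var > 0:
            eta = eta + rng.normal(
                0.0, np.sqrt(fitted.resid_var * infl)[:, None], size=eta.shape)
        if fitted.spec.response == "log_rate":
            rate = np.exp(eta)
        else:
            frac = 1.0 / (1.0 + np.exp(-eta))
            rate = frac * (data["envelope"].to_numpy(float) / pop)[:, None]
        out[:, cols] = rate * pop[:, None]
    index = pd.DataFrame({
        "location": data["location"].to_numpy(),
        "year": data["year"].to_numpy(),
        "age": data["age"].to_numpy() if "age" in data else 0,
        "sex": data["sex"].to_numpy() if "sex" in data else "both",
        "cause": cause,
    })
    return DrawCube(index, out)


def ensemble_predict_log_rate(fitted_models, weights,
                              data: pd.DataFrame) -> np.ndarray:
    """Weight-averaged point prediction of the ensemble on the log-rate
    scale."""
    weights = np.asarray(weights, dtype=float)
    preds = np.column_stack(
        [predict_log_rate(f, data) for f in fitted_models]
    )
    return preds @ weights


def partition_by_quality(data: pd.DataFrame, stars_by_location: dict,
                         threshold: int = 4) -> dict:
    """Data-rich / data-poor split.

    Locations rated at or above ``threshold`` stars form the data-rich
    group; their models see only data-rich rows.  Data-poor models keep all
    rows (borrowing strength from everywhere).
    """
    stars = data["location"].map(stars_by_location)
    if stars.isna().any():
        raise ValueError("star rating missing for some locations")
    rich = data[stars >= threshold].reset_index(drop=True)
    return {"data_rich": rich, "data_poor": data.reset_index(drop=True)}


def fit_negative_binomial(counts, exposure, n_draws: int = 1000, seed: int = 0):
    """Rare-cause rate estimation with a negative-binomial count model.

    Intercept-only NB2 regression of counts on a log-exposure offset.
    Returns a dict with the fitted ``rate`` (deaths per unit exposure),
    ``dispersion`` (NB2 alpha; 0 under the Poisson fallback), and ``draws``
    — parametric samples of the rate from the fitted sampling distribution.
    An all-zero series warns and returns zero draws.
    """
    y = np.asarray(counts)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    expo = np.broadcast_to(np.asarray(exposure, dtype=float), y.shape)
    if np.any(expo <= 0):
        raise ValueError("exposure must be positive")
    rng = np.random.default_rng(seed)
    if y.sum() == 0:
        warnings.warn("all-zero count series; returning zero-rate draws")
        return {"rate": 0.0, "dispersion": 0.0, "draws": np.zeros(n_draws)}
    X = np.ones((len(y), 1))
    offset = np.log(expo)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.NegativeBinomial(y, X, offset=offset).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.params)) or not np.all(
            np.isfinite(np.diag(res.cov_params()))
        ):
            raise RuntimeError("non-finite NB fit")
        beta0 = float(res.params[0])
        se0 = float(np.sqrt(res.cov_params()[0, 0]))
        dispersion = float(max(res.params[1], 0.0))
        if dispersion < 1e-3:
            # boundary: no overdispersion, Poisson is the degenerate limit
            raise RuntimeError("dispersion at boundary")
    except Exception:
        # Poisson fallback when the NB likelihood is degenerate (no
        # overdispersion to estimate)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        beta0 = float(res.params[0])
        se0 = float(res.bse[0])
        dispersion = 0.0
    draws = np.exp(rng.normal(beta0, se0, size=n_draws))
    return {"rate": float(np.exp(beta0)), "dispersion": dispersion, "draws": draws}
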