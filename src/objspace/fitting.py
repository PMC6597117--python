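"""Maximum-likelihood fitting and model comparison for the trace models.

Each session (one animal x one condition) is fit separately. The data enter
as the per-trial proportion q_t of exploration time allocated to slot 1's
object; the model's predicted proportion p_t gives a proportion-weighted
Bernoulli (cross-entropy) log-likelihood

    LL = sum_t [ q_t * ln p_t + (1 - q_t) * ln(1 - p_t) ]

so that the 50/50 chance model has LL = N * ln(1/2) independent of the
data, which the chance comparison presupposes. Predictions are clamped to
[1e-12, 1 - 1e-12] before taking logs. Optimization is multi-start
Nelder-Mead with alpha (and gamma) handled on the logit scale and m0 on the
log scale; beta is unconstrained, with heavy-tailed (Cauchy) start values.
Because beta = 0 reproduces chance exactly for any alpha, the optimum is
never allowed below the chance log-likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .memory_model import (
    MODEL_IDS,
    N_FREE_PARAMS,
    P_CLAMP,
    ModelParams,
    predict_proportions,
    session_trajectory,
    trials_to_arrays,
    _check_ordered,
)

#: Fitted |beta| at or above this value flags the session as an outlier;
#: such sessions are excluded from parameter summaries (but kept in the
#: information-criterion sums).
BETA_OUTLIER_THRESHOLD = 1000.0


class OptimizerFailure(RuntimeError):
    """Every optimization start failed; carries per-start diagnostics."""


def chance_log_likelihood(n_trials: int) -> float:
    """Log-likelihood of the model that always explores 50/50."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return n_trials * math.log(0.5)


def _cross_entropy_ll(q: np.ndarray, p: np.ndarray, w: np.ndarray | None = None) -> float:
    p = np.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    terms = q * np.log(p) + (1.0 - q) * np.log(1.0 - p)
    if w is not None:
        terms = w * terms
    return float(np.sum(terms))


def proportions_from_behavior(behavior: pd.DataFrame) -> np.ndarray:
    """Per-trial proportion for slot 1; NaN where total exploration is zero
    (such trials are skipped by the likelihood)."""
    t1 = behavior["time_obj1_s"].to_numpy(float)
    t2 = behavior["time_obj2_s"].to_numpy(float)
    total = t1 + t2
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(total > 0, t1 / np.where(total > 0, total, 1.0), np.nan)
    return q


def _align_behavior(behavior: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Align behavior rows to schedule trials on (day, trial_in_day)."""
    key = ["day", "trial_in_day"]
    merged = trials[key].merge(behavior, on=key, how="left", validate="one_to_one")
    if merged["time_obj1_s"].isna().any():
        missing = merged.loc[merged["time_obj1_s"].isna(), key].values.tolist()
        raise ValueError(f"behavior rows missing for trials {missing}")
    return merged


@dataclass
class FitResult:
    """Optimized parameters and fit diagnostics for one session."""

    params_opt: ModelParams
    ll_opt: float
    ll_chance: float
    pseudo_r2: float
    n_trials: int
    n_starts: int
    converged_fraction: float
    is_beta_outlier: bool

    @property
    def model_id(self) -> str:
        return self.params_opt.model_id

    @property
    def k(self) -> int:
        return self.params_opt.n_free

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.ll_opt

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n_trials) - 2 * self.ll_opt


class MemoryTraceModel(BaseEstimator):
    """Scikit-learn style estimator for one memory-trace model variant.

    Parameters
    ----------
    model_id : {"M1", "M2", "M3", "M4"}
        Model variant; M2/M3 add overnight forgetting, M3/M4 free the
        initial/attractor trace value m0.
    n_starts : int
        Number of random Nelder-Mead initializations (alpha, gamma ~ U(0,1)
        on the natural scale, beta ~ 5x standard Cauchy, m0 ~ U(0,1)). A
        deterministic chance start (alpha=0.5, beta=0) is always added.
    seed : int or None
        Seed for start sampling; fits are deterministic given the seed.

    Attributes (after ``fit``)
    --------------------------
    alpha_, beta_, gamma_, m0_ : fitted parameters (gamma_/m0_ None or 0
        where the model fixes them); params_ is the full ModelParams.
    ll_, ll_chance_, pseudo_r2_ : optimal log-likelihood, chance
        log-likelihood N*ln(1/2), and 1 - ll_/ll_chance_.
    n_trials_, converged_fraction_, is_beta_outlier_ : diagnostics.
    """

    def __init__(self, model_id: str = "M1", n_starts: int = 100,
                 seed: int | None = None):
        self.model_id = model_id
        self.n_starts = n_starts
        self.seed = seed

    # -- parameter-vector transforms ------------------------------------
    def _unpack(self, x: np.ndarray) -> ModelParams:
        from scipy.special import expit

        alpha = float(expit(x[0]))
        beta = float(x[1])
        gamma = m0 = None
        i = 2
        if self.model_id in ("M2", "M3"):
            gamma = float(expit(x[i]))
            i += 1
        if self.model_id in ("M3", "M4"):
            m0 = float(math.exp(min(x[i], 50.0)))
        return ModelParams(self.model_id, alpha, beta, gamma, m0 if m0 is not None else 0.0)

    def _sample_start(self, rng: np.random.Generator) -> np.ndarray:
        def logit(u: float) -> float:
            return math.log(u / (1.0 - u))

        x = [logit(rng.uniform(1e-6, 1.0 - 1e-6)), 5.0 * rng.standard_cauchy()]
        if self.model_id in ("M2", "M3"):
            x.append(logit(rng.uniform(1e-6, 1.0 - 1e-6)))
        if self.model_id in ("M3", "M4"):
            x.append(math.log(rng.uniform(1e-3, 1.0)))
        return np.asarray(x)

    # -- core -----------------------------------------------------------
    def fit(self, X, y, sample_weight: np.ndarray | None = None):
        """Fit by multi-start maximum likelihood.

        X: ordered session trials (DataFrame with day/trial_in_day/
        loc_slot1/loc_slot2, TrialConfig sequence, or (n,3) int array of
        day/loc1/loc2). y: per-trial exploration proportions for slot 1's
        object in [0, 1]; NaN entries (unexplored trials) are skipped.
        """
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"model_id must be one of {MODEL_IDS}")
        _check_ordered(X)
        days, l1, l2 = trials_to_arrays(X)
        q = np.asarray(y, dtype=float)
        if q.shape != (len(days),):
            raise ValueError(
                f"y has length {q.size}, expected one proportion per trial ({len(days)})"
            )
        mask = ~np.isnan(q)
        if not mask.any():
            raise ValueError("no explored trials: all proportions are NaN")
        if np.nanmin(q) < 0 or np.nanmax(q) > 1:
            raise ValueError("proportions must lie in [0, 1]")
        w = None
        if sample_weight is not None:
            w = np.asarray(sample_weight, dtype=float)[mask]
        qm = q[mask]
        model_id = self.model_id

        def neg_ll(x: np.ndarray) -> float:
            p = self._unpack(x)
            _, _, pr = session_trajectory(
                days, l1, l2, model_id, p.alpha, p.beta, p.gamma, p.m0
            )
            return -_cross_entropy_ll(qm, np.asarray(pr)[mask], w)

        rng = np.random.default_rng(self.seed)
        dim = 2 + (model_id in ("M2", "M3")) + (model_id in ("M3", "M4"))
        starts = [np.zeros(dim)]  # alpha=0.5, beta=0 (chance), gamma=0.5, m0=1
        starts += [self._sample_start(rng) for _ in range(max(0, self.n_starts - 1))]

        best_x = None
        best_f = math.inf
        n_ok = 0
        errors: list[str] = []
        for x0 in starts:
            try:
                res = optimize.minimize(
                    neg_ll, x0, method="Nelder-Mead",
                    options={"maxiter": 300 * dim, "xatol": 1e-4, "fatol": 1e-7},
                )
            except (FloatingPointError, ValueError) as exc:  # pragma: no cover
                errors.append(str(exc))
                continue
            n_ok += res.success
            if np.isfinite(res.fun) and res.fun < best_f:
                best_f = res.fun
                best_x = res.x
        if best_x is None:
            raise OptimizerFailure(
                f"all {len(starts)} starts failed; first errors: {errors[:3]}"
            )

        if w is None:
            ll_chance = int(mask.sum()) * math.log(0.5)
        else:
            ll_chance = float(np.sum(w)) * math.log(0.5)
        ll = -best_f
        params = self._unpack(best_x)
        if ll < ll_chance:
            # beta = 0 reproduces chance exactly for any alpha; never report worse.
            gamma = 1.0 if model_id in ("M2", "M3") else None
            m0 = 0.0
            params = ModelParams(model_id, 0.5, 0.0, gamma, m0)
            ll = ll_chance

        self.params_ = params
        self.alpha_ = params.alpha
        self.beta_ = params.beta
        self.gamma_ = params.gamma
        self.m0_ = params.m0
        self.ll_ = ll
        self.ll_chance_ = ll_chance
        self.pseudo_r2_ = 1.0 - ll / ll_chance
        self.n_trials_ = int(mask.sum())
        self.n_starts_ = len(starts)
        self.converged_fraction_ = n_ok / len(starts)
        self.is_beta_outlier_ = abs(params.beta) >= BETA_OUTLIER_THRESHOLD
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted exploration proportions for slot 1's object."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "params_")
        return predict_proportions(X, self.params_)

    def score(self, X, y) -> float:
        """Mean per-trial log-likelihood of y under the fitted model."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "params_")
        q = np.asarray(y, dtype=float)
        mask = ~np.isnan(q)
        p = self.predict(X)[mask]
        return _cross_entropy_ll(q[mask], p) / int(mask.sum())

    def fit_result_(self) -> FitResult:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "params_")
        return FitResult(
            params_opt=self.params_,
            ll_opt=self.ll_,
            ll_chance=self.ll_chance_,
            pseudo_r2=self.pseudo_r2_,
            n_trials=self.n_trials_,
            n_starts=self.n_starts_,
            converged_fraction=self.converged_fraction_,
            is_beta_outlier=self.is_beta_outlier_,
        )


def session_log_likelihood(behavior_record: pd.DataFrame, schedule_trials,
                           params: ModelParams,
                           time_weighted: bool = False) -> float:
    """Cross-entropy log-likelihood of one session under fixed parameters.

    Trials with zero total exploration contribute nothing (they are
    skipped). With ``time_weighted``, each trial's term is multiplied by
    its total exploration seconds.
    """
    trials = _trials_frame(schedule_trials)
    behavior = _align_behavior(behavior_record, trials)
    q = proportions_from_behavior(behavior)
    mask = ~np.isnan(q)
    p = predict_proportions(trials, params)
    w = None
    if time_weighted:
        w = (behavior["time_obj1_s"] + behavior["time_obj2_s"]).to_numpy(float)[mask]
    return _cross_entropy_ll(q[mask], p[mask], w)


def _trials_frame(schedule_trials) -> pd.DataFrame:
    if isinstance(schedule_trials, pd.DataFrame):
        return schedule_trials
    from .schedule import Schedule

    if isinstance(schedule_trials, Schedule):
        return schedule_trials.to_frame()
    return pd.DataFrame(
        {
            "day": [t.day for t in schedule_trials],
            "trial_in_day": [t.trial_in_day for t in schedule_trials],
            "loc_slot1": [t.loc_slot1 for t in schedule_trials],
            "loc_slot2": [t.loc_slot2 for t in schedule_trials],
        }
    )


def fit_session(behavior_record: pd.DataFrame, schedule_trials,
                model_id: str = "M1", n_starts: int = 100,
                seed: int | None = None,
                time_weighted: bool = False) -> FitResult:
    """Fit one model to one session; thin wrapper over MemoryTraceModel."""
    trials = _trials_frame(schedule_trials)
    behavior = _align_behavior(behavior_record, trials)
    q = proportions_from_behavior(behavior)
    w = None
    if time_weighted:
        w = (behavior["time_obj1_s"] + behavior["time_obj2_s"]).to_numpy(float)
    est = MemoryTraceModel(model_id=model_id, n_starts=n_starts, seed=seed)
    est.fit(trials, q, sample_weight=w)
    return est.fit_result_()


def likelihood_ratio_vs_chance(fit_result: FitResult) -> tuple[float, float]:
    """LR statistic 2*(LL_opt - LL_chance) and chi-square p-value with df =
    the model's free-parameter count."""
    stat = max(0.0, 2.0 * (fit_result.ll_opt - fit_result.ll_chance))
    p = float(stats.chi2.sf(stat, df=fit_result.k))
    return stat, p


def information_criteria(fit_results: Sequence[FitResult],
                         model_id: str | None = None) -> tuple[float, float]:
    """Summed per-session AIC and BIC over a set of same-model fits."""
    fits = list(fit_results)
    if not fits:
        raise ValueError("information_criteria requires at least one fit")
    mid = model_id or fits[0].model_id
    if any(f.model_id != mid for f in fits):
        raise ValueError("all fits must share the same model_id")
    return sum(f.aic for f in fits), sum(f.bic for f in fits)


def fits_frame(fits: Iterable[tuple[str, str, FitResult]]) -> pd.DataFrame:
    """Tidy fits table: one row per (animal, condition, model) fit."""
    rows = []
    for animal_id, condition, fr in fits:
        lr_stat, lr_p = likelihood_ratio_vs_chance(fr)
        rows.append(
            {
                "animal_id": animal_id,
                "condition": condition,
                "model": fr.model_id,
                "alpha": fr.params_opt.alpha,
                "beta": fr.params_opt.beta,
                "gamma": fr.params_opt.gamma,
                "m0": fr.params_opt.m0,
                "ll": fr.ll_opt,
                "ll_chance": fr.ll_chance,
                "pseudo_r2": fr.pseudo_r2,
                "aic": fr.aic,
                "bic": fr.bic,
                "lr_stat": lr_stat,
                "lr_p": lr_p,
                "beta_outlier": fr.is_beta_outlier,
            }
        )
    return pd.DataFrame(rows)


def fit_dataset(dataset, model_id: str = "M1", n_starts: int = 100,
                seed: int = 0) -> pd.DataFrame:
    """Fit one model to every session of a dataset; returns the fits table."""
    sessions = list(dataset.sessions())
    rng = np.random.default_rng(seed)
    out = []
    for sess in sessions:
        fr = fit_session(sess.behavior, sess.trials, model_id=model_id,
                         n_starts=n_starts, seed=int(rng.integers(2**31)))
        out.append((sess.animal_id, sess.condition, fr))
    return fits_frame(out)


def compare_models(dataset, model_ids: Sequence[str] = MODEL_IDS,
                   n_starts: int = 100, seed: int = 0) -> pd.DataFrame:
    """Fit every model to every session and tabulate the comparison.

    One row per model: parameter means/SEMs across sessions (excluding
    |beta| >= 1000 outlier sessions), mean LL and pseudo-R^2, summed AIC
    and BIC, and winner flags for the lowest total of each criterion.
    """
    sessions = list(dataset.sessions())
    if not sessions:
        raise ValueError("dataset contains no sessions")
    rng = np.random.default_rng(seed)
    session_seeds = [int(rng.integers(2**31)) for _ in sessions]
    rows = []
    for mid in model_ids:
        fits = [
            fit_session(s.behavior, s.trials, model_id=mid,
                        n_starts=n_starts, seed=session_seeds[i])
            for i, s in enumerate(sessions)
        ]
        aic_total, bic_total = information_criteria(fits, mid)
        kept = [f for f in fits if not f.is_beta_outlier] or fits

        def msem(values: list[float | None]) -> tuple[float, float]:
            vals = pd.Series([v for v in values if v is not None], dtype=float)
            if vals.empty:
                return float("nan"), float("nan")
            return float(vals.mean()), float(vals.sem())

        mean_a, sem_a = msem([f.params_opt.alpha for f in kept])
        mean_b, sem_b = msem([f.params_opt.beta for f in kept])
        mean_g, sem_g = msem([f.params_opt.gamma for f in kept])
        mean_m, sem_m = msem(
            [f.params_opt.m0 for f in kept] if mid in ("M3", "M4") else []
        )
        rows.append(
            {
                "model": mid,
                "n_sessions": len(fits),
                "n_beta_outliers": sum(f.is_beta_outlier for f in fits),
                "mean_alpha": mean_a, "sem_alpha": sem_a,
                "mean_beta": mean_b, "sem_beta": sem_b,
                "mean_gamma": mean_g, "sem_gamma": sem_g,
                "mean_m0": mean_m, "sem_m0": sem_m,
                "mean_ll": float(np.mean([f.ll_opt for f in fits])),
                "aic_total": aic_total,
                "bic_total": bic_total,
                "mean_pseudo_r2": float(np.mean([f.pseudo_r2 for f in fits])),
            }
        )
    table = pd.DataFrame(rows)
    table["aic_winner"] = table["aic_total"] == table["aic_total"].min()
    table["bic_winner"] = table["bic_total"] == table["bic_total"].min()
    return table
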