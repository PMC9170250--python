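"""Maximum-likelihood fitting and comparison of observer models.

The estimator :class:`CausalInferenceObserver` fits the causal-inference
ideal observer (or one of its restricted alternatives) to one subject's
trial data by staged maximum likelihood:

1. sensory stage - the unisensory localization trials identify the sensory
   noise SDs (auditory, and visual per reliability) through cumulative-
   Gaussian psychometric fits, exactly the model-implied MLE when the
   natural priors are centered;
2. inference stage - the multisensory trials identify the causal prior
   ``p_common``, the implicit choice prior, the explicit criterion
   ``p_combined`` and the lapse parameters by bounded multi-start
   quasi-Newton optimization of the Bernoulli trial likelihood, with
   response probabilities from :mod:`causalcue.observer`.

Model variants:

* ``full_CI``            - all inference/choice parameters free;
* ``alt_A_forced_fusion`` - p_common fixed at 1 (always integrate);
* ``alt_B_no_fusion``     - p_common fixed at 0 (never integrate);
* ``alt_C_no_lapse_bias`` - lapse bias fixed at 1/2;
* ``alt_D_choice_only``   - sensory and inference parameters frozen to a
  reference fit; only choice parameters (lapse rate/bias and, for implicit
  tasks, the choice prior) are free.

Model comparison uses AIC; absolute goodness of fit uses explainable
variance explained (EVE), which normalizes the model's error on
per-condition response proportions by the variance that is explainable
given binomial sampling noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .observer import (
    _cells_prob_explicit,
    _cells_prob_implicit,
    response_prob_unisensory,
)
from .params import ObserverParams, QuadratureSpec
from .psychometrics import PsychometricFunction
from .simulate import ResponseData, simulate_observer

__all__ = [
    "FitConfig",
    "FittedModel",
    "CausalInferenceObserver",
    "negative_log_likelihood",
    "fit_subject",
    "fit_aggregate",
    "compare_models",
    "explainable_variance_explained",
    "eve_from_proportions",
    "bootstrap_ci",
    "parameter_recovery_report",
    "VARIANTS",
]

_PROB_EPS = 1e-9

VARIANTS = (
    "full_CI",
    "alt_A_forced_fusion",
    "alt_B_no_fusion",
    "alt_C_no_lapse_bias",
    "alt_D_choice_only",
)

#: Parameter bounds for the inference-stage optimizer.
_BOUNDS = {
    "p_common": (0.0, 1.0),
    "p_choice_implicit": (1e-3, 1.0 - 1e-3),
    "p_combined": (1e-3, 1.0 - 1e-3),
    "lapse_rate": (0.0, 0.5),
    "lapse_bias": (0.0, 1.0),
    "sigma_a": (0.1, 60.0),
    "sigma_v.high": (0.1, 60.0),
    "sigma_v.medium": (0.1, 60.0),
    "sigma_v.low": (0.1, 60.0),
}

#: Default optimizer start per parameter (first multi-start).
_START = {
    "p_common": 0.5,
    "p_choice_implicit": 0.5,
    "p_combined": 0.5,
    "lapse_rate": 0.05,
    "lapse_bias": 0.5,
    "sigma_a": 5.0,
    "sigma_v.high": 2.0,
    "sigma_v.medium": 5.0,
    "sigma_v.low": 12.0,
}


def _get_param(params: ObserverParams, name: str):
    if name.startswith("sigma_v."):
        return params.sigma_v[name.split(".", 1)[1]]
    return getattr(params, name)


def _with_params(params: ObserverParams, names, values) -> ObserverParams:
    plain = {}
    sigma_v = None
    for n, v in zip(names, values):
        if n.startswith("sigma_v."):
            if sigma_v is None:
                sigma_v = dict(params.sigma_v)
            sigma_v[n.split(".", 1)[1]] = float(v)
        else:
            plain[n] = float(v)
    if sigma_v is not None:
        plain["sigma_v"] = sigma_v
    return params.replace(**plain)


@dataclass
class FitConfig:
    """Tunables of the fitting procedure.

    ``n_starts`` seeded multi-starts of the bounded quasi-Newton optimizer;
    ``quad`` controls the response-probability marginalization; ``n_boot``
    bootstrap resamples for 68% CIs (0 disables CI computation).
    """

    n_starts: int = 20
    quad: QuadratureSpec = field(default_factory=lambda: QuadratureSpec(order=41, bisect_iters=48))
    tol: float = 1e-8
    maxiter: int = 200
    joint_sensory: bool = True
    n_boot: int = 0
    ci_level: float = 0.68
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.quad, dict):
            self.quad = QuadratureSpec(**self.quad)
        self.quad.validate()


@dataclass
class FittedModel:
    """A fitted observer model with its fit statistics."""

    params: ObserverParams
    variant: str
    nll: float
    aic: float
    eve: Optional[float]
    ci68: Optional[Dict[str, Tuple[float, float]]]
    n_free_params: int
    free_names: Tuple[str, ...] = ()
    data_hash: Optional[int] = None
    nll_by_start: Tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "params": self.params.to_dict(),
            "nll": self.nll,
            "aic": self.aic,
            "eve": self.eve,
            "ci68": self.ci68,
            "n_free_params": self.n_free_params,
            "free_names": list(self.free_names),
            "data_hash": self.data_hash,
        }


# --------------------------------------------------------------------------
# Cell aggregation and the trial likelihood
# --------------------------------------------------------------------------

def _data_hash(trials: pd.DataFrame) -> int:
    cols = ["experiment", "condition", "eps_a", "eps_v", "reliability", "delta", "response"]
    df = trials[cols].sort_values(cols, ignore_index=True)
    return int(pd.util.hash_pandas_object(df, index=False).sum() % (2**63))


def _build_cells(trials: pd.DataFrame) -> dict:
    """Aggregate trials into unique stimulus cells with positive-response
    counts; the Bernoulli likelihood only needs one probability per cell."""
    cells: dict = {}
    t = trials
    uni_a = t[t["condition"] == "auditory_only"]
    if len(uni_a):
        g = uni_a.groupby("eps_a")["response"].agg([lambda r: (r == 1).sum(), "size"])
        cells[("uni_a", None)] = (
            g.index.to_numpy(float),
            g.iloc[:, 0].to_numpy(float),
            g.iloc[:, 1].to_numpy(float),
        )
    for rel in ("high", "medium", "low"):
        uni_v = t[(t["condition"] == "visual_only") & (t["reliability"] == rel)]
        if len(uni_v):
            g = uni_v.groupby("eps_v")["response"].agg([lambda r: (r == 1).sum(), "size"])
            cells[("uni_v", rel)] = (
                g.index.to_numpy(float),
                g.iloc[:, 0].to_numpy(float),
                g.iloc[:, 1].to_numpy(float),
            )
        for kind, exps in (("implicit", ("exp1", "exp2")), ("explicit", ("exp3",))):
            av = t[
                (t["condition"] == "audio_visual")
                & (t["reliability"] == rel)
                & t["experiment"].isin(exps)
            ]
            if len(av):
                g = av.groupby(["eps_a", "eps_v"])["response"].agg(
                    [lambda r: (r == 1).sum(), "size"]
                )
                ea = np.array([i[0] for i in g.index], float)
                ev = np.array([i[1] for i in g.index], float)
                cells[(kind, rel)] = (
                    (ea, ev),
                    g.iloc[:, 0].to_numpy(float),
                    g.iloc[:, 1].to_numpy(float),
                )
    return cells


def _cell_probs(params: ObserverParams, cells: dict, quad: QuadratureSpec):
    """Model probability of the positive response for every cell."""
    out = {}
    for key, (stim, k, n) in cells.items():
        kind, rel = key
        if kind == "uni_a":
            p = response_prob_unisensory(stim, params, "auditory")
        elif kind == "uni_v":
            p = response_prob_unisensory(stim, params, "visual", rel)
        elif kind == "implicit":
            p = _cells_prob_implicit(stim[0], stim[1], params, rel, quad)
        else:
            p = _cells_prob_explicit(stim[0], stim[1], params, rel, quad)
        out[key] = np.asarray(p, float)
    return out


def _nll_from_cells(params, cells, quad) -> float:
    probs = _cell_probs(params, cells, quad)
    nll = 0.0
    for key, (stim, k, n) in cells.items():
        p = np.clip(probs[key], _PROB_EPS, 1.0 - _PROB_EPS)
        nll -= float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))
    return nll


def negative_log_likelihood(params: ObserverParams, data, quad: QuadratureSpec = None) -> float:
    """Bernoulli negative log-likelihood of a dataset under the observer.

    Localization trials (exp1/exp2, unisensory and audio-visual) use the
    implicit rule; exp3 trials the explicit rule.  Synchrony (exp4) trials
    are handled by the descriptive Gaussian layer, not this likelihood.
    """
    trials = data.trials if isinstance(data, ResponseData) else data
    bad = set(trials["experiment"].unique()) - {"exp1", "exp2", "exp3"}
    if bad:
        raise ValueError(f"likelihood undefined for experiments {sorted(bad)}")
    quad = (quad or QuadratureSpec()).validate()
    params.validate()
    return _nll_from_cells(params, _build_cells(trials), quad)


# --------------------------------------------------------------------------
# The estimator
# --------------------------------------------------------------------------

class CausalInferenceObserver(BaseEstimator):
    """Sklearn-style estimator for the causal-inference observer model.

    Parameters
    ----------
    variant : str
        One of :data:`VARIANTS`.
    config : FitConfig, optional
    base_params : ObserverParams, optional
        Starting/frozen parameter set.  Required for ``alt_D_choice_only``
        (its sensory and inference parameters are frozen to this).

    Attributes
    ----------
    params_ : ObserverParams
        Fitted parameter set.
    nll_, aic_, eve_ : float
    ci68_ : dict or None
        Percentile bootstrap intervals per free parameter.
    result_ : FittedModel
    """

    def __init__(self, variant="full_CI", config=None, base_params=None):
        self.variant = variant
        self.config = config
        self.base_params = base_params

    # -- variant bookkeeping ----------------------------------------------
    def _free_names(self, has_implicit, has_explicit) -> List[str]:
        v = self.variant
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        names: List[str] = []
        if v == "alt_D_choice_only":
            names = ["lapse_rate", "lapse_bias"]
            if has_implicit:
                names.append("p_choice_implicit")
            return names
        if has_implicit:
            if v not in ("alt_A_forced_fusion", "alt_B_no_fusion"):
                names.append("p_common")
            names.append("p_choice_implicit")
        if has_explicit:
            names.append("p_combined")
        names.append("lapse_rate")
        if v != "alt_C_no_lapse_bias":
            names.append("lapse_bias")
        return names

    def _fixed(self) -> dict:
        return {
            "alt_A_forced_fusion": {"p_common": 1.0},
            "alt_B_no_fusion": {"p_common": 0.0},
            "alt_C_no_lapse_bias": {"lapse_bias": 0.5},
        }.get(self.variant, {})

    # -- stages ------------------------------------------------------------
    @staticmethod
    def _fit_sensory(trials: pd.DataFrame, params: ObserverParams) -> Tuple[ObserverParams, int]:
        """Unisensory psychometric stage; returns params and #fitted sigmas."""
        n_sensory = 0
        uni_a = trials[trials["condition"] == "auditory_only"]
        if len(uni_a):
            f = PsychometricFunction(lapse_mode="rate_only").fit(
                uni_a["eps_a"].to_numpy(float), (uni_a["response"] == 1).to_numpy(float)
            )
            params = params.replace(sigma_a=float(f.sigma_))
            n_sensory += 1
        sigma_v = dict(params.sigma_v)
        for rel in ("high", "medium", "low"):
            uni_v = trials[(trials["condition"] == "visual_only") & (trials["reliability"] == rel)]
            if len(uni_v):
                f = PsychometricFunction(lapse_mode="rate_only").fit(
                    uni_v["eps_v"].to_numpy(float), (uni_v["response"] == 1).to_numpy(float)
                )
                sigma_v[rel] = float(f.sigma_)
                n_sensory += 1
        return params.replace(sigma_v=sigma_v), n_sensory

    def _optimize(self, cells, names, start_params, cfg) -> Tuple[ObserverParams, float, list]:
        fixed = self._fixed()
        base = start_params
        for k, v in fixed.items():
            base = base.replace(**{k: v})
        if not names:
            return base, _nll_from_cells(base, cells, cfg.quad), []

        def make(theta) -> ObserverParams:
            return _with_params(base, names, theta)

        def nll(theta):
            return _nll_from_cells(make(theta), cells, cfg.quad)

        bounds = [_BOUNDS[n] for n in names]
        rng = np.random.default_rng(cfg.seed)
        starts = [np.array([np.clip(_get_param(base, n), *_BOUNDS[n]) for n in names])]
        starts.append(np.array([_START[n] for n in names]))
        while len(starts) < max(cfg.n_starts, 1):
            starts.append(np.array([rng.uniform(*_BOUNDS[n]) for n in names]))
        starts = starts[: max(cfg.n_starts, 1)]

        best = None
        nll_by_start = []
        for s in starts:
            res = minimize(
                nll, s, method="L-BFGS-B", bounds=bounds,
                options={"ftol": cfg.tol, "maxiter": cfg.maxiter},
            )
            nll_by_start.append(float(res.fun))
            key = (res.fun, float(np.linalg.norm(res.x)))
            if best is None or key < best[0]:
                best = (key, res)
        res = best[1]
        if not np.isfinite(res.fun):
            raise RuntimeError("observer fit did not converge from any start")
        return make(res.x), float(res.fun), nll_by_start

    # -- the sklearn surface ----------------------------------------------
    def fit(self, data: ResponseData, y=None):
        cfg = self.config or FitConfig()
        trials = data.trials if isinstance(data, ResponseData) else data
        trials = trials[trials["experiment"].isin(["exp1", "exp2", "exp3"])]
        if not len(trials):
            raise ValueError("no exp1/exp2/exp3 trials to fit")
        has_implicit = bool(
            len(trials[(trials["condition"] == "audio_visual") & (trials["experiment"] != "exp3")])
        )
        has_explicit = bool(len(trials[trials["experiment"] == "exp3"]))

        start = self.base_params or ObserverParams()
        if self.variant == "alt_D_choice_only":
            if self.base_params is None:
                raise ValueError("alt_D_choice_only requires base_params (a reference fit)")
            params, n_sensory = start, 0
        else:
            has_uni = bool(len(trials[trials["condition"] != "audio_visual"]))
            if not has_uni and self.base_params is None:
                raise ValueError(
                    "sensory parameters are unconstrained: include exp1 unisensory "
                    "trials or pass base_params with known sensory noise"
                )
            params, n_sensory = self._fit_sensory(trials, start)

        names = self._free_names(has_implicit, has_explicit)
        sensory_names = []
        if self.variant != "alt_D_choice_only" and (self.config or FitConfig()).joint_sensory:
            # refine the psychometric-stage sigmas jointly with the
            # inference parameters (the multisensory trials also carry
            # sensory information); only sigmas with unisensory data are
            # freed, so they stay identified
            if len(trials[trials["condition"] == "auditory_only"]):
                sensory_names.append("sigma_a")
            for rel in ("high", "medium", "low"):
                if len(trials[(trials["condition"] == "visual_only")
                              & (trials["reliability"] == rel)]):
                    sensory_names.append(f"sigma_v.{rel}")
        names = sensory_names + names
        cells = _build_cells(trials)
        params, nll, nll_by_start = self._optimize(cells, names, params, cfg)

        n_free = len(names) + (n_sensory - len(sensory_names))
        self.params_ = params
        self.free_names_ = tuple(names)
        self.nll_ = nll
        self.aic_ = 2.0 * n_free + 2.0 * nll
        self.n_free_params_ = n_free
        try:
            self.eve_ = explainable_variance_explained(params, trials, quad=cfg.quad)
        except ValueError:
            self.eve_ = None
        self.ci68_ = None
        if cfg.n_boot:
            self.ci68_ = self._bootstrap(trials, names, cfg)
        self.result_ = FittedModel(
            params=params,
            variant=self.variant,
            nll=nll,
            aic=self.aic_,
            eve=self.eve_,
            ci68=self.ci68_,
            n_free_params=n_free,
            free_names=tuple(names),
            data_hash=_data_hash(trials),
            nll_by_start=tuple(nll_by_start),
        )
        return self

    def _bootstrap(self, trials, names, cfg):
        warm = dataclasses.replace(cfg, n_starts=1, n_boot=0, seed=cfg.seed + 1)

        def refit(resampled):
            est = CausalInferenceObserver(self.variant, warm, base_params=self.params_)
            est.fit(ResponseData(resampled))
            return {n: _get_param(est.params_, n) for n in names}

        return bootstrap_ci(
            ResponseData(trials), refit, level=cfg.ci_level,
            n_boot=max(cfg.n_boot, 100), seed=cfg.seed,
        )

    def predict_proba(self, trials: pd.DataFrame):
        """Positive-response probability for every row of a trial table."""
        cells = _build_cells(trials.assign(response=1))
        probs = _cell_probs(self.params_, cells, (self.config or FitConfig()).quad)
        out = np.full(len(trials), np.nan)
        t = trials.reset_index(drop=True)
        for key, (stim, _, _) in cells.items():
            kind, rel = key
            if kind == "uni_a":
                mask = t["condition"] == "auditory_only"
                lookup = dict(zip(stim, probs[key]))
                out[mask] = [lookup[v] for v in t.loc[mask, "eps_a"]]
            elif kind == "uni_v":
                mask = (t["condition"] == "visual_only") & (t["reliability"] == rel)
                lookup = dict(zip(stim, probs[key]))
                out[mask] = [lookup[v] for v in t.loc[mask, "eps_v"]]
            else:
                exps = ("exp3",) if kind == "explicit" else ("exp1", "exp2")
                mask = (
                    (t["condition"] == "audio_visual")
                    & (t["reliability"] == rel)
                    & t["experiment"].isin(exps)
                )
                lookup = dict(zip(zip(stim[0], stim[1]), probs[key]))
                out[mask] = [
                    lookup[(a, v)] for a, v in zip(t.loc[mask, "eps_a"], t.loc[mask, "eps_v"])
                ]
        return out

    def score(self, data):
        """Mean per-trial log-likelihood (higher is better)."""
        trials = data.trials if isinstance(data, ResponseData) else data
        return -negative_log_likelihood(
            self.params_, trials, (self.config or FitConfig()).quad
        ) / len(trials)


# --------------------------------------------------------------------------
# Functional surface
# --------------------------------------------------------------------------

def fit_subject(data, variant="full_CI", config: FitConfig = None, base_params=None) -> FittedModel:
    """Fit one subject's joint unisensory + causal-inference data."""
    est = CausalInferenceObserver(variant=variant, config=config, base_params=base_params)
    return est.fit(data).result_


def fit_aggregate(cohort: Sequence[ResponseData], variant="full_CI", config=None,
                  base_params=None) -> FittedModel:
    """Pool trials across subjects into one aggregate subject, then fit.

    Bootstrap CIs (when enabled in the config) resample subjects, not
    trials, reflecting between-subject variability of the aggregate.
    """
    if not len(cohort):
        raise ValueError("need at least one subject")
    pooled = pd.concat([r.trials for r in cohort], ignore_index=True)
    cfg = config or FitConfig()
    point_cfg = dataclasses.replace(cfg, n_boot=0)
    est = CausalInferenceObserver(variant=variant, config=point_cfg, base_params=base_params)
    est.fit(ResponseData(pooled, subject_id="aggregate"))
    result = est.result_
    if cfg.n_boot:
        warm = dataclasses.replace(cfg, n_starts=1, n_boot=0, seed=cfg.seed + 1)

        def refit(subjects):
            pooled_b = pd.concat([r.trials for r in subjects], ignore_index=True)
            e = CausalInferenceObserver(variant, warm, base_params=est.params_)
            e.fit(ResponseData(pooled_b))
            return {n: _get_param(e.params_, n) for n in est.free_names_}

        result.ci68 = bootstrap_ci(
            list(cohort), refit, level=cfg.ci_level, n_boot=max(cfg.n_boot, 100), seed=cfg.seed
        )
    return result


def compare_models(fits: Sequence[FittedModel]) -> pd.DataFrame:
    """Rank fitted models on the same data by AIC (delta relative to best)."""
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("model comparison requires fits to identical data")
    df = pd.DataFrame(
        [
            {"variant": f.variant, "nll": f.nll, "aic": f.aic,
             "n_free_params": f.n_free_params, "eve": f.eve}
            for f in fits
        ]
    )
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df.sort_values("delta_aic", ignore_index=True)


def eve_from_proportions(observed, predicted, n_trials) -> float:
    """EVE on per-condition proportions with known trial counts.

    EVE = 1 - (MSE_model - vbar) / (Var_data - vbar), vbar the mean plug-in
    binomial variance p(1-p)/n.  Clipped to at most 1 (a saturated model
    reproducing the observed proportions exactly reports 1).
    """
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    n_trials = np.asarray(n_trials, float)
    vbar = float(np.mean(observed * (1 - observed) / n_trials))
    var_data = float(np.var(observed))
    if var_data <= vbar:
        raise ValueError("data variance does not exceed sampling noise; EVE undefined")
    mse = float(np.mean((observed - predicted) ** 2))
    return min(1.0, 1.0 - (mse - vbar) / (var_data - vbar))


def explainable_variance_explained(params_or_fit, data, quad=None) -> float:
    """EVE of model predictions on per-condition response proportions.

    EVE = 1 - (MSE_model - vbar) / (Var_data - vbar), where vbar is the
    average binomial sampling variance p(1-p)/n across conditions: a model
    as good as the generating process scores ~1 (clipped at 1), the grand
    mean scores ~0.  Undefined (raises) when the data's variance does not
    exceed its sampling noise.
    """
    params = params_or_fit.params if isinstance(params_or_fit, FittedModel) else params_or_fit
    trials = data.trials if isinstance(data, ResponseData) else data
    trials = trials[trials["experiment"].isin(["exp1", "exp2", "exp3"])]
    cells = _build_cells(trials)
    quad = (quad or QuadratureSpec(order=41, bisect_iters=48)).validate()
    probs = _cell_probs(params, cells, quad)
    obs, pred, ns = [], [], []
    for key, (stim, k, n) in cells.items():
        if np.any(n < 2):
            continue
        obs.append(k / n)
        pred.append(probs[key])
        ns.append(n)
    if not obs:
        raise ValueError("need >= 2 trials per condition to estimate EVE")
    return eve_from_proportions(
        np.concatenate(obs), np.concatenate(pred), np.concatenate(ns)
    )


def bootstrap_ci(data, fit_fn: Callable, level: float = 0.68, n_boot: int = 200,
                 seed: int = 0) -> Dict[str, Tuple[float, float]]:
    """Seeded nonparametric percentile bootstrap intervals.

    ``data`` is either a ResponseData (trials are resampled with
    replacement) or a sequence of ResponseData (subjects are resampled).
    ``fit_fn`` maps a resampled dataset to a dict of scalar estimates.
    """
    if level not in (0.68, 0.95):
        raise ValueError("level must be 0.68 or 0.95")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    draws: Dict[str, list] = {}
    for _ in range(n_boot):
        if isinstance(data, ResponseData):
            idx = rng.integers(len(data.trials), size=len(data.trials))
            sample = data.trials.iloc[idx].reset_index(drop=True)
        else:
            idx = rng.integers(len(data), size=len(data))
            sample = [data[i] for i in idx]
        est = fit_fn(sample)
        for k, v in est.items():
            if v is not None:
                draws.setdefault(k, []).append(float(v))
    alpha = (1.0 - level) / 2.0
    return {
        k: (float(np.quantile(v, alpha)), float(np.quantile(v, 1.0 - alpha)))
        for k, v in draws.items()
    }


def parameter_recovery_report(
    true_params: ObserverParams,
    schedules: Sequence[pd.DataFrame],
    n_reps: int = 10,
    seed: int = 0,
    config: FitConfig = None,
    variant: str = "full_CI",
) -> pd.DataFrame:
    """Simulate-then-refit study: per-parameter bias and RMSE.

    Each repetition simulates fresh responses on the given schedules from
    ``true_params`` and refits the observer; the report summarizes recovery
    of every free parameter.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = config or FitConfig()
    rng = np.random.default_rng(seed)
    sched = pd.concat(list(schedules), ignore_index=True)
    rows = []
    for rep in range(n_reps):
        sim = simulate_observer(sched, true_params, seed=int(rng.integers(2**31)))
        rep_cfg = dataclasses.replace(cfg, seed=int(rng.integers(2**31)))
        fm = fit_subject(sim, variant=variant, config=rep_cfg)
        rec = {"rep": rep}
        track = fm.free_names if "sigma_a" in fm.free_names else ("sigma_a",) + fm.free_names
        for name in track:
            rec[name] = _get_param(fm.params, name)
        rows.append(rec)
    est = pd.DataFrame(rows).drop(columns="rep")
    out = []
    for name in est.columns:
        truth = _get_param(true_params, name)
        err = est[name].to_numpy(float) - truth
        out.append(
            {
                "parameter": name,
                "truth": truth,
                "mean_estimate": float(est[name].mean()),
                "bias": float(err.mean()),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(out)
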