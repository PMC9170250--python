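"""Simulate observer responses on the experimental schedules.

``simulate_observer`` draws noisy measurements for every trial, applies the
generative model's decision rule (implicit localization for exp1/exp2,
explicit common-cause for exp3, the descriptive Gaussian synchrony curve
for exp4), then overwrites a seeded fraction of responses with lapses.
``make_cohort`` samples per-subject parameters from group distributions and
simulates a full multi-experiment dataset per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .conventions import (
    ASYNCHRONOUS,
    LEFT,
    NEGATIVE_CODE,
    POSITIVE_CODE,
    RESPONSE_CODES,
    RESPONSE_COLUMNS,
    RIGHT,
    SYNCHRONOUS,
)
from .observer import _half_line_posterior, explicit_decision, implicit_decision
from .params import CohortSpec, ObserverParams
from .schedules import make_schedule

__all__ = ["ResponseData", "simulate_observer", "make_cohort"]


@dataclass
class ResponseData:
    """A trial schedule paired with one response per trial.

    ``trials`` carries the canonical schedule columns plus a ``response``
    column; every response is one of the two legal codes for its experiment.
    """

    trials: pd.DataFrame
    subject_id: str = "s0"
    group: str = "synthetic"
    params: Optional[ObserverParams] = None

    def __post_init__(self):
        if "response" not in self.trials.columns:
            raise ValueError("ResponseData.trials must include a 'response' column")
        for exp, sub in self.trials.groupby("experiment"):
            legal = RESPONSE_CODES.get(exp)
            if legal is None:
                continue
            bad = set(sub["response"].unique()) - set(legal)
            if bad:
                raise ValueError(f"illegal response codes {bad} for {exp}")

    def __len__(self):
        return len(self.trials)

    def experiments(self):
        return tuple(sorted(self.trials["experiment"].unique()))

    def subset(self, experiment):
        sub = self.trials[self.trials["experiment"] == experiment].reset_index(drop=True)
        return ResponseData(sub, self.subject_id, self.group, self.params)

    def to_frame(self) -> pd.DataFrame:
        df = self.trials.copy()
        df["subject_id"] = self.subject_id
        df["group"] = self.group
        return df[list(RESPONSE_COLUMNS)]

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResponseData":
        subject = df["subject_id"].iloc[0] if "subject_id" in df else "s0"
        group = df["group"].iloc[0] if "group" in df else "synthetic"
        trials = df.drop(columns=[c for c in ("subject_id", "group") if c in df])
        return cls(trials.reset_index(drop=True), str(subject), str(group))

    @classmethod
    def from_csv(cls, path) -> "ResponseData":
        return cls.from_frame(pd.read_csv(path))


def _unisensory_side(x, sigma, mu_prior, sd_prior, p_choice):
    """Side report from a single noisy measurement (truncated-prior rule)."""
    tau = 1.0 / sigma**2 + 1.0 / sd_prior**2
    m = (x / sigma**2 + mu_prior / sd_prior**2) / tau
    belief = _half_line_posterior(m, tau**-0.5, mu_prior, sd_prior, p_choice)
    return np.where(belief >= 0.5, RIGHT, LEFT)


def _simulate_spatial(trials, params, rng):
    """Responses for exp1/exp2/exp3 trials (vectorized per condition block)."""
    resp = np.zeros(len(trials), dtype=int)
    cond = trials["condition"].to_numpy()
    rel_col = trials["reliability"].to_numpy()
    exp = trials["experiment"].iloc[0]

    idx = np.flatnonzero(cond == "auditory_only")
    if idx.size:
        x = rng.normal(trials["eps_a"].to_numpy(dtype=float)[idx], params.sigma_a)
        resp[idx] = _unisensory_side(
            x, params.sigma_a, params.mu_a_prior, params.sigma_a_prior, params.p_choice_implicit
        )

    for rel in ("high", "medium", "low"):
        idx = np.flatnonzero((cond == "visual_only") & (rel_col == rel))
        if idx.size:
            sig = params.sigma_v[rel]
            x = rng.normal(trials["eps_v"].to_numpy(dtype=float)[idx], sig)
            resp[idx] = _unisensory_side(
                x, sig, params.mu_v_prior, params.sigma_v_prior, params.p_choice_implicit
            )
        idx = np.flatnonzero((cond == "audio_visual") & (rel_col == rel))
        if idx.size:
            xa = rng.normal(trials["eps_a"].to_numpy(dtype=float)[idx], params.sigma_a)
            xv = rng.normal(trials["eps_v"].to_numpy(dtype=float)[idx], params.sigma_v[rel])
            rule = explicit_decision if exp == "exp3" else implicit_decision
            resp[idx] = rule(xa, xv, params, rel)
    return resp


def _apply_lapse(resp, experiment, params, rng):
    n = len(resp)
    lapse = rng.random(n) < params.lapse_rate
    favored = rng.random(n) < params.lapse_bias
    pos = POSITIVE_CODE[experiment]
    neg = NEGATIVE_CODE[experiment]
    return np.where(lapse, np.where(favored, pos, neg), resp)


def simulate_observer(
    schedule: pd.DataFrame,
    params: ObserverParams,
    seed: int = 0,
    subject_id: str = "s0",
    group: str = "synthetic",
) -> ResponseData:
    """Sample one response per trial of ``schedule`` from the observer model.

    Raises for exp5 schedules: the heading/object-motion task has no
    observer model here.
    """
    params.validate()
    exps = set(schedule["experiment"].unique())
    if "exp5" in exps:
        raise ValueError("no observer model for exp5; its schedule is design-only")
    rng = np.random.default_rng(seed)
    out = schedule.copy().reset_index(drop=True)
    resp = np.zeros(len(out), dtype=int)
    for exp in sorted(exps):
        mask = (out["experiment"] == exp).to_numpy()
        sub = out.loc[mask].reset_index(drop=True)
        if exp == "exp4":
            p_sync = params.synchrony.prob_synchronous(sub["delta"].to_numpy(dtype=float))
            r = np.where(rng.random(len(sub)) < p_sync, SYNCHRONOUS, ASYNCHRONOUS)
        else:
            r = _simulate_spatial(sub, params, rng)
        resp[mask] = _apply_lapse(r, exp, params, rng)
    out["response"] = resp
    return ResponseData(out, subject_id=subject_id, group=group, params=params)


def make_cohort(
    n_control: int,
    n_asd: int,
    spec: CohortSpec | None = None,
    seed: int = 0,
) -> List[ResponseData]:
    """Simulate a two-group cohort of observers.

    Per-subject parameters are drawn from the group distributions in
    ``spec``; each subject completes every experiment in ``spec.experiments``
    (one concatenated ResponseData per subject).
    """
    if n_control < 0 or n_asd < 0:
        raise ValueError("cohort sizes must be non-negative")
    spec = (spec or CohortSpec()).validate()
    rng = np.random.default_rng(seed)
    cohort: List[ResponseData] = []
    for group, gspec, n in (("control", spec.control, n_control), ("asd", spec.asd, n_asd)):
        for i in range(n):
            params = gspec.draw(rng, spec.base)
            frames = []
            sid = f"{group}_{i:02d}"
            for exp in spec.experiments:
                sched = make_schedule(exp, seed=int(rng.integers(2**31)))
                frames.append(
                    simulate_observer(
                        sched, params, seed=int(rng.integers(2**31)), subject_id=sid, group=group
                    ).trials
                )
            trials = pd.concat(frames, ignore_index=True)
            cohort.append(ResponseData(trials, subject_id=sid, group=group, params=params))
    return cohort


def cohort_to_frame(cohort) -> pd.DataFrame:
    """Stack a cohort into one long trial table (the CSV schema)."""
    return pd.concat([r.to_frame() for r in cohort], ignore_index=True)


def cohort_from_frame(df: pd.DataFrame) -> List[ResponseData]:
    return [
        ResponseData.from_frame(sub.reset_index(drop=True))
        for _, sub in df.groupby("subject_id", sort=True)
    ]
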