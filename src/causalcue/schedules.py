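"""Trial schedules for the five behavioral experiments.

Each generator enumerates the full factorial design of one experiment and
returns it in a seeded, interleaved order as a pandas DataFrame with the
canonical columns (see :mod:`causalcue.conventions`).  Designs:

* exp1 - audio-visual localization with small conflicts (cue-combination):
  auditory-only at 0, +-3, +-6, +-9 deg x 15 reps; visual-only at the 14
  nonzero locations +-20, +-10, +-5, +-2.5, +-1.25, +-0.65, +-0.32 deg x 3
  reliabilities x 15 reps; combined at 7 mean locations x 3 reliabilities x
  disparities {0, +6, -6} deg x 15 reps, cues placed at mean +- delta/2.
  Total 1680 trials.
* exp2 - auditory localization with disparate visual cues (implicit causal
  inference): disparities {0, +-3, +-6, +-12, +-24} deg x 7 speaker
  locations x 3 reliabilities x 8 reps = 1512 trials.
* exp3 - explicit common-cause report over the same spatial factorial with
  7 reps = 1323 trials.
* exp4 - synchrony judgment over 23 temporal disparities (0 to +-700 ms)
  x 25 reps = 575 trials.
* exp5 - heading discrimination with object motion: 2 directions x 5 speeds
  x 13 headings x 7 reps = 910 trials (schedule only; no observer model).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .conventions import TRIAL_COLUMNS

__all__ = [
    "make_schedule_exp1",
    "make_schedule_exp2",
    "make_schedule_exp3",
    "make_schedule_exp4",
    "make_schedule_exp5",
    "make_schedule",
]

SPEAKER_LOCATIONS = (-9.0, -6.0, -3.0, 0.0, 3.0, 6.0, 9.0)
VISUAL_LOCATIONS = tuple(
    s * m for m in (20.0, 10.0, 5.0, 2.5, 1.25, 0.65, 0.32) for s in (1.0, -1.0)
)
EXP2_DISPARITIES = (0.0, 3.0, -3.0, 6.0, -6.0, 12.0, -12.0, 24.0, -24.0)
EXP4_DISPARITIES_MS = tuple(
    s * d for d in (10.0, 20.0, 50.0, 80.0, 100.0, 150.0, 200.0, 250.0, 300.0, 500.0, 700.0)
    for s in (1.0, -1.0)
) + (0.0,)
EXP5_HEADINGS = (0.0, 5.0, -5.0, 10.0, -10.0, 15.0, -15.0, 20.0, -20.0, 25.0, -25.0, 45.0, -45.0)
EXP5_SPEEDS = (0.07, 0.13, 0.8, 2.67, 5.33)  # m/s

#: Mean stimulus locations for the exp1 conflict conditions, chosen so the
#: auditory cue (at mean + delta/2) always falls on a speaker.
EXP1_MEANS = {
    0.0: SPEAKER_LOCATIONS,
    6.0: (-12.0, -9.0, -6.0, -3.0, 0.0, 3.0, 6.0),
    -6.0: (-6.0, -3.0, 0.0, 3.0, 6.0, 9.0, 12.0),
}


def _finish(rows, seed):
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(df))
    return df.iloc[order].reset_index(drop=True)


def make_schedule_exp1(seed: int = 0) -> pd.DataFrame:
    """Interleaved cue-combination design (1680 trials)."""
    rows = []
    for rep in range(1, 16):
        for loc in SPEAKER_LOCATIONS:
            rows.append(("exp1", "auditory_only", loc, np.nan, None, np.nan, rep))
        for rel in ("high", "medium", "low"):
            for loc in VISUAL_LOCATIONS:
                rows.append(("exp1", "visual_only", np.nan, loc, rel, np.nan, rep))
            for delta, means in EXP1_MEANS.items():
                for m in means:
                    eps_a = m + delta / 2.0
                    eps_v = m - delta / 2.0
                    rows.append(("exp1", "audio_visual", eps_a, eps_v, rel, delta, rep))
    return _finish(rows, seed)


def _spatial_ci_schedule(experiment, n_reps, seed):
    rows = []
    for rep in range(1, n_reps + 1):
        for delta in EXP2_DISPARITIES:
            for loc in SPEAKER_LOCATIONS:
                for rel in ("high", "medium", "low"):
                    # auditory on the speaker; visual displaced by -delta
                    rows.append((experiment, "audio_visual", loc, loc - delta, rel, delta, rep))
    return _finish(rows, seed)


def make_schedule_exp2(seed: int = 0) -> pd.DataFrame:
    """Implicit causal-inference design (1512 trials)."""
    return _spatial_ci_schedule("exp2", 8, seed)


def make_schedule_exp3(seed: int = 0) -> pd.DataFrame:
    """Explicit spatial common-cause design (1323 trials)."""
    return _spatial_ci_schedule("exp3", 7, seed)


def make_schedule_exp4(seed: int = 0) -> pd.DataFrame:
    """Synchrony-judgment design over temporal disparity (575 trials)."""
    rows = []
    for rep in range(1, 26):
        for delta in EXP4_DISPARITIES_MS:
            rows.append(("exp4", "audio_visual", 0.0, 0.0, "high", delta, rep))
    return _finish(rows, seed)


def make_schedule_exp5(seed: int = 0) -> pd.DataFrame:
    """Heading/object-motion factorial (910 trials; schedule only).

    ``eps_v`` holds the heading (degrees, rightward positive) and ``delta``
    the signed object speed (m/s, sign = object motion direction); the
    reliability factor does not apply.
    """
    rows = []
    for rep in range(1, 8):
        for direction in (1.0, -1.0):
            for speed in EXP5_SPEEDS:
                for heading in EXP5_HEADINGS:
                    rows.append(
                        ("exp5", "visual_only", np.nan, heading, None, direction * speed, rep)
                    )
    return _finish(rows, seed)


_MAKERS = {
    "exp1": make_schedule_exp1,
    "exp2": make_schedule_exp2,
    "exp3": make_schedule_exp3,
    "exp4": make_schedule_exp4,
    "exp5": make_schedule_exp5,
}


def make_schedule(experiment: str, seed: int = 0) -> pd.DataFrame:
    """Dispatch to the named experiment's schedule generator."""
    try:
        return _MAKERS[experiment](seed)
    except KeyError:
        raise ValueError(f"unknown experiment {experiment!r}") from None
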