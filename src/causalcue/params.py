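"""Parameter containers for the generative observer model.

``ObserverParams`` collects everything needed to simulate (or evaluate the
likelihood of) one observer: sensory noise, natural location priors, the
causal prior ``p_common``, choice and lapse parameters, and the descriptive
synchrony-curve parameters used for the temporal experiment.  All containers
round-trip through JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

from .conventions import RELIABILITIES

__all__ = [
    "ObserverParams",
    "SynchronyParams",
    "QuadratureSpec",
    "CohortSpec",
    "GroupSpec",
    "DEFAULT_CONTROL",
    "DEFAULT_ASD",
]


@dataclass
class SynchronyParams:
    """Descriptive generator for synchrony judgments over temporal disparity.

    The probability of a 'synchronous' report is a Gaussian bump in the
    audio-visual asynchrony: ``amplitude * exp(-(delta - mean)^2 / (2 width^2))``,
    mixed with the observer's lapse process.  Units are milliseconds.
    """

    amplitude: float = 0.98
    mean: float = 0.0
    width: float = 171.68

    def validate(self) -> "SynchronyParams":
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError(f"synchrony amplitude must be in [0, 1], got {self.amplitude}")
        if self.width <= 0:
            raise ValueError(f"synchrony width must be > 0, got {self.width}")
        return self

    def prob_synchronous(self, delta_ms):
        import numpy as np

        d = np.asarray(delta_ms, dtype=float)
        return self.amplitude * np.exp(-((d - self.mean) ** 2) / (2.0 * self.width**2))


@dataclass
class ObserverParams:
    """All generative-model parameters for a single observer.

    Parameters
    ----------
    sigma_a : float
        Auditory sensory noise SD (degrees).
    sigma_v : mapping reliability -> float
        Visual sensory noise SD per reliability level (degrees).
    mu_a_prior, mu_v_prior : float
        Means of the Gaussian natural priors over auditory / visual location.
    sigma_a_prior, sigma_v_prior : float
        SDs of the natural priors (degrees).
    p_common : float
        Prior probability that both cues share one cause.
    p_choice_implicit : float
        Stimulus-independent prior toward the 'rightward' category in
        localization tasks.
    p_combined : float
        The single estimable mixture of p_common, explicit choice bias and
        task learning that governs explicit common-cause reports.
    lapse_rate, lapse_bias : float
        Probability of a stimulus-independent response and the probability
        that such a response is the task's positive code.
    synchrony : SynchronyParams
        Descriptive parameters for the temporal synchrony experiment.
    """

    sigma_a: float = 4.8
    sigma_v: Mapping[str, float] = field(
        default_factory=lambda: {"high": 1.10, "medium": 4.76, "low": 13.96}
    )
    mu_a_prior: float = 0.0
    sigma_a_prior: float = 25.0
    mu_v_prior: float = 0.0
    sigma_v_prior: float = 25.0
    p_common: float = 0.25
    p_choice_implicit: float = 0.5
    p_combined: float = 0.35
    lapse_rate: float = 0.03
    lapse_bias: float = 0.5
    synchrony: SynchronyParams = field(default_factory=SynchronyParams)

    def __post_init__(self):
        if isinstance(self.synchrony, dict):
            self.synchrony = SynchronyParams(**self.synchrony)
        self.sigma_v = dict(self.sigma_v)

    def validate(self) -> "ObserverParams":
        if self.sigma_a <= 0:
            raise ValueError(f"sigma_a must be > 0, got {self.sigma_a}")
        for r, s in self.sigma_v.items():
            if r not in RELIABILITIES:
                raise ValueError(f"unknown reliability level {r!r}")
            if s <= 0:
                raise ValueError(f"sigma_v[{r!r}] must be > 0, got {s}")
        if self.sigma_a_prior <= 0 or self.sigma_v_prior <= 0:
            raise ValueError("prior SDs must be > 0")
        for name in ("p_common", "p_choice_implicit", "p_combined", "lapse_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.lapse_rate <= 0.5:
            raise ValueError(f"lapse_rate must be in [0, 0.5], got {self.lapse_rate}")
        self.synchrony.validate()
        return self

    def replace(self, **kwargs) -> "ObserverParams":
        return dataclasses.replace(self, **kwargs)

    # -- JSON round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ObserverParams":
        return cls(**d)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, source) -> "ObserverParams":
        try:
            d = json.loads(source)
        except (TypeError, ValueError):
            with open(source) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


@dataclass
class QuadratureSpec:
    """Controls numerical marginalization over sensory measurements.

    ``order`` is the number of Gauss-Hermite nodes for the (smooth) outer
    integral over the visual measurement; the auditory dimension is handled
    in closed form (Gaussian CDF masses of the decision region), with
    ``bisect_iters`` bisection refinements of the implicit decision boundary.
    """

    order: int = 61
    bisect_iters: int = 60

    def validate(self) -> "QuadratureSpec":
        if self.order < 3:
            raise ValueError(f"quadrature order must be >= 3, got {self.order}")
        if self.bisect_iters < 10:
            raise ValueError("bisect_iters must be >= 10")
        return self


def _truncnorm_draw(rng, mean, sd, lo, hi):
    """One truncated-normal draw by rejection (bounds are wide in practice)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


@dataclass
class GroupSpec:
    """Population distribution of observer parameters for one group.

    Each entry maps a scalar ObserverParams field (or ``sigma_v.<level>`` /
    ``synchrony.<field>``) to ``(mean, sd)``; subjects are drawn from
    truncated normals respecting the parameter's legal bounds.
    """

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    BOUNDS = {
        "sigma_a": (1e-3, 60.0),
        "sigma_v.high": (1e-3, 60.0),
        "sigma_v.medium": (1e-3, 60.0),
        "sigma_v.low": (1e-3, 60.0),
        "sigma_a_prior": (1.0, 1e4),
        "sigma_v_prior": (1.0, 1e4),
        "mu_a_prior": (-30.0, 30.0),
        "mu_v_prior": (-30.0, 30.0),
        "p_common": (0.0, 1.0),
        "p_choice_implicit": (0.0, 1.0),
        "p_combined": (0.0, 1.0),
        "lapse_rate": (0.0, 0.5),
        "lapse_bias": (0.0, 1.0),
        "synchrony.amplitude": (0.0, 1.0),
        "synchrony.mean": (-500.0, 500.0),
        "synchrony.width": (10.0, 2000.0),
    }

    def validate(self) -> "GroupSpec":
        for key in list(self.means) + list(self.sds):
            if key not in self.BOUNDS:
                raise ValueError(f"unknown parameter key {key!r} in GroupSpec")
        for key, sd in self.sds.items():
            if sd < 0:
                raise ValueError(f"negative sd for {key!r}")
        return self

    def draw(self, rng, base: ObserverParams) -> ObserverParams:
        """Sample one observer around ``base`` with this group's overrides."""
        p = dataclasses.replace(base)
        p.sigma_v = dict(base.sigma_v)
        p.synchrony = dataclasses.replace(base.synchrony)
        for key, mean in self.means.items():
            sd = self.sds.get(key, 0.0)
            lo, hi = self.BOUNDS[key]
            val = _truncnorm_draw(rng, mean, sd, lo, hi) if sd > 0 else float(mean)
            if key.startswith("sigma_v."):
                p.sigma_v[key.split(".", 1)[1]] = val
            elif key.startswith("synchrony."):
                setattr(p.synchrony, key.split(".", 1)[1], val)
            else:
                setattr(p, key, val)
        return p.validate()


#: Study-condition defaults: sensory noise at the reported group-average
#: unisensory thresholds; control observers weakly favor a common cause,
#: ASD-like observers favor it three times as strongly in the implicit task
#: yet report 'common' less in the explicit task (lower p_combined).
DEFAULT_CONTROL = GroupSpec(
    means={
        "p_common": 0.25,
        "p_combined": 0.35,
        "lapse_rate": 0.03,
        "synchrony.amplitude": 0.98,
        "synchrony.width": 171.68,
    },
    sds={
        "p_common": 0.06,
        "p_combined": 0.05,
        "lapse_rate": 0.015,
        "synchrony.amplitude": 0.01,
        "synchrony.width": 25.0,
    },
)

DEFAULT_ASD = GroupSpec(
    means={
        "p_common": 0.75,
        "p_combined": 0.25,
        "lapse_rate": 0.05,
        "synchrony.amplitude": 0.83,
        "synchrony.width": 363.0,
    },
    sds={
        "p_common": 0.08,
        "p_combined": 0.05,
        "lapse_rate": 0.025,
        "synchrony.amplitude": 0.04,
        "synchrony.width": 60.0,
    },
)


@dataclass
class CohortSpec:
    """Population spec for a simulated two-group cohort.

    ``base`` supplies every parameter not overridden by the group specs, so
    sensory parameters are matched across groups by default (the empirical
    situation: unisensory thresholds do not differ between groups).
    """

    base: ObserverParams = field(default_factory=ObserverParams)
    control: GroupSpec = field(default_factory=lambda: dataclasses.replace(DEFAULT_CONTROL))
    asd: GroupSpec = field(default_factory=lambda: dataclasses.replace(DEFAULT_ASD))
    experiments: tuple = ("exp1", "exp2")

    def __post_init__(self):
        if isinstance(self.base, dict):
            self.base = ObserverParams.from_dict(self.base)
        if isinstance(self.control, dict):
            self.control = GroupSpec(**self.control)
        if isinstance(self.asd, dict):
            self.asd = GroupSpec(**self.asd)
        self.experiments = tuple(self.experiments)

    def validate(self) -> "CohortSpec":
        self.base.validate()
        self.control.validate()
        self.asd.validate()
        bad = [e for e in self.experiments if e not in ("exp1", "exp2", "exp3", "exp4")]
        if bad:
            raise ValueError(f"cohort experiments must be simulable (exp1-exp4), got {bad}")
        return self

    def to_json(self, path=None) -> str:
        d = {
            "base": self.base.to_dict(),
            "control": {"means": self.control.means, "sds": self.control.sds},
            "asd": {"means": self.asd.means, "sds": self.asd.sds},
            "experiments": list(self.experiments),
        }
        s = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, source) -> "CohortSpec":
        try:
            d = json.loads(source)
        except (TypeError, ValueError):
            with open(source) as fh:
                d = json.load(fh)
        return cls(**d)
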