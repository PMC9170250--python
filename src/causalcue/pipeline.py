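"""Simulate -> analyze -> fit -> report orchestration.

The pipeline is a thin, reproducible layer over the library: a single
``RunConfig`` (YAML or JSON) fixes the seed, cohort, experiments and fitting
options; every artifact records the config hash and seed.  The report stage
emits the study's analysis surfaces on the synthetic cohort: measured vs
predicted thresholds and visual weights (cue combination), auditory bias
against disparity with nested polynomial fits (implicit causal inference),
common-cause report curves with Gaussian fits (explicit tasks), and model
comparison tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import FitConfig, FittedModel, compare_models, fit_aggregate
from .fusion import fusion_prediction, measured_visual_weight
from .params import CohortSpec, ObserverParams
from .psychometrics import (
    DisparityPolynomial,
    GaussianCurve,
    PsychometricFunction,
    fit_gaussian_curve,
)
from .schedules import make_schedule
from .simulate import ResponseData, cohort_from_frame, cohort_to_frame, make_cohort

log = logging.getLogger("causalcue")

__all__ = [
    "RunConfig",
    "cmd_simulate",
    "cmd_fit",
    "cmd_report",
    "exp1_weight_table",
    "exp2_bias_table",
    "explicit_curve_table",
]


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    seed: int = 0
    experiments: Sequence[str] = ("exp1", "exp2", "exp3")
    n_control: int = 4
    n_asd: int = 4
    cohort: CohortSpec = field(default_factory=CohortSpec)
    variants: Sequence[str] = ("full_CI", "alt_A_forced_fusion", "alt_B_no_fusion")
    fit: FitConfig = field(default_factory=lambda: FitConfig(n_starts=3))
    outdir: str = "causalcue_run"

    def __post_init__(self):
        if isinstance(self.cohort, dict):
            self.cohort = CohortSpec(**self.cohort)
        if isinstance(self.fit, dict):
            self.fit = FitConfig(**self.fit)
        self.experiments = tuple(self.experiments)
        self.variants = tuple(self.variants)
        # exp5 is schedule-only (no observer model); the cohort simulates the rest
        simulable = tuple(e for e in self.experiments if e != "exp5")
        self.cohort = dataclasses.replace(self.cohort, experiments=simulable)

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "experiments": list(self.experiments),
            "n_control": self.n_control,
            "n_asd": self.n_asd,
            "cohort": json.loads(self.cohort.to_json()),
            "variants": list(self.variants),
            "fit": {
                "n_starts": self.fit.n_starts,
                "quad": {"order": self.fit.quad.order, "bisect_iters": self.fit.quad.bisect_iters},
                "maxiter": self.fit.maxiter,
                "joint_sensory": self.fit.joint_sensory,
                "n_boot": self.fit.n_boot,
                "seed": self.fit.seed,
            },
            "outdir": self.outdir,
        }
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        return cls(**d)


def _stamp(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed}


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def cmd_simulate(config: RunConfig) -> Path:
    """Simulate the configured cohort; write trial CSVs and parameter JSON."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = make_cohort(config.n_control, config.n_asd, config.cohort, seed=config.seed)
    frame = cohort_to_frame(cohort) if cohort else pd.DataFrame()
    data_path = out / "dataset.csv"
    frame.to_csv(data_path, index=False)
    gen = {r.subject_id: r.params.to_dict() for r in cohort if r.params is not None}
    (out / "generating_params.json").write_text(json.dumps(gen, indent=2, sort_keys=True) + "\n")
    if "exp5" in config.experiments:
        # design-only: no observer model for the heading task
        sched = make_schedule("exp5", seed=config.seed)
        sched.to_csv(out / "exp5_schedule.csv", index=False)
    manifest = _stamp(config) | {"n_subjects": len(cohort), "n_trials": int(len(frame))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    log.info("simulated %d subjects (%d trials) -> %s", len(cohort), len(frame), data_path)
    return data_path


def cmd_fit(config: RunConfig, dataset: Path) -> Path:
    """Fit the configured model variants to each group's aggregate subject."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    frame = pd.read_csv(dataset)
    cohort = cohort_from_frame(frame)
    fits_dir = out / "fits"
    fits_dir.mkdir(exist_ok=True)
    fit_log: List[dict] = []
    for group in sorted({r.group for r in cohort}):
        members = [r for r in cohort if r.group == group]
        for variant in config.variants:
            cfg = dataclasses.replace(config.fit, seed=config.seed)
            fm = fit_aggregate(members, variant=variant, config=cfg)
            rec = fm.to_dict() | _stamp(config) | {"group": group}
            path = fits_dir / f"{group}_{variant}.json"
            path.write_text(json.dumps(rec, indent=2, sort_keys=True) + "\n")
            fit_log.append(
                {"group": group, "variant": variant, "nll": fm.nll, "aic": fm.aic,
                 "nll_by_start": list(fm.nll_by_start)}
            )
            log.info("fit %s/%s: nll=%.1f aic=%.1f", group, variant, fm.nll, fm.aic)
    (out / "fit_log.json").write_text(json.dumps(fit_log, indent=2) + "\n")
    return fits_dir


# --------------------------------------------------------------------------
# Analysis surfaces
# --------------------------------------------------------------------------

def _psychometric(x, y):
    return PsychometricFunction(lapse_mode="rate_only").fit(np.asarray(x, float), np.asarray(y))


def exp1_weight_table(data: ResponseData) -> pd.DataFrame:
    """Measured vs predicted combined thresholds and visual weights (exp1).

    Per reliability: unisensory psychometric thresholds give the forced-
    fusion predictions; the no-conflict combined condition gives the
    measured combined threshold; the +-6 deg conflict conditions, analyzed
    against the mean stimulus location, give the measured visual weight.
    """
    t = data.trials[data.trials["experiment"] == "exp1"]
    if not len(t):
        raise ValueError("no exp1 trials")
    aud = t[t["condition"] == "auditory_only"]
    f_aud = _psychometric(aud["eps_a"], (aud["response"] == 1).astype(float))
    rows = []
    for rel in ("high", "medium", "low"):
        vis = t[(t["condition"] == "visual_only") & (t["reliability"] == rel)]
        f_vis = _psychometric(vis["eps_v"], (vis["response"] == 1).astype(float))
        pred = fusion_prediction(f_aud.sigma_, f_vis.sigma_)
        av = t[(t["condition"] == "audio_visual") & (t["reliability"] == rel)]
        mean_loc = (av["eps_a"] + av["eps_v"]) / 2.0
        mus = {}
        sig_meas = np.nan
        for delta, sub in av.groupby("delta"):
            f = _psychometric(
                mean_loc[sub.index], (sub["response"] == 1).astype(float)
            )
            if delta == 0:
                sig_meas = f.sigma_
            else:
                mus[float(delta)] = f.mu_
        w_meas, clipped = measured_visual_weight(mus[6.0], mus[-6.0], 6.0)
        rows.append(
            {
                "subject_id": data.subject_id,
                "group": data.group,
                "reliability": rel,
                "sigma_a": f_aud.sigma_,
                "sigma_v": f_vis.sigma_,
                "sigma_com_pred": pred.sigma_com,
                "sigma_com_meas": sig_meas,
                "w_v_pred": pred.w_v,
                "w_v_meas": w_meas,
                "w_v_clipped": clipped,
            }
        )
    return pd.DataFrame(rows)


def exp2_bias_table(data: ResponseData) -> pd.DataFrame:
    """Auditory bias vs disparity with nested polynomial fits (exp2)."""
    t = data.trials[(data.trials["experiment"] == "exp2") & (data.trials["condition"] == "audio_visual")]
    if not len(t):
        raise ValueError("no exp2 trials")
    rows = []
    for rel in ("high", "medium", "low"):
        sub = t[t["reliability"] == rel]
        biases = {}
        for delta, cell in sub.groupby("delta"):
            f = _psychometric(cell["eps_a"], (cell["response"] == 1).astype(float))
            biases[float(delta)] = -f.mu_  # bias: shift of the PSE toward the visual cue
        deltas = np.array(sorted(biases))
        bias = np.array([biases[d] for d in deltas])
        poly = DisparityPolynomial().fit(deltas, bias)
        for d, b in zip(deltas, bias):
            rows.append(
                {
                    "subject_id": data.subject_id,
                    "group": data.group,
                    "reliability": rel,
                    "delta": d,
                    "bias": b,
                    "a1": poly.coef_[1],
                    "a3": poly.coef_[3],
                    "r2_linear": poly.r_squared_by_order_["linear"],
                    "partial_r2_cubic": poly.partial_r2_cubic_,
                }
            )
    return pd.DataFrame(rows)


def explicit_curve_table(data: ResponseData, experiment="exp3") -> pd.DataFrame:
    """Common-cause (or synchrony) proportions per disparity with Gaussian fit."""
    t = data.trials[data.trials["experiment"] == experiment]
    if not len(t):
        raise ValueError(f"no {experiment} trials")
    g = t.groupby("delta")["response"].apply(lambda r: float((r == 1).mean()))
    deltas = g.index.to_numpy(float)
    props = g.to_numpy(float)
    fit = fit_gaussian_curve(deltas, props)
    return pd.DataFrame(
        {
            "subject_id": data.subject_id,
            "group": data.group,
            "experiment": experiment,
            "delta": deltas,
            "prop_common": props,
            "amplitude": fit.amplitude_,
            "mean": fit.mean_,
            "width": fit.width_,
            "r_squared": fit.r_squared_,
            "flat": fit.flat_,
        }
    )


def _regression_slope(x, y):
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[1])


def cmd_report(config: RunConfig, fits_dir: Optional[Path], dataset: Path) -> Path:
    """Emit figures and CSV tables for every analysis surface present."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(config.outdir)
    report = out / "report"
    report.mkdir(parents=True, exist_ok=True)
    frame = pd.read_csv(dataset)
    cohort = cohort_from_frame(frame)
    stamp = _stamp(config)

    summary: dict = dict(stamp)

    have = set(frame["experiment"].unique())
    if "exp1" in have:
        w = pd.concat([exp1_weight_table(r) for r in cohort], ignore_index=True)
        w.to_csv(report / "exp1_weights.csv", index=False)
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, (xm, xp, lab) in zip(
            axes,
            [("sigma_com_meas", "sigma_com_pred", "threshold (deg)"),
             ("w_v_meas", "w_v_pred", "visual weight")],
        ):
            for group, sub in w.groupby("group"):
                ax.scatter(sub[xm], sub[xp], label=group, alpha=0.7)
            lims = [w[[xm, xp]].min().min(), w[[xm, xp]].max().max()]
            ax.plot(lims, lims, "k--", lw=0.8)
            ax.set_xlabel(f"measured {lab}")
            ax.set_ylabel(f"predicted {lab}")
            ax.legend()
        fig.tight_layout()
        fig.savefig(report / "exp1_measured_vs_predicted.png", dpi=120)
        plt.close(fig)
        summary["weight_slope"] = _regression_slope(
            w["w_v_meas"].to_numpy(), w["w_v_pred"].to_numpy()
        )
        summary["threshold_slope"] = _regression_slope(
            w["sigma_com_meas"].to_numpy(), w["sigma_com_pred"].to_numpy()
        )

    if "exp2" in have:
        b = pd.concat([exp2_bias_table(r) for r in cohort], ignore_index=True)
        b.to_csv(report / "exp2_bias.csv", index=False)
        fig, ax = plt.subplots(figsize=(5, 4))
        for (group, rel), sub in b.groupby(["group", "reliability"]):
            m = sub.groupby("delta")["bias"].mean()
            ax.plot(m.index, m.values, marker="o", label=f"{group}/{rel}")
        ax.set_xlabel("disparity (deg)")
        ax.set_ylabel("auditory bias (deg)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(report / "exp2_bias_curves.png", dpi=120)
        plt.close(fig)

    for exp in ("exp3", "exp4"):
        if exp in have:
            c = pd.concat(
                [explicit_curve_table(r, exp) for r in cohort if exp in r.experiments()],
                ignore_index=True,
            )
            c.to_csv(report / f"{exp}_curves.csv", index=False)
            fig, ax = plt.subplots(figsize=(5, 4))
            for group, sub in c.groupby("group"):
                m = sub.groupby("delta")["prop_common"].mean()
                ax.plot(m.index, m.values, marker="o", label=group)
            ax.set_xlabel("disparity (deg)" if exp == "exp3" else "asynchrony (ms)")
            ax.set_ylabel("proportion common / synchronous")
            ax.legend()
            fig.tight_layout()
            fig.savefig(report / f"{exp}_curves.png", dpi=120)
            plt.close(fig)

    if fits_dir is not None and Path(fits_dir).exists():
        fits = []
        for path in sorted(Path(fits_dir).glob("*.json")):
            rec = json.loads(path.read_text())
            if rec.get("config_hash") != stamp["config_hash"]:
                raise ValueError(f"fit {path.name} does not match this config/dataset")
            fits.append(rec)
        rows = []
        for group in sorted({f["group"] for f in fits}):
            fms = [
                FittedModel(
                    params=ObserverParams.from_dict(f["params"]),
                    variant=f["variant"],
                    nll=f["nll"],
                    aic=f["aic"],
                    eve=f["eve"],
                    ci68=f["ci68"],
                    n_free_params=f["n_free_params"],
                    data_hash=f["data_hash"],
                )
                for f in fits
                if f["group"] == group
            ]
            cmp_df = compare_models(fms)
            cmp_df.insert(0, "group", group)
            rows.append(cmp_df)
        cmp_all = pd.concat(rows, ignore_index=True)
        cmp_all.to_csv(report / "model_comparison.csv", index=False)
        summary["model_comparison"] = cmp_all.to_dict(orient="records")

    (report / "summary.json").write_text(json.dumps(summary, indent=2, default=float) + "\n")
    return report
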