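"""Synthetic study-design generator.

Emulates the statistical structure of the real TDM cohort the model was
built on — 30 adults, median weight 72 kg (range 44-179), 2-10 doses of
1500 mg given 7-14 days apart, trough and end-of-infusion sampling at
each dose plus occasional extra sparse samples, creatinine clearance
31.7-283 mL/min — so that every pipeline stage can be exercised without
any patient data.  The generator returns both the observable event table
and the underlying truth (per-subject etas and parameters) for
parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import StudyDataset
from .pk import Regimen, _conc_matrix
from .population import PopulationModel, scaled_param_array

__all__ = ["StudyDesignConfig", "generate_study", "cockcroft_gault"]


@dataclass(frozen=True)
class StudyDesignConfig:
    """Design knobs for a synthetic cohort.

    Defaults emulate the modelled cohort; ``rich_sampling`` switches every
    subject to a fixed dense design (useful for recovery experiments).
    ``outlier_count``/``outlier_fold`` optionally corrupt that many random
    observations by the given fold-change.
    """

    n_subjects: int = 30
    dose_mg: float = 1500.0
    infusion_h: float = 0.5
    weight_median: float = 72.0
    weight_sigma_log: float = 0.22
    weight_bounds: tuple[float, float] = (44.0, 179.0)
    doses_min: int = 2
    doses_max: int = 10
    interval_days: tuple[float, float] = (7.0, 14.0)
    extra_samples_max: int = 2
    jitter_h: float = 0.25
    clcr_median: float = 66.2
    clcr_sigma_log: float = 0.45
    clcr_bounds: tuple[float, float] = (31.7, 283.0)
    outlier_count: int = 0
    outlier_fold: float = 10.0
    rich_sampling: bool = False
    rich_n_doses: int = 3
    rich_extra_samples: int = 2
    # washout visit after the last dose in the rich design: terminal-slope
    # estimation needs observation over ~2-3 terminal half-lives
    # (t1/2 ~ 17 d), which is what identifies the peripheral compartment
    rich_followup_days: tuple[float, float] = (42.0, 56.0)
    weight_sampler: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.doses_min < 2:
            raise ValueError("at least two doses per subject are required")
        if self.doses_max < self.doses_min:
            raise ValueError("doses_max must be >= doses_min")


# discrete distribution of doses-per-subject on 2..10, median 3 — mirrors a
# cohort where most patients get 2-4 doses and a long tail continues therapy
_DOSE_COUNT_PROBS = np.array(
    [0.25, 0.30, 0.15, 0.10, 0.07, 0.05, 0.04, 0.02, 0.02]
)


def _clipped_lognormal(
    rng: np.random.Generator,
    median: float,
    sigma: float,
    bounds: tuple[float, float],
    n: int,
) -> np.ndarray:
    """Log-normal draws (given median and log-SD) clipped by rejection."""
    out = np.empty(0)
    while out.size < n:
        draw = rng.lognormal(np.log(median), sigma, size=max(2 * n, 8))
        out = np.concatenate([out, draw[(draw >= bounds[0]) & (draw <= bounds[1])]])
    return out[:n]


def cockcroft_gault(age: float, weight: float, serum_creatinine: float, sex: str) -> float:
    """Creatinine clearance (mL/min) by the Cockcroft-Gault formula.

    ((140 - age) * weight) / (72 * Scr), multiplied by 0.85 for females.
    """
    if weight <= 0 or serum_creatinine <= 0 or age < 0:
        raise ValueError("age, weight and serum creatinine must be positive")
    clcr = (140.0 - age) * weight / (72.0 * serum_creatinine)
    if str(sex).lower() in ("f", "female", "1"):
        clcr *= 0.85
    return clcr


def generate_study(
    model: PopulationModel, design: StudyDesignConfig
) -> tuple[StudyDataset, dict]:
    """Draw one synthetic cohort from the generative model.

    Per subject: a body weight, dose schedule and sampling times per the
    design; true concentrations from the individual parameters; observed
    values with proportional residual noise (negative draws retained).
    Returns the dataset and a truth record with per-subject etas and true
    parameters.  Byte-reproducible given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    omegas = model.omegas
    rows = []
    truth: dict = {"subjects": {}, "seed": design.seed}
    outlier_candidates = []

    if design.weight_sampler == "uniform":
        weights = rng.uniform(*design.weight_bounds, size=design.n_subjects)
    else:
        weights = _clipped_lognormal(
            rng, design.weight_median, design.weight_sigma_log,
            design.weight_bounds, design.n_subjects,
        )
    clcrs = _clipped_lognormal(
        rng, design.clcr_median, design.clcr_sigma_log,
        design.clcr_bounds, design.n_subjects,
    )
    ages = rng.uniform(25.0, 90.0, size=design.n_subjects)
    sexes = rng.integers(0, 2, size=design.n_subjects)

    for i in range(design.n_subjects):
        sid = i
        weight = float(weights[i])
        if design.rich_sampling:
            n_doses = design.rich_n_doses
            intervals = np.full(n_doses - 1, 7.0 * 24.0)
        else:
            n_doses = int(
                rng.choice(
                    np.arange(design.doses_min, design.doses_max + 1),
                    p=_resized_probs(design),
                )
            )
            intervals = rng.uniform(
                design.interval_days[0] * 24.0,
                design.interval_days[1] * 24.0,
                size=n_doses - 1,
            )
        dose_times = np.concatenate([[0.0], np.cumsum(intervals)])
        fu_days = (
            design.rich_followup_days if design.rich_sampling
            else design.interval_days
        )
        follow_up = rng.uniform(fu_days[0] * 24.0, fu_days[1] * 24.0)

        sample_times = []
        for d, t0 in enumerate(dose_times):
            # end-of-infusion peak, jittered into the post-infusion phase
            sample_times.append(
                t0 + design.infusion_h + rng.uniform(0.0, design.jitter_h)
            )
            # trough immediately before the next dose (or a follow-up visit)
            t_next = dose_times[d + 1] if d + 1 < n_doses else t0 + follow_up
            sample_times.append(t_next - rng.uniform(0.0, design.jitter_h))
        if design.rich_sampling:
            sample_times.extend(
                rng.uniform(design.infusion_h, dose_times[-1] + follow_up,
                            size=design.rich_extra_samples)
            )
        else:
            n_extra = int(rng.integers(0, design.extra_samples_max + 1))
            if n_extra:
                sample_times.extend(
                    rng.uniform(design.infusion_h, dose_times[-1] + follow_up,
                                size=n_extra)
                )
        sample_times = np.sort(np.asarray(sample_times))

        eta = rng.normal(0.0, 1.0, size=4) * omegas
        params = scaled_param_array(model, weight) * np.exp(eta)
        true_conc = _conc_matrix(
            params[None, :],
            dose_times,
            np.full(n_doses, design.dose_mg / design.infusion_h),
            np.full(n_doses, design.infusion_h),
            sample_times,
        )[0]
        eps = rng.normal(0.0, model.resid_b, size=true_conc.size)
        dv = true_conc * (1.0 + eps)

        truth["subjects"][sid] = {
            "weight": weight,
            "eta": eta.tolist(),
            "params": params.tolist(),
        }
        common = {
            "WT": round(weight, 4),
            "CLCR": round(float(clcrs[i]), 4),
            "AGE": round(float(ages[i]), 1),
            "SEX": int(sexes[i]),
        }
        for t0 in dose_times:
            rows.append(
                {
                    "ID": sid, "TIME": round(float(t0), 4), "EVID": 1,
                    "AMT": design.dose_mg, "DUR": design.infusion_h,
                    "DV": np.nan, **common,
                }
            )
        for t, v in zip(sample_times, dv):
            rows.append(
                {
                    "ID": sid, "TIME": round(float(t), 4), "EVID": 0,
                    "AMT": np.nan, "DUR": np.nan, "DV": round(float(v), 6),
                    **common,
                }
            )
            outlier_candidates.append(len(rows) - 1)

    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"], kind="stable")
    df = df.reset_index(drop=True)

    injected = []
    if design.outlier_count:
        obs_idx = df.index[df["EVID"] == 0].to_numpy()
        chosen = rng.choice(obs_idx, size=design.outlier_count, replace=False)
        df.loc[chosen, "DV"] = df.loc[chosen, "DV"].abs() * design.outlier_fold
        injected = sorted(int(c) for c in chosen)
    truth["injected_outlier_rows"] = injected

    return StudyDataset(df), truth


def _resized_probs(design: StudyDesignConfig) -> np.ndarray:
    n = design.doses_max - design.doses_min + 1
    if design.doses_min == 2 and design.doses_max == 10:
        return _DOSE_COUNT_PROBS
    p = _DOSE_COUNT_PROBS[:n] if n <= _DOSE_COUNT_PROBS.size else np.concatenate(
        [_DOSE_COUNT_PROBS, np.full(n - _DOSE_COUNT_PROBS.size, 0.01)]
    )
    return p / p.sum()
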