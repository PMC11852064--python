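"""Longitudinal study dataset: dose and observation event records.

The canonical in-memory form is a pandas DataFrame of event rows in a
NONMEM-style dialect (one row per dose or observation, grouped by
subject), wrapped with validation and a compiled per-subject view used by
the likelihood machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

__all__ = ["StudyDataset", "SubjectData", "REQUIRED_COLUMNS", "COVARIATE_COLUMNS"]

REQUIRED_COLUMNS = ("ID", "TIME", "EVID", "AMT", "DUR", "DV", "WT")
COVARIATE_COLUMNS = ("CLCR", "AGE", "SEX", "ALB", "CRP", "HT")


@dataclass(frozen=True)
class SubjectData:
    """Compiled per-subject design: dose schedule, observations, covariates."""

    id: object
    weight: float
    dose_times: np.ndarray
    dose_rates: np.ndarray
    dose_durations: np.ndarray
    obs_times: np.ndarray
    obs_dv: np.ndarray
    covariates: dict[str, float] = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.obs_times.size


class StudyDataset:
    """Validated event table for estimation.

    Each subject must have at least one dose and one observation, all
    observations must fall strictly after the subject's first dose, and the
    baseline weight must be constant within subject.
    """

    def __init__(self, events: pd.DataFrame):
        self.events = _validate(events.reset_index(drop=True))

    @cached_property
    def subjects(self) -> list[SubjectData]:
        out = []
        for sid, grp in self.events.groupby("ID", sort=False):
            doses = grp[grp["EVID"] == 1]
            obs = grp[grp["EVID"] == 0]
            cov = {
                c.lower(): float(grp[c].iloc[0])
                for c in COVARIATE_COLUMNS
                if c in grp.columns and pd.notna(grp[c].iloc[0])
            }
            out.append(
                SubjectData(
                    id=sid,
                    weight=float(grp["WT"].iloc[0]),
                    dose_times=doses["TIME"].to_numpy(float),
                    dose_rates=(doses["AMT"] / doses["DUR"]).to_numpy(float),
                    dose_durations=doses["DUR"].to_numpy(float),
                    obs_times=obs["TIME"].to_numpy(float),
                    obs_dv=obs["DV"].to_numpy(float),
                    covariates=cov,
                )
            )
        return out

    @property
    def n_subjects(self) -> int:
        return self.events["ID"].nunique()

    @property
    def n_observations(self) -> int:
        return int((self.events["EVID"] == 0).sum())

    def observation_index(self) -> pd.DataFrame:
        """Observation rows (EVID 0) with their original row positions."""
        return self.events[self.events["EVID"] == 0]

    def subset_subjects(self, ids) -> "StudyDataset":
        mask = self.events["ID"].isin(set(ids))
        return StudyDataset(self.events[mask])

    def drop_rows(self, positions) -> "StudyDataset":
        """New dataset without the given row positions (e.g. flagged outliers).

        Subjects left without observations are dropped entirely (with a
        warning from the caller's side when relevant).
        """
        import warnings

        reduced = self.events.drop(index=list(positions))
        keep = []
        for sid, grp in reduced.groupby("ID", sort=False):
            if (grp["EVID"] == 0).any():
                keep.append(sid)
            else:
                warnings.warn(
                    f"subject {sid!r} lost all observations and was dropped",
                    stacklevel=2,
                )
        return StudyDataset(reduced[reduced["ID"].isin(keep)])

    def resample_subjects(self, rng: np.random.Generator) -> "StudyDataset":
        """Bootstrap resample: subjects drawn with replacement to original n.

        Re-labels drawn subjects 0..n-1 so duplicates remain distinct.
        """
        ids = list(dict.fromkeys(self.events["ID"]))
        drawn = rng.choice(len(ids), size=len(ids), replace=True)
        blocks = []
        for new_id, idx in enumerate(drawn):
            block = self.events[self.events["ID"] == ids[idx]].copy()
            block["ID"] = new_id
            blocks.append(block)
        return StudyDataset(pd.concat(blocks, ignore_index=True))


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    if not df["EVID"].isin([0, 1]).all():
        raise ValueError("EVID must be 0 (observation) or 1 (dose)")
    if (df["TIME"] < 0).any():
        raise ValueError("event times must be >= 0")
    doses = df["EVID"] == 1
    if df.loc[doses, "AMT"].isna().any() or (df.loc[doses, "AMT"] <= 0).any():
        raise ValueError("dose rows must carry a positive AMT")
    if df.loc[doses, "DUR"].isna().any() or (df.loc[doses, "DUR"] <= 0).any():
        raise ValueError("dose rows must carry a positive infusion DUR")
    if df.loc[~doses, "DV"].isna().any():
        raise ValueError("observation rows must carry a DV value")
    if df.loc[doses, "DV"].notna().any():
        raise ValueError("dose rows must not carry a DV value")
    for sid, grp in df.groupby("ID", sort=False):
        if grp["WT"].nunique() > 1:
            raise ValueError(f"subject {sid!r} has a non-constant baseline weight")
        g_doses = grp[grp["EVID"] == 1]
        g_obs = grp[grp["EVID"] == 0]
        if g_doses.empty or g_obs.empty:
            raise ValueError(
                f"subject {sid!r} needs at least one dose and one observation"
            )
        if (g_obs["TIME"] <= g_doses["TIME"].min()).any():
            raise ValueError(
                f"subject {sid!r} has observations at or before the first dose"
            )
        if not g_doses["TIME"].is_monotonic_increasing:
            raise ValueError(f"subject {sid!r} has unsorted dose times")
    return df
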