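"""Condition-labeled decay observations with replicate structure."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COLUMNS = ["time_min", "value", "replicate"]


@dataclass(frozen=True)
class DecayDataset:
    """Relative mRNA abundance vs. time after transcription shut-off.

    Observations are rows (time_min, value, replicate); replicates are
    independent biological measurements of the same condition.  ``normalized``
    records whether each replicate has been scaled to 1 at its reference
    (earliest) time point.
    """

    condition: str
    observations: pd.DataFrame = field(repr=False)
    normalized: bool = False

    def __post_init__(self):
        df = self.observations
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"observations missing columns {missing}")
        df = df.loc[:, _COLUMNS].reset_index(drop=True)
        if (df["value"] <= 0).any():
            raise ValueError("abundances must be > 0")
        if (df["time_min"] < 0).any():
            raise ValueError("times must be >= 0")
        if df.duplicated(["replicate", "time_min"]).any():
            raise ValueError("duplicate (replicate, time) observation")
        object.__setattr__(self, "observations", df)

    @property
    def times(self) -> np.ndarray:
        return self.observations["time_min"].to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.observations["value"].to_numpy(dtype=float)

    @property
    def replicates(self) -> tuple:
        return tuple(sorted(self.observations["replicate"].unique()))

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def normalize(self) -> "DecayDataset":
        """Scale each replicate so its earliest-time value equals 1."""
        if self.normalized:
            return self
        df = self.observations.copy()
        for rep, grp in df.groupby("replicate"):
            ref = grp.loc[grp["time_min"].idxmin(), "value"]
            df.loc[grp.index, "value"] = grp["value"] / ref
        return DecayDataset(self.condition, df, normalized=True)

    def averaged(self) -> "DecayDataset":
        """Collapse replicates to their mean at each time (single replicate 'mean')."""
        df = (
            self.observations.groupby("time_min", as_index=False)["value"]
            .mean()
            .assign(replicate="mean")
        )
        return DecayDataset(self.condition, df, normalized=self.normalized)

    @classmethod
    def from_arrays(
        cls,
        condition: str,
        times,
        values,
        replicate="r1",
        normalized: bool = False,
    ) -> "DecayDataset":
        df = pd.DataFrame(
            {"time_min": np.asarray(times, float), "value": np.asarray(values, float)}
        )
        df["replicate"] = replicate
        return cls(condition, df, normalized=normalized)
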