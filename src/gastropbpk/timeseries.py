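"""Replicate-aware concentration-time observations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError

COMPARTMENTS = (
    "blood",
    "plasma",
    "stomach_total",
    "stomach_precursor",
    "stomach_deep",
    "ach",
)

#: unit string expected for each compartment label
UNIT_FOR_COMPARTMENT = {c: ("nmol_per_g" if c == "ach" else "uM") for c in COMPARTMENTS}


@dataclass
class ConcentrationTimeSeries:
    """Observed concentrations for one compartment.

    Each record is one terminal (destructive) sample from one animal, so
    observations are independent across times and replicates.  Times are
    minutes post dose; values are μM for drug compartments and nmol per
    g wet tissue for ACh.
    """

    compartment: str
    times: np.ndarray  # min
    values: np.ndarray
    animal_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise InvalidArgumentError(f"unknown compartment {self.compartment!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InvalidArgumentError("times and values must be 1-D and aligned")
        if np.any(self.times < 0):
            raise InvalidArgumentError("observation times must be >= 0")
        if np.any(self.values < 0):
            raise InvalidArgumentError("observed concentrations must be >= 0")
        if self.animal_ids is None:
            self.animal_ids = np.array([f"r{i + 1}" for i in range(len(self.times))])
        else:
            self.animal_ids = np.asarray(self.animal_ids, dtype=object)
            if self.animal_ids.shape != self.times.shape:
                raise InvalidArgumentError("animal_ids must align with times")

    @property
    def unit(self) -> str:
        return UNIT_FOR_COMPARTMENT[self.compartment]

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_timepoints(self) -> int:
        return len(np.unique(self.times))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns time_min, compartment, value, unit, animal_id."""
        return pd.DataFrame(
            {
                "time_min": self.times,
                "compartment": self.compartment,
                "value": self.values,
                "unit": self.unit,
                "animal_id": self.animal_ids,
            }
        )

    def timepoint_means(self) -> pd.DataFrame:
        """Per-timepoint mean and SE across replicate animals."""
        df = self.to_frame().groupby("time_min")["value"]
        out = df.agg(["mean", "sem", "count"]).reset_index()
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame, compartment: str) -> "ConcentrationTimeSeries":
        sub = df[df["compartment"] == compartment]
        return cls(
            compartment=compartment,
            times=sub["time_min"].to_numpy(dtype=float),
            values=sub["value"].to_numpy(dtype=float),
            animal_ids=sub["animal_id"].to_numpy(dtype=object),
        )
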