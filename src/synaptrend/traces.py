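"""Fluorescence trace container shared by the imaging generators and analyses."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class FluorescenceTrace:
    """A fluorescence time series with its stimulus times.

    ``values`` is on whatever scale the modality uses (ΔG/R for Ca2+
    linescans, raw F or ΔF/F0 for glutamate-sensor recordings); ``meta``
    carries ground-truth annotations when the trace was generated.
    """

    time_ms: np.ndarray
    values: np.ndarray
    stim_times: tuple[float, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_ms.shape != self.values.shape:
            raise ValueError("time and value arrays must have equal shape")
        self.stim_times = tuple(float(s) for s in self.stim_times)

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def duration_ms(self) -> float:
        return float(self.time_ms[-1] - self.time_ms[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.time_ms, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, stim_times: Sequence[float]) -> "FluorescenceTrace":
        df = pd.read_csv(path)
        return cls(time_ms=df["time_ms"].to_numpy(),
                   values=df["value"].to_numpy(),
                   stim_times=tuple(stim_times))
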