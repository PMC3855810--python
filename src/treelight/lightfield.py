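"""Container for a light proxy evaluated at grid cells or trees."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Recognized light-proxy scales.
KINDS = ("cai", "log_cai", "nci")


@dataclass
class LightField:
    """Values of a light proxy at a set of focal points.

    ``ids`` are cell ids (int) or tree ids (str); ``kind`` records the scale:
    ``cai`` (fraction of full irradiance, in (0, 1]), ``log_cai`` (its natural
    log, <= 0 for raw CAI but conversions from NCI may exceed the observed
    range), or ``nci`` (raw neighborhood competition index, >= 0).
    """

    ids: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.ids.shape != self.values.shape:
            raise ValueError("ids and values must have equal length")
        if self.kind not in KINDS:
            raise ValueError(f"unknown light-field kind {self.kind!r}")
        if self.kind == "cai" and ((self.values <= 0) | (self.values > 1)).any():
            raise ValueError("CAI values must lie in (0, 1]")

    def log(self) -> "LightField":
        if self.kind != "cai":
            raise ValueError("log() applies to CAI fields only")
        return LightField(self.ids, np.log(self.values), "log_cai")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.ids, name="id"))

    def __len__(self) -> int:
        return len(self.values)
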