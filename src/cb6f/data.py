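"""Dataset container and CSV schema for paired PAM + gas-exchange series.

One row per observation.  Dark rows carry the dark-adapted reference levels
F_m and F_o (and no steady-state fluorescence); light rows carry F_s together
with the light-adapted F_m' and F_o'.  Gas-exchange columns follow LI-6800
conventions.  Missing values are empty fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SCHEMA", "Dataset"]

SCHEMA = [
    "time_s",
    "record_type",
    "Q",
    "T_leaf",
    "C_a",
    "O_mbar",
    "P_bar",
    "A",
    "E_mmol",
    "g_tc",
    "F_s",
    "F_m_or_Fm_prime",
    "F_o_or_Fo_prime",
]


@dataclass
class Dataset:
    """Ordered paired measurement series with dark reference records."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SCHEMA if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset is missing columns: {missing}")
        bad = set(self.frame["record_type"]) - {"dark", "light"}
        if bad:
            raise ValueError(f"unknown record_type values: {sorted(bad)}")
        if not (self.frame["record_type"] == "dark").any():
            raise ValueError("dataset needs at least one dark record (F_m, F_o)")
        t = self.frame["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError("timestamps must be monotone non-decreasing")

    # -- convenience views -------------------------------------------------
    @property
    def dark(self) -> pd.DataFrame:
        return self.frame[self.frame["record_type"] == "dark"]

    @property
    def light(self) -> pd.DataFrame:
        return self.frame[self.frame["record_type"] == "light"]

    def ascending(self) -> "Dataset":
        """Restrict light rows to the ascending light phase (up to peak Q).

        Dark rows are kept: they carry the F_m/F_o references the inversion
        needs.
        """
        q = self.frame["Q"].to_numpy(dtype=float)
        i_peak = int(np.argmax(q))
        keep = (np.arange(len(q)) <= i_peak) | (
            self.frame["record_type"] == "dark"
        ).to_numpy()
        return Dataset(self.frame[keep].reset_index(drop=True))

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, columns=SCHEMA, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        frame = pd.read_csv(path)
        missing = [c for c in SCHEMA if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        return cls(frame[SCHEMA].copy())

    def __len__(self) -> int:
        return len(self.frame)
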