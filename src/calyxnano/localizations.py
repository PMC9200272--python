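"""Containers and I/O for 3D single-molecule localization data.

All coordinates are in nanometres throughout the package.  A localization
table is the currency of the analysis half: one row per detected fluorophore
with columns ``x_nm, y_nm, z_nm, channel``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CSV_COLUMNS = ["x_nm", "y_nm", "z_nm", "channel"]


@dataclass
class LocalizationSet:
    """One channel's 3D localizations (nm).

    Parameters
    ----------
    xyz : (n, 3) float array
        Localization coordinates in nm.
    channel : str
        Channel label (e.g. ``"RIM1"``, ``"PSD95"``).
    """

    xyz: np.ndarray
    channel: str = "ch0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("localization coordinates must be finite")

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def subset(self, mask: np.ndarray) -> "LocalizationSet":
        return LocalizationSet(self.xyz[mask], self.channel, dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_nm": self.xyz[:, 0],
                "y_nm": self.xyz[:, 1],
                "z_nm": self.xyz[:, 2],
                "channel": self.channel,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, channel: str | None = None) -> "LocalizationSet":
        if channel is not None:
            df = df[df["channel"] == channel]
        elif df["channel"].nunique() == 1:
            channel = str(df["channel"].iloc[0])
        else:
            raise ValueError("multiple channels present; pass channel=...")
        return cls(df[["x_nm", "y_nm", "z_nm"]].to_numpy(float), channel)

    @classmethod
    def from_csv(cls, path, channel: str | None = None) -> "LocalizationSet":
        return cls.from_frame(pd.read_csv(path), channel)


def read_channels(path) -> dict[str, LocalizationSet]:
    """Read a localization CSV and split it into per-channel sets."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"localization CSV missing columns {missing}")
    return {
        str(ch): LocalizationSet(g[["x_nm", "y_nm", "z_nm"]].to_numpy(float), str(ch))
        for ch, g in df.groupby("channel", sort=True)
    }


def write_channels(path, sets) -> None:
    pd.concat([s.to_frame() for s in sets], ignore_index=True).to_csv(path, index=False)
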