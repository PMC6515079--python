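"""Spot-volume tables: the gels x spots fluorescence matrices for one channel."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpotVolumeTable",
    "TableError",
    "BD_ASC_PLUS",
    "BD_ASC_MINUS",
    "SPILL_SCAN",
    "PQD_POST",
    "PQD_CORRECTED",
    "SNO_RATIO",
]

# measured channels
BD_ASC_PLUS = "BD_ASC_PLUS"      # BODIPY scan of ascorbate-treated gels
BD_ASC_MINUS = "BD_ASC_MINUS"    # BODIPY scan of neocuproine-stabilised gels
SPILL_SCAN = "SPILL_SCAN"        # pre-stain BODIPY spillover in the PQD window
PQD_POST = "PQD_POST"            # post-stain Pro-Q Diamond scan
# derived channels
PQD_CORRECTED = "PQD_CORRECTED"  # PQD_POST minus SPILL_SCAN, clamped at zero
SNO_RATIO = "SNO_RATIO"          # per-sample ASC_MINUS / cognate ASC_PLUS ratio

MEASURED_CHANNELS = (BD_ASC_PLUS, BD_ASC_MINUS, SPILL_SCAN, PQD_POST)


class TableError(ValueError):
    """Raised on malformed or inconsistent spot-volume tables."""


@dataclass
class SpotVolumeTable:
    """A gels x spots matrix of non-negative fluorescence volumes.

    ``values`` is a DataFrame indexed by gel id (or sample id for derived
    per-sample ratio channels) with one column per spot id.  The ``normalized``
    flag guards against applying bias factors twice.
    """

    channel: str
    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise TableError(f"{self.channel}: duplicate gel ids")
        if self.values.columns.has_duplicates:
            raise TableError(f"{self.channel}: duplicate spot ids")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise TableError(f"{self.channel}: non-finite volumes")
        if (arr < 0).any():
            raise TableError(f"{self.channel}: negative volumes")

    @property
    def gel_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def spot_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_spots(self) -> int:
        return self.values.shape[1]

    def totals(self) -> pd.Series:
        """Per-gel sum of all spot volumes."""
        return self.values.sum(axis=1)

    def with_values(self, values: pd.DataFrame, **kw) -> "SpotVolumeTable":
        return replace(self, values=values, **kw)

    # -- tidy interchange ------------------------------------------------ #
    def to_tidy(self) -> pd.DataFrame:
        """Long format with columns gel_id, channel, spot_id, volume."""
        long = self.values.stack().rename("volume").reset_index()
        long.columns = ["gel_id", "spot_id", "volume"]
        long.insert(1, "channel", self.channel)
        return long

    @classmethod
    def from_tidy(cls, frame: pd.DataFrame, normalized: bool = False) -> "SpotVolumeTable":
        channels = frame["channel"].unique()
        if len(channels) != 1:
            raise TableError(f"expected one channel, found {sorted(channels)}")
        dup = frame.duplicated(subset=["gel_id", "spot_id"])
        if dup.any():
            first = frame.loc[dup, ["gel_id", "spot_id"]].iloc[0]
            raise TableError(
                f"duplicate (gel, spot) entry: ({first['gel_id']}, {first['spot_id']})"
            )
        wide = frame.pivot(index="gel_id", columns="spot_id", values="volume")
        if wide.isna().any().any():
            raise TableError(f"{channels[0]}: spot set differs between gels")
        wide.index.name = None
        wide.columns.name = None
        return cls(channel=str(channels[0]), values=wide, normalized=normalized)


def check_same_grid(a: SpotVolumeTable, b: SpotVolumeTable) -> None:
    """Require two tables to share gel and spot sets (same physical scans)."""
    if list(a.values.index) != list(b.values.index):
        raise TableError(f"{a.channel} and {b.channel} differ in gel sets")
    if list(a.values.columns) != list(b.values.columns):
        raise TableError(f"{a.channel} and {b.channel} differ in spot sets")
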