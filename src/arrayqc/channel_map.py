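"""Channel lookup table (LUT) for a multi-array Utah implant.

Three indexing systems identify the same electrode:

* global ID 1..1024 across the whole implant,
* (nsp_id 1..8, within_nsp 1..128) as stored in the per-NSP raw files,
* (array_id 1..16, within_array 1..64) on the physical 8x8 arrays.

Each NSP digitises two arrays (within-NSP channels 1-64 are the first array of
the pair, 65-128 the second), and each hardware reference wire serves the same
two arrays, so reference group k covers arrays 2k-1 and 2k.  Most arrays sit
in V1; a configurable subset (default arrays 1 and 2) is in V4.

Within-array numbering is fixed to row-major order of the 8x8 grid.  The real
implants' wiring order is a property of each monkey's deposited LUT, which
should be loaded with :func:`read_lut` when working with real data.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChannelLookupError, ConfigurationError

LUT_COLUMNS = [
    "global_id", "nsp_id", "within_nsp", "array_id", "within_array",
    "area", "reference_group",
]


@dataclass(frozen=True)
class ChannelRecord:
    global_id: int
    nsp_id: int
    within_nsp: int
    array_id: int
    within_array: int
    area: str
    reference_group: int


class LUT:
    """Bijective lookup table over the three channel indexing systems."""

    def __init__(self, table: pd.DataFrame):
        missing = set(LUT_COLUMNS) - set(table.columns)
        if missing:
            raise ConfigurationError(f"LUT missing columns: {sorted(missing)}")
        t = table[LUT_COLUMNS].reset_index(drop=True)
        for key in ("global_id", ["nsp_id", "within_nsp"], ["array_id", "within_array"]):
            if t.duplicated(subset=key).any():
                raise ConfigurationError(f"LUT not bijective in {key}")
        self.table = t
        self._by_global = {int(r.global_id): ChannelRecord(**r._asdict())
                           for r in t.itertuples(index=False)}
        self._by_nsp = {(r.nsp_id, r.within_nsp): r.global_id
                        for r in t.itertuples(index=False)}
        self._by_array = {(r.array_id, r.within_array): r.global_id
                          for r in t.itertuples(index=False)}

    def __len__(self) -> int:
        return len(self.table)

    # -- queries ---------------------------------------------------------
    def record(self, global_id: int) -> ChannelRecord:
        try:
            return self._by_global[int(global_id)]
        except KeyError:
            raise ChannelLookupError(f"global_id {global_id} not in LUT") from None

    def from_nsp(self, nsp_id: int, within_nsp: int) -> ChannelRecord:
        key = (int(nsp_id), int(within_nsp))
        if key not in self._by_nsp:
            raise ChannelLookupError(
                f"(nsp {nsp_id}, channel {within_nsp}) is not a neural channel")
        return self.record(self._by_nsp[key])

    def from_array(self, array_id: int, within_array: int) -> ChannelRecord:
        key = (int(array_id), int(within_array))
        if key not in self._by_array:
            raise ChannelLookupError(f"(array {array_id}, electrode {within_array}) not in LUT")
        return self.record(self._by_array[key])

    def globals_for_array(self, array_id: int) -> np.ndarray:
        sel = self.table[self.table.array_id == array_id]
        if sel.empty:
            raise ChannelLookupError(f"array {array_id} not in LUT")
        return sel.sort_values("within_array").global_id.to_numpy()

    def globals_for_nsp(self, nsp_id: int) -> np.ndarray:
        sel = self.table[self.table.nsp_id == nsp_id]
        if sel.empty:
            raise ChannelLookupError(f"nsp {nsp_id} not in LUT")
        return sel.sort_values("within_nsp").global_id.to_numpy()

    def reference_groups(self) -> dict[int, np.ndarray]:
        return {int(g): sub.global_id.to_numpy()
                for g, sub in self.table.groupby("reference_group")}

    @property
    def n_arrays(self) -> int:
        return int(self.table.array_id.nunique())

    @property
    def n_nsps(self) -> int:
        return int(self.table.nsp_id.nunique())


def build_lut(n_arrays: int = 16, electrodes_per_array: int = 64,
              v4_arrays: set[int] | frozenset[int] = frozenset({1, 2})) -> LUT:
    """Construct the default LUT: arrays 2k-1, 2k on NSP k, sharing reference k."""
    if n_arrays % 2:
        raise ConfigurationError("n_arrays must be even (two arrays per NSP)")
    v4 = set(int(a) for a in v4_arrays)
    if not v4 <= set(range(1, n_arrays + 1)):
        raise ConfigurationError(f"v4_arrays {sorted(v4)} outside 1..{n_arrays}")

    e = electrodes_per_array
    array_id = np.repeat(np.arange(1, n_arrays + 1), e)
    within_array = np.tile(np.arange(1, e + 1), n_arrays)
    global_id = np.arange(1, n_arrays * e + 1)
    nsp_id = (array_id + 1) // 2
    # first array of each pair occupies within-NSP channels 1..e, second e+1..2e
    within_nsp = within_array + ((array_id - 1) % 2) * e
    area = np.where(np.isin(array_id, sorted(v4)), "V4", "V1")
    reference_group = nsp_id.copy()

    return LUT(pd.DataFrame({
        "global_id": global_id, "nsp_id": nsp_id, "within_nsp": within_nsp,
        "array_id": array_id, "within_array": within_array,
        "area": area, "reference_group": reference_group,
    }))


def convert_index(lut: LUT, *, global_id: int | None = None,
                  nsp: tuple[int, int] | None = None,
                  array: tuple[int, int] | None = None) -> ChannelRecord:
    """Resolve any one of the three index systems to the full record."""
    given = [x is not None for x in (global_id, nsp, array)]
    if sum(given) != 1:
        raise ChannelLookupError("specify exactly one of global_id, nsp, array")
    if global_id is not None:
        return lut.record(global_id)
    if nsp is not None:
        return lut.from_nsp(*nsp)
    return lut.from_array(*array)


def write_lut(lut: LUT, path: str | Path) -> None:
    lut.table.to_csv(path, index=False)


def read_lut(path: str | Path) -> LUT:
    return LUT(pd.read_csv(path))
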