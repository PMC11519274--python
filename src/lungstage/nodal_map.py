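"""IASLC nodal-station map and regionality resolution.

Clinical N staging hinges on where a malignant node sits relative to the
primary tumor: ipsilateral hilar/peripheral stations (10-14) are N1,
ipsilateral mediastinal stations and the subcarinal station are N2, and
contralateral or supraclavicular involvement is N3.  Nodes outside the
IASLC map (axillary, abdominal, ...) are not regional at all — they are
distant disease and route to the M category.

The station table ships as a versioned, human-readable TSV
(``data/iaslc_stations.tsv``) so that the encoded map can be audited
without reading code; the module refuses to load a malformed table.
"""

from __future__ import annotations

import enum
from functools import lru_cache
from importlib import resources
from typing import Mapping

from .findings import Laterality, Side

__all__ = ["RegionClass", "resolve_station", "load_station_table", "StationRule"]


class RegionClass(enum.Enum):
    """Regionality of a nodal finding relative to the primary tumor."""

    N1_REGIONAL = "N1"
    N2_REGIONAL = "N2"
    N3_REGIONAL = "N3"
    EXTRATHORACIC = "extrathoracic"

    @property
    def n_rank(self) -> int:
        """Rank within the N ladder (N1 < N2 < N3); extrathoracic has none."""
        if self is RegionClass.EXTRATHORACIC:
            raise ValueError("extrathoracic findings do not contribute to N")
        return {"N1": 1, "N2": 2, "N3": 3}[self.value]


class StationRule:
    """One row of the station table."""

    __slots__ = ("station", "description", "ipsilateral", "contralateral")

    def __init__(self, station: str, description: str, ipsilateral: str, contralateral: str):
        self.station = station
        self.description = description
        self.ipsilateral = ipsilateral
        self.contralateral = contralateral


_CLASS_TOKENS = {"N1", "N2", "N3", "extrathoracic"}


def _parse_table(text: str) -> dict[str, StationRule]:
    rows: dict[str, StationRule] = {}
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen:
            if fields != ["station", "description", "ipsilateral", "contralateral"]:
                raise ValueError(f"station table line {lineno}: unexpected header {fields}")
            header_seen = True
            continue
        if len(fields) != 4:
            raise ValueError(f"station table line {lineno}: expected 4 fields, got {len(fields)}")
        station, desc, ipsi, contra = fields
        if station in rows:
            raise ValueError(f"station table line {lineno}: duplicate station {station!r}")
        if ipsi not in _CLASS_TOKENS or contra not in _CLASS_TOKENS:
            raise ValueError(f"station table line {lineno}: invalid class token in {fields}")
        if (ipsi == "extrathoracic") != (contra == "extrathoracic"):
            raise ValueError(f"station table line {lineno}: station cannot be half extrathoracic")
        rows[station] = StationRule(station, desc, ipsi, contra)
    if not header_seen:
        raise ValueError("station table has no header row")
    missing = [s for s in map(str, range(1, 15)) if s not in rows]
    if missing:
        raise ValueError(f"station table is missing IASLC stations: {missing}")
    return rows


@lru_cache(maxsize=1)
def load_station_table() -> Mapping[str, StationRule]:
    """Load and validate the packaged station table (cached)."""
    text = resources.files("lungstage.data").joinpath("iaslc_stations.tsv").read_text(encoding="utf-8")
    return _parse_table(text)


def resolve_station(
    station: str,
    station_side: Side | str,
    primary_side: Laterality | str,
) -> RegionClass:
    """Resolve a nodal station to its regionality class.

    Parameters
    ----------
    station
        IASLC station identifier ``"1"``–``"14"`` or an extrathoracic
        token from the station table (e.g. ``"axillary"``).
    station_side
        Recorded side of the node (``left``/``right``/``midline``).
    primary_side
        Side of the primary tumor.

    Notes
    -----
    Station 7 is N2 from either primary side.  Stations 5/6 are
    left-sided structures: they behave as ipsilateral mediastinal (N2)
    for a left primary and contralateral (N3) for a right primary.
    Station 1 (supraclavicular zone) is N3 regardless of side.
    """
    side = Side(station_side)
    p_side = Laterality(primary_side)
    table = load_station_table()
    rule = table.get(str(station).strip())
    if rule is None:
        raise ValueError(f"unknown nodal station token: {station!r}")
    if rule.ipsilateral == "extrathoracic":
        return RegionClass.EXTRATHORACIC
    if rule.station == "7":
        # midline by definition; side-independent
        chosen = rule.ipsilateral
    elif rule.station in {"5", "6"}:
        chosen = rule.ipsilateral if p_side is Laterality.LEFT else rule.contralateral
    else:
        if side is Side.MIDLINE:
            raise ValueError(f"station {rule.station} cannot be resolved from a midline recording")
        ipsi = (side.value == p_side.value)
        chosen = rule.ipsilateral if ipsi else rule.contralateral
    return {"N1": RegionClass.N1_REGIONAL, "N2": RegionClass.N2_REGIONAL, "N3": RegionClass.N3_REGIONAL}[chosen]
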