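"""Season definitions: fixed hemispheric seasons and moving 3-month windows.

A season is a 3-month window identified by its centre month.  The
fixed seasons follow the usual meteorological convention: Northern
Hemisphere spring is March–May (centred on April), summer June–August
(July), autumn September–November (October); Southern Hemisphere
seasons are offset by six months.  The moving-window variant slides the
same 3-month window through all twelve centre months, wrapping the
year boundary, so seasonality that peaks outside the fixed windows
(e.g. large lakes whose thermal maximum falls in September) is still
captured.

Months are indexed 1-based with January = 1 throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

SeasonName = Literal["spring", "summer", "autumn", "custom"]
Hemisphere = Literal["north", "south"]

_FIXED_CENTRE_NORTH: dict[str, int] = {"spring": 4, "summer": 7, "autumn": 10}
_HEMISPHERES = ("north", "south")


@dataclass(frozen=True)
class SeasonDefinition:
    """A 3-month season window centred on ``centre_month`` (1–12)."""

    name: SeasonName
    centre_month: int
    window: tuple[int, int, int]
    hemisphere: Hemisphere

    def __post_init__(self) -> None:
        if not 1 <= self.centre_month <= 12:
            raise ValueError(f"centre_month must be in 1..12, got {self.centre_month}")
        if self.hemisphere not in _HEMISPHERES:
            raise ValueError(f"unknown hemisphere: {self.hemisphere!r}")
        if self.window != window_around(self.centre_month):
            raise ValueError("window must be (centre-1, centre, centre+1) mod 12")


def window_around(centre_month: int) -> tuple[int, int, int]:
    """The (preceding, centre, following) months, wrapping the year."""
    prev = (centre_month - 2) % 12 + 1
    nxt = centre_month % 12 + 1
    return (prev, centre_month, nxt)


def season_for(name: str, hemisphere: str) -> SeasonDefinition:
    """Look up a fixed season for a hemisphere.

    >>> season_for("spring", "north").window
    (3, 4, 5)
    >>> season_for("summer", "south").centre_month
    1
    """
    if name not in _FIXED_CENTRE_NORTH:
        raise ValueError(
            f"unknown season {name!r}; expected one of {sorted(_FIXED_CENTRE_NORTH)}"
        )
    if hemisphere not in _HEMISPHERES:
        raise ValueError(f"unknown hemisphere: {hemisphere!r}")
    centre = _FIXED_CENTRE_NORTH[name]
    if hemisphere == "south":
        centre = (centre + 5) % 12 + 1  # six calendar months later
    return SeasonDefinition(name, centre, window_around(centre), hemisphere)  # type: ignore[arg-type]


def moving_windows(hemisphere: str = "north") -> list[SeasonDefinition]:
    """All twelve 3-month windows, one centred on each calendar month."""
    if hemisphere not in _HEMISPHERES:
        raise ValueError(f"unknown hemisphere: {hemisphere!r}")
    return [
        SeasonDefinition("custom", m, window_around(m), hemisphere)  # type: ignore[arg-type]
        for m in range(1, 13)
    ]


def hemisphere_of(latitude: float) -> Hemisphere:
    """Hemisphere assignment: latitude >= 0 is north (equator included)."""
    return "north" if latitude >= 0 else "south"
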