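"""Geographic state space for time-stratified range evolution.

Areas are discrete biogeographic units; a *range* is a non-empty set of
areas, encoded as a bitmask over area indices. Connectivity between areas
is piecewise-constant in time: each :class:`TimeSlice` carries a symmetric
0/1 adjacency matrix that says which pairs of areas were joined (by land
or a plausible dispersal corridor) during that interval. A range is
considered biologically plausible in a slice when its areas form a single
connected component of the slice's adjacency graph; the model's state
space is the union of the per-slice plausible ranges plus the absorbing
null (globally extinct) range.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Area",
    "TimeSlice",
    "GeoModel",
    "is_connected_range",
    "enumerate_allowed_ranges",
    "slice_at",
    "range_to_codes",
    "codes_to_range",
    "cycad_geography",
]

NULL_RANGE = 0  # bitmask of the absorbing extinct state


@dataclass(frozen=True)
class Area:
    """One biogeographic unit.

    ``latitude_class`` ("high" or "low") is used only when aggregating
    event counts into high- versus low-latitude totals.
    """

    index: int
    code: str
    name: str
    latitude_class: str = "low"

    def __post_init__(self):
        if self.latitude_class not in ("high", "low"):
            raise ValueError(
                f"latitude_class must be 'high' or 'low', got {self.latitude_class!r}"
            )


@dataclass
class TimeSlice:
    """A time interval (younger_bound, older_bound] Ma with fixed connectivity."""

    older_bound: float
    younger_bound: float
    adjacency: np.ndarray

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=int)
        a = self.adjacency
        if self.older_bound <= self.younger_bound:
            raise ValueError("older_bound must exceed younger_bound")
        if self.younger_bound < 0:
            raise ValueError("younger_bound must be >= 0 Ma")
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(self.adjacency, 1)

    @property
    def n_areas(self) -> int:
        return self.adjacency.shape[0]


def _bits(mask: int) -> list[int]:
    out = []
    a = 0
    while mask:
        if mask & 1:
            out.append(a)
        mask >>= 1
        a += 1
    return out


def is_connected_range(range_mask: int, adjacency: np.ndarray) -> bool:
    """True iff the occupied areas form one connected component.

    A singleton is always connected. The null range is rejected.
    """
    if range_mask == NULL_RANGE:
        raise ValueError("empty range")
    areas = _bits(range_mask)
    if len(areas) == 1:
        return True
    adjacency = np.asarray(adjacency)
    seen = {areas[0]}
    stack = [areas[0]]
    members = set(areas)
    while stack:
        b = stack.pop()
        for a in members - seen:
            if adjacency[b, a]:
                seen.add(a)
                stack.append(a)
    return seen == members


def enumerate_allowed_ranges(adjacency: np.ndarray, max_range_size: int) -> list[int]:
    """All non-null connected ranges of size <= max_range_size.

    Returned sorted by (size, bitmask value), which is the canonical state
    ordering used throughout the package.
    """
    if max_range_size < 1:
        raise ValueError("max_range_size must be >= 1")
    adjacency = np.asarray(adjacency)
    n = adjacency.shape[0]
    out = []
    for k in range(1, min(max_range_size, n) + 1):
        for combo in itertools.combinations(range(n), k):
            mask = 0
            for a in combo:
                mask |= 1 << a
            if is_connected_range(mask, adjacency):
                out.append(mask)
    out.sort(key=lambda m: (m.bit_count(), m))
    return out


def slice_at(time_ma: float, slices: Sequence[TimeSlice]) -> int:
    """Index of the slice containing ``time_ma``.

    A slice covers the half-open interval (younger_bound, older_bound],
    so a boundary time belongs to the younger slice; the youngest slice
    is additionally closed at 0 Ma, making the tiling total on
    [0, root_age].
    """
    if time_ma < 0:
        raise ValueError(f"time {time_ma} Ma is negative")
    for i, sl in enumerate(slices):
        if sl.younger_bound < time_ma <= sl.older_bound:
            return i
    if time_ma <= slices[-1].younger_bound:
        return len(slices) - 1
    raise ValueError(f"time {time_ma} Ma outside the slice tiling")


@dataclass
class GeoModel:
    """Areas, time slices, and the per-slice allowed-range state spaces.

    ``global_state_space`` is the ordered union over slices of allowed
    ranges plus the null range at index 0; ordering is deterministic
    (null, then by size, then bitmask value).
    """

    areas: list[Area]
    slices: list[TimeSlice]
    max_range_size: int = 5
    allowed_ranges_per_slice: list[frozenset[int]] = field(init=False)
    global_state_space: list[int] = field(init=False)
    state_index: dict[int, int] = field(init=False)

    def __post_init__(self):
        n = len(self.areas)
        if [a.index for a in self.areas] != list(range(n)):
            raise ValueError("area indices must be contiguous 0..A-1")
        if len({a.code for a in self.areas}) != n:
            raise ValueError("area codes must be unique")
        bounds_ok = all(
            abs(self.slices[i].younger_bound - self.slices[i + 1].older_bound) < 1e-9
            for i in range(len(self.slices) - 1)
        )
        if not bounds_ok or abs(self.slices[-1].younger_bound) > 1e-9:
            raise ValueError("slices must tile [root_age, 0] oldest first, ending at 0")
        for sl in self.slices:
            if sl.n_areas != n:
                raise ValueError("adjacency size does not match area count")
        self.allowed_ranges_per_slice = [
            frozenset(enumerate_allowed_ranges(sl.adjacency, self.max_range_size))
            for sl in self.slices
        ]
        union = set().union(*self.allowed_ranges_per_slice)
        states = sorted(union, key=lambda m: (m.bit_count(), m))
        self.global_state_space = [NULL_RANGE] + states
        self.state_index = {m: i for i, m in enumerate(self.global_state_space)}

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_states(self) -> int:
        return len(self.global_state_space)

    @property
    def oldest_bound(self) -> float:
        return self.slices[0].older_bound

    def slice_at(self, time_ma: float) -> int:
        return slice_at(time_ma, self.slices)

    def area_by_code(self, code: str) -> Area:
        for a in self.areas:
            if a.code == code:
                return a
        raise KeyError(code)

    def allowed_in_slice(self, mask: int, slice_index: int) -> bool:
        return mask in self.allowed_ranges_per_slice[slice_index]

    def allowed_state_indices(self, slice_index: int) -> np.ndarray:
        """Indices into global_state_space of ranges allowed in a slice."""
        allowed = self.allowed_ranges_per_slice[slice_index]
        return np.array(
            [i for i, m in enumerate(self.global_state_space) if m in allowed],
            dtype=int,
        )

    # -- config round-trip ------------------------------------------------

    def to_config(self) -> dict:
        return {
            "areas": [
                {"code": a.code, "name": a.name, "latitude_class": a.latitude_class}
                for a in self.areas
            ],
            "max_range_size": self.max_range_size,
            "slices": [
                {
                    "older_bound": float(sl.older_bound),
                    "younger_bound": float(sl.younger_bound),
                    "adjacency": sl.adjacency.tolist(),
                }
                for sl in self.slices
            ],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "GeoModel":
        areas = [
            Area(i, d["code"], d.get("name", d["code"]), d.get("latitude_class", "low"))
            for i, d in enumerate(cfg["areas"])
        ]
        slices = [
            TimeSlice(s["older_bound"], s["younger_bound"], np.array(s["adjacency"]))
            for s in cfg["slices"]
        ]
        return cls(areas=areas, slices=slices, max_range_size=int(cfg.get("max_range_size", 5)))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "GeoModel":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


def range_to_codes(mask: int, areas: Sequence[Area]) -> str:
    """Human-readable range label, e.g. ``WP+EP+GR``; null -> ``∅``."""
    if mask == NULL_RANGE:
        return "0"
    return "+".join(areas[a].code for a in _bits(mask))


def codes_to_range(label: str, areas: Sequence[Area]) -> int:
    by_code = {a.code: a.index for a in areas}
    mask = 0
    for code in label.split("+"):
        mask |= 1 << by_code[code.strip()]
    return mask


# ---------------------------------------------------------------------------
# Default cycad-style geography: 14 areas, 4 slices
# ---------------------------------------------------------------------------

_CYCAD_AREAS = [
    ("WP", "West Palearctic", "high"),
    ("EP", "East Palearctic", "high"),
    ("WN", "West Nearctic", "high"),
    ("EN", "East Nearctic", "high"),
    ("CA", "Central America", "low"),
    ("WI", "Caribbean Islands", "low"),
    ("SA", "South America", "low"),
    ("AF", "Africa", "low"),
    ("MA", "Madagascar", "low"),
    ("IN", "India", "low"),
    ("WA", "Southeast Asia", "low"),
    ("AU", "Australasia", "low"),
    ("GR", "Greenland", "high"),
    ("AN", "Antarctica", "high"),
]

# Edge lists per slice, by area code. These encode coarse paleogeographic
# connectivity: a Pangean supercontinent, its Mesozoic breakup into
# Laurasia and Gondwana, Paleogene remnant corridors (Greenland,
# Antarctica), and the modern configuration.
_CYCAD_EDGES = {
    # Carboniferous–Late Triassic (Pangea assembled)
    (358.9, 201.3): [
        ("WP", "EP"), ("WP", "GR"), ("WP", "EN"), ("GR", "EN"), ("EN", "WN"),
        ("WP", "AF"), ("EN", "CA"), ("CA", "SA"), ("CA", "WI"), ("WI", "SA"),
        ("SA", "AF"), ("SA", "AN"), ("AF", "MA"), ("MA", "IN"), ("IN", "AN"),
        ("AN", "AU"), ("WA", "EP"), ("WA", "IN"), ("AF", "AN"),
    ],
    # Jurassic–Cretaceous (Pangea breakup; Laurasia vs Gondwana)
    (201.3, 66.0): [
        ("WP", "EP"), ("WP", "GR"), ("GR", "EN"), ("EN", "WN"), ("WN", "EP"),
        ("EN", "CA"), ("CA", "WI"), ("WI", "SA"), ("CA", "SA"),
        ("SA", "AF"), ("SA", "AN"), ("AF", "MA"), ("MA", "IN"), ("IN", "AN"),
        ("AN", "AU"), ("WA", "EP"),
    ],
    # Paleogene (Greenland and Antarctic corridors persist into the interval)
    (66.0, 23.0): [
        ("WP", "EP"), ("WP", "GR"), ("GR", "EN"), ("EN", "WN"), ("WN", "EP"),
        ("WN", "CA"), ("EN", "CA"), ("CA", "WI"),
        ("SA", "AN"), ("AN", "AU"), ("AF", "MA"), ("AF", "WP"),
        ("IN", "EP"), ("IN", "WA"), ("WA", "EP"),
    ],
    # Neogene–present (modern configuration; Antarctica isolated)
    (23.0, 0.0): [
        ("WP", "EP"), ("WP", "AF"), ("WP", "GR"), ("GR", "EN"),
        ("EN", "WN"), ("WN", "EP"), ("WN", "CA"), ("EN", "CA"),
        ("CA", "WI"), ("WI", "SA"), ("CA", "SA"),
        ("AF", "MA"), ("IN", "EP"), ("IN", "WA"), ("WA", "EP"), ("WA", "AU"),
    ],
}


def cycad_geography(max_range_size: int = 5,
                    high_latitude: Iterable[str] | None = None) -> GeoModel:
    """The default 14-area, four-slice geographic model.

    ``high_latitude`` overrides which area codes count as high-latitude in
    event summaries (default: WP, EP, WN, EN, GR, AN).
    """
    high = set(high_latitude) if high_latitude is not None else {
        "WP", "EP", "WN", "EN", "GR", "AN"
    }
    areas = [
        Area(i, code, name, "high" if code in high else "low")
        for i, (code, name, _default) in enumerate(_CYCAD_AREAS)
    ]
    idx = {a.code: a.index for a in areas}
    slices = []
    for (older, younger), edges in _CYCAD_EDGES.items():
        adj = np.eye(len(areas), dtype=int)
        for u, v in edges:
            adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = 1
        slices.append(TimeSlice(older, younger, adj))
    return GeoModel(areas=areas, slices=slices, max_range_size=max_range_size)
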