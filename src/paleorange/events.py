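"""Extraction, dating and summary of biogeographic events.

Given best (most likely) ancestral ranges at every node, the tree is
walked once. At each internal node the cladogenetic scenario most
consistent with the best parent and daughter ranges is chosen (the one
minimizing implied anagenetic change), classifying the node as
sympatry, subset sympatry or vicariance. Differences between a
daughter's inherited corner range and its own best range become
anagenetic events on the branch: each gained area is a dispersal (one
"into" count for the gained area, one "out of" count per area of the
source range), each lost area an extirpation. Anagenetic events are
dated at branch midpoints and constrained by the time-stratified
geographic model: an event impossible in the midpoint's slice is
snapped to the midpoint of the nearest sub-interval of the branch where
it is possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence


import pandas as pd

from .dec import AncestralRangeTable, cladogenesis_distribution
from .geography import NULL_RANGE, GeoModel
from .trees import DatedTree

__all__ = [
    "EventRecord",
    "EventSummary",
    "classify_cladogenetic_event",
    "extract_anagenetic_events",
    "events_from_ancestral_table",
    "summarize_events",
]

logger = logging.getLogger(__name__)

CLADOGENETIC_TYPES = ("vicariance", "subset_sympatry", "sympatry")
ANAGENETIC_TYPES = ("dispersal", "extirpation")


@dataclass(frozen=True)
class EventRecord:
    """One inferred biogeographic event."""

    event_type: str
    node_index: int
    time: float
    slice_index: int
    gained_area: int | None = None
    lost_area: int | None = None
    source_areas: frozenset[int] = frozenset()
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.event_type == "dispersal":
            if self.gained_area is None or not self.source_areas:
                raise ValueError("dispersal needs a gained area and source areas")
        if self.event_type == "extirpation" and self.lost_area is None:
            raise ValueError("extirpation needs a lost area")


def classify_cladogenetic_event(parent_range: int, left_range: int,
                                right_range: int) -> str:
    """Classify a node's range inheritance.

    Vicariance: disjoint daughters jointly contained in the parent.
    Subset sympatry: one daughter keeps the (widespread) parent range,
    the other a proper subset. Sympatry: single-area parent copied to
    both daughters. Anything else is logged as "anagenetic-adjusted"
    (the configuration implies extra branch events, not a clean
    cladogenetic scenario).
    """
    if NULL_RANGE in (parent_range, left_range, right_range):
        raise ValueError("null range in cladogenetic configuration")
    union = left_range | right_range
    if (left_range & right_range) == 0 and (union | parent_range) == parent_range:
        return "vicariance"
    if parent_range.bit_count() == 1 and left_range == right_range == parent_range:
        return "sympatry"
    for a, b in ((left_range, right_range), (right_range, left_range)):
        if (a == parent_range and parent_range.bit_count() > 1
                and (b | parent_range) == parent_range and b != parent_range):
            return "subset_sympatry"
    logger.info(
        "unmatched cladogenetic configuration parent=%s left=%s right=%s",
        parent_range, left_range, right_range,
    )
    return "anagenetic-adjusted"


def _possible_subintervals(geo: GeoModel, t_young: float, t_old: float,
                           predicate) -> list[tuple[float, float]]:
    """Sub-intervals of the branch, split at slice bounds, where predicate(slice) holds."""
    cuts = [t_young]
    for sl in reversed(geo.slices):
        for b in (sl.younger_bound, sl.older_bound):
            if t_young < b < t_old:
                cuts.append(b)
    cuts = sorted(set(cuts)) + [t_old]
    out = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        if hi - lo <= 1e-12:
            continue
        if predicate(geo.slice_at(0.5 * (lo + hi))):
            out.append((lo, hi))
    return out


def _date_event(geo: GeoModel, t_young: float, t_old: float, predicate
                ) -> tuple[float, int, tuple[str, ...]]:
    """Midpoint dating with snapping to the nearest allowed sub-interval."""
    mid = 0.5 * (t_young + t_old)
    k = geo.slice_at(mid)
    if predicate(k):
        return mid, k, ()
    allowed = _possible_subintervals(geo, t_young, t_old, predicate)
    if not allowed:
        return mid, k, ("unconstrained",)
    lo, hi = min(allowed, key=lambda iv: min(abs(iv[0] - mid), abs(iv[1] - mid)))
    t = 0.5 * (lo + hi)
    return t, geo.slice_at(t), ("snapped",)


def extract_anagenetic_events(start_range: int, end_range: int,
                              node_index: int, t_young: float, t_old: float,
                              geo: GeoModel) -> list[EventRecord]:
    """Events along one branch, from its parent-side corner range to the
    range observed/estimated at its lower end.

    Each gained area yields one dispersal (sources = the full start
    range, so one out-of count per source area); each lost area one
    extirpation. Events are dated at the branch midpoint, snapped where
    the time-stratified model forbids them there.
    """
    if start_range == NULL_RANGE or end_range == NULL_RANGE:
        raise ValueError("null range on branch")
    sources = frozenset(
        a for a in range(geo.n_areas) if start_range >> a & 1
    )
    events: list[EventRecord] = []
    gained = end_range & ~start_range
    lost = start_range & ~end_range
    for a in range(geo.n_areas):
        if gained >> a & 1:
            def reachable(k, a=a):
                adj = geo.slices[k].adjacency
                return any(adj[b, a] for b in sources) and geo.allowed_in_slice(1 << a, k)

            t, k, flags = _date_event(geo, t_young, t_old, reachable)
            if "unconstrained" in flags:
                logger.info(
                    "dispersal into area %d on branch %d possible in no slice",
                    a, node_index,
                )
            events.append(EventRecord(
                "dispersal", node_index, t, k, gained_area=a,
                source_areas=sources, flags=flags,
            ))
        if lost >> a & 1:
            t, k, flags = _date_event(geo, t_young, t_old, lambda _k: True)
            events.append(EventRecord(
                "extirpation", node_index, t, k, lost_area=a, flags=flags,
            ))
    return events


def _corner_choice(parent_best: int, daughter_bests: tuple[int, int]
                   ) -> tuple[int, int]:
    """Corner ranges inherited by the daughters.

    Among the cladogenetic scenarios of the best parent range, pick the
    pair minimizing total implied anagenetic change (symmetric
    difference to each daughter's best range), breaking ties by fewer
    implied dispersals, then by scenario enumeration order.
    """
    best = None
    key = None
    for l, r, _w in cladogenesis_distribution(parent_best):
        changes = ((l ^ daughter_bests[0]).bit_count()
                   + (r ^ daughter_bests[1]).bit_count())
        disp = ((daughter_bests[0] & ~l).bit_count()
                + (daughter_bests[1] & ~r).bit_count())
        k = (changes, disp)
        if key is None or k < key:
            key, best = k, (l, r)
    return best


def events_from_ancestral_table(tree: DatedTree, table: AncestralRangeTable,
                                geo: GeoModel) -> list[EventRecord]:
    """One-pass event reconstruction from best ancestral range estimates."""
    events: list[EventRecord] = []
    corner: dict[int, int] = {}  # node index -> range inherited at branch top
    for node in tree.preorder():
        best = table.best(node.index)
        if not node.is_tip:
            c0, c1 = node.children
            l, r = _corner_choice(best, (table.best(c0.index), table.best(c1.index)))
            etype = classify_cladogenetic_event(best, l, r)
            events.append(EventRecord(
                etype, node.index, node.age, geo.slice_at(node.age),
            ))
            corner[c0.index] = l
            corner[c1.index] = r
        if node.parent is not None and node.parent.age - node.age > 1e-12:
            events.extend(extract_anagenetic_events(
                corner[node.index], best, node.index,
                node.age, node.parent.age, geo,
            ))
    return events


@dataclass
class EventSummary:
    """Per-area and aggregate event tallies (the bar-chart quantities)."""

    dispersal_into: dict[str, int]
    dispersal_out_of: dict[str, int]
    extirpation: dict[str, int]
    by_class: dict[str, dict[str, int]]  # {"high": {...}, "low": {...}}
    n_vicariance: int
    n_subset_sympatry: int
    n_sympatry: int
    n_dispersal: int
    n_extirpation: int
    extirpations_per_bin: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        areas = sorted(self.dispersal_into)
        return pd.DataFrame({
            "area": areas,
            "dispersal_into": [self.dispersal_into[a] for a in areas],
            "dispersal_out_of": [self.dispersal_out_of[a] for a in areas],
            "extirpation": [self.extirpation[a] for a in areas],
        })


def summarize_events(events: Iterable[EventRecord], geo: GeoModel,
                     time_bins: dict[str, tuple[float, float]] | None = None
                     ) -> EventSummary:
    """Tally events per area, per latitude class and per time bin.

    Dispersal out-of adds one count for every area of the source range.
    Default time bins split extirpations into Cenozoic (66–0 Ma) versus
    Mesozoic and Paleozoic (older than 66 Ma).
    """
    if time_bins is None:
        time_bins = {"Cenozoic": (66.0, 0.0),
                     "Mesozoic+Paleozoic": (float("inf"), 66.0)}
    codes = [a.code for a in geo.areas]
    into = {c: 0 for c in codes}
    out = {c: 0 for c in codes}
    ext = {c: 0 for c in codes}
    per_bin = {name: 0 for name in time_bins}
    nv = nss = nsy = nd = ne = 0
    for ev in events:
        if ev.event_type == "dispersal":
            nd += 1
            into[codes[ev.gained_area]] += 1
            for a in ev.source_areas:
                out[codes[a]] += 1
        elif ev.event_type == "extirpation":
            ne += 1
            ext[codes[ev.lost_area]] += 1
            for name, (older, younger) in time_bins.items():
                if younger <= ev.time < older:
                    per_bin[name] += 1
                    break
        elif ev.event_type == "vicariance":
            nv += 1
        elif ev.event_type == "subset_sympatry":
            nss += 1
        elif ev.event_type == "sympatry":
            nsy += 1
    by_class = {"high": {"dispersal_into": 0, "dispersal_out_of": 0, "extirpation": 0},
                "low": {"dispersal_into": 0, "dispersal_out_of": 0, "extirpation": 0}}
    for area in geo.areas:
        cls = by_class[area.latitude_class]
        cls["dispersal_into"] += into[area.code]
        cls["dispersal_out_of"] += out[area.code]
        cls["extirpation"] += ext[area.code]
    return EventSummary(
        dispersal_into=into, dispersal_out_of=out, extirpation=ext,
        by_class=by_class, n_vicariance=nv, n_subset_sympatry=nss,
        n_sympatry=nsy, n_dispersal=nd, n_extirpation=ne,
        extirpations_per_bin=per_bin,
    )


def events_to_frame(events: Sequence[EventRecord], geo: GeoModel) -> pd.DataFrame:
    """Flat event table (one row per event) for TSV output."""
    rows = []
    for ev in events:
        rows.append({
            "event_type": ev.event_type,
            "node": ev.node_index,
            "time_Ma": ev.time,
            "slice": ev.slice_index,
            "gained_area": geo.areas[ev.gained_area].code if ev.gained_area is not None else "",
            "lost_area": geo.areas[ev.lost_area].code if ev.lost_area is not None else "",
            "source_areas": "+".join(
                geo.areas[a].code for a in sorted(ev.source_areas)
            ),
            "flags": ",".join(ev.flags),
        })
    return pd.DataFrame(rows)
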