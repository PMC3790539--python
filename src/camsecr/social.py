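"""Social-group inference and residency classification from co-detections.

Individuals recorded on the same camera within a short time window (the
same video trigger, or within 15 minutes by default) are taken to be
travelling together.  Group membership is the transitive closure of this
pairwise relation: if A was seen with B and B with C, all three share a
group.  For species with stable one-male groups, minimum group size and
composition can additionally be derived by anchoring on identified adult
males and tallying every animal seen with them.

Residency of individuals (relevant for wide-ranging species such as
forest elephants) is scored from presence/absence over biweekly periods:
the mean waiting time in biweeks between successive capture periods,
with small waits indicating residents and long waits nonresidents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import DetectionRecord, ParameterError

__all__ = [
    "CoDetectionGraph", "GroupAssignment", "ResidencyProfile",
    "build_codetection_graph", "assign_groups", "group_composition", "residency",
]

RESIDENCY_PERIOD_DAYS = 14


@dataclass
class CoDetectionGraph:
    """Undirected graph of individuals co-detected at the same camera."""

    graph: nx.Graph
    window_minutes: float

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_evidence(self, a: str, b: str) -> list[tuple[str, datetime]]:
        return self.graph.edges[a, b]["evidence"]


@dataclass
class GroupAssignment:
    """Partition of individuals into social units (connected components)."""

    components: list[frozenset[str]]
    group_ids: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.group_ids:
            self.group_ids = {
                ind: g for g, comp in enumerate(self.components) for ind in comp
            }

    @property
    def solitary(self) -> set[str]:
        return {next(iter(c)) for c in self.components if len(c) == 1}

    @property
    def n_groups(self) -> int:
        """Number of non-singleton social units."""
        return sum(1 for c in self.components if len(c) > 1)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"individual_id": ind, "group_id": g, "group_size": len(self.components[g])}
            for g, comp in enumerate(self.components) for ind in sorted(comp)
        ]
        return pd.DataFrame(rows)


@dataclass
class ResidencyProfile:
    individual_id: str
    presence: np.ndarray          # bool per biweekly period
    mean_waiting_biweeks: float   # nan when < 2 capture periods
    label: str                    # resident | nonresident | intermediate | unclassifiable


def _identified(records) -> list[DetectionRecord]:
    return [r for r in records if r.identified]


def build_codetection_graph(records, window_minutes: float = 15.0) -> CoDetectionGraph:
    """Link individuals detected on the same camera within the time window.

    The window is inclusive (a pair exactly 15 minutes apart is linked).
    Unidentified (anonymous) detections are ignored; unknown-sex
    individuals are included.
    """
    if window_minutes < 0:
        raise ParameterError("window_minutes must be non-negative")
    g = nx.Graph()
    recs = _identified(records)
    g.add_nodes_from(r.individual_id for r in recs)
    window = timedelta(minutes=window_minutes)
    by_cam: dict[str, list[DetectionRecord]] = {}
    for r in recs:
        by_cam.setdefault(r.camera_id, []).append(r)
    for cam, rs in by_cam.items():
        rs.sort(key=lambda r: r.timestamp)
        for i, a in enumerate(rs):
            for b in rs[i + 1:]:
                if b.timestamp - a.timestamp > window:
                    break
                if a.individual_id == b.individual_id:
                    continue
                ev = (cam, a.timestamp)
                if g.has_edge(a.individual_id, b.individual_id):
                    g.edges[a.individual_id, b.individual_id]["evidence"].append(ev)
                else:
                    g.add_edge(a.individual_id, b.individual_id, evidence=[ev])
    return CoDetectionGraph(graph=g, window_minutes=window_minutes)


def assign_groups(codet: CoDetectionGraph) -> GroupAssignment:
    """Social units = connected components of the co-detection graph.

    Components are ordered deterministically by their smallest member id.
    """
    comps = [frozenset(c) for c in nx.connected_components(codet.graph)]
    comps.sort(key=lambda c: min(c))
    return GroupAssignment(components=comps)


def group_composition(records, anchors=None) -> pd.DataFrame:
    """Per-group age–sex tallies; with anchors, minimum group sizes.

    Without ``anchors`` every identified individual is tallied once by its
    age–sex class.  With ``anchors`` (e.g. the silverback of each stable
    group), each anchor's group is sized by the per-class *maximum*
    simultaneous tally over all clips (camera visits within 15 minutes of
    an anchor detection), plus the anchor itself — a minimum group size
    that needs no individual identification of the other members.
    """
    recs = [r for r in records]
    if anchors is None:
        ident = _identified(recs)
        by_id = {}
        for r in ident:
            by_id.setdefault(r.individual_id, r)
        rows = [
            {"individual_id": i, "sex": r.sex, "age_class": r.age_class}
            for i, r in sorted(by_id.items())
        ]
        df = pd.DataFrame(rows)
        return (
            df.groupby(["age_class", "sex"]).size().rename("count").reset_index()
        )
    window = timedelta(minutes=15)
    out = []
    detected_ids = {r.individual_id for r in recs if r.identified}
    for anchor in anchors:
        anchor_recs = [r for r in recs if r.individual_id == anchor]
        if not anchor_recs:
            import warnings
            warnings.warn(f"anchor {anchor} never detected; group skipped")
            continue
        class_max: dict[tuple[str, str], int] = {}
        for ar in anchor_recs:
            clip = [
                r for r in recs
                if r.camera_id == ar.camera_id
                and abs(r.timestamp - ar.timestamp) <= window
                and r.individual_id != anchor
            ]
            # tally companions in this clip by age-sex class (anonymous
            # companions count too: composition needs classes, not ids)
            tally: dict[tuple[str, str], int] = {}
            seen = set()
            for r in clip:
                key_id = r.individual_id if r.identified else id(r)
                if key_id in seen:
                    continue
                seen.add(key_id)
                k = (r.age_class, r.sex)
                tally[k] = tally.get(k, 0) + 1
            for k, v in tally.items():
                class_max[k] = max(class_max.get(k, 0), v)
        min_size = 1 + sum(class_max.values())
        row = {"anchor": anchor, "min_group_size": min_size}
        for (age, sex), v in sorted(class_max.items()):
            row[f"{age}_{sex}"] = v
        out.append(row)
    return pd.DataFrame(out)


def residency(records, window_start=None, n_periods: int = 26,
              resident_max: float = 5.0, nonresident_min: float = 15.0) -> list[ResidencyProfile]:
    """Classify individuals as resident/nonresident from biweekly presence.

    The residency window spans ``n_periods`` consecutive biweeks from
    ``window_start`` (default: the first detection date).  The score is
    the mean waiting time between successive presence periods, in
    biweeks; <=``resident_max`` is resident, >=``nonresident_min`` is
    nonresident, in between is intermediate.  Individuals present in
    fewer than two periods cannot be scored and are unclassifiable.
    """
    recs = _identified(records)
    if not recs:
        return []
    t0 = min(r.timestamp for r in recs).date() if window_start is None else window_start
    t_end = t0 + timedelta(days=n_periods * RESIDENCY_PERIOD_DAYS)
    if all(r.timestamp.date() >= t_end or r.timestamp.date() < t0 for r in recs):
        raise ParameterError("residency window contains no detections")
    by_id: dict[str, set[int]] = {}
    for r in recs:
        d = r.timestamp.date()
        if not (t0 <= d < t_end):
            continue
        p = (d - t0).days // RESIDENCY_PERIOD_DAYS
        by_id.setdefault(r.individual_id, set()).add(p)
    profiles = []
    for ind in sorted(by_id):
        periods = sorted(by_id[ind])
        presence = np.zeros(n_periods, dtype=bool)
        presence[periods] = True
        if len(periods) < 2:
            w = float("nan")
            label = "unclassifiable"
        else:
            w = float(np.mean(np.diff(periods)))
            if w <= resident_max:
                label = "resident"
            elif w >= nonresident_min:
                label = "nonresident"
            else:
                label = "intermediate"
        profiles.append(ResidencyProfile(ind, presence, w, label))
    return profiles


def residency_frame(profiles: list[ResidencyProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [p.individual_id for p in profiles],
            "n_periods_present": [int(p.presence.sum()) for p in profiles],
            "mean_waiting_biweeks": [p.mean_waiting_biweeks for p in profiles],
            "label": [p.label for p in profiles],
        }
    )
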