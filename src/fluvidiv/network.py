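"""Dendritic river networks and geomorphological residence-time proxies.

A river network is modelled as a strict tree of *reaches* (channel segments)
directed toward a single outlet.  Each reach carries a length (km) and the
lateral catchment area (km^2) draining directly into it.  Sampling sites are
anchored to nodes of the tree, and all statistics are defined over the
subtree upstream of a site:

``mean dendritic stream length``
    Average length of the flow paths from every spring (zero-in-degree node)
    upstream of a site down to that site.  Shared reaches below confluences
    contribute to every path passing through them, so the quantity tracks the
    average travel distance of a water parcel — and, at constant velocity, the
    mean in-stream residence time.

``cumulative dendritic distance``
    Total channel length upstream of the site, each reach counted once; a
    drainage-density measure, not a residence-time one.

``contact-zone ratio``
    Wetted perimeter over cross-sectional flow area (1/m) at long-term mean
    discharge; proxies the streambed/riparian contact per unit water volume,
    which shrinks by an order of magnitude from headwaters to a large river's
    lower course.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Reach",
    "RiverNetwork",
    "SamplingSite",
    "GeomorphMetrics",
    "springs_upstream",
    "spring_path_lengths",
    "mean_dendritic_stream_length",
    "median_dendritic_length",
    "cumulative_dendritic_distance",
    "catchment_area",
    "contact_zone_ratio",
    "fold_change",
    "compute_site_metrics",
    "read_network_tsv",
    "write_network_tsv",
    "read_sites_tsv",
    "write_sites_tsv",
]

NETWORK_COLUMNS = ["reach_id", "from_node", "to_node", "length_km", "lateral_area_km2"]
SITE_COLUMNS = ["site_id", "node", "river_km", "system"]


@dataclass(frozen=True)
class Reach:
    """A directed channel segment ``from_node -> to_node``.

    ``lateral_area_km2`` may be ``None`` when catchment areas are unknown;
    catchment-area queries then raise instead of guessing.
    """

    reach_id: str
    from_node: str
    to_node: str
    length_km: float
    lateral_area_km2: float | None = None

    def __post_init__(self) -> None:
        if not self.length_km > 0:
            raise ValueError(
                f"reach {self.reach_id!r}: length_km must be > 0, got {self.length_km}"
            )
        if self.lateral_area_km2 is not None and self.lateral_area_km2 < 0:
            raise ValueError(
                f"reach {self.reach_id!r}: lateral_area_km2 must be >= 0, "
                f"got {self.lateral_area_km2}"
            )
        if self.from_node == self.to_node:
            raise ValueError(f"reach {self.reach_id!r}: self-loop at {self.from_node!r}")


class RiverNetwork:
    """A rooted dendritic tree of reaches, directed toward a single outlet.

    Invariants enforced at construction:

    * every node except the outlet has exactly one downstream reach
      (braided channels / distributaries are rejected);
    * there is exactly one outlet and no cycles;
    * reach ids and (from_node) keys are unique.
    """

    def __init__(self, reaches: Iterable[Reach]):
        self.reaches: tuple[Reach, ...] = tuple(reaches)
        if not self.reaches:
            raise ValueError("empty network: at least one reach is required")

        ids = [r.reach_id for r in self.reaches]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate reach ids: {dup}")

        self._down: dict[str, Reach] = {}
        self._up: dict[str, list[Reach]] = {}
        nodes: set[str] = set()
        for r in self.reaches:
            nodes.add(r.from_node)
            nodes.add(r.to_node)
            if r.from_node in self._down:
                raise ValueError(
                    f"node {r.from_node!r} has more than one downstream reach "
                    "(braided channels/distributaries are not representable in a dendritic tree)"
                )
            self._down[r.from_node] = r
            self._up.setdefault(r.to_node, []).append(r)
        self.nodes: frozenset[str] = frozenset(nodes)

        outlets = [n for n in nodes if n not in self._down]
        if len(outlets) != 1:
            raise ValueError(
                f"network must have exactly one outlet, found {len(outlets)}: {sorted(outlets)}"
            )
        self.outlet: str = outlets[0]

        g = nx.DiGraph((r.from_node, r.to_node) for r in self.reaches)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("network contains a cycle; a dendritic network is a tree")
        # single outlet + unique downstream reach + acyclic => rooted tree

    # -- topology queries ---------------------------------------------------

    def upstream_reaches_of(self, node: str) -> list[Reach]:
        """Reaches flowing directly into ``node`` (empty at springs)."""
        self._require_node(node)
        return list(self._up.get(node, []))

    def downstream_reach_of(self, node: str) -> Reach | None:
        """The unique reach leaving ``node``; ``None`` at the outlet."""
        self._require_node(node)
        return self._down.get(node)

    def is_spring(self, node: str) -> bool:
        self._require_node(node)
        return node not in self._up

    @property
    def springs(self) -> frozenset[str]:
        return frozenset(n for n in self.nodes if n not in self._up)

    def upstream_subtree_reaches(self, node: str) -> list[Reach]:
        """All distinct reaches in the subtree draining to ``node``."""
        self._require_node(node)
        out: list[Reach] = []
        stack = [node]
        while stack:
            for r in self._up.get(stack.pop(), []):
                out.append(r)
                stack.append(r.from_node)
        return out

    def path_to_outlet(self, node: str) -> list[Reach]:
        """Reach sequence from ``node`` down to the outlet."""
        self._require_node(node)
        path: list[Reach] = []
        cur = node
        while (r := self._down.get(cur)) is not None:
            path.append(r)
            cur = r.to_node
        return path

    def _require_node(self, node: str) -> None:
        if node not in self.nodes:
            raise KeyError(f"node {node!r} is not in the network")


@dataclass(frozen=True)
class SamplingSite:
    """A sampling location anchored to a network node.

    ``river_km`` follows the fluvial convention of distance-to-mouth (the
    Danube's official numbering runs from rkm 2600 near the source region to
    rkm 0 at the mouth).  Sites that fall mid-reach must be represented by
    splitting the reach at import time.
    """

    site_id: str
    node: str
    river_km: float = 0.0
    system: str = "mainstem"  # "mainstem" | "tributary"

    def __post_init__(self) -> None:
        if self.river_km < 0:
            raise ValueError(f"site {self.site_id!r}: river_km must be >= 0")
        if self.system not in ("mainstem", "tributary"):
            raise ValueError(
                f"site {self.site_id!r}: system must be 'mainstem' or 'tributary', "
                f"got {self.system!r}"
            )


@dataclass(frozen=True)
class GeomorphMetrics:
    """Per-site geomorphological summary (units: km, km^2, 1/m)."""

    site_id: str
    mean_dendritic_stream_length_km: float
    median_dendritic_length_km: float
    cumulative_dendritic_distance_km: float
    catchment_area_km2: float | None = None
    contact_zone_ratio_per_m: float | None = None


def _anchor(network: RiverNetwork, site: SamplingSite | str) -> str:
    node = site.node if isinstance(site, SamplingSite) else site
    if node not in network.nodes:
        raise KeyError(f"site anchor node {node!r} is not in the network")
    return node


def springs_upstream(network: RiverNetwork, site: SamplingSite | str) -> set[str]:
    """Springs whose downstream path passes through the site's anchor node.

    The anchor itself is returned when it is a spring (degenerate catchment).
    """
    node = _anchor(network, site)
    if network.is_spring(node):
        return {node}
    reaches = network.upstream_subtree_reaches(node)
    up_nodes = {r.from_node for r in reaches}
    return {n for n in up_nodes if network.is_spring(n)}


def spring_path_lengths(network: RiverNetwork, site: SamplingSite | str) -> dict[str, float]:
    """Length (km) of the flow path from each upstream spring to the site.

    Shared reaches below confluences contribute to every path through them.
    """
    node = _anchor(network, site)
    if network.is_spring(node):
        return {node: 0.0}
    # depth-first descent, accumulating distance from the site going upstream
    lengths: dict[str, float] = {}
    stack: list[tuple[str, float]] = [(node, 0.0)]
    while stack:
        cur, acc = stack.pop()
        ups = network.upstream_reaches_of(cur)
        if not ups and cur != node:
            lengths[cur] = acc
        for r in ups:
            stack.append((r.from_node, acc + r.length_km))
    return lengths


def mean_dendritic_stream_length(network: RiverNetwork, site: SamplingSite | str) -> float:
    """Unweighted mean of all spring-to-site path lengths (km).

    Equal per-spring weights reflect the assumption of randomly distributed
    spring discharges; with constant flow velocity this is proportional to the
    mean in-stream residence time.
    """
    return float(statistics.fmean(spring_path_lengths(network, site).values()))


def median_dendritic_length(network: RiverNetwork, site: SamplingSite | str) -> float:
    """Median spring-to-site path length (km); midpoint rule for even counts."""
    return float(statistics.median(spring_path_lengths(network, site).values()))


def cumulative_dendritic_distance(network: RiverNetwork, site: SamplingSite | str) -> float:
    """Total channel length upstream of the site, each reach counted once (km)."""
    node = _anchor(network, site)
    return float(sum(r.length_km for r in network.upstream_subtree_reaches(node)))


def catchment_area(network: RiverNetwork, site: SamplingSite | str) -> float:
    """Sum of lateral catchment areas over the upstream subtree (km^2)."""
    node = _anchor(network, site)
    reaches = network.upstream_subtree_reaches(node)
    missing = [r.reach_id for r in reaches if r.lateral_area_km2 is None]
    if missing:
        raise ValueError(
            f"catchment area undefined: reaches without lateral_area_km2: {sorted(missing)[:5]}"
        )
    return float(sum(r.lateral_area_km2 for r in reaches))


def contact_zone_ratio(wetted_perimeter_m: float, cross_sectional_area_m2: float) -> float:
    """Streambed contact-zone ratio P/A (1/m) at mean discharge."""
    if not wetted_perimeter_m > 0:
        raise ValueError(f"wetted_perimeter_m must be > 0, got {wetted_perimeter_m}")
    if not cross_sectional_area_m2 > 0:
        raise ValueError(f"cross_sectional_area_m2 must be > 0, got {cross_sectional_area_m2}")
    return wetted_perimeter_m / cross_sectional_area_m2


def fold_change(upstream_ratio: float, downstream_ratio: float) -> float:
    """Upstream/downstream quotient of two contact-zone ratios (dimensionless)."""
    if not upstream_ratio > 0 or not downstream_ratio > 0:
        raise ValueError("both ratios must be > 0")
    return upstream_ratio / downstream_ratio


def compute_site_metrics(
    network: RiverNetwork,
    site: SamplingSite,
    *,
    wetted_perimeter_m: float | None = None,
    cross_sectional_area_m2: float | None = None,
) -> GeomorphMetrics:
    """All geomorphological statistics for one site; areas optional."""
    try:
        area: float | None = catchment_area(network, site)
    except ValueError:
        area = None
    ratio = None
    if wetted_perimeter_m is not None and cross_sectional_area_m2 is not None:
        ratio = contact_zone_ratio(wetted_perimeter_m, cross_sectional_area_m2)
    return GeomorphMetrics(
        site_id=site.site_id,
        mean_dendritic_stream_length_km=mean_dendritic_stream_length(network, site),
        median_dendritic_length_km=median_dendritic_length(network, site),
        cumulative_dendritic_distance_km=cumulative_dendritic_distance(network, site),
        catchment_area_km2=area,
        contact_zone_ratio_per_m=ratio,
    )


# -- TSV interchange --------------------------------------------------------


def read_network_tsv(path) -> RiverNetwork:
    """Read a reach edge-list TSV (``reach_id from_node to_node length_km lateral_area_km2``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in NETWORK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"network TSV {path}: missing columns {missing}")
    reaches = []
    for row in df.itertuples(index=False):
        area = getattr(row, "lateral_area_km2")
        area_f = None if area is None or pd.isna(area) or area == "" else float(area)
        reaches.append(
            Reach(
                reach_id=str(row.reach_id),
                from_node=str(row.from_node),
                to_node=str(row.to_node),
                length_km=float(row.length_km),
                lateral_area_km2=area_f,
            )
        )
    return RiverNetwork(reaches)


def write_network_tsv(network: RiverNetwork, path) -> None:
    df = pd.DataFrame(
        [
            (r.reach_id, r.from_node, r.to_node, r.length_km, r.lateral_area_km2)
            for r in network.reaches
        ],
        columns=NETWORK_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_sites_tsv(path, network: RiverNetwork | None = None) -> list[SamplingSite]:
    """Read a site table TSV (``site_id node river_km system``); order preserved."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sites TSV {path}: missing columns {missing}")
    sites = [
        SamplingSite(
            site_id=str(row.site_id),
            node=str(row.node),
            river_km=float(row.river_km),
            system=str(row.system),
        )
        for row in df.itertuples(index=False)
    ]
    if network is not None:
        for s in sites:
            if s.node not in network.nodes:
                raise KeyError(f"site {s.site_id!r}: anchor node {s.node!r} not in network")
    return sites


def write_sites_tsv(sites: Sequence[SamplingSite], path) -> None:
    df = pd.DataFrame(
        [(s.site_id, s.node, s.river_km, s.system) for s in sites], columns=SITE_COLUMNS
    )
    df.to_csv(path, sep="\t", index=False)
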