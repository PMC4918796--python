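"""Synthetic dendritic meta-communities under mass effects and species sorting.

The generator produces a random dendritic river network and OTU tables for
two size fractions under an explicit, minimal meta-community model:

1. **Headwater inoculation** — every spring starts from the same mix of a
   high-richness soil pool and a groundwater pool, plus a small seed of a
   low-richness typical-freshwater pool (standing variation for sorting to
   act on).
2. **Species sorting** — along a reach of length L the community spends a
   residence time tau = L / velocity during which freshwater-pool taxa enjoy
   a growth advantage sigma_s (1/d); relative abundances are multiplied by
   exp(g * tau) and renormalised.
3. **Mass effects** — lateral input across the streambed contact zone mixes
   the riparian (terrestrial) community back in.  The contact-zone ratio
   decays with accumulated catchment area, c = c0 * (A0 / (A0 + A_up))^gamma,
   and the mixed-in fraction over a reach is m = 1 - exp(-mu_L * c * L).
4. **Confluence mixing** — inflows combine weighted by accumulated catchment
   area (a discharge proxy).
5. **Read sampling** — free-living (FL) counts are multinomial draws from the
   water-column field; particle-associated (PA) counts admix a separate
   particle pool (at a Beta-distributed, sample-specific load) and add mild
   Dirichlet overdispersion before the multinomial draw, reproducing the
   higher richness and higher beta dispersion of PA samples.

Default scales follow the study system the model emulates: a freshwater
growth advantage of 0.30 1/d (between realistic bulk-community mean and
maximum growth rates of ~0.2 and ~1 1/d), a total mainstem residence time of
about 32 days — together strong enough sorting for the freshwater pool to
dominate at the mouth — and 7000 reads per sample.  All stochastic steps are
driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import Reach, RiverNetwork, SamplingSite
from .otu_io import OTUTable, TaxonomyMap
from .continuum import TermProfile

__all__ = [
    "SimulationParams",
    "SimulatedDataset",
    "generate_network",
    "derive_mainstem_sites",
    "simulate_continuum",
    "simulate",
    "ground_truth_report",
    "POOLS",
]

POOLS = ("soil", "ground", "fresh", "particle")

_FRESH_TRIBES = (
    "acI-B1", "acI-A7", "acI-C2", "LD12", "Polynucleobacter",
    "LD28", "Algoriphagus", "betI-A",
)

_TERM_PROFILES = {
    "soil": {"soil": 0.85, "sediment": 0.15},
    "ground": {"groundwater": 0.90, "aquifer": 0.10},
    "fresh": {"lake": 0.50, "river": 0.30, "epilimnion": 0.20},
    "particle": {},  # unannotated: exercises profile-missingness handling
}

_LINEAGES = {
    "soil": "Bacteria;Acidobacteria;SoilGroup",
    "ground": "Bacteria;Proteobacteria;GroundwaterGroup",
    "fresh_tribe": "Bacteria;Actinobacteria;acI;{tribe}",
    "fresh_clade": "Bacteria;Actinobacteria;acI",
    "particle": "Bacteria;Bacteroidetes;ParticleGroup",
}


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the synthetic dendritic meta-community generator.

    Units: lengths km, areas km^2, rates 1/d, velocity km/d, contact ratio 1/m.
    """

    seed: int = 0
    # network geometry
    n_springs: int = 64
    reach_length_log_mu: float = float(np.log(25.0))  # median reach length 25 km
    reach_length_log_sigma: float = 0.4
    lateral_area_per_km: float = 8.0  # km^2 of lateral catchment per km of channel
    lateral_area_log_sigma: float = 0.3
    # species pools (sizes and log-normal abundance shape)
    s_soil: int = 600
    s_ground: int = 300
    s_fresh: int = 80
    s_particle: int = 500
    pool_log_sigma: Mapping[str, float] = field(
        default_factory=lambda: {"soil": 1.2, "ground": 1.2, "fresh": 1.0, "particle": 1.2}
    )
    # headwater inoculum
    spring_soil_weight: float = 0.6
    spring_ground_weight: float = 0.4
    spring_freshwater_frac: float = 0.04
    # sorting and hydrology
    sorting_strength: float = 0.30  # growth advantage of freshwater taxa, 1/d
    mainstem_residence_d: float = 32.0  # sets velocity when flow_velocity_km_d is None
    flow_velocity_km_d: float | None = None
    # lateral mass effect
    contact_ratio_c0: float = 0.83  # headwater contact-zone ratio, 1/m
    contact_area_a0_km2: float = 200.0
    contact_decay_gamma: float = 1.0
    lateral_coupling: float = 0.03  # mu_L, per (1/m * km)
    # read sampling
    reads_per_sample: int = 7000
    pa_overdispersion: float = 4000.0  # Dirichlet concentration scale, > 0
    pa_particle_frac: float = 0.3
    pa_particle_frac_sd: float = 0.22  # between-sample s.d. of the particle admixture

    def __post_init__(self) -> None:
        if self.n_springs < 1:
            raise ValueError("n_springs must be >= 1")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        if self.pa_overdispersion <= 0:
            raise ValueError("pa_overdispersion must be > 0")
        for name in ("sorting_strength", "contact_decay_gamma", "lateral_coupling"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.s_soil, self.s_ground, self.s_fresh, self.s_particle) < 1:
            raise ValueError("all pools must be non-empty")
        if self.flow_velocity_km_d is not None and not self.flow_velocity_km_d > 0:
            raise ValueError("flow_velocity_km_d must be > 0")

    @classmethod
    def paper_like(cls, seed: int = 0, **overrides) -> "SimulationParams":
        """Sorting regime: growth advantage over ~32 d of mainstem residence,
        contact zone decaying downstream."""
        return cls(seed=seed, **overrides)

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SimulationParams":
        """No sorting, no contact decay: the expected composition is identical
        at every site, so any detected downstream trend is a false positive."""
        return cls(
            seed=seed,
            sorting_strength=0.0,
            contact_decay_gamma=0.0,
            **overrides,
        )


@dataclass(frozen=True)
class SimulatedDataset:
    """A simulated network, sites, OTU tables and full ground truth."""

    network: RiverNetwork
    sites: tuple[SamplingSite, ...]  # mainstem first (ordered down-river), then tributaries
    table: OTUTable
    meta: pd.DataFrame
    taxonomy: TaxonomyMap
    terms: TermProfile
    params: SimulationParams
    field: pd.DataFrame  # per-site expected water-column relative abundances (sites x OTUs)
    pool_of: Mapping[str, str]  # OTU id -> pool of origin

    @property
    def mainstem_sites(self) -> tuple[SamplingSite, ...]:
        return tuple(s for s in self.sites if s.system == "mainstem")


# -- network generation -----------------------------------------------------


def generate_network(params: SimulationParams) -> tuple[RiverNetwork, list[SamplingSite]]:
    """Random binary-merge dendritic tree with ``n_springs`` springs.

    Lineages starting at each spring are merged pairwise at random
    (coalescent-style), giving exactly n_springs - 1 confluences.  Reach
    lengths are log-normal; lateral areas scale with reach length.  The
    longest spring-to-outlet path is designated the mainstem and a sampling
    site is placed at every mainstem node, ordered source to mouth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 101]))

    def draw_length() -> float:
        return float(np.exp(rng.normal(params.reach_length_log_mu, params.reach_length_log_sigma)))

    def draw_area(length: float) -> float:
        jitter = float(np.exp(rng.normal(0.0, params.lateral_area_log_sigma)))
        return params.lateral_area_per_km * length * jitter

    reaches: list[Reach] = []
    heads = [f"S{i:03d}" for i in range(params.n_springs)]
    n_conf = 0

    def add_reach(u: str, v: str) -> None:
        nonlocal reaches
        length = draw_length()
        reaches.append(
            Reach(
                reach_id=f"R{len(reaches):04d}",
                from_node=u,
                to_node=v,
                length_km=length,
                lateral_area_km2=draw_area(length),
            )
        )

    while len(heads) > 1:
        i, j = sorted(rng.choice(len(heads), size=2, replace=False))
        conf = f"J{n_conf:03d}"
        n_conf += 1
        add_reach(heads[i], conf)
        add_reach(heads[j], conf)
        heads = [h for k, h in enumerate(heads) if k not in (i, j)] + [conf]
    add_reach(heads[0], "OUT")
    network = RiverNetwork(reaches)

    return network, derive_mainstem_sites(network)


def derive_mainstem_sites(network: RiverNetwork) -> list[SamplingSite]:
    """Sites at every node of the longest spring-to-outlet path, source to mouth.

    ``river_km`` is the along-mainstem distance to the mouth.
    """
    best_spring, best_len = None, -1.0
    for s in sorted(network.springs):
        total = sum(r.length_km for r in network.path_to_outlet(s))
        if total > best_len:
            best_spring, best_len = s, total
    path = network.path_to_outlet(best_spring)
    nodes = [best_spring] + [r.to_node for r in path]
    dist_to_mouth = [best_len - sum(r.length_km for r in path[:i]) for i in range(len(nodes))]
    return [
        SamplingSite(site_id=f"DS{i:02d}", node=n, river_km=max(0.0, d), system="mainstem")
        for i, (n, d) in enumerate(zip(nodes, dist_to_mouth))
    ]


def _tributary_sites(network: RiverNetwork, mainstem: Sequence[SamplingSite]) -> list[SamplingSite]:
    """One site at the head of each tributary branch entering the mainstem."""
    mainstem_nodes = {s.node for s in mainstem}
    rkm_of = {s.node: s.river_km for s in mainstem}
    out: list[SamplingSite] = []
    for s in mainstem:
        for r in network.upstream_reaches_of(s.node):
            if r.from_node not in mainstem_nodes:
                out.append(
                    SamplingSite(
                        site_id=f"TR{len(out):02d}",
                        node=r.from_node,
                        river_km=rkm_of[s.node],
                        system="tributary",
                    )
                )
    return out


# -- community simulation ---------------------------------------------------


def _pool_vectors(params: SimulationParams, rng) -> tuple[list[str], dict[str, np.ndarray], dict[str, str]]:
    """OTU ids, within-pool normalised abundance vectors over the full OTU axis,
    and the OTU -> pool map."""
    sizes = {
        "soil": params.s_soil,
        "ground": params.s_ground,
        "fresh": params.s_fresh,
        "particle": params.s_particle,
    }
    otu_ids: list[str] = []
    pool_of: dict[str, str] = {}
    for pool in POOLS:
        for i in range(sizes[pool]):
            oid = f"{pool}_{i:04d}"
            otu_ids.append(oid)
            pool_of[oid] = pool
    total = len(otu_ids)
    vectors: dict[str, np.ndarray] = {}
    offset = 0
    for pool in POOLS:
        size = sizes[pool]
        raw = np.exp(rng.normal(0.0, params.pool_log_sigma[pool], size=size))
        vec = np.zeros(total)
        vec[offset : offset + size] = raw / raw.sum()
        vectors[pool] = vec
        offset += size
    return otu_ids, vectors, pool_of


def simulate_continuum(
    network: RiverNetwork,
    params: SimulationParams,
    sites: Sequence[SamplingSite] | None = None,
) -> SimulatedDataset:
    """Run the mass-effects/species-sorting model over a network and sample reads.

    The expected relative-abundance field is deterministic given the seed (it
    reuses the seed-derived pool draws); only the read sampling is
    stochastic, again seed-derived.  Raises on zero velocity or empty pools.
    """
    if sites is None:
        sites = derive_mainstem_sites(network)
    sites = list(sites) + _tributary_sites(network, [s for s in sites if s.system == "mainstem"])

    mainstem = [s for s in sites if s.system == "mainstem"]
    mainstem_len = sum(
        r.length_km for r in network.path_to_outlet(mainstem[0].node)
    ) if mainstem else 0.0
    velocity = params.flow_velocity_km_d
    if velocity is None:
        if mainstem_len <= 0:
            raise ValueError("cannot derive flow velocity: empty mainstem")
        velocity = mainstem_len / params.mainstem_residence_d
    if not velocity > 0:
        raise ValueError("flow velocity must be > 0")

    rng_pools = np.random.default_rng(np.random.SeedSequence([params.seed, 202]))
    otu_ids, pools, pool_of = _pool_vectors(params, rng_pools)

    w_soil = params.spring_soil_weight
    w_ground = params.spring_ground_weight
    terr = (w_soil * pools["soil"] + w_ground * pools["ground"]) / (w_soil + w_ground)
    eps = params.spring_freshwater_frac
    spring_state = (1.0 - eps) * terr + eps * pools["fresh"]
    riparian = spring_state  # the same terrestrial-groundwater source feeds springs and banks

    growth = np.array([params.sorting_strength if pool_of[o] == "fresh" else 0.0 for o in otu_ids])

    def transport(x: np.ndarray, reach: Reach, area_up: float) -> np.ndarray:
        tau = reach.length_km / velocity
        if params.sorting_strength > 0:
            x = x * np.exp(growth * tau)
            x = x / x.sum()
        c = params.contact_ratio_c0 * (
            params.contact_area_a0_km2 / (params.contact_area_a0_km2 + area_up)
        ) ** params.contact_decay_gamma
        m = 1.0 - np.exp(-params.lateral_coupling * c * reach.length_km)
        return (1.0 - m) * x + m * riparian

    # post-order traversal: resolve all inflows before a node's own state
    state: dict[str, np.ndarray] = {}
    area_at: dict[str, float] = {}
    stack = [(network.outlet, False)]
    while stack:
        node, ready = stack.pop()
        ups = network.upstream_reaches_of(node)
        if not ups:
            state[node] = spring_state
            area_at[node] = 0.0
            continue
        if not ready:
            stack.append((node, True))
            stack.extend((r.from_node, False) for r in ups)
            continue
        mixed = np.zeros_like(spring_state)
        weights = []
        parts = []
        for r in ups:
            a_up = area_at[r.from_node]
            parts.append(transport(state[r.from_node], r, a_up))
            weights.append(a_up + (r.lateral_area_km2 or 0.0))
        weights = np.asarray(weights, dtype=float)
        if weights.sum() == 0:
            weights = np.ones_like(weights)
        for w, p in zip(weights / weights.sum(), parts):
            mixed += w * p
        state[node] = mixed
        area_at[node] = float(sum(area_at[r.from_node] + (r.lateral_area_km2 or 0.0) for r in ups))

    field = pd.DataFrame(
        np.vstack([state[s.node] for s in sites]), index=[s.site_id for s in sites], columns=otu_ids
    )
    field.index.name = "site_id"

    # read sampling
    rng_reads = np.random.default_rng(np.random.SeedSequence([params.seed, 303]))
    n_reads = params.reads_per_sample
    rows, sample_ids, meta_rows = [], [], []
    for s in sites:
        x = state[s.node]
        fl = rng_reads.multinomial(n_reads, x / x.sum())
        rows.append(fl)
        sample_ids.append(f"{s.site_id}-FL")
        meta_rows.append((f"{s.site_id}-FL", s.site_id, "FL", s.system))

        frac = _draw_particle_frac(params, rng_reads)
        base = (1.0 - frac) * x + frac * pools["particle"]
        support = base > 0
        alpha = params.pa_overdispersion * base[support]
        p = np.zeros_like(base)
        p[support] = rng_reads.dirichlet(alpha)
        pa = rng_reads.multinomial(n_reads, p / p.sum())
        rows.append(pa)
        sample_ids.append(f"{s.site_id}-PA")
        meta_rows.append((f"{s.site_id}-PA", s.site_id, "PA", s.system))

    counts = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=otu_ids, dtype=np.int64)
    counts.index.name = "sample_id"
    table = OTUTable(counts)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "site_id", "fraction", "system"]
    ).set_index("sample_id")

    taxonomy = _build_taxonomy(otu_ids, pool_of)
    terms = TermProfile(
        weights={o: dict(_TERM_PROFILES[pool_of[o]]) for o in otu_ids if _TERM_PROFILES[pool_of[o]]}
    )
    return SimulatedDataset(
        network=network,
        sites=tuple(sites),
        table=table,
        meta=meta,
        taxonomy=taxonomy,
        terms=terms,
        params=params,
        field=field,
        pool_of=pool_of,
    )


def _draw_particle_frac(params: SimulationParams, rng) -> float:
    """Per-sample particle load: Beta-distributed around ``pa_particle_frac``.

    Particle quantity and quality vary between sites (sediments, algae,
    detritus), which inflates the compositional spread of PA samples without
    removing taxa."""
    m, sd = params.pa_particle_frac, params.pa_particle_frac_sd
    if sd <= 0:
        return m
    nu = m * (1.0 - m) / sd**2 - 1.0
    if nu <= 0:
        raise ValueError("pa_particle_frac_sd too large for the given mean")
    return float(rng.beta(m * nu, (1.0 - m) * nu))


def _build_taxonomy(otu_ids: Sequence[str], pool_of: Mapping[str, str]) -> TaxonomyMap:
    """Freshwater-pool OTUs map to tribe (70%) or clade/lineage level; others to none."""
    lineage, level, tribe = {}, {}, {}
    fresh_seen = 0
    for o in otu_ids:
        pool = pool_of[o]
        if pool == "fresh":
            if fresh_seen % 10 < 7:
                t = _FRESH_TRIBES[fresh_seen % len(_FRESH_TRIBES)]
                lineage[o] = _LINEAGES["fresh_tribe"].format(tribe=t)
                level[o] = "tribe"
                tribe[o] = t
            else:
                lineage[o] = _LINEAGES["fresh_clade"]
                level[o] = "clade_lineage"
            fresh_seen += 1
        else:
            lineage[o] = _LINEAGES[pool]
            level[o] = "none"
    return TaxonomyMap(lineage=lineage, freshwater_level=level, tribe=tribe)


def simulate(params: SimulationParams) -> SimulatedDataset:
    """Generate a network and simulate the meta-community in one call."""
    network, sites = generate_network(params)
    return simulate_continuum(network, params, sites=sites)


def ground_truth_report(dataset: SimulatedDataset) -> pd.DataFrame:
    """Per-site expected pool shares and expected rarefied richness.

    Pool shares summarise the pre-sampling water-column field; expected
    richness is sum_i 1 - (1 - p_i)^N for a multinomial draw of N reads.
    Deterministic given the dataset.
    """
    n = dataset.params.reads_per_sample
    pool_idx = {pool: [o for o in dataset.field.columns if dataset.pool_of[o] == pool] for pool in POOLS}
    rows = []
    for site_id, p in dataset.field.iterrows():
        vec = p.to_numpy()
        shares = {f"share_{pool}": float(p[pool_idx[pool]].sum()) for pool in POOLS}
        shares["expected_richness"] = float((1.0 - (1.0 - vec) ** n).sum())
        rows.append({"site_id": site_id, **shares})
    return pd.DataFrame(rows).set_index("site_id")
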