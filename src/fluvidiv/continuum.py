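"""Continuum statistics: core community, first occurrences, trend fits,
freshwater-taxon and habitat-term proportions.

These operations quantify how a river's bacterioplankton changes
downstream: the occupancy-defined core community and its read share, the
per-site count of first-time OTU observations, ordinary-least-squares fits
of per-sample responses against dendritic predictors, and read-weighted
proportions of freshwater-database annotations and environment-ontology
habitat terms (e.g. "soil", "groundwater").  Tributary samples are excluded
from mainstem trends by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .otu_io import OTUTable, TaxonomyMap, occupancy

__all__ = [
    "CoreSet",
    "RegressionFit",
    "TermProfile",
    "FreshwaterProportions",
    "core_otus",
    "core_read_proportion",
    "first_occurrence_counts",
    "fit_continuum",
    "freshwater_proportions",
    "tribe_heatmap_matrix",
    "habitat_term_proportion",
    "term_proportions",
    "tributary_rkm",
    "read_terms_tsv",
    "write_terms_tsv",
]

DANUBE_LENGTH_KM = 2780.0  # official source-to-mouth length


@dataclass(frozen=True)
class CoreSet:
    """OTUs present in at least a fraction ``q`` of mainstem samples of one size fraction."""

    fraction: str
    q: float
    otu_ids: frozenset[str]
    n_samples: int  # mainstem samples of the fraction over which occupancy was computed

    def __post_init__(self) -> None:
        if not 0 < self.q <= 1:
            raise ValueError(f"q must be in (0, 1], got {self.q}")

    def __len__(self) -> int:
        return len(self.otu_ids)


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"regression needs n >= 3, got {self.n}")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


@dataclass(frozen=True)
class TermProfile:
    """Per-OTU habitat-term frequencies (an external SEQenv-style annotation).

    ``weights[otu][term]`` is a non-negative weight; an OTU may be absent or
    have an empty profile, in which case it contributes to neither numerator
    nor denominator of term proportions.
    """

    weights: Mapping[str, Mapping[str, float]]

    def normalized(self, otu_id: str) -> dict[str, float]:
        prof = self.weights.get(otu_id, {})
        total = sum(prof.values())
        if total <= 0:
            return {}
        return {t: w / total for t, w in prof.items()}

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(t for prof in self.weights.values() for t in prof)

    def profiled_otus(self) -> frozenset[str]:
        return frozenset(o for o, prof in self.weights.items() if sum(prof.values()) > 0)


class FreshwaterProportions(NamedTuple):
    tribe: float
    clade_lineage: float
    nontypical: float


# -- core community ---------------------------------------------------------


def core_otus(
    table: OTUTable,
    meta: pd.DataFrame,
    fraction: str,
    q: float = 0.90,
    presence_min: int = 1,
) -> CoreSet:
    """OTUs present in at least ``q`` of the mainstem samples of one size fraction.

    "At least 90%" is implemented as occupancy >= ceil(q * n); tributary
    samples never enter the occupancy computation.
    """
    if not 0 < q <= 1:
        raise ValueError(f"q must be in (0, 1], got {q}")
    sel = meta.index[(meta["fraction"] == fraction) & (meta["system"] == "mainstem")]
    sel = [s for s in table.sample_ids if s in set(sel)]
    if not sel:
        raise ValueError(f"no mainstem samples of fraction {fraction!r}")
    sub = table.select_samples(sel)
    occ = occupancy(sub, presence_min=presence_min)
    threshold = int(np.ceil(q * len(sel)))
    members = frozenset(occ.index[occ >= threshold])
    return CoreSet(fraction=fraction, q=q, otu_ids=members, n_samples=len(sel))


def core_read_proportion(sample_counts: pd.Series, core: CoreSet) -> float:
    """Share of a sample's reads that belong to core OTUs, in [0, 1]."""
    total = float(sample_counts.sum())
    if total <= 0:
        raise ValueError("sample has zero total reads")
    in_core = sample_counts.index.isin(core.otu_ids)
    return float(sample_counts[in_core].sum()) / total


def first_occurrence_counts(
    table: OTUTable,
    site_order: Sequence[str],
    meta: pd.DataFrame | None = None,
) -> pd.Series:
    """Number of OTUs first observed at each site, scanning upstream to downstream.

    Each OTU is attributed to the first site (in ``site_order``) where it has
    a positive count; counts therefore sum to the number of distinct OTUs
    observed across the ordered sites.  When ``meta`` is given, a site's
    presence pools all of its samples; otherwise ``site_order`` is taken to
    list sample ids directly.
    """
    presence_rows = []
    for site in site_order:
        if meta is not None:
            samples = [s for s in table.sample_ids if s in set(meta.index[meta["site_id"] == site])]
            if not samples:
                raise KeyError(f"site {site!r} has no samples in the table")
            pres = (table.counts.loc[samples] >= 1).any(axis=0)
        else:
            pres = table.sample(site) >= 1
        presence_rows.append(pres.to_numpy())
    pres_mat = np.asarray(presence_rows)  # sites x OTUs
    seen_before = np.zeros(pres_mat.shape[1], dtype=bool)
    counts = np.zeros(len(site_order), dtype=int)
    for i in range(pres_mat.shape[0]):
        new = pres_mat[i] & ~seen_before
        counts[i] = int(new.sum())
        seen_before |= pres_mat[i]
    return pd.Series(counts, index=list(site_order), name="first_occurrences")


# -- trend fits -------------------------------------------------------------


def fit_continuum(y, predictor) -> RegressionFit:
    """OLS fit y = a + b x with R^2 and the two-sided p-value for the slope.

    Pairs with a missing value in either variable are dropped; at least three
    complete pairs are required.  p-values are reported unadjusted.
    """
    ys = pd.Series(y, dtype=float)
    xs = pd.Series(predictor, dtype=float)
    if isinstance(y, pd.Series) and isinstance(predictor, pd.Series):
        xs = xs.reindex(ys.index)
    elif len(ys) != len(xs):
        raise ValueError(f"length mismatch: y has {len(ys)}, predictor has {len(xs)}")
    keep = ys.notna() & xs.notna()
    yv, xv = ys[keep].to_numpy(), xs[keep].to_numpy()
    if yv.size < 3:
        raise ValueError(f"regression needs >= 3 complete pairs, got {yv.size}")
    if np.ptp(xv) == 0:
        raise ValueError("predictor is constant")
    if np.ptp(yv) == 0:
        return RegressionFit(slope=0.0, intercept=float(yv[0]), r_squared=0.0, p_value=1.0, n=yv.size)
    res = stats.linregress(xv, yv)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(yv.size),
    )


# -- freshwater annotation and habitat terms --------------------------------


def freshwater_proportions(
    sample_counts: pd.Series, taxonomy: TaxonomyMap
) -> FreshwaterProportions:
    """Read-weighted shares of tribe-, clade/lineage- and non-matching OTUs.

    The three proportions partition the sample's reads, so they sum to 1.
    """
    total = float(sample_counts.sum())
    if total <= 0:
        raise ValueError("sample has zero total reads")
    sums = {"tribe": 0.0, "clade_lineage": 0.0, "none": 0.0}
    for otu, n in sample_counts.items():
        if n:
            sums[taxonomy.level_of(otu)] += float(n)
    return FreshwaterProportions(
        tribe=sums["tribe"] / total,
        clade_lineage=sums["clade_lineage"] / total,
        nontypical=sums["none"] / total,
    )


def tribe_heatmap_matrix(
    table: OTUTable, taxonomy: TaxonomyMap, top_n: int = 8
) -> pd.DataFrame:
    """Relative abundance of the overall top-``top_n`` freshwater tribes per sample.

    Tribes are ranked by their total read share across the whole table; the
    returned frame is tribes x samples with values in [0, 1].
    """
    tribe_of = {o: taxonomy.tribe[o] for o in table.otu_ids if o in taxonomy.tribe}
    if not tribe_of:
        raise ValueError("no tribe labels available for any OTU in the table")
    by_tribe = table.counts.T.groupby(pd.Series(tribe_of), sort=False).sum()  # tribes x samples
    ranked = by_tribe.sum(axis=1).sort_values(ascending=False, kind="stable")
    top = ranked.index[:top_n]
    totals = table.sample_totals()
    if (totals == 0).any():
        raise ValueError(f"samples with zero reads: {totals.index[totals == 0].tolist()}")
    return by_tribe.loc[top].div(totals, axis=1)


def term_proportions(sample_counts: pd.Series, profile: TermProfile) -> pd.Series:
    """Read-weighted habitat-term proportions for one sample (sums to 1).

    Each OTU's term profile is normalised to sum 1; OTUs without a profile
    are excluded from both numerator and denominator so that annotation
    missingness does not dilute the terms.
    """
    profiled = profile.profiled_otus()
    num: dict[str, float] = {}
    denom = 0.0
    for otu, n in sample_counts.items():
        if n and otu in profiled:
            denom += float(n)
            for t, w in profile.normalized(otu).items():
                num[t] = num.get(t, 0.0) + float(n) * w
    if denom == 0:
        raise ValueError("no reads from profiled OTUs in this sample")
    return pd.Series({t: v / denom for t, v in num.items()}, name="term_proportion").sort_index()


def habitat_term_proportion(
    sample_counts: pd.Series, profile: TermProfile, term: str
) -> float:
    """Proportion of one habitat term (e.g. "soil") among a sample's profiled reads."""
    if term not in profile.terms:
        raise KeyError(f"unknown term {term!r}; known terms: {sorted(profile.terms)}")
    props = term_proportions(sample_counts, profile)
    return float(props.get(term, 0.0))


def tributary_rkm(
    tributary_length_km: float, danube_length_km: float = DANUBE_LENGTH_KM
) -> float:
    """Equivalent river-kilometre of a tributary mouth: main-river length minus tributary length."""
    if tributary_length_km < 0:
        raise ValueError(f"tributary length must be >= 0, got {tributary_length_km}")
    if tributary_length_km >= danube_length_km:
        raise ValueError("tributary length must be smaller than the main river's length")
    return danube_length_km - tributary_length_km


# -- term-profile TSV interchange -------------------------------------------


def read_terms_tsv(path) -> TermProfile:
    """Read a long-format term table (``otu_id term weight``)."""
    df = pd.read_csv(path, sep="\t", dtype={"otu_id": str, "term": str})
    for col in ("otu_id", "term", "weight"):
        if col not in df.columns:
            raise ValueError(f"terms TSV {path}: missing column {col!r}")
    weights: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        w = float(row.weight)
        if w < 0:
            raise ValueError(f"terms TSV {path}: negative weight for {row.otu_id}/{row.term}")
        weights.setdefault(str(row.otu_id), {})[str(row.term)] = w
    return TermProfile(weights=weights)


def write_terms_tsv(profile: TermProfile, path) -> None:
    rows = [
        (otu, term, w)
        for otu, prof in profile.weights.items()
        for term, w in prof.items()
    ]
    pd.DataFrame(rows, columns=["otu_id", "term", "weight"]).to_csv(path, sep="\t", index=False)
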