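"""End-to-end orchestration: table processing -> diversity -> continuum stats.

The pipeline mirrors standard amplicon practice: lineage filtering first,
rarefaction next (a deep depth for alpha diversity, the minimum sample depth
for beta diversity so no sample is lost), then the per-sample statistics and
trend fits against dendritic predictors.  Every stochastic stage draws its
seed from the single run seed, so identical configurations give identical
outputs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import continuum as cont
from . import diversity as div
from . import network as net
from . import otu_io

log = logging.getLogger("fluvidiv")

DEFAULT_LINEAGE_LABELS = (
    "Plastid",
    "Mitochondrion",
    "Thaumarchaeota",
    "Crenarchaeota",
    "Euryarchaeota",
)

PREDICTOR = "mean_dendritic_stream_length_km"


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run."""

    table: str
    meta: str
    network: str
    sites: str
    taxonomy: str | None = None
    terms: str | None = None
    out_dir: str = "fluvidiv_out"
    alpha_depth: int = 7000
    beta_depth: int | str = "min"  # fixed depth or "min" = smallest sample total
    q: float = 0.90
    n_perm: int = 999
    seed: int = 42

    def validate(self) -> None:
        for name in ("table", "meta", "network", "sites"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        for name in ("taxonomy", "terms"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.alpha_depth < 1:
            raise ValueError("alpha_depth must be >= 1")
        if self.beta_depth != "min" and int(self.beta_depth) < 1:
            raise ValueError("beta_depth must be >= 1 or 'min'")


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent sub-seeds derived from the run seed (kept below 2^31)."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


# -- analysis stages (pure, in-memory) --------------------------------------


def geomorph_stage(
    network: net.RiverNetwork, sites: Sequence[net.SamplingSite]
) -> pd.DataFrame:
    """Per-site geomorphological metrics as a site-indexed frame."""
    rows = []
    for s in sites:
        m = net.compute_site_metrics(network, s)
        rows.append(
            {
                "site_id": s.site_id,
                "system": s.system,
                "river_km": s.river_km,
                "mean_dendritic_stream_length_km": m.mean_dendritic_stream_length_km,
                "median_dendritic_length_km": m.median_dendritic_length_km,
                "cumulative_dendritic_distance_km": m.cumulative_dendritic_distance_km,
                "catchment_area_km2": m.catchment_area_km2,
            }
        )
    return pd.DataFrame(rows).set_index("site_id")


def alpha_stage(
    table: otu_io.OTUTable,
    meta: pd.DataFrame,
    site_metrics: pd.DataFrame,
    *,
    alpha_depth: int = 7000,
    q: float = 0.90,
    seed: int = 0,
    taxonomy: otu_io.TaxonomyMap | None = None,
    terms: cont.TermProfile | None = None,
) -> tuple[pd.DataFrame, otu_io.RarefactionReport]:
    """Per-sample alpha diversity, core-community share and annotation trends.

    Chao1 and Pielou's J are computed on the table rarefied to
    ``alpha_depth``; core membership (occupancy >= q of mainstem samples per
    fraction) and the core read proportion are computed on the unrarefied
    table so that membership is not seed-dependent.
    """
    rare, report = otu_io.rarefy(table, depth=alpha_depth, seed=seed)
    cores = {
        f: cont.core_otus(table, meta, fraction=f, q=q)
        for f in otu_io.FRACTIONS
        if ((meta["fraction"] == f) & (meta["system"] == "mainstem")).any()
    }
    rows = []
    for s in rare.sample_ids:
        counts = rare.sample(s)
        m = meta.loc[s]
        row: dict = {
            "sample_id": s,
            "site_id": m["site_id"],
            "fraction": m["fraction"],
            "system": m["system"],
            "chao1": div.chao1(counts),
            "pielou_j": div.pielou_evenness(counts),
        }
        core = cores.get(m["fraction"])
        if core is not None:
            row["core_proportion"] = cont.core_read_proportion(table.sample(s), core)
        if taxonomy is not None:
            fw = cont.freshwater_proportions(table.sample(s), taxonomy)
            row["fw_tribe"] = fw.tribe
            row["fw_clade_lineage"] = fw.clade_lineage
            row["fw_nontypical"] = fw.nontypical
        if terms is not None:
            props = cont.term_proportions(table.sample(s), terms)
            row["term_soil"] = float(props.get("soil", 0.0))
            row["term_groundwater"] = float(props.get("groundwater", 0.0))
            row["term_soil_groundwater"] = row["term_soil"] + row["term_groundwater"]
        rows.append(row)
    alpha = pd.DataFrame(rows).set_index("sample_id")
    alpha[PREDICTOR] = alpha["site_id"].map(site_metrics[PREDICTOR])
    return alpha, report


def regression_stage(
    alpha: pd.DataFrame, predictor: str = PREDICTOR
) -> dict[str, cont.RegressionFit]:
    """Mainstem-only OLS trends of each response against a dendritic predictor.

    Keys are ``<response>__<fraction>``; tributary samples are excluded.
    """
    responses = [
        c
        for c in (
            "chao1",
            "pielou_j",
            "core_proportion",
            "term_soil",
            "term_groundwater",
            "term_soil_groundwater",
            "fw_tribe",
        )
        if c in alpha.columns
    ]
    fits: dict[str, cont.RegressionFit] = {}
    main = alpha[alpha["system"] == "mainstem"]
    for fraction in sorted(main["fraction"].unique()):
        sub = main[main["fraction"] == fraction]
        for resp in responses:
            try:
                fits[f"{resp}__{fraction}"] = cont.fit_continuum(sub[resp], sub[predictor])
            except ValueError as exc:  # too few sites, constant predictor, ...
                log.warning("regression %s__%s skipped: %s", resp, fraction, exc)
    return fits


def first_occurrence_stage(
    table: otu_io.OTUTable, meta: pd.DataFrame, site_metrics: pd.DataFrame
) -> pd.Series:
    """First-occurrence counts over mainstem sites ordered source to mouth."""
    main = site_metrics[site_metrics["system"] == "mainstem"]
    order = main.sort_values(PREDICTOR).index.tolist()
    sampled = set(meta["site_id"])
    order = [s for s in order if s in sampled]
    main_samples = meta.index[meta["system"] == "mainstem"]
    sub = table.select_samples([s for s in table.sample_ids if s in set(main_samples)])
    return cont.first_occurrence_counts(sub, order, meta)


def beta_stage(
    table: otu_io.OTUTable,
    meta: pd.DataFrame,
    site_metrics: pd.DataFrame,
    *,
    beta_depth: int | str = "min",
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Bray-Curtis, NMDS, and the permutation-test suite on both fractions.

    The table is rarefied to the minimum sample depth (so every sample is
    retained), OTUs left with fewer than two reads are dropped, and the
    size-fraction contrast is tested by PERMANOVA and beta dispersion.
    Fraction concordance (Procrustes) compares per-fraction NMDS
    configurations matched by site.
    """
    seeds = _child_seeds(seed, 6)
    depth = int(table.sample_totals().min()) if beta_depth == "min" else int(beta_depth)
    rare, rare_report = otu_io.rarefy(table, depth=depth, seed=seeds[0])
    rare = otu_io.drop_rare_otus(rare, min_reads=2)
    dm = div.bray_curtis(rare)
    ordination = div.nmds(dm, k=2, seed=seeds[1])
    grouping = meta.loc[list(dm.ids), "fraction"]

    results: dict = {
        "beta_depth": depth,
        "beta_dropped_samples": list(rare_report.dropped_samples),
        "distance_matrix": dm,
        "nmds": ordination,
        "permanova_fraction": div.permanova(dm, grouping, n_perm=n_perm, seed=seeds[2]),
    }
    disp, dists = div.beta_dispersion(dm, grouping, n_perm=n_perm, seed=seeds[3])
    results["beta_dispersion_fraction"] = disp
    results["dispersion_distances"] = dists

    mdsl = meta.loc[list(dm.ids), "site_id"].map(site_metrics[PREDICTOR])
    results["envfit"] = {}
    per_fraction_scores: dict[str, pd.DataFrame] = {}
    for i, fraction in enumerate(sorted(grouping.unique())):
        ids = [s for s in dm.ids if grouping[s] == fraction]
        if len(ids) < 4:
            continue
        sub_dm = dm.filter(ids)
        sub_ord = div.nmds(sub_dm, k=2, seed=seeds[4] + i)
        results["envfit"][fraction] = div.envfit_vector(
            sub_ord, mdsl.loc[ids], n_perm=n_perm, seed=seeds[5] + i
        )
        scores = sub_ord.as_frame()
        scores.index = meta.loc[ids, "site_id"]
        per_fraction_scores[fraction] = scores

    if len(per_fraction_scores) == 2:
        (fa, xa), (fb, xb) = sorted(per_fraction_scores.items())
        common = [s for s in xa.index if s in set(xb.index)]
        if len(common) >= 4:
            results["procrustes_fractions"] = div.procrustes_test(
                xa.loc[common], xb.loc[common], n_perm=n_perm, seed=seeds[5] + 7
            )
    return results


# -- full run ---------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write the result tree plus a manifest.

    Any stage failure aborts with the stage name; outputs written so far are
    flagged as partial in the manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "fluvidiv_version": __version__,
        "config": {k: str(v) for k, v in asdict(config).items()},
        "seed": config.seed,
        "stages": [],
        "partial": True,
    }
    seeds = _child_seeds(config.seed, 4)
    results: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            value = fn()
        except Exception as exc:
            manifest["stages"].append({"name": name, "status": "failed", "error": str(exc)})
            _write_json(out / "manifest.json", manifest)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(
            {"name": name, "status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
        )
        log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return value

    # load
    def _load():
        table = otu_io.read_table(config.table)
        meta = otu_io.read_metadata_tsv(config.meta)
        otu_io.validate_metadata(table, meta)
        network = net.read_network_tsv(config.network)
        sites = net.read_sites_tsv(config.sites, network)
        taxonomy = otu_io.read_taxonomy_tsv(config.taxonomy) if config.taxonomy else None
        terms = cont.read_terms_tsv(config.terms) if config.terms else None
        return table, meta, network, sites, taxonomy, terms

    table, meta, network, sites, taxonomy, terms = stage("load", _load)

    def _filter():
        if taxonomy is None:
            return table, None
        return otu_io.drop_lineages(table, taxonomy, DEFAULT_LINEAGE_LABELS)

    filtered, removal = stage("lineage_filter", _filter)
    if removal is not None:
        manifest["lineage_removal"] = {
            "n_otus_removed": removal.n_otus_removed,
            "n_reads_removed": removal.n_reads_removed,
        }

    site_metrics = stage("network_metrics", lambda: geomorph_stage(network, sites))
    alpha, rep = stage(
        "alpha",
        lambda: alpha_stage(
            filtered,
            meta,
            site_metrics,
            alpha_depth=config.alpha_depth,
            q=config.q,
            seed=seeds[0],
            taxonomy=taxonomy,
            terms=terms,
        ),
    )
    manifest["alpha_depth"] = config.alpha_depth
    manifest["alpha_dropped_samples"] = list(rep.dropped_samples)
    fits = stage("regressions", lambda: regression_stage(alpha))
    first_occ = stage("first_occurrence", lambda: first_occurrence_stage(filtered, meta, site_metrics))
    beta = stage(
        "beta",
        lambda: beta_stage(
            filtered,
            meta,
            site_metrics,
            beta_depth=config.beta_depth,
            n_perm=config.n_perm,
            seed=seeds[1],
        ),
    )

    results.update(
        site_metrics=site_metrics, alpha=alpha, regressions=fits, first_occurrence=first_occ, beta=beta
    )
    write_results(results, out)
    manifest["partial"] = False
    _write_json(out / "manifest.json", manifest)
    results["manifest"] = manifest
    return results


def write_results(results: Mapping, out: Path) -> None:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    results["site_metrics"].to_csv(out / "site_metrics.tsv", sep="\t")
    results["alpha"].to_csv(out / "alpha_diversity.tsv", sep="\t")
    _write_json(
        out / "regressions.json",
        {k: asdict(v) for k, v in results["regressions"].items()},
    )
    results["first_occurrence"].to_frame().to_csv(out / "first_occurrence.tsv", sep="\t")
    beta = results["beta"]
    dm = beta["distance_matrix"]
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        out / "bray_curtis.tsv", sep="\t"
    )
    ordination = beta["nmds"]
    ordination.as_frame().to_csv(out / "nmds_scores.tsv", sep="\t")
    _write_json(out / "nmds.json", {"stress": ordination.stress, "k": ordination.k})
    tests = {
        "permanova_fraction": _test_dict(beta["permanova_fraction"]),
        "beta_dispersion_fraction": _test_dict(beta["beta_dispersion_fraction"]),
        "envfit": {f: _test_dict(t) for f, t in beta["envfit"].items()},
    }
    if "procrustes_fractions" in beta:
        tests["procrustes_fractions"] = _test_dict(beta["procrustes_fractions"])
    _write_json(out / "permutation_tests.json", tests)


def _test_dict(t: div.PermutationTestResult) -> dict:
    d = {
        "statistic": t.statistic,
        "statistic_name": t.statistic_name,
        "p_value": t.p_value,
        "n_permutations": t.n_permutations,
    }
    for k, v in t.extras.items():
        if isinstance(v, (int, float, str)):
            d[k] = v
        elif isinstance(v, dict):
            d[k] = v
        elif isinstance(v, np.ndarray):
            d[k] = v.tolist()
    return d


def _write_json(path: Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")


def collate_report(out_dir) -> dict:
    """Collect the JSON/TSV outputs of a finished run into one summary dict."""
    out = Path(out_dir)
    summary: dict = {}
    for name in ("manifest", "regressions", "nmds", "permutation_tests"):
        p = out / f"{name}.json"
        if p.exists():
            summary[name] = json.loads(p.read_text())
    for name in ("site_metrics", "alpha_diversity", "first_occurrence"):
        p = out / f"{name}.tsv"
        if p.exists():
            summary[f"{name}_rows"] = int(len(pd.read_csv(p, sep="\t")))
    return summary
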