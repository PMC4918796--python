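"""Continuum statistics: core community, downstream trends, habitat terms.

The occupancy-defined core community (OTUs in >= 90% of mainstem samples of
a fraction) grows in read share downstream as species sorting concentrates
the community on few competitive freshwater taxa; richness, evenness and the
soil/groundwater habitat-term share decline.  Trends are OLS fits against
mean dendritic stream length, the residence-time proxy.
"""

import pandas as pd

from fluvidiv import (
    SimulationParams,
    chao1,
    core_otus,
    core_read_proportion,
    first_occurrence_counts,
    fit_continuum,
    habitat_term_proportion,
    mean_dendritic_stream_length,
    rarefy,
    simulate,
)

ds = simulate(SimulationParams.paper_like(seed=7))
rarefied, _ = rarefy(ds.table, depth=7000, seed=1)
core = core_otus(ds.table, ds.meta, fraction="FL", q=0.90)
print(f"core community (FL, q=0.90): {len(core)} OTUs over {core.n_samples} mainstem samples")

mdsl = {s.site_id: mean_dendritic_stream_length(ds.network, s) for s in ds.mainstem_sites}
rows = []
for sample_id in rarefied.sample_ids:
    m = ds.meta.loc[sample_id]
    if m["fraction"] != "FL" or m["system"] != "mainstem":
        continue
    rows.append(
        {
            "mdsl_km": mdsl[m["site_id"]],
            "chao1": chao1(rarefied.sample(sample_id)),
            "core_share": core_read_proportion(ds.table.sample(sample_id), core),
            "soil_term": habitat_term_proportion(ds.table.sample(sample_id), ds.terms, "soil"),
        }
    )
df = pd.DataFrame(rows).sort_values("mdsl_km")
print(df.round(3).to_string(index=False))

for response in ("chao1", "core_share", "soil_term"):
    fit = fit_continuum(df[response], df["mdsl_km"])
    print(f"{response} ~ mean dendritic stream length: slope={fit.slope:+.4g}/km, "
          f"R2={fit.r_squared:.2f}, p={fit.p_value:.2g}")

site_order = [s.site_id for s in ds.mainstem_sites]
first = first_occurrence_counts(ds.table, site_order, ds.meta)
print("first occurrences per site (source -> mouth):", first.tolist(),
      "| total distinct OTUs:", int(first.sum()))
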