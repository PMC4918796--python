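"""OTU-table hygiene: lineage removal, rarefaction, occupancy.

Amplicon count tables carry unwanted organellar/archaeal OTUs and unequal
sequencing depths.  The standard chain removes unwanted lineages first, then
subsamples every sample to a common depth (without replacement), so that
richness and evenness are comparable across samples.
"""

import pandas as pd

from fluvidiv import OTUTable, TaxonomyMap, drop_lineages, drop_rare_otus, occupancy, rarefy

counts = pd.DataFrame(
    {
        "otu_chloro": [120, 80, 60],
        "otu_acI": [300, 500, 800],
        "otu_soil": [400, 150, 40],
        "otu_rare": [1, 0, 0],
    },
    index=pd.Index(["upstream", "midstream", "downstream"], name="sample_id"),
)
table = OTUTable(counts)
taxonomy = TaxonomyMap(
    lineage={
        "otu_chloro": "Bacteria;Cyanobacteria;Chloroplast",
        "otu_acI": "Bacteria;Actinobacteria;acI",
        "otu_soil": "Bacteria;Acidobacteria",
        "otu_rare": "Bacteria;unknown",
    }
)

filtered, report = drop_lineages(table, taxonomy, ["Chloroplast", "Mitochondrion"])
print(f"lineage filter removed {report.n_otus_removed} OTU(s), {report.n_reads_removed} reads")

filtered = drop_rare_otus(filtered, min_reads=2)  # global singletons out
print("OTUs kept:", filtered.otu_ids)

depth = int(filtered.sample_totals().min())
rarefied, rep = rarefy(filtered, depth=depth, seed=42)
print(f"rarefied to {depth} reads/sample; dropped: {list(rep.dropped_samples) or 'none'}")
print(rarefied.counts)
print("occupancy (samples per OTU):")
print(occupancy(rarefied).to_string())
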