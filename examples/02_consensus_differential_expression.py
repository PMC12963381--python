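"""High-confidence differential expression by three-engine consensus.

Simulates a single neuronal cluster across the early disease contrast
(intermediate vs low pathology) with 25 planted DE genes (|log2FC| = 1),
runs the hurdle mixed model, the 50% subsampling bootstrap, and the
pseudobulk negative-binomial test, then intersects them into the
high-confidence set.
"""

import scresilience as sr
from scresilience.diffexpr import Contrast

cfg = sr.CohortConfig(n_donors_per_group=14, n_celltypes=1, n_cells_per_donor=22,
                      n_genes=500, n_de_genes=25, de_log2fc=1.0,
                      n_marker_genes_per_type=0, seed=1)
ds, truth = sr.simulate_cohort(cfg)
nm = sr.normalize_log(ds)
contrast = Contrast("early")

mixed = sr.fit_hurdle_mixed(nm, ds.cell_meta, ds.donor_meta, contrast)
print(f"mixed model: {len(mixed.significant_genes)} significant genes "
      f"({mixed.info['donor_handling']}, {mixed.info['n_donors']} donors)")

boot = sr.bootstrap_de(nm, ds.cell_meta, ds.donor_meta, contrast,
                       n_iter=50, seed=2)
print(f"bootstrap: {int(boot.table['significant'].sum())} genes with "
      f">= {round(boot.info['min_support'] * 50 / 100)} / 50 directional support")

pb, nexp = sr.pseudobulk_aggregate(ds)
pb.index = [i.split("|")[0] for i in pb.index]
res_pb = sr.pseudobulk_de(pb, nexp.sum(axis=0),
                          ds.donor_meta["pathology_group"], contrast)
print(f"pseudobulk NB: {int(res_pb.table['significant'].sum())} significant genes")

hc = sr.consensus_high_confidence(mixed, bootstrap=boot, pseudobulk=res_pb)
planted = set(truth.de_genes["T0"])
print(f"\nhigh-confidence set: {len(hc.genes)} genes "
      f"({len(hc.genes & planted)} of {len(planted)} planted recovered, "
      f"{len(hc.genes - planted)} unplanted)")
print(hc.table.head(10).to_string())
print("\nEach high-confidence gene is mixed-significant AND corroborated by"
      "\nbootstrap support, pseudobulk significance, or hub membership.")
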