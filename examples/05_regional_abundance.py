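"""Regional abundance of high-ADNP (AHNP) neuronal clusters.

Generates a synthetic atlas cluster-annotation table with planted AHNP
clusters, classifies clusters by the 6+ ADNP / <3 non-ADNP rule,
attributes cluster cells to dissections proportionally, and ranks
regions by estimated AHNP cell count.
"""

import npvuln as nv
from npvuln.regional import round_half_up

params = nv.AnnotationGeneratorParams(seed=5)
records, region_map, truth = nv.generate_cluster_annotation(params)

table = nv.estimate_regional_counts(records, params.adnp_list, params.np_panel,
                                    region_map=region_map, level="region")
table["ahnp_cell_estimate"] = table["ahnp_cell_estimate"].map(round_half_up)
print("AHNP cell estimates per region:")
print(nv.rank_top_regions(table, 5).to_string(index=False))
print("\nplanted totals:", truth["per_region"])

mec = nv.dissection_membership_breakdown(records, "MEC", params.adnp_list, params.np_panel)
print("\nMEC breakdown by neurotransmitter:")
print(mec.round(1).to_string(index=False))
# The recovered ranking matches the planted one exactly; the breakdown shows
# which neurotransmitter classes the MEC's AHNP cells belong to.
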