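"""Vaccine-vaccine association network, centralities, and communities.

Loads the packaged 28-vaccine / 32-gene association table, links two
vaccines whenever they share a central gene, ranks the vaccines with the
four centrality metrics, and splits the network into communities by
greedy modularity maximization.
"""

from condl import AssociationTable, build_concept_network, concept_centrality
from condl import greedy_communities
from condl import fixtures as fx

table = AssociationTable.from_gene_sets(fx.table2_gene_sets())
graph = build_concept_network(table)
print(
    f"vaccine-vaccine network: {graph.number_of_nodes()} vaccines, "
    f"{graph.number_of_edges()} edges"
)

report = concept_centrality(graph)
top = report.sort_values(["degree", "betweenness"], ascending=False).head(5)
print("\nmost central vaccines (degree, eigenvector, closeness, betweenness):")
for vaccine, row in top.iterrows():
    print(
        f"  {vaccine:15s} {row.degree:4.0f} {row.eigenvector:11.4f} "
        f"{row.closeness:9.4f} {row.betweenness:11.2f}"
    )

partition = greedy_communities(graph)
print(
    f"\ngreedy modularity: {len(partition.communities)} communities, "
    f"sizes {partition.sizes}, Q = {partition.q:.4f}"
)
for i, community in enumerate(partition.communities):
    print(f"  community {i}: {', '.join(sorted(community))}")
# The two hubs (BCG Vaccine and LVS) touch every other vaccine; the two
# communities separate the mostly-viral from the mostly-bacterial vaccines.
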