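"""Full pipeline on synthetic data: sequences → DNV → centroids →
summed distance matrix → BIONJ tree → natural graph.

Four populations in two superpopulation pairs are simulated by mutating
a common ancestor along a known two-level tree; the pipeline should
recover that topology (Robinson-Foulds distance 0).
"""

from skbio import TreeNode

from dnvphylo import (
    build_natural_graph,
    bionj_tree,
    distance_matrix,
    divided_natural_vector,
    group_by_population,
    personal_vector,
    population_centroids,
    robinson_foulds,
    sum_matrices,
)
from dnvphylo.graph import to_edge_tsv
from dnvphylo.phylo import newick_string
from dnvphylo.simulate import PopulationTreeSpec, simulate_population_sequences

matrices = []
for chromosome in range(2):  # two independent "chromosomes", matrices summed
    spec = PopulationTreeSpec(seed=100 + chromosome)
    seqs, panel, generating_newick = simulate_population_sequences(spec)
    vectors = [
        personal_vector([divided_natural_vector(s, 4).flat()], s.identifier)
        for s in seqs
    ]
    centroids = sorted(
        population_centroids(group_by_population(vectors, panel)),
        key=lambda c: c.population,
    )
    matrices.append(distance_matrix(centroids))

total = sum_matrices(matrices)
print("summed distance matrix labels:", total.labels)
tree = bionj_tree(total)
print("inferred:  ", newick_string(tree))
print("generating:", generating_newick)
rf = robinson_foulds(tree, TreeNode.read([generating_newick]))
print(f"Robinson-Foulds distance = {rf}  (0 means the topology was recovered)")

graph = build_natural_graph(total)
print("\nnatural graph edges (layer 1 = nearest population, layer 2 = nearest group):")
print(to_edge_tsv(graph))
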