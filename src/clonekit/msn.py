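"""Minimum spanning network over genets.

Nodes are genets (represented by their medoid multilocus genotype — a
real observed MLG, never a consensus), edges are genetic distances.  The
network is built Kruskal-style on ascending edge weights; whenever an
edge is accepted, all other edges of equal weight that also join two
components distinct at that point are accepted too, so ties are retained
and the result is a network containing every tied minimum spanning tree
rather than one arbitrary tree.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .distances import pairwise_matrix
from .model import Dataset, DistanceMatrix, GenetAssignment, GenotypeTable


def genet_medoid(
    data: Dataset | GenotypeTable,
    assignment: GenetAssignment,
    dm: DistanceMatrix | None = None,
) -> list[int]:
    """Index of the medoid sample of each genet (1..G order).

    The medoid minimizes the summed genetic distance to the other
    members; ties are broken by lowest sample id.  ``dm`` is the
    sample-level distance matrix (computed with IAM if omitted).
    """
    gt = data.genotypes if isinstance(data, Dataset) else data
    if gt.samples != assignment.samples:
        raise ValueError("assignment samples do not match genotype table")
    if dm is None:
        dm = pairwise_matrix(gt, model="iam")
    medoids = []
    for g in range(1, assignment.n_genets + 1):
        members = assignment.members(g)
        sub = dm.values[np.ix_(members, members)]
        tot = sub.sum(axis=1)
        best = min(
            zip(tot, [gt.samples[i] for i in members], members),
            key=lambda t: (t[0], t[1]),
        )[2]
        medoids.append(best)
    return medoids


def build_msn(dm: DistanceMatrix, node_sizes=None) -> nx.Graph:
    """Minimum spanning network from a full genet-level distance matrix.

    Returns a networkx Graph whose nodes carry ``size`` attributes (when
    given) and whose edges carry ``weight``.  The edge set is the union
    of all minimum spanning trees under the tie-retention rule described
    in the module docstring.
    """
    n = dm.n
    if n < 1:
        raise ValueError("empty distance matrix")
    G = nx.Graph()
    sizes = [1] * n if node_sizes is None else list(node_sizes)
    for k, gid in enumerate(dm.ids):
        G.add_node(gid, size=int(sizes[k]))
    if n == 1:
        return G

    iu = np.triu_indices(n, k=1)
    edges = sorted(zip(dm.values[iu], iu[0], iu[1]))
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    k = 0
    while k < len(edges):
        w = edges[k][0]
        group = []
        while k < len(edges) and edges[k][0] == w:
            group.append(edges[k])
            k += 1
        # components snapshot before this weight level
        accepted = [(i, j) for _, i, j in group if find(int(i)) != find(int(j))]
        for i, j in accepted:
            G.add_edge(dm.ids[int(i)], dm.ids[int(j)], weight=float(w))
        for i, j in accepted:
            ri, rj = find(int(i)), find(int(j))
            if ri != rj:
                parent[ri] = rj
    return G


def msn_from_assignment(
    data: Dataset | GenotypeTable,
    assignment: GenetAssignment,
    model: str = "dissimilarity",
    relative: bool = True,
) -> tuple[nx.Graph, DistanceMatrix]:
    """Medoid genotypes -> genet distance matrix -> MSN.

    Relative dissimilarity is the default edge distance.  Genet node ids
    are ``"G<rank>"``.
    """
    gt = data.genotypes if isinstance(data, Dataset) else data
    medoids = genet_medoid(gt, assignment)
    sub = gt.subset(medoids)
    sub.samples = [f"G{g}" for g in range(1, assignment.n_genets + 1)]
    if len(medoids) == 1:
        gdm = DistanceMatrix(sub.samples, np.zeros((1, 1)), model)
    else:
        gdm = pairwise_matrix(sub, model=model, relative=relative)
    return build_msn(gdm, node_sizes=assignment.sizes()), gdm


def write_graphml(path, graph: nx.Graph) -> None:
    nx.write_graphml(graph, path)
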