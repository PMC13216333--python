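"""Independent brute-force oracles used to validate the fast paths.

These deliberately avoid the implementations they check: set similarity
is maximized by exhaustive enumeration of all one-to-one partial
matchings, and symmetry classes come from a full automorphism search
with networkx's VF2 matcher.
"""

import math

import networkx as nx
from rdkit import Chem


def brute_force_set_similarity(xs, ys, sigma):
    """Max over all one-to-one partial matchings of the kernel sum,
    normalized by sqrt(mn).  Exponential; use only for tiny inputs."""
    m, n = len(xs), len(ys)
    if m == 0 or n == 0:
        return 0.0

    def kernel(a, b):
        return math.exp(-((a - b) ** 2) / (2.0 * sigma**2))

    best = 0.0

    def rec(i, used, total):
        nonlocal best
        if i == m:
            best = max(best, total)
            return
        rec(i + 1, used, total)  # leave xs[i] unmatched
        for j in range(n):
            if not used & (1 << j):
                rec(i + 1, used | (1 << j), total + kernel(xs[i], ys[j]))

    rec(0, 0, 0.0)
    return best / math.sqrt(m * n)


def _mol_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), label=(atom.GetSymbol(), atom.GetFormalCharge(),
                                         atom.GetTotalNumHs()))
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(),
                   order=str(bond.GetBondType()))
    return g


def automorphism_orbits(mol: Chem.Mol) -> list[list[int]]:
    """Atom orbits under the full automorphism group (VF2 enumeration)."""
    g = _mol_graph(mol)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g,
        node_match=lambda a, b: a["label"] == b["label"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    n = mol.GetNumAtoms()
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for mapping in matcher.isomorphisms_iter():
        for src, dst in mapping.items():
            union(src, dst)
    orbits: dict[int, list[int]] = {}
    for i in range(n):
        orbits.setdefault(find(i), []).append(i)
    return sorted(sorted(o) for o in orbits.values())
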