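"""Independent brute-force oracles and random-case generators for tests.

These deliberately avoid the package's algorithms: the local-alignment oracle
enumerates alignment paths directly (no dynamic programming), and the random
tree generators build cases for the exhaustive reconciliation search.
"""

from __future__ import annotations

import numpy as np

from retroexpand.trees import Node


def brute_force_local_score(a: str, b: str, match: float, mismatch: float,
                            gap_open: float, gap_extend: float) -> float:
    """Best local alignment score by exhaustive path enumeration.

    Explores every monotone alignment path from every start pair, scoring gap
    runs as open + len * extend; prunes branches whose optimistic completion
    cannot beat the incumbent. Exponential — for tiny sequences only.
    """
    n, m = len(a), len(b)
    best = 0.0  # the empty alignment scores 0

    def extend(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if score > best:
            best = score
        if score + min(n - i, m - j) * match <= best:
            return
        if i < n and j < m:
            s = match if a[i] == b[j] else mismatch
            extend(i + 1, j + 1, score + s, "M")
        if i < n:
            g = gap_extend if last == "D" else gap_open + gap_extend
            extend(i + 1, j, score + g, "D")
        if j < m:
            g = gap_extend if last == "I" else gap_open + gap_extend
            extend(i, j + 1, score + g, "I")

    for i in range(n):
        for j in range(m):
            extend(i, j, 0.0, "")
    return best


def random_rooted_binary_tree(names: list[str], rng: np.random.Generator,
                              max_age: float = 50.0) -> Node:
    """Random rooted binary tree over the given leaf names, with random
    coalescent-style node ages."""
    nodes = [Node(name=n, age=0.0) for n in names]
    age = 0.0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        age += float(rng.uniform(1.0, max_age / max(len(names), 2)))
        parent = Node(age=age)
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def random_reconciliation_case(rng: np.random.Generator,
                               max_species: int = 4, max_genes: int = 6):
    """(gene_tree, species_tree, leaf_map) with <= max_genes gene leaves over
    <= max_species species."""
    n_sp = int(rng.integers(2, max_species + 1))
    species = [f"S{i}" for i in range(n_sp)]
    stree = random_rooted_binary_tree(list(species), rng)
    n_genes = int(rng.integers(2, max_genes + 1))
    leaf_names = [f"g{i}" for i in range(n_genes)]
    gtree = random_rooted_binary_tree(list(leaf_names), rng)
    leaf_map = {g: species[int(rng.integers(0, n_sp))] for g in leaf_names}
    return gtree, stree, leaf_map
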