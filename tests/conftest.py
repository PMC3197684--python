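import numpy as np
import pytest

from cryptotyper.phylo import p_distance_matrix
from cryptotyper.seqalign import AlignmentBlock
from cryptotyper.synthetic_data import SimConfig, generate_sequences


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def clone_records(sim_config):
    return generate_sequences(sim_config)


@pytest.fixture(scope="session")
def its_block(clone_records):
    return AlignmentBlock([r for r in clone_records if r.marker == "ITS"])


@pytest.fixture(scope="session")
def its_pdist(its_block):
    return p_distance_matrix(its_block)


@pytest.fixture(scope="session")
def its_groups(its_block):
    return {r.id: r.genotype for r in its_block.rows}


def random_rooted_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary tree for oracle tests.

    Returns (newick string, labels, adjacency dict label/node -> list of
    (neighbor, branch length)). Built by repeated random joins, so it is
    independent of any tree code in the package.
    """
    labels = [f"T{i}" for i in range(n_leaves)]
    nodes = list(labels)
    adj: dict = {lab: [] for lab in labels}
    reprs = {lab: lab for lab in labels}
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(0.01, 0.3, size=2)
        new = f"_n{counter}"
        counter += 1
        adj[new] = [(a, la), (b, lb)]
        adj[a].append((new, la))
        adj[b].append((new, lb))
        reprs[new] = f"({reprs[a]}:{la:.10f},{reprs[b]}:{lb:.10f})"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [new]
    return reprs[nodes[0]] + ";", labels, adj


def brute_force_path_lengths(adj: dict, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path sums by breadth-first walks over the adjacency."""
    n = len(labels)
    out = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        nxt.append(v)
            frontier = nxt
        for j, dst in enumerate(labels):
            out[i, j] = dist[dst]
    return out
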