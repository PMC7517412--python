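"""Weighted modularity and Louvain-style module detection.

Modularity of a partition {c_i} of a weighted undirected network A is

    Q = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(c_i, c_j)

with node strengths k_i = Σ_j A_ij and total weight m = (Σ_ij A_ij)/2.
Q compares the weight inside modules against the expectation of a
degree-preserving random null; Q = 0 for the all-in-one partition.

Module detection is greedy multilevel (Louvain-style) maximization,
implemented here directly so that tie-breaking and restart order are fully
controlled by a seeded generator: each restart sweeps nodes in a freshly
shuffled order, moving a node to the neighboring module with the largest
positive gain until no move improves Q by more than a small tolerance, then
aggregates modules into super-nodes and repeats. The best of ``n_restarts``
partitions by Q is returned; ties keep the first encountered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, ValidationError
from .network import BrainNetwork

__all__ = ["ModulePartition", "modularity_q", "detect_modules"]

_GAIN_TOL = 1e-10


@dataclass
class ModulePartition:
    """Node → module assignment with its modularity.

    ``assignment`` maps 0-based node position to a 1-based contiguous module
    id; modules are numbered by descending size, ties broken by the smallest
    contained node index.
    """

    assignment: np.ndarray
    q: float

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        ids = np.unique(a)
        if ids.size == 0 or not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise ValidationError("module ids must be contiguous 1..C")
        self.assignment = a

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max())

    def members(self, module_id: int) -> np.ndarray:
        """0-based node positions belonging to a module."""
        return np.nonzero(self.assignment == module_id)[0]

    def sizes(self) -> list[int]:
        return [int((self.assignment == m).sum()) for m in range(1, self.n_modules + 1)]


def _adjacency(network) -> np.ndarray:
    if isinstance(network, BrainNetwork):
        return network.adjacency
    return np.asarray(network, dtype=float)


def modularity_q(network, assignment) -> float:
    """Evaluate Q for an explicit assignment (array, dict, or partition)."""
    w = _adjacency(network)
    n = w.shape[0]
    if isinstance(assignment, ModulePartition):
        comm = assignment.assignment
    elif isinstance(assignment, dict):
        if set(assignment) != set(range(n)) and set(assignment) != set(range(1, n + 1)):
            raise ValidationError("assignment must cover every node")
        base = 1 if min(assignment) == 1 else 0
        comm = np.array([assignment[i + base] for i in range(n)])
    else:
        comm = np.asarray(assignment)
        if comm.shape != (n,):
            raise ValidationError("assignment must cover every node")
    two_m = w.sum()
    if two_m <= 0:
        raise DomainError("modularity undefined for an all-zero network")
    k = w.sum(axis=1)
    q = 0.0
    for c in np.unique(comm):
        idx = comm == c
        q += w[np.ix_(idx, idx)].sum() / two_m - (k[idx].sum() / two_m) ** 2
    return float(q)


def _local_move(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One level of greedy node moving; returns a compact 0-based labeling."""
    n = w.shape[0]
    comm = np.arange(n)
    k = w.sum(axis=1)
    two_m = w.sum()
    sigma_tot = k.copy()  # per-community total strength
    neighbors = [np.nonzero(w[i])[0] for i in range(n)]
    improved = True
    while improved:
        improved = False
        order = rng.permutation(n)
        for i in order:
            ci = comm[i]
            # strength from i to each neighboring community (self excluded)
            w_to: dict[int, float] = {ci: 0.0}
            for j in neighbors[i]:
                if j == i:
                    continue
                w_to[comm[j]] = w_to.get(comm[j], 0.0) + w[i, j]
            # detach i from its community
            sigma_tot[ci] -= k[i]
            best_c, best_gain = ci, w_to.get(ci, 0.0) - k[i] * sigma_tot[ci] / two_m
            for c, wic in w_to.items():
                if c == ci:
                    continue
                gain = wic - k[i] * sigma_tot[c] / two_m
                if gain > best_gain + _GAIN_TOL:
                    best_c, best_gain = c, gain
            sigma_tot[best_c] += k[i]
            if best_c != ci:
                comm[i] = best_c
                improved = True
    # compact labels
    _, compact = np.unique(comm, return_inverse=True)
    return compact


def _louvain_once(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    membership = np.arange(w.shape[0])
    current = w
    while True:
        labels = _local_move(current, rng)
        n_comm = labels.max() + 1
        if n_comm == current.shape[0]:
            break
        # aggregate: M[a, b] = total weight between communities a and b
        onehot = np.zeros((current.shape[0], n_comm))
        onehot[np.arange(current.shape[0]), labels] = 1.0
        current = onehot.T @ current @ onehot
        membership = labels[membership]
    return membership


def _renumber(assignment: np.ndarray) -> np.ndarray:
    """1-based ids by descending module size, then smallest node index."""
    ids = np.unique(assignment)
    keyed = sorted(
        ids,
        key=lambda c: (-(assignment == c).sum(), np.nonzero(assignment == c)[0][0]),
    )
    remap = {c: i + 1 for i, c in enumerate(keyed)}
    return np.array([remap[c] for c in assignment])


def detect_modules(network, seed: int, n_restarts: int = 100) -> ModulePartition:
    """Best-of-restarts Louvain partition, deterministic given the seed.

    Raises
    ------
    DomainError
        If the network has no edges.
    """
    w = _adjacency(network)
    if w.sum() <= 0:
        raise DomainError("cannot detect modules in an empty network")
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best_assign: np.ndarray | None = None
    best_q = -np.inf
    for _ in range(n_restarts):
        membership = _louvain_once(w, rng)
        q = modularity_q(w, membership)
        if q > best_q + _GAIN_TOL:
            best_q = q
            best_assign = membership
    assert best_assign is not None
    return ModulePartition(assignment=_renumber(best_assign), q=float(best_q))
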