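"""Discrete Bayesian network: model, BIC scoring, MH structure search, inference.

The network has M binary region-decision nodes x^(1)..x^(M) plus one binary
label node y (PD=1 / APS=0), indexed 0..M-1 for the regions and M for the
label.  The joint factorizes over the DAG as

    p(x, y) = prod_v theta_{v | Pa(v)}

with one conditional probability table (CPT) per node.  Structure is learned
by a Metropolis-Hastings random walk over DAG space scored by the Bayesian
information criterion (BIC), parameters by Dirichlet-MAP counting, and
classification by exact posterior enumeration over the label with the
tie-break chain: posterior argmax, then majority vote over the region
decisions, then the vote of the most accurate region.

All structures here are small (<= ~10 binary nodes), so inference is exact
and enumeration-based oracles remain tractable for testing.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path

import numpy as np

from ._common import LABEL_PD, LABEL_APS, InferenceError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# data and model containers
# ---------------------------------------------------------------------------

@dataclass
class DiscreteDataset:
    """N fully observed binary rows over M region decisions + the label.

    Column layout: columns 0..M-1 are region decisions, column M is the label.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("dataset must be N x (M+1) with M >= 1")
        if self.data.size and self.data.max() > 1:
            raise ValueError("dataset entries must be binary")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def m_regions(self) -> int:
        return self.data.shape[1] - 1

    @property
    def labels(self) -> np.ndarray:
        return self.data[:, -1]

    @property
    def decisions(self) -> np.ndarray:
        return self.data[:, :-1]


class DAGStructure:
    """Directed acyclic graph over M region nodes plus the label node.

    Nodes are integers 0..n_nodes-1; by convention node ``n_nodes - 1`` is the
    label.  Acyclicity is validated at construction.
    """

    __slots__ = ("n_nodes", "edges")

    def __init__(self, n_nodes: int, edges=()):
        if n_nodes < 1:
            raise ValueError("need at least one node")
        edges = frozenset((int(a), int(b)) for a, b in edges)
        for a, b in edges:
            if not (0 <= a < n_nodes and 0 <= b < n_nodes) or a == b:
                raise ValueError(f"invalid edge ({a}, {b})")
        self.n_nodes = int(n_nodes)
        self.edges = edges
        if not _is_acyclic(self.adjacency()):
            raise ValueError("edge set contains a directed cycle")

    @property
    def label_node(self) -> int:
        return self.n_nodes - 1

    def parents(self, node: int) -> tuple[int, ...]:
        return tuple(sorted(a for a, b in self.edges if b == node))

    def adjacency(self) -> np.ndarray:
        adj = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for a, b in self.edges:
            adj[a, b] = True
        return adj

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DAGStructure)
            and self.n_nodes == other.n_nodes
            and self.edges == other.edges
        )

    def __hash__(self) -> int:
        return hash((self.n_nodes, self.edges))

    def __repr__(self) -> str:
        return f"DAGStructure(n_nodes={self.n_nodes}, edges={sorted(self.edges)})"

    def to_json(self) -> str:
        return json.dumps(
            {"n_nodes": self.n_nodes, "edges": sorted(map(list, self.edges))}
        )

    @classmethod
    def from_json(cls, text: str) -> "DAGStructure":
        obj = json.loads(text)
        return cls(obj["n_nodes"], [tuple(e) for e in obj["edges"]])


@dataclass
class CPTSet:
    """Conditional probability tables, one per node.

    ``tables[v]`` has shape ``(2,) * len(parents[v]) + (2,)``: the leading
    axes index the parent states (in increasing parent order), the last axis
    the node's own state.  Every conditional distribution sums to 1.
    """

    parents: dict[int, tuple[int, ...]]
    tables: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        for v, tab in self.tables.items():
            tab = np.asarray(tab, dtype=float)
            expected = (2,) * len(self.parents[v]) + (2,)
            if tab.shape != expected:
                raise ValueError(f"CPT for node {v}: shape {tab.shape} != {expected}")
            if np.any(tab < 0):
                raise ValueError(f"CPT for node {v} has negative entries")
            if not np.allclose(tab.sum(axis=-1), 1.0, atol=1e-12):
                raise ValueError(f"CPT rows for node {v} do not sum to 1")
            self.tables[v] = tab

    def prob(self, node: int, assignment) -> float:
        idx = tuple(int(assignment[p]) for p in self.parents[node])
        return float(self.tables[node][idx + (int(assignment[node]),)])

    def to_json(self) -> str:
        obj = {
            str(v): {"parents": list(self.parents[v]), "table": self.tables[v].tolist()}
            for v in sorted(self.tables)
        }
        return json.dumps(obj)

    @classmethod
    def from_json(cls, text: str) -> "CPTSet":
        obj = json.loads(text)
        parents = {int(v): tuple(d["parents"]) for v, d in obj.items()}
        tables = {int(v): np.asarray(d["table"], dtype=float) for v, d in obj.items()}
        return cls(parents=parents, tables=tables)


@dataclass
class MHTrace:
    """Per-iteration record of the structure sampler."""

    moves: list[tuple[str, int, int]] = field(default_factory=list)
    accepted: list[bool] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.accepted)

    @property
    def acceptance_ratio(self) -> float:
        return float(np.mean(self.accepted)) if self.accepted else 0.0

    def cumulative_acceptance(self) -> np.ndarray:
        acc = np.asarray(self.accepted, dtype=float)
        if acc.size == 0:
            return acc
        return np.cumsum(acc) / np.arange(1, acc.size + 1)


# ---------------------------------------------------------------------------
# joint probability and exact inference
# ---------------------------------------------------------------------------

def joint_probability(structure: DAGStructure, cpts: CPTSet, assignment) -> float:
    """Evaluate the factorized joint at one full assignment (0/1 per node)."""
    assignment = np.asarray(assignment)
    if assignment.shape != (structure.n_nodes,):
        raise ValueError(
            f"assignment must cover all {structure.n_nodes} nodes, "
            f"got shape {assignment.shape}"
        )
    p = 1.0
    for v in range(structure.n_nodes):
        p *= cpts.prob(v, assignment)
    return p


def posterior_label(structure: DAGStructure, cpts: CPTSet, evidence) -> float:
    """Exact p(y = PD | region decisions) by enumeration over the label.

    ``evidence`` gives the M region-decision values; the label node is summed
    out of the joint and normalized.
    """
    evidence = np.asarray(evidence)
    m = structure.n_nodes - 1
    if evidence.shape != (m,):
        raise ValueError(f"evidence must cover all {m} region nodes")
    assignment = np.empty(structure.n_nodes, dtype=int)
    assignment[:m] = evidence
    probs = {}
    for y in (LABEL_APS, LABEL_PD):
        assignment[m] = y
        probs[y] = joint_probability(structure, cpts, assignment)
    total = probs[LABEL_APS] + probs[LABEL_PD]
    if total <= 0.0:
        raise InferenceError("evidence has zero probability under the model")
    return probs[LABEL_PD] / total


def classify(
    structure: DAGStructure,
    cpts: CPTSet,
    decisions,
    region_accuracies=None,
    tie_tol: float = 1e-12,
) -> int:
    """Label a subject from its region decisions.

    Posterior argmax; an exact 0.5/0.5 posterior tie (within ``tie_tol``)
    falls back to the majority vote over the region decisions, and a tied
    vote falls back to the decision of the region with the highest training
    accuracy.
    """
    from .classifiers import majority_vote  # local import: avoid cycle at import time

    p_pd = posterior_label(structure, cpts, decisions)
    if abs(p_pd - 0.5) <= tie_tol:
        return majority_vote(decisions, region_accuracies)
    return LABEL_PD if p_pd > 0.5 else LABEL_APS


# ---------------------------------------------------------------------------
# BIC scoring
# ---------------------------------------------------------------------------

def family_bic(child: int, parents: tuple[int, ...], dataset: DiscreteDataset) -> float:
    """BIC contribution of one (child | parents) family.

    Maximized multinomial log-likelihood of the child given each parent
    configuration, minus (q/2) ln N where q = 2^|parents| is the number of
    free parameters (binary child: one free parameter per configuration).
    Empty cells contribute 0 via the 0 ln 0 := 0 convention.
    """
    n = dataset.n
    cols = dataset.data[:, list(parents) + [child]].astype(np.int64)
    # encode each (parent config, child value) pair as one integer
    code = np.zeros(n, dtype=np.int64)
    for c in range(cols.shape[1]):
        code = (code << 1) | cols[:, c]
    counts = np.bincount(code, minlength=2 ** cols.shape[1]).reshape(-1, 2)
    totals = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_terms = counts * (np.log(counts) - np.log(totals)[:, None])
    ll = float(np.nansum(np.where(counts > 0, ll_terms, 0.0)))
    q = 2 ** len(parents)
    return ll - 0.5 * q * math.log(n) if n > 0 else 0.0


def bic_score(structure: DAGStructure, dataset: DiscreteDataset) -> float:
    """BIC of a structure: decomposes as the sum of its family scores."""
    if dataset.n < 1:
        raise ValueError("dataset must contain at least one row")
    if dataset.n_nodes != structure.n_nodes:
        raise ValueError("dataset width does not match the structure")
    return sum(
        family_bic(v, structure.parents(v), dataset) for v in range(structure.n_nodes)
    )


# ---------------------------------------------------------------------------
# Metropolis-Hastings structure search
# ---------------------------------------------------------------------------

def _is_acyclic(adj: np.ndarray) -> bool:
    # Kahn's algorithm on the boolean adjacency matrix
    adj = adj.copy()
    indeg = adj.sum(axis=0)
    stack = list(np.flatnonzero(indeg == 0))
    seen = 0
    while stack:
        v = stack.pop()
        seen += 1
        for w in np.flatnonzero(adj[v]):
            adj[v, w] = False
            indeg[w] -= 1
            if indeg[w] == 0:
                stack.append(w)
    return seen == adj.shape[0]


def _has_path(adj: np.ndarray, src: int, dst: int) -> bool:
    """Directed reachability src -> dst by DFS."""
    if src == dst:
        return True
    stack = [src]
    seen = np.zeros(adj.shape[0], dtype=bool)
    seen[src] = True
    while stack:
        v = stack.pop()
        for w in np.flatnonzero(adj[v]):
            if w == dst:
                return True
            if not seen[w]:
                seen[w] = True
                stack.append(w)
    return False


def _valid_moves(adj: np.ndarray) -> list[tuple[str, int, int]]:
    """All single-edge moves (add / delete / reverse) preserving acyclicity."""
    n = adj.shape[0]
    moves: list[tuple[str, int, int]] = []
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            if adj[a, b]:
                moves.append(("delete", a, b))
                # reversing a->b is valid iff no other directed path a ~> b
                adj[a, b] = False
                if not _has_path(adj, a, b):
                    moves.append(("reverse", a, b))
                adj[a, b] = True
            elif not adj[b, a] and not _has_path(adj, b, a):
                moves.append(("add", a, b))
    return moves


def _apply_move(adj: np.ndarray, move: tuple[str, int, int]) -> None:
    kind, a, b = move
    if kind == "add":
        adj[a, b] = True
    elif kind == "delete":
        adj[a, b] = False
    elif kind == "reverse":
        adj[a, b] = False
        adj[b, a] = True
    else:  # pragma: no cover
        raise ValueError(f"unknown move {kind}")


def _adj_to_structure(adj: np.ndarray) -> DAGStructure:
    edges = [(int(a), int(b)) for a, b in zip(*np.nonzero(adj))]
    return DAGStructure(adj.shape[0], edges)


def mh_structure_search(
    dataset: DiscreteDataset | None,
    n_iter: int = 1000,
    burn_in: int = 200,
    seed: int = 0,
    score=None,
    n_nodes: int | None = None,
    initial: DAGStructure | None = None,
) -> tuple[DAGStructure, MHTrace]:
    """Random-walk Metropolis-Hastings over DAG space scored by BIC.

    At each iteration one move is proposed uniformly among the valid
    single-edge moves (add / delete / reverse, acyclicity-preserving) and
    accepted with probability ``min(1, exp(dscore) * |N(G)| / |N(G')|)``,
    where |N(.)| counts the valid moves from a state — the Hastings correction
    for the state-dependent proposal.  Returns the highest-scoring structure
    visited from ``burn_in`` onwards (the initial structure if no iteration
    reaches the burn-in) together with the full trace.

    Parameters
    ----------
    dataset
        Training rows; may be None when a custom ``score`` is supplied.
    score
        Optional callable ``score(structure) -> float`` replacing the BIC
        (used e.g. to check sampler correctness under a flat score).  With the
        default BIC score, per-family scores are cached across iterations.
    n_nodes
        Required when ``dataset`` is None.
    initial
        Starting structure; defaults to the empty graph.
    """
    if dataset is not None:
        n_nodes = dataset.n_nodes
    if n_nodes is None:
        raise ValueError("n_nodes is required when no dataset is given")

    family_cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def structure_score(adj: np.ndarray) -> float:
        if score is not None:
            return float(score(_adj_to_structure(adj)))
        total = 0.0
        for v in range(n_nodes):
            pa = tuple(int(p) for p in np.flatnonzero(adj[:, v]))
            key = (v, pa)
            if key not in family_cache:
                family_cache[key] = family_bic(v, pa, dataset)
            total += family_cache[key]
        return total

    rng = np.random.default_rng(seed)
    adj = (initial.adjacency() if initial is not None else
           np.zeros((n_nodes, n_nodes), dtype=bool))
    current_score = structure_score(adj)
    best_adj, best_score = adj.copy(), current_score
    best_seen = False
    trace = MHTrace()

    for it in range(n_iter):
        moves = _valid_moves(adj)
        if not moves:  # single-node graph: nothing to propose
            break
        move = moves[rng.integers(len(moves))]
        proposal = adj.copy()
        _apply_move(proposal, move)
        proposal_score = structure_score(proposal)
        n_back = len(_valid_moves(proposal))
        log_alpha = (proposal_score - current_score) + math.log(len(moves) / n_back)
        accepted = math.log(rng.random()) < min(0.0, log_alpha)
        if accepted:
            adj = proposal
            current_score = proposal_score
        trace.moves.append(move)
        trace.accepted.append(bool(accepted))
        trace.scores.append(current_score)
        if it >= burn_in and (not best_seen or current_score > best_score):
            best_adj, best_score = adj.copy(), current_score
            best_seen = True

    if not best_seen:  # chain never reached the burn-in: return its final state
        best_adj = adj
    return _adj_to_structure(best_adj), trace


# ---------------------------------------------------------------------------
# MAP parameter fitting
# ---------------------------------------------------------------------------

def fit_cpts_map(
    structure: DAGStructure, dataset: DiscreteDataset, alpha: float = 1.0
) -> CPTSet:
    """Dirichlet-MAP CPT estimates: theta = (N_state + alpha) / (N_config + 2 alpha).

    ``alpha = 1`` is the Laplace default; ``alpha = 0`` gives the MLE, with a
    uniform fallback (logged) for parent configurations never observed.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    parents: dict[int, tuple[int, ...]] = {}
    tables: dict[int, np.ndarray] = {}
    for v in range(structure.n_nodes):
        pa = structure.parents(v)
        parents[v] = pa
        cols = dataset.data[:, list(pa) + [v]].astype(np.int64)
        code = np.zeros(dataset.n, dtype=np.int64)
        for c in range(cols.shape[1]):
            code = (code << 1) | cols[:, c]
        counts = (
            np.bincount(code, minlength=2 ** cols.shape[1])
            .reshape((2,) * len(pa) + (2,))
            .astype(float)
        )
        totals = counts.sum(axis=-1, keepdims=True)
        if alpha == 0 and np.any(totals == 0):
            logger.warning(
                "node %d: unseen parent configuration with alpha=0; uniform fallback", v
            )
            counts = np.where(totals == 0, 0.5, counts)
            totals = counts.sum(axis=-1, keepdims=True)
        tables[v] = (counts + alpha) / (totals + 2 * alpha)
    return CPTSet(parents=parents, tables=tables)


# ---------------------------------------------------------------------------
# convenience constructors and small-graph utilities
# ---------------------------------------------------------------------------

def naive_structure(m_regions: int) -> DAGStructure:
    """The naive-fusion DAG: label -> every region-decision node."""
    label = m_regions
    return DAGStructure(m_regions + 1, [(label, x) for x in range(m_regions)])


def naive_cpts_from_accuracies(
    accuracies, prevalence: float = 39 / 87
) -> tuple[DAGStructure, CPTSet]:
    """Naive network parameterized directly by per-region accuracies.

    Under conditional independence, a region whose decision agrees with the
    label with probability a_m has CPT p(x_m = y | y) = a_m; the label's
    marginal is its prevalence.  This is the accuracy-parameterized fusion
    mode: it needs no decision table, only the M scalar accuracies.
    """
    acc = np.asarray(accuracies, dtype=float)
    structure = naive_structure(acc.size)
    parents: dict[int, tuple[int, ...]] = {}
    tables: dict[int, np.ndarray] = {}
    label = acc.size
    parents[label] = ()
    tables[label] = np.array([1.0 - prevalence, prevalence])
    for m, a in enumerate(acc):
        parents[m] = (label,)
        # rows indexed by y: p(x_m | y=0) = [a, 1-a], p(x_m | y=1) = [1-a, a]
        tables[m] = np.array([[a, 1.0 - a], [1.0 - a, a]])
    return structure, CPTSet(parents=parents, tables=tables)


def enumerate_dags(n_nodes: int):
    """Yield every labeled DAG on ``n_nodes`` nodes (use only for n <= 5).

    Iterates over orientation/absence choices per node pair and filters by
    acyclicity; there are 25 DAGs on 3 nodes and 543 on 4.
    """
    pairs = list(combinations(range(n_nodes), 2))
    for choice in product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (a, b), c in zip(pairs, choice):
            if c == 1:
                edges.append((a, b))
            elif c == 2:
                edges.append((b, a))
        adj = np.zeros((n_nodes, n_nodes), dtype=bool)
        for a, b in edges:
            adj[a, b] = True
        if _is_acyclic(adj):
            yield DAGStructure(n_nodes, edges)


def markov_equivalent(g1: DAGStructure, g2: DAGStructure) -> bool:
    """True iff the DAGs share skeleton and v-structures (same equivalence class)."""
    if g1.n_nodes != g2.n_nodes:
        return False

    def skeleton(g: DAGStructure):
        return {frozenset(e) for e in g.edges}

    def v_structures(g: DAGStructure):
        vs = set()
        skel = skeleton(g)
        for v in range(g.n_nodes):
            for a, b in combinations(g.parents(v), 2):
                if frozenset((a, b)) not in skel:
                    vs.add((a, v, b))
        return vs

    return skeleton(g1) == skeleton(g2) and v_structures(g1) == v_structures(g2)


def save_model(structure: DAGStructure, cpts: CPTSet, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "structure": json.loads(structure.to_json()),
                "cpts": json.loads(cpts.to_json()),
            },
            indent=2,
        )
    )


def load_model(path: str | Path) -> tuple[DAGStructure, CPTSet]:
    obj = json.loads(Path(path).read_text())
    return (
        DAGStructure.from_json(json.dumps(obj["structure"])),
        CPTSet.from_json(json.dumps(obj["cpts"])),
    )
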