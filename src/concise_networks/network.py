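"""Assembly of state networks and edge sparsification.

A state network is a directed weighted network over *state nodes*,
each belonging to a physical node.  State node ``alpha`` of physical
node ``i`` links to state node ``beta`` of successor ``j`` with weight

    P(alpha_i -> beta_j) = P(alpha_i -> j) * P(i -> beta_j)
                         = Xout_i[j, alpha] * Xin_j[i, beta]

so each state's out-weights sum to 1.  Setting every rank to 1 yields
the first-order network; one state per observed predecessor with
``Xout = X`` and ``Xin = I`` yields the full second-order network; the
concise network sits between the two.

Sparsification is two-stage: a threshold trim of low-importance
state-node neighborhood entries, then the disparity filter, which
keeps edges whose weight is improbably large under a uniform-split
null for their node's strength, with removed edges re-added by weight
until the network is weakly connected again.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .corpus import TrigramCounts
from .dynamics import posterior_dynamics
from .nmf import StateSplit, split_node

logger = logging.getLogger(__name__)

__all__ = [
    "StateNetwork",
    "BackboneReport",
    "assemble_network",
    "build_first_order",
    "build_second_order",
    "trim_state_edges",
    "disparity_backbone",
    "jaccard_similarity",
    "export_infomap_states",
    "read_infomap_states",
]


@dataclass
class StateNetwork:
    """Directed weighted network over state nodes.

    ``states`` holds ``(state_id, physical_label, state_index)``
    triples; ``edges`` holds ``(source_id, target_id, weight)``.
    """

    states: list[tuple[int, str, int]]
    edges: list[tuple[int, int, float]]
    physical_map: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.physical_map:
            pm: dict[str, list[int]] = {}
            for sid, phys, _ in self.states:
                pm.setdefault(phys, []).append(sid)
            self.physical_map = pm
        for _, _, w in self.edges:
            if w <= 0:
                raise ValueError("edge weights must be positive")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def out_weights(self) -> dict[int, float]:
        out: dict[int, float] = {sid: 0.0 for sid, _, _ in self.states}
        for s, _, w in self.edges:
            out[s] += w
        return out

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for sid, phys, alpha in self.states:
            g.add_node(sid, physical=phys, alpha=alpha)
        for s, t, w in self.edges:
            g.add_edge(s, t, weight=w)
        return g


@dataclass
class BackboneReport:
    edges_before: int
    edges_after: int
    readded_for_connectivity: int
    threshold: float


def assemble_network(
    splits: Mapping[str, StateSplit],
    extra_nodes: set[str] | None = None,
) -> StateNetwork:
    """Link state nodes across splits into a state network.

    Every split center contributes its state nodes; successors that
    were never a center (and any ``extra_nodes``, e.g. trajectory
    endpoints) receive a single pass-through state.  An edge from
    state ``alpha`` of ``i`` into the states of a split successor
    ``j`` requires ``i`` to be an observed predecessor of ``j``; when
    it is not (the trigram ``i -> j -> .`` was never observed) the
    corresponding flow has no destination state and is dropped with a
    log message.
    """
    centers = sorted(splits)
    passthrough = set(extra_nodes or ())
    for center in centers:
        split = splits[center]
        if split.successors is None:
            raise ValueError(f"split of {center!r} is missing successor labels")
        passthrough.update(split.successors)
        if split.predecessors is not None:
            passthrough.update(split.predecessors)
    passthrough -= set(centers)

    states: list[tuple[int, str, int]] = []
    state_id: dict[tuple[str, int], int] = {}
    for center in centers:
        for alpha in range(splits[center].rank):
            state_id[(center, alpha)] = len(states)
            states.append((len(states), center, alpha))
    for label in sorted(passthrough):
        state_id[(label, 0)] = len(states)
        states.append((len(states), label, 0))

    edges: dict[tuple[int, int], float] = {}
    dropped_mass = 0.0
    for center in centers:
        split = splits[center]
        assert split.successors is not None
        for alpha in range(split.rank):
            src = state_id[(center, alpha)]
            for k_idx, j in enumerate(split.successors):
                w_out = float(split.Xout[k_idx, alpha])
                if w_out <= 0:
                    continue
                if j in splits:
                    tgt_split = splits[j]
                    assert tgt_split.predecessors is not None
                    try:
                        i_idx = tgt_split.predecessors.index(center)
                    except ValueError:
                        logger.info(
                            "no observed trigram %s -> %s -> .; dropping flow %.3g",
                            center, j, w_out,
                        )
                        dropped_mass += w_out
                        continue
                    for beta in range(tgt_split.rank):
                        w = w_out * float(tgt_split.Xin[i_idx, beta])
                        if w > 0:
                            key = (src, state_id[(j, beta)])
                            edges[key] = edges.get(key, 0.0) + w
                else:
                    key = (src, state_id[(j, 0)])
                    edges[key] = edges.get(key, 0.0) + w_out
    if dropped_mass > 0:
        logger.info("total out-flow dropped for unobserved predecessors: %.4g", dropped_mass)
    edge_list = [(s, t, w) for (s, t), w in sorted(edges.items())]
    return StateNetwork(states=states, edges=edge_list)


def _rank1_splits(
    counts: Mapping[str, TrigramCounts], mu_policy: float | str
) -> dict[str, StateSplit]:
    return {
        center: split_node(posterior_dynamics(tc, mu_policy), r=1)
        for center, tc in counts.items()
    }


def build_first_order(
    counts: Mapping[str, TrigramCounts],
    mu_policy: float | str = 0.0,
    extra_nodes: set[str] | None = None,
) -> StateNetwork:
    """First-order network: the analytic rank-1 split of every center.

    At ``mu = 0`` (default) each node's out-distribution is the
    first-order MLE ``M1``.
    """
    return assemble_network(_rank1_splits(counts, mu_policy), extra_nodes=extra_nodes)


def build_second_order(
    counts: Mapping[str, TrigramCounts],
    mu_policy: float | str = "auto",
    extra_nodes: set[str] | None = None,
) -> StateNetwork:
    """Full second-order network: one state per observed predecessor.

    Each center uses ``Xout = X`` and ``Xin = I``, so its implied
    dynamics reproduce the target dynamics exactly (flow overlap 1).
    """
    splits: dict[str, StateSplit] = {}
    for center, tc in counts.items():
        dyn = posterior_dynamics(tc, mu_policy)
        r = dyn.X.shape[1]
        splits[center] = StateSplit(
            center=center,
            rank=r,
            Xin=np.eye(r),
            Xout=dyn.X.copy(),
            overlap=1.0,
            loss=0.0,
            predecessors=dyn.predecessors,
            successors=dyn.successors,
        )
    return assemble_network(splits, extra_nodes=extra_nodes)


def trim_state_edges(
    splits: Mapping[str, StateSplit],
    sigma: float,
    extra_nodes: set[str] | None = None,
) -> StateNetwork:
    """Trim low-importance state-node neighborhood entries and reassemble.

    For a rank-``r`` split, the in-edge ``i -> alpha`` is kept iff
    ``Xin[i, alpha] >= sigma / r`` and the out-edge ``alpha -> k`` iff
    ``Xout[k, alpha] / sum_beta Xout[k, beta] >= sigma / r``; smaller
    ``sigma`` retains more edges.  Surviving in-splits and
    out-distributions are renormalized so downstream random walks see
    stochastic matrices; a state losing every out-entry keeps a unit
    self-loop in the assembled network.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    trimmed: dict[str, StateSplit] = {}
    for center, split in splits.items():
        thr = sigma / split.rank
        Xin = np.where(split.Xin >= thr, split.Xin, 0.0)
        rowsums = Xin.sum(axis=1)
        dead_rows = rowsums <= 0
        if np.any(dead_rows):
            # keep each predecessor's single strongest state if all fall below
            best = np.argmax(split.Xin[dead_rows], axis=1)
            Xin[np.flatnonzero(dead_rows), best] = 1.0
            rowsums = Xin.sum(axis=1)
        Xin = Xin / rowsums[:, None]

        succ_share = split.Xout / split.Xout.sum(axis=1, keepdims=True).clip(min=1e-300)
        Xout = np.where(succ_share >= thr, split.Xout, 0.0)
        colsums = Xout.sum(axis=0)
        removed = 1.0 - colsums
        if np.any(removed > 1e-12):
            logger.info(
                "center %s: trimmed out-mass per state %s",
                center, np.round(removed.clip(min=0.0), 4).tolist(),
            )
        dead_cols = colsums <= 0
        colsums[dead_cols] = 1.0  # dangling states handled at assembly
        Xout = Xout / colsums
        trimmed[center] = replace(split, Xin=Xin, Xout=Xout)
    net = assemble_network(trimmed, extra_nodes=extra_nodes)
    out = net.out_weights()
    dangling = [
        (sid, sid, 1.0)
        for sid, phys, _ in net.states
        if out[sid] <= 0 and phys in trimmed
    ]
    if dangling:
        net = StateNetwork(states=net.states, edges=net.edges + dangling)
    return net


def disparity_backbone(
    net: StateNetwork, alpha_threshold: float
) -> tuple[StateNetwork, BackboneReport]:
    """Disparity-filter backbone with weak-connectivity repair.

    An edge with normalized weight ``p`` in a degree-``k`` star has
    significance score ``(1 - p)^(k - 1)``; it is kept when the score
    falls below ``alpha_threshold`` in either its source's out-star or
    its target's in-star.  Stars of degree 1 keep their edge.  Removed
    edges are re-added in decreasing weight order until the network is
    as weakly connected as before filtering.
    """
    if not 0 < alpha_threshold < 1:
        raise ValueError("alpha_threshold must be in (0, 1)")
    out_star: dict[int, list[tuple[int, float]]] = {}
    in_star: dict[int, list[tuple[int, float]]] = {}
    for idx, (s, t, w) in enumerate(net.edges):
        out_star.setdefault(s, []).append((idx, w))
        in_star.setdefault(t, []).append((idx, w))

    keep = np.zeros(len(net.edges), dtype=bool)
    for star in list(out_star.values()) + list(in_star.values()):
        if len(star) == 1:
            keep[star[0][0]] = True
            continue
        weights = np.array([w for _, w in star])
        p = weights / weights.sum()
        scores = (1.0 - p) ** (len(star) - 1)
        for (idx, _), score in zip(star, scores):
            if score < alpha_threshold:
                keep[idx] = True

    kept = [e for e, k in zip(net.edges, keep) if k]
    removed = sorted(
        (e for e, k in zip(net.edges, keep) if not k), key=lambda e: -e[2]
    )

    def n_components(edges: list[tuple[int, int, float]]) -> int:
        g = nx.Graph()
        g.add_nodes_from(sid for sid, _, _ in net.states)
        g.add_edges_from((s, t) for s, t, _ in edges)
        return nx.number_connected_components(g)

    target_components = n_components(net.edges)
    readded = 0
    for edge in removed:
        if n_components(kept) <= target_components:
            break
        kept.append(edge)
        readded += 1
    if readded:
        kept.sort(key=lambda e: (e[0], e[1]))
    report = BackboneReport(
        edges_before=len(net.edges),
        edges_after=len(kept),
        readded_for_connectivity=readded,
        threshold=alpha_threshold,
    )
    return StateNetwork(states=list(net.states), edges=kept), report


def jaccard_similarity(set_a: set, set_b: set) -> float:
    """|A ∩ B| / |A ∪ B|, defined as 0 when both sets are empty."""
    union = set_a | set_b
    if not union:
        return 0.0
    return len(set_a & set_b) / len(union)


def export_infomap_states(net: StateNetwork, file: str | Path) -> None:
    """Write the Infomap state-network format (1-based, stable ids)."""
    physical = sorted(net.physical_map)
    phys_id = {label: i + 1 for i, label in enumerate(physical)}
    lines = ["*Vertices"]
    for label in physical:
        lines.append(f'{phys_id[label]} "{label}"')
    lines.append("*States")
    for sid, phys, alpha in net.states:
        lines.append(f'{sid + 1} {phys_id[phys]} "{phys}_{alpha}"')
    lines.append("*Links")
    for s, t, w in net.edges:
        lines.append(f"{s + 1} {t + 1} {w:.12g}")
    Path(file).write_text("\n".join(lines) + "\n")


def read_infomap_states(file: str | Path) -> StateNetwork:
    """Parse a state network written by :func:`export_infomap_states`."""
    section = None
    phys_label: dict[int, str] = {}
    states: list[tuple[int, str, int]] = []
    edges: list[tuple[int, int, float]] = []
    per_phys_count: dict[int, int] = {}
    for raw in Path(file).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("*"):
            section = line.lower()
            continue
        parts = line.split(maxsplit=2)
        if section == "*vertices":
            phys_label[int(parts[0])] = parts[1].strip('"')
        elif section == "*states":
            pid = int(parts[1])
            alpha = per_phys_count.get(pid, 0)
            per_phys_count[pid] = alpha + 1
            states.append((int(parts[0]) - 1, phys_label[pid], alpha))
        elif section == "*links":
            edges.append((int(parts[0]) - 1, int(parts[1]) - 1, float(parts[2])))
    return StateNetwork(states=states, edges=edges)
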