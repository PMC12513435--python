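#!/usr/bin/env python
"""Opt-in reproduction of the real-data analyses (requires downloads).

Not part of the default test suite: both analyses depend on external
datasets that must be fetched and pre-converted by the user.

Law-firm information flow
    Input: two 71x71 binary sociomatrices (whitespace-separated .dat,
    one row per person) for the co-work and friendship relations.
    Nonreciprocated ties are discarded (the undirected edge requires
    both directions).  Reports: undirected edge counts of the co-work
    and friendship networks and their shared edges; the number of
    state nodes of the full second-order network built from the
    two-layer relay trigrams; the size of the concise network at flow
    overlap threshold 0.9.

        python scripts/external_repro.py lazega --work ELwork.dat \\
            --friend ELfriend.dat --seed 1

Airport transit flow
    Input: a path file with one domestic itinerary per line
    (whitespace-separated airport codes), pre-extracted from the
    Bureau of Transportation Statistics DB1B coupon sample.
    Reports: total non-return transits, the 10 largest hubs, the
    rank-1 and rank-2 flow overlap for Denver, the concise state-node
    count at threshold 0.7, and the number of state nodes a full
    second-order model of the top-10 hubs would need.

        python scripts/external_repro.py airports --paths itineraries.txt \\
            --seed 1
"""

from __future__ import annotations

import argparse
import json

import numpy as np

from concise_networks import (
    PathCorpus,
    extract_trigram_counts,
    generate_layered_trigrams,
    load_path_corpus,
    posterior_dynamics,
    select_rank,
    split_node,
    top_transit_nodes,
)


def _reciprocated_edges(matrix: np.ndarray) -> set[tuple[int, int]]:
    sym = (matrix > 0) & (matrix.T > 0)
    return {(i, j) for i, j in zip(*np.nonzero(sym)) if i < j}


def run_lazega(work_file: str, friend_file: str, seed: int) -> dict:
    work = np.loadtxt(work_file)
    friend = np.loadtxt(friend_file)
    e_work = _reciprocated_edges(work)
    e_friend = _reciprocated_edges(friend)
    shared = e_work & e_friend
    lbl = lambda e: (f"P{e[0]:02d}", f"P{e[1]:02d}")
    counts = generate_layered_trigrams(
        layer1=[lbl(e) for e in sorted(e_friend)],
        layer2=[lbl(e) for e in sorted(e_work)],
        n_per_pred=1000,
        seed=seed,
    )
    so_states = sum(len(tc.predecessors) for tc in counts.values())
    rng = np.random.default_rng(seed)
    concise_states = 0
    split_nodes = 0
    for center in sorted(counts):
        dyn = posterior_dynamics(counts[center], "auto")
        r_cap = min(12, dyn.X.shape[1])
        split = select_rank(dyn, 0.9, r_cap, n_restarts=10, seed=int(rng.integers(2**31)))
        concise_states += split.rank
        split_nodes += split.rank > 1
    return {
        "work_edges": len(e_work),
        "friendship_edges": len(e_friend),
        "shared_edges": len(shared),
        "second_order_state_nodes": so_states,
        "concise_state_nodes": concise_states,
        "nodes_with_multiple_states": split_nodes,
    }


def run_airports(paths_file: str, seed: int, denver: str = "DEN") -> dict:
    corpus = load_path_corpus(paths_file)
    counts = extract_trigram_counts(corpus, exclude_returns=True)
    total_transits = sum(tc.total for tc in counts.values())
    hubs = top_transit_nodes(counts, 10)
    so_states_top10 = sum(len(counts[h].predecessors) for h in hubs)
    rng = np.random.default_rng(seed)
    out: dict = {
        "total_transits": total_transits,
        "top10_hubs": hubs,
        "second_order_states_top10": so_states_top10,
    }
    if denver in counts:
        dyn = posterior_dynamics(counts[denver], "auto")
        r1 = split_node(dyn, 1)
        r2 = split_node(dyn, 2, n_restarts=10, seed=int(rng.integers(2**31)))
        out["denver_overlap_r1"] = r1.overlap
        out["denver_overlap_r2"] = r2.overlap
    concise_states = 0
    for hub in hubs:
        dyn = posterior_dynamics(counts[hub], "auto")
        split = select_rank(
            dyn, 0.7, min(12, dyn.X.shape[1]), n_restarts=10,
            seed=int(rng.integers(2**31)),
        )
        concise_states += split.rank
    out["concise_states_top10"] = concise_states
    return out


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    sub = parser.add_subparsers(dest="command", required=True)
    p1 = sub.add_parser("lazega")
    p1.add_argument("--work", required=True)
    p1.add_argument("--friend", required=True)
    p1.add_argument("--seed", type=int, default=1)
    p2 = sub.add_parser("airports")
    p2.add_argument("--paths", required=True)
    p2.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    if args.command == "lazega":
        result = run_lazega(args.work, args.friend, args.seed)
    else:
        result = run_airports(args.paths, args.seed)
    print(json.dumps(result, indent=2, default=str))


if __name__ == "__main__":
    main()
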