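"""Independent brute-force oracles shared by the test modules.

These deliberately re-derive results by exhaustive enumeration, without
touching the implementation paths they are used to check.
"""

import itertools

import networkx as nx


def brute_force_partitions(lines, tolerance):
    """Every partition of `lines` into internally consistent triplets.

    A triplet (sorted descending: hi, mid, lo) is consistent when
    |lo − (hi − mid)| ≤ tolerance, mid > 0, and hi ≤ 2·mid (η ≤ 1).
    Returns a set of partitions, each a frozenset of frozensets of line
    values (rounded for hashability).
    """

    def consistent(triple):
        hi, mid, lo = sorted(triple, reverse=True)
        return abs(lo - (hi - mid)) <= tolerance and hi <= 2 * mid and mid > 0

    def partitions(indices):
        if not indices:
            yield []
            return
        first = indices[0]
        rest = indices[1:]
        for i, j in itertools.combinations(range(len(rest)), 2):
            combo = (first, rest[i], rest[j])
            remaining = [r for k, r in enumerate(rest) if k not in (i, j)]
            for tail in partitions(remaining):
                yield [combo] + tail

    found = set()
    for part in partitions(list(range(len(lines)))):
        if all(consistent([lines[i] for i in combo]) for combo in part):
            found.add(
                frozenset(
                    frozenset(round(lines[i], 9) for i in combo) for combo in part
                )
            )
    return found


def brute_force_mces(g_a, g_b):
    """Maximum connected common edge subgraph size by full enumeration.

    Enumerates every connected edge subset of the smaller graph and tests
    a label-preserving monomorphic embedding into the other (atoms on
    element + aromaticity, bonds on order).
    """
    ga, gb = g_a.to_networkx(), g_b.to_networkx()
    if ga.number_of_edges() > gb.number_of_edges():
        ga, gb = gb, ga
    node_match = lambda x, y: (x["element"], x["aromatic"]) == (
        y["element"], y["aromatic"])
    edge_match = lambda x, y: x["order"] == y["order"]
    edges = list(ga.edges)
    best = 0
    for k in range(len(edges), 0, -1):
        if k <= best:
            break
        for subset in itertools.combinations(edges, k):
            h = ga.edge_subgraph(subset)
            if not nx.is_connected(h):
                continue
            gm = nx.isomorphism.GraphMatcher(
                gb, h, node_match=node_match, edge_match=edge_match
            )
            if gm.subgraph_is_monomorphic():
                best = k
                break
    return best
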