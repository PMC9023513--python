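"""Information-theoretic connectedness scoring of node sets (CTD).

Given a weighted metabolite co-perturbation network and a set S of perturbed
nodes, we ask: is S unusually *connected* in the network?  The answer is
phrased in coding terms.  A fixed-length enumerative code names any size-k
subset of an n-node network in log2(C(n, k)) bits.  A network-adaptive code
can do better when S is clustered: name one start node (log2(n) bits), then
walk the network by probability diffusion, re-anchoring on every member of
S found, and transmit one found/not-found bit per ranked node until the
last member is reached.  The transcript is self-terminating and replayable,
so the adaptive code is prefix-free and uniquely decodable; by Kraft's
inequality at most C(n, k) * 2**(-b) subsets of size k can save b or more
bits over the fixed code.  Hence

    p <= 2**(-bits_saved)

is an honest connectedness p-value with no permutation testing: highly
connected sets save many bits, scattered sets save none.

Everything here is deterministic: diffusion is a finite recursive mass
split, and all ties break lexicographically by node id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "WalkRanking",
    "CtdResult",
    "fixed_code_bits",
    "diffuse",
    "adaptive_walk",
    "information_content",
    "ctd_pvalue",
]

#: Fraction of incoming mass a non-terminal node keeps for its own score;
#: the remainder is passed on to unvisited neighbours.  Keeping half makes
#: scores decay smoothly with network distance from the anchors.
RETENTION = 0.5


@dataclass(frozen=True)
class WalkRanking:
    """One adaptive walk: the node ranking and where members of S were found.

    ``found_positions`` are 1-based positions *after* the start node, i.e.
    the j-th ranked node after the start has position j.
    """

    start_node: str
    ranking: tuple[str, ...]
    found_positions: tuple[int, ...]


@dataclass(frozen=True)
class CtdResult:
    """Outcome of scoring one node set against one network."""

    input_set: frozenset[str]
    optimal_subset: frozenset[str]
    encoding_bits: float          # adaptive-code length of optimal_subset
    fixed_bits: float             # log2(C(n, |optimal_subset|))
    bits_saved: float
    p_value: float
    full_set_bits: float          # adaptive-code length of the whole input set
    full_set_p: float
    best_walk: WalkRanking = field(compare=False)


def fixed_code_bits(n_nodes: int, k: int) -> float:
    """Fixed-length enumerative code for a size-k subset of n nodes (bits)."""
    return math.log2(math.comb(n_nodes, k))


def _check_anchors(network, anchors, visited) -> None:
    for a in anchors:
        if not network.has_node(a):
            raise ValueError(f"anchor {a!r} not in network")
    if not set(anchors) <= set(visited):
        raise ValueError("anchors must be contained in visited")


def diffuse(network, anchors, visited, threshold: float = 1e-4):
    """Spread unit mass from each anchor over unvisited nodes.

    Each anchor's unit mass flows to its unvisited neighbours in proportion
    to absolute edge weight (co-perturbation strength matters, its sign does
    not).  A node that receives mass keeps a ``RETENTION`` share and passes
    the rest along to neighbours not yet holding mass on this propagation;
    mass below *threshold*, or mass arriving at a dead end, is retained
    outright.  Returns ``{node: score}`` over exactly the unvisited nodes
    reached; the total returned never exceeds ``len(anchors)``.
    """
    _check_anchors(network, anchors, visited)
    visited = set(visited)
    scores: dict[str, float] = {}

    def spread(node: str, mass: float, blocked: frozenset[str]) -> None:
        targets = [
            (nbr, abs(w)) for nbr, w in network.neighbors_weighted(node)
            if nbr not in visited and nbr not in blocked and abs(w) > 0.0
        ]
        total = sum(w for _, w in targets)
        if not targets or total == 0.0:
            # dead end: the current holder keeps everything
            if node not in visited:
                scores[node] = scores.get(node, 0.0) + mass
            return
        for nbr, w in sorted(targets):
            share = mass * w / total
            if share < threshold:
                scores[nbr] = scores.get(nbr, 0.0) + share
                continue
            keep = share * RETENTION
            scores[nbr] = scores.get(nbr, 0.0) + keep
            spread(nbr, share - keep, blocked | {nbr})

    for a in sorted(anchors):
        spread(a, 1.0, frozenset({a}))
    return scores


def adaptive_walk(network, s, start: str) -> WalkRanking:
    """Rank network nodes from *start*, re-anchoring on every member of S found.

    At each step the next node is the unvisited node with the highest
    diffusion score from the members of S found so far (ties by node id).
    Members of S join the anchor set the moment they are ranked, which steers
    the walk into the region of the network S occupies.  The walk stops once
    every reachable member of S is ranked, or when diffusion finds no more
    mass to spread (members beyond that point are unreachable and are charged
    a fixed-length pointer by :func:`information_content`).
    """
    s = frozenset(s)
    if start not in s:
        raise ValueError(f"start node {start!r} not in the encoded set")
    if not network.has_node(start):
        raise ValueError(f"start node {start!r} not in network")
    members = s & frozenset(network.nodes())
    ranking = [start]
    anchors = {start}
    visited = {start}
    found_positions: list[int] = []
    position = 0
    while members - anchors:
        scores = diffuse(network, anchors, visited)
        scores = {v: m for v, m in scores.items() if m > 0.0}
        if not scores:
            break  # disconnected remainder: stop, rest is unreachable
        best = min(scores, key=lambda v: (-scores[v], v))
        ranking.append(best)
        visited.add(best)
        position += 1
        if best in members:
            anchors.add(best)
            found_positions.append(position)
    return WalkRanking(start_node=start, ranking=tuple(ranking),
                       found_positions=tuple(found_positions))


def _walk_code_length(network, walk: WalkRanking, s: frozenset[str]) -> float:
    """Adaptive-code length (bits) of the set S given one walk.

    log2(n) names the start node; the last found position upper-bounds the
    walk transcript needed to recover every found member; each member the
    walk never reached is named by its own fixed-length log2(n) pointer.
    """
    n = network.n_nodes()
    log2n = math.log2(n)
    found = {walk.ranking[p] for p in walk.found_positions}
    unreachable = s - found - {walk.start_node}
    last = max(walk.found_positions) if walk.found_positions else 0
    return log2n + last + len(unreachable) * log2n


def information_content(network, s):
    """Minimal adaptive-code length of S over all start choices.

    Returns ``(bits, best_walk)``.  For a singleton this is exactly
    ``log2(n)``; for a k-clique whose members are found consecutively it is
    ``log2(n) + (k - 1)``.
    """
    s = frozenset(s)
    if not s:
        raise ValueError("cannot encode an empty set")
    missing = s - frozenset(network.nodes())
    if missing:
        raise ValueError(f"set members not in network: {sorted(missing)}")
    best_bits = math.inf
    best_walk = None
    for start in sorted(s):
        walk = adaptive_walk(network, s, start)
        bits = _walk_code_length(network, walk, s)
        if bits < best_bits:  # first (lexicographic) start wins ties
            best_bits = bits
            best_walk = walk
    return best_bits, best_walk


def ctd_pvalue(network, s) -> CtdResult:
    """Connectedness p-value of S and its optimal highly connected subset.

    Every walk prefix ending at a found member F_j (the first j members
    found, j >= 1 counting the start) is itself an encodable subset costing
    ``log2(n) + position(j-th found)`` bits against ``log2(C(n, j))`` fixed
    bits.  The subset maximising the bits saved is reported with
    ``p = 2**(-bits_saved)``; ties prefer larger subsets, then the
    lexicographically smaller one.  The full input set's encoding and p-value
    are reported alongside.
    """
    s = frozenset(s)
    members = s & frozenset(network.nodes())
    if not members:
        raise ValueError("no scoreable nodes: set does not intersect network")
    n = network.n_nodes()
    log2n = math.log2(n)

    best = None  # (bits_saved, j, subset, encoding_bits, walk)
    full_bits = math.inf
    full_walk = None
    for start in sorted(members):
        walk = adaptive_walk(network, members, start)
        fb = _walk_code_length(network, walk, members)
        if fb < full_bits:
            full_bits = fb
            full_walk = walk
        # prefix subsets: start alone (j=1), then start + first i found members
        prefixes = [(1, 0.0, frozenset({start}))]
        acc = {start}
        for pos in walk.found_positions:
            acc = acc | {walk.ranking[pos]}
            prefixes.append((len(acc), float(pos), frozenset(acc)))
        for j, last_pos, subset in prefixes:
            enc = log2n + last_pos
            saved = fixed_code_bits(n, j) - enc
            key = (saved, j, tuple(sorted(subset)))
            if best is None or (saved, j) > (best[0], best[1]) or (
                (saved, j) == (best[0], best[1]) and key[2] < tuple(sorted(best[2]))
            ):
                best = (saved, j, subset, enc, walk)
    saved, j, subset, enc, walk = best
    return CtdResult(
        input_set=members,
        optimal_subset=subset,
        encoding_bits=enc,
        fixed_bits=fixed_code_bits(n, j),
        bits_saved=saved,
        p_value=min(1.0, 2.0 ** (-saved)),
        full_set_bits=full_bits,
        full_set_p=min(
            1.0,
            2.0 ** (-(fixed_code_bits(n, len(members)) - full_bits))),
        best_walk=walk,
    )
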