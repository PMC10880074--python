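"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's vectorised code paths: scoring is
a plain Python loop over matrix entries, placement enumeration is a
nested loop over all offsets, clustering is a breadth-first transitive
closure over a pairwise adjacency relation, and the Pareto front is an
O(n^2) dominance check.
"""

from __future__ import annotations

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def score_box(logprob, seq: str, start: int) -> float:
    return sum(
        logprob[BASE_INDEX[seq[start + j]], j] for j in range(logprob.shape[1])
    )


def brute_placements(seq: str, pair, anchor: int | None = None) -> list[dict]:
    """Every geometry-valid placement, scored by direct summation."""
    l35, l10 = pair.pssm35.length, pair.pssm10.length
    n = len(seq)
    out = []
    for p35 in range(0, n - l35 + 1):
        for sp in range(pair.spacer_min, pair.spacer_max + 1):
            p10 = p35 + l35 + sp
            if p10 + l10 > n:
                continue
            if anchor is not None:
                d = anchor - p10 - l10
                if not (pair.tss_dist_min <= d <= pair.tss_dist_max):
                    continue
            else:
                d = None
            out.append(
                {
                    "p35": p35,
                    "p10": p10,
                    "spacer": sp,
                    "d": d,
                    "s35": score_box(pair.pssm35.logprob, seq, p35),
                    "s10": score_box(pair.pssm10.logprob, seq, p10),
                }
            )
    return out


def brute_best(seq: str, pair, anchor: int | None = None) -> dict | None:
    """Maximal-total placement; ties -> smaller spacer, then largest p10."""
    placements = brute_placements(seq, pair, anchor)
    if not placements:
        return None
    return min(
        placements,
        key=lambda h: (-(h["s35"] + h["s10"]), h["spacer"], -h["p10"]),
    )


def brute_cluster(positions: list[int], max_gap: int) -> list[frozenset[int]]:
    """Connected components of the |pi - pj| <= max_gap relation."""
    pos = sorted(set(positions))
    unseen = set(pos)
    clusters = []
    while unseen:
        seed = min(unseen)
        comp = {seed}
        frontier = [seed]
        unseen.discard(seed)
        while frontier:
            p = frontier.pop()
            near = [q for q in list(unseen) if abs(q - p) <= max_gap]
            for q in near:
                unseen.discard(q)
                comp.add(q)
                frontier.append(q)
        clusters.append(frozenset(comp))
    return sorted(clusters, key=min)


def dominates(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] >= b[0] and a[1] >= b[1] and (a[0] > b[0] or a[1] > b[1])


def brute_pareto(points: list[tuple[float, float]]) -> set[tuple[float, float]]:
    return {p for p in points if not any(dominates(q, p) for q in points)}
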