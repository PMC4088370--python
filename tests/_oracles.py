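"""Independent brute-force oracles, deliberately naive.

These implementations share no code path with the package: distances come
from a dense Floyd-Warshall triple loop, hypergeometric tails from exact
enumeration of draws with rational arithmetic.  They are only feasible on
tiny instances, which is the point.
"""

from fractions import Fraction
from itertools import combinations

INF = float("inf")


def floyd_warshall(nodes, edges):
    """All-pairs hop distances via the O(n^3) dynamic programme."""
    nodes = list(nodes)
    dist = {u: {v: (0 if u == v else INF) for v in nodes} for u in nodes}
    for u, v in edges:
        dist[u][v] = 1
        dist[v][u] = 1
    for k in nodes:
        for i in nodes:
            dik = dist[i][k]
            if dik is INF:
                continue
            for j in nodes:
                if dik + dist[k][j] < dist[i][j]:
                    dist[i][j] = dik + dist[k][j]
    return dist


def components_from_distances(dist):
    """Connected components implied by a finite-distance relation."""
    seen, comps = set(), []
    for u in dist:
        if u in seen:
            continue
        comp = {v for v in dist if dist[u][v] < INF}
        seen |= comp
        comps.append(comp)
    return comps


def largest_component(dist):
    return max(components_from_distances(dist), key=lambda c: (len(c), min(c)))


def oracle_eccentricities(dist, component):
    return {u: max(int(dist[u][v]) for v in component) for u in component}


def oracle_centre(dist):
    """(centres, radius) over the largest component, by exhaustive argmin."""
    ecc = oracle_eccentricities(dist, largest_component(dist))
    radius = min(ecc.values())
    return {u for u, e in ecc.items() if e == radius}, radius


def oracle_diameter(dist):
    ecc = oracle_eccentricities(dist, largest_component(dist))
    return max(ecc.values())


def hypergeometric_upper_tail(population, successes, draws, observed):
    """P(X >= observed) by enumerating every draw of ``draws`` items.

    Exact rational arithmetic over all C(population, draws) subsets; the
    first ``successes`` items of the population are the successes.
    """
    hits = 0
    total = 0
    for subset in combinations(range(population), draws):
        total += 1
        if sum(1 for item in subset if item < successes) >= observed:
            hits += 1
    return Fraction(hits, total)
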