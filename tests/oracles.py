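"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (definitions, exhaustive
enumeration) and deliberately shares no code with the package.
"""

from itertools import combinations

import numpy as np


def bh_stepup(p):
    """Benjamini–Hochberg straight from the step-up definition:
    q_i = min over j>=i (ordered) of p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end  # 1-based rank of this p-value
        running_min = min(running_min, p[idx] * m / rank)
        q[idx] = running_min
    return np.clip(q, 0, 1)


def mannwhitney_exact_two_sided(a, b):
    """Exact two-sided Mann–Whitney p by exhaustive label enumeration.

    Two-sided p = fraction of labelings whose U is at least as extreme
    (in |U - n1*n2/2|) as the observed one.  Requires no ties.
    """
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y) + 0.5 * sum(
            1 for x in group_a for y in group_b if x == y
        )

    mid = n1 * len(b) / 2.0
    obs = abs(u_stat(a, b) - mid)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(ga, gb) - mid) >= obs - 1e-12:
            count += 1
    return count / total


def classify_pair(exons1, exons2, strand):
    """Case analysis on the exon-set difference of a two-isoform gene.

    Returns a set of (event_type, signature) tuples.  Written independently
    of the pipeline classifier: it looks only at which exons are private to
    each isoform and how they relate by boundaries.
    """
    e1 = sorted(exons1)
    e2 = sorted(exons2)
    s1, s2 = set(e1), set(e2)
    only1 = sorted(s1 - s2)
    only2 = sorted(s2 - s1)
    found = set()

    def internal(ex, exons):
        i = exons.index(ex)
        return 0 < i < len(exons) - 1

    # cassette: a private internal exon whose neighbours are consecutive
    # shared exons in the other isoform
    for mine, theirs, priv in ((e1, e2, only1), (e2, e1, only2)):
        for ex in priv:
            if not internal(ex, mine):
                continue
            i = mine.index(ex)
            prev, nxt = mine[i - 1], mine[i + 1]
            if prev in theirs and nxt in theirs:
                j = theirs.index(prev)
                if j + 1 < len(theirs) and theirs[j + 1] == nxt:
                    found.add(("CE", ex))

    # mutually exclusive: one private internal exon on each side, disjoint,
    # same shared neighbours
    for x1 in only1:
        for x2 in only2:
            if not (internal(x1, e1) and internal(x2, e2)):
                continue
            i, j = e1.index(x1), e2.index(x2)
            if e1[i - 1] == e2[j - 1] and e1[i + 1] == e2[j + 1]:
                if x1[1] <= x2[0] or x2[1] <= x1[0]:
                    found.add(("MXE", tuple(sorted((x1, x2)))))

    # alternative donor/acceptor: private exons sharing exactly one boundary,
    # with the same shared exon across the variable junction
    for x1 in only1:
        for x2 in only2:
            if x1[0] == x2[0] and x1[1] != x2[1]:
                i, j = e1.index(x1), e2.index(x2)
                if i + 1 < len(e1) and j + 1 < len(e2) and e1[i + 1] == e2[j + 1]:
                    label = "A5SS" if strand == "+" else "A3SS"
                    found.add((label, (x1[0], tuple(sorted((x1[1], x2[1]))))))
            elif x1[1] == x2[1] and x1[0] != x2[0]:
                i, j = e1.index(x1), e2.index(x2)
                if i > 0 and j > 0 and e1[i - 1] == e2[j - 1]:
                    label = "A3SS" if strand == "+" else "A5SS"
                    found.add((label, (x1[1], tuple(sorted((x1[0], x2[0]))))))

    # retained intron: a private exon spanning two consecutive exons of the
    # other isoform boundary-to-boundary
    for mine, theirs, priv in ((e1, e2, only1), (e2, e1, only2)):
        for ex in priv:
            for j in range(len(theirs) - 1):
                x, y = theirs[j], theirs[j + 1]
                if ex[0] == x[0] and ex[1] == y[1] and y[0] - x[1] >= 2:
                    found.add(("RI", (x[1], y[0])))
    return found


def hypergeom_tail_by_permutation(n_universe, set_size, study_size, overlap, rng, n_perm=100_000):
    """P(X >= overlap) by Monte-Carlo label permutation."""
    universe = np.arange(n_universe)
    members = set(range(set_size))
    hits = 0
    for _ in range(n_perm):
        study = rng.choice(universe, size=study_size, replace=False)
        if sum(1 for g in study if g in members) >= overlap:
            hits += 1
    return hits / n_perm
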