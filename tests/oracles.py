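"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive -- exhaustive enumeration, no
shared code with the package beyond the standard genetic code table
(re-derived locally) -- so agreement with the implementation is a real
cross-check, not a tautology.
"""

from __future__ import annotations

import math
from itertools import permutations

_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


# --------------------------------------------------------------------------
# Nei-Gojobori

def brute_sites(codon: str) -> tuple[float, float]:
    """Site counts by listing all nine single-base neighbors."""
    aa = CODE[codon]
    s = n = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            other = CODE[codon[:pos] + base + codon[pos + 1 :]]
            if other == "*":
                continue  # counts toward neither class
            if other == aa:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def brute_codon_diffs(ca: str, cb: str) -> tuple[float, float]:
    """Average syn/nonsyn differences over shortest pathways."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur, s, n = ca, 0, 0
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if CODE[nxt] == "*":
                if not allow_stops:
                    return None
                n += 1
            elif CODE[nxt] == CODE[cur]:
                s += 1
            else:
                n += 1
            cur = nxt
        return s, n

    results = [
        r for r in (walk(o, False) for o in permutations(positions))
        if r is not None
    ]
    if not results:
        results = [walk(o, True) for o in permutations(positions)]
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def brute_kaks(seq_a: str, seq_b: str) -> dict:
    """Full NG86 + Jukes-Cantor on a short gapless codon pair."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        sa, na = brute_sites(ca)
        sb, nb = brute_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        ds, dn = brute_codon_diffs(ca, cb)
        Sd += ds
        Nd += dn
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    jc = lambda p: None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN,
            "Ks": jc(pS), "Ka": jc(pN)}


# --------------------------------------------------------------------------
# tandem clustering (single linkage by pairwise ordinal distance)

def brute_single_linkage(ordinals: list[int], max_intervening: int):
    """Clusters by exhaustive pairwise linking; returns sorted tuples."""
    parent = list(range(len(ordinals)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(ordinals)):
        for j in range(i + 1, len(ordinals)):
            if abs(ordinals[i] - ordinals[j]) - 1 <= max_intervening:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i, o in enumerate(ordinals):
        groups.setdefault(find(i), []).append(o)
    return sorted(
        tuple(sorted(g)) for g in groups.values() if len(g) >= 2
    )


# --------------------------------------------------------------------------
# collinear chains (longest monotone subsequence)

def longest_monotone_chain(points, max_gap):
    """Longest subsequence monotone on both axes with per-step gaps
    bounded by max_gap, by exhaustive dynamic programming."""
    pts = sorted(points)
    best_len = 0
    for direction in (1, -1):
        n = len(pts)
        dp = [1] * n
        for j in range(n):
            for i in range(j):
                a_gap = pts[j][0] - pts[i][0]
                b_step = (pts[j][1] - pts[i][1]) * direction
                if 0 < a_gap <= max_gap and 0 < b_step <= max_gap:
                    dp[j] = max(dp[j], dp[i] + 1)
        best_len = max(best_len, max(dp, default=0))
    return best_len


# --------------------------------------------------------------------------
# ALR windows / glycomodules

def brute_alr_windows(seq: str, window: int, min_frac: float):
    """Merged maximal qualifying windows by scanning every window."""
    qual = []
    for start in range(len(seq) - window + 1):
        chunk = seq[start : start + window]
        frac = sum(c in "PAST" for c in chunk) / window
        if frac >= min_frac:
            qual.append((start, start + window))
    merged = []
    for s, e in qual:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def brute_glycomodules(seq: str, dipeptides) -> int:
    count = i = 0
    while i < len(seq) - 1:
        if seq[i : i + 2] in dipeptides:
            count += 1
            i += 2
        else:
            i += 1
    return count


# --------------------------------------------------------------------------
# duplication-loss reconciliation (exhaustive minimum over mappings)

def brute_dl_minimum(gene_tree, species_tree, leaf_map) -> int:
    """Minimum duplications + losses over every valid mapping of gene
    internal nodes to species nodes (dendropy trees, rooted)."""
    s_nodes = list(species_tree.preorder_node_iter())
    depth, parent = {}, {}
    for nd in s_nodes:
        parent[nd] = nd.parent_node
        depth[nd] = 0 if nd.parent_node is None else depth[nd.parent_node] + 1

    def is_anc(a, b):  # a ancestor-or-equal of b
        while b is not None:
            if b is a:
                return True
            b = parent[b]
        return False

    leaf_node = {lf.taxon.label: lf for lf in species_tree.leaf_node_iter()}
    g_nodes = list(gene_tree.postorder_node_iter())
    internals = [g for g in g_nodes if not g.is_leaf()]
    fixed = {
        g: leaf_node[leaf_map[g.taxon.label]]
        for g in g_nodes
        if g.is_leaf()
    }

    best = [None]

    def cost(assign):
        total_dup = total_loss = 0
        mapping = dict(fixed)
        mapping.update(assign)
        for g in internals:
            mg = mapping[g]
            kids = g.child_nodes()
            for c in kids:
                if not is_anc(mg, mapping[c]):
                    return None
            in_distinct = (
                len(kids) == 2
                and mapping[kids[0]] is not mg
                and mapping[kids[1]] is not mg
                and _separated(mapping[kids[0]], mapping[kids[1]], mg,
                               parent)
            )
            dup = not in_distinct
            total_dup += dup
            for c in kids:
                dist = depth[mapping[c]] - depth[mg]
                total_loss += dist if dup else dist - 1
        return total_dup + total_loss

    def rec(idx, assign):
        if idx == len(internals):
            c = cost(assign)
            if c is not None and (best[0] is None or c < best[0]):
                best[0] = c
            return
        for s in s_nodes:
            assign[internals[idx]] = s
            rec(idx + 1, assign)
        del assign[internals[idx]]

    rec(0, {})
    return best[0]


def _separated(ma, mb, mg, parent):
    """True if ma and mb descend through distinct children of mg."""
    def child_toward(target):
        prev = target
        node = target
        while node is not mg:
            prev, node = node, parent[node]
        return prev

    return child_toward(ma) is not child_toward(mb)


# --------------------------------------------------------------------------
# random additive trees

def random_additive_tree(n_taxa: int, rng):
    """Random rooted binary tree with positive lengths; returns
    (newick string, taxon labels)."""
    labels = [f"t{i}" for i in range(1, n_taxa + 1)]
    nodes = [(lbl, f"{lbl}:{rng.uniform(0.5, 3.0):.4f}") for lbl in labels]
    while len(nodes) > 1:
        i = rng.integers(0, len(nodes))
        a = nodes.pop(int(i))
        j = rng.integers(0, len(nodes))
        b = nodes.pop(int(j))
        length = rng.uniform(0.5, 3.0)
        merged = (None, f"({a[1]},{b[1]}):{length:.4f}")
        nodes.append(merged)
    newick = nodes[0][1]
    newick = newick.rsplit(":", 1)[0] + ";"
    return newick, labels
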