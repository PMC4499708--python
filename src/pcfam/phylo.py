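"""Gene-family phylogenetics: distances, neighbor joining, bootstrap,
gene-tree/species-tree reconciliation and retrogene donor inference.

Trees are :class:`dendropy.Tree` objects throughout.  Reconciliation
uses the classic last-common-ancestor (LCA) mapping: each gene-tree
node g maps to the species node M(g) = LCA of its children's mappings;
g is a duplication iff it maps to the same species node as one of its
children, and losses follow from the depth difference along each gene
edge (duplication-loss parsimony).  Ancestral copy numbers at labelled
species nodes (V, E, T, A, G, Eu, R) count the gene lineages whose
mapping passes through each node.

Retrogene donors are inferred from intron presence/absence: an
intronless subclade sister to (or below) an intron-bearing gene is
taken to descend from that gene by retroposition, since a retrogene is
reverse-transcribed from spliced mRNA and lacks the conserved intron.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "ReconciliationResult",
    "IntronPlacement",
    "RetroEvent",
    "protein_distance",
    "neighbor_joining",
    "bootstrap",
    "reconcile",
    "ancestral_counts",
    "map_introns_to_domain",
    "infer_retro_donors",
]


# ---------------------------------------------------------------------------
# distances

@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match taxon count")
        if np.isnan(m).any():
            raise ValueError("NaN distances are forbidden")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("diagonal must be zero")
        self.matrix = m

    def __len__(self) -> int:
        return len(self.ids)


def _pairwise_p(a: str, b: str) -> float:
    comparable = mismatch = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        mismatch += x != y
    if comparable == 0:
        raise ValueError("pair with zero comparable columns")
    return mismatch / comparable


def protein_distance(
    alignment: dict[str, str], correction: str = "kimura"
) -> DistanceMatrix:
    """Pairwise protein distance over non-gap columns.

    ``correction="p"`` returns the raw proportion of mismatches;
    ``"kimura"`` applies d = -ln(1 - p - p^2/5), with ``inf`` beyond
    the correction's domain.
    """
    ids = list(alignment)
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = _pairwise_p(alignment[ids[i]], alignment[ids[j]])
            if correction == "p":
                d = p
            elif correction == "kimura":
                arg = 1 - p - p * p / 5
                d = math.inf if arg <= 0 else -math.log(arg)
            else:
                raise ValueError(f"unknown correction {correction!r}")
            m[i, j] = m[j, i] = d
    return DistanceMatrix(ids, m)


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Q-matrix ties are broken by joining the lowest-index pair (taxa in
    input order, joined nodes appended).  Negative branch lengths are
    clamped to zero with the deficit moved to the sibling branch.
    Returns an unrooted tree (dendropy trifurcation at the seed node).
    """
    n = len(D)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.isfinite(D.matrix).all():
        raise ValueError(
            "non-finite distances (saturated pairs?) cannot be joined"
        )
    taxa = dendropy.TaxonNamespace(D.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for name in D.ids:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(name)
        nodes.append(node)
    d = D.matrix.copy()
    active = list(range(n))

    def clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return la, max(lb, 0.0)

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * sub[i, j] - R[i] - R[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        ai, aj = active[i], active[j]
        li = sub[i, j] / 2 + (R[i] - R[j]) / (2 * (r - 2))
        lj = sub[i, j] - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[ai])
        parent.add_child(nodes[aj])
        nodes[ai].edge.length = li
        nodes[aj].edge.length = lj
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        for idx in active:
            if idx in (ai, aj):
                continue
            d[k, idx] = d[idx, k] = (d[ai, idx] + d[aj, idx] - d[ai, aj]) / 2
        nodes.append(parent)
        active = [x for x in active if x not in (ai, aj)] + [k]

    # final three nodes: closed-form three-point formulas
    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    center = dendropy.Node()
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        center.add_child(node)
        node.edge.length = max(length, 0.0)
    tree.seed_node = center
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


def tree_splits(tree: dendropy.Tree) -> dict[frozenset[str], float | None]:
    """Nontrivial unrooted splits, each keyed by the side not containing
    the lexicographically smallest taxon; value is the edge length."""
    all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(all_taxa)
    splits: dict[frozenset[str], float | None] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_taxa - side
        if len(side) >= 2 and len(all_taxa - side) >= 2:
            splits[side] = node.edge.length
    return splits


def bootstrap(
    alignment: dict[str, str],
    n_reps: int = 1000,
    seed: int = 0,
    correction: str = "kimura",
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """Column-resampling bootstrap support for the NJ point estimate.

    Replicate r draws columns with a generator seeded ``seed + r``, so
    runs are reproducible and independent of taxon order.  A replicate
    pair pushed past distance-correction saturation is capped at twice
    the largest finite distance in that replicate rather than dropped.
    Returns the point-estimate tree and support (percent) per
    nontrivial split.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids = sorted(alignment)
    aln = {i: alignment[i] for i in ids}
    ncol = len(next(iter(aln.values())))
    point = neighbor_joining(protein_distance(aln, correction))
    focal = tree_splits(point)
    counts = {split: 0 for split in focal}
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        cols = rng.integers(0, ncol, size=ncol)
        resampled = {
            i: "".join(s[c] for c in cols) for i, s in aln.items()
        }
        D = protein_distance(resampled, correction)
        if np.isinf(D.matrix).any():
            cap = 2 * D.matrix[np.isfinite(D.matrix)].max()
            D.matrix[np.isinf(D.matrix)] = max(cap, 1.0)
        rep_tree = neighbor_joining(D)
        rep_splits = tree_splits(rep_tree)
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    support = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return point, support


# ---------------------------------------------------------------------------
# reconciliation

def _species_key(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return "|".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


@dataclass
class ReconciliationResult:
    n_duplications: int
    n_losses: int
    duplication_nodes: list[str]            # species key where each dup maps
    losses_per_branch: dict[str, int]       # species branch (child key) -> losses
    copies_at: dict[str, int]               # species node key -> lineage count
    gains_per_branch: dict[str, int] = field(default_factory=dict)


def _index_species(species_tree: dendropy.Tree):
    nodes = list(species_tree.preorder_node_iter())
    depth = {}
    parent = {}
    for node in nodes:
        parent[node] = node.parent_node
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1
    leaf_to_node = {lf.taxon.label: lf for lf in species_tree.leaf_node_iter()}
    return nodes, depth, parent, leaf_to_node


def _lca(u, v, depth, parent):
    while depth[u] > depth[v]:
        u = parent[u]
    while depth[v] > depth[u]:
        v = parent[v]
    while u is not v:
        u, v = parent[u], parent[v]
    return u


def reconcile(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_map: dict[str, str],
) -> ReconciliationResult:
    """LCA reconciliation of a rooted gene tree with a rooted species tree.

    ``leaf_map`` sends each gene-tree leaf label to a species-tree leaf
    label.  Duplications, per-branch losses (most-parsimonious
    duplication-loss history) and ancestral copy numbers are returned;
    the copy number at species node s counts the gene lineages entering
    the divergence at s (so it equals the observed per-species count at
    the leaves).
    """
    s_nodes, depth, parent, leaf_to_node = _index_species(species_tree)

    mapping: dict[dendropy.Node, dendropy.Node] = {}
    is_dup: dict[dendropy.Node, bool] = {}
    for g in gene_tree.postorder_node_iter():
        if g.is_leaf():
            label = g.taxon.label if g.taxon else g.label
            if label not in leaf_map:
                raise ValueError(f"gene leaf {label!r} missing from leaf map")
            sp = leaf_map[label]
            if sp not in leaf_to_node:
                raise ValueError(f"species {sp!r} not in species tree")
            mapping[g] = leaf_to_node[sp]
        else:
            children = g.child_nodes()
            m = mapping[children[0]]
            for c in children[1:]:
                m = _lca(m, mapping[c], depth, parent)
            mapping[g] = m
            is_dup[g] = any(mapping[c] is m for c in children)

    losses_per_branch: dict[str, int] = {}
    gains_per_branch: dict[str, int] = {}
    n_losses = 0

    def add_loss(species_child_node):
        key = _species_key(species_child_node)
        losses_per_branch[key] = losses_per_branch.get(key, 0) + 1

    for g, dup in is_dup.items():
        if dup:
            key = _species_key(mapping[g])
            gains_per_branch[key] = gains_per_branch.get(key, 0) + 1

    for g in gene_tree.preorder_node_iter():
        if g.is_leaf() and g.parent_node is None:
            break
        for c in g.child_nodes():
            u, v = mapping[g], mapping[c]
            dist = depth[v] - depth[u]
            n_edge_losses = dist if is_dup.get(g, False) else max(dist - 1, 0)
            n_losses += n_edge_losses
            # walk the species path from v up to u, placing one loss in
            # the sibling branch at each skipped divergence
            path = [v]
            w = v
            while w is not u:
                w = parent[w]
                path.append(w)
            path.reverse()  # u ... v
            start = 0 if is_dup.get(g, False) else 1
            for idx in range(start, len(path) - 1):
                here, down = path[idx], path[idx + 1]
                for sib in here.child_nodes():
                    if sib is not down:
                        add_loss(sib)

    # copies at species node s = gene lineages present at the divergence
    # of s; a duplication mapped to s happened before that divergence, so
    # its product lineages all count (this makes leaf counts equal the
    # observed per-species gene numbers)
    copies_at: dict[str, int] = {}
    g_root = gene_tree.seed_node
    root_map = mapping[g_root]

    def is_ancestor_or_equal(anc, node):
        while node is not None:
            if node is anc:
                return True
            node = parent[node]
        return False

    for s in s_nodes:
        def above(g):
            m = mapping[g]
            if m is not s and is_ancestor_or_equal(m, s):
                return True
            return m is s and is_dup.get(g, False)

        count = 0
        for g in gene_tree.preorder_node_iter():
            if g is g_root:
                continue
            p = g.parent_node
            if above(p) and not above(g) and is_ancestor_or_equal(
                s, mapping[g]
            ):
                count += 1
        if s is root_map and not above(g_root):
            count += 1
        copies_at[_species_key(s)] = count

    dup_nodes = [
        _species_key(mapping[g]) for g, d in is_dup.items() if d
    ]
    return ReconciliationResult(
        n_duplications=sum(is_dup.values()),
        n_losses=n_losses,
        duplication_nodes=sorted(dup_nodes),
        losses_per_branch=losses_per_branch,
        copies_at=copies_at,
        gains_per_branch=gains_per_branch,
    )


def ancestral_counts(
    results: list[ReconciliationResult],
    labeled_nodes: list[str],
) -> dict:
    """Sum ancestral copy numbers and per-branch gains/losses over families."""
    totals = {}
    for label in labeled_nodes:
        if results and not any(label in r.copies_at for r in results):
            raise KeyError(f"label {label!r} not found in any reconciliation")
        totals[label] = sum(r.copies_at.get(label, 0) for r in results)
    gains: dict[str, int] = {}
    losses: dict[str, int] = {}
    for r in results:
        for k, v in r.gains_per_branch.items():
            gains[k] = gains.get(k, 0) + v
        for k, v in r.losses_per_branch.items():
            losses[k] = losses.get(k, 0) + v
    return {"copies": totals, "gains": gains, "losses": losses}


# ---------------------------------------------------------------------------
# intron evidence and retrogene donors

@dataclass(frozen=True)
class IntronPlacement:
    """Introns of one gene relative to a protein-domain span."""

    gene_id: str
    has_conserved_intron: bool
    introns_in_domain: tuple[tuple[float, int], ...]  # (residue pos, phase)


def map_introns_to_domain(
    gene_model,
    pcld_span: tuple[int, int],
    protein_length: int | None = None,
) -> IntronPlacement:
    """Locate intron insertion points within a protein-domain span.

    The insertion point of an intron after L coding bases is residue
    L/3 (fractional for phase 1 and 2 introns); it is *in* the domain
    when span_start <= L/3 < span_end (0-based half-open protein
    coordinates).
    """
    if protein_length is not None:
        clen = gene_model.coding_length
        if clen not in (3 * protein_length, 3 * (protein_length + 1)):
            raise ValueError(
                f"{gene_model.gene_id}: coding length {clen} inconsistent "
                f"with protein length {protein_length}"
            )
    s, e = pcld_span
    lengths = [b - a + 1 for a, b in gene_model.exons]
    if gene_model.strand == "-":
        lengths = lengths[::-1]
    in_domain = []
    upstream = 0
    for length in lengths[:-1]:
        upstream += length
        residue = upstream / 3
        if s <= residue < e:
            in_domain.append((residue, upstream % 3))
    return IntronPlacement(
        gene_id=gene_model.gene_id,
        has_conserved_intron=bool(in_domain),
        introns_in_domain=tuple(in_domain),
    )


@dataclass
class RetroEvent:
    donor: str | None
    retro_genes: list[str]
    stem_label: str = "R"
    tandem_expansion: bool = False


def infer_retro_donors(
    clade: dendropy.Tree,
    evidence: dict[str, bool],
    tandem_clusters: list[list[str]] | None = None,
) -> list[RetroEvent]:
    """Identify retrogene donors inside a rooted clade.

    ``evidence`` maps gene id -> has_conserved_intron.  Maximal
    intronless subclades are labelled as retroposition events (R at the
    stem); the donor is the intron-bearing gene nearest the stem
    (lexicographically smallest on ties) — an intron-bearing gene is
    never labelled as a retrocopy.  When a retro clade's members sit in
    one tandem cluster its internal expansion is marked tandem (T).
    If the clade carries no intron-bearing gene at all, no donor is
    guessed and an empty list is returned.
    """
    def leaf_ids(node):
        return [
            (lf.taxon.label if lf.taxon else lf.label)
            for lf in node.leaf_iter()
        ]

    all_leaves = leaf_ids(clade.seed_node)
    for gid in all_leaves:
        if gid not in evidence:
            raise ValueError(f"no intron evidence for {gid!r}")
    bearers = {g for g in all_leaves if evidence[g]}
    if not bearers:
        return []
    if len(bearers) == len(all_leaves):
        return []

    def all_intronless(node):
        return all(not evidence[g] for g in leaf_ids(node))

    events: list[RetroEvent] = []
    stack = [clade.seed_node]
    maximal: list[dendropy.Node] = []
    while stack:
        node = stack.pop()
        if all_intronless(node):
            maximal.append(node)
        else:
            stack.extend(node.child_nodes())

    for node in maximal:
        genes = sorted(leaf_ids(node))
        donor = None
        anc = node.parent_node
        excluded = set(genes)
        while anc is not None and donor is None:
            outside = [
                g for g in leaf_ids(anc)
                if g not in excluded and evidence[g]
            ]
            if outside:
                donor = min(outside)
            excluded = set(leaf_ids(anc))
            anc = anc.parent_node
        tandem = False
        if tandem_clusters and len(genes) >= 2:
            tandem = any(
                sum(g in cluster for g in genes) >= 2
                for cluster in tandem_clusters
            )
        events.append(
            RetroEvent(donor=donor, retro_genes=genes,
                       tandem_expansion=tandem)
        )
    events.sort(key=lambda e: e.retro_genes)
    return events
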