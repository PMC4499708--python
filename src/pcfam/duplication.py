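"""Dating and mechanism classification of duplicate gene pairs.

A paralog pair's age is T = Ks / (2 lambda), with lambda the clock-like
synonymous substitution rate per site per year (defaults: Arabidopsis
1.5e-8, maize 6.5e-9).  Mechanism is assigned by precedence: *tandem*
when both genes sit in one tandem cluster (few intervening genes on the
same chromosome), else *segmental* when the pair is an anchor of -- or
spans -- a collinear block of within-genome paralog anchors, else
*retrotransposition* for dispersed pairs, strengthened when exactly one
member lacks the conserved intron (a retrogene hallmark).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .kaks import KaKsResult

__all__ = [
    "ClockRate",
    "ParalogPair",
    "SyntenyBlock",
    "CLOCK_RATES",
    "date_duplication",
    "classify_selection",
    "find_tandem_clusters",
    "chain_collinear_anchors",
    "classify_duplication_pair",
    "lineage_gain",
    "percent_change",
]


@dataclass(frozen=True)
class ClockRate:
    """Synonymous substitutions per site per year for one species."""

    species: str
    lam: float

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("clock rate must be positive")


#: Published clock rates used for dating.
CLOCK_RATES = {
    "arabidopsis": ClockRate("arabidopsis", 1.5e-8),
    "maize": ClockRate("maize", 6.5e-9),
}


@dataclass
class ParalogPair:
    gene_a: str
    gene_b: str
    kaks: KaKsResult | None = None
    mechanism: str = "unknown"  # tandem | segmental | retrotransposition | unknown
    T_mya: float | None = None


@dataclass
class SyntenyBlock:
    """A chain of collinear within-genome paralog anchors."""

    chrom_a: str
    chrom_b: str
    anchors: list[tuple[int, int]] = field(default_factory=list)  # ordinals

    @property
    def orientation(self) -> str:
        if len(self.anchors) < 2:
            return "same"
        return "same" if self.anchors[1][1] > self.anchors[0][1] else "inverted"

    def span_a(self) -> tuple[int, int]:
        xs = [a for a, _ in self.anchors]
        return min(xs), max(xs)

    def span_b(self) -> tuple[int, int]:
        ys = [b for _, b in self.anchors]
        return min(ys), max(ys)


def date_duplication(
    ks: float, rate: ClockRate | float, decimals: int = 2
) -> float:
    """Age of a duplication in million years: T = Ks / (2 lambda).

    Rounded half-up to ``decimals`` places (set ``decimals=None`` for
    the raw value).  Saturated Ks must be filtered by the caller; this
    routine only requires Ks >= 0.
    """
    lam = rate.lam if isinstance(rate, ClockRate) else float(rate)
    if ks < 0:
        raise ValueError("Ks must be nonnegative")
    t_myr = ks / (2 * lam) / 1e6
    if decimals is None:
        return t_myr
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(t_myr)).quantize(q, rounding=ROUND_HALF_UP))


def classify_selection(result: KaKsResult, tol: float = 1e-9) -> str:
    """Selection regime from Ka/Ks: purifying (<1), positive (>1), neutral."""
    if result.ratio is None:
        return "unclassified"
    if abs(result.ratio - 1) <= tol:
        return "neutral"
    return "positive" if result.ratio > 1 else "purifying"


def find_tandem_clusters(genes, max_intervening: int = 5):
    """Single-linkage tandem clusters of family genes on one chromosome.

    ``genes`` are GeneModel records of ONE family; ordinals must count
    all genes of the genome so that the ordinal gap between consecutive
    family members equals intervening genes + 1.  Members at most
    ``max_intervening`` non-family genes apart are linked; clusters of
    at least two genes are returned as lists of gene_ids, ordered along
    the chromosome.
    """
    by_chrom: dict[tuple[str, str], list] = {}
    for g in genes:
        by_chrom.setdefault((g.species, g.chromosome), []).append(g)
    clusters: list[list[str]] = []
    for group in by_chrom.values():
        group.sort(key=lambda g: g.ordinal)
        current = [group[0]]
        for prev, cur in zip(group, group[1:]):
            if cur.ordinal - prev.ordinal - 1 <= max_intervening:
                current.append(cur)
            else:
                if len(current) >= 2:
                    clusters.append([g.gene_id for g in current])
                current = [cur]
        if len(current) >= 2:
            clusters.append([g.gene_id for g in current])
    return clusters


def chain_collinear_anchors(
    anchors,
    min_anchors: int = 3,
    max_ordinal_gap: int = 20,
) -> list[SyntenyBlock]:
    """Greedy chaining of paralog anchors into collinear blocks.

    ``anchors`` is an iterable of (chrom_a, ordinal_a, chrom_b,
    ordinal_b).  Within each chromosome pair, anchors sorted on the
    first chromosome are chained while the ordinal step stays within
    ``max_ordinal_gap`` on both chromosomes and monotone (increasing or
    decreasing) on the second; chains with at least ``min_anchors``
    anchors become :class:`SyntenyBlock` records.
    """
    by_pair: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for ca, oa, cb, ob in anchors:
        by_pair.setdefault((ca, cb), []).append((oa, ob))
    blocks: list[SyntenyBlock] = []
    for (ca, cb), pts in by_pair.items():
        pts.sort()
        used = [False] * len(pts)
        for direction in (1, -1):
            for i in range(len(pts)):
                if used[i]:
                    continue
                chain = [pts[i]]
                chain_idx = [i]
                for j in range(i + 1, len(pts)):
                    if used[j]:
                        continue
                    a_gap = pts[j][0] - chain[-1][0]
                    b_step = (pts[j][1] - chain[-1][1]) * direction
                    if a_gap == 0:
                        continue
                    if a_gap > max_ordinal_gap:
                        break
                    if 0 < b_step <= max_ordinal_gap:
                        chain.append(pts[j])
                        chain_idx.append(j)
                if len(chain) >= min_anchors:
                    for k in chain_idx:
                        used[k] = True
                    blocks.append(SyntenyBlock(ca, cb, chain))
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, b.anchors[0]))
    return blocks


def classify_duplication_pair(
    pair: ParalogPair,
    gene_locs: dict[str, tuple[str, int]],
    clusters: list[list[str]],
    blocks: list[SyntenyBlock],
    intron_evidence: dict[str, bool] | None = None,
) -> str:
    """Assign the duplication mechanism with precedence tandem >
    segmental > retrotransposition.

    ``gene_locs`` maps gene_id -> (chromosome, ordinal).  A pair is
    *tandem* when both genes are in one tandem cluster; *segmental*
    when it is an anchor of a block or both genes fall within the
    ordinal spans of one block's two chromosomes; otherwise dispersed
    pairs are *retrotransposition* (intron presence/absence evidence is
    recorded but not required).  Unplaced genes yield ``unknown``.
    """
    a, b = pair.gene_a, pair.gene_b
    if a not in gene_locs or b not in gene_locs:
        pair.mechanism = "unknown"
        return pair.mechanism
    for cluster in clusters:
        if a in cluster and b in cluster:
            pair.mechanism = "tandem"
            return pair.mechanism
    ca, oa = gene_locs[a]
    cb, ob = gene_locs[b]
    for blk in blocks:
        pairs_on = {(blk.chrom_a, blk.chrom_b), (blk.chrom_b, blk.chrom_a)}
        if (ca, cb) not in pairs_on:
            continue
        if (ca, cb) == (blk.chrom_a, blk.chrom_b):
            pa, pb = (oa, ob)
        else:
            pa, pb = (ob, oa)
        if (pa, pb) in blk.anchors:
            pair.mechanism = "segmental"
            return pair.mechanism
        (a0, a1), (b0, b1) = blk.span_a(), blk.span_b()
        if a0 <= pa <= a1 and b0 <= pb <= b1:
            pair.mechanism = "segmental"
            return pair.mechanism
    pair.mechanism = "retrotransposition"
    if intron_evidence is not None:
        has_a = intron_evidence.get(a)
        has_b = intron_evidence.get(b)
        # exactly one intronless member is the classic retrogene signature;
        # recorded for reporting, classification does not depend on it
        pair.retro_intron_support = (  # type: ignore[attr-defined]
            has_a is not None and has_b is not None and has_a != has_b
        )
    return pair.mechanism


def lineage_gain(extant_count: int, ancestral_count: int) -> tuple[int, int]:
    """Net gained and lost copies between an ancestral and extant count.

    Returns ``(gained, lost)``; exactly one of the two is nonzero
    unless the counts are equal.
    """
    if extant_count < 0 or ancestral_count < 0:
        raise ValueError("counts must be nonnegative")
    diff = extant_count - ancestral_count
    return (diff, 0) if diff >= 0 else (0, -diff)


def percent_change(ancestral: int, extant: int) -> float:
    """Percent decrease from the ancestral count, one decimal, half-up."""
    if ancestral <= 0:
        raise ValueError("ancestral count must be positive")
    pct = 100 * (ancestral - extant) / ancestral
    return float(Decimal(repr(pct)).quantize(Decimal("0.1"), ROUND_HALF_UP))
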