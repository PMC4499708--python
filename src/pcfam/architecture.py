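"""Structural typing of phytocyanin proteins.

Phytocyanins are classified into ten architecture types from four
features: an N-terminal secretion signal (SP), the number of
plastocyanin-like domains (PCLD, 1-3), an AGP-like region (ALR: a
Pro/Ala/Ser/Thr-rich segment) and a C-terminal GPI-anchor signal (GAS).
Type I is the full architecture (SP + one PCLD + ALR + GAS); type II
lacks only the GAS; types VI, VIII and IX lack both ALR and GAS; types
III, IV, VIII and X carry two PCLDs and type V three.  Proteins whose
ALR also contains arabinogalactan glycomodules (short dipeptides such
as AP/PA/SP/TP) and an SP are flagged as arabinogalactan-protein (AGP)
candidates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .catalog_io import FeatureAnnotation, SequenceRecord

__all__ = [
    "ArchitectureCall",
    "DEFAULT_DECISION_TABLE",
    "AG_DIPEPTIDES",
    "detect_alr",
    "detect_ag_glycomodules",
    "classify_architecture",
    "summarize_catalog",
]

#: Dipeptides diagnostic of arabinogalactan glycosylation within a
#: PAST-rich region.
AG_DIPEPTIDES = frozenset({"AP", "PA", "SP", "TP", "GP", "VP"})

PAST = frozenset("PAST")

#: (has_sp, pcld_count, has_alr, has_gas) -> roman type label.  pcld_count
#: of 3 dominates every other feature (type V).  The table is total over
#: all 24 tuples; entries marked here cover the 1- and 2-PCLD cases and
#: `None` wildcards collapse where a feature is irrelevant.
_TYPE_RULES: list[tuple[tuple, str]] = [
    # (sp, count, alr, gas)
    ((None, 3, None, None), "V"),
    ((True, 1, True, True), "I"),
    ((True, 1, True, False), "II"),
    ((True, 1, False, True), "VII"),
    ((True, 1, False, False), "VI"),
    ((False, 1, None, None), "IX"),  # the SP-less single-PCLD type, like X for 2 PCLDs
    ((True, 2, True, True), "III"),
    ((True, 2, True, False), "IV"),
    ((True, 2, False, None), "VIII"),
    ((False, 2, None, None), "X"),
]


def _expand_rules(rules) -> dict[tuple[bool, int, bool, bool], str]:
    table: dict[tuple[bool, int, bool, bool], str] = {}
    for (sp, count, alr, gas), label in rules:
        for sp_v in ([sp] if sp is not None else [True, False]):
            for c_v in ([count] if count is not None else [1, 2, 3]):
                for alr_v in ([alr] if alr is not None else [True, False]):
                    for gas_v in ([gas] if gas is not None else [True, False]):
                        table.setdefault((sp_v, c_v, alr_v, gas_v), label)
    return table


#: Total decision table over all 2*3*2*2 = 24 feature tuples.
DEFAULT_DECISION_TABLE = _expand_rules(_TYPE_RULES)


@dataclass(frozen=True)
class ArchitectureCall:
    gene_id: str
    type_label: str  # I..X or "unclassified"
    evidence: tuple  # (has_sp, pcld_count, has_alr, has_gas)


def detect_alr(
    protein: SequenceRecord,
    window_len: int = 10,
    min_past_fraction: float = 0.5,
    exclude_n_terminal: int = 0,
) -> list[tuple[int, int]]:
    """Find PAST-rich (AGP-like) regions by sliding-window scan.

    Every window of ``window_len`` residues whose P/A/S/T fraction is at
    least ``min_past_fraction`` qualifies; overlapping or adjacent
    qualifying windows are merged into maximal intervals (0-based
    half-open).  ``exclude_n_terminal`` masks a leading signal peptide.
    Sequences shorter than the window yield no intervals.
    """
    seq = protein.residues
    n = len(seq)
    if n < window_len:
        return []
    is_past = [c in PAST for c in seq]
    count = sum(is_past[:window_len])
    intervals: list[list[int]] = []
    for start in range(0, n - window_len + 1):
        if start > 0:
            count += is_past[start + window_len - 1] - is_past[start - 1]
        if start < exclude_n_terminal:
            continue
        if count / window_len >= min_past_fraction:
            end = start + window_len
            if intervals and start <= intervals[-1][1]:
                intervals[-1][1] = max(intervals[-1][1], end)
            else:
                intervals.append([start, end])
    return [(s, e) for s, e in intervals]


def detect_ag_glycomodules(
    protein: SequenceRecord,
    region: tuple[int, int],
    dipeptides: frozenset[str] = AG_DIPEPTIDES,
) -> tuple[int, list[int]]:
    """Count non-overlapping AG glycomodule dipeptides inside ``region``.

    Scans left to right; a matched dipeptide consumes both residues.
    Returns (count, start positions).  ``region`` is 0-based half-open
    and must lie within the sequence.
    """
    s, e = region
    if s < 0 or e > len(protein.residues) or s >= e:
        raise IndexError(f"region {region} outside sequence of length "
                         f"{len(protein.residues)}")
    seq = protein.residues
    positions: list[int] = []
    i = s
    while i < e - 1:
        if seq[i : i + 2] in dipeptides:
            positions.append(i)
            i += 2
        else:
            i += 1
    return len(positions), positions


def classify_architecture(
    f: FeatureAnnotation,
    has_alr: bool | None = None,
    table: dict | None = None,
) -> ArchitectureCall:
    """Assign the architecture type from the resolved feature tuple.

    ``has_alr`` defaults to whether the annotation carries any ALR span.
    Proteins without a PCLD, or with more than three, are labelled
    ``unclassified`` (the former are flagged for catalog exclusion).
    """
    table = DEFAULT_DECISION_TABLE if table is None else table
    if has_alr is None:
        has_alr = bool(f.alr_spans)
    count = f.pcld_count
    key = (bool(f.has_sp), count, bool(has_alr), bool(f.has_gas))
    if count < 1 or count > 3:
        return ArchitectureCall(f.gene_id, "unclassified", key)
    return ArchitectureCall(f.gene_id, table[key], key)


def summarize_catalog(
    calls: list[ArchitectureCall],
    features: dict[str, FeatureAnnotation],
    agp_candidates: set[str] | None = None,
    species_of: dict[str, str] | None = None,
) -> dict:
    """Census of the annotated catalog.

    Counts secretion signals, GPI-anchor signals, AGP candidates (an SP
    plus at least one ALR with qualifying glycomodules), the per-type
    histogram and, when ``species_of`` is given, a per-species breakdown.
    """
    n_sp = sum(1 for f in features.values() if f.has_sp)
    n_gas = sum(1 for f in features.values() if f.has_gas)
    if agp_candidates is None:
        agp_candidates = {
            f.gene_id
            for f in features.values()
            if f.has_sp and f.alr_spans
        }
    # AGP candidacy requires a secretion signal
    agp_candidates = {
        g for g in agp_candidates if g in features and features[g].has_sp
    }
    hist = Counter(c.type_label for c in calls)
    summary = {
        "n_genes": len(calls),
        "n_sp": n_sp,
        "n_gas": n_gas,
        "n_agp_candidates": len(agp_candidates),
        "type_histogram": dict(hist),
    }
    if species_of is not None:
        per_species: dict[str, Counter] = {}
        for c in calls:
            sp = species_of.get(c.gene_id, "unknown")
            per_species.setdefault(sp, Counter())[c.type_label] += 1
        summary["per_species"] = {k: dict(v) for k, v in per_species.items()}
    return summary
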