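"""Pairwise Ka/Ks estimation by the Nei-Gojobori (1986) counting method.

For each codon, each of the three positions contributes fractional
synonymous and nonsynonymous *sites* according to how many of its three
possible single-nucleotide changes are synonymous under the standard
genetic code.  Observed differences between a codon pair are decomposed
over all shortest substitution pathways between the two codons,
averaging the synonymous/nonsynonymous split over pathways; pathways
passing through a stop codon are excluded.  The resulting proportions
pS = Sd/S and pN = Nd/N are corrected for multiple hits with the
Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3).  The ratio Ka/Ks below 1
indicates purifying selection, above 1 positive selection.

Stop-codon treatment at the site-counting step is configurable: by
default a mutation that would create a stop codon counts toward neither
site class (so S+N falls short of 3 x codons by the excluded fraction);
alternatively such mutations can be counted as nonsynonymous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from .catalog_io import FormatError, SequenceRecord

__all__ = [
    "STANDARD_CODE",
    "CodonAlignment",
    "KaKsResult",
    "SaturationError",
    "backtranslate",
    "ng86_sites",
    "ng86_pair",
    "jukes_cantor",
]

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
#: Codon -> amino acid ('*' = stop), standard nuclear code.
STANDARD_CODE: dict[str, str] = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


class SaturationError(ValueError):
    """Proportion of differences beyond the Jukes-Cantor domain (p >= 3/4)."""


@dataclass(frozen=True)
class CodonAlignment:
    """A gap-free pair of equal-length codon sequences."""

    seq_a: str
    seq_b: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise FormatError("codon alignment sequences differ in length")
        if len(self.seq_a) % 3 != 0:
            raise FormatError("codon alignment length not a multiple of 3")
        for seq in (self.seq_a, self.seq_b):
            for i in range(0, len(seq) - 3, 3):  # internal stops only
                if STANDARD_CODE.get(seq[i : i + 3]) == "*":
                    raise FormatError(f"internal stop codon at {i}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass(frozen=True)
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ka: float | None
    Ks: float | None
    ratio: float | None
    saturated_s: bool = False
    saturated_n: bool = False


def backtranslate(
    protein_alignment: dict[str, str] | list[SequenceRecord],
    cds_records: dict[str, str] | list[SequenceRecord],
) -> dict[str, CodonAlignment]:
    """Thread CDS codons onto an aligned protein pair.

    Each aligned protein must translate exactly from its CDS (standard
    code, terminal stop stripped); alignment gaps become ``---`` codon
    gaps, and codon columns gapped in either member of a pair are
    dropped pairwise.  Returns one :class:`CodonAlignment` per unordered
    id pair, keyed ``"idA|idB"`` in input order.
    """
    if not isinstance(protein_alignment, dict):
        protein_alignment = {r.id: r.residues for r in protein_alignment}
    if not isinstance(cds_records, dict):
        cds_records = {r.id: r.residues for r in cds_records}

    codon_rows: dict[str, list[str]] = {}
    for pid, aligned in protein_alignment.items():
        cds = cds_records[pid]
        if len(cds) % 3 != 0:
            raise FormatError(f"{pid}: CDS length not a multiple of 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and STANDARD_CODE.get(codons[-1]) == "*":
            codons = codons[:-1]
        ungapped = aligned.replace("-", "")
        if len(codons) != len(ungapped):
            raise FormatError(
                f"{pid}: protein length {len(ungapped)} does not match "
                f"{len(codons)} CDS codons"
            )
        for pos, (aa, codon) in enumerate(zip(ungapped, codons)):
            trans = STANDARD_CODE.get(codon, "X")
            if aa != trans and aa != "X":
                raise FormatError(
                    f"{pid}: residue {pos + 1} is {aa} but CDS codon "
                    f"{codon} translates to {trans}"
                )
        row, k = [], 0
        for aa in aligned:
            if aa == "-":
                row.append("---")
            else:
                row.append(codons[k])
                k += 1
        codon_rows[pid] = row

    ids = list(codon_rows)
    out: dict[str, CodonAlignment] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            cols = [
                (ca, cb)
                for ca, cb in zip(codon_rows[a], codon_rows[b])
                if "-" not in ca and "-" not in cb
            ]
            out[f"{a}|{b}"] = CodonAlignment(
                "".join(c[0] for c in cols),
                "".join(c[1] for c in cols),
                source_id=f"{a}|{b}",
            )
    return out


def ng86_sites(
    codon: str,
    code: dict[str, str] | None = None,
    stop_policy: str = "exclude",
) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Each position contributes (synonymous changes)/3 synonymous sites;
    changes creating a stop codon count toward neither class under the
    default ``stop_policy="exclude"``, or as nonsynonymous under
    ``"nonsynonymous"``.
    """
    code = STANDARD_CODE if code is None else code
    aa = code.get(codon)
    if aa is None:
        raise FormatError(f"ambiguous or invalid codon {codon!r}")
    if aa == "*":
        raise FormatError(f"stop codon {codon!r} has no site decomposition")
    s = n = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1 :]
            aa2 = code[neighbor]
            if aa2 == "*":
                if stop_policy == "nonsynonymous":
                    n += 1 / 3
                continue
            if aa2 == aa:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def _pathway_counts(
    ca: str, cb: str, code: dict[str, str], allow_stop_paths: bool
) -> tuple[float, float]:
    """Average (syn, nonsyn) differences over shortest pathways ca -> cb."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    totals: list[tuple[int, int]] = []
    for order in permutations(diff):
        cur, s, n, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if code[nxt] == "*" and not allow_stop_paths:
                ok = False
                break
            s += code[nxt] == code[cur] and code[nxt] != "*"
            n += code[nxt] != code[cur] or code[nxt] == "*"
            cur = nxt
        if ok:
            totals.append((s, n))
    if not totals:  # every pathway crosses a stop: fall back to all pathways
        return _pathway_counts(ca, cb, code, allow_stop_paths=True)
    return (
        sum(t[0] for t in totals) / len(totals),
        sum(t[1] for t in totals) / len(totals),
    )


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - 4p/3), valid for p < 3/4."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        raise SaturationError(f"p = {p} is at or beyond saturation (3/4)")
    return 0.0 if p == 0 else -0.75 * math.log(1 - 4 * p / 3)


def ng86_pair(
    aln: CodonAlignment,
    code: dict[str, str] | None = None,
    stop_policy: str = "exclude",
) -> KaKsResult:
    """Nei-Gojobori Ka/Ks for one codon-aligned pair.

    Site totals are averaged over the two sequences; differences are
    averaged over shortest substitution pathways.  Saturated proportions
    (p >= 3/4) leave the corrected rate undefined and set a flag.
    """
    code = STANDARD_CODE if code is None else code
    s_a = s_b = n_a = n_b = sd = nd = 0.0
    for ca, cb in aln.codons():
        sa, na = ng86_sites(ca, code, stop_policy)
        sb, nb = ng86_sites(cb, code, stop_policy)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        ds, dn = _pathway_counts(ca, cb, code, allow_stop_paths=False)
        sd += ds
        nd += dn
    S = (s_a + s_b) / 2
    N = (n_a + n_b) / 2
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    sat_s = pS >= 0.75
    sat_n = pN >= 0.75
    Ks = None if sat_s else jukes_cantor(pS)
    Ka = None if sat_n else jukes_cantor(pN)
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    return KaKsResult(
        S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN,
        Ka=Ka, Ks=Ks, ratio=ratio,
        saturated_s=sat_s, saturated_n=sat_n,
    )
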