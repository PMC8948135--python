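"""Nucleotide composition, strand skews, and codon-usage statistics.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C) are the standard
signed measures of strand compositional asymmetry; a negative AT-skew means
Ts outnumber As on the reported strand.  RSCU (relative synonymous codon
usage) is the observed count of a codon divided by its expectation were all
codons of its synonymous family used equally.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio.Data import CodonTable

__all__ = [
    "CompositionStats",
    "RSCUTable",
    "composition_stats",
    "skew_from_percentages",
    "rscu",
    "synonymous_families",
]


@dataclass(frozen=True)
class CompositionStats:
    counts: dict[str, int]
    a_pct: float
    t_pct: float
    g_pct: float
    c_pct: float
    at_content: float
    gc_content: float
    at_skew: float | None  # None when A+T == 0
    gc_skew: float | None  # None when G+C == 0


def _skew(x: float, y: float) -> float | None:
    return None if x + y == 0 else (x - y) / (x + y)


def composition_stats(seq: str) -> CompositionStats:
    """Base counts, percentages and skews of a nucleotide sequence.

    Ns are counted but excluded from every denominator.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = Counter(seq)
    bad = set(counts) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    a, t, g, c = counts["A"], counts["T"], counts["G"], counts["C"]
    denom = a + t + g + c
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    pct = {b: 100.0 * counts[b] / denom for b in "ATGC"}
    return CompositionStats(
        counts=dict(counts),
        a_pct=pct["A"], t_pct=pct["T"], g_pct=pct["G"], c_pct=pct["C"],
        at_content=pct["A"] + pct["T"],
        gc_content=pct["G"] + pct["C"],
        at_skew=_skew(a, t),
        gc_skew=_skew(g, c),
    )


def skew_from_percentages(
    a_pct: float, t_pct: float, g_pct: float, c_pct: float
) -> tuple[float | None, float | None]:
    """Skews straight from (possibly rounded) printed percentages.

    No re-normalization: the published percentages are used as given.
    """
    if min(a_pct, t_pct, g_pct, c_pct) < 0:
        raise ValueError("percentages must be non-negative")
    return _skew(a_pct, t_pct), _skew(g_pct, c_pct)


# ---------------------------------------------------------------------------
# RSCU under the invertebrate mitochondrial genetic code (NCBI table 5)

_INVERT_MITO = CodonTable.unambiguous_dna_by_id[5]


def synonymous_families(table_id: int = 5) -> dict[str, tuple[str, ...]]:
    """Synonymous codon families keyed by member codon.

    Families group sense codons by (amino acid, first two codon bases), so
    six-fold amino acids split into their two-fold NNR and four-fold NNN
    boxes (e.g. Leu(UUR) vs Leu(CUN)) — the convention of codon-usage tables
    reported for mitogenomes.
    """
    tab = CodonTable.unambiguous_dna_by_id[table_id]
    groups: dict[tuple[str, str], list[str]] = {}
    for codon, aa in tab.forward_table.items():
        groups.setdefault((aa, codon[:2]), []).append(codon)
    fam: dict[str, tuple[str, ...]] = {}
    for members in groups.values():
        members_t = tuple(sorted(members))
        for codon in members_t:
            fam[codon] = members_t
    return fam


@dataclass(frozen=True)
class RSCUTable:
    """Per-codon observed counts and RSCU values (stop codons excluded)."""

    counts: dict[str, int]
    rscu: dict[str, float]

    def of(self, codon: str) -> float:
        return self.rscu[codon.upper().replace("U", "T")]


def rscu(cds_list: list[str], table_id: int = 5) -> RSCUTable:
    """RSCU over a set of coding sequences.

    Incomplete terminal codons (1–2 trailing bases from truncated stops) are
    trimmed per sequence.  RSCU(c) = count(c) * family_size / family_total;
    codons of an entirely unused family carry RSCU 0 by convention.
    """
    if not cds_list:
        raise ValueError("empty CDS list")
    fam = synonymous_families(table_id)
    counts: Counter[str] = Counter()
    for cds in cds_list:
        cds = cds.upper().replace("U", "T")
        cds = cds[: len(cds) - len(cds) % 3]
        if not cds:
            raise ValueError("CDS shorter than one codon")
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if codon in fam:  # sense codons only
                counts[codon] += 1
    values: dict[str, float] = {}
    for codon, members in fam.items():
        family_total = sum(counts[m] for m in members)
        if family_total == 0:
            values[codon] = 0.0
        else:
            values[codon] = counts[codon] * len(members) / family_total
    return RSCUTable(counts={c: counts[c] for c in fam}, rscu=values)
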