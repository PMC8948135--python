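"""Mitogenome feature-annotation tables and their derived statistics.

A metazoan mitochondrial genome is a small circular molecule carrying a
near-invariant inventory: 13 protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs
and one large non-coding control region (CR).  An annotation table records,
for each feature, its 1-based inclusive coordinate interval on the circle,
its strand, and (for PCGs) start/stop codons.  From the table alone one can
derive the statistics conventionally reported for a new mitogenome:
intergenic spacers, gene overlaps, and per-category partition lengths.

Coordinates follow the 1-based fully-closed convention of published feature
tables; converters to 0-based half-open slices exist only at I/O boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

PCG_NAMES = frozenset(
    ["cox1", "cox2", "cox3", "nad1", "nad2", "nad3", "nad4", "nad4L",
     "nad5", "nad6", "atp6", "atp8", "cob"]
)
RRNA_NAMES = frozenset(["rrnS", "rrnL"])
TRNA_AA = ["A", "R", "N", "D", "C", "Q", "E", "G", "H", "I", "K", "M",
           "F", "P", "T", "W", "Y", "V", "S1", "S2", "L1", "L2"]
TRNA_NAMES = frozenset("trn" + aa for aa in TRNA_AA)
CR_NAMES = frozenset(["CR"])
ALL_GENE_NAMES = PCG_NAMES | RRNA_NAMES | TRNA_NAMES | CR_NAMES

CATEGORIES = ("PCG", "tRNA", "rRNA", "control_region")

#: category implied by a feature name
def category_of(name: str) -> str:
    if name in PCG_NAMES:
        return "PCG"
    if name in TRNA_NAMES:
        return "tRNA"
    if name in RRNA_NAMES:
        return "rRNA"
    if name in CR_NAMES:
        return "control_region"
    raise ValueError(f"unknown gene name: {name!r}")


class AnnotationError(ValueError):
    """Raised when a feature table violates a structural invariant."""


@dataclass(frozen=True)
class GeneFeature:
    """One named, stranded interval on a circular genome (1-based, closed)."""

    name: str
    category: str
    start: int
    end: int
    strand: str
    start_codon: str | None = None
    stop_codon: str | None = None
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.name not in ALL_GENE_NAMES:
            raise AnnotationError(f"feature {self.name!r}: name not in controlled vocabulary")
        if self.category != category_of(self.name):
            raise AnnotationError(
                f"feature {self.name!r}: category {self.category!r} inconsistent with name"
            )
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"feature {self.name!r}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"feature {self.name!r}: strand must be '+' or '-'")
        is_pcg = self.category == "PCG"
        if is_pcg and (self.start_codon is None or self.stop_codon is None):
            raise AnnotationError(f"PCG {self.name!r} must carry start and stop codons")
        if not is_pcg and (self.start_codon is not None or self.stop_codon is not None):
            raise AnnotationError(f"non-PCG {self.name!r} must not carry codons")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def slice0(self) -> slice:
        """0-based half-open slice for sequence extraction."""
        return slice(self.start - 1, self.end)


@dataclass(frozen=True)
class AnnotationTable:
    """A validated, start-sorted feature table for one circular genome."""

    genome_length: int
    features: tuple[GeneFeature, ...]

    def __post_init__(self) -> None:
        feats = tuple(sorted(self.features, key=lambda f: f.start))
        object.__setattr__(self, "features", feats)
        names = [f.name for f in feats]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise AnnotationError(f"duplicate feature names: {dupes}")
        for f in feats:
            if f.end > self.genome_length:
                raise AnnotationError(
                    f"feature {f.name!r} ends at {f.end} beyond genome length {self.genome_length}"
                )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_category(self, category: str) -> tuple[GeneFeature, ...]:
        return tuple(f for f in self.features if f.category == category)


@dataclass(frozen=True)
class SpacerRecord:
    upstream: str
    downstream: str
    gap: int  # signed: >0 spacer, <0 overlap, 0 abutting
    closing: bool = False  # the origin-spanning last->first pair


@dataclass(frozen=True)
class SpacerReport:
    """Intergenic spacer / gene-overlap accounting over consecutive pairs.

    One record per consecutive-by-start pair plus the circular closing pair
    (last feature back to the first across the origin, flagged
    ``closing``).  The signed gap for a pair is
    ``downstream.start - upstream.end - 1``.  The summary properties follow
    the convention of published feature tables, whose intergenic-length
    column covers only the linear pairs: the closing record is kept in
    ``records`` but excluded from the counts and totals.
    """

    records: tuple[SpacerRecord, ...]

    def _linear_gaps(self) -> list[int]:
        return [r.gap for r in self.records if not r.closing]

    @property
    def n_spacers(self) -> int:
        return sum(1 for g in self._linear_gaps() if g > 0)

    @property
    def total_spacer_bp(self) -> int:
        return sum(g for g in self._linear_gaps() if g > 0)

    @property
    def min_spacer(self) -> int | None:
        gaps = [g for g in self._linear_gaps() if g > 0]
        return min(gaps) if gaps else None

    @property
    def max_spacer(self) -> int | None:
        gaps = [g for g in self._linear_gaps() if g > 0]
        return max(gaps) if gaps else None

    @property
    def n_overlaps(self) -> int:
        return sum(1 for g in self._linear_gaps() if g < 0)

    @property
    def total_overlap_bp(self) -> int:
        return sum(-g for g in self._linear_gaps() if g < 0)

    @property
    def max_overlap_bp(self) -> int | None:
        ovl = [-g for g in self._linear_gaps() if g < 0]
        return max(ovl) if ovl else None

    def overlapping_pairs(self) -> list[tuple[str, str, int]]:
        return [(r.upstream, r.downstream, -r.gap)
                for r in self.records if r.gap < 0 and not r.closing]

    def intergenic_column(self) -> list[int]:
        """The signed per-pair gaps as a feature table prints them
        (linear pairs only, in start order)."""
        return self._linear_gaps()


def spacer_overlap_report(table: AnnotationTable) -> SpacerReport:
    """Signed gaps between consecutive features, including the origin-spanning pair."""
    feats = table.features
    records = []
    for up, down in zip(feats, feats[1:]):
        records.append(SpacerRecord(up.name, down.name, down.start - up.end - 1))
    if len(feats) > 1:
        last, first = feats[-1], feats[0]
        closing = table.genome_length - last.end + first.start - 1
        records.append(SpacerRecord(last.name, first.name, closing, closing=True))
    return SpacerReport(tuple(records))


def partition_lengths(table: AnnotationTable) -> dict[str, int]:
    """Total bp per feature category; overlapping bp counted once per feature."""
    out: dict[str, int] = {}
    for f in table.features:
        out[f.category] = out.get(f.category, 0) + f.length
    return out


# ---------------------------------------------------------------------------
# table I/O: tab-separated, header row, "." for absent values

_COLUMNS = ["name", "category", "start", "end", "strand",
            "start_codon", "stop_codon", "anticodon"]
_GENOME_LENGTH_RE = re.compile(r"^#\s*genome_length\s*=\s*(\d+)\s*$")


def read_annotation(path: str | Path) -> AnnotationTable:
    """Parse a tab-separated feature table.

    A comment line ``# genome_length=N`` fixes the circular genome length;
    without it the maximum feature end is used.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    genome_length: int | None = None
    rows: list[tuple[int, list[str]]] = []
    header: list[str] | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        m = _GENOME_LENGTH_RE.match(line)
        if m:
            genome_length = int(m.group(1))
            continue
        if line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = [p.strip() for p in parts]
            if header != _COLUMNS:
                raise AnnotationError(
                    f"line {lineno}: expected header {_COLUMNS}, got {header}"
                )
            continue
        rows.append((lineno, parts))
    if header is None or not rows:
        raise AnnotationError(f"{path}: no feature rows found")

    feats = []
    for lineno, parts in rows:
        if len(parts) != len(_COLUMNS):
            raise AnnotationError(f"line {lineno}: expected {len(_COLUMNS)} columns, got {len(parts)}")
        rec = dict(zip(_COLUMNS, (p.strip() for p in parts)))
        try:
            start, end = int(rec["start"]), int(rec["end"])
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: non-integral coordinates") from exc
        opt = {k: (None if rec[k] in (".", "") else rec[k])
               for k in ("start_codon", "stop_codon", "anticodon")}
        try:
            feats.append(GeneFeature(rec["name"], rec["category"], start, end,
                                     rec["strand"], **opt))
        except AnnotationError as exc:
            raise AnnotationError(f"line {lineno}: {exc}") from exc
    if genome_length is None:
        genome_length = max(f.end for f in feats)
    return AnnotationTable(genome_length, tuple(feats))


def write_annotation(table: AnnotationTable, path: str | Path) -> None:
    path = Path(path)
    out = [f"# genome_length={table.genome_length}", "\t".join(_COLUMNS)]
    for f in table.features:
        out.append("\t".join([
            f.name, f.category, str(f.start), str(f.end), f.strand,
            f.start_codon or ".", f.stop_codon or ".", f.anticodon or ".",
        ]))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# codon inventory

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def codon_inventory(
    table: AnnotationTable, seq: str
) -> tuple[dict[str, str], dict[str, str]]:
    """First codon and trailing (possibly truncated) stop for every PCG.

    Minus-strand PCGs are reverse-complemented before reading.  A PCG length
    of ``3k`` yields a full triplet stop, ``3k+1`` a single-base stop and
    ``3k+2`` a two-base stop — the truncated forms completed in vivo by
    polyadenylation of the transcript.
    """
    seq = seq.upper()
    starts: dict[str, str] = {}
    stops: dict[str, str] = {}
    for f in table.by_category("PCG"):
        if f.length < 6:
            raise AnnotationError(f"PCG {f.name!r} shorter than 6 nt")
        sub = seq[f.slice0()]
        if f.strand == "-":
            sub = revcomp(sub)
        starts[f.name] = sub[:3]
        rem = f.length % 3
        stops[f.name] = sub[-3:] if rem == 0 else sub[-rem:]
    return starts, stops
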