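"""Signed circular gene-order algebra.

A mitochondrial gene arrangement is a circular sequence of oriented genes.
Because the molecule has no distinguished origin and can be read from either
strand, two orders are the same arrangement iff one is a rotation of the
other or of its reflection (reverse the sequence and flip every
orientation).  Canonical form quotients by both: rotate the anchor gene
(cox1 by default) to the front and, if the anchor is on the minus strand,
reflect the whole order first.

Breakpoint distance is computed on signed gene extremities: every gene
contributes a tail (5') and head (3') end, an adjacency joins the two ends
that meet between circular neighbours, and the distance between two orders
over the same gene set is  n - shared_adjacencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from .annotation import AnnotationTable

DEFAULT_ANCHOR = "cox1"


class SignedGene(NamedTuple):
    label: str
    orientation: int  # +1 or -1

    def flipped(self) -> "SignedGene":
        return SignedGene(self.label, -self.orientation)

    def __str__(self) -> str:
        return self.label if self.orientation > 0 else "-" + self.label


def parse_signed_gene(token: str) -> SignedGene:
    token = token.strip()
    if not token or token in ("-", "+"):
        raise ValueError(f"bad gene token: {token!r}")
    if token.startswith("-"):
        return SignedGene(token[1:].strip(), -1)
    if token.startswith("+"):
        return SignedGene(token[1:].strip(), +1)
    return SignedGene(token, +1)


@dataclass(frozen=True)
class SignedGeneOrder:
    """A circular (or, for dimer monomers, linear) sequence of signed genes."""

    genes: tuple[SignedGene, ...]
    circular: bool = True
    anchor: str = DEFAULT_ANCHOR
    history: tuple = field(default=(), compare=False, repr=False)

    def __post_init__(self) -> None:
        labels = [g.label for g in self.genes]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate gene labels: {dupes}")
        for g in self.genes:
            if not g.label:
                raise ValueError("empty gene label")
            if g.orientation not in (+1, -1):
                raise ValueError(f"bad orientation for {g.label!r}")

    # -- basic views --------------------------------------------------------
    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def labels(self) -> tuple[str, ...]:
        return tuple(g.label for g in self.genes)

    def label_set(self) -> frozenset[str]:
        return frozenset(g.label for g in self.genes)

    def index_of(self, label: str) -> int:
        for i, g in enumerate(self.genes):
            if g.label == label:
                return i
        raise KeyError(label)

    # -- transforms ---------------------------------------------------------
    def with_genes(self, genes: Iterable[SignedGene], event=None) -> "SignedGeneOrder":
        hist = self.history + (event,) if event is not None else self.history
        return SignedGeneOrder(tuple(genes), self.circular, self.anchor, hist)

    def rotated(self, k: int) -> "SignedGeneOrder":
        if not self.circular:
            raise ValueError("cannot rotate a linear order")
        n = len(self.genes)
        k %= n
        return self.with_genes(self.genes[k:] + self.genes[:k])

    def reflected(self) -> "SignedGeneOrder":
        """The same molecule read from the other strand."""
        return self.with_genes(tuple(g.flipped() for g in reversed(self.genes)))

    def restricted(self, keep: frozenset[str]) -> "SignedGeneOrder":
        return self.with_genes(tuple(g for g in self.genes if g.label in keep))

    def strand_homogeneity(self) -> float:
        """Fraction of genes on the majority strand (0.5..1)."""
        if not self.genes:
            raise ValueError("empty order")
        plus = sum(1 for g in self.genes if g.orientation > 0)
        return max(plus, len(self.genes) - plus) / len(self.genes)


def canonicalize(order: SignedGeneOrder) -> SignedGeneOrder:
    """Rotation/reflection-invariant normal form: anchor first, + oriented.

    Idempotent; raises KeyError if the anchor label is absent.
    """
    if not order.circular:
        raise ValueError("canonical form is defined for circular orders")
    i = order.index_of(order.anchor)
    if order.genes[i].orientation < 0:
        order = order.reflected()
        i = order.index_of(order.anchor)
    return order.rotated(i)


def orders_equal(a: SignedGeneOrder, b: SignedGeneOrder) -> bool:
    """Equality of circular arrangements up to rotation and reflection."""
    if a.label_set() != b.label_set():
        return False
    anchor = a.anchor if a.anchor in a.label_set() else next(iter(a.labels()))
    ca = canonicalize(SignedGeneOrder(a.genes, True, anchor))
    cb = canonicalize(SignedGeneOrder(b.genes, True, anchor))
    return ca.genes == cb.genes


def from_annotation(table: AnnotationTable, anchor: str = DEFAULT_ANCHOR) -> SignedGeneOrder:
    """Gene order read off an annotation table in start-coordinate order."""
    genes = tuple(
        SignedGene(f.name, +1 if f.strand == "+" else -1) for f in table.features
    )
    return SignedGeneOrder(genes, circular=True, anchor=anchor)


# ---------------------------------------------------------------------------
# adjacencies and distances

def _ends(g: SignedGene) -> tuple[tuple[str, str], tuple[str, str]]:
    """(left end, right end) of a gene as laid on the circle."""
    tail, head = (g.label, "t"), (g.label, "h")
    return (tail, head) if g.orientation > 0 else (head, tail)


def adjacencies(order: SignedGeneOrder) -> frozenset[frozenset[tuple[str, str]]]:
    """Oriented gene-end adjacencies of a circular order (n genes -> n pairs)."""
    if not order.circular:
        raise ValueError("adjacencies are defined for circular orders")
    n = len(order.genes)
    out = set()
    for i in range(n):
        _, right = _ends(order.genes[i])
        left, _ = _ends(order.genes[(i + 1) % n])
        out.add(frozenset((right, left)))
    return frozenset(out)


@dataclass(frozen=True)
class DistanceReport:
    breakpoint_distance: int
    shared_adjacencies: int
    common_labels: frozenset[str]
    strand_homogeneity_a: float
    strand_homogeneity_b: float

    @property
    def strand_homogeneity(self) -> float:
        return min(self.strand_homogeneity_a, self.strand_homogeneity_b)


def distance(a: SignedGeneOrder, b: SignedGeneOrder) -> DistanceReport:
    """Breakpoint distance between two circular orders.

    Orders with unequal label sets are restricted to their intersection
    (recorded in the report) before comparison.
    """
    common = a.label_set() & b.label_set()
    if not common:
        raise ValueError("orders share no gene labels")
    ra, rb = a.restricted(common), b.restricted(common)
    shared = len(adjacencies(ra) & adjacencies(rb))
    return DistanceReport(
        breakpoint_distance=len(common) - shared,
        shared_adjacencies=shared,
        common_labels=common,
        strand_homogeneity_a=ra.strand_homogeneity(),
        strand_homogeneity_b=rb.strand_homogeneity(),
    )


# ---------------------------------------------------------------------------
# one-gene-per-line text format

def read_order(path: str | Path, circular: bool = True,
               anchor: str = DEFAULT_ANCHOR) -> SignedGeneOrder:
    """Read a gene order: one gene per line, leading '-' for minus strand,
    '#' comments and blank lines ignored."""
    genes = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            genes.append(parse_signed_gene(line))
    if not genes:
        raise ValueError(f"{path}: no genes found")
    return SignedGeneOrder(tuple(genes), circular=circular, anchor=anchor)


def read_gene_list(path: str | Path) -> tuple[SignedGene, ...]:
    """Read a raw signed gene list without the unique-label invariant.

    Used for verbatim transcriptions of published lists, which may carry
    typographic anomalies (duplicated or missing labels) that a validated
    SignedGeneOrder would reject.
    """
    genes = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            genes.append(parse_signed_gene(line))
    if not genes:
        raise ValueError(f"{path}: no genes found")
    return tuple(genes)


def write_order(order: SignedGeneOrder, path: str | Path,
                header: str | None = None) -> None:
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    lines.extend(str(g) for g in order.genes)
    Path(path).write_text("\n".join(lines) + "\n")
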