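"""Rearrangement operators on signed circular gene orders.

The operators model the mechanisms invoked for mitogenome gene-order
evolution:

* ``duplicate_genome`` — tandem duplication of the whole molecule into a
  head-to-tail circular dimer of two identical monomers;
* ``polarity_loss`` — non-random loss: from one monomer all genes of one
  transcriptional polarity are deleted, from the other monomer all genes of
  the opposite polarity, so each gene survives exactly once;
* ``recombination_join`` — 3'-3' fusion of the two surviving monomers: the
  second monomer's gene sequence is reversed and its transcription polarity
  flipped, so a +-polarity monomer 1 and a −-polarity monomer 2 fuse into a
  single-stranded circular product;
* ``tdrl_translocate`` — tandem duplication–random loss of a contiguous
  segment: the segment is duplicated in tandem and one copy of each
  duplicated gene deleted, which can permute genes within the segment but
  never changes an orientation;
* ``invert`` — reversal of a contiguous segment with orientation flip.

All operators are pure; derived orders carry an event provenance log.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping

from .gene_order import SignedGene, SignedGeneOrder

EVENT_KINDS = (
    "whole_genome_duplication",
    "polarity_loss",
    "random_loss",
    "recombination_join",
    "inversion",
    "tdrl_translocation",
)


@dataclass(frozen=True)
class RearrangementEvent:
    """One algebraic transformation step with kind-specific parameters."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind: {self.kind!r}")


@dataclass(frozen=True)
class TaggedGene:
    gene: SignedGene
    copy: int  # 1 or 2


@dataclass(frozen=True)
class DimerOrder:
    """Circular head-to-tail dimer: every gene label present exactly twice."""

    genes: tuple[TaggedGene, ...]
    anchor: str
    history: tuple = field(default=(), compare=False, repr=False)

    def __post_init__(self) -> None:
        labels = [t.gene.label for t in self.genes]
        for l in set(labels):
            if labels.count(l) != 2:
                raise ValueError(f"dimer must carry {l!r} exactly twice")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class MonomerPair:
    """The two linear monomers left after loss, before recombination."""

    monomer1: SignedGeneOrder
    monomer2: SignedGeneOrder
    history: tuple = field(default=(), compare=False, repr=False)


def duplicate_genome(order: SignedGeneOrder,
                     event: RearrangementEvent | None = None) -> DimerOrder:
    """Tandem duplication of the entire genome into a circular dimer.

    The dimer is linearized (cut) at the order's start, so monomer copies
    run in the order the input was written in.
    """
    tagged = tuple(TaggedGene(g, 1) for g in order.genes) + tuple(
        TaggedGene(g, 2) for g in order.genes
    )
    hist = order.history + ((event,) if event else ())
    return DimerOrder(tagged, order.anchor, hist)


def polarity_loss(dimer: DimerOrder,
                  polarity_rule: Mapping[str, int] | None = None,
                  event: RearrangementEvent | None = None) -> MonomerPair:
    """Non-random loss predetermined by transcriptional polarity.

    ``polarity_rule`` maps orientation ('+'/'-') to the monomer copy (1/2)
    that KEEPS genes of that orientation; it must be a bijection.  Relative
    order within each surviving monomer is preserved; each gene label
    survives exactly once across the two monomers.
    """
    rule = dict(polarity_rule or {"+": 1, "-": 2})
    if set(rule.keys()) != {"+", "-"} or set(rule.values()) != {1, 2}:
        raise ValueError("polarity rule must biject {'+','-'} onto {1,2}")
    keep = {(+1): rule["+"], (-1): rule["-"]}
    half = len(dimer.genes) // 2
    monomers: dict[int, list[SignedGene]] = {1: [], 2: []}
    for i, tg in enumerate(dimer.genes):
        copy = tg.copy
        if keep[tg.gene.orientation] == copy:
            monomers[copy].append(tg.gene)
    hist = dimer.history + ((event,) if event else ())
    m1 = SignedGeneOrder(tuple(monomers[1]), circular=False, anchor=dimer.anchor)
    m2 = SignedGeneOrder(tuple(monomers[2]), circular=False, anchor=dimer.anchor)
    return MonomerPair(m1, m2, hist)


def recombination_join(m1: SignedGeneOrder, m2: SignedGeneOrder,
                       mode: str = "3p-3p",
                       event: RearrangementEvent | None = None) -> SignedGeneOrder:
    """Fuse two linear monomers into one circular molecule.

    Under the 3'-3' mode the second monomer's gene sequence is reversed and
    every orientation in it flipped (its transcription polarity is
    reversed); the two lists are then concatenated and circularized.  With
    an all-+ monomer 1 and an all-− monomer 2 the product is entirely +.
    """
    if mode != "3p-3p":
        raise ValueError(f"unknown join mode: {mode!r}")
    if m1.label_set() & m2.label_set():
        raise ValueError("monomers share gene labels")
    m2_part = tuple(g.flipped() for g in reversed(m2.genes))
    hist = m1.history + ((event,) if event else ())
    return SignedGeneOrder(m1.genes + m2_part, circular=True,
                           anchor=m1.anchor, history=hist)


# ---------------------------------------------------------------------------
# segment helpers

def _segment_indices(order: SignedGeneOrder, first: str, last: str) -> list[int]:
    """Indices of the contiguous circular span from `first` to `last` inclusive."""
    n = len(order.genes)
    i = order.index_of(first)
    idx = [i]
    while order.genes[idx[-1]].label != last:
        idx.append((idx[-1] + 1) % n)
        if len(idx) > n:
            raise ValueError(f"span {first!r}..{last!r} does not close")
    if not order.circular and idx and max(idx) - min(idx) + 1 != len(idx):
        raise ValueError("span wraps around a linear order")
    return idx


def tdrl_translocate(order: SignedGeneOrder, segment: tuple[str, str],
                     loss_pattern: Mapping[str, int] | None = None,
                     seed: int | None = None,
                     event: RearrangementEvent | None = None) -> SignedGeneOrder:
    """Tandem duplication–random loss over a contiguous circular span.

    The span from ``segment[0]`` to ``segment[1]`` (inclusive) is duplicated
    in tandem; ``loss_pattern`` maps each gene in the span to the copy (1 or
    2) that is KEPT.  Without an explicit pattern, kept copies are drawn
    uniformly using ``seed``.  Gene content is conserved and no orientation
    ever changes; only genes inside the span can move.
    """
    idx = _segment_indices(order, segment[0], segment[1])
    span = [order.genes[i] for i in idx]
    span_labels = [g.label for g in span]
    if loss_pattern is None:
        rng = random.Random(seed)
        loss_pattern = {l: rng.choice((1, 2)) for l in span_labels}
    extra = set(loss_pattern) - set(span_labels)
    missing = set(span_labels) - set(loss_pattern)
    if extra or missing:
        raise ValueError(
            f"loss pattern must cover the span exactly (extra={sorted(extra)}, "
            f"missing={sorted(missing)})"
        )
    if any(v not in (1, 2) for v in loss_pattern.values()):
        raise ValueError("loss pattern must keep copy 1 or copy 2 of each gene")

    kept_tandem = [g for g in span if loss_pattern[g.label] == 1] + [
        g for g in span if loss_pattern[g.label] == 2
    ]
    new_genes = list(order.genes)
    for pos, i in enumerate(idx):
        new_genes[i] = kept_tandem[pos]
    hist = (event,) if event else ()
    return SignedGeneOrder(tuple(new_genes), order.circular, order.anchor,
                           order.history + hist)


def invert(order: SignedGeneOrder, segment: tuple[str, str],
           event: RearrangementEvent | None = None) -> SignedGeneOrder:
    """Reverse a contiguous span and flip every orientation inside it.

    The span runs from ``segment[0]`` to ``segment[1]`` in reading
    direction; after an inversion the same physical span is therefore
    addressed with its endpoints swapped.
    """
    idx = _segment_indices(order, segment[0], segment[1])
    span = [order.genes[i] for i in idx]
    flipped = [g.flipped() for g in reversed(span)]
    new_genes = list(order.genes)
    for pos, i in enumerate(idx):
        new_genes[i] = flipped[pos]
    hist = (event,) if event else ()
    return SignedGeneOrder(tuple(new_genes), order.circular, order.anchor,
                           order.history + hist)


# ---------------------------------------------------------------------------
# uniform dispatch

def apply_event(state, ev: RearrangementEvent):
    """Apply one event to the current state (order, dimer, or monomer pair).

    Raises TypeError on a kind/state mismatch.  The applied event is
    recorded in the result's provenance history.
    """
    if ev.kind == "whole_genome_duplication":
        if not isinstance(state, SignedGeneOrder):
            raise TypeError("whole_genome_duplication needs a SignedGeneOrder")
        return duplicate_genome(state, event=ev)
    if ev.kind == "polarity_loss":
        if not isinstance(state, DimerOrder):
            raise TypeError("polarity_loss needs a DimerOrder")
        return polarity_loss(state, ev.params.get("rule"), event=ev)
    if ev.kind == "recombination_join":
        if not isinstance(state, MonomerPair):
            raise TypeError("recombination_join needs a MonomerPair")
        return recombination_join(state.monomer1, state.monomer2,
                                  ev.params.get("mode", "3p-3p"), event=ev)
    if ev.kind in ("tdrl_translocation", "random_loss"):
        if not isinstance(state, SignedGeneOrder):
            raise TypeError(f"{ev.kind} needs a SignedGeneOrder")
        segment = tuple(ev.params["segment"])
        pattern = ev.params.get("keep")
        if pattern is not None:
            default = ev.params.get("default_keep")
            if default is not None:
                idx = _segment_indices(state, segment[0], segment[1])
                full = {state.genes[i].label: default for i in idx}
                full.update(pattern)
                pattern = full
        return tdrl_translocate(state, segment, pattern, ev.seed, event=ev)
    if ev.kind == "inversion":
        if not isinstance(state, SignedGeneOrder):
            raise TypeError("inversion needs a SignedGeneOrder")
        return invert(state, tuple(ev.params["segment"]), event=ev)
    raise ValueError(f"unknown event kind: {ev.kind!r}")
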