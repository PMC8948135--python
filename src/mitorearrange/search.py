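"""Brute-force enumeration of single rearrangement events.

Given a source and a target order over the same genes, enumerate every
single TDRL (segment + loss pattern) or inversion (segment) applicable to
the source, deduplicate by the resulting canonical arrangement, and flag
the candidates that reach the target.  Intended for small orders: TDRL
candidates grow as span * 2^span, inversions as n^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .gene_order import SignedGeneOrder, canonicalize, orders_equal
from .rearrange import RearrangementEvent, invert, tdrl_translocate


@dataclass(frozen=True)
class EventCandidate:
    event: RearrangementEvent
    resulting_order: SignedGeneOrder
    matches_target: bool


def _canonical_key(order: SignedGeneOrder):
    anchor = order.anchor if order.anchor in order.label_set() else order.genes[0].label
    return canonicalize(SignedGeneOrder(order.genes, True, anchor)).genes


def _check_same_labels(source: SignedGeneOrder, target: SignedGeneOrder) -> None:
    if source.label_set() != target.label_set():
        raise ValueError("source and target must share the same gene labels")


def enumerate_tdrl(source: SignedGeneOrder, target: SignedGeneOrder,
                   max_span: int = 6) -> list[EventCandidate]:
    """All single TDRL events on `source` within the span bound.

    Candidates are deduplicated by resulting canonical order (many loss
    patterns are biologically indistinguishable); each retained candidate
    records one representative event.
    """
    _check_same_labels(source, target)
    n = len(source.genes)
    if max_span > n:
        raise ValueError("max_span exceeds order size")
    seen: dict[tuple, EventCandidate] = {}
    for start in range(n):
        for span in range(1, max_span + 1):
            labels = [source.genes[(start + k) % n].label for k in range(span)]
            segment = (labels[0], labels[-1])
            for kept in product((1, 2), repeat=span):
                pattern = dict(zip(labels, kept))
                ev = RearrangementEvent("tdrl_translocation",
                                        {"segment": list(segment), "keep": pattern})
                result = tdrl_translocate(source, segment, pattern)
                key = _canonical_key(result)
                if key not in seen:
                    seen[key] = EventCandidate(ev, result,
                                               orders_equal(result, target))
    return list(seen.values())


def enumerate_inversions(source: SignedGeneOrder,
                         target: SignedGeneOrder) -> list[EventCandidate]:
    """All single segment inversions on `source`, deduplicated canonically."""
    _check_same_labels(source, target)
    n = len(source.genes)
    seen: dict[tuple, EventCandidate] = {}
    for start in range(n):
        for span in range(1, n + 1):
            first = source.genes[start].label
            last = source.genes[(start + span - 1) % n].label
            ev = RearrangementEvent("inversion", {"segment": [first, last]})
            result = invert(source, (first, last))
            key = _canonical_key(result)
            if key not in seen:
                seen[key] = EventCandidate(ev, result,
                                           orders_equal(result, target))
    return list(seen.values())


def matching_candidates(cands: list[EventCandidate]) -> list[EventCandidate]:
    return [c for c in cands if c.matches_target]
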