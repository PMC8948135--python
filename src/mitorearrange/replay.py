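"""Scenario replay: run an ordered event list and verify the outcome.

A Scenario packages a start order, an event sequence, optional expected
intermediates, and a target order.  Replaying applies the events in turn
(checking that each event kind matches the current state kind), logs every
intermediate, and compares the final circular order with the target by
rotation/reflection-invariant canonical form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .gene_order import (
    SignedGene,
    SignedGeneOrder,
    canonicalize,
    orders_equal,
    read_order,
)
from .rearrange import (
    DimerOrder,
    MonomerPair,
    RearrangementEvent,
    apply_event,
)


@dataclass(frozen=True)
class Scenario:
    start_order: SignedGeneOrder
    events: tuple[RearrangementEvent, ...]
    target_order: SignedGeneOrder
    expected_intermediates: tuple[tuple[int, SignedGeneOrder], ...] = ()
    name: str = ""


@dataclass(frozen=True)
class Mismatch:
    position: int
    expected: str
    observed: str


@dataclass(frozen=True)
class LabelSetDiff:
    missing: tuple[str, ...]  # in a but not b
    extra: tuple[str, ...]    # in b but not a


@dataclass(frozen=True)
class StepRecord:
    index: int  # 0 = start state; i = state after event i
    kind: str
    state: object
    intermediate_diff: tuple[Mismatch, ...] | LabelSetDiff | None = None


@dataclass(frozen=True)
class ReplayResult:
    steps: tuple[StepRecord, ...]
    final_order: SignedGeneOrder | None
    final_match: bool
    mismatches: tuple[Mismatch, ...] | LabelSetDiff

    @property
    def final_strand_homogeneity(self) -> float:
        if self.final_order is None:
            raise ValueError("scenario did not end in a single circular order")
        return self.final_order.strand_homogeneity()


def _as_genes(x) -> tuple[SignedGene, ...]:
    if isinstance(x, SignedGeneOrder):
        return x.genes
    return tuple(x)


def diff_orders(a, b) -> tuple[Mismatch, ...] | LabelSetDiff:
    """Positional differences between two gene lists / circular orders.

    For equal label sets both sides are canonicalized (circular orders) or
    compared as-is (raw lists), and per-position mismatches are returned —
    empty iff the arrangements are equal.  For unequal label sets a
    LabelSetDiff of missing/extra labels (as multisets) is returned instead.
    """
    ga, gb = _as_genes(a), _as_genes(b)
    la, lb = [g.label for g in ga], [g.label for g in gb]
    if sorted(la) != sorted(lb):
        missing = sorted(_multiset_minus(la, lb))
        extra = sorted(_multiset_minus(lb, la))
        return LabelSetDiff(tuple(missing), tuple(extra))
    if isinstance(a, SignedGeneOrder) and isinstance(b, SignedGeneOrder) \
            and a.circular and b.circular:
        anchor = a.anchor if a.anchor in a.label_set() else la[0]
        ga = canonicalize(SignedGeneOrder(ga, True, anchor)).genes
        gb = canonicalize(SignedGeneOrder(gb, True, anchor)).genes
    out = [
        Mismatch(i, str(x), str(y))
        for i, (x, y) in enumerate(zip(ga, gb))
        if x != y
    ]
    return tuple(out)


def _multiset_minus(xs: list[str], ys: list[str]) -> list[str]:
    ys = list(ys)
    out = []
    for x in xs:
        if x in ys:
            ys.remove(x)
        else:
            out.append(x)
    return out


def _state_kind(state) -> str:
    if isinstance(state, SignedGeneOrder):
        return "order"
    if isinstance(state, DimerOrder):
        return "dimer"
    if isinstance(state, MonomerPair):
        return "monomer_pair"
    return type(state).__name__


def replay(scenario: Scenario) -> ReplayResult:
    """Apply the scenario's events in order and compare with its target."""
    state = scenario.start_order
    expected = dict(scenario.expected_intermediates)
    steps = [StepRecord(0, _state_kind(state), state,
                        _maybe_diff(expected.get(0), state))]
    for i, ev in enumerate(scenario.events, start=1):
        try:
            state = apply_event(state, ev)
        except (TypeError, ValueError, KeyError) as exc:
            raise type(exc)(f"step {i} ({ev.kind}): {exc}") from exc
        steps.append(StepRecord(i, _state_kind(state), state,
                                _maybe_diff(expected.get(i), state)))

    if isinstance(state, SignedGeneOrder) and state.circular:
        mismatches = diff_orders(state, scenario.target_order)
        final_match = mismatches == () and orders_equal(state, scenario.target_order)
        return ReplayResult(tuple(steps), state, final_match, mismatches)
    return ReplayResult(tuple(steps), None, False,
                        LabelSetDiff((), ()))


def _maybe_diff(expected, state):
    if expected is None or not isinstance(state, SignedGeneOrder):
        return None
    return diff_orders(expected, state)


# ---------------------------------------------------------------------------
# scenario files (YAML): order file paths + event list

def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario file; order paths are resolved relative to the file."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    base = path.parent

    def _order(ref) -> SignedGeneOrder:
        p = Path(ref)
        if not p.is_absolute():
            p = base / p
        return read_order(p)

    events = tuple(
        RearrangementEvent(
            kind=e["kind"],
            params={k: v for k, v in e.items()
                    if k not in ("kind", "seed", "description")},
            seed=e.get("seed"),
            description=e.get("description", ""),
        )
        for e in doc.get("events", [])
    )
    inter = tuple(
        (int(i), _order(ref))
        for i, ref in (doc.get("expected_intermediates") or {}).items()
    )
    return Scenario(
        start_order=_order(doc["start_order"]),
        events=events,
        target_order=_order(doc["target_order"]),
        expected_intermediates=inter,
        name=doc.get("name", path.stem),
    )


def save_scenario(scenario: Scenario, path: str | Path,
                  start_ref: str, target_ref: str) -> None:
    """Serialize a scenario; the order files must be written separately."""
    doc = {
        "name": scenario.name,
        "start_order": start_ref,
        "target_order": target_ref,
        "events": [
            {"kind": e.kind, **e.params,
             **({"seed": e.seed} if e.seed is not None else {}),
             **({"description": e.description} if e.description else {})}
            for e in scenario.events
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
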