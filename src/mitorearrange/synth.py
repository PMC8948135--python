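"""Synthetic mitogenomes and evolved gene orders with controlled structure.

``synth_genome`` realizes an annotation-table blueprint — feature lengths,
strands, signed inter-feature gaps, per-partition base composition, and PCG
start/stop codons — as a concrete sequence plus its exact annotation table,
deterministically per seed.  Per-partition composition is realized by
exact-count base pools (largest-remainder apportionment, then shuffling),
so partitions of realistic size land within ±1% of their targets even after
codon overwriting.

``evolve_order`` draws a random event history (inversions, TDRLs, or the
whole-genome duplication → polarity loss → 3'-3' join macro) and returns
the final order together with a fully explicit, replayable history.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotation import (
    AnnotationTable,
    GeneFeature,
    category_of,
    revcomp,
)
from .gene_order import SignedGeneOrder
from .rearrange import (
    RearrangementEvent,
    apply_event,
)

__all__ = [
    "FeaturePlan",
    "GenomeSpec",
    "EvolutionSpec",
    "synth_genome",
    "evolve_order",
    "spec_from_table",
]


@dataclass(frozen=True)
class FeaturePlan:
    name: str
    length: int
    strand: str = "+"
    start_codon: str | None = None
    stop_codon: str | None = None
    anticodon: str | None = None

    @property
    def category(self) -> str:
        return category_of(self.name)


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint for one synthetic circular mitogenome.

    ``gaps[i]`` is the signed gap following feature i (negative = overlap
    with the next feature); the last entry closes the circle back to
    position 1.  ``composition`` maps a category (or the fallback key
    ``"genome"``, used for spacers) to target (A, T, G, C) percentages.
    """

    features: tuple[FeaturePlan, ...]
    gaps: tuple[int, ...]
    composition: Mapping[str, tuple[float, float, float, float]]
    seed: int

    def __post_init__(self) -> None:
        if len(self.gaps) != len(self.features):
            raise ValueError("need one signed gap per feature (last closes the circle)")
        if any(f.length <= 0 for f in self.features):
            raise ValueError("feature lengths must be positive")
        for key, pcts in self.composition.items():
            if abs(sum(pcts) - 100.0) > 0.5:
                raise ValueError(f"composition {key!r} does not sum to 100%")
        if "genome" not in self.composition:
            raise ValueError("composition must provide a 'genome' fallback entry")


def _base_pool(length: int, pcts: Sequence[float], rng: random.Random) -> list[str]:
    """Exact-count base pool by largest-remainder apportionment, shuffled.

    Targets are treated as proportions (printed percentage rows may sum to
    99.8-100.2 after rounding), so the pool always has exactly ``length``
    bases.
    """
    total = sum(pcts)
    ideal = [length * p / total for p in pcts]
    counts = [int(x) for x in ideal]
    short = length - sum(counts)
    order = sorted(range(4), key=lambda i: ideal[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    pool = [b for b, c in zip("ATGC", counts) for _ in range(c)]
    rng.shuffle(pool)
    return pool


def synth_genome(spec: GenomeSpec) -> tuple[str, AnnotationTable]:
    """Realize a GenomeSpec as (sequence, annotation table).

    Coordinates implement the gap plan exactly; an infeasible plan (running
    coordinate below 1) raises ValueError.
    """
    rng = random.Random(spec.seed)

    # --- coordinates
    feats: list[GeneFeature] = []
    pos = 1
    for plan, gap in zip(spec.features, spec.gaps):
        if pos < 1:
            raise ValueError(f"infeasible plan: feature {plan.name!r} would start at {pos}")
        start, end = pos, pos + plan.length - 1
        feats.append(GeneFeature(plan.name, plan.category, start, end, plan.strand,
                                 plan.start_codon, plan.stop_codon, plan.anticodon))
        pos = end + gap + 1
    genome_length = feats[-1].end + spec.gaps[-1]
    if genome_length < max(f.end for f in feats):
        raise ValueError("infeasible plan: closing gap truncates the genome")

    # --- sequence: feature bodies first, spacers after, codons last
    seq = [None] * genome_length
    for plan, feat in zip(spec.features, feats):
        pcts = spec.composition.get(plan.category, spec.composition["genome"])
        body = _base_pool(feat.length, pcts, rng)
        seq[feat.start - 1 : feat.end] = body
    gap_positions = [i for i, b in enumerate(seq) if b is None]
    filler = _base_pool(len(gap_positions), spec.composition["genome"], rng)
    for i, b in zip(gap_positions, filler):
        seq[i] = b

    for feat in feats:
        if feat.category != "PCG":
            continue
        _write_codon(seq, feat, feat.start_codon, at_start=True)
        _write_codon(seq, feat, feat.stop_codon, at_start=False)

    return "".join(seq), AnnotationTable(genome_length, tuple(feats))


def _write_codon(seq: list, feat: GeneFeature, codon: str, at_start: bool) -> None:
    """Overwrite the reading-frame start codon or (possibly truncated) stop."""
    if at_start:
        piece = codon
        span = range(feat.start - 1, feat.start - 1 + 3)
    else:
        rem = feat.length % 3
        want = 3 if rem == 0 else rem
        piece = codon[:want] if len(codon) >= want else codon
        want = len(piece)
        span = range(feat.end - want, feat.end)
    if feat.strand == "-":
        piece = revcomp(piece)
        width = len(piece)
        if at_start:
            span = range(feat.end - width, feat.end)
        else:
            span = range(feat.start - 1, feat.start - 1 + width)
    for i, b in zip(span, piece):
        seq[i] = b


def spec_from_table(table: AnnotationTable,
                    composition: Mapping[str, tuple[float, float, float, float]],
                    seed: int) -> GenomeSpec:
    """Blueprint mirroring an existing annotation table (lengths, strands,
    codons and signed gaps), so the realized genome reproduces its
    coordinates exactly."""
    feats = table.features
    plans = tuple(
        FeaturePlan(f.name, f.length, f.strand, f.start_codon, f.stop_codon,
                    f.anticodon)
        for f in feats
    )
    gaps = [dn.start - up.end - 1 for up, dn in zip(feats, feats[1:])]
    gaps.append(table.genome_length - feats[-1].end + feats[0].start - 1)
    return GenomeSpec(plans, tuple(gaps), dict(composition), seed)


# ---------------------------------------------------------------------------
# evolved gene orders

@dataclass(frozen=True)
class EvolutionSpec:
    """Random rearrangement history specification.

    ``kind_probs`` weights the drawable event kinds: ``inversion``,
    ``tdrl_translocation``, and ``tdnl_rc`` (the duplication → polarity loss
    → 3'-3' join macro, which expands to three events and requires a plain
    circular order as input).  ``max_span`` bounds inversion/TDRL segment
    lengths in genes.
    """

    start: SignedGeneOrder
    n_events: int
    kind_probs: Mapping[str, float] = field(
        default_factory=lambda: {"inversion": 0.5, "tdrl_translocation": 0.5})
    max_span: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.kind_probs.values()) - 1.0) > 1e-9:
            raise ValueError("kind probabilities must sum to 1")
        bad = set(self.kind_probs) - {"inversion", "tdrl_translocation", "tdnl_rc"}
        if bad:
            raise ValueError(f"unknown event kinds: {sorted(bad)}")
        if self.n_events < 0:
            raise ValueError("n_events must be non-negative")


def _random_span(order: SignedGeneOrder, max_span: int,
                 rng: random.Random) -> tuple[str, str]:
    n = len(order.genes)
    span = rng.randint(1, max(1, min(max_span, n - 1)))
    start = rng.randrange(n)
    return (order.genes[start].label,
            order.genes[(start + span - 1) % n].label)


def evolve_order(spec: EvolutionSpec
                 ) -> tuple[SignedGeneOrder, tuple[RearrangementEvent, ...]]:
    """Draw ``n_events`` random events and apply them.

    Every drawn event is recorded with fully explicit parameters (segments
    and kept-copy patterns), so replaying the returned history from the
    start order reproduces the final order exactly, with no seeds needed.
    """
    rng = random.Random(spec.seed)
    kinds = sorted(spec.kind_probs)
    weights = [spec.kind_probs[k] for k in kinds]
    state = spec.start
    history: list[RearrangementEvent] = []
    for _ in range(spec.n_events):
        kind = rng.choices(kinds, weights=weights)[0]
        if kind == "inversion":
            seg = _random_span(state, spec.max_span, rng)
            ev = RearrangementEvent("inversion", {"segment": list(seg)})
            state = apply_event(state, ev)
            history.append(ev)
        elif kind == "tdrl_translocation":
            seg = _random_span(state, spec.max_span, rng)
            labels = _span_labels(state, seg)
            pattern = {l: rng.choice((1, 2)) for l in labels}
            ev = RearrangementEvent("tdrl_translocation",
                                    {"segment": list(seg), "keep": pattern})
            state = apply_event(state, ev)
            history.append(ev)
        else:  # tdnl_rc macro
            macro = (
                RearrangementEvent("whole_genome_duplication"),
                RearrangementEvent("polarity_loss",
                                   {"rule": {"+": 1, "-": 2}}),
                RearrangementEvent("recombination_join", {"mode": "3p-3p"}),
            )
            for ev in macro:
                state = apply_event(state, ev)
                history.append(ev)
    return state, tuple(history)


def _span_labels(order: SignedGeneOrder, segment: tuple[str, str]) -> list[str]:
    n = len(order.genes)
    i = order.index_of(segment[0])
    labels = [order.genes[i].label]
    while labels[-1] != segment[1]:
        i = (i + 1) % n
        labels.append(order.genes[i].label)
    return labels
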