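"""Rearrangement operators: duplication, polarity loss, join, TDRL, inversion."""

import random
from itertools import product

import pytest

from mitorearrange import (
    RearrangementEvent,
    SignedGene,
    SignedGeneOrder,
    apply_event,
    canonicalize,
    duplicate_genome,
    invert,
    orders_equal,
    polarity_loss,
    recombination_join,
    tdrl_translocate,
)
from mitorearrange import datasets
from conftest import random_order


def _order(spec: str, circular=True, anchor=None) -> SignedGeneOrder:
    genes = tuple(
        SignedGene(tok.lstrip("-"), -1 if tok.startswith("-") else 1)
        for tok in spec.split()
    )
    return SignedGeneOrder(genes, circular=circular, anchor=anchor or genes[0].label)


class TestDuplication:
    def test_dimer_size(self, ancestral):
        d = duplicate_genome(ancestral)
        assert len(d) == 76

    def test_singleton(self):
        d = duplicate_genome(_order("CR"))
        assert len(d) == 2

    def test_drop_copy2_restores_original(self, ancestral):
        d = duplicate_genome(ancestral)
        copy1 = tuple(t.gene for t in d.genes if t.copy == 1)
        assert copy1 == ancestral.genes


class TestPolarityLoss:
    def test_survivor_partition(self, ancestral):
        pair = polarity_loss(duplicate_genome(ancestral))
        s1, s2 = pair.monomer1.label_set(), pair.monomer2.label_set()
        assert s1 | s2 == ancestral.label_set()
        assert s1 & s2 == frozenset()

    def test_monomer1_matches_printed_list(self, ancestral):
        """Plus-strand survivors equal the published monomer-1 gene list."""
        pair = polarity_loss(duplicate_genome(ancestral))
        assert pair.monomer1.genes == datasets.monomer1_printed().genes

    def test_monomer2_survivors(self, ancestral):
        pair = polarity_loss(duplicate_genome(ancestral))
        assert all(g.orientation == -1 for g in pair.monomer2.genes)
        assert len(pair.monomer2) == 15
        assert "trnY" in pair.monomer2.label_set()  # omitted in the printed list

    def test_uniform_polarity_degenerate(self, polydesmus):
        pair = polarity_loss(duplicate_genome(polydesmus))
        assert len(pair.monomer1) == len(polydesmus)
        assert len(pair.monomer2) == 0

    def test_bad_rule_rejected(self, ancestral):
        d = duplicate_genome(ancestral)
        with pytest.raises(ValueError):
            polarity_loss(d, {"+": 1, "-": 1})


class TestRecombinationJoin:
    # The post-join arrangement derived by hand from the published monomer
    # lists: monomer 1 verbatim, then monomer 2 reversed with polarity
    # flipped (trnY restored, nad1 in place of the misprinted nad4L).
    EXPECTED_POST_JOIN = (
        "trnI trnM nad2 trnW cox1 cox2 trnK trnD atp8 atp6 cox3 trnG nad3 "
        "trnA trnR trnN trnS1 trnE trnT nad6 cob trnS2 CR rrnS trnV rrnL "
        "trnL1 trnL2 nad1 trnP nad4L nad4 trnH nad5 trnF trnY trnC trnQ"
    )

    def test_polarity_monomers_join_single_stranded(self, ancestral):
        pair = polarity_loss(duplicate_genome(ancestral))
        joined = recombination_join(pair.monomer1, pair.monomer2)
        assert joined.circular
        assert joined.strand_homogeneity() == 1.0
        assert joined.genes == _order(self.EXPECTED_POST_JOIN).genes

    def test_empty_m2_circularizes_m1(self):
        m1 = _order("a b c", circular=False)
        m2 = SignedGeneOrder((), circular=False)
        joined = recombination_join(m1, m2)
        assert joined.circular and joined.genes == m1.genes

    def test_reflection_invariance(self, ancestral):
        pair = polarity_loss(duplicate_genome(ancestral))
        joined = recombination_join(pair.monomer1, pair.monomer2)
        assert orders_equal(joined, joined.reflected())

    def test_overlapping_labels_rejected(self):
        with pytest.raises(ValueError):
            recombination_join(_order("a b", circular=False),
                               _order("-b -c", circular=False))


class TestTDRL:
    def test_trnt_local_rearrangement(self):
        """Duplicating nad4..trnT and losing redundant copies yields the
        published local reading trnT-nad4-nad4L."""
        o = _order("-trnF -trnH -nad4 -nad4L trnT -trnP")
        out = tdrl_translocate(o, ("nad4", "trnT"),
                               {"nad4": 2, "nad4L": 2, "trnT": 1})
        assert [str(g) for g in out.genes] == \
            ["-trnF", "-trnH", "trnT", "-nad4", "-nad4L", "-trnP"]

    def test_keep_all_first_copies_is_identity(self, polydesmus):
        labels = polydesmus.labels()
        out = tdrl_translocate(polydesmus, (labels[3], labels[10]),
                               {l: 1 for l in labels[3:11]})
        assert out.genes == polydesmus.genes

    def test_gene_content_conserved_any_pattern(self):
        rng = random.Random(17)
        for _ in range(100):
            o = random_order(rng, rng.randint(3, 10))
            n = len(o)
            start = rng.randrange(n)
            span = rng.randint(1, n)
            labels = [o.genes[(start + k) % n].label for k in range(span)]
            pattern = {l: rng.choice((1, 2)) for l in labels}
            out = tdrl_translocate(o, (labels[0], labels[-1]), pattern)
            assert sorted(out.labels()) == sorted(o.labels())
            # orientations never change under TDRL
            orient = {g.label: g.orientation for g in o.genes}
            assert all(g.orientation == orient[g.label] for g in out.genes)

    def test_incomplete_pattern_rejected(self):
        o = _order("a b c d")
        with pytest.raises(ValueError, match="missing"):
            tdrl_translocate(o, ("a", "c"), {"a": 1, "b": 2})
        with pytest.raises(ValueError):
            tdrl_translocate(o, ("a", "b"), {"a": 3, "b": 1})

    def test_random_pattern_seeded(self):
        o = _order("a b c d e f")
        r1 = tdrl_translocate(o, ("b", "e"), seed=99)
        r2 = tdrl_translocate(o, ("b", "e"), seed=99)
        assert r1.genes == r2.genes


def _brute_force_invert(genes, i, span):
    """List-slice oracle for inversion on a circular tuple."""
    n = len(genes)
    idx = [(i + k) % n for k in range(span)]
    seg = [genes[j] for j in idx]
    seg = [SignedGene(g.label, -g.orientation) for g in reversed(seg)]
    out = list(genes)
    for j, g in zip(idx, seg):
        out[j] = g
    return tuple(out)


class TestInvert:
    def test_two_gene_segment(self):
        o = _order("trnY trnQ trnC trnI")
        out = invert(o, ("trnQ", "trnC"))
        assert [str(g) for g in out.genes] == ["trnY", "-trnC", "-trnQ", "trnI"]

    def test_involution(self):
        """Re-inverting the same physical span restores the order.

        Spans are named by their endpoint labels in reading direction, so
        after an inversion the same span is addressed with the endpoints
        swapped.
        """
        rng = random.Random(23)
        for _ in range(50):
            o = random_order(rng, rng.randint(2, 9))
            n = len(o)
            i, span = rng.randrange(n), rng.randint(1, n)
            seg = (o.genes[i].label, o.genes[(i + span - 1) % n].label)
            assert invert(invert(o, seg), (seg[1], seg[0])).genes == o.genes

    def test_whole_order_inversion_canonically_neutral(self, polydesmus):
        labels = polydesmus.labels()
        out = invert(polydesmus, (labels[0], labels[-1]))
        assert orders_equal(out, polydesmus)

    def test_exhaustive_against_list_oracle(self):
        """Every segment of a 6-gene order, checked against slice algebra."""
        o = _order("a -b c d -e f")
        n = len(o)
        for i, span in product(range(n), range(1, n + 1)):
            seg = (o.genes[i].label, o.genes[(i + span - 1) % n].label)
            assert invert(o, seg).genes == _brute_force_invert(o.genes, i, span)


class TestApplyEvent:
    def test_dispatch_wgd(self, ancestral):
        out = apply_event(ancestral, RearrangementEvent("whole_genome_duplication"))
        assert len(out) == 76

    def test_kind_state_mismatch(self, ancestral):
        with pytest.raises(TypeError):
            apply_event(ancestral, RearrangementEvent("recombination_join"))

    def test_inversion_deterministic(self, polydesmus):
        ev = RearrangementEvent("inversion", {"segment": ["trnQ", "trnC"]}, seed=1)
        a = apply_event(polydesmus, ev)
        b = apply_event(polydesmus, ev)
        assert a.genes == b.genes

    def test_random_loss_seeded_reproducible(self, polydesmus):
        ev = RearrangementEvent("random_loss",
                                {"segment": ["trnK", "atp6"]}, seed=1234)
        a = apply_event(polydesmus, ev)
        b = apply_event(polydesmus, ev)
        assert a.genes == b.genes

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            RearrangementEvent("teleportation")

    def test_provenance_recorded(self, polydesmus):
        ev = RearrangementEvent("inversion", {"segment": ["trnQ", "trnC"]})
        out = apply_event(polydesmus, ev)
        assert out.history[-1] is ev


class TestSingleStrandTheorem:
    def test_mixed_polarity_orders_become_single_stranded(self):
        """Duplication, polarity loss and a 3'-3' join always yield a
        single-stranded circular order (smoke-scale; the full-scale run
        lives in the acceptance suite)."""
        rng = random.Random(31)
        for _ in range(300):
            o = random_order(rng, rng.randint(2, 20), mixed=True)
            pair = polarity_loss(duplicate_genome(o))
            joined = recombination_join(pair.monomer1, pair.monomer2)
            assert joined.strand_homogeneity() == 1.0
            assert joined.label_set() == o.label_set()
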