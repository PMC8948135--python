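"""Bundled reference fixtures: the published annotation table, gene orders,
and the shipped rearrangement scenario."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .annotation import AnnotationTable, read_annotation
from .gene_order import SignedGene, SignedGeneOrder, read_gene_list, read_order
from .replay import Scenario, load_scenario

#: Published per-partition base percentages (A, T, G, C), used as synthesis
#: targets. "genome" is the whole-mitogenome row, applied to spacers.
POLYDESMUS_COMPOSITION: dict[str, tuple[float, float, float, float]] = {
    "genome": (25.3, 40.9, 24.2, 9.7),
    "PCG": (22.5, 42.3, 25.1, 9.9),
    "tRNA": (31.2, 36.6, 22.0, 10.1),
    "rRNA": (33.1, 37.1, 20.8, 8.97),
    "control_region": (34.6, 38.4, 21.9, 5.0),
}


def _data_path(*parts: str) -> Path:
    return Path(resources.files("mitorearrange").joinpath("data", *parts))


def polydesmus_table() -> AnnotationTable:
    """The published 38-feature annotation table (15,036 bp genome)."""
    return read_annotation(_data_path("polydesmus_gzcs2019.tsv"))


def ancestral_order() -> SignedGeneOrder:
    """Ancestral arthropod ground-pattern gene order (38 elements, mixed strands)."""
    return read_order(_data_path("orders", "ancestral_arthropod.order"))


def polydesmus_order() -> SignedGeneOrder:
    """The Polydesmus arrangement from the annotation table (all +)."""
    return read_order(_data_path("orders", "polydesmus_gzcs2019.order"))


def monomer1_printed() -> SignedGeneOrder:
    """Monomer-1 survivor list as printed (linear, all +)."""
    return read_order(_data_path("orders", "monomer1_printed.order"),
                      circular=False)


def monomer2_printed() -> tuple[SignedGene, ...]:
    """Monomer-2 survivor list as printed, anomalies preserved (raw list)."""
    return read_gene_list(_data_path("orders", "monomer2_printed.order"))


def final_printed() -> tuple[SignedGene, ...]:
    """The printed final arrangement, anomalies preserved (raw list)."""
    return read_gene_list(_data_path("orders", "final_printed.order"))


def tdnrl_rc_scenario() -> Scenario:
    """The shipped TD(N\\R)L + RC scenario: ancestral order -> Polydesmus order."""
    return load_scenario(_data_path("scenarios", "tdnrl_rc.yaml"))


def tdnrl_rc_scenario_path() -> Path:
    return _data_path("scenarios", "tdnrl_rc.yaml")


def table_path() -> Path:
    return _data_path("polydesmus_gzcs2019.tsv")
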