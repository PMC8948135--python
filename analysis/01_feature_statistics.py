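#!/usr/bin/env python
"""Feature-table statistics of the Polydesmus sp. GZCS-2019 mitogenome.

Derives the spacer/overlap accounting and partition lengths from the
bundled annotation table and writes them to results/feature_statistics.tsv.
"""

from pathlib import Path

from mitorearrange import datasets, partition_lengths, spacer_overlap_report

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = datasets.polydesmus_table()
    rep = spacer_overlap_report(table)
    parts = partition_lengths(table)

    rows = [
        ("genome_length_bp", table.genome_length),
        ("n_features", len(table)),
        ("n_spacers", rep.n_spacers),
        ("total_spacer_bp", rep.total_spacer_bp),
        ("spacer_range_bp", f"{rep.min_spacer}-{rep.max_spacer}"),
        ("n_overlaps", rep.n_overlaps),
        ("total_overlap_bp", rep.total_overlap_bp),
        ("max_overlap_bp", rep.max_overlap_bp),
    ] + [(f"partition_bp[{c}]", bp) for c, bp in sorted(parts.items())]

    OUT.mkdir(exist_ok=True)
    out = OUT / "feature_statistics.tsv"
    out.write_text("statistic\tvalue\n" +
                   "\n".join(f"{k}\t{v}" for k, v in rows) + "\n")

    print(f"The {table.genome_length:,} bp genome carries {len(table)} features.")
    print(f"Intergenic spacers: {rep.total_spacer_bp} bp in {rep.n_spacers} regions "
          f"({rep.min_spacer}-{rep.max_spacer} bp).")
    print(f"Gene overlaps: {rep.total_overlap_bp} bp at {rep.n_overlaps} junctions, "
          f"deepest {rep.max_overlap_bp} bp:")
    for u, d, bp in rep.overlapping_pairs():
        print(f"  {u}/{d}: {bp} bp")
    print(f"Partitions (bp): {parts}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
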