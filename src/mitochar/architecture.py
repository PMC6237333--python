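"""Genome-organization statistics from an annotation table alone.

Everything here is coordinate arithmetic on a :class:`~mitochar.io_formats.
FeatureTable`: per-feature lengths, overlaps and intergenic spacers between
consecutive features, and strand/class distribution. No sequence is needed,
which lets a published feature table be analysed as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import Feature, FeatureTable

GapList = list[tuple[str, str, int]]


@dataclass
class ArchitectureReport:
    genome_length: int
    per_feature_length: dict[str, int]
    overlaps: GapList
    spacers: GapList
    strand_counts: dict[tuple[str, str], int]
    pcg_total_length: int
    ol_as_feature: bool = True
    # secondary view with OL treated as intergenic spacer territory
    overlaps_ol_excluded: GapList = field(default_factory=list)
    spacers_ol_excluded: GapList = field(default_factory=list)

    @property
    def total_overlap_bp(self) -> int:
        return sum(bp for _, _, bp in self.overlaps)

    @property
    def total_spacer_bp(self) -> int:
        return sum(bp for _, _, bp in self.spacers)

    def to_dict(self) -> dict:
        return {
            "genome_length": self.genome_length,
            "per_feature_length": self.per_feature_length,
            "overlaps": [list(t) for t in self.overlaps],
            "spacers": [list(t) for t in self.spacers],
            "overlaps_ol_excluded": [list(t) for t in self.overlaps_ol_excluded],
            "spacers_ol_excluded": [list(t) for t in self.spacers_ol_excluded],
            "strand_counts": {f"{c}/{s}": n for (c, s), n in self.strand_counts.items()},
            "pcg_total_length": self.pcg_total_length,
            "total_overlap_bp": self.total_overlap_bp,
            "total_spacer_bp": self.total_spacer_bp,
        }


def feature_lengths(table: FeatureTable) -> dict[str, int]:
    """Length (end - start + 1) of every feature, keyed by name."""
    return {f.name: f.length for f in table.features}


def adjacent_gaps(table: FeatureTable,
                  include_classes: tuple[str, ...] | None = None,
                  ) -> tuple[GapList, GapList]:
    """Overlaps and spacers between consecutive features.

    Consecutive means by start coordinate among the included classes; when the
    table is circular the last->first pair is closed across the origin. For a
    pair (prev, next): ``gap = next.start - prev.end - 1``. Negative gap is an
    overlap of ``|gap|`` bp, positive a spacer, zero abutting (reported in
    neither list).
    """
    feats = [f for f in table.features
             if include_classes is None or f.feature_class in include_classes]
    overlaps: GapList = []
    spacers: GapList = []
    if len(feats) < 2:
        return overlaps, spacers
    pairs = list(zip(feats, feats[1:]))
    if table.circular:
        pairs.append((feats[-1], feats[0]))
    for prev, nxt in pairs:
        if nxt.start > prev.start or not table.circular:
            gap = nxt.start - prev.end - 1
        else:  # wrap across the origin
            gap = (table.genome_length - prev.end) + (nxt.start - 1)
        if gap < 0:
            overlaps.append((prev.name, nxt.name, -gap))
        elif gap > 0:
            spacers.append((prev.name, nxt.name, gap))
    return overlaps, spacers


def strand_distribution(table: FeatureTable) -> dict[tuple[str, str], int]:
    """Feature counts per (class, strand) pair; absent pairs count 0."""
    counts: dict[tuple[str, str], int] = {}
    for fclass in ("PCG", "tRNA", "rRNA", "OL", "CR"):
        for strand in ("H", "L"):
            counts[(fclass, strand)] = 0
    for f in table.features:
        counts[(f.feature_class, f.strand)] += 1
    return counts


def occupancy_overlap(table: FeatureTable, name_a: str, name_b: str) -> int:
    """Overlap in bp between two named features by per-position occupancy.

    Brute-force companion to :func:`adjacent_gaps` used to resolve multi-way
    overlaps: counts positions covered by both features.
    """
    a, b = table.get(name_a), table.get(name_b)
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def characterize_architecture(table: FeatureTable) -> ArchitectureReport:
    """Full organization report.

    Two gap views are produced: the primary one treats the light-strand
    replication origin (OL) as a real feature; the secondary excludes it, under
    which the trnN-trnC gap surfaces as the genome's longest spacer.
    """
    all_classes = ("PCG", "tRNA", "rRNA", "OL", "CR")
    no_ol = tuple(c for c in all_classes if c != "OL")
    overlaps, spacers = adjacent_gaps(table, all_classes)
    overlaps_no_ol, spacers_no_ol = adjacent_gaps(table, no_ol)
    lengths = feature_lengths(table)
    return ArchitectureReport(
        genome_length=table.genome_length,
        per_feature_length=lengths,
        overlaps=overlaps,
        spacers=spacers,
        overlaps_ol_excluded=overlaps_no_ol,
        spacers_ol_excluded=spacers_no_ol,
        strand_counts=strand_distribution(table),
        pcg_total_length=sum(f.length for f in table.pcgs),
    )
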