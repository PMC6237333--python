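"""Base composition and strand-asymmetry (skew) statistics.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C), computed on the
heavy strand. A positive AT skew means an excess of A over T; mitochondrial
genomes of most teleosts show a mildly positive AT skew and a strongly
negative GC skew (more C than G on the heavy strand). N bases are excluded
from both numerator and denominator; a zero denominator yields an undefined
(None) skew rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import FeatureTable, GenomeRecord, PCG_NAMES, extract_gene_sequence


@dataclass
class CompositionReport:
    scope: str
    counts: dict[str, int]
    pct: dict[str, float]
    at_pct: float
    at_skew: float | None
    gc_skew: float | None

    @property
    def length(self) -> int:
        return sum(self.counts.values())

    def rounded(self, pct_dp: int = 2, skew_dp: int = 4) -> dict:
        """Presentation view: percentages to 2 d.p., skews to 4 d.p."""
        return {
            "scope": self.scope,
            "counts": dict(self.counts),
            "pct": {b: round(v, pct_dp) for b, v in self.pct.items()},
            "at_pct": round(self.at_pct, pct_dp),
            "at_skew": None if self.at_skew is None else round(self.at_skew, skew_dp),
            "gc_skew": None if self.gc_skew is None else round(self.gc_skew, skew_dp),
        }


def skew(x: int, y: int) -> float | None:
    """(x - y)/(x + y), or None when x + y == 0."""
    return None if x + y == 0 else (x - y) / (x + y)


def composition_from_counts(counts: dict[str, int],
                            scope: str = "genome") -> CompositionReport:
    a, c, g, t = (counts.get(b, 0) for b in "ACGT")
    total = a + c + g + t
    if total == 0:
        raise ValueError("no A/C/G/T bases to summarise")
    pct = {b: 100.0 * counts.get(b, 0) / total for b in "ACGT"}
    return CompositionReport(
        scope=scope,
        counts={b: counts.get(b, 0) for b in "ACGT"},
        pct=pct,
        at_pct=100.0 * (a + t) / total,
        at_skew=skew(a, t),
        gc_skew=skew(g, c),
    )


def base_composition(seq: str, scope: str = "genome") -> CompositionReport:
    """Composition report of one sequence; Ns are ignored throughout."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    return composition_from_counts({b: seq.count(b) for b in "ACGT"}, scope)


def codon_position_split(cds: str) -> tuple[str, str, str]:
    """Bases at codon positions 1/2/3 of one in-frame CDS.

    The 1-2 nt of an incomplete terminal stop codon fall at positions 1(,2)
    by ordinary frame arithmetic.
    """
    return cds[0::3], cds[1::3], cds[2::3]


def pcg_concat_composition(record: GenomeRecord, table: FeatureTable,
                           ) -> dict[str, CompositionReport]:
    """Composition of the 13 concatenated protein-coding genes.

    Returns reports for the overall concatenation and for each codon position
    (scopes ``PCG-concat`` and ``codon-pos-1/2/3``). Positions are assigned
    per codon within each gene independently, so the reading frame restarts
    at every gene regardless of incomplete terminal codons upstream.
    """
    present = {f.name for f in table.pcgs}
    missing = [g for g in PCG_NAMES if g not in present]
    if missing:
        raise ValueError(f"missing protein-coding genes: {missing}")
    pos_seqs = ["", "", ""]
    overall = []
    for f in table.pcgs:
        cds = extract_gene_sequence(record, f)
        overall.append(cds)
        for i, part in enumerate(codon_position_split(cds)):
            pos_seqs[i] += part
    out = {"PCG-concat": base_composition("".join(overall), "PCG-concat")}
    for i, s in enumerate(pos_seqs, 1):
        out[f"codon-pos-{i}"] = base_composition(s, f"codon-pos-{i}")
    return out


def per_gene_composition(record: GenomeRecord, table: FeatureTable,
                         classes: tuple[str, ...] = ("PCG", "rRNA", "tRNA", "CR"),
                         ) -> dict[str, CompositionReport]:
    return {
        f.name: base_composition(extract_gene_sequence(record, f), f.name)
        for f in table.features if f.feature_class in classes
    }


def sliding_gc_skew(seq: str, window: int, step: int = 1,
                    circular: bool = False) -> list[tuple[int, float | None]]:
    """GC skew in sliding windows; (1-based window start, skew) pairs.

    With ``circular`` set, windows wrap past the end so every start position
    up to len(seq) is reported.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if window > len(seq):
        raise ValueError("window exceeds sequence length")
    seq = seq.upper()
    n = len(seq)
    starts = range(0, n if circular else n - window + 1, step)
    out = []
    for s in starts:
        w = seq[s:s + window]
        if circular and len(w) < window:
            w += seq[:window - len(w)]
        out.append((s + 1, skew(w.count("G"), w.count("C"))))
    return out
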