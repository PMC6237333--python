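"""Codon extraction, start/stop classification, counting and RSCU.

Works under the vertebrate mitochondrial genetic code (NCBI translation
table 2) by default: ATA codes Met, TGA codes Trp, and AGA/AGG are stop
codons. Mitochondrial genes frequently end on an incomplete stop (a bare T
or TA at the annotated gene boundary, completed to TAA by polyadenylation of
the transcript); those trailing 1-2 nt are classified as an incomplete stop,
never as a codon.

RSCU (relative synonymous codon usage) for codon c in a synonymous family of
size k with counts n_i is RSCU_c = n_c / (mean of the family counts)
= k * n_c / sum_i n_i. A uniformly used family therefore has RSCU 1 for every
member, and family RSCU values always average to 1 when the family occurs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

BASES = "ACGT"


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: codon->amino-acid map plus start/stop sets."""

    table_id: int
    forward: dict[str, str]          # sense codon -> 1-letter amino acid
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    @classmethod
    def from_ncbi(cls, table_id: int = 2) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(
            table_id=table_id,
            forward=dict(t.forward_table),
            start_codons=frozenset(t.start_codons),
            stop_codons=frozenset(t.stop_codons),
        )

    @property
    def sense_codons(self) -> list[str]:
        return sorted(self.forward)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def aa(self, codon: str) -> str | None:
        """Amino acid for a sense codon, None for a stop, 'X' if ambiguous."""
        if codon in self.stop_codons:
            return None
        if codon in self.forward:
            return self.forward[codon]
        return "X"

    def families(self) -> dict[str, frozenset[str]]:
        """Synonymous families: amino acid -> set of sense codons."""
        fam: dict[str, set[str]] = {}
        for codon, aa in self.forward.items():
            fam.setdefault(aa, set()).add(codon)
        return {aa: frozenset(cods) for aa, cods in fam.items()}


VERTEBRATE_MITO = GeneticCode.from_ncbi(2)


@dataclass(frozen=True)
class CodonClassification:
    gene: str
    start_codon: str
    stop_codon: str
    stop_complete: bool

    @property
    def canonical_start(self) -> bool:
        return self.start_codon == "ATG"


@dataclass
class CodonCountTable:
    counts: dict[str, int]
    rscu: dict[str, float | None]
    families: dict[str, frozenset[str]]

    def to_rows(self, code: GeneticCode) -> list[tuple[str, str, int, float | None]]:
        """(codon, amino acid, count, RSCU) rows sorted by amino acid."""
        rows = []
        for aa, fam in sorted(self.families.items()):
            for codon in sorted(fam):
                rows.append((codon, aa, self.counts.get(codon, 0),
                             self.rscu.get(codon)))
        return rows


class InternalStopError(ValueError):
    """A stop codon occurs before the terminal position of a CDS."""

    def __init__(self, gene: str, codon: str, offset: int):
        self.offset = offset
        super().__init__(
            f"{gene or 'CDS'}: internal stop codon {codon} at nucleotide offset {offset}"
        )


def extract_codons(cds_seq: str, code: GeneticCode = VERTEBRATE_MITO,
                   gene: str = "", check_internal_stops: bool = True,
                   ) -> tuple[list[str], CodonClassification]:
    """Split an annotated CDS into codons plus a start/stop classification.

    The trailing 1-2 nt of a CDS whose length is not a multiple of 3 are
    returned as an incomplete stop codon. A complete terminal 3-mer is
    reported as the stop when it is one under ``code``; otherwise it is kept
    as an ordinary codon and the classification notes the (unusual) absence
    of a terminal stop by reporting it with ``stop_complete=True``.
    """
    cds_seq = cds_seq.upper()
    if len(cds_seq) < 4:
        raise ValueError("CDS shorter than 4 nt")
    n_full = len(cds_seq) // 3
    tail = cds_seq[3 * n_full:]
    codons = [cds_seq[3 * i:3 * i + 3] for i in range(n_full)]
    if tail:  # incomplete terminal stop (T or TA)
        stop, stop_complete = tail, False
    elif code.is_stop(codons[-1]):
        stop, stop_complete = codons.pop(), True
    else:
        stop, stop_complete = codons[-1], True
    if check_internal_stops:
        for i, codon in enumerate(codons):
            if code.is_stop(codon):
                raise InternalStopError(gene, codon, 3 * i + 1)
    return codons, CodonClassification(gene=gene, start_codon=cds_seq[:3],
                                       stop_codon=stop, stop_complete=stop_complete)


def classify_start(cds_seq: str, code: GeneticCode = VERTEBRATE_MITO,
                   ) -> tuple[str, bool]:
    """First codon of a CDS and whether it is the canonical ATG."""
    if len(cds_seq) < 3:
        raise ValueError("CDS shorter than one codon")
    first = cds_seq[:3].upper()
    return first, first == "ATG"


def count_codons(codon_lists: list[list[str]],
                 code: GeneticCode = VERTEBRATE_MITO,
                 exclude_start: bool = False) -> dict[str, int]:
    """Pooled codon counts over genes; stop codons are never counted."""
    counts: dict[str, int] = {c: 0 for c in code.sense_codons}
    for codons in codon_lists:
        use = codons[1:] if exclude_start else codons
        for codon in use:
            if code.is_stop(codon):
                continue
            if codon in counts:
                counts[codon] += 1
    return counts


def rscu(counts: dict[str, int], code: GeneticCode = VERTEBRATE_MITO,
         ) -> dict[str, float | None]:
    """RSCU per sense codon; families never seen get None, not 0.

    Stop codons present in ``counts`` are ignored with a warning: they are
    not members of any synonymous family.
    """
    ignored = [c for c in counts if code.is_stop(c) and counts[c] > 0]
    if ignored:
        logger.warning("ignoring stop codons in RSCU input: %s", sorted(ignored))
    out: dict[str, float | None] = {}
    for aa, fam in code.families().items():
        total = sum(counts.get(c, 0) for c in fam)
        k = len(fam)
        for c in sorted(fam):
            out[c] = None if total == 0 else counts.get(c, 0) * k / total
    return out


def codon_usage_table(codon_lists: list[list[str]],
                      code: GeneticCode = VERTEBRATE_MITO,
                      exclude_start: bool = False) -> CodonCountTable:
    counts = count_codons(codon_lists, code, exclude_start=exclude_start)
    return CodonCountTable(counts=counts, rscu=rscu(counts, code),
                           families=code.families())


def translate(cds_seq: str, code: GeneticCode = VERTEBRATE_MITO) -> str:
    """Translate an in-frame CDS; terminal (or incomplete) stop is dropped.

    Codons containing non-ACGT characters translate to 'X'. A stop codon
    before the terminal position raises.
    """
    codons, _ = extract_codons(cds_seq, code, check_internal_stops=True)
    aas = []
    for codon in codons:
        if code.is_stop(codon):  # terminal non-dropped stop cannot occur here
            continue
        aas.append(code.forward.get(codon, "X") if set(codon) <= set(BASES) else "X")
    if not aas:
        raise ValueError("empty translation after stop trimming")
    return "".join(aas)


def all_sense_codons(code: GeneticCode = VERTEBRATE_MITO) -> list[str]:
    """All sense codons of the code (60 under the vertebrate mito table:
    64 minus TAA/TAG/AGA/AGG)."""
    return [c for c in ("".join(p) for p in product(BASES, repeat=3))
            if not code.is_stop(c)]
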