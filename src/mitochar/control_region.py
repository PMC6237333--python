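"""Motif, conserved-block and tandem-repeat scanning of non-coding regions.

The control region (D-loop) of teleost mitogenomes carries short conserved
motifs (e.g. ATGTA and its complement TACAT, termination-associated
GGTTTTT / CTTAATG variants) and conserved sequence blocks (CSB-F/E/D and
CSB-1/2/3). This module provides a mismatch-tolerant two-strand motif
scanner, an exact-match tandem-repeat finder, and a hairpin check for the
light-strand replication origin (OL).

The tandem scanner is a deliberate simplification of alignment-scored repeat
finders: it reports maximal exact arrays only. Mitogenome control regions of
most Beloniformes carry no tandem arrays, so an exact negative scan is the
informative output.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import reverse_complement


@dataclass(frozen=True)
class MotifHit:
    motif: str
    position: int          # 1-based offset of the window within the region
    strand: str            # H: motif as given; L: its reverse complement
    mismatches: int


@dataclass(frozen=True)
class TandemRepeat:
    period: int
    copies: float          # >= 2, possibly fractional (partial last copy)
    start: int             # 1-based
    consensus: str

    @property
    def span(self) -> int:
        return round(self.period * self.copies)


@dataclass(frozen=True)
class HairpinCheck:
    stem_length: int
    loop_length: int
    paired_fraction: float


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_motifs(region_seq: str, motifs: list[str] | dict[str, int],
                max_mismatch: int = 0, circular: bool = False,
                ) -> list[MotifHit]:
    """All (possibly overlapping) hits of each motif on both strands.

    ``motifs`` is a list (shared ``max_mismatch``) or a {motif: max_mismatch}
    mapping. An L-strand hit at position p means the reverse complement of
    the motif matches the forward region window starting at p. With
    ``circular`` set the scan wraps across the region end, positions staying
    1..len(region).
    """
    region_seq = region_seq.upper()
    if isinstance(motifs, dict):
        items = [(m.upper(), mm) for m, mm in motifs.items()]
    else:
        items = [(m.upper(), max_mismatch) for m in motifs]
    n = len(region_seq)
    hits: list[MotifHit] = []
    for motif, mm in items:
        m = len(motif)
        if m == 0 or m > n:
            continue
        scan_seq = region_seq + (region_seq[:m - 1] if circular else "")
        n_starts = n if circular else n - m + 1
        rc = reverse_complement(motif)
        for i in range(n_starts):
            window = scan_seq[i:i + m]
            d = _hamming(window, motif)
            if d <= mm:
                hits.append(MotifHit(motif, i + 1, "H", d))
            if rc != motif:
                d2 = _hamming(window, rc)
                if d2 <= mm:
                    hits.append(MotifHit(motif, i + 1, "L", d2))
    hits.sort(key=lambda h: (h.position, h.motif, h.strand))
    return hits


def _is_primitive(unit: str) -> bool:
    """True when the repeat unit is not itself a whole number of copies of a
    shorter unit."""
    p = len(unit)
    for q in range(1, p):
        if p % q == 0 and unit == unit[:q] * (p // q):
            return False
    return True


def find_tandem_repeats(region_seq: str, min_period: int = 1,
                        max_period: int = 10, min_copies: float = 2.0,
                        ) -> list[TandemRepeat]:
    """Maximal exact tandem arrays with primitive period.

    An array at (start, period) extends while ``seq[i] == seq[i - period]``;
    copies = span / period (fractional final copy allowed). Arrays whose unit
    is non-primitive duplicate a shorter-period report and are suppressed, as
    are arrays wholly contained in a longer reported span at the same period.
    """
    seq = region_seq.upper()
    n = len(seq)
    if not (1 <= min_period <= max_period):
        raise ValueError("need 1 <= min_period <= max_period")
    max_period = min(max_period, n // 2)
    found: list[TandemRepeat] = []
    for p in range(min_period, max_period + 1):
        i = 0
        while i + 2 * p <= n:
            # extend the match run seq[j] == seq[j-p] starting at i+p
            j = i + p
            while j < n and seq[j] == seq[j - p]:
                j += 1
            span = j - i
            copies = span / p
            unit = seq[i:i + p]
            if copies >= min_copies and copies >= 2.0 and _is_primitive(unit):
                found.append(TandemRepeat(period=p, copies=copies,
                                          start=i + 1, consensus=unit))
            # a maximal run ending at j cannot restart before j - p + 1
            i = max(i + 1, j - p + 1) if span >= 2 * p else i + 1
    # drop arrays fully nested inside another reported array's span
    out: list[TandemRepeat] = []
    for r in found:
        nested = any(
            o is not r and o.start <= r.start and
            o.start + o.span >= r.start + r.span and
            (o.span > r.span or (o.span == r.span and o.period > r.period))
            for o in found
        )
        if not nested:
            out.append(r)
    out.sort(key=lambda r: (r.start, r.period))
    return out


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
          ("G", "T"), ("T", "G")}  # Watson-Crick + G.U wobble (DNA alphabet)


def can_pair(x: str, y: str) -> bool:
    return (x, y) in _PAIRS


def hairpin_check(seq: str, min_loop: int = 3) -> HairpinCheck:
    """Best end-anchored stem-loop of a short element such as the OL.

    Pairs the sequence ends inward (5' prefix against 3' suffix, Watson-Crick
    plus G.U) until the first non-pairing position or until the unpaired loop
    would shrink below ``min_loop``. Returns stem length, loop length and the
    fraction of residues paired.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 8:
        raise ValueError("sequence too short for a hairpin check")
    stem = 0
    while 2 * (stem + 1) + min_loop <= n and can_pair(seq[stem], seq[n - 1 - stem]):
        stem += 1
    return HairpinCheck(stem_length=stem, loop_length=n - 2 * stem,
                        paired_fraction=2 * stem / n)


#: default conserved-block consensus profile for teleost control regions.
#: These consensus strings are conventional motifs from the comparative
#: vertebrate CR literature, not derived from any single genome; they are
#: user-replaceable via scan profiles (name -> (sequence, max_mismatch)).
DEFAULT_CSB_PROFILE: dict[str, tuple[str, int]] = {
    "CSB-F": ("ATGTACTAATATACAT", 4),
    "CSB-E": ("AGGGACATA", 2),
    "CSB-D": ("TCTTATCCTTGATCA", 4),
    "CSB-1": ("TTAATGCATGA", 3),
    "CSB-2": ("CAAACCCCCCTACCCCC", 4),
    "CSB-3": ("TGCCAAACCCCAAAAACA", 4),
    "TAS": ("TACAT", 0),
    "motif-ATGTA": ("ATGTA", 0),
    "motif-GGTTTTT": ("GGTTTTT", 1),
    "motif-CTTAATG": ("CTTAATG", 1),
}


def scan_csb_profile(region_seq: str,
                     profile: dict[str, tuple[str, int]] | None = None,
                     ) -> dict[str, list[MotifHit]]:
    """Scan a control region against a named consensus-block profile."""
    profile = DEFAULT_CSB_PROFILE if profile is None else profile
    return {
        name: scan_motifs(region_seq, {seq: mm})
        for name, (seq, mm) in profile.items()
    }
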