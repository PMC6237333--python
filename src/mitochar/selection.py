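"""Nei-Gojobori (1986) Ka/Ks estimation for pairwise aligned CDSs.

Site counting: at each codon position the synonymous-site fraction is the
proportion of the single-nucleotide neighbours that encode the same amino
acid; neighbours that are stop codons are excluded from the denominator, so
each position always contributes s + n = 1 site split between the two
classes and every codon contributes exactly 3 sites.

Difference counting between two codons averages over all minimal mutational
pathways (orderings of the differing positions), discarding pathways that
pass through a stop codon. The pathway average is unweighted, the classic
NG86 choice.

Proportions ps = Sd/S and pn = Nd/N are corrected for multiple hits with the
Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p); p >= 3/4 is reported as
saturated rather than clamped. omega = Ka/Ks is undefined when Ks = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

from .codon_usage import BASES, GeneticCode, VERTEBRATE_MITO

logger = logging.getLogger(__name__)


@dataclass
class KaKsResult:
    gene: str
    n_codons: int          # aligned codons used (after pairwise exclusion)
    S: float               # synonymous sites (averaged over the two sequences)
    N: float               # nonsynonymous sites
    Sd: float              # synonymous differences
    Nd: float              # nonsynonymous differences
    ps: float | None
    pn: float | None
    Ks: float | None       # None when saturated (ps >= 3/4)
    Ka: float | None
    ratio: float | None    # Ka/Ks; None when Ks is 0 or either rate undefined
    saturated: bool = False


def codon_neighbors(codon: str) -> list[str]:
    """The 9 codons one nucleotide change away."""
    out = []
    for pos in range(3):
        for b in BASES:
            if b != codon[pos]:
                out.append(codon[:pos] + b + codon[pos + 1:])
    return out


def count_sites(codon: str, code: GeneticCode = VERTEBRATE_MITO,
                ) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Per position: fraction of non-stop single-nucleotide neighbours that are
    synonymous. s + n = 3 always (a position whose neighbours are all stops
    contributes a full nonsynonymous site).
    """
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = code.forward[codon]
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1:]
            if code.is_stop(nb):
                continue
            tot += 1
            if code.forward[nb] == aa:
                syn += 1
        if tot:
            s += syn / tot
    return s, 3.0 - s


def count_differences(codon_a: str, codon_b: str,
                      code: GeneticCode = VERTEBRATE_MITO,
                      ) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, pathway-averaged.

    All orderings of the differing positions are enumerated; orderings whose
    intermediate codons are stops are discarded. If every ordering is
    blocked, each differing position is classified independently in the
    context of ``codon_a`` (unordered fallback, logged).
    """
    if code.is_stop(codon_a) or code.is_stop(codon_b):
        raise ValueError("stop codons are not comparable")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []  # (sd, nd) per surviving pathway
    for order in permutations(diff_pos):
        cur = codon_a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if code.is_stop(nxt):
                ok = False
                break
            if code.forward[cur] == code.forward[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            valid.append((sd, nd))
    if valid:
        return (sum(v[0] for v in valid) / len(valid),
                sum(v[1] for v in valid) / len(valid))
    # all pathways blocked by stops: classify each position in isolation
    logger.warning("all mutational pathways %s->%s blocked by stops; "
                   "falling back to per-position classification",
                   codon_a, codon_b)
    sd = nd = 0
    for pos in diff_pos:
        alt = codon_a[:pos] + codon_b[pos] + codon_a[pos + 1:]
        if not code.is_stop(alt) and code.forward[codon_a] == code.forward[alt]:
            sd += 1
        else:
            nd += 1
    return float(sd), float(nd)


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def _usable(codon: str) -> bool:
    return set(codon) <= set(BASES)


def kaks_pair(cds_a: str, cds_b: str, code: GeneticCode = VERTEBRATE_MITO,
              gene: str = "") -> KaKsResult:
    """NG86 Ka/Ks for one aligned, gap-stripped in-frame CDS pair.

    Codon columns containing gaps, ambiguity codes or stop codons in either
    sequence are excluded pairwise. Terminal incomplete-stop nucleotides
    (length mod 3) are trimmed first.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDSs must have equal length")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    usable = len(cds_a) - len(cds_a) % 3
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, usable, 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if not (_usable(ca) and _usable(cb)):
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            continue
        sa, na = count_sites(ca, code)
        sb, nb = count_sites(cb, code)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = count_differences(ca, cb, code)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons after pairwise exclusion")
    ps = Sd / S if S > 0 else None
    pn = Nd / N if N > 0 else None
    Ks = jukes_cantor(ps) if ps is not None else None
    Ka = jukes_cantor(pn) if pn is not None else None
    saturated = (ps is not None and ps >= 0.75) or (pn is not None and pn >= 0.75)
    ratio = None
    if Ks is not None and Ka is not None and Ks > 0:
        ratio = Ka / Ks
    return KaKsResult(gene=gene, n_codons=n_codons, S=S, N=N, Sd=Sd, Nd=Nd,
                      ps=ps, pn=pn, Ks=Ks, Ka=Ka, ratio=ratio,
                      saturated=saturated)


def kaks_gene_table(alignment: dict[str, str], pairs: list[tuple[str, str]],
                    code: GeneticCode = VERTEBRATE_MITO,
                    gene: str = "") -> list[KaKsResult]:
    """Pairwise Ka/Ks for named taxon pairs within one gene alignment.

    Reported values are per-pair; downstream summaries (e.g. a per-gene mean
    ratio over all pairs) should label themselves as pairwise means.
    """
    out = []
    for a, b in pairs:
        res = kaks_pair(alignment[a], alignment[b], code, gene=gene)
        out.append(res)
    return out
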