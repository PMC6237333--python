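"""Ground-truth generators: mitogenomes, tRNAs, codon alignments, trees.

Everything the analysis stages consume can be simulated here with known
truth, so the whole pipeline is testable at desk scale without downloads.
All generators are deterministic under their seed.

The synthetic mitogenome emulates a typical teleost molecule: 39 features
(13 protein-coding genes, 22 tRNAs, 2 rRNAs, the light-strand replication
origin and the control region) in the canonical vertebrate gene order, with
the canonical irregularities planted — one GTG start (cox1), three genes
with incomplete T stop codons (cox2, nad4, cytb), one light-strand PCG
(nad6), eight light-strand tRNAs, one DHU-less serine tRNA, control-region
motifs, and an OL hairpin. Gene lengths default to the H. quoyi annotation
shipped with the package, so length bookkeeping mirrors a real genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .codon_usage import BASES, GeneticCode, VERTEBRATE_MITO
from .control_region import can_pair
from .io_formats import (CANONICAL_GENE_ORDER, Feature, FeatureTable,
                         GenomeRecord, reference_feature_table,
                         reverse_complement)
from .selection import codon_neighbors
from .trna_structure import AC_LOOP, CloverleafModel

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: tRNAs on the light strand in the canonical vertebrate order
L_STRAND_TRNAS = frozenset({"trnQ", "trnA", "trnN", "trnC", "trnY",
                            "trnS1", "trnE", "trnP"})


# ---------------------------------------------------------------------------
# tRNA generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrnaSpec:
    """Designed cloverleaf arm lengths; defaults give a 72 nt tRNA."""

    acceptor: int = 7
    spacer1: int = 2
    dhu_stem: int = 4          # 0 => DHU-less, dhu_loop is the connector
    dhu_loop: int = 8
    spacer2: int = 1
    ac_stem: int = 5
    variable: int = 4
    t_stem: int = 5
    t_loop: int = 7
    spacer3: int = 1
    gu_pairs: int = 0          # planted wobble pairs (placed in stems)
    anticodon: str = "GAT"

    @property
    def length(self) -> int:
        return (2 * self.acceptor + self.spacer1 + 2 * self.dhu_stem
                + self.dhu_loop + self.spacer2 + 2 * self.ac_stem + AC_LOOP
                + self.variable + 2 * self.t_stem + self.t_loop + self.spacer3)


def generate_trna(spec: TrnaSpec | None = None, seed: int = 0,
                  ) -> tuple[str, CloverleafModel]:
    """A tRNA gene sequence realizing ``spec`` plus its true fold.

    Stems are sampled as Watson-Crick pairs, with ``spec.gu_pairs`` of them
    replaced by G.T wobbles; loops and spacers are A/C-rich so they cannot
    pair with each other and extend stems by accident.
    """
    spec = spec or TrnaSpec()
    if not 55 <= spec.length <= 95:
        raise ValueError(f"designed length {spec.length} outside 55..95")
    if spec.dhu_stem not in (0, 3, 4):
        raise ValueError("dhu_stem must be 0, 3 or 4")
    rng = np.random.default_rng(seed)
    n = spec.length
    seq = [""] * n

    def fill_unpaired(start: int, length: int) -> None:
        for k in range(start, start + length):
            seq[k] = rng.choice(["A", "A", "C"])

    pairs: list[tuple[int, int]] = []

    def fill_stem(start: int, stem: int, loop: int) -> None:
        fill_unpaired(start + stem, loop)
        for i in range(stem):
            x, y = start + i, start + 2 * stem + loop - 1 - i
            five = rng.choice(list("ACGT"))
            comp = {"A": "T", "T": "A", "G": "C", "C": "G"}[five]
            seq[x], seq[y] = five, comp
            pairs.append((x, y))

    # acceptor stem spans the molecule ends
    for i in range(spec.acceptor):
        five = rng.choice(list("ACGT"))
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}[five]
        seq[i], seq[n - 1 - i] = five, comp
        pairs.append((i, n - 1 - i))
    pos = spec.acceptor
    fill_unpaired(pos, spec.spacer1)
    pos += spec.spacer1
    if spec.dhu_stem:
        fill_stem(pos, spec.dhu_stem, spec.dhu_loop)
        pos += 2 * spec.dhu_stem + spec.dhu_loop
    else:
        fill_unpaired(pos, spec.dhu_loop)
        pos += spec.dhu_loop
    fill_unpaired(pos, spec.spacer2)
    pos += spec.spacer2
    fill_stem(pos, spec.ac_stem, AC_LOOP)
    # write the anticodon into loop positions 3..5 (of 7)
    ac_loop_start = pos + spec.ac_stem
    seq[ac_loop_start + 2:ac_loop_start + 5] = list(spec.anticodon)
    pos += 2 * spec.ac_stem + AC_LOOP
    fill_unpaired(pos, spec.variable)
    pos += spec.variable
    fill_stem(pos, spec.t_stem, spec.t_loop)
    pos += 2 * spec.t_stem + spec.t_loop
    fill_unpaired(pos, spec.spacer3)

    # plant G.U wobbles on the first gu_pairs stem pairs
    if spec.gu_pairs > len(pairs):
        raise ValueError("more planted G.U pairs than stem positions")
    for k in range(spec.gu_pairs):
        x, y = pairs[k]
        seq[x], seq[y] = "G", "T"

    sequence = "".join(seq)
    assert all(can_pair(sequence[i], sequence[j]) for i, j in pairs)
    model = CloverleafModel(
        acceptor_stem=spec.acceptor,
        dhu_arm=(spec.dhu_stem, spec.dhu_loop) if spec.dhu_stem else None,
        anticodon_arm=(spec.ac_stem, AC_LOOP),
        tpsic_arm=(spec.t_stem, spec.t_loop),
        gu_pairs=sum(1 for i, j in pairs
                     if {sequence[i], sequence[j]} == {"G", "T"}),
        anticodon=spec.anticodon,
        pairs=tuple(sorted(pairs)),
    )
    return sequence, model


# ---------------------------------------------------------------------------
# codon evolution
# ---------------------------------------------------------------------------

def random_sense_codons(n: int, rng: np.random.Generator,
                        code: GeneticCode = VERTEBRATE_MITO,
                        base_probs: np.ndarray | None = None) -> list[str]:
    """n random sense codons; with ``base_probs`` (A,C,G,T) the codons are
    drawn with probability proportional to the product of their base
    frequencies, which lets simulated coding sequence carry a target
    composition bias the way real mitochondrial codon usage does."""
    codons = code.sense_codons
    if base_probs is None:
        idx = rng.integers(0, len(codons), size=n)
    else:
        lookup = dict(zip("ACGT", base_probs))
        w = np.array([lookup[c[0]] * lookup[c[1]] * lookup[c[2]]
                      for c in codons])
        idx = rng.choice(len(codons), size=n, p=w / w.sum())
    return [codons[i] for i in idx]


def _neighbor_rates(codon: str, omega: float, kappa: float,
                    code: GeneticCode) -> tuple[list[str], np.ndarray]:
    nbs, rates = [], []
    aa = code.forward[codon]
    for nb in codon_neighbors(codon):
        if code.is_stop(nb):
            continue
        pos = next(i for i in range(3) if nb[i] != codon[i])
        r = kappa if _TRANSITION[codon[pos]] == nb[pos] else 1.0
        if code.forward[nb] != aa:
            r *= omega
        nbs.append(nb)
        rates.append(r)
    return nbs, np.array(rates)


def evolve_codon_sequence(codons: list[str], branch_length: float,
                          omega: float, kappa: float,
                          rng: np.random.Generator,
                          code: GeneticCode = VERTEBRATE_MITO,
                          rate_scale: float | None = None) -> list[str]:
    """Gillespie simulation of codon substitution along one branch.

    Branch length is in expected substitutions per codon at the neutral
    scale fixed by ``rate_scale`` (mean total leaving rate over the ancestor
    codons; computed here when not supplied). Stop codons are forbidden
    states; transitions are ``kappa``-fold faster and nonsynonymous changes
    are ``omega``-fold slower.
    """
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if branch_length < 0:
        raise ValueError("branch length must be non-negative")
    if rate_scale is None:
        totals = [_neighbor_rates(c, omega, kappa, code)[1].sum()
                  for c in codons]
        rate_scale = float(np.mean(totals)) or 1.0
    out = []
    for codon in codons:
        t = 0.0
        cur = codon
        while True:
            nbs, rates = _neighbor_rates(cur, omega, kappa, code)
            total = rates.sum() / rate_scale
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= branch_length:
                break
            cur = nbs[rng.choice(len(nbs), p=rates / rates.sum())]
        out.append(cur)
    return out


def evolve_codon_alignment(ancestor_codons: list[str], tree: str,
                           omega: float, kappa: float = 2.0, seed: int = 0,
                           code: GeneticCode = VERTEBRATE_MITO,
                           ) -> dict[str, str]:
    """Evolve an ancestral in-frame CDS down a newick tree.

    Returns {leaf label: CDS string}; alignments are gap-free by
    construction (substitutions only).
    """
    for c in ancestor_codons:
        if code.is_stop(c):
            raise ValueError(f"ancestor contains stop codon {c}")
    t = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    rng = np.random.default_rng(seed)
    totals = [_neighbor_rates(c, omega, kappa, code)[1].sum()
              for c in ancestor_codons]
    scale = float(np.mean(totals)) or 1.0
    states: dict[int, list[str]] = {id(t.seed_node): list(ancestor_codons)}
    out: dict[str, str] = {}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        parent_state = states[id(node.parent_node)]
        bl = node.edge.length or 0.0
        child = evolve_codon_sequence(parent_state, bl, omega, kappa, rng,
                                      code, rate_scale=scale)
        states[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label] = "".join(child)
    return out


# ---------------------------------------------------------------------------
# random trees and additive matrices
# ---------------------------------------------------------------------------

def random_tree(n_taxa: int, seed: int = 0, min_bl: float = 0.05,
                max_bl: float = 1.0) -> str:
    """Random binary unrooted topology with uniform branch lengths, as
    newick over taxa t1..tN."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)

    def bl() -> float:
        return float(rng.uniform(min_bl, max_bl))

    nodes = [f"t{i + 1}:{bl():.6f}" for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{bl():.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]},{nodes[2]});"


def tree_distance_matrix(newick: str) -> tuple[list[str], np.ndarray]:
    """Leaf labels (sorted) and the additive patristic distance matrix."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    by_label = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(by_label[labels[i]], by_label[labels[j]])
            D[i, j] = D[j, i] = d
    return labels, D


# ---------------------------------------------------------------------------
# whole-mitogenome generator
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int | None = None        # None: determined by the layout
    target_at_skew: float = 0.0307
    target_gc_skew: float = -0.2899
    at_content: float = 0.568               # A+T fraction for free regions
    skew_tolerance: float = 0.01
    gene_order: tuple[str, ...] = CANONICAL_GENE_ORDER
    omega: float = 0.1
    kappa: float = 2.0
    tree: str | None = None
    dhu_less_trna: str = "trnS2"
    gtg_start_gene: str = "cox1"
    incomplete_stop_genes: tuple[str, ...] = ("cox2", "nad4", "cytb")
    spacer_range: tuple[int, int] = (0, 5)

    def __post_init__(self) -> None:
        for s in (self.target_at_skew, self.target_gc_skew):
            if not -1.0 < s < 1.0:
                raise ValueError("skew targets must lie strictly in (-1, 1)")


@dataclass
class SyntheticMitogenome:
    record: GenomeRecord
    table: FeatureTable
    trna_models: dict[str, CloverleafModel]
    planted_motifs: dict[str, list[int]]    # motif -> 1-based CR offsets
    config: SimulationConfig = field(repr=False, default=None)


def _base_probs(at: float, at_skew: float, gc_skew: float) -> np.ndarray:
    gc = 1.0 - at
    return np.array([
        at * (1 + at_skew) / 2,   # A
        gc * (1 - gc_skew) / 2,   # C
        gc * (1 + gc_skew) / 2,   # G
        at * (1 - at_skew) / 2,   # T
    ])


def _random_pcg(length: int, start_codon: str, stop_codon: str,
                rng: np.random.Generator, code: GeneticCode,
                base_probs: np.ndarray | None = None) -> str:
    """Random CDS: start codon + sense codons + (possibly incomplete) stop."""
    n_body = (length - 3 - len(stop_codon)) // 3
    if 3 + 3 * n_body + len(stop_codon) != length:
        raise ValueError(f"CDS length {length} incompatible with stop "
                         f"{stop_codon!r}")
    body = random_sense_codons(n_body, rng, code, base_probs=base_probs)
    return start_codon + "".join(body) + stop_codon


_CR_MOTIF_PLAN = (("GGTTTTT", (40, 300, 560)), ("CTTAATG", (120, 700)),
                  ("ATGTA", (200,)), ("TACAT", (450,)))


def generate_mitogenome(cfg: SimulationConfig | None = None,
                        code: GeneticCode = VERTEBRATE_MITO,
                        ) -> SyntheticMitogenome:
    """Simulate a complete annotated circular mitogenome.

    Feature lengths follow the packaged reference annotation; intergenic
    spacers are drawn from ``cfg.spacer_range``. After assembly, free
    positions (rRNA, spacers, non-motif control region) are flipped A<->T /
    G<->C until both genome-wide skews sit within ``cfg.skew_tolerance`` of
    their targets.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    ref_features = {f.name: f for f in reference_feature_table()}
    probs = _base_probs(cfg.at_content, cfg.target_at_skew, cfg.target_gc_skew)

    def random_free(length: int) -> str:
        return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])

    pieces: list[str] = []
    features: list[Feature] = []
    free_positions: list[int] = []     # genome coords (0-based) safe to flip
    trna_models: dict[str, CloverleafModel] = {}
    planted: dict[str, list[int]] = {m: [] for m, _ in _CR_MOTIF_PLAN}
    pos = 0  # 0-based running end

    def add_spacer() -> None:
        nonlocal pos
        lo, hi = cfg.spacer_range
        length = int(rng.integers(lo, hi + 1))
        if length:
            s = random_free(length)
            pieces.append(s)
            free_positions.extend(range(pos, pos + length))
            pos += length

    names = list(cfg.gene_order)
    for k, name in enumerate(names):
        ref = ref_features[name]
        length = ref.length
        strand = ref.strand
        start_codon = stop_codon = None
        if ref.feature_class == "PCG":
            start_codon = "GTG" if name == cfg.gtg_start_gene else "ATG"
            if name in cfg.incomplete_stop_genes:
                stop_codon = "T"
            elif name == "nad2":
                stop_codon = "TAG"
            else:
                stop_codon = "TAA"
            cds_probs = probs[[0, 1, 2, 3]] if strand == 'H' else probs[[3, 2, 1, 0]]
            cds = _random_pcg(length, start_codon, stop_codon, rng, code,
                              base_probs=cds_probs)
            seg = reverse_complement(cds) if strand == "L" else cds
        elif ref.feature_class == "tRNA":
            spec = TrnaSpec(dhu_stem=0, dhu_loop=10) \
                if name == cfg.dhu_less_trna else TrnaSpec()
            seq, model = generate_trna(spec, seed=int(rng.integers(2 ** 31)))
            trna_models[name] = model
            seg = reverse_complement(seq) if strand == "L" else seq
            length = len(seq)
        elif ref.feature_class == "rRNA":
            seg = random_free(length)
            free_positions.extend(range(pos, pos + length))
        elif ref.feature_class == "OL":
            stem = "".join(rng.choice(list("ACGT"), size=11))
            loop = "".join(rng.choice(["A", "C"], size=length - 22))
            hair = stem + loop + reverse_complement(stem)
            seg = reverse_complement(hair) if strand == "L" else hair
        else:  # CR with planted motifs
            cr = list(random_free(length))
            motif_pos: set[int] = set()
            for motif, offsets in _CR_MOTIF_PLAN:
                for off in offsets:
                    cr[off - 1:off - 1 + len(motif)] = list(motif)
                    planted[motif].append(off)
                    motif_pos.update(range(off - 1, off - 1 + len(motif)))
            seg = "".join(cr)
            free_positions.extend(pos + i for i in range(length)
                                  if i not in motif_pos)
        pieces.append(seg)
        features.append(Feature(name, ref.feature_class, strand,
                                pos + 1, pos + len(seg),
                                start_codon, stop_codon))
        pos += len(seg)
        if k < len(names) - 1:
            add_spacer()

    genome = list("".join(pieces))
    if cfg.genome_length is not None:
        if cfg.genome_length < len(genome):
            raise ValueError(
                f"genome_length {cfg.genome_length} too small for the layout "
                f"({len(genome)} bp required)")
        pad = cfg.genome_length - len(genome)
        if pad:
            tail = random_free(pad)
            free_positions.extend(range(len(genome), len(genome) + pad))
            genome.extend(tail)
            cr = features[-1]
            features[-1] = replace(cr, end=cr.end + pad)

    _polish_skews(genome, free_positions, cfg, rng)
    record = GenomeRecord(id=f"SYN{cfg.seed:08d}", sequence="".join(genome),
                          circular=True)
    table = FeatureTable(genome_length=len(genome), features=features,
                         circular=True)
    return SyntheticMitogenome(record=record, table=table,
                               trna_models=trna_models,
                               planted_motifs=planted, config=cfg)


def _polish_skews(genome: list[str], free: list[int], cfg: SimulationConfig,
                  rng: np.random.Generator, max_iter: int = 200000) -> None:
    """Flip free A<->T / G<->C positions until both skews hit target."""
    counts = {b: 0 for b in "ACGT"}
    for b in genome:
        counts[b] += 1
    free_by_base: dict[str, list[int]] = {b: [] for b in "ACGT"}
    for i in free:
        free_by_base[genome[i]].append(i)
    for _ in range(max_iter):
        at = (counts["A"] - counts["T"]) / max(1, counts["A"] + counts["T"])
        gc = (counts["G"] - counts["C"]) / max(1, counts["G"] + counts["C"])
        d_at = at - cfg.target_at_skew
        d_gc = gc - cfg.target_gc_skew
        half = cfg.skew_tolerance / 2
        if abs(d_at) <= half and abs(d_gc) <= half:
            return
        if abs(d_at) > abs(d_gc):
            src, dst = ("A", "T") if d_at > 0 else ("T", "A")
        else:
            src, dst = ("G", "C") if d_gc > 0 else ("C", "G")
        pool = free_by_base[src]
        if not pool:
            raise ValueError("skew targets unreachable with available free "
                             "positions")
        k = int(rng.integers(len(pool)))
        i = pool.pop(k)
        genome[i] = dst
        free_by_base[dst].append(i)
        counts[src] -= 1
        counts[dst] += 1
    raise ValueError("skew polishing did not converge")
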