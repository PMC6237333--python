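"""Supermatrix construction, distances, neighbor joining, bootstrap and
monophyly testing.

The inference stage implemented here is deliberately desk-scale: pairwise
distances (p, JC69 or K2P) on the concatenated protein-coding genes,
neighbor-joining agglomeration, and nonparametric bootstrap over alignment
columns. Heavier model-based inference (ML/Bayesian) is left to external
tools; trees they produce can be imported as newick and interrogated with
the same monophyly predicate.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .io_formats import PCG_NAMES

logger = logging.getLogger(__name__)

#: canonical concatenation order = gene order of the annotation table
CANONICAL_PCG_ORDER = tuple(PCG_NAMES)

_NT = set("ACGT")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class Supermatrix:
    taxa: list[str]
    sequences: dict[str, str]            # taxon -> concatenated row
    partitions: dict[str, tuple[int, int]]  # gene -> (start, end) 1-based incl.
    type: str = "nt"                     # "nt" or "aa"

    def __post_init__(self) -> None:
        lengths = {len(self.sequences[t]) for t in self.taxa}
        if len(lengths) != 1:
            raise ValueError("unequal supermatrix row lengths")
        (self.n_columns,) = lengths

    def columns_view(self) -> np.ndarray:
        """(n_taxa, n_columns) array of single characters."""
        return np.array([list(self.sequences[t]) for t in self.taxa])

    def resample_columns(self, cols: np.ndarray) -> "Supermatrix":
        arr = self.columns_view()[:, cols]
        seqs = {t: "".join(row) for t, row in zip(self.taxa, arr)}
        return Supermatrix(taxa=list(self.taxa), sequences=seqs,
                           partitions={"resampled": (1, len(cols))},
                           type=self.type)


@dataclass
class Phylogeny:
    newick: str                                  # with branch lengths
    supports: dict[frozenset, float] = field(default_factory=dict)
    taxon_groups: dict[str, str] = field(default_factory=dict)

    def tree(self, namespace: dendropy.TaxonNamespace | None = None,
             ) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick", preserve_underscores=True,
                                 taxon_namespace=namespace)

    def newick_with_supports(self) -> str:
        """Newick string with bootstrap percentages as internal-node labels."""
        tree = self.tree()
        taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        for node in tree.preorder_internal_node_iter():
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            key = _normalize_split(below, taxa)
            if key in self.supports:
                node.label = f"{self.supports[key]:.0f}"
        return tree.as_string(schema="newick", suppress_rooting=True).strip()


def concatenate(per_gene_alignments: dict[str, dict[str, str]],
                gene_order: tuple[str, ...] | None = None,
                type: str = "nt") -> Supermatrix:
    """Concatenate per-gene alignments into a partitioned supermatrix.

    Every gene must cover the identical taxon set and be aligned (equal
    within-gene lengths); otherwise the error lists every gene x taxon hole.
    Genes are appended in ``gene_order`` (default: annotation-table order for
    known genes, then alphabetical for the rest).
    """
    if not per_gene_alignments:
        raise ValueError("no alignments given")
    if gene_order is None:
        known = [g for g in CANONICAL_PCG_ORDER if g in per_gene_alignments]
        rest = sorted(g for g in per_gene_alignments if g not in CANONICAL_PCG_ORDER)
        gene_order = tuple(known + rest)
    all_taxa = sorted({t for aln in per_gene_alignments.values() for t in aln})
    holes = [(g, t) for g in gene_order for t in all_taxa
             if t not in per_gene_alignments[g]]
    if holes:
        raise ValueError(f"missing taxa in alignments: {holes}")
    partitions: dict[str, tuple[int, int]] = {}
    rows = {t: [] for t in all_taxa}
    col = 0
    for g in gene_order:
        aln = per_gene_alignments[g]
        glen = {len(s) for s in aln.values()}
        if len(glen) != 1:
            raise ValueError(f"{g}: unaligned input (unequal sequence lengths)")
        (width,) = glen
        partitions[g] = (col + 1, col + width)
        col += width
        for t in all_taxa:
            rows[t].append(aln[t].upper())
    return Supermatrix(taxa=all_taxa,
                       sequences={t: "".join(parts) for t, parts in rows.items()},
                       partitions=partitions, type=type)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _pair_distance(a: str, b: str, model: str) -> float:
    """Distance between two rows with pairwise deletion; nan when saturated."""
    valid = [(x, y) for x, y in zip(a, b) if x in _NT and y in _NT]
    if not valid:
        return math.nan
    n = len(valid)
    if model == "p" or model == "jc69":
        p = sum(x != y for x, y in valid) / n
        if model == "p":
            return p
        arg = 1.0 - (4.0 / 3.0) * p
        return math.nan if arg <= 0 else -0.75 * math.log(arg)
    if model == "k2p":
        P = sum((x, y) in _TRANSITIONS for x, y in valid) / n
        Q = sum(x != y and (x, y) not in _TRANSITIONS for x, y in valid) / n
        a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            return math.nan
        return -0.5 * math.log(a1 * math.sqrt(a2))
    raise ValueError(f"unknown distance model {model!r}")


def distance_matrix(sm: Supermatrix, model: str = "k2p") -> np.ndarray:
    """Symmetric pairwise distance matrix; saturated entries are nan."""
    model = model.lower()
    if model == "k2p" and sm.type != "nt":
        raise ValueError("K2P requires a nucleotide matrix")
    n = len(sm.taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _pair_distance(sm.sequences[sm.taxa[i]],
                                               sm.sequences[sm.taxa[j]], model)
    return D


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children")  # children: list of (child, branch length)

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(D: np.ndarray, labels: list[str]) -> Phylogeny:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Negative branch-length estimates are clamped to zero (the clamped total
    is logged). Returns an unrooted tree as newick with branch lengths.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if D.shape != (n, n):
        raise ValueError("matrix shape does not match label count")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains undefined entries")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("matrix must be symmetric with zero diagonal")

    nodes = [_Node(label=l) for l in labels]
    idx = list(range(n))
    D = D.copy()
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(idx) > 3:
        m = len(idx)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        fi, fj = idx[i_], idx[j_]
        dij = sub[i_, j_]
        li = clamp(0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2)))
        lj = clamp(dij - li)
        new = _Node(children=[(nodes[fi], li), (nodes[fj], lj)])
        # distances from the new node to the remaining ones
        new_row = np.zeros(D.shape[0] + 1)
        for k_, fk in enumerate(idx):
            if fk in (fi, fj):
                continue
            new_row[fk] = 0.5 * (D[fi, fk] + D[fj, fk] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(new)
        idx = [k for k in idx if k not in (fi, fj)] + [len(nodes) - 1]

    # resolve the final three nodes around a central vertex (three-point)
    a, b, c = idx
    la = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    root = _Node(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    if clamped:
        logger.info("neighbor joining clamped %.6g of negative branch length",
                    clamped)
    return Phylogeny(newick=root.newick() + ";")


# ---------------------------------------------------------------------------
# bipartitions, bootstrap, tree comparison
# ---------------------------------------------------------------------------

def _normalize_split(side: frozenset, taxa: set | frozenset) -> frozenset:
    """Canonical form of a bipartition: the side not containing the
    alphabetically first taxon."""
    ref = min(taxa)
    return frozenset(taxa - side) if ref in side else frozenset(side)


def bipartitions(phylo: Phylogeny | str) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree as canonical leaf sets."""
    newick = phylo.newick if isinstance(phylo, Phylogeny) else phylo
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out: set[frozenset] = set()
    for node in tree.preorder_internal_node_iter():
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(below) <= len(taxa) - 2:
            out.add(_normalize_split(below, taxa))
    return out


def bootstrap(sm: Supermatrix, model: str = "k2p", replicates: int = 100,
              seed: int = 0, per_gene: bool = False) -> Phylogeny:
    """NJ tree with bootstrap supports (% of replicates containing each
    original bipartition).

    Columns are resampled with replacement; with ``per_gene`` the resampling
    is stratified within each partition so every replicate keeps the original
    per-gene column counts.
    """
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    rng = np.random.default_rng(seed)
    base = neighbor_joining(distance_matrix(sm, model), sm.taxa)
    base_bips = bipartitions(base)
    hits = {b: 0 for b in base_bips}
    ncol = sm.n_columns
    for _ in range(replicates):
        if per_gene:
            cols = np.concatenate([
                rng.integers(lo - 1, hi, size=hi - lo + 1)
                for lo, hi in sm.partitions.values()
            ])
        else:
            cols = rng.integers(0, ncol, size=ncol)
        rep_sm = sm.resample_columns(cols)
        D = distance_matrix(rep_sm, model)
        if np.isnan(D).any():
            continue  # saturated replicate contributes no support
        rep_bips = bipartitions(neighbor_joining(D, rep_sm.taxa))
        for b in base_bips & rep_bips:
            hits[b] += 1
    supports = {b: 100.0 * k / replicates for b, k in hits.items()}
    return Phylogeny(newick=base.newick, supports=supports,
                     taxon_groups=dict(getattr(sm, "taxon_groups", {}) or {}))


def robinson_foulds(a: Phylogeny | str, b: Phylogeny | str) -> int:
    """Unweighted RF (symmetric) distance between two unrooted trees."""
    ns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=a.newick if isinstance(a, Phylogeny) else a,
                           schema="newick", taxon_namespace=ns)
    tb = dendropy.Tree.get(data=b.newick if isinstance(b, Phylogeny) else b,
                           schema="newick", taxon_namespace=ns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb)


def is_monophyletic(phylo: Phylogeny | str, taxa_subset: set[str],
                    outgroup: str) -> tuple[bool, set[str]]:
    """Does ``taxa_subset`` form a clade once the tree is rooted on
    ``outgroup``?

    Returns (verdict, intruders): the intruders are the taxa inside the
    subset's smallest containing clade that are not subset members (empty
    when monophyletic).
    """
    newick = phylo.newick if isinstance(phylo, Phylogeny) else phylo
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    if outgroup not in labels:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    missing = set(taxa_subset) - labels
    if missing or not taxa_subset:
        raise ValueError(f"unknown or empty taxon subset: {sorted(missing)}")
    og_node = tree.find_node_with_taxon_label(outgroup)
    tree.reroot_at_edge(og_node.edge, update_bipartitions=False)
    mrca = tree.mrca(taxon_labels=list(taxa_subset))
    clade = {l.taxon.label for l in mrca.leaf_iter()}
    intruders = clade - set(taxa_subset)
    return (not intruders, intruders)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_phylip(sm: Supermatrix, path) -> None:
    """Relaxed PHYLIP (name, two spaces, sequence)."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.n_columns}\n")
        for t in sm.taxa:
            fh.write(f"{t.replace(' ', '_')}  {sm.sequences[t]}\n")


def write_nexus(sm: Supermatrix, path) -> None:
    """NEXUS with a sets block carrying the gene partitions."""
    datatype = "DNA" if sm.type == "nt" else "PROTEIN"
    buf = io.StringIO()
    buf.write("#NEXUS\nBEGIN DATA;\n")
    buf.write(f"  DIMENSIONS NTAX={len(sm.taxa)} NCHAR={sm.n_columns};\n")
    buf.write(f"  FORMAT DATATYPE={datatype} MISSING=? GAP=-;\n  MATRIX\n")
    for t in sm.taxa:
        buf.write(f"    {t.replace(' ', '_')}  {sm.sequences[t]}\n")
    buf.write("  ;\nEND;\nBEGIN SETS;\n")
    for g, (lo, hi) in sm.partitions.items():
        buf.write(f"  CHARSET {g} = {lo}-{hi};\n")
    buf.write("END;\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
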