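"""Architecture-constrained cloverleaf validation of annotated tRNA genes.

This is not general RNA secondary-structure prediction: the search space is
the canonical cloverleaf layout only, written on the DNA gene sequence
(U == T). The layout, 5'->3':

    acceptor 5' (a bp) | spacer1 | DHU 5'(d) loop d_l DHU 3'(d) | spacer2 |
    anticodon 5'(c) loop(7) anticodon 3'(c) | variable(v) |
    T-arm 5'(t) loop t_l T-arm 3'(t) | spacer3 | acceptor 3' (a bp)

with a in 6..9 (a few mitochondrial tRNAs extend the acceptor stem to 9 bp),
d in {0, 3, 4} (0 models the DHU-less serine tRNA common to vertebrate
mitochondria), c in 4..6 with a fixed 7 nt anticodon loop, t in 4..5.
Every stem position must pair (Watson-Crick or G.U wobble); the placement
maximizing the number of paired positions wins, ties broken by more acceptor
pairs, then fewer G.U pairs, then leftmost DHU arm.
"""

from __future__ import annotations

from dataclasses import dataclass

from .control_region import can_pair

# placement grid bounds
ACCEPTOR_RANGE = range(6, 10)
DHU_STEM_CHOICES = (0, 3, 4)
DHU_LOOP_RANGE = range(4, 12)
DHU_ABSENT_GAP_RANGE = range(2, 13)   # unpaired connector when d == 0
AC_STEM_RANGE = range(4, 7)
AC_LOOP = 7
VAR_RANGE = range(0, 10)
T_STEM_RANGE = range(4, 6)
T_LOOP_RANGE = range(3, 10)
SPACER1_RANGE = range(0, 4)
SPACER2_RANGE = range(0, 3)
SPACER3_RANGE = range(0, 4)
MIN_LEN, MAX_LEN = 55, 95


@dataclass(frozen=True)
class CloverleafModel:
    acceptor_stem: int
    dhu_arm: tuple[int, int] | None      # (stem bp, loop nt); None = absent
    anticodon_arm: tuple[int, int]
    tpsic_arm: tuple[int, int]
    gu_pairs: int
    anticodon: str
    pairs: tuple[tuple[int, int], ...]   # 0-based (i, j) paired positions

    @property
    def total_paired(self) -> int:
        return 2 * len(self.pairs)

    @property
    def score(self) -> int:
        return len(self.pairs)


def _stem_pairs(seq: str, start: int, stem: int, loop: int,
                ) -> list[tuple[int, int]] | None:
    """Pairs of a hairpin arm at ``start`` (5' stem start), or None if any
    stem position fails to pair."""
    pairs = []
    for i in range(stem):
        x, y = start + i, start + 2 * stem + loop - 1 - i
        if not can_pair(seq[x], seq[y]):
            return None
        pairs.append((x, y))
    return pairs


def _acceptor_pairs(seq: str, a: int) -> list[tuple[int, int]] | None:
    n = len(seq)
    pairs = []
    for i in range(a):
        if not can_pair(seq[i], seq[n - 1 - i]):
            return None
        pairs.append((i, n - 1 - i))
    return pairs


def enumerate_placements(n: int):
    """Yield every grid placement tiling a sequence of length n.

    A placement is the tuple (a, s1, d, dl, s2, c, v, t, tl, s3); when d == 0
    dl is the unpaired DHU-replacement gap.
    """
    for a in ACCEPTOR_RANGE:
        for s1 in SPACER1_RANGE:
            for d in DHU_STEM_CHOICES:
                dl_range = DHU_ABSENT_GAP_RANGE if d == 0 else DHU_LOOP_RANGE
                for dl in dl_range:
                    for s2 in SPACER2_RANGE:
                        for c in AC_STEM_RANGE:
                            for t in T_STEM_RANGE:
                                for tl in T_LOOP_RANGE:
                                    for s3 in SPACER3_RANGE:
                                        used = (2 * a + s1 + 2 * d + dl + s2
                                                + 2 * c + AC_LOOP + t * 2 + tl
                                                + s3)
                                        v = n - used
                                        if v in VAR_RANGE:
                                            yield (a, s1, d, dl, s2, c, v,
                                                   t, tl, s3)


def _evaluate(seq: str, placement: tuple) -> CloverleafModel | None:
    a, s1, d, dl, s2, c, v, t, tl, s3 = placement
    acc = _acceptor_pairs(seq, a)
    if acc is None:
        return None
    pos = a + s1
    dhu_pairs: list[tuple[int, int]] = []
    if d > 0:
        got = _stem_pairs(seq, pos, d, dl)
        if got is None:
            return None
        dhu_pairs = got
    pos += 2 * d + dl if d > 0 else dl
    pos += s2
    ac = _stem_pairs(seq, pos, c, AC_LOOP)
    if ac is None:
        return None
    anticodon = seq[pos + c + 2: pos + c + 5]
    pos += 2 * c + AC_LOOP + v
    tp = _stem_pairs(seq, pos, t, tl)
    if tp is None:
        return None
    pairs = tuple(acc + dhu_pairs + ac + tp)
    gu = sum(1 for i, j in pairs if {seq[i], seq[j]} == {"G", "T"})
    return CloverleafModel(
        acceptor_stem=a,
        dhu_arm=(d, dl) if d > 0 else None,
        anticodon_arm=(c, AC_LOOP),
        tpsic_arm=(t, tl),
        gu_pairs=gu,
        anticodon=anticodon,
        pairs=pairs,
    )


def _rank(seq_len: int, placement: tuple, model: CloverleafModel) -> tuple:
    dhu_start = placement[0] + placement[1]
    return (-model.score, -model.acceptor_stem, model.gu_pairs, dhu_start,
            placement)


def fold_cloverleaf(trna_seq: str) -> CloverleafModel:
    """Best-scoring cloverleaf placement for one tRNA gene sequence.

    Raises when the length is outside 55..95 nt or no placement pairs fully;
    a DHU arm whose best stem would be under 3 bp is reported absent.
    """
    seq = trna_seq.upper().replace("U", "T")
    n = len(seq)
    if not MIN_LEN <= n <= MAX_LEN:
        raise ValueError(f"tRNA length {n} outside {MIN_LEN}..{MAX_LEN} nt")
    best: tuple | None = None
    best_model: CloverleafModel | None = None
    for placement in enumerate_placements(n):
        model = _evaluate(seq, placement)
        if model is None:
            continue
        key = _rank(n, placement, model)
        if best is None or key < best:
            best, best_model = key, model
    if best_model is None:
        raise ValueError("sequence admits no cloverleaf placement")
    return best_model


def count_gu_pairs(model: CloverleafModel, seq: str) -> int:
    """G.U wobble pairs among the model's paired positions (DNA alphabet,
    so the pair reads G/T)."""
    seq = seq.upper().replace("U", "T")
    return sum(1 for i, j in model.pairs if {seq[i], seq[j]} == {"G", "T"})


def fold_report(trna_seqs: dict[str, str]) -> dict[str, CloverleafModel | None]:
    """Fold every annotated tRNA; unfoldable sequences map to None."""
    out: dict[str, CloverleafModel | None] = {}
    for name, seq in trna_seqs.items():
        try:
            out[name] = fold_cloverleaf(seq)
        except ValueError:
            out[name] = None
    return out


def dot_bracket(model: CloverleafModel, seq_len: int) -> str:
    chars = ["."] * seq_len
    for i, j in model.pairs:
        chars[i], chars[j] = "(", ")"
    return "".join(chars)
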