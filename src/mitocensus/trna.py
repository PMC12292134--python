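"""Template-constrained cloverleaf folding of mitochondrial tRNAs.

Instead of thermodynamic folding, a tRNA is fit to the canonical
cloverleaf template — acceptor stem, D(HU) arm, anticodon arm, variable
loop, T(ΨC) arm — by exhaustive search over the template's geometric
windows, maximizing the number of paired stem bases.  Allowed pairs are
Watson–Crick plus the G·U wobble (G·T on the DNA alphabet used
throughout).  This suffices for the arm-level claims mitogenome papers
make (arm presence/absence, e.g. the recurrent D-arm loss of
mitochondrial trnS1, and wobble-pair censuses) while staying fully
deterministic: ties are broken toward canonical arm dimensions, then by
leftmost placement.

An arm is reported absent when its stem pairs fewer than
``FoldConfig.arm_min_pairs`` (default 2) bases in the best-scoring fold,
so a single spurious pair cannot manufacture an arm.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import TRNA, MitogenomeRecord

__all__ = ["FoldConfig", "Arm", "Cloverleaf", "fold_cloverleaf",
           "wobble_census", "trna_length_report", "TrnaLengthReport"]

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

ARM_NAMES = ("acceptor", "D", "anticodon", "T")


@dataclass(frozen=True)
class FoldConfig:
    """Search windows of the cloverleaf template (all lengths in nt).

    Defaults cover the dimensions of published vertebrate mitochondrial
    tRNA structures (55–95 nt overall).
    """

    acceptor_stem: tuple[int, ...] = (6, 7, 8)          # 7 ± 1 bp
    d_stem: tuple[int, ...] = (3, 4)                    # 0 (absent) added internally
    d_loop: tuple[int, int] = (4, 12)
    d_region_absent: tuple[int, int] = (4, 16)          # unpaired span when D arm absent
    link1: tuple[int, ...] = (1, 2, 3)                  # acceptor→D connector
    link2: tuple[int, ...] = (0, 1, 2)                  # D→anticodon connector
    anticodon_stem: tuple[int, ...] = (4, 5)
    anticodon_loop: int = 7
    variable_loop: tuple[int, int] = (3, 23)
    t_stem: tuple[int, ...] = (4, 5)
    t_loop: tuple[int, int] = (5, 9)
    tail: tuple[int, ...] = (0, 1, 2, 3)                # discriminator etc.
    length_range: tuple[int, int] = (55, 95)
    arm_min_pairs: int = 2


@dataclass
class Arm:
    """One arm of a folded cloverleaf."""

    name: str
    stem5: tuple[int, int]              # (start, length), 0-based
    stem3: tuple[int, int]
    loop: tuple[int, int] | None
    pairs: list[tuple[int, int]]        # matched (5', 3') positions only
    present: bool

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class Cloverleaf:
    """Best-scoring cloverleaf fit of one tRNA sequence."""

    sequence: str
    arms: dict[str, Arm]
    score: int                          # total paired bases across stems
    geometry: dict[str, int]
    anticodon: str | None = None
    anticodon_found: bool | None = None  # None when no anticodon supplied

    @property
    def wobble_pairs(self) -> list[tuple[str, tuple[int, int]]]:
        """(arm, (i, j)) for every matched pair that is G·T."""
        out = []
        for name in ARM_NAMES:
            for i, j in self.arms[name].pairs:
                if {self.sequence[i], self.sequence[j]} == {"G", "T"}:
                    out.append((name, (i, j)))
        return out

    @property
    def has_wobble(self) -> bool:
        return bool(self.wobble_pairs)

    @property
    def present_arms(self) -> tuple[str, ...]:
        return tuple(n for n in ARM_NAMES if self.arms[n].present)

    def dot_bracket(self) -> str:
        chars = ["."] * len(self.sequence)
        for arm in self.arms.values():
            for i, j in arm.pairs:
                chars[i], chars[j] = "(", ")"
        return "".join(chars)


def _pair_matrix(seq: str) -> np.ndarray:
    """A[i, j] = number of matched pairs on the anti-diagonal run
    (i, j), (i+1, j-1), ... — enables O(1) stem scoring."""
    L = len(seq)
    m = np.zeros((L, L), dtype=np.int32)
    for i in range(L):
        for j in range(L):
            if (seq[i], seq[j]) in _PAIRS:
                m[i, j] = 1
    a = np.zeros((L + 1, L + 1), dtype=np.int32)  # index shift on j: a[i, j+1]
    for i in range(L - 1, -1, -1):
        for j in range(L):
            a[i, j + 1] = m[i, j] + (a[i + 1, j] if j >= 1 else 0)
    return a


def _stem_score(a: np.ndarray, i: int, j: int, m: int) -> int:
    """Matched pairs among (i, j), (i+1, j-1), ..., length m."""
    if m == 0:
        return 0
    hi = a[i, j + 1]
    lo = a[i + m, j - m + 1] if j - m + 1 >= 0 else 0
    return int(hi - lo)


def fold_cloverleaf(
    seq: str,
    anticodon: str | None = None,
    config: FoldConfig = FoldConfig(),
) -> Cloverleaf:
    """Fold a tRNA sequence onto the cloverleaf template.

    Exhaustive search over all template geometries; the fold maximizing
    total paired bases wins, ties broken by distance from canonical arm
    dimensions and then by leftmost placement.  If an anticodon triplet is
    supplied and does not occur in the chosen anticodon loop, the result
    carries ``anticodon_found=False`` (a warning flag, not an error).
    """
    seq = seq.upper().replace("U", "T")
    if set(seq) - set("ACGT"):
        raise ValueError(f"sequence contains characters outside ACGT: "
                         f"{sorted(set(seq) - set('ACGT'))}")
    L = len(seq)
    lo, hi = config.length_range
    if not (lo <= L <= hi):
        raise ValueError(f"tRNA length {L} outside supported range [{lo}, {hi}]")

    A = _pair_matrix(seq)
    acl = config.anticodon_loop
    v_lo, v_hi = config.variable_loop

    best = None  # (-score, canon_dev, geom_tuple, payload)

    d_options = [(0, dl) for dl in range(config.d_region_absent[0],
                                         config.d_region_absent[1] + 1)]
    d_options += [(d, dl) for d in config.d_stem
                  for dl in range(config.d_loop[0], config.d_loop[1] + 1)]

    for a_len, l1, (d, dl), l2, c, t, tl, tail in product(
        config.acceptor_stem, config.link1, d_options, config.link2,
        config.anticodon_stem, config.t_stem,
        range(config.t_loop[0], config.t_loop[1] + 1), config.tail,
    ):
        fixed = 2 * a_len + l1 + 2 * d + dl + l2 + 2 * c + acl + 2 * t + tl + tail
        v = L - fixed
        if not (v_lo <= v <= v_hi):
            continue
        # absolute segment starts
        p_d5 = a_len + l1
        p_d3 = p_d5 + d + dl
        p_ac5 = p_d3 + d + l2
        p_ac3 = p_ac5 + c + acl
        p_t5 = p_ac3 + c + v
        p_t3 = p_t5 + t + tl
        p_acc3 = p_t3 + t

        s_acc = _stem_score(A, 0, p_acc3 + a_len - 1, a_len)
        s_d = _stem_score(A, p_d5, p_d3 + d - 1, d) if d else 0
        s_ac = _stem_score(A, p_ac5, p_ac3 + c - 1, c)
        s_t = _stem_score(A, p_t5, p_t3 + t - 1, t)
        score = s_acc + s_d + s_ac + s_t

        canon_dev = (
            abs(a_len - 7) + (abs(d - 4) if d else 4) + abs(c - 5) + abs(t - 5)
            + abs(tl - 7) + abs(l1 - 2) + abs(l2 - 1)
            + (abs(dl - 8) if d else 0) + abs(v - 4) + abs(tail - 1)
        )
        geom = (a_len, l1, d, dl, l2, c, t, tl, tail, v)
        key = (-score, canon_dev, geom)
        if best is None or key < best[0]:
            best = (key, geom)

    if best is None:
        raise ValueError(f"no template geometry fits length {L}; widen FoldConfig")

    (neg_score, _, _), geom = best
    a_len, l1, d, dl, l2, c, t, tl, tail, v = geom
    p_d5 = a_len + l1
    p_d3 = p_d5 + d + dl
    p_ac5 = p_d3 + d + l2
    p_ac3 = p_ac5 + c + acl
    p_t5 = p_ac3 + c + v
    p_t3 = p_t5 + t + tl
    p_acc3 = p_t3 + t

    def matched(i0: int, j_end: int, m: int) -> list[tuple[int, int]]:
        return [(i0 + k, j_end - k) for k in range(m)
                if (seq[i0 + k], seq[j_end - k]) in _PAIRS]

    arms = {
        "acceptor": Arm("acceptor", (0, a_len), (p_acc3, a_len), None,
                        matched(0, p_acc3 + a_len - 1, a_len), False),
        "D": Arm("D", (p_d5, d), (p_d3, d), (p_d5 + d, dl),
                 matched(p_d5, p_d3 + d - 1, d) if d else [], False),
        "anticodon": Arm("anticodon", (p_ac5, c), (p_ac3, c), (p_ac5 + c, acl),
                         matched(p_ac5, p_ac3 + c - 1, c), False),
        "T": Arm("T", (p_t5, t), (p_t3, t), (p_t5 + t, tl),
                 matched(p_t5, p_t3 + t - 1, t), False),
    }
    for arm in arms.values():
        arm.present = arm.n_pairs >= config.arm_min_pairs

    found = None
    if anticodon is not None:
        ac = anticodon.upper().replace("U", "T")
        loop_start, loop_len = arms["anticodon"].loop
        found = ac in seq[loop_start : loop_start + loop_len]

    return Cloverleaf(
        sequence=seq, arms=arms, score=-neg_score,
        geometry=dict(zip(
            ("acceptor_stem", "link1", "d_stem", "d_loop", "link2",
             "anticodon_stem", "t_stem", "t_loop", "tail", "variable_loop"),
            geom[:8] + (geom[8], geom[9]),
        )),
        anticodon=anticodon, anticodon_found=found,
    )


def wobble_census(
    structures: Mapping[str, Cloverleaf] | Sequence[Cloverleaf],
) -> tuple[Counter, dict[str, bool]]:
    """Count wobble (G·T) stem pairs per arm across a set of folded tRNAs.

    Returns ``(arm_counts, has_wobble)`` where ``has_wobble`` flags each
    tRNA (by mapping key, or list index as string).
    """
    if not isinstance(structures, Mapping):
        structures = {str(i): s for i, s in enumerate(structures)}
    arm_counts: Counter = Counter({n: 0 for n in ARM_NAMES})
    flags: dict[str, bool] = {}
    for name, cl in structures.items():
        for arm, _pair in cl.wobble_pairs:
            arm_counts[arm] += 1
        flags[name] = cl.has_wobble
    return arm_counts, flags


@dataclass(frozen=True)
class TrnaLengthReport:
    n: int
    min_bp: int
    max_bp: int
    total_bp: int
    shortest: tuple[str, ...]
    longest: tuple[str, ...]


def trna_length_report(record: MitogenomeRecord) -> TrnaLengthReport:
    """Min/max/total tRNA gene lengths from annotation coordinates."""
    trnas = [f for f in record.features if f.category == TRNA]
    if not trnas:
        raise ValueError("record has no tRNA features")
    lengths = {f.name: f.length for f in trnas}
    mn, mx = min(lengths.values()), max(lengths.values())
    return TrnaLengthReport(
        n=len(trnas), min_bp=mn, max_bp=mx, total_bp=sum(lengths.values()),
        shortest=tuple(sorted(n for n, l in lengths.items() if l == mn)),
        longest=tuple(sorted(n for n, l in lengths.items() if l == mx)),
    )
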