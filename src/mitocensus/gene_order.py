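"""Gene-order extraction and rearrangement comparison between mitogenomes.

Orders are signed sequences of gene symbols (sign = strand).  The default
comparison is unsigned — a strand flip alone does not create a breakpoint
— because mitogenome rearrangement surveys of this kind describe
translocations; signed mode is available by flag.  Circular orders are
canonicalized to start at trnF (the conventional vertebrate first gene)
when present, making all outputs rotation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import MitogenomeRecord

__all__ = ["GeneOrder", "extract_order", "breakpoint_distance", "diff_blocks",
           "Block"]


@dataclass(frozen=True)
class GeneOrder:
    """An ordered, signed gene arrangement for one taxon."""

    taxon: str
    symbols: tuple[str, ...]            # gene names, order as annotated
    signs: tuple[int, ...]              # +1 / -1 per symbol (strand)
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"{self.taxon}: empty gene order")
        if len(self.symbols) != len(set(self.symbols)):
            dups = sorted({s for s in self.symbols if self.symbols.count(s) > 1})
            raise ValueError(f"{self.taxon}: duplicate gene symbols {dups}")
        if len(self.signs) != len(self.symbols):
            raise ValueError("signs and symbols differ in length")

    def __len__(self) -> int:
        return len(self.symbols)

    @classmethod
    def from_symbols(cls, taxon: str, symbols: Sequence[str],
                     circular: bool = True) -> "GeneOrder":
        """Build from plain symbols; a leading ``-`` marks minus strand."""
        syms, signs = [], []
        for s in symbols:
            if s.startswith("-"):
                syms.append(s[1:])
                signs.append(-1)
            else:
                syms.append(s)
                signs.append(1)
        return cls(taxon=taxon, symbols=tuple(syms), signs=tuple(signs),
                   circular=circular)

    def canonical(self) -> "GeneOrder":
        """Rotate a circular order to start at trnF, else at the
        lexicographically smallest symbol; linear orders are returned
        unchanged."""
        if not self.circular:
            return self
        anchor = "trnF" if "trnF" in self.symbols else min(self.symbols)
        k = self.symbols.index(anchor)
        return GeneOrder(
            taxon=self.taxon,
            symbols=self.symbols[k:] + self.symbols[:k],
            signs=self.signs[k:] + self.signs[:k],
            circular=True,
        )

    def adjacencies(self, *, signed: bool = False) -> set:
        """Set of neighbouring-gene adjacencies (circular closure included
        for circular orders).

        Unsigned: an adjacency is the unordered symbol pair.  Signed: the
        oriented pair, identified with its reverse-complement reading
        ``(a, b) == (-b, -a)``.
        """
        n = len(self.symbols)
        idx = range(n if self.circular else n - 1)
        out = set()
        for i in idx:
            j = (i + 1) % n
            if signed:
                a = (self.signs[i], self.symbols[i])
                b = (self.signs[j], self.symbols[j])
                rc = ((-b[0], b[1]), (-a[0], a[1]))
                out.add(min((a, b), rc))
            else:
                out.add(frozenset((self.symbols[i], self.symbols[j])))
        return out


def extract_order(record: MitogenomeRecord) -> GeneOrder:
    """Gene order of an annotated record, symbols in ascending start order
    (control region included as a symbol)."""
    feats = sorted(record.features, key=lambda f: f.start)
    if not feats:
        raise ValueError(f"record {record.id} has no features")
    return GeneOrder(
        taxon=record.id,
        symbols=tuple(f.name for f in feats),
        signs=tuple(-1 if f.strand == "-" else 1 for f in feats),
        circular=record.topology == "circular",
    )


def _check_same_symbols(a: GeneOrder, b: GeneOrder) -> None:
    sa, sb = set(a.symbols), set(b.symbols)
    if sa != sb:
        only_a, only_b = sorted(sa - sb), sorted(sb - sa)
        raise ValueError(
            f"gene sets differ: only in {a.taxon}: {only_a}; "
            f"only in {b.taxon}: {only_b}"
        )


def breakpoint_distance(a: GeneOrder, b: GeneOrder, *, signed: bool = False) -> int:
    """Number of adjacencies of ``a`` absent from ``b`` (symmetric on equal
    symbol sets; 0 iff the orders coincide up to rotation for circular
    orders)."""
    _check_same_symbols(a, b)
    return len(a.adjacencies(signed=signed) - b.adjacencies(signed=signed))


@dataclass(frozen=True)
class Block:
    """A maximal run of ``a`` that is also contiguous (same direction)
    in ``b``."""

    symbols: tuple[str, ...]

    @property
    def label(self) -> str:
        if len(self.symbols) == 1:
            return self.symbols[0]
        return f"{self.symbols[0]}-{self.symbols[-1]}"

    def __len__(self) -> int:
        return len(self.symbols)


def diff_blocks(a: GeneOrder, b: GeneOrder) -> tuple[list[Block], list[Block]]:
    """Decompose ``a`` into maximal blocks contiguous in ``b``.

    Returns ``(blocks, displaced)``: the greedy maximal-common-run
    decomposition of the (canonicalized, for circular input) order of
    ``a`` with respect to ``b``, and the displaced blocks — every block
    except the longest one, which serves as the conserved backbone.
    Identical orders give a single block and no displaced blocks; a
    reciprocal translocation of two blocks reports exactly those two.
    """
    _check_same_symbols(a, b)
    ca = a.canonical() if a.circular else a
    n = len(ca.symbols)
    pos_b = {s: i for i, s in enumerate(b.symbols)}
    nb = len(b.symbols)

    def adjacent_in_b(x: str, y: str) -> bool:
        i, j = pos_b[x], pos_b[y]
        if b.circular:
            return (i + 1) % nb == j
        return i + 1 == j

    # break positions: i such that (a[i], a[i+1]) is not a forward adjacency in b
    breaks = [i for i in range(n if ca.circular else n - 1)
              if not adjacent_in_b(ca.symbols[i], ca.symbols[(i + 1) % n])]

    if not breaks:
        return [Block(ca.symbols)], []

    blocks: list[Block] = []
    # blocks run from just after one break to the next break (circularly)
    start = (breaks[-1] + 1) % n if ca.circular else 0
    boundaries = breaks if ca.circular else breaks + [n - 1]
    cur = start
    for brk in boundaries:
        syms = []
        i = cur
        while True:
            syms.append(ca.symbols[i])
            if i == brk:
                break
            i = (i + 1) % n
        blocks.append(Block(tuple(syms)))
        cur = (brk + 1) % n
    # rotate block list so the longest (backbone) block comes first
    longest = max(range(len(blocks)), key=lambda k: len(blocks[k]))
    blocks = blocks[longest:] + blocks[:longest]
    displaced = blocks[1:]
    return blocks, displaced
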