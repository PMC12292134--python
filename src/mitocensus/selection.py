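"""Pairwise dN/dS by the Nei–Gojobori (1986) counting method, with
Jukes–Cantor correction, plus distance-matrix plumbing (p-distance and a
neighbor-joining topology check).

The NG86 estimator counts, per codon, the fraction of the three possible
single-nucleotide changes at each position that are synonymous — giving
fractional synonymous (S) and nonsynonymous (N) site totals with
S + N = 3 × codons — and classifies observed between-sequence differences
by averaging over all minimal substitution pathways for multi-hit codons.
Proportions pS = sd/S and pN = nd/N are corrected with the Jukes–Cantor
formula d = −(3/4)·ln(1 − (4/3)p), undefined for p ≥ 3/4.

The genetic code is fixed to the vertebrate mitochondrial code (table 2);
changes creating a stop codon count as nonsynonymous at site-counting
time, and substitution pathways passing through a stop codon are excluded
from pathway averaging (all-blocked codons fall back to unrestricted
averaging).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .codon_usage import STOP_CODONS, translate_codon

__all__ = [
    "NG86Result", "ng86_pairwise", "gene_dnds_average", "GeneDnDs",
    "p_distance_matrix", "nj_tree", "jukes_cantor", "codon_sites",
    "codon_differences",
]

_BASES = "ACGT"


class FrameError(ValueError):
    """Internal stop codon — the sequence is not a clean in-frame CDS."""


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; ``None`` (undefined) for p ≥ 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def codon_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one sense
    codon: at each position, the fraction of the three possible changes
    that preserve the amino acid (changes to stops are nonsynonymous)."""
    aa = translate_codon(codon)
    if aa is None:
        raise FrameError(f"stop codon {codon} has no site decomposition")
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if translate_codon(alt) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _pathways(c1: str, c2: str) -> list[list[tuple[str, str]]]:
    """All orderings of the differing positions as lists of (from, to)
    codon steps."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            cur = nxt
        paths.append(steps)
    return paths


def codon_differences(c1: str, c2: str, *, exclude_stop_paths: bool = True) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense
    codons, averaged over minimal substitution pathways.

    By default pathways whose intermediate codons are stops are excluded
    (if every pathway is blocked, all are used — the conventional
    fallback); ``exclude_stop_paths=False`` averages over all pathways
    unconditionally, counting stop-traversing steps as nonsynonymous.
    """
    if c1 == c2:
        return 0.0, 0.0
    for c in (c1, c2):
        if c in STOP_CODONS:
            raise FrameError(f"stop codon {c} in comparison")
    paths = _pathways(c1, c2)
    open_paths = paths
    if exclude_stop_paths:
        open_paths = [
            p for p in paths
            if all(step_to not in STOP_CODONS for _, step_to in p[:-1])
        ] or paths
    sd = nd = 0.0
    for p in open_paths:
        for frm, to in p:
            if translate_codon(frm) == translate_codon(to) and to not in STOP_CODONS \
               and frm not in STOP_CODONS:
                sd += 1
            else:
                nd += 1
    k = len(open_paths)
    return sd / k, nd / k


@dataclass(frozen=True)
class NG86Result:
    """Full NG86 decomposition for one sequence pair."""

    S: float            # synonymous sites (fractional, pair-averaged)
    N: float            # nonsynonymous sites
    sd: float           # synonymous differences
    nd: float           # nonsynonymous differences
    codons: int         # codons actually compared (after pairwise filtering)

    @property
    def pS(self) -> float:
        return self.sd / self.S if self.S > 0 else 0.0

    @property
    def pN(self) -> float:
        return self.nd / self.N if self.N > 0 else 0.0

    @property
    def dS(self) -> float | None:
        return jukes_cantor(self.pS)

    @property
    def dN(self) -> float | None:
        return jukes_cantor(self.pN)

    @property
    def omega(self) -> float | None:
        """dN/dS; missing when dS is 0 or undefined (or dN undefined)."""
        ds, dn = self.dS, self.dN
        if ds is None or dn is None or ds == 0.0:
            return None
        return dn / ds


def _codons(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not a multiple of 3")
    return [seq[i : i + 3].upper() for i in range(0, len(seq), 3)]


def ng86_pairwise(
    cds_a: str | Sequence[str],
    cds_b: str | Sequence[str],
    *,
    allow_terminal_stop: bool = True,
    exclude_stop_paths: bool = True,
) -> NG86Result:
    """NG86 comparison of two equal-length, in-frame, gap-free CDS.

    Codons containing ambiguity characters (anything outside ACGT) in
    either sequence are dropped pairwise.  A shared terminal stop codon is
    trimmed (``allow_terminal_stop``); a stop anywhere else raises
    :class:`FrameError`.
    """
    a = list(cds_a) if not isinstance(cds_a, str) else _codons(cds_a)
    b = list(cds_b) if not isinstance(cds_b, str) else _codons(cds_b)
    a = [c.upper() for c in a]
    b = [c.upper() for c in b]
    if len(a) != len(b):
        raise ValueError(f"codon count mismatch: {len(a)} vs {len(b)}")
    if allow_terminal_stop and a and (a[-1] in STOP_CODONS or b[-1] in STOP_CODONS):
        a, b = a[:-1], b[:-1]

    S = N = sd = nd = 0.0
    n_used = 0
    for i, (ca, cb) in enumerate(zip(a, b)):
        if set(ca) - set(_BASES) or set(cb) - set(_BASES):
            continue  # pairwise ambiguity drop
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise FrameError(f"internal stop codon at codon {i + 1} ({ca}/{cb})")
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        ds_, dn_ = codon_differences(ca, cb, exclude_stop_paths=exclude_stop_paths)
        sd += ds_
        nd += dn_
        n_used += 1
    if n_used == 0:
        raise ValueError("no comparable codons after pairwise filtering")
    return NG86Result(S=S, N=N, sd=sd, nd=nd, codons=n_used)


@dataclass
class GeneDnDs:
    """Unweighted pair-mean dN/dS summary for one gene across a species set."""

    gene: str
    mean_dN: float
    mean_dS: float
    mean_omega: float | None
    n_pairs: int
    n_omega_pairs: int          # pairs contributing to the omega mean
    n_excluded: int             # pairs with undefined dS/dN or omega
    pairs: pd.DataFrame         # per-pair table

    @property
    def excluded_pairs(self) -> int:
        return self.n_excluded


def gene_dnds_average(
    sequences: Mapping[str, str | Sequence[str]],
    *,
    gene: str = "gene",
) -> GeneDnDs:
    """Average NG86 rates over all unordered species pairs of one gene.

    Sequences must be pre-aligned in frame and of equal codon length
    (ragged sets are rejected — alignment is upstream of this package).
    Pairs with undefined dS or dN are excluded from the dN/dS mean and
    counted in ``n_excluded``; they also drop out of the dN/dS mean when
    dS = 0.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 species")
    species = sorted(sequences)
    rows = []
    dn_vals, ds_vals, omega_vals = [], [], []
    excluded = 0
    for sp1, sp2 in combinations(species, 2):
        res = ng86_pairwise(sequences[sp1], sequences[sp2])
        ds, dn, om = res.dS, res.dN, res.omega
        rows.append({
            "gene": gene, "pair": f"{sp1}|{sp2}", "S": res.S, "N": res.N,
            "sd": res.sd, "nd": res.nd,
            "dS": math.nan if ds is None else ds,
            "dN": math.nan if dn is None else dn,
            "omega": math.nan if om is None else om,
        })
        if ds is None or dn is None:
            excluded += 1
            continue
        ds_vals.append(ds)
        dn_vals.append(dn)
        if om is not None:
            omega_vals.append(om)
        else:
            excluded += 1
    if not ds_vals:
        raise ValueError("no usable pairs (all dS/dN undefined)")
    return GeneDnDs(
        gene=gene,
        mean_dN=float(np.mean(dn_vals)),
        mean_dS=float(np.mean(ds_vals)),
        mean_omega=float(np.mean(omega_vals)) if omega_vals else None,
        n_pairs=len(rows),
        n_omega_pairs=len(omega_vals),
        n_excluded=excluded,
        pairs=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# distance / tree plumbing


def p_distance_matrix(sequences: Mapping[str, str]) -> pd.DataFrame:
    """Symmetric matrix of raw proportions of differing sites between
    equal-length concatenated sequences; sites with a non-ACGT character
    in either member of a pair are ignored for that pair."""
    species = sorted(sequences)
    lengths = {len(sequences[s]) for s in species}
    if len(lengths) != 1:
        raise ValueError(f"sequences differ in length: {sorted(lengths)}")
    arrs = {s: np.frombuffer(sequences[s].upper().encode(), dtype="S1") for s in species}
    bases = np.frombuffer(b"ACGT", dtype="S1")
    valid = {s: np.isin(arrs[s], bases) for s in species}
    n = len(species)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        a, b = arrs[species[i]], arrs[species[j]]
        ok = valid[species[i]] & valid[species[j]]
        total = int(ok.sum())
        if total == 0:
            raise ValueError(f"no comparable sites between {species[i]} and {species[j]}")
        p = float(((a != b) & ok).sum()) / total
        mat[i, j] = mat[j, i] = p
    return pd.DataFrame(mat, index=species, columns=species)


def nj_tree(matrix: pd.DataFrame) -> str:
    """Unrooted neighbor-joining tree (Newick) from a symmetric distance
    matrix.  Taxa are processed in sorted label order, which makes
    tie-breaking deterministic."""
    if matrix.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("distances must be finite")
    order = sorted(matrix.index)
    m = matrix.loc[order, order]
    dm = DistanceMatrix(m.values, ids=list(order))
    tree = _skbio_nj(dm)
    return str(tree).strip()
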