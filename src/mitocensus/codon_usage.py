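"""Codon extraction, RSCU and amino-acid usage under the vertebrate
mitochondrial genetic code (NCBI translation table 2).

Under table 2 AGA/AGG are stop codons, ATA encodes Met and TGA encodes
Trp — all three differ from the standard code and matter for every
statistic here.  RSCU (relative synonymous codon usage) for a sense codon
c in a synonymous family F is::

    RSCU_c = count_c * |F| / sum(count_f for f in F)

so a uniformly used family has RSCU 1 for every member and family RSCU
values always sum to the family size when the family was observed at all.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio.Data import CodonTable

from .io import PCG, GeneFeature, MitogenomeRecord

__all__ = [
    "VERTEBRATE_MITO", "GENETIC_CODE_ID", "STOP_CODONS", "SENSE_CODONS",
    "translate_codon", "synonymous_family", "CodonList", "CodonUsageTable",
    "extract_cds", "rscu", "start_stop_census", "amino_acid_composition",
]

GENETIC_CODE_ID = 2
VERTEBRATE_MITO = CodonTable.unambiguous_dna_by_id[GENETIC_CODE_ID]
STOP_CODONS = frozenset(VERTEBRATE_MITO.stop_codons)  # TAA, TAG, AGA, AGG
SENSE_CODONS = tuple(sorted(VERTEBRATE_MITO.forward_table))
ALL_CODONS = tuple(sorted(a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"))

#: amino acid by sense codon (one-letter), table 2
AA_BY_CODON: dict[str, str] = dict(VERTEBRATE_MITO.forward_table)

_FAMILIES: dict[str, tuple[str, ...]] = {}
for _c, _aa in AA_BY_CODON.items():
    _FAMILIES.setdefault(_aa, ())
_FAMILIES = {
    aa: tuple(sorted(c for c, a in AA_BY_CODON.items() if a == aa))
    for aa in _FAMILIES
}


def translate_codon(codon: str) -> str | None:
    """One-letter amino acid, or ``None`` for a stop codon."""
    return AA_BY_CODON.get(codon.upper())


def synonymous_family(codon: str) -> tuple[str, ...]:
    """All sense codons encoding the same amino acid (includes ``codon``)."""
    aa = translate_codon(codon)
    if aa is None:
        raise ValueError(f"{codon} is a stop codon under table {GENETIC_CODE_ID}")
    return _FAMILIES[aa]


@dataclass
class CodonList:
    """In-frame codons of one CDS, with the bookkeeping the censuses need."""

    gene: str
    codons: list[str]
    start_codon: str
    terminal_triplet: str
    trailing_bases: str = ""  # non-empty when length % 3 != 0 (incomplete stop)

    @property
    def incomplete(self) -> bool:
        return bool(self.trailing_bases)


def extract_cds(record: MitogenomeRecord, feature: GeneFeature) -> CodonList:
    """Split a protein-coding feature into codons.

    Minus-strand features are reverse-complemented first, so codons read
    in coding orientation.  A trailing partial codon (annotation length not
    divisible by 3 — the incomplete-stop convention) is trimmed and kept in
    ``trailing_bases``.  The first codon and the terminal triplet (the last
    complete codon, or the annotated tail) are exposed separately.
    """
    if feature.category != PCG:
        raise ValueError(f"{feature.name} is not a protein-coding gene")
    seq = record.feature_sequence(feature, oriented=True)
    n_codons, rem = divmod(len(seq), 3)
    if n_codons < 2:
        raise ValueError(f"{feature.name}: CDS shorter than 2 codons")
    codons = [seq[i : i + 3] for i in range(0, n_codons * 3, 3)]
    trailing = seq[n_codons * 3 :]
    # terminal triplet as annotated: last 3 bases of the span, which is the
    # last full codon when rem == 0 and the partial tail context otherwise
    terminal = seq[-3:]
    return CodonList(gene=feature.name, codons=codons, start_codon=codons[0],
                     terminal_triplet=terminal, trailing_bases=trailing)


@dataclass
class CodonUsageTable:
    """64-codon counts with RSCU and amino-acid tallies."""

    codon_counts: Counter = field(default_factory=Counter)
    genetic_code: int = GENETIC_CODE_ID

    @classmethod
    def from_codon_lists(
        cls,
        cds_list: Iterable[CodonList],
        *,
        include_start: bool = True,
        include_terminal: bool = False,
    ) -> "CodonUsageTable":
        """Aggregate codon counts over genes.

        Start codons are counted by default (a per-gene single-codon
        effect); terminal triplets are excluded by default because
        annotated terminal triplets are frequently incomplete stops or
        abutted neighbours rather than real codons.
        """
        counts: Counter = Counter()
        for cl in cds_list:
            codons = list(cl.codons)
            if not include_terminal and not cl.incomplete:
                codons = codons[:-1]
            if not include_start:
                codons = codons[1:]
            counts.update(c for c in codons if set(c) <= set("ACGT"))
        return cls(codon_counts=counts)

    @property
    def total(self) -> int:
        return sum(self.codon_counts.values())

    def aa_counts(self) -> Counter:
        """Amino-acid counts (stops tallied under ``*``)."""
        out: Counter = Counter()
        for codon, n in self.codon_counts.items():
            out[translate_codon(codon) or "*"] += n
        return out

    def rscu(self) -> dict[str, float | None]:
        return rscu(self.codon_counts)

    def to_frame(self, *, decimals: int | None = 2) -> pd.DataFrame:
        vals = self.rscu()
        rows = []
        for codon in ALL_CODONS:
            aa = translate_codon(codon) or "*"
            r = vals.get(codon)
            rows.append({
                "codon": codon, "aa": aa, "count": self.codon_counts.get(codon, 0),
                "rscu": (round(r, decimals) if decimals is not None else r)
                if r is not None else float("nan"),
            })
        return pd.DataFrame(rows)


def rscu(codon_counts: Mapping[str, int]) -> dict[str, float | None]:
    """RSCU per sense codon; a family never observed gets ``None`` for all
    its members (stop codons are not part of any family)."""
    out: dict[str, float | None] = {}
    for aa, family in _FAMILIES.items():
        total = sum(codon_counts.get(c, 0) for c in family)
        for c in family:
            out[c] = None if total == 0 else codon_counts.get(c, 0) * len(family) / total
    return out


def start_stop_census(
    record: MitogenomeRecord,
) -> tuple[Counter, Counter, float]:
    """Tally start codons and terminal triplets over the 13 PCGs.

    Annotated triplets are used verbatim when present; otherwise they are
    derived from the sequence.  Returns ``(start_tally, terminal_tally,
    taa_percent)`` where ``taa_percent = 100 * #TAA / #PCGs`` rounded to one
    decimal.  Terminal triplets that are not valid table-2 stops (incomplete
    stops such as ACT/TCT/CCT) are tallied as printed.
    """
    starts: Counter = Counter()
    terminals: Counter = Counter()
    n_pcg = 0
    for f in record.features:
        if f.category != PCG:
            continue
        n_pcg += 1
        start, term = f.start_codon, f.stop_codon
        if (start is None or term is None) and record.sequence is not None:
            cl = extract_cds(record, f)
            start = start or cl.start_codon
            term = term or cl.terminal_triplet
        if start is None or term is None:
            raise ValueError(
                f"{f.name}: no annotated start/stop triplet and no sequence to derive one"
            )
        starts[start.upper()] += 1
        terminals[term.upper()] += 1
    if n_pcg == 0:
        raise ValueError("record has no protein-coding genes")
    taa_pct = round(100.0 * terminals.get("TAA", 0) / n_pcg, 1)
    return starts, terminals, taa_pct


def amino_acid_composition(
    tables: Mapping[str, CodonUsageTable],
    *,
    as_frequency: bool = True,
) -> pd.DataFrame:
    """Species × amino-acid matrix from translated codon counts
    (heatmap-ready; rows ordered by species label, columns alphabetical).

    Stop tallies are dropped; with ``as_frequency`` each row is normalized
    to sum to 1.
    """
    if not tables:
        raise ValueError("need at least one species")
    rows = {}
    for species in sorted(tables):
        aa = tables[species].aa_counts()
        aa.pop("*", None)
        rows[species] = aa
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    df = df.reindex(sorted(df.columns), axis=1)
    if as_frequency:
        df = df.div(df.sum(axis=1), axis=0)
    return df
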