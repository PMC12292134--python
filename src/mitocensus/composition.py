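"""Base composition and strand-asymmetry (skew) statistics.

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C) are the standard
strand-asymmetry measures for mitogenomes; both live in [−1, 1] and are
undefined (reported as missing, never coerced to 0) when the denominator
is zero.  N bases are counted separately and excluded from every
denominator, keeping content and skew pure four-letter statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .io import CONTROL_REGION, PCG, TRNA, GeneFeature, MitogenomeRecord

__all__ = ["CompositionSummary", "base_composition", "at_skew", "gc_skew",
           "region_report", "report_frame"]


@dataclass(frozen=True)
class CompositionSummary:
    """Base counts and derived statistics for one labelled region."""

    region_label: str
    a: int
    c: int
    g: int
    t: int
    n: int = 0

    @property
    def total(self) -> int:
        """Non-N length."""
        return self.a + self.c + self.g + self.t

    @property
    def at_content(self) -> float:
        """Percent A+T over non-N positions."""
        return 100.0 * (self.a + self.t) / self.total

    @property
    def gc_content(self) -> float:
        return 100.0 * (self.g + self.c) / self.total

    @property
    def at_skew(self) -> float | None:
        return at_skew(self.a, self.t)

    @property
    def gc_skew(self) -> float | None:
        return gc_skew(self.g, self.c)

    def __add__(self, other: "CompositionSummary") -> "CompositionSummary":
        return CompositionSummary(
            region_label=f"{self.region_label}+{other.region_label}",
            a=self.a + other.a, c=self.c + other.c, g=self.g + other.g,
            t=self.t + other.t, n=self.n + other.n,
        )


def base_composition(seq: str, label: str = "region") -> CompositionSummary:
    """Count bases of a sequence (case-insensitive, alphabet {A,C,G,T,N})."""
    if not seq:
        raise ValueError("empty sequence")
    up = seq.upper()
    bad = set(up) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains characters outside ACGTN: {sorted(bad)}")
    return CompositionSummary(
        region_label=label,
        a=up.count("A"), c=up.count("C"), g=up.count("G"), t=up.count("T"),
        n=up.count("N"),
    )


def at_skew(a: float, t: float) -> float | None:
    """(A − T)/(A + T); ``None`` when A + T = 0.  Accepts counts or
    percentages — the statistic is scale-invariant."""
    if a + t == 0:
        return None
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> float | None:
    """(G − C)/(G + C); ``None`` when G + C = 0."""
    if g + c == 0:
        return None
    return (g - c) / (g + c)


def region_report(record: MitogenomeRecord) -> list[CompositionSummary]:
    """Composition summaries for the whole genome, every feature, and the
    conventional aggregate regions (concatenated PCGs, concatenated tRNAs,
    control region).

    Per-feature rows are computed on the annotated plus-strand span (the
    convention of whole-table mitogenome statistics); minus-strand features
    additionally get a ``<name> (RC)`` row on the reading-strand
    (reverse-complement) sequence, since skews flip sign between strands.
    """
    if record.sequence is None:
        raise ValueError(f"record {record.id} carries no sequence")
    out: list[CompositionSummary] = [base_composition(record.sequence, "genome")]

    def concat(category: str) -> str:
        return "".join(
            record.feature_sequence(f, oriented=False)
            for f in record.features if f.category == category
        )

    pcg = concat(PCG)
    if pcg:
        out.append(base_composition(pcg, "PCGs (concatenated)"))
    trna = concat(TRNA)
    if trna:
        out.append(base_composition(trna, "tRNAs (concatenated)"))
    for f in record.features:
        if f.category == CONTROL_REGION:
            out.append(base_composition(record.feature_sequence(f, oriented=False),
                                        "control region"))
    for f in record.features:
        out.append(base_composition(record.feature_sequence(f, oriented=False), f.name))
        if f.strand == "-":
            out.append(base_composition(record.feature_sequence(f, oriented=True),
                                        f"{f.name} (RC)"))
    return out


def report_frame(summaries: list[CompositionSummary], *, decimals: int | None = 2) -> pd.DataFrame:
    """Tabulate summaries (TSV-ready; percentages rounded to ``decimals``,
    pass ``None`` for full precision)."""
    rows = []
    for s in summaries:
        row = {
            "region": s.region_label, "A": s.a, "C": s.c, "G": s.g, "T": s.t, "N": s.n,
            "AT_pct": s.at_content, "GC_pct": s.gc_content,
            "AT_skew": s.at_skew if s.at_skew is not None else math.nan,
            "GC_skew": s.gc_skew if s.gc_skew is not None else math.nan,
        }
        if decimals is not None:
            for k in ("AT_pct", "GC_pct"):
                row[k] = round(row[k], decimals)
            for k in ("AT_skew", "GC_skew"):
                row[k] = round(row[k], 4) if not math.isnan(row[k]) else row[k]
        rows.append(row)
    return pd.DataFrame(rows)
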