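"""Reading, writing and coordinate bookkeeping for annotated mitogenomes.

A mitogenome is represented as a :class:`MitogenomeRecord`: an optional
circular nucleotide sequence plus an ordered list of :class:`GeneFeature`
annotations (1-based, inclusive coordinates on both ends, so that
``length = stop - start + 1``).  Records can be built from a tab-separated
feature table (the schema used in mitogenome papers: Gene, Start, Stop,
Strand, Length, Interval, Start Coding, Stop Coding) or from a GenBank
flat file via Biopython.

The census operations (:func:`junction_census`, :func:`strand_census`)
reproduce the standard genome-organization statistics of mitogenome
descriptions: counts of seamless junctions, overlaps and intergenic gaps
between consecutive genes, and the heavy/light strand split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "MitogenomeRecord",
    "JunctionCensus",
    "normalize_gene_name",
    "load_gene_name_map",
    "parse_feature_table",
    "write_feature_table",
    "parse_genbank",
    "write_genbank",
    "linear_gap",
    "junction_census",
    "strand_census",
    "load_reference_annotation",
]

PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"
CONTROL_REGION = "control_region"

CATEGORIES = (PCG, TRNA, RRNA, CONTROL_REGION)

#: Unicode characters accepted as a minus sign in input tables.
_MINUS_CHARS = "−–—"


class ParseError(ValueError):
    """Malformed input file (bad coordinate, unknown strand, ...)."""


class ValidationError(ValueError):
    """Input parsed but is internally inconsistent (declared vs computed)."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on a mitogenome.

    Coordinates are 1-based and inclusive on both ends.  ``strand`` is
    ``"+"``, ``"-"`` or ``None`` (the control region is conventionally left
    unassigned).  ``start_codon`` / ``stop_codon`` hold the annotated first
    and terminal triplet of a protein-coding gene verbatim — the terminal
    triplet of an incomplete stop (completed by polyadenylation) is kept
    as annotated, not "fixed".
    """

    name: str
    category: str
    start: int
    stop: int
    strand: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")
        if not (1 <= self.start <= self.stop):
            raise ValueError(
                f"{self.name}: require 1 <= start <= stop, got {self.start}..{self.stop}"
            )
        if self.strand not in ("+", "-", None):
            raise ValueError(f"{self.name}: bad strand {self.strand!r}")
        if self.category != PCG and (self.start_codon or self.stop_codon):
            raise ValueError(f"{self.name}: start/stop codons only valid for PCGs")

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


@dataclass
class MitogenomeRecord:
    """An annotated (optionally sequence-less) mitochondrial genome."""

    id: str
    features: list[GeneFeature]
    sequence: str | None = None
    topology: str = "circular"

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            bad = set(self.sequence) - set("ACGTN")
            if bad:
                raise ParseError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
            for f in self.features:
                if f.stop > len(self.sequence):
                    raise ValidationError(
                        f"feature {f.name} ({f.start}..{f.stop}) outside sequence "
                        f"of length {len(self.sequence)}"
                    )

    @property
    def length(self) -> int:
        """Molecule length: sequence length, else the annotation span."""
        if self.sequence is not None:
            return len(self.sequence)
        return max(f.stop for f in self.features) if self.features else 0

    def feature_sequence(self, feat: GeneFeature, *, oriented: bool = True) -> str:
        """Sequence of one feature; reverse-complemented for minus strand
        when ``oriented`` (the default), so the result reads 5'→3'."""
        if self.sequence is None:
            raise ValueError(f"record {self.id} carries no sequence")
        region = self.sequence[feat.start - 1 : feat.stop]
        if oriented and feat.strand == "-":
            return str(Seq(region).reverse_complement())
        return region

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def sorted_by_start(self) -> "MitogenomeRecord":
        rec = replace_record(self, features=sorted(self.features, key=lambda f: f.start))
        return rec


def replace_record(rec: MitogenomeRecord, **kw) -> MitogenomeRecord:
    new = MitogenomeRecord(
        id=kw.get("id", rec.id),
        features=kw.get("features", list(rec.features)),
        sequence=kw.get("sequence", rec.sequence),
        topology=kw.get("topology", rec.topology),
    )
    return new


@dataclass
class JunctionCensus:
    """Census of consecutive-feature junctions in annotation order.

    The census is linear over the printed feature order: the wrap-around
    junction from the last feature (control region) back to the first is
    not counted, so ``seamless + n_overlaps + n_gaps == len(features) - 1``.
    """

    seamless: int
    overlaps: list[tuple[str, int]] = field(default_factory=list)  # (pair, |gap|)
    gaps: list[tuple[str, int]] = field(default_factory=list)  # (pair, gap)

    @property
    def n_overlaps(self) -> int:
        return len(self.overlaps)

    @property
    def n_gaps(self) -> int:
        return len(self.gaps)

    def to_dict(self) -> dict:
        return {
            "seamless": self.seamless,
            "overlaps": {"count": self.n_overlaps, "pairs": [list(p) for p in self.overlaps]},
            "gaps": {"count": self.n_gaps, "pairs": [list(p) for p in self.gaps]},
        }


# ---------------------------------------------------------------------------
# gene-name normalization


def load_gene_name_map(path: str | Path | None = None) -> dict[str, str]:
    """Load the alias→canonical-symbol table (shipped as package data;
    pass ``path`` to use an edited copy)."""
    if path is None:
        text = resources.files("mitocensus.data").joinpath("gene_name_map.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    return {k.lower(): v for k, v in raw.items() if not k.startswith("_")}


_DEFAULT_NAME_MAP = None


def _default_name_map() -> dict[str, str]:
    global _DEFAULT_NAME_MAP
    if _DEFAULT_NAME_MAP is None:
        _DEFAULT_NAME_MAP = load_gene_name_map()
    return _DEFAULT_NAME_MAP


def normalize_gene_name(raw: str, name_map: Mapping[str, str] | None = None) -> tuple[str, str | None]:
    """Normalize a gene label to its canonical symbol.

    Returns ``(symbol, anticodon)``; the anticodon is extracted from a
    trailing parenthesis as in ``trnS1(gct)`` and is ``None`` otherwise.
    Unknown labels are returned stripped but otherwise untouched.
    """
    if name_map is None:
        name_map = _default_name_map()
    label = raw.strip().strip("*")
    anticodon = None
    if label.endswith(")") and "(" in label:
        base, _, rest = label.partition("(")
        cand = rest[:-1].strip().lower()
        if len(cand) == 3 and set(cand) <= set("acgtu"):
            anticodon = cand.replace("u", "t")
            label = base.strip()
    return name_map.get(label.lower(), label), anticodon


def _infer_category(symbol: str) -> str:
    low = symbol.lower()
    if low.startswith("trn"):
        return TRNA
    if low.startswith("rrn") or "rrna" in low:
        return RRNA
    if low in ("d-loop", "dloop", "control_region", "oh", "ol"):
        return CONTROL_REGION
    return PCG


# ---------------------------------------------------------------------------
# feature-table I/O

_TABLE_COLUMNS = ["Gene", "Start", "Stop", "Strand", "Length", "Interval",
                  "Start Coding", "Stop Coding"]


def _parse_int(text: str, *, row: str, column: str) -> int:
    """Parse a coordinate/length cell; thousands separators are stripped and
    typographic minus signs accepted."""
    cleaned = text.strip().replace(",", "").replace(" ", "")
    for ch in _MINUS_CHARS:
        cleaned = cleaned.replace(ch, "-")
    try:
        return int(cleaned)
    except ValueError:
        raise ParseError(f"row {row!r}: malformed integer {text!r} in column {column}") from None


def parse_feature_table(
    path: str | Path,
    *,
    record_id: str | None = None,
    name_map: Mapping[str, str] | None = None,
    validate: bool = True,
) -> MitogenomeRecord:
    """Parse a tab-separated annotation table into a sequence-less record.

    The declared Length column is cross-checked against ``stop - start + 1``
    and the declared Interval column against the computed junction gap;
    disagreement raises :class:`ValidationError` listing both values
    (``validate=False`` downgrades nothing — it skips the cross-checks).
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty feature table")
    header = [h.strip() for h in lines[0].split("\t")]
    missing = [c for c in _TABLE_COLUMNS[:3] if c not in header]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    idx = {c: header.index(c) for c in header}

    feats: list[GeneFeature] = []
    declared_intervals: list[int | None] = []
    for ln in lines[1:]:
        cells = ln.split("\t")

        def cell(col: str) -> str:
            i = idx.get(col)
            return cells[i].strip() if i is not None and i < len(cells) else ""

        raw_name = cell("Gene")
        symbol, anticodon = normalize_gene_name(raw_name, name_map)
        category = _infer_category(symbol)
        start = _parse_int(cell("Start"), row=raw_name, column="Start")
        stop = _parse_int(cell("Stop"), row=raw_name, column="Stop")
        strand_raw = cell("Strand")
        for ch in _MINUS_CHARS:
            strand_raw = strand_raw.replace(ch, "-")
        strand = strand_raw if strand_raw in ("+", "-") else None
        start_codon = cell("Start Coding") or None
        stop_codon = cell("Stop Coding") or None
        if category != PCG:
            start_codon = stop_codon = None
        feat = GeneFeature(
            name=symbol, category=category, start=start, stop=stop,
            strand=strand, start_codon=start_codon, stop_codon=stop_codon,
            anticodon=anticodon,
        )
        if validate and cell("Length"):
            declared = _parse_int(cell("Length"), row=raw_name, column="Length")
            if declared != feat.length:
                raise ValidationError(
                    f"row {raw_name!r}: declared length {declared} != computed "
                    f"{feat.length} (= {stop} - {start} + 1)"
                )
        declared_intervals.append(
            _parse_int(cell("Interval"), row=raw_name, column="Interval")
            if cell("Interval") else None
        )
        feats.append(feat)

    if validate:
        for i in range(len(feats) - 1):
            declared = declared_intervals[i]
            if declared is None:
                continue
            computed = linear_gap(feats[i], feats[i + 1])
            if declared != computed:
                raise ValidationError(
                    f"row {feats[i].name!r}: declared interval {declared} != "
                    f"computed gap {computed} to {feats[i + 1].name}"
                )

    return MitogenomeRecord(id=record_id or path.stem, features=feats, sequence=None)


def write_feature_table(record: MitogenomeRecord, path: str | Path) -> None:
    """Write the normalized tab-separated feature table (round-trips with
    :func:`parse_feature_table`)."""
    rows = ["\t".join(_TABLE_COLUMNS)]
    for i, f in enumerate(record.features):
        interval = (
            str(linear_gap(f, record.features[i + 1]))
            if i + 1 < len(record.features) else ""
        )
        name = f.name + (f"({f.anticodon})" if f.anticodon else "")
        rows.append("\t".join([
            name, str(f.start), str(f.stop), f.strand or "", str(f.length),
            interval, f.start_codon or "", f.stop_codon or "",
        ]))
    Path(path).write_text("\n".join(rows) + "\n")


def load_reference_annotation() -> MitogenomeRecord:
    """The published *Elops machnata* annotation table shipped with the
    package (sequence-less; 37 genes plus the control region)."""
    src = resources.files("mitocensus.data").joinpath("elops_machnata_annotation.tsv")
    with resources.as_file(src) as p:
        return parse_feature_table(p, record_id="Elops_machnata")


# ---------------------------------------------------------------------------
# GenBank I/O

_GB_TYPE_BY_CATEGORY = {PCG: "CDS", TRNA: "tRNA", RRNA: "rRNA", CONTROL_REGION: "D-loop"}
_CATEGORY_BY_GB_TYPE = {"CDS": PCG, "tRNA": TRNA, "rRNA": RRNA,
                        "D-loop": CONTROL_REGION, "misc_feature": CONTROL_REGION}


def parse_genbank(path: str | Path, *, name_map: Mapping[str, str] | None = None) -> MitogenomeRecord:
    """Parse a single-record GenBank flat file.

    Features on a ``complement(...)`` location get ``strand="-"``; names are
    normalized to canonical symbols; PCG start/terminal triplets are derived
    from the sequence.  Multi-record files and features outside the sequence
    (including origin-spanning compound locations) are rejected.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise ParseError(f"{path}: expected exactly one GenBank record, found {len(records)}")
    gb = records[0]
    seq = str(gb.seq).upper()
    topology = gb.annotations.get("topology", "linear")

    feats: list[GeneFeature] = []
    for sf in gb.features:
        if sf.type not in _CATEGORY_BY_GB_TYPE:
            continue
        if len(sf.location.parts) != 1:
            raise ParseError(
                f"{path}: feature {sf.type} at {sf.location} has a compound "
                "(origin-spanning?) location; not supported"
            )
        start = int(sf.location.start) + 1  # Biopython is 0-based half-open
        stop = int(sf.location.end)
        if stop > len(seq) or start < 1:
            raise ParseError(f"{path}: feature at {start}..{stop} outside sequence")
        label = (
            sf.qualifiers.get("gene", [None])[0]
            or sf.qualifiers.get("product", [None])[0]
            or sf.type
        )
        symbol, anticodon = normalize_gene_name(label, name_map)
        anticodon = sf.qualifiers.get("anticodon", [anticodon])[0]
        category = _CATEGORY_BY_GB_TYPE[sf.type]
        strand = None
        if category != CONTROL_REGION:
            strand = "-" if sf.location.strand == -1 else "+"
        start_codon = stop_codon = None
        if category == PCG:
            region = seq[start - 1 : stop]
            if strand == "-":
                region = str(Seq(region).reverse_complement())
            if len(region) >= 6:
                start_codon, stop_codon = region[:3], region[-3:]
        feats.append(GeneFeature(
            name=symbol, category=category, start=start, stop=stop,
            strand=strand, start_codon=start_codon, stop_codon=stop_codon,
            anticodon=anticodon,
        ))
    feats.sort(key=lambda f: (f.start, f.stop))
    return MitogenomeRecord(id=gb.id or Path(path).stem, features=feats,
                            sequence=seq, topology=topology)


def write_genbank(record: MitogenomeRecord, path: str | Path) -> None:
    """Write a record (sequence required) as a GenBank flat file that
    round-trips through :func:`parse_genbank`."""
    if record.sequence is None:
        raise ValueError("cannot write GenBank without a sequence")
    sr = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id[:16].replace(" ", "_"),
        description="synthetic annotated mitogenome" if record.id.startswith("SYNTH")
        else "annotated mitogenome",
        # fixed date keeps writes byte-reproducible across sessions
        annotations={"molecule_type": "DNA", "topology": record.topology,
                     "date": "01-JAN-2000"},
    )
    for f in record.features:
        strand = {"+": 1, "-": -1, None: None}[f.strand]
        loc = FeatureLocation(f.start - 1, f.stop, strand=strand)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        sr.features.append(SeqFeature(loc, type=_GB_TYPE_BY_CATEGORY[f.category],
                                      qualifiers=quals))
    SeqIO.write([sr], str(path), "genbank")


# ---------------------------------------------------------------------------
# census operations


def linear_gap(prev: GeneFeature, nxt: GeneFeature) -> int:
    """Non-coding distance between consecutive features:
    ``nxt.start - prev.stop - 1`` (negative = overlap, 0 = seamless)."""
    return nxt.start - prev.stop - 1


def junction_census(record: MitogenomeRecord) -> JunctionCensus:
    """Classify every consecutive junction (annotation order, linear — the
    wrap-around junction is excluded) as seamless, overlap or gap."""
    feats = record.features
    if len(feats) < 2:
        raise ValueError("junction census needs at least 2 features")
    seamless = 0
    overlaps: list[tuple[str, int]] = []
    gaps: list[tuple[str, int]] = []
    for a, b in zip(feats, feats[1:]):
        g = linear_gap(a, b)
        pair = f"{a.name}/{b.name}"
        if g == 0:
            seamless += 1
        elif g < 0:
            overlaps.append((pair, -g))
        else:
            gaps.append((pair, g))
    return JunctionCensus(seamless=seamless, overlaps=overlaps, gaps=gaps)


def strand_census(record: MitogenomeRecord) -> tuple[int, int]:
    """(plus, minus) gene counts; strand-less features (control region)
    are excluded."""
    plus = sum(1 for f in record.features if f.strand == "+")
    minus = sum(1 for f in record.features if f.strand == "-")
    return plus, minus
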