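"""Combined characterization report: one directory of TSV/JSON outputs
covering every analysis stage the inputs support.

Sequence-free inputs (a bare feature table) are first-class: the census,
strand and tRNA-length sections are produced and the sequence-dependent
sections (composition, codon usage, tRNA folding) are skipped with a
notice.  With two or more genomes a gene-order comparison section is
added.  Outputs are byte-reproducible for identical inputs and config
(fixed floating-point formatting, sorted keys).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .codon_usage import CodonUsageTable, extract_cds, start_stop_census
from .composition import region_report, report_frame
from .gene_order import breakpoint_distance, diff_blocks, extract_order
from .io import (PCG, TRNA, MitogenomeRecord, junction_census, parse_feature_table,
                 parse_genbank, strand_census, write_feature_table)
from .trna import fold_cloverleaf, trna_length_report, wobble_census

__all__ = ["ReportBundle", "run_report", "load_input"]


class StageError(RuntimeError):
    """A report stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ReportBundle:
    """Manifest of a finished report run."""

    out_dir: Path
    records: list[str]
    sections: dict[str, str]            # section → produced file or "skipped: why"
    metadata: dict

    def path(self, section: str) -> Path:
        return self.out_dir / self.sections[section]


def load_input(path: str | Path) -> MitogenomeRecord:
    """Sniff + parse one input (GenBank flat file or TSV feature table)."""
    path = Path(path)
    head = path.read_text(errors="replace").lstrip()[:5].upper()
    if head.startswith("LOCUS"):
        return parse_genbank(path)
    return parse_feature_table(path)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _census_dict(rec: MitogenomeRecord) -> dict:
    jc = junction_census(rec)
    plus, minus = strand_census(rec)
    tl = trna_length_report(rec)
    out = {
        "record": rec.id,
        "length_bp": rec.length,
        "n_features": len(rec.features),
        "junctions": jc.to_dict(),
        "strand": {"plus": plus, "minus": minus},
        "trna_lengths": {
            "n": tl.n, "min_bp": tl.min_bp, "max_bp": tl.max_bp,
            "total_bp": tl.total_bp, "shortest": list(tl.shortest),
            "longest": list(tl.longest),
        },
    }
    try:
        starts, stops, taa = start_stop_census(rec)
        out["start_codons"] = dict(sorted(starts.items()))
        out["terminal_triplets"] = dict(sorted(stops.items()))
        out["taa_percent"] = taa
    except ValueError:
        out["start_codons"] = None  # no annotation and no sequence
    return out


def run_report(
    inputs: list[str | Path],
    out_dir: str | Path,
    *,
    config: dict | None = None,
) -> ReportBundle:
    """Run every applicable stage on the inputs and write the bundle.

    On a stage failure, partial outputs are preserved next to a FAILED
    marker naming the stage, and :class:`StageError` is raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or {}
    sections: dict[str, str] = {}
    stage = "parse"
    try:
        records = [load_input(p) for p in inputs]

        stage = "census"
        census = [_census_dict(r) for r in records]
        (out / "census.json").write_text(json.dumps(census, indent=2, sort_keys=True))
        sections["census"] = "census.json"
        for r in records:
            write_feature_table(r, out / f"features_{r.id}.tsv")
        sections["features"] = f"features_<record>.tsv ({len(records)} files)"

        for r in records:
            if r.sequence is None:
                sections[f"composition:{r.id}"] = "skipped: input carries no sequence"
                sections[f"codons:{r.id}"] = "skipped: input carries no sequence"
                sections[f"trna_structure:{r.id}"] = "skipped: input carries no sequence"
                continue
            stage = f"composition:{r.id}"
            _write_tsv(report_frame(region_report(r)), out / f"composition_{r.id}.tsv")
            sections[f"composition:{r.id}"] = f"composition_{r.id}.tsv"

            stage = f"codons:{r.id}"
            cds = [extract_cds(r, f) for f in r.features if f.category == PCG]
            table = CodonUsageTable.from_codon_lists(
                cds, include_start=config.get("include_start", True))
            _write_tsv(table.to_frame(), out / f"codon_usage_{r.id}.tsv")
            sections[f"codons:{r.id}"] = f"codon_usage_{r.id}.tsv"

            stage = f"trna_structure:{r.id}"
            folds = {}
            for f in r.features:
                if f.category == TRNA:
                    folds[f.name] = fold_cloverleaf(r.feature_sequence(f),
                                                    anticodon=f.anticodon)
            arm_counts, flags = wobble_census(folds)
            rows = []
            for name, cl in folds.items():
                for arm_name in ("acceptor", "D", "anticodon", "T"):
                    arm = cl.arms[arm_name]
                    rows.append({
                        "trna": name, "arm": arm_name, "present": arm.present,
                        "stem_pairs": arm.n_pairs,
                        "wobble_pairs": sum(1 for a, _ in cl.wobble_pairs
                                            if a == arm_name),
                    })
            _write_tsv(pd.DataFrame(rows), out / f"trna_structure_{r.id}.tsv")
            (out / f"trna_dotbracket_{r.id}.txt").write_text(
                "".join(f">{n}\n{cl.sequence}\n{cl.dot_bracket()}\n"
                        for n, cl in folds.items()))
            sections[f"trna_structure:{r.id}"] = f"trna_structure_{r.id}.tsv"

        if len(records) >= 2:
            stage = "gene_order"
            orders = [extract_order(r) for r in records]
            rows = []
            for i in range(len(orders)):
                for j in range(i + 1, len(orders)):
                    try:
                        d = breakpoint_distance(orders[i], orders[j])
                        _, displaced = diff_blocks(orders[i], orders[j])
                        blocks = ";".join(b.label for b in displaced) or "-"
                    except ValueError as e:
                        d, blocks = -1, f"incomparable: {e}"
                    rows.append({"a": orders[i].taxon, "b": orders[j].taxon,
                                 "breakpoints": d, "displaced_blocks": blocks})
            _write_tsv(pd.DataFrame(rows), out / "gene_order.tsv")
            sections["gene_order"] = "gene_order.tsv"

        stage = "metadata"
        meta = {
            "version": __version__,
            "inputs": [str(p) for p in inputs],
            "config": config,
            "config_hash": hashlib.sha256(
                json.dumps(config, sort_keys=True).encode()).hexdigest()[:16],
        }
        (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        sections["metadata"] = "metadata.json"
    except Exception as e:  # preserve partials, mark the failed stage
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {e}\n")
        if isinstance(e, StageError):
            raise
        raise StageError(stage, e) from e

    return ReportBundle(out_dir=out, records=[r.id for r in records],
                        sections=sections, metadata=meta)
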