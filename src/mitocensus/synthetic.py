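"""Synthetic annotated mitogenomes with known ground truth.

The generator lays out a circular ~16.7 kb vertebrate-style mitogenome
(13 PCGs, 22 tRNAs, 2 rRNAs, control region) from an order template
transcribed from a published teleost annotation, so the default genome
reproduces that genome's junction structure (seamless/overlap/gap
census) by construction.  Protein-coding genes are valid
vertebrate-mitochondrial-code ORFs sampled from a codon-bias vector;
tRNA genes instantiate designed cloverleaf structures (optionally
without a D arm, and with designed G·T wobble pairs); the control region
is filled at elevated AT.  Every generated dataset ships a sidecar dict
recording the true parameters, so pipeline outputs can be asserted
against ground truth rather than re-runs.

Annotated overlaps are resolved "first writer wins": where two features
share bases, the later feature adopts the bases already laid down.  With
the default layout this corrupts only stop-codon tails and tRNA termini
(never start codons or D arms); affected features are flagged
``overlap_affected`` in the sidecar and realized start/terminal triplets
are re-extracted from the assembled genome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
from Bio import Phylo

from .codon_usage import AA_BY_CODON, SENSE_CODONS, STOP_CODONS, translate_codon
from .gene_order import GeneOrder
from .io import (CONTROL_REGION, PCG, RRNA, TRNA, GeneFeature,
                 MitogenomeRecord, linear_gap, load_reference_annotation)

__all__ = ["GeneratorConfig", "TrnaDesign", "generate_trna", "generate_genome",
           "evolve_sequences", "inject_rearrangement", "default_order_template",
           "FeatureSpec"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# order template


@dataclass(frozen=True)
class FeatureSpec:
    """One slot of the layout template."""

    name: str
    category: str
    length: int
    strand: str | None
    gap_after: int | None           # linear gap to the next feature (None = last)
    anticodon: str | None = None
    start_codon: str = "ATG"        # PCGs only


def default_order_template() -> list[FeatureSpec]:
    """Layout template transcribed from the published *E. machnata*
    annotation: 37 genes + control region with its exact junction
    (overlap/gap) structure, lengths and strands."""
    ref = load_reference_annotation()
    specs = []
    for i, f in enumerate(ref.features):
        gap = linear_gap(f, ref.features[i + 1]) if i + 1 < len(ref.features) else None
        specs.append(FeatureSpec(
            name=f.name, category=f.category, length=f.length, strand=f.strand,
            gap_after=gap, anticodon=f.anticodon,
            start_codon=f.start_codon or "ATG",
        ))
    return specs


# ---------------------------------------------------------------------------
# tRNA designs


@dataclass(frozen=True)
class TrnaDesign:
    """Ground-truth cloverleaf design for one generated tRNA.

    ``wobble`` maps arm name → number of designed G·T pairs in that stem.
    ``d_arm=False`` replaces the whole D region by an unpairable C/A
    linker (the mitochondrial trnS1 situation).
    """

    length: int = 72
    d_arm: bool = True
    wobble: Mapping[str, int] = field(default_factory=dict)
    anticodon: str | None = None
    #: stem bases are drawn at this AT fraction (a Watson-Crick pair keeps
    #: the AT/GC balance of its 5' base, so stems track the genome target)
    at_fraction: float = 0.5


# canonical arm dimensions used by designs (match the folder's canonical
# tie-break preferences): acceptor 7, D 4, anticodon 5, T 5
_CANON = dict(a=7, l1=2, d=4, dl=8, l2=1, c=5, acl=7, v=4, t=5, tl=7, tail=1)


def _design_geometry(length: int, d_arm: bool) -> dict[str, int]:
    """Fit canonical geometry to a target length by adjusting the
    flexible spans (variable loop, D loop, T loop, tail, connectors)."""
    g = dict(_CANON)
    bounds = {"v": (3, 23), "dl": (4, 12), "tl": (5, 9), "tail": (0, 3), "l1": (1, 3)}

    def total() -> int:
        return (2 * g["a"] + g["l1"] + 2 * g["d"] + g["dl"] + g["l2"]
                + 2 * g["c"] + g["acl"] + g["v"] + 2 * g["t"] + g["tl"] + g["tail"])

    for key in ("v", "dl", "tl", "tail", "l1"):
        lo, hi = bounds[key]
        delta = length - total()
        if delta == 0:
            break
        step = max(lo, min(hi, g[key] + delta))
        g[key] = step
    if total() != length:
        raise ValueError(f"cannot fit canonical cloverleaf geometry to length {length}")
    return g


def generate_trna(
    rng: np.random.Generator,
    design: TrnaDesign = TrnaDesign(),
    *,
    verify: bool = True,
    max_tries: int = 50,
) -> tuple[str, dict]:
    """Build a tRNA sequence realizing ``design`` and return it with the
    ground-truth sidecar (arm presence, wobble counts/positions, geometry).

    Stems are random with exact Watson–Crick complements (G·T at designed
    wobble positions); loops and connectors are drawn from {C, A}, which
    cannot pair with each other.  With ``verify`` (the default) candidates
    are rejection-sampled until the designed structure is what the
    template folder actually recovers — loop bases can occasionally pair
    with stem bases in a shifted register, and rejection guarantees the
    sidecar really is ground truth.  Sampling stays deterministic under a
    fixed generator state.
    """
    for _ in range(max_tries):
        seq, truth = _build_trna(rng, design)
        if not verify:
            return seq, truth
        from .trna import fold_cloverleaf  # local import: avoid cycle at import time

        cl = fold_cloverleaf(seq, anticodon=design.anticodon)
        presence = {a: cl.arms[a].present for a in cl.arms}
        folded_wobble = {a: 0 for a in cl.arms}
        for arm, _pair in cl.wobble_pairs:
            folded_wobble[arm] += 1
        ok = (presence == truth["arms_present"]
              and folded_wobble == truth["wobble"]
              and (design.anticodon is None or cl.anticodon_found))
        if ok:
            return seq, truth
    raise RuntimeError(f"could not realize tRNA design {design} in {max_tries} tries")


def _build_trna(rng: np.random.Generator, design: TrnaDesign) -> tuple[str, dict]:
    g = _design_geometry(design.length, design.d_arm)

    def loop(n: int) -> str:
        return "".join(rng.choice(["C", "A"], size=n))

    at = design.at_fraction
    stem_probs = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]

    def stem(n: int, arm: str, lo_pos: int = 1) -> tuple[str, str, int]:
        """(5' side, 3' side, n_wobble). Wobble positions are kept away
        from stem ends so annotated-overlap corruption at tRNA termini
        cannot destroy them."""
        five = list(rng.choice(list("ACGT"), size=n, p=stem_probs))
        n_wob = min(design.wobble.get(arm, 0), max(0, n - lo_pos - 1))
        positions = rng.choice(np.arange(lo_pos, n - 1), size=n_wob,
                               replace=False) if n_wob else []
        for p in positions:
            five[p] = "G" if rng.random() < 0.5 else "T"
        three = [{"A": "T", "C": "G", "G": "C", "T": "A"}[b] for b in five]
        for p in positions:
            three[p] = "T" if five[p] == "G" else "G"
        # 3' side is read back-to-front in the cloverleaf
        return "".join(five), "".join(reversed(three)), int(n_wob)

    acc5, acc3, w_acc = stem(g["a"], "acceptor", lo_pos=2)
    if design.d_arm:
        d5, d3, w_d = stem(g["d"], "D")
        d_region = d5 + loop(g["dl"]) + d3
    else:
        d_region = loop(2 * g["d"] + g["dl"])
        w_d = 0
    ac5, ac3, w_ac = stem(g["c"], "anticodon")
    t5, t3, w_t = stem(g["t"], "T")

    acl = list(loop(g["acl"]))
    anticodon = design.anticodon
    if anticodon:
        ac_trip = anticodon.upper().replace("U", "T")
        acl[2:5] = list(ac_trip)
    seq = (acc5 + loop(g["l1"]) + d_region + loop(g["l2"])
           + ac5 + "".join(acl) + ac3 + loop(g["v"])
           + t5 + loop(g["tl"]) + t3 + acc3 + loop(g["tail"]))
    assert len(seq) == design.length

    truth = {
        "length": design.length,
        "d_arm": design.d_arm,
        "arms_present": {"acceptor": True, "D": design.d_arm,
                         "anticodon": True, "T": True},
        "wobble": {"acceptor": w_acc, "D": w_d, "anticodon": w_ac, "T": w_t},
        "anticodon": design.anticodon,
        "geometry": g,
    }
    return seq, truth


def default_trna_wobble_plan(trna_names: Sequence[str]) -> dict[str, dict[str, int]]:
    """Deterministic wobble assignment emulating the published census
    shape: 13 tRNAs carry wobble pairs, distributed as acceptor 8, T 7,
    anticodon 7, D 6 (the D-armless tRNA gets none in its D arm)."""
    plan: dict[str, dict[str, int]] = {n: {} for n in trna_names}
    carriers = list(trna_names[:13])
    for i, name in enumerate(carriers):
        w: dict[str, int] = {}
        if i < 8:
            w["acceptor"] = 1
        if 5 <= i <= 11:
            w["T"] = 1
        if 6 <= i <= 12:
            w["anticodon"] = 1
        if 7 <= i <= 12:
            w["D"] = 1
        plan[name] = w
    return plan


# ---------------------------------------------------------------------------
# genome generation


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic mitogenome.

    Defaults emulate the published study conditions: genome-wide AT
    fraction 0.5253 with the control region at 0.6333, the published
    order/junction template, a D-armless trnS1, GTG start for cox1 (all
    from the template), and the 13-carrier wobble plan.
    """

    seed: int = 0
    at_fraction: float = 0.5253
    cr_at_fraction: float = 0.6333
    genome_length: int | None = None        # None → determined by the layout
    order_template: list[FeatureSpec] | None = None
    codon_bias: Mapping[str, float] | None = None   # over sense codons
    trna_templates: Mapping[str, TrnaDesign] | None = None
    d_armless: tuple[str, ...] = ("trnS1",)
    syn_rate: float = 0.1                    # evolve_sequences defaults
    nonsyn_rate: float = 0.02

    def validate(self) -> None:
        if not (0.0 < self.at_fraction < 1.0):
            raise ValueError("at_fraction must be in (0, 1)")
        if not (0.0 < self.cr_at_fraction < 1.0):
            raise ValueError("cr_at_fraction must be in (0, 1)")
        if self.codon_bias is not None:
            w = np.array(list(self.codon_bias.values()), dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("codon_bias weights must be non-negative and normalizable")


def _codon_bias_from_at(at: float) -> dict[str, float]:
    """Independent-base codon weights matching a genome-wide AT target."""
    p = {"A": at / 2, "T": at / 2, "G": (1 - at) / 2, "C": (1 - at) / 2}
    return {c: p[c[0]] * p[c[1]] * p[c[2]] for c in SENSE_CODONS}


def _random_bases(rng: np.random.Generator, n: int, at: float) -> str:
    probs = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _pcg_sequence(rng: np.random.Generator, length: int, start_codon: str,
                  bias: Mapping[str, float]) -> str:
    """A valid table-2 ORF: start codon, sense codons from the bias vector
    (no in-frame stops by construction), complete or incomplete stop."""
    n_codons, rem = divmod(length, 3)
    codons = list(bias)
    w = np.array([bias[c] for c in codons], dtype=float)
    w = w / w.sum()
    n_middle = n_codons - 1 - (1 if rem == 0 else 0)
    middle = rng.choice(codons, size=max(n_middle, 0), p=w)
    tail = {0: "", 1: "T", 2: "TA"}[rem]
    stop = ("TAA" if rng.random() < 0.7 else "TAG") if rem == 0 else ""
    return start_codon + "".join(middle) + stop + tail


def generate_genome(cfg: GeneratorConfig) -> tuple[MitogenomeRecord, dict]:
    """Generate an annotated circular mitogenome plus its ground-truth
    sidecar.  Same config (incl. seed) ⇒ byte-identical output."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    template = list(cfg.order_template or default_order_template())
    bias = dict(cfg.codon_bias or _codon_bias_from_at(cfg.at_fraction))

    # coordinates
    coords: list[tuple[FeatureSpec, int, int]] = []
    pos = 1
    for spec in template:
        start, stop = pos, pos + spec.length - 1
        coords.append((spec, start, stop))
        pos = stop + 1 + (spec.gap_after or 0)
    span = max(stop for _, _, stop in coords)
    if cfg.genome_length is not None:
        if cfg.genome_length < span:
            raise ValueError(
                f"infeasible layout: features span {span} bp > genome_length "
                f"{cfg.genome_length}"
            )
        extra = cfg.genome_length - span
        if extra and coords[-1][0].category == CONTROL_REGION:
            spec, start, stop = coords[-1]
            coords[-1] = (replace_speclen(spec, spec.length + extra), start, stop + extra)
            span += extra
    L = span

    trna_names = [s.name for s in template if s.category == TRNA]
    wobble_plan = default_trna_wobble_plan(trna_names)
    designs: dict[str, TrnaDesign] = {}
    for s in template:
        if s.category != TRNA:
            continue
        if cfg.trna_templates and s.name in cfg.trna_templates:
            designs[s.name] = cfg.trna_templates[s.name]
        else:
            designs[s.name] = TrnaDesign(
                length=s.length, d_arm=s.name not in cfg.d_armless,
                wobble=wobble_plan.get(s.name, {}), anticodon=s.anticodon,
                at_fraction=cfg.at_fraction,
            )

    genome: list[str | None] = [None] * L
    sidecar_features = []
    trna_truth: dict[str, dict] = {}
    for spec, start, stop in coords:
        if spec.category == PCG:
            gene_seq = _pcg_sequence(rng, spec.length, spec.start_codon, bias)
        elif spec.category == TRNA:
            gene_seq, truth = generate_trna(rng, designs[spec.name])
            trna_truth[spec.name] = truth
        elif spec.category == RRNA:
            gene_seq = _random_bases(rng, spec.length, cfg.at_fraction)
        else:  # control region
            gene_seq = _random_bases(rng, spec.length, cfg.cr_at_fraction)
        genomic = _revcomp(gene_seq) if spec.strand == "-" else gene_seq
        affected = False
        for i, base in enumerate(genomic):
            gi = start - 1 + i
            if genome[gi] is None:
                genome[gi] = base
            else:
                affected = True  # first writer wins
        sidecar_features.append({
            "name": spec.name, "category": spec.category, "start": start,
            "stop": stop, "strand": spec.strand, "length": stop - start + 1,
            "overlap_affected": affected,
            "designed_start_codon": spec.start_codon if spec.category == PCG else None,
            "trna_design": trna_truth.get(spec.name),
        })
    for i in range(L):
        if genome[i] is None:
            genome[i] = _random_bases(rng, 1, cfg.at_fraction)
    seq = "".join(genome)  # type: ignore[arg-type]

    features = []
    for spec, start, stop in coords:
        start_codon = stop_codon = None
        if spec.category == PCG:
            region = seq[start - 1 : stop]
            if spec.strand == "-":
                region = _revcomp(region)
            start_codon, stop_codon = region[:3], region[-3:]
        features.append(GeneFeature(
            name=spec.name, category=spec.category, start=start, stop=stop,
            strand=spec.strand, start_codon=start_codon, stop_codon=stop_codon,
            anticodon=spec.anticodon,
        ))
    record = MitogenomeRecord(id=f"SYNTH{cfg.seed:08d}", features=features,
                              sequence=seq, topology="circular")
    for fd, f in zip(sidecar_features, features):
        fd["realized_start_codon"] = f.start_codon
        fd["realized_stop_codon"] = f.stop_codon

    sidecar = {
        "config": {
            "seed": cfg.seed, "at_fraction": cfg.at_fraction,
            "cr_at_fraction": cfg.cr_at_fraction, "genome_length": L,
        },
        "junction_spec": {
            "seamless": sum(1 for s in template if s.gap_after == 0),
            "overlaps": sum(1 for s in template
                            if s.gap_after is not None and s.gap_after < 0),
            "gaps": sum(1 for s in template
                        if s.gap_after is not None and s.gap_after > 0),
        },
        "order": [("-" if s.strand == "-" else "") + s.name for s in template],
        "d_armless": [n for n, d in designs.items() if not d.d_arm],
        "features": sidecar_features,
    }
    return record, sidecar


def replace_speclen(spec: FeatureSpec, length: int) -> FeatureSpec:
    return FeatureSpec(name=spec.name, category=spec.category, length=length,
                       strand=spec.strand, gap_after=spec.gap_after,
                       anticodon=spec.anticodon, start_codon=spec.start_codon)


# ---------------------------------------------------------------------------
# sequence evolution along a tree

_SYN_NEIGHBORS: dict[str, list[str]] = {}
_NONSYN_NEIGHBORS: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    syn, non = [], []
    for _pos in range(3):
        for _b in "ACGT":
            if _b == _c[_pos]:
                continue
            _alt = _c[:_pos] + _b + _c[_pos + 1 :]
            if _alt in STOP_CODONS:
                continue
            (syn if AA_BY_CODON[_alt] == AA_BY_CODON[_c] else non).append(_alt)
    _SYN_NEIGHBORS[_c] = syn
    _NONSYN_NEIGHBORS[_c] = non


def evolve_sequences(
    root: str | int,
    tree: str,
    *,
    syn_rate: float,
    nonsyn_rate: float,
    seed: int | np.random.Generator = 0,
    single_hit: bool = False,
) -> tuple[dict[str, str], list[dict]]:
    """Evolve codon sequences along a Newick tree.

    ``root`` is either an in-frame sense-codon sequence or a codon count
    (a random root is then drawn).  Rates are expected substitutions per
    codon per unit branch length, split into synonymous moves (within a
    table-2 family, single-nucleotide) and nonsynonymous moves (across
    families, single-nucleotide, never creating a stop).  Returns
    ``(tip_sequences, event_log)``; the event log is the ground truth for
    dN/dS tests (``nonsyn_rate=0`` guarantees identical protein sequences).

    With ``single_hit`` every codon position is mutated at most once over
    the whole tree, so between any two tips each differing codon differs
    by exactly one nucleotide — the regime in which the NG86 counting
    classification is exact (a synonymous-only run then gives dN = 0 and
    a nonsynonymous-only run dS = 0, by construction).
    """
    if syn_rate < 0 or nonsyn_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(root, int):
        root_codons = list(rng.choice(list(SENSE_CODONS), size=root))
    else:
        root_codons = [root[i : i + 3].upper() for i in range(0, len(root), 3)]
        bad = [c for c in root_codons if c not in AA_BY_CODON]
        if bad:
            raise ValueError(f"root contains non-sense codons: {bad[:5]}")
    n = len(root_codons)

    phylo = Phylo.read(StringIO(tree), "newick")
    tips: dict[str, str] = {}
    events: list[dict] = []
    untouched: set[int] = set(range(n))  # single-hit bookkeeping (whole tree)

    def descend(clade, codons: list[str]) -> None:
        codons = list(codons)
        bl = clade.branch_length or 0.0
        n_syn = rng.poisson(syn_rate * bl * n)
        n_non = rng.poisson(nonsyn_rate * bl * n)
        kinds = ["S"] * n_syn + ["N"] * n_non
        rng.shuffle(kinds)
        for kind in kinds:
            table = _SYN_NEIGHBORS if kind == "S" else _NONSYN_NEIGHBORS
            for _ in range(50):
                i = int(rng.integers(n))
                if single_hit and i not in untouched:
                    continue
                cands = table[codons[i]]
                if cands:
                    untouched.discard(i)
                    new = cands[int(rng.integers(len(cands)))]
                    events.append({"branch": clade.name, "codon_index": i,
                                   "kind": kind, "from": codons[i], "to": new})
                    codons[i] = new
                    break
        if clade.is_terminal():
            if not clade.name:
                raise ValueError("tree has unnamed tips")
            tips[clade.name] = "".join(codons)
        else:
            for child in clade.clades:
                descend(child, codons)

    descend(phylo.root, root_codons)
    return tips, events


# ---------------------------------------------------------------------------
# rearrangement injection


def inject_rearrangement(
    order: GeneOrder,
    block_a: Sequence[str],
    block_b: Sequence[str],
) -> GeneOrder:
    """Exchange two disjoint contiguous blocks of a gene order (a
    reciprocal translocation); all other adjacencies are preserved."""
    syms = list(order.symbols)
    signs = list(order.signs)

    def locate(block: Sequence[str]) -> int:
        m = len(block)
        for i in range(len(syms) - m + 1):
            if syms[i : i + m] == list(block):
                return i
        raise ValueError(f"block {list(block)} is not contiguous in {order.taxon}")

    ia, ib = locate(block_a), locate(block_b)
    la, lb = len(block_a), len(block_b)
    if ia == ib and list(block_a) == list(block_b):
        return order  # self-swap is the identity
    if ia > ib:
        (ia, la), (ib, lb) = (ib, lb), (ia, la)
        block_a, block_b = block_b, block_a
    if ia + la > ib:
        raise ValueError("blocks overlap")
    sign_a, sign_b = signs[ia : ia + la], signs[ib : ib + lb]
    new_syms = (syms[:ia] + list(block_b) + syms[ia + la : ib]
                + list(block_a) + syms[ib + lb :])
    new_signs = (signs[:ia] + sign_b + signs[ia + la : ib]
                 + sign_a + signs[ib + lb :])
    return GeneOrder(taxon=order.taxon, symbols=tuple(new_syms),
                     signs=tuple(new_signs), circular=order.circular)
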