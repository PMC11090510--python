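"""Synthetic annotated genomes with planted CoCoNuT loci and ground truth.

Every stage of the pipeline is testable without a database download: the
generator assembles proteins from domain tokens — real sequence segments
carrying the literal motifs the built-in scanners detect (Walker A/B and
the Nx(xx)D signature, HEPN RxxxxH/RxH, the VWA MIDAS pattern, CPxC
repeats, heptad repeats for coiled-coils) embedded in seeded random
background — plus named placeholder tags for profile-only domains, which
the mock profile-search adapter replays as domain hits. Operon geometry
follows the planted architectures: co-oriented genes with intergenic gaps
drawn at or below the 90 nt linkage threshold, including occasional
overlapping reading frames (negative gaps).

Spacer segments inside regions the motif scanners examine exclude the
motif's own anchor residues, so each planted locus is architecture-
unambiguous by construction; background elsewhere is uniform over the
20-letter alphabet.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional

from . import vocab
from .core import AA_ALPHABET, Contig, DomainHit, GeneRecord, ProteinRecord
from .io import GenomeBundle

COCONUT_LABELS = ("I-A", "I-B", "Pseudo-I-B", "I-C", "II", "III-A", "III-B", "III-C")

HEPTAD = "IEALEKK"  # ideal coiled-coil heptad (core I/L at a/d)
WALKER_A = "GESGSGKS"
WALKER_B = "ILLVDE"
_SIGNATURE = {1: "NVD", 2: "NSSD", 3: "NVSTD"}


@dataclass
class SimConfig:
    seed: int = 0
    loci_per_subtype: int = 1
    non_coconut_count: int = 2
    decoy_count: int = 6
    contig_count: int = 0  # 0 = one planted locus per contig
    mean_intergenic_gap_nt: int = 45  # within-operon gaps ~ U[0, 2*mean]
    overlap_prob: float = 0.2  # chance of overlapping reading frames
    include_superoperons: bool = True
    include_extended_IIIA: bool = True

    def __post_init__(self) -> None:
        for name in ("loci_per_subtype", "non_coconut_count", "decoy_count",
                     "contig_count", "mean_intergenic_gap_nt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TruthRecord:
    locus_id: str
    contig_id: str
    label: str
    roles: dict[str, str]  # gene_id -> component role
    mcrB_gene_id: Optional[str]
    mcrC_gene_id: Optional[str]
    motif_positions: dict[str, int] = field(default_factory=dict)
    ancillary: dict[str, object] = field(default_factory=dict)


class SyntheticGenome(NamedTuple):
    bundle: GenomeBundle
    truth: list[TruthRecord]
    planted: dict[str, list[tuple[str, int, int]]]  # protein_id -> (name, start, end)


def _bg(rng: random.Random, n: int, forbid: str = "") -> str:
    alphabet = [a for a in AA_ALPHABET if a not in forbid]
    return "".join(rng.choice(alphabet) for _ in range(n))


class _ProteinBuilder:
    def __init__(self) -> None:
        self.parts: list[str] = []
        self.tags: list[tuple[str, int, int]] = []
        self.marks: dict[str, int] = {}
        self._len = 0

    def add(self, seq: str, *names: str, mark: Optional[str] = None) -> None:
        start = self._len
        self.parts.append(seq)
        self._len += len(seq)
        for name in names:
            self.tags.append((name, start, self._len))
        if mark is not None:
            self.marks[mark] = start

    def coiled_coil(self, heptads: int) -> None:
        self.add(HEPTAD * heptads)

    @property
    def sequence(self) -> str:
        return "".join(self.parts)


def _gtpase(b: _ProteinBuilder, rng: random.Random, spacer_k: int = 1,
            insert_aa: int = 12) -> None:
    """GTPase domain with Walker A, Walker B, and an N-x{k}-D signature
    ``insert_aa`` residues after Walker B. Spacers exclude the residues
    that would create spurious Walker or signature matches."""
    start = b._len
    b.add(_bg(rng, 20, forbid="K"))
    b.add(WALKER_A)
    b.add(_bg(rng, 18, forbid="D"))
    b.add(WALKER_B)
    b.add(_bg(rng, insert_aa, forbid="ND"))
    b.add(_SIGNATURE[spacer_k] + "E", mark="signature_N")
    b.add(_bg(rng, 25))
    b.tags.append((vocab.COG1401, start, b._len))


def _hepn(b: _ProteinBuilder, rng: random.Random, motif: str = "RxxxxH") -> None:
    start = b._len
    b.add(_bg(rng, 10, forbid="RH"))
    b.add("RNIAEH" if motif == "RxxxxH" else "RSH")
    b.add(_bg(rng, 24, forbid="RH"))
    b.tags.append((vocab.HEPN, start, b._len))


def _vwa(b: _ProteinBuilder, rng: random.Random, intact: bool = True) -> None:
    start = b._len
    b.add(_bg(rng, 15, forbid="DST"))
    b.add("DLSYS")
    b.add(_bg(rng, 40, forbid="DT"))
    b.add("T" if intact else "A")
    b.add(_bg(rng, 30, forbid="DT"))
    b.add("D")
    b.add(_bg(rng, 10, forbid="DT"))
    b.tags.append((vocab.VWA, start, b._len))


def _znr(b: _ProteinBuilder, rng: random.Random, n_cpxc: int) -> None:
    start = b._len
    b.add(_bg(rng, 6, forbid="C"))
    for _ in range(n_cpxc):
        b.add("CPAC")
        b.add(_bg(rng, 6, forbid="C"))
    b.tags.append((vocab.ZNR, start, b._len))


def _tagged(b: _ProteinBuilder, rng: random.Random, name: str, length: int) -> None:
    b.add(_bg(rng, length), name)


# ---------------------------------------------------------------------------
# Component protein builders
# ---------------------------------------------------------------------------


def _make_cnuB(rng: random.Random, label: str) -> _ProteinBuilder:
    b = _ProteinBuilder()
    if label == "I-A":
        _tagged(b, rng, vocab.CSD, 60)
        b.coiled_coil(10)
        _gtpase(b, rng, spacer_k=1, insert_aa=110)  # helical insert
    elif label in ("I-B", "Pseudo-I-B"):
        _tagged(b, rng, vocab.CSD, 60)
        _tagged(b, rng, vocab.YTH, 60)
        _gtpase(b, rng, spacer_k=1)
    elif label == "I-C":
        _tagged(b, rng, vocab.CSD, 60)
        _tagged(b, rng, vocab.YTH, 60)
        b.coiled_coil(10)
        _gtpase(b, rng, spacer_k=1)
    elif label == "non_CoCoNuT_McrBC":
        _tagged(b, rng, "DUF3578", 60)  # ADAM methylcytosine-binding domain
        _gtpase(b, rng, spacer_k=2)
    else:  # II, III-A, III-B, III-C: coiled-coil fused at the N-terminus
        b.coiled_coil(10)
        _gtpase(b, rng, spacer_k=1)
    return b


def _make_cnuC(rng: random.Random, label: str) -> _ProteinBuilder:
    b = _ProteinBuilder()
    if label == "III-A":  # CnuCD fusion: DUF2357 + Hsp70 NBD/SBD + HEAT
        _tagged(b, rng, vocab.DUF2357, 80)
        _tagged(b, rng, vocab.CSD, 60)
        b.coiled_coil(10)
        _tagged(b, rng, vocab.HSP70, 120)
        _tagged(b, rng, vocab.HEAT, 60)
        return b
    _tagged(b, rng, vocab.IG_LIKE, 50)
    _tagged(b, rng, vocab.DUF2357, 80)
    if label == "I-A":
        _tagged(b, rng, vocab.CSD, 60)
        b.coiled_coil(10)
        _znr(b, rng, 3)
        _tagged(b, rng, vocab.PD_DEXK, 70)
    elif label == "II":  # reductive evolution: CSD lost, two CPxC motifs
        b.coiled_coil(6)
        _znr(b, rng, 2)
        _tagged(b, rng, vocab.PD_DEXK, 70)
    elif label in ("I-B", "I-C", "Pseudo-I-B", "III-B", "III-C",
                   "non_CoCoNuT_McrBC"):
        _tagged(b, rng, vocab.PD_DEXK, 70)
    return b


def _make_cnuH(rng: random.Random, label: str) -> _ProteinBuilder:
    b = _ProteinBuilder()
    if label in ("II", "III-A"):
        _tagged(b, rng, vocab.SPB, 55)
        _tagged(b, rng, vocab.RTL, 50)
        _tagged(b, rng, vocab.SF1_HELICASE, 150)
        b.coiled_coil(5)  # helical insertion after Walker A
        _tagged(b, rng, vocab.OB_STALK, 60)
    elif label == "III-B":  # Sul7s-like wHTH; Vsr effector fused directly
        _tagged(b, rng, vocab.WHTH, 50)
        _tagged(b, rng, vocab.SF1_HELICASE, 150)
        b.coiled_coil(5)
        _tagged(b, rng, vocab.OB_STALK, 60)
        _tagged(b, rng, vocab.VSR, 60)
    else:  # III-C
        _tagged(b, rng, vocab.SF1_HELICASE, 150)
        b.coiled_coil(5)
    return b


def _make_cnuE(rng: random.Random, label: str) -> _ProteinBuilder:
    b = _ProteinBuilder()
    _tagged(b, rng, vocab.WHTH, 60)
    b.coiled_coil(5)
    if label == "II":
        _hepn(b, rng, "RxxxxH")
    elif label == "III-A":
        _hepn(b, rng, "RxxxxH")
        _bgpad = _bg(rng, 15, forbid="RH")
        b.add(_bgpad)
        _hepn(b, rng, "RxH")  # shortened motif closest to the C-terminus
    else:  # III-C: distorted wHTH fused to two PLD endonucleases
        _tagged(b, rng, vocab.PLD, 50)
        _tagged(b, rng, vocab.PLD, 50)
    return b


def _make_cnuA(rng: random.Random, label: str) -> _ProteinBuilder:
    b = _ProteinBuilder()
    if label == "I-B":
        _tagged(b, rng, vocab.PYD, 50)
        b.coiled_coil(10)
        _tagged(b, rng, vocab.REC, 55)
    else:  # III-B: nothing recognizable but the coiled-coil
        b.coiled_coil(10)
    return b


def _make_cnuD(rng: random.Random) -> _ProteinBuilder:
    b = _ProteinBuilder()
    _tagged(b, rng, vocab.HSP70, 120)
    b.coiled_coil(5)
    return b


def _simple_protein(rng: random.Random, tags_lengths: list[tuple[str, int]],
                    cc_heptads: int = 0) -> _ProteinBuilder:
    b = _ProteinBuilder()
    if cc_heptads:
        b.coiled_coil(cc_heptads)
    for name, length in tags_lengths:
        _tagged(b, rng, name, length)
    return b


# ---------------------------------------------------------------------------
# Contig assembly
# ---------------------------------------------------------------------------


class _ContigBuilder:
    def __init__(self, contig_id: str) -> None:
        self.contig_id = contig_id
        self.genes: list[GeneRecord] = []
        self.proteins: dict[str, ProteinRecord] = {}
        self.planted: dict[str, list[tuple[str, int, int]]] = {}
        self.cursor = 100
        self._n = 0

    def add_gene(self, strand: str, builder: _ProteinBuilder,
                 gap_before: int) -> GeneRecord:
        seq = builder.sequence
        start = max(0, self.cursor + gap_before)
        end = start + 3 * (len(seq) + 1)
        self._n += 1
        gene_id = f"{self.contig_id}_g{self._n:03d}"
        pid = f"{self.contig_id}_p{self._n:03d}"
        gene = GeneRecord(
            gene_id=gene_id, contig_id=self.contig_id, start=start, end=end,
            strand=strand, protein_id=pid, protein_length=len(seq),
        )
        self.genes.append(gene)
        self.proteins[pid] = ProteinRecord(protein_id=pid, sequence=seq)
        if builder.tags:
            self.planted[pid] = list(builder.tags)
        self.cursor = end
        return gene

    def finish(self) -> Contig:
        return Contig(
            contig_id=self.contig_id, genes=self.genes, length=self.cursor + 500
        )


def _operon_gap(rng: random.Random, cfg: SimConfig) -> int:
    if rng.random() < cfg.overlap_prob:
        return -4  # overlapping reading frames
    return rng.randint(0, 2 * cfg.mean_intergenic_gap_nt)


def _filler(rng: random.Random) -> _ProteinBuilder:
    b = _ProteinBuilder()
    b.add(_bg(rng, rng.randint(120, 180)))
    return b


def _add_fillers(cb: _ContigBuilder, rng: random.Random, n: int, strand: str) -> None:
    for _ in range(n):
        cb.add_gene(strand, _filler(rng), rng.randint(250, 600))


def _locus_gene_specs(
    rng: random.Random, label: str, cfg: SimConfig, extended_variant: Optional[str]
) -> list[tuple[str, _ProteinBuilder, int]]:
    """Transcription-ordered (role, builder, gap_class) specs for one locus.
    gap_class: 0 = within-operon gap (<= 90 nt), 1 = superoperon spacing."""
    specs: list[tuple[str, _ProteinBuilder, int]] = []

    def op(role: str, b: _ProteinBuilder) -> None:
        specs.append((role, b, 0))

    def sup(role: str, b: _ProteinBuilder) -> None:
        specs.append((role, b, 1))

    if label == "II" and cfg.include_superoperons:
        sup("accessory", _simple_protein(rng, [(vocab.CARF_RTCR, 120)]))
        sup("accessory", _simple_protein(rng, [(vocab.HSDR, 140)]))
        sup("accessory", _simple_protein(rng, [(vocab.HSDM, 140)]))
        sup("accessory", _simple_protein(rng, [(vocab.HSDS, 120)]))
        sup("accessory", _simple_protein(rng, [(vocab.BRNT_LIKE, 90)]))

    if label in ("II", "III-A"):
        if label == "III-A" and extended_variant is not None:
            vb = _ProteinBuilder()
            _vwa(vb, rng, intact=True)
            op("accessory", vb)
            if extended_variant == "EssC_like":
                op("accessory", _simple_protein(rng, [(vocab.ESSC_ATPASE, 200)], cc_heptads=5))
                op("accessory", _simple_protein(rng, [(vocab.WXG100, 95)]))
                op("accessory", _simple_protein(rng, [(vocab.WXG100, 95)]))
                op("accessory", _simple_protein(rng, [(vocab.D_EXK, 80)], cc_heptads=5))
            elif extended_variant == "SpoVK_like":
                op("accessory", _simple_protein(rng, [(vocab.SPOVK_ATPASE, 200)]))
                op("accessory", _simple_protein(rng, [(vocab.GLY_ZIP, 90)]))
            else:  # VirB4_like
                op("accessory", _simple_protein(rng, [(vocab.VIRB4_ATPASE, 200)]))
            vb2 = _ProteinBuilder()
            _vwa(vb2, rng, intact=False)  # internal copy lacks the threonine
            op("accessory", vb2)
        else:
            vb = _ProteinBuilder()
            _vwa(vb, rng, intact=True)
            op("accessory", vb)
        # rest of the TerY-P triad
        op("accessory", _simple_protein(rng, [(vocab.PP2C, 180)]))
        stk = _ProteinBuilder()
        _tagged(stk, rng, vocab.STK, 200)
        _znr(stk, rng, 1)
        op("accessory", stk)

    if label == "I-B":
        op("CnuA", _make_cnuA(rng, "I-B"))
    if label == "III-B":
        op("CnuA", _make_cnuA(rng, "III-B"))
        op("CnuD", _make_cnuD(rng))
    if label == "III-C":
        op("CnuD", _make_cnuD(rng))
    if label in ("II", "III-A", "III-B", "III-C"):
        op("CnuH", _make_cnuH(rng, label))
    if label in ("II", "III-A", "III-C"):
        op("CnuE", _make_cnuE(rng, label))

    op("CnuB", _make_cnuB(rng, label))
    op("CnuCD" if label == "III-A" else "CnuC", _make_cnuC(rng, label))
    return specs


def _plant_locus(
    cb: _ContigBuilder, rng: random.Random, label: str, cfg: SimConfig,
    extended_variant: Optional[str], locus_id: str,
) -> TruthRecord:
    strand = rng.choice("+-")
    specs = _locus_gene_specs(rng, label, cfg, extended_variant)
    gaps = []
    for _role, _b, gap_class in specs[1:]:
        gaps.append(rng.randint(95, 190) if gap_class == 1 else _operon_gap(rng, cfg))
    # first gene's own gap class decides spacing from the fillers
    lead_gap = rng.randint(250, 600)
    placement = list(zip(specs, [lead_gap] + gaps))
    if strand == "-":
        # preserve transcription order on the reverse strand
        ordered = placement[::-1]
        gap_seq = [lead_gap] + [g for (_s, g) in placement[:0:-1]]
        placement = [(spec, gap) for (spec, _), gap in zip(ordered, gap_seq)]
    roles: dict[str, str] = {}
    motif_positions: dict[str, int] = {}
    mcrB_id = mcrC_id = None
    for (role, builder, _gc), gap in placement:
        gene = cb.add_gene(strand, builder, gap)
        roles[gene.gene_id] = role
        if role == "CnuB":
            mcrB_id = gene.gene_id
            if "signature_N" in builder.marks:
                motif_positions["signature_N"] = builder.marks["signature_N"]
        if role in ("CnuC", "CnuCD"):
            mcrC_id = gene.gene_id
    return TruthRecord(
        locus_id=locus_id,
        contig_id=cb.contig_id,
        label=label,
        roles=roles,
        mcrB_gene_id=mcrB_id,
        mcrC_gene_id=mcrC_id,
        motif_positions=motif_positions,
        ancillary={
            "tery_p": label in ("II", "III-A"),
            "extended_IIIA": extended_variant or "none",
            "superoperon": label == "II" and cfg.include_superoperons,
        },
    )


def _plant_decoy(cb: _ContigBuilder, rng: random.Random, kind: int) -> None:
    if kind == 0:
        # MoxR-like AAA+ singleton: one alias class, no qualifying partner
        # (flanking genes opposite strand, gaps above the linkage threshold)
        _add_fillers(cb, rng, 2, "-")
        cb.add_gene("+", _simple_protein(rng, [("MoxR", 300)]), 400)
        _add_fillers(cb, rng, 2, "-")
    elif kind == 1:
        # stand-alone Type I RM operon: no McrBC aliases at all
        for name in (vocab.HSDR, vocab.HSDM, vocab.HSDS):
            cb.add_gene("+", _simple_protein(rng, [(name, 140)]), rng.randint(20, 80))
    else:
        _add_fillers(cb, rng, 3, rng.choice("+-"))


def generate_genome(config: SimConfig) -> SyntheticGenome:
    """Generate annotated contigs with planted loci of every subtype, plus
    non-CoCoNuT McrBC operons and decoys, and the matching ground truth.
    All output is fully determined by ``config.seed``."""
    rng = random.Random(config.seed)
    builders: list[_ContigBuilder] = []
    truth: list[TruthRecord] = []

    extended_cycle = ("EssC_like", "SpoVK_like", "VirB4_like")
    locus_plan: list[tuple[str, Optional[str]]] = []
    iiia_counter = 0
    for label in COCONUT_LABELS:
        for _rep in range(config.loci_per_subtype):
            ext = None
            if label == "III-A" and config.include_extended_IIIA:
                ext = extended_cycle[iiia_counter % 3]
                iiia_counter += 1
            locus_plan.append((label, ext))
    for _ in range(config.non_coconut_count):
        locus_plan.append(("non_CoCoNuT_McrBC", None))

    n_shared = config.contig_count
    shared: list[_ContigBuilder] = [
        _ContigBuilder(f"ctg{j:02d}") for j in range(n_shared)
    ]
    for i, (label, ext) in enumerate(locus_plan):
        if n_shared:
            cb = shared[i % n_shared]
        else:
            cb = _ContigBuilder(f"ctg_{label.replace('-', '').replace('_', '')}_{i:02d}")
            builders.append(cb)
        _add_fillers(cb, rng, 5, "-")
        truth.append(
            _plant_locus(cb, rng, label, config, ext, locus_id=f"locus{i:03d}")
        )
        _add_fillers(cb, rng, 5, "-")
    builders.extend(shared)

    for d in range(config.decoy_count):
        cb = _ContigBuilder(f"decoy{d:02d}")
        _plant_decoy(cb, rng, d % 3)
        builders.append(cb)

    contigs = [cb.finish() for cb in builders if cb.genes]
    proteins: dict[str, ProteinRecord] = {}
    planted: dict[str, list[tuple[str, int, int]]] = {}
    for cb in builders:
        proteins.update(cb.proteins)
        planted.update(cb.planted)
    bundle = GenomeBundle(contigs=contigs, proteins=proteins, hits=None)
    return SyntheticGenome(bundle=bundle, truth=truth, planted=planted)


# ---------------------------------------------------------------------------
# Mock profile-search adapter
# ---------------------------------------------------------------------------

_FP_NAMES = ("TPR", "MBL_fold", "4TM", "DUF9999")


def mock_profile_adapter(
    planted: dict[str, list[tuple[str, int, int]]],
    false_positive_rate: float = 0.0,
    seed: int = 0,
    false_positive_names: tuple[str, ...] = _FP_NAMES,
) -> Callable[..., list[DomainHit]]:
    """An adapter replaying planted annotations at E-value 1e-10, optionally
    injecting reproducible false-positive hits for robustness testing."""

    def adapter(protein: ProteinRecord, database: str = "cdd_pfam") -> list[DomainHit]:
        hits = [
            DomainHit(
                protein_id=protein.protein_id,
                domain_name=name,
                start_aa=start,
                end_aa=end,
                evalue=1e-10,
            )
            for name, start, end in planted.get(protein.protein_id, [])
        ]
        if false_positive_rate > 0:
            prng = random.Random(
                (seed << 32) ^ zlib.crc32(protein.protein_id.encode())
            )
            if prng.random() < false_positive_rate:
                length = len(protein.sequence)
                start = prng.randrange(0, max(1, length - 10))
                hits.append(
                    DomainHit(
                        protein_id=protein.protein_id,
                        domain_name=prng.choice(false_positive_names),
                        start_aa=start,
                        end_aa=min(length, start + 10),
                        evalue=9e-4,
                    )
                )
        return sorted(hits, key=lambda h: (h.start_aa, h.domain_name))

    return adapter


# ---------------------------------------------------------------------------
# Clustering fixture
# ---------------------------------------------------------------------------


def generate_clustering_fixture(
    n_families: int,
    seqs_per_family: int,
    divergence: float,
    seed: int,
    length: int = 120,
    check_margin: bool = True,
) -> dict[str, str]:
    """Planted-partition protein families: each family derives from its own
    random ancestor by per-site point mutation at the given rate. Verifies
    at generation time that within-family identity exceeds across-family
    identity (the planted partition is recoverable)."""
    if not 0 <= divergence <= 0.6:
        raise ValueError("divergence must be in [0, 0.6]")
    rng = random.Random(seed)
    seqs: dict[str, str] = {}
    families: list[list[str]] = []
    for f in range(n_families):
        ancestor = _bg(rng, length)
        ids = []
        for m in range(seqs_per_family):
            seq = list(ancestor)
            for i in range(length):
                if rng.random() < divergence:
                    seq[i] = rng.choice([a for a in AA_ALPHABET if a != seq[i]])
            sid = f"fam{f:02d}_s{m:02d}"
            seqs[sid] = "".join(seq)
            ids.append(sid)
        families.append(ids)
    if check_margin and n_families > 1 and seqs_per_family > 1:
        from .clustering import pairwise_identity

        within = min(
            pairwise_identity(seqs[fam[0]], seqs[fam[1]]) for fam in families
        )
        across = max(
            pairwise_identity(seqs[a[0]], seqs[b[0]])
            for i, a in enumerate(families)
            for b in families[i + 1 :]
        )
        if within <= across:
            raise ValueError(
                f"planted partition not recoverable: within {within:.2f} "
                f"<= across {across:.2f}"
            )
    return seqs
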