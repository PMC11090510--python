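"""The CoCoNuT typing grammar.

Validated McrBC systems are assigned a type/subtype from domain
architecture plus the GTPase signature motif: the NxD variant gates
membership in the CoCoNuT clade, and the subtypes are distinguished by the
helicase (CnuH) / effector (CnuE) composition, the effector's nuclease
complement (one HEPN, two HEPN, two PLD, or a fused Vsr-like nuclease), the
Type I-A helical insert in the GTPase, and the presence of the separate
coiled-coil protein CnuA. Ancillary modules (the TerY-P triad, extended
Type III-A ATPase insertions between duplicated VWA genes, and CARF/RtcR
superoperons) are detected from the annotated neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Union

from . import vocab
from .census import (
    Neighborhood,
    gene_domain_names,
    index_hits,
    operonic_chain,
)
from .core import (
    CandidateSystem,
    Contig,
    DomainHit,
    GeneRecord,
    MotifVariant,
    SignatureMotif,
    ValidationTier,
    intergenic_gap,
)
from .motifs import AliasTables


class Label(str, Enum):
    I_A = "I-A"
    I_B = "I-B"
    PSEUDO_I_B = "Pseudo-I-B"
    I_C = "I-C"
    II = "II"
    III_A = "III-A"
    III_B = "III-B"
    III_C = "III-C"
    NON_COCONUT = "non_CoCoNuT_McrBC"
    UNCLASSIFIED = "unclassified"


class ExtendedIIIA(str, Enum):
    ESSC_LIKE = "EssC_like"
    SPOVK_LIKE = "SpoVK_like"
    VIRB4_LIKE = "VirB4_like"
    NONE = "none"


#: The implemented taxonomy: three types, seven subtypes. Pseudo-Type I-B is
#: a derived variant of Type I-B (it lost the separate CnuA gene), not an
#: eighth subtype.
COCONUT_TYPES: tuple[str, ...] = ("I", "II", "III")
COCONUT_SUBTYPES: tuple[str, ...] = ("I-A", "I-B", "I-C", "II", "III-A", "III-B", "III-C")


class Role(str, Enum):
    CNUA = "CnuA"
    CNUB = "CnuB"
    CNUC = "CnuC"
    CNUCD = "CnuCD"
    CNUD = "CnuD"
    CNUE = "CnuE"
    CNUH = "CnuH"
    ACCESSORY = "accessory"


@dataclass
class ComponentRole:
    role: Role
    gene: GeneRecord
    evidence: list[str] = field(default_factory=list)


@dataclass
class SuperoperonRecord:
    """A co-oriented run of genes linking a CARF/RtcR regulator to a
    CoCoNuT, possibly with embedded ancillary defense systems."""

    carf_gene: GeneRecord
    member_genes: list[GeneRecord]
    same_direction: bool
    span_nt: int
    embedded_systems: list[str] = field(default_factory=list)


@dataclass
class CoCoNuTCall:
    locus_id: str
    contig_id: str
    label: Label
    components: list[ComponentRole] = field(default_factory=list)
    tery_p: bool = False
    carf_association: Optional[SuperoperonRecord] = None
    extended_IIIA: ExtendedIIIA = ExtendedIIIA.NONE
    tier: Optional[ValidationTier] = None
    signature: Optional[SignatureMotif] = None
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.extended_IIIA is not ExtendedIIIA.NONE and self.label is not Label.III_A:
            raise ValueError("extended Type III-A variants require label III-A")
        if self.tery_p and self.label not in (Label.II, Label.III_A):
            raise ValueError("TerY-P is only found with Types II and III-A")


HitsLike = Union[list[DomainHit], dict[str, list[DomainHit]]]


def _hits_index(hits: HitsLike) -> dict[str, list[DomainHit]]:
    return hits if isinstance(hits, dict) else index_hits(hits)


_NON_CNUA_DOMAINS = {
    vocab.COG1401,
    vocab.DUF2357,
    vocab.SF1_HELICASE,
    vocab.WHTH,
    vocab.HEPN,
    vocab.PLD,
    vocab.VSR,
    vocab.HSP70,
    vocab.VWA,
    vocab.PP2C,
    vocab.STK,
    vocab.CARF_RTCR,
    vocab.ESSC_ATPASE,
    vocab.SPOVK_ATPASE,
    vocab.VIRB4_ATPASE,
    vocab.D_EXK,
}


def _has_long_cc(
    gene: Optional[GeneRecord], idx: dict[str, list[DomainHit]], min_aa: int = 50
) -> bool:
    """True when the gene carries a substantial predicted coiled-coil
    segment. The length gate separates the long coiled-coils that define
    Cnu components from isolated windows that clear the score threshold by
    chance in unrelated proteins."""
    if gene is None or not gene.protein_id:
        return False
    return any(
        h.domain_name == vocab.COILED_COIL and (h.end_aa - h.start_aa) >= min_aa
        for h in idx.get(gene.protein_id, [])
    )


def _is_cnua_like(
    gene: Optional[GeneRecord],
    idx: dict[str, list[DomainHit]],
    names: Optional[set[str]] = None,
    min_cc_aa: int = 50,
) -> bool:
    """A stand-alone coiled-coil protein: a long coiled-coil and none of
    the core-component domains. PYD/REC fusions (Type I-B CnuA) qualify."""
    if names is None:
        names = gene_domain_names(gene, idx) if gene is not None else set()
    return _has_long_cc(gene, idx, min_cc_aa) and not (names & _NON_CNUA_DOMAINS)


def detect_tery_p(
    neighborhood: Neighborhood, hits: HitsLike
) -> tuple[bool, Optional[str]]:
    """TerY-P triad: three consecutive same-strand genes carrying VWA, PP2C,
    and STK-fused-to-ZnR hits, in that order or reversed. Returns the flag
    and a diagnostic for near-misses (e.g. the kinase lacking its ZnR)."""
    idx = _hits_index(hits)
    genes = neighborhood.genes
    diagnostic = None
    for i in range(len(genes) - 2):
        triad = genes[i : i + 3]
        if len({g.strand for g in triad}) != 1:
            continue
        names = [gene_domain_names(g, idx) for g in triad]
        for order in (names, names[::-1]):
            if vocab.VWA in order[0] and vocab.PP2C in order[1] and vocab.STK in order[2]:
                if vocab.ZNR in order[2]:
                    return True, None
                diagnostic = "tery_p_kinase_missing_znr"
    return False, diagnostic


def detect_extended_IIIA(
    neighborhood: Neighborhood, hits: HitsLike
) -> tuple[ExtendedIIIA, dict[str, str]]:
    """Extended Type III-A variants: a diagnostic ATPase inserted between
    duplicated TerY-like VWA genes (EssC-like requires at least one WXG100
    gene in the insert; for the VirB4-like variant the ATPase may instead
    have migrated to the 3' end, leaving the duplicated VWA genes at 5').
    The MIDAS state of each VWA gene is recorded: the 5'-most copy is
    expected intact, the internal copy degraded (missing its threonine)."""
    idx = _hits_index(hits)
    genes = neighborhood.genes
    vwa_positions = [
        i for i, g in enumerate(genes) if vocab.VWA in gene_domain_names(g, idx)
    ]
    midas: dict[str, str] = {}
    for i in vwa_positions:
        names = gene_domain_names(genes[i], idx)
        if "MIDAS_intact" in names:
            midas[genes[i].gene_id] = "intact"
        elif "MIDAS_degraded_no_T" in names:
            midas[genes[i].gene_id] = "degraded_no_T"
        else:
            midas[genes[i].gene_id] = "absent"
    if len(vwa_positions) < 2:
        return ExtendedIIIA.NONE, midas
    for a, b in zip(vwa_positions, vwa_positions[1:]):
        block = genes[a + 1 : b]
        block_names: set[str] = set()
        for g in block:
            block_names |= gene_domain_names(g, idx)
        wxg_count = sum(
            1 for g in block if vocab.WXG100 in gene_domain_names(g, idx)
        )
        if vocab.ESSC_ATPASE in block_names and wxg_count >= 1:
            return ExtendedIIIA.ESSC_LIKE, midas
        if vocab.SPOVK_ATPASE in block_names and vocab.GLY_ZIP in block_names:
            return ExtendedIIIA.SPOVK_LIKE, midas
        if vocab.VIRB4_ATPASE in block_names:
            return ExtendedIIIA.VIRB4_LIKE, midas
    # VirB4-like ATPase migrated away from the duplicated VWA genes
    strand = genes[vwa_positions[0]].strand
    if any(
        vocab.VIRB4_ATPASE in gene_domain_names(g, idx)
        for g in genes
        if g.strand == strand
    ):
        return ExtendedIIIA.VIRB4_LIKE, midas
    return ExtendedIIIA.NONE, midas


def detect_carf_superoperon(
    contig: Contig,
    locus_genes: list[GeneRecord],
    hits: HitsLike,
    superoperon_gap_nt: int = 200,
) -> Optional[SuperoperonRecord]:
    """Walk upstream of the locus in the direction of transcription while
    genes stay co-oriented and closely spaced; if a CARF/RtcR gene is
    reached, return the superoperon record with embedded ancillary-system
    tags for the intervening genes."""
    idx = _hits_index(hits)
    if not locus_genes:
        return None
    strand = locus_genes[0].strand
    positions = {g.gene_id: i for i, g in enumerate(contig.genes)}
    locus_idx = sorted(positions[g.gene_id] for g in locus_genes if g.gene_id in positions)
    if not locus_idx:
        return None
    if strand == "+":
        start, step = locus_idx[0], -1
    else:
        start, step = locus_idx[-1], +1
    walked: list[GeneRecord] = []
    prev = contig.genes[start]
    i = start + step
    carf_gene: Optional[GeneRecord] = None
    while 0 <= i < len(contig.genes):
        g = contig.genes[i]
        if g.strand != strand or intergenic_gap(prev, g) > superoperon_gap_nt:
            break
        walked.append(g)
        if vocab.CARF_RTCR in gene_domain_names(g, idx):
            carf_gene = g
            break
        prev = g
        i += step
    if carf_gene is None:
        return None
    intervening = walked[:-1]
    embedded: list[str] = []
    for g in intervening:
        for name in sorted(gene_domain_names(g, idx)):
            tag = vocab.EMBEDDED_SYSTEM_TAGS.get(name)
            if tag and tag not in embedded:
                embedded.append(tag)
    members = sorted(walked + locus_genes, key=lambda g: g.start)
    span = max(g.end for g in members) - min(g.start for g in members)
    return SuperoperonRecord(
        carf_gene=carf_gene,
        member_genes=members,
        same_direction=True,
        span_nt=span,
        embedded_systems=embedded,
    )


def _locus_genes(
    system: CandidateSystem, neighborhood: Neighborhood, gap_nt: int = 90
) -> list[GeneRecord]:
    """The predicted operon: the transitive same-strand close-spacing chain
    through the system's anchor gene."""
    anchor = system.mcrB_gene or system.mcrC_gene
    return operonic_chain(neighborhood, anchor, gap_nt=gap_nt)


def assign_roles(
    system: CandidateSystem,
    locus_genes: list[GeneRecord],
    hits: HitsLike,
    label: Label,
) -> list[ComponentRole]:
    """Map each locus gene to exactly one Cnu component role from its domain
    evidence. Conflicting evidence demotes a gene to accessory."""
    if label is Label.NON_COCONUT:
        return []
    idx = _hits_index(hits)
    roles: list[ComponentRole] = []
    for g in locus_genes:
        names = gene_domain_names(g, idx)
        evidence = sorted(names)
        if vocab.COG1401 in names and vocab.DUF2357 in names:
            roles.append(ComponentRole(Role.ACCESSORY, g, evidence + ["conflict:fused_BC"]))
        elif vocab.COG1401 in names:
            roles.append(ComponentRole(Role.CNUB, g, evidence))
        elif vocab.DUF2357 in names and vocab.HSP70 in names:
            roles.append(ComponentRole(Role.CNUCD, g, evidence))
        elif vocab.DUF2357 in names:
            roles.append(ComponentRole(Role.CNUC, g, evidence))
        elif vocab.SF1_HELICASE in names:
            roles.append(ComponentRole(Role.CNUH, g, evidence))
        elif vocab.WHTH in names and names & {vocab.HEPN, vocab.PLD}:
            roles.append(ComponentRole(Role.CNUE, g, evidence))
        elif (
            vocab.HSP70 in names
            and vocab.COILED_COIL in names
            and label in (Label.III_B, Label.III_C)
        ):
            roles.append(ComponentRole(Role.CNUD, g, evidence))
        elif _is_cnua_like(g, idx, names=names):
            roles.append(ComponentRole(Role.CNUA, g, evidence))
        else:
            roles.append(ComponentRole(Role.ACCESSORY, g, evidence))
    return roles


def classify_locus(
    system: CandidateSystem,
    hits: HitsLike,
    neighborhood: Neighborhood,
    config=None,
) -> CoCoNuTCall:
    """Assign a CoCoNuT type/subtype to a validated system.

    The decision grammar is ordered, first match wins; ``unclassified`` is a
    valid outcome and carries diagnostics. Gene order within the locus does
    not affect the label (only strand, gaps, and domain content do).
    """
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    idx = _hits_index(hits)
    contig = Contig(
        contig_id=neighborhood.contig_id,
        genes=list(neighborhood.genes),
        length=max(g.end for g in neighborhood.genes),
    )
    locus = _locus_genes(system, neighborhood, gap_nt=cfg.gap_nt)
    island = neighborhood.genes
    diagnostics: list[str] = []

    def names_of(g: Optional[GeneRecord]) -> set[str]:
        return gene_domain_names(g, idx) if g is not None else set()

    cnuB = system.mcrB_gene
    cnuB_names = names_of(cnuB)
    cnuC_names = names_of(system.mcrC_gene)

    cnuH_gene = next(
        (g for g in locus if vocab.SF1_HELICASE in names_of(g)), None
    )
    cnuE_gene = next(
        (
            g
            for g in locus
            if g is not cnuH_gene
            and vocab.WHTH in names_of(g)
            and names_of(g) & {vocab.HEPN, vocab.PLD}
        ),
        None,
    )
    hepn_count = sum(
        1
        for h in idx.get(cnuE_gene.protein_id, [])
        if h.domain_name == vocab.HEPN
    ) if cnuE_gene is not None and cnuE_gene.protein_id else 0
    pld_count = sum(
        1
        for h in idx.get(cnuE_gene.protein_id, [])
        if h.domain_name == vocab.PLD
    ) if cnuE_gene is not None and cnuE_gene.protein_id else 0

    sig = system.signature
    helical_insert = (
        sig is not None
        and sig.gap_from_walker_b is not None
        and sig.gap_from_walker_b >= cfg.insert_min_aa
    )
    min_cc = cfg.min_coiled_coil_aa
    cnuA_locus = [g for g in locus if _is_cnua_like(g, idx, min_cc_aa=min_cc)]
    cnuA_island = [g for g in island if _is_cnua_like(g, idx, min_cc_aa=min_cc)]
    cnuB_long_cc = _has_long_cc(cnuB, idx, min_aa=min_cc)
    ib_like = (
        vocab.CSD in cnuB_names
        and not cnuB_long_cc
        and not helical_insert
    )

    label: Label
    if sig is None or sig.variant is not MotifVariant.NXD:
        label = Label.NON_COCONUT
        diagnostics.append("rule0:signature_not_NxD")
    elif (
        cnuH_gene is not None
        and vocab.VSR in names_of(cnuH_gene)
        and cnuE_gene is None
    ):
        label = Label.III_B
        diagnostics.append("rule1:vsr_fused_to_helicase")
    elif cnuE_gene is not None and pld_count == 2:
        label = Label.III_C
        diagnostics.append("rule2:cnuE_two_PLD")
    elif (cnuE_gene is not None and hepn_count == 2) or vocab.HSP70 in cnuC_names:
        label = Label.III_A
        diagnostics.append("rule3:two_HEPN_or_cnuC_Hsp70_fusion")
    elif cnuE_gene is not None and hepn_count == 1 and cnuH_gene is not None:
        label = Label.II
        diagnostics.append("rule4:one_HEPN_with_helicase")
    elif cnuH_gene is None and cnuE_gene is None and helical_insert:
        label = Label.I_A
        diagnostics.append("rule5:gtpase_helical_insert")
    elif (
        cnuH_gene is None
        and any(
            {vocab.PYD, vocab.REC} <= names_of(g) for g in cnuA_locus
        )
    ):
        label = Label.I_B
        diagnostics.append("rule6:cnuA_PYD_REC")
    elif cnuH_gene is None and ib_like and not cnuA_island:
        label = Label.PSEUDO_I_B
        diagnostics.append("rule7:IB_architecture_no_cnuA_in_island")
    elif (
        cnuH_gene is None
        and vocab.CSD in cnuB_names
        and cnuB_long_cc
        and not cnuA_locus
        and not helical_insert
    ):
        label = Label.I_C
        diagnostics.append("rule8:csd_coiled_coil_gtpase")
        if vocab.YTH not in cnuB_names:
            diagnostics.append("yth_absent:I-C_vs_I-B_discriminator_unavailable")
    else:
        label = Label.UNCLASSIFIED
        diagnostics.append("rule9:no_architecture_matched")

    tery, tery_diag = detect_tery_p(neighborhood, idx)
    if tery_diag:
        diagnostics.append(tery_diag)
    tery_p = tery and label in (Label.II, Label.III_A)
    if tery and not tery_p:
        diagnostics.append("tery_p_like_module_outside_II_IIIA_ignored")

    extended = ExtendedIIIA.NONE
    if label is Label.III_A:
        extended, midas = detect_extended_IIIA(neighborhood, idx)
        if extended is not ExtendedIIIA.NONE:
            diagnostics.append(f"extended_IIIA_midas:{midas}")

    carf = None
    if label in (Label.II, Label.III_A):
        carf = detect_carf_superoperon(
            contig, locus, idx, superoperon_gap_nt=cfg.superoperon_gap_nt
        )

    components = assign_roles(system, locus, idx, label)
    return CoCoNuTCall(
        locus_id=system.locus_id,
        contig_id=system.contig_id,
        label=label,
        components=components,
        tery_p=tery_p,
        carf_association=carf,
        extended_IIIA=extended,
        tier=system.tier,
        signature=sig,
        diagnostics=diagnostics,
    )


def classify_all(
    systems: list[CandidateSystem],
    bundle,
    hits: HitsLike,
    config=None,
) -> list[CoCoNuTCall]:
    """Classify every validated system against its own neighborhood."""
    from .census import extract_neighborhood
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    contigs = {c.contig_id: c for c in bundle.contigs}
    calls = []
    for system in systems:
        contig = contigs[system.contig_id]
        anchor = system.mcrB_gene or system.mcrC_gene
        neighborhood = extract_neighborhood(contig, anchor, k=cfg.flank_genes)
        calls.append(classify_locus(system, hits, neighborhood, config=cfg))
    return calls
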