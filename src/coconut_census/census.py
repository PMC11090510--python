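"""Neighborhood extraction, three-tier filtering, and McrB/McrC pairing.

A neighborhood is the anchor gene plus up to 10 genes on each side of it
on the same contig. Neighborhoods are first filtered strictly (a primary
McrB GTPase hit, or one McrB-alias plus one McrC-alias hit), then with
relaxed criteria (a single alias hit plus an adjacent, co-oriented gene of
sufficient size to be the missing component), and finally rescued (no
alias hits at all, but a raw homology-search hit in operonic association
with a sufficiently large partner). Validated neighborhoods are resolved
into McrB/McrC pairs by greedy nearest-neighbor matching; unpaired
components become orphans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import vocab
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
from .motifs import AliasTables, ProfileSearchAdapter, annotate_proteins, effective_signature


@dataclass
class Neighborhood:
    """The anchor gene and at most ``k`` genes on each side, contig order."""

    anchor: GeneRecord
    genes: list[GeneRecord]
    contig_id: str

    def __post_init__(self) -> None:
        if self.anchor not in self.genes:
            raise ValueError("anchor must be a member of the neighborhood")


@dataclass
class FunnelCounts:
    """Per-tier census counts (the identification funnel)."""

    input: int = 0
    strict_pass: int = 0
    relaxed_pass: int = 0
    rescued_pass: int = 0
    paired: int = 0
    orphan: int = 0

    def __post_init__(self) -> None:
        for name in ("input", "strict_pass", "relaxed_pass", "rescued_pass",
                     "paired", "orphan"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative funnel count {name}")


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str
    partner: Optional[GeneRecord] = None
    inferred_role: Optional[str] = None


def extract_neighborhood(contig: Contig, anchor: GeneRecord, k: int = 10) -> Neighborhood:
    """The anchor plus min(k, available) genes on each side, truncating at
    contig ends."""
    try:
        idx = contig.genes.index(anchor)
    except ValueError as exc:
        raise ValueError(
            f"anchor {anchor.gene_id} is not a gene of contig {contig.contig_id}"
        ) from exc
    lo = max(0, idx - k)
    hi = min(len(contig.genes), idx + k + 1)
    return Neighborhood(anchor=anchor, genes=contig.genes[lo:hi], contig_id=contig.contig_id)


def index_hits(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    return by_protein


def gene_domain_names(gene: GeneRecord, hits_by_protein: dict[str, list[DomainHit]]) -> set[str]:
    if gene.protein_id is None:
        return set()
    return {h.domain_name for h in hits_by_protein.get(gene.protein_id, [])}


def gene_alias_classes(
    gene: GeneRecord, hits_by_protein: dict[str, list[DomainHit]], alias: AliasTables
) -> set[str]:
    """Which McrBC component classes ('B', 'C') this gene has evidence for."""
    names = gene_domain_names(gene, hits_by_protein)
    classes: set[str] = set()
    if names & alias.mcrB_evidence:
        classes.add("B")
    if names & alias.mcrC_aliases:
        classes.add("C")
    return classes


def strict_filter(
    n: Neighborhood, hits_by_protein: dict[str, list[DomainHit]], alias: AliasTables
) -> FilterResult:
    """Pass iff any gene has a primary McrB GTPase (COG1401) hit, or some
    gene has an McrB-alias hit and some (possibly different) gene has an
    McrC-alias hit."""
    has_primary = any(
        gene_domain_names(g, hits_by_protein) & alias.primary_mcrB for g in n.genes
    )
    if has_primary:
        return FilterResult(True, "primary_mcrB_hit")
    has_b = any(
        gene_domain_names(g, hits_by_protein) & alias.mcrB_aliases for g in n.genes
    )
    has_c = any(
        gene_domain_names(g, hits_by_protein) & alias.mcrC_aliases for g in n.genes
    )
    if has_b and has_c:
        return FilterResult(True, "both_alias_classes")
    return FilterResult(False, "missing_alias_class")


def _adjacent_genes(n: Neighborhood, gene: GeneRecord) -> list[GeneRecord]:
    idx = n.genes.index(gene)
    out = []
    if idx > 0:
        out.append(n.genes[idx - 1])
    if idx + 1 < len(n.genes):
        out.append(n.genes[idx + 1])
    return out


def relaxed_filter(
    n: Neighborhood,
    hits_by_protein: dict[str, list[DomainHit]],
    alias: AliasTables,
    gap_nt: int = 90,
    min_mcrB_aa: int = 200,
    min_mcrC_aa: int = 150,
) -> FilterResult:
    """One alias class only: pass iff a gene adjacent to the alias hit is
    within ``gap_nt`` nucleotides, on the same strand, and encodes a protein
    strictly larger than the size gate for the missing component (>200 aa
    for McrB, >150 aa for McrC). Adjacency means the nearest gene on either
    side, since operon order can be reversed."""
    hit_genes: list[tuple[GeneRecord, str]] = []
    classes_seen: set[str] = set()
    for g in n.genes:
        classes = gene_alias_classes(g, hits_by_protein, alias)
        classes_seen |= classes
        for c in classes:
            hit_genes.append((g, c))
    if len(classes_seen) != 1:
        return FilterResult(False, "not_exactly_one_alias_class")
    present = classes_seen.pop()
    missing_min = min_mcrC_aa if present == "B" else min_mcrB_aa
    missing_role = "McrC" if present == "B" else "McrB"
    for g, _cls in hit_genes:
        for partner in _adjacent_genes(n, g):
            if partner.strand != g.strand:
                continue
            if intergenic_gap(g, partner) > gap_nt:
                continue
            if partner.protein_length > missing_min:
                return FilterResult(
                    True, "adjacent_partner", partner=partner, inferred_role=missing_role
                )
    return FilterResult(False, "no_qualifying_partner")


def operonic_chain(
    n: Neighborhood, anchor: GeneRecord, gap_nt: int = 90
) -> list[GeneRecord]:
    """Genes reachable from the anchor through a chain of same-strand
    neighbors with successive intergenic gaps <= ``gap_nt``."""
    idx = n.genes.index(anchor)
    chain = [anchor]
    for j in range(idx - 1, -1, -1):
        g, prev = n.genes[j], chain[0]
        if g.strand == anchor.strand and intergenic_gap(g, prev) <= gap_nt:
            chain.insert(0, g)
        else:
            break
    for j in range(idx + 1, len(n.genes)):
        g, prev = n.genes[j], chain[-1]
        if g.strand == anchor.strand and intergenic_gap(prev, g) <= gap_nt:
            chain.append(g)
        else:
            break
    return chain


def rescue_filter(
    n: Neighborhood,
    search_hit_ids: set[str],
    hits_by_protein: dict[str, list[DomainHit]],
    alias: AliasTables,
    gap_nt: int = 90,
    min_mcrB_aa: int = 200,
    min_mcrC_aa: int = 150,
    anchor_role: str = "McrB",
) -> FilterResult:
    """No alias hits anywhere, but the anchor is a raw homology-search hit:
    pass iff a gene in (transitive) operonic association with the anchor is
    large enough to be the other McrBC component."""
    if any(gene_alias_classes(g, hits_by_protein, alias) for g in n.genes):
        return FilterResult(False, "alias_hits_present")
    if n.anchor.gene_id not in search_hit_ids:
        return FilterResult(False, "anchor_not_a_search_hit")
    missing_min = min_mcrC_aa if anchor_role == "McrB" else min_mcrB_aa
    missing_role = "McrC" if anchor_role == "McrB" else "McrB"
    for g in operonic_chain(n, n.anchor, gap_nt=gap_nt):
        if g is n.anchor:
            continue
        if g.protein_length > missing_min:
            return FilterResult(
                True, "operonic_partner", partner=g, inferred_role=missing_role
            )
    return FilterResult(False, "no_operonic_partner")


def _order_reversed(b: GeneRecord, c: GeneRecord) -> bool:
    """True when McrC precedes McrB in the direction of transcription."""
    if b.strand == "+":
        return c.start < b.start
    return c.start > b.start


def pair_mcrbc(
    n: Neighborhood,
    hits_by_protein: dict[str, list[DomainHit]],
    alias: AliasTables,
    tier: ValidationTier = ValidationTier.STRICT,
    max_intervening: int = 2,
) -> list[CandidateSystem]:
    """Greedy nearest-neighbor pairing of McrB-class with McrC-class genes.

    Pairs are formed closest-first (fewest intervening genes, then smallest
    nucleotide distance); each gene is used at most once; unpaired
    components are emitted as orphans. A gene carrying both McrB- and
    McrC-class evidence — the extremely rare fusion case — becomes a
    single-gene system flagged as fused.
    """
    b_genes: list[GeneRecord] = []
    c_genes: list[GeneRecord] = []
    systems: list[CandidateSystem] = []
    for g in n.genes:
        classes = gene_alias_classes(g, hits_by_protein, alias)
        if classes == {"B", "C"}:
            systems.append(
                CandidateSystem(
                    mcrB_gene=g,
                    mcrC_gene=None,
                    intervening_gene_count=0,
                    order_reversed=False,
                    tier=tier,
                    fused=True,
                )
            )
        elif classes == {"B"}:
            b_genes.append(g)
        elif classes == {"C"}:
            c_genes.append(g)

    index_of = {g.gene_id: i for i, g in enumerate(n.genes)}
    candidates = []
    for b in b_genes:
        for c in c_genes:
            intervening = abs(index_of[b.gene_id] - index_of[c.gene_id]) - 1
            if intervening > max_intervening:
                continue
            distance = abs(intergenic_gap(b, c))
            candidates.append((intervening, distance, b.gene_id, c.gene_id, b, c))
    candidates.sort(key=lambda t: t[:4])
    used: set[str] = set()
    for intervening, _dist, _bid, _cid, b, c in candidates:
        if b.gene_id in used or c.gene_id in used:
            continue
        used.add(b.gene_id)
        used.add(c.gene_id)
        systems.append(
            CandidateSystem(
                mcrB_gene=b,
                mcrC_gene=c,
                intervening_gene_count=intervening,
                order_reversed=_order_reversed(b, c),
                tier=tier,
            )
        )
    for b in b_genes:
        if b.gene_id not in used:
            systems.append(
                CandidateSystem(
                    mcrB_gene=b,
                    mcrC_gene=None,
                    intervening_gene_count=0,
                    order_reversed=False,
                    tier=tier,
                )
            )
    for c in c_genes:
        if c.gene_id not in used:
            systems.append(
                CandidateSystem(
                    mcrB_gene=None,
                    mcrC_gene=c,
                    intervening_gene_count=0,
                    order_reversed=False,
                    tier=tier,
                )
            )
    systems.sort(key=lambda s: s.locus_id)
    return systems


def _attach_signature(
    system: CandidateSystem,
    bundle,
    hits_by_protein: dict[str, list[DomainHit]],
    signature_window: int = 60,
    insert_scan_window: int = 200,
) -> None:
    gene = system.mcrB_gene
    if gene is None or gene.protein_id is None:
        return
    seq = bundle.proteins[gene.protein_id].sequence
    gtpase_hits = [
        h
        for h in hits_by_protein.get(gene.protein_id, [])
        if h.domain_name == vocab.COG1401
    ]
    if not gtpase_hits:
        return
    system.signature = effective_signature(
        seq,
        gtpase_hits[0],
        window=signature_window,
        insert_scan_window=insert_scan_window,
    )


def run_census(
    bundle,
    adapter: ProfileSearchAdapter,
    alias: Optional[AliasTables] = None,
    config=None,
) -> tuple[list[CandidateSystem], FunnelCounts]:
    """Run the full identification funnel over a genome bundle.

    Every anchored neighborhood receives exactly one outcome (strict /
    relaxed / rescued / rejected). Anchors are genes with McrBC alias or
    primary-profile evidence, plus genes tagged as raw homology-search hits
    (the rescue path). Systems found in overlapping neighborhoods are
    de-duplicated by their gene identities; output order is deterministic.
    """
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    alias = alias or AliasTables()
    hits = bundle.hits
    if hits is None:
        hits = annotate_proteins(
            bundle,
            adapter,
            alias=alias,
            evalue_threshold=cfg.evalue,
            cc_window=cfg.coiled_coil_window,
            cc_threshold=cfg.coiled_coil_threshold,
            signature_window=cfg.signature_window,
            insert_scan_window=cfg.insert_scan_window,
        )
    hits_by_protein = index_hits(hits)

    search_tags = {vocab.MCRB_SEARCH_HIT, vocab.MCRC_SEARCH_HIT}
    funnel = FunnelCounts()
    systems: dict[tuple, CandidateSystem] = {}

    for contig in bundle.contigs:
        for gene in contig.genes:
            names = gene_domain_names(gene, hits_by_protein)
            is_alias_anchor = bool(
                names & (alias.mcrB_evidence | alias.mcrC_aliases)
            )
            is_search_anchor = bool(names & search_tags)
            if not (is_alias_anchor or is_search_anchor):
                continue
            funnel.input += 1
            n = extract_neighborhood(contig, gene, k=cfg.flank_genes)
            tier: Optional[ValidationTier] = None
            found: list[CandidateSystem] = []

            res = strict_filter(n, hits_by_protein, alias)
            if res.passed:
                tier = ValidationTier.STRICT
                funnel.strict_pass += 1
                found = pair_mcrbc(
                    n, hits_by_protein, alias, tier=tier,
                    max_intervening=cfg.max_intervening,
                )
            else:
                res = relaxed_filter(
                    n, hits_by_protein, alias,
                    gap_nt=cfg.gap_nt,
                    min_mcrB_aa=cfg.min_mcrB_aa,
                    min_mcrC_aa=cfg.min_mcrC_aa,
                )
                if res.passed:
                    tier = ValidationTier.RELAXED_ONE_ALIAS
                    funnel.relaxed_pass += 1
                    hit_gene = gene
                    partner = res.partner
                    if res.inferred_role == "McrC":
                        b, c = hit_gene, partner
                    else:
                        b, c = partner, hit_gene
                    found = [
                        CandidateSystem(
                            mcrB_gene=b,
                            mcrC_gene=c,
                            intervening_gene_count=0,
                            order_reversed=_order_reversed(b, c),
                            tier=tier,
                        )
                    ]
                elif is_search_anchor:
                    res = rescue_filter(
                        n, {gene.gene_id}, hits_by_protein, alias,
                        gap_nt=cfg.gap_nt,
                        min_mcrB_aa=cfg.min_mcrB_aa,
                        min_mcrC_aa=cfg.min_mcrC_aa,
                        anchor_role=cfg.rescue_anchor_role,
                    )
                    if res.passed:
                        tier = ValidationTier.RESCUED_NO_ALIAS
                        funnel.rescued_pass += 1
                        if cfg.rescue_anchor_role == "McrB":
                            b, c = gene, res.partner
                        else:
                            b, c = res.partner, gene
                        found = [
                            CandidateSystem(
                                mcrB_gene=b,
                                mcrC_gene=c,
                                intervening_gene_count=0,
                                order_reversed=_order_reversed(b, c),
                                tier=tier,
                            )
                        ]

            for s in found:
                key = (
                    s.contig_id,
                    s.mcrB_gene.gene_id if s.mcrB_gene else None,
                    s.mcrC_gene.gene_id if s.mcrC_gene else None,
                )
                if key not in systems:
                    _attach_signature(
                        s, bundle, hits_by_protein,
                        signature_window=cfg.signature_window,
                        insert_scan_window=cfg.insert_scan_window,
                    )
                    systems[key] = s

    out = sorted(systems.values(), key=lambda s: s.locus_id)
    for s in out:
        if s.mcrB_gene is not None and (s.mcrC_gene is not None or s.fused):
            funnel.paired += 1
        else:
            funnel.orphan += 1
    return out, funnel
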