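import pytest

from coconut_census import vocab
from coconut_census.census import Neighborhood, extract_neighborhood, index_hits
from coconut_census.classify import (
    COCONUT_SUBTYPES,
    COCONUT_TYPES,
    CoCoNuTCall,
    ExtendedIIIA,
    Label,
    Role,
    assign_roles,
    classify_locus,
    detect_carf_superoperon,
    detect_extended_IIIA,
    detect_tery_p,
)
from coconut_census.core import (
    CandidateSystem,
    Contig,
    DomainHit,
    GeneRecord,
    MotifVariant,
    SignatureMotif,
    ValidationTier,
)

NXD = SignatureMotif(MotifVariant.NXD, position_aa=100, follower="E", gap_from_walker_b=20)
NXD_INSERT = SignatureMotif(MotifVariant.NXD, position_aa=200, follower="E", gap_from_walker_b=80)
NO_SIG = SignatureMotif(MotifVariant.NONE)


def build(specs, contig_id="c"):
    """specs: (gene_id, gap_before, strand, aa, domains); domain entries are
    names (auto interval) or (name, start, end) tuples."""
    genes, hits = [], []
    pos = 100
    for gene_id, gap, strand, aa, domains in specs:
        start = pos + gap
        end = start + aa * 3 + 3
        pos = end
        pid = f"{gene_id}_p"
        genes.append(
            GeneRecord(gene_id, contig_id, start, end, strand,
                       protein_id=pid, protein_length=aa)
        )
        for d in domains:
            if isinstance(d, tuple):
                name, s, e = d
            else:
                name, s, e = d, 5, min(aa, 65)
            hits.append(DomainHit(pid, name, s, e, evalue=1e-12))
    return genes, hits


def locus(specs, b_id, c_id=None, sig=NXD, contig_id="c"):
    genes, hits = build(specs, contig_id)
    by_id = {g.gene_id: g for g in genes}
    system = CandidateSystem(
        mcrB_gene=by_id.get(b_id),
        mcrC_gene=by_id.get(c_id) if c_id else None,
        intervening_gene_count=0,
        order_reversed=False,
        tier=ValidationTier.STRICT,
        signature=sig,
    )
    anchor = system.mcrB_gene or system.mcrC_gene
    nbhd = Neighborhood(anchor=anchor, genes=genes, contig_id=contig_id)
    return system, hits, nbhd


B_CORE = [vocab.COG1401]
C_CORE = [vocab.DUF2357, vocab.PD_DEXK]
CC60 = (vocab.COILED_COIL, 10, 70)


class TestTaxonomy:
    def test_three_types(self):
        assert COCONUT_TYPES == ("I", "II", "III")
        assert len(COCONUT_TYPES) == 3

    def test_seven_subtypes(self):
        assert len(COCONUT_SUBTYPES) == 7
        assert COCONUT_SUBTYPES == ("I-A", "I-B", "I-C", "II", "III-A", "III-B", "III-C")
        for sub in COCONUT_SUBTYPES:
            assert any(sub == t or sub.startswith(t + "-") for t in COCONUT_TYPES)

    def test_pseudo_ib_is_a_label_but_not_a_subtype(self):
        assert Label.PSEUDO_I_B.value == "Pseudo-I-B"
        assert "Pseudo-I-B" not in COCONUT_SUBTYPES

    def test_every_subtype_is_a_label(self):
        values = {label.value for label in Label}
        assert set(COCONUT_SUBTYPES) <= values


class TestDecisionRules:
    def test_rule0_non_nxd_is_non_coconut(self):
        system, hits, nbhd = locus(
            [("b", 0, "+", 400, B_CORE), ("c", 40, "+", 300, C_CORE)],
            "b", "c", sig=NO_SIG,
        )
        call = classify_locus(system, hits, nbhd)
        assert call.label is Label.NON_COCONUT
        assert call.components == []
        assert "rule0:signature_not_NxD" in call.diagnostics

    def test_rule1_vsr_helicase_is_IIIB(self):
        system, hits, nbhd = locus(
            [
                ("h", 0, "+", 900, [vocab.SF1_HELICASE, vocab.VSR, CC60, vocab.HSP70]),
                ("b", 40, "+", 400, B_CORE),
                ("c", 40, "+", 300, C_CORE),
            ],
            "b", "c",
        )
        assert classify_locus(system, hits, nbhd).label is Label.III_B

    def test_rule2_two_pld_is_IIIC(self):
        system, hits, nbhd = locus(
            [
                ("h", 0, "+", 800, [vocab.SF1_HELICASE]),
                ("e", 40, "+", 500, [vocab.WHTH, (vocab.PLD, 100, 220), (vocab.PLD, 260, 380)]),
                ("b", 40, "+", 400, B_CORE),
                ("c", 40, "+", 300, C_CORE),
            ],
            "b", "c",
        )
        assert classify_locus(system, hits, nbhd).label is Label.III_C

    def test_rule3_two_hepn_is_IIIA(self):
        system, hits, nbhd = locus(
            [
                ("h", 0, "+", 800, [vocab.SF1_HELICASE]),
                ("e", 40, "+", 500, [vocab.WHTH, (vocab.HEPN, 100, 180), (vocab.HEPN, 300, 380)]),
                ("b", 40, "+", 400, B_CORE),
                ("c", 40, "+", 300, C_CORE),
            ],
            "b", "c",
        )
        assert classify_locus(system, hits, nbhd).label is Label.III_A

    def test_rule3_cnuC_hsp70_fusion_is_IIIA(self):
        system, hits, nbhd = locus(
            [
                ("b", 0, "+", 400, B_CORE),
                ("c", 40, "+", 900, C_CORE + [vocab.HSP70]),
            ],
            "b", "c",
        )
        assert classify_locus(system, hits, nbhd).label is Label.III_A

    def test_rule4_one_hepn_with_helicase_is_II(self):
        system, hits, nbhd = locus(
            [
                ("h", 0, "+", 800, [vocab.SF1_HELICASE, vocab.OB_STALK]),
                ("e", 40, "+", 400, [vocab.WHTH, (vocab.HEPN, 100, 180)]),
                ("b", 40, "+", 400, B_CORE),
                ("c", 40, "+", 300, C_CORE),
            ],
            "b", "c",
        )
        assert classify_locus(system, hits, nbhd).label is Label.II

    def test_rule5_helical_insert_boundary(self):
        specs = [("b", 0, "+", 600, B_CORE), ("c", 40, "+", 300, C_CORE)]
        at = SignatureMotif(MotifVariant.NXD, position_aa=300, follower="E",
                            gap_from_walker_b=80)
        below = SignatureMotif(MotifVariant.NXD, position_aa=300, follower="E",
                               gap_from_walker_b=79)
        system, hits, nbhd = locus(specs, "b", "c", sig=at)
        assert classify_locus(system, hits, nbhd).label is Label.I_A
        system, hits, nbhd = locus(specs, "b", "c", sig=below)
        assert classify_locus(system, hits, nbhd).label is not Label.I_A

    def test_rule6_cnuA_pyd_rec_is_IB(self):
        system, hits, nbhd = locus(
            [
                ("a", 0, "+", 300, [CC60, vocab.PYD, vocab.REC]),
                ("b", 40, "+", 400, B_CORE + [vocab.CSD]),
                ("c", 40, "+", 300, C_CORE),
            ],
            "b", "c",
        )
        call = classify_locus(system, hits, nbhd)
        assert call.label is Label.I_B
        roles = {c.gene.gene_id: c.role for c in call.components}
        assert roles["a"] is Role.CNUA

    def test_rule7_pseudo_IB_when_no_cnuA_in_island(self):
        system, hits, nbhd = locus(
            [
                ("b", 0, "+", 400, B_CORE + [vocab.CSD]),
                ("c", 40, "+", 300, C_CORE),
            ],
            "b", "c",
        )
        assert classify_locus(system, hits, nbhd).label is Label.PSEUDO_I_B

    def test_rule7_blocked_by_cnuA_elsewhere_in_island(self):
        # the coiled-coil gene sits across a strand break: in the island
        # but outside the operonic locus, so rule 6 cannot fire either
        system, hits, nbhd = locus(
            [
                ("a", 0, "-", 300, [CC60, vocab.PYD, vocab.REC]),
                ("b", 400, "+", 400, B_CORE + [vocab.CSD]),
                ("c", 40, "+", 300, C_CORE),
            ],
            "b", "c",
        )
        call = classify_locus(system, hits, nbhd)
        assert call.label is not Label.PSEUDO_I_B
        assert call.label is not Label.I_B

    def test_rule8_csd_plus_long_cc_is_IC(self):
        system, hits, nbhd = locus(
            [
                ("b", 0, "+", 700, B_CORE + [vocab.CSD, CC60]),
                ("c", 40, "+", 300, C_CORE),
            ],
            "b", "c",
        )
        call = classify_locus(system, hits, nbhd)
        assert call.label is Label.I_C
        assert "yth_absent:I-C_vs_I-B_discriminator_unavailable" in call.diagnostics

    def test_rule8_with_yth_no_discriminator_diagnostic(self):
        system, hits, nbhd = locus(
            [
                ("b", 0, "+", 700, B_CORE + [vocab.CSD, vocab.YTH, CC60]),
                ("c", 40, "+", 300, C_CORE),
            ],
            "b", "c",
        )
        call = classify_locus(system, hits, nbhd)
        assert call.label is Label.I_C
        assert not any(d.startswith("yth_absent") for d in call.diagnostics)

    def test_rule9_unclassified_with_diagnostics(self):
        system, hits, nbhd = locus(
            [("b", 0, "+", 400, B_CORE), ("c", 40, "+", 300, C_CORE)],
            "b", "c",
        )
        call = classify_locus(system, hits, nbhd)
        assert call.label is Label.UNCLASSIFIED
        assert "rule9:no_architecture_matched" in call.diagnostics

    def test_short_coiled_coil_does_not_make_cnuA(self):
        short_cc = (vocab.COILED_COIL, 10, 45)  # 35 aa < 50 aa gate
        base = [
            ("a", 0, "+", 300, [short_cc, vocab.PYD, vocab.REC]),
            ("b", 40, "+", 400, B_CORE + [vocab.CSD]),
            ("c", 40, "+", 300, C_CORE),
        ]
        system, hits, nbhd = locus(base, "b", "c")
        assert classify_locus(system, hits, nbhd).label is not Label.I_B
        long_version = [("a", 0, "+", 300, [CC60, vocab.PYD, vocab.REC])] + base[1:]
        system, hits, nbhd = locus(long_version, "b", "c")
        assert classify_locus(system, hits, nbhd).label is Label.I_B


TERY = [
    ("v", 0, "+", 300, [vocab.VWA, "MIDAS_intact"]),
    ("p", 40, "+", 250, [vocab.PP2C]),
    ("k", 40, "+", 350, [vocab.STK, vocab.ZNR]),
]


def tery_neighborhood(specs):
    genes, hits = build(specs)
    return Neighborhood(anchor=genes[0], genes=genes, contig_id="c"), hits


class TestTerYP:
    def test_intact_triad_detected(self):
        nbhd, hits = tery_neighborhood(TERY)
        assert detect_tery_p(nbhd, hits) == (True, None)

    def test_reversed_order_detected(self):
        nbhd, hits = tery_neighborhood(TERY[::-1])
        assert detect_tery_p(nbhd, hits) == (True, None)

    def test_kinase_missing_znr_near_miss(self):
        specs = TERY[:2] + [("k", 40, "+", 350, [vocab.STK])]
        nbhd, hits = tery_neighborhood(specs)
        assert detect_tery_p(nbhd, hits) == (False, "tery_p_kinase_missing_znr")

    def test_strand_break_rejected(self):
        specs = TERY[:2] + [("k", 40, "-", 350, [vocab.STK, vocab.ZNR])]
        nbhd, hits = tery_neighborhood(specs)
        assert detect_tery_p(nbhd, hits) == (False, None)

    def test_tery_p_only_flags_II_and_IIIA(self):
        specs = TERY + [
            ("b", 60, "+", 400, B_CORE + [vocab.CSD]),
            ("c", 40, "+", 300, C_CORE),
        ]
        system, hits, nbhd = locus(specs, "b", "c")
        call = classify_locus(system, hits, nbhd)
        assert call.label is Label.PSEUDO_I_B
        assert call.tery_p is False
        assert "tery_p_like_module_outside_II_IIIA_ignored" in call.diagnostics


class TestExtendedIIIA:
    def vwa(self, gid, gap, midas):
        return (gid, gap, "+", 300, [vocab.VWA, midas])

    def test_essC_requires_wxg100(self):
        with_wxg = [
            self.vwa("v1", 0, "MIDAS_intact"),
            ("atp", 40, "+", 900, [vocab.ESSC_ATPASE, vocab.D_EXK]),
            ("w1", 40, "+", 100, [vocab.WXG100]),
            self.vwa("v2", 40, "MIDAS_degraded_no_T"),
        ]
        nbhd, hits = tery_neighborhood(with_wxg)
        variant, midas = detect_extended_IIIA(nbhd, hits)
        assert variant is ExtendedIIIA.ESSC_LIKE
        assert midas == {"v1": "intact", "v2": "degraded_no_T"}
        no_wxg = [s for s in with_wxg if s[0] != "w1"]
        nbhd, hits = tery_neighborhood(no_wxg)
        assert detect_extended_IIIA(nbhd, hits)[0] is ExtendedIIIA.NONE

    def test_spovk_requires_gly_zip(self):
        specs = [
            self.vwa("v1", 0, "MIDAS_intact"),
            ("atp", 40, "+", 700, [vocab.SPOVK_ATPASE]),
            ("gz", 40, "+", 120, [vocab.GLY_ZIP]),
            self.vwa("v2", 40, "MIDAS_degraded_no_T"),
        ]
        nbhd, hits = tery_neighborhood(specs)
        assert detect_extended_IIIA(nbhd, hits)[0] is ExtendedIIIA.SPOVK_LIKE
        without = [s for s in specs if s[0] != "gz"]
        nbhd, hits = tery_neighborhood(without)
        assert detect_extended_IIIA(nbhd, hits)[0] is ExtendedIIIA.NONE

    def test_virb4_between_or_migrated(self):
        between = [
            self.vwa("v1", 0, "MIDAS_intact"),
            ("atp", 40, "+", 800, [vocab.VIRB4_ATPASE]),
            self.vwa("v2", 40, "MIDAS_degraded_no_T"),
        ]
        nbhd, hits = tery_neighborhood(between)
        assert detect_extended_IIIA(nbhd, hits)[0] is ExtendedIIIA.VIRB4_LIKE
        migrated = [
            self.vwa("v1", 0, "MIDAS_intact"),
            self.vwa("v2", 40, "MIDAS_degraded_no_T"),
            ("x", 40, "+", 200, []),
            ("atp", 40, "+", 800, [vocab.VIRB4_ATPASE]),
        ]
        nbhd, hits = tery_neighborhood(migrated)
        assert detect_extended_IIIA(nbhd, hits)[0] is ExtendedIIIA.VIRB4_LIKE

    def test_single_vwa_is_none(self):
        specs = [
            self.vwa("v1", 0, "MIDAS_intact"),
            ("atp", 40, "+", 800, [vocab.VIRB4_ATPASE]),
        ]
        nbhd, hits = tery_neighborhood(specs)
        variant, midas = detect_extended_IIIA(nbhd, hits)
        assert variant is ExtendedIIIA.NONE
        assert midas == {"v1": "intact"}


class TestCarfSuperoperon:
    def carf_contig(self, carf_gap=100, carf_strand="+", extra=()):
        specs = [
            ("carf", 0, carf_strand, 400, [vocab.CARF_RTCR]),
            *extra,
            ("b", carf_gap, "+", 400, B_CORE),
            ("c", 40, "+", 300, C_CORE),
        ]
        genes, hits = build(specs)
        contig = Contig("c", genes, length=genes[-1].end + 100)
        by_id = {g.gene_id: g for g in genes}
        return contig, [by_id["b"], by_id["c"]], hits

    def test_direct_association(self):
        contig, locus_genes, hits = self.carf_contig(carf_gap=150)
        record = detect_carf_superoperon(contig, locus_genes, hits)
        assert record is not None
        assert record.carf_gene.gene_id == "carf"
        assert record.same_direction is True
        member_ids = [g.gene_id for g in record.member_genes]
        assert member_ids == ["carf", "b", "c"]

    def test_gap_boundary_200(self):
        contig, locus_genes, hits = self.carf_contig(carf_gap=200)
        assert detect_carf_superoperon(contig, locus_genes, hits) is not None
        contig, locus_genes, hits = self.carf_contig(carf_gap=201)
        assert detect_carf_superoperon(contig, locus_genes, hits) is None

    def test_strand_break_blocks(self):
        contig, locus_genes, hits = self.carf_contig(carf_strand="-")
        assert detect_carf_superoperon(contig, locus_genes, hits) is None

    def test_embedded_systems_tagged(self):
        extra = [
            ("hr", 100, "+", 900, [vocab.HSDR]),
            ("hm", 60, "+", 500, [vocab.HSDM]),
            ("bt", 60, "+", 90, [vocab.BRNT_LIKE]),
        ]
        contig, locus_genes, hits = self.carf_contig(carf_gap=60, extra=extra)
        record = detect_carf_superoperon(contig, locus_genes, hits)
        assert record is not None
        assert set(record.embedded_systems) == {"TypeI_RM", "BrnT_like"}
        assert len(record.embedded_systems) == 2  # TypeI_RM tagged once

    def test_minus_strand_walks_downstream(self):
        specs = [
            ("c", 0, "-", 300, C_CORE),
            ("b", 40, "-", 400, B_CORE),
            ("carf", 100, "-", 400, [vocab.CARF_RTCR]),
        ]
        genes, hits = build(specs)
        contig = Contig("c", genes, length=genes[-1].end + 100)
        locus_genes = [g for g in genes if g.gene_id in ("b", "c")]
        record = detect_carf_superoperon(contig, locus_genes, hits)
        assert record is not None and record.carf_gene.gene_id == "carf"


class TestAssignRoles:
    def roles_for(self, specs, label=Label.III_A):
        genes, hits = build(specs)
        system = CandidateSystem(
            mcrB_gene=genes[0], mcrC_gene=None, intervening_gene_count=0,
            order_reversed=False, tier=ValidationTier.STRICT, signature=NXD,
        )
        assigned = assign_roles(system, genes, index_hits(hits), label)
        return {c.gene.gene_id: c for c in assigned}

    def test_fused_bc_conflict_demoted(self):
        roles = self.roles_for([("f", 0, "+", 700, B_CORE + C_CORE)])
        assert roles["f"].role is Role.ACCESSORY
        assert "conflict:fused_BC" in roles["f"].evidence

    def test_cnuCD_fusion(self):
        roles = self.roles_for(
            [("b", 0, "+", 400, B_CORE),
             ("cd", 40, "+", 900, [vocab.DUF2357, vocab.HSP70])],
            label=Label.III_B,
        )
        assert roles["cd"].role is Role.CNUCD

    def test_cnuD_only_for_type_III_BC(self):
        specs = [("b", 0, "+", 400, B_CORE),
                 ("d", 40, "+", 600, [vocab.HSP70, CC60])]
        assert self.roles_for(specs, Label.III_B)["d"].role is Role.CNUD
        assert self.roles_for(specs, Label.II)["d"].role is Role.ACCESSORY

    def test_non_coconut_has_no_components(self):
        genes, hits = build([("b", 0, "+", 400, B_CORE)])
        system = CandidateSystem(
            mcrB_gene=genes[0], mcrC_gene=None, intervening_gene_count=0,
            order_reversed=False, tier=ValidationTier.STRICT, signature=NO_SIG,
        )
        assert assign_roles(system, genes, index_hits(hits), Label.NON_COCONUT) == []


class TestCallValidation:
    def test_extended_variant_requires_IIIA(self):
        with pytest.raises(ValueError, match="III-A"):
            CoCoNuTCall("l", "c", Label.II, extended_IIIA=ExtendedIIIA.ESSC_LIKE)

    def test_tery_p_requires_II_or_IIIA(self):
        with pytest.raises(ValueError, match="TerY-P"):
            CoCoNuTCall("l", "c", Label.I_A, tery_p=True)
        CoCoNuTCall("l", "c", Label.II, tery_p=True)  # allowed


class TestEndToEnd:
    def test_labels_match_simulated_truth(self, pipeline):
        truth_by_contig = {t.contig_id: t for t in pipeline["truth"]}
        assert len(pipeline["calls"]) == len(truth_by_contig)
        for call in pipeline["calls"]:
            truth = truth_by_contig[call.contig_id]
            assert call.label.value == truth.label, call.contig_id

    def test_IIIA_cnuE_has_exactly_two_hepn(self, pipeline):
        idx = index_hits(pipeline["hits"])
        calls = [c for c in pipeline["calls"] if c.label is Label.III_A]
        assert calls
        for call in calls:
            cnuE = [c for c in call.components if c.role is Role.CNUE]
            assert len(cnuE) == 1
            hepn = [
                h for h in idx[cnuE[0].gene.protein_id]
                if h.domain_name == vocab.HEPN
            ]
            assert len(hepn) == 2

    def test_ancillary_flags_match_truth(self, pipeline):
        truth_by_contig = {t.contig_id: t for t in pipeline["truth"]}
        for call in pipeline["calls"]:
            truth = truth_by_contig[call.contig_id]
            assert call.tery_p == truth.ancillary.get("tery_p", False)
            assert call.extended_IIIA.value == truth.ancillary.get(
                "extended_IIIA", "none"
            )
            if truth.ancillary.get("superoperon", False):
                assert call.carf_association is not None

    def test_roles_match_truth(self, pipeline):
        truth_by_contig = {t.contig_id: t for t in pipeline["truth"]}
        for call in pipeline["calls"]:
            truth = truth_by_contig[call.contig_id]
            if truth.label == "non_CoCoNuT_McrBC":
                continue
            assigned = {
                c.gene.gene_id: c.role.value
                for c in call.components
                if c.role is not Role.ACCESSORY
            }
            expected = {
                gid: role for gid, role in truth.roles.items()
                if role in assigned  # truth roles use the same Cnu names
                or role.startswith("Cnu")
            }
            for gid, role in expected.items():
                assert assigned.get(gid) == role, (call.contig_id, gid)
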