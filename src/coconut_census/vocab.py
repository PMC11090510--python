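"""Domain-name vocabulary shared by the annotator, classifier, and simulator.

These are the profile-database names the pipeline recognizes. Motif-bearing
domains (GTPase, HEPN, VWA, ZnR) are additionally scanned at the sequence
level; the rest are recognized purely from profile-search (adapter) hit
names.
"""

# McrB GTPase primary profile and the coiled-coil / effector vocabulary
COG1401 = "COG1401"            # McrB GTPase domain
DUF2357 = "DUF2357"            # McrC N-terminal helical bundle
PD_DEXK = "PD_DExK"            # McrC PD-(D/E)xK endonuclease (possibly inactivated)
IG_LIKE = "Ig_like"            # immunoglobulin-like beta-sandwich
ZNR = "ZnR"                    # zinc ribbon
CSD = "CSD"                    # cold shock domain (OB-fold)
YTH = "YTH"                    # YTH-like EVE-superfamily domain
PYD = "PYD"                    # pyrin/CARD-like DEATH-superfamily domain
REC = "REC"                    # phosphoacceptor receiver domain
SPB = "SPB"                    # SmpB-like OB-fold
RTL = "RTL"                    # RNase-toxin-like (RelE/Colicin D fold)
OB_STALK = "OB_stalk"          # OB-fold on the helicase stalk extension
WHTH = "wHTH"                  # elongated winged HTH
HEPN = "HEPN"                  # HEPN ribonuclease domain
VSR = "Vsr"                    # very-short-patch-repair PD-(D/E)xK nuclease
PLD = "PLD"                    # phospholipase D family nuclease
HSP70 = "Hsp70"                # Hsp70-like NBD/SBD unit
HEAT = "HEAT"                  # HEAT-like helical repeats
SF1_HELICASE = "SF1_helicase"  # UPF1-like superfamily 1 helicase (CnuH)
COILED_COIL = "coiled_coil"    # built-in heptad heuristic hit

# TerY-P triad
VWA = "VWA"
PP2C = "PP2C"
STK = "STK"

# Extended Type III-A inserts
ESSC_ATPASE = "EssC_ATPase"
SPOVK_ATPASE = "SpoVK_ATPase"
VIRB4_ATPASE = "VirB4_ATPase"
WXG100 = "WXG100"
GLY_ZIP = "Gly_zip"
D_EXK = "D_ExK"

# CARF/RtcR superoperons and embedded ancillary systems
CARF_RTCR = "CARF_RtcR"
HSDR = "HsdR"
HSDM = "HsdM"
HSDS = "HsdS"
DRUANTIA_III = "Druantia_III"
BREX = "BREX"
SHDA = "ShdA"
BRNT_LIKE = "BrnT_like"

# Raw homology-search tags (the seam for the out-of-scope database search)
MCRB_SEARCH_HIT = "McrB_PSSM_hit"
MCRC_SEARCH_HIT = "McrC_PSSM_hit"

# Hit names mapped to embedded-system tags in superoperon records
EMBEDDED_SYSTEM_TAGS: dict[str, str] = {
    HSDR: "TypeI_RM",
    HSDM: "TypeI_RM",
    HSDS: "TypeI_RM",
    DRUANTIA_III: "Druantia_III",
    BREX: "BREX",
    SHDA: "Shield_ShdA",
    BRNT_LIKE: "BrnT_like",
}
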