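"""Sequence-level annotation.

Scanners for the McrB GTPase Nx(xx)D signature motif, HEPN RxxxxH/RxH
RNase motifs, the VWA MIDAS motif, zinc-ribbon CPxC repeats, a heptad
coiled-coil heuristic, plus the pluggable profile-search adapter contract
and the McrB/McrC alias tables used to filter genomic neighborhoods.

Every scanner is a pure function of its inputs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Protocol, Sequence

from . import vocab
from .core import (
    DomainHit,
    HitSource,
    MotifVariant,
    ProteinRecord,
    SignatureMotif,
)

# ---------------------------------------------------------------------------
# Alias tables (neighborhood filtering vocabulary)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AliasTables:
    """Profile names accepted as evidence for McrB-like and McrC-like genes.

    Several of the McrB aliases are not McrB-specific: they are domains
    commonly fused to McrB GTPase homologs, or larger AAA+ families that
    contain McrB homologs; bona fide homologs frequently hit these instead
    of the primary GTPase profile.
    """

    mcrB_aliases: frozenset[str] = frozenset(
        {
            "MoxR",
            "AAA_5",
            "COG4127",
            "DUF4357",
            "Smc",
            "WEMBL",
            "Myosin_tail_1",
            "DUF3578",
            "EVE",
            "Mrr_N",
            "pfam01878",
        }
    )
    mcrC_aliases: frozenset[str] = frozenset(
        {
            "McrBC",
            "McrC",
            "PF09823",
            "DUF2357",
            "COG1700",
            "PDDEXK_7",
            "RE_LlaJI",
        }
    )
    primary_mcrB: frozenset[str] = frozenset({vocab.COG1401})
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if not self.allow_overlap and (self.mcrB_aliases & self.mcrC_aliases):
            raise ValueError("McrB and McrC alias sets must be disjoint")

    @property
    def mcrB_evidence(self) -> frozenset[str]:
        return self.primary_mcrB | self.mcrB_aliases


class ProfileSearchAdapter(Protocol):
    """Contract for plugging in an external profile search.

    Implementations must be deterministic for fixed inputs and return hits
    satisfying the DomainHit invariants. The shipped mock adapter replays
    planted synthetic-genome annotations; a production adapter would wrap a
    real profile search over CDD/Pfam.
    """

    def __call__(
        self, protein: ProteinRecord, database: str = "cdd_pfam"
    ) -> list[DomainHit]:
        ...


# ---------------------------------------------------------------------------
# Signature motif (Walker A / Walker B / Nx(xx)D)
# ---------------------------------------------------------------------------

WALKER_A_RE = re.compile(r"G.{4}GK[ST]")
# Standard P-loop NTPase Walker B: four hydrophobics then DE.
WALKER_B_HYDROPHOBIC = "ILVMFA"
WALKER_B_RE = re.compile(rf"[{WALKER_B_HYDROPHOBIC}]{{4}}DE")

_SPACER_TO_VARIANT = {1: MotifVariant.NXD, 2: MotifVariant.NXXD, 3: MotifVariant.NXXXD}


def scan_signature_motif(
    seq: str, gtpase_hit: DomainHit, window: int = 60
) -> SignatureMotif:
    """Locate the GTPase signature motif downstream of Walker B.

    Returns the first N-x{1..3}-D match whose N lies within ``window``
    residues after the Walker B motif, inside the GTPase domain hit.
    Positions are scanned left to right and, at each asparagine, the
    shortest spacer is tried first, so ties resolve to the shortest spacer
    at the earliest position. When Walker A or Walker B cannot be located
    inside the hit the variant is ``none`` with a diagnostic flag.
    """
    region = seq[gtpase_hit.start_aa : gtpase_hit.end_aa]
    wa = WALKER_A_RE.search(region)
    if wa is None:
        return SignatureMotif(MotifVariant.NONE, diagnostic="no_walker_a")
    wb = WALKER_B_RE.search(region, wa.end())
    if wb is None:
        return SignatureMotif(MotifVariant.NONE, diagnostic="no_walker_b")
    wb_end = gtpase_hit.start_aa + wb.end()
    zone_end = min(gtpase_hit.end_aa, wb_end + window)
    for pos in range(wb_end, zone_end):
        if seq[pos] != "N":
            continue
        for spacer in (1, 2, 3):
            dpos = pos + spacer + 1
            if dpos < gtpase_hit.end_aa and dpos < len(seq) and seq[dpos] == "D":
                follower = seq[dpos + 1] if dpos + 1 < len(seq) else None
                return SignatureMotif(
                    variant=_SPACER_TO_VARIANT[spacer],
                    position_aa=pos,
                    follower=follower,
                    gap_from_walker_b=pos - wb_end,
                )
    return SignatureMotif(MotifVariant.NONE, diagnostic="no_motif_in_window")


def effective_signature(
    seq: str,
    gtpase_hit: DomainHit,
    window: int = 60,
    insert_scan_window: int = 200,
) -> SignatureMotif:
    """Signature scan tolerant of the Type I-A helical insert.

    The compact motif sits within ``window`` residues of Walker B; Type I-A
    GTPases carry a helical insert between Walker B and the NxD motif, so
    when the default window finds nothing the scan is repeated with the
    extended window and the Walker-B-to-N spacing is preserved on the
    result so the insert heuristic can fire downstream.
    """
    sig = scan_signature_motif(seq, gtpase_hit, window=window)
    if sig.variant is not MotifVariant.NONE or sig.diagnostic != "no_motif_in_window":
        return sig
    return scan_signature_motif(seq, gtpase_hit, window=insert_scan_window)


# ---------------------------------------------------------------------------
# HEPN, MIDAS, CPxC
# ---------------------------------------------------------------------------

HEPN_FULL_RE = re.compile(r"R.{4}H")
HEPN_SHORT_RE = re.compile(r"R.H")


def scan_hepn(
    seq: str, hepn_regions: Optional[Sequence[tuple[int, int]]] = None
) -> list[tuple[str, int]]:
    """Find HEPN RNase motifs.

    All non-overlapping RxxxxH matches are reported. Shortened RxH matches
    carry almost no information on their own, so they are reported only
    inside regions annotated as HEPN domains (``hepn_regions``,
    half-open aa intervals) and only where they do not overlap a full
    RxxxxH match.
    """
    results: list[tuple[str, int]] = []
    full_spans: list[tuple[int, int]] = []
    for m in HEPN_FULL_RE.finditer(seq):
        results.append(("RxxxxH", m.start()))
        full_spans.append((m.start(), m.end()))
    for m in HEPN_SHORT_RE.finditer(seq):
        s, e = m.start(), m.end()
        if any(s < fe and fs < e for fs, fe in full_spans):
            continue
        if hepn_regions is None or not any(
            rs <= s and e <= re_ for rs, re_ in hepn_regions
        ):
            continue
        results.append(("RxH", s))
    results.sort(key=lambda t: t[1])
    return results


class MidasState(str, Enum):
    INTACT = "intact"
    DEGRADED_NO_T = "degraded_no_T"
    ABSENT = "absent"


MIDAS_HEAD_RE = re.compile(r"(?=D.S.S)")


def scan_midas(
    seq: str,
    t_window: tuple[int, int] = (20, 80),
    d_window: tuple[int, int] = (10, 60),
) -> MidasState:
    """Classify the VWA MIDAS motif (DxSxS...T...D) in a sequence.

    ``intact`` requires DxSxS followed by a threonine within ``t_window``
    residues and an aspartate within ``d_window`` residues after the
    threonine. ``degraded_no_T`` covers the internal-VWA state where the
    middle threonine is missing but the downstream aspartate still falls
    within the combined window.
    """
    t_lo, t_hi = t_window
    d_lo, d_hi = d_window
    degraded = False
    for m in MIDAS_HEAD_RE.finditer(seq):
        head_end = m.start() + 5
        for t in range(head_end + t_lo, min(head_end + t_hi + 1, len(seq))):
            if seq[t] != "T":
                continue
            for d in range(t + 1 + d_lo, min(t + 1 + d_hi + 1, len(seq))):
                if seq[d] == "D":
                    return MidasState.INTACT
        lo = head_end + t_lo + 1 + d_lo
        hi = head_end + t_hi + 1 + d_hi
        if any(seq[d] == "D" for d in range(lo, min(hi + 1, len(seq)))):
            degraded = True
    return MidasState.DEGRADED_NO_T if degraded else MidasState.ABSENT


CPXC_RE = re.compile(r"CP.C")


def count_cpxc(seq: str) -> int:
    """Count non-overlapping Zn-binding CPxC motifs, left to right."""
    return sum(1 for _ in CPXC_RE.finditer(seq))


# ---------------------------------------------------------------------------
# Coiled-coil heptad heuristic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoiledCoilSegment:
    start_aa: int
    end_aa: int
    score: float

    def __post_init__(self) -> None:
        if self.end_aa <= self.start_aa:
            raise ValueError("empty coiled-coil segment")


# Heptad positions a..g = 0..6; positions a/d form the hydrophobic core.
_CORE_RESIDUES = set("LIVMFA")
_POLAR_RESIDUES = set("EKRDQN")
_CORE_PROP = 2.2      # core residue at a/d
_CORE_OFF = 0.6       # core residue elsewhere
_POLAR_PROP = 1.4     # polar residue at b,c,e,f,g
_POLAR_OFF = 0.4      # polar residue at a/d
_PRO_PROP = 0.25      # proline breaks helices everywhere
_GLY_PROP = 0.7


def _log_propensity(residue: str, heptad_pos: int) -> float:
    at_core = heptad_pos in (0, 3)
    if residue == "P":
        return math.log(_PRO_PROP)
    if residue == "G":
        return math.log(_GLY_PROP)
    if residue in _CORE_RESIDUES:
        return math.log(_CORE_PROP if at_core else _CORE_OFF)
    if residue in _POLAR_RESIDUES:
        # polar/charged residues are favored at the solvent-exposed
        # positions and disfavored in the hydrophobic core
        return math.log(_POLAR_OFF if at_core else _POLAR_PROP)
    return 0.0


# Best achievable per-position mean log-propensity (core at a/d, polar elsewhere)
_LOG_GM_MAX = (2 * math.log(_CORE_PROP) + 5 * math.log(_POLAR_PROP)) / 7


def coiled_coil_window_score(window_seq: str) -> float:
    """Score one window: best-over-7-frames geometric mean of heptad
    propensities, normalized to [0, 1] against the ideal heptad."""
    n = len(window_seq)
    best = -math.inf
    for frame in range(7):
        total = sum(
            _log_propensity(window_seq[j], (j + frame) % 7) for j in range(n)
        )
        best = max(best, total / n)
    return min(1.0, max(0.0, best / _LOG_GM_MAX))


def predict_coiled_coil(
    seq: str, window: int = 28, threshold: float = 0.5
) -> list[CoiledCoilSegment]:
    """Sliding-window heptad-propensity coiled-coil prediction.

    Maximal runs of windows scoring at or above ``threshold`` are merged
    into segments. Sequences shorter than the window yield no segments.
    """
    if len(seq) < window:
        return []
    scores = [
        coiled_coil_window_score(seq[i : i + window])
        for i in range(len(seq) - window + 1)
    ]
    segments: list[CoiledCoilSegment] = []
    run_start: Optional[int] = None
    run_best = 0.0
    for i, s in enumerate(scores + [-1.0]):  # sentinel flushes the last run
        if s >= threshold:
            if run_start is None:
                run_start = i
                run_best = s
            else:
                run_best = max(run_best, s)
        elif run_start is not None:
            segments.append(
                CoiledCoilSegment(
                    start_aa=run_start, end_aa=(i - 1) + window, score=run_best
                )
            )
            run_start = None
    return segments


# ---------------------------------------------------------------------------
# Whole-bundle annotation
# ---------------------------------------------------------------------------


def annotate_proteins(
    bundle,
    adapter: ProfileSearchAdapter,
    alias: Optional[AliasTables] = None,
    evalue_threshold: float = 0.001,
    cc_window: int = 28,
    cc_threshold: float = 0.5,
    signature_window: int = 60,
    insert_scan_window: int = 200,
    diagnostics: Optional[dict[str, str]] = None,
) -> list[DomainHit]:
    """Union of adapter (profile) hits and built-in motif/coiled-coil hits.

    Adapter hits above the E-value threshold are dropped; duplicate
    identical hits are de-duplicated; an adapter failure on one protein is
    recorded as a per-protein diagnostic rather than aborting the run.
    Output order is deterministic: (protein_id, start_aa, domain_name).
    """
    alias = alias or AliasTables()
    seen: set[tuple] = set()
    out: list[DomainHit] = []

    def add(hit: DomainHit) -> None:
        key = (hit.protein_id, hit.domain_name, hit.start_aa, hit.end_aa, hit.source)
        if key not in seen:
            seen.add(key)
            out.append(hit)

    for pid in sorted(bundle.proteins):
        protein = bundle.proteins[pid]
        seq = protein.sequence
        try:
            adapter_hits = adapter(protein)
        except Exception as exc:  # noqa: BLE001 - adapter seam, not fatal
            if diagnostics is not None:
                diagnostics[pid] = f"adapter failure: {exc}"
            adapter_hits = []
        kept: list[DomainHit] = []
        for h in adapter_hits:
            if h.evalue is not None and h.evalue > evalue_threshold:
                continue
            if h.end_aa > len(seq):
                if diagnostics is not None:
                    diagnostics[pid] = f"adapter hit {h.domain_name} out of bounds"
                continue
            kept.append(h)
            add(h)

        for seg in predict_coiled_coil(seq, window=cc_window, threshold=cc_threshold):
            add(
                DomainHit(
                    protein_id=pid,
                    domain_name=vocab.COILED_COIL,
                    start_aa=seg.start_aa,
                    end_aa=seg.end_aa,
                    source=HitSource.COILED_COIL,
                )
            )

        gtpase_hits = [h for h in kept if h.domain_name in alias.primary_mcrB]
        for gh in gtpase_hits:
            sig = effective_signature(
                seq, gh, window=signature_window, insert_scan_window=insert_scan_window
            )
            if sig.variant is not MotifVariant.NONE:
                spacer = {"NxD": 1, "NxxD": 2, "NxxxD": 3}[sig.variant.value]
                add(
                    DomainHit(
                        protein_id=pid,
                        domain_name=sig.variant.value,
                        start_aa=sig.position_aa,
                        end_aa=sig.position_aa + spacer + 2,
                        source=HitSource.MOTIF,
                    )
                )

        hepn_regions = [
            (h.start_aa, h.end_aa) for h in kept if h.domain_name == vocab.HEPN
        ]
        for name, pos in scan_hepn(seq, hepn_regions=hepn_regions):
            span = 6 if name == "RxxxxH" else 3
            add(
                DomainHit(
                    protein_id=pid,
                    domain_name=name,
                    start_aa=pos,
                    end_aa=pos + span,
                    source=HitSource.MOTIF,
                )
            )

        for vh in (h for h in kept if h.domain_name == vocab.VWA):
            state = scan_midas(seq[vh.start_aa : vh.end_aa])
            if state is not MidasState.ABSENT:
                add(
                    DomainHit(
                        protein_id=pid,
                        domain_name=f"MIDAS_{state.value}",
                        start_aa=vh.start_aa,
                        end_aa=vh.end_aa,
                        source=HitSource.MOTIF,
                    )
                )

        for m in CPXC_RE.finditer(seq):
            add(
                DomainHit(
                    protein_id=pid,
                    domain_name="CPxC",
                    start_aa=m.start(),
                    end_aa=m.end(),
                    source=HitSource.MOTIF,
                )
            )

    out.sort(key=lambda h: (h.protein_id, h.start_aa, h.domain_name))
    return out
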