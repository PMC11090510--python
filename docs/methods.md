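# Methods

This document records the algorithms, parameter choices, and deliberate
limitations of `coconut_census`. Modules are listed in pipeline order.

## Data model (`core`)

Genes use 0-based half-open nucleotide coordinates internally;
`to_external_coords`/`from_external_coords` convert to the 1-based inclusive
convention used by GFF3. `intergenic_gap` is orientation-free and returns a
non-positive value for overlapping reading frames (a real and common operon
feature, so overlaps must count as "adjacent"). Proteins are validated
against the 20-letter alphabet plus `X`; domain hits are half-open amino-acid
intervals with an optional E-value (`None` means "not applicable", e.g. the
built-in coiled-coil heuristic).

## I/O (`io_formats`)

GFF3 (CDS features only; `##sequence-region` sets contig length), FASTA
(first header token is the ID), a 6-column TSV for domain hits, and Newick
via scikit-bio. Parsers fail fast and name the offending line number.
Reports are written as a JSON document (version, config, funnel counters,
full calls) plus a one-row-per-locus TSV for spreadsheet use.

## Motif annotation (`motif_annotation`)

Profile-database search is out of scope; it enters through an adapter
callable `(protein, database) -> [DomainHit]`. `annotate_proteins` merges
adapter hits (filtered at E ≤ 1e-3) with the built-in sequence-level
scanners and records per-protein diagnostics when the adapter fails.

- **GTPase signature.** Inside a COG1401 hit, Walker A (`G....GK[ST]`) is
  located first, then Walker B (four hydrophobics + `DE`) downstream of it,
  then the first `N x{1..3} D` whose asparagine lies within 60 aa after
  Walker B (ties resolve to the earliest position, shortest spacer). The
  Walker-B-to-N spacing is kept on the result. `effective_signature`
  re-scans with a 200 aa window when the compact window finds nothing, so
  the Type I-A helical insert (spacing ≥ 80 aa) does not mask the motif.
- **HEPN.** All non-overlapping `R....H` matches anywhere; shortened `R.H`
  matches are reported only inside annotated HEPN regions and never inside
  a full match (alone they carry almost no information).
- **MIDAS.** `DxSxS … T … D` with the threonine 20–80 aa after the head and
  the aspartate 10–60 aa after the threonine; a missing threonine with the
  aspartate still in the combined window is classified `degraded_no_T`,
  the state expected of the internal VWA copy in extended Type III-A loci.
- **CPxC.** Non-overlapping count, left to right.
- **Coiled-coil.** A 28-residue window is scored over all 7 heptad frames:
  per-position propensities (core residues LIVMFA favored at a/d, polar
  EKRDQN favored at b,c,e,f,g, proline strongly penalized everywhere),
  geometric-mean-normalized so a perfect heptad scores 1.0; windows with
  best-frame score ≥ 0.5 are merged into segments. This is a deliberately
  simple stand-in for dedicated predictors, sufficient for the simulator's
  planted heptad arrays and for real sequences' long CnuA/CnuB coils.

## Neighborhood census (`neighborhood_census`)

Neighborhoods are the anchor ± 10 genes, truncated at contig ends. The
three filter tiers (strict / relaxed / rescue) are described in the README;
all three share the same alias tables, the ≤ 90 nt same-strand adjacency
rule, and the strict `> 200 aa` (McrB) / `> 150 aa` (McrC) size gates.
Operonic association is the transitive same-strand chain with successive
gaps ≤ 90 nt. Pairing is greedy nearest-first with at most 2 intervening
genes, records order reversal relative to transcription, and never reuses a
gene; unpaired candidates become orphans with tier `orphan_manual`. The
funnel counters (input, per-tier passes, paired, orphan) are reported
alongside the systems.

## Profile clustering (`profile_clustering`)

Pairwise identity is matches / alignment-length under BLOSUM62 global
alignment with gap open 11, extend 1 (Biopython `PairwiseAligner`; a gap of
length k costs 11 + (k−1)). Greedy clustering processes sequences
longest-first for determinism. Each cluster is center-star aligned around
its centroid; profiles are per-column frequencies over 20 aa + gap with a
0.01 pseudocount (`X` spreads uniformly over the amino-acid bins). The
cluster-cluster score is the best ungapped sliding-offset sum of column dot
products; clusters merge by single linkage when cross/max(self_A, self_B)
is **strictly greater** than 0.1, and merged clusters are re-aligned and
re-profiled. Three cluster–merge iterations run with early stop at a
fixpoint; the cluster count never increases.

**Known limitation.** With the raw dot-product score, two *unrelated*
single-sequence profiles of typical protein length have a cross/self ratio
of roughly 0.05–0.12 (per-column match probability ~1/20, inflated by
taking the best offset), so the 0.1 merge threshold can chain unrelated
families at the profile stage. The scoring and threshold are deliberately
kept as stated above — they are the procedure's defining post-conditions — and the
behavior is deterministic; the greedy (identity) stage still recovers
planted families exactly, and the acceptance script reports both counts.

Representatives come from a second greedy pass at 0.9 identity; trees are
neighbor-joining over 1 − identity distances (exact on additive matrices;
the 2-leaf case splits the single distance). This is an adapter-level
stand-in for external maximum-likelihood tree building.

## Classification (`coconut_classifier`)

The taxonomy enumerates 3 types and 7 subtypes; Pseudo-Type I-B is a
derived variant of I-B (lost CnuA), not an eighth subtype. The decision
grammar is ordered, first match wins:

0. signature not NxD → `non_CoCoNuT_McrBC`;
1. Vsr fused to the CnuH helicase, no separate CnuE → III-B;
2. CnuE with two PLD domains → III-C;
3. CnuE with two HEPN domains, or CnuC–Hsp70 fusion → III-A;
4. CnuE with one HEPN plus a CnuH → II;
5. no CnuH/CnuE but the GTPase helical insert (Walker-B→NxD ≥ 80 aa) → I-A;
6. CnuA carrying PYD + REC in the locus → I-B;
7. I-B-like CnuB (CSD, no long coiled-coil) and no CnuA anywhere in the
   island → Pseudo-I-B;
8. CSD plus a long coiled-coil on CnuB → I-C (with a diagnostic when the
   YTH discriminator against I-B is unavailable);
9. otherwise `unclassified`, with diagnostics.

"CnuA-like" requires a coiled-coil segment of **≥ 50 aa** and none of the
core-component domains: isolated 28-residue windows clear the score
threshold by chance in unrelated proteins (~3.6σ events over proteome-scale
scanning), while genuine Cnu coiled-coils are long. The same length gate
applies to the CnuB coiled-coil used by rules 7/8. Extended-III-A ATPases
(EssC/SpoVK/VirB4-like) are excluded from CnuA candidacy explicitly.

Ancillary modules: the TerY-P triad is three consecutive same-strand genes
with VWA, PP2C, and STK+ZnR in order (either direction), flagged only for
Types II/III-A; extended Type III-A variants are diagnostic ATPases between
duplicated VWA genes (EssC-like requires a WXG100 gene in the insert,
SpoVK-like a glycine-zipper partner, VirB4-like may have migrated to the
locus 3′ end), with the MIDAS state of each VWA copy recorded; CARF/RtcR
superoperons are found by walking upstream in the direction of
transcription while genes stay co-oriented with gaps ≤ 200 nt, tagging
embedded defense systems (Type I RM, BREX, Druantia III, ShdA, BrnT-like).

Role assignment maps each locus gene to exactly one component
(CnuA/B/C/CD/D/E/H or accessory); conflicting evidence (e.g. a fused
GTPase+DUF2357 gene) demotes to accessory with an explicit conflict note.

## Synthetic data (`synthetic_data`)

The simulator plants one locus per subtype (plus non-CoCoNuT McrBC operons
and decoy neighborhoods) in seeded uniform-random protein background, with
every motif the scanners look for spelled literally (Walker A/B, the
NxD/NxxD/NxxxD signatures, HEPN `R....H`, MIDAS, CPxC, heptad arrays) and
anchor residues excluded from spacer regions so no spurious earlier match
can pre-empt a planted one. Operon gaps are U[0, 90] nt with a 20% chance
of a 4 nt overlap; superoperon gaps are 95–190 nt (above the operon chain
threshold, below the superoperon walk threshold); flanking decoy genes sit
on the opposite strand at 250–600 nt. Strands are randomized with
transcription order preserved. The generator returns the annotated bundle,
a ground-truth record per locus (label, roles, motif positions, ancillary
flags), and the planted domain intervals; `mock_profile_adapter` replays
those intervals as profile hits, optionally injecting deterministic
non-vocabulary false positives for robustness testing.
`generate_clustering_fixture` builds planted-partition families and
verifies the within/across identity margin.

## Testing

Unit and Hypothesis property tests cover every module (derandomized,
seeded); `tests/test_acceptance.py` holds one test per acceptance
criterion: census decision boundaries, clustering thresholds/iterations on
constructed fixtures (including an exact-0.1 profile pair proving the
strict inequality, and a three-cluster fixture whose merges need two rounds
plus a confirming third), the 3/7 taxonomy with the two-HEPN CnuE, and the
property suites (planted-truth recovery over ≥ 3 seeds, an independent
affine-gap DP oracle, NJ additive recovery, clustering invariants, naive
motif oracles over 1,000 random sequences, and format round-trips).
`scripts/acceptance.py --seed N --out F` recomputes the headline quantities
from scratch.
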