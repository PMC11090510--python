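# coconut-census

Detection, clustering, and classification of CoCoNuT systems — a subclass of
McrBC-family Type IV restriction systems marked by extensive coiled-coils and
tandem nucleases — from annotated prokaryotic genomes.

## The scientific problem

McrBC systems are two-component, modification-dependent restriction modules:
McrB is an AAA+ GTPase that engages the target nucleic acid, and McrC carries
a DUF2357 helical bundle that activates the GTPase plus a PD-(D/E)xK
endonuclease (often inactivated). A distinctive branch of this family — the
**CoCoNuTs** (**co**iled-**co**il **nu**clease **t**andem systems) — replaces
or augments the canonical DNA-targeting apparatus with long coiled-coil
segments and tandem RNA-cleaving nucleases (HEPN, PLD), and is predicted to
target RNA rather than DNA. Membership in the CoCoNuT clade is gated by the
**NxD** variant of the McrB GTPase signature motif (versus NxxD/NxxxD in
classical McrBC).

Given annotated contigs (genes + protein sequences) and per-protein domain
annotations, this package answers three questions:

1. **Census** — which gene neighborhoods contain a bona fide McrBC system?
   A three-tier funnel mirrors decreasing evidence strength:
   - *strict*: a primary McrB GTPase (COG1401) profile hit, or hits from both
     the McrB-alias and McrC-alias domain classes in the same neighborhood;
   - *relaxed*: only one alias class is present, but an adjacent same-strand
     gene within **90 nt** encodes a protein large enough to be the missing
     component (**> 200 aa** for McrB, **> 150 aa** for McrC);
   - *rescue*: no alias hits at all, but the anchor is a raw homology-search
     hit and a gene in transitive operonic association with it passes the
     same size gates.
   Candidate McrB/McrC genes are then paired greedily (nearest first, at most
   2 intervening genes, order- and strand-aware), and each locus keeps a
   neighborhood of **10 genes per flank** for downstream context analysis.

2. **Clustering** — which candidate proteins form homolog families?
   Greedy incremental clustering at **0.5** fractional identity
   (BLOSUM62 global alignment, gap open 11 / extend 1), center-star
   alignment of each cluster, per-column frequency profiles, and
   single-linkage merging of clusters whose profile cross-score to
   self-score ratio **strictly exceeds 0.1**, iterated **3** times with
   early stop. Representatives for neighbor-joining trees come from a
   second greedy pass at **0.9** identity.

3. **Classification** — which CoCoNuT type/subtype is each validated locus?
   The taxonomy has **3 types and 7 subtypes** (I-A, I-B, I-C, II, III-A,
   III-B, III-C) plus the derived Pseudo-Type I-B variant. The ordered
   decision grammar uses the NxD gate, the helicase (CnuH) and effector
   (CnuE) composition, the effector's nuclease complement (one HEPN, two
   HEPN, two PLD, or a Vsr-like fusion), the Type I-A helical insert in the
   GTPase (Walker-B-to-NxD spacing ≥ 80 aa), and the stand-alone coiled-coil
   protein CnuA. Ancillary modules — the TerY-P triad, extended Type III-A
   ATPase insertions between duplicated VWA genes, and CARF/RtcR
   superoperons — are detected from the annotated neighborhood.

Database-scale homology search and maximum-likelihood phylogenetics are out
of scope; both enter through adapter seams (a profile-search callable and a
distance-based NJ stand-in) so the surrounding logic is fully testable with
the bundled synthetic-genome simulator.

## Worked example

Simulate a genome with one planted locus of every subtype, run the full
pipeline, and inspect the report:

```sh
coconut-census run-all --seed 7 --out-dir demo
```

```
wrote 16 contigs, 169 proteins, 10 planted loci to demo
10 loci classified: I-A=1, I-B=1, I-C=1, II=1, III-A=1, III-B=1, III-C=1, Pseudo-I-B=1, non_CoCoNuT_McrBC=2
pipeline outputs written to demo
```

`demo/report.tsv` then contains one row per locus, e.g. (columns abridged):

| locus_id | label | tier | signature | roles |
|---|---|---|---|---|
| ctg_IA_00:…g006\|…g007 | I-A | strict | NxD | CnuB:…g006;CnuC:…g007 |
| ctg_IIIA_04:…g007\|…g008 | III-A | strict | NxD | CnuB:…;CnuC:…;CnuH:…;CnuE:… |

`demo/report.json` carries the full records (components with evidence,
TerY-P and extended-III-A flags, CARF superoperon membership, diagnostics),
and `demo/clusters.json` / `demo/representatives.nwk` the CnuB homolog
families and representatives tree.

The same stages are available separately on real inputs: `simulate`,
`annotate`, `census`, `cluster`, and `classify` all read/write plain GFF3,
FASTA, TSV, JSON, and Newick. See `coconut-census <cmd> --help`; thresholds
can be overridden with a YAML file via `--config`.

As a library:

```python
from coconut_census import (
    SimConfig, generate_genome, mock_profile_adapter,
    annotate_proteins, run_census, classify_all, GenomeBundle,
)

genome = generate_genome(SimConfig(seed=7))
adapter = mock_profile_adapter(genome.planted)
hits = annotate_proteins(genome.bundle, adapter)
bundle = GenomeBundle(genome.bundle.contigs, genome.bundle.proteins, hits)
systems, funnel = run_census(bundle, adapter)
calls = classify_all(systems, bundle, hits)
print({c.label.value for c in calls})
```

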