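# Methods

`orpscan` screens microbial proteomes for type 1 (microbial) rhodopsin
homologs and characterizes the ones that lack the Schiff-base lysine —
opsin-related proteins (ORPs).  This note describes the models and
procedures, the tunable parameters, what the synthetic data emulate, the
numerical choices, and the known limitations.

## The classification model

Type 1 opsins are seven-transmembrane photoreceptors whose function
depends on a covalent Schiff-base linkage between a conserved helix-7
lysine (K216 in bacteriorhodopsin numbering) and retinal.  The defining
test of the pipeline is therefore read at a single alignment column:

* **K** at the Schiff column → canonical opsin; the family label
  (BR, BR2, HR, SRI, SRII, SR3, MR) is taken from the nearest reference
  by alignment score, a desk-scale stand-in for clade affiliation in a
  full phylogeny.  The neighbor-joining monophyly check corroborates it.
* **any other residue** → ORP.  Arginine defines group A; a residue from
  the hydrophobic set `{L, I, V, M, F, A}` defines group B; anything
  else is group-unassigned.  G and W are deliberately excluded from the
  hydrophobic set: G occurs at other fingerprint columns in group B
  sequences and W is aromatic-bulky rather than aliphatic.  The set is a
  config key (`hydrophobic_set`).
* **a gap** → unassigned, never ORP: a truncation is not a substitution
  and carries no evidence about the Schiff position.

Beyond the Schiff column, each hit is fingerprinted at ten further
functional positions in sensory-rhodopsin-II numbering: the signaling
set Y51, R72, D189, Y199 (the Y51/R72 hydrogen-bond pair and the
transducer-contacting D189/Y199) and the retinal-pocket set W76, V108,
F127, W171, Y174, W178.  ORPs characteristically lose pocket residues
(76→D and 178→A in group A; 178→G and a polar 127 in group B; 174→L in
both) while conserving the signaling positions — the pattern that
motivates reading them out per class in the conservation report.

## Homology search and the decoy-calibrated gate

Searches replace E-value statistics with an explicit null.  A position
log-odds profile (pseudocount 0.5, uniform 1/20 background, columns
over 50% gaps dropped) is built from the packaged family alignment.  A
query's profile score is its optimal free-end-gap alignment score
against that profile.  The gate cutoff is `mean + k·SD` of the profile
scores of 200 seed-fixed dipeptide-shuffled decoys built from the panel
sequences: `k = 4` is the `standard` preset (permissive-search intent),
`k = 6` the `strict` preset used for the retinal-pathway screen.
Dipeptide shuffling preserves local composition biases and so gives a
conservative null; plain residue shuffling is available as an option.
On the packaged panel the decoy null sits near score 4 ± 2 while true
family members score above 500, so the presets are far from the
boundary.  A hit must additionally reach `min_identity` (0.25) and
`min_coverage` (0.5) against its best reference.  For the five
single-exemplar retinal-pathway genes (crtY, brp, crtE, crtB, crtI) the
same calibration is applied per reference, with decoys being shuffles of
that reference scored by pairwise alignment.

Pairwise alignment is affine-gap Needleman–Wunsch (Gotoh), with a gap of
length `k` costing `gap_open + k·gap_extend` (defaults 11/1, BLOSUM62).
Search and anchoring use the free-end-gap (semi-global) mode, since the
rhodopsin domain spans most of these short proteins.  Traceback ties are
broken deterministically (diagonal, then up, then left); ties between
references at equal score go to the lexicographically smallest id.  The
dynamic program is checked in the test suite against brute-force
enumeration of all alignments for short sequences and against an
independent implementation (Biopython's `PairwiseAligner`) on random
pairs.

## Reference anchoring

Fingerprint positions are defined on the packaged SRII exemplar and
transferred to each query through the pairwise alignment: reference
position → aligned query position, or a gap marker.  Anchorability
requires 15% *global* identity — matches divided by the shorter
sequence's length — rather than identity over aligned columns, which a
tiny well-matching island could satisfy.  The Schiff column itself is
located structurally (the column of the reference alignment holding the
reference's Schiff lysine) and reported under the label 216 for
continuity with the bacteriorhodopsin-numbering convention; columns move
with alignments, printed labels should not.

## The packaged reference panel

The panel is synthetic: seven 240-residue family exemplars derived from
one seeded backbone (30% substitution divergence per non-SRII family,
fingerprint positions held canonical), plus five synthetic exemplars of
the retinal-biosynthesis genes at realistic lengths.  It is built
deterministically in code (`orpscan.references`) and can be exported
with `write_reference_panel`.  Swapping in a curated panel of real
sequences is a drop-in replacement — every downstream stage only assumes
a FASTA of family representatives whose SRII entry carries the
fingerprint residues at the literature positions.

## Phylogenetics

Distances are p-distances over pairwise-deleted gapped columns
(pairwise rather than complete deletion, so fragmentary queries retain
signal), optionally Poisson-corrected (−ln(1−p), error on saturation).
Neighbor joining is the standard Saitou–Nei agglomeration with two
determinism guarantees: ties in Q go to the lexicographically smallest
label pair (internal nodes labelled by their smallest leaf), and
negative branch-length estimates are clamped to zero with the
difference moved to the sibling edge (logged).  On additive inputs the
reconstruction is exact; the suite verifies topology and branch lengths
to 1e-9 on seeded random trees of up to 8 leaves, and cross-checks
topologies against scikit-bio's NJ.  The pipeline's tree is built on a
reference-anchored pseudo-alignment (each hit's residues written into
reference columns, insertions dropped) — adequate at desk scale, not a
substitute for a real MSA on large diverse sets.

## Genome context

Context is measured in gene ranks on the same contig, never base pairs,
making labels invariant under coordinate translation and whole-contig
strand flips.  Rules, in priority order: a transducer-category neighbor
within `adjacency_rank` (1) → `transducer_adjacent`; at least
`taxis_min_neighbors` (2) chemotaxis/flagellar genes within
`proximity_rank` (10) → `taxis_operon_proximal`; at least one stress
gene in the window → `stress_proximal`; otherwise `unlinked`.
"Adjacent" means zero intervening genes, either strand; co-orientation
with the target is reported as a flag rather than required, since the
claims being operationalized are adjacency-based, not operon
predictions.  Product strings are categorized by case-insensitive
substring against an editable packaged vocabulary
(`data/context_vocabulary.tsv`), first category wins in the priority
order transducer > taxis_operon > stress.

## Retinal-pathway co-occurrence

crtE, crtB and crtI build lycopene; crtY cyclizes it to β-carotene; brp
cleaves β-carotene into retinal.  Presence of crtY AND brp is the
retinal-capability proxy (the terminal, retinal-specific steps); all
five flags are reported so the implication "capable genomes carry the
full complement" remains checkable on any input.  The co-occurrence
summary lists genomes whose only opsins are ORPs, and among them those
lacking capability — the genomic signature of a retinal-independent
opsin function.

## Spectral calling

A spectrum is background-subtracted and normalized to a control's
280 nm absorbance; without a control it is normalized to its own A280
and flagged `self_normalized`.  The holo/apo decision asks whether the
maximum in the 480–580 nm window exceeds a straight chord across the
window endpoints by at least `min_prominence_sd` (3) times the noise SD,
estimated from the linearly detrended 600–800 nm region.  The verdict is
invariant under positive rescaling.  Two numerical choices matter for
λmax on broad bands (σ ≈ 30 nm): the spectrum is Savitzky–Golay smoothed
(21-point quadratic window) before locating the maximum, and the apex is
refined by a quadratic vertex fit — and λmax is read from the spectrum
itself, not the chord-subtracted excess, whose slope would shift a broad
band's apparent apex by several nm.  With these choices a planted 550 nm
band is recovered within ±0.6 nm across 200 noise realizations, and the
false-positive rate on flat noise-only spectra is below 1%.

## Synthetic data: what it emulates, and what it does not

The generator plants truth for every stage: class sequences are family
backbones (ORPs share a common 15%-diverged SRII-derived backbone, which
makes them a clade) with background substitutions at a configurable rate
and exact fingerprint edits applied *after* mutation; decoys are
dipeptide-shuffled panel members; genome layouts embed each ORP in a
chosen context with its supporting genes at fixed ranks; pathway genes
are planted per genome; spectra are Gaussian bands plus noise on the
250–800 nm, 2 nm grid.

The default configuration is the study condition used throughout the
tests and the acceptance script: 25 opsins (16 canonical over seven
families; 3 group A and 6 group B ORPs, preserving the roughly 1:2 A:B
ratio seen in haloarchaeal surveys), 10 decoys, 10 genomes at 60 genes
each, background rate 0.05, seed 7.  Four genomes are ORP-only; three of
those lack all pathway genes and one keeps brp alone (a partial
complement), mirroring the observed genome classes at desk scale.
Group A ORPs are all planted transducer-adjacent; group B cycles over
transducer, taxis-operon, stress and unlinked contexts.

What passing on these data shows: the pipeline's rules and plumbing are
correct and deterministic — planted labels are recovered exactly at 5%
background noise, and recovery degrades only as divergence approaches
the detection floor.  What it does not show: performance on real
proteomes, where start-site miscalls, indels, fragmentary sequences,
paralogy and annotation noise all occur.  The generator has no indel
model beyond optional fixed deletions and no phylogenetically realistic
substitution process.

## Problem sizes

Everything is sized for a single CPU: the default screen (35 proteins ×
7 references plus gate calibration) completes in seconds; the alignment
brute-force check enumerates all pairs of length ≤ 4 over a 3-letter
alphabet; NJ consistency uses 50 random trees of 4–8 leaves; spectral
calling uses 200 noise realizations.  These sizes are the package's
validation conditions, chosen to make the whole suite re-runnable in
minutes.

## Known limitations

* Family assignment by nearest reference collapses clade structure into
  best single-reference score; a weak MR exemplar can absorb BR-like
  sequences (and vice versa).  The panel keeps MR distinct; collapsing
  it into a BR-like group is a one-line panel edit.
* The decoy-calibrated gate is not an E-value; its presets are
  operational stand-ins for familiar stringencies, valid relative to the
  packaged panel and decoy model.
* The reference-anchored pseudo-MSA discards insertions relative to the
  reference; deep or heavily inserted sequences lose signal there.
* Context classification trusts product annotations; unannotated or
  renamed transducers produce `unlinked` labels.
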