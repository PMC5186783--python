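# Methods

## Scope and data model

hydroscan takes per-genome annotated inputs — a protein FASTA, gene
coordinates (GFF3 or a documented TSV dialect) and strain metadata
(habitat, morphological subsection) — and produces per-genome family
presence states, catalytic-residue verdicts, gene-cluster arrangement
labels, functional-capability calls and stratified co-occurrence tables.
Annotation is assumed given: there is no gene calling, and no GenBank/EMBL
parsing. Coordinates are held internally as 0-based half-open intervals;
GFF3 (1-based inclusive, CDS rows only) converts at the boundary, and the
round trip preserves printed coordinates exactly. Sequences are
restricted to the 20 canonical residues plus `X`; other ambiguity codes
are rejected at parse time because the scoring matrix is defined over
20+X.

## Homology search

Searches use exact Smith–Waterman local alignment with affine gaps in
place of a heuristic seeded search: results are deterministic, and
correctness can be certified against independent oracles. Scoring is
BLOSUM62 with gap open 11 / extend 1 in the BLAST cost convention (a gap
of length k costs 11 + k); `X` scores 0 against everything (neutral
ambiguity). Alignment is computed by `Bio.Align.PairwiseAligner`, which
guarantees the optimal score; tie-breaking among co-optimal alignments is
the aligner's deterministic canonical traceback order.

E-values follow the ungapped Karlin–Altschul form `E = K·m·n·exp(−λS)`
with the published BLOSUM62 constants K = 0.041, λ = 0.267 as defaults
(config-overridable). These constants are not estimated per run, so
e-values are comparable only within a run — adequate, since they are used
solely for thresholding. Threshold comparisons are made in log10 space:
near-identical full-length homologs reach scores whose e-values underflow
double precision to 0.0.

Per-family thresholds default to 1e-10 for structural subunits and 1e-6
for accessory/maturation proteins. These are deliberately permissive:
related families (the [NiFe] large subunits of the hox, hup and
membrane-bound enzymes, for instance) cross-hit each other's searches at
any threshold that still accepts true orthologs. The discriminating step
is the reciprocal best hit: a hit is confirmed only when its best-scoring
partner in the query source proteome — which contains the queries *and*
their paralogous neighbours — is the original query. The check is
one-directional (target → source proteome), which is what permits
multiple confirmed copies of one family in a genome (the multicopy
endopeptidase state) while still rejecting paralogs; the symmetric
mutual-best relation over two whole proteomes is available separately as
`rbh_pairs`.

## Motif verification

Each checked family has a reference anchor and a list of 1-based site
positions with allowed residue sets (the anchor must itself satisfy every
site). Targets are globally aligned to the anchor — true global, end gaps
penalized, same scoring scheme as the search — and each site is read
through the alignment position map. A site aligned to a gap, or showing
`X`, is never conserved. The verdict is `conserved` only if every site
is; otherwise `degenerate`, which downgrades the family's presence state
to `present_degenerate` when *no* copy in the genome is intact (a single
intact copy keeps the family functional). Pairwise anchoring replaces
multiple alignment deliberately: at the identity levels involved the
position transfer is unambiguous, and the procedure is deterministic and
oracle-checkable.

The shipped site sets are an editable default exported with the panel
(`panel/motifs.yaml`): Ni-ligand and [FeS]-cluster cysteines for the
hox/hup structural subunits, the membrane-bound proximal-cluster
O₂-tolerance signature (six cysteines + proline, Hyd-1 numbering
17/19/20/115/120/149 and 242), and the group 3b small-subunit 4-Cys
ligand set. The published survey describes the group-diagnostic L1/L2
consensus sets only qualitatively, so real-proteome use requires curating
these sets; nothing else in the pipeline changes.

## Capability calling

`hox_functional` = complete {hoxE,F,U,Y,H,W} ∧ complete {hypA–F} ∧ all
hox structural motifs conserved; `hup_functional` analogously with
{hupS,L,W}. Degenerate presence breaks completeness. `nitrogen_fixing` =
nifH ∧ nifD ∧ nifK ∧ nifB ∧ nifE ∧ nifN, with nifU/S/V ignored as
dispensable. Every false verdict carries reasons naming each failed
criterion, and the function is pure (identical inputs give identical
output, including reason order).

O₂-tolerance candidates are graded per group. Group 1 (membrane-bound):
structural pair + conserved proximal signature + at minimum hoxZ ∧ hoxM
gives *questionable*; the full accessory set hoxZMLOQRTV elevates to
*candidate*; anything less is *rejected* with reasons. This encodes the
graded conclusion a survey reaches for an accessory-poor genome. Group
3b: all four subunits (α, β, γ, δ) + complete hyp + conserved
small-subunit cysteines. Group 3d is the hox enzyme itself, so its
candidacy is the hox verdict; no separate query family exists for it.

"Incomplete" is defined as ≥1 but not all members of a system present —
distinct from "absent" (zero members) — because survey-style accounting
needs both counts. Whether missing maturation genes alone should count a
genome as incomplete is a genuinely open reading; here hyp completeness
affects the functional verdict but the per-system content states (hox,
hup, nif) are computed from each system's own genes.

## Cluster arrangements

Two member genes co-cluster when they lie on the same replicon with at
most `max_intervening` (default 3) non-member genes between them,
transitively closed. A gene-count rule was chosen over a base-pair
distance because it is independent of annotation density; the parameter
is a CLI flag. "Between" is evaluated on the interval order in a form
symmetric under coordinate mirroring, and labels are invariant under
mirroring and input order (property-tested).

hox groups G1, G2, G3 and G7 follow their published definitions
(EFUYH same-orientation cluster + distal W; all six in one
same-orientation cluster; EFUY cluster with H and W elsewhere; FUYHW
cluster with distal E). Extra hoxW-only clusters (multicopy
endopeptidase) do not change the group. G4–G6 share only the hoxE+hoxF
co-clustering and are distinguished by a partition-signature lookup table
shipped as data with explicitly placeholder assignments
(UYHW+EF → G4, UYH+EF+W → G5, EF+UY+H+W → G6): the published material
defines these groups only pictorially, so the mapping is config, not
code, and unknown signatures fall back to `unclassified`. The hup groups
likewise use a config table over the two published axes — hupW clustered
with hupSL or distal, and xisC interruption of hupS, hupL or neither —
with five of the six axis combinations mapped and the sixth
unclassified. xisC interruption is detected either as an xisC gene
strictly inside a subunit's span or as a subunit split into two features
flanking an xisC feature. hyp labels are the canonical partition
signature of cluster sizes, with "6" and "5+1" hard-mapped to classes 1
and 2.

## Co-occurrence summaries

Each genome gets one (hox, hup, nif) three-state combination; counts and
percentages are tabulated overall and per habitat / subsection stratum.
Percentages are kept at full precision in the TSVs and rounded half-up to
integers for display, matching the integer granularity survey figures
print; per-stratum counts always sum to the stratum size. Tree annotation
emits one row per newick leaf in tree order with three-state marks,
degenerate flags, functional verdicts and arrangement labels; leaves
without a matching genome are marked missing with a warning rather than
failing the run. No statistical association tests are performed — the
output is proportions, as in the survey being emulated.

## Synthetic data

The query panel itself is synthetic (the package ships no third-party
sequence data): one query per family at a realistic length (90–750 aa),
built deterministically from a fixed internal seed so panels are
byte-identical everywhere. Three similarity groups — [NiFe] large
subunits (hoxH, hupL, mbh1_large, sh3b_alpha), small subunits (hoxY,
hupS, mbh1_small, sh3b_delta) and peptidases (hoxW, hupW, hoxM) — are
derived from shared ancestors at ~26% per-member divergence, giving
~50–55% pairwise identity: enough to cross loose thresholds (exercising
reciprocal rejection) while losing cleanly to a near-identical ortholog.
Motif anchor residues are forced at their defined positions. The query
source proteome adds paralog siblings (45% divergence) for eight families
plus unrelated filler proteins.

Planted genes copy panel queries with 2% random substitutions that avoid
motif sites, so presence detection and motif verdicts stay independent
test axes; explicit site mutations and C-terminal truncations create
degenerate states on demand. Paralog decoys are derived from the siblings
(default 85–90% identity to the sibling, hence ~50% to the query):
they pass family thresholds and are rejected by the reciprocal check.
Background genes draw from a uniform residue model at 150–600 aa.
Layout realizes requested arrangements exactly: blocks of adjacent genes
(80 nt intergenic) separated by runs of 4 background genes (one more than
the default co-clustering tolerance), block order shuffled per seed,
xisC elements nested inside a widened target-subunit span. An
unrealizable request (too few background genes to isolate the blocks,
foreign genes in a system plan) fails before any output is written.
Everything is deterministic per seed; cohort genomes get child seeds from
the master seed, and category mixes are apportioned by largest remainder.

What the generator does **not** emulate: real sequence composition and
domain structure, annotation errors, split/fragmented assemblies,
horizontal-transfer mosaicism, and genuinely ambiguous paralogy depths.
Passing round-trip tests therefore demonstrates the pipeline's logic —
detection, discrimination against the planted decoy structure,
classification, accounting — not calibrated performance on real
proteomes, where thresholds and motif sets must be curated (the published
survey calibrated per-protein thresholds against its supplementary query
list, which is not reproduced here).

## Benchmark problem sizes and numerics

The benchmark cohort is 30 genomes (~70 proteins each) spanning all seven
hox and five hup arrangements, five hyp classes, substitution- and
truncation-induced degenerate states, incomplete sets, multicopy hoxW,
paralog decoys, the three O₂-tolerance archetypes and hydrogenase-free
genomes; a full pipeline pass takes ~2 minutes on one CPU. Alignment
correctness is certified against two independent oracles: exhaustive
recursive enumeration of all gapped alignments (all pairs over a 4-letter
alphabet at short lengths, seeded samples to length 6) and a plain-Python
Gotoh three-matrix DP; agreement is exact, not approximate. Scores are
integers in matrix units throughout, so float equality is safe.
Deterministic tie-breaks: best query per target and best reciprocal
partner by higher score then lexicographically smallest id; hits ordered
by ascending e-value, then score, then protein id.

## Known limitations

* E-value statistics use fixed ungapped constants; absolute e-values are
  nominal (thresholding is the only consumer).
* The G4–G6 and hup G1–G5 lookup assignments are placeholders pending
  curation against the published drawings; the partition/axis machinery
  is the deliverable.
* One query per family; profile or HMM search is out of scope, as are
  translated searches and composition-based statistics.
* Species trees are consumed, never built.
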