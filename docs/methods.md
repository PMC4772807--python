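# Methods

This note records the models, rules and design choices behind `neuropep`, the
parameters that matter, and what the synthetic-fixture tests do and do not
demonstrate about real data.

## ORF extraction (`neuropep.seqio`)

Contigs are translated in all six frames with the standard genetic code.
Every maximal stop-to-stop segment is considered; within a segment the
reported ORF runs from the first methionine (leftmost-longest convention).
With `allow_partial` enabled, a segment abutting the 5' contig edge is
reported from the segment start (`partial5` set when it does not begin with
M) and a segment running off the 3' edge without a stop is reported as
`partial3`; without it, only complete ORFs are returned. The default minimum
ORF length is 60 residues — comfortably below the shortest precursors
reported for starfish (83 residues) while suppressing spurious short ORFs.
Nucleotide coordinates are 0-based half-open on the forward strand
internally and become 1-based inclusive only in GFF3 output. Ambiguity codes
other than N are rejected at parse time; N translates to X and X never
matches any motif, so ambiguous sequence degrades predictably rather than
silently matching.

## Signal peptides (`neuropep.signalpep`)

The built-in heuristic encodes the tripartite signal-peptide architecture:

* candidate cleavage positions p ∈ [15, 45] (capped at length − 5 for
  proteins of 25–50 residues; proteins under 25 residues return "absent"
  with a warning rather than raising);
* rule 1 — net charge of the n-region (residues before the hydrophobic core)
  ≥ 0 (K/R = +1, D/E = −1);
* rule 2 — a hydrophobic core of ≥ 7 consecutive residues with mean
  Kyte–Doolittle hydropathy ≥ 1.5, ending 3–6 residues before the cleavage
  point (the c-region geometry; anchoring the core near the cleavage point
  stops distal positions from re-using the same core);
* rule 3 — small residues ({A,G,S,C,T,V}) at −3 and −1.

Score = best core mean hydropathy + 1 per satisfied small-residue position.
Ties between passing positions are resolved toward the **larger** position,
i.e. the longer signal peptide: when two adjacent positions share the same
hydrophobic core and both present acceptable −3/−1 residues, the distal site
is the one a signal peptidase reaches after the full c-region. All knobs are
configurable (`SignalParams`). The heuristic is a desk-scale device, not a
reimplementation of a neural-network predictor; that is why imported
predictions (TSV: `id`, `present`, `cleave_after`) take precedence over the
heuristic whenever provided, and curated analyses are expected to use them.

## Cleavage grammar (`neuropep.cleavage`)

Maximal K/R runs downstream of the signal peptide are decomposed
deterministically: runs of three are a single tribasic site (never nested
dibasics); runs of four or more give the leftmost three as tribasic with the
remainder re-examined; runs of two are dibasic sites (`KR` canonical, the
other pairs extended). The monobasic rule (lone R with another basic residue
2, 4 or 6 positions upstream) is off in de novo mode and on in curation mode,
because lone basics inside genuine peptides are common and the rule is
precision-hostile in blind scans. Segmentation excludes site residues from
every segment and satisfies the exact tiling invariant, which the property
suite fuzzes over 10,000 random proteins.

## Maturation (`neuropep.maturation`)

Amidation consumes exactly one terminal glycine, the standard
peptidylglycine α-amidating monooxygenase mechanism; pyroglutamate formation
applies only to N-terminal glutamine and flags the peptide without editing
the sequence. Disulfide capacity is ⌊n_Cys/2⌋; connectivity is out of scope.
Sulfation candidates (tyrosines) are flagged only for peptides classified
CCK-type, where the modification is characteristic, unless globally enabled.
De novo mode discards products shorter than 3 residues (the shortest
reported mature products are tetrapeptides; the floor sits one below);
curation mode keeps everything. One known annotation quirk is supported
explicitly: some curated records report an amidated peptide whose terminal
glycine is retained in the printed sequence; `mature(..., amide_without_g=True)`
marks amidation without consuming a residue for such cases rather than
silently resolving the inconsistency.

Structural detectors: a neurophysin domain is the region downstream of the
last cleavage site containing exactly 14 cysteines (the conserved count);
an acidic spacer has ≥ 6 D/E residues making up ≥ 20% of the segment (the
fraction guard keeps long random segments from qualifying by count alone);
the insulin/relaxin layout requires a B-chain segment (exactly 2 Cys,
C-x(11)-C), one connecting segment, and an A-chain segment (exactly 4 Cys,
CC-x(3)-C-x(8)-C), reported in precursor order.

## Family motifs (`neuropep.families`)

The registry holds one entry per family signature, each anchored at exactly
one terminus, with optional amidation/pyroglutamate requirements, cysteine
constraints and length ranges. Notable choices:

* the tachykinin motif's middle position is widened from the observed L/I to
  the full hydrophobic class {A,V,L,I,M,F,W,Y};
* the CCK motif generalises the two observed octapeptides to
  `[DQ]YGxGLF[WF]-NH2`;
* the TRH entry is structural (amidated pyroglutamyl tetrapeptide) rather
  than sequence-based;
* the insulin B-chain motif is anchored to the chain's N-terminus with a
  four-residue offset matching the fixture layout, and the relaxin
  receptor-binding motif `RxxxRxxI/V` is approximated as C-terminal —
  both are approximations recorded here because no positional evidence
  pins them down;
* families with no known sequence motif (PDF-, CRH-, orexin-, MCH-,
  somatostatin-type, …) are left to homology screening; MCH/SS-type
  candidates get structural hints only (cysteine pair, C-terminal precursor
  position).

Classification is multi-label with no arbitration: family reassignment is an
analyst's decision, not the classifier's. User registries (YAML) may add or
override entries by family name; duplicates within one file are an error.

## Homology screening (`neuropep.homology`)

Full Smith–Waterman dynamic programming (Gotoh affine-gap recurrences) with
BLOSUM62 and gap open 11 / extend 1 (a gap of length k costs 11 + k).
Desk-scale datasets do not need heuristic seeding, and e-value statistics
are deliberately out of scope: screening uses a permissive raw-score
threshold (default 30), which reproduces the recall-oriented intent of a
very permissive e-value cut-off without Karlin–Altschul calibration.
Tie-breaks are deterministic (smallest target start, then query start, then
shortest alignment; traceback prefers substitutions). The score is validated
three ways in the tests: exhaustive path enumeration on tiny pairs, an
independent top-down recursion on 1,000 pairs up to length 8, and
`Bio.Align.PairwiseAligner` on longer random pairs.

## Composite ranking (`neuropep.ranking`)

The ranking score replaces an unpublished precursor-likeness HMM with a
documented weighted sum (weights in the README; all configurable, all
non-negative except the length penalty term). It is monotone in every piece
of evidence, so adding a cleavage site or an amide glycine can never demote
a candidate. The site count is capped at 10 to stop basic-rich junk ORFs
from accumulating unbounded credit, and proteins beyond 500 residues pay
0.01/residue. Ties are broken by amide-glycine count then protein id. The
default cut-off of 500 candidates matches the screening depth used in the
original analysis workflow. In de novo mode peptides are only excised when a
signal peptide is present — a protein that cannot enter the secretory
pathway cannot shed neuropeptides — which also keeps decoys at score ≤ 0.

## Synthetic fixtures (`neuropep.synth`)

The generator is the study-conditions module, not a tunable benchmark. Its
defaults plant four architectures that give every detector a positive
control: a multi-copy precursor (1 + 11 copies of a pyroglutamyl amidated
tetrapeptide, mirroring the reported TRH-type layout), a neurophysin-bearing
precursor (two amidated NGFFYG copies + a 14-cysteine domain), an
insulin/relaxin B–C–A layout, and an acidic-spacer precursor. Planted
peptides contain no K/R (enforced; violating specs raise), signal peptides
pass the heuristic by construction, codons are drawn uniformly from
synonymous sets with a seeded RNG, and an in-frame stop is placed directly
upstream of the start codon so the planted ORF is maximal. Eight decoys
(length-matched random ORFs, rejection-sampled to fail the signal heuristic
and to contain no planted peptide) accompany them. Each emitted contig is
certified: the de novo pipeline must recover exactly the planted peptides
(nothing on decoys) or the codon/UTR sample is redrawn — the same
rejection-sampling stance used for decoys. Generation is byte-identical for
a fixed seed.

What passing end-to-end tests shows: the pipeline stages compose without
coordinate drift, and the ranking separates architecture-bearing ORFs from
featureless ones. What it does not show: performance on real transcriptomes,
where signal peptides diverge from the heuristic's idealised architecture,
cleavage usage is context-dependent, assemblies contain frameshifts and
chimeras, and peptides can carry K/R internally. The evaluator's exact-match
criterion (identical precursor coordinates and sequence) is deliberately
strict; real-data benchmarking would need a tolerance-based matcher and
curated ground truth.

## Problem sizes

The property suite and the acceptance script use 1,000 random pairs
(lengths ≤ 8) for alignment-oracle agreement, 10,000 fuzzed proteins for
the tiling invariant, 10,000 fuzzed peptides for classifier-oracle
agreement, and 20 generator seeds (4 precursors + 8 decoys each) for
end-to-end discovery — sizes at which every oracle is exact and the whole
suite runs in seconds.

## Known limitations

* The signal heuristic is architecture-based, not statistical; its
  boundaries on real proteins will differ from dedicated predictors, which
  is why imported tables take precedence.
* Monobasic-site criteria differ between curated annotations; per-precursor
  reproduction may require per-case cleavage rules.
* No e-value statistics, no profile/HMM search, no disulfide connectivity,
  no mass-spectrometric validation logic.
* The insulin B-chain and relaxin receptor-binding registry entries encode
  positional approximations (see above).
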