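# Methods

## The model

MAPK docking motifs (D-motifs) are short linear motifs, 7–18 residues,
that bind the docking groove shared by ERK, p38 and JNK kinases.  The
groove has two parts: the acidic common-docking (CD) region, contacted by
one or two basic residues (the θ positions, Arg/Lys), and a hydrophobic
groove with a lower pocket and pockets A and B, filled by three
hydrophobic residues (φL, φA, φB).  All classes instantiate one generic
scheme,

    θ(1,2) – x(0–5) – φL – x(spacing) – φA – x – φB,

and differ in three structural parameters: the φL→φA spacing (1 or 2
intervening residues), the θ→φL linker length (short, 0–2, for
JNK-binding motifs; longer, 3–5, for ERK/p38-binding motifs), and the
conformation of the N-terminal region (linear vs helical).  The seven
shipped classes are:

| class        | spacing | linker | extra context                          |
|--------------|---------|--------|----------------------------------------|
| JIP1         | 2       | 0–2    | —                                      |
| NFAT4        | 1       | 0–2    | —                                      |
| MEF2A_MEF2A  | 1       | 3–5    | —                                      |
| MEF2A_MKK6   | 1       | 3–5    | S/T immediately before the θ block     |
| DCC          | 2       | 3–5    | —                                      |
| HePTP_Ste7   | 1       | 3–5    | hydrophobic φU two residues upstream   |
| HePTP_HePTP  | 1       | 3–5    | hydrophobic φU four residues upstream  |

Default alphabets: θ {R,K}; φA/φB {L,I,V,M,F}; φL {L,I,V,M,F,P} (the
lower pocket tolerates proline, as in the JIP1 and DCC peptides).  The
"tight" strictness narrows the φ alphabets (φL {L,I,P}, φA {L,I,V},
φB {L,I,V,F}).  The MKK6 S/T preference and the φU offsets of the
helical-extension subtypes are heuristics: the class schema is a YAML
file, and any of these choices can be replaced without touching code.
Nonstandard residues (X/U/B/Z) are kept in sequences but never satisfy a
θ or φ class.

Scanning reports every (class, core span) combination, overlapping hits
included; the same span matching several classes is several hits.  The φ
core of a hit is determined by the class and the φB position, so where
one core admits several θ-count/linker parses the scanner reports a
single hit with the minimal start and then the maximal θ count, keeping
the alternatives in a detail field.  One consequence: a loose-only parse
can extend the reported span of a hit relative to its tight counterpart,
so strictness monotonicity holds at the level of match windows (same
class and φ core, loose start ≤ tight start), not of literal span sets.

## Filter cascade

Four composable predicates applied in order, each recording pass/fail and
a reason per hit; counts conserve at every step.

1. **Disorder** – keep a hit iff its span overlaps (≥1 shared residue) a
   binding-region run at the primary cutoff (default 0.4), or a run at
   the secondary cutoff (0.3) while one of the 20-residue flanks has mean
   disorder strictly above 0.45 (flanks truncate at the termini).  Run
   membership is score ≥ cutoff.  The companion calibration routine
   lowers the cutoffs from the predictor's default 0.5 on a 0.05 grid
   (secondary = primary − 0.1) until ≥90% of a set of known positives
   pass, returning the highest such pair.
2. **Accessibility** – discard hits in proteins carrying a signal peptide
   (either a SignalP-style call, or a Phobius-only call backed by a
   SignalP score strictly above 0.3) and no transmembrane segment; with
   transmembrane segments the hit survives only if its span lies entirely
   in intracellular topology (unknown topology fails, conservatively).
3. **Localization** – discard hits whose protein scores at or above the
   per-compartment thresholds (extracellular 25, membrane 25, ER 15,
   Golgi 9; inclusive), unless rescued by a transmembrane segment plus an
   entirely intracellular span.  Proteins without localization scores
   pass (absent predictions are the common case).
4. **Structure** – discard hits overlapping a folded Pfam-style domain
   interval, a curated family/repeat/motif interval (opt-in list), or a
   predicted coiled coil.

Missing predictor tracks are tri-state: a config switch chooses between
erroring (strict) and failing the hit with reason "no-track"
(permissive, the default for step 1, which is the central filter;
localization absence passes).

## PSSM

Training data are groups of fixed-length, gap-free peptides; one group is
one independently evolved motif plus its vertebrate orthologs.  Peptide
weights are patristic distances from the reference species plus ε = 0.01
(so the reference itself contributes), normalized within each group to
sum 1 — this is how "groups pooled with equal weights" and the single
per-sequence frequency formula are reconciled.  Frequencies per position:

    X_i = ( Σ_s w_s · I(s_i = X) + p · X_b ) / ( Σ_s w_s + p )

with pseudo-count p = √(raw peptide count) by default (numeric override
allowed, including 0) and X_b a shipped Swiss-Prot composition table
(config-replaceable).  Scores are sums of base-2 log-odds
log2(X_i / X_b); base 2 keeps scores commensurate with logo bits, and any
fixed base only rescales rankings.  With p = 0, absent residues produce a
−∞ log-odds sentinel and the model is flagged.  Residues outside the
20-letter alphabet score the column's floor (minimum) log-odds.

Logos use the pseudo-count-free frequencies: column information
R_i = log2 20 − (H_i + e_n), with Shannon entropy H_i (0·log 0 := 0) and
small-sample correction e_n = 19/(2·ln 2·n) for n raw peptides; negative
R_i clamps to 0 and letter heights are X_i · R_i.

## Evaluation

Negatives are consensus-conforming windows lying entirely inside folded
domain intervals — sequence-compatible but structurally incapable decoys.
Cross-validation partitions *groups* (never individual orthologs) into k
folds uniformly at random; per repetition each fold is held out once, the
model is trained on the rest, the held-out reference instances are scored
against the full negative set, and the pooled fold scores give one
repetition ROC/AUC (pooling, rather than averaging fold AUCs, is a
package choice recorded here because either reading is defensible).
Negatives are reused across folds and never trained on.  Default 100
repetitions with a seeded generator; AUC is the Mann–Whitney probability
(ties 0.5).

## Conservation

Species distance is the patristic path sum on the species tree.  Motif
presence in a homolog: the row's ungapped sequence within the reference
motif's alignment-column span ±window (10 columns by default, matching
precomputed-ortholog usage; 50 for coarser homolog sets) contains at
least one class-consensus match.  The maximum traceable distance (MTD) is
anchored at the reference species — the farthest motif-bearing homolog —
with an optional max-pairwise mode.  Windows are measured in alignment
columns because columns behave sanely under gaps.

Relative motif conservation compares mean identity-to-reference (gaps
count as mismatch) over motif columns against up to 10 flank columns per
side; the ratio gets an infinity sentinel when flanks are fully diverged.

A phosphosite is an S/T-P dipeptide in the reference; it is "present" in
a homolog when the aligned residue at the site column is S or T and the
next ungapped residue is P (the consensus must be intact, not merely the
S/T).  Its normalized traceable distance is the weight fraction of rows
where the site is present, using the same distance-based weights as PSSM
training by default (uniform weights are one parameter away); the score
is invariant to uniform weight rescaling and equals 1 iff universal.
Site selection excludes candidates within 10 residues of the motif span
and returns the maximum-scoring survivor, ties to the smallest position.

## Synthetic data

The generators emulate the production inputs without any downloads.

* Trees: random coalescent joins with branch lengths uniform in the depth
  range (default 0.1–1.0, roughly Ensembl-scale vertebrate distances).
* Proteomes: background residues i.i.d. from the Swiss-Prot composition
  (so background log-odds are ≈0-centered), one planted canonical
  instance (single θ, minimal linker) per planted protein inside an
  8-residue inert buffer free of basic/hydrophobic residues, which makes
  the planted parse provably unique within its class.  A scan-and-repair
  pass mutates the θ/φ-capable residues of any accidental background
  match to inert ones, guaranteeing zero non-planted consensus matches.
  Plant contexts set tracks so each hit realizes one intended cascade
  outcome (pass; anchor-low pass at 0.40–0.44 with ordered flanks;
  ordered/domain fail; secreted fail; ER fail; coil fail; in-domain
  decoy), recorded in a truth table.
* Ortholog families: all groups share one planted consensus; orthologs
  mutate per position at the noise rate (θ/φ within their allowed sets,
  intervening positions within an inert flank alphabet), species outside
  a group's clade have the motif gapped out, and 10-column flanks diverge
  at rate 0.5.  Reference rows carry the exact consensus.

Defaults used throughout testing are the study conditions: 15 ortholog
groups on an 8-species tree at 15% noise for parameter recovery, a
1,000-protein proteome with 280 planted contexts for cascade accounting,
and 5-fold × 100-repetition cross-validation.

What the generator does **not** model: indels beyond whole-motif
deletion, rate heterogeneity, compositional biases of disordered regions,
correlated predictor errors, or motifs in structured context that real
predictors would score ambiguously.  Passing tests therefore demonstrate
the correctness of the decision logic and the statistics under the stated
conditions, not predictor-level performance on real proteomes.

## Numerical choices and degenerate inputs

* All coordinates 1-based inclusive everywhere; no half-open intervals.
* Threshold directions follow the decision rules literally: run
  membership ≥, flank disorder >, SignalP >, localization ≥.
* Column sums of PSSM frequencies are asserted to 1e-9; AUC oracle
  agreement to 1e-12.
* Empty sequence scan → empty list; empty hit list through the cascade →
  all-zero report; single-row alignments are rejected where a comparison
  row is required; a reference without the motif is an error for MTD.
* Ties: scored windows order by (score desc, protein id, position); site
  selection by smallest position.
* Seeds: every stochastic routine takes an explicit seed and uses an
  owned numpy Generator; identical inputs and seeds give byte-identical
  outputs.

## Known limitations

* The per-class alphabets and the subtype context offsets are heuristic
  stand-ins for structure-derived definitions; they are config data, not
  code.
* The fixed-length PSSM scores only windows matching the model length;
  variable-geometry hits of the same class are skipped (a gapped or
  multi-length profile is out of scope).
* Realignment of extracted motif windows is out of scope; alignments are
  consumed as given.
* Reverse (revD) motifs and FxFP motifs are not modeled.
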