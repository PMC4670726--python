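# dmotif

Discovery and evolutionary analysis of MAPK docking motifs (D-motifs) in
protein sequences.

Mitogen-activated protein kinases (ERK, p38, JNK) recognize most of their
partners not at the catalytic site but through a docking groove that binds
short linear motifs — D-motifs — located in intrinsically disordered
regions of substrates, activating kinases, phosphatases and scaffolds.
D-motifs follow a loose generic consensus

    θ(1,2) – x(0–5) – φL – x(1,2) – φA – x – φB

(θ: Arg/Lys contacting the acidic common-docking region; φL/φA/φB:
hydrophobics filling the lower pocket and pockets A/B), which is far too
permissive on its own: structural classes defined by the φ spacing, the
θ→φ linker length and the N-terminal conformation are what carry kinase
specificity.  `dmotif` is a toolkit for people who want to find candidate
MAPK-interacting proteins in a proteome and ask how those interactions
evolved:

* **scan** — class-based consensus scanning with seven parameterized,
  YAML-overridable D-motif classes (JIP1, NFAT4, two MEF2A subtypes, DCC,
  two HePTP subtypes);
* **filter** — a four-step cascade over precomputed predictor tracks:
  disordered binding regions (with adaptive cutoff calibration),
  intracellular accessibility, localization, and structural context
  (domains, coiled coils), with per-step accounting;
* **pssm** — evolutionarily weighted position-specific scoring matrices:
  ortholog peptides weighted by patristic distance from the reference
  species, pooled over independently evolved motif groups with equal
  group weights, base-2 log-odds scoring, and sequence-logo matrices with
  small-sample correction;
* **evaluate** — ROC/AUC against in-domain decoy negatives under
  group-aware fivefold cross-validation;
* **conserve** — motif presence across ortholog alignments, maximum
  traceable evolutionary distance, motif-vs-flank conservation, and
  phosphosite (S/T-P) conservation scores;
* **simulate** — seeded generators for proteomes with planted motifs and
  coherent tracks, species trees, and clade-confined ortholog families,
  each with a machine-readable truth table.

See `docs/methods.md` for the model, the formulas and the design choices.

## Worked example

Scan the JIP1-derived JNK docking peptide and score it with a small PSSM:

```python
from dmotif import (ProteinRecord, default_class_definitions, scan_sequence,
                    TrainingPeptide, build_pssm, score_peptide, swissprot_background)

rec = ProteinRecord("pepJIP1", "DTYRPKRPTTLNLFP")
for hit in scan_sequence(rec, default_class_definitions("loose")):
    print(hit.class_name, hit.start, hit.end, hit.matched_sequence,
          hit.theta_positions, hit.phi_positions)
```

prints

```
DCC 4 13 RPKRPTTLNL (4,) (8, 11, 13)
JIP1 6 13 KRPTTLNL (6, 7) (8, 11, 13)
```

i.e. the peptide carries a JIP1-class hit spanning residues 6–13: the
basic block K6-R7 docks the CD region, P8 occupies the lower pocket, and
L11/L13 fill pockets A and B (the same window also satisfies the looser
DCC-class consensus — overlapping class membership is expected and
reported).  A one-peptide PSSM with no pseudo-count and a uniform
background scores its own training peptide at L·log2 20:

```python
model = build_pssm({"G1": [TrainingPeptide("KRPTTLNL", "HUMAN", "G1")]},
                   pseudo=0)
print(round(score_peptide(model, "KRPTTLNL"), 3))   # 34.575 = 8 * log2(20)
```

The same operations are available from the shell:

```bash
dmotif simulate proteome --n-proteins 100 --plant JIP1:5:disordered_pass \
       --seed 1 --out sim/
dmotif scan --fasta sim/proteome.fasta --out sim/hits.tsv
dmotif filter --hits sim/hits.tsv --fasta sim/proteome.fasta \
       --tracks sim/scores.tsv --intervals sim/intervals.gff3 \
       --localization sim/localization.tsv \
       --out sim/survivors.tsv --report sim/report.tsv
```

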