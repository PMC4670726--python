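"""ROC/AUC evaluation with simulated negatives and group-aware cross-validation.

Negatives are consensus-conforming windows that lie inside folded Pfam-style
domains: sequences that match the motif pattern but cannot function as
docking sites.  Cross-validation splits by ortholog *group* so that no
independently evolved motif contributes peptides to both training and
testing; the held-out reference (human) instances are scored as positives
against the full negative set, fold scores are pooled into one ROC per
repetition, and repetitions differ only in the random fold assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from dmotif.io_formats import ProteinRecord, TrackSet
from dmotif.motif_patterns import MotifClassDef, MotifHit, scan_sequence
from dmotif.pssm_model import Background, TrainingPeptide, build_pssm, score_peptide


@dataclass
class EvaluationResult:
    aucs: list[float]
    mean_auc: float
    sd_auc: float
    n_pos: int
    n_neg: int
    seed: int

    def __post_init__(self) -> None:
        if not all(0.0 <= a <= 1.0 for a in self.aucs):
            raise ValueError("AUC outside [0, 1]")


def simulate_negatives(
    records: Sequence[ProteinRecord],
    tracks: Mapping[str, TrackSet],
    class_def: MotifClassDef,
) -> list[MotifHit]:
    """Consensus matches lying entirely within a Pfam domain interval.

    Deduplicated by (protein, span).  Returns an empty list (no error) when
    no domain intervals exist anywhere.
    """
    negatives: list[MotifHit] = []
    seen: set[tuple[str, int, int]] = set()
    for rec in records:
        ts = tracks.get(rec.id)
        if ts is None:
            continue
        domains = ts.intervals_of("pfam_domain")
        if not domains:
            continue
        for hit in scan_sequence(rec, [class_def]):
            key = (rec.id, hit.start, hit.end)
            if key in seen:
                continue
            if any(iv.start <= hit.start and hit.end <= iv.end for iv in domains):
                seen.add(key)
                negatives.append(hit)
    return negatives


def auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Area under the ROC curve; Mann-Whitney pair convention, ties at 0.5."""
    if len(pos_scores) == 0 or len(neg_scores) == 0:
        raise ValueError("both score lists must be non-empty")
    y = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    s = np.concatenate([np.asarray(pos_scores, float), np.asarray(neg_scores, float)])
    return float(roc_auc_score(y, s))


def crossvalidate(
    groups: Mapping[str, Sequence[TrainingPeptide]],
    positives: Mapping[str, str],
    negatives: Sequence[str],
    background: Background | None = None,
    k: int = 5,
    reps: int = 100,
    seed: int = 0,
) -> EvaluationResult:
    """Group-aware k-fold cross-validated AUC over ``reps`` repetitions.

    ``groups`` holds the weighted training peptides per ortholog group;
    ``positives`` maps group id to the held-out test peptide of that group
    (the reference-species motif instance); ``negatives`` are peptide
    sequences reused across folds and never trained on.  Per repetition,
    groups are partitioned into k folds uniformly at random, each fold is
    held out once, and the pooled fold scores give one repetition AUC.
    """
    group_ids = sorted(groups)
    if len(group_ids) < k:
        raise ValueError(f"need at least {k} groups, got {len(group_ids)}")
    if not negatives:
        raise ValueError("negatives must be non-empty")
    missing = [g for g in group_ids if g not in positives]
    if missing:
        raise ValueError(f"groups without a test positive: {missing}")
    rng = np.random.default_rng(seed)
    aucs: list[float] = []
    for _ in range(reps):
        order = rng.permutation(len(group_ids))
        folds: list[list[str]] = [[] for _ in range(k)]
        for pos, gi in enumerate(order):
            folds[pos % k].append(group_ids[gi])
        pooled_pos: list[float] = []
        pooled_neg: list[float] = []
        for fold in folds:
            held_out = set(fold)
            train = {g: groups[g] for g in group_ids if g not in held_out}
            assert not any(g in held_out for g in train)  # group integrity
            model = build_pssm(train, background=background)
            pooled_pos.extend(score_peptide(model, positives[g]) for g in fold)
            pooled_neg.extend(score_peptide(model, n) for n in negatives)
        aucs.append(auc(pooled_pos, pooled_neg))
    arr = np.asarray(aucs)
    return EvaluationResult(
        aucs=arr.tolist(),
        mean_auc=float(arr.mean()),
        sd_auc=float(arr.std(ddof=1)) if reps > 1 else 0.0,
        n_pos=len(positives),
        n_neg=len(negatives),
        seed=seed,
    )


def score_correlation(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Pearson product-moment correlation between two score vectors."""
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("score vectors must have equal length >= 3")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("scores must be finite")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in scores")
    return float(stats.pearsonr(a, b).statistic)
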