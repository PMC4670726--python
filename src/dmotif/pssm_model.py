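"""Evolutionarily weighted position-specific scoring matrices.

A PSSM is trained from groups of fixed-length, gap-free motif peptides.
One group is one independently evolved motif together with its vertebrate
orthologs; groups contribute with equal total weight, which is implemented
by normalizing the phylogenetic sequence weights within each group to 1
before pooling.  Per-position frequencies are

    X_i = (sum_s w_s * I(s_i = X) + p * X_b) / (sum_s w_s + p)

with p the pseudo-count (default sqrt of the raw number of training
peptides) and X_b the background frequency of the residue.  Scores are
sums of base-2 log-odds log2(X_i / X_b) over positions.

Sequence-logo information content per column is R_i = log2(20) - (H_i +
e_n) with Shannon entropy H_i (0 * log 0 := 0), small-sample correction
e_n = 19 / (2 ln 2 n) for n raw peptides, and negative R_i clamped to 0;
letter heights are X_i * R_i computed from the pseudo-count-free model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from dmotif.io_formats import ProteinRecord, SpeciesTree
from dmotif.motif_patterns import MotifClassDef, scan_sequence

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

# Amino-acid composition of UniProtKB/Swiss-Prot (percent, release-era
# statistics); normalized on construction.  Config-replaceable.
_SWISSPROT_COMPOSITION = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}


@dataclass(frozen=True)
class Background:
    """Residue background frequencies over the 20-letter alphabet."""

    frequencies: tuple[float, ...]  # ordered as ALPHABET

    def __post_init__(self) -> None:
        arr = np.asarray(self.frequencies)
        if arr.shape != (20,):
            raise ValueError("background needs exactly 20 frequencies")
        if np.any(arr <= 0):
            raise ValueError("background frequencies must be > 0")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @classmethod
    def from_mapping(cls, freqs: Mapping[str, float]) -> "Background":
        arr = np.array([float(freqs[aa]) for aa in ALPHABET])
        arr = arr / arr.sum()
        return cls(tuple(arr.tolist()))

    @classmethod
    def uniform(cls) -> "Background":
        return cls(tuple([1.0 / 20] * 20))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.frequencies)

    def __getitem__(self, aa: str) -> float:
        return self.frequencies[_AA_INDEX[aa]]


def swissprot_background() -> Background:
    """The shipped Swiss-Prot composition table."""
    return Background.from_mapping(_SWISSPROT_COMPOSITION)


@dataclass(frozen=True)
class TrainingPeptide:
    """One gap-free motif peptide from one species within one group."""

    sequence: str
    species: str
    group_id: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not set(self.sequence) <= set(ALPHABET):
            bad = sorted(set(self.sequence) - set(ALPHABET))
            raise ValueError(f"nonstandard residues {bad} in training peptide")
        if not math.isfinite(self.weight) or self.weight < 0:
            raise ValueError("peptide weight must be finite and >= 0")


def compute_weights(
    peptides: Sequence[TrainingPeptide],
    tree: SpeciesTree,
    reference_species: str,
    epsilon: float = 0.01,
) -> list[float]:
    """Phylogenetic weights for one group, normalized to sum 1.

    The raw weight of a peptide is the patristic distance from the
    reference species to its species, plus ``epsilon`` so the reference
    itself still contributes.  Within-group normalization implements equal
    total weight per group when groups are pooled.
    """
    if reference_species not in tree.leaf_names:
        raise KeyError(f"reference species {reference_species!r} not in tree")
    raw = []
    for pep in peptides:
        if pep.species not in tree.leaf_names:
            raise KeyError(f"species {pep.species!r} not in tree")
        raw.append(tree.distance(reference_species, pep.species) + epsilon)
    total = sum(raw)
    if total == 0:
        return [1.0 / len(raw)] * len(raw)
    return [w / total for w in raw]


@dataclass
class PSSMModel:
    """Per-position frequencies and base-2 log-odds with training metadata."""

    length: int
    frequencies: np.ndarray  # (20, L)
    log_odds: np.ndarray  # (20, L)
    background: Background
    pseudo_count: float
    n_peptides: int
    n_groups: int
    class_name: str = ""
    provenance: dict = field(default_factory=dict)

    def column(self, i: int) -> np.ndarray:
        """Frequency column for 1-based position i."""
        return self.frequencies[:, i - 1]


def _weighted_counts(groups: Mapping[str, Sequence[TrainingPeptide]], length: int) -> np.ndarray:
    counts = np.zeros((20, length))
    for peps in groups.values():
        group_total = sum(p.weight for p in peps)
        if group_total <= 0:
            raise ValueError("group weights must sum to > 0")
        for pep in peps:
            w = pep.weight / group_total
            for i, aa in enumerate(pep.sequence):
                counts[_AA_INDEX[aa], i] += w
    return counts


def build_pssm(
    groups: Mapping[str, Sequence[TrainingPeptide]],
    background: Background | None = None,
    pseudo: float | str = "sqrt",
    class_name: str = "",
) -> PSSMModel:
    """Pool group-normalized weighted counts into frequencies and log-odds.

    ``pseudo='sqrt'`` uses sqrt(total raw peptide count); a numeric value
    >= 0 overrides it.  With p = 0, residues absent from a column get a
    -inf log-odds sentinel and the model is flagged in its provenance.
    """
    if not groups:
        raise ValueError("at least one training group required")
    background = background or swissprot_background()
    lengths = {len(p.sequence) for peps in groups.values() for p in peps}
    if len(lengths) != 1:
        raise ValueError(f"training peptides differ in length: {sorted(lengths)}")
    length = lengths.pop()
    n_peptides = sum(len(p) for p in groups.values())
    if pseudo == "sqrt":
        p = math.sqrt(n_peptides)
    else:
        p = float(pseudo)
        if p < 0:
            raise ValueError("pseudo-count must be >= 0")
    counts = _weighted_counts(groups, length)  # column sums equal n_groups
    bg = background.as_array()[:, None]
    freqs = (counts + p * bg) / (counts.sum(axis=0, keepdims=True) + p)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(freqs / bg)
    species = sorted({pep.species for peps in groups.values() for pep in peps})
    prov = {
        "groups": sorted(groups),
        "species": species,
        "weight_scheme": "patristic-distance-from-reference, group-normalized",
        "has_zero_frequencies": bool(np.any(freqs == 0)),
    }
    return PSSMModel(
        length=length,
        frequencies=freqs,
        log_odds=log_odds,
        background=background,
        pseudo_count=p,
        n_peptides=n_peptides,
        n_groups=len(groups),
        class_name=class_name,
        provenance=prov,
    )


def score_peptide(model: PSSMModel, peptide: str) -> float:
    """Sum of per-position log-odds for a peptide of the model length.

    Residues outside the 20-letter alphabet contribute the column's floor
    (minimum) log-odds.
    """
    peptide = peptide.upper()
    if len(peptide) != model.length:
        raise ValueError(f"peptide length {len(peptide)} != model length {model.length}")
    total = 0.0
    for i, aa in enumerate(peptide):
        col = model.log_odds[:, i]
        idx = _AA_INDEX.get(aa)
        total += float(col[idx]) if idx is not None else float(col.min())
    return total


def scan_with_pssm(
    model: PSSMModel,
    records: Sequence[ProteinRecord],
    class_def: MotifClassDef,
) -> pd.DataFrame:
    """Score every consensus-matching window of the model's length.

    Windows come from the consensus scanner; only hits whose core span
    length equals the model length are scorable against a fixed-length
    matrix.  Rows are ranked by descending score, ties broken by protein
    id then position.
    """
    rows = []
    for rec in records:
        for hit in scan_sequence(rec, [class_def]):
            if hit.end - hit.start + 1 != model.length:
                continue
            rows.append(
                (rec.id, class_def.name, hit.start, hit.end, hit.matched_sequence,
                 score_peptide(model, hit.matched_sequence))
            )
    df = pd.DataFrame(
        rows, columns=["protein_id", "class_name", "start", "end", "matched_sequence", "score"]
    )
    return df.sort_values(
        ["score", "protein_id", "start"], ascending=[False, True, True]
    ).reset_index(drop=True)


@dataclass
class LogoMatrix:
    """Per-position information content (bits) and letter heights."""

    information: np.ndarray  # (L,)
    heights: np.ndarray  # (20, L)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.heights, index=list(ALPHABET))
        df.columns = [i + 1 for i in range(self.heights.shape[1])]
        return df


def logo_matrix(model: PSSMModel, n_peptides: int | None = None) -> LogoMatrix:
    """Sequence-logo matrix from a pseudo-count-free model.

    ``n_peptides`` defaults to the model's raw peptide count and enters the
    small-sample correction e_n = 19 / (2 ln 2 n).
    """
    n = model.n_peptides if n_peptides is None else n_peptides
    if n < 1:
        raise ValueError("n_peptides must be >= 1")
    freqs = model.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    entropy = -plogp.sum(axis=0)
    e_n = 19.0 / (2.0 * math.log(2.0) * n)
    information = np.clip(math.log2(20) - (entropy + e_n), 0.0, None)
    heights = freqs * information[None, :]
    return LogoMatrix(information=information, heights=heights)


# ---------------------------------------------------------------------------
# serialization


def save_model(model: PSSMModel, out_dir: str | Path) -> None:
    """Write frequencies.tsv, log_odds.tsv and a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = [str(i + 1) for i in range(model.length)]
    pd.DataFrame(model.frequencies, index=list(ALPHABET), columns=cols).to_csv(
        out / "frequencies.tsv", sep="\t"
    )
    pd.DataFrame(model.log_odds, index=list(ALPHABET), columns=cols).to_csv(
        out / "log_odds.tsv", sep="\t"
    )
    meta = {
        "length": model.length,
        "pseudo_count": model.pseudo_count,
        "n_peptides": model.n_peptides,
        "n_groups": model.n_groups,
        "class_name": model.class_name,
        "background": dict(zip(ALPHABET, model.background.frequencies)),
        "provenance": model.provenance,
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_model(model_dir: str | Path) -> PSSMModel:
    d = Path(model_dir)
    meta = json.loads((d / "model.json").read_text())
    freqs = pd.read_csv(d / "frequencies.tsv", sep="\t", index_col=0).to_numpy()
    log_odds = pd.read_csv(d / "log_odds.tsv", sep="\t", index_col=0).to_numpy()
    return PSSMModel(
        length=int(meta["length"]),
        frequencies=freqs,
        log_odds=log_odds,
        background=Background.from_mapping(meta["background"]),
        pseudo_count=float(meta["pseudo_count"]),
        n_peptides=int(meta["n_peptides"]),
        n_groups=int(meta["n_groups"]),
        class_name=meta.get("class_name", ""),
        provenance=meta.get("provenance", {}),
    )


def peptides_with_weights(
    groups: Mapping[str, Sequence[TrainingPeptide]],
    tree: SpeciesTree,
    reference_species: str,
    epsilon: float = 0.01,
    weight_fn: Callable[[SpeciesTree, str, str], float] | None = None,
) -> dict[str, list[TrainingPeptide]]:
    """Attach phylogenetic weights to every group's peptides.

    ``weight_fn(tree, reference, species)`` overrides the default
    distance-plus-epsilon weight; weights are normalized within groups.
    """
    out: dict[str, list[TrainingPeptide]] = {}
    for gid, peps in groups.items():
        if weight_fn is None:
            weights = compute_weights(peps, tree, reference_species, epsilon)
        else:
            raw = [weight_fn(tree, reference_species, p.species) for p in peps]
            total = sum(raw)
            weights = [w / total for w in raw]
        out[gid] = [
            TrainingPeptide(p.sequence, p.species, p.group_id, w) for p, w in zip(peps, weights)
        ]
    return out
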