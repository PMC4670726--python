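"""Seeded generators for end-to-end fixtures with machine-readable truth.

The generators emulate the inputs the pipeline consumes in production:
proteomes with docking motifs planted in coherent predictor-track context,
consensus decoys inside folded domains, species trees, and ortholog
families in which a planted motif is confined to a chosen clade.  Every
planted feature is recorded in a truth table so each downstream module can
be tested against intended outcomes without any external downloads.

Planted motif instances use the class's canonical fixed-length geometry
(one theta residue, minimal linker) and are embedded in an inert buffer
free of basic and hydrophobic residues, which makes the planted parse
unique within its class.  Background positions are sampled from the
shipped Swiss-Prot composition; a scan-and-repair pass then mutates any
accidental consensus match outside planted spans (basic/hydrophobic
residues are replaced with inert ones), so background regions are
guaranteed free of class-consensus matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from dmotif.io_formats import Interval, OrthologAlignment, ProteinRecord, SpeciesTree, TrackSet, read_tree_string
from dmotif.motif_patterns import (
    MotifClassDef,
    default_class_definitions,
    scan_sequence,
)
from dmotif.pssm_model import _SWISSPROT_COMPOSITION, ALPHABET, TrainingPeptide

#: residues that can never act as theta (R/K) or any phi position
INERT_ALPHABET = "ACDEGHNQSTWY"
#: inert residues used in alignment flanks (no C/W to keep them plain)
FLANK_ALPHABET = "ADEGHNQSTY"

PLANT_CONTEXTS = (
    "disordered_pass",
    "disordered_pass_low",
    "ordered_fail",
    "secreted_fail",
    "er_fail",
    "coil_fail",
    "decoy_in_domain",
)

#: intended cascade outcome per context: (step1, step2, step3, step4, survive)
CONTEXT_EXPECTATIONS = {
    "disordered_pass": ("pass", "pass", "pass", "pass", True),
    "disordered_pass_low": ("pass", "pass", "pass", "pass", True),
    "ordered_fail": ("fail", "NA", "NA", "NA", False),
    "secreted_fail": ("pass", "fail", "NA", "NA", False),
    "er_fail": ("pass", "pass", "fail", "NA", False),
    "coil_fail": ("pass", "pass", "pass", "fail", False),
    "decoy_in_domain": ("fail", "NA", "NA", "NA", False),
}

_BG_RESIDUES = np.array(list(_SWISSPROT_COMPOSITION))
_BG_PROBS = np.array(list(_SWISSPROT_COMPOSITION.values()))
_BG_PROBS = _BG_PROBS / _BG_PROBS.sum()


# ---------------------------------------------------------------------------
# species trees


def simulate_tree(
    n_leaves: int,
    seed: int = 0,
    depth_range: tuple[float, float] = (0.1, 1.0),
) -> SpeciesTree:
    """Random coalescent-style species tree with uniform branch lengths.

    Leaves are named S01, S02, ... in join order; identical (n_leaves,
    seed, depth_range) yield byte-identical Newick.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    lo, hi = depth_range
    nodes = [f"S{i + 1:02d}" for i in range(n_leaves)]
    subtrees = list(nodes)
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        bi, bj = rng.uniform(lo, hi, size=2)
        merged = f"({subtrees[i]}:{bi:.6f},{subtrees[j]}:{bj:.6f})"
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)] + [merged]
    return read_tree_string(subtrees[0] + ";")


# ---------------------------------------------------------------------------
# planted motif instances


def sample_motif_instance(
    cdef: MotifClassDef, rng: np.random.Generator
) -> tuple[str, dict[int, str]]:
    """One canonical-geometry instance of the class consensus.

    Returns the core sequence and the required upstream context residues
    keyed by negative offset (for classes with N-terminal constraints).
    """
    tc, lk = cdef.canonical_geometry()
    def pick(alphabet: Iterable[str]) -> str:
        letters = sorted(alphabet)
        return letters[int(rng.integers(len(letters)))]

    core = (
        [pick(cdef.theta_alphabet) for _ in range(tc)]
        + [pick(INERT_ALPHABET) for _ in range(lk)]
        + [pick(cdef.phi_l)]
        + [pick(INERT_ALPHABET) for _ in range(cdef.spacing)]
        + [pick(cdef.phi_a), pick(INERT_ALPHABET), pick(cdef.phi_b)]
    )
    context: dict[int, str] = {}
    for off, allowed in cdef.extra_constraints:
        if off < 0:
            context[off] = pick(allowed)
        else:
            core[off] = pick(allowed & (set(core[off]) | allowed))
    return "".join(core), context


@dataclass(frozen=True)
class PlantSpec:
    """What to plant: (class_name, count, context)."""

    class_name: str
    count: int
    context: str

    def __post_init__(self) -> None:
        if self.context not in PLANT_CONTEXTS:
            raise ValueError(f"unknown plant context {self.context!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")


def _repair_background(
    seq: list[str],
    protected: set[int],
    classes: Sequence[MotifClassDef],
    protein_id: str,
    max_rounds: int = 20,
) -> None:
    """Mutate accidental consensus matches outside protected spans to inert.

    Replaces basic/hydrophobic residues of offending hits (at unprotected
    1-based positions) with inert ones until the scan is clean.
    """
    mutable_targets = set("RKLIVMFP")
    for _ in range(max_rounds):
        record = ProteinRecord(id=protein_id, sequence="".join(seq))
        offenders = []
        for hit in scan_sequence(record, classes):
            span_positions = set(range(hit.start, hit.end + 1))
            if span_positions <= protected:
                continue  # alias of a planted motif; leave intact
            fixable = [
                p
                for p in sorted(span_positions - protected)
                if seq[p - 1] in mutable_targets
            ]
            if fixable:
                offenders.append(fixable)
        if not offenders:
            return
        for fixable in offenders:
            for p in fixable:
                seq[p - 1] = INERT_ALPHABET[(p * 7) % len(INERT_ALPHABET)]
    raise RuntimeError(f"background repair did not converge for {protein_id!r}")


def _baseline_tracks(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    anchor = rng.uniform(0.02, 0.25, size=n)
    disorder = rng.uniform(0.15, 0.40, size=n)
    return anchor, disorder


def simulate_proteome(
    n_proteins: int,
    plant_spec: Sequence[PlantSpec | tuple[str, int, str]],
    seed: int = 0,
    protein_length: tuple[int, int] = (120, 220),
) -> tuple[list[ProteinRecord], dict[str, TrackSet], pd.DataFrame]:
    """Synthetic proteome with planted motifs and coherent predictor tracks.

    One planted motif per protein; proteins beyond the planted count are
    pure background.  Returns (records, tracks, truth_table) where the
    truth table holds one row per planted feature with its intended
    per-step cascade outcome.
    """
    spec = [p if isinstance(p, PlantSpec) else PlantSpec(*p) for p in plant_spec]
    n_plants = sum(p.count for p in spec)
    if n_plants > n_proteins:
        raise ValueError(f"cannot plant {n_plants} motifs into {n_proteins} proteins")
    rng = np.random.default_rng(seed)
    classes = default_class_definitions("loose")
    class_by = {c.name: c for c in classes}
    plants: list[tuple[str, str]] = []
    for p in spec:
        if p.class_name not in class_by:
            raise ValueError(f"unknown motif class {p.class_name!r}")
        plants.extend((p.class_name, p.context) for _ in range(p.count))

    records: list[ProteinRecord] = []
    tracks: dict[str, TrackSet] = {}
    truth_rows = []
    buffer = 8  # inert residues flanking each planted core

    for idx in range(n_proteins):
        pid = f"P{idx + 1:04d}"
        n = int(rng.integers(protein_length[0], protein_length[1] + 1))
        seq = list(rng.choice(_BG_RESIDUES, size=n, p=_BG_PROBS))
        anchor, disorder = _baseline_tracks(rng, n)
        intervals: list[Interval] = []
        localization: dict[str, float] | None = None
        signalp_score: float | None = None
        phobius_signal: bool | None = None
        protected: set[int] = set()

        if idx < n_plants:
            class_name, context = plants[idx]
            cdef = class_by[class_name]
            core, upstream = sample_motif_instance(cdef, rng)
            L = len(core)
            lo = buffer + 12  # keep room for signal peptides and flanks
            hi = n - L - buffer
            start = int(rng.integers(lo, hi))
            end = start + L - 1
            seq[start - 1 : end] = list(core)
            for off in range(-buffer, L + buffer):
                p = start + off
                if 1 <= p <= n and not (0 <= off < L):
                    seq[p - 1] = FLANK_ALPHABET[int(rng.integers(len(FLANK_ALPHABET)))]
            for off, ch in upstream.items():
                seq[start + off - 1] = ch
            protected = set(range(max(1, start - buffer), min(n, end + buffer) + 1))

            if context in ("disordered_pass", "secreted_fail", "er_fail", "coil_fail"):
                anchor[start - 1 : end] = rng.uniform(0.55, 0.85, size=L)
                disorder[max(0, start - 21) : min(n, end + 20)] = rng.uniform(0.6, 0.9, size=min(n, end + 20) - max(0, start - 21))
            elif context == "disordered_pass_low":
                # visible only once the cutoff is lowered to 0.4, and the
                # flanks stay at ordered baseline so the secondary-cutoff
                # disorder fallback cannot rescue the hit earlier
                anchor[start - 1 : end] = rng.uniform(0.40, 0.44, size=L)
            elif context in ("ordered_fail", "decoy_in_domain"):
                anchor[start - 1 : end] = rng.uniform(0.02, 0.20, size=L)
                disorder[max(0, start - 21) : min(n, end + 20)] = rng.uniform(0.05, 0.30, size=min(n, end + 20) - max(0, start - 21))
                intervals.append(
                    Interval("pfam_domain", max(1, start - 5), min(n, end + 5), source="synthetic")
                )
            if context == "secreted_fail":
                intervals.append(Interval("signal_peptide", 1, 18, source="synthetic"))
                signalp_score = float(rng.uniform(0.6, 0.95))
                phobius_signal = True
            if context == "er_fail":
                localization = {"er": 20.0, "cytoplasm": 5.0}
            if context == "coil_fail":
                intervals.append(
                    Interval("coiled_coil", max(1, start - 2), min(n, end + 2), source="synthetic")
                )
            s1, s2, s3, s4, survive = CONTEXT_EXPECTATIONS[context]
            truth_rows.append(
                (pid, class_name, start, end, core, context, s1, s2, s3, s4, survive)
            )

        _repair_background(seq, protected, classes, pid)
        record = ProteinRecord(id=pid, sequence="".join(seq))
        records.append(record)
        tracks[pid] = TrackSet(
            protein_id=pid,
            length=n,
            anchor=np.clip(anchor, 0.0, 1.0),
            disorder=np.clip(disorder, 0.0, 1.0),
            intervals=intervals,
            localization=localization,
            signalp_score=signalp_score,
            phobius_signal=phobius_signal,
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "protein_id",
            "class_name",
            "start",
            "end",
            "core_sequence",
            "context",
            "expected_step1",
            "expected_step2",
            "expected_step3",
            "expected_step4",
            "expected_survive",
        ],
    )
    return records, tracks, truth


# ---------------------------------------------------------------------------
# ortholog families


def simulate_ortholog_groups(
    tree: SpeciesTree,
    n_groups: int,
    class_def: MotifClassDef,
    clade_map: Mapping[str, Sequence[str]] | None = None,
    noise_rate: float = 0.15,
    seed: int = 0,
    reference_species: str | None = None,
    flank: int = 10,
    flank_noise: float = 0.5,
) -> tuple[dict[str, OrthologAlignment], dict[str, list[TrainingPeptide]], pd.DataFrame]:
    """Ortholog families sharing one planted consensus, optionally clade-confined.

    Each group G01..Gnn carries the same planted canonical-geometry
    consensus in its reference row; other motif-bearing species carry
    per-position noisy copies (theta/phi positions mutate within their
    allowed sets with probability ``noise_rate``, intervening positions
    within the inert flank alphabet).  Species outside ``clade_map[gid]``
    have the motif deleted (gapped out) in the alignment and contribute no
    training peptide.  Returns (alignments, training groups, truth table);
    the truth table records the planted consensus and per-species presence.
    """
    if not 0.0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    species = tree.leaf_names
    reference = reference_species or species[0]
    if reference not in species:
        raise KeyError(f"reference species {reference!r} not in tree")
    gids = [f"G{i + 1:02d}" for i in range(n_groups)]
    if clade_map is None:
        clade_map = {gid: species for gid in gids}
    for gid in gids:
        members = set(clade_map.get(gid, ()))
        unknown = members - set(species)
        if unknown:
            raise KeyError(f"clade of {gid} names unknown species {sorted(unknown)}")
        if reference not in members:
            raise ValueError(f"reference {reference!r} must bear the motif in group {gid}")

    consensus, _ = sample_motif_instance(class_def, rng)
    L = len(consensus)
    tc, lk = class_def.canonical_geometry()
    l_off, a_off, b_off = class_def.phi_offsets(tc, lk)
    constrained = set(range(tc)) | {l_off, a_off, b_off}
    allowed_at = {}
    for i in range(L):
        if i < tc:
            allowed_at[i] = sorted(class_def.theta_alphabet)
        elif i == l_off:
            allowed_at[i] = sorted(class_def.phi_l)
        elif i == a_off:
            allowed_at[i] = sorted(class_def.phi_a)
        elif i == b_off:
            allowed_at[i] = sorted(class_def.phi_b)
        else:
            allowed_at[i] = list(FLANK_ALPHABET)

    alignments: dict[str, OrthologAlignment] = {}
    groups: dict[str, list[TrainingPeptide]] = {}
    truth_rows = []
    for gid in gids:
        bearers = set(clade_map[gid])
        ref_flank_l = "".join(rng.choice(list(FLANK_ALPHABET), size=flank))
        ref_flank_r = "".join(rng.choice(list(FLANK_ALPHABET), size=flank))
        rows: dict[str, str] = {}
        peptides: list[TrainingPeptide] = []
        for sp in species:
            fl = [
                ch
                if rng.random() >= flank_noise
                else FLANK_ALPHABET[int(rng.integers(len(FLANK_ALPHABET)))]
                for ch in ref_flank_l + ref_flank_r
            ]
            flank_l, flank_r = "".join(fl[:flank]), "".join(fl[flank:])
            if sp == reference:
                flank_l, flank_r = ref_flank_l, ref_flank_r
                motif = consensus
            elif sp in bearers:
                motif = "".join(
                    ch
                    if rng.random() >= noise_rate
                    else allowed_at[i][int(rng.integers(len(allowed_at[i])))]
                    for i, ch in enumerate(consensus)
                )
            else:
                motif = "-" * L
            rows[sp] = flank_l + motif + flank_r
            if sp in bearers:
                peptides.append(TrainingPeptide(motif, sp, gid))
            truth_rows.append((gid, sp, sp in bearers))
        alignments[gid] = OrthologAlignment(rows, reference)
        groups[gid] = peptides

    truth = pd.DataFrame(truth_rows, columns=["group_id", "species", "bears_motif"])
    truth.attrs["consensus"] = consensus
    truth.attrs["motif_span"] = (flank + 1, flank + L)
    return alignments, groups, truth
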