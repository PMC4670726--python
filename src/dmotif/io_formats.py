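"""Readers and writers for every external representation the pipeline touches.

All coordinates are 1-based inclusive protein positions (UniProt/GFF3
convention) throughout the package; no half-open coordinates anywhere.
Nonstandard residues (X, U, B, Z) are retained in sequences but never
satisfy a theta or phi residue class and are excluded from background
frequency estimation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: interval kinds understood by the filter cascade
INTERVAL_KINDS = frozenset(
    {
        "pfam_domain",
        "pfam_other",
        "coiled_coil",
        "transmembrane",
        "topology_intracellular",
        "topology_extracellular",
        "signal_peptide",
    }
)


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence with a unique accession."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """One annotated segment, 1-based inclusive."""

    kind: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in INTERVAL_KINDS:
            raise ValueError(f"unknown interval kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval coordinates ({self.start}, {self.end}) for kind {self.kind!r}"
            )

    def overlaps(self, start: int, end: int) -> bool:
        """True if the interval shares at least one residue with [start, end]."""
        return self.start <= end and start <= self.end


@dataclass
class TrackSet:
    """Per-residue predictor scores and interval annotations for one protein.

    Missing tracks are explicit ``None`` (tri-state present/absent), never
    silently zero-filled: the filter cascade decides per step how to treat
    absence.
    """

    protein_id: str
    length: int
    anchor: np.ndarray | None = None  # binding-region propensity in [0, 1]
    disorder: np.ndarray | None = None  # disorder propensity in [0, 1]
    intervals: list[Interval] = field(default_factory=list)
    localization: dict[str, float] | None = None  # compartment -> score
    signalp_score: float | None = None
    phobius_signal: bool | None = None

    def __post_init__(self) -> None:
        for name in ("anchor", "disorder"):
            track = getattr(self, name)
            if track is None:
                continue
            track = np.asarray(track, dtype=float)
            if track.shape != (self.length,):
                raise ValueError(
                    f"{name} track of {self.protein_id!r} has length "
                    f"{track.shape[0]}, expected {self.length}"
                )
            if np.any(track < 0) or np.any(track > 1):
                raise ValueError(f"{name} track of {self.protein_id!r} outside [0, 1]")
            setattr(self, name, track)
        for iv in self.intervals:
            if iv.end > self.length:
                raise ValueError(
                    f"interval ({iv.start}, {iv.end}) of {self.protein_id!r} "
                    f"exceeds sequence length {self.length}"
                )

    def intervals_of(self, *kinds: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.kind in kinds]

    @property
    def has_transmembrane(self) -> bool:
        return len(self.intervals_of("transmembrane")) > 0


class SpeciesTree:
    """A rooted species tree with named leaves and non-negative branch lengths.

    Thin wrapper over :class:`dendropy.Tree` exposing patristic (path-sum)
    distances between leaves.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate leaf names in species tree")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("species tree has an edge without branch length")
            if edge.length < 0:
                raise ValueError("species tree has a negative branch length")
        self.leaf_names: list[str] = leaves
        self._pdm = tree.phylogenetic_distance_matrix()
        self._taxa = {t.label: t for t in tree.taxon_namespace}

    def distance(self, species_a: str, species_b: str) -> float:
        """Sum of branch lengths on the unique leaf-to-leaf path."""
        for sp in (species_a, species_b):
            if sp not in self._taxa:
                raise KeyError(f"species {sp!r} not in tree")
        if species_a == species_b:
            return 0.0
        return float(self._pdm.patristic_distance(self._taxa[species_a], self._taxa[species_b]))

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree


class OrthologAlignment:
    """Species-labeled aligned homologs with a designated reference row.

    Provides the mapping between ungapped reference residue positions
    (1-based) and alignment columns (1-based).  The gap character ``-`` is
    the only non-residue symbol allowed.
    """

    GAP = "-"

    def __init__(self, rows: Mapping[str, str], reference_species: str):
        if not rows:
            raise ValueError("alignment has no rows")
        lengths = {len(s) for s in rows.values()}
        if len(lengths) != 1:
            raise ValueError("ragged alignment: rows differ in column count")
        if reference_species not in rows:
            raise KeyError(f"reference species {reference_species!r} not in alignment")
        self.rows: dict[str, str] = {sp: s.upper() for sp, s in rows.items()}
        self.reference_species = reference_species
        self.n_columns = lengths.pop()
        ref = self.rows[reference_species]
        # pos2col[i] = alignment column (1-based) of reference residue i+1
        self._pos2col = [c + 1 for c, ch in enumerate(ref) if ch != self.GAP]
        self._col2pos = {c: p + 1 for p, c in enumerate(self._pos2col)}

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    @property
    def reference_sequence(self) -> str:
        return self.rows[self.reference_species].replace(self.GAP, "")

    def column_of(self, reference_position: int) -> int:
        """Alignment column holding the given reference residue."""
        if not 1 <= reference_position <= len(self._pos2col):
            raise IndexError(
                f"reference position {reference_position} outside 1..{len(self._pos2col)}"
            )
        return self._pos2col[reference_position - 1]

    def position_of(self, column: int) -> int | None:
        """Reference residue at the column, or None if the reference is gapped."""
        return self._col2pos.get(column)

    def ungapped(self, species: str, col_start: int, col_end: int) -> str:
        """Residues of one row within a 1-based inclusive column range."""
        return self.rows[species][col_start - 1 : col_end].replace(self.GAP, "")


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into upper-cased records, order preserved."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), description=rec.description)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


_GFF3_COLUMNS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]


def _read_gff3_intervals(path: str | Path) -> dict[str, list[Interval]]:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=_GFF3_COLUMNS,
        dtype={"seqid": str, "type": str},
    )
    out: dict[str, list[Interval]] = {}
    for row in df.itertuples(index=False):
        if row.type not in INTERVAL_KINDS:
            raise ValueError(f"unknown interval kind {row.type!r} in {path}")
        iv = Interval(kind=row.type, start=int(row.start), end=int(row.end), source=str(row.source))
        out.setdefault(row.seqid, []).append(iv)
    return out


def read_tracks(
    scores_path: str | Path | None,
    intervals_path: str | Path | None,
    localization_path: str | Path | None,
    proteins: Sequence[ProteinRecord],
) -> dict[str, TrackSet]:
    """Assemble per-protein :class:`TrackSet` objects from the on-disk tables.

    ``scores_path``: TSV with columns (protein_id, position, anchor, disorder);
    ``intervals_path``: GFF3 with the interval kind in the *type* column;
    ``localization_path``: TSV with rows either (protein_id, compartment,
    score) or the reserved compartments ``signalp_score`` / ``phobius_signal``.
    Any of the three paths may be None; the corresponding tracks stay absent.
    Proteins missing from the scores table get explicit absent tracks.
    """
    lengths = {rec.id: len(rec) for rec in proteins}
    anchor: dict[str, np.ndarray] = {}
    disorder: dict[str, np.ndarray] = {}
    if scores_path is not None:
        df = pd.read_csv(scores_path, sep="\t", dtype={"protein_id": str})
        required = {"protein_id", "position", "anchor", "disorder"}
        if not required.issubset(df.columns):
            raise ValueError(f"scores table must have columns {sorted(required)}")
        for pid, sub in df.groupby("protein_id", sort=False):
            if pid not in lengths:
                continue
            n = lengths[pid]
            pos = sub["position"].to_numpy(int)
            if pos.min() < 1 or pos.max() > n:
                bad = pos[(pos < 1) | (pos > n)][0]
                raise ValueError(f"score position {bad} outside 1..{n} for protein {pid!r}")
            a = np.full(n, np.nan)
            d = np.full(n, np.nan)
            a[pos - 1] = sub["anchor"].to_numpy(float)
            d[pos - 1] = sub["disorder"].to_numpy(float)
            if np.isnan(a).any() or np.isnan(d).any():
                raise ValueError(f"incomplete score track for protein {pid!r}")
            anchor[pid] = a
            disorder[pid] = d

    intervals = _read_gff3_intervals(intervals_path) if intervals_path is not None else {}

    localization: dict[str, dict[str, float]] = {}
    signalp: dict[str, float] = {}
    phobius: dict[str, bool] = {}
    if localization_path is not None:
        df = pd.read_csv(localization_path, sep="\t", dtype={"protein_id": str, "compartment": str})
        if not {"protein_id", "compartment", "score"}.issubset(df.columns):
            raise ValueError("localization table must have columns protein_id, compartment, score")
        for row in df.itertuples(index=False):
            if row.compartment == "signalp_score":
                signalp[row.protein_id] = float(row.score)
            elif row.compartment == "phobius_signal":
                phobius[row.protein_id] = bool(int(row.score))
            else:
                localization.setdefault(row.protein_id, {})[row.compartment] = float(row.score)

    tracks: dict[str, TrackSet] = {}
    for rec in proteins:
        pid = rec.id
        tracks[pid] = TrackSet(
            protein_id=pid,
            length=lengths[pid],
            anchor=anchor.get(pid),
            disorder=disorder.get(pid),
            intervals=intervals.get(pid, []),
            localization=localization.get(pid),
            signalp_score=signalp.get(pid),
            phobius_signal=phobius.get(pid),
        )
    return tracks


def write_tracks(
    tracks: Mapping[str, TrackSet],
    scores_path: str | Path,
    intervals_path: str | Path,
    localization_path: str | Path,
) -> None:
    """Write TrackSets back to the three on-disk tables read_tracks consumes."""
    score_rows = []
    loc_rows = []
    with open(intervals_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for pid, ts in tracks.items():
            if ts.anchor is not None:
                for i in range(ts.length):
                    score_rows.append((pid, i + 1, ts.anchor[i], ts.disorder[i]))
            for iv in ts.intervals:
                gff.write(
                    f"{pid}\t{iv.source or '.'}\t{iv.kind}\t{iv.start}\t{iv.end}\t.\t.\t.\t.\n"
                )
            if ts.localization is not None:
                for comp, score in ts.localization.items():
                    loc_rows.append((pid, comp, score))
            if ts.signalp_score is not None:
                loc_rows.append((pid, "signalp_score", ts.signalp_score))
            if ts.phobius_signal is not None:
                loc_rows.append((pid, "phobius_signal", int(ts.phobius_signal)))
    pd.DataFrame(score_rows, columns=["protein_id", "position", "anchor", "disorder"]).to_csv(
        scores_path, sep="\t", index=False
    )
    pd.DataFrame(loc_rows, columns=["protein_id", "compartment", "score"]).to_csv(
        localization_path, sep="\t", index=False
    )


def read_tree(path: str | Path) -> SpeciesTree:
    """Read a Newick species tree with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", rooting="default-rooted")
    return SpeciesTree(tree)


def read_tree_string(newick: str) -> SpeciesTree:
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="default-rooted")
    return SpeciesTree(tree)


def read_alignment(path: str | Path, reference_species: str) -> OrthologAlignment:
    """Read an aligned FASTA keyed by species identifier."""
    with open(path) as fh:
        text = fh.read()
    # Bio.AlignIO rejects ragged rows; surface its message with our context
    try:
        msa = AlignIO.read(io.StringIO(text), "fasta")
    except ValueError as exc:
        raise ValueError(f"cannot read alignment {path}: {exc}") from exc
    return OrthologAlignment({rec.id: str(rec.seq) for rec in msa}, reference_species)


HIT_TABLE_COLUMNS = [
    "protein_id",
    "class_name",
    "start",
    "end",
    "matched_sequence",
    "theta_positions",
    "phi_positions",
    "filter_status",
    "pssm_score",
    "external_score",
]


def write_hits(hits_table: pd.DataFrame, path: str | Path) -> None:
    """Write a hit table as TSV with the documented header."""
    missing = [c for c in HIT_TABLE_COLUMNS if c not in hits_table.columns]
    if missing:
        raise ValueError(f"hit table missing columns {missing}")
    hits_table.to_csv(path, sep="\t", index=False, columns=HIT_TABLE_COLUMNS)


def read_hits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "class_name": str})
    missing = [c for c in HIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hit table missing columns {missing}")
    return df
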