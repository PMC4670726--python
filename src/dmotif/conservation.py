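"""Evolutionary conservation of docking motifs and phosphorylation sites.

Species distances are patristic: the direct sum of branch lengths on the
path between two leaves of the species tree.  A motif's maximum traceable
distance (MTD) is the largest distance from the reference species to any
homolog that still carries a consensus match near the reference motif's
alignment position.  Phosphosite conservation is the weight fraction of
alignment rows in which the S/T-P consensus around the mapped site column
is intact ("normalized average traceable evolutionary distance").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from dmotif.io_formats import OrthologAlignment, ProteinRecord, SpeciesTree
from dmotif.motif_patterns import MotifClassDef, scan_sequence


@dataclass
class ConservationResult:
    presence: dict[str, bool]
    mtd: float
    motif_score: float
    flank_score: float
    ratio: float


@dataclass
class PhosphositeRecord:
    """One S/TP consensus site in the reference with its conservation score."""

    position: int  # reference position of the S/T residue
    evidence: str
    traceable_distance: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.traceable_distance <= 1.0:
            raise ValueError("normalized traceable distance must lie in [0, 1]")


def patristic_distance(tree: SpeciesTree, species_a: str, species_b: str) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    return tree.distance(species_a, species_b)


def motif_presence(
    alignment: OrthologAlignment,
    reference_span: tuple[int, int],
    class_def: MotifClassDef,
    window: int = 10,
) -> dict[str, bool]:
    """Per-species: does a class-consensus match occur near the reference motif?

    The search region is the reference motif's alignment-column span
    extended by ``window`` columns on each side; each species' row is
    ungapped within that region and scanned with the class definition.
    A fully gapped window gives presence False.
    """
    start, end = reference_span
    col_lo = max(1, alignment.column_of(start) - window)
    col_hi = min(alignment.n_columns, alignment.column_of(end) + window)
    presence: dict[str, bool] = {}
    for sp in alignment.species:
        segment = alignment.ungapped(sp, col_lo, col_hi)
        if not segment:
            presence[sp] = False
            continue
        rec = ProteinRecord(id=sp, sequence=segment)
        presence[sp] = len(scan_sequence(rec, [class_def])) > 0
    return presence


def max_traceable_distance(
    presence: Mapping[str, bool],
    tree: SpeciesTree,
    reference_species: str,
    pairwise: bool = False,
) -> float:
    """Maximum patristic distance between species bearing the motif.

    By default anchored at the reference species (distance from the
    reference to the farthest motif-bearing homolog); ``pairwise=True``
    takes the maximum over all motif-bearing pairs instead.
    """
    if not presence.get(reference_species, False):
        raise ValueError(f"reference species {reference_species!r} does not bear the motif")
    bearers = [sp for sp, present in presence.items() if present]
    if pairwise:
        return max(
            tree.distance(a, b) for a in bearers for b in bearers
        )
    return max(tree.distance(reference_species, sp) for sp in bearers)


def relative_motif_conservation(
    alignment: OrthologAlignment,
    span: tuple[int, int],
    flank: int = 10,
) -> tuple[float, float, float]:
    """Identity-to-reference conservation of motif columns versus flanks.

    A column's conservation is the fraction of non-reference rows whose
    residue equals the reference residue (gaps count as mismatch).
    Returns (motif_score, flank_score, ratio); the ratio is +inf when the
    flanks are fully diverged but the motif is not.
    """
    others = [sp for sp in alignment.species if sp != alignment.reference_species]
    if not others:
        raise ValueError("alignment needs at least one non-reference row")
    ref_row = alignment.rows[alignment.reference_species]
    col_lo = alignment.column_of(span[0])
    col_hi = alignment.column_of(span[1])

    def column_score(col: int) -> float:
        ref_aa = ref_row[col - 1]
        same = sum(1 for sp in others if alignment.rows[sp][col - 1] == ref_aa != "-")
        return same / len(others)

    motif_cols = range(col_lo, col_hi + 1)
    flank_cols = [
        c
        for c in (*range(col_lo - flank, col_lo), *range(col_hi + 1, col_hi + flank + 1))
        if 1 <= c <= alignment.n_columns
    ]
    motif_score = sum(map(column_score, motif_cols)) / len(list(motif_cols))
    flank_score = sum(map(column_score, flank_cols)) / len(flank_cols) if flank_cols else 0.0
    if flank_score == 0.0:
        ratio = float("inf") if motif_score > 0 else 0.0
    else:
        ratio = motif_score / flank_score
    return (motif_score, flank_score, ratio)


def _site_intact(alignment: OrthologAlignment, species: str, site_column: int) -> bool:
    """S/T at the site column and P as the next ungapped residue."""
    row = alignment.rows[species]
    if row[site_column - 1] not in "ST":
        return False
    for col in range(site_column + 1, alignment.n_columns + 1):
        ch = row[col - 1]
        if ch != OrthologAlignment.GAP:
            return ch == "P"
    return False


def distance_weight_fn(
    tree: SpeciesTree, reference_species: str, species: str, epsilon: float = 0.01
) -> float:
    """Default phylogenetic weight: patristic distance from reference + eps."""
    return tree.distance(reference_species, species) + epsilon


def uniform_weight_fn(tree: SpeciesTree, reference_species: str, species: str) -> float:
    return 1.0


def phosphosite_traceable_distance(
    alignment: OrthologAlignment,
    site: int,
    tree: SpeciesTree | None = None,
    reference_species: str | None = None,
    weight_fn: Callable[..., float] | None = None,
) -> float:
    """Weight fraction of rows in which the S/T-P consensus site is intact.

    ``site`` is the 1-based reference position of the S/T residue; the
    reference must carry an intact S/T-P dipeptide there.  Weights default
    to the same distance-based scheme used for PSSM training; the score is
    invariant to uniform weight rescaling and equals 1 iff the site is
    present in every row.
    """
    reference_species = reference_species or alignment.reference_species
    ref_seq = alignment.reference_sequence
    if site < 1 or site >= len(ref_seq):
        raise ValueError(f"site {site} has no following residue in the reference")
    if ref_seq[site - 1] not in "ST" or ref_seq[site] != "P":
        raise ValueError(f"reference position {site} is not an S/T-P consensus site")
    site_col = alignment.column_of(site)
    if weight_fn is None:
        if tree is None:
            weight_fn = uniform_weight_fn
        else:
            weight_fn = distance_weight_fn
    total = 0.0
    present = 0.0
    for sp in alignment.species:
        w = weight_fn(tree, reference_species, sp)
        total += w
        if _site_intact(alignment, sp, site_col):
            present += w
    return present / total


def select_candidate_site(
    alignment: OrthologAlignment,
    sites: Sequence[tuple[int, str]],
    motif_span: tuple[int, int],
    tree: SpeciesTree | None = None,
    reference_species: str | None = None,
    min_distance: int = 10,
    weight_fn: Callable[..., float] | None = None,
) -> PhosphositeRecord | None:
    """Pick the most traceable MAPK phosphosite outside the docking motif.

    Sites within ``min_distance`` residues of the core motif span are
    excluded (candidates must be more than 10 residues away); among the
    rest the site with the maximum normalized traceable distance wins,
    ties broken by the smallest position.  Returns None when every site is
    excluded.
    """
    if not sites:
        raise ValueError("at least one candidate site required")
    start, end = motif_span
    best: PhosphositeRecord | None = None
    for position, evidence in sorted(sites):
        if start - min_distance <= position <= end + min_distance:
            continue
        score = phosphosite_traceable_distance(
            alignment, position, tree, reference_species, weight_fn
        )
        if best is None or score > best.traceable_distance:
            best = PhosphositeRecord(position=position, evidence=evidence, traceable_distance=score)
    return best
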