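"""Four-step candidate filtering over precomputed predictor tracks.

Step 1 keeps hits in disordered binding regions (ANCHOR-style runs, with a
fallback at a lower cutoff when a 20-residue flank is sufficiently
disordered).  Step 2 removes hits that are secreted and so inaccessible to
a cytoplasmic kinase.  Step 3 removes hits in proteins confidently
predicted extracellular / membrane / ER / Golgi.  Step 4 removes hits
inside folded (Pfam-style) domains and coiled coils.

Threshold comparisons follow the wording of the underlying decision rules
literally: ANCHOR-region membership uses >= cutoff, flank disorder and the
signal-peptide score use strict >, and localization scores use >=.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from dmotif.io_formats import TrackSet
from dmotif.motif_patterns import MotifHit

STEP_NAMES = ("step1_disorder", "step2_accessibility", "step3_localization", "step4_structure")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade; defaults are the adopted operating point."""

    anchor_primary_cutoff: float = 0.4
    anchor_secondary_cutoff: float = 0.3
    flank_length: int = 20
    flank_disorder_min: float = 0.45
    signalp_min_for_phobius: float = 0.3
    wolf_thresholds: tuple[tuple[str, float], ...] = (
        ("extracellular", 25.0),
        ("membrane", 25.0),
        ("er", 15.0),
        ("golgi", 9.0),
    )
    pfam_blacklist_kinds: frozenset[str] = frozenset({"pfam_domain"})
    curated_pfam_other: frozenset[tuple[str, int, int]] = frozenset()  # (protein, start, end)
    coil_filter_on: bool = True
    missing_track_policy: str = "permissive"  # or "strict"
    steps_enabled: tuple[bool, bool, bool, bool] = (True, True, True, True)

    def __post_init__(self) -> None:
        for c in (self.anchor_primary_cutoff, self.anchor_secondary_cutoff):
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"anchor cutoff {c} outside [0, 1]")
        if self.flank_length < 1:
            raise ValueError("flank_length must be >= 1")
        if any(t < 0 for _, t in self.wolf_thresholds):
            raise ValueError("localization thresholds must be >= 0")
        if self.missing_track_policy not in ("permissive", "strict"):
            raise ValueError("missing_track_policy must be 'permissive' or 'strict'")


@dataclass
class FilterReport:
    """Per-step attrition accounting: in = out + removed at every step."""

    steps: list[str] = field(default_factory=list)
    n_in: list[int] = field(default_factory=list)
    n_removed: list[int] = field(default_factory=list)
    n_out: list[int] = field(default_factory=list)

    def add(self, step: str, n_in: int, n_removed: int) -> None:
        self.steps.append(step)
        self.n_in.append(n_in)
        self.n_removed.append(n_removed)
        self.n_out.append(n_in - n_removed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": self.steps, "in": self.n_in, "removed": self.n_removed, "out": self.n_out}
        )


class MissingTrackError(RuntimeError):
    """A predictor track required by a filter step is absent (strict mode)."""


def anchor_regions(scores: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """Maximal runs of consecutive positions with score >= cutoff (1-based)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score track")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    above = scores >= cutoff
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2] + 1, edges[1::2]
    return list(zip(starts.tolist(), ends.tolist()))


def _overlaps_any(start: int, end: int, regions: Sequence[tuple[int, int]]) -> bool:
    return any(s <= end and start <= e for s, e in regions)


def _flank_mean(track: np.ndarray, lo: int, hi: int) -> float | None:
    """Mean of track over 1-based inclusive [lo, hi] clipped to the sequence."""
    lo, hi = max(lo, 1), min(hi, len(track))
    if lo > hi:
        return None
    return float(np.mean(track[lo - 1 : hi]))


def step1_disorder(hit: MotifHit, tracks: TrackSet, cfg: FilterConfig) -> tuple[str, str]:
    """Disordered binding-region filter.

    Pass iff the core span overlaps an anchor region at the primary cutoff,
    or overlaps one at the secondary cutoff while at least one 20-residue
    flank has mean disorder strictly above ``flank_disorder_min``.
    """
    if tracks.anchor is None or tracks.disorder is None:
        if cfg.missing_track_policy == "strict":
            raise MissingTrackError(f"no anchor/disorder track for {hit.protein_id!r}")
        return ("fail", "no-track")
    primary = anchor_regions(tracks.anchor, cfg.anchor_primary_cutoff)
    if _overlaps_any(hit.start, hit.end, primary):
        return ("pass", "anchor-primary")
    secondary = anchor_regions(tracks.anchor, cfg.anchor_secondary_cutoff)
    if _overlaps_any(hit.start, hit.end, secondary):
        left = _flank_mean(tracks.disorder, hit.start - cfg.flank_length, hit.start - 1)
        right = _flank_mean(tracks.disorder, hit.end + 1, hit.end + cfg.flank_length)
        for side, mean in (("left", left), ("right", right)):
            if mean is not None and mean > cfg.flank_disorder_min:
                return ("pass", f"anchor-secondary+{side}-flank")
        return ("fail", "flanks-ordered")
    return ("fail", "no-anchor-region")


def _span_entirely_intracellular(hit: MotifHit, tracks: TrackSet) -> bool:
    intra = tracks.intervals_of("topology_intracellular")
    pos_covered = [
        any(iv.start <= p <= iv.end for iv in intra) for p in range(hit.start, hit.end + 1)
    ]
    return len(intra) > 0 and all(pos_covered)


def step2_accessibility(hit: MotifHit, tracks: TrackSet, cfg: FilterConfig) -> tuple[str, str]:
    """Secretion filter: discard extracellular-facing hits.

    A protein counts signal-positive if SignalP calls a signal peptide, or
    if Phobius alone calls one while the SignalP score is still above the
    floor.  Signal-positive proteins without any transmembrane segment are
    discarded outright; with transmembrane segments the hit survives only
    if its core span is entirely within intracellular topology.
    """
    signalp_positive = len(tracks.intervals_of("signal_peptide")) > 0
    phobius_signal = bool(tracks.phobius_signal)
    sp_score = tracks.signalp_score if tracks.signalp_score is not None else 0.0
    signal = signalp_positive or (phobius_signal and sp_score > cfg.signalp_min_for_phobius)
    if not signal:
        return ("pass", "no-signal-peptide")
    if not tracks.has_transmembrane:
        return ("fail", "secreted")
    if len(tracks.intervals_of("topology_intracellular", "topology_extracellular")) == 0:
        return ("fail", "topology-unknown")
    if _span_entirely_intracellular(hit, tracks):
        return ("pass", "intracellular-span")
    return ("fail", "not-intracellular")


def step3_localization(hit: MotifHit, tracks: TrackSet, cfg: FilterConfig) -> tuple[str, str]:
    """Compartment filter on per-protein localization scores.

    Fails iff any listed compartment reaches its threshold, unless the
    protein has a transmembrane segment and the core span is entirely
    intracellular.  Absent localization scores pass (most proteins carry
    no confident prediction).
    """
    if tracks.localization is None:
        return ("pass", "no-localization-scores")
    offending = [
        comp
        for comp, threshold in cfg.wolf_thresholds
        if tracks.localization.get(comp, 0.0) >= threshold
    ]
    if not offending:
        return ("pass", "below-thresholds")
    if tracks.has_transmembrane and _span_entirely_intracellular(hit, tracks):
        return ("pass", "intracellular-span")
    return ("fail", "compartment:" + ",".join(offending))


def step4_structure(hit: MotifHit, tracks: TrackSet, cfg: FilterConfig) -> tuple[str, str]:
    """Structural-context filter: folded domains and coiled coils.

    Fails iff the core span shares >= 1 residue with a blacklisted
    interval: pfam_domain always; pfam_other only when that interval is in
    the user-supplied curation set; coiled_coil when the coil filter is on.
    """
    for iv in tracks.intervals:
        if not iv.overlaps(hit.start, hit.end):
            continue
        if iv.kind in cfg.pfam_blacklist_kinds:
            return ("fail", f"in-{iv.kind}")
        if iv.kind == "pfam_other" and (hit.protein_id, iv.start, iv.end) in cfg.curated_pfam_other:
            return ("fail", "in-curated-pfam_other")
        if iv.kind == "coiled_coil" and cfg.coil_filter_on:
            return ("fail", "in-coiled-coil")
    return ("pass", "no-structured-overlap")


_STEP_FUNCS = {
    "step1_disorder": step1_disorder,
    "step2_accessibility": step2_accessibility,
    "step3_localization": step3_localization,
    "step4_structure": step4_structure,
}


def run_cascade(
    hits: Sequence[MotifHit],
    tracks: Mapping[str, TrackSet],
    cfg: FilterConfig | None = None,
) -> tuple[list[MotifHit], FilterReport]:
    """Apply steps 1-4 in order with per-hit and per-step accounting.

    Every hit carries the full per-step status (pass / fail / NA for steps
    after the first failure or disabled steps); the report records the
    weakly decreasing survivor counts.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport()
    surviving = list(hits)
    for step_name, enabled in zip(STEP_NAMES, cfg.steps_enabled):
        func = _STEP_FUNCS[step_name]
        n_in = len(surviving)
        if not enabled:
            for hit in surviving:
                hit.filter_status[step_name] = ("NA", "disabled")
            report.add(step_name, n_in, 0)
            continue
        next_round: list[MotifHit] = []
        for hit in surviving:
            ts = tracks.get(hit.protein_id)
            if ts is None:
                if cfg.missing_track_policy == "strict":
                    raise MissingTrackError(f"no tracks for protein {hit.protein_id!r}")
                status, reason = ("fail", "no-track")
            else:
                status, reason = func(hit, ts, cfg)
            hit.filter_status[step_name] = (status, reason)
            if status == "pass":
                next_round.append(hit)
        report.add(step_name, n_in, n_in - len(next_round))
        removed = [h for h in surviving if h.filter_status[step_name][0] != "pass"]
        for hit in removed:
            for later in STEP_NAMES[STEP_NAMES.index(step_name) + 1 :]:
                hit.filter_status[later] = ("NA", "already-removed")
        surviving = next_round
    return surviving, report


def first_failing_step(hit: MotifHit) -> str | None:
    """Name of the first cascade step that removed the hit, if any."""
    for step in STEP_NAMES:
        status, _ = hit.filter_status.get(step, ("NA", ""))
        if status == "fail":
            return step
    return None


def calibrate_anchor_cutoff(
    positive_hits: Sequence[MotifHit],
    tracks: Mapping[str, TrackSet],
    target_retention: float = 0.90,
    cfg: FilterConfig | None = None,
) -> tuple[float, float, bool]:
    """Adaptively lower the anchor cutoffs until known positives are retained.

    Searches a descending grid of primary cutoffs from 0.5 (step 0.05,
    secondary = primary - 0.1, floored at 0.05) and returns the highest
    (primary, secondary) pair for which the disorder step retains at least
    ``target_retention`` of the positives.  The third element of the return
    value is a warning flag, set when even the grid minimum falls short (the
    minimum is then returned).
    """
    if not positive_hits:
        raise ValueError("no positive hits to calibrate against")
    cfg = cfg or FilterConfig()
    grid = np.arange(0.5, 0.05 - 1e-9, -0.05)
    last_pair = (0.05, 0.05)
    for primary in grid:
        primary = round(float(primary), 2)
        secondary = round(max(primary - 0.1, 0.05), 2)
        trial = replace(
            cfg, anchor_primary_cutoff=primary, anchor_secondary_cutoff=secondary
        )
        n_pass = 0
        for hit in positive_hits:
            ts = tracks.get(hit.protein_id)
            if ts is None:
                continue
            status, _ = step1_disorder(hit, ts, trial)
            n_pass += status == "pass"
        last_pair = (primary, secondary)
        if n_pass / len(positive_hits) >= target_retention:
            return (primary, secondary, False)
    return (*last_pair, True)
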