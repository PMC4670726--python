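import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmotif.filter_cascade import (
    FilterConfig,
    MissingTrackError,
    anchor_regions,
    calibrate_anchor_cutoff,
    first_failing_step,
    run_cascade,
    step1_disorder,
    step2_accessibility,
    step3_localization,
    step4_structure,
)
from dmotif.io_formats import Interval, TrackSet
from dmotif.motif_patterns import MotifHit


def make_hit(start=30, end=37, pid="P1"):
    return MotifHit(
        protein_id=pid,
        class_name="JIP1",
        start=start,
        end=end,
        matched_sequence="K" * (end - start + 1),
        theta_positions=(start,),
        phi_positions=(start + 1, start + 4, start + 6),
    )


def make_tracks(length=100, anchor=None, disorder=None, **kw):
    if anchor is None:
        anchor = np.full(length, 0.1)
    if disorder is None:
        disorder = np.full(length, 0.3)
    return TrackSet("P1", length=length, anchor=anchor, disorder=disorder, **kw)


class TestAnchorRegions:
    def test_simple_run(self):
        assert anchor_regions(np.array([0.1, 0.5, 0.6, 0.2]), 0.4) == [(2, 3)]

    def test_all_below(self):
        assert anchor_regions(np.array([0.1, 0.2]), 0.4) == []

    def test_cutoff_zero_spans_everything(self):
        assert anchor_regions(np.zeros(7), 0.0) == [(1, 7)]

    def test_membership_is_inclusive_at_cutoff(self):
        assert anchor_regions(np.array([0.4, 0.39]), 0.4) == [(1, 1)]

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            anchor_regions(np.array([0.5]), 1.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60), st.floats(0, 1))
    def test_regions_cover_exactly_positions_at_or_above_cutoff(self, scores, cutoff):
        scores = np.array(scores)
        regions = anchor_regions(scores, cutoff)
        covered = set()
        for s, e in regions:
            assert s <= e
            covered |= set(range(s, e + 1))
        assert covered == {i + 1 for i, v in enumerate(scores) if v >= cutoff}


class TestStep1:
    def test_pass_inside_primary_anchor_run(self):
        anchor = np.full(100, 0.1)
        anchor[25:45] = 0.5
        status, reason = step1_disorder(make_hit(), make_tracks(anchor=anchor), FilterConfig())
        assert status == "pass" and reason == "anchor-primary"

    def test_flank_mean_exactly_at_threshold_fails(self):
        """The disorder fallback requires strictly more than 0.45."""
        anchor = np.full(100, 0.1)
        anchor[25:45] = 0.35  # secondary-only region
        disorder = np.full(100, 0.45)
        status, _ = step1_disorder(
            make_hit(), make_tracks(anchor=anchor, disorder=disorder), FilterConfig()
        )
        assert status == "fail"

    def test_flank_mean_just_above_threshold_passes(self):
        anchor = np.full(100, 0.1)
        anchor[25:45] = 0.35
        disorder = np.full(100, 0.2)
        disorder[9:29] = 0.46  # the 20 residues left of start=30
        status, reason = step1_disorder(
            make_hit(), make_tracks(anchor=anchor, disorder=disorder), FilterConfig()
        )
        assert status == "pass" and "left-flank" in reason

    def test_truncated_flank_uses_available_residues(self):
        anchor = np.full(20, 0.35)
        disorder = np.full(20, 0.9)
        hit = make_hit(start=2, end=9)
        status, _ = step1_disorder(hit, make_tracks(20, anchor, disorder), FilterConfig())
        assert status == "pass"

    def test_missing_track_policies(self):
        ts = TrackSet("P1", length=50)
        assert step1_disorder(make_hit(), ts, FilterConfig()) == ("fail", "no-track")
        with pytest.raises(MissingTrackError):
            step1_disorder(make_hit(), ts, FilterConfig(missing_track_policy="strict"))


class TestStep2:
    def test_no_signal_no_tm_passes(self):
        assert step2_accessibility(make_hit(), make_tracks(), FilterConfig())[0] == "pass"

    def test_signalp_positive_without_tm_fails(self):
        ts = make_tracks(intervals=[Interval("signal_peptide", 1, 20)])
        assert step2_accessibility(make_hit(), ts, FilterConfig())[0] == "fail"

    def test_phobius_only_signal_needs_signalp_score_above_floor(self):
        low = make_tracks(signalp_score=0.3, phobius_signal=True)
        assert step2_accessibility(make_hit(), low, FilterConfig())[0] == "pass"  # 0.3 not > 0.3
        high = make_tracks(signalp_score=0.31, phobius_signal=True)
        assert step2_accessibility(make_hit(), high, FilterConfig())[0] == "fail"

    def test_signal_with_tm_kept_iff_span_intracellular(self):
        base = [
            Interval("signal_peptide", 1, 20),
            Interval("transmembrane", 60, 80),
        ]
        inside = make_tracks(intervals=base + [Interval("topology_intracellular", 25, 50)])
        assert step2_accessibility(make_hit(), inside, FilterConfig())[0] == "pass"
        outside = make_tracks(intervals=base + [Interval("topology_extracellular", 25, 50)])
        assert step2_accessibility(make_hit(), outside, FilterConfig())[0] == "fail"

    def test_signal_with_tm_but_no_topology_is_conservative_fail(self):
        ts = make_tracks(
            intervals=[Interval("signal_peptide", 1, 20), Interval("transmembrane", 60, 80)]
        )
        assert step2_accessibility(make_hit(), ts, FilterConfig()) == ("fail", "topology-unknown")


class TestStep3:
    def test_low_scores_pass(self):
        ts = make_tracks(localization={"extracellular": 0.0, "golgi": 0.0})
        assert step3_localization(make_hit(), ts, FilterConfig())[0] == "pass"

    def test_threshold_is_inclusive(self):
        ts = make_tracks(localization={"golgi": 9.0})
        status, reason = step3_localization(make_hit(), ts, FilterConfig())
        assert status == "fail" and "golgi" in reason

    def test_er_rescued_by_tm_and_intracellular_span(self):
        ts = make_tracks(
            localization={"er": 20.0},
            intervals=[
                Interval("transmembrane", 60, 80),
                Interval("topology_intracellular", 20, 50),
            ],
        )
        assert step3_localization(make_hit(), ts, FilterConfig())[0] == "pass"

    def test_absent_localization_passes(self):
        assert step3_localization(make_hit(), make_tracks(), FilterConfig())[0] == "pass"


class TestStep4:
    def test_disjoint_intervals_pass(self):
        ts = make_tracks(intervals=[Interval("pfam_domain", 60, 90)])
        assert step4_structure(make_hit(), ts, FilterConfig())[0] == "pass"

    def test_single_residue_overlap_fails(self):
        ts = make_tracks(intervals=[Interval("pfam_domain", 37, 50)])
        assert step4_structure(make_hit(), ts, FilterConfig())[0] == "fail"

    def test_pfam_other_requires_curation(self):
        ts = make_tracks(intervals=[Interval("pfam_other", 20, 50)])
        assert step4_structure(make_hit(), ts, FilterConfig())[0] == "pass"
        cfg = FilterConfig(curated_pfam_other=frozenset({("P1", 20, 50)}))
        assert step4_structure(make_hit(), ts, cfg)[0] == "fail"

    def test_coil_filter_switch(self):
        ts = make_tracks(intervals=[Interval("coiled_coil", 30, 40)])
        assert step4_structure(make_hit(), ts, FilterConfig())[0] == "fail"
        assert step4_structure(make_hit(), ts, FilterConfig(coil_filter_on=False))[0] == "pass"


class TestCascade:
    def test_empty_input(self):
        survivors, report = run_cascade([], {}, FilterConfig())
        assert survivors == [] and all(n == 0 for n in report.n_in)

    def test_all_steps_disabled_is_identity(self):
        hits = [make_hit()]
        cfg = FilterConfig(steps_enabled=(False, False, False, False))
        survivors, report = run_cascade(hits, {"P1": make_tracks()}, cfg)
        assert survivors == hits
        assert report.n_removed == [0, 0, 0, 0]

    def test_counts_conserve_and_decrease(self):
        anchor = np.full(100, 0.1)
        anchor[25:45] = 0.5
        good = make_tracks(anchor=anchor)
        bad = make_tracks()
        hits = [make_hit(pid="P1"), make_hit(pid="P2")]
        survivors, report = run_cascade(hits, {"P1": good, "P2": bad})
        df = report.to_frame()
        assert (df["in"] == df["removed"] + df["out"]).all()
        assert (df["out"].diff().dropna() <= 0).all()
        assert df["out"].iloc[0] == len(survivors) or df["out"].iloc[-1] == len(survivors)
        assert first_failing_step(hits[1]) == "step1_disorder"
        # removed hits carry NA for later steps
        assert hits[1].filter_status["step4_structure"] == ("NA", "already-removed")


class TestCalibration:
    def _positives(self, anchor_level, disorder_level=0.2):
        anchor = np.full(100, 0.05)
        anchor[25:45] = anchor_level
        disorder = np.full(100, disorder_level)
        return [make_hit()], {"P1": make_tracks(anchor=anchor, disorder=disorder)}

    def test_positives_at_half_need_no_lowering(self):
        hits, tracks = self._positives(0.55)
        assert calibrate_anchor_cutoff(hits, tracks) == (0.5, 0.4, False)

    def test_positives_visible_only_at_point_four(self):
        """Positives detectable only with the lowered cutoff reproduce the
        adopted (0.4, 0.3) operating point."""
        hits, tracks = self._positives(0.42)
        assert calibrate_anchor_cutoff(hits, tracks) == (0.4, 0.3, False)

    def test_unreachable_target_sets_warning(self):
        hits, tracks = self._positives(0.01)
        primary, secondary, warned = calibrate_anchor_cutoff(hits, tracks, target_retention=1.0)
        assert warned and primary == 0.05

    def test_empty_positives_error(self):
        with pytest.raises(ValueError):
            calibrate_anchor_cutoff([], {})
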