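"""Grid-search controller: grid geometry, escalation, scoring, full runs."""

import numpy as np
import pytest

from samhs import (
    ExcitabilityField,
    GridSpec,
    NoiseModel,
    RecruitmentCurve,
    ScalarStimSource,
    SearchConfig,
    SubjectPhantom,
    TraceStimSource,
    TrialRecord,
    build_grid,
    run_chs,
    run_mhs_emulation,
    score_point,
    select_candidates,
)
from samhs.phantom import FDI_MNI_MM
from samhs.search import _Session, escalate, tiebreak
from tests.conftest import make_phantom


def rec(p2p, accepted=True):
    return TrialRecord(p2p=p2p, latency=24.0, accepted=accepted,
                       reasons=frozenset() if accepted else frozenset({"low_amplitude"}))


class TestBuildGrid:
    def test_coarse_grid_geometry(self):
        pts = build_grid(GridSpec(center=FDI_MNI_MM, n_rows=4, n_cols=4, spacing=10.0))
        assert pts.shape == (16, 3)
        assert np.allclose(pts.mean(axis=0), FDI_MNI_MM)
        assert np.ptp(pts[:, 0]) == pytest.approx(30.0)
        assert np.ptp(pts[:, 1]) == pytest.approx(30.0)

    def test_fine_grid_centroid(self):
        center = np.array([1.0, -2.0, 3.0])
        pts = build_grid(GridSpec(center=center, n_rows=3, n_cols=3, spacing=5.0))
        assert pts.shape == (9, 3)
        assert np.allclose(pts.mean(axis=0), center)

    def test_nearest_neighbour_distance_equals_spacing(self):
        # oracle: brute-force pairwise distances
        pts = build_grid(GridSpec(center=np.zeros(3), n_rows=4, n_cols=4, spacing=10.0))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        d[np.eye(len(pts), dtype=bool)] = np.inf
        assert np.allclose(d.min(axis=1), 10.0)

    def test_serpentine_order_minimises_travel(self):
        pts = build_grid(GridSpec(center=np.zeros(3), n_rows=4, n_cols=4, spacing=10.0))
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert np.allclose(steps, 10.0)  # every hop moves one spacing

    def test_rotation_preserves_centroid_and_spacing(self):
        spec = GridSpec(center=np.zeros(3), n_rows=4, n_cols=4, spacing=10.0, rotation=30.0)
        pts = build_grid(spec)
        assert np.allclose(pts.mean(axis=0), 0.0, atol=1e-12)
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert np.allclose(steps, 10.0)


class _FixedSource:
    """Stub stimulator: responds (accepted) only at/above a set intensity."""

    def __init__(self, threshold):
        self.threshold = threshold

    def stimulate(self, position, intensity):
        ok = intensity >= self.threshold
        return rec(500.0 if ok else 0.0, accepted=ok)


def _session(source, config=None, seed=0):
    cfg = config or SearchConfig()
    return _Session(source, np.random.default_rng(seed), cfg)


class TestEscalation:
    def test_never_detected_reaches_ceiling(self):
        s = _session(_FixedSource(threshold=1000))
        intensity, detected = escalate(s, np.zeros(3), 45.0, "escalation")
        assert intensity == 75.0 and not detected

    def test_detected_at_start_no_escalation(self):
        s = _session(_FixedSource(threshold=40))
        intensity, detected = escalate(s, np.zeros(3), 45.0, "escalation")
        assert intensity == 45.0 and detected

    def test_detected_after_one_step(self):
        s = _session(_FixedSource(threshold=50))
        intensity, detected = escalate(s, np.zeros(3), 45.0, "escalation")
        assert intensity == 55.0 and detected


class TestScoring:
    def test_stability_and_mean_over_valid_only(self):
        responses = [rec(600), rec(700), rec(0, accepted=False), rec(650)]
        score = score_point(responses, SearchConfig(), 3)
        assert score.stability == 3
        assert score.mean_p2p == pytest.approx(650.0)
        assert score.point_index == 3

    def test_all_rejected_scores_zero(self):
        score = score_point([rec(0, accepted=False)] * 4, SearchConfig())
        assert score.stability == 0 and score.mean_p2p == 0.0

    def test_stability_outranks_amplitude_in_selection(self):
        # exhaustive over small response sets: a 4/4 point beats a 3/4 point
        # with higher amplitude under the lexicographic rule
        cfg = SearchConfig()
        scores = [
            score_point([rec(400)] * 4, cfg, 0),
            score_point([rec(900)] * 3 + [rec(0, accepted=False)], cfg, 1),
        ]
        assert [c.point_index for c in select_candidates(scores, cfg)] == [0]


class TestSelectCandidates:
    def test_dominant_point_is_singleton(self):
        cfg = SearchConfig()
        scores = [score_point([rec(a)] * 4, cfg, i) for i, a in enumerate([1000, 500, 300])]
        assert [c.point_index for c in select_candidates(scores, cfg)] == [0]

    def test_equal_means_both_returned(self):
        cfg = SearchConfig()
        scores = [score_point([rec(800)] * 4, cfg, i) for i in range(2)]
        assert len(select_candidates(scores, cfg)) == 2

    def test_tolerance_band(self):
        # tol = 0.1, means {1000, 950, 500}, all stable -> first two
        cfg = SearchConfig(candidate_tol=0.10)
        scores = [score_point([rec(a)] * 4, cfg, i) for i, a in enumerate([1000, 950, 500])]
        assert [c.point_index for c in select_candidates(scores, cfg)] == [0, 1]

    def test_fallback_to_max_stability_when_none_stable(self):
        cfg = SearchConfig()
        scores = [
            score_point([rec(500)] * 2 + [rec(0, False)] * 2, cfg, 0),
            score_point([rec(700)] + [rec(0, False)] * 3, cfg, 1),
        ]
        assert [c.point_index for c in select_candidates(scores, cfg)] == [0]


class TestTiebreak:
    def test_single_candidate_unchanged(self):
        cfg = SearchConfig()
        s = _session(_FixedSource(0))
        pts = build_grid(GridSpec(center=np.zeros(3)))
        only = score_point([rec(500)] * 4, cfg, 5)
        winner, intensity = tiebreak(s, [only], pts, 65.0, "coarse")
        assert winner.point_index == 5 and intensity == 65.0

    def test_persistent_tie_hits_floor_then_deterministic_pick(self):
        cfg = SearchConfig()
        s = _session(_FixedSource(0))  # always identical responses -> tie persists
        pts = build_grid(GridSpec(center=np.zeros(3)))
        cands = [score_point([rec(500)] * 4, cfg, i) for i in (2, 7)]
        winner, intensity = tiebreak(s, cands, pts, 45.0, "coarse")
        assert intensity == cfg.intensity_floor
        assert winner.point_index == 2  # lowest visit index on a full tie

    def test_lower_intensity_separates_diverging_points(self):
        # two candidates at different distances from the true hotspot: at
        # reduced intensity only the nearer stays above threshold
        phantom = make_phantom(center_offset=(2.0, 2.0, 0.0), amp_cv=0.0, baseline_rms=0.0,
                               latency_sd=0.0)
        rng = np.random.default_rng(0)
        source = ScalarStimSource(phantom, rng)
        cfg = SearchConfig()
        s = _Session(source, rng, cfg)
        pts = build_grid(GridSpec(center=FDI_MNI_MM, n_rows=4, n_cols=4, spacing=10.0))
        dists = np.linalg.norm(pts - phantom.field.hotspot_center, axis=1)
        near, far = np.argsort(dists)[:2]
        cands = [score_point([rec(500)] * 4, cfg, int(near)),
                 score_point([rec(500)] * 4, cfg, int(far))]
        winner, _ = tiebreak(s, cands, pts, 55.0, "coarse")
        assert winner.point_index == near


class TestRunChs:
    def test_noiseless_hotspot_on_node_recovered_exactly(self):
        phantom = make_phantom(center_offset=(5.0, 5.0, 0.0), amp_cv=0.0, baseline_rms=0.0,
                               latency_sd=0.0)
        result = run_chs(phantom, seed=1)
        assert result.success
        assert np.allclose(result.position, phantom.field.hotspot_center)

    def test_noiseless_off_node_hotspot_within_half_fine_diagonal(self):
        phantom = make_phantom(center_offset=(3.0, -6.5, 0.0), amp_cv=0.0, baseline_rms=0.0,
                               latency_sd=0.0)
        result = run_chs(phantom, seed=2)
        err = np.linalg.norm(result.position - phantom.field.hotspot_center)
        assert result.success and err <= 3.6

    def test_zero_excitability_fails_after_full_escalation(self):
        phantom = SubjectPhantom(
            curve=RecruitmentCurve(a_max=1e-6, i50=50, slope=0.3),
            noise=NoiseModel(amp_cv=0.0, baseline_rms=0.0),
        )
        result = run_chs(phantom, seed=3)
        assert not result.success and result.position is None
        assert max(result.intensity_trail) == 75.0

    def test_determinism_same_seed_same_result(self, default_phantom):
        a = run_chs(default_phantom, seed=42)
        b = run_chs(default_phantom, seed=42)
        assert np.allclose(a.position, b.position)
        assert a.final_intensity == b.final_intensity
        assert a.session_log == b.session_log

    def test_pulse_accounting(self, default_phantom):
        cfg = SearchConfig()
        result = run_chs(default_phantom, cfg, seed=11)
        assert result.pulse_count == len(result.session_log)
        # every pulse belongs to a burst of pulses_per_point at one
        # (stage, point, intensity) combination
        frame = result.log_frame()
        bursts = frame.groupby(["stage", "point_index", "intensity_pct_mso"]).size()
        assert (bursts % cfg.pulses_per_point == 0).all()
        assert result.pulse_count == bursts.sum()

    def test_fine_stage_disabled_stops_at_coarse(self, default_phantom):
        result = run_chs(default_phantom, SearchConfig(fine_stage=False), seed=5)
        assert result.stage == "coarse"
        assert np.allclose(result.position, result.coarse_position)

    def test_position_is_a_grid_point_of_its_stage(self, default_phantom):
        result = run_chs(default_phantom, seed=9)
        fine = build_grid(GridSpec(center=result.coarse_position, n_rows=3, n_cols=3, spacing=5.0))
        assert np.any(np.all(np.isclose(fine, result.position), axis=1))

    def test_trace_and_scalar_sources_agree_on_verdicts(self):
        # the scalar shortcut must reproduce the full EMG chain's accept
        # decisions and amplitudes for matched draws
        phantom = make_phantom(amp_cv=0.0, baseline_rms=0.0, latency_sd=0.0)
        pos = phantom.field.hotspot_center + np.array([4.0, 0, 0])
        for intensity in (40.0, 50.0, 60.0):
            scalar = ScalarStimSource(phantom, np.random.default_rng(0)).stimulate(pos, intensity)
            traced = TraceStimSource(phantom, np.random.default_rng(0)).stimulate(pos, intensity)
            assert scalar.accepted == traced.accepted
            if scalar.p2p > 1.0:
                assert traced.p2p == pytest.approx(scalar.p2p, rel=0.02)


class TestMhsEmulation:
    def test_noiseless_steep_phantom_converges(self):
        phantom = make_phantom(center_offset=(4.0, 3.0, 0.0), amp_cv=0.0, baseline_rms=0.0,
                               latency_sd=0.0)
        result = run_mhs_emulation(phantom, seed=1)
        assert result.success
        assert np.linalg.norm(result.position - phantom.field.hotspot_center) < 20.0

    def test_zero_excitability_phantom_fails(self):
        phantom = SubjectPhantom(
            curve=RecruitmentCurve(a_max=1e-6, i50=50, slope=0.3),
            noise=NoiseModel(amp_cv=0.0, baseline_rms=0.0),
        )
        result = run_mhs_emulation(phantom, seed=2)
        assert not result.success

    def test_localization_error_wider_than_chs(self):
        # direction check on matched phantoms: the grid search should
        # localize better (smaller median error) than the random walk
        rng = np.random.default_rng(77)
        chs_err, mhs_err = [], []
        for k in range(25):
            offset = rng.uniform(-10, 10, 2)
            phantom = make_phantom(center_offset=(*offset, 0.0), amp_cv=0.2)
            truth = phantom.field.hotspot_center
            a = run_chs(phantom, seed=1000 + k)
            b = run_mhs_emulation(phantom, seed=2000 + k)
            if a.success:
                chs_err.append(np.linalg.norm(a.position - truth))
            if b.success:
                mhs_err.append(np.linalg.norm(b.position - truth))
        assert np.median(chs_err) < np.median(mhs_err)
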