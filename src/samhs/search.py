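"""Semi-automated grid search for the motor hotspot.

The controller reproduces the two-stage cobot hotspot search (CHS): a
coarse 4x4 grid with 10 mm spacing seeded on the group-mean FDI coordinate,
intensity escalation from 45% MSO in 10% steps (up to three times, ceiling
75%), four pulses per grid point, stability scoring (a point is "stable"
when at least 3 of 4 pulses yield accepted MEPs), amplitude-based candidate
selection with a 5%-MSO-step tie-break at reduced intensity, and an
optional fine 3x3 / 5 mm grid centred on the coarse winner.  A
pseudo-random manual-search (MHS) emulator is provided as a comparator.

Stimulation is abstracted behind :class:`StimSource`; two back-ends exist:

* :class:`ScalarStimSource` — draws the noisy p2p amplitude directly from
  the phantom and applies the amplitude / pre-activation accept rules.
  Fast; the default for batch simulation.
* :class:`TraceStimSource` — renders the full synthetic EMG epoch, filters
  it and runs the complete QC chain.  Slower, used to validate that the
  scalar shortcut is faithful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from . import emg
from .phantom import FDI_MNI_MM, SubjectPhantom, sample_response, simulate_trial


@dataclass
class GridSpec:
    """Planar rectangular stimulation grid in MNI-like mm coordinates."""

    center: np.ndarray
    n_rows: int = 4
    n_cols: int = 4
    spacing: float = 10.0   # mm
    rotation: float = 0.0   # degrees to the longitudinal fissure (midline)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector (mm)")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if min(self.n_rows, self.n_cols) < 1:
            raise ValueError("grid must have at least one row and column")


@dataclass
class SearchConfig:
    start_intensity: float = 45.0   # % MSO
    escalation_step: float = 10.0   # % MSO
    max_escalations: int = 3
    pulses_per_point: int = 4
    stability_min: int = 3          # accepted MEPs required of pulses_per_point
    tiebreak_step: float = 5.0      # % MSO decrement between tie-break rounds
    intensity_floor: float | None = None  # default: start - 2 * tiebreak_step
    candidate_tol: float = 0.10     # relative amplitude band for co-candidates
    isi: float = 4.0                # s
    jitter: float = 0.10
    fine_stage: bool = True
    lexicographic_stability: bool = True  # stability outranks amplitude

    def __post_init__(self):
        if self.start_intensity + self.max_escalations * self.escalation_step > 100:
            raise ValueError("escalation ceiling exceeds 100% MSO")
        if not (1 <= self.stability_min <= self.pulses_per_point):
            raise ValueError("need 1 <= stability_min <= pulses_per_point")
        if self.intensity_floor is None:
            self.intensity_floor = self.start_intensity - 2 * self.tiebreak_step

    @property
    def ceiling(self) -> float:
        return min(self.start_intensity + self.max_escalations * self.escalation_step, 100.0)


@dataclass
class PointScore:
    point_index: int
    stability: int       # count of accepted MEPs
    mean_p2p: float      # uV over accepted MEPs, 0 when none


@dataclass
class TrialRecord:
    p2p: float              # uV
    latency: float | None   # ms
    accepted: bool
    reasons: frozenset = field(default_factory=frozenset)


@dataclass
class HotspotResult:
    success: bool
    position: np.ndarray | None
    final_intensity: float
    stage: str                   # {"coarse", "fine", "manual"}
    pulse_count: int
    intensity_trail: list
    session_log: list            # one dict per pulse
    coarse_position: np.ndarray | None = None
    message: str = ""

    def log_frame(self):
        import pandas as pd

        return pd.DataFrame(self.session_log)

    def to_dict(self) -> dict:
        return {
            "success": self.success,
            "position_mm": None if self.position is None else [float(v) for v in self.position],
            "final_intensity_pct_mso": self.final_intensity,
            "stage": self.stage,
            "pulse_count": self.pulse_count,
            "intensity_trail": list(self.intensity_trail),
            "coarse_position_mm": None
            if self.coarse_position is None
            else [float(v) for v in self.coarse_position],
            "message": self.message,
        }


# ---------------------------------------------------------------------------
# Stimulation back-ends
# ---------------------------------------------------------------------------

class StimSource(Protocol):
    def stimulate(self, position, intensity: float) -> TrialRecord: ...


class ScalarStimSource:
    """Amplitude-level simulated stimulator (no waveform synthesis)."""

    def __init__(self, phantom: SubjectPhantom, rng: np.random.Generator, min_p2p: float = 50.0):
        self.phantom = phantom
        self.rng = rng
        self.min_p2p = min_p2p

    def stimulate(self, position, intensity: float) -> TrialRecord:
        amp, latency, pre = sample_response(self.phantom, position, intensity, self.rng)
        reasons = set()
        if amp < self.min_p2p:
            reasons.add(emg.LOW_AMPLITUDE)
        if pre:
            reasons.add(emg.PREACTIVATION_NEAR)
        return TrialRecord(
            p2p=amp, latency=latency, accepted=not reasons, reasons=frozenset(reasons)
        )


class TraceStimSource:
    """Full-chain simulated stimulator: synthetic EMG -> band-pass -> QC."""

    def __init__(
        self,
        phantom: SubjectPhantom,
        rng: np.random.Generator,
        profile: emg.QCProfile | None = None,
        filter_spec: emg.FilterSpec | None = None,
        rate: float = 5000.0,
        pre_ms: float = 400.0,
        post_ms: float = 100.0,
    ):
        self.phantom = phantom
        self.rng = rng
        self.profile = profile or emg.QCProfile.muc()
        self.filter_spec = filter_spec or emg.FilterSpec()
        self.rate, self.pre_ms, self.post_ms = rate, pre_ms, post_ms

    def stimulate(self, position, intensity: float) -> TrialRecord:
        trace, _, _, _ = simulate_trial(
            self.phantom, position, intensity, self.rng,
            rate=self.rate, pre_ms=self.pre_ms, post_ms=self.post_ms,
        )
        feats, verdict = emg.qc_trial(emg.bandpass(trace, self.filter_spec), self.profile)
        return TrialRecord(
            p2p=feats.p2p, latency=feats.latency,
            accepted=verdict.accepted, reasons=verdict.reasons,
        )


# ---------------------------------------------------------------------------
# Grid construction
# ---------------------------------------------------------------------------

def build_grid(spec: GridSpec) -> np.ndarray:
    """Grid points (n_rows*n_cols, 3) in deterministic serpentine visit order.

    Columns run along x (medial-lateral), rows along y (posterior-anterior);
    the grid is centred on ``spec.center`` and rotated about the vertical
    axis by ``spec.rotation`` degrees.  Visiting starts at the posterior
    (min-y), min-x corner and alternates direction row by row, minimising
    travel between consecutive points.
    """
    xs = (np.arange(spec.n_cols) - (spec.n_cols - 1) / 2.0) * spec.spacing
    ys = (np.arange(spec.n_rows) - (spec.n_rows - 1) / 2.0) * spec.spacing
    pts = []
    for r, y in enumerate(ys):
        row = [(x, y) for x in xs]
        if r % 2 == 1:
            row.reverse()
        pts.extend(row)
    pts = np.array(pts, dtype=float)
    if spec.rotation:
        a = np.deg2rad(spec.rotation)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        pts = pts @ rot.T
    out = np.zeros((len(pts), 3))
    out[:, :2] = pts
    return out + spec.center


# ---------------------------------------------------------------------------
# Controller primitives
# ---------------------------------------------------------------------------

class _Session:
    """Bookkeeping shared by one search run: clock, log, pulse counter."""

    def __init__(self, source: StimSource, rng: np.random.Generator, config: SearchConfig):
        self.source = source
        self.rng = rng
        self.config = config
        self.t = 0.0
        self.log: list[dict] = []
        self.intensity_trail: list[float] = []

    def pulse(self, position, intensity: float, stage: str, point_index: int) -> TrialRecord:
        rec = self.source.stimulate(position, intensity)
        self.log.append(
            {
                "time_s": round(self.t, 3),
                "stage": stage,
                "point_index": point_index,
                "x_mm": float(position[0]),
                "y_mm": float(position[1]),
                "z_mm": float(position[2]),
                "intensity_pct_mso": float(intensity),
                "p2p_uV": rec.p2p,
                "latency_ms": rec.latency,
                "accepted": rec.accepted,
                "reasons": ";".join(sorted(rec.reasons)),
            }
        )
        self.t += float(
            self.rng.uniform(
                self.config.isi * (1 - self.config.jitter),
                self.config.isi * (1 + self.config.jitter),
            )
        )
        return rec

    def burst(self, position, intensity: float, stage: str, point_index: int) -> list[TrialRecord]:
        return [
            self.pulse(position, intensity, stage, point_index)
            for _ in range(self.config.pulses_per_point)
        ]

    def note_intensity(self, intensity: float) -> None:
        if not self.intensity_trail or self.intensity_trail[-1] != intensity:
            self.intensity_trail.append(float(intensity))


def escalate(
    session: _Session, position, start_intensity: float, stage: str,
    ceiling: float | None = None,
) -> tuple[float, bool]:
    """Raise intensity in fixed steps while no MEP is detected.

    Delivers one burst per level; detection (any accepted MEP) halts the
    escalation.  Returns (final intensity, detected flag); the final
    intensity never exceeds ``ceiling`` (default
    min(start + max_escalations*step, 100)).
    """
    cfg = session.config
    intensity = start_intensity
    if ceiling is None:
        ceiling = min(start_intensity + cfg.max_escalations * cfg.escalation_step, 100.0)
    while True:
        session.note_intensity(intensity)
        recs = session.burst(position, intensity, stage, point_index=-1)
        if any(r.accepted for r in recs):
            return intensity, True
        if intensity >= ceiling:
            return intensity, False
        intensity = min(intensity + cfg.escalation_step, ceiling)


def score_point(responses: list[TrialRecord], config: SearchConfig, point_index: int = 0) -> PointScore:
    """Stability = accepted-MEP count; mean p2p over accepted trials only."""
    valid = [r.p2p for r in responses if r.accepted]
    mean = float(np.mean(valid)) if valid else 0.0
    return PointScore(point_index=point_index, stability=len(valid), mean_p2p=mean)


def select_candidates(scores: list[PointScore], config: SearchConfig) -> list[PointScore]:
    """Stable points whose mean amplitude is within ``candidate_tol`` of the best.

    When no point reaches ``stability_min`` the fallback is the set of
    points sharing the maximal stability.
    """
    stable = [s for s in scores if s.stability >= config.stability_min]
    if not stable:
        top = max(s.stability for s in scores)
        return [s for s in scores if s.stability == top]
    if config.lexicographic_stability:
        top_stab = max(s.stability for s in stable)
        pool = [s for s in stable if s.stability == top_stab]
    else:
        pool = stable
    best = max(s.mean_p2p for s in pool)
    return [s for s in pool if s.mean_p2p >= (1.0 - config.candidate_tol) * best]


def _final_pick(cands: list[PointScore]) -> PointScore:
    # deterministic ladder: stability desc, mean p2p desc, visit index asc
    return max(cands, key=lambda s: (s.stability, s.mean_p2p, -s.point_index))


def tiebreak(
    session: _Session,
    candidates: list[PointScore],
    points: np.ndarray,
    intensity: float,
    stage: str,
) -> tuple[PointScore, float]:
    """Discriminate tied candidates by re-testing them at reduced intensity.

    Intensity drops by ``tiebreak_step`` each round; each surviving
    candidate is re-stimulated with a full burst and the selection rule is
    re-applied to the fresh scores.  Stops on a unique winner or at
    ``intensity_floor`` (then: highest stability, highest amplitude, lowest
    visit index).  A round in which every candidate loses all MEPs carries
    no discriminative information — the round is rolled back and the
    previous candidates stand.
    """
    cfg = session.config
    while len(candidates) > 1 and intensity > cfg.intensity_floor:
        lowered = max(intensity - cfg.tiebreak_step, cfg.intensity_floor)
        session.note_intensity(lowered)
        rescored = []
        for c in candidates:
            recs = session.burst(points[c.point_index], lowered, stage, c.point_index)
            rescored.append(score_point(recs, cfg, c.point_index))
        if max(s.stability for s in rescored) == 0:
            break  # sub-threshold for everyone: previous round stands
        intensity = lowered
        candidates = select_candidates(rescored, cfg)
    return _final_pick(candidates), intensity


def _sweep_stage(
    session: _Session, points: np.ndarray, intensity: float, stage: str, ceiling: float
) -> tuple[PointScore, float, list[PointScore]]:
    """Sweep all grid points; escalate and re-sweep while no stable point.

    The workflow's "no MEPs detected -> raise intensity" rule applies to
    the grid sweep as well: if no point reaches ``stability_min`` and the
    escalation ceiling has not been reached, the whole grid is re-visited
    one step higher.  Only at the ceiling is a sub-criterion best point
    (or failure, when nothing responds at all) accepted.
    """
    cfg = session.config
    while True:
        scores = []
        session.note_intensity(intensity)
        for i, p in enumerate(points):
            recs = session.burst(p, intensity, stage, i)
            scores.append(score_point(recs, cfg, i))
        if max(s.stability for s in scores) >= cfg.stability_min or intensity >= ceiling:
            break
        intensity = min(intensity + cfg.escalation_step, ceiling)
    if max(s.stability for s in scores) == 0:
        # nothing responded even at the ceiling: report as-is, no tie-break
        return PointScore(point_index=0, stability=0, mean_p2p=0.0), intensity, scores
    candidates = select_candidates(scores, cfg)
    winner, intensity = tiebreak(session, candidates, points, intensity, stage)
    return winner, intensity, scores


def run_chs(
    phantom: SubjectPhantom,
    config: SearchConfig | None = None,
    seed: int = 0,
    seed_point: np.ndarray | None = None,
    stim_source: StimSource | None = None,
    fine_spacing: float = 5.0,
    fine_shape: tuple[int, int] = (3, 3),
) -> HotspotResult:
    """Run the full two-stage cobot hotspot search against a phantom.

    Seed-point escalation, coarse 4x4 sweep, candidate selection and
    tie-break, then (unless disabled) a fine 3x3 grid centred on the coarse
    winner, starting from the intensity in force at the end of the coarse
    stage and re-entering the escalation sub-procedure if that intensity no
    longer elicits MEPs.  If no MEP is obtained anywhere at the escalation
    ceiling the run aborts with an explicit failure result.
    """
    config = config or SearchConfig()
    rng = np.random.default_rng(seed)
    source = stim_source or ScalarStimSource(phantom, rng)
    session = _Session(source, rng, config)
    center = FDI_MNI_MM.copy() if seed_point is None else np.asarray(seed_point, float)

    coarse_grid = build_grid(GridSpec(center=center, n_rows=4, n_cols=4, spacing=10.0))
    intensity, _detected = escalate(
        session, center, config.start_intensity, "escalation", ceiling=config.ceiling
    )
    winner, intensity, scores = _sweep_stage(
        session, coarse_grid, intensity, "coarse", config.ceiling
    )
    if winner.stability == 0:
        return HotspotResult(
            success=False, position=None, final_intensity=intensity, stage="coarse",
            pulse_count=len(session.log), intensity_trail=session.intensity_trail,
            session_log=session.log,
            message="no MEP at any coarse grid point at the escalation ceiling",
        )
    coarse_pos = coarse_grid[winner.point_index]

    if not config.fine_stage:
        return HotspotResult(
            success=True, position=coarse_pos, final_intensity=intensity, stage="coarse",
            pulse_count=len(session.log), intensity_trail=session.intensity_trail,
            session_log=session.log, coarse_position=coarse_pos,
        )

    fine_grid = build_grid(
        GridSpec(center=coarse_pos, n_rows=fine_shape[0], n_cols=fine_shape[1], spacing=fine_spacing)
    )
    # same procedure as the coarse stage, starting from the current intensity
    intensity, _ = escalate(
        session, coarse_pos, intensity, "fine-escalation", ceiling=config.ceiling
    )
    fwinner, intensity, _ = _sweep_stage(session, fine_grid, intensity, "fine", config.ceiling)
    if fwinner.stability == 0:
        return HotspotResult(
            success=False, position=None, final_intensity=intensity, stage="fine",
            pulse_count=len(session.log), intensity_trail=session.intensity_trail,
            session_log=session.log, coarse_position=coarse_pos,
            message="no MEP at any fine grid point at the escalation ceiling",
        )
    fine_pos = fine_grid[fwinner.point_index]
    stage = "coarse" if np.allclose(fine_pos, coarse_pos) else "fine"
    return HotspotResult(
        success=True, position=fine_pos, final_intensity=intensity, stage=stage,
        pulse_count=len(session.log), intensity_trail=session.intensity_trail,
        session_log=session.log, coarse_position=coarse_pos,
    )


def run_mhs_emulation(
    phantom: SubjectPhantom,
    config: SearchConfig | None = None,
    seed: int = 0,
    seed_point: np.ndarray | None = None,
    stim_source: StimSource | None = None,
    step_mm: float = 7.0,
    start_scatter_mm: float = 10.0,
    max_points: int = 40,
    patience: int = 6,
) -> HotspotResult:
    """Pseudo-random manual hotspot search (comparator strategy).

    Amplitude-guided stochastic hill-climb: start near the seed coordinate,
    propose Gaussian in-plane steps (~``step_mm``), keep a proposal when its
    (stability, mean amplitude) score beats the incumbent, and stop once a
    stable point has seen ``patience`` consecutive non-improvements.
    Exceeding ``max_points`` without a stable point is a failure.
    """
    config = config or SearchConfig()
    rng = np.random.default_rng(seed)
    source = stim_source or ScalarStimSource(phantom, rng)
    session = _Session(source, rng, config)
    center = FDI_MNI_MM.copy() if seed_point is None else np.asarray(seed_point, float)

    theta = rng.uniform(0, 2 * np.pi)
    r = start_scatter_mm * np.sqrt(rng.uniform())
    start = center + np.array([r * np.cos(theta), r * np.sin(theta), 0.0])

    intensity, _ = escalate(session, start, config.start_intensity, "escalation")
    best_pos = start
    best = score_point(session.burst(start, intensity, "manual", 0), config, 0)
    stale = 0
    for k in range(1, max_points):
        if best.stability >= config.stability_min and stale >= patience:
            break
        prop = best_pos + np.array([rng.normal(0, step_mm), rng.normal(0, step_mm), 0.0])
        sc = score_point(session.burst(prop, intensity, "manual", k), config, k)
        if (sc.stability, sc.mean_p2p) > (best.stability, best.mean_p2p):
            best, best_pos, stale = sc, prop, 0
        else:
            stale += 1
    if best.stability < config.stability_min:
        return HotspotResult(
            success=False, position=None, final_intensity=intensity, stage="manual",
            pulse_count=len(session.log), intensity_trail=session.intensity_trail,
            session_log=session.log, message="no stable point within the iteration cap",
        )
    return HotspotResult(
        success=True, position=best_pos, final_intensity=intensity, stage="manual",
        pulse_count=len(session.log), intensity_trail=session.intensity_trail,
        session_log=session.log,
    )
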