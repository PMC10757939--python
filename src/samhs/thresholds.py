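"""Resting motor threshold (RMT) and SI1mV estimation, plus MEP batches.

RMT follows the relative-frequency definition: the lowest stimulator
intensity (% MSO, integer) at which at least 5 of 10 pulses elicit accepted
MEPs of >= 50 uV peak-to-peak.  The staircase steps down by 2% MSO while
the criterion holds and up by 1% once it fails, terminating on the lowest
passing level whose next-lower level failed.

SI1mV hunts the intensity whose mean MEP amplitude lies in the 0.85-1.15 mV
band around 1 mV: probe blocks of five pulses, stepping 2% MSO while more
than 0.3 mV from target and 1% otherwise.

Batches (e.g., 20 MEPs at 120% RMT, 25 at SI1mV) are acquired through the
same stimulation source and summarised as mean +/- SD of amplitude and
latency over accepted trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .phantom import SubjectPhantom
from .search import ScalarStimSource, StimSource, TrialRecord


@dataclass
class ThresholdConfig:
    pulses_per_level: int = 10
    valid_min: int = 5            # "at least 50% of trials"
    step_down: int = 2            # % MSO while criterion holds
    step_up: int = 1              # % MSO after it fails
    level_cap: int = 60           # max distinct level tests before aborting
    si_block: int = 5             # pulses per SI1mV probe block
    si_band_mv: tuple[float, float] = (0.85, 1.15)
    si_target_mv: float = 1.0
    si_step_small: int = 1        # % MSO near the target
    si_step_big: int = 2          # % MSO when > si_big_gap_mv away
    si_big_gap_mv: float = 0.3
    si_refine_tol_mv: float = 0.05  # accept without neighbour probe when this close
    si_refine_pulses: int = 20    # pulses per intensity in the confirm/refine phase
    si_cap: int = 60              # max probe blocks


@dataclass
class RmtResult:
    rmt: int | None               # % MSO, None on failure
    trials_per_level: dict = field(default_factory=dict)  # level -> (valid, total)
    success: bool = True
    message: str = ""


@dataclass
class Si1mvResult:
    intensity: int | None         # % MSO, None on failure
    mean_p2p_mv: float | None     # mean of the accepting probe block
    band: tuple[float, float] = (0.85, 1.15)
    trail: list = field(default_factory=list)  # (intensity, block mean mV)
    success: bool = True
    message: str = ""


def _as_source(stim_source, seed) -> StimSource:
    if isinstance(stim_source, SubjectPhantom):
        return ScalarStimSource(stim_source, np.random.default_rng(seed))
    return stim_source


def _clamp(level: float) -> int:
    return int(min(max(round(level), 1), 100))


def intensity_120(rmt: float) -> int:
    """120% of RMT, rounded half-up to the stimulator's integer grid, capped at 100."""
    return int(min(math.floor(1.2 * rmt + 0.5), 100))


def estimate_rmt(
    stim_source,
    hotspot,
    start_intensity: float,
    config: ThresholdConfig | None = None,
    seed: int = 0,
) -> RmtResult:
    """Relative-frequency staircase for the resting motor threshold.

    ``stim_source`` may be a :class:`StimSource` or a bare phantom (then a
    scalar source seeded with ``seed`` is created).  The criterion is
    unreachable when even 100% MSO fails -> explicit failure result.
    """
    cfg = config or ThresholdConfig()
    source = _as_source(stim_source, seed)
    counts: dict[int, tuple[int, int]] = {}

    def passes(level: int) -> bool:
        recs = [source.stimulate(hotspot, level) for _ in range(cfg.pulses_per_level)]
        valid = sum(r.accepted for r in recs)
        counts[level] = (valid, cfg.pulses_per_level)
        return valid >= cfg.valid_min

    level = _clamp(start_intensity)
    tests = 0
    # ascend first if the starting level already fails
    while not passes(level):
        tests += 1
        if level >= 100:
            return RmtResult(None, counts, success=False,
                             message="criterion unreachable at 100% MSO")
        if tests > cfg.level_cap:
            return RmtResult(None, counts, success=False, message="level cap exceeded")
        level = _clamp(level + cfg.step_up)
    # descend while passing
    while level > 1:
        tests += 1
        if tests > cfg.level_cap:
            return RmtResult(None, counts, success=False, message="level cap exceeded")
        nxt = _clamp(level - cfg.step_down)
        if passes(nxt):
            level = nxt
            continue
        # nxt failed; close the gap upward until a level passes again
        probe = nxt
        while True:
            probe = _clamp(probe + cfg.step_up)
            if probe >= level:
                # the level just below `level` failed -> level is the RMT
                return RmtResult(level, counts)
            tests += 1
            if tests > cfg.level_cap:
                return RmtResult(None, counts, success=False, message="level cap exceeded")
            if passes(probe):
                level = probe
                break
        # re-enter descent from the new, lower passing level
        if counts.get(_clamp(level - cfg.step_up), (cfg.valid_min, 0))[0] < cfg.valid_min:
            return RmtResult(level, counts)
    return RmtResult(level, counts)


def find_si1mv(
    stim_source,
    hotspot,
    rmt: float,
    config: ThresholdConfig | None = None,
    seed: int = 0,
) -> Si1mvResult:
    """Iterative hunt for the ~1 mV intensity, anchored at 120% of RMT.

    Probe blocks of ``si_block`` pulses; the block mean (accepted trials)
    steers the intensity toward the 1 mV target until it lands in the
    0.85-1.15 mV acceptance band.  Because the hunt approaches from below,
    stopping on a single noisy block would be biased toward intensities
    whose true mean sits under the band (the first lucky block wins); an
    in-band block is therefore confirmed with a second block at the same
    intensity.  Because the integer %-MSO grid is coarse relative to the
    band, an in-band intensity can still sit at a band edge; unless the
    confirmed mean is already within ``si_refine_tol_mv`` of the target,
    the neighbouring intensity toward the target is probed once and the
    intensity with the confirmed mean closest to 1 mV is returned.  A
    plateau below the band at 100% MSO is an explicit failure.
    """
    cfg = config or ThresholdConfig()
    source = _as_source(stim_source, seed)
    intensity = intensity_120(rmt)
    trail = []
    lo, hi = cfg.si_band_mv

    def confirmed_mean(level: int) -> float:
        recs = [source.stimulate(hotspot, level) for _ in range(cfg.si_refine_pulses)]
        valid = [r.p2p for r in recs if r.accepted]
        m = (float(np.mean(valid)) if valid else 0.0) / 1000.0
        trail.append((level, m))
        return m

    for _ in range(cfg.si_cap):
        recs = [source.stimulate(hotspot, intensity) for _ in range(cfg.si_block)]
        valid = [r.p2p for r in recs if r.accepted]
        mean_mv = (float(np.mean(valid)) if valid else 0.0) / 1000.0
        trail.append((intensity, mean_mv))
        if lo <= mean_mv <= hi:
            mean_mv = confirmed_mean(intensity)
            if lo <= mean_mv <= hi:
                if abs(mean_mv - cfg.si_target_mv) > cfg.si_refine_tol_mv:
                    neighbour = _clamp(
                        intensity + (1 if mean_mv < cfg.si_target_mv else -1)
                    )
                    if neighbour != intensity:
                        m2 = confirmed_mean(neighbour)
                        if lo <= m2 <= hi and abs(m2 - cfg.si_target_mv) < abs(
                            mean_mv - cfg.si_target_mv
                        ):
                            intensity, mean_mv = neighbour, m2
                return Si1mvResult(intensity, mean_mv, band=cfg.si_band_mv, trail=trail)
        step = cfg.si_step_big if abs(mean_mv - cfg.si_target_mv) > cfg.si_big_gap_mv else cfg.si_step_small
        if mean_mv < lo:
            if intensity >= 100:
                return Si1mvResult(None, mean_mv, band=cfg.si_band_mv, trail=trail,
                                   success=False,
                                   message="amplitude plateau below the 1 mV band")
            intensity = _clamp(intensity + step)
        else:
            if intensity <= 1:
                return Si1mvResult(None, mean_mv, band=cfg.si_band_mv, trail=trail,
                                   success=False, message="band unreachable above 1% MSO")
            intensity = _clamp(intensity - step)
    return Si1mvResult(None, trail[-1][1] if trail else None, band=cfg.si_band_mv,
                       trail=trail, success=False, message="probe-block cap exceeded")


def acquire_batch(
    stim_source,
    hotspot,
    intensity: float,
    n: int,
    seed: int = 0,
) -> list[TrialRecord]:
    """Acquire ``n`` QC-processed trials at a fixed intensity."""
    if n < 1:
        raise ValueError("n must be >= 1")
    source = _as_source(stim_source, seed)
    return [source.stimulate(hotspot, intensity) for _ in range(n)]


def summarize_batch(trials: list[TrialRecord]) -> dict:
    """Mean +/- SD of p2p (uV) and latency (ms) over accepted trials."""
    amps = np.array([t.p2p for t in trials if t.accepted], dtype=float)
    lats = np.array(
        [t.latency for t in trials if t.accepted and t.latency is not None], dtype=float
    )
    def _ms(x):
        if x.size == 0:
            return (float("nan"), float("nan"))
        return (float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0)
    amp_mean, amp_sd = _ms(amps)
    lat_mean, lat_sd = _ms(lats)
    return {
        "n_total": len(trials),
        "n_accepted": int(sum(t.accepted for t in trials)),
        "p2p_mean_uV": amp_mean,
        "p2p_sd_uV": amp_sd,
        "latency_mean_ms": lat_mean,
        "latency_sd_ms": lat_sd,
    }
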