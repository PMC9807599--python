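"""Closed-loop 1D cursor-control task simulator.

Trial structure: 2 s intertrial interval, 2 s target presentation, then up
to 6 s of cursor control with feedback.  The cursor starts at mid-screen and
moves with velocity proportional to the normalized control value, updated
every 40 ms.  A trial ends as a *hit* (correct target zone reached), a
*miss* (the invisible target on the opposite side reached), or *invalid*
(neither zone within 6 s).  Performance is percent valid correct (PVC):
hits / (hits + misses), invalid trials excluded.

Sign conventions: rightward / upward is the positive screen direction.  LR
control is C4 - C3 so right-hand imagery (ERD at C3) drives the cursor
right.  UD up-velocity is proportional to minus the normalized C4 + C3
value: both-hands imagery suppresses mu bilaterally, pushing the sum below
its running mean and the cursor up, while voluntary rest moves it down.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .chain import ChainConfig, Normalizer, raw_control_value, sliding_band_amplitudes
from .errors import InvalidArgumentError, SimulationError, UndefinedPVCError
from .montage import BCI_CHANNELS, MontageLayout
from .synth import BOTH_MI, LEFT_MI, REST, RIGHT_MI, SubjectModel, SubjectStream

# target label -> (MI condition during the trial, positive-direction flag)
_TARGET_CONDITION = {
    ("LR", "left"): (LEFT_MI, False),
    ("LR", "right"): (RIGHT_MI, True),
    ("UD", "up"): (BOTH_MI, True),
    ("UD", "down"): (REST, False),
}


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and timing of the 1D cursor task."""

    task: str = "LR"
    iti_s: float = 2.0
    presentation_s: float = 2.0
    max_control_s: float = 6.0
    update_interval_s: float = 0.040
    gain: float = 0.25            # screen-widths per second per unit control
    target_halfwidth: float = 0.1  # screen fraction; zones [0, hw] and [1-hw, 1]
    ud_up_sign: float = -1.0       # up-velocity = ud_up_sign * gain * control

    def __post_init__(self):
        if self.task not in ("LR", "UD"):
            raise InvalidArgumentError("task must be 'LR' or 'UD'")
        for name in ("iti_s", "presentation_s", "max_control_s",
                     "update_interval_s", "gain"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if not (0.0 < self.target_halfwidth < 0.5):
            raise InvalidArgumentError("target_halfwidth must be in (0, 0.5)")
        if abs(self.ud_up_sign) != 1.0:
            raise InvalidArgumentError("ud_up_sign must be +1 or -1")

    @property
    def max_ticks(self) -> int:
        return int(round(self.max_control_s / self.update_interval_s))

    def targets(self) -> tuple[str, str]:
        return ("left", "right") if self.task == "LR" else ("down", "up")

    def directional(self, control: float) -> float:
        """Signed velocity component toward the positive (right/up) side."""
        return control if self.task == "LR" else self.ud_up_sign * control


@dataclass
class TrialRecord:
    """One cursor-control trial."""

    task: str
    target: str
    outcome: str               # hit | miss | invalid
    duration: float            # seconds of cursor control
    trajectory: np.ndarray     # per-tick positions, starting from 0.5
    controls: np.ndarray       # normalized control values consumed


@dataclass
class RunResult:
    """One run of cursor-control trials with its PVC."""

    task: str
    trials: list[TrialRecord]
    seed: int = 0
    practice: bool = False

    def counts(self) -> dict[str, int]:
        c = {"hit": 0, "miss": 0, "invalid": 0}
        for t in self.trials:
            c[t.outcome] += 1
        return c

    @property
    def pvc(self) -> float:
        return percent_valid_correct(self.trials)


@dataclass(frozen=True)
class SessionDesign:
    """Run structure of one session (part 1, intervention, part 2)."""

    runs_per_task: int = 3
    trials_per_run: int = 25
    tasks: tuple[str, ...] = ("LR", "UD")
    fs: float = 1000.0
    include_practice: bool = False
    intervention: str = "meditation"

    def __post_init__(self):
        if self.runs_per_task < 1 or self.trials_per_run < 1:
            raise InvalidArgumentError("runs and trials must be >= 1")
        if any(t not in ("LR", "UD") for t in self.tasks):
            raise InvalidArgumentError("tasks must be 'LR' / 'UD'")


@dataclass
class SessionResult:
    """Part-1 and part-2 runs of one session."""

    part1: list[RunResult]
    part2: list[RunResult]
    intervention: str
    design: SessionDesign

    @property
    def runs(self) -> list[RunResult]:
        return self.part1 + self.part2

    def _trials(self, part: int, task: str) -> list[TrialRecord]:
        runs = self.part1 if part == 1 else self.part2
        return [t for r in runs if r.task == task and not r.practice
                for t in r.trials]

    def pooled_pvc(self, part: int, task: str) -> float:
        """PVC pooled over all analysed trials of one part and task."""
        return percent_valid_correct(self._trials(part, task))

    def mean_pvc(self, part: int, task: str) -> float:
        """Mean of per-run PVCs (runs with no valid trial are skipped)."""
        runs = [r for r in (self.part1 if part == 1 else self.part2)
                if r.task == task and not r.practice]
        vals = []
        for r in runs:
            try:
                vals.append(r.pvc)
            except UndefinedPVCError:
                continue
        if not vals:
            raise UndefinedPVCError(f"no valid trials in part {part} {task}")
        return float(np.mean(vals))


# ---------------------------------------------------------------------------
# trial-level primitives


def percent_valid_correct(trials: Sequence[TrialRecord]) -> float:
    """PVC (%) = 100 x hits / (hits + misses); invalid trials excluded."""
    if not trials:
        raise InvalidArgumentError("empty trial list")
    hits = sum(1 for t in trials if t.outcome == "hit")
    misses = sum(1 for t in trials if t.outcome == "miss")
    if hits + misses == 0:
        raise UndefinedPVCError("no decided (hit/miss) trials")
    return 100.0 * hits / (hits + misses)


def simulate_trial(control_source: Iterable[float], target: str,
                   config: TaskConfig, rng=None) -> TrialRecord:
    """Drive one trial from a stream of normalized control values.

    The cursor starts at 0.5; each tick it moves ``gain * control * dt``
    along the signed axis.  It stops the moment either target zone is
    entered; running out of the 6 s budget (or of control values) ends the
    trial as invalid.
    """
    if target not in config.targets():
        raise InvalidArgumentError(
            f"target {target!r} invalid for task {config.task}")
    positive_target = target in ("right", "up")
    dt = config.update_interval_s
    hi = 1.0 - config.target_halfwidth
    lo = config.target_halfwidth
    pos = 0.5
    traj = [pos]
    used = []
    outcome = "invalid"
    duration = config.max_control_s
    for k, c in enumerate(control_source):
        if k >= config.max_ticks:
            break
        c = float(c)
        if not math.isfinite(c):
            raise SimulationError("non-finite control value")
        used.append(c)
        pos = pos + config.gain * config.directional(c) * dt
        pos = 0.0 if pos < 0.0 else (1.0 if pos > 1.0 else pos)
        traj.append(pos)
        if pos >= hi or pos <= lo:
            reached_positive = pos >= hi
            outcome = "hit" if reached_positive == positive_target else "miss"
            duration = (k + 1) * dt
            break
    return TrialRecord(config.task, target, outcome, duration,
                       np.array(traj), np.array(used))


def balanced_targets(task_config: TaskConfig, n_trials: int,
                     rng: np.random.Generator,
                     majority_positive: bool | None = None) -> list[str]:
    """Balanced pseudo-random target sequence (13/12-style split)."""
    neg, pos = task_config.targets()
    n_pos = n_trials // 2
    if n_trials % 2:
        if majority_positive is None:
            majority_positive = bool(rng.integers(2))
        n_pos += int(majority_positive)
    seq = [pos] * n_pos + [neg] * (n_trials - n_pos)
    rng.shuffle(seq)
    return seq


# ---------------------------------------------------------------------------
# closed-loop run engine


class _RunEngine:
    """Streams subject EEG through the online chain, tick by tick.

    The Laplacian-filtered C3/C4 histories are appended block-wise; AR band
    amplitudes for all due ticks are computed in one vectorized batch, then
    the normalizer consumes them sequentially (it is the only stateful
    per-tick element).  Ticks fire every 40 ms from the first full AR
    window, through intertrial intervals as well, exactly as an online
    system's normalizer would see them.
    """

    def __init__(self, subject: SubjectModel, montage: MontageLayout,
                 chain: ChainConfig, fs: float, task: str, stream_seed: int):
        self.chain = chain
        self.task = task
        self.fs = fs
        labels = chain.required_channels()
        self.montage = montage.subset(labels) if set(labels) != set(montage.labels) \
            else montage
        self.stream = SubjectStream(subject, self.montage, fs, seed=stream_seed)
        self.w3 = chain.lap_c3.weights(self.montage.labels)
        self.w4 = chain.lap_c4.weights(self.montage.labels)
        self.win = chain.ar.window_samples(fs)
        self.hop = max(1, int(round(chain.update_interval_s * fs)))
        self.lap3 = np.zeros(0)
        self.lap4 = np.zeros(0)
        self.normalizer = Normalizer(chain.buffer_ticks)
        self._next_end = self.win - 1

    def emit(self, condition: str, duration_s: float) -> int:
        """Generate a block; returns its first sample index."""
        n = int(round(duration_s * self.fs))
        block = self.stream.emit(condition, n)
        start = len(self.lap3)
        self.lap3 = np.concatenate([self.lap3, self.w3 @ block])
        self.lap4 = np.concatenate([self.lap4, self.w4 @ block])
        return start

    def process_due_ticks(self) -> list[tuple[int, float]]:
        """Normalize all ticks whose window is now complete."""
        n = len(self.lap3)
        ends = np.arange(self._next_end, n, self.hop)
        if len(ends) == 0:
            return []
        self._next_end = int(ends[-1]) + self.hop
        a3 = sliding_band_amplitudes(self.lap3, self.fs, self.chain.ar, ends)
        a4 = sliding_band_amplitudes(self.lap4, self.fs, self.chain.ar, ends)
        out = []
        for e, x3, x4 in zip(ends, a3, a4):
            raw = raw_control_value(x3, x4, self.task)
            out.append((int(e), self.normalizer.update(raw)))
        return out


def simulate_run(subject: SubjectModel, task: str = "LR",
                 config: TaskConfig | None = None, seed: int = 0,
                 chain: ChainConfig | None = None,
                 montage: MontageLayout | None = None,
                 trials_per_run: int = 25, fs: float = 1000.0,
                 majority_positive: bool | None = None,
                 practice: bool = False) -> RunResult:
    """Simulate one closed-loop run of cursor-control trials.

    The subject emits EEG per trial condition, the online chain produces
    normalized control values every 40 ms, and the cursor integrates them.
    Deterministic given ``seed`` (targets and EEG share one seed sequence).
    """
    config = config or TaskConfig(task=task)
    if config.task != task:
        config = replace(config, task=task)
    chain = chain or ChainConfig()
    montage = montage or MontageLayout.standard(BCI_CHANNELS)
    ss = np.random.SeedSequence(seed)
    s_targets, s_stream = ss.spawn(2)
    rng = np.random.default_rng(s_targets)
    stream_seed = int(s_stream.generate_state(1)[0] & 0x7FFFFFFF)
    engine = _RunEngine(subject, montage, chain, fs, task, stream_seed)
    targets = balanced_targets(config, trials_per_run, rng, majority_positive)
    fb_samples = int(round(config.max_control_s * fs))
    trials = []
    for target in targets:
        condition, _ = _TARGET_CONDITION[(task, target)]
        engine.emit(REST, config.iti_s)
        engine.emit(condition, config.presentation_s)
        fb_start = engine.emit(condition, config.max_control_s)
        ticks = engine.process_due_ticks()
        fb_controls = [z for e, z in ticks
                       if fb_start <= e < fb_start + fb_samples]
        trials.append(simulate_trial(fb_controls, target, config))
    return RunResult(task, trials, seed=seed, practice=practice)


def simulate_session(subject: SubjectModel, design: SessionDesign | None = None,
                     seed: int = 0, chain: ChainConfig | None = None,
                     montage: MontageLayout | None = None) -> SessionResult:
    """Simulate part 1, apply the intervention effect, then part 2.

    The intervention adds ``subject.intervention_effect`` to both ERD depths
    (clipped to [0, 1]) for part-2 runs.  Each run gets its own child seed
    and a freshly adapting normalizer.
    """
    design = design or SessionDesign()
    montage = montage or MontageLayout.standard(BCI_CHANNELS)
    ss = np.random.SeedSequence(seed)
    n_runs = len(design.tasks) * (design.runs_per_task + int(design.include_practice))
    seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(2 * n_runs)]
    seed_iter = iter(seeds)

    def part(subj: SubjectModel) -> list[RunResult]:
        runs = []
        for i, t in enumerate(design.tasks):
            for j in range(design.runs_per_task + int(design.include_practice)):
                runs.append(simulate_run(
                    subj, task=t, seed=next(seed_iter), chain=chain,
                    montage=montage, trials_per_run=design.trials_per_run,
                    fs=design.fs, majority_positive=bool((i + j) % 2),
                    practice=design.include_practice and j == 0))
        return runs

    part1 = part(subject)
    part2 = part(subject.after_intervention())
    return SessionResult(part1, part2, design.intervention, design)
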