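"""Block-design layout of the two-condition creative/simple experiment.

One record is 13 minutes sampled at 0.33 Hz: 3 min pre-task rest, 7 min
task, 3 min post-task rest, segmented into thirteen 60 s periods. A short
baseline window (10 samples, ~33 s) precedes the first pre-task rest and
anchors the change-rate normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PERIOD_LABELS", "CONDITIONS", "ExperimentDesign"]

PERIOD_LABELS: tuple[str, ...] = (
    "pretask_rest1",
    "pretask_rest2",
    "pretask_rest3",
    "t1",
    "t2",
    "t3",
    "t4",
    "t5",
    "t6",
    "t7",
    "posttask_rest1",
    "posttask_rest2",
    "posttask_rest3",
)

CONDITIONS: tuple[str, ...] = ("simple", "creative")


@dataclass(frozen=True)
class ExperimentDesign:
    periods: tuple[str, ...] = PERIOD_LABELS
    conditions: tuple[str, ...] = CONDITIONS
    period_duration_s: float = 60.0
    sampling_rate_hz: float = 0.33
    baseline_samples: int = 10

    def __post_init__(self) -> None:
        if self.period_duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("period duration and sampling rate must be positive")
        if self.baseline_samples < 1:
            raise ValueError("baseline_samples must be >= 1")

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    @property
    def dt(self) -> float:
        """Sampling interval, s."""
        return 1.0 / self.sampling_rate_hz

    @property
    def task_duration_s(self) -> float:
        return self.n_periods * self.period_duration_s

    @property
    def n_record_samples(self) -> int:
        """Samples in the 13-period record proper (excluding baseline)."""
        return int(np.ceil(self.task_duration_s * self.sampling_rate_hz - 1e-9))

    @property
    def n_samples(self) -> int:
        """Total samples including the pre-record baseline window."""
        return self.baseline_samples + self.n_record_samples

    def sample_times(self) -> np.ndarray:
        """Times (s) of every sample; t=0 is the start of pretask rest1, the
        baseline samples sit at negative times."""
        idx = np.arange(self.n_samples) - self.baseline_samples
        return idx * self.dt

    def period_windows(self, offset: float = 0.0) -> list[tuple[float, float]]:
        """Half-open [start, end) windows of the 13 periods in record time."""
        return [
            (offset + p * self.period_duration_s, offset + (p + 1) * self.period_duration_s)
            for p in range(self.n_periods)
        ]

    def period_index(self, t: np.ndarray) -> np.ndarray:
        """Period index of each time (half-open windows; -1 outside)."""
        t = np.asarray(t, dtype=float)
        idx = np.floor(t / self.period_duration_s).astype(int)
        idx[(t < 0) | (idx >= self.n_periods)] = -1
        return idx
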