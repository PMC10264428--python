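"""Vigilance-state vocabulary and hypnogram container.

The hypnogram is the atomic bookkeeping object of the pipeline: one label
per fixed-length scoring epoch, plus the epoch length and the clock hour at
which the recording starts (used for circadian binning).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = ["VigilanceState", "Hypnogram", "STATE_ALIASES"]


class VigilanceState(str, Enum):
    """The three vigilance states scored on 4-s epochs."""

    WAKE = "WAKE"
    NREM = "NREM"
    REM = "REM"

    def __str__(self) -> str:  # round-trip via str()
        return self.value


#: Accepted spellings when parsing external label files.
STATE_ALIASES = {
    "WAKE": VigilanceState.WAKE,
    "W": VigilanceState.WAKE,
    "WAKEFULNESS": VigilanceState.WAKE,
    "NREM": VigilanceState.NREM,
    "NREMS": VigilanceState.NREM,
    "N": VigilanceState.NREM,
    "SWS": VigilanceState.NREM,
    "REM": VigilanceState.REM,
    "REMS": VigilanceState.REM,
    "R": VigilanceState.REM,
}

# Fixed integer codes for vectorised operations.
STATE_ORDER = (VigilanceState.WAKE, VigilanceState.NREM, VigilanceState.REM)
STATE_TO_CODE = {s: i for i, s in enumerate(STATE_ORDER)}
CODE_TO_STATE = {i: s for i, s in enumerate(STATE_ORDER)}


def parse_state(token: str) -> VigilanceState:
    """Parse a state label, accepting the documented aliases."""
    try:
        return STATE_ALIASES[str(token).strip().upper()]
    except KeyError:
        raise ValueError(f"unknown vigilance state label: {token!r}") from None


@dataclass
class Hypnogram:
    """Per-epoch vigilance labels with epoch length and clock anchoring.

    Parameters
    ----------
    labels : sequence of VigilanceState
        One label per non-overlapping scoring epoch.
    epoch_seconds : float
        Epoch duration in seconds (default 4).
    start_hour_of_day : float
        Clock hour at which epoch 0 begins (default 9.0, i.e. 09:00).
    """

    labels: np.ndarray
    epoch_seconds: float = 4.0
    start_hour_of_day: float = 9.0
    _codes: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        lab = list(self.labels)
        if len(lab) == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        for x in lab:
            if not isinstance(x, VigilanceState):
                raise ValueError(f"invalid hypnogram label: {x!r}")
        arr = np.empty(len(lab), dtype=object)
        arr[:] = lab
        object.__setattr__(self, "labels", arr)
        object.__setattr__(
            self, "_codes", np.array([STATE_TO_CODE[s] for s in lab], dtype=np.int8)
        )

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            self.epoch_seconds == other.epoch_seconds
            and self.start_hour_of_day == other.start_hour_of_day
            and np.array_equal(self.codes, other.codes)
        )

    @property
    def codes(self) -> np.ndarray:
        """Integer codes (WAKE=0, NREM=1, REM=2), aligned with labels."""
        return self._codes

    @classmethod
    def from_codes(
        cls, codes, epoch_seconds: float = 4.0, start_hour_of_day: float = 9.0
    ) -> "Hypnogram":
        labels = [CODE_TO_STATE[int(c)] for c in np.asarray(codes)]
        return cls(labels, epoch_seconds, start_hour_of_day)

    def hour_of_day(self) -> np.ndarray:
        """Clock hour (mod 24) at the start of each epoch."""
        t = np.arange(len(self)) * self.epoch_seconds / 3600.0
        return (self.start_hour_of_day + t) % 24.0

    def fractions(self) -> dict:
        """Empirical fraction of epochs in each state."""
        n = len(self)
        return {s: float(np.mean(self.codes == STATE_TO_CODE[s])) for s in STATE_ORDER}

    def duration_seconds(self) -> float:
        return len(self) * self.epoch_seconds
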