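"""Multichannel signal container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Recording"]

#: role strings understood by the pipeline
ROLE_EEG = "eeg"
ROLE_EMG = "emg"

DEFAULT_ROLES = {
    "eeg_v1": ROLE_EEG,
    "eeg_s1": ROLE_EEG,
    "eeg_m1": ROLE_EEG,
    "emg": ROLE_EMG,
}


@dataclass
class Recording:
    """Named signal channels sharing one sampling rate.

    channels maps channel name -> 1-D float array (physical units, µV);
    channel_roles maps channel name -> "eeg" | "emg".
    """

    channels: dict
    sampling_rate_hz: float
    channel_roles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not self.channels:
            raise ValueError("recording must contain at least one channel")
        lengths = {name: len(sig) for name, sig in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        self.channels = {
            name: np.asarray(sig, dtype=np.float64) for name, sig in self.channels.items()
        }
        if not self.channel_roles:
            self.channel_roles = {
                name: DEFAULT_ROLES.get(name, ROLE_EEG) for name in self.channels
            }
        missing = set(self.channel_roles) - set(self.channels)
        if missing:
            raise ValueError(f"channel_roles refer to unknown channels: {sorted(missing)}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def eeg_channels(self) -> list:
        return [n for n, r in self.channel_roles.items() if r == ROLE_EEG]

    def emg_channel(self) -> str:
        """Name of the EMG channel; raises if the recording has none."""
        emg = [n for n, r in self.channel_roles.items() if r == ROLE_EMG]
        if not emg:
            raise ValueError(
                "recording has no channel with role 'emg' "
                f"(available roles: {self.channel_roles})"
            )
        return emg[0]

    def copy(self) -> "Recording":
        return Recording(
            {n: s.copy() for n, s in self.channels.items()},
            self.sampling_rate_hz,
            dict(self.channel_roles),
        )
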