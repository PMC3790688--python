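"""Continuous-recording container and the trigger-code table."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage

#: bijective trigger code <-> meaning table (written into marker files)
EVENT_CODES = {
    1: "S1_rivalry_changed",
    2: "S1_rivalry_same",
    3: "S1_rivalry_noresponse",
    4: "S1_fusion_change_correct",
    5: "S1_fusion_same_correct",
    6: "S1_fusion_incorrect",
    7: "S2_onset",
    8: "mask_onset",
}
EVENT_LABELS = {v: k for k, v in EVENT_CODES.items()}

S1_CODES = (1, 2, 3, 4, 5, 6)


def s1_event_label(condition: str, outcome, response_correct) -> str:
    """Trigger label for an S1 onset given the trial's behavioral outcome."""
    if condition == "rivalry":
        if outcome == "changed":
            return "S1_rivalry_changed"
        if outcome == "same":
            return "S1_rivalry_same"
        return "S1_rivalry_noresponse"
    if response_correct is True:
        return (
            "S1_fusion_change_correct"
            if outcome == "changed"
            else "S1_fusion_same_correct"
        )
    return "S1_fusion_incorrect"


@dataclass
class RawRecording:
    """Channels x samples voltage matrix (µV) with events and montage."""

    data: np.ndarray
    fs: float
    montage: Montage
    events: list[tuple[int, int, str]] = field(default_factory=list)
    reference_state: str = "recording_reference"
    unusable_edge: int = 0  # samples at each end invalidated by filtering

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"data has {self.data.shape[0]} channels, montage has "
                f"{len(self.montage)}"
            )
        last = -1
        for sample, code, label in self.events:
            if not 0 <= sample < self.n_samples:
                raise ValueError(f"event sample {sample} outside record")
            if sample < last:
                raise ValueError("event samples must be non-decreasing")
            last = sample

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "RawRecording":
        return RawRecording(
            self.data.copy(),
            self.fs,
            self.montage,
            list(self.events),
            self.reference_state,
            self.unusable_edge,
        )

    def events_with_label(self, prefix: str) -> list[tuple[int, int, str]]:
        return [e for e in self.events if e[2].startswith(prefix)]
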