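"""Electrode montage: names, roles, unit-sphere positions, and row labels.

The recording setup emulated here is a 66-electrode active cap in a
modified 10-20 layout: 59 informative scalp channels (including FCz,
which starts life as the recording reference and becomes an ordinary
scalp channel after off-line re-referencing), 4 EOG channels, 2 earlobe
channels used for the linked-earlobe reference, and a ground that is
never recorded.  Scalp rows run front to back: F, FC, C, CP, P, PO, O;
channels whose name matches none of those prefixes (AF, T, TP sites)
carry the row label "other".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("scalp", "eog", "earlobe", "ground", "reference")

#: row prefixes, longest-match-first so that FC3 -> FC and not F
_ROW_PREFIXES = ("FC", "CP", "PO", "F", "C", "P", "O")

# 59 informative scalp channels (modified 10-20, FCz included post-reref)
SCALP_59 = (
    "Fp1 Fp2 AF7 AF3 AF4 AF8 "
    "F7 F3 F1 Fz F2 F4 F8 "
    "FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 "
    "T7 C5 C3 C1 Cz C2 C4 C6 T8 "
    "TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 "
    "P7 P5 P3 P1 Pz P2 P4 P6 P8 "
    "PO9 PO7 PO3 POz PO4 PO8 PO10 "
    "O1 Oz O2"
).split()

EOG_4 = ["HEOGL", "HEOGR", "VEOGU", "VEOGD"]
EARLOBES = ["A1", "A2"]

# EOG sites are not 10-05 positions; head frame is x=right, y=front, z=up.
_EOG_POS = {
    "HEOGL": (-0.62, 0.72, -0.31),
    "HEOGR": (0.62, 0.72, -0.31),
    "VEOGU": (0.30, 0.86, 0.18),
    "VEOGD": (0.30, 0.88, -0.36),
}


def row_label(name: str) -> str:
    """Scalp row for a channel name by longest-prefix match.

    >>> row_label("POz"), row_label("FC3"), row_label("T7")
    ('PO', 'FC', 'other')
    """
    for prefix in _ROW_PREFIXES:
        if name.startswith(prefix):
            return prefix
    return "other"


@dataclass
class Montage:
    """Channel names, roles, and unit-sphere positions."""

    names: list[str]
    roles: list[str]
    positions: np.ndarray  # (n_channels, 3), unit vectors
    row_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate channel names: {dupes}")
        if self.positions.shape != (len(self.names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            warnings.warn("non-unit electrode positions; normalizing", stacklevel=2)
            self.positions = self.positions / norms[:, None]
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        if not self.row_labels:
            self.row_labels = [
                row_label(n) if r == "scalp" else "other"
                for n, r in zip(self.names, self.roles)
            ]

    # -- lookups -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    def channels_with_role(self, role: str) -> list[str]:
        return [n for n, r in zip(self.names, self.roles) if r == role]

    @property
    def scalp_names(self) -> list[str]:
        return self.channels_with_role("scalp")

    @property
    def eog_names(self) -> list[str]:
        return self.channels_with_role("eog")

    @property
    def earlobe_names(self) -> list[str]:
        return self.channels_with_role("earlobe")

    def channels_in_rows(self, rows) -> list[str]:
        rows = set(rows)
        return [
            n
            for n, r, lbl in zip(self.names, self.roles, self.row_labels)
            if r == "scalp" and lbl in rows
        ]

    def geodesic(self, name_a: str, name_b: str) -> float:
        """Great-circle distance (radians) between two electrodes."""
        a = self.positions[self.index(name_a)]
        b = self.positions[self.index(name_b)]
        return float(np.arccos(np.clip(a @ b, -1.0, 1.0)))

    def geodesic_to_point(self, point: np.ndarray) -> np.ndarray:
        """Great-circle distance from every channel to a unit vector."""
        point = np.asarray(point, dtype=float)
        point = point / np.linalg.norm(point)
        return np.arccos(np.clip(self.positions @ point, -1.0, 1.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "role": self.roles,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "row_label": self.row_labels,
            }
        )

    def subset(self, names) -> "Montage":
        idx = self.indices(names)
        return Montage(
            [self.names[i] for i in idx],
            [self.roles[i] for i in idx],
            self.positions[idx],
        )


def default_montage() -> Montage:
    """The 65-channel fixture: 59 scalp + 4 EOG + 2 earlobes.

    Scalp and earlobe coordinates come from the standard 10-05 layout
    bundled with :mod:`mne`, re-centred on a best-fit sphere and
    normalized to unit radius; EOG sites use fixed periocular vectors.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    pos = std.get_positions()["ch_pos"]

    wanted = SCALP_59 + EARLOBES
    pts = np.array([pos[n] for n in wanted], dtype=float)
    center = _fit_sphere_center(pts)
    unit = pts - center
    unit /= np.linalg.norm(unit, axis=1)[:, None]

    names = SCALP_59 + EOG_4 + EARLOBES
    roles = ["scalp"] * len(SCALP_59) + ["eog"] * 4 + ["earlobe"] * 2
    eog = np.array([_EOG_POS[n] for n in EOG_4], dtype=float)
    eog /= np.linalg.norm(eog, axis=1)[:, None]
    positions = np.vstack([unit[: len(SCALP_59)], eog, unit[len(SCALP_59):]])
    return Montage(names, roles, positions)


def _fit_sphere_center(pts: np.ndarray) -> np.ndarray:
    # linear least squares: |p - c|^2 = r^2  =>  2 p.c + (r^2 - |c|^2) = |p|^2
    a = np.hstack([2 * pts, np.ones((len(pts), 1))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol[:3]


def load_montage(path) -> Montage:
    """Read a montage TSV with columns name, role, x, y, z."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "role", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"montage file missing columns: {sorted(missing)}")
    return Montage(
        df["name"].astype(str).tolist(),
        df["role"].astype(str).tolist(),
        df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def save_montage(montage: Montage, path) -> None:
    montage.to_frame().to_csv(path, sep="\t", index=False)
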