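"""File formats: BrainVision triplets, montage TSV, events JSON, epochs HDF5.

The BrainVision dialect is fixed to multiplexed IEEE float32
little-endian with µV resolution 1.0, so write/read round-trips are
exact to float32 precision and marker positions are exact.  Channel
roles, positions, and the trigger-code table are carried in comment
lines of the header so a triplet is self-describing; standard readers
ignore comments.
"""

from __future__ import annotations

import io
import json
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .montage import Montage
from .preprocessing import EpochSet
from .recording import EVENT_CODES, RawRecording


class BrainVisionError(ValueError):
    """Inconsistent or unreadable BrainVision triplet."""


def write_brainvision(raw: RawRecording, basename: str | Path) -> tuple[Path, Path, Path]:
    """Write <basename>.vhdr/.vmrk/.eeg; returns the three paths."""
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    stem = base.name

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by rivalerp",
        "; Trigger code table:",
    ]
    for code, meaning in EVENT_CODES.items():
        lines.append(f";   S{code:>3} = {meaning}")
    lines.append(f"; ReferenceState: {raw.reference_state}")
    for name, role in zip(raw.montage.names, raw.montage.roles):
        lines.append(f"; ChannelRole: {name}={role}")
    for name, pos in zip(raw.montage.names, raw.montage.positions):
        lines.append(
            f"; ChannelPosition: {name}={pos[0]:.6f},{pos[1]:.6f},{pos[2]:.6f}"
        )
    lines += [
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={raw.n_channels}",
        f"SamplingInterval={1e6 / raw.fs:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(raw.montage.names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (sample, code, _label) in enumerate(raw.events, start=2):
        # marker positions are 1-based in data points
        mlines.append(f"Mk{k}=Stimulus,S{code:>3},{sample + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    raw.data.T.astype("<f4").tofile(eeg)  # multiplexed: sample-major
    return vhdr, vmrk, eeg


_KV = re.compile(r"^([^;=\[][^=]*)=(.*)$")


def _parse_ini(text: str):
    """Key-value pairs and comments; unknown keys preserved-but-ignored."""
    pairs, comments = {}, []
    for line in text.splitlines():
        line = line.rstrip("\r\n")
        if line.startswith(";"):
            comments.append(line[1:].strip())
            continue
        m = _KV.match(line)
        if m:
            pairs[m.group(1).strip()] = m.group(2).strip()
    return pairs, comments


def read_brainvision(basename: str | Path) -> RawRecording:
    """Read a triplet written by :func:`write_brainvision`."""
    base = Path(basename)
    vhdr = base.with_suffix(".vhdr")
    if not vhdr.exists():
        raise FileNotFoundError(vhdr)
    pairs, comments = _parse_ini(vhdr.read_text(encoding="utf-8"))

    if pairs.get("DataFormat", "BINARY") != "BINARY":
        raise BrainVisionError(f"unsupported DataFormat {pairs.get('DataFormat')}")
    if pairs.get("BinaryFormat") != "IEEE_FLOAT_32":
        raise BrainVisionError(f"unsupported BinaryFormat {pairs.get('BinaryFormat')}")
    if pairs.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise BrainVisionError("only MULTIPLEXED orientation is supported")
    try:
        n_channels = int(pairs["NumberOfChannels"])
        fs = 1e6 / float(pairs["SamplingInterval"])
    except KeyError as err:
        raise BrainVisionError(f"header missing {err}") from err

    names = []
    for i in range(1, n_channels + 1):
        try:
            names.append(pairs[f"Ch{i}"].split(",")[0])
        except KeyError:
            raise BrainVisionError(f"header lists {n_channels} channels but Ch{i} "
                                   "is missing") from None

    roles = {}
    positions = {}
    reference_state = "recording_reference"
    for c in comments:
        if c.startswith("ChannelRole:"):
            name, role = c.split(":", 1)[1].strip().split("=")
            roles[name] = role
        elif c.startswith("ChannelPosition:"):
            name, xyz = c.split(":", 1)[1].strip().split("=")
            positions[name] = [float(v) for v in xyz.split(",")]
        elif c.startswith("ReferenceState:"):
            reference_state = c.split(":", 1)[1].strip()
    if set(names) <= set(roles) and set(names) <= set(positions):
        montage = Montage(
            names,
            [roles[n] for n in names],
            np.array([positions[n] for n in names]),
        )
    else:
        # triplet from another writer: fall back to name-based roles
        from .montage import default_montage

        default = default_montage()
        if set(names) <= set(default.names):
            montage = default.subset(names)
        else:
            raise BrainVisionError(
                "header carries no channel roles/positions and channel names "
                "do not match the default montage"
            )

    eeg = base.with_suffix(".eeg")
    if not eeg.exists():
        raise FileNotFoundError(eeg)
    payload = eeg.stat().st_size
    if payload % (4 * n_channels):
        raise BrainVisionError(
            f"binary size {payload} bytes is not a whole number of "
            f"{n_channels}-channel float32 frames"
        )
    data = np.fromfile(eeg, dtype="<f4").reshape(-1, n_channels).T.astype(float)

    vmrk = base.with_suffix(".vmrk")
    events = []
    if vmrk.exists():
        mpairs, _ = _parse_ini(vmrk.read_text(encoding="utf-8"))
        for key in sorted(
            (k for k in mpairs if k.startswith("Mk")), key=lambda k: int(k[2:])
        ):
            fields = mpairs[key].split(",")
            if fields[0] != "Stimulus":
                continue
            code = int(fields[1].lstrip("S").strip())
            sample = int(fields[2]) - 1
            events.append((sample, code, EVENT_CODES.get(code, f"S{code}")))
    return RawRecording(data, fs, montage, events, reference_state)


# ---------------------------------------------------------------------------
# sidecars


def write_events_json(raw: RawRecording, path: str | Path) -> None:
    payload = {
        "code_table": EVENT_CODES,
        "fs": raw.fs,
        "events": [
            {"sample": int(s), "code": int(c), "label": l} for s, c, l in raw.events
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Persist an epoch set (data, times, mask, metadata) as HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("times_ms", data=epochs.times_ms)
        f.create_dataset("keep_mask", data=epochs.keep_mask)
        f.attrs["fs"] = epochs.fs
        f.attrs["channels"] = json.dumps(epochs.channels)
        f.attrs["channel_roles"] = json.dumps(epochs.channel_roles)
        f.attrs["metadata"] = epochs.metadata.to_json(orient="table")
        f.attrs["rejection_report"] = json.dumps(epochs.rejection_report)


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        metadata = pd.read_json(io.StringIO(f.attrs["metadata"]), orient="table")
        return EpochSet(
            f["data"][()],
            f["times_ms"][()],
            json.loads(f.attrs["channels"]),
            json.loads(f.attrs["channel_roles"]),
            float(f.attrs["fs"]),
            metadata,
            f["keep_mask"][()],
            json.loads(f.attrs["rejection_report"]),
        )
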