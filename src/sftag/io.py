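"""File interchange: video frame directories, EEG containers, event tables."""

from __future__ import annotations

import pathlib
import re

import numpy as np
import pandas as pd

from .eeg import EEGRecording
from .geometry import BandGeometry
from .tagging import VideoClip

__all__ = [
    "read_frame_dir",
    "write_frame_dir",
    "read_recording_h5",
    "write_recording_h5",
    "read_recording_bdf",
    "read_events_csv",
]


def write_frame_dir(clip: VideoClip, path) -> None:
    """Write a clip as numbered PNG frames.

    Achromatic clips (all RGB channels equal) are stored as 16-bit
    grayscale PNG — the lossless path used for verification; color clips
    fall back to 8-bit RGB (PNG imposes 8 bits per color channel here).
    """
    import imageio.v3 as iio

    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    gray = np.allclose(clip.frames[..., 0], clip.frames[..., 1]) and np.allclose(
        clip.frames[..., 0], clip.frames[..., 2]
    )
    for i, frame in enumerate(clip.frames):
        if gray:
            img = (frame[..., 0] * 65535 + 0.5).astype(np.uint16)
        else:
            img = (frame * 255 + 0.5).astype(np.uint8)
        iio.imwrite(path / f"frame_{i:05d}.png", img)
    (path / "clip.json").write_text(
        pd.Series(
            {"fps": clip.fps, "pixels_per_degree": clip.geometry.pixels_per_degree}
        ).to_json()
    )


def read_frame_dir(path, fps: float | None = None, pixels_per_degree: float | None = None) -> VideoClip:
    import imageio.v3 as iio

    path = pathlib.Path(path)
    files = sorted(p for p in path.iterdir() if re.fullmatch(r"frame_\d+\.png", p.name))
    if not files:
        raise FileNotFoundError(f"no frame_NNNNN.png files in {path}")
    meta_file = path / "clip.json"
    meta = pd.read_json(meta_file, typ="series") if meta_file.exists() else pd.Series(dtype=float)
    fps = fps or float(meta.get("fps", 30.0))
    ppd = pixels_per_degree or meta.get("pixels_per_degree")
    frames = []
    for f in files:
        img = iio.imread(f)
        img = img.astype(float) / np.iinfo(img.dtype).max
        if img.ndim == 2:
            img = np.repeat(img[..., None], 3, axis=-1)
        frames.append(img[..., :3])
    geom = BandGeometry(pixels_per_degree=float(ppd)) if ppd else BandGeometry()
    return VideoClip(frames=np.stack(frames), fps=fps, geometry=geom)


def write_recording_h5(rec: EEGRecording, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.data)
        f.attrs["sfreq"] = rec.sfreq
        f.create_dataset(
            "channel_names", data=np.array(rec.ch_names, dtype=h5py.string_dtype())
        )
        g = f.create_group("events")
        for col in ("onset_sample", "video_id", "condition"):
            g.create_dataset(col, data=rec.events[col].to_numpy())


def read_recording_h5(path, events: pd.DataFrame | None = None) -> EEGRecording:
    import h5py

    with h5py.File(path, "r") as f:
        data = f["samples"][()]
        sfreq = float(f.attrs["sfreq"])
        ch_names = tuple(s.decode() if isinstance(s, bytes) else s for s in f["channel_names"][()])
        if events is None and "events" in f:
            events = pd.DataFrame(
                {c: f["events"][c][()] for c in ("onset_sample", "video_id", "condition")}
            )
    if events is None:
        events = pd.DataFrame(columns=["onset_sample", "video_id", "condition"])
    return EEGRecording(data=data, sfreq=sfreq, ch_names=ch_names, events=events)


def read_recording_bdf(path, events: pd.DataFrame) -> EEGRecording:
    """Load a BioSemi BDF / EDF(+) file (via MNE) into the plain container."""
    import mne

    path = str(path)
    if path.lower().endswith(".bdf"):
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(
        data=data, sfreq=float(raw.info["sfreq"]), ch_names=tuple(raw.ch_names), events=events
    )


def read_events_csv(path) -> pd.DataFrame:
    ev = pd.read_csv(path)
    need = {"onset_sample", "video_id", "condition"}
    missing = need - set(ev.columns)
    if missing:
        raise ValueError(f"events CSV missing columns: {sorted(missing)}")
    return ev
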