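"""WAV / CSV / JSON reading and writing.

Onset lists are plain 1-D numpy arrays of milliseconds, sorted ascending.
WAV files are written as 32-bit float to avoid quantization; PCM 16/24/32
and float inputs are accepted and rescaled to [-1, 1]. Multi-channel
recordings are averaged down to mono, because the pipeline is defined on a
single free-field mono recording.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .config import InputError, Waveform

__all__ = ["read_wav", "write_wav", "read_onsets", "write_onsets"]

_PCM_SCALE = {np.dtype(np.int16): 2 ** 15, np.dtype(np.int32): 2 ** 31,
              np.dtype(np.uint8): None}


def read_wav(path: str | Path) -> Waveform:
    """Read a WAV file as a mono float waveform scaled to [-1, 1]."""
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise InputError(f"WAV file {path} contains no samples")
    data = np.atleast_2d(data.T).T  # (n, channels)
    if data.dtype == np.uint8:  # 8-bit PCM is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:
        samples = data.astype(np.float64)
    mono = samples.mean(axis=1)
    return Waveform(mono, int(rate))


def write_wav(path: str | Path, wave: Waveform) -> None:
    """Write a waveform as 32-bit float WAV."""
    wavfile.write(Path(path), wave.sample_rate,
                  wave.samples.astype(np.float32))


def read_onsets(path: str | Path) -> np.ndarray:
    """Read an onset list (ms) from CSV (one value per row) or JSON array.

    Values are returned sorted ascending; unsorted input triggers a warning.
    An empty file yields an empty list — downstream stages decide whether
    that is acceptable.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputError(f"cannot read onset file {path}: {exc}") from exc
    stripped = text.strip()
    if not stripped:
        return np.array([], dtype=np.float64)
    if path.suffix.lower() == ".json" or stripped.startswith("["):
        try:
            values = json.loads(stripped)
        except json.JSONDecodeError as exc:
            raise InputError(f"cannot parse JSON onsets in {path}: {exc}") from exc
        values = np.asarray(values, dtype=np.float64)
    else:
        rows = [r.strip() for r in stripped.splitlines() if r.strip()]
        parsed = []
        for i, row in enumerate(rows):
            cell = row.split(",")[0].strip()
            try:
                parsed.append(float(cell))
            except ValueError:
                if i == 0:  # optional header row
                    continue
                raise InputError(
                    f"non-numeric onset at row {i} of {path}: {row!r}"
                ) from None
        values = np.asarray(parsed, dtype=np.float64)
    if values.size and np.any(np.diff(values) < 0):
        warnings.warn(f"onsets in {path} were not sorted; sorting", stacklevel=2)
        values = np.sort(values)
    return values


def write_onsets(path: str | Path, onsets: np.ndarray) -> None:
    """Write an onset list (ms) as a JSON array or single-column CSV."""
    path = Path(path)
    onsets = np.asarray(onsets, dtype=np.float64)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps([float(x) for x in onsets]) + "\n")
    else:
        path.write_text("\n".join(f"{x:.6f}" for x in onsets) + "\n")
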