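"""WAV input/output and segmentation into sequences and analysis frames.

Recordings are handled as mono clips with amplitudes in [-1, 1].  Labeled
intervals are tiled into consecutive, non-overlapping 100 ms *sequences*
(the classification unit), and each sequence is further cut into
2048-sample *analysis frames* (the feature-extraction unit) with 50 %
overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .errors import FormatError, ValidationError
from .labels import validate_label

#: Duration of one classification sequence in seconds.
SEQUENCE_SECONDS = 0.1
#: Default analysis frame length in samples (~46 ms at 44.1 kHz).
FRAME_LENGTH = 2048
#: Default hop between frame starts (50 % overlap).
FRAME_HOP = 1024


@dataclass
class AudioClip:
    """A mono audio recording with amplitudes normalised to [-1, 1]."""

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""
    day_tag: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("AudioClip requires a non-empty 1-D sample array")
        if self.sample_rate <= 0:
            raise ValidationError(f"sample_rate must be positive, got {self.sample_rate}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def sequence_length(self) -> int:
        """Samples per 100 ms sequence at this clip's rate (4410 at 44.1 kHz)."""
        return round(SEQUENCE_SECONDS * self.sample_rate)


@dataclass
class SequenceWindow:
    """One 100 ms window of a clip, carrying its behaviour label."""

    clip: AudioClip
    start_sample: int
    length_samples: int
    label: str | None = None
    sequence_id: str = ""

    def __post_init__(self) -> None:
        if self.start_sample < 0:
            raise ValidationError("start_sample must be non-negative")
        if self.start_sample + self.length_samples > self.clip.samples.size:
            raise ValidationError("sequence window extends past end of clip")
        if self.label is not None:
            validate_label(self.label)
        if not self.sequence_id:
            self.sequence_id = f"{self.clip.source_id}:{self.start_sample}"

    @property
    def samples(self) -> np.ndarray:
        return self.clip.samples[self.start_sample : self.start_sample + self.length_samples]


@dataclass
class Frame:
    """One fixed-length analysis frame cut from a sequence window."""

    samples: np.ndarray
    parent_sequence: str
    frame_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)


def read_wav(path: str | Path, source_id: str | None = None, day_tag: str = "") -> AudioClip:
    """Read a PCM/float RIFF WAV file into an :class:`AudioClip`.

    Integer samples are rescaled to [-1, 1]; multichannel audio is averaged
    to mono (the recordings this models came from a single shotgun
    microphone).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises bare ValueError for bad RIFF
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype.kind == "i":
        scale = float(2 ** (8 * data.dtype.itemsize - 1))
        samples = data.astype(np.float64) / scale
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    np.clip(samples, -1.0, 1.0, out=samples)
    return AudioClip(
        samples=samples,
        sample_rate=int(rate),
        source_id=source_id if source_id is not None else path.stem,
        day_tag=day_tag,
    )


def write_wav(path: str | Path, clip: AudioClip, bit_depth: int = 16) -> None:
    """Write a clip as PCM16 or float32 WAV."""
    if bit_depth == 16:
        data = np.round(np.clip(clip.samples, -1.0, 1.0) * 32767.0).astype(np.int16)
    elif bit_depth == 32:
        data = clip.samples.astype(np.float32)
    else:
        raise FormatError(f"unsupported bit depth {bit_depth}; use 16 or 32")
    wavfile.write(str(path), clip.sample_rate, data)


def read_label_table(path: str | Path) -> list[tuple[float, float, str]]:
    """Read a tab-separated label table: ``start_s  end_s  label`` per line.

    Lines starting with ``#`` and blank lines are ignored.
    """
    intervals: list[tuple[float, float, str]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(
                f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
            )
        start_s, end_s, label = float(parts[0]), float(parts[1]), parts[2].strip()
        intervals.append((start_s, end_s, validate_label(label)))
    return intervals


def write_label_table(path: str | Path, intervals: list[tuple[float, float, str]]) -> None:
    lines = ["# start_s\tend_s\tlabel"]
    lines += [f"{s:.6f}\t{e:.6f}\t{lab}" for s, e, lab in intervals]
    Path(path).write_text("\n".join(lines) + "\n")


def segment_sequences(
    clip: AudioClip,
    label_table: list[tuple[float, float, str]],
    rms_floor: float | None = None,
) -> list[SequenceWindow]:
    """Tile each labeled interval with consecutive 100 ms windows.

    A trailing remainder shorter than 100 ms is dropped.  Optionally,
    windows whose RMS amplitude falls below ``rms_floor`` are excluded
    (modelling the removal of low-fidelity recording stretches; off by
    default because no universal threshold exists).

    Raises :class:`ValidationError` on overlapping intervals or intervals
    outside the clip.
    """
    intervals = sorted(label_table, key=lambda t: t[0])
    for (s1, e1, _), (s2, _, _) in zip(intervals, intervals[1:]):
        if s2 < e1 - 1e-12:
            raise ValidationError(
                f"label intervals overlap: [{s1}, {e1}) and starting {s2}"
            )
    seq_len = clip.sequence_length()
    windows: list[SequenceWindow] = []
    for start_s, end_s, label in intervals:
        if end_s <= start_s:
            raise ValidationError(f"empty label interval [{start_s}, {end_s})")
        if end_s > clip.duration_s + 1e-9:
            raise ValidationError(
                f"label interval [{start_s}, {end_s}) exceeds clip duration {clip.duration_s:.3f} s"
            )
        start = round(start_s * clip.sample_rate)
        end = min(round(end_s * clip.sample_rate), clip.samples.size)
        n_windows = (end - start) // seq_len
        for i in range(n_windows):
            w = SequenceWindow(
                clip=clip,
                start_sample=start + i * seq_len,
                length_samples=seq_len,
                label=label,
            )
            if rms_floor is not None:
                rms = float(np.sqrt(np.mean(w.samples**2)))
                if rms < rms_floor:
                    continue
            windows.append(w)
    return windows


def frame_sequence(
    window: SequenceWindow, frame_len: int = FRAME_LENGTH, hop: int = FRAME_HOP
) -> list[Frame]:
    """Cut a sequence window into overlapping analysis frames.

    Frames start at 0, hop, 2·hop, … while ``start + frame_len`` fits in
    the window; a window shorter than one frame is unusable and raises.
    """
    x = window.samples
    if x.size < frame_len:
        raise ValidationError(
            f"sequence of {x.size} samples is shorter than one {frame_len}-sample frame"
        )
    n_frames = (x.size - frame_len) // hop + 1
    return [
        Frame(
            samples=x[i * hop : i * hop + frame_len],
            parent_sequence=window.sequence_id,
            frame_index=i,
        )
        for i in range(n_frames)
    ]


def default_frame_length(sample_rate: int) -> int:
    """Smallest power of two covering 46 ms at ``sample_rate`` (2048 at 44.1 kHz)."""
    need = 0.046 * sample_rate
    return int(2 ** math.ceil(math.log2(need)))
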