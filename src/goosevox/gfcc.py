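"""Greenwood Function Cepstral Coefficients (and the mel variant).

The Greenwood cochlear map assumes that a species perceives frequency on a
logarithmic scale,

    F_p = (1/a) * log10(F_Hz / A + k),

with species-specific constants.  Given the hearing range (f_min, f_max)
and the empirical constant k ≈ 0.88, the remaining constants follow as
A = f_min / (1 - k) and a = log10(f_max / A + k), which pins the perceived
axis to [0, 1] over the hearing range.  Cepstral coefficients are then
computed exactly as MFCCs are, but with filter centres equally spaced on
the Greenwood axis instead of the mel axis: windowed frame → power
spectrum → band energies through a bank of 20 overlapping band filters →
log → cosine transform.  The feature vector keeps 21 coefficients
(c_0 … c_20, the 0th included).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .audio_io import Frame, SequenceWindow, frame_sequence
from .errors import ConfigError, ValidationError

#: Default hearing/vocalisation band (Hz): barnacle-goose calls carry most
#: of their spectral energy between 500 and 6000 Hz.
DEFAULT_F_MIN = 500.0
DEFAULT_F_MAX = 6000.0
#: Greenwood integration constant; ≈0.88 across species.
DEFAULT_K = 0.88
#: Floor applied to band energies before the log.
ENERGY_FLOOR = 1e-10

#: Feature column names c0 … c20.
FEATURE_COLUMNS = [f"c{i}" for i in range(21)]


@dataclass(frozen=True)
class PerceptualScale:
    """A Hz ↔ perceived-frequency warping (Greenwood or mel family)."""

    family: Literal["greenwood", "mel"]
    f_min: float
    f_max: float
    k: float = DEFAULT_K
    A: float = 0.0
    a: float = 0.0


def greenwood_scale(
    f_min: float = DEFAULT_F_MIN, f_max: float = DEFAULT_F_MAX, k: float = DEFAULT_K
) -> PerceptualScale:
    """Build a Greenwood scale from the hearing range and constant ``k``.

    The derived constants satisfy perceived(f_min) = 0 and
    perceived(f_max) = 1.
    """
    if not 0.0 < k < 1.0:
        raise ConfigError(f"Greenwood k must lie in (0, 1), got {k}")
    if not 0.0 < f_min < f_max:
        raise ConfigError(f"need 0 < f_min < f_max, got ({f_min}, {f_max})")
    A = f_min / (1.0 - k)
    a = float(np.log10(f_max / A + k))
    return PerceptualScale(family="greenwood", f_min=f_min, f_max=f_max, k=k, A=A, a=a)


def mel_scale(f_min: float = 0.0, f_max: float = DEFAULT_F_MAX) -> PerceptualScale:
    """The human mel warping, F_mel = (1000/log 2)·log(1 + F/1000)."""
    if f_min < 0 or f_max <= f_min:
        raise ConfigError(f"need 0 <= f_min < f_max, got ({f_min}, {f_max})")
    return PerceptualScale(family="mel", f_min=f_min, f_max=f_max)


def perceived_frequency(freq_hz, scale: PerceptualScale):
    """Map physical frequency (Hz) to perceived units under ``scale``.

    Strictly increasing; for the Greenwood family the hearing range maps
    onto [0, 1], for mel 1000 Hz maps to 1000 mel.
    """
    f = np.asarray(freq_hz, dtype=np.float64)
    if np.any(f < 0):
        raise ValidationError("frequency must be non-negative")
    if scale.family == "greenwood":
        out = np.log10(f / scale.A + scale.k) / scale.a
    else:
        out = 1000.0 / np.log(2.0) * np.log1p(f / 1000.0)
    return out if out.ndim else float(out)


def inverse_perceived_frequency(perceived, scale: PerceptualScale):
    """Inverse of :func:`perceived_frequency` (used to place filter centres)."""
    p = np.asarray(perceived, dtype=np.float64)
    if scale.family == "greenwood":
        lo = perceived_frequency(scale.f_min, scale)
        hi = perceived_frequency(scale.f_max, scale)
        if np.any(p < lo - 1e-9) or np.any(p > hi + 1e-9):
            raise ValidationError(
                f"perceived value outside [{lo:.6g}, {hi:.6g}] for this scale"
            )
        out = scale.A * (np.power(10.0, scale.a * p) - scale.k)
    else:
        if np.any(p < 0):
            raise ValidationError("perceived mel value must be non-negative")
        out = 1000.0 * (np.exp2(p / 1000.0) - 1.0)
    return out if out.ndim else float(out)


@dataclass
class FilterBank:
    """Band filters over one-sided FFT bins, centres on the perceived axis."""

    weights: np.ndarray          # (n_filters, n_bins), each row unit-area
    center_freqs: np.ndarray     # Hz
    scale: PerceptualScale
    n_fft: int
    sample_rate: float
    shape: str


_SHAPES = {
    "hamming": lambda t: 0.54 - 0.46 * np.cos(2.0 * np.pi * t),
    "hanning": lambda t: 0.5 - 0.5 * np.cos(2.0 * np.pi * t),
    "triangular": lambda t: 1.0 - np.abs(2.0 * t - 1.0),
}


def build_filterbank(
    scale: PerceptualScale,
    n_filters: int = 20,
    n_fft: int = 2048,
    sample_rate: float = 44100.0,
    shape: str = "hamming",
) -> FilterBank:
    """Build ``n_filters`` overlapping band filters on the perceived axis.

    Centres are uniformly spaced between perceived(f_min) and
    perceived(f_max) with spacing Δp = (p_max − p_min)/(n_filters + 1);
    filter j spans from centre j−1 to centre j+1 (edge filters span to the
    band edges), carrying the chosen window shape over its support.  Rows
    are normalised to unit area.
    """
    if shape not in _SHAPES:
        raise ConfigError(f"unknown filter shape {shape!r}; choose from {sorted(_SHAPES)}")
    nyquist = sample_rate / 2.0
    if scale.f_max > nyquist + 1e-9:
        raise ConfigError(
            f"scale upper edge {scale.f_max} Hz exceeds Nyquist {nyquist} Hz"
        )
    p_min = perceived_frequency(scale.f_min, scale)
    p_max = perceived_frequency(scale.f_max, scale)
    dp = (p_max - p_min) / (n_filters + 1)
    centers_p = p_min + dp * np.arange(1, n_filters + 1)
    edges_p = np.concatenate(([p_min], centers_p, [p_max]))

    n_bins = n_fft // 2 + 1
    bin_freqs = np.arange(n_bins) * sample_rate / n_fft
    # perceived position of every bin inside the band; NaN outside
    in_band = (bin_freqs > scale.f_min) & (bin_freqs < scale.f_max)
    bin_p = np.full(n_bins, np.nan)
    bin_p[in_band] = perceived_frequency(bin_freqs[in_band], scale)

    win = _SHAPES[shape]
    weights = np.zeros((n_filters, n_bins))
    for j in range(n_filters):
        lo, hi = edges_p[j], edges_p[j + 2]
        sel = in_band & (bin_p >= lo) & (bin_p <= hi)
        t = (bin_p[sel] - lo) / (hi - lo)
        weights[j, sel] = win(t)
        area = weights[j].sum()
        if area <= 0:
            raise ConfigError(
                f"filter {j} has empty support; increase n_fft or widen the band"
            )
        weights[j] /= area
    center_freqs = np.asarray(
        [inverse_perceived_frequency(p, scale) for p in centers_p]
    )
    return FilterBank(
        weights=weights,
        center_freqs=center_freqs,
        scale=scale,
        n_fft=n_fft,
        sample_rate=sample_rate,
        shape=shape,
    )


def cepstral_basis(n_coeffs: int, n_bands: int, printed_phase: bool = False) -> np.ndarray:
    """Cosine-transform matrix C[n, k] = cos(n (k + ½) π / K).

    ``printed_phase=True`` switches to the (k − ½) phase variant; the
    default is the orthogonal DCT-II convention, which preserves the
    flat-spectrum identity (all higher cepstra vanish on a flat log
    spectrum).
    """
    n = np.arange(n_coeffs)[:, None]
    k = np.arange(n_bands)[None, :]
    half = -0.5 if printed_phase else 0.5
    return np.cos(n * (k + half) * np.pi / n_bands)


def bands_to_cepstra(log_energies: np.ndarray, n_coeffs: int = 21,
                     printed_phase: bool = False) -> np.ndarray:
    """Cosine transform of per-band log energies, c_n = Σ_k S_k cos(n(k+½)π/K)."""
    S = np.atleast_2d(np.asarray(log_energies, dtype=np.float64))
    C = cepstral_basis(n_coeffs, S.shape[1], printed_phase)
    out = S @ C.T
    return out[0] if np.asarray(log_energies).ndim == 1 else out


def extract_cepstra(
    frame: Frame | np.ndarray,
    bank: FilterBank,
    n_coeffs: int = 21,
    printed_phase: bool = False,
) -> np.ndarray:
    """Cepstral coefficients of one analysis frame.

    Pipeline: Hamming time window → one-sided power spectrum → per-filter
    energies → natural log (floored at ``ENERGY_FLOOR``) → cosine
    transform → first ``n_coeffs`` coefficients, c_0 included.
    """
    x = frame.samples if isinstance(frame, Frame) else np.asarray(frame, np.float64)
    if x.size != bank.n_fft:
        raise ValidationError(
            f"frame length {x.size} does not match filterbank n_fft {bank.n_fft}"
        )
    windowed = x * np.hamming(x.size)
    power = np.abs(np.fft.rfft(windowed)) ** 2
    energies = bank.weights @ power
    log_e = np.log(np.maximum(energies, ENERGY_FLOOR))
    return bands_to_cepstra(log_e, n_coeffs=n_coeffs, printed_phase=printed_phase)


@dataclass
class FeatureConfig:
    """Everything the feature extractor needs to be reproducible."""

    scale_family: str = "greenwood"
    f_min: float = DEFAULT_F_MIN
    f_max: float = DEFAULT_F_MAX
    k: float = DEFAULT_K
    n_filters: int = 20
    n_coeffs: int = 21
    shape: str = "hamming"
    frame_len: int = 2048
    hop: int = 1024
    printed_phase: bool = False

    def make_scale(self) -> PerceptualScale:
        if self.scale_family == "greenwood":
            return greenwood_scale(self.f_min, self.f_max, self.k)
        if self.scale_family == "mel":
            return mel_scale(self.f_min, self.f_max)
        raise ConfigError(f"unknown scale family {self.scale_family!r}")

    def make_filterbank(self, sample_rate: float) -> FilterBank:
        return build_filterbank(
            self.make_scale(),
            n_filters=self.n_filters,
            n_fft=self.frame_len,
            sample_rate=sample_rate,
            shape=self.shape,
        )


def extract_features(
    sequences: Iterable[SequenceWindow], config: FeatureConfig | None = None
) -> pd.DataFrame:
    """Extract one cepstral row per analysis frame of every sequence.

    Returns a labelled feature table with columns ``clip``, ``sequence_id``,
    ``frame_index``, ``day_tag``, ``label`` and ``c0`` … ``c20``, ordered by
    (clip, sequence, frame).  Deterministic: identical input produces a
    bitwise-identical table.
    """
    config = config or FeatureConfig()
    banks: dict[float, FilterBank] = {}
    records: list[dict] = []
    for window in sequences:
        rate = window.clip.sample_rate
        if rate not in banks:
            banks[rate] = config.make_filterbank(rate)
        for frame in frame_sequence(window, config.frame_len, config.hop):
            coeffs = extract_cepstra(
                frame, banks[rate], config.n_coeffs, config.printed_phase
            )
            rec = {
                "clip": window.clip.source_id,
                "sequence_id": window.sequence_id,
                "frame_index": frame.frame_index,
                "day_tag": window.clip.day_tag,
                "label": window.label,
            }
            rec.update(zip(FEATURE_COLUMNS[: config.n_coeffs], coeffs))
            records.append(rec)
    columns = ["clip", "sequence_id", "frame_index", "day_tag", "label"]
    columns += FEATURE_COLUMNS[: config.n_coeffs]
    return pd.DataFrame.from_records(records, columns=columns)
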