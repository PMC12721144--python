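"""Modulation Power Spectrum (MPS) of audio stimuli.

The MPS is the squared magnitude of the two-dimensional Fourier transform
of a (mean-removed) log-magnitude spectrogram.  Its axes are temporal
modulation rate in Hz (how fast spectral content changes over time) and
spectral modulation scale in cycles/Hz (how finely power varies across
frequency).  Averaging the MPS over one axis gives a modulation profile
along the other; profiles of different stimuli on a common axis can be
compared with paired t-tests across modulation bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import gaussian


@dataclass
class Spectrogram:
    """Log-magnitude short-time spectrum: (frequency bin x time frame)."""

    values: np.ndarray  # dB, floored
    freqs: np.ndarray  # Hz, strictly increasing
    frame_times: np.ndarray  # s, strictly increasing
    window_s: float
    hop_s: float

    @property
    def n_freqs(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class MPSMatrix:
    """Modulation power over (spectral scale, temporal rate), half-plane.

    The underlying 2D transform of a real spectrogram is conjugate
    symmetric, so only the non-negative spectral-scale half is reported;
    the temporal-rate axis keeps both signs.  `total_power` is the full
    plane's mean squared transform magnitude, which by Parseval equals
    the total squared deviation of the mean-removed log spectrogram.
    """

    power: np.ndarray  # (n_scales x n_rates), >= 0
    temporal_rates: np.ndarray  # Hz, signed, strictly increasing
    spectral_scales: np.ndarray  # cycles/Hz, >= 0, strictly increasing
    total_power: float


@dataclass
class ModulationProfile:
    """Power against one modulation axis, averaged over the other."""

    axis: np.ndarray
    power: np.ndarray
    kind: str  # "temporal" or "spectral"


def log_spectrogram(
    audio: np.ndarray,
    sample_rate: float,
    window_s: float = 0.05,
    hop_s: float = 0.01,
    floor_db: float = -80.0,
) -> Spectrogram:
    """Gaussian-windowed log-magnitude spectrogram, floored at `floor_db`.

    The floor is relative to the maximum magnitude, so silence maps to a
    uniform `floor_db` and no bin underflows to -inf.
    """
    audio = np.asarray(audio, dtype=float)
    if not np.all(np.isfinite(audio)):
        raise ValueError("audio must be finite")
    if hop_s >= window_s:
        raise ValueError(f"hop ({hop_s}s) must be shorter than the window ({window_s}s)")
    m = int(round(window_s * sample_rate))
    if m > audio.size:
        raise ValueError(f"window ({m} samples) longer than the signal ({audio.size})")
    if m % 2 == 0:
        m += 1
    hop = max(1, int(round(hop_s * sample_rate)))
    win = gaussian(m, std=m / 6.0, sym=True)
    sft = ShortTimeFFT(win, hop=hop, fs=sample_rate, fft_mode="onesided")
    S = sft.stft(audio)
    # keep only frames whose window is fully supported by the signal:
    # zero-padded boundary frames would inject spurious slow temporal
    # modulation into the MPS
    p0 = sft.lower_border_end[1]
    p1 = sft.upper_border_begin(audio.size)[1]
    if p1 - p0 >= 8:
        S = S[:, p0:p1]
    else:
        p0 = 0
    mag = np.abs(S)
    ref = mag.max()
    if ref == 0:
        logmag = np.full(mag.shape, floor_db)
    else:
        logmag = 20.0 * np.log10(np.maximum(mag / ref, 10 ** (floor_db / 20.0)))
    n_frames = logmag.shape[1]
    frame_times = p0 * sft.delta_t + sft.delta_t * np.arange(n_frames)
    return Spectrogram(
        values=logmag,
        freqs=sft.f,
        frame_times=frame_times,
        window_s=window_s,
        hop_s=hop / sample_rate,
    )


def compute_mps(spec: Spectrogram) -> MPSMatrix:
    """MPS: squared magnitude of the 2D FFT of the mean-removed log spectrogram.

    Axes are centred with the zero-modulation bin in the middle; the
    spectral-scale axis is reduced to its non-negative half (conjugate
    symmetry of the transform of a real matrix).
    """
    if spec.n_freqs < 8 or spec.n_frames < 8:
        raise ValueError("spectrogram too small for a meaningful MPS (need >= 8 x 8)")
    X = spec.values - spec.values.mean()
    F = np.fft.fft2(X)
    power = np.abs(F) ** 2
    n_f, n_t = X.shape
    total_power = float(power.sum() / (n_f * n_t))  # == sum(X**2) by Parseval

    rates = np.fft.fftshift(np.fft.fftfreq(n_t, d=spec.hop_s))
    df = float(spec.freqs[1] - spec.freqs[0])
    scales = np.fft.fftshift(np.fft.fftfreq(n_f, d=df))
    power = np.fft.fftshift(power)
    keep = scales >= 0
    return MPSMatrix(
        power=power[keep, :],
        temporal_rates=rates,
        spectral_scales=scales[keep],
        total_power=total_power,
    )


def modulation_profiles(mps: MPSMatrix) -> Tuple[ModulationProfile, ModulationProfile]:
    """(temporal, spectral) profiles: the MPS averaged over the other axis."""
    temporal = ModulationProfile(
        axis=mps.temporal_rates, power=mps.power.mean(axis=0), kind="temporal"
    )
    spectral = ModulationProfile(
        axis=mps.spectral_scales, power=mps.power.mean(axis=1), kind="spectral"
    )
    return temporal, spectral


def peak_modulation_rate(profile: ModulationProfile, exclude_dc: bool = True) -> float:
    """Axis position of the profile's maximum (DC bin excluded by default).

    The zero-rate column carries the static spectral structure, which
    dwarfs genuine temporal modulation; peak queries therefore look at
    non-zero rates, and on the signed temporal axis the magnitude of the
    peak rate is returned.
    """
    mask = np.ones(profile.axis.size, dtype=bool)
    if exclude_dc:
        mask &= profile.axis != 0
    if profile.kind == "temporal":
        mask &= profile.axis > 0  # symmetric in magnitude; report the positive side
    idx = np.nonzero(mask)[0]
    best = idx[np.argmax(profile.power[idx])]
    return float(abs(profile.axis[best]))


def compare_conditions(profiles: Dict[str, ModulationProfile]) -> pd.DataFrame:
    """Pairwise paired t-tests of modulation profiles across bins.

    Modulation power spans many orders of magnitude across bins, so the
    paired t is computed on log10 power (a tiny relative floor guards the
    zeros).  Profiles must share a common axis.  Identical profiles give
    t = 0, p = 1; a constant multiplicative offset (zero bin-wise
    variance of the log differences) is a degenerate comparison and is
    flagged instead of returning a spurious p-value.
    """
    names = list(profiles)
    rows = []
    for a, b in combinations(names, 2):
        pa, pb = profiles[a], profiles[b]
        if pa.axis.shape != pb.axis.shape or not np.allclose(pa.axis, pb.axis):
            raise ValueError(f"profiles {a!r} and {b!r} are on different axes")
        scale = max(pa.power.max(), pb.power.max(), 1e-300)
        la = np.log10(np.maximum(pa.power, 1e-12 * scale))
        lb = np.log10(np.maximum(pb.power, 1e-12 * scale))
        diff = la - lb
        if np.allclose(pa.power, pb.power):
            t, p, flag = 0.0, 1.0, ""
        elif np.ptp(diff) < 1e-12:
            t, p, flag = np.nan, np.nan, "degenerate: zero bin-wise variance"
        else:
            t, p = sps.ttest_rel(la, lb)
            flag = ""
        rows.append({"pair": (a, b), "kind": pa.kind, "t": float(t) if t == t else np.nan,
                     "p": float(p) if p == p else np.nan, "flag": flag})
    return pd.DataFrame(rows)


def mps_of_audio(
    audio: np.ndarray,
    sample_rate: float,
    window_s: float = 0.05,
    hop_s: float = 0.01,
    floor_db: float = -80.0,
) -> Tuple[MPSMatrix, ModulationProfile, ModulationProfile]:
    """Convenience: spectrogram -> MPS -> (temporal, spectral) profiles."""
    spec = log_spectrogram(audio, sample_rate, window_s=window_s, hop_s=hop_s, floor_db=floor_db)
    mps = compute_mps(spec)
    temporal, spectral = modulation_profiles(mps)
    return mps, temporal, spectral
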