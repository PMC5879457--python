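"""Input-impedance estimation from forced-oscillation waveform records.

The perturbation is a known discrete tone set, so the primary estimator is
per-frequency least-squares sinusoid regression: each signal is regressed
on [cos, sin, 1] at each probe frequency over an integer number of
fundamental cycles, giving complex Fourier coefficients whose ratio is
Z(f) = P(f)/V'(f).  Over integer-cycle records this is numerically
identical to reading the FFT bin, which serves as the independent oracle
in the test suite.  A segment-averaged magnitude-squared coherence between
pressure and flow provides per-frequency quality control.

Sign convention: elastic reactance is negative, Z = RL - i EL/(2 pi f),
hence EL(f) = -2 pi f Im Z(f).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synthetic_data import WaveformRecord, fundamental_frequency

__all__ = [
    "ImpedanceSpectrum",
    "RESpectra",
    "estimate_impedance",
    "spectra_from_impedance",
    "filter_by_coherence",
]


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex input impedance at the probe frequencies, with coherence QC.

    A frequency whose flow coefficient fell below the estimation floor is
    flagged invalid: its z_re/z_im are NaN and its coherence 0.
    """

    animal_id: str
    peep: float
    freqs: np.ndarray
    z_re: np.ndarray
    z_im: np.ndarray
    coherence: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("freqs must be a non-empty 1-D array")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be positive and strictly increasing")
        for name in ("z_re", "z_im", "coherence"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != f.shape:
                raise ValueError(f"{name} must match freqs in length")
        coh = np.asarray(self.coherence, dtype=float)
        if np.any((coh < 0) | (coh > 1)):
            raise ValueError("coherence must lie in [0, 1]")

    @property
    def z(self) -> np.ndarray:
        return np.asarray(self.z_re) + 1j * np.asarray(self.z_im)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "peep": self.peep,
                "freq": self.freqs,
                "z_re": self.z_re,
                "z_im": self.z_im,
                "coherence": self.coherence,
            }
        )


@dataclass(frozen=True)
class RESpectra:
    """Resistance (cmH2O.s/mL) and elastance (cmH2O/mL) spectra."""

    freqs: np.ndarray
    rl: np.ndarray
    el: np.ndarray
    animal_id: str = "unknown"
    peep: float = float("nan")

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 1 or np.any(f < 0):
            raise ValueError("freqs must be 1-D and non-negative")
        for name in ("rl", "el"):
            if np.asarray(getattr(self, name)).shape != f.shape:
                raise ValueError(f"{name} must match freqs in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "peep": self.peep,
                "freq": self.freqs,
                "rl": self.rl,
                "el": self.el,
            }
        )


def _phasor_coefficients(x: np.ndarray, t: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Complex amplitude of each tone by least squares on [cos, sin, 1].

    For x = A sin(wt + phi) the returned coefficient is A e^{i phi}.
    """
    out = np.empty(freqs.size, dtype=complex)
    for i, f in enumerate(freqs):
        w = 2.0 * np.pi * f * t
        design = np.column_stack([np.cos(w), np.sin(w), np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        # sin(wt+phi) = cos(phi) sin(wt) + sin(phi) cos(wt)
        out[i] = coef[1] + 1j * coef[0]
    return out


def _segment_coherence(record: WaveformRecord, freqs: np.ndarray) -> np.ndarray:
    """Welch magnitude-squared coherence sampled at the nearest bin to each tone.

    Segment length is chosen so that at least 4 half-overlapping segments
    fit.  When whole fundamental periods fit in a segment, rectangular
    windows over whole-period segments are used: every tone then completes
    integer cycles per segment, so there is no leakage between tone bins
    and a noiseless record scores coherence 1 at every tone.
    """
    n = record.t.size
    f0 = fundamental_frequency(freqs)
    period = record.sample_rate / f0
    n_cycles = int(np.floor(n / period))
    m = int(np.floor(2 * n_cycles / 5))  # periods per segment for >= 4 segments
    if m >= 1 and abs(period - round(period)) < 1e-9:
        nper = int(round(period)) * m
        window = "boxcar"
    else:
        nper = min(n, 1 << max(3, int(np.floor(np.log2(max(2 * n / 5, 8))))))
        window = "hann"
    f_grid, coh = sps.coherence(
        record.pressure, record.flow, fs=record.sample_rate,
        window=window, nperseg=nper, noverlap=nper // 2,
    )
    idx = np.abs(f_grid[:, None] - freqs[None, :]).argmin(axis=0)
    return np.clip(coh[idx], 0.0, 1.0)


def estimate_impedance(
    record: WaveformRecord,
    freqs,
    transient: float = 1.0,
    flow_floor: float = 1e-6,
) -> ImpedanceSpectrum:
    """Estimate Z(f) = P(f)/V'(f) at each probe frequency.

    The record is first trimmed: the leading ``transient`` seconds are
    discarded, then the remainder is cut to the largest whole number of
    cycles of the fundamental (GCD of the probe frequencies) so the
    sinusoid regressors are orthogonal.  Requires at least two full cycles
    of the lowest frequency after trimming.  Tones whose flow coefficient
    magnitude falls below ``flow_floor`` are flagged invalid (NaN impedance,
    zero coherence) rather than divided out.
    """
    freqs = np.sort(np.asarray(list(freqs), dtype=float))
    if np.any(freqs <= 0):
        raise ValueError("probe frequencies must be positive")
    nyquist = record.sample_rate / 2.0
    if np.any(freqs >= nyquist):
        raise ValueError(f"aliased probe frequency at or above Nyquist ({nyquist} Hz)")

    # trim transient, then cut to whole fundamental cycles
    i0 = int(round(transient * record.sample_rate))
    if i0 >= record.t.size:
        raise ValueError("transient longer than the record")
    f0 = fundamental_frequency(freqs)
    period_samples = record.sample_rate / f0
    n_avail = record.t.size - i0
    n_cycles = int(np.floor(n_avail / period_samples))
    if n_cycles < 1:
        raise ValueError("record too short: less than one fundamental cycle after transient")
    n_keep = int(round(n_cycles * period_samples))
    sl = slice(i0, i0 + n_keep)
    t = record.t[sl] - record.t[sl.start]
    flow = record.flow[sl]
    pressure = record.pressure[sl]

    if n_keep / record.sample_rate < 2.0 / freqs.min():
        raise ValueError("record must cover at least 2 full cycles of the lowest frequency")

    flow_c = _phasor_coefficients(flow, t, freqs)
    pres_c = _phasor_coefficients(pressure, t, freqs)
    trimmed = replace(record, t=record.t[sl] - record.t[sl.start], flow=flow, pressure=pressure)
    coherence = _segment_coherence(trimmed, freqs)

    valid = np.abs(flow_c) >= flow_floor
    z = np.full(freqs.size, np.nan + 1j * np.nan, dtype=complex)
    z[valid] = pres_c[valid] / flow_c[valid]
    coherence = np.where(valid, coherence, 0.0)

    return ImpedanceSpectrum(
        animal_id=record.animal_id,
        peep=record.peep,
        freqs=freqs,
        z_re=z.real,
        z_im=z.imag,
        coherence=coherence,
    )


def spectra_from_impedance(spec: ImpedanceSpectrum) -> RESpectra:
    """Decompose Z into RL(f) = Re Z and EL(f) = -2 pi f Im Z."""
    f = np.asarray(spec.freqs, dtype=float)
    return RESpectra(
        freqs=f,
        rl=np.asarray(spec.z_re, dtype=float),
        el=-2.0 * np.pi * f * np.asarray(spec.z_im, dtype=float),
        animal_id=spec.animal_id,
        peep=spec.peep,
    )


def filter_by_coherence(spec: ImpedanceSpectrum, threshold: float = 0.9) -> ImpedanceSpectrum:
    """Drop frequencies with coherence below ``threshold`` (order preserved)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"coherence threshold must be in [0, 1]; got {threshold}")
    keep = np.asarray(spec.coherence) >= threshold
    if not keep.any():
        raise ValueError(
            f"all frequencies fall below coherence {threshold}: record unusable"
        )
    return ImpedanceSpectrum(
        animal_id=spec.animal_id,
        peep=spec.peep,
        freqs=np.asarray(spec.freqs)[keep],
        z_re=np.asarray(spec.z_re)[keep],
        z_im=np.asarray(spec.z_im)[keep],
        coherence=np.asarray(spec.coherence)[keep],
    )
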