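"""Apo/holo calling from absorbance spectra.

A retinal-bound (holo) opsin absorbs in the 480-580 nm band; the apo
protein does not.  The call subtracts a buffer background, normalizes to
a control's 280 nm absorbance, and then asks whether the maximum in the
band rises above a chord baseline across the window by at least
``min_prominence_sd`` noise standard deviations, with noise estimated
from the flat 600-800 nm region (outside opsin absorption).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .config import Thresholds
from .io import SpectrumRecord


@dataclass(frozen=True)
class RetinalCall:
    bound: bool
    lambda_max: float | None
    prominence_sd: float
    noise_sd: float
    self_normalized: bool = False


def preprocess(
    sample: SpectrumRecord,
    background: SpectrumRecord,
    control_a280: float | None,
) -> tuple[SpectrumRecord, bool]:
    """Background-subtract and normalize to the control's A280.

    When no control absorbance is supplied the spectrum is normalized to
    its own background-subtracted A280 (flagged in the returned tuple's
    second element, and downstream in :class:`RetinalCall`).
    """
    if sample.wavelengths.shape != background.wavelengths.shape or np.any(
        sample.wavelengths != background.wavelengths
    ):
        raise ValueError("sample and background must share one wavelength grid")
    corrected = sample.absorbances - background.absorbances
    self_normalized = control_a280 is None
    if self_normalized:
        control_a280 = float(
            np.interp(280.0, sample.wavelengths, corrected)
        )
    if control_a280 <= 0:
        raise ValueError(f"control A280 must be positive, got {control_a280}")
    return (
        SpectrumRecord(
            wavelengths=sample.wavelengths.copy(),
            absorbances=corrected / control_a280,
        ),
        self_normalized,
    )


def detect_retinal_peak(
    s: SpectrumRecord,
    window: tuple[float, float] = Thresholds.spectra_window_nm,
    min_prominence_sd: float = Thresholds.min_prominence_sd,
    noise_region: tuple[float, float] = Thresholds.noise_region_nm,
    self_normalized: bool = False,
) -> RetinalCall:
    """Decide retinal-bound vs apo from a preprocessed spectrum.

    ``bound`` iff the in-window maximum exceeds the straight chord between
    the window endpoints by at least ``min_prominence_sd`` times the noise
    SD.  The verdict is invariant under positive rescaling of the whole
    spectrum: both the excess and the noise scale together.
    """
    wl, ab = s.wavelengths, s.absorbances
    lo, hi = window
    if wl[0] > lo or wl[-1] < max(hi, noise_region[1]):
        raise ValueError(
            f"spectrum [{wl[0]}, {wl[-1]}] nm does not cover window and noise region"
        )
    nmask = (wl >= noise_region[0]) & (wl <= noise_region[1])
    noise = ab[nmask]
    # detrend linearly: slow drift should not inflate the noise estimate
    coeffs = np.polyfit(wl[nmask], noise, 1)
    noise_sd = float(np.std(noise - np.polyval(coeffs, wl[nmask]), ddof=1))

    # Savitzky-Golay smoothing before locating the maximum: a retinal band
    # is tens of nm wide, so a 21-point (42 nm) quadratic window preserves
    # its shape while keeping grid-level noise from shifting the argmax.
    smooth = savgol_filter(ab, min(21, len(ab) // 2 * 2 - 1), 2)
    wmask = (wl >= lo) & (wl <= hi)
    wwl, wab = wl[wmask], smooth[wmask]
    a_lo = float(np.interp(lo, wl, smooth))
    a_hi = float(np.interp(hi, wl, smooth))
    chord = a_lo + (a_hi - a_lo) * (wwl - lo) / (hi - lo)
    excess = wab - chord
    k = int(np.argmax(excess))
    prominence = excess[k] / noise_sd if noise_sd > 0 else np.inf * np.sign(excess[k])
    bound = bool(prominence >= min_prominence_sd)
    lambda_max = None
    if bound:
        # lambda_max is read from the spectrum itself, not the
        # chord-subtracted excess (the chord's slope would shift a broad
        # band's apex), and refined with a quadratic vertex fit because the
        # top of a wide band is flat relative to the noise
        km = int(np.argmax(wab))
        sl = slice(max(0, km - 15), min(len(wwl), km + 16))
        c2, c1, _ = np.polyfit(wwl[sl] - wwl[km], wab[sl], 2)
        lambda_max = float(wwl[km])
        if c2 < 0:
            vertex = wwl[km] - c1 / (2 * c2)
            lambda_max = float(np.clip(vertex, lo, hi))
    return RetinalCall(
        bound=bound,
        lambda_max=lambda_max,
        prominence_sd=float(prominence),
        noise_sd=noise_sd,
        self_normalized=self_normalized,
    )
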