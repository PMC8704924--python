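"""Carotenoid-diagnostic features of DAD absorption spectra.

A carotenoid chromophore shows up to three vibronic bands in the visible
(conventionally I, II, III in order of wavelength, band II carrying the
global maximum). Two desk-side descriptors discriminate isomers that mass
spectrometry cannot:

* spectral fine structure %III/II = 100 * (A_III - A_min) / (A_II - A_min),
  with both band heights referenced to the trough between bands II and III —
  which makes the index invariant to scaling and to a constant baseline;
* a "cis peak" near 320-370 nm flagging cis-isomerized chromophores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .spectra_model import DadSpectrum

#: window where carotenoid vibronic bands live
BAND_RANGE_NM = (380.0, 560.0)
#: window where the cis peak lives
CIS_RANGE_NM = (320.0, 370.0)
#: minimum cis-peak height as a fraction of band II (curated default)
CIS_MIN_FRAC = 0.05
#: minimum separation of band maxima
BAND_WINDOW_NM = 15.0


@dataclass
class UvvisFeatures:
    lambda_max: list[float]
    percent_iii_ii: float | None = None
    cis_peak: bool = False
    cis_peak_lambda: float | None = None

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.lambda_max[1:], self.lambda_max)):
            raise ValueError("lambda_max must be strictly increasing")
        if self.percent_iii_ii is not None and self.percent_iii_ii < 0:
            raise ValueError("%III/II must be >= 0")
        if self.cis_peak != (self.cis_peak_lambda is not None):
            raise ValueError("cis_peak_lambda must be present iff cis_peak")


def find_bands(spectrum: DadSpectrum, window_nm: float = BAND_WINDOW_NM) -> list[float]:
    """Locate up to three absorption band maxima in 380-560 nm.

    Local maxima separated by at least ``window_nm`` are found on the grid;
    if more than three survive, the three tallest are kept. A monotone
    spectrum returns an empty list (no carotenoid chromophore).
    """
    if not window_nm > 0:
        raise ValueError("window_nm must be positive")
    lo, hi = BAND_RANGE_NM
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    wl = spectrum.wavelengths[mask]
    ab = spectrum.absorbances[mask]
    if wl.size < 3:
        return []
    step = float(np.median(np.diff(wl)))
    distance = max(1, int(round(window_nm / step)))
    idx, _ = find_peaks(ab, distance=distance)
    if idx.size == 0:
        return []
    if idx.size > 3:
        idx = idx[np.argsort(ab[idx])[-3:]]
    return sorted(float(wl[i]) for i in idx)


def _band_absorbance(spectrum: DadSpectrum, wl_nm: float) -> float:
    i = int(np.argmin(np.abs(spectrum.wavelengths - wl_nm)))
    return float(spectrum.absorbances[i])


def fine_structure(spectrum: DadSpectrum,
                   window_nm: float = BAND_WINDOW_NM) -> float | None:
    """Spectral fine structure %III/II, or None when it is undefined.

    Band III is the longest-wavelength band, band II the one before it; both
    heights are measured from the trough between them. Returns None for
    fewer than two bands or when band II does not rise above the trough
    (never infinity).
    """
    bands = find_bands(spectrum, window_nm)
    if len(bands) < 2:
        return None
    lam_ii, lam_iii = bands[-2], bands[-1]
    between = (spectrum.wavelengths >= lam_ii) & (spectrum.wavelengths <= lam_iii)
    if not np.any(between):
        return None
    a_min = float(np.min(spectrum.absorbances[between]))
    a_ii = _band_absorbance(spectrum, lam_ii)
    a_iii = _band_absorbance(spectrum, lam_iii)
    if a_ii <= a_min:
        return None
    return max(0.0, 100.0 * (a_iii - a_min) / (a_ii - a_min))


def detect_cis_peak(spectrum: DadSpectrum,
                    min_frac: float = CIS_MIN_FRAC,
                    cis_range_nm: tuple[float, float] = CIS_RANGE_NM,
                    ) -> tuple[bool, float | None]:
    """Flag a cis peak: a local maximum in 320-370 nm at >= 5% of band II."""
    lo, hi = cis_range_nm
    if not spectrum.covers(300.0, 400.0):
        warnings.warn("DAD spectrum does not cover 300-400 nm; cis peak undetermined")
        return False, None
    bands = find_bands(spectrum)
    if not bands:
        return False, None
    lam_ii = bands[-2] if len(bands) >= 2 else bands[-1]
    a_ii = _band_absorbance(spectrum, lam_ii)
    if a_ii <= 0:
        return False, None
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    wl = spectrum.wavelengths[mask]
    ab = spectrum.absorbances[mask]
    if wl.size < 3:
        return False, None
    idx, _ = find_peaks(ab)
    idx = [i for i in idx if ab[i] >= min_frac * a_ii]
    if not idx:
        return False, None
    best = max(idx, key=lambda i: ab[i])
    return True, float(wl[best])


def extract_features(spectrum: DadSpectrum,
                     window_nm: float = BAND_WINDOW_NM) -> UvvisFeatures:
    """All UV-vis descriptors for one spectrum in a single pass."""
    bands = find_bands(spectrum, window_nm)
    fs = fine_structure(spectrum, window_nm)
    if spectrum.covers(300.0, 400.0):
        cis, cis_lam = detect_cis_peak(spectrum)
    else:
        cis, cis_lam = False, None
    return UvvisFeatures(bands, fs, cis, cis_lam)
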