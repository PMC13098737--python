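"""The seven-step spectral preprocessing chain.

Order of operations (after accumulation averaging): dark-count subtraction,
instrument-response correction, wavenumber calibration, Savitzky-Golay
smoothing (order 3, window 11), rolling-ball baseline removal, truncation to
700-1700 cm^-1, and per-spectrum standard normal variate (SNV)
normalization. Each step is a separately testable pure function on
:class:`~fcdraman.core.Spectrum`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import savgol_filter

from .core import CalibrationRefs, Spectrum, ValidationError, WavenumberAxis

__all__ = [
    "PreprocessConfig",
    "average_accumulations",
    "subtract_dark",
    "correct_instrument_response",
    "fit_wavenumber_map",
    "calibrate_wavenumber",
    "smooth_savitzky_golay",
    "remove_baseline_rollingball",
    "truncate_axis",
    "normalize_snv",
    "run_preprocessing",
]


@dataclass
class PreprocessConfig:
    """Tunable parameters of the preprocessing chain.

    ``ball_radius`` must exceed the widest expected band FWHM (<= 60 cm^-1)
    while staying well below the autofluorescence-baseline scale;
    ``target_spacing`` is the uniform grid the calibration step resamples to
    (1.1 cm^-1, the instrument's stated spectral resolution), anchored so a
    grid point falls exactly on 700 cm^-1.
    """

    sg_order: int = 3
    sg_window: int = 11
    ball_radius: float = 120.0
    truncate_lo: float = 700.0
    truncate_hi: float = 1700.0
    calib_degree: int = 3
    target_spacing: float = 1.1
    grid_anchor: float = 700.0

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValidationError("sg_window must be odd and > sg_order")
        if self.ball_radius <= 60.0:
            raise ValidationError("ball_radius must exceed the largest band FWHM (60 cm^-1)")
        if not (self.truncate_lo < self.truncate_hi):
            raise ValidationError("invalid truncation range")


def _check_shared_axis(a: Spectrum, b: Spectrum) -> None:
    if len(a.axis) != len(b.axis) or not np.allclose(a.axis.values, b.axis.values):
        raise ValidationError(
            f"axis mismatch between {a.spectrum_id!r} and {b.spectrum_id!r}")


def average_accumulations(accumulations: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of repeated acquisitions of one cell."""
    if len(accumulations) == 0:
        raise ValidationError("no accumulations to average")
    first = accumulations[0]
    for s in accumulations[1:]:
        _check_shared_axis(first, s)
    mean = np.mean([s.intensity for s in accumulations], axis=0)
    sid = first.spectrum_id.split("/acc")[0]
    return Spectrum(sid, first.axis, mean, stage="averaged")


def subtract_dark(s: Spectrum, dark: Spectrum) -> Spectrum:
    """Remove the detector dark-count background (laser-off measurement)."""
    _check_shared_axis(s, dark)
    return s.with_(intensity=s.intensity - dark.intensity, stage="dark_subtracted")


def estimate_response(refs: CalibrationRefs, sg_order: int = 3, sg_window: int = 11) -> np.ndarray:
    """Relative instrument-response estimate, rescaled to unit mean.

    The measured intensity-standard spectrum is smoothed and divided by the
    standard's certified curve; the unit-mean rescaling makes the correction
    invariant to the standard's exposure/gain.
    """
    smoothed = savgol_filter(refs.response_measured.intensity, sg_window, sg_order)
    certified = refs.response_certified.intensity
    if np.any(certified <= 0):
        raise ValidationError("certified response curve must be strictly positive")
    est = smoothed / certified
    if np.any(est <= 0):
        raise ValidationError("estimated instrument response is nonpositive at some bins")
    return est / np.mean(est)


def correct_instrument_response(s: Spectrum, refs: CalibrationRefs,
                                sg_order: int = 3, sg_window: int = 11) -> Spectrum:
    """Divide out the relative spectral sensitivity of the instrument."""
    _check_shared_axis(s, refs.response_measured)
    est = estimate_response(refs, sg_order, sg_window)
    return s.with_(intensity=s.intensity / est, stage="response_corrected")


def fit_wavenumber_map(refs: CalibrationRefs, degree: int = 3) -> tuple[np.ndarray, float]:
    """Least-squares polynomial map measured -> known positions.

    Returns (np.polyval coefficients, residual RMS in cm^-1).
    """
    tbl = refs.wavenumber_ref_peaks
    measured = tbl["measured_position"].to_numpy(float)
    known = tbl["known_position"].to_numpy(float)
    if len(tbl) < degree + 1:
        raise ValidationError(
            f"need >= {degree + 1} reference peak pairs for a degree-{degree} map")
    coeffs = np.polyfit(measured, known, degree)
    resid = np.polyval(coeffs, measured) - known
    return coeffs, float(np.sqrt(np.mean(resid ** 2)))


def calibrate_wavenumber(s: Spectrum, refs: CalibrationRefs, degree: int = 3,
                         resample_spacing: float | None = None,
                         grid_anchor: float = 700.0) -> Spectrum:
    """Remap the wavenumber axis through the fitted calibration polynomial.

    With ``resample_spacing`` set, intensities are linearly re-interpolated
    onto a uniform grid of that spacing whose points satisfy
    ``anchor + k*spacing`` (so truncation at the anchor keeps an exact
    endpoint); otherwise the remapped (slightly non-uniform) axis is kept.
    """
    coeffs, _rms = fit_wavenumber_map(refs, degree)
    mapped = np.polyval(coeffs, s.axis.values)
    if np.any(np.diff(mapped) <= 0):
        raise ValidationError("fitted wavenumber map is non-monotone over the axis")
    if resample_spacing is None:
        return s.with_(axis=WavenumberAxis(mapped), stage="calibrated")
    k_lo = int(np.ceil((mapped[0] - grid_anchor) / resample_spacing - 1e-9))
    k_hi = int(np.floor((mapped[-1] - grid_anchor) / resample_spacing + 1e-9))
    grid = grid_anchor + resample_spacing * np.arange(k_lo, k_hi + 1)
    y = np.interp(grid, mapped, s.intensity)
    return s.with_(axis=WavenumberAxis(grid), intensity=y, stage="calibrated")


def smooth_savitzky_golay(s: Spectrum, order: int = 3, window: int = 11) -> Spectrum:
    """Savitzky-Golay smoothing: local least-squares polynomial of the given
    order over a centered window; edge points use the polynomial fitted to
    the one-sided truncated window."""
    n = len(s.axis)
    if window % 2 == 0:
        raise ValidationError("window must be odd")
    if window <= order:
        raise ValidationError("window must exceed the polynomial order")
    if window > n:
        raise ValidationError("window exceeds spectrum length")
    y = s.intensity
    out = savgol_filter(y, window, order)
    # One-sided truncated windows at the edges (no reflection/extrapolation).
    half = window // 2
    idx = np.arange(n, dtype=float)
    for i in range(half):
        sl = slice(0, i + half + 1)
        out[i] = np.polyval(np.polyfit(idx[sl], y[sl], order), idx[i])
        sr = slice(n - 1 - i - half, n)
        out[n - 1 - i] = np.polyval(np.polyfit(idx[sr], y[sr], order), idx[n - 1 - i])
    return s.with_(intensity=out, stage="smoothed")


def _opening(x: np.ndarray, y: np.ndarray, radius: float) -> np.ndarray:
    """Morphological opening with a ball structuring element.

    The ball is circular in (cm^-1, scaled-intensity) space: intensities are
    scaled so the signal's peak-to-peak range corresponds to the axis span,
    which keeps the ball's curvature meaningful across inputs. An opening
    (erosion then dilation) yields the lower envelope that a ball of the
    given radius can reach — the classical rolling-ball background.
    """
    spacing = float(np.median(np.diff(x)))
    if radius <= spacing:
        raise ValidationError("ball radius must exceed the bin spacing")
    w = int(np.floor(radius / spacing))
    ptp = float(np.ptp(y))
    if ptp == 0.0:
        return y.copy()  # constant signal is its own background
    scale = ptp / (x[-1] - x[0])  # intensity units per cm^-1
    offs = np.arange(-w, w + 1) * spacing
    dome = scale * np.sqrt(np.maximum(radius ** 2 - offs ** 2, 0.0))
    ypad = np.pad(y, w, mode="edge")
    win = sliding_window_view(ypad, 2 * w + 1)
    eroded = np.min(win - dome, axis=1)
    epad = np.pad(eroded, w, mode="edge")
    ewin = sliding_window_view(epad, 2 * w + 1)
    return np.max(ewin + dome, axis=1)


def _robust_trend(x: np.ndarray, y: np.ndarray, degree: int = 7,
                  n_iter: int = 12, clip: float = 1.0) -> np.ndarray:
    """Asymmetrically clipped polynomial trend (peaks excluded from the fit).

    Iteratively fits a polynomial and drops points lying more than
    ``clip`` residual-SDs ABOVE the fit, so Raman bands (one-sided
    excursions) stop pulling the trend up while the smooth background is
    followed. This pre-flattening lets the subsequent ball opening operate
    on a nearly level residual, where its geometry no longer depends on the
    background's steepness.
    """
    degree = min(degree, y.size - 2)
    u = (x - x.mean()) / (x[-1] - x[0])
    keep = np.ones(y.size, dtype=bool)
    fit = np.zeros_like(y)
    for _ in range(n_iter):
        if keep.sum() <= degree + 1:
            break
        fit = np.polyval(np.polyfit(u[keep], y[keep], degree), u)
        r = y - fit
        sd = float(np.std(r[keep], ddof=1))
        if sd == 0.0:
            break
        keep = r < clip * sd
    return fit


def _rolling_ball_baseline(x: np.ndarray, y: np.ndarray, radius: float) -> np.ndarray:
    """Background estimate: robust polynomial pre-flattening + ball opening.

    The rolling ball alone cannot follow a steep fluorescence decay without
    its errors depending on the decay's amplitude, so the background is
    split into a smooth robust-polynomial trend plus a morphological-opening
    correction of the flattened residual.
    """
    if float(np.ptp(y)) == 0.0:
        return y.copy()
    trend = _robust_trend(x, y)
    resid = y - trend
    return trend + _opening(x, resid, radius)


def remove_baseline_rollingball(s: Spectrum, radius: float = 120.0,
                                smooth_window: int = 11, smooth_order: int = 3
                                ) -> tuple[Spectrum, Spectrum]:
    """Estimate and subtract the slowly varying autofluorescence background.

    Returns (corrected spectrum, baseline spectrum). The morphological
    opening is smoothed with the same Savitzky-Golay settings as the
    smoothing step before subtraction.
    """
    if radius <= 0:
        raise ValidationError("radius must be positive")
    x, y = s.axis.values, s.intensity
    baseline = _rolling_ball_baseline(x, y, radius)
    if np.ptp(baseline) > 0 and smooth_window < baseline.size:
        baseline = savgol_filter(baseline, smooth_window, smooth_order)
    corrected = s.with_(intensity=y - baseline, stage="debaselined")
    return corrected, s.with_(intensity=baseline, stage="debaselined")


def truncate_axis(s: Spectrum, lo: float = 700.0, hi: float = 1700.0) -> Spectrum:
    """Restrict to the fingerprint region [lo, hi] cm^-1 (closed interval)."""
    mask = (s.axis.values >= lo) & (s.axis.values <= hi)
    if mask.sum() < 2:
        raise ValidationError(f"truncation to [{lo}, {hi}] leaves no usable bins")
    return s.with_(axis=WavenumberAxis(s.axis.values[mask]),
                   intensity=s.intensity[mask], stage="truncated")


def normalize_snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: per-spectrum (x - mean)/SD (sample SD)."""
    sd = float(np.std(s.intensity, ddof=1))
    if sd == 0.0:
        raise ValidationError(f"spectrum {s.spectrum_id!r}: constant intensity, SNV undefined")
    return s.with_(intensity=(s.intensity - np.mean(s.intensity)) / sd, stage="snv")


def run_preprocessing(spectra: Sequence[Spectrum] | Mapping[str, Sequence[Spectrum]],
                      refs: CalibrationRefs,
                      config: PreprocessConfig | None = None
                      ) -> tuple[list[Spectrum], list[dict]]:
    """Apply the full chain in order; returns processed spectra + audit log.

    ``spectra`` is either a sequence of raw/averaged spectra or a mapping
    spectrum_id -> accumulation list (averaged first). Spectra are processed
    independently; only the calibration references are shared.
    """
    config = config or PreprocessConfig()
    if isinstance(spectra, Mapping):
        inputs = [average_accumulations(accs) for accs in spectra.values()]
    else:
        inputs = list(spectra)
    for s in inputs:
        if s.stage not in ("raw", "averaged"):
            raise ValidationError(f"spectrum {s.spectrum_id!r} has stage {s.stage!r}; "
                                  "expected raw or averaged")
    # Shared, fit-once reference corrections.
    response = estimate_response(refs, config.sg_order, config.sg_window)
    _coeffs, calib_rms = fit_wavenumber_map(refs, config.calib_degree)

    out: list[Spectrum] = []
    audit: list[dict] = []
    for s in inputs:
        try:
            t = subtract_dark(s, refs.dark)
            t = t.with_(intensity=t.intensity / response, stage="response_corrected")
            t = calibrate_wavenumber(t, refs, config.calib_degree,
                                     resample_spacing=config.target_spacing,
                                     grid_anchor=config.grid_anchor)
            t = smooth_savitzky_golay(t, config.sg_order, config.sg_window)
            t, baseline = remove_baseline_rollingball(t, config.ball_radius,
                                                      config.sg_window, config.sg_order)
            t = truncate_axis(t, config.truncate_lo, config.truncate_hi)
            t = normalize_snv(t)
        except ValidationError as e:
            raise ValidationError(f"preprocessing {s.spectrum_id!r}: {e}") from e
        out.append(t)
        audit.append({
            "spectrum_id": s.spectrum_id,
            "calibration_residual_rms_cm1": calib_rms,
            "baseline_median": float(np.median(baseline.intensity)),
            "n_bins_final": len(t.axis),
            "stage": t.stage,
        })
    return out, audit
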