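"""Gaussian peak-fit feature extraction.

Each SNV spectrum is reduced to a fixed-length feature vector: peaks are
detected, fitted with Gaussians g(x) = h*exp(-4 ln2 (x-mu)^2/w^2) (plus a
local constant offset absorbing the SNV shift), pooled into a dataset-wide
consensus peak set, and expanded into 3 features per consensus peak
(position, height, FWHM). A spectrum missing a consensus band gets a
constrained refit with the position pinned near the consensus, so absent
bands appear as near-zero heights rather than missing values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .core import Spectrum, ValidationError

__all__ = [
    "PeakFit",
    "ConsensusPeakSet",
    "PeakConfig",
    "detect_peaks",
    "fit_gaussian_peaks",
    "build_consensus",
    "extract_features",
    "features_from_spectra",
]

FWHM_FACTOR = 4.0 * np.log(2.0)
FWHM_BOUNDS = (2.0, 60.0)


@dataclass
class PeakConfig:
    """Detection/fit/consensus parameters (all in cm^-1 unless noted)."""

    prominence_factor: float = 3.0     # x noise estimate
    min_prominence_frac: float = 0.05  # x peak-to-peak range (absolute floor)
    min_separation: float = 8.0
    fit_window: float = 15.0           # half-width of the fit window
    position_tolerance: float = 5.0    # candidate-matching tolerance
    prevalence_threshold: float = 0.80


@dataclass
class PeakFit:
    """One fitted Gaussian band."""

    position: float
    height: float
    fwhm: float
    residual_rms: float
    offset: float = 0.0
    converged: bool = True


@dataclass
class ConsensusPeakSet:
    """Dataset-wide peak positions defining the shared feature space."""

    positions: np.ndarray          # ascending consensus positions, cm^-1
    tolerance: float               # matching tolerance, cm^-1
    prevalence: np.ndarray         # fraction of spectra where detected

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.prevalence = np.asarray(self.prevalence, float)
        if np.any(np.diff(self.positions) <= self.tolerance):
            raise ValidationError("consensus positions closer than the matching tolerance")

    def __len__(self) -> int:
        return int(self.positions.size)

    def to_dict(self) -> dict:
        return {"positions": self.positions.tolist(), "tolerance": self.tolerance,
                "prevalence": self.prevalence.tolist()}


def _gauss(x: np.ndarray, h: float, mu: float, w: float, c: float) -> np.ndarray:
    return h * np.exp(-FWHM_FACTOR * (x - mu) ** 2 / w ** 2) + c


def noise_estimate(y: np.ndarray) -> float:
    """Robust noise SD from successive differences (MAD-based, / sqrt(2))."""
    d = np.diff(y)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def detect_peaks(s: Spectrum, prominence_factor: float = 3.0,
                 min_separation: float = 8.0,
                 min_prominence_frac: float = 0.05) -> np.ndarray:
    """Candidate peak positions: local maxima separated by at least
    ``min_separation`` cm^-1 whose prominence exceeds both
    ``prominence_factor`` times the noise level and
    ``min_prominence_frac`` of the spectrum's peak-to-peak range (the
    floor keeps near-noiseless spectra from yielding microscopic bumps)."""
    if s.stage != "snv":
        raise ValidationError("peak detection expects an SNV-normalized spectrum")
    y = s.intensity
    noise = max(noise_estimate(y), 1e-12)
    prominence = max(prominence_factor * noise, min_prominence_frac * float(np.ptp(y)))
    distance = max(1, int(np.ceil(min_separation / s.axis.spacing)))
    idx, _props = find_peaks(y, prominence=prominence, distance=distance)
    return s.axis.values[idx]


def fit_gaussian_peaks(s: Spectrum, candidates: Sequence[float],
                       fit_window: float = 15.0,
                       position_tolerance: float = 5.0) -> list[PeakFit]:
    """Nonlinear least-squares Gaussian fit around each candidate position.

    Bounds: h >= 0, FWHM in [2, 60] cm^-1, mu within +/- tolerance of the
    candidate; a local constant offset is co-fitted. To keep blended
    doublets apart, each candidate's window is truncated at half the
    distance to its nearest neighboring candidate. Non-converged fits fall
    back to (candidate position, local amplitude, moment-based width) and
    are flagged.
    """
    x, y = s.axis.values, s.intensity
    spacing = s.axis.spacing
    cand = np.sort(np.asarray(list(candidates), float))
    fits: list[PeakFit] = []
    for c in candidates:
        if not (x[0] <= c <= x[-1]):
            raise ValidationError(f"candidate {c} outside the axis span")
        others = cand[cand != c]
        half_dist = float(np.min(np.abs(others - c)) / 2.0) if others.size else np.inf
        win = float(np.clip(min(fit_window, half_dist), 4.0 * spacing, fit_window))
        m = (x >= c - win) & (x <= c + win)
        xs, ys = x[m], y[m]
        ptol = min(position_tolerance, win)
        lo_c, hi_c = max(c - ptol, x[0]), min(c + ptol, x[-1])
        c0 = float(np.min(ys))
        h0 = max(float(np.max(ys) - c0), 1e-9)
        try:
            popt, _ = curve_fit(
                _gauss, xs, ys, p0=[h0, c, 10.0, c0],
                bounds=([0.0, lo_c, FWHM_BOUNDS[0], -np.inf],
                        [np.inf, hi_c, FWHM_BOUNDS[1], np.inf]),
                maxfev=2000)
            h, mu, w, off = (float(v) for v in popt)
            resid = float(np.sqrt(np.mean((_gauss(xs, *popt) - ys) ** 2)))
            fits.append(PeakFit(mu, h, w, resid, off, True))
        except RuntimeError:
            # Moment-based fallback on the positive part of the window.
            pos = np.maximum(ys - c0, 0.0)
            tot = pos.sum()
            width = (np.sqrt(8 * np.log(2) * ((pos * (xs - c) ** 2).sum() / tot))
                     if tot > 0 else 10.0)
            fits.append(PeakFit(float(c), h0, float(np.clip(width, *FWHM_BOUNDS)),
                                float(np.std(ys)), c0, False))
    return fits


def build_consensus(fits_by_spectrum: Mapping[str, Sequence[PeakFit]],
                    tolerance: float = 5.0,
                    prevalence_threshold: float = 0.80) -> ConsensusPeakSet:
    """Cluster fitted positions across spectra into the consensus peak set.

    Single-linkage clustering in 1-D (sorted positions split where the gap
    exceeds ``tolerance``); clusters detected in at least
    ``prevalence_threshold`` of spectra are retained, each represented by
    the median member position.
    """
    if len(fits_by_spectrum) < 2:
        raise ValidationError("need at least two spectra to build a consensus")
    sids, positions = [], []
    for sid, fits in fits_by_spectrum.items():
        for f in fits:
            sids.append(sid)
            positions.append(f.position)
    if not positions:
        raise ValidationError("no fitted peaks supplied")
    positions = np.asarray(positions)
    sids = np.asarray(sids, dtype=object)
    order = np.argsort(positions, kind="stable")
    positions, sids = positions[order], sids[order]
    breaks = np.flatnonzero(np.diff(positions) > tolerance) + 1
    n_spectra = len(fits_by_spectrum)
    cons_pos, cons_prev = [], []
    for grp_pos, grp_sid in zip(np.split(positions, breaks), np.split(sids, breaks)):
        prevalence = len(set(grp_sid)) / n_spectra
        if prevalence >= prevalence_threshold:
            cons_pos.append(float(np.median(grp_pos)))
            cons_prev.append(prevalence)
    if not cons_pos:
        raise ValidationError("no peak cluster reaches the prevalence threshold")
    return ConsensusPeakSet(np.array(cons_pos), tolerance, np.array(cons_prev))


def _feature_columns(consensus: ConsensusPeakSet) -> list[str]:
    cols = []
    for p in consensus.positions:
        nom = int(round(p))
        cols += [f"{nom}_position", f"{nom}_height", f"{nom}_fwhm"]
    return cols


def extract_features(spectra: Sequence[Spectrum],
                     consensus: ConsensusPeakSet,
                     fits_by_spectrum: Mapping[str, Sequence[PeakFit]] | None = None,
                     fit_window: float = 15.0) -> pd.DataFrame:
    """Per-spectrum feature matrix: 3 columns (position, height, FWHM) per
    consensus peak, indexed by spectrum_id. Uses each spectrum's matched fit
    when one lies within the consensus tolerance, otherwise a constrained
    refit at the consensus position (height bounded at zero), so absent
    bands yield near-zero heights instead of gaps."""
    if len(consensus) == 0:
        raise ValidationError("empty consensus peak set")
    rows = {}
    for s in spectra:
        if consensus.positions[0] < s.axis.values[0] or consensus.positions[-1] > s.axis.values[-1]:
            raise ValidationError(
                f"spectrum {s.spectrum_id!r} axis does not cover the consensus positions")
        fits = list(fits_by_spectrum.get(s.spectrum_id, [])) if fits_by_spectrum else []
        fitted_pos = np.array([f.position for f in fits]) if fits else np.empty(0)
        vals = []
        for i, p in enumerate(consensus.positions):
            match = None
            if fitted_pos.size:
                j = int(np.argmin(np.abs(fitted_pos - p)))
                if abs(fitted_pos[j] - p) <= consensus.tolerance:
                    match = fits[j]
            if match is None:
                # Constrained refit; window truncated at the nearest
                # neighboring consensus peak, as in the free fit.
                gaps = [abs(q - p) / 2.0 for k, q in enumerate(consensus.positions) if k != i]
                win = min(fit_window, min(gaps)) if gaps else fit_window
                match = fit_gaussian_peaks(s, [p], fit_window=win,
                                           position_tolerance=consensus.tolerance)[0]
            vals += [match.position, match.height, match.fwhm]
        rows[s.spectrum_id] = vals
    out = pd.DataFrame.from_dict(rows, orient="index", columns=_feature_columns(consensus))
    out.index.name = "spectrum_id"
    return out


def features_from_spectra(spectra: Sequence[Spectrum],
                          config: PeakConfig | None = None
                          ) -> tuple[pd.DataFrame, ConsensusPeakSet]:
    """Full feature pipeline: detect -> fit -> consensus -> feature matrix."""
    config = config or PeakConfig()
    fits_by_spectrum = {}
    for s in spectra:
        cands = detect_peaks(s, config.prominence_factor, config.min_separation,
                             config.min_prominence_frac)
        fits_by_spectrum[s.spectrum_id] = fit_gaussian_peaks(
            s, cands, config.fit_window, config.position_tolerance)
    consensus = build_consensus(fits_by_spectrum, config.position_tolerance,
                                config.prevalence_threshold)
    matrix = extract_features(spectra, consensus, fits_by_spectrum, config.fit_window)
    return matrix, consensus
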