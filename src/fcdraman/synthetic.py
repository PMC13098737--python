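"""Synthetic single-cell Raman spectra with the statistical structure of the
FCD study: class-dependent Gaussian bands on an autofluorescence baseline,
passed through a simple CCD instrument model (response curve, wavenumber
distortion, dark counts, shot noise, accumulation averaging).

The generator also emits the calibration reference measurements (dark,
intensity standard, wavenumber reference peaks) distorted by the same
instrument model, so the full preprocessing chain can be exercised and
checked against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CalibrationRefs,
    Spectrum,
    ValidationError,
    WavenumberAxis,
    band_catalogue,
)

__all__ = [
    "ClassProfile",
    "InstrumentModel",
    "SimulatedSpectrum",
    "SyntheticDataset",
    "default_profiles",
    "default_instrument",
    "simulate_spectrum",
    "simulate_dataset",
    "gaussian_bands",
    "NUISANCE_BANDS",
]

FWHM_FACTOR = 4.0 * np.log(2.0)

#: Class-shared bands without diagnostic contrast, placed >= 27 cm^-1 from
#: every catalogue band so each resolves as its own peak. Eight of them:
#: the 1593/1602 cm^-1 catalogue pair blends into a single consensus peak
#: at the 1.1 cm^-1 resolution, so 17 + 8 profile bands yield the 24
#: consistently detected dataset-wide peaks.
NUISANCE_BANDS = (720.0, 880.0, 960.0, 1070.0, 1160.0, 1390.0, 1490.0, 1690.0)

#: Relative base amplitude per band (multiplies ``base_height``); strong
#: phenylalanine/CH2 bands, weaker nucleic-acid bands, modest shoulders.
_BASE_AMPLITUDE = {
    758.0: 0.75, 827.0: 0.70, 852.0: 0.90, 933.0: 0.80, 1002.0: 1.60,
    1031.0: 1.00, 1101.0: 0.85, 1124.0: 0.80, 1201.0: 0.70, 1263.0: 0.95,
    1302.0: 1.10, 1337.0: 0.95, 1447.0: 1.40, 1554.0: 0.80, 1593.0: 0.90,
    1602.0: 0.90, 1657.0: 1.20,
    720.0: 0.55, 880.0: 0.60, 960.0: 0.55, 1070.0: 0.65, 1160.0: 0.55,
    1390.0: 0.60, 1490.0: 0.60, 1690.0: 0.65,
}

#: FWHM in cm^-1 per band. The 1593/1602 pair sits 9 cm^-1 apart and needs
#: narrow widths to resolve as two peaks at 1.1 cm^-1 resolution.
_BASE_FWHM = {1593.0: 6.0, 1602.0: 6.0}
_DEFAULT_FWHM = 12.0


def gaussian_bands(x: np.ndarray, positions: np.ndarray, heights: np.ndarray,
                   fwhms: np.ndarray) -> np.ndarray:
    """Sum of Gaussian bands h*exp(-4 ln2 (x-mu)^2 / w^2)."""
    x = np.asarray(x, float)[:, None]
    return np.sum(
        np.asarray(heights, float)
        * np.exp(-FWHM_FACTOR * (x - np.asarray(positions, float)) ** 2
                 / np.asarray(fwhms, float) ** 2),
        axis=1,
    )


@dataclass
class ClassProfile:
    """Mean band structure of one diagnostic class.

    ``bands`` has columns position, mean_height, height_cv, fwhm. Baseline is
    an exponential autofluorescence decay A*exp(-(x-300)/tau).
    """

    diagnosis: str
    bands: pd.DataFrame
    baseline_amplitude: float
    baseline_tau: float = 700.0
    n_spectra: int | None = None


@dataclass
class InstrumentModel:
    """Simple CCD Raman instrument: 1024 bins over 300-1800 cm^-1.

    ``distortion_coeffs`` are np.polyval coefficients of the monotone map
    from the instrument's nominal (measured) axis to true wavenumber; the
    wavenumber-calibration step must recover this map. ``response`` is the
    relative spectral sensitivity (strictly positive). Per-accumulation noise
    is Gaussian with variance dark_noise_sd^2 + shot_scale * signal, the
    standard CCD dark + shot-noise model.
    """

    n_bins: int = 1024
    lo: float = 300.0
    hi: float = 1800.0
    accumulations: int = 10
    dark_level: float = 100.0
    dark_noise_sd: float = 5.0
    shot_scale: float = 1.0
    response_center: float = 1150.0
    response_width: float = 520.0
    response_floor: float = 0.55
    response_gain: float = 0.8
    distortion_coeffs: np.ndarray | None = None
    spike_prob: float = 0.0
    spike_amplitude: float = 5000.0

    def __post_init__(self) -> None:
        if self.distortion_coeffs is None:
            self.distortion_coeffs = _default_distortion(self.lo, self.hi)
        self.distortion_coeffs = np.asarray(self.distortion_coeffs, float)
        ax = self.axis().values
        if np.any(np.diff(self.true_wavenumber(ax)) <= 0):
            raise ValidationError("distortion polynomial not monotone over the axis")
        if np.any(self.response(ax) <= 0):
            raise ValidationError("response curve must be strictly positive")

    def axis(self) -> WavenumberAxis:
        """Nominal (uncalibrated) acquisition axis."""
        return WavenumberAxis.raw_default(self.n_bins, self.lo, self.hi)

    def response(self, x: np.ndarray) -> np.ndarray:
        """Relative instrument sensitivity at nominal wavenumber x."""
        return self.response_floor + self.response_gain * np.exp(
            -((np.asarray(x, float) - self.response_center) / self.response_width) ** 2)

    def true_wavenumber(self, measured: np.ndarray) -> np.ndarray:
        """Map nominal axis values to true wavenumbers."""
        return np.polyval(self.distortion_coeffs, np.asarray(measured, float))

    def apparent_position(self, true: np.ndarray) -> np.ndarray:
        """Invert the distortion: where a true wavenumber lands on the nominal axis."""
        if not hasattr(self, "_inv_grid"):
            dense = np.linspace(self.lo - 20.0, self.hi + 20.0, 20001)
            object.__setattr__(self, "_inv_grid", (np.polyval(self.distortion_coeffs, dense), dense))
        tv, dense = self._inv_grid
        a = np.interp(np.asarray(true, float), tv, dense)
        deriv = np.polyder(np.poly1d(self.distortion_coeffs))
        for _ in range(3):  # Newton refinement to machine precision
            a = a - (np.polyval(self.distortion_coeffs, a) - true) / deriv(a)
        return a


def _default_distortion(lo: float, hi: float) -> np.ndarray:
    """A gentle cubic distortion (|shift| <= ~3 cm^-1), monotone over [lo, hi]."""
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    # T(a) = a + 1.2 + 0.8 u - 0.5 u^2 + 0.3 u^3, u = (a - mid)/half
    u = np.poly1d([1.0 / half, -mid / half])
    p = np.poly1d([0.0, 0.0, 1.0, 0.0]) + 1.2 + 0.8 * u - 0.5 * u ** 2 + 0.3 * u ** 3
    return p.coeffs


def default_instrument(**overrides) -> InstrumentModel:
    return InstrumentModel(**overrides)


def default_profiles(effect_scale: float = 3.0, base_height: float = 500.0,
                     height_cv: float = 0.15,
                     baseline_amplitude: float | None = None,
                     baseline_tau: float = 700.0) -> dict[str, ClassProfile]:
    """Build the three class profiles (normal, FCD_IIa, FCD_IIb).

    Every profile contains the 17 catalogue bands plus 7 shared nuisance
    bands (24 detectable peaks). At each diagnostically contrasted band the
    between-class mean-height difference equals
    ``effect_scale * height_cv * base amplitude`` — i.e. effect_scale times
    the within-class height SD. The contrast directions follow the observed
    mean-spectrum comparisons (e.g. FCD higher at 758, normal higher at
    1002 for the lesion-vs-normal contrast; IIb higher at 852..1593, IIa
    higher at 1002 for the subtype contrast).

    ``baseline_amplitude`` defaults to 10x the mean band height, so baseline
    removal is genuinely exercised.
    """
    if effect_scale < 0:
        raise ValueError("effect_scale must be >= 0")
    cat = band_catalogue()
    positions = [b.position for b in cat] + list(NUISANCE_BANDS)
    d1 = {b.position: {"FCD": 1.0, "normal": -1.0}.get(b.fcd_vs_normal, 0.0) for b in cat}
    d2 = {b.position: {"IIb": 1.0, "IIa": -1.0}.get(b.iia_vs_iib, 0.0) for b in cat}

    rows: dict[str, list] = {"normal": [], "FCD_IIa": [], "FCD_IIb": []}
    for pos in sorted(positions):
        b = base_height * _BASE_AMPLITUDE[pos]
        w = _BASE_FWHM.get(pos, _DEFAULT_FWHM)
        delta = effect_scale * height_cv * b
        s1, s2 = d1.get(pos, 0.0), d2.get(pos, 0.0)
        mean_normal = b - s1 * delta / 2.0
        mean_fcd = b + s1 * delta / 2.0
        mean_iia = mean_fcd - s2 * delta / 2.0
        mean_iib = mean_fcd + s2 * delta / 2.0
        for label, h in (("normal", mean_normal), ("FCD_IIa", mean_iia), ("FCD_IIb", mean_iib)):
            if h <= 0:
                raise ValueError(f"effect_scale {effect_scale} drives band {pos} non-positive")
            rows[label].append((pos, h, height_cv, w))

    if baseline_amplitude is None:
        mean_h = base_height * float(np.mean([_BASE_AMPLITUDE[p] for p in positions]))
        baseline_amplitude = 10.0 * mean_h
    return {
        label: ClassProfile(
            diagnosis=label,
            bands=pd.DataFrame(rows[label], columns=["position", "mean_height", "height_cv", "fwhm"]),
            baseline_amplitude=float(baseline_amplitude),
            baseline_tau=baseline_tau,
        )
        for label in ("normal", "FCD_IIa", "FCD_IIb")
    }


@dataclass
class SimulatedSpectrum:
    """One simulated acquisition with its ground truth."""

    accumulations: list[Spectrum]
    averaged: Spectrum
    truth: dict


def _height_jitter(rng: np.random.Generator, cv: np.ndarray, n: int) -> np.ndarray:
    """Multiplicative log-normal jitter with mean 1 and SD ~= cv per band."""
    cv = np.asarray(cv, float)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=(n,) if np.ndim(cv) == 0 else cv.shape))


def simulate_spectrum(profile: ClassProfile, instrument: InstrumentModel,
                      seed: int | np.random.Generator, spectrum_id: str = "sim",
                      patient_multiplier: np.ndarray | float = 1.0) -> SimulatedSpectrum:
    """Forward-simulate one cell acquisition (all accumulations + average).

    Clean signal = sum of Gaussian bands with per-spectrum log-normal height
    jitter, multiplied by the response curve, plus the exponential
    autofluorescence baseline and the dark level; per-accumulation Gaussian
    noise with variance dark_noise_sd^2 + shot_scale*signal; accumulations
    averaged pointwise. Reproducible under a fixed integer seed.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    elif isinstance(seed, (int, np.integer)):
        rng = np.random.default_rng(int(seed))
    else:
        raise TypeError("seed must be an integer or a numpy Generator")
    if instrument.accumulations < 1:
        raise ValueError("need at least one accumulation")

    axis = instrument.axis()
    a = axis.values
    bands = profile.bands
    mu_true = bands["position"].to_numpy(float)
    jitter = _height_jitter(rng, bands["height_cv"].to_numpy(float), len(bands))
    heights = bands["mean_height"].to_numpy(float) * jitter * np.asarray(patient_multiplier, float)
    fwhm = bands["fwhm"].to_numpy(float)

    # Bands appear at their apparent (distorted) positions on the nominal axis.
    mu_apparent = instrument.apparent_position(mu_true)
    clean = gaussian_bands(a, mu_apparent, heights, fwhm)
    baseline = profile.baseline_amplitude * np.exp(-(a - instrument.lo) / profile.baseline_tau)
    noiseless = clean * instrument.response(a) + baseline + instrument.dark_level

    noise_sd = np.sqrt(instrument.dark_noise_sd ** 2
                       + instrument.shot_scale * np.maximum(noiseless - 0.0, 0.0))
    accs: list[Spectrum] = []
    for k in range(instrument.accumulations):
        y = noiseless + rng.normal(0.0, 1.0, a.size) * noise_sd
        if instrument.spike_prob > 0 and rng.random() < instrument.spike_prob:
            y[rng.integers(0, a.size)] += instrument.spike_amplitude
        accs.append(Spectrum(f"{spectrum_id}/acc{k}", axis, np.maximum(y, 0.0), stage="raw"))
    avg = Spectrum(spectrum_id, axis,
                   np.mean([s.intensity for s in accs], axis=0), stage="averaged")
    truth = {
        "positions_true": mu_true,
        "positions_apparent": mu_apparent,
        "heights": heights,
        "fwhm": fwhm,
        "baseline": baseline,
        "noiseless": noiseless,
        "clean": clean,
    }
    return SimulatedSpectrum(accs, avg, truth)


# Known positions of the wavenumber-calibration compound (acetaminophen-like
# band list restricted to the acquisition range).
_WAVENUMBER_REF_KNOWN = (465.1, 651.6, 797.2, 857.9, 968.7, 1105.5, 1168.5,
                         1236.8, 1278.5, 1323.9, 1371.5, 1561.5, 1648.4)


def make_calibration_refs(instrument: InstrumentModel, rng: np.random.Generator,
                          certified_scale: float = 1000.0,
                          n_dark_accumulations: int = 100) -> CalibrationRefs:
    """Reference measurements consistent with the instrument model.

    Dark: many-accumulation average of laser-off frames. Intensity standard:
    certified smooth curve times the true response (plus mild noise).
    Wavenumber references: known positions with their apparent positions
    under the instrument's distortion map.
    """
    axis = instrument.axis()
    a = axis.values
    dark = instrument.dark_level + rng.normal(
        0.0, instrument.dark_noise_sd / np.sqrt(n_dark_accumulations), a.size)
    certified = certified_scale * (0.4 + np.exp(-((a - 1200.0) / 900.0) ** 2))
    measured = certified * instrument.response(a) * (
        1.0 + rng.normal(0.0, 1e-3, a.size))
    known = np.array(_WAVENUMBER_REF_KNOWN)
    peaks = pd.DataFrame({
        "known_position": known,
        "measured_position": instrument.apparent_position(known),
    })
    return CalibrationRefs(
        dark=Spectrum("ref_dark", axis, dark, stage="averaged"),
        response_measured=Spectrum("ref_response_measured", axis, measured, stage="averaged"),
        response_certified=Spectrum("ref_response_certified", axis, certified, stage="averaged"),
        wavenumber_ref_peaks=peaks,
    )


@dataclass
class SyntheticDataset:
    spectra: list[Spectrum]
    meta: pd.DataFrame
    refs: CalibrationRefs
    truth: pd.DataFrame  # per spectrum x band: true heights
    params: dict


def _split_counts(total: int, groups: int) -> list[int]:
    """Distribute ``total`` over ``groups`` as evenly as possible, deterministically."""
    base, rem = divmod(total, groups)
    return [base + (1 if g < rem else 0) for g in range(groups)]


def simulate_dataset(profiles: Mapping[str, ClassProfile] | None = None,
                     instrument: InstrumentModel | None = None,
                     counts: Mapping[str, int] | None = None,
                     patients_per_class: Mapping[str, int] | None = None,
                     specimens_per_patient: int = 2,
                     patient_sd: float = 0.05,
                     seed: int = 0,
                     keep_accumulations: bool = False) -> SyntheticDataset:
    """Simulate a full cohort with patient/specimen hierarchy plus references.

    Defaults mirror the study design: 700 normal spectra, 396 FCD IIa and
    374 FCD IIb (1470 in total). Patients carry a small log-normal band-height
    offset (SD ``patient_sd``) shared by all their spectra, giving the data a
    mild intra-patient correlation. FCD IIb cells alternate between
    dysmorphic neurons and balloon cells.
    """
    profiles = profiles if profiles is not None else default_profiles()
    instrument = instrument if instrument is not None else default_instrument()
    counts = dict(counts) if counts is not None else {"normal": 700, "FCD_IIa": 396, "FCD_IIb": 374}
    patients_per_class = dict(patients_per_class) if patients_per_class is not None else {
        "normal": 18, "FCD_IIa": 9, "FCD_IIb": 9}
    for label, n in counts.items():
        if n < 1:
            raise ValueError(f"counts[{label!r}] must be >= 1")

    rng = np.random.default_rng(int(seed))
    refs = make_calibration_refs(instrument, rng)

    spectra: list[Spectrum] = []
    accumulations: dict[str, list[Spectrum]] = {}
    meta_rows, truth_rows = [], []
    for label in sorted(counts):
        profile = profiles[label]
        n_total = counts[label]
        n_pat = max(1, min(patients_per_class.get(label, 1), n_total))
        per_patient = _split_counts(n_total, n_pat)
        n_bands = len(profile.bands)
        idx = 0
        for p in range(n_pat):
            patient_id = f"{label}_pat{p:03d}"
            pmult = _height_jitter(rng, np.full(n_bands, patient_sd), n_bands)
            n_spec = max(1, specimens_per_patient)
            per_specimen = _split_counts(per_patient[p], n_spec)
            for sp, n_here in enumerate(per_specimen):
                specimen_id = f"{patient_id}_spc{sp}"
                for _ in range(n_here):
                    sid = f"{label}_{idx:04d}"
                    idx += 1
                    sim = simulate_spectrum(profile, instrument, rng, spectrum_id=sid,
                                            patient_multiplier=pmult)
                    spectra.append(sim.averaged)
                    if keep_accumulations:
                        accumulations[sid] = sim.accumulations
                    if label == "FCD_IIb":
                        cell = "balloon_cell" if rng.random() < 0.5 else "dysmorphic_neuron"
                    elif label == "FCD_IIa":
                        cell = "dysmorphic_neuron"
                    else:
                        cell = "normal_neuron"
                    meta_rows.append((sid, patient_id, specimen_id, cell, label))
                    truth_rows.append(dict(zip(
                        (f"h{int(round(q))}" for q in sim.truth["positions_true"]),
                        sim.truth["heights"]), spectrum_id=sid))
    meta = pd.DataFrame(meta_rows, columns=["spectrum_id", "patient_id", "specimen_id",
                                            "cell_type", "diagnosis"])
    truth = pd.DataFrame(truth_rows).set_index("spectrum_id")
    params = {
        "counts": counts, "patients_per_class": patients_per_class,
        "specimens_per_patient": specimens_per_patient, "patient_sd": patient_sd,
        "seed": int(seed),
    }
    ds = SyntheticDataset(spectra, meta, refs, truth, params)
    if keep_accumulations:
        ds.params["accumulations"] = accumulations  # type: ignore[assignment]
    return ds
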