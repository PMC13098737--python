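"""Domain types for single-cell Raman spectra and the reference band catalogue.

The pipeline operates on spectra acquired at 785 nm over 300-1800 cm^-1
(1024 detector bins) and, after preprocessing, on a truncated 700-1700 cm^-1
axis. Every spectrum carries a processing ``stage`` tag so that each
operation can assert what it receives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "CELL_TYPES",
    "DIAGNOSES",
    "WavenumberAxis",
    "Spectrum",
    "CellMeta",
    "BandAssignment",
    "CalibrationRefs",
    "band_catalogue",
    "catalogue_positions",
    "ValidationError",
    "validate_spectrum",
]

#: Processing stages in pipeline order.
STAGES = (
    "raw",
    "averaged",
    "dark_subtracted",
    "response_corrected",
    "calibrated",
    "smoothed",
    "debaselined",
    "truncated",
    "snv",
)

CELL_TYPES = ("normal_neuron", "dysmorphic_neuron", "balloon_cell")
DIAGNOSES = ("normal", "FCD_IIa", "FCD_IIb")


class ValidationError(ValueError):
    """A spectrum or metadata record violated a structural invariant."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing Raman-shift axis in cm^-1.

    Values must be finite, lie within [100, 4000] and contain at least two
    bins. The raw acquisition axis spans 300-1800 cm^-1 in 1024 bins; the
    truncated analysis axis spans 700-1700 cm^-1.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValidationError("axis must be 1-D with at least 2 bins")
        if not np.all(np.isfinite(v)):
            raise ValidationError("axis contains non-finite values")
        if np.any(np.diff(v) <= 0):
            raise ValidationError("axis must be strictly increasing")
        if v[0] < 100.0 or v[-1] > 4000.0:
            raise ValidationError("axis outside the plausible Raman range [100, 4000] cm^-1")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    @property
    def spacing(self) -> float:
        """Median bin spacing in cm^-1."""
        return float(np.median(np.diff(self.values)))

    @classmethod
    def raw_default(cls, n_bins: int = 1024, lo: float = 300.0, hi: float = 1800.0) -> "WavenumberAxis":
        """The nominal acquisition axis: ``n_bins`` uniform bins over [lo, hi]."""
        return cls(np.linspace(lo, hi, n_bins))


@dataclass
class Spectrum:
    """One single-cell Raman spectrum at a given processing stage.

    ``intensity`` holds detector counts for raw/averaged stages and unitless
    values after SNV normalization.
    """

    spectrum_id: str
    axis: WavenumberAxis
    intensity: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.intensity.shape != (len(self.axis),):
            raise ValidationError(
                f"spectrum {self.spectrum_id!r}: intensity length "
                f"{self.intensity.size} != axis length {len(self.axis)}"
            )

    def with_(self, *, intensity: np.ndarray | None = None,
              axis: WavenumberAxis | None = None, stage: str | None = None) -> "Spectrum":
        """Copy with replaced fields (axis/intensity/stage)."""
        return Spectrum(
            spectrum_id=self.spectrum_id,
            axis=axis if axis is not None else self.axis,
            intensity=np.array(self.intensity if intensity is None else intensity, dtype=float),
            stage=stage if stage is not None else self.stage,
        )


def validate_spectrum(s: Spectrum, atol: float = 1e-9) -> None:
    """Assert the stage-specific invariants of a spectrum.

    raw spectra must be nonnegative; SNV spectra must have mean 0 and sample
    standard deviation 1 within ``atol``.
    """
    if not np.all(np.isfinite(s.intensity)):
        raise ValidationError(f"spectrum {s.spectrum_id!r}: non-finite intensity")
    if s.stage == "raw" and np.any(s.intensity < 0):
        raise ValidationError(f"spectrum {s.spectrum_id!r}: raw intensities must be nonnegative")
    if s.stage == "snv":
        m = float(np.mean(s.intensity))
        sd = float(np.std(s.intensity, ddof=1))
        if abs(m) > atol or abs(sd - 1.0) > atol:
            raise ValidationError(
                f"spectrum {s.spectrum_id!r}: SNV invariant violated (mean={m:.3g}, sd={sd:.6g})"
            )


@dataclass(frozen=True)
class CellMeta:
    """Provenance of one spectrum: patient, specimen and histological label."""

    spectrum_id: str
    patient_id: str
    specimen_id: str
    cell_type: str
    diagnosis: str

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValidationError(f"unknown cell_type {self.cell_type!r}")
        if self.diagnosis not in DIAGNOSES:
            raise ValidationError(f"unknown diagnosis {self.diagnosis!r}")
        # Histological consistency: normal cortex contributes only normal
        # neurons; FCD IIa lesions contain dysmorphic neurons but no balloon
        # cells (balloon cells define type IIb).
        if self.diagnosis == "normal" and self.cell_type != "normal_neuron":
            raise ValidationError(
                f"{self.spectrum_id!r}: diagnosis 'normal' requires cell_type 'normal_neuron'"
            )
        if self.diagnosis == "FCD_IIa" and self.cell_type != "dysmorphic_neuron":
            raise ValidationError(
                f"{self.spectrum_id!r}: diagnosis 'FCD_IIa' requires cell_type 'dysmorphic_neuron'"
            )


@dataclass(frozen=True)
class BandAssignment:
    """One reference Raman band with its tentative biomolecular assignment.

    ``fcd_vs_normal`` records which group shows the higher band in the
    lesion-versus-normal comparison ('FCD', 'normal' or 'ns'); ``iia_vs_iib``
    does the same for the subtype comparison ('IIa', 'IIb' or 'ns').
    """

    position: float
    vibration_mode: str
    molecule: str
    fcd_vs_normal: str = "ns"
    iia_vs_iib: str = "ns"


# Reference catalogue of the 17 principal bands observed in normal cortex and
# FCD type II cells, with contrast directions from the mean-spectrum
# comparisons (which group had the higher band).
_BAND_CATALOGUE: tuple[BandAssignment, ...] = (
    BandAssignment(758.0, "nu_s (indole ring breathing)", "Tryptophan", "FCD", "ns"),
    BandAssignment(827.0, "nu_2 PO2- stretch", "Nucleic acid", "FCD", "ns"),
    BandAssignment(852.0, "Tyrosine ring breathing and proline", "Protein (collagen)", "FCD", "IIb"),
    BandAssignment(933.0, "nu(C-C) skeletal of collagen backbone", "Protein (collagen)", "FCD", "ns"),
    BandAssignment(1002.0, "nu ring breathing", "Phenylalanine and protein", "normal", "IIa"),
    BandAssignment(1031.0, "delta(C-H) and bending mode", "Phenylalanine and protein", "normal", "IIb"),
    BandAssignment(1101.0, "Amide III", "Proteins", "ns", "IIb"),
    BandAssignment(1124.0, "nu(C-C) skeletal of acyl backbone in lipid (transconformation)", "Lipid", "ns", "IIb"),
    BandAssignment(1201.0, "Amide III", "Proteins", "ns", "IIb"),
    BandAssignment(1263.0, "Ring breathing modes of the DNA/RNA bases; =C-H bend (protein)", "DNA/RNA", "FCD", "IIb"),
    BandAssignment(1302.0, "delta(CH2) twisting, wagging, and phospholipid", "Lipid and protein combination", "normal", "IIb"),
    BandAssignment(1337.0, "Ring breathing modes in the DNA bases", "DNA", "FCD", "ns"),
    BandAssignment(1447.0, "CH2 deformation (protein vibration)", "A marker for protein concentration", "normal", "IIb"),
    BandAssignment(1554.0, "nu(CN) and (NH) amide I", "Protein", "FCD", "IIb"),
    BandAssignment(1593.0, "C=C vibration", "Retinoid and enzymes", "ns", "IIb"),
    BandAssignment(1602.0, "delta(C=C)", "Phenylalanine and protein", "FCD", "ns"),
    BandAssignment(1657.0, "Amide I and fatty acids", "Triglycerides", "FCD", "ns"),
)


def band_catalogue() -> list[BandAssignment]:
    """The packaged 17-band reference catalogue (758-1657 cm^-1)."""
    return list(_BAND_CATALOGUE)


def catalogue_positions() -> np.ndarray:
    """Catalogue band positions in cm^-1, ascending."""
    return np.array([b.position for b in _BAND_CATALOGUE])


def catalogue_lookup(position: float, tol: float = 0.5) -> BandAssignment | None:
    """Return the catalogue band at ``position`` (within ``tol`` cm^-1), or None."""
    for b in _BAND_CATALOGUE:
        if abs(b.position - position) <= tol:
            return b
    return None


@dataclass
class CalibrationRefs:
    """Reference measurements required by the preprocessing chain.

    ``dark``: detector spectrum with the laser off. ``response_measured``:
    measured spectrum of the intensity standard; ``response_certified``: the
    standard's certified smooth emission curve on the same axis.
    ``wavenumber_ref_peaks``: table with columns ``known_position`` and
    ``measured_position`` (cm^-1) for the wavenumber-calibration compound.
    """

    dark: Spectrum
    response_measured: Spectrum
    response_certified: Spectrum
    wavenumber_ref_peaks: pd.DataFrame

    def __post_init__(self) -> None:
        ax = self.dark.axis.values
        for name in ("response_measured", "response_certified"):
            other = getattr(self, name).axis.values
            if other.shape != ax.shape or not np.allclose(other, ax):
                raise ValidationError(f"calibration reference {name} does not share the dark axis")
        need = {"known_position", "measured_position"}
        if not need.issubset(self.wavenumber_ref_peaks.columns):
            raise ValidationError(f"wavenumber_ref_peaks needs columns {sorted(need)}")
        if len(self.wavenumber_ref_peaks) < 4:
            raise ValidationError("need >= 4 wavenumber reference peaks (cubic map)")
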