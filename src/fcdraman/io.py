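"""Readers and writers for the long-form CSV interchange formats.

Canonical spectral interchange is long-form CSV with one row per
(spectrum, wavenumber): columns ``spectrum_id, wavenumber, intensity``.
Metadata is a separate CSV keyed by ``spectrum_id``. Calibration references
are a directory of four CSVs. All joins go through ``spectrum_id``; row
order is never meaningful.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CalibrationRefs,
    CellMeta,
    Spectrum,
    ValidationError,
    WavenumberAxis,
    validate_spectrum,
)

log = logging.getLogger(__name__)

SPECTRA_COLUMNS = ("spectrum_id", "wavenumber", "intensity")
META_COLUMNS = ("spectrum_id", "patient_id", "specimen_id", "cell_type", "diagnosis")


class FormatError(ValueError):
    """An input file does not have the expected tabular layout."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing column(s) {missing}")


def read_spectra(path: str | Path, meta_path: str | Path | None = None,
                 stage: str = "raw") -> tuple[list[Spectrum], pd.DataFrame | None]:
    """Read long-form spectra (and optionally metadata) from CSV.

    Returns one :class:`Spectrum` per distinct ``spectrum_id`` plus the
    metadata table restricted and joined to those ids. Spectra with a
    descending axis are sorted ascending (with a logged notice); duplicate
    (spectrum_id, wavenumber) rows and ids absent from the metadata raise.
    """
    df = pd.read_csv(path)
    _require_columns(df, SPECTRA_COLUMNS, str(path))
    dup = df.duplicated(subset=["spectrum_id", "wavenumber"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise FormatError(
            f"duplicated (spectrum_id, wavenumber) row: "
            f"({first['spectrum_id']!r}, {first['wavenumber']})"
        )
    spectra: list[Spectrum] = []
    for sid, grp in df.groupby("spectrum_id", sort=True):
        w = grp["wavenumber"].to_numpy(dtype=float)
        y = grp["intensity"].to_numpy(dtype=float)
        if np.all(np.diff(w) < 0):
            log.info("spectrum %r has a descending axis; sorting ascending", sid)
            w, y = w[::-1], y[::-1]
        elif np.any(np.diff(w) <= 0):
            order = np.argsort(w, kind="stable")
            w, y = w[order], y[order]
        try:
            axis = WavenumberAxis(w)
        except ValidationError as e:
            raise ValidationError(f"spectrum {sid!r}: {e}") from e
        spectra.append(Spectrum(str(sid), axis, y, stage=stage))

    meta = None
    if meta_path is not None:
        meta = read_metadata(meta_path)
        have = set(meta["spectrum_id"])
        orphans = sorted(s.spectrum_id for s in spectra if s.spectrum_id not in have)
        if orphans:
            raise FormatError(f"spectrum_id(s) present in data but not metadata: {orphans[:5]}")
    return spectra, meta


def read_metadata(meta_path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, dtype=str)
    _require_columns(meta, META_COLUMNS, str(meta_path))
    # Row-wise validation of the enums and histology constraints.
    for rec in meta.itertuples(index=False):
        CellMeta(rec.spectrum_id, rec.patient_id, rec.specimen_id, rec.cell_type, rec.diagnosis)
    return meta


def write_spectra(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as long-form CSV (full float precision)."""
    frames = [
        pd.DataFrame({
            "spectrum_id": s.spectrum_id,
            "wavenumber": s.axis.values,
            "intensity": s.intensity,
        })
        for s in spectra
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def write_refs(refs: CalibrationRefs, directory: str | Path) -> None:
    """Write calibration references as four CSVs under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name in ("dark", "response_measured", "response_certified"):
        s: Spectrum = getattr(refs, name)
        pd.DataFrame({"wavenumber": s.axis.values, "intensity": s.intensity}).to_csv(
            d / f"{name}.csv", index=False, float_format="%.17g")
    refs.wavenumber_ref_peaks.to_csv(d / "wavenumber_ref_peaks.csv", index=False,
                                     float_format="%.17g")


def read_refs(directory: str | Path) -> CalibrationRefs:
    d = Path(directory)
    specs = {}
    for name in ("dark", "response_measured", "response_certified"):
        df = pd.read_csv(d / f"{name}.csv")
        _require_columns(df, ("wavenumber", "intensity"), f"{name}.csv")
        specs[name] = Spectrum(name, WavenumberAxis(df["wavenumber"].to_numpy(float)),
                               df["intensity"].to_numpy(float), stage="averaged")
    peaks = pd.read_csv(d / "wavenumber_ref_peaks.csv")
    return CalibrationRefs(specs["dark"], specs["response_measured"],
                           specs["response_certified"], peaks)


def validation_report(spectra: Sequence[Spectrum], path: str | Path | None = None) -> dict:
    """Validate every spectrum; return (and optionally write) a JSON report."""
    report: dict = {"n_spectra": len(spectra), "failures": []}
    for s in spectra:
        try:
            validate_spectrum(s)
        except ValidationError as e:
            report["failures"].append({"spectrum_id": s.spectrum_id, "error": str(e)})
    report["ok"] = not report["failures"]
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    return report
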