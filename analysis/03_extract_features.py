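"""Build the consensus peak set and the Gaussian peak-feature matrix.

Detects peaks in every SNV spectrum, fits Gaussians, clusters the fitted
positions into the dataset-wide consensus set and expands each spectrum
into 3 features per consensus peak (position, height, FWHM). Writes
results/features/ including an annotated consensus table (nearest
catalogue band within 5 cm^-1).

Usage: python analysis/03_extract_features.py
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from fcdraman.core import band_catalogue
from fcdraman.io import read_spectra
from fcdraman.peaks import PeakConfig, features_from_spectra

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="inp", type=Path,
                    default=ROOT / "results" / "preprocessed" / "spectra_snv.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "features")
    args = ap.parse_args()

    spectra, _ = read_spectra(args.inp, stage="snv")
    X, consensus = features_from_spectra(spectra, PeakConfig())

    args.out.mkdir(parents=True, exist_ok=True)
    X.to_csv(args.out / "features.csv")
    (args.out / "consensus.json").write_text(json.dumps(consensus.to_dict(), indent=2))

    cat = band_catalogue()
    rows = []
    for p, prev in zip(consensus.positions, consensus.prevalence):
        nearest = min(cat, key=lambda b: abs(b.position - p))
        hit = abs(nearest.position - p) <= consensus.tolerance
        rows.append({"consensus_cm1": round(float(p), 1), "prevalence": round(float(prev), 2),
                     "catalogue_cm1": nearest.position if hit else None,
                     "assignment": nearest.molecule if hit else "(unassigned)"})
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "consensus_annotated.csv", index=False)

    print(f"{X.shape[0]} spectra x {X.shape[1]} features "
          f"from {len(consensus)} consensus peaks:")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
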