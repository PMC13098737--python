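"""Sensitivity of the held-out metrics to the train/test split.

The study reports a single 20% held-out evaluation. This driver refits the
final classifier (at each model's selected hyperparameters) across 20
different split seeds and reports the spread of accuracy and AUC — the
honest error bar on a single-split figure. It also repeats the split with
patient-level grouping, where all spectra of a patient stay on one side,
to expose any patient-leakage optimism in the spectrum-level split.

Usage: python analysis/05_split_sensitivity.py
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from fcdraman.classify import evaluate_on_test, fit_final_model, split_train_test
from fcdraman.io import read_metadata
from fcdraman.pipeline import MODEL1_GROUPING, MODEL2_GROUPING

ROOT = Path(__file__).resolve().parents[1]


def band(X, y, positive, n_features, C, groups, stratify_by, seeds=range(20)):
    accs, aucs = [], []
    for seed in seeds:
        (X_tr, y_tr), (X_te, y_te) = split_train_test(
            X, y, 0.2, seed=seed, stratify_by=stratify_by, groups=groups)
        model = fit_final_model(X_tr, y_tr, positive, n_features, C, seed=seed)
        rep = evaluate_on_test(model, X_te, y_te)
        accs.append(rep.accuracy)
        aucs.append(rep.auc)
    return np.array(accs), np.array(aucs)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", type=Path,
                    default=ROOT / "results" / "features" / "features.csv")
    ap.add_argument("--meta", type=Path,
                    default=ROOT / "results" / "cohort" / "metadata.csv")
    ap.add_argument("--models", type=Path, default=ROOT / "results" / "models")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "split_sensitivity.csv")
    args = ap.parse_args()

    X = pd.read_csv(args.features, index_col="spectrum_id")
    meta = read_metadata(args.meta).set_index("spectrum_id")
    labels, patients = meta["diagnosis"], meta["patient_id"]

    rows = []
    for name, positive, grouping, label in (
            ("model1", "FCDII", MODEL1_GROUPING, "FCD II vs normal"),
            ("model2", "FCD_IIb", MODEL2_GROUPING, "FCD IIa vs IIb")):
        rep = json.loads((args.models / f"{name}_report.json").read_text())
        y = labels.map(lambda v: grouping.get(v))
        keep = y.notna()
        Xm, ym, gm = X.loc[keep], y.loc[keep], patients.loc[keep]
        for stratify in ("class", "patient"):
            accs, aucs = band(Xm, ym, positive, rep["best_n_features"],
                              rep["best_C"], gm, stratify)
            rows.append({
                "model": label, "split": stratify,
                "accuracy_mean": round(float(accs.mean()), 3),
                "accuracy_min": round(float(accs.min()), 3),
                "accuracy_max": round(float(accs.max()), 3),
                "auc_mean": round(float(aucs.mean()), 3),
                "auc_min": round(float(aucs.min()), 3),
            })
    table = pd.DataFrame(rows)
    table.to_csv(args.out, index=False)
    print("held-out metrics across 20 split seeds "
          "(fixed hyperparameters from the main run):")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
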