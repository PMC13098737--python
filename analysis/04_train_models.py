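"""Train and evaluate both diagnostic models on the feature matrix.

Model 1 separates FCD type II (IIa + IIb pooled) from normal neurons;
model 2 separates the subtypes IIa and IIb on the 770 FCD spectra. Each
model: 20% held out before training, fivefold cross-validated grid search
over C and the retained-feature count (L1 selection inside every fold),
final L2 linear SVM, metrics at the upper-left ROC operating point.

Usage: python analysis/04_train_models.py [--seed 42]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from fcdraman.classify import ModelConfig, run_model
from fcdraman.io import read_metadata
from fcdraman.pipeline import MODEL1_GROUPING, MODEL2_GROUPING

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--features", type=Path,
                    default=ROOT / "results" / "features" / "features.csv")
    ap.add_argument("--meta", type=Path,
                    default=ROOT / "results" / "cohort" / "metadata.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "models")
    args = ap.parse_args()

    X = pd.read_csv(args.features, index_col="spectrum_id")
    labels = read_metadata(args.meta).set_index("spectrum_id")["diagnosis"]
    cfg = ModelConfig(seed=args.seed)

    args.out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, positive, grouping, label in (
            ("model1", "FCDII", MODEL1_GROUPING, "FCD II vs normal"),
            ("model2", "FCD_IIb", MODEL2_GROUPING, "FCD IIa vs IIb")):
        rep = run_model(X, labels, positive, cfg, grouping=grouping)
        (args.out / f"{name}_report.json").write_text(json.dumps(rep.to_dict(), indent=2))
        rep.roc.to_csv(args.out / f"{name}_roc.csv", index=False)
        rows.append({
            "model": label,
            "trained": sum(rep.train_counts.values()),
            "tested": sum(rep.test_counts.values()),
            "sensitivity_%": round(100 * rep.sensitivity),
            "specificity_%": round(100 * rep.specificity),
            "accuracy_%": round(100 * rep.accuracy),
            "AUC": round(rep.auc, 3),
            "C": rep.best_C,
            "features": rep.best_n_features,
        })
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "summary.csv", index=False)
    print(table.to_string(index=False))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
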