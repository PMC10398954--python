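#!/usr/bin/env python
"""Classify patients vs controls: fused aPSD + C/L + SPN features, LOOCV SVM.

Rebuilds the cohort feature container from the 03/04 artifacts, runs the
leave-one-out linear SVM (SPN filters and z-scaling refit within each
training fold), and writes results/classification.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from rseeg.classify import CohortFeatures, loocv_svm
from rseeg.io import BAND_BY_NAME

ROOT = Path(__file__).resolve().parents[1]
BANDS = [BAND_BY_NAME["delta"], BAND_BY_NAME["theta"]]


def main() -> None:
    metrics = pd.read_csv(ROOT / "results" / "graph_metrics.tsv", sep="\t")
    sids = metrics["subject_id"].tolist()
    labels = (metrics["group"] == "patient").astype(int).to_numpy()
    adjacency, apsd, c, l = {}, {}, {}, {}
    for band in BANDS:
        ws = [
            pd.read_csv(ROOT / "scratch" / "adjacency" / band.name / f"{sid}.csv", index_col=0).to_numpy()
            for sid in sids
        ]
        adjacency[band.name] = np.array(ws)
        table = pd.read_csv(ROOT / "results" / f"apsd_{band.name}.tsv", sep="\t", index_col=0)
        apsd[band.name] = table.loc[sids].mean(axis=1).to_numpy()
        c[band.name] = metrics[f"C_{band.name}"].to_numpy()
        l[band.name] = metrics[f"L_{band.name}"].to_numpy()
    cohort = CohortFeatures(
        subject_ids=sids, labels=labels, bands=BANDS, adjacency=adjacency, apsd=apsd, c=c, l=l
    )
    report = loocv_svm(cohort)
    out = ROOT / "results" / "classification.json"
    out.write_text(json.dumps(report.to_dict(), indent=1))
    print(
        f"LOOCV over {len(sids)} subjects: accuracy {report.accuracy}%, "
        f"sensitivity {report.sensitivity}%, specificity {report.specificity}%"
    )
    wrong = [s for s, t, p in zip(sids, report.y_true, report.y_pred) if t != p]
    print(f"misclassified: {wrong if wrong else 'none'}")


if __name__ == "__main__":
    main()
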