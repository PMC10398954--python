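#!/usr/bin/env python
"""Band-wise PLV adjacency matrices and weighted graph metrics (C, L).

Writes per-subject adjacency CSVs under scratch/adjacency/<band>/ and the
graph metrics table under results/graph_metrics.tsv for the delta and theta
bands, where the group effects live.
"""

from pathlib import Path

import pandas as pd

from rseeg.io import BAND_BY_NAME, load_cohort, read_recording
from rseeg.network import build_network, network_metrics
from rseeg.preprocess import preprocess_recording

ROOT = Path(__file__).resolve().parents[1]
BANDS = [BAND_BY_NAME["delta"], BAND_BY_NAME["theta"]]


def main() -> None:
    manifest = load_cohort(ROOT / "scratch" / "cohort" / "manifest.tsv")
    rows = []
    for sid, group, path in manifest:
        epochs = preprocess_recording(read_recording(path))
        row = {"subject_id": sid, "group": group}
        for band in BANDS:
            net = build_network(epochs, band)
            out_dir = ROOT / "scratch" / "adjacency" / band.name
            out_dir.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(
                net.W, index=net.channel_labels, columns=net.channel_labels
            ).to_csv(out_dir / f"{sid}.csv")
            c, length = network_metrics(net.W)
            row[f"C_{band.name}"] = c
            row[f"L_{band.name}"] = length
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "results" / "graph_metrics.tsv", sep="\t", index=False)
    print("group means:")
    print(df.groupby("group").mean(numeric_only=True).round(3))


if __name__ == "__main__":
    main()
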