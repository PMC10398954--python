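#!/usr/bin/env python
"""Patient-vs-control statistics: channel aPSD maps, PLV edge maps, C and L.

Consumes the tables written by 03/04 (no recomputation from raw EEG),
applies independent-sample t-tests with BH-FDR per (band x feature-kind)
family at alpha = 0.01, and writes results/stats_<band>_<kind>.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rseeg.stats import compare_cohort, upper_triangle

ROOT = Path(__file__).resolve().parents[1]
BANDS = ("delta", "theta")


def _load_adjacency(band: str, subject_ids):
    ws = []
    for sid in subject_ids:
        df = pd.read_csv(ROOT / "scratch" / "adjacency" / band / f"{sid}.csv", index_col=0)
        ws.append(df.to_numpy())
    return np.array(ws), list(df.columns)


def main() -> None:
    metrics = pd.read_csv(ROOT / "results" / "graph_metrics.tsv", sep="\t")
    is_patient = (metrics["group"] == "patient").to_numpy()
    sids = metrics["subject_id"].tolist()
    for band in BANDS:
        apsd = pd.read_csv(ROOT / "results" / f"apsd_{band}.tsv", sep="\t", index_col=0)
        apsd = apsd.loc[sids]
        chan_map = compare_cohort(
            apsd.to_numpy()[is_patient], apsd.to_numpy()[~is_patient], list(apsd.columns)
        )
        ws, labels = _load_adjacency(band, sids)
        edge_ids, iu, ju = upper_triangle(labels)
        edges = ws[:, iu, ju]
        edge_map = compare_cohort(edges[is_patient], edges[~is_patient], edge_ids)
        metric_cols = [f"C_{band}", f"L_{band}"]
        mvals = metrics[metric_cols].to_numpy()
        metric_map = compare_cohort(mvals[is_patient], mvals[~is_patient], ["C", "L"])
        for kind, sm in [("channels", chan_map), ("edges", edge_map), ("metrics", metric_map)]:
            sm.to_frame().to_csv(ROOT / "results" / f"stats_{band}_{kind}.tsv", sep="\t", index=False)
        up = int((chan_map.sig & (chan_map.t > 0)).sum())
        down = int((edge_map.sig & (edge_map.t < 0)).sum())
        print(
            f"{band}: {up}/{len(apsd.columns)} channels enhanced, "
            f"{down}/{len(edge_ids)} edges attenuated "
            f"(patients), C t={metric_map.t[0]:.1f}, L t={metric_map.t[1]:.1f}"
        )


if __name__ == "__main__":
    main()
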