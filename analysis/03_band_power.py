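#!/usr/bin/env python
"""Welch spectra and absolute band power (aPSD) for all subjects and bands.

Writes per-band channel x subject aPSD tables (results/apsd_<band>.tsv) and
a per-subject grand-average table across the five canonical bands.
"""

from pathlib import Path

import pandas as pd

from rseeg.io import CANONICAL_BANDS, load_cohort, read_recording
from rseeg.preprocess import preprocess_recording
from rseeg.spectral import apsd_table, welch_psd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    manifest = load_cohort(ROOT / "scratch" / "cohort" / "manifest.tsv")
    per_band: dict[str, list] = {b.name: [] for b in CANONICAL_BANDS}
    grand_rows = []
    subject_ids, channel_labels = [], None
    for sid, group, path in manifest:
        rec = read_recording(path)
        spec = welch_psd(preprocess_recording(rec))
        table = apsd_table(spec)  # channels x bands
        channel_labels = spec.channel_labels
        subject_ids.append(sid)
        for j, band in enumerate(CANONICAL_BANDS):
            per_band[band.name].append(table[:, j])
        grand_rows.append(
            {"subject_id": sid, "group": group}
            | {band.name: table[:, j].mean() for j, band in enumerate(CANONICAL_BANDS)}
        )
    for name, rows in per_band.items():
        pd.DataFrame(rows, index=subject_ids, columns=channel_labels).to_csv(
            ROOT / "results" / f"apsd_{name}.tsv", sep="\t"
        )
    grand = pd.DataFrame(grand_rows)
    grand.to_csv(ROOT / "results" / "grand_apsd.tsv", sep="\t", index=False)
    means = grand.groupby("group")[[b.name for b in CANONICAL_BANDS]].mean()
    print("grand-average aPSD by group (uV^2/Hz bin sums):")
    print(means.round(2))
    print("patient/control ratio:")
    print((means.loc["patient"] / means.loc["control"]).round(3))


if __name__ == "__main__":
    main()
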