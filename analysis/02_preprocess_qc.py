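#!/usr/bin/env python
"""Preprocess every subject and report the artifact-rejection yield.

Chain: average re-reference -> 0.5-45 Hz zero-phase band-pass -> 5 s
segmentation -> +/-90 uV amplitude rejection.  Writes per-subject epoch
counts to results/preprocess_qc.tsv.
"""

from pathlib import Path

import pandas as pd

from rseeg.io import load_cohort, read_recording
from rseeg.preprocess import preprocess_recording

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    manifest = load_cohort(ROOT / "scratch" / "cohort" / "manifest.tsv")
    rows = []
    for sid, group, path in manifest:
        rec = read_recording(path)
        epochs = preprocess_recording(rec)
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "epochs_total": int(epochs.kept_mask.size),
                "epochs_kept": epochs.n_epochs,
                "artifact_events": rec.meta.get("artifacts", {}).get("n_events", 0),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "results" / "preprocess_qc.tsv", sep="\t", index=False)
    kept = df["epochs_kept"].sum()
    total = df["epochs_total"].sum()
    print(f"kept {kept}/{total} epochs ({100 * kept / total:.1f}%) across {len(df)} subjects")
    print(df.groupby("group")[["epochs_kept", "artifact_events"]].mean().round(2))


if __name__ == "__main__":
    main()
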