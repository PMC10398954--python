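"""Group comparisons: feature-wise two-sample t-tests with BH-FDR correction.

Each feature family (channels of one band, upper-triangle edges of one band,
or graph metrics) is tested with an independent-samples Student t-test
(pooled variance; Welch optional) and corrected jointly within the family by
the Benjamini-Hochberg step-up procedure.  The sign convention is
patients-minus-controls: positive t means the feature is larger in patients.
Significance is declared at adjusted p < alpha with alpha = 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

__all__ = ["StatMap", "ttest_map", "fdr_correct", "compare_cohort", "upper_triangle"]


@dataclass
class StatMap:
    """Per-feature statistics for one patient-vs-control comparison."""

    feature_ids: list[str]
    t: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    sig: np.ndarray
    alpha: float

    @property
    def direction(self) -> np.ndarray:
        """+1 where patients > controls, -1 where patients < controls."""
        return np.sign(self.t).astype(int)

    @property
    def n_significant(self) -> int:
        return int(self.sig.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "t": self.t,
                "p_raw": self.p_raw,
                "p_fdr": self.p_fdr,
                "sig": self.sig,
                "direction": self.direction,
            }
        )


def ttest_map(
    group_a: np.ndarray, group_b: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided independent-samples t per feature column (A minus B).

    Features with zero variance in both groups get t = NaN and p = NaN
    (undefined test) rather than an arbitrary value.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValidationError("feature dimensions differ between groups")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValidationError("need at least 2 subjects per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # scipy returns t=0/p=1 for equal means with zero pooled variance only in
    # some versions; normalize: zero spread in both groups -> undefined
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    same = degenerate & (a.mean(axis=0) == b.mean(axis=0))
    t[degenerate] = np.nan
    p[degenerate] = np.nan
    t[same] = 0.0
    p[same] = 1.0
    return t, p


def fdr_correct(p_raw: np.ndarray, alpha: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg adjusted p-values and the sig mask (p_fdr < alpha)."""
    p = np.asarray(p_raw, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    p_adj = np.full_like(p, np.nan)
    if finite.any():
        _, adj, _, _ = multipletests(p[finite], alpha=alpha, method="fdr_bh")
        p_adj[finite] = adj
    mask = np.zeros(p.shape, dtype=bool)
    mask[finite] = p_adj[finite] < alpha
    return p_adj, mask


def compare_cohort(
    patients: np.ndarray,
    controls: np.ndarray,
    feature_ids: list[str],
    alpha: float = 0.01,
    equal_var: bool = True,
) -> StatMap:
    """t-test per feature (patients minus controls) + BH-FDR within the family."""
    t, p = ttest_map(patients, controls, equal_var=equal_var)
    if len(feature_ids) != t.size:
        raise ValidationError("feature_ids length inconsistent with feature matrix")
    p_fdr, sig = fdr_correct(p, alpha=alpha)
    return StatMap(feature_ids=list(feature_ids), t=t, p_raw=p, p_fdr=p_fdr, sig=sig, alpha=alpha)


def upper_triangle(labels: list[str]) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Edge ids and (i, j) indices of the strict upper triangle."""
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    ids = [f"{labels[i]}-{labels[j]}" for i, j in zip(iu, ju)]
    return ids, iu, ju
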