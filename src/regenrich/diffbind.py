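"""Tissue-vs-rest differential binding on consensus-peak counts.

A peak is called differentially bound in a tissue when its normalized
signal there differs from the mean of all other tissues by more than
``min_fold`` (default 2) AND the comparison is significant at ``alpha``
(default 0.05, raw p).  Signal is TMM-normalized log2-CPM; the default
p-value comes from a Welch two-sample t-test (focal samples vs the rest),
but any per-peak p-value function with the same signature can be plugged
in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import CountMatrix, normalized_cpm, tmm_factors

__all__ = ["DBResult", "differential_binding_test", "welch_pvalues"]


@dataclass(frozen=True)
class DBResult:
    peak_id: str
    tissue: str
    log2_fold: float
    p_value: float  # NaN when undefined (single-sample group)
    significant: bool
    direction: str  # up | down


PValueFn = Callable[[np.ndarray, np.ndarray], np.ndarray]
"""(peaks × focal samples, peaks × rest samples) → per-peak p-values."""


def welch_pvalues(focal: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test per row; NaN where a group has <2 samples."""
    if focal.shape[1] < 2 or rest.shape[1] < 2:
        return np.full(focal.shape[0], np.nan)
    return stats.ttest_ind(focal, rest, axis=1, equal_var=False).pvalue


def differential_binding_test(
        counts: CountMatrix, sample_sheet: pd.DataFrame, tissue: str,
        alpha: float = 0.05, min_fold: float = 2.0,
        rest_mean: str = "samples",
        factors: pd.Series | None = None,
        p_value_fn: PValueFn = welch_pvalues) -> list[DBResult]:
    """Differential binding of every peak in ``tissue`` versus all others.

    ``rest_mean`` chooses how the other-tissue average is formed: over all
    rest samples ("samples") or as the mean of per-tissue means
    ("tissue_means"), which matters when replicate numbers differ.
    """
    tissues = set(sample_sheet["tissue"])
    if tissue not in tissues:
        raise ValueError(f"tissue {tissue!r} not in sample sheet")
    if len(tissues) < 2:
        raise ValueError("differential binding needs ≥2 tissues")
    if rest_mean not in ("samples", "tissue_means"):
        raise ValueError("rest_mean must be 'samples' or 'tissue_means'")

    if factors is None:
        factors = tmm_factors(counts)
    logcpm = normalized_cpm(counts, factors, log2=True)

    focal_samples = sample_sheet.loc[sample_sheet["tissue"] == tissue, "sample"]
    rest_sheet = sample_sheet[sample_sheet["tissue"] != tissue]
    focal = logcpm[[s for s in focal_samples if s in logcpm.columns]]
    rest_cols = [s for s in rest_sheet["sample"] if s in logcpm.columns]
    rest = logcpm[rest_cols]

    if rest_mean == "samples":
        rest_avg = rest.mean(axis=1)
    else:
        per_tissue = {t: rest[[s for s in g["sample"] if s in rest.columns]].mean(axis=1)
                      for t, g in rest_sheet.groupby("tissue")}
        rest_avg = pd.DataFrame(per_tissue).mean(axis=1)

    fold = focal.mean(axis=1) - rest_avg  # log2 scale
    pvals = p_value_fn(focal.to_numpy(), rest.to_numpy())

    log2_min = np.log2(min_fold)
    out = []
    for i, peak_id in enumerate(logcpm.index):
        lf, p = float(fold.iloc[i]), float(pvals[i])
        sig = bool(not np.isnan(p) and p < alpha and abs(lf) > log2_min)
        out.append(DBResult(str(peak_id), tissue, lf, p, sig,
                            "up" if lf >= 0 else "down"))
    return out


def db_results_frame(results: Sequence[DBResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
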