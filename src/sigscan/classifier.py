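"""MSI calling from homopolymer marker panels.

Samples are scored by their number of positive markers; the MSI calling
threshold is chosen by maximizing the Matthews correlation coefficient
(MCC) against an immunohistochemistry truth set, and calls can be
cross-tabulated against the extended Bethesda panel's three categories
(MSS: 0/10 markers, MSI-L: 1-2/10, MSI-H: >=3/10).  Samples below the
chosen threshold form a single MSS/MSI-L class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

POSITIVE, NEGATIVE, MISSING = "positive", "negative", "missing"
MSI, MSS = "MSI", "MSS/MSI-L"
BETHESDA = ("MSS", "MSI-L", "MSI-H")


def _to_numeric(matrix: pd.DataFrame) -> pd.DataFrame:
    """Accept {positive, negative, missing} strings or 1/0/NaN numerics."""
    if matrix.dtypes.apply(lambda d: d == object).any():
        mapping = {POSITIVE: 1.0, NEGATIVE: 0.0, MISSING: np.nan}
        bad = set(np.unique(matrix.astype(object).to_numpy().astype(str))) - set(
            mapping
        ) - {"nan"}
        if bad:
            raise ValueError(f"unexpected genotype values: {sorted(bad)}")
        return matrix.replace(mapping).astype(float)
    vals = matrix.to_numpy(dtype=float)
    ok = np.isnan(vals) | (vals == 0) | (vals == 1)
    if not ok.all():
        raise ValueError("numeric genotype matrices must contain only 0, 1 or NaN")
    return matrix.astype(float)


def score_samples(
    matrix: pd.DataFrame,
    threshold: int = 3,
    missing_as_negative: bool = False,
) -> pd.DataFrame:
    """Positive-marker counts and MSI calls at a fixed threshold.

    Missing genotypes are excluded from the count by default (the
    conservative choice); ``missing_as_negative`` gives the alternative
    fixed-denominator mode.  A sample with no callable marker is flagged
    uncallable rather than silently called negative.
    """
    num = _to_numeric(matrix)
    n_called = num.notna().sum(axis=1)
    counts = num.sum(axis=1, skipna=True).astype(int)
    if missing_as_negative:
        n_called = pd.Series(num.shape[1], index=num.index)
    uncallable = n_called == 0
    call = np.where(counts >= threshold, MSI, MSS)
    call = np.where(uncallable, "uncallable", call)
    return pd.DataFrame(
        {
            "n_positive": counts,
            "n_called": n_called,
            "call": call,
            "uncallable": uncallable,
        },
        index=num.index,
    )


def matthews_cc(tp: int, fp: int, tn: int, fn: int) -> float:
    """MCC from confusion counts; defined as 0 when any marginal is zero."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclass
class ClassifierEvaluation:
    table: pd.DataFrame      # theta, TP, FP, TN, FN, sensitivity, specificity, mcc
    best_threshold: int
    best_mcc: float

    @property
    def roc(self) -> pd.DataFrame:
        out = self.table.copy()
        out["fpr"] = 1 - out["specificity"]
        return out[["theta", "fpr", "sensitivity"]]


def optimize_threshold(
    matrix: pd.DataFrame,
    truth: pd.Series,
    missing_as_negative: bool = False,
) -> ClassifierEvaluation:
    """Scan every threshold 0..n_markers and pick the MCC-optimal one.

    ``truth`` is boolean (True = MMR-deficient by IHC).  Ties in MCC are
    broken toward the smallest threshold (maximal sensitivity).  Samples
    with no callable marker are excluded from the evaluation.
    """
    truth = truth.reindex(matrix.index)
    if truth.isna().any():
        raise ValueError("truth labels missing for some samples")
    truth = truth.astype(bool)
    if truth.all() or (~truth).all():
        raise ValueError("truth contains a single class; MCC undefined")
    scores = score_samples(matrix, threshold=0, missing_as_negative=missing_as_negative)
    callable_mask = ~scores["uncallable"]
    counts = scores.loc[callable_mask, "n_positive"].to_numpy()
    y = truth[callable_mask].to_numpy()

    rows = []
    for theta in range(matrix.shape[1] + 1):
        pred = counts >= theta
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        tn = int(np.sum(~pred & ~y))
        fn = int(np.sum(~pred & y))
        sens = tp / (tp + fn) if (tp + fn) else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        rows.append((theta, tp, fp, tn, fn, sens, spec, matthews_cc(tp, fp, tn, fn)))
    table = pd.DataFrame(
        rows, columns=["theta", "TP", "FP", "TN", "FN", "sensitivity", "specificity", "mcc"]
    )
    best = int(table.loc[table["mcc"].idxmax(), "theta"])  # idxmax takes first max
    return ClassifierEvaluation(table, best, float(table["mcc"].max()))


def bethesda_classify(counts, n_markers: int = 10, cutpoints=(1, 3)):
    """Bethesda categories from positive-marker counts out of the 10-marker panel.

    0 markers -> MSS; 1-2 -> MSI-L; >=3 -> MSI-H (cutpoints configurable).
    """
    arr = np.asarray(counts)
    if np.any(arr < 0) or np.any(arr > n_markers):
        raise ValueError(f"counts must be within 0..{n_markers}")
    low, high = cutpoints
    out = np.full(arr.shape, "MSS", dtype=object)
    out[arr >= low] = "MSI-L"
    out[arr >= high] = "MSI-H"
    if np.isscalar(counts) or np.ndim(counts) == 0:
        return out.item()
    return pd.Series(out, index=counts.index if isinstance(counts, pd.Series) else None)


@dataclass
class Concordance:
    table: pd.DataFrame
    discordant: pd.DataFrame


def concordance_table(calls_panel: pd.Series, calls_bethesda: pd.Series) -> Concordance:
    """Cross-tabulate panel calls {MSI, MSS/MSI-L} against Bethesda categories.

    Discordant samples (panel MSI without Bethesda MSI-H, or vice versa)
    are listed for follow-up.
    """
    only_a = set(calls_panel.index) - set(calls_bethesda.index)
    only_b = set(calls_bethesda.index) - set(calls_panel.index)
    if only_a or only_b:
        raise ValueError(
            f"sample sets differ; only in panel: {sorted(only_a)}, "
            f"only in Bethesda: {sorted(only_b)}"
        )
    calls_bethesda = calls_bethesda.reindex(calls_panel.index)
    tab = pd.crosstab(calls_panel, calls_bethesda)
    tab = tab.reindex(index=[MSI, MSS], columns=list(BETHESDA), fill_value=0)
    disc_mask = (calls_panel == MSI) != (calls_bethesda == "MSI-H")
    disc = pd.DataFrame(
        {
            "panel": calls_panel[disc_mask],
            "bethesda": calls_bethesda[disc_mask],
        }
    )
    return Concordance(tab, disc)
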