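"""Agreement statistics between two measurement methods.

Used to validate the scanner pipeline against a reference (a desktop
scanner, manual counting, or the synthetic generator's analytic truth):

* MAPE — mean absolute per cent error, (100/n)·Σ|x_ref − x_test|/x_ref;
* APE SD — population standard deviation of the per-sample absolute per
  cent errors;
* R² — squared Pearson correlation of the two methods' values;
* per-class discrimination error — fraction of members of each true class
  assigned a different class.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "mape",
    "ape_sd",
    "r_squared",
    "discrimination_error",
    "evaluate_traits",
]


def _paired(reference, test) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape or ref.ndim != 1:
        raise ValueError("reference and test must be 1-D arrays of equal length")
    if ref.size < 1:
        raise ValueError("need at least one sample")
    return ref, tst


def _ape_percent(reference, test) -> np.ndarray:
    ref, tst = _paired(reference, test)
    if np.any(ref == 0):
        raise ValueError("reference values must be non-zero for per cent errors")
    return 100.0 * np.abs(ref - tst) / np.abs(ref)


def mape(reference, test) -> float:
    """Mean absolute per cent error of ``test`` against ``reference`` (%)."""
    return float(_ape_percent(reference, test).mean())


def ape_sd(reference, test) -> float:
    """Population SD of the absolute per cent errors (%)."""
    return float(np.std(_ape_percent(reference, test)))


def r_squared(reference, test) -> float:
    """Squared Pearson correlation between the two methods' values.

    NaN when either vector is constant (the correlation is undefined).
    """
    ref, tst = _paired(reference, test)
    if ref.size < 2 or np.ptp(ref) == 0 or np.ptp(tst) == 0:
        return math.nan
    return float(np.corrcoef(ref, tst)[0, 1] ** 2)


def discrimination_error(
    true_labels, predicted_labels, classes: tuple[str, ...] | None = None
) -> dict[str, float]:
    """Per-class misclassification rate in per cent.

    For each true class, the percentage of its members whose predicted
    class differs.  Classes absent from ``true_labels`` map to NaN (not
    0).  Labels outside the class set raise ``ValueError``.
    """
    truth = list(true_labels)
    pred = list(predicted_labels)
    if len(truth) != len(pred):
        raise ValueError("label sequences must have equal length")
    if classes is None:
        classes = tuple(dict.fromkeys(truth))
    unknown = set(truth) - set(classes)
    if unknown:
        raise ValueError(f"unknown true labels: {sorted(unknown)}")
    out: dict[str, float] = {}
    for cls in classes:
        members = [p for t, p in zip(truth, pred) if t == cls]
        if not members:
            out[cls] = math.nan
        else:
            wrong = sum(p != cls for p in members)
            out[cls] = 100.0 * wrong / len(members)
    return out


def evaluate_traits(
    truth: pd.DataFrame,
    measured: pd.DataFrame,
    traits: list[str],
    key: str = "plant_id",
) -> pd.DataFrame:
    """Agreement report for selected trait columns of two keyed tables.

    Returns one row per trait: n, MAPE (%), APE SD (%), R².
    """
    merged = truth.merge(measured, on=key, suffixes=("_ref", "_test"))
    rows = []
    for trait in traits:
        ref = merged[f"{trait}_ref"].to_numpy(dtype=float)
        tst = merged[f"{trait}_test"].to_numpy(dtype=float)
        keep = ~(np.isnan(ref) | np.isnan(tst))
        ref, tst = ref[keep], tst[keep]
        rows.append(
            {
                "trait": trait,
                "n": int(ref.size),
                "mape_pct": mape(ref, tst) if ref.size else math.nan,
                "ape_sd_pct": ape_sd(ref, tst) if ref.size else math.nan,
                "r_squared": r_squared(ref, tst),
            }
        )
    return pd.DataFrame(rows)
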