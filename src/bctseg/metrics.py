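"""Segmentation overlap metrics, rater-agreement statistics, and the
density bias audit.

Overlap between two binary regions A and B:

* Dice similarity coefficient  DSC = 2|A n B| / (|A| + |B|), in [0, 1];
  DSC > 0.75 is the conventional "excellent agreement" bound;
* difference coefficient       DC  = |A xor B| / ((|A| + |B|) / 2),
  in [0, 2];
* logit-transformed Dice       LDSC = ln(DSC / (1 - DSC)), mapping
  (0, 1) onto the real line for normal-theory inference (paired
  t-tests on LDSC values).

Inter-rater reliability of Likert scores uses Cronbach's alpha,
alpha = k/(k-1) * (1 - sum_i var_i / var_total), with population
variances (any consistent variance convention leaves alpha unchanged).

The bias audit quantifies how merging a mis-segmented component (skin,
muscle or skinfold) into the breast soft-tissue mask shifts the
HU-derived density, in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calibration import CalibrationTable
from .core_io import LabelMap, Volume
from .density import hu_derived_density

__all__ = [
    "OverlapResult",
    "dsc",
    "dc",
    "ldsc",
    "overlap",
    "paired_ldsc_test",
    "cronbach_alpha",
    "bias_audit",
]


@dataclass
class OverlapResult:
    dsc: float
    dc: float
    ldsc: float | None
    n_a: int
    n_b: int


def _counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    if a.shape != b.shape:
        raise ValueError("regions must share the same grid")
    a = a.astype(bool)
    b = b.astype(bool)
    return int(np.count_nonzero(a)), int(np.count_nonzero(b)), int(np.count_nonzero(a & b))


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|)."""
    na, nb, ni = _counts(a, b)
    if na + nb == 0:
        raise ValueError("both regions are empty")
    return 2.0 * ni / (na + nb)


def dc(a: np.ndarray, b: np.ndarray) -> float:
    """Difference coefficient |A xor B| / ((|A| + |B|) / 2)."""
    na, nb, ni = _counts(a, b)
    if na + nb == 0:
        raise ValueError("both regions are empty")
    n_xor = na + nb - 2 * ni
    return n_xor / ((na + nb) / 2.0)


def ldsc(dsc_value: float) -> float:
    """Logit-transformed Dice, ln(DSC / (1 - DSC)); unbounded at 0 and 1."""
    if not 0.0 < dsc_value < 1.0:
        raise ValueError("LDSC is unbounded at DSC of exactly 0 or 1")
    return float(np.log(dsc_value / (1.0 - dsc_value)))


def overlap(a: np.ndarray, b: np.ndarray) -> OverlapResult:
    na, nb, ni = _counts(a, b)
    d = dsc(a, b)
    return OverlapResult(
        dsc=d,
        dc=dc(a, b),
        ldsc=ldsc(d) if 0.0 < d < 1.0 else None,
        n_a=na,
        n_b=nb,
    )


def paired_ldsc_test(set1: list[float], set2: list[float]) -> float:
    """Two-sided paired t-test on logit-transformed Dice values.

    Returns the p-value; identical lists give p = 1.
    """
    if len(set1) != len(set2):
        raise ValueError("paired samples must have equal length")
    if len(set1) < 2:
        raise ValueError("need at least two pairs")
    t1 = np.array([ldsc(x) for x in set1])
    t2 = np.array([ldsc(x) for x in set2])
    if np.allclose(t1, t2):
        return 1.0
    res = stats.ttest_rel(t1, t2)
    return float(res.pvalue)


def cronbach_alpha(scores: np.ndarray) -> float:
    """Cronbach's alpha of a raters x items score matrix.

    Rows are the k raters (the "items" of the reliability model),
    columns the rated objects.  Population variances are used for both
    the per-rater and the total (column-sum) variance; alpha is
    invariant to that convention as long as it is consistent.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least two raters")
    k = scores.shape[0]
    item_vars = scores.var(axis=1)  # population variance per rater
    total_var = scores.sum(axis=0).var()
    if total_var == 0:
        raise ValueError("zero total variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def bias_audit(v: Volume, labels: LabelMap, cal: CalibrationTable) -> dict[str, float]:
    """Density bias from merging a mis-segmented component into the breast.

    For each of skin, muscle and skinfold present in the label map, the
    HU-derived density is recomputed with that component merged into the
    breast soft-tissue mask; the entry is the signed difference to the
    correct estimate in percentage points.  Absent components are
    omitted.
    """
    base_mask = labels.mask("fat", "gland")
    if not base_mask.any():
        raise ValueError("label map contains no breast soft tissue")
    d_base = hu_derived_density(v, base_mask, cal)
    audit: dict[str, float] = {}
    for comp in ("skin", "muscle", "skinfold"):
        comp_mask = labels.mask(comp)
        if not comp_mask.any():
            continue
        d_with = hu_derived_density(v, base_mask | comp_mask, cal)
        audit[comp] = 100.0 * (d_with - d_base)
    return audit
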