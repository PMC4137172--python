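"""Semi-quantitative and quantitative comparison between growth conditions.

Three unrelated statistics live here because they share the same role in the
workflow — deciding which proteins differ between pyruvate fermentation and
Fe(III) reduction:

* **Normalized total spectra.**  Label-free spectrum counting; the sum of
  spectral counts in each sample is scaled to a common value (the mean of
  the raw per-sample totals), so counts are comparable across samples when
  equal protein amounts were loaded.
* **The fold / absolute / error rule.**  A protein is differentially
  abundant when its mean normalized count in one condition is at least
  ``fold_min`` times the other (default 2), the absolute difference is at
  least ``abs_min`` (default 5, guarding against the unreliability of very
  low counts), and the ``mean ± error`` intervals of the two conditions do
  not overlap.  The error estimator is the sample standard deviation or, for
  a duplicate pair, the semi-difference ``|x1 - x2| / 2``.
* **Significance B.**  An intensity-binned robust outlier statistic on
  dimethyl-label log2 ratios: within each intensity bin the null spread is
  estimated from the median and the 15.87th/84.13th percentiles (the
  one-sigma quantiles of a Gaussian), the robust z-score is the ratio
  distance from the median in units of the one-sided spread, and the
  two-sided tail probability is ``erfc(z / sqrt(2))``.  P-values are
  adjusted across all proteins by Benjamini-Hochberg.
* **ΔΔCt.**  The comparative-qPCR formula: relative expression per condition
  is ``2^(-ΔCt)`` against a reference gene, cross-condition fold change is
  ``2^(-ΔΔCt)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erfc
from statsmodels.stats.multitest import multipletests

from .core_io import SpectralCountMatrix

__all__ = [
    "ConditionSummary",
    "DifferentialCall",
    "QpcrResult",
    "normalize_total_spectra",
    "summarize_condition",
    "call_differential_expression",
    "significance_b",
    "delta_delta_ct",
]


@dataclass(frozen=True)
class ConditionSummary:
    """Mean and error of a protein's normalized counts in one condition."""

    protein_id: str
    condition: str
    mean: float
    error: float
    error_mode: str  # {sd, semi_difference}
    n: int

    def __post_init__(self) -> None:
        if self.mean < 0 or self.error < 0:
            raise ValueError("mean and error must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.error_mode not in ("sd", "semi_difference"):
            raise ValueError(f"unknown error_mode {self.error_mode!r}")
        if self.error_mode == "semi_difference" and self.n != 2:
            raise ValueError("semi_difference is defined for exactly two replicates")
        if self.n == 1 and self.error != 0:
            raise ValueError("a single replicate has zero error by convention")


@dataclass(frozen=True)
class DifferentialCall:
    protein_id: str
    direction: str  # {up_in_A, up_in_B, none}
    fold: float
    abs_diff: float
    separated: bool

    def __post_init__(self) -> None:
        if self.direction not in ("up_in_A", "up_in_B", "none"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass(frozen=True)
class QpcrResult:
    gene: str
    ct_target_A: float
    ct_ref_A: float
    ct_target_B: float
    ct_ref_B: float
    delta_ct_A: float
    delta_ct_B: float
    delta_delta_ct: float
    fold: float
    rel_expression_A: float
    rel_expression_B: float


def normalize_total_spectra(
    matrix: SpectralCountMatrix,
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Scale each sample so all per-sample totals equal the mean raw total.

    Returns ``(normalized, factors, common_value)`` where ``normalized`` is a
    float DataFrame (proteins x samples), ``factors`` the per-sample scaling
    factors ``common_value / total_j``, and ``common_value`` the mean of the
    raw per-sample totals.  Within-sample rank order is conserved.
    """
    frame = matrix.to_frame().astype(float)
    if frame.shape[1] == 0:
        raise ValueError("matrix has no samples")
    totals = frame.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    common_value = float(totals.mean())
    factors = common_value / totals
    normalized = frame * factors
    return normalized, factors, common_value


def summarize_condition(
    protein_id: str,
    condition: str,
    values,
    error_mode: str = "sd",
) -> ConditionSummary:
    """Average one protein's replicate counts within a condition.

    ``error_mode="sd"`` uses the sample standard deviation (n-1 denominator);
    ``"semi_difference"`` uses ``|x1 - x2| / 2`` and requires exactly two
    replicates.  A single replicate gets error 0.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size < 1:
        raise ValueError("at least one replicate value required")
    mean = float(values.mean())
    if values.size == 1:
        error = 0.0
    elif error_mode == "semi_difference":
        if values.size != 2:
            raise ValueError("semi_difference requires exactly two replicates")
        error = float(abs(values[0] - values[1]) / 2)
    elif error_mode == "sd":
        error = float(values.std(ddof=1))
    else:
        raise ValueError(f"unknown error_mode {error_mode!r}")
    return ConditionSummary(
        protein_id=protein_id,
        condition=condition,
        mean=mean,
        error=error,
        error_mode=error_mode,
        n=int(values.size),
    )


def call_differential_expression(
    summary_A: ConditionSummary,
    summary_B: ConditionSummary,
    fold_min: float = 2.0,
    abs_min: float = 5.0,
) -> DifferentialCall:
    """Apply the fold / absolute-difference / error-separation rule.

    The higher condition must be at least ``fold_min`` times the lower, the
    absolute difference at least ``abs_min``, and the two ``mean ± error``
    intervals strictly separated.  When the lower mean is zero the fold is
    reported as infinity.  Swapping the arguments flips the direction and
    changes nothing else.
    """
    if summary_A.protein_id != summary_B.protein_id:
        raise ValueError("summaries are for different proteins")
    if summary_A.condition == summary_B.condition:
        raise ValueError("summaries are for the same condition")
    a, b = summary_A.mean, summary_B.mean
    hi, lo = max(a, b), min(a, b)
    err_hi, err_lo = (
        (summary_A.error, summary_B.error)
        if a >= b
        else (summary_B.error, summary_A.error)
    )
    if hi == lo:
        fold = 1.0
    elif lo == 0:
        fold = math.inf
    else:
        fold = hi / lo
    abs_diff = hi - lo
    separated = (hi - err_hi) > (lo + err_lo)
    passes = fold >= fold_min and abs_diff >= abs_min and separated
    if not passes:
        direction = "none"
    elif a > b:
        direction = "up_in_A"
    else:
        direction = "up_in_B"
    return DifferentialCall(
        protein_id=summary_A.protein_id,
        direction=direction,
        fold=fold,
        abs_diff=abs_diff,
        separated=separated,
    )


# Gaussian one-sigma quantiles: the spread estimators of significance B.
_UPPER_Q = 0.8413
_LOWER_Q = 0.1587


def significance_b(
    table: pd.DataFrame,
    bin_size: int = 300,
    center_median: bool = False,
) -> pd.DataFrame:
    """Intensity-binned robust outlier p-values for log2 dimethyl ratios.

    Rows are sorted by intensity and cut into consecutive bins of at least
    ``bin_size`` rows (the final remainder is merged into the last bin; with
    fewer than ``bin_size`` rows everything is one bin).  Within a bin, with
    ``m`` the median and ``u``/``l`` the 84.13th/15.87th percentiles of the
    log2 ratios (linear interpolation), the robust z-score of ratio ``r`` is
    ``(r - m)/(u - m)`` above the median and ``(m - r)/(m - l)`` below, and
    ``p = erfc(z / sqrt(2))`` capped at 1.  Degenerate spread (``u == m`` or
    ``m == l``) yields z = 0 on the affected side.  ``p_adjusted`` is the
    Benjamini-Hochberg adjustment across all rows.  Output row order matches
    the input; the result is invariant to input row order.

    ``center_median=True`` subtracts each bin's median from its ratios first
    (off by default; the ratios are assumed already mixing-normalized).
    """
    if bin_size < 3:
        raise ValueError("bin_size must be >= 3")
    required = {"protein_id", "log2_ratio", "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ratio table missing columns {sorted(missing)}")
    if len(table) < 1:
        raise ValueError("empty ratio table")
    intensity = table["intensity"].to_numpy(dtype=float)
    if (intensity <= 0).any():
        raise ValueError("intensities must be positive")
    ratios = table["log2_ratio"].to_numpy(dtype=float)

    n = len(table)
    # stable sort on (intensity, original position) so ties cannot make the
    # result depend on input row order
    order = np.lexsort((np.arange(n), intensity))
    n_bins = max(1, n // bin_size)
    bin_of_sorted = np.minimum(np.arange(n) // bin_size, n_bins - 1)
    bin_index = np.empty(n, dtype=int)
    bin_index[order] = bin_of_sorted

    robust_z = np.zeros(n)
    shifted = ratios.copy()
    for b in range(n_bins):
        mask = bin_index == b
        r = ratios[mask]
        m = float(np.median(r))
        if center_median:
            shifted[mask] = r - m
            r = r - m
            m = 0.0
        u = float(np.quantile(r, _UPPER_Q))
        l = float(np.quantile(r, _LOWER_Q))
        z = np.zeros(r.size)
        above = r >= m
        if u > m:
            z[above] = (r[above] - m) / (u - m)
        below = ~above
        if m > l:
            z[below] = (m - r[below]) / (m - l)
        robust_z[mask] = z

    p = np.minimum(erfc(robust_z / math.sqrt(2.0)), 1.0)
    _, p_adjusted, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "protein_id": table["protein_id"].to_numpy(),
            "log2_ratio": shifted if center_median else ratios,
            "intensity": intensity,
            "robust_z": robust_z,
            "p": p,
            "p_adjusted": np.maximum(p_adjusted, p),
            "bin_index": bin_index,
        }
    )
    return out


def delta_delta_ct(
    ct_target_A: float,
    ct_ref_A: float,
    ct_target_B: float,
    ct_ref_B: float,
    gene: str = "",
) -> QpcrResult:
    """Comparative qPCR: ΔCt per condition, ΔΔCt across conditions.

    ``ΔCt = Ct(target) - Ct(reference)`` within each condition;
    ``ΔΔCt = ΔCt_A - ΔCt_B``; the A-vs-B expression fold change is
    ``2^(-ΔΔCt)`` and per-condition expression relative to the reference
    gene is ``2^(-ΔCt)``.
    """
    delta_a = ct_target_A - ct_ref_A
    delta_b = ct_target_B - ct_ref_B
    ddct = delta_a - delta_b
    return QpcrResult(
        gene=gene,
        ct_target_A=ct_target_A,
        ct_ref_A=ct_ref_A,
        ct_target_B=ct_target_B,
        ct_ref_B=ct_ref_B,
        delta_ct_A=delta_a,
        delta_ct_B=delta_b,
        delta_delta_ct=ddct,
        fold=2.0 ** (-ddct),
        rel_expression_A=2.0 ** (-delta_a),
        rel_expression_B=2.0 ** (-delta_b),
    )
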