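"""Sensitivity, threshold-sweep and missing-data analyses.

Each analysis evaluates the appraisal indices over an ordered family of
inputs — gradient populations, nested locus subsets, or masked copies of a
matrix — and summarises the trend with an ordinary least-squares slope or a
Pearson correlation against the complete-data series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidityError
from .genotype_io import GenotypeMatrix
from .grouping import ThresholdRule
from .indices import METHODS, evaluate
from .simulate import inject_missing, nested_subsets

__all__ = ["SensitivityCurve", "sensitivity_curve", "ols_slope", "threshold_sweep", "missing_sweep"]


@dataclass(frozen=True)
class SensitivityCurve:
    """An ordered (index, value) series for one appraisal method."""

    x: tuple
    y: tuple
    method: str
    rule: ThresholdRule | None = None

    def __post_init__(self):
        if len(self.x) != len(self.y) or len(self.x) < 2:
            raise ValueError("curve needs >= 2 (x, y) points of equal length")
        if any(b <= a for a, b in zip(self.x, self.x[1:])):
            raise ValueError("x must be strictly increasing")

    @property
    def slope(self) -> float:
        return ols_slope(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "method": self.method, "value": self.y})


def ols_slope(curve) -> float:
    """Ordinary least-squares slope of value against the 1-based index."""
    x, y = (curve.x, curve.y) if isinstance(curve, SensitivityCurve) else curve
    if len(x) < 2:
        raise ValueError("need >= 2 points to fit a slope")
    return float(stats.linregress(np.asarray(x, float), np.asarray(y, float)).slope)


def sensitivity_curve(
    populations,
    method: str,
    rule: ThresholdRule | None = None,
    undefined_pairs: str = "error",
) -> SensitivityCurve:
    """Evaluate one method over an ordered list of populations (x = 1..k)."""
    populations = list(populations)
    if len(populations) < 2:
        raise ValueError("need >= 2 populations for a sensitivity curve")
    y = tuple(
        evaluate(pop, method, rule, undefined_pairs).value for pop in populations
    )
    return SensitivityCurve(tuple(range(1, len(y) + 1)), y, method.lower(), rule)


def threshold_sweep(
    matrix: GenotypeMatrix,
    methods,
    m_values,
    subset_sizes,
    seed: int,
    metric: str = "count",
) -> pd.DataFrame:
    """Grid of index values over nested locus subsets x variety thresholds.

    Only the comparison- and ratio-based indices respond to the threshold;
    requesting the others is a validity error.
    """
    methods = [m.lower() for m in methods]
    bad = [m for m in methods if m not in ("c-vdp", "r-vdp")]
    if bad:
        raise ValidityError(
            f"threshold sweep applies to c-vdp and r-vdp only (the variety threshold of "
            f"p-vdp must be perfect match; tdp is threshold-invariant): got {bad}"
        )
    subsets = nested_subsets(matrix, sorted(subset_sizes, reverse=True), seed)
    records = []
    for sub in subsets:
        for m_val in m_values:
            rule = ThresholdRule(metric, m_val)
            for method in methods:
                res = evaluate(sub, method, rule)
                records.append(
                    {"n_loci": sub.n_loci, "M": m_val, "method": method, "value": res.value}
                )
    return pd.DataFrame.from_records(records)


def missing_sweep(
    matrix: GenotypeMatrix,
    rates,
    methods,
    rule: ThresholdRule,
    seed: int,
    subset_sizes=None,
    undefined_pairs: str = "same",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stability of the indices under increasing missing-data rates.

    For each rate, masked copies of the matrix (and of its nested locus
    subsets, when ``subset_sizes`` is given) are scored, and each rate's
    series is correlated (Pearson) with the complete-data series, pairing
    points by subset size.

    The probability-based index is excluded by definition. Pairs left with
    no overlapping locus by the mask default to the ``same`` classification:
    without evidence of a difference the samples cannot be declared
    different varieties, consistent with masking being a type-II
    (underestimation) error.

    Returns (long-format value table, per-method/rate correlation table).
    """
    methods = [m.lower() for m in methods]
    bad = [m for m in methods if m not in ("tdp", "c-vdp", "r-vdp")]
    if bad:
        raise ValidityError(
            f"the probability-based index cannot be used for loci combinations with "
            f"missing data: got {bad}"
        )
    rates = list(rates)
    if subset_sizes is None:
        subset_sizes = [matrix.n_loci]
    subsets = nested_subsets(matrix, sorted(subset_sizes, reverse=True), seed)

    records = []
    for r_idx, rate in enumerate(rates):
        for sub in subsets:
            masked = inject_missing(sub, rate, seed=seed + 1 + r_idx)
            for method in methods:
                res = evaluate(masked, method, rule, undefined_pairs=undefined_pairs)
                records.append(
                    {"rate": rate, "n_loci": sub.n_loci, "method": method, "value": res.value}
                )
    values = pd.DataFrame.from_records(records)

    corr_records = []
    for method in methods:
        pivot = (
            values[values["method"] == method]
            .pivot(index="n_loci", columns="rate", values="value")
            .sort_index()
        )
        baseline = 0 if 0 in pivot.columns else rates[0]
        base = pivot[baseline]
        for rate in rates:
            series = pivot[rate]
            ok = base.notna() & series.notna()
            if series[ok].equals(base[ok]):
                r = 1.0
            elif ok.sum() >= 2 and base[ok].nunique() > 1 and series[ok].nunique() > 1:
                r = float(stats.pearsonr(base[ok], series[ok]).statistic)
            else:
                r = float("nan")
            corr_records.append({"method": method, "rate": rate, "pearson_r": r})
    return values, pd.DataFrame.from_records(corr_records)
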