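"""Cross-validation against a reference method (incurred-sample rules).

A new bioanalytical platform is compared with an established one on
incurred (real study) samples.  Each pair is conform when the
difference between the two measured concentrations is within +/-20% of
their mean; the cross-validation passes when at least 67% of pairs
conform (on at least 20 samples).  A Pearson product-moment correlation
(two-sided p from the t transform with n-2 df) summarizes the agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurement",
    "CrossValResult",
    "conformity",
    "cross_validate",
    "pearson_correlation",
    "average_duplicates",
    "simulate_paired_concentrations",
]


@dataclass
class PairedMeasurement:
    """One sample quantified by both methods."""

    conc_method_a: float
    conc_method_b: float
    pct_difference: float  # % of the pair mean; nan when both are zero
    conform: bool
    defined: bool = True
    sample_id: str | None = None


def conformity(
    a: float,
    b: float,
    limit_pct: float = 20.0,
    sample_id: str | None = None,
) -> PairedMeasurement:
    """Incurred-sample conformity of one pair.

    pct_difference = 100 * (a - b) / ((a + b) / 2); conform iff its
    absolute value is <= limit_pct.  Both-zero pairs are flagged
    undefined rather than raising.
    """
    if a < 0 or b < 0:
        raise ValueError("concentrations must be >= 0")
    if a == 0 and b == 0:
        return PairedMeasurement(
            conc_method_a=a, conc_method_b=b, pct_difference=float("nan"),
            conform=False, defined=False, sample_id=sample_id,
        )
    diff = 100.0 * (a - b) / ((a + b) / 2.0)
    return PairedMeasurement(
        conc_method_a=float(a), conc_method_b=float(b),
        pct_difference=float(diff), conform=bool(abs(diff) <= limit_pct),
        sample_id=sample_id,
    )


def pearson_correlation(pairs: Sequence[PairedMeasurement]) -> tuple[float, float]:
    """Pearson r and two-sided p over the paired concentrations."""
    a = np.array([p.conc_method_a for p in pairs], dtype=float)
    b = np.array([p.conc_method_b for p in pairs], dtype=float)
    if len(a) < 3:
        raise ValueError("correlation requires n >= 3 pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation requires non-zero variance in both methods")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CrossValResult:
    n: int
    n_conform: int
    conforming_fraction: float
    verdict: bool
    r: float | None
    p_value: float | None
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n, "n_conform": self.n_conform,
            "conforming_fraction": self.conforming_fraction, "verdict": self.verdict,
            "r": self.r, "p_value": self.p_value, "warning": self.warning,
        }


def cross_validate(
    pairs: Sequence[PairedMeasurement],
    min_fraction: float = 0.67,
    min_n: int = 20,
) -> CrossValResult:
    """Verdict over all defined pairs: conforming fraction >= min_fraction.

    Pairs flagged undefined (both methods zero) are excluded from the
    denominator.  Fewer than ``min_n`` samples yields a warning.
    """
    if not pairs:
        raise ValueError("no paired measurements")
    defined = [p for p in pairs if p.defined]
    if not defined:
        raise ValueError("all pairs are undefined (both methods zero)")
    n = len(defined)
    n_conform = sum(p.conform for p in defined)
    fraction = n_conform / n
    try:
        r, p_value = pearson_correlation(defined)
    except ValueError:
        r, p_value = None, None
    warning = f"only {n} incurred samples; guidelines recommend >= {min_n}" if n < min_n else None
    return CrossValResult(
        n=n, n_conform=n_conform, conforming_fraction=float(fraction),
        verdict=bool(fraction >= min_fraction), r=r, p_value=p_value, warning=warning,
    )


def average_duplicates(
    df: pd.DataFrame,
    sample_col: str = "sample_id",
    a_col: str = "conc_method_a",
    b_col: str = "conc_method_b",
) -> pd.DataFrame:
    """Average technical duplicates per sample and method before pairing.

    Raw duplicates are retained by the caller; this returns one row per
    sample with the per-method means.
    """
    return (
        df.groupby(sample_col, sort=True)[[a_col, b_col]].mean().reset_index()
    )


def simulate_paired_concentrations(
    n_samples: int,
    method_cv: float,
    seed,
    conc_range: tuple[float, float] = (10.0, 800.0),
) -> list[PairedMeasurement]:
    """Paired concentrations with independent log-normal method noise.

    True trough-like concentrations are drawn log-uniformly over
    ``conc_range``; each method reports the truth times a mean-1
    log-normal factor with the given CV.  Used for the trend checks of
    the conformity rule.
    """
    rng = np.random.default_rng(seed)
    truth = np.exp(rng.uniform(np.log(conc_range[0]), np.log(conc_range[1]), n_samples))
    sigma = np.sqrt(np.log1p(method_cv**2)) if method_cv > 0 else 0.0
    factor = lambda: (
        rng.lognormal(-0.5 * sigma * sigma, sigma, n_samples) if sigma > 0 else np.ones(n_samples)
    )
    a = truth * factor()
    b = truth * factor()
    return [
        conformity(float(ai), float(bi), sample_id=f"S{i+1}")
        for i, (ai, bi) in enumerate(zip(a, b))
    ]
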