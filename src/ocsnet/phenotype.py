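"""SOCS scoring, symptom-group definitions, and covariate-adjusted inference.

The Short Obsessive-Compulsive Disorder Screener (SOCS) has seven
parent-rated items on a 0/1/2 scale (never/sometimes/often). Sumscores of
6 or more define the 'probable OCD' group; sumscore 0 defines symptom-free
controls; scoring 'often' (2) on at least one item defines the posthoc
'high OCS' group, compared against children with all items <= 1. One
missing item is tolerated via the weighted sumscore (sum of 6 items *
7/6); two or more missing items exclude the subject.

Group inference is ordinary least squares with age, sex and ethnicity
covariates (model 2 adds the CBCL total minus its OCS items), percentile
bootstrap confidence intervals (10,000 resamples by default), parametric
t-based p-values, and Benjamini-Hochberg FDR within each test family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PhenotypeRecord",
    "RegressionResult",
    "socs_sumscore",
    "classify_groups",
    "fit_model",
    "fdr_correct",
    "impute_ethnicity",
    "ETHNICITY_LEVELS",
    "SOCS_CUTOFF",
]

SOCS_CUTOFF = 6
N_SOCS_ITEMS = 7
ETHNICITY_LEVELS = ("Dutch", "Non-Dutch Western", "Non-Dutch Non-Western")


@dataclass(frozen=True)
class PhenotypeRecord:
    """One subject's SOCS items, derived groups and model covariates."""

    subject_id: str
    socs_items: tuple[float, ...]  # 7 values in {0,1,2}; NaN = missing
    age: float
    sex: int  # 0/1
    ethnicity: str | None  # None = missing, imputed later
    cbcl_adj: float  # CBCL total minus CBCL-OCS items

    def __post_init__(self) -> None:
        items = tuple(float(v) for v in self.socs_items)
        object.__setattr__(self, "socs_items", items)
        if len(items) != N_SOCS_ITEMS:
            raise ValueError("SOCS has exactly 7 items")
        for v in items:
            if not math.isnan(v) and v not in (0.0, 1.0, 2.0):
                raise ValueError(f"SOCS item outside {{0,1,2}}: {v}")
        if self.ethnicity is not None and self.ethnicity not in ETHNICITY_LEVELS:
            raise ValueError(f"unknown ethnicity level: {self.ethnicity}")
        if self.cbcl_adj < 0:
            raise ValueError("cbcl_adj must be non-negative")

    @property
    def socs_sum(self) -> float:
        return socs_sumscore(self.socs_items)

    @property
    def excluded_missing_socs(self) -> bool:
        return sum(math.isnan(v) for v in self.socs_items) > 1

    @property
    def groups(self) -> dict[str, bool]:
        return classify_groups(self.socs_items)


def socs_sumscore(items) -> float:
    """SOCS sumscore with the single-missing-item weighting rule.

    No missing items: plain sum (0-14). Exactly one missing: sum of the six
    observed items * (7/6). Two or more missing: NaN (subject excluded).
    """
    items = [float(v) for v in items]
    if len(items) != N_SOCS_ITEMS:
        raise ValueError("SOCS has exactly 7 items")
    for v in items:
        if not math.isnan(v) and v not in (0.0, 1.0, 2.0):
            raise ValueError(f"SOCS item outside {{0,1,2}}: {v}")
    n_missing = sum(math.isnan(v) for v in items)
    if n_missing == 0:
        return float(sum(items))
    if n_missing == 1:
        return float(np.nansum(items) * (N_SOCS_ITEMS / (N_SOCS_ITEMS - 1)))
    return float("nan")


def classify_groups(items) -> dict[str, bool]:
    """Symptom-group flags from the 7 SOCS items.

    probable_ocd: sumscore >= 6 (weighted if one item missing).
    control: sumscore == 0.
    high_ocs: any item scored 2 ('often').
    high_ocs_comparison: all observed items <= 1 (the posthoc contrast group).
    """
    s = socs_sumscore(items)
    vals = [float(v) for v in items]
    any_two = any((not math.isnan(v)) and v == 2.0 for v in vals)
    return {
        "probable_ocd": bool(not math.isnan(s) and s >= SOCS_CUTOFF),
        "control": bool(s == 0.0),
        "high_ocs": any_two,
        "high_ocs_comparison": not any_two,
        "excluded_missing_socs": sum(math.isnan(v) for v in vals) > 1,
    }


@dataclass(frozen=True)
class RegressionResult:
    """Table-shaped regression output for one outcome."""

    outcome_name: str
    B: float
    ci_low: float
    ci_high: float
    beta_std: float
    t: float
    p: float
    n: int
    n_boot: int
    n_redrawn: int = 0
    p_fdr_significant: bool | None = None


def _design(
    predictor: np.ndarray, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, predictor, covariates]; ethnicity dummy-coded.

    Reference level for ethnicity is 'Dutch'.
    """
    cols = [np.ones_like(predictor, dtype=float), np.asarray(predictor, dtype=float)]
    names = ["intercept", "predictor"]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                levels = [l for l in ETHNICITY_LEVELS if l in set(col)] or sorted(set(col))
                for lev in levels[1:]:
                    cols.append((col == lev).to_numpy(dtype=float))
                    names.append(f"{name}[{lev}]")
            else:
                cols.append(col.to_numpy(dtype=float))
                names.append(name)
    return np.column_stack(cols), names


def fit_model(
    outcome: np.ndarray,
    predictor: np.ndarray,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    outcome_name: str = "outcome",
) -> RegressionResult:
    """Bootstrapped covariate-adjusted linear model for one outcome.

    B, t and the two-sided p-value come from the OLS fit; the standardized
    beta rescales B by sd(predictor)/sd(outcome); the 95% CI is a
    percentile case-resampling bootstrap of B with ``n_boot`` iterations
    (``n_boot=0`` skips the bootstrap, returning NaN bounds). Resamples
    with zero predictor variance are redrawn and counted.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("outcome and predictor must be 1-D and equal length")
    if x.std() == 0:
        raise ValueError("predictor has zero variance")
    X, names = _design(x, covariates)
    n, k = X.shape
    if n < 10 * k:
        raise ValueError(f"need n >= 10 x {k} design columns, got n={n}")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("singular design matrix")

    fit = sm.OLS(y, X).fit()
    B = float(fit.params[1])
    t = float(fit.tvalues[1])
    p = float(fit.pvalues[1])
    beta_std = B * x.std() / y.std() if y.std() > 0 else 0.0

    ci_low = ci_high = float("nan")
    n_redrawn = 0
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            while True:
                idx = rng.integers(0, n, size=n)
                if x[idx].std() > 0:
                    break
                n_redrawn += 1
            Xi, yi = X[idx], y[idx]
            coef, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
            boots[b] = coef[1]
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    return RegressionResult(
        outcome_name=outcome_name,
        B=B,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        beta_std=float(beta_std),
        t=t,
        p=p,
        n=n,
        n_boot=n_boot,
        n_redrawn=n_redrawn,
    )


def fdr_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags over one test family."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def apply_fdr(results: list[RegressionResult], q: float = 0.05) -> list[RegressionResult]:
    """Return copies of ``results`` with BH-FDR flags set within the family."""
    flags = fdr_correct([r.p for r in results], q=q)
    out = []
    for r, f in zip(results, flags):
        out.append(
            RegressionResult(
                **{**r.__dict__, "p_fdr_significant": bool(f)}
            )
        )
    return out


def impute_ethnicity(
    values: pd.Series,
    seed: int = 0,
    mode: str = "draw",
) -> pd.Series:
    """Fill missing ethnicity from the observed category distribution.

    ``mode='draw'``: stochastic draws proportional to observed frequencies
    (seeded); ``mode='modal'``: deterministic modal category. A stand-in
    for the study's chained-equation multiple imputation.
    """
    values = values.copy()
    missing = values.isna()
    if missing.all():
        raise ValueError("cannot impute: all ethnicity values missing")
    if missing.mean() >= 0.5:
        raise ValueError("cannot impute: >= 50% of ethnicity values missing")
    if not missing.any():
        return values
    observed = values[~missing]
    freq = observed.value_counts(normalize=True)
    if mode == "modal":
        values[missing] = freq.idxmax()
    elif mode == "draw":
        rng = np.random.default_rng(seed)
        values[missing] = rng.choice(freq.index.to_numpy(), size=int(missing.sum()), p=freq.to_numpy())
    else:
        raise ValueError("mode must be 'draw' or 'modal'")
    return values
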