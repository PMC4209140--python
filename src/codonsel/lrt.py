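"""Likelihood-ratio tests between nested site models and Storey q-values.

The test statistic is LRT = 2 (lnL_alt - lnL_null), compared to a chi-square
distribution with k = np_alt - np_null degrees of freedom.  Numerical
optimization can leave the statistic slightly negative when the null sits at
its boundary; such values are reported as-is with P = 1.00 (the tabular
convention), never raised as errors.

For the boundary test M8a-M8 the plain chi-square(1) reference is the
default; the 50:50 mixture of chi-square(0) and chi-square(1) that boundary
theory suggests is available via ``null="mixture"`` and is strictly less
conservative.

False-discovery control across many gene x clade tests uses Storey (2002)
q-values with the bootstrap choice of the pi0 tuning parameter lambda,
mirroring the R ``qvalue`` package with ``pi0.meth = "bootstrap"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: nested (null, alternative) pairs this package tests
NESTED_PAIRS = {("M1a", "M2a"), ("M7", "M8"), ("M8a", "M8")}


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail chi-square probability; non-positive statistics map to 1."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if x <= 0:
        return 1.0
    return float(stats.chi2.sf(x, df))


@dataclass
class LRTResult:
    comparison_label: str
    lnL_null: float
    lnL_alt: float
    statistic: float
    df: int
    p_value: float

    def __str__(self):
        return (
            f"{self.comparison_label}: LRT = {self.statistic:.2f}, "
            f"df = {self.df}, P = {self.p_value:.2f}"
        )


def compute_lrt(null, alt, *, null_distribution: str = "chi2") -> LRTResult:
    """LRT between a fitted null and a fitted alternative model.

    ``null`` and ``alt`` are results objects exposing ``model_id``, ``lnL``
    and ``nparams``.  The pair must be one of the supported nestings.
    """
    pair = (null.model_id, alt.model_id)
    if pair not in NESTED_PAIRS:
        raise ValueError(f"{pair[0]} is not a supported null for {pair[1]}")
    df = alt.nparams - null.nparams
    if df < 1:
        raise ValueError("alternative must have more free parameters than the null")
    statistic = 2.0 * (alt.lnL - null.lnL)
    p = chi2_sf(statistic, df)
    if null_distribution == "mixture":
        # 50:50 chi2_0 : chi2_1 boundary mixture (df 1 case)
        p = 0.5 * p if statistic > 0 else 1.0
    elif null_distribution != "chi2":
        raise ValueError("null_distribution must be 'chi2' or 'mixture'")
    return LRTResult(
        comparison_label=f"{null.model_id}-{alt.model_id}",
        lnL_null=float(null.lnL),
        lnL_alt=float(alt.lnL),
        statistic=float(statistic),
        df=int(df),
        p_value=float(p),
    )


@dataclass
class QValueSet:
    p_values: np.ndarray
    q_values: np.ndarray
    pi0: float
    lambda_grid: np.ndarray
    n_bootstrap: int
    fdr_level: float = 0.1

    def significant(self) -> np.ndarray:
        return self.q_values <= self.fdr_level

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p": self.p_values,
                "q": self.q_values,
                "significant": self.significant(),
            }
        )


def _pi0_bootstrap(p, lambda_grid, n_bootstrap, rng):
    """Storey's bootstrap selection of lambda: minimize the estimated MSE of
    pi0_hat(lambda) around the plug-in minimum over the grid."""
    m = len(p)
    pi0_hat = np.array(
        [np.mean(p > lam) / (1.0 - lam) for lam in lambda_grid]
    )
    pi0_hat = np.minimum(pi0_hat, 1.0)
    target = pi0_hat.min()
    mse = np.zeros(len(lambda_grid))
    for _ in range(n_bootstrap):
        pb = rng.choice(p, size=m, replace=True)
        pi0_b = np.minimum(
            np.array([np.mean(pb > lam) / (1.0 - lam) for lam in lambda_grid]), 1.0
        )
        mse += (pi0_b - target) ** 2
    best = int(np.argmin(mse))
    return float(np.clip(pi0_hat[best], 1e-8, 1.0))


def storey_qvalues(
    p_values,
    *,
    lambda_grid=None,
    n_bootstrap: int = 100,
    seed: int = 0,
    fdr_level: float = 0.1,
    pi0: float | None = None,
) -> QValueSet:
    """Storey (2002) q-values with bootstrap pi0; deterministic given seed.

    Pinning ``pi0=1`` reduces the procedure exactly to Benjamini-Hochberg
    adjusted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) < 1:
        raise ValueError("p_values must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.951, 0.05)
    lambda_grid = np.asarray(lambda_grid, float)

    if pi0 is None:
        rng = np.random.default_rng(seed)
        pi0 = _pi0_bootstrap(p, lambda_grid, n_bootstrap, rng)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")

    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueSet(
        p_values=p,
        q_values=q,
        pi0=float(pi0),
        lambda_grid=lambda_grid,
        n_bootstrap=n_bootstrap,
        fdr_level=fdr_level,
    )


def lrt_table(rows: list[dict], *, fdr_level: float = 0.1, seed: int = 0, per_group: str | None = "clade") -> pd.DataFrame:
    """Assemble gene x clade LRT rows and append q-values.

    ``rows`` are dicts with at least gene, clade, lnL_null, lnL_alt, np_null,
    np_alt.  q-values are computed within each ``per_group`` level (the
    default mirrors per-clade correction), or jointly when ``per_group`` is
    None.
    """
    frame = pd.DataFrame(rows)
    frame["LRT"] = 2.0 * (frame["lnL_alt"] - frame["lnL_null"])
    frame["df"] = frame["np_alt"] - frame["np_null"]
    frame["p"] = [chi2_sf(x, df) for x, df in zip(frame["LRT"], frame["df"])]
    frame["q"] = np.nan
    groups = [frame.index] if per_group is None else [
        idx for _, idx in frame.groupby(per_group).groups.items()
    ]
    for idx in groups:
        qs = storey_qvalues(frame.loc[idx, "p"].to_numpy(), seed=seed, fdr_level=fdr_level)
        frame.loc[idx, "q"] = qs.q_values
    frame["significant"] = frame["q"] <= fdr_level
    return frame
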