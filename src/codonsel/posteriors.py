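"""Per-site posterior probabilities of selection classes (NEB and BEB).

NEB (naive empirical Bayes) plugs the MLEs of the mixture into Bayes' rule
for each site.  BEB (Bayes empirical Bayes) additionally averages over a
discrete prior grid on the mixture parameters, weighting each grid point by
its full-data likelihood, which accounts for the sampling error in the
mixture-parameter estimates.  The BEB grid follows the published scheme:
for M8 the grid runs over (p0, omega_s) with the beta shapes held at their
MLEs; for M2a it runs over (p0, p1) on a triangular simplex grid together
with omega0 in (0, 1) and omega2 in (1, omega2_max).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

#: beta-category omega at or above this value counts as "neutral" when the
#: three-way aggregate is formed for beta-based models
NEUTRAL_OMEGA_CUTOFF = 0.95

SITE_FLAGS = ((0.99, "**"), (0.95, "*"))


@dataclass
class SitePosterior:
    """Per-codon-site posterior class memberships and three-way aggregates."""

    method: str  # "NEB" or "BEB"
    model_id: str
    class_posteriors: np.ndarray  # (n_sites, n_classes)
    class_omegas: np.ndarray
    p_negative: np.ndarray
    p_neutral: np.ndarray
    p_positive: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.class_posteriors.shape[0]

    @property
    def sites(self) -> np.ndarray:
        """1-based codon-column numbers."""
        return np.arange(1, self.n_sites + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.sites,
                "p_negative": self.p_negative,
                "p_neutral": self.p_neutral,
                "p_positive": self.p_positive,
            }
        )


def _category_masks(model_id: str, class_omegas: np.ndarray):
    """Boolean masks (negative, neutral, positive) over the class axis."""
    n = len(class_omegas)
    neg = np.zeros(n, bool)
    neu = np.zeros(n, bool)
    pos = np.zeros(n, bool)
    if model_id == "M1a":
        neg[0], neu[1] = True, True
    elif model_id == "M2a":
        neg[0], neu[1], pos[2] = True, True, True
    elif model_id == "M8":
        beta = class_omegas[:-1]
        neg[:-1] = beta < NEUTRAL_OMEGA_CUTOFF
        neu[:-1] = beta >= NEUTRAL_OMEGA_CUTOFF
        pos[-1] = True
    elif model_id == "M8a":
        beta = class_omegas[:-1]
        neg[:-1] = beta < NEUTRAL_OMEGA_CUTOFF
        neu[:-1] = beta >= NEUTRAL_OMEGA_CUTOFF
        neu[-1] = True
    else:  # M7
        neg[:] = class_omegas < NEUTRAL_OMEGA_CUTOFF
        neu[:] = ~neg
    return neg, neu, pos


def _posterior_from_matrix(post, model_id, class_omegas, method) -> SitePosterior:
    neg, neu, pos = _category_masks(model_id, class_omegas)
    return SitePosterior(
        method=method,
        model_id=model_id,
        class_posteriors=post,
        class_omegas=np.asarray(class_omegas, float),
        p_negative=post[:, neg].sum(axis=1),
        p_neutral=post[:, neu].sum(axis=1),
        p_positive=post[:, pos].sum(axis=1),
    )


def neb_posteriors(fit) -> SitePosterior:
    """Plug-in empirical Bayes site posteriors at the MLE."""
    if fit.site_class_loglik is None:
        raise ValueError("fit carries no cached site-class likelihoods")
    with np.errstate(divide="ignore"):
        logw = np.log(np.maximum(fit.class_weights, 1e-300))
    z = fit.site_class_loglik + logw[None, :]
    post = np.exp(z - logsumexp(z, axis=1, keepdims=True))
    return _posterior_from_matrix(post, fit.model_id, fit.class_omegas, "NEB")


def _single_class_logliks(fit, omegas: np.ndarray) -> np.ndarray:
    """(n_patterns, len(omegas)) log-likelihoods of single-omega classes at
    the fitted kappa and branch scaling."""
    model = fit.model
    if model is None:
        raise ValueError("BEB needs the originating CodonSiteModel (fit.model)")
    scale = fit.tree_scale if fit.tree_scale is not None else 1.0
    return model.engine.class_site_loglik(
        np.asarray(omegas, float), fit.kappa, scale, fit.branch_lengths
    )


def beb_posteriors(fit, n_grid: int = 10, omega2_max: float = 11.0, grid_points=None) -> SitePosterior:
    """Bayes empirical Bayes site posteriors for an M2a or M8 fit.

    ``grid_points`` overrides the prior grid with explicit
    ``(weights, omegas)`` pairs (a single pair at the MLE reproduces NEB).
    """
    if fit.model_id not in ("M2a", "M8"):
        raise ValueError("BEB is defined for M2a and M8 fits only")
    model = fit.model
    if model is None:
        raise ValueError("BEB needs the originating CodonSiteModel (fit.model)")
    engine = model.engine
    counts = engine.pattern_weight

    if grid_points is not None:
        grids = [(np.asarray(w, float), np.asarray(om, float)) for w, om in grid_points]
    elif fit.model_id == "M8":
        grids = _m8_grid(fit, n_grid, omega2_max)
    else:
        grids = _m2a_grid(n_grid, omega2_max)

    # distinct omegas across the grid -> one pruning pass for all of them
    all_omegas = np.unique(np.concatenate([om for _, om in grids]))
    single = _single_class_logliks(fit, all_omegas)  # (n_pat, n_omegas)
    col = {w: i for i, w in enumerate(all_omegas)}

    n_pat = single.shape[0]
    n_classes = len(grids[0][1])

    def _conditional(w, omegas):
        lmat = single[:, [col[x] for x in omegas]]
        with np.errstate(divide="ignore"):
            z = lmat + np.log(np.maximum(w, 1e-300))[None, :]
        norm = logsumexp(z, axis=1)
        return z, norm

    # two passes: grid-point data likelihoods first, then the weighted
    # accumulation (avoids holding every conditional matrix in memory)
    log_marg = np.empty(len(grids))  # log f(X | theta_g)
    for g, (w, omegas) in enumerate(grids):
        _, norm = _conditional(w, omegas)
        log_marg[g] = float(np.dot(counts, norm))
    gpost = np.exp(log_marg - logsumexp(log_marg))  # P(theta_g | X), uniform prior

    site_post = np.zeros((n_pat, n_classes))
    for g, (w, omegas) in enumerate(grids):
        if gpost[g] < 1e-14:
            continue
        z, norm = _conditional(w, omegas)
        site_post += gpost[g] * np.exp(z - norm[:, None])

    site_post = engine.expand_to_sites(site_post)
    return _posterior_from_matrix(site_post, fit.model_id, fit.class_omegas, "BEB")


def _m8_grid(fit, n_grid: int, omega2_max: float):
    """Grid over (p0, omega_s); beta categories fixed at the MLE shapes."""
    beta_omegas = fit.class_omegas[:-1]
    ncat = len(beta_omegas)
    mids = (np.arange(n_grid) + 0.5) / n_grid
    p0_grid = mids
    ws_grid = 1.0 + mids * (omega2_max - 1.0)
    grids = []
    for p0 in p0_grid:
        w = np.full(ncat + 1, p0 / ncat)
        w[-1] = 1.0 - p0
        for ws in ws_grid:
            grids.append((w, np.append(beta_omegas, ws)))
    return grids


def _m2a_grid(n_grid: int, omega2_max: float):
    """Triangular (p0, p1) grid x omega0 grid x omega2 grid, equal weights."""
    mids = (np.arange(n_grid) + 0.5) / n_grid
    omega0_grid = mids
    omega2_grid = 1.0 + mids * (omega2_max - 1.0)
    grids = []
    for i in range(n_grid):
        for j in range(n_grid - i):
            p0, p1 = mids[i], mids[j]
            p2 = 1.0 - p0 - p1
            if p2 < 0:
                continue
            w = np.array([p0, p1, p2])
            for w0 in omega0_grid:
                for w2 in omega2_grid:
                    grids.append((w, np.array([w0, 1.0, w2])))
    return grids


def classify_sites(post: SitePosterior, threshold: float = 0.50) -> pd.DataFrame:
    """Sites with P(positive) above the reporting cutoff, flagged '*' above
    0.95 and '**' above 0.99 (1-based positions)."""
    frame = post.to_frame()
    hits = frame[frame["p_positive"] > threshold].copy()
    flags = []
    for p in hits["p_positive"]:
        flag = ""
        for cut, mark in SITE_FLAGS:
            if p > cut:
                flag = mark
                break
        flags.append(flag)
    hits["flag"] = flags
    return hits.reset_index(drop=True)
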