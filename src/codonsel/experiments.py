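"""Reusable simulation experiments: calibration and power checks of the
M8a-M8 machinery on synthetic alignments.

These are the study-condition experiments the test-suite and the
reproduction script both run; they are part of the package so their
protocols (tree shapes, generating parameters, fitting options) are defined
in exactly one place.

Generating conditions
---------------------
The null-calibration experiment simulates purifying-selection-dominated
genes: M8a with p0 = 0.85 and Beta(0.4, 1.6) (mean omega ~ 0.2), kappa 2.5,
uniform codon frequencies, on random coalescent trees with mean branch
length 0.15 substitutions/codon — values chosen to resemble a conserved
vertebrate coding gene.  Bulk replicates use the 'fast' single-start fitting
profile with the alternative warm-started from its null (which also
enforces the nested lnL ordering); one-off fits use the full multi-start
default.
"""

from __future__ import annotations

import numpy as np

from .lrt import compute_lrt
from .posteriors import beb_posteriors
from .simulate import coalescent_tree, simulate_alignment
from .sitemodels import CodonSiteModel, SiteClassModel

_N_STATES = 61


def _uniform_pi():
    return np.full(_N_STATES, 1.0 / _N_STATES)


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))


M8A_NULL = SiteClassModel("M8a", p0=0.85, beta_p=0.4, beta_q=1.6)
M8_POSITIVE = SiteClassModel("M8", p0=0.9, beta_p=0.4, beta_q=1.6, omega2=4.0)
M2A_POSITIVE = SiteClassModel("M2a", p0=0.60, p1=0.25, omega0=0.1, omega2=3.0)
DEFAULT_KAPPA = 2.5


def simulate_null_dataset(n_taxa: int, n_codons: int, seed: int):
    """One M8a (no positive selection) alignment + its tree."""
    tree = coalescent_tree(n_taxa, _subseed(seed, 0), mean_branch_length=0.15)
    aln, truth = simulate_alignment(
        tree, M8A_NULL, _uniform_pi(), DEFAULT_KAPPA, n_codons, _subseed(seed, 1)
    )
    return aln, tree, truth


def fit_m8a_m8_pair(aln, tree, *, fast: bool = True, maxiter: int = 200):
    """Fit the M8a null and the M8 alternative warm-started from the null.

    In the fast protocol the alternative starts from the null's MLEs with
    omega_s at the boundary (which reproduces the null likelihood exactly,
    so lnL(M8) >= lnL(M8a) by construction) and once more with omega_s
    pushed to 2.5; the default protocol adds the full cold multi-start.
    """
    if fast:
        null = CodonSiteModel(aln, tree, "M8a").fit(starts="fast", maxiter=80, ftol=1e-7)
        m8 = CodonSiteModel(aln, tree, "M8")
        warm = m8.start_from(null)  # omega_s at the boundary: equals the null
        alt = m8.fit(
            starts=[{**warm, "omega2": 2.5}], eval_points=[warm],
            maxiter=80, ftol=1e-7,
        )
    else:
        null = CodonSiteModel(aln, tree, "M8a").fit(maxiter=maxiter)
        alt = CodonSiteModel(aln, tree, "M8").fit(init_from=null, maxiter=maxiter)
    return null, alt


def type_one_error_experiment(
    n_reps: int = 100,
    *,
    n_taxa: int = 8,
    n_codons: int = 300,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the M8a-M8 chi-square(1) test on null simulations.

    The test at the omega_s = 1 boundary is asymptotically conservative, so
    the rate should not exceed alpha by more than Monte-Carlo noise.
    """
    pvals = []
    stats = []
    for rep in range(n_reps):
        aln, tree, _ = simulate_null_dataset(n_taxa, n_codons, _subseed(seed, 100 + rep))
        null, alt = fit_m8a_m8_pair(aln, tree, fast=True)
        res = compute_lrt(null, alt)
        pvals.append(res.p_value)
        stats.append(res.statistic)
    pvals = np.array(pvals)
    return {
        "rejection_rate": float(np.mean(pvals < alpha)),
        "alpha": alpha,
        "n_reps": n_reps,
        "p_values": pvals,
        "statistics": np.array(stats),
    }


def nesting_experiment(
    n_datasets: int = 10, *, n_taxa: int = 6, n_codons: int = 200, seed: int = 0
) -> dict:
    """lnL orderings of the nested pairs (M8 vs M8a, M2a vs M1a) on data
    simulated under the M8a null."""
    m8_margin, m2a_margin = [], []
    for rep in range(n_datasets):
        aln, tree, _ = simulate_null_dataset(n_taxa, n_codons, _subseed(seed, 500 + rep))
        m8a, m8 = fit_m8a_m8_pair(aln, tree, fast=True)
        m1a = CodonSiteModel(aln, tree, "M1a").fit(starts="fast", ftol=1e-8)
        m2a = CodonSiteModel(aln, tree, "M2a").fit(
            starts="fast", init_from=m1a, ftol=1e-8
        )
        m8_margin.append(m8.lnL - m8a.lnL)
        m2a_margin.append(m2a.lnL - m1a.lnL)
    return {
        "m8_minus_m8a": np.array(m8_margin),
        "m2a_minus_m1a": np.array(m2a_margin),
        "n_datasets": n_datasets,
    }


def m2a_recovery_experiment(
    *, n_taxa: int = 12, n_codons: int = 600, seed: int = 0
) -> dict:
    """Fit M2a to data simulated under M2a (omega2 = 3, p2 = 0.15) and
    report the recovered positive-selection omega."""
    tree = coalescent_tree(n_taxa, _subseed(seed, 0), mean_branch_length=0.15)
    aln, truth = simulate_alignment(
        tree, M2A_POSITIVE, _uniform_pi(), DEFAULT_KAPPA, n_codons, _subseed(seed, 1)
    )
    fit = CodonSiteModel(aln, tree, "M2a").fit(starts="default")
    return {
        "omega2_hat": float(fit.params.omega2),
        "omega2_true": float(M2A_POSITIVE.omega2),
        "p2_hat": float(1.0 - fit.params.p0 - fit.params.p1),
        "fit": fit,
        "truth": truth,
    }


def beb_discrimination_experiment(
    *, n_taxa: int = 12, n_codons: int = 600, seed: int = 0
) -> dict:
    """AUC of BEB P(positive) for truly positive vs purifying/neutral sites
    on an M8 simulation (omega_s = 4, p_s = 0.1)."""
    tree = coalescent_tree(n_taxa, _subseed(seed, 0), mean_branch_length=0.15)
    aln, truth = simulate_alignment(
        tree, M8_POSITIVE, _uniform_pi(), DEFAULT_KAPPA, n_codons, _subseed(seed, 1)
    )
    fit = CodonSiteModel(aln, tree, "M8").fit(starts="fast", maxiter=300)
    post = beb_posteriors(fit)
    positive_class = len(truth.class_omegas) - 1
    labels = truth.site_class == positive_class
    auc = rank_auc(post.p_positive, labels)
    return {"auc": auc, "posterior": post, "truth": truth, "fit": fit}


def rank_auc(score: np.ndarray, label: np.ndarray) -> float:
    """Mann-Whitney AUC of score for label=True vs label=False."""
    score = np.asarray(score, float)
    label = np.asarray(label, bool)
    pos, neg = score[label], score[~label]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both positive and negative sites")
    order = np.argsort(np.concatenate([pos, neg]), kind="stable")
    ranks = np.empty(len(order))
    ranks[order] = np.arange(1, len(order) + 1)
    # midranks for ties
    allv = np.concatenate([pos, neg])
    sorted_v = np.sort(allv)
    uniq, start = np.unique(sorted_v, return_index=True)
    for i, v in enumerate(uniq):
        end = start[i + 1] if i + 1 < len(uniq) else len(sorted_v)
        mid = (start[i] + 1 + end) / 2.0
        ranks[allv == v] = mid
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))
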