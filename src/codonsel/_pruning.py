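"""Felsenstein pruning for codon site-class mixtures.

The engine is built once per (alignment, tree, frequency vector) and then
evaluated many times during optimization.  Site columns are compressed to
unique patterns; per evaluation it builds one GY94 generator per distinct
omega, exponentiates it once per branch via the cached symmetric
eigendecomposition, and runs a single vectorized postorder pass for all
classes and patterns simultaneously.  Gap/N codons enter as all-ones partial
likelihoods (missing data), so they are marginalized rather than dropped.

Numerical safety: partial likelihoods are rescaled to a per-pattern maximum
of 1 at every internal node, with the log scale factors accumulated
separately, so deep trees cannot underflow.
"""

from __future__ import annotations

import numpy as np

from .alignment import CodonAlignment
from .genetics import (
    GeneticCode,
    _gy94_structure,
    standard_genetic_code,
    validate_frequencies,
)
from .trees import TreeIndex, tree_index

_TINY = 1e-300


class _SymmetricGY94:
    """Cached components of the symmetrized GY94 generator for fixed pi.

    For reversible Q, B = diag(pi)^(1/2) Q diag(pi)^(-1/2) is symmetric and
    decomposes into four fixed structural matrices scaled by 1, kappa,
    omega and kappa*omega (synonymous/nonsynonymous x transversion/
    transition), so each (kappa, omega) needs only a linear combination and
    one eigh call.
    """

    def __init__(self, pi: np.ndarray, code: GeneticCode):
        single, transition, nonsyn = _gy94_structure(code)
        self.sqrt_pi = np.sqrt(pi)
        w = np.outer(self.sqrt_pi, self.sqrt_pi)
        self.syn_tv = np.where(single & ~transition & ~nonsyn, w, 0.0)
        self.syn_ts = np.where(single & transition & ~nonsyn, w, 0.0)
        self.ns_tv = np.where(single & ~transition & nonsyn, w, 0.0)
        self.ns_ts = np.where(single & transition & nonsyn, w, 0.0)

    def neutral_rate(self, kappa: float) -> float:
        """Expected substitutions per unit time at omega = 1."""
        b = self.syn_tv + kappa * self.syn_ts + self.ns_tv + kappa * self.ns_ts
        return float(self.sqrt_pi @ (b @ self.sqrt_pi))

    def eigensystem(self, kappa: float, omega: float):
        """(lam, right, left) of the generator: P(t) = right @
        diag(exp(lam t)) @ left.

        All omega classes share one scale — the neutral (omega = 1) rate —
        so branch lengths are expected substitutions per codon at
        neutrality and classes keep their relative rates (an omega > 1
        class evolves faster than a purifying class, as it must in a
        mixture; the free tree-scale parameter absorbs the overall factor).
        """
        b = (
            self.syn_tv
            + kappa * self.syn_ts
            + omega * self.ns_tv
            + (kappa * omega) * self.ns_ts
        )
        rate = self.neutral_rate(kappa)
        if rate <= 0:
            raise ValueError("degenerate rate matrix: zero total rate")
        row = b @ self.sqrt_pi
        b[np.diag_indices_from(b)] = -row / self.sqrt_pi
        b /= rate
        lam, u = np.linalg.eigh(b)
        right = u / self.sqrt_pi[:, None]
        left = u.T * self.sqrt_pi[None, :]
        return lam, right, left


class PruningEngine:
    def __init__(
        self,
        aln: CodonAlignment,
        tree,
        pi: np.ndarray,
        code: GeneticCode | None = None,
    ):
        self.code = code or standard_genetic_code()
        self.aln = aln
        self.tree: TreeIndex = tree_index(tree)
        self.pi = validate_frequencies(pi, self.code.n_states)

        tree_taxa = set(self.tree.taxa)
        aln_taxa = set(aln.taxa)
        if tree_taxa != aln_taxa:
            raise ValueError(
                "tree and alignment taxa differ: "
                f"only-in-tree={sorted(tree_taxa - aln_taxa)}, "
                f"only-in-alignment={sorted(aln_taxa - tree_taxa)}"
            )

        states = aln.state_matrix(self.code)  # (n_taxa, n_sites)
        row_of = {t: i for i, t in enumerate(aln.taxa)}
        # reorder rows to match tree leaf order (postorder index -> row)
        self._leaf_rows = {
            node: row_of[taxon]
            for node, taxon in enumerate(self.tree.leaf_taxon)
            if taxon is not None
        }
        cols = states.T  # (n_sites, n_taxa)
        patterns, inverse, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns          # (n_pat, n_taxa)
        self.pattern_of_site = inverse    # (n_sites,)
        self.pattern_weight = counts.astype(float)
        self.n_sites = aln.n_sites
        self.n_patterns = patterns.shape[0]
        self._sym = _SymmetricGY94(self.pi, self.code)
        # per leaf node: pattern state vector and observed mask
        self._leaf_states = {
            node: self.patterns[:, row] for node, row in self._leaf_rows.items()
        }

    # ------------------------------------------------------------------

    def _probability_matrices(self, omegas: np.ndarray, kappa: float, lengths: np.ndarray) -> np.ndarray:
        """(n_omegas, n_nodes - 1, n, n) transition matrices P(t)^T per
        branch (transposed: entry [j, i] = P(i -> j)), postorder node index;
        the root has no branch and no entry."""
        branch_nodes = self.tree.n_nodes - 1
        n = self.code.n_states
        out = np.empty((len(omegas), branch_nodes, n, n))
        for c, omega in enumerate(omegas):
            lam, right, left = self._sym.eigensystem(kappa, omega)
            ee = np.exp(np.outer(lengths[:branch_nodes], lam))
            p = np.matmul(right[None, :, :] * ee[:, None, :], left)
            np.clip(p, 0.0, None, out=p)
            out[c] = np.swapaxes(p, 1, 2)
        return out

    def class_site_loglik(
        self,
        omegas,
        kappa: float,
        scale: float = 1.0,
        branch_lengths: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-pattern per-class log-likelihoods, shape (n_patterns, n_class).

        ``branch_lengths`` (indexed by postorder node, branch above the node)
        overrides the tree's lengths; ``scale`` multiplies whichever is used.
        """
        omegas = np.asarray(omegas, dtype=float)
        uniq_omegas, class_of = np.unique(omegas, return_inverse=True)
        if scale < 0:
            raise ValueError("tree scale must be non-negative")
        lengths = (
            self.tree.edge_length if branch_lengths is None else np.asarray(branch_lengths)
        )
        if np.any(lengths < 0):
            raise ValueError("branch lengths must be non-negative")
        lengths = lengths * scale

        tree = self.tree
        n_class = len(uniq_omegas)  # duplicate omegas share one column
        n_pat = self.n_patterns

        # root-is-leaf degenerate tree: likelihood is just pi at the tip
        if tree.n_nodes == 1:
            states = self.patterns[:, self._leaf_rows[tree.root]]
            site = np.zeros(n_pat)
            observed = states >= 0
            site[observed] = np.log(self.pi[states[observed]])
            return np.tile(site[:, None], (1, len(omegas)))

        pmats = self._probability_matrices(uniq_omegas, kappa, lengths)

        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros((n_class, n_pat))
        for node in range(tree.n_nodes):
            kids = tree.children[node]
            if not kids:
                continue  # leaf: consumed by its parent below
            partial = None
            for child in kids:
                if tree.children[child]:
                    # pmats holds P^T, so summing over the child state axis
                    # is a plain (contiguous) matmul
                    contrib = np.matmul(partials.pop(child), pmats[:, child])
                else:
                    states = self._leaf_states[child]
                    missing = states < 0
                    # row gather of P^T: contrib[p, i] = P(i -> state_p)
                    contrib = pmats[:, child][:, np.where(missing, 0, states), :]
                    if missing.any():
                        contrib[:, missing, :] = 1.0  # marginalize gap/N codons
                if partial is None:
                    partial = contrib
                else:
                    partial *= contrib
            peak = partial.max(axis=2)
            np.maximum(peak, _TINY, out=peak)
            partial /= peak[:, :, None]
            logscale += np.log(peak)
            partials[node] = partial

        root_partial = partials.pop(tree.root)
        site_log = np.log(np.maximum(root_partial @ self.pi, _TINY)) + logscale
        return site_log.T[:, class_of]  # (n_pat, n_class), duplicates re-expanded

    def expand_to_sites(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map a per-pattern array (first axis) back to per-site order."""
        return per_pattern[self.pattern_of_site]

    def mixture_loglik(self, log_weights: np.ndarray, pattern_loglik: np.ndarray) -> float:
        """Total lnL = sum over patterns of weighted logsumexp across classes."""
        m = pattern_loglik.max(axis=1)
        s = np.log(np.exp(pattern_loglik - m[:, None]) @ np.exp(log_weights)) + m
        return float(np.dot(self.pattern_weight, s))
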