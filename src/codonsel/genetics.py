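"""Genetic-code bookkeeping and the Goldman-Yang codon substitution process.

The model state space is the 61 sense codons of the standard genetic code,
ordered lexicographically over (A, C, G, T) with the three stop codons
removed; this ordering is fixed so that cached matrices and serialized
frequency vectors are portable.

The instantaneous rate matrix follows Goldman & Yang: a codon can only change
at a single nucleotide position per event; the rate to codon ``j`` is
``pi_j``, multiplied by ``kappa`` for a transition (A<->G, C<->T) and by
``omega`` (dN/dS) when the change is nonsynonymous.  The generator is
normalized so that one unit of time corresponds to one expected substitution
per codon at equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
#: purine/pyrimidine partners: a substitution is a transition iff it is one
#: of A<->G or C<->T.
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

FREQUENCY_METHODS = ("equal", "F1x4", "F3x4", "empirical")


@dataclass(frozen=True, eq=False)  # identity hash: instances are cached singletons
class GeneticCode:
    """A codon -> amino-acid table over the 64 nucleotide triplets."""

    codon_to_aa: dict[str, str]  # amino acid one-letter, or "*" for stop
    sense_codons: tuple[str, ...]
    stop_codons: tuple[str, ...]
    _index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if len(self.codon_to_aa) != 64:
            raise ValueError("genetic code must cover all 64 triplets")
        if set(self.sense_codons) | set(self.stop_codons) != set(self.codon_to_aa):
            raise ValueError("sense + stop codons must partition the 64 triplets")
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.sense_codons)}
        )

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon.upper()]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon.upper()] == "*"

    def is_synonymous(self, codon_a: str, codon_b: str) -> bool:
        aa, ab = self.translate(codon_a), self.translate(codon_b)
        if "*" in (aa, ab):
            raise ValueError("synonymy is undefined for stop codons")
        return aa == ab

    def index(self, codon: str) -> int:
        """Position of a sense codon in the fixed state ordering."""
        return self._index[codon.upper()]


@lru_cache(maxsize=1)
def standard_genetic_code() -> GeneticCode:
    """The standard (NCBI table 1) genetic code with 61 sense codons."""
    table = CodonTable.unambiguous_dna_by_id[1]
    all_codons = [a + b + c for a in BASES for b in BASES for c in BASES]
    stops = set(table.stop_codons)
    codon_to_aa = {
        c: ("*" if c in stops else table.forward_table[c]) for c in all_codons
    }
    sense = tuple(c for c in all_codons if c not in stops)
    return GeneticCode(codon_to_aa, sense, tuple(sorted(stops)))


def validate_frequencies(pi: np.ndarray, n_states: int = 61) -> np.ndarray:
    """Check a codon equilibrium-frequency vector and return it as float64."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (n_states,):
        raise ValueError(f"frequency vector must have length {n_states}")
    if np.any(pi < 0):
        raise ValueError("codon frequencies must be non-negative")
    if abs(pi.sum() - 1.0) > 1e-12:
        raise ValueError("codon frequencies must sum to 1 (within 1e-12)")
    return pi


def _codon_counts(aln, code: GeneticCode) -> np.ndarray:
    """Counts of unambiguous sense codons across the whole alignment."""
    counts = np.zeros(code.n_states)
    for seq in aln.sequences:
        for k in range(0, len(seq), 3):
            codon = seq[k : k + 3]
            if "-" in codon or "N" in codon:
                continue
            counts[code.index(codon)] += 1
    return counts


def estimate_codon_frequencies(aln, method: str = "F3x4", code: GeneticCode | None = None) -> np.ndarray:
    """Equilibrium codon frequencies from alignment data.

    ``equal``: every sense codon 1/61.  ``F1x4``: product of overall
    nucleotide frequencies.  ``F3x4``: product of codon-position-specific
    nucleotide frequencies.  ``empirical``: observed codon proportions.
    F1x4/F3x4 products are renormalized over the sense codons.
    """
    code = code or standard_genetic_code()
    if method not in FREQUENCY_METHODS:
        raise ValueError(f"unknown frequency method {method!r}")
    if method == "equal":
        return np.full(code.n_states, 1.0 / code.n_states)

    # nucleotide counts per codon position over unambiguous bases
    nt_counts = np.zeros((3, 4))
    for seq in aln.sequences:
        for k in range(0, len(seq), 3):
            codon = seq[k : k + 3]
            for pos, base in enumerate(codon):
                if base in BASES:
                    nt_counts[pos, BASES.index(base)] += 1
    if nt_counts.sum() == 0:
        raise ValueError("alignment contains no unambiguous codon data")

    if method == "empirical":
        counts = _codon_counts(aln, code)
        if counts.sum() == 0:
            raise ValueError("alignment contains no unambiguous codon data")
        pi = counts / counts.sum()
        # keep strictly positive so likelihoods stay finite
        pi = np.maximum(pi, 1e-10)
    else:
        if method == "F1x4":
            freqs = nt_counts.sum(axis=0)
            freqs = np.tile(freqs / freqs.sum(), (3, 1))
        else:  # F3x4
            row_sums = nt_counts.sum(axis=1, keepdims=True)
            if np.any(row_sums == 0):
                raise ValueError("alignment contains no unambiguous codon data")
            freqs = nt_counts / row_sums
        pi = np.array(
            [
                freqs[0, BASES.index(c[0])]
                * freqs[1, BASES.index(c[1])]
                * freqs[2, BASES.index(c[2])]
                for c in code.sense_codons
            ]
        )
        if pi.sum() <= 0:
            raise ValueError("degenerate nucleotide composition")
        pi = np.maximum(pi, 1e-12)
    return pi / pi.sum()


@lru_cache(maxsize=4)
def _gy94_structure(code: GeneticCode):
    """Structural masks of the GY94 generator for a given code.

    Returns boolean (n, n) arrays: single-nucleotide change, transition,
    nonsynonymous.  Cached because they only depend on the code.
    """
    n = code.n_states
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    codons = code.sense_codons
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(codons[i], codons[j]) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transition[i, j] = diffs[0] in _TRANSITIONS
            nonsyn[i, j] = not code.is_synonymous(codons[i], codons[j])
    return single, transition, nonsyn


@dataclass
class RateMatrix:
    """A normalized, time-reversible GY94 generator."""

    q: np.ndarray
    pi: np.ndarray
    kappa: float
    omega: float
    scale: float = 1.0  # expected substitutions per unit time after normalization


def build_rate_matrix(
    pi: np.ndarray,
    kappa: float,
    omega: float,
    code: GeneticCode | None = None,
    *,
    reference_omega: float | None = None,
) -> RateMatrix:
    """GY94 instantaneous rate matrix.

    By default the generator is normalized to 1 expected substitution per
    unit time *at its own omega* (the convention for a standalone matrix).
    With ``reference_omega`` the normalizing rate is computed at that omega
    instead — site-class mixtures must share one reference (typically 1.0,
    the neutral rate) so that faster classes stay faster.
    """
    code = code or standard_genetic_code()
    pi = validate_frequencies(pi, code.n_states)
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    single, transition, nonsyn = _gy94_structure(code)

    def _raw(om):
        q = np.where(single, pi[np.newaxis, :], 0.0)
        q = np.where(transition, kappa * q, q)
        q = np.where(nonsyn, om * q, q)
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    q = _raw(omega)
    ref = omega if reference_omega is None else reference_omega
    rate = -np.dot(pi, np.diag(_raw(ref)))
    if rate <= 0:
        # the standard code always admits synonymous changes, so this only
        # triggers for a degenerate custom code
        raise ValueError("degenerate rate matrix: zero total rate")
    qn = q / rate
    # scale = expected substitutions per unit time of this matrix: 1 under
    # self-normalization, the rate relative to the reference otherwise
    return RateMatrix(
        q=qn, pi=pi, kappa=kappa, omega=omega, scale=-float(np.dot(pi, np.diag(qn)))
    )


class ReversibleExpm:
    """Matrix exponential of a reversible generator via symmetrization.

    For reversible Q, B = diag(pi)^(1/2) Q diag(pi)^(-1/2) is symmetric, so
    P(t) = diag(pi)^(-1/2) U exp(L t) U' diag(pi)^(1/2) with B = U L U'.  The
    eigendecomposition is computed once and reused across branch lengths.
    """

    def __init__(self, rm: RateMatrix):
        sqrt_pi = np.sqrt(rm.pi)
        b = (sqrt_pi[:, None] * rm.q) / sqrt_pi[None, :]
        lam, u = np.linalg.eigh((b + b.T) / 2.0)
        self.lam = lam
        self.left = u.T * sqrt_pi[None, :]       # U' diag(pi)^(1/2)
        self.right = u / sqrt_pi[:, None]        # diag(pi)^(-1/2) U
        self.pi = rm.pi

    def __call__(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        p = (self.right * np.exp(self.lam * t)[None, :]) @ self.left
        np.clip(p, 0.0, 1.0, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


def transition_matrix(rm: RateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Q t): row-stochastic transition probabilities."""
    return ReversibleExpm(rm)(t)
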