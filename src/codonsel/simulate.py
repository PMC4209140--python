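"""Synthetic-data generators for every pipeline stage.

* codon alignments evolved along a tree under a site-class omega mixture
  (the exact generative counterpart of the fitted models);
* disease-mutation count tables whose Poisson rate rises with the posterior
  probability of negative selection (so counts fall with P(positive), the
  qualitative relationship the mutation analysis targets);
* ddG stability tables with three substitution classes drawn from shifted
  log-normal distributions centred to requested medians (right-skewed, as
  empirical stability scans are).

All generators draw from a single ``numpy.random.default_rng(seed)`` in a
fixed documented order (site classes, then the root states, then branch
transitions in preorder), so outputs are bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .genetics import ReversibleExpm, build_rate_matrix, standard_genetic_code, validate_frequencies
from .integration import DDG_CLASSES
from .sitemodels import SiteClassModel
from .trees import TreeIndex, tree_index

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationTruth:
    """Ground truth of a simulated alignment."""

    site_class: np.ndarray  # per-site class index into the expanded classes
    site_omega: np.ndarray  # per-site true omega
    class_proportions: np.ndarray
    class_omegas: np.ndarray
    model: SiteClassModel
    kappa: float
    seed: int


def coalescent_tree(
    n_taxa: int, seed: int, *, mean_branch_length: float = 0.2, prefix: str = "t"
) -> dendropy.Tree:
    """Random bifurcating tree with exponential coalescence depths, rescaled
    so the mean branch length equals ``mean_branch_length`` (in expected
    substitutions per codon)."""
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"{prefix}{i + 1}" for i in range(n_taxa)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for i in range(n_taxa):
        node = dendropy.Node(taxon=taxa[i])
        node.age = 0.0
        nodes.append(node)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent.age = t
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = parent.age - a.age
        b.edge.length = parent.age - b.age
        nodes.append(parent)
    tree.seed_node = nodes[0]
    lengths = [e.length for e in tree.preorder_edge_iter() if e.length is not None]
    factor = mean_branch_length / float(np.mean(lengths))
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = e.length * factor
    return tree


def simulate_alignment(
    tree,
    model: SiteClassModel,
    pi: np.ndarray,
    kappa: float,
    n_sites: int,
    seed: int,
) -> tuple[CodonAlignment, SimulationTruth]:
    """Evolve ``n_sites`` codon columns along ``tree`` under a site-class
    mixture.  The state space excludes stop codons, so none are emitted."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    code = standard_genetic_code()
    pi = validate_frequencies(pi, code.n_states)
    idx: TreeIndex = tree_index(tree)
    classes = model.site_classes()
    props = np.array([p for p, _ in classes])
    omegas = np.array([w for _, w in classes])

    rng = np.random.default_rng(seed)
    site_class = rng.choice(len(classes), size=n_sites, p=props)
    root_states = rng.choice(code.n_states, size=n_sites, p=pi)

    # per distinct omega: cached eigendecomposition for fast P(t) per branch;
    # classes share the neutral-rate scale so branch lengths mean the same
    # thing for every class and omega > 1 sites genuinely evolve faster
    expms = {}
    for w in np.unique(omegas):
        expms[w] = ReversibleExpm(
            build_rate_matrix(pi, kappa, w, code, reference_omega=1.0)
        )

    states = np.empty((idx.n_nodes, n_sites), dtype=np.int64)
    states[idx.root] = root_states
    preorder = range(idx.n_nodes - 2, -1, -1)  # all non-root, parents first
    for node in preorder:
        parent_states = states[idx.parent[node]]
        t = idx.edge_length[node]
        child = np.empty(n_sites, dtype=np.int64)
        for ci, w in enumerate(omegas):
            sites = np.nonzero(site_class == ci)[0]
            if len(sites) == 0:
                continue
            pmat = expms[w](t)
            cum = np.cumsum(pmat, axis=1)
            cum[:, -1] = 1.0
            u = rng.random(len(sites))
            rows = cum[parent_states[sites]]
            child[sites] = (u[:, None] > rows).sum(axis=1)
        states[node] = child

    taxa, rows = [], []
    for node, taxon in enumerate(idx.leaf_taxon):
        if taxon is None:
            continue
        taxa.append(taxon)
        rows.append("".join(code.sense_codons[s] for s in states[node]))
    aln = CodonAlignment(taxa, rows)
    truth = SimulationTruth(
        site_class=site_class,
        site_omega=omegas[site_class],
        class_proportions=props,
        class_omegas=omegas,
        model=model,
        kappa=kappa,
        seed=seed,
    )
    return aln, truth


def simulate_mutation_counts(
    posteriors, coupling: float, mean_count: float = 2.0, seed: int = 0
) -> pd.DataFrame:
    """Per-site Poisson mutation counts coupled to the probability of
    negative selection: rate = mean_count * exp(coupling * (P(neg) - 0.5)).

    ``coupling=0`` gives counts independent of selection; positive coupling
    concentrates mutations on negatively selected sites, which induces the
    inverse relationship with P(positive).
    """
    if mean_count <= 0:
        raise ValueError("mean_count must be positive")
    frame = posteriors.to_frame() if hasattr(posteriors, "to_frame") else posteriors.copy()
    rng = np.random.default_rng(seed)
    rate = mean_count * np.exp(coupling * (frame["p_negative"].to_numpy(float) - 0.5))
    counts = rng.poisson(rate)
    return pd.DataFrame({"position": frame["site"].to_numpy(int), "count": counts})


def simulate_ddg_table(
    n_positions: int,
    class_medians: dict[str, float],
    spread: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """ddG rows per class: median-targeted shifted log-normal draws.

    Each class draws ``ddg = (median - 1) + exp(spread * Z)`` with standard
    normal Z, whose median is exactly the requested one and whose right skew
    mimics empirical stability-scan distributions.
    """
    if spread < 0:
        raise ValueError("spread must be non-negative")
    unknown = set(class_medians) - set(DDG_CLASSES)
    if unknown:
        raise ValueError(f"unknown ddG classes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for cls in DDG_CLASSES:
        if cls not in class_medians:
            continue
        med = float(class_medians[cls])
        if not np.isfinite(med):
            raise ValueError("class medians must be finite")
        z = rng.standard_normal(n_positions)
        ddg = (med - 1.0) + np.exp(spread * z)
        froms = rng.integers(0, 20, size=n_positions)
        shifts = rng.integers(1, 20, size=n_positions)
        for pos in range(n_positions):
            rows.append(
                {
                    "position": pos + 1,
                    "from_aa": _AMINO_ACIDS[froms[pos]],
                    "to_aa": _AMINO_ACIDS[(froms[pos] + shifts[pos]) % 20],
                    "class": cls,
                    "ddg": float(ddg[pos]),
                }
            )
    return pd.DataFrame(rows)


def synthetic_posteriors(n_sites: int, seed: int = 0):
    """A synthetic SitePosterior-like frame (Dirichlet rows), handy for
    exercising the mutation-coupling generator without fitting a model."""
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet([4.0, 1.5, 0.8], size=n_sites)
    return pd.DataFrame(
        {
            "site": np.arange(1, n_sites + 1),
            "p_negative": probs[:, 0],
            "p_neutral": probs[:, 1],
            "p_positive": probs[:, 2],
        }
    )
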