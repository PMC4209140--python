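"""Site-class mixture likelihood: enumeration oracle, pulley-principle
invariance, beta discretization, and class expansion."""

import dendropy
import numpy as np
import pytest
from scipy import integrate, stats

from codonsel import (
    CodonAlignment,
    SiteClassModel,
    build_rate_matrix,
    discretize_beta,
    expand_site_classes,
    log_likelihood,
    read_newick,
    standard_genetic_code,
    transition_matrix,
)
from codonsel._pruning import PruningEngine
from codonsel.genetics import GeneticCode
from codonsel.simulate import coalescent_tree, simulate_alignment


class TestDiscretizeBeta:
    def test_uniform_beta_gives_interval_midpoints(self):
        values = discretize_beta(1.0, 1.0, 10)
        assert np.allclose(values, np.arange(0.05, 1.0, 0.1), atol=1e-9)

    def test_single_category_is_the_mean(self):
        assert discretize_beta(2.0, 3.0, 1)[0] == pytest.approx(0.4, abs=1e-12)

    @pytest.mark.parametrize("p,q,k", [(2.0, 3.0, 4), (0.3, 1.7, 10), (5.0, 0.4, 7)])
    def test_matches_quadrature_oracle(self, p, q, k):
        """Category values equal conditional means computed by numeric
        integration of x * beta_pdf over each quantile interval."""
        edges = stats.beta.ppf(np.linspace(0, 1, k + 1), p, q)
        oracle = []
        for a, b in zip(edges[:-1], edges[1:]):
            num, _ = integrate.quad(lambda x: x * stats.beta.pdf(x, p, q), a, b)
            oracle.append(num * k)  # each interval has probability 1/k
        values = discretize_beta(p, q, k)
        assert np.allclose(values, oracle, atol=1e-8)
        assert np.all(np.diff(values) > 0)
        assert np.all((values > 0) & (values < 1))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            discretize_beta(0.0, 1.0, 10)
        with pytest.raises(ValueError):
            discretize_beta(1.0, 1.0, 0)


class TestExpandSiteClasses:
    def test_m1a(self):
        model = SiteClassModel("M1a", p0=0.7, omega0=0.2)
        classes = expand_site_classes(model)
        assert classes[0] == (0.7, 0.2)
        assert classes[1][0] == pytest.approx(0.3)
        assert classes[1][1] == 1.0

    def test_m2a(self):
        model = SiteClassModel("M2a", p0=0.6, p1=0.3, omega0=0.1, omega2=2.5)
        classes = expand_site_classes(model)
        assert len(classes) == 3
        assert classes[2][0] == pytest.approx(0.1)
        assert classes[2][1] == 2.5

    def test_m8_weights(self):
        model = SiteClassModel("M8", p0=0.9, beta_p=1.0, beta_q=1.0, omega2=2.0)
        classes = expand_site_classes(model)
        assert len(classes) == 11
        assert np.allclose([p for p, _ in classes[:-1]], 0.09)
        assert classes[-1] == (pytest.approx(0.1), 2.0)

    def test_m8a_boundary_p0_one(self):
        model = SiteClassModel("M8a", p0=1.0, beta_p=2.0, beta_q=2.0)
        classes = expand_site_classes(model)
        assert classes[-1][0] == pytest.approx(0.0)
        assert classes[-1][1] == 1.0
        assert sum(p for p, _ in classes) == pytest.approx(1.0)

    def test_simplex_violation_raises(self):
        model = SiteClassModel("M2a", p0=0.8, p1=0.5, omega0=0.1, omega2=2.0)
        with pytest.raises(ValueError):
            expand_site_classes(model)


def _enumeration_loglik(aln, classes, pi, kappa, code):
    """Brute-force likelihood of ((A,B),(C,D)) by summing over all 61^3
    internal-node states, with explicit transition-probability tensors."""
    t = {"A": 0.2, "B": 0.35, "C": 0.1, "D": 0.4, "AB": 0.15, "CD": 0.25}
    row = {name: aln.sequences[aln.taxa.index(name)] for name in "ABCD"}
    total = 0.0
    for s in range(aln.n_sites):
        site_lik = 0.0
        for prop, omega in classes:
            # classes share the neutral-rate scale, as in the mixture model
            rm = build_rate_matrix(pi, kappa, omega, code, reference_omega=1.0)
            P = {k: transition_matrix(rm, v) for k, v in t.items()}

            def tip_vector(name):
                codon = row[name][3 * s : 3 * s + 3]
                if "-" in codon or "N" in codon:
                    return np.ones(61)
                vec = np.zeros(61)
                vec[code.index(codon)] = 1.0
                return vec

            a, b, c, d = (tip_vector(n) for n in "ABCD")
            # sum over internal states i (AB ancestor), j (CD ancestor), r (root)
            like = 0.0
            for r in range(61):
                term_ab = 0.0
                for i in range(61):
                    term_ab += P["AB"][r, i] * (P["A"][i] @ a) * (P["B"][i] @ b)
                term_cd = 0.0
                for j in range(61):
                    term_cd += P["CD"][r, j] * (P["C"][j] @ c) * (P["D"][j] @ d)
                like += pi[r] * term_ab * term_cd
            site_lik += prop * like
        total += np.log(site_lik)
    return total


class TestMixtureLikelihood:
    def test_single_taxon_is_log_pi(self, uniform_pi):
        aln = CodonAlignment(["A"], ["ATGAAA"])
        tree = read_newick("(A:0.0);")
        code = standard_genetic_code()
        lnl, site = log_likelihood(aln, tree, [(1.0, 0.5)], uniform_pi, 2.0)
        expected = np.log(uniform_pi[code.index("ATG")]) + np.log(
            uniform_pi[code.index("AAA")]
        )
        assert lnl == pytest.approx(expected, abs=1e-10)

    def test_enumeration_oracle_four_taxa_two_sites(self, four_taxon_tree, uniform_pi):
        aln = CodonAlignment(
            ["A", "B", "C", "D"], ["ATGAAA", "ATGAAG", "ATAAAA", "CTGAGA"]
        )
        classes = [(0.6, 0.2), (0.3, 1.0), (0.1, 2.5)]
        code = standard_genetic_code()
        lnl, _ = log_likelihood(aln, four_taxon_tree, classes, uniform_pi, 2.3)
        oracle = _enumeration_loglik(aln, classes, uniform_pi, 2.3, code)
        assert lnl == pytest.approx(oracle, abs=1e-8)

    def test_missing_data_marginalized_in_oracle(self, four_taxon_tree, uniform_pi):
        aln = CodonAlignment(
            ["A", "B", "C", "D"], ["ATG---", "ATGAAG", "ATANNN", "CTGAGA"]
        )
        classes = [(0.8, 0.1), (0.2, 1.0)]
        code = standard_genetic_code()
        lnl, _ = log_likelihood(aln, four_taxon_tree, classes, uniform_pi, 1.8)
        oracle = _enumeration_loglik(aln, classes, uniform_pi, 1.8, code)
        assert lnl == pytest.approx(oracle, abs=1e-8)

    def test_degenerate_mixture_equals_single_class(self, four_taxon_tree, uniform_pi):
        aln = CodonAlignment(
            ["A", "B", "C", "D"], ["ATGAAA", "ATGAAG", "ATAAAA", "CTGAGA"]
        )
        lnl_mix, _ = log_likelihood(
            aln, four_taxon_tree, [(1.0, 0.7)], uniform_pi, 2.0
        )
        lnl_padded, _ = log_likelihood(
            aln, four_taxon_tree, [(1.0, 0.7), (0.0, 3.0)], uniform_pi, 2.0
        )
        assert lnl_mix == pytest.approx(lnl_padded, abs=1e-9)

    def test_taxon_mismatch_raises(self, four_taxon_tree, uniform_pi):
        aln = CodonAlignment(["A", "B", "C", "X"], ["ATG", "ATG", "ATA", "CTG"])
        with pytest.raises(ValueError):
            log_likelihood(aln, four_taxon_tree, [(1.0, 0.5)], uniform_pi, 2.0)

    def test_rerooting_invariance(self, uniform_pi):
        """Under a reversible model the likelihood does not depend on root
        placement (pulley principle): rerooting on every branch of a 6-taxon
        tree leaves lnL unchanged."""
        tree = coalescent_tree(6, seed=5, mean_branch_length=0.2)
        model = SiteClassModel("M2a", p0=0.6, p1=0.3, omega0=0.15, omega2=2.0)
        aln, _ = simulate_alignment(tree, model, uniform_pi, 2.0, 40, seed=9)
        classes = expand_site_classes(model)
        base, _ = log_likelihood(aln, tree, classes, uniform_pi, 2.0)
        values = []
        newick = tree.as_string(schema="newick")
        edges = [
            e for e in dendropy.Tree.get(data=newick, schema="newick").preorder_edge_iter()
        ]
        n_edges = len([e for e in edges if e.head_node.parent_node is not None])
        for k in range(n_edges):
            t2 = dendropy.Tree.get(data=newick, schema="newick")
            edge = [
                e for e in t2.preorder_edge_iter() if e.head_node.parent_node is not None
            ][k]
            if edge.length is None or edge.length <= 0:
                continue
            t2.reroot_at_edge(edge, length1=edge.length / 2, length2=edge.length / 2)
            lnl, _ = log_likelihood(aln, t2, classes, uniform_pi, 2.0)
            values.append(lnl)
        assert len(values) >= 5
        assert np.abs(np.array(values) - base).max() < 1e-8

    def test_omega_one_ignores_the_synonymy_partition(self, four_taxon_tree, uniform_pi):
        """At omega = 1 the process is blind to amino-acid identity, so a
        scrambled genetic code (same codons, different amino acids) gives an
        identical likelihood."""
        code = standard_genetic_code()
        scrambled_map = dict(code.codon_to_aa)
        # reassign amino acids cyclically among sense codons
        senses = list(code.sense_codons)
        for i, codon in enumerate(senses):
            scrambled_map[codon] = code.codon_to_aa[senses[(i + 7) % len(senses)]]
        scrambled = GeneticCode(scrambled_map, code.sense_codons, code.stop_codons)
        aln = CodonAlignment(
            ["A", "B", "C", "D"], ["ATGAAA", "ATGAAG", "ATAAAA", "CTGAGA"]
        )
        lnl_std = PruningEngine(aln, four_taxon_tree, uniform_pi, code)
        lnl_scr = PruningEngine(aln, four_taxon_tree, uniform_pi, scrambled)
        a = lnl_std.class_site_loglik(np.array([1.0]), 2.5)
        b = lnl_scr.class_site_loglik(np.array([1.0]), 2.5)
        assert np.abs(a - b).max() < 1e-10
        # sanity: away from omega = 1 the partition matters
        a2 = lnl_std.class_site_loglik(np.array([0.2]), 2.5)
        b2 = lnl_scr.class_site_loglik(np.array([0.2]), 2.5)
        assert np.abs(a2 - b2).max() > 1e-6
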