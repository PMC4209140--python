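"""Mutation-count regression and ddG class summaries."""

import numpy as np
import pandas as pd
import pytest

from codonsel import (
    CodonAlignment,
    map_alignment_to_reference,
    selection_mutation_regression,
    stability_class_summary,
)
from codonsel.integration import clip_for_display, validate_stability_table
from codonsel.simulate import simulate_ddg_table, simulate_mutation_counts, synthetic_posteriors


class TestReferenceMapping:
    def test_ungapped_reference_is_identity(self):
        aln = CodonAlignment(["ref", "o"], ["ATGAAACCT", "ATGAAGCCA"])
        assert map_alignment_to_reference(aln, "ref") == {1: 1, 2: 2, 3: 3}

    def test_gapped_reference_shifts_numbering(self):
        aln = CodonAlignment(["ref", "o"], ["ATGAAA---CCT", "ATGAAGTGGCCA"])
        mapping = map_alignment_to_reference(aln, "ref")
        assert mapping == {1: 1, 2: 2, 4: 3}
        assert 3 not in mapping

    def test_missing_reference_rejected(self):
        aln = CodonAlignment(["a"], ["ATG"])
        with pytest.raises(KeyError):
            map_alignment_to_reference(aln, "ref")

    def test_mature_protein_numbering_offset(self):
        # legacy numbering starting after a 2-residue leader
        aln = CodonAlignment(["ref", "o"], ["ATGAAACCTTGG", "ATGAAGCCATGG"])
        mapping = map_alignment_to_reference(aln, "ref", numbering_offset=2)
        assert mapping == {3: 1, 4: 2}


class TestRegression:
    def _posteriors(self, p_positive):
        p = np.asarray(p_positive, float)
        return pd.DataFrame(
            {
                "site": np.arange(1, len(p) + 1),
                "p_negative": 1 - p,
                "p_neutral": np.zeros(len(p)),
                "p_positive": p,
            }
        )

    def test_collinear_toy_gives_perfect_negative_correlation(self):
        """Counts {0,1,2,3} against mean posteriors {0.8,0.6,0.4,0.2}."""
        post = self._posteriors([0.8, 0.6, 0.4, 0.2])
        muts = pd.DataFrame({"position": [1, 2, 3, 4], "count": [0, 1, 2, 3]})
        res = selection_mutation_regression(post, muts)
        assert res.r_positive == pytest.approx(-1.0, abs=1e-12)
        assert res.r_negative == pytest.approx(+1.0, abs=1e-12)
        assert res.slope_positive == pytest.approx(-0.2, abs=1e-12)

    def test_constant_counts_flagged_undefined(self):
        post = self._posteriors([0.8, 0.6, 0.4])
        muts = pd.DataFrame({"position": [1, 2, 3], "count": [2, 2, 2]})
        res = selection_mutation_regression(post, muts)
        assert res.r_positive is None
        assert "positive" in res.undefined

    def test_coupled_simulation_recovers_sign_pattern(self):
        post = synthetic_posteriors(500, seed=3)
        muts = simulate_mutation_counts(post, coupling=2.0, mean_count=2.0, seed=4)
        res = selection_mutation_regression(post, muts)
        assert res.r_positive < -0.5
        assert res.r_negative > 0.5

    def test_zero_coupling_is_uncorrelated(self):
        post = synthetic_posteriors(2000, seed=5)
        muts = simulate_mutation_counts(post, coupling=0.0, mean_count=2.0, seed=6)
        res = selection_mutation_regression(post, muts, mode="per_site")
        assert abs(res.r_positive) < 0.1

    def test_sign_recovery_across_seeds(self):
        """The inverse relationship is recovered in >= 19 of 20 seeds."""
        pos_ok = neg_ok = 0
        for seed in range(20):
            post = synthetic_posteriors(500, seed=seed)
            muts = simulate_mutation_counts(post, coupling=2.0, seed=1000 + seed)
            res = selection_mutation_regression(post, muts)
            pos_ok += res.r_positive < 0
            neg_ok += res.r_negative > 0
        assert pos_ok >= 19
        assert neg_ok >= 19

    def test_missing_sites_counted_as_zero_or_dropped(self):
        post = self._posteriors([0.9, 0.5, 0.1, 0.7, 0.3])
        muts = pd.DataFrame({"position": [1, 3, 5], "count": [0, 5, 2]})
        res_zero = selection_mutation_regression(post, muts, mode="per_site")
        assert res_zero.n_points == 5
        res_drop = selection_mutation_regression(
            post, muts, mode="per_site", missing_count="drop"
        )
        assert res_drop.n_points == 3


class TestStabilitySummary:
    def test_median_of_three(self):
        tab = pd.DataFrame(
            {
                "position": [1, 2, 3],
                "from_aa": list("AAA"),
                "to_aa": list("VLK"),
                "class": ["disease"] * 3,
                "ddg": [1.0, 2.0, 3.0],
            }
        )
        out = stability_class_summary(tab)
        assert out.loc[out["class"] == "disease", "median"].item() == 2.0

    def test_single_row_class(self):
        tab = pd.DataFrame(
            {
                "position": [1],
                "from_aa": ["A"],
                "to_aa": ["V"],
                "class": ["evolutionary"],
                "ddg": [0.42],
            }
        )
        out = stability_class_summary(tab)
        assert out["median"].item() == pytest.approx(0.42)
        assert "disease" not in set(out["class"])  # absent, not zero

    def test_row_order_and_clip_invariance(self):
        tab = simulate_ddg_table(
            400, {"all19": 0.8, "evolutionary": 0.2, "disease": 2.0}, seed=9
        )
        shuffled = tab.sample(frac=1.0, random_state=1)
        a = stability_class_summary(tab).set_index("class")
        b = stability_class_summary(shuffled).set_index("class")
        assert np.allclose(a["median"], b["median"])
        clipped = clip_for_display(tab, cap=10.0)
        assert clipped["ddg"].max() <= 10.0
        assert np.allclose(
            stability_class_summary(tab)["median"], a["median"]
        )

    def test_simulated_medians_ordering(self):
        """Generator targeted at the published median ranges reproduces the
        ordering evolutionary < all19 < disease."""
        tab = simulate_ddg_table(
            2000, {"all19": 0.8, "evolutionary": 0.2, "disease": 2.0}, seed=11
        )
        out = stability_class_summary(tab).set_index("class")["median"]
        assert out["evolutionary"] < out["all19"] < out["disease"]

    def test_unknown_class_rejected(self):
        tab = pd.DataFrame(
            {
                "position": [1],
                "from_aa": ["A"],
                "to_aa": ["V"],
                "class": ["weird"],
                "ddg": [1.0],
            }
        )
        with pytest.raises(ValueError):
            validate_stability_table(tab)
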