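"""DEG calling, variance shrinkage, chi-square and GO proportion checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from smrnapipe.expression_diff import (
    call_degs,
    chi_square_gof,
    chrom_distribution_test,
    go_proportions,
    squeeze_variances,
)

DESIGN = pd.DataFrame(
    {
        "sample": ["mut_1", "mut_2", "mut_3", "wt_1", "wt_2", "wt_3"],
        "genotype": ["mut"] * 3 + ["wt"] * 3,
    }
)


def make_matrix(values):
    return pd.DataFrame(
        values,
        index=pd.Index([f"g{i}" for i in range(len(values))], name="gene_id"),
        columns=DESIGN["sample"],
    )


class TestCallDegs:
    def test_identical_groups_give_no_degs(self):
        rng = np.random.default_rng(0)
        half = rng.normal(8, 1, size=(50, 3))
        matrix = make_matrix(np.hstack([half, half]))
        degs = call_degs(matrix, DESIGN)
        assert (degs["direction"] == "unchanged").all()
        assert (degs["p_value"] == 1.0).all()

    def test_strong_effect_detected_with_direction(self):
        rng = np.random.default_rng(1)
        values = rng.normal(8, 0.25, size=(100, 6))
        values[0, :3] += 3.0
        values[1, :3] -= 3.0
        degs = call_degs(make_matrix(values), DESIGN).set_index("gene_id")
        assert degs.loc["g0", "direction"] == "up"
        assert degs.loc["g1", "direction"] == "down"

    def test_direction_partition(self):
        rng = np.random.default_rng(2)
        values = rng.normal(8, 0.25, size=(80, 6))
        values[:10, :3] += 2.0
        degs = call_degs(make_matrix(values), DESIGN)
        counts = degs["direction"].value_counts()
        assert counts.sum() == len(degs)

    def test_welch_zero_variance_degenerate(self):
        values = np.tile(np.array([5.0, 5, 5, 5, 5, 5]), (2, 1))
        values[1] = [7, 7, 7, 5, 5, 5]
        degs = call_degs(make_matrix(values), DESIGN, method="welch").set_index("gene_id")
        assert degs.loc["g0", "p_value"] == 1.0  # equal means, no variance
        assert degs.loc["g1", "p_value"] == 0.0  # shifted means, no variance

    def test_bh_q_values_monotone_in_p(self):
        rng = np.random.default_rng(3)
        values = rng.normal(8, 0.25, size=(60, 6))
        values[:20, :3] += rng.normal(1, 0.5, size=(20, 1))
        degs = call_degs(make_matrix(values), DESIGN).sort_values("p_value")
        assert (np.diff(degs["q_value"]) >= -1e-12).all()

    def test_requires_two_replicates(self):
        design = DESIGN.iloc[[0, 3, 4]]
        with pytest.raises(ValueError, match="replicates"):
            call_degs(make_matrix(np.zeros((5, 6)))[design["sample"]], design)

    def test_moderated_beats_welch_at_three_replicates(self):
        """Variance shrinkage recovers power that per-gene Welch lacks."""
        rng = np.random.default_rng(4)
        values = rng.normal(8, 0.25, size=(200, 6))
        values[:20, :3] += 1.0
        matrix = make_matrix(values)
        mod = call_degs(matrix, DESIGN, min_lfc=0.0)
        welch = call_degs(matrix, DESIGN, min_lfc=0.0, method="welch")
        n_mod = (mod["direction"][:20] == "up").sum()
        n_welch = (welch["direction"][:20] == "up").sum()
        assert n_mod > n_welch


class TestSqueezeVariances:
    def test_posterior_lies_between_sample_and_prior(self):
        rng = np.random.default_rng(5)
        d, s0 = 4, 0.25**2
        s2 = s0 * rng.chisquare(d, size=2000) / d
        post, d0, s02 = squeeze_variances(s2, d)
        lo = np.minimum(s2, s02)
        hi = np.maximum(s2, s02)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_recovers_common_variance_scale(self):
        """With chi-square-only dispersion the prior matches the truth."""
        rng = np.random.default_rng(6)
        d, s0 = 4, 0.0625
        s2 = s0 * rng.chisquare(d, size=20_000) / d
        _, d0, s02 = squeeze_variances(s2, d)
        assert s02 == pytest.approx(s0, rel=0.1)
        assert d0 > 10  # sampling noise alone: heavy shrinkage


class TestChiSquare:
    def test_proportional_observed_gives_zero_and_one(self):
        stat, df, p = chi_square_gof([10, 20, 30], [10, 20, 30])
        assert stat == 0.0 and p == 1.0 and df == 2

    def test_closed_form_df1(self):
        stat, df, p = chi_square_gof([10, 0], [5, 5])
        assert stat == 10.0 and df == 1
        assert p == pytest.approx(1.565e-3, rel=1e-3)
        # survival function vs the erfc closed form for df=1
        assert p == pytest.approx(float(special.erfc(np.sqrt(10 / 2))), rel=1e-10)

    def test_chrom_test_relabeling_invariance(self):
        degs = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(30)],
                "chrom": ["A"] * 20 + ["B"] * 10,
                "direction": ["up"] * 30,
            }
        )
        expressed = pd.Series(["A"] * 50 + ["B"] * 50, index=[f"e{i}" for i in range(100)])
        t1 = chrom_distribution_test(degs, expressed)
        relabel = {"A": "B", "B": "A"}
        degs2 = degs.assign(chrom=degs["chrom"].map(relabel))
        t2 = chrom_distribution_test(degs2, expressed.map(relabel))
        assert t1.statistic == pytest.approx(t2.statistic)
        assert t1.p_value == pytest.approx(t2.p_value)

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(7)
        chroms = [f"chr{i}" for i in range(1, 13)]
        expressed = pd.Series(
            rng.choice(chroms, size=5000), index=[f"e{i}" for i in range(5000)]
        )
        # 1000 DEGs concentrated on three chromosomes
        de_chroms = rng.choice(chroms[:3], size=700).tolist() + rng.choice(
            chroms, size=300
        ).tolist()
        degs = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(1000)],
                "chrom": de_chroms,
                "direction": ["up"] * 1000,
            }
        )
        t = chrom_distribution_test(degs, expressed)
        assert t.df == 11
        assert t.p_value < 1e-6
        assert sum(t.observed.values()) == 1000
        assert sum(t.expected.values()) == pytest.approx(1000)


class TestGOProportions:
    degs = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(10)],
            "direction": ["up", "down"] + ["unchanged"] * 8,
        }
    )

    def test_proportion_arithmetic(self):
        table = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(10)], "category": ["c1"] * 10}
        )
        out = go_proportions(self.degs, table)
        assert out.loc[0, "proportion"] == 0.2

    def test_category_without_de_genes(self):
        table = pd.DataFrame({"gene_id": ["g5", "g6"], "category": ["c2", "c2"]})
        out = go_proportions(self.degs, table)
        assert out.loc[0, "proportion"] == 0.0

    def test_gene_in_two_categories_counts_in_each(self):
        table = pd.DataFrame(
            {"gene_id": ["g0", "g0", "g2"], "category": ["c1", "c2", "c2"]}
        )
        out = go_proportions(self.degs, table).set_index("category")
        assert out.loc["c1", "n_de_in_category"] == 1
        assert out.loc["c2", "n_de_in_category"] == 1
        # ordering: c2 has more expressed genes than c1
        assert out.index.tolist() == ["c2", "c1"]

    def test_unexpressed_genes_ignored(self):
        table = pd.DataFrame({"gene_id": ["nope"], "category": ["c9"]})
        assert go_proportions(self.degs, table).empty
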