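"""Tree I/O, independent contrasts and lambda = 1 PGLS."""

import numpy as np
import pandas as pd
import pytest

import tacdec as td
from tacdec.comparative import (
    MODEL_STRUCTURES,
    PhylogenyError,
    RankError,
    TraitError,
    canonical_name,
    contrasts_matrix,
    contrasts_regression,
    independent_contrasts,
    is_bifurcating,
    partial_out_contrasts,
    pgls_fit,
    phylo_vcv,
    prune_to_taxa,
    resolve_polytomies,
    transform_traits,
    tree_from_string,
)


def make_table(species, **overrides):
    n = len(species)
    base = pd.DataFrame(
        {
            "species": species,
            "deception_count": np.arange(n) + 1,
            "cooperativeness": (np.arange(n) % 4),
            "neocortex_ratio": np.linspace(1.5, 3.0, n),
            "neocortex_volume": np.linspace(10, 80, n),
            "research_effort": np.arange(10, 10 + n),
        }
    )
    for key, value in overrides.items():
        base[key] = value
    return base


class TestNewickIO:
    def test_two_tip_tree(self):
        tree = tree_from_string("(A:1,B:1);")
        lengths = [leaf.edge.length for leaf in tree.leaf_node_iter()]
        assert lengths == [1.0, 1.0]
        assert len(tree.leaf_nodes()) == 2

    def test_internal_edge(self):
        tree = tree_from_string("((A:1,B:1):0.5,C:1.5);")
        internal = [n for n in tree.preorder_internal_node_iter() if n.parent_node]
        assert len(internal) == 1 and internal[0].edge.length == 0.5

    def test_round_trip_preserves_lengths(self, tmp_path):
        tree = tree_from_string("((A:1.25,B:0.75):0.5,C:1.5);")
        path = tmp_path / "t.nwk"
        td.write_newick(tree, str(path))
        back = td.read_newick(str(path))
        _, C1 = phylo_vcv(tree)
        _, C2 = phylo_vcv(back)
        assert np.max(np.abs(C1 - C2)) < 1e-9

    def test_polytomy_accepted_and_flagged(self):
        tree = tree_from_string("(A:1,B:1,C:1);")
        assert not is_bifurcating(tree)
        resolved = resolve_polytomies(tree, seed=0)
        assert is_bifurcating(resolved)
        # zero-length resolution leaves the covariance structure unchanged
        labels, C = phylo_vcv(tree)
        labels2, C2 = phylo_vcv(resolved)
        order = [labels2.index(l) for l in labels]
        assert np.max(np.abs(C - C2[np.ix_(order, order)])) < 1e-12

    @pytest.mark.parametrize(
        "newick",
        [
            "[&U] (A:1,B:1,C:1);",  # explicitly unrooted
            "(A:1,A:1);",           # duplicate tips
            "(A:1,B);",             # missing branch length
        ],
    )
    def test_bad_input_rejected(self, newick):
        with pytest.raises(PhylogenyError):
            tree_from_string(newick)


class TestPrune:
    def test_prune_to_all_tips_is_identity(self):
        tree = tree_from_string("((A:1,B:1):0.5,C:1.5);")
        pruned = prune_to_taxa(tree, ["A", "B", "C"])
        _, C1 = phylo_vcv(tree)
        _, C2 = phylo_vcv(pruned)
        assert np.max(np.abs(C1 - C2)) < 1e-12

    def test_path_lengths_preserved(self):
        tree = tree_from_string("((A:1,B:1):0.5,C:1.5);")
        pruned = prune_to_taxa(tree, ["A", "C"])
        labels, C = phylo_vcv(pruned)
        # patristic distance A-C: depth_A + depth_C - 2 * shared = 1.5 + 1.5 - 0
        i, j = labels.index("A"), labels.index("C")
        assert C[i, i] + C[j, j] - 2 * C[i, j] == pytest.approx(3.0, abs=1e-12)

    def test_unknown_taxon_listed(self):
        tree = tree_from_string("(A:1,B:1);")
        with pytest.raises(PhylogenyError, match="nope"):
            prune_to_taxa(tree, ["A", "Nope"])

    def test_single_taxon_refused(self):
        tree = tree_from_string("(A:1,B:1);")
        with pytest.raises(PhylogenyError):
            prune_to_taxa(tree, ["A"])

    def test_name_canonicalization(self):
        assert canonical_name("Pan_troglodytes ") == canonical_name("pan troglodytes")
        tree = tree_from_string("(Pan_troglodytes:1,Gorilla_gorilla:1);")
        pruned = prune_to_taxa(tree, ["pan troglodytes", "GORILLA GORILLA"])
        assert len(pruned.leaf_nodes()) == 2


class TestTransforms:
    def test_log_plus_one_response(self):
        table = make_table(["a", "b", "c"], deception_count=[0, 9, 3])
        out = transform_traits(table.set_index("species"))
        assert out.loc["a", "log_deception"] == 0.0
        assert out.loc["b", "log_deception"] == pytest.approx(np.log(10), abs=1e-9)

    def test_effort_of_one_maps_to_zero(self):
        out = transform_traits(make_table(["a", "b"], research_effort=[1, 10]).set_index("species"))
        assert out.loc["a", "log_research_effort"] == 0.0

    def test_nonpositive_covariates_rejected(self):
        with pytest.raises(TraitError):
            transform_traits(make_table(["a", "b"], research_effort=[0, 5]))
        with pytest.raises(TraitError):
            transform_traits(make_table(["a", "b"], neocortex_volume=[-1.0, 5.0]))


class TestIndependentContrasts:
    def test_two_tip_hand_computation(self):
        tree = tree_from_string("(A:1,B:1);")
        result = independent_contrasts(tree, {"A": 3.0, "B": 1.0})
        assert len(result.contrasts) == 1
        assert abs(result.contrasts.iloc[0, 0]) == pytest.approx(2 / np.sqrt(2), abs=1e-9)
        assert result.variances.iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_constant_trait_gives_zero_contrasts(self):
        tree = td.simulate_yule_tree(12, seed=3)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        result = independent_contrasts(tree, {t: 7.0 for t in tips})
        assert np.allclose(result.contrasts.to_numpy(), 0.0)

    def test_count_is_tips_minus_one(self):
        tree = td.simulate_yule_tree(20, seed=4)
        values = td.simulate_bm(tree, 1.0, seed=5)
        assert len(independent_contrasts(tree, values).contrasts) == 19

    def test_branch_scaling_halves_contrasts(self):
        """Multiplying all branch lengths by 4 divides each standardized
        contrast by 2 (variances scale linearly, contrasts by sqrt)."""
        tree = td.simulate_yule_tree(10, seed=6)
        values = td.simulate_bm(tree, 1.0, seed=7)
        scaled = tree.clone(depth=1)
        for node in scaled.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length *= 4.0
        c1 = independent_contrasts(tree, values).contrasts.to_numpy()
        c2 = independent_contrasts(scaled, values).contrasts.to_numpy()
        assert np.max(np.abs(c2 - c1 / 2.0)) < 1e-9

    def test_zero_daughter_branches_named(self):
        tree = tree_from_string("((A:0,B:0):1,C:1);")
        with pytest.raises(PhylogenyError, match="node"):
            independent_contrasts(tree, {"A": 1.0, "B": 2.0, "C": 3.0})

    def test_polytomy_requires_resolution(self):
        tree = tree_from_string("(A:1,B:1,C:1);")
        with pytest.raises(PhylogenyError, match="polytom"):
            independent_contrasts(tree, {"A": 1.0, "B": 2.0, "C": 3.0})


class TestPGLS:
    def test_star_tree_equals_ols(self):
        """With no shared history the Brownian covariance is proportional to
        the identity and PGLS reduces to ordinary least squares."""
        from statsmodels.regression.linear_model import OLS

        species = [f"s{i}" for i in range(8)]
        tree = tree_from_string("(" + ",".join(f"{s}:2.0" for s in species) + ");")
        rng = np.random.default_rng(8)
        table = make_table(species,
                           deception_count=rng.integers(0, 40, 8),
                           cooperativeness=[0, 1, 2, 3, 0, 1, 2, 3])
        fit = pgls_fit(tree, table, model="ratio_model")
        data = transform_traits(table.set_index("species"))
        X = np.column_stack([np.ones(8)] + [
            data[p].to_numpy() for p in MODEL_STRUCTURES["ratio_model"]
        ])
        ols = OLS(data["log_deception"].to_numpy(), X).fit()
        assert np.max(np.abs(fit.params.to_numpy() - ols.params)) < 1e-8
        assert np.max(np.abs(fit.bse.to_numpy() - ols.bse)) < 1e-8

    @pytest.mark.parametrize("n_tips, seed", [(10, 0), (25, 1), (60, 2), (100, 3)])
    @pytest.mark.parametrize("model", ["ratio_model", "volume_model"])
    def test_gls_equals_contrasts_regression(self, n_tips, seed, model):
        """The asserted lambda = 1 <-> independent-contrasts equivalence:
        slopes, standard errors and t statistics agree across the two
        independent routes."""
        tree, table, _ = td.simulate_comparative_dataset(
            td.SyntheticSpec(seed=seed, n_tips=n_tips)
        )
        fit = pgls_fit(tree, table, model=model)
        alt = contrasts_regression(tree, table, model=model)
        for term in MODEL_STRUCTURES[model]:
            assert fit.params[term] == pytest.approx(alt.params[term], abs=1e-8)
            assert fit.tvalues[term] == pytest.approx(alt.tvalues[term], abs=1e-8)
        assert fit.df_resid == alt.df_resid

    def test_df_bookkeeping(self):
        tree, table, _ = td.simulate_comparative_dataset(td.SyntheticSpec(seed=9))
        fit = pgls_fit(tree, table, model="ratio_model")
        assert fit.df_resid == fit.nobs - 4
        assert ((fit.pvalues >= 0) & (fit.pvalues <= 1)).all()

    def test_tip_order_invariance(self):
        tree, table, _ = td.simulate_comparative_dataset(td.SyntheticSpec(seed=10))
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        f1 = pgls_fit(tree, table, model="ratio_model")
        f2 = pgls_fit(tree, shuffled, model="ratio_model")
        assert np.max(np.abs(f1.params.to_numpy() - f2.params.to_numpy())) < 1e-10

    def test_invariant_to_zero_length_root_stem(self):
        tree, table, _ = td.simulate_comparative_dataset(td.SyntheticSpec(seed=11))
        import dendropy

        rerooted = tree.clone(depth=1)
        new_root = dendropy.Node()
        old = rerooted.seed_node
        new_root.add_child(old)
        old.edge.length = 0.0
        rerooted.seed_node = new_root
        f1 = pgls_fit(tree, table, model="ratio_model")
        f2 = pgls_fit(rerooted, table, model="ratio_model")
        assert np.max(np.abs(f1.params.to_numpy() - f2.params.to_numpy())) < 1e-10

    def test_constant_predictor_raises_rank_error(self):
        tree, table, _ = td.simulate_comparative_dataset(td.SyntheticSpec(seed=12))
        table["cooperativeness"] = 2
        with pytest.raises(RankError):
            pgls_fit(tree, table, model="ratio_model")

    def test_too_few_species(self):
        tree = tree_from_string("(a:1,(b:0.5,c:0.5):0.5);")
        with pytest.raises(TraitError):
            pgls_fit(tree, make_table(["a", "b", "c"]), model="ratio_model")


class TestPartialledContrasts:
    def test_empty_nuisance_returns_raw_contrasts(self):
        tree, table, _ = td.simulate_comparative_dataset(td.SyntheticSpec(seed=13))
        out = partial_out_contrasts(tree, table, "cooperativeness", [])
        data = transform_traits(table.set_index("species"))
        raw = contrasts_matrix(tree, data, ["log_deception", "cooperativeness"])
        assert np.max(np.abs(out["y"].to_numpy() - raw["log_deception"].to_numpy())) < 1e-12
        assert np.max(np.abs(out["x"].to_numpy() - raw["cooperativeness"].to_numpy())) < 1e-12

    def test_frisch_waugh_slope_matches_full_fit(self):
        tree, table, _ = td.simulate_comparative_dataset(td.SyntheticSpec(seed=14, n_tips=40))
        out = partial_out_contrasts(
            tree, table, "cooperativeness", ["neocortex_ratio", "log_research_effort"]
        )
        slope = float(out["x"] @ out["y"] / (out["x"] @ out["x"]))
        fit = pgls_fit(tree, table, model="ratio_model")
        assert slope == pytest.approx(fit.params["cooperativeness"], abs=1e-8)

    def test_residuals_orthogonal_to_nuisances(self):
        tree, table, _ = td.simulate_comparative_dataset(td.SyntheticSpec(seed=15, n_tips=30))
        nuisances = ["neocortex_ratio", "log_research_effort"]
        out = partial_out_contrasts(tree, table, "cooperativeness", nuisances)
        data = transform_traits(table.set_index("species"))
        Z = contrasts_matrix(tree, data, nuisances).to_numpy()
        for k in range(Z.shape[1]):
            assert abs(out["y"].to_numpy() @ Z[:, k]) < 1e-10
            assert abs(out["x"].to_numpy() @ Z[:, k]) < 1e-10


class TestReferenceComparison:
    def test_comparison_table_on_synthetic_standin(self):
        """End-to-end validation mode against externally supplied
        coefficients (a synthetic stand-in table, not the published data)."""
        tree, table, _ = td.simulate_comparative_dataset(td.SyntheticSpec(seed=16, n_tips=24))
        reference = pd.DataFrame(
            [
                {"model": "ratio_model", "term": "cooperativeness",
                 "beta": 0.96, "se": 0.34, "p": 0.010},
                {"model": "volume_model", "term": "cooperativeness",
                 "beta": 0.97, "se": 0.36, "p": 0.013},
            ]
        )
        out = td.compare_to_reference(tree, table, reference)
        assert {"beta_fit", "se_fit", "p_fit", "beta_diff"} <= set(out.columns)
        assert len(out) == 2
        fit = pgls_fit(tree, table, model="ratio_model")
        assert out.loc[0, "beta_fit"] == pytest.approx(fit.params["cooperativeness"])
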