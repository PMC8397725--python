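"""Generators: determinism, positivity, cluster structure, status biasing."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.cluster import KMeans

from tpdiv.errors import ConfigurationError, InputError
from tpdiv.iucn import IUCN_CATEGORIES
from tpdiv.synthetic import (
    SyntheticConfig,
    assign_iucn_status,
    gen_brownian_traits,
    gen_phylogeny,
    gen_realms,
    gen_trait_table,
    mask_traits,
)


class TestConfig:
    def test_bad_probabilities_rejected(self):
        probs = {c: 1.0 / 7 for c in IUCN_CATEGORIES}
        probs["CR"] += 0.01
        with pytest.raises(ConfigurationError):
            SyntheticConfig(category_probs=probs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_species": 0},
            {"sharing": 1.5},
            {"threat_bias": -1.0},
            {"archetype_spread": -0.1},
        ],
    )
    def test_bad_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(**kwargs)


class TestTraitTable:
    def test_reproducible_and_positive(self):
        cfg = SyntheticConfig(seed=5)
        a, b = gen_trait_table(cfg), gen_trait_table(cfg)
        pd.testing.assert_frame_equal(a, b)
        assert (a > 0).all().all()
        assert a.shape == (cfg.n_species, cfg.n_traits)

    def test_zero_spread_collapses_to_archetype_centres(self):
        cfg = SyntheticConfig(n_species=50, n_archetypes=3, archetype_spread=0.0, seed=2)
        table = gen_trait_table(cfg)
        log_t = np.log(table.to_numpy())
        # every species' log-traits coincide with one of 3 centres
        assert len(np.unique(np.round(log_t, 10), axis=0)) == 3

    def test_two_archetypes_recovered_by_kmeans(self):
        # oracle: clustering on the generated log-traits recovers the mixture
        cfg = SyntheticConfig(
            n_species=200, n_traits=4, n_archetypes=2, archetype_spread=0.08, seed=11
        )
        table = gen_trait_table(cfg)
        truth = np.array(table.attrs["archetype"])
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(np.log(table.to_numpy()))
        labels = km.labels_
        purity = max(
            np.mean(labels == truth),
            np.mean(labels == 1 - truth),
        )
        assert purity > 0.95


class TestPhylogeny:
    def test_topology_and_ultrametric(self):
        tree = gen_phylogeny(3, birth=1.0, death=0.0, seed=1)
        leaves = tree.leaf_nodes()
        assert len(leaves) == 3
        internal = [n for n in tree if not n.is_leaf()]
        assert len(internal) == 2
        depths = [leaf.distance_from_root() for leaf in leaves]
        assert np.allclose(depths, depths[0])

    def test_branch_lengths_positive(self):
        tree = gen_phylogeny(40, birth=1.0, death=0.4, seed=9)
        for leaf in tree.leaf_nodes():
            assert leaf.edge.length > 0

    def test_same_seed_same_newick(self):
        a = gen_phylogeny(20, 1.0, 0.2, seed=7).as_string(schema="newick")
        b = gen_phylogeny(20, 1.0, 0.2, seed=7).as_string(schema="newick")
        assert a == b

    def test_death_at_least_birth_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_phylogeny(10, 1.0, 1.0, seed=0)


class TestBrownianTraits:
    def test_reproducible(self):
        tree = gen_phylogeny(30, 1.0, 0.0, seed=3)
        a = gen_brownian_traits(tree, 3, sigma=0.5, seed=4)
        b = gen_brownian_traits(tree, 3, sigma=0.5, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert (a > 0).all().all()

    def test_tiny_sigma_collapses_to_root_value(self):
        tree = gen_phylogeny(10, 1.0, 0.0, seed=3)
        table = gen_brownian_traits(tree, 2, sigma=1e-12, seed=5)
        assert np.allclose(table.to_numpy(), 1.0, atol=1e-6)

    def test_sigma_nonpositive_rejected(self):
        tree = gen_phylogeny(10, 1.0, 0.0, seed=3)
        with pytest.raises(ConfigurationError):
            gen_brownian_traits(tree, 2, sigma=0.0, seed=5)

    def test_close_relatives_more_similar(self):
        # simulation oracle: squared log-trait distance grows with patristic
        # distance on average (positive correlation across many trees)
        corrs = []
        for s in range(40):
            tree = gen_phylogeny(25, 1.0, 0.0, seed=s)
            table = gen_brownian_traits(tree, 1, sigma=1.0, seed=1000 + s)
            taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
            pdm = tree.phylogenetic_distance_matrix()
            log_t = np.log(table.to_numpy()[:, 0])
            pat, d2 = [], []
            for i in range(len(taxa)):
                for j in range(i + 1, len(taxa)):
                    pat.append(pdm.patristic_distance(taxa[i], taxa[j]))
                    d2.append((log_t[i] - log_t[j]) ** 2)
            corrs.append(stats.spearmanr(pat, d2).statistic)
        assert np.mean(corrs) > 0.2
        assert np.mean(np.array(corrs) > 0) > 0.9


class TestRealms:
    def test_no_sharing_single_realm_each(self):
        cfg = SyntheticConfig(n_realms=4, sharing=0.0, seed=1)
        m = gen_realms([f"s{i}" for i in range(100)], cfg)
        assert (m.groupby("species_id").size() == 1).all()

    def test_full_sharing_two_realms(self):
        cfg = SyntheticConfig(n_realms=2, sharing=1.0, seed=1)
        m = gen_realms([f"s{i}" for i in range(50)], cfg)
        assert (m.groupby("species_id").size() == 2).all()

    def test_union_covers_species_list(self):
        cfg = SyntheticConfig(n_realms=6, sharing=0.3, seed=2)
        ids = [f"s{i}" for i in range(80)]
        m = gen_realms(ids, cfg)
        assert set(m["species_id"]) == set(ids)

    def test_empty_species_list_rejected(self):
        with pytest.raises(InputError):
            gen_realms([], SyntheticConfig())


class TestStatus:
    def test_unbiased_statuses_independent_of_traits(self):
        # with no bias, status-vs-trait-tercile chi-squared rejects at the
        # nominal 5% rate (within Monte Carlo error over 200 tables)
        rejections = 0
        n_tables = 200
        for s in range(n_tables):
            cfg = SyntheticConfig(n_species=240, threat_bias=0.0, seed=s)
            traits = gen_trait_table(cfg)
            status = assign_iucn_status(traits, cfg)
            terciles = pd.qcut(traits.iloc[:, 0], 3, labels=False)
            threatened = status.isin(["CR", "EN", "VU", "NT"])
            table = pd.crosstab(terciles, threatened)
            if table.shape == (3, 2):
                p = stats.chi2_contingency(table).pvalue
                rejections += p < 0.05
        assert 0.03 <= rejections / n_tables <= 0.07

    def test_strong_bias_concentrates_threat_in_large_species(self):
        wins = 0
        for s in range(100):
            cfg = SyntheticConfig(n_species=200, threat_bias=4.0, seed=s)
            traits = gen_trait_table(cfg)
            status = assign_iucn_status(traits, cfg)
            cr = traits.loc[status == "CR"].iloc[:, 0]
            lc = traits.loc[status == "LC"].iloc[:, 0]
            if len(cr) and len(lc):
                wins += cr.mean() > lc.mean()
            else:
                wins += 1  # no comparison possible; don't count against
        assert wins >= 99

    def test_degenerate_probs_all_cr(self):
        probs = {c: 0.0 for c in IUCN_CATEGORIES}
        probs["CR"] = 1.0
        cfg = SyntheticConfig(category_probs=probs, seed=3)
        traits = gen_trait_table(cfg)
        assert (assign_iucn_status(traits, cfg) == "CR").all()

    def test_marginals_match_probs_without_bias(self):
        cfg = SyntheticConfig(n_species=6000, threat_bias=0.0, seed=8)
        traits = gen_trait_table(cfg)
        status = assign_iucn_status(traits, cfg)
        freqs = status.value_counts(normalize=True)
        for cat, p in cfg.category_probs.items():
            assert abs(freqs.get(cat, 0.0) - p) < 0.02


class TestMasking:
    def test_zero_fraction_unchanged(self):
        cfg = SyntheticConfig(seed=1)
        traits = gen_trait_table(cfg)
        result = mask_traits(traits, 0.0, seed=1)
        pd.testing.assert_frame_equal(result.masked, traits)

    def test_exact_row_count(self):
        cfg = SyntheticConfig(n_species=100, seed=1)
        traits = gen_trait_table(cfg)
        result = mask_traits(traits, 0.1, seed=2)
        assert result.mask.any(axis=1).sum() == 10

    def test_pattern_copied_exactly(self):
        cfg = SyntheticConfig(n_species=50, n_traits=6, seed=1)
        traits = gen_trait_table(cfg)
        pattern = traits.iloc[:1].copy()
        pattern.index = pd.Index(["tmpl"], name="species_id")
        pattern.iloc[0, 2] = np.nan
        pattern.iloc[0, 5] = np.nan
        result = mask_traits(traits, 0.2, pattern_source=pattern, seed=3)
        masked_rows = result.mask.index[result.mask.any(axis=1)]
        for sp in masked_rows:
            assert list(result.masked.columns[result.masked.loc[sp].isna()]) == [
                traits.columns[2],
                traits.columns[5],
            ]

    def test_originals_recoverable(self):
        cfg = SyntheticConfig(n_species=60, seed=4)
        traits = gen_trait_table(cfg)
        result = mask_traits(traits, 0.25, seed=5)
        restored = result.masked.fillna(result.original)
        pd.testing.assert_frame_equal(restored, traits)

    def test_bad_fraction_rejected(self):
        traits = gen_trait_table(SyntheticConfig(seed=1))
        with pytest.raises(ConfigurationError):
            mask_traits(traits, 1.5, seed=0)
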