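"""Generator tests: phylogeny/mass simulation, vortex signatures in the
raw trajectories, and the cross-module acceptance contract."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from extvortex.lpd import apply_selection_criteria
from extvortex.phylo import phylo_correlation
from extvortex.simulate import (
    VortexGeneratorConfig,
    generate_study,
    simulate_body_masses,
    simulate_extirpation_series,
    simulate_phylogeny,
)


class TestPhylogenySim:
    def test_two_species_cherry_with_unit_branches(self):
        t = simulate_phylogeny(2, seed=0)
        assert sorted(t.tip_labels) == ["sp001", "sp002"]
        for leaf in t.tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(1.0)

    def test_sixteen_species_binary_ultrametric(self):
        t = simulate_phylogeny(16, seed=1)
        internal = [n for n in t.tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == 15
        for leaf in t.tree.leaf_node_iter():
            depth, node = 0.0, leaf
            while node.parent_node is not None:
                depth += node.edge.length
                node = node.parent_node
            assert depth == pytest.approx(1.0, abs=1e-12)

    def test_same_seed_same_newick(self):
        assert simulate_phylogeny(9, seed=5).as_newick() == \
            simulate_phylogeny(9, seed=5).as_newick()

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_phylogeny(1)


class TestBodyMassSim:
    def test_zero_rate_gives_root_mass_everywhere(self):
        t = simulate_phylogeny(6, seed=2)
        masses = simulate_body_masses(t, root_log10_mass=1.3, bm_rate=0.0, seed=0)
        assert all(m == pytest.approx(10**1.3) for m in masses.values())

    def test_tip_variance_matches_brownian_rate(self):
        t = simulate_phylogeny(4, seed=3)
        rate = 0.5
        vals = []
        for rep in range(400):
            masses = simulate_body_masses(t, 0.0, rate, seed=rep)
            vals.append([np.log10(masses[sp]) for sp in sorted(masses)])
        tip_var = np.var(np.array(vals), axis=0, ddof=1)
        # root-to-tip depth is 1 after Grafen scaling, so Var = rate * 1
        np.testing.assert_allclose(tip_var, rate, rtol=0.15)

    def test_cherry_tips_more_correlated_than_distant_tips(self):
        from extvortex.phylo import grafen_lengths, parse_newick

        t = grafen_lengths(parse_newick("((A,B),C);"))
        vals = np.array([
            [np.log10(simulate_body_masses(t, 0.0, 1.0, seed=rep)[sp])
             for sp in ("A", "B", "C")]
            for rep in range(400)
        ])
        cov = np.cov(vals.T)
        assert cov[0, 1] > cov[0, 2] + 0.1
        assert cov[0, 1] == pytest.approx(0.5, abs=0.15)  # shared depth * rate

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_body_masses(simulate_phylogeny(3, seed=0), 0.0, -1.0)


class TestExtirpationSeries:
    def test_deterministic_decline_hits_threshold_on_schedule(self):
        cfg = VortexGeneratorConfig(
            sigma2=0.0, tau2=0.0, allee_strength=0.0, variance_inflation=0.0,
            phylo_sd=0.0, species_sd=0.0, base_drift=-0.25,
            init_log_abundance=5.0, missing_frac=0.0, seed=0,
        )
        series, attempts = simulate_extirpation_series(cfg, 0.0, 1.0, seed=0,
                                                       start_year=1990)
        # x_t = 5 - 0.25 t first drops below 0 at t = 21
        years = series.years
        values = series.values
        assert attempts == 1
        assert values[-2:] == [0.0, 0.0]
        assert years[-2] == 1990 + 21
        assert len([v for v in values if v > 0]) == 21
        np.testing.assert_allclose(values[0], np.exp(5.0))

    def test_drift_deteriorates_near_extinction(self, rng):
        cfg = VortexGeneratorConfig(
            allee_strength=0.1, variance_inflation=0.0, phylo_sd=0.0,
            species_sd=0.0, missing_frac=0.0,
        )
        first, last = [], []
        for _ in range(150):
            s, _ = simulate_extirpation_series(cfg, 0.0, 1.0,
                                               seed=int(rng.integers(2**31)))
            logs = [np.log(v) for v in s.values if v > 0]
            d = np.diff(logs)
            first.append(np.mean(d[:3]))
            last.append(np.mean(d[-3:]))
        assert np.mean(last) < np.mean(first) - 0.05

    def test_variance_inflates_near_extinction(self, rng):
        cfg = VortexGeneratorConfig(
            allee_strength=0.0, variance_inflation=1.0, phylo_sd=0.0,
            species_sd=0.0, missing_frac=0.0, tau2=0.0,
        )
        first, last = [], []
        for _ in range(150):
            s, _ = simulate_extirpation_series(cfg, 0.0, 1.0,
                                               seed=int(rng.integers(2**31)))
            logs = [np.log(v) for v in s.values if v > 0]
            d = np.diff(logs)
            first.extend(d[:3])
            last.extend(d[-3:])
        assert np.var(last) > 1.5 * np.var(first)

    def test_observation_noise_leaves_ma1_signature(self, rng):
        # with sigma2 = 0 the observed log increments are an MA(1) process:
        # lag-1 autocovariance = -tau2
        tau2 = 0.04
        cfg = VortexGeneratorConfig(
            sigma2=0.0, tau2=tau2, allee_strength=0.0, variance_inflation=0.0,
            phylo_sd=0.0, species_sd=0.0, base_drift=-0.3,
            init_log_abundance=5.0, missing_frac=0.0,
        )
        pairs = []
        for _ in range(500):
            s, _ = simulate_extirpation_series(cfg, 0.0, 1.0,
                                               seed=int(rng.integers(2**31)))
            d = np.diff([np.log(v) for v in s.values if v > 0])
            d = d - d.mean()
            pairs.extend(d[:-1] * d[1:])
        assert np.mean(pairs) == pytest.approx(-tau2, rel=0.2)

    def test_unreachable_extinction_reports_acceptance(self):
        cfg = VortexGeneratorConfig(
            base_drift=0.05, allee_strength=0.0, sigma2=0.001, tau2=0.0,
            phylo_sd=0.0, species_sd=0.0, max_tries=15,
        )
        with pytest.raises(RuntimeError, match="acceptance rate"):
            simulate_extirpation_series(cfg, 0.0, 1.0, seed=1)


class TestStudy:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = VortexGeneratorConfig(n_species=6, n_populations=7, seed=9)
        p1 = generate_study(cfg).to_dir(tmp_path / "a")
        p2 = generate_study(cfg).to_dir(tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_all_series_pass_selection(self, small_study):
        for s in small_study.series:
            assert apply_selection_criteria(s).accepted

    def test_every_species_has_mass_and_tip(self, small_study):
        tips = set(small_study.tree.tip_labels)
        for sp in small_study.species_of_series.values():
            assert sp in tips
            assert sp in small_study.body_masses

    def test_phylogenetic_structure_in_realized_drifts(self):
        # with purely phylogenetic intercept variance, closely related species
        # have more similar drift intercepts (distance rank correlation > 0);
        # the rank statistic is invariant to the phylogenetic scale, so a
        # modest one keeps every species' extirpation reachable
        rhos = []
        for rep in range(20):
            cfg = VortexGeneratorConfig(
                n_species=12, n_populations=12, phylo_sd=0.06, species_sd=0.0,
                seed=100 + rep,
            )
            study = generate_study(cfg)
            corr = study.correlation
            drifts = study.truth["species_drift_intercepts"]
            d_effect, d_tree = [], []
            for i, a in enumerate(corr.species):
                for j in range(i + 1, len(corr.species)):
                    b = corr.species[j]
                    d_effect.append(abs(drifts[a] - drifts[b]))
                    d_tree.append(1.0 - corr.matrix[i, j])
            rhos.append(spearmanr(d_effect, d_tree).statistic)
        assert np.mean(rhos) > 0.1

    def test_acceptance_rate_recorded(self, small_study):
        assert 0 < small_study.acceptance_rate <= 1
        assert small_study.truth["acceptance_rate"] == small_study.acceptance_rate
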