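import numpy as np
import pytest

from xlmodel.crosslinks import DEFAULT_LINKERS, distance_threshold
from xlmodel.modeling import (Configuration, ConfigurationEnsemble, MembraneSlab,
                              ModelingConfigError, Scorer, assess_sampling,
                              build_representation, cluster_ensemble,
                              configuration_to_structure, sample_monte_carlo, score)
from xlmodel.structure import ResidueRef, superpose_coords  # noqa: F401 (oracles)
from xlmodel.synth import (ToySpec, generate_toy_complex, perturb_configuration,
                           simulate_crosslinks)

from conftest import ca_only, make_structure


@pytest.fixture(scope="module")
def toy2():
    return generate_toy_complex(ToySpec(n_bodies=2, residues_per_body=25, seed=3))


@pytest.fixture(scope="module")
def rep2(toy2):
    return build_representation(toy2.structure, toy2.body_spec)


class TestRepresentation:
    def test_bodies_plus_linker_beads_partition(self, toy2, rep2):
        assert rep2.n_bodies == 2
        assert len(rep2.bead_indices) == len(toy2.linker_residues)
        covered = set(np.concatenate(rep2.body_members)) | set(rep2.bead_indices)
        assert covered == set(range(rep2.n_residues))

    def test_single_body_covering_everything(self, toy2):
        s = toy2.structure
        rep = build_representation(s, {"all": [r.ref for r in s]})
        assert rep.n_bodies == 1 and len(rep.bead_indices) == 0

    def test_overlapping_bodies_rejected(self, toy2):
        s = toy2.structure
        refs = [r.ref for r in s]
        with pytest.raises(ModelingConfigError, match="assigned to both"):
            build_representation(s, {"a": refs[:10], "b": refs[5:15]})

    def test_seven_body_spec_counts(self):
        toy = generate_toy_complex(ToySpec(n_bodies=7, residues_per_body=12, seed=5,
                                           chains=[0, 0, 1, 1, 2, 3, 4],
                                           linker_length=4))
        rep = build_representation(toy.structure, toy.body_spec)
        assert rep.n_bodies == 7
        in_bodies = sum(len(m) for m in rep.body_members)
        assert len(rep.bead_indices) == len(toy.structure) - in_bodies

    def test_missing_ca_interpolated_and_flagged(self):
        residues = [ca_only("A", i, "ALA", (3.8 * i, 0, 0)) for i in range(1, 6)]
        residues[2] = ("A", 3, "ALA", [("N", "N", (7.6, 0, 0))])  # no Calpha
        s = make_structure(residues)
        rep = build_representation(s, {"b": [ResidueRef("A", i) for i in (1, 2, 5)]})
        assert rep.interpolated == [ResidueRef("A", 3)]
        # midpoint of the flanking Calpha anchors at x=7.6 and x=15.2
        np.testing.assert_allclose(rep.reference_coords[2], [11.4, 0, 0], atol=1e-9)

    def test_secondary_structure_promotes_extra_bodies(self, toy2):
        s = toy2.structure
        body_refs = list(toy2.body_spec.values())[0]
        ann = {r.ref: "coil" for r in s}
        free = [r.ref for r in s if r.ref not in set(body_refs)]
        for ref in free[:6]:
            ann[ref] = "helix"
        rep = build_representation(s, {"b0": body_refs}, ss_annotation=ann)
        assert rep.n_bodies == 2  # named body + promoted helix run


class TestScoring:
    def test_native_with_zero_noise_links_has_zero_crosslink_term(self, toy2, rep2):
        xl, _ = simulate_crosslinks(toy2.structure, DEFAULT_LINKERS["BS3"], 40, 0.0,
                                    seed=1)
        sb = score(Configuration.identity(rep2), rep2, xl)
        assert sb.crosslink_term == 0.0
        assert sb.total == pytest.approx(sb.membrane_term + sb.connectivity_term
                                         + sb.excluded_volume_term + sb.crosslink_term)

    def test_two_overlapping_beads_excluded_volume(self):
        # two isolated glycine beads (radius 2.3) on different chains, 1.6 A apart
        s = make_structure([ca_only("A", 1, "GLY", (0, 0, 0)),
                            ca_only("B", 1, "GLY", (1.6, 0, 0))])
        rep = build_representation(s, {})
        sb = score(Configuration.identity(rep), rep)
        assert sb.excluded_volume_term == pytest.approx((2.3 + 2.3 - 1.6) ** 2)

    def test_matches_term_by_term_oracle(self, toy2, rep2):
        xl, _ = simulate_crosslinks(toy2.structure, DEFAULT_LINKERS["DSG"], 50, 0.3,
                                    seed=4)
        membrane = MembraneSlab(residues=[rep2.residue_refs[i]
                                          for i in rep2.body_members[0][:10]],
                                half_thickness=15.0)
        config = perturb_configuration(Configuration.identity(rep2), 8.0, 30.0, seed=2)
        got = score(config, rep2, xl, membrane)

        coords = config.coords(rep2)
        thr = distance_threshold(DEFAULT_LINKERS["DSG"])
        xl_term = 0.0
        for link in xl:
            d = np.linalg.norm(coords[rep2.index_of(link.site_a)]
                               - coords[rep2.index_of(link.site_b)])
            xl_term += max(0.0, d - thr) ** 2
        conn = sum(max(0.0, np.linalg.norm(coords[a] - coords[b]) - 3.8) ** 2
                   for a, b in rep2.connectivity_pairs)
        ev = 0.0
        for i in range(rep2.n_residues):
            for j in range(i + 1, rep2.n_residues):
                if rep2.ev_mask[i, j]:
                    d = np.linalg.norm(coords[i] - coords[j])
                    ev += max(0.0, rep2.bead_radii[i] + rep2.bead_radii[j] - d) ** 2
        mem = sum(max(0.0, abs(coords[rep2.index_of(r)][2]) - 15.0) ** 2
                  for r in membrane.residues)
        assert got.crosslink_term == pytest.approx(xl_term, abs=1e-9)
        assert got.connectivity_term == pytest.approx(conn, abs=1e-9)
        assert got.excluded_volume_term == pytest.approx(ev, abs=1e-9)
        assert got.membrane_term == pytest.approx(mem, abs=1e-9)
        assert got.total == pytest.approx(xl_term + conn + ev + mem, abs=1e-9)

    def test_invariant_under_global_rigid_motion(self, toy2, rep2):
        # no membrane: the slab frame is the only absolute frame in the score
        xl, _ = simulate_crosslinks(toy2.structure, DEFAULT_LINKERS["BS3"], 30, 0.2,
                                    seed=5)
        scorer = Scorer(rep2, xl)
        config = perturb_configuration(Configuration.identity(rep2), 5.0, 20.0, seed=7)
        base = scorer.score_coords(config.coords(rep2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = config.coords(rep2) @ rot.T + np.array([11.0, -4.0, 9.0])
        after = scorer.score_coords(moved)
        assert after.total == pytest.approx(base.total, rel=1e-9)


class TestMonteCarlo:
    def test_best_score_not_worse_than_start(self, toy2, rep2):
        xl, _ = simulate_crosslinks(toy2.structure, DEFAULT_LINKERS["BS3"], 30, 0.0,
                                    seed=1)
        ens = sample_monte_carlo(rep2, xl, n_steps=2000, seed=3, record_every=100)
        start = sample_monte_carlo(rep2, xl, n_steps=1, seed=3, record_every=1)
        assert ens.totals.min() <= start.totals.min()

    def test_deterministic_replay(self, toy2, rep2):
        xl, _ = simulate_crosslinks(toy2.structure, DEFAULT_LINKERS["BS3"], 30, 0.0,
                                    seed=1)
        a = sample_monte_carlo(rep2, xl, n_steps=1500, seed=9, record_every=50)
        b = sample_monte_carlo(rep2, xl, n_steps=1500, seed=9, record_every=50)
        np.testing.assert_array_equal(a.totals, b.totals)
        np.testing.assert_array_equal(a.coords_array(), b.coords_array())

    def test_seeded_subsample(self, toy2, rep2):
        ens = sample_monte_carlo(rep2, None, n_steps=500, seed=2, record_every=10)
        sub1 = ens.subsample(10, seed=4)
        sub2 = ens.subsample(10, seed=4)
        assert len(sub1) == 10
        np.testing.assert_array_equal(sub1.totals, sub2.totals)


def planted_two_state_ensemble(rep, n_each=5, separation=45.0):
    truth = Configuration.identity(rep)
    configs = []
    for k in range(n_each):
        configs.append(perturb_configuration(truth, 1.0, 2.0, seed=k))
    shifted = truth.copy()
    shifted.body_translations[1] += np.array([0.0, separation, 0.0])
    for k in range(n_each):
        configs.append(perturb_configuration(shifted, 1.0, 2.0, seed=100 + k))
    scores = [score(c, rep) for c in configs]
    return ConfigurationEnsemble(rep, configs, scores)


class TestClustering:
    def test_identical_models_single_cluster_zero_precision(self, rep2):
        c = Configuration.identity(rep2)
        ens = ConfigurationEnsemble(rep2, [c.copy() for _ in range(4)],
                                    [score(c, rep2)] * 4)
        result = cluster_ensemble(ens, threshold=5.0)
        assert len(result.populations) == 1
        assert result.precisions[0] == pytest.approx(0.0, abs=1e-9)

    def test_planted_two_state_memberships(self, rep2):
        ens = planted_two_state_ensemble(rep2)
        result = cluster_ensemble(ens, threshold=10.0)
        assert len(result.populations) == 2
        labels = result.labels
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_cluster_precision_not_above_ensemble_precision(self, rep2):
        ens = planted_two_state_ensemble(rep2)
        result = cluster_ensemble(ens, threshold=10.0)
        assert (result.precisions <= result.ensemble_precision + 1e-9).all()

    def test_matches_connected_component_oracle(self, rep2):
        rng = np.random.default_rng(0)
        truth = Configuration.identity(rep2)
        configs = [perturb_configuration(truth, float(rng.uniform(0, 12)),
                                         float(rng.uniform(0, 30)), seed=k)
                   for k in range(50)]
        ens = ConfigurationEnsemble(rep2, configs, [score(c, rep2) for c in configs])
        threshold = 8.0
        result = cluster_ensemble(ens, threshold=threshold)
        # oracle: single linkage at t == connected components of the d<=t graph
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(range(50))
        m = result.rmsd_matrix
        for i in range(50):
            for j in range(i + 1, 50):
                if m[i, j] <= threshold:
                    g.add_edge(i, j)
        comps = {frozenset(c) for c in nx.connected_components(g)}
        got = {frozenset(np.flatnonzero(result.labels == c))
               for c in np.unique(result.labels)}
        assert got == comps

    def test_invalid_threshold_rejected(self, rep2):
        ens = planted_two_state_ensemble(rep2, n_each=2)
        with pytest.raises(ModelingConfigError):
            cluster_ensemble(ens, threshold=0.0)


class TestConvergence:
    def test_identical_runs_converged(self, toy2, rep2):
        xl, _ = simulate_crosslinks(toy2.structure, DEFAULT_LINKERS["BS3"], 30, 0.0,
                                    seed=1)
        run = sample_monte_carlo(rep2, xl, n_steps=1000, seed=5, record_every=50)
        report = assess_sampling(run, run)
        assert report.converged
        assert report.score_ks_pvalue == pytest.approx(1.0)

    def test_disjoint_basins_not_converged(self, rep2):
        truth = Configuration.identity(rep2)
        far = truth.copy()
        far.body_translations[1] += np.array([0.0, 60.0, 0.0])
        runs = []
        for base, seed0 in ((truth, 0), (far, 50)):
            configs = [perturb_configuration(base, 1.0, 3.0, seed=seed0 + k)
                       for k in range(12)]
            runs.append(ConfigurationEnsemble(rep2, configs,
                                              [score(c, rep2) for c in configs]))
        report = assess_sampling(runs[0], runs[1], threshold_grid=[5.0, 10.0, 20.0])
        assert not report.converged

    def test_mismatched_inputs_rejected(self, rep2, toy2):
        small = generate_toy_complex(ToySpec(n_bodies=1, residues_per_body=10, seed=1))
        rep_small = build_representation(small.structure, small.body_spec)
        e1 = ConfigurationEnsemble(rep2, [Configuration.identity(rep2)],
                                   [score(Configuration.identity(rep2), rep2)])
        e2 = ConfigurationEnsemble(rep_small, [Configuration.identity(rep_small)],
                                   [score(Configuration.identity(rep_small), rep_small)])
        with pytest.raises(ModelingConfigError):
            assess_sampling(e1, e2)


class TestInterchange:
    def test_configuration_round_trips_to_structure(self, rep2):
        config = Configuration.identity(rep2)
        s = configuration_to_structure(rep2, config)
        np.testing.assert_allclose(s.ca_coords(), config.coords(rep2), atol=1e-9)

    def test_satisfaction_better_in_best_cluster_than_random(self, toy2, rep2):
        xl, _ = simulate_crosslinks(toy2.structure, DEFAULT_LINKERS["BS3"], 40, 0.0,
                                    seed=1)
        ens = sample_monte_carlo(rep2, xl, n_steps=8000, seed=2, record_every=200)
        result = cluster_ensemble(ens, threshold=10.0)
        from xlmodel.crosslinks import classify_satisfaction
        best = configuration_to_structure(
            rep2, ens.configurations[result.centroids[0]])
        rng_cfg = perturb_configuration(Configuration.identity(rep2), 30.0, 90.0,
                                        seed=77)
        random_s = configuration_to_structure(rep2, rng_cfg)
        assert (classify_satisfaction(xl, best).satisfied_fraction
                >= classify_satisfaction(xl, random_s).satisfied_fraction)
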