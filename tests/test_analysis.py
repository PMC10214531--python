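import numpy as np
import pytest

from xlmodel.analysis import (AnalysisConfigError, helix_rotation_angle,
                              pca_rigid_body_centers, per_component_rmsd,
                              satisfaction_percentages)
from xlmodel.crosslinks import DEFAULT_LINKERS, classify_satisfaction
from xlmodel.modeling import (Configuration, ConfigurationEnsemble,
                              build_representation, configuration_to_structure,
                              score)
from xlmodel.structure import superpose_coords
from xlmodel.synth import (ToySpec, generate_toy_complex, perturb_configuration,
                           simulate_crosslinks)

from conftest import ca_only, make_structure


@pytest.fixture(scope="module")
def toy2():
    return generate_toy_complex(ToySpec(n_bodies=2, residues_per_body=25, seed=3))


@pytest.fixture(scope="module")
def rep2(toy2):
    return build_representation(toy2.structure, toy2.body_spec)


def ensemble_of(rep, configs):
    return ConfigurationEnsemble(rep, configs, [score(c, rep) for c in configs])


@pytest.fixture(scope="module")
def align_sel(toy2):
    return list(toy2.body_spec["body0"])


class TestPca:
    def test_identical_models_have_zero_variance(self, rep2, align_sel):
        c = Configuration.identity(rep2)
        ens = ensemble_of(rep2, [c.copy() for _ in range(5)])
        profile = pca_rigid_body_centers(ens, align_sel, n_clusters=1)
        assert profile.explained_variance[0] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(profile.coordinates, profile.coordinates[0])

    def test_three_planted_clusters_recovered(self, rep2, align_sel):
        truth = Configuration.identity(rep2)
        configs, expected = [], []
        offsets = [np.zeros(3), np.array([0, 20.0, 0]), np.array([0, 0, 20.0])]
        for label, off in enumerate(offsets):
            base = truth.copy()
            base.body_translations[1] += off
            for k in range(10):
                configs.append(perturb_configuration(base, 1.0, 0.0,
                                                     seed=label * 100 + k))
                expected.append(label)
        ens = ensemble_of(rep2, configs)
        profile = pca_rigid_body_centers(ens, align_sel, n_clusters=3,
                                         bodies=["body1"], seed=0)
        # membership agreement up to label permutation
        from scipy.optimize import linear_sum_assignment
        expected = np.asarray(expected)
        confusion = np.zeros((3, 3))
        for e, g in zip(expected, profile.cluster_labels):
            confusion[e, g] += 1
        rows, cols = linear_sum_assignment(-confusion)
        agreement = confusion[rows, cols].sum() / len(expected)
        assert agreement >= 0.95

    def test_pc_coordinates_match_eigendecomposition_oracle(self, rep2, align_sel):
        rng = np.random.default_rng(5)
        truth = Configuration.identity(rep2)
        configs = [perturb_configuration(truth, float(rng.uniform(0, 8)),
                                         float(rng.uniform(0, 20)), seed=k)
                   for k in range(30)]
        ens = ensemble_of(rep2, configs)
        profile = pca_rigid_body_centers(ens, align_sel, n_clusters=2,
                                         n_components=2, seed=1)
        feats = profile.features
        centered = feats - feats.mean(axis=0)
        cov = centered.T @ centered / (len(feats) - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        for k in range(2):
            oracle = centered @ evecs[:, order[k]]
            got = profile.coordinates[:, k]
            assert (np.allclose(got, oracle, atol=1e-6)
                    or np.allclose(got, -oracle, atol=1e-6))
            assert profile.explained_variance[k] == pytest.approx(evals[order[k]],
                                                                  rel=1e-6)

    def test_explained_variance_conserves_total(self, rep2, align_sel):
        rng = np.random.default_rng(6)
        truth = Configuration.identity(rep2)
        configs = [perturb_configuration(truth, 4.0, 10.0, seed=k) for k in range(12)]
        ens = ensemble_of(rep2, configs)
        profile = pca_rigid_body_centers(ens, align_sel, n_clusters=2,
                                         n_components=6, seed=1)
        feats = profile.features
        total_var = ((feats - feats.mean(0)) ** 2).sum() / (len(feats) - 1)
        assert profile.explained_variance.sum() == pytest.approx(total_var, rel=1e-6)
        assert (np.diff(profile.explained_variance) <= 1e-9).all()

    def test_ensemble_centroid_matches_exhaustive_oracle(self, rep2, align_sel):
        rng = np.random.default_rng(8)
        truth = Configuration.identity(rep2)
        configs = [perturb_configuration(truth, float(rng.uniform(0, 10)), 5.0, seed=k)
                   for k in range(15)]
        ens = ensemble_of(rep2, configs)
        profile = pca_rigid_body_centers(ens, align_sel, n_clusters=2, seed=0)
        coords = ens.coords_array()
        sums = []
        for i in range(len(ens)):
            sums.append(sum(superpose_coords(coords[i], coords[j]).rmsd
                            for j in range(len(ens)) if j != i))
        assert profile.ensemble_centroid == int(np.argmin(sums))

    def test_too_many_clusters_rejected(self, rep2, align_sel):
        ens = ensemble_of(rep2, [Configuration.identity(rep2) for _ in range(3)])
        with pytest.raises(AnalysisConfigError):
            pca_rigid_body_centers(ens, align_sel, n_clusters=10)


class TestPerComponentRmsd:
    def test_reference_against_itself_is_zero(self, toy2, rep2, align_sel):
        ens = ensemble_of(rep2, [Configuration.identity(rep2)])
        comps = {name: list(refs) for name, refs in toy2.body_spec.items()}
        df = per_component_rmsd(ens, toy2.structure, comps, align_sel)
        assert df.rmsd.abs().max() < 1e-9

    def test_translated_component_concentrates_at_offset(self, toy2, rep2, align_sel):
        shifted = Configuration.identity(rep2)
        shifted.body_translations[1] += np.array([10.0, 0.0, 0.0])
        ens = ensemble_of(rep2, [shifted.copy() for _ in range(4)])
        df = per_component_rmsd(ens, toy2.structure,
                                {"moved": list(toy2.body_spec["body1"])}, align_sel)
        assert df.rmsd.values == pytest.approx([10.0] * 4, abs=1e-6)

    def test_matches_per_model_oracle(self, toy2, rep2, align_sel):
        rng = np.random.default_rng(3)
        truth = Configuration.identity(rep2)
        configs = [perturb_configuration(truth, 5.0, 15.0, seed=k) for k in range(6)]
        ens = ensemble_of(rep2, configs)
        comps = {"body1": list(toy2.body_spec["body1"])}
        df = per_component_rmsd(ens, toy2.structure, comps, align_sel)
        anchor_idx = [rep2.index_of(r) for r in align_sel]
        comp_idx = [rep2.index_of(r) for r in comps["body1"]]
        ref_anchor = toy2.structure.ca_coords(align_sel)
        ref_comp = toy2.structure.ca_coords(comps["body1"])
        for m, config in enumerate(configs):
            coords = config.coords(rep2)
            sp = superpose_coords(coords[anchor_idx], ref_anchor)
            moved = sp.apply(coords)[comp_idx]
            oracle = float(np.sqrt(((moved - ref_comp) ** 2).sum(1).mean()))
            assert df[(df.model == m)].rmsd.iloc[0] == pytest.approx(oracle, abs=1e-9)

    def test_empty_component_rejected(self, toy2, rep2, align_sel):
        ens = ensemble_of(rep2, [Configuration.identity(rep2)])
        with pytest.raises(AnalysisConfigError):
            per_component_rmsd(ens, toy2.structure, {"empty": []}, align_sel)


def helical_structure(n=18, rotate=None, label="helix"):
    # 18 residues at 100 deg/residue = 5 exact turns, so the principal axis
    # of the Calpha cloud is exactly the helix axis
    from xlmodel.synth import _helix_coords
    coords = _helix_coords(n)
    # non-collinear anchor (small helix offset in x) so superposition is well posed
    anchor_coords = _helix_coords(6) + np.array([50.0, 0.0, 0.0])
    anchor = [ca_only("A", i + 1, "ALA", c) for i, c in enumerate(anchor_coords)]
    if rotate is not None:
        coords = coords @ rotate.T
    helix = [ca_only("A", 100 + i, "ALA", c) for i, c in enumerate(coords)]
    return make_structure(anchor + helix, label=label)


def _rotation_about(axis, angle):
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _axis_oracle(coords):
    centered = coords - coords.mean(axis=0)
    evals, evecs = np.linalg.eigh(centered.T @ centered)
    axis = evecs[:, np.argmax(evals)]
    if np.dot(axis, coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis


class TestHelixRotation:
    anchor = [("A", i + 1) for i in range(6)]
    helix = [("A", 100 + i) for i in range(18)]

    def _refs(self, pairs):
        from xlmodel.structure import ResidueRef
        return [ResidueRef(c, n) for c, n in pairs]

    def test_same_structure_zero_angle(self):
        s = helical_structure()
        angle = helix_rotation_angle(s, s, self._refs(self.helix), self._refs(self.anchor))
        assert angle == pytest.approx(0.0, abs=1e-6)

    def test_constructed_ninety_degree_rotation(self):
        from xlmodel.analysis import helix_axis
        ref = helical_structure()
        axis = helix_axis(ref.ca_coords(self._refs(self.helix)))
        perp = np.cross(axis, [1.0, 0.0, 0.0])
        rot = _rotation_about(perp / np.linalg.norm(perp), np.pi / 2)
        model = helical_structure(rotate=rot, label="rot")
        angle = helix_rotation_angle(model, ref, self._refs(self.helix),
                                     self._refs(self.anchor))
        assert angle == pytest.approx(90.0, abs=1e-6)

    def test_symmetry(self):
        ref = helical_structure()
        theta = np.deg2rad(40.0)
        rot = np.array([[1.0, 0, 0],
                        [0, np.cos(theta), -np.sin(theta)],
                        [0, np.sin(theta), np.cos(theta)]])
        model = helical_structure(rotate=rot, label="rot40")
        hsel, asel = self._refs(self.helix), self._refs(self.anchor)
        assert helix_rotation_angle(model, ref, hsel, asel) == pytest.approx(
            helix_rotation_angle(ref, model, hsel, asel), abs=1e-9)

    @pytest.mark.parametrize("theta_deg", [15.0, 60.0, 120.0, 170.0])
    def test_matches_arccos_oracle(self, theta_deg):
        rot = _rotation_about(np.array([1.0, 0, 0]), np.deg2rad(theta_deg))
        ref = helical_structure()
        model = helical_structure(rotate=rot, label=f"rot{theta_deg}")
        angle = helix_rotation_angle(model, ref, self._refs(self.helix),
                                     self._refs(self.anchor))
        # independent oracle: eigen-decomposition axes, N->C orientation,
        # arccos of the dot product
        expected = np.degrees(np.arccos(np.clip(np.dot(
            _axis_oracle(ref.ca_coords(self._refs(self.helix))),
            _axis_oracle(model.ca_coords(self._refs(self.helix)))), -1, 1)))
        assert angle == pytest.approx(expected, abs=1e-6)

    def test_too_short_helix_rejected(self):
        s = helical_structure()
        with pytest.raises(AnalysisConfigError, match=">= 4"):
            helix_rotation_angle(s, s, self._refs(self.helix[:3]),
                                 self._refs(self.anchor))


class TestSatisfactionPercentages:
    def test_ground_truth_ensemble_fully_satisfied(self, toy2, rep2):
        xl, _ = simulate_crosslinks(toy2.structure, DEFAULT_LINKERS["BS3"], 30, 0.0,
                                    seed=2)
        ens = ensemble_of(rep2, [Configuration.identity(rep2) for _ in range(3)])
        df = satisfaction_percentages(ens, xl)
        assert (df.pct_satisfied == 100.0).all()

    def test_single_model_matches_classify_satisfaction(self, toy2, rep2):
        xl, _ = simulate_crosslinks(toy2.structure, DEFAULT_LINKERS["DSG"], 30, 0.4,
                                    seed=3)
        config = perturb_configuration(Configuration.identity(rep2), 6.0, 20.0, seed=1)
        ens = ensemble_of(rep2, [config])
        df = satisfaction_percentages(ens, xl)
        s = configuration_to_structure(rep2, config)
        expected = 100.0 * classify_satisfaction(xl, s).satisfied_fraction
        summary = df.attrs["summary"]
        assert summary.loc["DSG", "min"] == pytest.approx(expected)
        assert summary.loc["DSG", "max"] == pytest.approx(expected)

    def test_range_endpoints_attained_by_models(self, toy2, rep2):
        xl, _ = simulate_crosslinks(toy2.structure, DEFAULT_LINKERS["BS3"], 30, 0.2,
                                    seed=4)
        configs = [perturb_configuration(Configuration.identity(rep2), s_, 10.0, seed=s)
                   for s, s_ in enumerate([0.0, 4.0, 12.0, 25.0])]
        ens = ensemble_of(rep2, configs)
        df = satisfaction_percentages(ens, xl)
        summary = df.attrs["summary"]
        vals = set(df.pct_satisfied.round(9))
        assert round(float(summary.loc["BS3", "min"]), 9) in vals
        assert round(float(summary.loc["BS3", "max"]), 9) in vals
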