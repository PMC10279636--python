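"""Synthetic generator: calibration, determinism, planted structure."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import i0e, i1e

from plvnet import (
    CouplingSpec,
    ExperimentDesign,
    generate_epochs,
    instantaneous_phase,
    plant_communities,
    plant_effect,
    plv_matrix,
    plv_to_kappa,
)
from plvnet.simulate import generate_phases, simulate_metric_table
from plvnet.io import load_epochs, save_epochs


class TestPlvToKappa:
    @pytest.mark.parametrize("target", [0.0, 0.1, 0.5, 0.9, 0.99])
    def test_bessel_ratio_inverts(self, target):
        kappa = plv_to_kappa(target)
        assert kappa >= 0
        ratio = i1e(kappa) / i0e(kappa) if kappa > 0 else 0.0
        assert abs(ratio - target) <= 1e-6

    def test_monte_carlo_resultant_length(self, rng):
        # independent check: mean resultant length of von Mises draws
        kappa = plv_to_kappa(0.5)
        draws = rng.vonmises(0.0, kappa, 200_000)
        r_hat = abs(np.mean(np.exp(1j * draws)))
        assert abs(r_hat - 0.5) < 0.01

    @given(st.floats(min_value=0.0, max_value=0.97))
    def test_inversion_property(self, target):
        kappa = plv_to_kappa(target)
        ratio = i1e(kappa) / i0e(kappa) if kappa > 0 else 0.0
        assert abs(ratio - target) <= 1e-6

    def test_unit_target_rejected(self):
        with pytest.raises(ValueError):
            plv_to_kappa(1.0)
        with pytest.raises(ValueError):
            plv_to_kappa(-0.1)


class TestPlantCommunities:
    def test_two_module_block_structure(self):
        spec = plant_communities(6, [0, 0, 0, 1, 1, 1], 0.8, 0.1)
        block = spec.target_plv
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            assert block[i, j] == 0.8
        assert np.all(block[:3, 3:] == 0.1)
        assert np.all(np.diag(block) == 1.0)

    def test_equal_within_between_rejected(self):
        with pytest.raises(ValueError):
            plant_communities(4, [0, 0, 1, 1], 0.5, 0.5)

    def test_large_block_means(self):
        member = np.array([0] * 30 + [1] * 118)
        spec = plant_communities(148, member, 0.7, 0.2)
        p = spec.target_plv
        same = member[:, None] == member[None, :]
        off = ~np.eye(148, dtype=bool)
        assert p[same & off].mean() == pytest.approx(0.7)
        assert p[~same].mean() == pytest.approx(0.2)

    def test_asymmetric_target_rejected(self):
        bad = np.eye(3)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError):
            CouplingSpec(n_nodes=3, target_plv=bad)


class TestGenerateEpochs:
    def test_deterministic_bit_identical(self):
        spec = plant_communities(4, [0, 0, 1, 1], 0.7, 0.2)
        a = generate_epochs(("s1", "overt", "fear"), spec, 5, seed=11)
        b = generate_epochs(("s1", "overt", "fear"), spec, 5, seed=11)
        assert a.data.tobytes() == b.data.tobytes()
        c = generate_epochs(("s1", "overt", "sad"), spec, 5, seed=11)
        assert a.data.tobytes() != c.data.tobytes()

    def test_epoch_axis_matches_design(self):
        spec = plant_communities(3, [0, 0, 0], 0.6, 0.0)
        ep = generate_epochs(("s1", "overt", "fear"), spec, 2, seed=0)
        assert ep.data.shape == (2, 3, 333)
        assert ep.t0_s == -0.5
        assert ep.fs_hz == 256.0

    def test_perfectly_locked_oscillators(self):
        target = np.ones((3, 3))
        spec = CouplingSpec(n_nodes=3, target_plv=target, noise_sd=0.0)
        ep = generate_epochs(("s1", "overt", "fear"), spec, 30, seed=2)
        cm = plv_matrix(instantaneous_phase(ep), window=(0.0, 0.8), edge_trim_s=0.05)
        off = cm.plv[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off - 1.0) <= 0.01)

    def test_noiseless_carrier_amplitude(self):
        target = np.ones((2, 2))
        spec = CouplingSpec(n_nodes=2, target_plv=target, amplitude=1.0, noise_sd=0.0)
        ep = generate_epochs(("s1", "overt", "fear"), spec, 4, seed=0)
        assert np.max(np.abs(ep.data)) <= 1.0 + 1e-12
        assert np.max(np.abs(ep.data)) > 0.99

    @pytest.mark.parametrize("target", [0.3, 0.6])
    def test_downstream_plv_calibration(self, target):
        # signal path incl. Hilbert phase extraction, 200 epochs
        p = np.array([[1.0, target], [target, 1.0]])
        spec = CouplingSpec(n_nodes=2, target_plv=p, noise_sd=0.1)
        ests = []
        for seed in range(3):
            ep = generate_epochs(("s1", "overt", "fear"), spec, 200, seed=seed)
            cm = plv_matrix(instantaneous_phase(ep), window=(0.0, 0.8))
            ests.append(cm.plv[0, 1])
        assert abs(np.mean(ests) - target) <= 0.05

    def test_true_phase_plv_exact_in_expectation(self):
        spec = plant_communities(6, [0, 0, 0, 1, 1, 1], 0.8, 0.1)
        ph = generate_phases(("s1", "overt", "fear"), spec, 200, seed=3)
        cm = plv_matrix(ph, window=(0.0, 0.8))
        within = [cm.plv[i, j] for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]]
        between = cm.plv[:3, 3:].ravel()
        assert abs(np.mean(within) - 0.8) <= 0.05
        assert abs(np.mean(between) - 0.1) <= 0.05

    def test_spectral_peak_at_carrier(self):
        spec = plant_communities(2, [0, 0], 0.6, 0.0, noise_sd=0.4, amplitude=1.0)
        ep = generate_epochs(("s1", "overt", "fear"), spec, 50, seed=5)
        freqs = np.fft.rfftfreq(ep.n_samples, 1 / ep.fs_hz)
        spectrum = np.abs(np.fft.rfft(ep.data, axis=2)) ** 2
        peak = freqs[spectrum.mean(axis=(0, 1)).argmax()]
        assert abs(peak - 10.0) < 0.5


class TestPlantEffect:
    def _design(self, n=4):
        return ExperimentDesign(n_subjects=n, trials_per_cell=5, seed=0)

    def test_null_configuration_identity(self):
        base = plant_communities(4, [0, 0, 1, 1], 0.7, 0.2)
        specs = plant_effect(self._design(), base, {}, subject_sd=0.0, seed=0)
        assert len(specs) == 4 * 2 * 4
        for spec in specs.values():
            np.testing.assert_array_equal(spec.target_plv, base.target_plv)

    def test_increment_applied_to_cross_pairs(self):
        base = plant_communities(4, [0, 0, 1, 1], 0.7, 0.2)
        specs = plant_effect(
            self._design(), base, {("overt", "fear"): 0.2}, subject_sd=0.0, seed=0
        )
        bumped = specs[("s1", "overt", "fear")].target_plv
        plain = specs[("s1", "covert", "fear")].target_plv
        assert bumped[0, 2] == pytest.approx(0.4)
        assert bumped[0, 1] == pytest.approx(0.7)  # within pairs untouched
        assert plain[0, 2] == pytest.approx(0.2)

    def test_subject_intercepts_shift_all_couplings(self):
        base = plant_communities(4, [0, 0, 1, 1], 0.7, 0.2)
        specs = plant_effect(self._design(), base, {}, subject_sd=0.05, seed=1)
        offsets = set()
        for (subj, _, _), spec in specs.items():
            offsets.add(round(spec.target_plv[0, 1] - 0.7, 12))
        # one distinct offset per subject, constant across that subject's cells
        assert len(offsets) == 4

    def test_excessive_increment_rejected(self):
        base = plant_communities(4, [0, 0, 1, 1], 0.9, 0.85)
        with pytest.raises(ValueError):
            plant_effect(
                self._design(), base, {("overt", "fear"): 0.2}, subject_sd=0.0, seed=0
            )

    def test_unknown_cell_rejected(self):
        base = plant_communities(4, [0, 0, 1, 1], 0.7, 0.2)
        with pytest.raises(ValueError):
            plant_effect(
                self._design(), base, {("overt", "disgust"): 0.1}, subject_sd=0, seed=0
            )


class TestMetricLevelSimulation:
    def test_balanced_table_shape_and_effect(self, rng):
        design = ExperimentDesign(n_subjects=6, trials_per_cell=1, seed=0)
        table = simulate_metric_table(
            design, effect={("overt", "fear"): 5.0}, subject_sd=0.0, resid_sd=0.01, rng=rng
        )
        assert len(table) == 6 * 8
        cell = table[(table.condition == "overt") & (table.emotion == "fear")]
        rest = table[~((table.condition == "overt") & (table.emotion == "fear"))]
        assert cell["value"].mean() > rest["value"].mean() + 4


def test_epoch_array_hdf5_roundtrip(tmp_path):
    spec = plant_communities(3, [0, 0, 1], 0.6, 0.1)
    ep = generate_epochs(("s1", "overt", "fear"), spec, 4, seed=9)
    ep.node_labels = ["a", "b", "c"]
    path = tmp_path / "epochs.h5"
    save_epochs(ep, path)
    back = load_epochs(path)
    np.testing.assert_array_equal(back.data, ep.data)
    assert back.fs_hz == ep.fs_hz
    assert back.t0_s == ep.t0_s
    assert back.node_labels == ["a", "b", "c"]
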