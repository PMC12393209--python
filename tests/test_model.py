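import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from cardiodki.acquisition import AcquisitionScheme
from cardiodki.model import (W_INDEX, DiffusionTensor, KurtosisTensor,
                             VoxelSignalModel, dapp, design_matrix,
                             full_to_w15, kapp, mean_diffusivity,
                             predict_signal, rotate_w15, w15_to_full)

# phantom-truth axially symmetric tensor: eigenvalues solved from the global
# MD = 1.66e-3 mm^2/s and FA = 0.31 of the study this package emulates
LAM_PAR, LAM_PERP = 2.27421e-3, 1.35290e-3
D_AXIAL = np.diag([LAM_PERP, LAM_PERP, LAM_PAR])   # symmetry axis = z


def isotropic_w15(k):
    w = np.zeros(15)
    w[0] = w[1] = w[2] = k
    w[9] = w[10] = w[11] = k / 3.0
    return w


def contract81(w15, n):
    """Brute-force 81-term contraction oracle."""
    full = w15_to_full(w15)
    total = 0.0
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    total += n[i] * n[j] * n[k] * n[l] * full[i, j, k, l]
    return total


class TestDapp:
    def test_isotropic(self):
        D = np.eye(3) * 1.7e-3
        for n in (np.array([1.0, 0, 0]), np.array([0, 0.6, 0.8])):
            assert dapp(D, n) == pytest.approx(1.7e-3, rel=1e-12)

    def test_axially_symmetric_along_axis(self):
        assert dapp(D_AXIAL, np.array([0.0, 0.0, 1.0])) == \
            pytest.approx(2.274e-3, abs=1e-6)

    def test_axially_symmetric_perpendicular_any_azimuth(self):
        for phi in np.linspace(0, 2 * np.pi, 7):
            n = np.array([np.cos(phi), np.sin(phi), 0.0])
            assert dapp(D_AXIAL, n) == pytest.approx(1.353e-3, abs=1e-6)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError):
            dapp(np.eye(3), np.array([1.0, 1.0, 0.0]))


class TestKapp:
    def test_isotropic_identity(self):
        D = np.eye(3) * 1.66e-3
        w = isotropic_w15(0.32)
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = rng.standard_normal(3)
            n /= np.linalg.norm(n)
            assert kapp(D, w, n) == pytest.approx(0.32, rel=1e-10)
            assert contract81(w, n) == pytest.approx(0.32, rel=1e-10)

    def test_gaussian_limit_zero_kurtosis(self):
        assert kapp(D_AXIAL, np.zeros(15), np.array([0.0, 0, 1])) == 0.0

    def test_axial_element_gives_printed_axial_kurtosis(self):
        # W3333 = AK * lam_par^2 / MD^2 with AK = 0.27
        w = np.zeros(15)
        w[2] = 0.5067
        got = kapp(D_AXIAL, w, np.array([0.0, 0.0, 1.0]))
        assert got == pytest.approx(0.27, abs=5e-4)

    def test_undefined_kurtosis_flagged_not_raised(self):
        D = np.diag([-1e-3, 1e-3, 1e-3])
        out = kapp(D, isotropic_w15(0.3), np.array([1.0, 0.0, 0.0]))
        assert np.isnan(out)

    def test_multiplicity_bookkeeping_vs_81_terms(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            w = rng.standard_normal(15)
            n = rng.standard_normal(3)
            n /= np.linalg.norm(n)
            D = np.eye(3) * 1e-3
            assert kapp(D, w, n) == pytest.approx(contract81(w, n), rel=1e-12)


class TestPredictSignal:
    def scheme_1d(self, bvals, n=(0.0, 0.0, 1.0)):
        bvals = np.asarray(bvals, float)
        return AcquisitionScheme(bvals, np.tile(n, (len(bvals), 1)),
                                 np.arange(len(bvals)),
                                 np.zeros(len(bvals), int))

    def test_printed_isotropic_value(self):
        # S = exp(-1350*1.66e-3 + (1/6)*1350^2*(1.66e-3)^2*0.32) = 0.13903
        model = VoxelSignalModel(1.0, DiffusionTensor(np.eye(3) * 1.66e-3),
                                 KurtosisTensor(isotropic_w15(0.32)))
        s = predict_signal(model, self.scheme_1d([1350.0]))
        assert s[0] == pytest.approx(0.13903, abs=2e-5)

    def test_b0_returns_s0(self):
        model = VoxelSignalModel(3.7, DiffusionTensor(D_AXIAL),
                                 KurtosisTensor(isotropic_w15(0.3)))
        s = predict_signal(model, self.scheme_1d([0.0]))
        assert s[0] == pytest.approx(3.7, rel=1e-14)

    def test_zero_kurtosis_log_linear_in_b(self):
        model = VoxelSignalModel(1.0, DiffusionTensor(D_AXIAL),
                                 KurtosisTensor(np.zeros(15)))
        b = np.arange(0, 1500, 250.0)
        s = predict_signal(model, self.scheme_1d(b))
        second_diff = np.diff(np.log(s), n=2)
        assert np.allclose(second_diff, 0.0, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(b=st.floats(0.0, 2000.0),
           nx=st.floats(-1.0, 1.0), ny=st.floats(-1.0, 1.0),
           nz=st.floats(0.1, 1.0), k=st.floats(-0.5, 1.5))
    def test_quadratic_term_forms_identical_property(self, b, nx, ny, nz, k):
        """(1/6) b^2 MD^2 (n^4:W) == (1/6) b^2 Dapp^2 Kapp for any direction,
        b-value and kurtosis scale (the two textbook forms are one model)."""
        n = np.array([nx, ny, nz])
        n /= np.linalg.norm(n)
        D = D_AXIAL
        w = isotropic_w15(k)
        md = mean_diffusivity(D)
        lhs = b ** 2 / 6.0 * md ** 2 * contract81(w, n)
        rhs = b ** 2 / 6.0 * dapp(D, n) ** 2 * kapp(D, w, n)
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-15)

    def test_md_and_dapp_scaled_forms_agree(self, truth_voxel):
        D, w = truth_voxel
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = rng.standard_normal(3)
            n /= np.linalg.norm(n)
            b = rng.uniform(100, 1350)
            md = mean_diffusivity(D)
            via_md = -b * dapp(D, n) + b ** 2 / 6.0 * md ** 2 * contract81(w, n)
            via_kapp = -b * dapp(D, n) + \
                b ** 2 / 6.0 * dapp(D, n) ** 2 * kapp(D, w, n)
            assert via_md == pytest.approx(via_kapp, rel=1e-12)


class TestRotationEquivariance:
    def test_dapp_kapp_signal_invariant_under_joint_rotation(self, truth_voxel):
        D, w = truth_voxel
        rng = np.random.default_rng(11)
        for _ in range(5):
            R = Rotation.random(random_state=rng).as_matrix()
            n = rng.standard_normal(3)
            n /= np.linalg.norm(n)
            Dr = R @ D @ R.T
            wr = rotate_w15(w, R)
            nr = R @ n
            assert dapp(Dr, nr) == pytest.approx(dapp(D, n), rel=1e-10)
            assert kapp(Dr, wr, nr) == pytest.approx(kapp(D, w, n), rel=1e-8)
            # oracle: rotated contraction equals unrotated contraction
            assert contract81(wr, nr) == pytest.approx(contract81(w, n),
                                                       rel=1e-8)

    def test_w15_expand_reduce_roundtrip(self):
        rng = np.random.default_rng(1)
        w = rng.standard_normal(15)
        assert np.allclose(full_to_w15(w15_to_full(w)), w, atol=1e-15)

    def test_full_tensor_is_symmetric_under_permutations(self):
        w = np.arange(15.0)
        full = w15_to_full(w)
        assert np.allclose(full, np.transpose(full, (1, 0, 2, 3)))
        assert np.allclose(full, np.transpose(full, (3, 2, 1, 0)))
        assert np.allclose(full, np.transpose(full, (0, 2, 1, 3)))


class TestDesignMatrix:
    def test_has_22_columns_full_rank_on_protocol(self, protocol):
        X = design_matrix(protocol)
        assert X.shape == (756, 22)
        assert np.linalg.matrix_rank(X) == 22

    def test_single_direction_reduces_to_1d_vandermonde(self):
        b = np.array([100.0, 450.0, 900.0])
        n = np.array([0.0, 0.0, 1.0])
        scheme = AcquisitionScheme(b, np.tile(n, (3, 1)), np.arange(3),
                                   np.zeros(3, int))
        X = design_matrix(scheme, check=False)
        # along z only columns 1 (const), D33 and W3333 survive
        nonzero = np.nonzero(np.any(np.abs(X) > 0, axis=0))[0]
        assert nonzero.tolist() == [0, 3, 9]
        assert np.allclose(X[:, 0], 1.0)
        assert np.allclose(X[:, 3], -b)
        assert np.allclose(X[:, 9], b ** 2 / 6.0)

    def test_single_shell_rejected_for_dki(self):
        b = np.full(30, 900.0)
        rng = np.random.default_rng(0)
        v = rng.standard_normal((30, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        scheme = AcquisitionScheme(b, v, np.zeros(30, int), np.arange(30))
        with pytest.raises(ValueError, match="rank-deficient"):
            design_matrix(scheme)

    def test_coefficient_layout_matches_forward_model(self, truth_voxel,
                                                      protocol):
        D, w = truth_voxel
        md = mean_diffusivity(D)
        beta = np.concatenate([[np.log(2.0)],
                               [D[i, j] for i, j in
                                ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2),
                                 (1, 2))],
                               md ** 2 * w])
        model = VoxelSignalModel(2.0, DiffusionTensor(D), KurtosisTensor(w))
        assert np.allclose(np.exp(design_matrix(protocol) @ beta),
                           predict_signal(model, protocol), rtol=1e-12)
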