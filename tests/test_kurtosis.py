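import numpy as np
import pytest

from dwikit import kurtosis, phantom, tensor
from dwikit.kurtosis import (AxiKurtosisFit, axi_log_signal, axi_to_full,
                             dki_design_matrix, dki_metrics, fit_dki_signals,
                             fit_axisymmetric_dki_signals, w_monomials,
                             w_full_to_unique, w_unique_to_full, W_INDICES)


def _random_dki_coeffs(rng, n=1):
    """Physically plausible random [lnS0, D, MD^2 W] coefficient rows."""
    out = np.empty((n, 22))
    for i in range(n):
        a = rng.normal(0, 1, (3, 3))
        evals = rng.uniform(0.3e-3, 2.0e-3, 3)
        q, _ = np.linalg.qr(a)
        d = q @ np.diag(evals) @ q.T
        w = rng.uniform(-0.3, 1.5, 15) * W_INDICES_SCALE
        md = np.trace(d) / 3
        out[i, :7] = tensor.tensor_to_coeff_row(rng.normal(0, 0.2), d)
        out[i, 7:] = md ** 2 * w
    return out


# diagonal W entries get a bigger share to keep K(n) mostly positive
W_INDICES_SCALE = np.array([1.0 if len(set(q)) == 1 else 0.3
                            for q in W_INDICES])


class TestWTensorBookkeeping:
    def test_fifteen_independent_components(self):
        assert len(W_INDICES) == 15

    def test_expand_collapse_round_trip(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=15)
        assert np.allclose(w_full_to_unique(w_unique_to_full(w)), w)

    def test_full_tensor_is_fully_symmetric(self):
        rng = np.random.default_rng(1)
        full = w_unique_to_full(rng.normal(size=15))
        assert np.allclose(full, np.transpose(full, (1, 0, 2, 3)))
        assert np.allclose(full, np.transpose(full, (2, 3, 0, 1)))
        assert np.allclose(full, np.transpose(full, (0, 2, 1, 3)))

    def test_monomials_evaluate_contraction(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=15)
        full = w_unique_to_full(w)
        dirs = rng.standard_normal((20, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        direct = np.einsum("mi,mj,mk,ml,ijkl->m", dirs, dirs, dirs, dirs, full)
        assert np.allclose(w_monomials(dirs) @ w, direct, atol=1e-12)


class TestFitDKI:
    def test_single_shell_rejected(self, scheme_1shell):
        with pytest.raises(ValueError, match="2 nonzero shells"):
            fit_dki_signals(np.ones((1, len(scheme_1shell))), scheme_1shell)

    def test_noiseless_round_trip(self, scheme_2shell):
        rng = np.random.default_rng(3)
        coeffs = _random_dki_coeffs(rng, 5)
        sig = np.exp(coeffs @ dki_design_matrix(scheme_2shell).T)
        fit = fit_dki_signals(sig, scheme_2shell, "ols")
        assert np.abs(fit.coeffs - coeffs).max() < 1e-8

    def test_gaussian_signal_gives_zero_kurtosis(self, scheme_2shell,
                                                 wm_tensor):
        row = tensor.tensor_to_coeff_row(0.0, wm_tensor)
        sig = np.exp(tensor.dti_design_matrix(scheme_2shell) @ row)[None, :]
        fit = fit_dki_signals(sig, scheme_2shell, "ols")
        assert np.abs(fit.w_unique).max() < 1e-8

    def test_ols_matches_explicit_normal_equation_oracle(self, scheme_2shell):
        x = dki_design_matrix(scheme_2shell)
        rng = np.random.default_rng(4)
        coeffs = _random_dki_coeffs(rng, 100)
        sig = np.exp(coeffs @ x.T) * np.exp(rng.normal(0, 0.02,
                                                       (100, x.shape[0])))
        fit = fit_dki_signals(sig, scheme_2shell, "ols")
        logs = np.log(sig)
        scale = np.abs(x).max(axis=0)
        xs = x / scale
        for i in range(100):
            oracle = np.linalg.solve(xs.T @ xs, xs.T @ logs[i]) / scale
            assert np.abs(fit.coeffs[i] - oracle).max() < 1e-10

    def test_nlls_refines_to_truth(self, scheme_2shell):
        rng = np.random.default_rng(5)
        coeffs = _random_dki_coeffs(rng, 2)
        sig = np.exp(coeffs @ dki_design_matrix(scheme_2shell).T)
        fit = fit_dki_signals(sig, scheme_2shell, "nlls")
        assert fit.converged.all()
        assert np.abs(fit.coeffs - coeffs).max() < 1e-8

    def test_dki_diffusivity_exceeds_dti_on_kurtotic_signal(self,
                                                            scheme_2shell,
                                                            wm_tensor):
        """The positive-kurtosis curvature biases DTI diffusivities low;
        DKI absorbs it in the b^2 term (kurtosis bias, MW = 1 at b_max
        2500 s/mm^2)."""
        iso_w = np.zeros(15)
        for m, q in enumerate(W_INDICES):
            if len(set(q)) == 1:
                iso_w[m] = 1.0
            elif all(q.count(i) == 2 for i in set(q)):
                iso_w[m] = 1.0 / 3.0
        md = np.trace(wm_tensor) / 3
        coeffs = np.concatenate([tensor.tensor_to_coeff_row(0.0, wm_tensor),
                                 md ** 2 * iso_w])
        sig = np.exp(coeffs @ dki_design_matrix(scheme_2shell).T)[None, :]
        dki_fit = fit_dki_signals(sig, scheme_2shell, "ols")
        dti_fit = tensor.fit_dti_signals(sig, scheme_2shell, "ols")
        md_dki = dki_fit.md[0]
        md_dti = tensor.dti_metrics_from_coeffs(dti_fit.coeffs)["md"][0]
        assert md_dki > md_dti
        assert md_dki == pytest.approx(md, rel=1e-6)


class TestAxisymmetric:
    TRUE = np.array([0.1, 0.7, 1.1, 1.7e-3, 0.5e-3, 0.8, 0.6, 1.1])

    def test_noiseless_round_trip(self, scheme_2shell):
        sig = np.exp(axi_log_signal(self.TRUE, scheme_2shell))[None, :]
        fit = fit_axisymmetric_dki_signals(sig, scheme_2shell)
        assert fit.converged.all()
        assert np.abs(fit.params[0] - self.TRUE).max() < 1e-6

    def test_axis_recovered_within_tenth_degree(self, scheme_2shell):
        sig = np.exp(axi_log_signal(self.TRUE, scheme_2shell))[None, :]
        fit = fit_axisymmetric_dki_signals(sig, scheme_2shell)
        th, ph = self.TRUE[1], self.TRUE[2]
        u_true = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                           np.cos(th)])
        cosang = abs(fit.axes[0] @ u_true)  # antipodal equivalence
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 0.1

    def test_eight_parameters_and_gauge(self, scheme_2shell):
        p = self.TRUE.copy()
        p[1] = 2.6  # theta beyond pi/2: must be re-gauged to the antipode
        sig = np.exp(axi_log_signal(p, scheme_2shell))[None, :]
        fit = fit_axisymmetric_dki_signals(sig, scheme_2shell)
        assert fit.params.shape[1] == 8
        assert 0 <= fit.params[0, 1] <= np.pi / 2 + 1e-12

    def test_isotropic_gaussian_flagged_degenerate(self, scheme_2shell):
        d = 0.8e-3
        row = tensor.tensor_to_coeff_row(0.0, d * np.eye(3))
        sig = np.exp(tensor.dti_design_matrix(scheme_2shell) @ row)[None, :]
        fit = fit_axisymmetric_dki_signals(sig, scheme_2shell)
        assert fit.degenerate[0]
        assert fit.params[0, 3] == pytest.approx(fit.params[0, 4], rel=1e-6)
        assert np.abs(fit.params[0, 5:]).max() < 1e-6

    def test_expand_refit_round_trip(self, scheme_2shell):
        """Expanding to full tensors, resynthesizing and refitting reproduces
        the eight inputs."""
        sig = np.exp(axi_log_signal(self.TRUE, scheme_2shell))[None, :]
        fit = fit_axisymmetric_dki_signals(sig, scheme_2shell)
        full = axi_to_full(fit)
        resig = full.predict(scheme_2shell)
        refit = fit_axisymmetric_dki_signals(resig, scheme_2shell)
        assert np.abs(refit.params[0] - self.TRUE).max() < 1e-6


class TestAxiToFull:
    def test_zero_amplitudes_give_zero_tensor(self):
        params = np.array([[0.0, 0.4, 1.0, 1.5e-3, 0.5e-3, 0.0, 0.0, 0.0]])
        fit = AxiKurtosisFit(params=params, rms_error=np.zeros(1))
        full = axi_to_full(fit)
        assert np.abs(full.coeffs[0, 7:]).max() < 1e-18

    def test_directional_kurtosis_equivalence(self, scheme_2shell):
        """W(n) of the expanded tensors equals the axisymmetric closed form
        on 1000 random directions."""
        params = np.array([[0.0, 0.7, 2.3, 1.7e-3, 0.4e-3, 0.9, 0.5, 1.3]])
        fit = AxiKurtosisFit(params=params, rms_error=np.zeros(1))
        full = axi_to_full(fit)
        rng = np.random.default_rng(6)
        dirs = rng.standard_normal((1000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        w_expanded = w_monomials(dirs) @ full.w_unique[0]
        u = fit.axes[0]
        c2 = (dirs @ u) ** 2
        mw, aw, rw = params[0, 5:]
        wmix = kurtosis._axi_mix(mw, aw, rw)
        w_axi = c2 ** 2 * aw + (1 - c2) ** 2 * rw + 6 * c2 * (1 - c2) * wmix
        assert np.abs(w_expanded - w_axi).max() < 1e-10


class TestMetrics:
    def test_isotropic_w_all_metrics_equal_amplitude(self):
        """For isotropic D and isotropic W, symmetry forces
        MK = AK = RK = MW = AW = RW = w."""
        w_amp = 0.7
        d = 1.0e-3
        iso_w = np.zeros(15)
        for m, q in enumerate(W_INDICES):
            if len(set(q)) == 1:
                iso_w[m] = w_amp
            elif all(q.count(i) == 2 for i in set(q)):
                iso_w[m] = w_amp / 3.0
        coeffs = np.concatenate([tensor.tensor_to_coeff_row(0.0, d * np.eye(3)),
                                 d ** 2 * iso_w])[None, :]
        fit = kurtosis.KurtosisFit(coeffs=coeffs, algorithm="OLS",
                                   rms_error=np.zeros(1))
        met = dki_metrics(fit)
        for val in (met.mk, met.ak, met.rk, met.mw, met.aw, met.rw):
            assert val[0] == pytest.approx(w_amp, abs=1e-10)

    def test_zero_w_gives_zero_metrics(self, wm_tensor):
        coeffs = np.concatenate([tensor.tensor_to_coeff_row(0.0, wm_tensor),
                                 np.zeros(15)])[None, :]
        fit = kurtosis.KurtosisFit(coeffs=coeffs, algorithm="OLS",
                                   rms_error=np.zeros(1))
        met = dki_metrics(fit)
        for val in met.as_dict().values():
            assert abs(val[0]) < 1e-12

    def test_mk_quadrature_matches_monte_carlo(self):
        """Spherical-mean MK against a 10^6-point Monte-Carlo average."""
        rng = np.random.default_rng(7)
        coeffs = _random_dki_coeffs(rng, 1)
        fit = kurtosis.KurtosisFit(coeffs=coeffs, algorithm="OLS",
                                   rms_error=np.zeros(1))
        met = dki_metrics(fit)
        dirs = rng.standard_normal((1_000_000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        d_n = np.einsum("mi,ij,mj->m", dirs, fit.tensors[0], dirs)
        w_n = w_monomials(dirs) @ fit.w_unique[0]
        mk_mc = np.mean((fit.md[0] / d_n) ** 2 * w_n)
        assert met.mk[0] == pytest.approx(mk_mc, abs=1e-3)

    def test_rotation_invariance(self):
        from scipy.stats import special_ortho_group
        rng = np.random.default_rng(8)
        coeffs = _random_dki_coeffs(rng, 1)
        fit = kurtosis.KurtosisFit(coeffs=coeffs, algorithm="OLS",
                                   rms_error=np.zeros(1))
        base = dki_metrics(fit)
        full_w = w_unique_to_full(fit.w_unique[0])
        d = fit.tensors[0]
        md2 = fit.md[0] ** 2
        for r in special_ortho_group.rvs(3, size=10, random_state=9):
            d_rot = r @ d @ r.T
            w_rot = np.einsum("ia,jb,kc,ld,abcd->ijkl", r, r, r, r, full_w)
            rc = np.concatenate([
                tensor.tensor_to_coeff_row(coeffs[0, 0], d_rot),
                md2 * w_full_to_unique(w_rot)])[None, :]
            met = dki_metrics(kurtosis.KurtosisFit(coeffs=rc, algorithm="OLS",
                                                   rms_error=np.zeros(1)))
            for key in ("MK", "MW"):
                assert met.as_dict()[key][0] == pytest.approx(
                    base.as_dict()[key][0], abs=1e-8)

    def test_nonpositive_directional_diffusivity_flagged(self):
        coeffs = np.concatenate([
            tensor.tensor_to_coeff_row(0.0, np.diag([1e-3, 1e-3, -1e-4])),
            0.1 * np.ones(15) * 1e-7])[None, :]
        fit = kurtosis.KurtosisFit(coeffs=coeffs, algorithm="OLS",
                                   rms_error=np.zeros(1))
        met = dki_metrics(fit)
        assert met.invalid[0]
        assert np.isnan(met.mk[0])


class TestAxialSymmetryOfFullFit:
    def test_full_fit_of_axisymmetric_truth_obeys_symmetry(self, scheme_2shell):
        """Full DKI fitted to axisymmetric signals satisfies the axial
        symmetry relations of W in the symmetry frame."""
        p = np.array([0.0, 0.0, 0.0, 1.7e-3, 0.5e-3, 0.8, 0.6, 1.1])  # axis z
        sig = np.exp(axi_log_signal(p, scheme_2shell))[None, :]
        fit = fit_dki_signals(sig, scheme_2shell, "ols")
        w = {q: fit.w_unique[0][m] for m, q in enumerate(W_INDICES)}
        # axis along z: x/y play symmetric roles
        assert w[(0, 0, 0, 0)] == pytest.approx(w[(1, 1, 1, 1)], abs=1e-8)
        assert w[(0, 0, 2, 2)] == pytest.approx(w[(1, 1, 2, 2)], abs=1e-8)
        assert w[(0, 0, 1, 1)] == pytest.approx(w[(0, 0, 0, 0)] / 3, abs=1e-8)
        for q, val in w.items():
            odd = any(q.count(i) % 2 for i in range(3))
            if odd:
                assert abs(val) < 1e-8
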