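"""Structure factors against closed forms and brute force; target gradients."""

import numpy as np
import pytest

import qrl
from qrl.crystal_model import Atom, ReflectionSet, StructureModel, UnitCell
from qrl.scattering import (FormFactorTable, SFCalculation, ScatteringError,
                            auto_wA, calc_structure_factors,
                            estimate_shell_params, generate_hkl, r_factors,
                            scale_k, target_lsq, target_mlf)


def brute_force_sf(model, hkl, table=None):
    """Independent direct sum, one reflection and one atom at a time."""
    table = table or FormFactorTable.default()
    out = np.zeros(len(hkl), dtype=complex)
    for ih, h in enumerate(hkl):
        d = model.cell.d_spacing(np.array(h)[None, :])[0]
        s2 = (0.5 / d) ** 2
        for rot, tr in zip(model.ops.rotations, model.ops.translations):
            for a in model.atoms:
                ca, cb, cc = table.coefficients(a.element)
                f = float(np.sum(ca * np.exp(-cb * s2)) + cc)
                frac = np.linalg.solve(model.cell.orth_matrix, a.pos)
                phase = 2j * np.pi * (np.array(h) @ (rot @ frac + tr))
                out[ih] += a.occupancy * f * np.exp(-a.b_iso * s2) * np.exp(phase)
    return out


@pytest.fixture(scope="module")
def random_12atom_model():
    rng = np.random.default_rng(42)
    cell = UnitCell(12, 13, 11, 85, 92, 105)
    elements = ["C", "N", "O", "S", "Fe", "C", "N", "O", "C", "C", "N", "O"]
    atoms = [Atom(element=e, pos=rng.uniform(0, 10, 3),
                  occupancy=rng.uniform(0.5, 1.0), b_iso=rng.uniform(2, 25))
             for e in elements]
    return StructureModel(cell, atoms)


class TestFormFactors:
    def test_f0_matches_electron_count(self):
        table = FormFactorTable.default()
        for el, z in [("H", 1), ("C", 6), ("N", 7), ("O", 8), ("S", 16),
                      ("Fe", 26), ("Cu", 29), ("Mo", 42)]:
            f0 = table.factor(el, np.array([0.0]))[0]
            assert abs(f0 - z) / z < 0.02

    def test_text_table_roundtrip(self, tmp_path):
        table = FormFactorTable.default()
        a, b, c = table.coefficients("C")
        p = tmp_path / "ff.txt"
        p.write_text("C " + " ".join(f"{v:.8f}" for v in [*a, *b, c]) + "\n")
        t2 = FormFactorTable.from_text(p)
        assert np.allclose(t2.factor("C", np.array([0.1])),
                           table.factor("C", np.array([0.1])), atol=1e-6)


class TestStructureFactors:
    def test_atom_at_origin_gives_zero_phase(self):
        cell = UnitCell(10, 10, 10)
        m = StructureModel(cell, [Atom(element="C", pos=[0, 0, 0], b_iso=0.0)])
        hkl = generate_hkl(cell, 2.0)
        F = calc_structure_factors(m, hkl)
        table = FormFactorTable.default()
        s2 = (0.5 / cell.d_spacing(hkl)) ** 2
        assert np.abs(F.imag).max() < 1e-12
        assert np.allclose(F.real, table.factor("C", s2))

    def test_symmetric_pair_closed_form(self):
        cell = UnitCell(10, 10, 10)
        x = 0.21
        b = 7.0
        m = StructureModel(cell, [
            Atom(element="N", pos=[10 * x, 0, 0], b_iso=b),
            Atom(element="N", pos=[-10 * x, 0, 0], b_iso=b)])
        hkl = np.array([[h, 0, 0] for h in range(1, 6)])
        F = calc_structure_factors(m, hkl)
        table = FormFactorTable.default()
        s2 = (0.5 / cell.d_spacing(hkl)) ** 2
        expected = 2 * table.factor("N", s2) * np.exp(-b * s2) * \
            np.cos(2 * np.pi * hkl[:, 0] * x)
        assert np.abs(F.imag).max() < 1e-10
        assert np.allclose(F.real, expected, rtol=1e-12)

    def test_matches_brute_force(self, random_12atom_model):
        hkl = generate_hkl(random_12atom_model.cell, 1.8)[:500]
        F = calc_structure_factors(random_12atom_model, hkl)
        Fb = brute_force_sf(random_12atom_model, hkl)
        assert np.abs(F - Fb).max() / np.abs(Fb).max() < 1e-10

    def test_friedel_symmetry(self, random_12atom_model):
        hkl = generate_hkl(random_12atom_model.cell, 2.5)[:100]
        Fp = calc_structure_factors(random_12atom_model, hkl)
        Fm = calc_structure_factors(random_12atom_model, -hkl)
        assert np.allclose(np.abs(Fp), np.abs(Fm), rtol=1e-12)

    def test_symmetry_ops_match_expanded_model(self):
        """A twofold operator equals explicitly doubling the atoms."""
        from qrl.crystal_model import SymmetryOps
        cell = UnitCell(10, 10, 10)
        rot = np.diag([-1.0, -1.0, 1.0])
        tr = np.array([0.0, 0.0, 0.5])
        a1 = Atom(element="O", pos=[1.2, 2.3, 3.4], b_iso=5.0)
        m_sym = StructureModel(cell, [a1], ops=SymmetryOps(
            rotations=[np.eye(3), rot], translations=[np.zeros(3), tr]))
        frac = np.linalg.solve(cell.orth_matrix, a1.pos)
        frac2 = rot @ frac + tr
        a2 = Atom(element="O", pos=cell.orth_matrix @ frac2, b_iso=5.0)
        m_exp = StructureModel(cell, [a1, a2])
        hkl = generate_hkl(cell, 2.0)
        assert np.allclose(calc_structure_factors(m_sym, hkl),
                           calc_structure_factors(m_exp, hkl), rtol=1e-10)

    def test_missing_element_reported(self):
        table = FormFactorTable({})
        with pytest.raises(ScatteringError, match="Xx"):
            table.coefficients("Xx")


class TestScaling:
    def test_identity_scale(self, rng):
        f = rng.uniform(1, 10, 50)
        assert np.isclose(scale_k(f, f), 1.0)

    def test_linear_scale(self, rng):
        f = rng.uniform(1, 10, 50)
        assert np.isclose(scale_k(2 * f, f), 2.0)

    def test_matches_numeric_minimum(self, rng):
        fo = rng.uniform(1, 10, 100)
        fc = rng.uniform(1, 10, 100)
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(lambda k: np.sum((fo - k * fc) ** 2),
                              bounds=(0, 10), method="bounded",
                              options={"xatol": 1e-12})
        assert abs(scale_k(fo, fc) - res.x) < 1e-6

    def test_empty_working_set_rejected(self):
        with pytest.raises(ScatteringError):
            scale_k(np.array([]), np.array([]))


class TestRFactors:
    def _refl(self, fobs, free=None):
        n = len(fobs)
        hkl = np.array([[i + 1, 0, 0] for i in range(n)])
        free = np.zeros(n, bool) if free is None else np.asarray(free)
        return ReflectionSet(hkl, fobs, np.full(n, 0.1), free)

    def test_perfect_model_r_zero(self):
        r = self._refl([10.0, 20.0])
        rw, rf = r_factors(r, np.array([10.0, 20.0]))
        assert rw == 0.0
        assert np.isnan(rf)

    def test_hand_arithmetic(self):
        # Fo = {10, 10}, k|Fc| = {9, 11}: k = 1 already optimal; R = 2/20
        r = self._refl([10.0, 10.0])
        rw, _ = r_factors(r, np.array([9.0, 11.0]))
        k = scale_k(np.array([10.0, 10.0]), np.array([9.0, 11.0]))
        expected = (abs(10 - k * 9) + abs(10 - k * 11)) / 20.0
        assert np.isclose(rw, expected)
        assert np.isclose(rw, 0.10, atol=0.002)

    def test_permutation_invariance(self, rng, toy_noiseless):
        refl = toy_noiseless.reflections
        amp = SFCalculation(toy_noiseless.true_model, refl.hkl).amplitudes
        perm = rng.permutation(len(refl))
        refl_p = ReflectionSet(refl.hkl[perm], refl.fobs[perm],
                               refl.sigma[perm], refl.free[perm])
        assert np.allclose(r_factors(refl, amp), r_factors(refl_p, amp[perm]),
                           equal_nan=True)


class TestTargetLsq:
    def test_zero_at_generating_model(self, toy_noiseless):
        tv = target_lsq(toy_noiseless.true_model, toy_noiseless.reflections)
        assert tv.energy < 1e-12
        assert np.abs(tv.grad).max() < 1e-8

    def test_sigma_scaling_law(self, toy_perturbed):
        refl = toy_perturbed.reflections
        tv1 = target_lsq(toy_perturbed.start_model, refl)
        refl2 = ReflectionSet(refl.hkl, refl.fobs, 2 * refl.sigma, refl.free)
        tv2 = target_lsq(toy_perturbed.start_model, refl2)
        assert np.isclose(tv2.energy, tv1.energy / 4)

    def test_gradient_matches_finite_differences(self, toy_perturbed, fd):
        m = toy_perturbed.start_model.copy()
        refl = toy_perturbed.reflections
        tv = target_lsq(m, refl)
        idx = np.where(m.mobile)[0][:3]

        def ene(x):
            m.xyz[idx] = x.reshape(-1, 3)
            return target_lsq(m, refl).energy

        x0 = m.xyz[idx].ravel().copy()
        g_fd = fd(ene, x0, h=1e-4)
        g_an = tv.grad[idx].ravel()
        denom = np.maximum(np.abs(g_fd), 1e-8)
        assert (np.abs(g_fd - g_an) / denom).max() < 1e-5

    def test_frozen_atoms_have_zero_gradient(self, toy_perturbed):
        tv = target_lsq(toy_perturbed.start_model, toy_perturbed.reflections)
        frozen = ~toy_perturbed.start_model.mobile
        assert np.all(tv.grad[frozen] == 0.0)

    def test_free_set_does_not_contribute(self, toy_perturbed):
        refl = toy_perturbed.reflections
        tv1 = target_lsq(toy_perturbed.start_model, refl)
        # corrupt the free reflections wildly: energy and gradient unchanged
        fobs2 = refl.fobs.copy()
        fobs2[refl.free] *= 17.0
        refl2 = ReflectionSet(refl.hkl, fobs2, refl.sigma, refl.free)
        tv2 = target_lsq(toy_perturbed.start_model, refl2)
        assert tv1.energy == tv2.energy
        assert np.array_equal(tv1.grad, tv2.grad)


class TestTargetMlf:
    def test_sigma_a_near_one_for_perfect_model(self, toy_noiseless):
        sp = estimate_shell_params(toy_noiseless.true_model,
                                   toy_noiseless.reflections, 8)
        assert sp.sigma_a.min() >= 0.99

    def test_ranking_consistent_with_lsq(self, toy_noiseless):
        """On noiseless data the better of two models wins under both targets."""
        toy = toy_noiseless
        good = toy.true_model.copy()
        bad = toy.true_model.copy()
        bad.xyz[bad.mobile] += 0.15
        lsq_good = target_lsq(good, toy.reflections).energy
        lsq_bad = target_lsq(bad, toy.reflections).energy
        mlf_good = target_mlf(good, toy.reflections).energy
        mlf_bad = target_mlf(bad, toy.reflections).energy
        assert (lsq_good < lsq_bad) == (mlf_good < mlf_bad)

    def test_gradient_matches_finite_differences(self, toy_perturbed, fd):
        m = toy_perturbed.start_model.copy()
        refl = toy_perturbed.reflections
        sp = estimate_shell_params(m, refl, 5)
        tv = target_mlf(m, refl, shell_params=sp)
        idx = np.where(m.mobile)[0][:3]

        def ene(x):
            m.xyz[idx] = x.reshape(-1, 3)
            return target_mlf(m, refl, shell_params=sp).energy

        x0 = m.xyz[idx].ravel().copy()
        g_fd = fd(ene, x0, h=1e-4)
        g_an = tv.grad[idx].ravel()
        denom = np.maximum(np.abs(g_fd), 1e-8)
        assert (np.abs(g_fd - g_an) / denom).max() < 1e-4

    def test_fallback_to_lsq_when_shells_unpopulated(self, toy_perturbed):
        refl = toy_perturbed.reflections.subset(np.arange(len(
            toy_perturbed.reflections)) < 30)
        with pytest.warns(UserWarning, match="falling back"):
            tv = target_mlf(toy_perturbed.start_model, refl)
        assert tv.info["target"] == "lsq"


class TestAutoWA:
    def test_equal_norms_give_unity(self, toy_perturbed):
        m = toy_perturbed.start_model
        tv = target_lsq(m, toy_perturbed.reflections)
        wa = auto_wA(m, toy_perturbed.reflections, tv.grad)
        assert np.isclose(wa, 1.0)

    def test_well_defined_under_data_rescaling(self, toy_perturbed):
        refl = toy_perturbed.reflections
        m = toy_perturbed.start_model
        from qrl.restraints import mm_energy
        g_mm = mm_energy(m, toy_perturbed.mm_params).grad
        wa1 = auto_wA(m, refl, g_mm)
        refl2 = ReflectionSet(refl.hkl, 3 * refl.fobs, 3 * refl.sigma, refl.free)
        wa2 = auto_wA(m, refl2, g_mm)
        assert np.isfinite(wa1) and np.isfinite(wa2) and wa1 > 0 and wa2 > 0

    def test_perfect_model_raises_helpful_error(self, toy_noiseless):
        m = toy_noiseless.true_model
        with pytest.raises(ScatteringError, match="perturbed"):
            auto_wA(m, toy_noiseless.reflections, np.ones((len(m), 3)))

    def test_explicit_crystallographic_weight_accepted(self):
        """A literature-style explicit w_A (e.g. 0.0794) bypasses the heuristic."""
        cfg = qrl.RefinementConfig(w_a=0.0794)
        assert cfg.resolved_w_a() == 0.0794
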