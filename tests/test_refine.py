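"""Combined energy assembly, coordinate/2QM/ADP refinement behaviour."""

import numpy as np
import pytest

import qrl
from qrl.crystal_model import ModelError, RegionSelection
from qrl.refine import (RefinementConfig, RefinementError, build_region_params,
                        refine_2qm, refine_adps, refine_coordinates,
                        resolve_auto_wa, total_energy)
from qrl.scattering import SFCalculation
from qrl.toyfactory import ToySpec, make_toy_crystal, make_two_conformer_toy


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ModelError):
            RefinementConfig(w_mm=0.0)
        with pytest.raises(ModelError):
            RefinementConfig(occupancies=(1.5, -0.5))
        with pytest.raises(ModelError):
            RefinementConfig(target="bogus")

    def test_unresolved_auto_wa_instructs_caller(self, toy_perturbed):
        cfg = RefinementConfig(w_a="auto")
        with pytest.raises(RefinementError, match="auto"):
            total_energy(toy_perturbed.start_model, toy_perturbed.region,
                         toy_perturbed.reflections, cfg, toy_perturbed.mm_params)

    def test_resolve_auto_wa(self, toy_perturbed):
        cfg = RefinementConfig(w_a="auto")
        cfg2 = resolve_auto_wa(toy_perturbed.start_model, toy_perturbed.region,
                               toy_perturbed.reflections, cfg,
                               toy_perturbed.mm_params)
        assert isinstance(cfg2.w_a, float) and cfg2.w_a > 0


class TestTotalEnergy:
    def test_small_wmm_approaches_pure_region_energy(self, toy_perturbed):
        toy = toy_perturbed
        cfg = RefinementConfig(w_a=1.0, w_mm=1e-12)
        tv = total_energy(toy.start_model, toy.region, toy.reflections, cfg,
                          toy.mm_params)
        assert tv.energy == pytest.approx(tv.info["e_qm1"], rel=1e-6)

    def test_whole_model_region_partition(self):
        """Region = whole model ⇒ E_MM − E_MM1 = 0."""
        toy = make_toy_crystal(ToySpec(seed=31, n_env=4, perturb_rmsd=0.1))
        m = toy.start_model.copy()
        m.mobile[:] = True
        region = RegionSelection(indices=np.arange(len(m)))
        cfg = RefinementConfig(w_a=0.5)
        tv = total_energy(m, region, toy.reflections, cfg, toy.mm_params)
        assert tv.info["e_mm"] == pytest.approx(tv.info["e_mm1"], abs=1e-10)
        expected = tv.info["e_qm1"] + cfg.w_mm * cfg.resolved_w_a() * tv.info["e_xray"]
        assert tv.energy == pytest.approx(expected, rel=1e-12)

    def test_assembled_gradient_finite_differences(self, toy_perturbed, fd):
        toy = toy_perturbed
        m = toy.start_model.copy()
        cfg = RefinementConfig(w_a=0.5)
        rp = [build_region_params(m, toy.region, toy.mm_params)]
        tv = total_energy(m, toy.region, toy.reflections, cfg, toy.mm_params,
                          region_params=rp)
        idx = np.where(m.mobile)[0][:3]

        def ene(x):
            m.xyz[idx] = x.reshape(-1, 3)
            return total_energy(m, toy.region, toy.reflections, cfg,
                                toy.mm_params, region_params=rp).energy

        g_fd = fd(ene, m.xyz[idx].ravel().copy(), h=1e-4)
        g_an = tv.grad[idx].ravel()
        denom = np.maximum(np.abs(g_fd), 1e-8)
        assert (np.abs(g_fd - g_an) / denom).max() < 1e-4

    def test_xray_term_independent_of_epsilon(self, toy_perturbed):
        toy = toy_perturbed
        cfg1 = RefinementConfig(w_a=1.0, epsilon=1.0)
        cfg80 = RefinementConfig(w_a=1.0, epsilon=80.0)
        tv1 = total_energy(toy.start_model, toy.region, toy.reflections, cfg1,
                           toy.mm_params)
        tv80 = total_energy(toy.start_model, toy.region, toy.reflections, cfg80,
                            toy.mm_params)
        assert tv1.info["e_xray"] == tv80.info["e_xray"]
        assert tv1.info["e_qm1"] != tv80.info["e_qm1"]


class TestRefineCoordinates:
    def test_start_at_minimum_stays_put(self):
        """Uncharged noiseless toy started at the generating model."""
        toy = make_toy_crystal(ToySpec(seed=41, region_net_charge=0.0,
                                       noise=0.0, perturb_rmsd=0.0))
        cfg = RefinementConfig(w_a=1.0, use_lj=False)
        refined, trace = refine_coordinates(toy.start_model, toy.region,
                                            toy.reflections, cfg, toy.mm_params)
        assert trace.converged
        assert trace.rows[-1]["cycle"] <= 2
        assert np.abs(refined.xyz - toy.true_model.xyz).max() < 1e-4

    def test_parameter_recovery(self):
        toy = make_toy_crystal(ToySpec(seed=11, noise=0.0, perturb_rmsd=0.3,
                                       region_net_charge=0.0))
        cfg = RefinementConfig(w_a="auto", max_cycles=300, use_lj=False)
        refined, trace = refine_coordinates(toy.start_model, toy.region,
                                            toy.reflections, cfg, toy.mm_params)
        idx = toy.region.indices
        rmsd = np.sqrt(np.mean(np.sum(
            (refined.xyz[idx] - toy.true_model.xyz[idx]) ** 2, axis=1)))
        assert rmsd < 0.02
        assert trace.rows[-1]["r_work"] < 0.01

    def test_zero_xray_weight_ignores_data(self, toy_perturbed):
        toy = toy_perturbed
        cfg = RefinementConfig(w_a=0.0, max_cycles=100)
        refined, trace = refine_coordinates(toy.start_model, toy.region,
                                            toy.reflections, cfg, toy.mm_params)
        # restrained region optimization: energy (not R) is what drops
        assert trace.rows[-1]["e_total"] < trace.rows[0]["e_total"]

    def test_frozen_atoms_bit_identical(self, toy_perturbed):
        toy = toy_perturbed
        cfg = RefinementConfig(w_a="auto", max_cycles=50)
        refined, _ = refine_coordinates(toy.start_model, toy.region,
                                        toy.reflections, cfg, toy.mm_params)
        frozen = ~toy.start_model.mobile
        assert np.array_equal(refined.xyz[frozen], toy.start_model.xyz[frozen])

    def test_energy_nonincreasing_over_cycles(self, toy_perturbed):
        toy = toy_perturbed
        cfg = RefinementConfig(w_a="auto", max_cycles=100)
        _, trace = refine_coordinates(toy.start_model, toy.region,
                                      toy.reflections, cfg, toy.mm_params)
        e = [row["e_total"] for row in trace.rows]
        assert all(b <= a + cfg.conv_energy for a, b in zip(e, e[1:]))

    def test_trace_columns_complete(self, toy_perturbed):
        toy = toy_perturbed
        cfg = RefinementConfig(w_a="auto", max_cycles=20)
        _, trace = refine_coordinates(toy.start_model, toy.region,
                                      toy.reflections, cfg, toy.mm_params)
        df = trace.to_dataframe()
        for col in ("cycle", "e_total", "e_qm1", "e_mm", "e_mm1", "e_xray",
                    "r_work", "r_free", "max_grad", "max_shift"):
            assert col in df.columns
        assert df["cycle"].is_monotonic_increasing


class TestRefine2QM:
    def test_p_equal_one_reduces_to_single_conformer(self):
        tc = make_two_conformer_toy(ToySpec(seed=13, noise=0.0,
                                            perturb_rmsd=0.1), p=0.86)
        # reference: same occupancy assignment (A present, B absent)
        model = tc.start_model.copy()
        only_a = sorted(set(tc.region_a.indices) - set(tc.region_b.indices))
        only_b = sorted(set(tc.region_b.indices) - set(tc.region_a.indices))
        model.occupancy[only_a] = 1.0  # ligand B stays environment: occupancy kept
        model.sync_atoms()
        cfg = RefinementConfig(w_a=0.1, max_cycles=60)
        ref_single, tr_single = refine_coordinates(
            model, tc.region_a, tc.reflections, cfg, tc.mm_params)
        empty_b = RegionSelection(indices=np.array([], dtype=int))
        ref_2qm, tr_2qm = refine_2qm(tc.start_model, tc.region_a, empty_b,
                                     (1.0, 0.0), tc.reflections, cfg,
                                     tc.mm_params)
        assert abs(tr_single.rows[-1]["e_total"] -
                   tr_2qm.rows[-1]["e_total"]) < 1e-9
        assert np.abs(ref_single.xyz - ref_2qm.xyz).max() < 1e-9

    def test_occupancy_weighted_fcalc_matches_brute_force(self):
        tc = make_two_conformer_toy(ToySpec(seed=14, noise=0.0), p=0.7)
        m = tc.true_model
        amp = SFCalculation(m, tc.reflections.hkl).f_total
        # brute force: sum the conformer-exclusive atoms with occ p and 1−p
        from tests_helpers_sf import occupancy_weighted_brute_force
        fb = occupancy_weighted_brute_force(m, tc.reflections.hkl)
        assert np.abs(amp - fb).max() / np.abs(fb).max() < 1e-10

    def test_recovery_of_both_conformers(self):
        tc = make_two_conformer_toy(ToySpec(seed=13, noise=0.0,
                                            perturb_rmsd=0.1), p=0.86)
        cfg = RefinementConfig(w_a="auto", max_cycles=300)
        refined, _ = refine_2qm(tc.start_model, tc.region_a, tc.region_b,
                                (0.86, 0.14), tc.reflections, cfg, tc.mm_params)
        for reg in (tc.region_a, tc.region_b):
            idx = reg.indices
            rmsd = np.sqrt(np.mean(np.sum(
                (refined.xyz[idx] - tc.true_model.xyz[idx]) ** 2, axis=1)))
            assert rmsd < 0.05

    def test_swapping_conformers_and_occupancy_is_symmetric(self):
        tc = make_two_conformer_toy(ToySpec(seed=15, noise=0.0,
                                            perturb_rmsd=0.05), p=0.7)
        cfg = RefinementConfig(w_a=0.1, max_cycles=80)
        r1, t1 = refine_2qm(tc.start_model, tc.region_a, tc.region_b,
                            (0.7, 0.3), tc.reflections, cfg, tc.mm_params)
        r2, t2 = refine_2qm(tc.start_model, tc.region_b, tc.region_a,
                            (0.3, 0.7), tc.reflections, cfg, tc.mm_params)
        assert abs(t1.rows[-1]["e_total"] - t2.rows[-1]["e_total"]) < 1e-6
        assert np.abs(r1.xyz - r2.xyz).max() < 1e-6

    def test_invalid_occupancy_rejected(self):
        tc = make_two_conformer_toy(ToySpec(seed=16), p=0.5)
        cfg = RefinementConfig(w_a=0.1)
        with pytest.raises(ModelError):
            refine_2qm(tc.start_model, tc.region_a, tc.region_b, (1.5, -0.5),
                       tc.reflections, cfg, tc.mm_params)


class TestRefineADPs:
    def test_recovers_known_b_values(self):
        toy = make_toy_crystal(ToySpec(seed=9, noise=0.0, perturb_rmsd=0.0))
        m = toy.true_model.copy()
        true_b = m.b_iso.copy()
        m.b_iso[m.mobile] = 15.0  # uniform wrong start
        cfg = RefinementConfig(w_a=1.0)
        refined = refine_adps(m, toy.reflections, cfg, toy.mm_params)
        rel = np.abs(refined.b_iso[m.mobile] - true_b[m.mobile]) / true_b[m.mobile]
        assert rel.max() < 0.05
        assert np.array_equal(refined.xyz, m.xyz)  # coordinates untouched

    def test_b_gradient_finite_differences(self, toy_perturbed, fd):
        from qrl.scattering import target_lsq
        m = toy_perturbed.start_model.copy()
        refl = toy_perturbed.reflections
        tv = target_lsq(m, refl, with_b_grad=True)
        idx = np.where(m.mobile)[0][:4]

        def ene(b):
            m.b_iso[idx] = b
            return target_lsq(m, refl).energy

        g_fd = fd(ene, m.b_iso[idx].copy(), h=1e-4)
        denom = np.maximum(np.abs(g_fd), 1e-8)
        assert (np.abs(g_fd - tv.b_grad[idx]) / denom).max() < 1e-5

    def test_lower_bound_clamps_at_one(self):
        # data generated with B below the bound: refinement must clamp at 1 Å²
        toy = make_toy_crystal(ToySpec(seed=17, noise=0.0, perturb_rmsd=0.0,
                                       region_b_iso=0.4))
        m = toy.true_model.copy()
        m.b_iso[m.mobile] = 5.0
        cfg = RefinementConfig(w_a=1.0, adp_similarity_weight=0.0)
        refined = refine_adps(m, toy.reflections, cfg)
        b = refined.b_iso[m.mobile]
        assert np.all(b >= 1.0)
        # the bound is active: most atoms clamp exactly at 1 Å² (the overall
        # scale factor lets a few sit slightly above it)
        assert np.mean(b == 1.0) >= 0.5

    def test_all_frozen_is_noop_with_warning(self, toy_perturbed):
        m = toy_perturbed.start_model.copy()
        m.mobile[:] = False
        cfg = RefinementConfig(w_a=1.0)
        with pytest.warns(UserWarning, match="frozen"):
            refined = refine_adps(m, toy_perturbed.reflections, cfg)
        assert np.array_equal(refined.b_iso, m.b_iso)
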