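"""Detector-space fluorescence, PAM indices, and the b6f conductance
diagnostics."""

import numpy as np
import pytest

from cb6f.fluorescence import (
    DetectorModel,
    FluorescenceLevels,
    PamIndices,
    estimate_vmax_b6f,
    fluorescence_levels,
    pam_indices,
)
from cb6f.light_reactions import PhotochemicalConstants
from cb6f.solver import LeafParameters, light_saturation_point, solve_steady_state
from cb6f.stoichiometry import Environment


def _indices_sweep(leaf, env, k, qs, detector=DetectorModel(eps_f1=0.0)):
    out = []
    for q in qs:
        st = solve_steady_state(float(q), leaf, env, k)
        out.append(pam_indices(fluorescence_levels(st, k, detector), float(q)))
    return out


class TestLevels:
    def test_fm_with_pure_psii_signal(self, leaf, env, k):
        """All centers closed, no NPQ, ε_F1=0: F_m/S = α2·K_F2/(K_D2+K_F2)."""
        st = solve_steady_state(0.0, leaf, env, k)
        levels = fluorescence_levels(st, k, DetectorModel(eps_f1=0.0))
        assert levels.f_m == pytest.approx(0.44 * 0.05 / 0.6)
        assert levels.f_o == pytest.approx(0.44 * 0.05 / 5.1)

    def test_genty_identity(self, leaf, env, k):
        """1 − Fs/Fm' equals the mechanistic Φ_P2 exactly for ε_F1=0, K_U2=0."""
        for q in (100.0, 400.0, 1000.0, 2400.0):
            st = solve_steady_state(q, leaf, env, k)
            levels = fluorescence_levels(st, k, DetectorModel(eps_f1=0.0))
            apparent = 1.0 - levels.f_s / levels.f_m_prime
            assert apparent == pytest.approx(st.psii.big_phi_p2, abs=1e-12)

    def test_psi_contamination_lowers_apparent_yield(self, leaf, env, k):
        st = solve_steady_state(400.0, leaf, env, k)
        clean = fluorescence_levels(st, k, DetectorModel(eps_f1=0.0))
        dirty = fluorescence_levels(st, k, DetectorModel(eps_f1=2.0))
        assert (1 - dirty.f_s / dirty.f_m_prime) < (1 - clean.f_s / clean.f_m_prime)
        assert (1 - clean.f_s / clean.f_m_prime) == pytest.approx(
            st.psii.big_phi_p2, abs=1e-12
        )

    def test_psi_share_of_dark_fo(self, leaf, env, k):
        """With ε_F1/ε_F2 = 2 the PS I share of F_o follows the yield sums."""
        st = solve_steady_state(0.0, leaf, env, k)
        det = DetectorModel(eps_f2=1.0, eps_f1=2.0)
        levels = fluorescence_levels(st, k, det)
        psi_part = 0.41 * (0.05 / 15.1) * 2.0
        psii_part = 0.44 * (0.05 / 5.1)
        assert psi_part / (psi_part + psii_part) == pytest.approx(
            psi_part / levels.f_o, rel=1e-12
        )

    def test_level_ordering_across_states(self, leaf, env, k):
        for q in np.linspace(50.0, 2400.0, 20):
            st = solve_steady_state(q, leaf, env, k)
            lv = fluorescence_levels(st, k, DetectorModel(eps_f1=1.5))
            assert lv.f_o_prime <= lv.f_s + 1e-12
            assert lv.f_s <= lv.f_m_prime + 1e-12
            assert lv.f_m_prime <= lv.f_m + 1e-12


class TestPamIndices:
    EX = FluorescenceLevels(f_s=800.0, f_m=3905.0, f_m_prime=1600.0,
                            f_o=568.0, f_o_prime=600.0)

    def test_caption_formulas(self):
        """Arithmetic of the index definitions on plausible level values."""
        idx = pam_indices(self.EX, 1000.0)
        assert idx.phi_p2_app == pytest.approx(0.5)
        assert idx.npq == pytest.approx(1.4406, abs=1e-3)
        assert idx.qp == pytest.approx(0.8)
        assert idx.ql == pytest.approx(0.6)
        assert idx.lef_app == pytest.approx(212.5)
        assert idx.k_lake == pytest.approx(531.25)
        assert idx.k_puddle == pytest.approx(212.5 / 0.2)

    def test_partition_sums_to_one(self):
        idx = pam_indices(self.EX, 1000.0)
        assert idx.phi_p2_app + idx.phi_n2_app + idx.phi_df2_app == pytest.approx(
            1.0, abs=1e-12
        )

    def test_npq_zero_when_fm_equals_fmp(self):
        lv = FluorescenceLevels(800.0, 1600.0, 1600.0, 568.0, 600.0)
        assert pam_indices(lv, 500.0).npq == pytest.approx(0.0)

    def test_degenerate_levels_flagged_not_thrown(self):
        lv = FluorescenceLevels(800.0, 3905.0, 800.0, 568.0, 800.0)
        idx = pam_indices(lv, 500.0)
        assert np.isnan(idx.qp) and np.isnan(idx.ql)

    def test_detector_scale_invariance(self, leaf, env, k):
        st = solve_steady_state(700.0, leaf, env, k)
        a = pam_indices(fluorescence_levels(st, k, DetectorModel(s_det=1.0)), 700.0)
        b = pam_indices(fluorescence_levels(st, k, DetectorModel(s_det=37.0)), 700.0)
        for name in ("phi_p2_app", "npq", "qp", "ql", "lef_app", "k_lake"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-12)

    def test_qp_equals_open_fraction(self, leaf, env, k):
        """qP = 1 − f2 exactly for ε_F1 = 0 and K_U2 = 0 (puddle model)."""
        for q in (200.0, 800.0, 2000.0):
            st = solve_steady_state(q, leaf, env, k)
            idx = pam_indices(fluorescence_levels(st, k, DetectorModel()), q)
            assert idx.qp == pytest.approx(1.0 - st.f2, abs=1e-12)
            assert idx.ql <= idx.qp + 1e-12


class TestVmaxDiagnostic:
    def test_single_record_extrapolation(self):
        rec = PamIndices(0.5, 0.2, 0.3, 1.0, 0.7, 0.6, 100.0,
                         k_lake=100.0 / 0.4, k_puddle=100.0 / 0.3)
        assert estimate_vmax_b6f([rec]) == pytest.approx(250.0)

    def test_empty_mask_rejected(self):
        rec = PamIndices(0.5, 0.2, 0.3, 1.0, 0.7, 0.6, 100.0, 250.0, 333.0)
        with pytest.raises(ValueError):
            estimate_vmax_b6f([rec], [False])

    def test_lake_sweep_recovers_vmax_within_two_percent(self):
        """Under the diagnostic's validity conditions — lake connectivity,
        the experimenter's α2 convention, negligible CEF1 — k_Lake under
        limiting light recovers V_max(CB6F) within 2 %."""
        leaf = LeafParameters(alpha_2=0.425, alpha_1=0.425)
        env = Environment(c=1000.0)
        k = PhotochemicalConstants(k_u2=1000.0)
        qs = np.linspace(50.0, 2400.0, 40)
        idx = _indices_sweep(leaf, env, k, qs)
        q_sat = light_saturation_point(leaf, env, k)
        est = estimate_vmax_b6f(idx, qs < 0.9 * q_sat)
        assert est == pytest.approx(leaf.v_max_cb6f, rel=0.02)

    def test_saturating_records_pull_estimate_down(self):
        """Photosynthetic control above saturation lowers k_Lake."""
        leaf = LeafParameters(alpha_2=0.425, alpha_1=0.425)
        env = Environment(c=200.0)
        k = PhotochemicalConstants(k_u2=1000.0)
        qs = np.linspace(50.0, 2400.0, 40)
        idx = _indices_sweep(leaf, env, k, qs)
        q_sat = light_saturation_point(leaf, env, k)
        lim = estimate_vmax_b6f(idx, qs < 0.9 * q_sat)
        sat = estimate_vmax_b6f(idx, qs > 1.2 * q_sat)
        assert sat < lim < leaf.v_max_cb6f

    def test_sub_lake_connectivity_underestimates(self):
        """On puddle-type data the lake index 1−qL overstates PQ reduction,
        so the extrapolation underestimates V_max — the direction the
        diagnostic's caveats predict."""
        leaf = LeafParameters(alpha_2=0.425, alpha_1=0.425)
        env = Environment(c=200.0)
        qs = np.linspace(50.0, 500.0, 15)
        k0 = PhotochemicalConstants(k_u2=0.0)
        est = estimate_vmax_b6f(_indices_sweep(leaf, env, k0, qs))
        assert est < 0.6 * leaf.v_max_cb6f
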