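"""Serial-transfer protocol tests: resets, carryover history, frequency dynamics."""

import numpy as np
import pytest

from phagepass.core_model import ANCESTOR, PhageParams, SystemState
from phagepass.dde_engine import HistoryBuffer, integrate_transfer
from phagepass.regimes import (
    ExtinctionError,
    RegimeConfig,
    reset_fractional,
    reset_pfu,
    run_regime,
)


def three_types(phis=(4e-9, 2e-9, 6e-9), deltas=(1.7e-2, 1.7e-2, 1.7e-2)):
    return [
        PhageParams(lab, phi=phi, delta=d)
        for lab, phi, d in zip(("anc", "slow", "fast"), phis, deltas)
    ]


class TestPfuReset:
    def make_end_state(self, P):
        return SystemState(180.0, 5e5, 3e7, np.asarray(P, dtype=float))

    def test_proportional_rescale(self):
        cfg = RegimeConfig(180.0, 2, "pfu_reset", reset_pfu=1e7, initial_P=(1e7, 0, 0))
        hist = HistoryBuffer(3, 0.01)
        hist.append(1e8, np.array([8e9, 1e9, 1e9]))
        state, _ = reset_pfu(self.make_end_state([8e9, 1e9, 1e9]), hist, cfg)
        assert state.P == pytest.approx([8e6, 1e6, 1e6])
        assert state.B == 1e8
        assert state.B_I == 0.0

    def test_composition_preserved_exactly(self):
        cfg = RegimeConfig(180.0, 2, "pfu_reset", initial_P=(1e7, 0, 0))
        hist = HistoryBuffer(3, 0.01)
        hist.append(1e8, np.array([3e9, 5e8, 7e8]))
        end = self.make_end_state([3e9, 5e8, 7e8])
        state, _ = reset_pfu(end, hist, cfg)
        assert state.P / state.P.sum() == pytest.approx(end.P / end.P.sum(), rel=1e-14)

    def test_extinct_population_raises_with_index(self):
        cfg = RegimeConfig(180.0, 2, "pfu_reset", initial_P=(1e7,))
        hist = HistoryBuffer(1, 0.01)
        hist.append(1e8, np.array([0.0]))
        with pytest.raises(ExtinctionError) as exc:
            reset_pfu(SystemState(180.0, 1e8, 0.0, np.array([0.0])), hist, cfg, transfer_index=4)
        assert exc.value.transfer_index == 4

    def test_no_release_after_chloroform_reset(self):
        # history is cleared: the first lysis-time window of the new transfer
        # has zero release flux
        cfg = RegimeConfig(30.0, 2, "pfu_reset", initial_P=(1e7,))
        state = SystemState(0.0, 1e8, 0.0, np.array([1e7]))
        hist = HistoryBuffer(1, 0.01)
        traj, state, hist = integrate_transfer(state, hist, [ANCESTOR], 30.0, 0.01)
        state, hist = reset_pfu(state, hist, cfg)
        traj2, _, _ = integrate_transfer(state, hist, [ANCESTOR], 30.0, 0.01)
        flux = traj2.release_flux([ANCESTOR])[0]
        within_tau = traj2.t_local < ANCESTOR.tau
        assert np.all(flux[within_tau] == 0.0)


class TestFractionalReset:
    def test_densities_scaled_by_fraction(self):
        cfg = RegimeConfig(30.0, 2, "fractional_carryover", carryover_fraction=0.02,
                           initial_P=(1e7,))
        hist = HistoryBuffer(1, 0.01)
        hist.append(1e8, np.array([4e9]))
        end = SystemState(30.0, 2e6, 5e7, np.array([4e9]))
        state, _ = reset_fractional(end, hist, cfg)
        assert state.B_I == pytest.approx(1e6)
        assert state.P[0] == pytest.approx(8e7)
        assert state.B == 1e8

    def test_total_phage_scales_exactly(self):
        cfg = RegimeConfig(30.0, 2, "fractional_carryover", carryover_fraction=0.1,
                           initial_P=(1e7, 1e6))
        hist = HistoryBuffer(2, 0.01)
        hist.append(1e8, np.array([3e9, 9e8]))
        end = SystemState(30.0, 2e6, 5e7, np.array([3e9, 9e8]))
        state, _ = reset_fractional(end, hist, cfg)
        assert state.P.sum() == pytest.approx(0.1 * end.P.sum(), rel=1e-14)

    def test_carried_cohort_bursts_on_schedule_at_diluted_magnitude(self):
        # cells infected before the reset lyse on their original schedule;
        # dilution scales the release pulse by exactly the carried fraction
        f = 0.02
        cfg = RegimeConfig(30.0, 2, "fractional_carryover", carryover_fraction=f,
                           initial_P=(1e7,))
        state = SystemState(0.0, 1e8, 0.0, np.array([1e7]))
        hist = HistoryBuffer(1, 0.01)
        traj1, end, hist = integrate_transfer(state, hist, [ANCESTOR], 30.0, 0.01)
        # continuation without any reset, as the f-scaled reference
        ref_state = SystemState(0.0, 1e8, 0.0, np.array([1e7]))
        ref_hist = HistoryBuffer(1, 0.01)
        _, ref_mid, ref_hist = integrate_transfer(ref_state, ref_hist, [ANCESTOR], 30.0, 0.01)
        ref_traj, _, _ = integrate_transfer(ref_mid, ref_hist, [ANCESTOR], 30.0, 0.01)

        state2, hist = reset_fractional(end, hist, cfg)
        traj2, _, _ = integrate_transfer(state2, hist, [ANCESTOR], 30.0, 0.01)
        flux2 = traj2.release_flux([ANCESTOR])[0]
        ref_flux = ref_traj.release_flux([ANCESTOR])[0]
        # 4 min into the new transfer the lag (17 min) reaches 13 min before
        # the reset: pure pre-reset history on both paths
        i = int(round(4.0 / 0.01))
        assert flux2[i] == pytest.approx(f * ref_flux[i], rel=1e-12)

    def test_identity_carryover_continues_trajectory(self):
        # f = 1 with fresh_B equal to the end-of-transfer B is a no-op reset
        cfg = RegimeConfig(30.0, 2, "fractional_carryover", carryover_fraction=1.0,
                           fresh_B=0.0, initial_P=(1e7,))
        params = [ANCESTOR.replace(phi=0.0)]  # keep B untouched so fresh_B=end B=0 works
        state = SystemState(0.0, 0.0, 0.0, np.array([1e7]))
        hist = HistoryBuffer(1, 0.01)
        _, end, hist = integrate_transfer(state, hist, params, 30.0, 0.01)
        state2, hist = reset_fractional(end, hist, cfg)
        traj2, final, _ = integrate_transfer(state2, hist, params, 30.0, 0.01)
        # pure decay continues: P(60) = 1e7 * exp(-delta*60)
        assert final.P[0] == pytest.approx(1e7 * np.exp(-1.7e-2 * 60.0), rel=1e-3)


class TestRunRegime:
    def test_single_type_frequency_is_one(self):
        cfg = RegimeConfig(30.0, 3, "fractional_carryover", initial_P=(1e7,))
        res = run_regime(cfg, [ANCESTOR])
        assert np.all(res.frequencies == 1.0)

    def test_identical_types_keep_initial_frequencies(self):
        params = three_types(phis=(4e-9,) * 3)
        cfg = RegimeConfig(30.0, 4, "fractional_carryover",
                           initial_P=(5e6, 3e6, 2e6))
        res = run_regime(cfg, params)
        expect = np.array([0.5, 0.3, 0.2])
        for n in range(4):
            assert res.frequencies[n] == pytest.approx(expect, rel=1e-9)

    def test_long_transfers_select_fast_adsorber(self):
        # rare fast-adsorbing mutant rises monotonically under 3-h transfers
        params = three_types()
        cfg = RegimeConfig(180.0, 4, "pfu_reset",
                           initial_P=(0.99e7, 0.005e7, 0.005e7))
        res = run_regime(cfg, params)
        fast = res.frequencies[:, 2]
        assert np.all(np.diff(fast) > 0)

    def test_initial_p_length_checked(self):
        cfg = RegimeConfig(30.0, 2, "fractional_carryover", initial_P=(1e7,))
        with pytest.raises(Exception):
            run_regime(cfg, three_types())
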