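import numpy as np
import pytest

from fearcircuit import basic_model as B, extended_model as X, metrics as M, schedule as S
from fearcircuit.extended_model import ExtendedParams, ExtendedState, Perturbation


class TestActivities:
    def test_zero_state(self):
        assert X.compute_activities_ext(ExtendedState(), 1, ExtendedParams()) == (0, 0, 0, 0)

    def test_silencing_untrained_extinction_units_changes_nothing(self):
        state = ExtendedState(w_F=1.0, w_P=1.0)
        F, P, E1, E2 = X.compute_activities_ext(
            state, 1, ExtendedParams(), Perturbation("silence", "extinction")
        )
        assert (F, P, E1, E2) == (1.0, 1.0, 0.0, 0.0)

    def test_activation_drive_reaches_itc_linearly(self):
        params = ExtendedParams(w_E2_E1=1.0)
        _, _, E1, E2 = X.compute_activities_ext(
            ExtendedState(), 1, params, Perturbation("activate", "extinction", drive=0.7)
        )
        assert E1 == 0.7 and E2 == pytest.approx(0.7)

    def test_activation_default_drive_is_la_activity(self):
        state = ExtendedState(w_P=0.8)
        _, P, E1, _ = X.compute_activities_ext(
            state, 1, ExtendedParams(), Perturbation("activate", "extinction")
        )
        assert E1 == P == pytest.approx(0.8)


class TestWeightUpdates:
    def test_resting_trial_runs_only_relaxation(self):
        params = ExtendedParams(beta_E2=0.1, beta_E2_inf=0.05)
        state = ExtendedState(w_F=1.0, w_P=1.0, w_E1=0.3, w_E2=0.6, w_E2_inf=0.2)
        new = X.update_weights_ext(state, 0, 0.0, params)
        assert (new.w_F, new.w_P, new.w_E1) == (1.0, 1.0, 0.3)
        assert new.w_E2 == pytest.approx(0.6 - 0.1 * 0.4)
        assert new.w_E2_inf == pytest.approx(0.2 + 0.05 * 0.4)

    def test_relaxation_fixed_point(self):
        state = ExtendedState(w_F=1.0, w_P=1.0, w_E2=0.4, w_E2_inf=0.4)
        new = X.update_weights_ext(state, 0, 0.0, ExtendedParams())
        assert new == state

    def test_silencing_blocks_consolidation_but_not_extinction(self):
        """With the vmPFC silenced, the fast ITC term still learns while the
        capacity's vmPFC-driven learning term is shut off."""
        params = ExtendedParams(beta_E2=0.0, beta_E2_inf=0.0)
        state = ExtendedState(w_F=1.0, w_P=1.0, w_E1=0.4)
        pert = Perturbation("silence", (0, 1))
        new = X.update_weights_ext(state, 1, 0.0, params, pert)
        assert new.w_E2 > state.w_E2  # early-phase extinction learning intact
        assert new.w_E2_inf == state.w_E2_inf  # no E1 -> no capacity growth
        assert new.w_E1 == state.w_E1  # silenced unit undergoes no plasticity

    def test_consolidation_matches_linear_recursion(self):
        """Resting-phase (w_E2, w_E2inf) dynamics follow the analytic solution
        of the coupled linear relaxation to 1e-10."""
        beta, beta_inf = 0.03, 0.011
        params = ExtendedParams(beta_E2=beta, beta_E2_inf=beta_inf)
        w2_0, winf_0 = 0.7, 0.2
        state = ExtendedState(w_F=1.0, w_P=1.0, w_E1=0.3, w_E2=w2_0, w_E2_inf=winf_0)
        records = X.run_ext(S.resting(200), params, initial_state=state)
        lam = 1.0 - beta - beta_inf
        c = beta_inf * w2_0 + beta * winf_0
        d0 = w2_0 - winf_0
        for t, rec in enumerate(records, start=1):
            w2 = (c + beta * d0 * lam**t) / (beta + beta_inf)
            winf = (c - beta_inf * d0 * lam**t) / (beta + beta_inf)
            assert rec.state_after.w_E2 == pytest.approx(w2, abs=1e-10)
            assert rec.state_after.w_E2_inf == pytest.approx(winf, abs=1e-10)
        # geometric convergence of the gap
        final_gap = abs(records[-1].state_after.w_E2 - records[-1].state_after.w_E2_inf)
        assert final_gap < abs(d0) * lam**199 + 1e-12


class TestReduction:
    @pytest.mark.parametrize("p_us", [0.5, 1.0])
    def test_extended_reduces_to_basic_model(self, p_us):
        """With consolidation and the vmPFC->ITC coupling disabled, the ITC
        pathway reproduces the basic model's extinction unit exactly."""
        sched = S.concat(
            S.partial_reinforcement(40, p_us, seed=3), S.extinction(30), S.retrieval(2)
        )
        bp = B.BasicParams()
        xp = ExtendedParams(
            alpha_E2=bp.alpha_E, w_F_E2=bp.w_FE,
            beta_E2=0.0, alpha_E2_inf=0.0, beta_E2_inf=0.0, w_E2_E1=0.0,
        )
        basic = B.run(sched, bp)
        ext = X.run_ext(sched, xp)
        for rb, rx in zip(basic, ext):
            assert rx.F == rb.F
            assert rx.P == rb.P
            assert rx.E2 == rb.E
            assert rx.state_after.w_E2 == rb.state_after.w_E
            assert rx.state_after.w_F == rb.state_after.w_F


class TestPerturbationValidation:
    def test_window_outside_schedule_rejected(self):
        sched = S.extinction(5)
        with pytest.raises(ValueError):
            X.run_ext(sched, perturbations=[Perturbation("silence", (2, 9))])

    def test_missing_phase_window_rejected(self):
        sched = S.extinction(5)
        with pytest.raises(ValueError):
            X.run_ext(sched, perturbations=[Perturbation("silence", "retrieval")])

    def test_contradictory_overlap_rejected(self, fig3_schedule):
        perts = [
            Perturbation("silence", "extinction"),
            Perturbation("activate", (70, 80)),
        ]
        with pytest.raises(ValueError, match="contradictory"):
            X.run_ext(fig3_schedule, perturbations=perts)

    def test_invalid_modes_rejected(self):
        with pytest.raises(ValueError):
            Perturbation("ablate", "extinction")
        with pytest.raises(ValueError):
            Perturbation("silence", "extinction", target="P")


def _retrieval_fear(fig3_schedule, perturbations):
    records = X.run_ext(fig3_schedule, perturbations=perturbations)
    return [r for r in records if r.phase == "retrieval"][0].F


@pytest.fixture(scope="module")
def fears(fig3_schedule):
    return {
        "ctrl": _retrieval_fear(fig3_schedule, []),
        "act_ext": _retrieval_fear(fig3_schedule, [Perturbation("activate", "extinction")]),
        "act_ret": _retrieval_fear(fig3_schedule, [Perturbation("activate", "retrieval")]),
        "sil_ext": _retrieval_fear(fig3_schedule, [Perturbation("silence", "extinction")]),
        "sil_ret": _retrieval_fear(fig3_schedule, [Perturbation("silence", "retrieval")]),
    }


class TestVmPFCPerturbations:
    """The optogenetic-style retrieval contrasts, at default parameters."""

    def test_control_shows_small_spontaneous_recovery(self, fig3_schedule, fears):
        records = X.run_ext(fig3_schedule)
        end_ext = [r for r in records if r.phase == "extinction"][-1].F
        assert fears["ctrl"] > end_ext  # recovery after the resting phase
        assert fears["ctrl"] < 0.2  # but only to a small extent

    def test_silencing_during_extinction_blocks_consolidation(self, fears):
        assert fears["sil_ext"] > fears["ctrl"] + 0.05

    def test_activation_during_extinction_abolishes_recovery(self, fears):
        assert fears["act_ext"] <= fears["ctrl"]

    def test_activation_during_retrieval_suppresses_fear(self, fears):
        assert fears["act_ret"] < fears["ctrl"]

    def test_silencing_during_retrieval_has_little_effect(self, fears):
        """The retrieval of extinction memory barely depends on the vmPFC:
        silencing it at retrieval moves fear far less than silencing it
        during extinction does."""
        gap = abs(fears["sil_ret"] - fears["ctrl"])
        effect = fears["sil_ext"] - fears["ctrl"]
        assert gap < 0.5 * effect

    def test_perturbation_flag_recorded(self, fig3_schedule):
        records = X.run_ext(
            fig3_schedule, perturbations=[Perturbation("silence", "extinction")]
        )
        flags = {r.phase: r.perturbed for r in records}
        assert flags["extinction"] is True and flags["conditioning"] is False


@pytest.fixture(scope="module")
def base():
    c = S.DEFAULT_COUNTS
    return S.concat(
        S.partial_reinforcement(c["conditioning"], 0.5, 1.0, seed=7),
        S.extinction(c["extinction"]),
    )


class TestShockProcedure:
    def test_stronger_us_unlocks_extinction(self, base):
        table = X.run_shock_experiment(base, [1.0, 3.0])
        f1 = float(table.final_F[table.us_multiplier == 1.0].iloc[0])
        f3 = float(table.final_F[table.us_multiplier == 3.0].iloc[0])
        assert f3 < f1
        assert f3 < 0.05

    def test_same_intensity_us_reinforces_fear(self, base):
        pre = X.run_ext(base)[-1].F
        sched = S.shock_procedure(base, 1.0, 1, S.DEFAULT_COUNTS["reextinction"])
        records = X.run_ext(sched)
        recon_idx = max(i for i, r in enumerate(records) if r.phase == "reconditioning")
        post = records[recon_idx + 1].F
        assert post > pre

    def test_single_multiplier_grid(self, base):
        table = X.run_shock_experiment(base, [1.0])
        assert list(table.columns) == ["us_multiplier", "final_F"]
        assert len(table) == 1
        sched = S.shock_procedure(base, 1.0, 1, S.DEFAULT_COUNTS["reextinction"])
        assert table.final_F.iloc[0] == X.run_ext(sched)[-1].F

    def test_empty_grid_rejected(self, base):
        with pytest.raises(ValueError):
            X.run_shock_experiment(base, [])


class TestExtendedPREE:
    def test_residual_and_time_constant_monotone_in_p(self):
        c = S.DEFAULT_COUNTS
        residuals, taus = [], []
        for p in (0.3, 0.5, 0.7, 1.0):
            sched = S.concat(
                S.partial_reinforcement(c["conditioning"], p, mode="deterministic_interleave"),
                S.extinction(c["extinction"]),
            )
            records = X.run_ext(sched)
            residuals.append(M.residual_fear(records, "extinction"))
            fit = M.fit_extinction_time_constant(M.extinction_fear_series(records))
            assert fit.converged
            taus.append(fit.tau)
        assert np.all(np.diff(residuals) <= 1e-9)
        assert np.all(np.diff(taus) <= 1e-9)
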