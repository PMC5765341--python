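import math

import numpy as np
import pytest

from ab10drive import (
    DegenerateParametersError,
    DriveParams,
    GameteFreqState,
    classify_equilibrium_stability,
    classify_outcome,
    find_internal_equilibria,
    global_outcome,
    iterate_to_equilibrium,
    residual,
    step,
)
from ab10drive.equilibria import count_internal_equilibria_batch
from ab10drive.model import model_weights
from ab10drive.sweep import SCENARIOS, _composite_weights, sample_param_arrays

# neither allele invades when rare: heterozygote costs dominate the weak drive
BISTABLE = DriveParams(d=0.1, f=0.4, h_f=1.0, m=0.4, h_m=1.0)
LETHAL = DriveParams(d=0.5, v=1.0)  # recessive homozygous lethality


class TestResidual:
    def test_fixations_are_exact_zeros(self, maize_solid):
        assert residual(GameteFreqState(0, 0), maize_solid) == (0.0, 0.0)
        assert residual(GameteFreqState(1, 1), maize_solid) == (0.0, 0.0)

    def test_neutral_sex_averaging(self):
        r = residual(GameteFreqState(0.3, 0.7), DriveParams())
        assert r == pytest.approx((0.2, -0.2), abs=1e-14)


class TestEnumeration:
    @pytest.mark.parametrize("method", ["newton", "elimination"])
    def test_homozygous_lethal_equilibrium(self, method):
        eqs = find_internal_equilibria(LETHAL, method=method)
        assert len(eqs) == 1
        pm_hat = (1 - math.sqrt(1 / 3)) / 2
        assert eqs[0].p_m == pytest.approx(pm_hat, abs=1e-10)
        assert eqs[0].p_f == pytest.approx(1.5 * pm_hat, abs=1e-10)
        assert eqs[0].stability == "stable"

    @pytest.mark.parametrize("method", ["newton", "elimination"])
    def test_cost_free_driver_has_no_interior_equilibrium(self, method):
        assert find_internal_equilibria(DriveParams(d=0.5), method=method) == []

    def test_bistable_interior_equilibrium_is_unstable(self):
        eqs = find_internal_equilibria(BISTABLE)
        assert len(eqs) == 1
        assert eqs[0].stability in ("unstable", "saddle")

    def test_neutral_family_rejected(self):
        with pytest.raises(DegenerateParametersError):
            find_internal_equilibria(DriveParams())

    def test_residual_norm_invariant(self, rng):
        # every reported equilibrium is a fixed point to 1e-10
        found = 0
        for _ in range(100):
            p = DriveParams(*rng.uniform(0, 1, 9))
            for eq in find_internal_equilibria(p, method="elimination"):
                nxt = step(eq.state, p)
                assert max(abs(nxt.p_f - eq.p_f),
                           abs(nxt.p_m - eq.p_m)) < 1e-10
                found += 1
        assert found > 0

    def test_newton_and_elimination_agree(self, rng):
        for _ in range(150):
            p = DriveParams(*rng.uniform(0, 1, 9))
            a = find_internal_equilibria(p, method="newton")
            b = find_internal_equilibria(p, method="elimination")
            assert len(a) == len(b)
            for ea, eb in zip(a, b):
                assert ea.p_f == pytest.approx(eb.p_f, abs=1e-8)
                assert ea.p_m == pytest.approx(eb.p_m, abs=1e-8)

    def test_batch_counts_match_single_calls(self, rng):
        p = sample_param_arrays(SCENARIOS["general"], 60, rng)
        counts = count_internal_equilibria_batch(
            *_composite_weights(p), method="newton"
        )
        names = list(p)
        for i in range(60):
            single = find_internal_equilibria(
                DriveParams(**{k: p[k][i] for k in names})
            )
            assert counts[i] == len(single)

    def test_sympy_resultant_oracle(self):
        # independent symbolic elimination of the fixed-point system
        import sympy as sp

        for params in (LETHAL, BISTABLE, DriveParams(
                d=0.3, f=0.65, h_f=0.212, s=0.19, h_s=0.327, m=0.063,
                h_m=0.176)):
            w = model_weights(params)
            A, B, Bd, C, E = (sp.Rational(str(round(x, 12))) for x in w)
            pf, pm = sp.symbols("pf pm", real=True)
            S = pf + pm - 2 * pf * pm
            P = A * pf * pm * (1 - pf) + (Bd - B * pf) * S \
                - pf * (1 - pf) * (1 - pm)
            Q = C * pf * pm * (1 - pm) + E * (sp.Rational(1, 2) - pm) * S \
                - pm * (1 - pf) * (1 - pm)
            res = sp.resultant(sp.Poly(P, pf), sp.Poly(Q, pf), pf)
            interior = []
            for root in sp.Poly(res, pm).real_roots():
                pm_val = float(root)
                if not 1e-6 < pm_val < 1 - 1e-6:
                    continue
                sols = sp.solve(Q.subs(pm, root), pf)
                for s in sols:
                    pf_val = float(s)
                    if 1e-6 < pf_val < 1 - 1e-6 and \
                            abs(float(P.subs({pf: s, pm: root}))) < 1e-9:
                        interior.append((pf_val, pm_val))
            mine = find_internal_equilibria(params, method="elimination")
            assert len(mine) == len(interior)
            for eq, (pf_val, pm_val) in zip(
                    mine, sorted(interior)):
                assert eq.p_f == pytest.approx(pf_val, abs=1e-6)
                assert eq.p_m == pytest.approx(pm_val, abs=1e-6)

    def test_at_most_three_interior_equilibria(self, rng):
        p = sample_param_arrays(SCENARIOS["general"], 20_000, rng)
        counts = count_internal_equilibria_batch(
            *_composite_weights(p), method="elimination"
        )
        assert counts.max() <= 3


class TestStabilityLabels:
    def test_labels_agree_with_basin_behavior(self):
        # iterating from a small perturbation returns to a stable
        # equilibrium and departs from an unstable one
        eq = find_internal_equilibria(LETHAL)[0]
        for dpf in (-1e-3, 1e-3):
            traj = iterate_to_equilibrium(
                GameteFreqState(eq.p_f + dpf, eq.p_m), LETHAL, tol=1e-13
            )
            assert traj.final.p_f == pytest.approx(eq.p_f, abs=1e-8)

        eq_u = find_internal_equilibria(BISTABLE)[0]
        lo = iterate_to_equilibrium(
            GameteFreqState(eq_u.p_f - 1e-2, eq_u.p_m - 1e-2), BISTABLE
        )
        hi = iterate_to_equilibrium(
            GameteFreqState(eq_u.p_f + 1e-2, eq_u.p_m + 1e-2), BISTABLE
        )
        assert lo.final.p_f < 1e-6 and hi.final.p_f > 1 - 1e-6

    def test_fixation_labels_match_eigenvalues(self, maize_solid):
        p = maize_solid.replace(d=0.3)  # both eigenvalues > 1
        assert classify_equilibrium_stability(GameteFreqState(0, 0), p) \
            in ("unstable", "saddle")
        assert classify_equilibrium_stability(GameteFreqState(1, 1), p) \
            in ("unstable", "saddle")


class TestGlobalOutcome:
    def test_maize_polymorphism(self, maize_solid):
        gb = global_outcome(maize_solid.replace(d=0.3), tol=1e-11,
                            max_gen=300_000)
        assert gb.outcome == "STABLE_POLYMORPHISM"
        assert len(gb.attractors) == 1
        assert gb.agrees_with_eigenvalues

    def test_cost_free_driver_fixes_from_anywhere(self):
        gb = global_outcome(DriveParams(d=0.5))
        assert gb.outcome == "AB10_FIXATION"
        assert gb.agrees_with_eigenvalues

    def test_bistable_depends_on_start(self):
        gb = global_outcome(BISTABLE)
        assert gb.outcome == "BISTABLE"
        labels = {p["label"] for p in gb.per_start}
        assert labels == {"loss", "fixation"}
        assert gb.agrees_with_eigenvalues

    def test_neutral_family_rejected(self):
        with pytest.raises(DegenerateParametersError):
            global_outcome(DriveParams())

    def test_agreement_flag_consistency(self, rng):
        # with at most one interior equilibrium and a clear eigenvalue
        # signal, global behavior follows the classification
        from ab10drive import lambda0, lambda1

        checked = 0
        for _ in range(40):
            p = DriveParams(*rng.uniform(0, 1, 9))
            l0, l1 = lambda0(p), lambda1(p)
            if min(abs(l0 - 1), abs(min(l1, 10) - 1)) < 0.05:
                continue  # near-transcritical: convergence too slow
            if len(find_internal_equilibria(p, method="elimination")) > 1:
                continue  # eigenvalues are not claimed to predict these
            gb = global_outcome(p, tol=1e-11, max_gen=200_000)
            if gb.cycling:
                continue
            assert gb.agrees_with_eigenvalues, (p, gb.outcome, l0, l1)
            checked += 1
        assert checked > 10
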