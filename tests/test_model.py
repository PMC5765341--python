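import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ab10drive import (
    DegenerateNormalizerError,
    DriveParams,
    GameteFreqState,
    adult_allele_frequency,
    adult_genotype_frequencies,
    iterate_to_equilibrium,
    max_transmission,
    mean_fitnesses,
    step,
)
from conftest import random_params

unit = st.floats(0.0, 1.0, allow_nan=False)


class TestStep:
    @given(p_f=unit, p_m=unit)
    @settings(deadline=None)
    def test_neutral_map_averages_the_sexes(self, p_f, p_m):
        nxt = step(GameteFreqState(p_f, p_m), DriveParams())
        mean = (p_f + p_m) / 2
        assert nxt.p_f == pytest.approx(mean, abs=1e-14)
        assert nxt.p_m == pytest.approx(mean, abs=1e-14)

    def test_drive_only_from_even_start(self):
        # complete drive, no costs: ovule pool shifts to 0.75, pollen stays
        nxt = step(GameteFreqState(0.5, 0.5), DriveParams(d=1.0))
        assert nxt == pytest.approx((0.75, 0.5))

    @given(p_f=unit, p_m=unit, data=st.data())
    @settings(deadline=None, max_examples=200)
    def test_closure_and_absorption(self, p_f, p_m, data):
        params = DriveParams(*(data.draw(unit) for _ in range(9)))
        try:
            nxt = step(GameteFreqState(p_f, p_m), params)
        except DegenerateNormalizerError:
            return  # extreme corner, allowed to be undefined
        assert 0.0 <= nxt.p_f <= 1.0 and 0.0 <= nxt.p_m <= 1.0
        for corner in ((0.0, 0.0), (1.0, 1.0)):
            try:
                fixed = step(GameteFreqState(*corner), params)
            except DegenerateNormalizerError:
                continue
            assert fixed == corner

    def test_degenerate_normalizer_raises(self):
        # driver fixed and homozygote completely sterile through ovules
        with pytest.raises(DegenerateNormalizerError):
            step(GameteFreqState(1.0, 1.0), DriveParams(f=1.0))

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            step(GameteFreqState(-0.1, 0.5), DriveParams())


class TestMeanFitnesses:
    def test_resident_wildtype_is_reference(self, rng):
        for p in random_params(rng, 20):
            assert mean_fitnesses(GameteFreqState(0, 0), p) == (1.0, 1.0)

    def test_driver_fixed(self):
        p = DriveParams(f=0.3, s=0.2, v=0.1, m=0.4)
        W_f, W_m = mean_fitnesses(GameteFreqState(1, 1), p)
        assert W_f == pytest.approx((1 - 0.3) * (1 - 0.1) * (1 - 0.2))
        assert W_m == pytest.approx((1 - 0.4) * (1 - 0.1))

    @given(p_f=unit, p_m=unit)
    @settings(deadline=None)
    def test_neutral_fitness_is_one(self, p_f, p_m):
        W_f, W_m = mean_fitnesses(GameteFreqState(p_f, p_m), DriveParams())
        assert W_f == pytest.approx(1.0, abs=1e-15)
        assert W_m == pytest.approx(1.0, abs=1e-15)

    def test_bounded_by_one(self, rng):
        for p in random_params(rng, 50):
            pf, pm = rng.uniform(0, 1, 2)
            W_f, W_m = mean_fitnesses(GameteFreqState(pf, pm), p)
            assert 0.0 <= W_f <= 1.0 and 0.0 <= W_m <= 1.0


class TestIteration:
    def test_cost_free_driver_sweeps(self):
        traj = iterate_to_equilibrium(
            GameteFreqState(0.01, 0.01), DriveParams(d=0.5), tol=1e-12
        )
        assert traj.converged
        assert traj.final.p_f == pytest.approx(1.0, abs=1e-9)
        assert traj.final.p_m == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("d", [0.1, 0.3, 0.5, 0.8])
    def test_homozygous_lethal_closed_form(self, d):
        # v = 1, h = 0: the interior equilibrium solves
        # p_f = (1+d) p_m with 2(1+d) p_m^2 - 2(1+d) p_m + d = 0
        params = DriveParams(d=d, v=1.0)
        traj = iterate_to_equilibrium(GameteFreqState(0.5, 0.5), params)
        assert traj.converged
        pm_hat = (1 - math.sqrt((1 - d) / (1 + d))) / 2
        assert traj.final.p_m == pytest.approx(pm_hat, abs=1e-10)
        assert traj.final.p_f == pytest.approx((1 + d) * pm_hat, abs=1e-10)

    def test_neutral_equalizes_in_one_step(self):
        traj = iterate_to_equilibrium(
            GameteFreqState(0.3, 0.7), DriveParams(), record=True
        )
        assert traj.converged
        assert traj.states[1] == pytest.approx((0.5, 0.5))
        assert traj.final == pytest.approx((0.5, 0.5))

    def test_trajectory_frame_columns(self):
        traj = iterate_to_equilibrium(
            GameteFreqState(0.2, 0.2), DriveParams(d=0.4), record=True
        )
        frame = traj.to_frame()
        assert list(frame.columns) == ["generation", "p_f", "p_m", "W_f", "W_m"]
        assert len(frame) == len(traj.states)
        assert frame["generation"].iloc[0] == 0

    def test_monotone_drive_benefit(self, maize_solid):
        # equilibrium ovule frequency weakly increases with drive
        hats = []
        for d in np.arange(0.30, 0.56, 0.05):
            traj = iterate_to_equilibrium(
                GameteFreqState(0.5, 0.5), maize_solid.replace(d=float(d)),
                tol=1e-12,
            )
            hats.append(traj.final.p_f)
        assert all(b >= a - 1e-9 for a, b in zip(hats, hats[1:]))

    def test_bad_tol_rejected(self):
        with pytest.raises(ValueError):
            iterate_to_equilibrium(GameteFreqState(0.5, 0.5), DriveParams(),
                                   tol=0.0)


class TestAdultCensus:
    def test_corners(self, maize_solid):
        assert adult_genotype_frequencies(
            GameteFreqState(1, 1), maize_solid
        ) == (1, 0, 0)
        assert adult_genotype_frequencies(
            GameteFreqState(0, 0), maize_solid
        ) == (0, 0, 1)
        assert adult_allele_frequency(GameteFreqState(1, 1), maize_solid) == 1
        assert adult_allele_frequency(GameteFreqState(0, 0), maize_solid) == 0

    @given(p=unit)
    @settings(deadline=None)
    def test_neutral_hardy_weinberg(self, p):
        hom, het, wt = adult_genotype_frequencies(
            GameteFreqState(p, p), DriveParams()
        )
        q = 1 - p
        assert hom == pytest.approx(p * p, abs=1e-14)
        assert het == pytest.approx(2 * p * q, abs=1e-14)
        assert wt == pytest.approx(q * q, abs=1e-14)
        assert adult_allele_frequency(GameteFreqState(p, p), DriveParams()) \
            == pytest.approx(p, abs=1e-14)

    def test_fecundity_costs_excluded(self):
        # f and m act after flowering: they must not move the adult census
        state = GameteFreqState(0.4, 0.3)
        base = DriveParams(s=0.2, h_s=0.5, v=0.1, h=0.3)
        with_fec = base.replace(f=0.9, h_f=0.9, m=0.9, h_m=0.9)
        assert adult_genotype_frequencies(state, base) == \
            adult_genotype_frequencies(state, with_fec)


class TestMaxTransmission:
    def test_mechanistic_cap(self):
        # 2/3 MII patterns with full drive: 2/3 * 1 + 1/3 * 1/2 = 5/6
        assert max_transmission(2 / 3, 1.0) == pytest.approx(5 / 6, abs=1e-15)

    @pytest.mark.parametrize("e", [0.0, 0.3, 1.0])
    def test_pure_mi_is_mendelian(self, e):
        assert max_transmission(0.0, e) == 0.5

    def test_no_drive_given_mii(self):
        assert max_transmission(1.0, 0.5) == 0.5

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            max_transmission(1.2, 0.5)
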