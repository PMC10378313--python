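"""Mosaic flux-force model: per-pathway fluxes, totals, critical force ratios."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from gearshift import (
    Pathway,
    TransducerSystem,
    catabolic_reversal_force_ratio,
    flux_ratio_stoichiometry,
    force_ratio,
    leak_flux,
    pathway_atp_flux,
    pathway_catabolic_flux,
    stall_force_ratio,
    total_fluxes,
)
from conftest import random_system


class TestTypes:
    def test_pathway_rejects_bad_values(self):
        with pytest.raises(ValueError):
            Pathway(stoichiometry=-1.0, weight=0.5)
        with pytest.raises(ValueError):
            Pathway(stoichiometry=1.0, weight=1.5)

    def test_system_requires_weights_summing_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            TransducerSystem(pathways=(Pathway(1.0, 0.8), Pathway(2.0, 0.3)))

    def test_system_rejects_nonpositive_scales(self):
        good = (Pathway(1.0, 1.0),)
        with pytest.raises(ValueError):
            TransducerSystem(pathways=good, capacity=0.0)
        with pytest.raises(ValueError):
            TransducerSystem(pathways=good, gibbs_catabolic=-1.0)
        with pytest.raises(ValueError):
            TransducerSystem(pathways=good, leak=-0.1)

    def test_two_pathway_constructor_splits_capacity(self, two_gear_system):
        assert two_gear_system.weights == (0.8, 0.2)
        assert two_gear_system.stoichiometries == (1.0, 2.0)
        assert two_gear_system.nu == pytest.approx(1.2)


@pytest.mark.parametrize(
    "gp, gc, expected",
    [(0.75, 1.0, 0.75), (0.0, 1.0, 0.0), (2.0, 4.0, 0.5)],
)
def test_force_ratio(gp, gc, expected):
    assert force_ratio(gp, gc) == expected


def test_force_ratio_requires_positive_catabolic_gibbs():
    with pytest.raises(ValueError):
        force_ratio(1.0, 0.0)
    with pytest.raises(ValueError):
        force_ratio(1.0, -2.0)


class TestPathwayFluxes:
    @pytest.mark.parametrize(
        "i, x, expected",
        [(0, 0.0, 0.8), (1, 0.5, 0.0), (0, 1.0, 0.0)],
    )
    def test_catabolic_flux(self, two_gear_system, i, x, expected):
        assert pathway_catabolic_flux(two_gear_system, i, x) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "i, x, expected",
        [(1, 0.0, 0.4), (1, 0.75, -0.2)],  # reversed into hydrolysis at high X
    )
    def test_atp_flux(self, two_gear_system, i, x, expected):
        assert pathway_atp_flux(two_gear_system, i, x) == pytest.approx(expected)

    def test_zero_stoichiometry_pathway_makes_no_atp(self):
        s = TransducerSystem(pathways=(Pathway(0.0, 0.5), Pathway(2.0, 0.5)))
        for x in (0.0, 0.3, 1.0):
            assert pathway_atp_flux(s, 0, x) == 0.0

    def test_index_out_of_range(self, two_gear_system):
        with pytest.raises(IndexError):
            pathway_catabolic_flux(two_gear_system, 2, 0.1)
        with pytest.raises(IndexError):
            pathway_atp_flux(two_gear_system, -1, 0.1)


class TestLeak:
    def test_no_leak_no_flux(self, two_gear_system):
        assert leak_flux(two_gear_system, 0.7) == 0.0

    def test_leak_proportional_to_force_ratio(self):
        s = TransducerSystem(pathways=(Pathway(1.0, 1.0),), leak=0.1)
        assert leak_flux(s, 0.5) == pytest.approx(0.05)
        assert leak_flux(s, 0.0) == 0.0


class TestTotals:
    def test_stall_point_zero_synthesis(self, two_gear_system):
        st = total_fluxes(two_gear_system, 0.75)
        assert st.jp_total == pytest.approx(0.0, abs=1e-12)
        assert st.flux_ratio_stoichiometry == pytest.approx(0.0, abs=1e-12)
        assert st.efficiency == pytest.approx(0.0, abs=1e-12)

    def test_catabolic_reversal_undefined_flux_ratio(self, two_gear_system):
        st = total_fluxes(two_gear_system, 1.0 / 1.2)
        assert st.jc_total == pytest.approx(0.0, abs=1e-12)
        assert st.flux_ratio_stoichiometry is None
        assert st.efficiency is None

    def test_single_fully_coupled_pathway_has_constant_flux_ratio(self):
        s = TransducerSystem(pathways=(Pathway(1.0, 1.0),))
        for x in (0.0, 0.3, 0.7, 0.99):
            assert flux_ratio_stoichiometry(s, x) == pytest.approx(1.0)

    def test_negative_force_ratio_rejected(self, two_gear_system):
        with pytest.raises(ValueError):
            total_fluxes(two_gear_system, -0.1)

    def test_reverse_operation_flag(self, two_gear_system):
        assert not total_fluxes(two_gear_system, 0.5).reverse_operation
        assert total_fluxes(two_gear_system, 0.9).reverse_operation


class TestFluxRatioStoichiometry:
    def test_at_zero_force_equals_weighted_average(self, two_gear_system):
        assert flux_ratio_stoichiometry(two_gear_system, 0.0) == pytest.approx(1.2)

    def test_zero_one_stoichiometry_special_case(self):
        # n1=0, n2=1, no leak: n(X) = 1 / (1 + (1-phi)/(phi*(1-X)))
        s = TransducerSystem.two_pathway(phi=0.5, n1=0.0, n2=1.0)
        assert flux_ratio_stoichiometry(s, 0.5) == pytest.approx(1.0 / 3.0)

    def test_single_pathway_with_leak_special_case(self):
        # phi=1, n2=1, leak>0: n(X) = 1 - leak*X/(1-X)
        s = TransducerSystem.two_pathway(phi=1.0, n1=0.0, n2=1.0, leak=0.2)
        assert flux_ratio_stoichiometry(s, 0.5) == pytest.approx(0.8)

    @pytest.mark.parametrize("phi", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("leak", [0.0, 0.1, 0.4])
    def test_special_cases_recovered_from_general_form(self, phi, leak):
        """The two closed-form reductions follow from the general n(X)."""
        xs = np.linspace(0.0, 0.9, 10)
        # reduction 1: stoichiometries (0, 1)
        s1 = TransducerSystem.two_pathway(phi=phi, n1=0.0, n2=1.0, leak=leak)
        for x in xs:
            expected = (phi * (1 - x) - leak * x) / ((1 - phi) + phi * (1 - x))
            assert flux_ratio_stoichiometry(s1, x) == pytest.approx(expected, rel=1e-12)
        # reduction 2: all capacity in one unit-stoichiometry pathway
        s2 = TransducerSystem.two_pathway(phi=1.0, n1=0.0, n2=1.0, leak=leak)
        for x in xs:
            expected = 1.0 - leak * x / (1.0 - x)
            assert flux_ratio_stoichiometry(s2, x) == pytest.approx(expected, rel=1e-12)


class TestCriticalForceRatios:
    def test_two_gear_stall(self, two_gear_system):
        assert stall_force_ratio(two_gear_system) == pytest.approx(0.75)

    def test_two_gear_catabolic_reversal(self, two_gear_system):
        x = catabolic_reversal_force_ratio(two_gear_system)
        assert x == pytest.approx(1.0 / 1.2)
        assert round(x, 2) == 0.83

    def test_single_pathway_stalls_at_reciprocal_stoichiometry(self):
        for n in (1.0, 2.0, 3.5):
            s = TransducerSystem(pathways=(Pathway(n, 1.0),))
            assert stall_force_ratio(s) == pytest.approx(1.0 / n)
            assert catabolic_reversal_force_ratio(s) == pytest.approx(1.0 / n)

    def test_dual_pathway_one_three_stall(self):
        s = TransducerSystem.two_pathway(phi=0.375, n1=1.0, n2=3.0)
        assert stall_force_ratio(s) == pytest.approx(0.4375)

    def test_dual_pathway_reversal(self):
        s = TransducerSystem.two_pathway(phi=0.25, n1=1.0, n2=3.0)
        assert catabolic_reversal_force_ratio(s) == pytest.approx(1.0 / 1.5)

    def test_zero_synthesis_system_has_no_critical_ratios(self):
        s = TransducerSystem(pathways=(Pathway(0.0, 1.0),), leak=0.1)
        with pytest.raises(ValueError):
            stall_force_ratio(s)
        with pytest.raises(ValueError):
            catabolic_reversal_force_ratio(s)

    def test_closed_forms_agree_with_bisection(self):
        """Roots of the affine totals found by bracketing match closed forms."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 25:
            s = random_system(rng)
            if s.nu <= 1e-6:
                continue
            checked += 1
            x_stall = stall_force_ratio(s)
            x_rev = catabolic_reversal_force_ratio(s)
            f_jp = lambda x: total_fluxes(s, x).jp_total
            f_jc = lambda x: total_fluxes(s, x).jc_total
            assert brentq(f_jp, 0.0, 2 * x_stall, xtol=1e-12) == pytest.approx(
                x_stall, abs=1e-9
            )
            assert brentq(f_jc, 0.0, 2 * x_rev, xtol=1e-12) == pytest.approx(
                x_rev, abs=1e-9
            )


class TestInvariants:
    def test_totals_are_affine_in_force_ratio(self):
        """Three points on any random system's total flux curves are collinear."""
        rng = np.random.default_rng(7)
        xs = (0.1, 0.45, 0.8)
        for _ in range(100):
            s = random_system(rng)
            for attr in ("jc_total", "jp_total"):
                y = [getattr(total_fluxes(s, x), attr) for x in xs]
                interp = y[0] + (y[2] - y[0]) * (xs[1] - xs[0]) / (xs[2] - xs[0])
                assert y[1] == pytest.approx(interp, rel=1e-9, abs=1e-9)

    def test_conservation_of_atp_flux(self):
        """Total synthesis equals coupled synthesis minus the leak, exactly."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            s = random_system(rng)
            scale = s.capacity * s.gibbs_catabolic
            for x in np.linspace(0.0, 1.5, 7):
                st = total_fluxes(s, float(x))
                coupled = math.fsum(
                    n * jc for n, jc in zip(s.stoichiometries, st.jc_per_pathway)
                )
                assert st.jp_total == pytest.approx(
                    coupled - st.jp_leak, abs=1e-12 * max(1.0, scale)
                )
                assert st.jc_total == pytest.approx(
                    math.fsum(st.jc_per_pathway), abs=1e-12 * max(1.0, scale)
                )

    def test_flux_ratio_stoichiometry_decreases(self):
        """n(X) is non-increasing before catabolic reversal, strictly so when
        distinct stoichiometries are active or a leak exists."""
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 100:
            s = random_system(rng)
            if s.nu <= 1e-6:
                continue
            checked += 1
            xs = np.linspace(0.0, 0.999 / s.nu, 50)
            ns = [flux_ratio_stoichiometry(s, float(x)) for x in xs]
            assert all(v is not None for v in ns)
            diffs = np.diff(ns)
            active = {n for n, w in zip(s.stoichiometries, s.weights) if w > 0}
            if len(active) > 1 or s.leak > 0:
                assert np.all(diffs < 1e-12)
                assert ns[0] - ns[-1] > 0
            else:
                assert np.all(np.abs(diffs) < 1e-9)

    def test_efficiency_has_single_interior_maximum(self):
        """eta vanishes at 0 and at stall, is positive between, and is
        unimodal there.  A completely coupled system is the degenerate
        limit: its stall point coincides with the catabolic-reversal
        singularity and eta = n*X climbs linearly toward 1 instead."""
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 100:
            s = random_system(rng)
            if s.nu <= 1e-3:
                continue
            checked += 1
            x_stall = stall_force_ratio(s)
            assert total_fluxes(s, 0.0).efficiency == 0.0
            xs = np.linspace(0.0, x_stall, 200)[1:-1]
            etas = np.array([total_fluxes(s, float(x)).efficiency for x in xs])
            assert np.all(etas > 0)
            active = {n for n, w in zip(s.stoichiometries, s.weights) if w > 0}
            if len(active) > 1 or s.leak > 0:
                assert total_fluxes(s, x_stall).efficiency == pytest.approx(
                    0.0, abs=1e-9
                )
                sign_changes = np.sum(np.diff(np.sign(np.diff(etas))) != 0)
                assert sign_changes <= 1
            else:
                assert np.all(np.diff(etas) > 0)
                assert etas[-1] < 1.0

    def test_synthesis_stalls_before_catabolism_reverses(self):
        rng = np.random.default_rng(19)
        checked = 0
        while checked < 100:
            s = random_system(rng)
            if s.nu <= 1e-6:
                continue
            checked += 1
            active = {n for n, w in zip(s.stoichiometries, s.weights) if w > 0}
            x_stall = stall_force_ratio(s)
            x_rev = catabolic_reversal_force_ratio(s)
            if len(active) > 1 or s.leak > 0:
                assert x_stall < x_rev
            else:
                assert x_stall == pytest.approx(x_rev, rel=1e-12)
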