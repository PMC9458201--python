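import math
from dataclasses import replace

import numpy as np
import pytest

from cdbind.constants import KB, STANDARD_VOLUME
from cdbind.restraints import (
    BoreschRestraint,
    CycleLegs,
    ReplicaSet,
    RestraintTrace,
    aggregate_replicas,
    assemble_cycle,
    boresch_analytical,
    derive_force_constants,
    select_restraints,
)
from cdbind.synthetic import gen_restraint_timeseries
from conftest import boresch_quadrature_oracle

KT = KB * 298.0


@pytest.fixture
def restraint():
    return BoreschRestraint(
        r0=5.0, thetaA0=90.0, thetaB0=90.0, phiA0=0.0, phiB0=60.0, phiC0=-120.0,
        k_r=40.0, k_thetaA=40.0, k_thetaB=40.0, k_phiA=40.0, k_phiB=40.0, k_phiC=40.0,
    )


class TestBoreschAnalytical:
    def test_volume_doubling_adds_kt_ln2(self, restraint):
        base = boresch_analytical(restraint, standard_volume=STANDARD_VOLUME)
        doubled = boresch_analytical(restraint, standard_volume=2 * STANDARD_VOLUME)
        assert doubled - base == pytest.approx(KT * math.log(2.0), abs=1e-12)

    def test_force_constant_scaling(self, restraint):
        # doubling all six K grows sqrt(prod K) by 2^3 = 8 -> +kT ln 8
        doubled = replace(
            restraint,
            k_r=2 * restraint.k_r, k_thetaA=2 * restraint.k_thetaA,
            k_thetaB=2 * restraint.k_thetaB, k_phiA=2 * restraint.k_phiA,
            k_phiB=2 * restraint.k_phiB, k_phiC=2 * restraint.k_phiC,
        )
        delta = boresch_analytical(doubled) - boresch_analytical(restraint)
        assert delta == pytest.approx(KT * math.log(8.0), abs=1e-9)

    def test_matches_quadrature_in_stiff_regime(self, restraint):
        # all angular stds sqrt(kT/K) < 10 degrees
        for k in (25.0, 40.0, 100.0):
            stiff = replace(
                restraint,
                k_r=k, k_thetaA=k, k_thetaB=k, k_phiA=k, k_phiB=k, k_phiC=k,
            )
            assert math.degrees(math.sqrt(KT / k)) < 10.0
            analytic = boresch_analytical(stiff)
            numeric = boresch_quadrature_oracle(stiff)
            assert abs(analytic - numeric) < 0.02

    def test_moderate_stiffness_close_to_quadrature(self, restraint):
        # K=10 sits outside the <10 degree stiff regime; agreement degrades
        # gracefully but stays within 0.05 kcal/mol at theta0=90
        soft = replace(
            restraint, k_r=10.0, k_thetaA=10.0, k_thetaB=10.0,
            k_phiA=10.0, k_phiB=10.0, k_phiC=10.0,
        )
        assert abs(boresch_analytical(soft) - boresch_quadrature_oracle(soft)) < 0.05

    def test_monte_carlo_oracle_converges(self, restraint):
        # sample-based estimate of the restrained configuration integral:
        # Z = prod_dof E[J(x)] * sqrt(2 pi kT / K), J = r^2, sin(theta), 1
        def mc_estimate(n, seed):
            trace = gen_restraint_timeseries(restraint, n, 298.0, seed=seed)
            z = 1.0
            for dof, k in restraint.force_constants.items():
                x = trace.values[dof]
                if dof == "r":
                    jac = np.mean(x**2)
                elif dof.startswith("theta"):
                    jac = np.mean(np.sin(np.radians(x)))
                else:
                    jac = 1.0
                z *= jac * math.sqrt(2 * math.pi * KT / k)
            return KT * math.log(8 * math.pi**2 * STANDARD_VOLUME / z)

        analytic = boresch_analytical(restraint)
        errors = [abs(mc_estimate(n, seed=8) - analytic) for n in (1_000, 10_000, 100_000)]
        assert errors[2] < errors[0]
        assert errors[2] < 0.02

    def test_rejects_degenerate_theta(self, restraint):
        with pytest.raises(ValueError):
            BoreschRestraint(
                r0=5.0, thetaA0=0.0, thetaB0=90.0, phiA0=0.0, phiB0=0.0, phiC0=0.0,
                k_r=10.0, k_thetaA=10.0, k_thetaB=10.0, k_phiA=10.0, k_phiB=10.0, k_phiC=10.0,
            )

    def test_rejects_nonpositive_temperature(self, restraint):
        with pytest.raises(ValueError):
            boresch_analytical(restraint, temperature=0.0)


def _trace_from_arrays(r, tA, tB, pA, pB, pC, cid=""):
    return RestraintTrace(
        values={"r": r, "thetaA": tA, "thetaB": tB, "phiA": pA, "phiB": pB, "phiC": pC},
        candidate_id=cid,
    )


class TestSelectRestraints:
    def test_single_candidate_and_nearest_frame(self, restraint):
        trace = gen_restraint_timeseries(restraint, 50, seed=1, candidate_id="only")
        chosen, frame = select_restraints([trace])
        assert chosen == "only"
        assert 0 <= frame < 50

    def test_stiffness_ratio_ordering(self, restraint):
        loose = gen_restraint_timeseries(restraint, 400, seed=2, candidate_id="loose")
        stiff_restraint = replace(
            restraint,
            k_r=100 * restraint.k_r, k_thetaA=100 * restraint.k_thetaA,
            k_thetaB=100 * restraint.k_thetaB, k_phiA=100 * restraint.k_phiA,
            k_phiB=100 * restraint.k_phiB, k_phiC=100 * restraint.k_phiC,
        )
        stiff = gen_restraint_timeseries(stiff_restraint, 400, seed=3, candidate_id="stiff")
        for normalize in (False, True):
            chosen, _ = select_restraints([loose, stiff], normalize=normalize)
            assert chosen == "stiff"

    def test_frame_exactly_at_mean_is_reference(self):
        # 3 frames; middle frame sits exactly at every per-dof mean
        mk = lambda lo, mid, hi: np.array([lo, mid, hi])
        trace = _trace_from_arrays(
            mk(4.0, 5.0, 6.0), mk(80.0, 90.0, 100.0), mk(85.0, 90.0, 95.0),
            mk(-10.0, 0.0, 10.0), mk(50.0, 60.0, 70.0), mk(-130.0, -120.0, -110.0),
            cid="c",
        )
        _, frame = select_restraints([trace])
        assert frame == 1

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_restraints([])


class TestDeriveForceConstants:
    def test_round_trip_recovers_k(self, restraint):
        n = 100_000
        trace = gen_restraint_timeseries(restraint, n, 298.0, seed=4)
        derived = derive_force_constants(trace, 298.0)
        # relative SE of a Gaussian sample variance is sqrt(2/n)
        tol = 3.0 * math.sqrt(2.0 / n)
        for dof, k_true in restraint.force_constants.items():
            k_est = derived.force_constants[dof]
            assert abs(k_est / k_true - 1.0) < tol

    def test_equilibria_recovered(self, restraint):
        trace = gen_restraint_timeseries(restraint, 100_000, 298.0, seed=5)
        derived = derive_force_constants(trace, 298.0)
        assert derived.r0 == pytest.approx(restraint.r0, abs=0.01)
        assert derived.phiC0 == pytest.approx(restraint.phiC0, abs=0.5)

    def test_constant_trace_rejected(self):
        const = np.full(10, 5.0)
        trace = _trace_from_arrays(const, const + 85, const + 85, const, const, const)
        with pytest.raises(ValueError):
            derive_force_constants(trace)

    def test_circular_mean_at_wrap_point(self, restraint):
        # dihedral straddling +/-180 with ~5 degree spread: the circular
        # mean must land near the wrap, not near 0 as a naive mean would
        wrap_restraint = replace(restraint, phiC0=179.0, k_phiC=80.0)
        trace = gen_restraint_timeseries(wrap_restraint, 20_000, seed=6)
        assert np.any(trace.values["phiC"] < -170) and np.any(trace.values["phiC"] > 170)
        derived = derive_force_constants(trace)
        dist_to_wrap = min(abs(derived.phiC0 - 179.0), abs(derived.phiC0 + 181.0))
        assert dist_to_wrap < 1.0
        naive = float(np.mean(trace.values["phiC"]))
        assert abs(naive) < 120.0  # the naive vector average collapses toward 0


class TestCycle:
    def test_all_zero(self):
        est = assemble_cycle(CycleLegs(0.0, 0.0, 0.0, 0.0))
        assert est.value == 0.0 and est.uncertainty == 0.0

    def test_arithmetic_contract(self):
        est = assemble_cycle(CycleLegs(2.0, 1.0, 3.0, -1.0))
        assert est.value == pytest.approx(1.0)

    def test_linearity_under_negation(self):
        legs = CycleLegs(2.0, 1.0, 3.0, -1.0, 0.1, 0.2, 0.3, 0.4)
        negated = CycleLegs(-2.0, -1.0, -3.0, 1.0, 0.1, 0.2, 0.3, 0.4)
        a, b = assemble_cycle(legs), assemble_cycle(negated)
        assert a.value == pytest.approx(-b.value)
        assert a.uncertainty == pytest.approx(b.uncertainty)

    def test_uncertainty_is_root_sum_square(self):
        est = assemble_cycle(CycleLegs(0, 0, 0, 0, 3.0, 4.0, 0.0, 0.0))
        assert est.uncertainty == pytest.approx(5.0)

    def test_cycle_and_aggregation_commute(self):
        # assembling per-replica then averaging equals averaging per-leg
        # then assembling (linearity of both operations)
        rng = np.random.default_rng(9)
        leg_sets = [CycleLegs(*rng.normal(0, 2, 4)) for _ in range(4)]
        assembled = [assemble_cycle(legs).value for legs in leg_sets]
        route_a = np.mean(assembled)
        mean_legs = CycleLegs(
            np.mean([l.dG_solv_elec_vdw for l in leg_sets]),
            np.mean([l.dG_solv_restr for l in leg_sets]),
            np.mean([l.dG_prot_elec_vdw for l in leg_sets]),
            np.mean([l.dG_prot_restr for l in leg_sets]),
        )
        route_b = assemble_cycle(mean_legs).value
        assert abs(route_a - route_b) < 1e-12


class TestAggregateReplicas:
    def test_2hp_row(self):
        rs = ReplicaSet([(-1.45, 0.46), (-1.39, 0.28), (-1.55, 0.40), (-1.21, 0.36)])
        agg = aggregate_replicas(rs)
        assert round(agg.value, 2) == -1.40
        assert round(agg.uncertainty, 2) == 0.76

    def test_26me_row(self):
        rs = ReplicaSet([(-5.21, 0.37), (-5.14, 0.28), (-4.53, 0.45), (-5.47, 0.39)])
        agg = aggregate_replicas(rs)
        assert round(agg.value, 2) == -5.09

    def test_single_replica_identity(self):
        agg = aggregate_replicas(ReplicaSet([(-3.2, 0.5)]))
        assert agg.value == -3.2 and agg.uncertainty == 0.5

    def test_negative_uncertainty_rejected(self):
        with pytest.raises(ValueError):
            ReplicaSet([(-1.0, -0.1)])
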