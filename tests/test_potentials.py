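"""Potential decomposition, forces, and analytic free-energy oracles."""

from fractions import Fraction

import numpy as np
import pytest

from ladybugs import (
    Configuration,
    DoubleWellModel,
    GaussianLigandModel,
    LambdaVector,
    PotentialModel,
    UnsupportedOracleError,
    analytic_end_state_dG,
    build_single_site_graph,
    build_multisite_graph,
    make_double_well_model,
    make_gaussian_ligand_model,
    state_energy_vector,
    total_gradient,
    total_potential,
)

F = Fraction


def lam(*sites):
    return LambdaVector(tuple(tuple(F(x).limit_denominator(1000) for x in s) for s in sites))


class UnitCrossModel(PotentialModel):
    """Two sites, constant unit cross term, zero internal terms."""

    def __init__(self):
        super().__init__(x0_dim=0, sub_dims=[[1, 1], [1, 1]])

    def internal_energy(self, y, c, x):
        return 0.0

    def internal_grad(self, y, c, x):
        return np.zeros_like(x)

    def cross_energy(self, y, c, z, d, xa, xb):
        return 1.0

    @property
    def has_cross(self):
        return True


class TestTotalPotential:
    def test_end_state_reduction(self, rng):
        m = make_gaussian_ligand_model([1.0, 3.0], offsets=[0.5, -0.2])
        conf = Configuration(m, rng.normal(size=m.n_dof))
        v = lam((1, 0))
        x0, x11 = conf.x0, conf.sub(0, 0)
        expected = (
            m.env_energy(x0)
            + m.internal_energy(0, 0, x11)
            + m.restraint_energy(0, 0, x11)
            + m.restraint_energy(0, 1, conf.sub(0, 1))
        )
        assert total_potential(conf, v, m) == pytest.approx(expected, rel=1e-12)

    def test_zero_weight_substituent_contributes_nothing(self, rng):
        m = make_gaussian_ligand_model([1.0, 3.0])
        conf = Configuration(m, rng.normal(size=m.n_dof))
        v = lam((1, 0))
        e1 = total_potential(conf, v, m)
        # move the decoupled substituent: only its restraint may change
        conf2 = conf.copy()
        conf2.sub(0, 1)[:] = 7.7
        e2 = total_potential(conf2, v, m)
        d_restraint = m.restraint_energy(0, 1, conf2.sub(0, 1)) - m.restraint_energy(
            0, 1, conf.sub(0, 1)
        )
        assert e2 - e1 == pytest.approx(d_restraint, rel=1e-12)

    def test_unit_cross_term_quarter_weight(self):
        m = UnitCrossModel()
        conf = Configuration(m)
        v = lam((0.5, 0.5), (0.5, 0.5))
        # 4 cross-site substituent pairs x 0.25 x unit energy
        assert total_potential(conf, v, m) == pytest.approx(1.0)

    def test_invalid_state_rejected(self):
        m = make_gaussian_ligand_model([1.0, 1.0])
        with pytest.raises(ValueError):
            total_potential(Configuration(m), lam((0.6, 0.6)), m)

    def test_linearity_in_each_lambda(self, rng):
        """V is affine along any interpolation between two states of one edge."""
        m = make_gaussian_ligand_model([1.0, 4.0], offsets=[0.3, -0.3])
        conf = Configuration(m, rng.normal(size=m.n_dof))
        e0 = total_potential(conf, lam((1, 0)), m)
        e1 = total_potential(conf, lam((0, 1)), m)
        for t in (0.25, 0.5, 0.75):
            et = total_potential(conf, lam((1 - t, t)), m)
            assert et == pytest.approx((1 - t) * e0 + t * e1, rel=1e-10)

    def test_bilinear_across_sites(self):
        m = UnitCrossModel()
        conf = Configuration(m)

        def V(a, b):
            return total_potential(conf, lam((a, 1 - a), (b, 1 - b)), m)

        # mixed second difference of a bilinear form is constant
        h = 0.25
        d2 = V(0.5 + h, 0.5 + h) - V(0.5 + h, 0.5 - h) - V(0.5 - h, 0.5 + h) + V(0.5 - h, 0.5 - h)
        d2b = V(0.75 + 0.1, 0.5 + h) - V(0.75 + 0.1, 0.5 - h) - V(0.75 - 0.1, 0.5 + h) + V(
            0.75 - 0.1, 0.5 - h
        )
        assert d2 == pytest.approx(d2b * (2 * h) / (2 * 0.1), abs=1e-10)


class TestStateEnergyVector:
    def test_single_state_graph(self, rng):
        g = build_single_site_graph(1, 0.1)
        m = make_gaussian_ligand_model([2.0])
        conf = Configuration(m, rng.normal(size=m.n_dof))
        u = state_energy_vector(conf, g, m, include_env=True)
        assert u.shape == (1,)
        assert u[0] == pytest.approx(total_potential(conf, g.states[0], m))

    def test_env_constant_cancels(self, rng):
        g = build_single_site_graph(2, 0.5)
        m1 = make_gaussian_ligand_model([1.0, 2.0], env_spring=1.0)
        m2 = make_gaussian_ligand_model([1.0, 2.0], env_spring=5.0)
        x = rng.normal(size=m1.n_dof)
        u1 = state_energy_vector(Configuration(m1, x), g, m1, include_env=True)
        u2 = state_energy_vector(Configuration(m2, x), g, m2, include_env=True)
        assert np.allclose(u1 - u1.min(), u2 - u2.min())

    def test_default_omits_baseline(self, rng):
        g = build_single_site_graph(2, 0.5)
        m = make_gaussian_ligand_model([1.0, 2.0])
        conf = Configuration(m, rng.normal(size=m.n_dof))
        u = state_energy_vector(conf, g, m)
        full = np.array([total_potential(conf, s, m) for s in g.states])
        assert np.allclose(full - u, m.baseline_energy(conf))

    def test_symmetric_pair_symmetry(self):
        g = build_single_site_graph(2, 0.25)
        m = make_gaussian_ligand_model([2.0, 2.0])
        conf = m.initial_configuration()  # both substituents at the shared minimum
        u = state_energy_vector(conf, g, m)
        swapped = {tuple(s.as_array()): ui for s, ui in zip(g.states, u)}
        for s, ui in zip(g.states, u):
            a, b = s.as_array()
            assert ui == pytest.approx(swapped[(b, a)], abs=1e-12)


@pytest.mark.parametrize(
    "model",
    [
        make_gaussian_ligand_model([1.0, 4.0], offsets=[0.5, -0.5]),
        make_gaussian_ligand_model([[1.0, 2.0], [3.0, 0.5]], coupling=0.7),
        make_gaussian_ligand_model([1.0, 2.0], cross_spring=None, env_spring=2.0),
        make_double_well_model([2.0, 1.0], [1.0, 1.5], tilts=[0.2, -0.1]),
        UnitCrossModel(),
    ],
    ids=["gaussian", "gaussian-coupled", "gaussian-env", "double-well", "cross"],
)
def test_forces_match_numerical_gradient(model, rng):
    counts = model.substituent_counts
    if len(counts) == 1:
        g = build_single_site_graph(counts[0], 0.25)
    else:
        g = build_multisite_graph(list(counts), 0.25)
    v = g.states[rng.integers(len(g))]
    x = rng.normal(size=model.n_dof)
    grad = total_gradient(Configuration(model, x), v, model)
    h = 1e-6
    for i in range(model.n_dof):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        num = (
            total_potential(Configuration(model, xp), v, model)
            - total_potential(Configuration(model, xm), v, model)
        ) / (2 * h)
        assert grad[i] == pytest.approx(num, rel=1e-5, abs=1e-7)


class TestGaussianOracle:
    def test_identical_wells_zero(self):
        m = make_gaussian_ligand_model([1.5, 1.5])
        g = build_single_site_graph(2, 0.1)
        _, dg, _ = analytic_end_state_dG(m, g, 1.0)
        assert np.allclose(dg, 0.0)

    def test_k14_half_log4_vs_quadrature(self):
        m = make_gaussian_ligand_model([1.0, 4.0])
        g = build_single_site_graph(2, 0.1)
        _, dg, _ = analytic_end_state_dG(m, g, 1.0)
        assert dg[1] == pytest.approx(0.5 * np.log(4.0), rel=1e-12)
        # independent quadrature of the configurational integrals
        x = np.linspace(-12, 12, 20001)
        G = [-np.log(np.trapezoid(np.exp(-0.5 * k * x**2), x)) for k in (1.0, 4.0)]
        assert dg[1] == pytest.approx(G[1] - G[0], abs=1e-9)

    def test_cycle_closure_three_ligands(self):
        m = make_gaussian_ligand_model([1.0, 2.0, 4.0])
        g = build_single_site_graph(3, 0.1)
        _, dg, _ = analytic_end_state_dG(m, g, 1.0)
        d12, d23, d31 = dg[1] - dg[0], dg[2] - dg[1], dg[0] - dg[2]
        assert d12 + d23 + d31 == pytest.approx(0.0, abs=1e-12)
        assert d12 == pytest.approx(0.5 * np.log(2.0), rel=1e-12)

    def test_coupled_model_hessian_route_vs_grid(self):
        """With an environment coupling spring the Hessian-determinant route
        must agree with direct 2-D numerical integration."""
        m = make_gaussian_ligand_model([1.0, 4.0], offsets=[0.4, -0.4], coupling=0.8)
        g = build_single_site_graph(2, 0.1)
        _, dg, _ = analytic_end_state_dG(m, g, 1.0)

        x = np.linspace(-8, 8, 241)
        X0, X1, X2 = np.meshgrid(x, x, x, indexing="ij", sparse=True)

        def Z(active):
            U = 0.5 * m.env_spring * X0**2
            for c, Xc in ((0, X1), (1, X2)):
                U = U + 0.5 * m.restraint_k * (Xc - m.offsets[0][c]) ** 2
                if c == active:
                    U = U + 0.5 * (m.springs[0][c] - m.restraint_k) * (
                        Xc - m.offsets[0][c]
                    ) ** 2 + 0.5 * m.coupling * (X0 - Xc) ** 2
            return np.trapezoid(np.trapezoid(np.trapezoid(np.exp(-U), x), x), x)

        ref = -np.log(Z(1)) + np.log(Z(0))
        assert dg[1] == pytest.approx(ref, abs=2e-3)

    def test_bad_springs_rejected(self):
        with pytest.raises(ValueError):
            make_gaussian_ligand_model([1.0, -2.0])
        with pytest.raises(ValueError):
            make_gaussian_ligand_model([1.0, 2.0], restraint_k=0.0)


class TestDoubleWell:
    def test_symmetric_wells_equal_populations(self):
        m = make_double_well_model(3.0, 1.0, n_substituents=2)
        left, right = m.well_populations(0, kT=1.0)
        assert left == pytest.approx(0.5, abs=1e-9)
        assert right == pytest.approx(0.5, abs=1e-9)

    def test_tilted_population_ratio(self):
        delta = 0.8
        m = DoubleWellModel([6.0], [1.3], tilts=[delta / (2 * 1.3)])
        left, right = m.well_populations(0, kT=1.0)
        # deep-well limit: P(+a)/P(-a) -> exp(-beta * energy offset)
        # quadrature is the ground truth; the Boltzmann ratio holds to ~10%
        assert right / left == pytest.approx(np.exp(-delta), rel=0.15)

    def test_zero_barrier_quadrature_matches_grid(self):
        m = make_double_well_model(0.0, 1.0, n_substituents=2)
        g = build_single_site_graph(2, 0.5)
        _, dg, err = analytic_end_state_dG(m, g, 1.0)
        x = np.linspace(-15, 15, 40001)
        G = [-np.log(np.trapezoid(np.exp(-m.well_potential(c, x)), x)) for c in (0, 1)]
        assert dg[1] == pytest.approx(G[1] - G[0], abs=1e-8)

    def test_cycle_closure(self):
        m = make_double_well_model([2.0, 3.0, 1.5], [1.0, 1.2, 0.8], tilts=[0.0, 0.4, -0.2])
        g = build_single_site_graph(3, 0.1)
        _, dg, err = analytic_end_state_dG(m, g, 1.0)
        assert (dg[1] - dg[0]) + (dg[2] - dg[1]) + (dg[0] - dg[2]) == pytest.approx(0, abs=1e-10)
        assert np.all(err < 1e-6)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            make_double_well_model(-1.0, 1.0, n_substituents=2)
        with pytest.raises(ValueError):
            make_double_well_model(1.0, 0.0, n_substituents=2)


def test_unsupported_oracle():
    m = UnitCrossModel()
    g = build_multisite_graph([2, 2], 0.5)
    with pytest.raises(UnsupportedOracleError):
        analytic_end_state_dG(m, g, 1.0)
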