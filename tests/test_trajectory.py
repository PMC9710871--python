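import numpy as np
import pytest
from scipy.linalg import expm

import velonode as vn
from velonode import AnalyticField, IntegratorSpec


def const_field(c):
    c = np.asarray(c, dtype=float)
    return AnalyticField(lambda x: c, len(c))


def linear_field(A):
    A = np.asarray(A, dtype=float)
    return AnalyticField(lambda x: A @ x, A.shape[0])


# stable rotation-contraction system used by several solver tests
A_STABLE = np.array([[-0.3, 0.4, 0.0],
                     [-0.4, -0.3, 0.1],
                     [0.0, -0.1, -0.2]])


class TestEuler:
    def test_constant_field_closed_form(self):
        """Euler with scale 1: x0, x0+c, x0+2c, x0+3c."""
        c = np.array([0.5, -1.0])
        spec = IntegratorSpec(method="euler", velocity_scale=1.0, n_steps=3,
                              intermediate_steps=1, clip_nonnegative=False)
        traj = vn.integrate(const_field(c), np.array([1.0, 5.0]), spec)
        expected = np.array([[1, 5], [1.5, 4], [2, 3], [2.5, 2]])
        np.testing.assert_allclose(traj.states, expected, atol=1e-12)
        assert np.all(np.diff(traj.times) > 0)

    def test_zero_field_stays_put(self):
        spec = IntegratorSpec(n_steps=4)
        x0 = np.array([1.0, 2.0])
        traj = vn.integrate(const_field([0.0, 0.0]), x0, spec)
        assert np.all(traj.states == x0)

    def test_scale_equivariance(self):
        """Doubling velocity_scale while halving step_time leaves Euler
        trajectories unchanged."""
        rng = np.random.default_rng(0)
        A = -0.3 * np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        x0 = rng.uniform(0.5, 1.5, 3)
        s1 = IntegratorSpec(velocity_scale=0.5, step_time=1.0, n_steps=6,
                            clip_nonnegative=False)
        s2 = IntegratorSpec(velocity_scale=1.0, step_time=0.5, n_steps=6,
                            clip_nonnegative=False)
        t1 = vn.integrate(linear_field(A), x0, s1)
        t2 = vn.integrate(linear_field(A), x0, s2)
        np.testing.assert_allclose(t1.states, t2.states, rtol=1e-12)

    def test_nonnegativity_clipping(self):
        spec = IntegratorSpec(method="euler", velocity_scale=1.0, n_steps=3,
                              intermediate_steps=1, clip_nonnegative=True)
        traj = vn.integrate(const_field([-1.0, 0.0]), np.array([1.5, 1.0]),
                            spec)
        assert (traj.states >= 0).all()


class TestAdaptiveSolvers:
    def test_dop853_matches_matrix_exponential(self):
        """DOP853 on f(x)=Ax agrees with expm(A t) x0 to 1e-4 relative."""
        x0 = np.array([1.0, 0.5, 2.0])
        spec = IntegratorSpec(method="dop853", velocity_scale=1.0, n_steps=4,
                              intermediate_steps=2, clip_nonnegative=False,
                              rtol=1e-10, atol=1e-12)
        traj = vn.integrate(linear_field(A_STABLE), x0, spec)
        t_total = 4 * 2 * 1.0
        expected = expm(A_STABLE * t_total) @ x0
        rel = np.linalg.norm(traj.states[-1] - expected) / np.linalg.norm(expected)
        assert rel < 1e-4

    def test_adaptive_solvers_converge_to_fine_euler(self):
        """RK23 and DOP853 trajectories approach the Euler trajectory as the
        Euler step count grows, on the linear-field stub."""
        x0 = np.array([1.0, 0.5, 2.0])
        ref = {}
        for method in ("rk23", "dop853"):
            spec = IntegratorSpec(method=method, velocity_scale=1.0,
                                  n_steps=2, intermediate_steps=1,
                                  clip_nonnegative=False,
                                  rtol=1e-10, atol=1e-12)
            ref[method] = vn.integrate(linear_field(A_STABLE), x0, spec).states[-1]
        errs = []
        for m in (2, 8, 32, 128):
            spec = IntegratorSpec(method="euler", velocity_scale=1.0,
                                  n_steps=2, intermediate_steps=m,
                                  step_time=1.0 / m, clip_nonnegative=False)
            end = vn.integrate(linear_field(A_STABLE), x0, spec).states[-1]
            errs.append(np.linalg.norm(end - ref["dop853"]))
        assert errs[-1] < errs[0] / 10
        assert errs[-1] < 1e-2
        assert np.linalg.norm(ref["rk23"] - ref["dop853"]) < 1e-3


class TestRetrograde:
    def test_constant_field_reverses(self):
        c = np.array([0.5, 0.25])
        spec = IntegratorSpec(method="euler", velocity_scale=1.0, n_steps=2,
                              intermediate_steps=1, clip_nonnegative=False)
        traj = vn.integrate_retrograde(const_field(c), np.array([2.0, 2.0]),
                                       spec)
        expected = np.array([[2, 2], [1.5, 1.75], [1.0, 1.5]])
        np.testing.assert_allclose(traj.states, expected, atol=1e-12)
        assert traj.direction == "retrograde"
        assert np.all(np.diff(traj.times) < 0)

    def test_zero_field_round_trip_exact(self):
        spec = IntegratorSpec(n_steps=3)
        x0 = np.array([1.0, 2.0])
        fwd = vn.integrate(const_field([0.0, 0.0]), x0, spec)
        back = vn.integrate_retrograde(const_field([0.0, 0.0]),
                                       fwd.states[-1], spec)
        np.testing.assert_array_equal(back.states[-1], x0)

    def test_euler_round_trip_error_shrinks_with_step(self):
        """Forward-then-retrograde Euler returns near x0, with the error
        shrinking as the step size decreases (linear stable field, no
        anchoring, no clipping)."""
        x0 = np.array([1.0, 0.5, 2.0])
        errs = []
        for m in (1, 4, 16):
            spec = IntegratorSpec(method="euler", velocity_scale=1.0,
                                  n_steps=3, intermediate_steps=m,
                                  step_time=0.5 / m, clip_nonnegative=False)
            f = linear_field(A_STABLE)
            fwd = vn.integrate(f, x0, spec)
            back = vn.integrate_retrograde(f, fwd.states[-1], spec)
            errs.append(np.linalg.norm(back.states[-1] - x0))
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < 1e-2


class TestStepBudget:
    def test_single_gene_arithmetic(self):
        """SD=1, mean |v|=1: the ±2 SD range is 4·SD, so 4 steps."""
        expr = np.array([[0.0], [2.0]])  # SD = 1 (population)
        vel = np.array([[1.0], [-1.0]])  # mean |v| = 1
        ds = vn.Dataset(expr, vel, ["g"], ["A", "A"])
        budget = vn.estimate_step_budget(ds, 95)
        np.testing.assert_allclose(budget.per_gene_step_counts, [4.0])
        assert budget.max_steps == 4

    def test_percentile_matches_numpy_oracle(self):
        expr = np.array([[0.0, 0.0], [2.0, 50.0]])  # SDs 1, 25
        vel = np.array([[1.0, 1.0], [1.0, 1.0]])
        ds = vn.Dataset(expr, vel, ["a", "b"], ["A", "A"])
        budget = vn.estimate_step_budget(ds, 95)
        counts = np.array([4.0, 100.0])
        assert budget.max_steps == int(np.ceil(np.percentile(counts, 95)))

    def test_velocity_homogeneity(self, toggle_dataset):
        """Scaling every velocity ×2 halves the budget (up to rounding)."""
        ds = toggle_dataset
        fast = vn.Dataset(ds.expression, ds.velocity * 2.0, ds.gene_names,
                          ds.cell_labels)
        b1 = vn.estimate_step_budget(ds, 95)
        b2 = vn.estimate_step_budget(fast, 95)
        assert abs(b2.max_steps - b1.max_steps / 2) <= 1

    def test_zero_velocity_genes_excluded(self):
        expr = np.array([[0.0, 1.0], [2.0, 1.0], [1.0, 1.0]])
        vel = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        ds = vn.Dataset(expr, vel, ["a", "b"], ["A"] * 3)
        budget = vn.estimate_step_budget(ds, 95)
        assert budget.excluded_genes == ["b"]
        with pytest.raises(ValueError, match="zero mean"):
            vn.estimate_step_budget(
                vn.Dataset(expr, np.zeros_like(vel), ["a", "b"], ["A"] * 3),
                95,
            )


class TestReferenceProjection:
    def test_self_is_own_nearest_neighbor(self, toggle_dataset):
        proj = vn.fit_reference_projection(toggle_dataset, 10)
        nn = proj.nearest(toggle_dataset.expression[:5], 1)
        np.testing.assert_array_equal(nn[:, 0], np.arange(5))

    def test_distances_preserved_on_low_rank_data(self):
        """If all variance lies in pca_dims dimensions, pairwise distances
        survive projection."""
        rng = np.random.default_rng(4)
        basis = rng.standard_normal((3, 10))
        coords = rng.standard_normal((50, 3))
        X = coords @ basis + 15.0   # shift keeps entries positive, rank 3
        ds = vn.Dataset(X, np.zeros_like(X), [f"g{i}" for i in range(10)],
                        ["A"] * 50)
        proj = vn.fit_reference_projection(ds, 3)
        Y = proj.transform(X)
        dX = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        dY = np.linalg.norm(Y[:, None] - Y[None, :], axis=-1)
        np.testing.assert_allclose(dX, dY, atol=1e-8)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (30, 5))
        ds = vn.Dataset(X, np.zeros_like(X), [f"g{i}" for i in range(5)],
                        ["A"] * 30)
        proj = vn.fit_reference_projection(ds, 5)
        recon = proj.pca.inverse_transform(proj.transform(X))
        np.testing.assert_allclose(recon, X, atol=1e-10)

    def test_rank_deficient_reduces_with_warning(self):
        X = np.tile(np.linspace(0, 1, 40)[:, None], (1, 6))  # rank 1
        ds = vn.Dataset(X, np.zeros_like(X), [f"g{i}" for i in range(6)],
                        ["A"] * 40)
        with pytest.warns(UserWarning, match="reduced"):
            vn.fit_reference_projection(ds, 39)


class TestAnchoring:
    def test_anchored_state_is_mean_of_neighbors(self, toggle_dataset,
                                                 trained_field):
        """Every anchored state is the mean of its anchor_k reference cells
        (hence inside their convex hull)."""
        ds = toggle_dataset
        spec = IntegratorSpec(anchor=True, anchor_k=5, n_steps=3,
                              pca_dims=10)
        traj = vn.integrate(trained_field, ds.expression[0], spec,
                            reference=ds)
        assert len(traj.anchor_events) == 3
        for step, nn in traj.anchor_events:
            np.testing.assert_allclose(
                traj.states[step], ds.expression[list(nn)].mean(axis=0),
                rtol=1e-12
            )

    def test_anchor_without_reference_rejected(self, trained_field):
        spec = IntegratorSpec(anchor=True, n_steps=2)
        with pytest.raises(ValueError, match="reference"):
            vn.integrate(trained_field, np.ones(20), spec)


def test_attractor_capture_on_bistable_system(toggle_system):
    """Under the true toggle-switch field, ≥90% of trajectories started on
    the sampled manifold terminate within a small radius of an attractor."""
    sys_ = toggle_system
    ds = vn.sample_cells(sys_, 200, seed=6, dropout_rate=0.0,
                         count_noise_scale=0.0)
    f = AnalyticField(sys_.rhs, sys_.n_genes)
    spec = IntegratorSpec(velocity_scale=1.0, n_steps=12,
                          intermediate_steps=5, step_time=0.5)
    states, _, _, _ = vn.integrate_batch(f, ds.expression, spec)
    finals = states[-1][:, :2]
    d = np.minimum(
        np.linalg.norm(finals - sys_.attractors[0][:2], axis=1),
        np.linalg.norm(finals - sys_.attractors[1][:2], axis=1),
    )
    assert (d < 0.25).mean() >= 0.9
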