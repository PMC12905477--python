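import numpy as np
import pytest

from hemovasc.network import BiophysicalParams, physiological_parameter_space
from hemovasc.pinn import (
    CollocationSet,
    NetworkEmulator,
    TrainConfig,
    conv_matrix,
    make_collocation,
)

SPACE2 = physiological_parameter_space(1, include=("f2_large", "f3_large[0]"))


class _FakeDataset:
    """Minimal stand-in exposing the flat_batch interface (synthetic)."""

    def __init__(self, t, Theta, q, p):
        self._data = (t, Theta, q, p)

    def flat_batch(self, vid):
        return self._data


SPACE3 = physiological_parameter_space(
    1, include=("f2_large", "f3_large[0]", "f3_small[0]")
)


@pytest.fixture(scope="module")
def emu_single(single_vessel, base_params, inflow_gp):
    return NetworkEmulator(
        single_vessel, SPACE2, base_params, inflow_gp, width=8, depth=2,
        seed=0,
    )


@pytest.fixture(scope="module")
def emu_bif(bifurcation3, base_params, inflow_gp):
    emu = NetworkEmulator(
        bifurcation3, SPACE3, base_params, inflow_gp, width=8, depth=2,
        seed=1,
    )
    emu.set_normalisation(
        {
            vid: {"q_mean": 25.0, "q_std": 40.0, "p_mean": 1.1e5,
                  "p_std": 2e4}
            for vid in emu.nets
        }
    )
    return emu


def mid_theta(space, n=1):
    return np.broadcast_to(space.denormalise(np.full(space.dim, 0.5)),
                           (n, space.dim))


class TestEmbedding:
    def test_time_zero_features(self, emu_single):
        X = emu_single.embed(1, 0.0, 0.0, mid_theta(SPACE2))
        assert X[0, 1] == pytest.approx(1.0)
        assert X[0, 2] == pytest.approx(0.0)

    def test_quarter_period_features(self, emu_single):
        X = emu_single.embed(1, 0.0, 0.25, mid_theta(SPACE2))
        assert X[0, 1] == pytest.approx(0.0, abs=1e-15)
        assert X[0, 2] == pytest.approx(1.0)

    def test_integer_period_shifts_identical(self, emu_single):
        th = mid_theta(SPACE2)
        a = emu_single.embed(1, 2.0, 0.37, th)
        b = emu_single.embed(1, 2.0, 0.37 + 3.0, th)
        assert np.allclose(a, b, atol=1e-12)

    def test_out_of_bounds_theta_rejected_or_clipped(self, emu_single):
        bad = SPACE2.upper * 1.5
        with pytest.raises(ValueError):
            emu_single.embed(1, 0.0, 0.0, bad[None])
        X = emu_single.embed(1, 0.0, 0.0, bad[None], clip=True)
        assert np.all(X[:, 3:] <= 1.0)


class TestStructuralExactness:
    def test_untrained_inflow_exact_at_inlet(self, emu_single, inflow_gp):
        t = np.linspace(0, 1, 33)
        q, _ = emu_single.predict(1, 0.0, t, mid_theta(SPACE2, 33))
        assert np.max(np.abs(q - inflow_gp.qin(t))) < 1e-12 * np.max(
            np.abs(q)
        )

    def test_outlet_is_pure_network_output(self, emu_single):
        c = emu_single.ctx[1]
        t = np.linspace(0, 1, 9)
        th = mid_theta(SPACE2, 9)
        q, _ = emu_single.predict(1, c.L, t, th)
        X = emu_single.embed(1, np.full(9, c.L), t, th)
        Y, _, _ = emu_single.nets[1].forward(X)
        assert np.allclose(q, c.q_mean + c.q_std * Y[:, 0], atol=1e-12)

    def test_untrained_periodicity_exact(self, emu_single):
        t = np.linspace(0, 1, 17)
        th = mid_theta(SPACE2, 17)
        q1, p1 = emu_single.predict(1, 3.0, t, th)
        q2, p2 = emu_single.predict(1, 3.0, t + 5.0, th)
        assert np.max(np.abs(q1 - q2)) < 1e-9
        assert np.max(np.abs(p1 - p2)) < 1e-9

    def test_reference_pressure_gives_unstressed_area(
        self, single_vessel, base_params, inflow_gp
    ):
        emu = NetworkEmulator(
            single_vessel, SPACE2, base_params, inflow_gp, width=8, depth=2
        )
        # force the pressure head to output exactly p0
        emu.nets[1].params["Wout"][:] = 0.0
        _, p, A = emu.predict(
            1, 2.0, np.array([0.1]), mid_theta(SPACE2), with_area=True
        )
        assert p[0] == pytest.approx(base_params.p0)
        assert A[0] == pytest.approx(single_vessel.vessels[1].A0, rel=1e-12)


@pytest.fixture(scope="module")
def coll_bif(emu_bif):
    return make_collocation(
        emu_bif, n_pde=64, n_bif=32, n_imp=3, m_imp=16, seed=0
    )


class TestLossOracles:
    def test_bifurcation_loss_matches_naive_loop(self, emu_bif, rng):
        t = rng.uniform(0, 1, 11)
        Theta = SPACE3.denormalise(rng.uniform(0.1, 0.9, (11, 3)))
        val, _ = emu_bif.loss_bifurcation(t, Theta, want_grads=False)
        # naive per-point loop
        total = 0.0
        cp = emu_bif.ctx[1]
        for i in range(11):
            th = Theta[i : i + 1]
            qp, pp = emu_bif.predict(1, cp.L, t[i : i + 1], th)
            q1, p1 = emu_bif.predict(2, 0.0, t[i : i + 1], th)
            q2, p2 = emu_bif.predict(3, 0.0, t[i : i + 1], th)
            total += float(((qp - q1 - q2) / cp.q_std)[0] ** 2)
            total += float(((pp - p1) / cp.p_std)[0] ** 2)
            total += float(((pp - p2) / cp.p_std)[0] ** 2)
        assert val == pytest.approx(total / 33, rel=1e-12)

    def test_bifurcation_loss_zero_for_consistent_outputs(
        self, bifurcation3, base_params, inflow_gp
    ):
        emu = NetworkEmulator(
            bifurcation3, SPACE3, base_params, inflow_gp, width=8, depth=2
        )
        for vid in emu.nets:
            emu.nets[vid].params["Wout"][:] = 0.0  # all outputs 0
        # zero flow splits as 0 = 0 + 0 with equal (zero) pressures, except
        # the root mixing adds q_in at the parent outlet (cos term vanishes
        # at x=L), so residuals are exactly zero
        t = np.linspace(0, 1, 7)
        val, _ = emu.loss_bifurcation(
            t, mid_theta(SPACE3, 7), want_grads=False
        )
        assert val < 1e-24

    def test_data_loss_matches_hand_mse(self, emu_bif, rng):
        t = rng.uniform(0, 1, 10)
        Theta = SPACE3.denormalise(rng.uniform(0.1, 0.9, (10, 3)))
        q_sim = rng.normal(30, 5, 10)
        p_sim = rng.normal(1e5, 1e4, 10)
        batch = {2: (t, Theta, q_sim, p_sim)}
        val, _ = emu_bif.loss_data(batch, want_grads=False)
        c = emu_bif.ctx[2]
        qp, pp = emu_bif.predict(2, c.L / 2, t, Theta)
        hand = (
            ((qp - q_sim) / c.q_std) ** 2 + ((pp - p_sim) / c.p_std) ** 2
        ).sum() / 10
        assert val == pytest.approx(float(hand), rel=1e-12)

    def test_outflow_loss_matches_time_domain_convolution(
        self, emu_bif, coll_bif
    ):
        val, _ = emu_bif.loss_outflow(coll_bif, want_grads=False)
        # recompute with explicit O(m^2) circular convolution
        tj = coll_bif.imp_times
        m = tj.size
        total, count = 0.0, 0
        for vid, mats in coll_bif.imp_conv.items():
            c = emu_bif.ctx[vid]
            for i, th in enumerate(coll_bif.imp_theta):
                Theta = np.broadcast_to(th, (m, 3))
                q, p = emu_bif.predict(vid, c.L, tj, Theta)
                C = mats[i]
                pc = np.array(
                    [sum(C[a, b] * q[b] for b in range(m)) for a in range(m)]
                )
                total += (((p - pc) / c.p_std) ** 2).sum()
                count += m
        assert val == pytest.approx(total / count, rel=1e-10)

    def test_pde_mass_residual_zero_for_manufactured_solution(
        self, single_vessel, base_params, inflow_gp
    ):
        # constant outputs: A independent of t, q independent of x at the
        # outlet half of the vessel -> evaluate away from the inflow mixing
        emu = NetworkEmulator(
            single_vessel, SPACE2, base_params, inflow_gp, width=8, depth=2
        )
        emu.nets[1].params["Wout"][:] = 0.0
        x = np.full(16, 4.0)
        t = np.linspace(0, 1, 16)
        th = mid_theta(SPACE2, 16)
        # constant q_hat and p_hat: residuals reduce to the inflow-mixing
        # terms; at the pure-network limit sin/cos terms remain, so instead
        # verify with the mixing bypassed via a daughter-type vessel
        emu.ctx[1].is_root = False
        val, _ = emu.loss_pde({1: (x, t, th)}, want_grads=False)
        # q=const in x and t, p=const -> all derivatives vanish except the
        # friction term  Cf q / sqrt(A) with q = q_mean = 0
        assert val < 1e-20
        emu.ctx[1].is_root = True

    def test_pde_residual_matches_finite_differences(self, emu_bif, rng):
        """Exact input derivatives agree with central differences of
        predict at interior points."""
        c = emu_bif.ctx[2]
        x = rng.uniform(0.5, c.L - 0.5, 20)
        t = rng.uniform(0, 1, 20)
        Theta = SPACE3.denormalise(rng.uniform(0.2, 0.8, (20, 3)))
        X = emu_bif.embed(2, x, t, Theta)
        S = emu_bif._xt_tangents(2, t, 20)
        Y, TY, _ = emu_bif.nets[2].forward(X, S)
        h = 1e-5
        for k, dx_dt in ((0, "x"), (1, "t")):
            if dx_dt == "x":
                Xp = emu_bif.embed(2, x + h, t, Theta)
                Xm = emu_bif.embed(2, x - h, t, Theta)
            else:
                Xp = emu_bif.embed(2, x, t + h, Theta)
                Xm = emu_bif.embed(2, x, t - h, Theta)
            Yp, _, _ = emu_bif.nets[2].forward(Xp)
            Ym, _, _ = emu_bif.nets[2].forward(Xm)
            fd = (Yp - Ym) / (2 * h)
            assert np.allclose(fd, TY[k], rtol=1e-4, atol=1e-8)

    @pytest.mark.parametrize("loss", ["pde", "bif", "imp", "sim"])
    def test_loss_gradients_match_finite_differences(
        self, emu_bif, coll_bif, loss
    ):
        rng = np.random.default_rng(
            {"pde": 11, "bif": 22, "imp": 33, "sim": 44}[loss]
        )
        t = rng.uniform(0, 1, 6)
        Theta = SPACE3.denormalise(rng.uniform(0.2, 0.8, (6, 3)))
        if loss == "pde":
            x = rng.uniform(0, emu_bif.ctx[2].L, 6)
            fn = lambda: emu_bif.loss_pde({2: (x, t, Theta)})
            vid = 2
        elif loss == "bif":
            fn = lambda: emu_bif.loss_bifurcation(t, Theta)
            vid = 1
        elif loss == "imp":
            fn = lambda: emu_bif.loss_outflow(coll_bif)
            vid = 3
        else:
            q_sim = rng.normal(30, 5, 6)
            p_sim = rng.normal(1e5, 1e4, 6)
            fn = lambda: emu_bif.loss_data({2: (t, Theta, q_sim, p_sim)})
            vid = 2
        val, grads = fn()
        net = emu_bif.nets[vid]
        gflat = np.concatenate(
            [np.asarray(grads[vid][k]).ravel() for k in net.param_names()]
        )
        flat = net.get_flat()
        for i in rng.choice(flat.size, 8, replace=False):
            v = flat.copy()
            v[i] += 1e-6
            net.set_flat(v)
            fp = fn()[0]
            v[i] -= 2e-6
            net.set_flat(v)
            fm = fn()[0]
            fd = (fp - fm) / 2e-6
            assert fd == pytest.approx(gflat[i], rel=2e-4, abs=1e-9)
        net.set_flat(flat)


class TestWeighting:
    def test_equal_norms_give_lambda_four(self, emu_bif):
        emu_bif.loss_weights = {k: 1.0 for k in emu_bif.loss_weights}
        emu_bif.update_weights(
            {"bif": 2.0, "pde": 2.0, "imp": 2.0, "sim": 2.0}, gamma=0.0
        )
        assert all(
            v == pytest.approx(4.0) for v in emu_bif.loss_weights.values()
        )

    def test_moving_average_blend(self, emu_bif):
        emu_bif.loss_weights = {k: 1.0 for k in emu_bif.loss_weights}
        emu_bif.update_weights(
            {"bif": 2.0, "pde": 2.0, "imp": 2.0, "sim": 2.0}, gamma=0.9
        )
        # gamma*1 + (1-gamma)*4 = 1.3
        assert all(
            v == pytest.approx(1.3) for v in emu_bif.loss_weights.values()
        )

    def test_unequal_norms_substitution(self, emu_bif):
        emu_bif.loss_weights = {k: 0.0 for k in emu_bif.loss_weights}
        emu_bif.update_weights(
            {"bif": 2.0, "pde": 1.0, "imp": 1.0, "sim": 1.0}, gamma=0.0
        )
        assert emu_bif.loss_weights["bif"] == pytest.approx(2.5)
        assert emu_bif.loss_weights["pde"] == pytest.approx(5.0)

    def test_zero_norm_component_skipped(self, emu_bif):
        emu_bif.loss_weights = {k: 1.0 for k in emu_bif.loss_weights}
        emu_bif.update_weights({"bif": 0.0, "pde": 1.0}, gamma=0.0)
        assert emu_bif.loss_weights["bif"] == 1.0


class TestTraining:
    def test_short_training_reduces_loss(
        self, single_vessel, base_params, inflow_gp
    ):
        emu = NetworkEmulator(
            single_vessel, SPACE2, base_params, inflow_gp, width=8, depth=2,
            seed=3,
        )
        emu.set_normalisation(
            {1: {"q_mean": 30.0, "q_std": 50.0, "p_mean": 1.1e5,
                 "p_std": 2e4}}
        )
        coll = make_collocation(
            emu, n_pde=128, n_bif=16, n_imp=2, m_imp=16, seed=3
        )
        emu.train(
            None, coll,
            TrainConfig(steps=150, mode="physics_only", seed=3,
                        batch_pde=64, log_every=149),
        )
        first = emu.history["loss"][0]["total"]
        last = emu.history["loss"][-1]["total"]
        assert last < first

    def test_checkpoint_round_trip(self, emu_bif, tmp_path):
        path = tmp_path / "ckpt.npz"
        emu_bif.save_checkpoint(path)
        q0, p0 = emu_bif.predict(2, 1.0, np.array([0.3]), mid_theta(SPACE3))
        for vid in emu_bif.nets:
            emu_bif.nets[vid].set_flat(
                emu_bif.nets[vid].get_flat() * 0.0
            )
        emu_bif.load_checkpoint(path)
        q1, p1 = emu_bif.predict(2, 1.0, np.array([0.3]), mid_theta(SPACE3))
        assert q1 == pytest.approx(q0)

    def test_transfer_warm_start_onto_perturbed_geometry(
        self, base_params, inflow_gp, tmp_path, rng
    ):
        """A checkpoint from one patient-like geometry warm-starts the
        emulator of a slightly perturbed geometry: the warm-started
        network's data fit is far better than a fresh initialisation."""
        from hemovasc.network import fixture_network

        net_a = fixture_network("single_vessel")
        net_b = fixture_network("single_vessel", seed=9)  # ~3% jitter
        stats = {1: {"q_mean": 30.0, "q_std": 50.0, "p_mean": 1.1e5,
                     "p_std": 2e4}}
        src = NetworkEmulator(net_a, SPACE2, base_params, inflow_gp,
                              width=8, depth=2, seed=0)
        src.set_normalisation(stats)
        # teach the source something non-trivial: fit a synthetic target
        t = np.linspace(0, 1, 40)
        Theta = np.broadcast_to(SPACE2.denormalise(np.full(2, 0.5)),
                                (40, 2))
        q_target = 30 + 20 * np.sin(2 * np.pi * t)
        p_target = 1.1e5 + 1e4 * np.cos(2 * np.pi * t)
        src.train(
            _FakeDataset(t, Theta, q_target, p_target), None,
            TrainConfig(steps=400, mode="data_only", seed=0,
                        log_every=400),
        )
        path = tmp_path / "src.npz"
        src.save_checkpoint(path)

        warm = NetworkEmulator(net_b, SPACE2, base_params, inflow_gp,
                               width=8, depth=2, seed=4)
        with pytest.raises(ValueError):
            warm.load_checkpoint(path)  # different geometry
        warm.load_checkpoint(path, strict=False)
        cold = NetworkEmulator(net_b, SPACE2, base_params, inflow_gp,
                               width=8, depth=2, seed=4)
        cold.set_normalisation(stats)
        batch = {1: (t, Theta, q_target, p_target)}
        warm_loss, _ = warm.loss_data(batch, want_grads=False)
        cold_loss, _ = cold.loss_data(batch, want_grads=False)
        assert warm_loss < 0.2 * cold_loss

    def test_checkpoint_refuses_mismatched_network(
        self, emu_bif, emu_single, tmp_path
    ):
        path = tmp_path / "ckpt.npz"
        emu_bif.save_checkpoint(path)
        with pytest.raises(ValueError):
            emu_single.load_checkpoint(path)


def test_conv_matrix_is_circulant_of_kernel(base_params):
    from hemovasc.impedance import tree_root_impedance, outflow_pressure
    from hemovasc.network import StructuredTreeSpec

    k = tree_root_impedance(StructuredTreeSpec(), base_params, 0.3, m=16)
    C = conv_matrix(k, 16)
    q = np.random.default_rng(0).standard_normal(16)
    assert np.allclose(C @ q, outflow_pressure(q, k), atol=1e-8)
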