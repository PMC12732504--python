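import numpy as np
import pytest

import perturbflow as pf
from perturbflow import probe
from perturbflow.probe import ProbeError


def finite_difference_gradient(fn, z, h=1e-4):
    """Central-difference oracle for a scalar function of z (batched rows)."""
    z = np.atleast_2d(z)
    g = np.zeros_like(z)
    for j in range(z.shape[1]):
        e = np.zeros(z.shape[1])
        e[j] = h
        g[:, j] = (fn(z + e) - fn(z - e)) / (2 * h)
    return g


class TestOutputGradient:
    def test_matches_finite_differences_genes(self, tiny_model, rng):
        model = tiny_model[0]
        z = rng.standard_normal((30, model.config.latent_dim))
        for gene in (0, 17, 59):
            g = probe.output_gradient(model, z, gene)
            fd = finite_difference_gradient(lambda zz: model.decode_mean(zz)[:, gene], z)
            rel = np.abs(g - fd).max() / np.abs(fd).max()
            assert rel < 1e-4

    def test_matches_finite_differences_aux(self, tiny_model, rng):
        model = tiny_model[0]
        z = rng.standard_normal((30, model.config.latent_dim))
        for name in ("condition", "time"):
            g = probe.output_gradient(model, z, name)
            fd = finite_difference_gradient(
                lambda zz: model.aux_forward(zz, name).ravel(), z
            )
            assert np.abs(g - fd).max() <= 1e-4 * max(np.abs(fd).max(), 1e-12)

    def test_continuous_head_gradient_is_its_weight_vector(self, tiny_model):
        # a linear read-out has a constant gradient: exactly its weights
        model = tiny_model[0]
        z = np.zeros((3, model.config.latent_dim))
        g = probe.output_gradient(model, z, "time")
        np.testing.assert_array_equal(g, np.tile(model.aux_W["time"], (3, 1)))

    def test_constant_output_zero_gradient(self, tiny_model):
        model = tiny_model[0]
        saved = model.aux_W["time"].copy()
        model.aux_W["time"] = np.zeros_like(saved)
        try:
            g = probe.output_gradient(model, np.ones((2, model.config.latent_dim)), "time")
            np.testing.assert_array_equal(g, 0.0)
        finally:
            model.aux_W["time"] = saved

    def test_unknown_output_raises(self, tiny_model):
        with pytest.raises(pf.ModelError):
            probe.output_gradient(tiny_model[0], np.zeros(4), "nope")


class TestIntegrateFlow:
    def test_zero_delta_stays_put(self, tiny_model):
        model = tiny_model[0]
        z0 = np.ones(model.config.latent_dim)
        traj = probe.integrate_flow(model, z0, 0, delta=0.0, n_steps=5)
        assert np.all(traj.points == z0)

    def test_euler_step_identity(self, tiny_model, rng):
        # consecutive points satisfy the forward-Euler recurrence exactly
        model = tiny_model[0]
        z0 = rng.standard_normal(model.config.latent_dim)
        traj = probe.integrate_flow(model, z0, 3, delta=-0.01, n_steps=4)
        for t in range(4):
            g = probe.output_gradient(model, traj.points[t], 3)[0]
            np.testing.assert_allclose(
                traj.points[t + 1], traj.points[t] - 0.01 * g, rtol=0, atol=1e-14
            )

    def test_first_order_output_change(self, tiny_model, rng):
        # for small steps, Δy per step ≈ δ‖∇‖² (first-order Taylor)
        model = tiny_model[0]
        z0 = rng.standard_normal(model.config.latent_dim) * 0.5
        g0 = probe.output_gradient(model, z0, 7)[0]
        delta = 1e-3 / max(np.linalg.norm(g0), 1e-9) * 0.5
        traj = probe.integrate_flow(model, z0, 7, delta=delta, n_steps=1)
        change = traj.output_values[1] - traj.output_values[0]
        predicted = delta * np.linalg.norm(g0) ** 2
        assert change == pytest.approx(predicted, rel=0.05)

    def test_knockdown_monotone_and_recovers_cluster(self, knockdown_run):
        """Negative-stepsize flows on the top effect gene walk wild-type
        cells toward the knockout population while the gene's decoded
        expression never increases."""
        kr = knockdown_run
        model, gt, emb = kr["model"], kr["gt"], kr["emb"]
        cond = gt.condition
        cent1 = emb[cond == 1].mean(axis=0)
        rng = np.random.default_rng(0)
        starts = rng.choice(np.flatnonzero(cond == 0), 40, replace=False)
        closer = 0
        for i in starts:
            traj = probe.integrate_flow(
                model, emb[i], int(gt.effect_genes[0]), delta=-0.001, n_steps=400
            )
            d0 = np.linalg.norm(traj.points[0] - cent1)
            d1 = np.linalg.norm(traj.points[-1] - cent1)
            closer += d1 < d0
            assert (np.diff(traj.output_values) <= 1e-12).mean() >= 0.95
        assert closer / len(starts) >= 0.8


class TestSampleEvalPoints:
    def test_subsample_full_and_seeded(self, rng):
        pts = rng.standard_normal((50, 3))
        full = probe.sample_eval_points(pts, 50, "subsample", seed=0)
        np.testing.assert_array_equal(np.sort(full, axis=0), np.sort(pts, axis=0))
        a = probe.sample_eval_points(pts, 10, "subsample", seed=4)
        b = probe.sample_eval_points(pts, 10, "subsample", seed=4)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ProbeError):
            probe.sample_eval_points(pts, 51, "subsample")

    def test_grid2d_lattice(self):
        latents = np.array([[-3.0, -3.0], [3.0, 3.0]])
        grid = probe.sample_eval_points(latents, 400, "grid2d")
        assert grid.shape == (400, 2)
        xs = np.unique(grid[:, 0])
        assert len(xs) == 20
        np.testing.assert_allclose(np.diff(xs), np.diff(xs)[0])
        with pytest.raises(ProbeError):
            probe.sample_eval_points(np.zeros((5, 3)), 4, "grid2d")


class TestDensityMask:
    def test_training_points_kept_at_full_quantile(self, rng):
        pts = rng.standard_normal((40, 2))
        mask = probe.density_mask(pts, pts, k=3, quantile=1.0)
        assert mask.all()

    def test_far_point_masked(self, rng):
        train = rng.standard_normal((40, 2))
        far = np.array([[100.0, 100.0]])
        assert not probe.density_mask(far, train, k=3, quantile=1.0)[0]

    def test_matches_brute_force(self, rng):
        train = rng.standard_normal((25, 2))
        cand = np.vstack([rng.standard_normal((10, 2)), [[5, 5]], [[0, 0]]])
        k, q = 4, 0.8
        got = probe.density_mask(cand, train, k=k, quantile=q)
        # exhaustive pairwise-distance oracle
        def kth(p, ref, kk):
            d = np.sort(np.linalg.norm(ref - p, axis=1))
            return d[kk - 1]

        ref_stat = np.array(
            [kth(train[i], np.delete(train, i, axis=0), k) for i in range(25)]
        )
        cutoff = np.quantile(ref_stat, q)
        expected = np.array([kth(c, train, k) <= cutoff for c in cand])
        np.testing.assert_array_equal(got, expected)

    def test_k_too_large(self, rng):
        with pytest.raises(ProbeError):
            probe.density_mask(np.zeros((2, 2)), np.zeros((3, 2)), k=4)


class TestPCAProjection:
    def _field(self, rng, d=5, n=40):
        pts = rng.standard_normal((n, d))
        vecs = rng.standard_normal((n, d))
        return pf.GradientField(pts, vecs, "toy")

    def test_2d_identity_up_to_sign(self, rng):
        pts = rng.standard_normal((30, 2)) * [3.0, 1.0]
        field = pf.GradientField(pts, rng.standard_normal((30, 2)), "toy")
        proj = probe.project_gradients_pca(field, pts)
        # axes may flip sign/order but the map is orthogonal
        R = proj.projector.components_
        np.testing.assert_allclose(R @ R.T, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(proj.vectors, field.vectors @ R.T, atol=1e-12)

    def test_vector_is_endpoint_difference_limit(self, rng):
        field = self._field(rng)
        proj = probe.project_gradients_pca(field, field.points)
        h = 1e-6
        shifted = pf.GradientField(field.points + h * field.vectors, field.vectors, "toy")
        proj2 = probe.project_gradients_pca(shifted, field.points)
        endpoint_diff = (proj2.points - proj.points) / h
        np.testing.assert_allclose(endpoint_diff, proj.vectors, atol=1e-6)

    def test_linearity_and_orthogonal_vector(self, rng):
        field = self._field(rng)
        proj = probe.project_gradients_pca(field, field.points)
        R = proj.projector.components_
        u, v = rng.standard_normal(5), rng.standard_normal(5)
        np.testing.assert_allclose(
            (2.5 * u + v) @ R.T, 2.5 * (u @ R.T) + v @ R.T, atol=1e-12
        )
        # a vector orthogonal to both axes projects to zero
        q, _ = np.linalg.qr(R.T)  # complement basis
        orth = rng.standard_normal(5)
        orth -= q @ (q.T @ orth)
        np.testing.assert_allclose(orth @ R.T, 0.0, atol=1e-10)

    def test_degenerate_rank_rejected(self):
        pts = np.outer(np.arange(10.0), [1.0, 2.0])  # collinear
        field = pf.GradientField(pts, pts, "toy")
        with pytest.raises(ProbeError):
            probe.project_gradients_pca(field, pts)


class TestGridInterpolate:
    def test_constant_field(self, rng):
        pts = rng.standard_normal((30, 2))
        vecs = np.tile([1.5, -2.0], (30, 1))
        proj = pf.Projection2D("pca", pts, vecs)
        _, _, gu, gv = probe.grid_interpolate(proj, resolution=12)
        inside = ~np.isnan(gu)
        assert inside.any()
        np.testing.assert_allclose(gu[inside], 1.5, atol=1e-9)
        np.testing.assert_allclose(gv[~np.isnan(gv)], -2.0, atol=1e-9)

    def test_linear_field_exact_inside_hull(self, rng):
        pts = rng.standard_normal((60, 2))
        A = np.array([[0.5, -1.0], [2.0, 0.25]])
        vecs = pts @ A.T
        proj = pf.Projection2D("pca", pts, vecs)
        gx, gy, gu, gv = probe.grid_interpolate(proj, resolution=15)
        inside = ~np.isnan(gu)
        expected = np.stack([gx, gy], axis=-1) @ A.T
        np.testing.assert_allclose(gu[inside], expected[..., 0][inside], atol=1e-9)
        np.testing.assert_allclose(gv[inside], expected[..., 1][inside], atol=1e-9)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        proj = pf.Projection2D("pca", pts, pts)
        with pytest.raises(ProbeError):
            probe.grid_interpolate(proj)


class TestUMAPProjection:
    def test_flow_between_clusters_points_the_right_way(self, rng):
        # two clusters in 4-D; the field at cluster A points toward B
        a = rng.standard_normal((80, 4)) * 0.3
        b = rng.standard_normal((80, 4)) * 0.3 + np.array([6.0, 0, 0, 0])
        latents = np.vstack([a, b])
        origins = a[:25]
        vecs = np.tile([1.0, 0, 0, 0], (25, 1))
        field = pf.GradientField(origins, vecs, "toy")
        # total displacement carries the origins into cluster B's region
        proj = probe.project_gradients_umap(None, latents, field, delta_display=6.0, seed=0)
        emb_all = proj.projector.embedding_[: latents.shape[0]]
        cent_b = emb_all[80:].mean(axis=0)
        to_b = cent_b - proj.points
        agree = np.sign((proj.vectors * to_b).sum(axis=1)) > 0
        assert agree.mean() > 0.5

    def test_zero_display_step_warns_and_zeroes(self, rng):
        latents = rng.standard_normal((40, 3))
        field = pf.GradientField(latents[:10], rng.standard_normal((10, 3)), "toy")
        with pytest.warns(UserWarning):
            proj = probe.project_gradients_umap(None, latents, field, delta_display=0.0, seed=0)
        np.testing.assert_allclose(proj.vectors, 0.0, atol=1e-8)


class TestExports:
    def test_field_and_trajectory_tsv(self, tiny_model, tmp_path, rng):
        import pandas as pd

        model = tiny_model[0]
        pts = rng.standard_normal((6, model.config.latent_dim))
        field = probe.gradient_field(model, pts, 0, mask=np.ones(6, bool))
        fp = tmp_path / "field.tsv"
        probe.export_field_tsv(field, str(fp))
        df = pd.read_csv(fp, sep="\t")
        assert len(df) == 6 and "grad0" in df.columns and df["mask"].all()
        traj = probe.integrate_flow(model, pts[0], 0, delta=-0.01, n_steps=3)
        tp = tmp_path / "traj.tsv"
        probe.export_trajectory_tsv(traj, str(tp))
        dt = pd.read_csv(tp, sep="\t")
        assert list(dt["step"]) == [0, 1, 2, 3]

    def test_mean_gradient_field(self, tiny_model, rng):
        model = tiny_model[0]
        pts = rng.standard_normal((4, model.config.latent_dim))
        f = probe.mean_gradient_field(model, pts, [0, 1, 2])
        manual = np.mean([model.output_gradient(pts, g) for g in (0, 1, 2)], axis=0)
        np.testing.assert_allclose(f.vectors, manual)
        with pytest.raises(ProbeError):
            probe.mean_gradient_field(model, pts, [])
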