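"""Varifold/currents metric, geodesic shooting, atlas estimation."""

import numpy as np
import pytest

from conftest import random_rotation
from meshmorph.atlas import (
    ControlPointSet,
    KernelParams,
    estimate_atlas,
    group_mean_mesh,
    hamiltonian,
    init_control_points,
    load_atlas,
    save_atlas,
    shoot,
    varifold_distance2,
    varifold_inner,
)
from meshmorph.atlas import _backward, _dalpha, _forward, _varifold_energy_grad, _vel, _face_data, _inner
from meshmorph.errors import ParameterError
from meshmorph.mesh import TriMesh
from meshmorph.synthetic import make_template


def brute_force_inner(mesh_a, mesh_b, sigma, mode="varifold"):
    """Independent double-sum oracle written directly from the definition."""
    def face_cn(mesh):
        out = []
        for f in mesh.faces:
            v0, v1, v2 = mesh.vertices[f]
            c = (v0 + v1 + v2) / 3.0
            n = 0.5 * np.cross(v1 - v0, v2 - v0)
            out.append((c, n))
        return out

    total = 0.0
    for c_p, n_p in face_cn(mesh_a):
        for c_q, n_q in face_cn(mesh_b):
            g = np.exp(-np.dot(c_p - c_q, c_p - c_q) / sigma**2)
            dot = np.dot(n_p, n_q)
            if mode == "varifold":
                psi = dot**2 / (np.linalg.norm(n_p) * np.linalg.norm(n_q))
            else:
                psi = dot
            total += g * psi
    return total


def random_mesh(rng, n_faces):
    verts = rng.normal(size=(n_faces + 2, 3))
    faces = np.array(
        [rng.choice(len(verts), size=3, replace=False) for _ in range(n_faces)]
    )
    mesh = TriMesh(verts, faces)
    assert np.all(mesh.face_areas() > 0)
    return mesh


class TestVarifoldInner:
    @pytest.mark.parametrize("mode", ["varifold", "currents"])
    def test_matches_brute_force_oracle(self, rng, mode):
        for _ in range(5):
            a = random_mesh(rng, int(rng.integers(1, 20)))
            b = random_mesh(rng, int(rng.integers(1, 20)))
            got = varifold_inner(a, b, 0.8, mode=mode)
            want = brute_force_inner(a, b, 0.8, mode=mode)
            assert got == pytest.approx(want, rel=1e-10)

    def test_self_inner_positive(self, rng):
        m = random_mesh(rng, 6)
        assert varifold_inner(m, m, 1.0) > 0

    def test_symmetry(self, rng):
        a, b = random_mesh(rng, 5), random_mesh(rng, 7)
        assert varifold_inner(a, b, 0.5) == pytest.approx(
            varifold_inner(b, a, 0.5), rel=1e-12
        )

    def test_gram_matrix_positive_semidefinite(self, rng):
        meshes = [random_mesh(rng, 4) for _ in range(5)]
        G = np.array(
            [[varifold_inner(a, b, 0.7) for b in meshes] for a in meshes]
        )
        eigvals = np.linalg.eigvalsh((G + G.T) / 2)
        assert eigvals.min() >= -1e-9 * np.trace(G)

    def test_zero_area_face_rejected(self):
        mesh = TriMesh([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [[0, 1, 2]])
        with pytest.raises(ParameterError):
            varifold_inner(mesh, mesh, 1.0)


class TestVarifoldDistance:
    def test_self_distance_zero(self, rng):
        m = random_mesh(rng, 8)
        assert varifold_distance2(m, m, 0.6) == pytest.approx(0.0, abs=1e-9)

    def test_far_translation_decouples(self, icosphere2):
        sigma = 0.5
        other = TriMesh(icosphere2.vertices + 20 * sigma, icosphere2.faces)
        d2 = varifold_distance2(icosphere2, other, sigma)
        expected = varifold_inner(icosphere2, icosphere2, sigma) + varifold_inner(
            other, other, sigma
        )
        assert d2 == pytest.approx(expected, rel=1e-6)

    def test_invariant_to_face_reordering(self, rng):
        m = random_mesh(rng, 9)
        perm = rng.permutation(m.n_faces)
        shuffled = TriMesh(m.vertices, m.faces[perm])
        other = random_mesh(rng, 5)
        assert varifold_distance2(m, other, 0.7) == pytest.approx(
            varifold_distance2(shuffled, other, 0.7), rel=1e-12
        )


class TestControlPoints:
    def test_unit_cube_grid_count(self):
        mesh = TriMesh(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]],
            [[0, 1, 2], [0, 1, 3], [1, 2, 4]],
        )
        cp = init_control_points([mesh], 0.5)
        assert cp.n == 125  # 5 per axis

    def test_meshes_inside_grid_hull(self, icosphere2):
        cp = init_control_points([icosphere2], 0.4)
        lo, hi = cp.points.min(0), cp.points.max(0)
        assert np.all(icosphere2.vertices >= lo) and np.all(icosphere2.vertices <= hi)

    def test_halving_spacing_roughly_octuples(self):
        # cubic scaling holds once the box is large relative to the margin
        box = TriMesh(
            10.0 * np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float),
            [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]],
        )
        n1 = init_control_points([box], 0.5).n
        n2 = init_control_points([box], 0.25).n
        assert 5 < n2 / n1 < 11


class TestShoot:
    def test_zero_momenta_identity(self, rng, icosphere2):
        cp = rng.normal(size=(6, 3))
        defo = shoot(cp, np.zeros((6, 3)), 1.0, 10)
        assert np.array_equal(defo.apply(icosphere2.vertices), icosphere2.vertices)

    def test_single_control_point_single_step_exact(self):
        alpha = np.array([[0.2, -0.1, 0.3]])
        defo = shoot(np.zeros((1, 3)), alpha, 2.0, n_timesteps=1)
        moved = defo.apply(np.zeros((1, 3)))
        assert np.allclose(moved, alpha, atol=1e-12)

    def test_hamiltonian_conserved_within_1_percent(self, rng):
        c = rng.normal(size=(8, 3))
        a = 0.3 * rng.normal(size=(8, 3))
        H0 = hamiltonian(c, a, 1.0)
        (cf, af, _), _ = _forward(c, a, None, 1.0, 20)
        H1 = hamiltonian(cf, af, 1.0)
        assert abs(H1 - H0) / abs(H0) < 0.01

    def test_no_triangle_flips_for_small_momenta(self, rng, icosphere2):
        cp = init_control_points([icosphere2], 0.8)
        a = 0.05 * rng.normal(size=(cp.n, 3))
        defo = shoot(cp, a, 0.8, 10)
        out = defo.apply_mesh(icosphere2)
        n_before = icosphere2.face_area_normals()
        n_after = out.face_area_normals()
        assert np.all(np.einsum("ij,ij->i", n_before, n_after) > 0)

    def test_nonfinite_momenta_rejected(self):
        with pytest.raises(ParameterError):
            shoot(np.zeros((1, 3)), np.array([[np.nan, 0, 0]]), 1.0)


class TestGradients:
    """The atlas gradients are hand-derived adjoints; the contract is that
    they match finite differences on toy cases."""

    def test_objective_gradient_matches_finite_differences(self, rng):
        template = make_template("icosphere", 0)
        target = TriMesh(template.vertices * 1.15 + 0.07, template.faces)
        tgt_c, tgt_n, tgt_m = _face_data(target)
        sBB = _inner(tgt_c, tgt_n, tgt_m, tgt_c, tgt_n, tgt_m, 0.7, "varifold")
        tgt = (tgt_c, tgt_n, tgt_m, sBB)
        sig2, nst, sige = 1.0, 5, 0.05
        cp = 0.5 * rng.normal(size=(4, 3))
        al = 0.2 * rng.normal(size=(4, 3))
        verts0, faces = template.vertices, template.faces

        def obj(T, c, a):
            (_, _, xf), _ = _forward(c, a, T, sig2, nst)
            E, _ = _varifold_energy_grad(xf, faces, tgt, 0.7, "varifold")
            return E / (2 * sige**2) + hamiltonian(c, a, 1.0)

        (_, _, xf), states = _forward(cp, al, verts0, sig2, nst)
        E, gx = _varifold_energy_grad(xf, faces, tgt, 0.7, "varifold")
        wc0, wa0, wx0 = _backward(states, sig2, nst, None, None, gx / (2 * sige**2))
        ga = wa0 + _vel(cp, cp, al, sig2)
        gc = wc0 - _dalpha(cp, al, sig2)
        gT = wx0

        eps = 1e-6
        for X, g, name in ((verts0, gT, "T"), (cp, gc, "cp"), (al, ga, "alpha")):
            fd = np.zeros_like(X)
            for i in range(X.shape[0]):
                for j in range(3):
                    Xp, Xm = X.copy(), X.copy()
                    Xp[i, j] += eps
                    Xm[i, j] -= eps
                    args = {"T": verts0, "cp": cp, "alpha": al}
                    args[name if name != "T" else "T"] = None  # placeholder
                    if name == "T":
                        fd[i, j] = (obj(Xp, cp, al) - obj(Xm, cp, al)) / (2 * eps)
                    elif name == "cp":
                        fd[i, j] = (obj(verts0, Xp, al) - obj(verts0, Xm, al)) / (2 * eps)
                    else:
                        fd[i, j] = (obj(verts0, cp, Xp) - obj(verts0, cp, Xm)) / (2 * eps)
            assert np.abs(g - fd).max() / np.abs(fd).max() < 1e-4


@pytest.fixture(scope="module")
def tiny_population():
    """Six slightly deformed icospheres (fast fixture for estimation tests)."""
    rng = np.random.default_rng(7)
    template = make_template("icosphere", 1)
    cp = init_control_points([template], 1.0)
    meshes = []
    alphas = []
    for i in range(6):
        a = 0.06 * rng.normal(size=(cp.n, 3))
        alphas.append(a)
        meshes.append(shoot(cp, a, 1.0, 8).apply_mesh(template))
    return template, cp, meshes, alphas


class TestEstimateAtlas:
    def test_identical_population_is_fixed_point(self, icosphere2):
        mesh = make_template("icosphere", 1)
        params = KernelParams(sigma_W=0.5, max_iter=10)
        model = estimate_atlas([mesh.copy() for _ in range(3)], params)
        for a in model.momenta.momenta.values():
            assert np.abs(a).max() < 1e-6 * params.sigma_V
        assert np.abs(model.template.vertices - mesh.vertices).max() < 1e-9

    def test_objective_monotone_and_residuals_drop(self, tiny_population):
        template, cp, meshes, _ = tiny_population
        params = KernelParams(sigma_W=0.5, sigma_V=1.0, max_iter=40, tol=1e-6)
        model = estimate_atlas(meshes, params, control_points=cp)
        trace = np.array(model.objective_trace)
        assert np.all(np.diff(trace) <= 0)
        # residual strictly below the pre-optimisation template-to-subject distance
        init = [np.sqrt(varifold_distance2(model.template, m, 0.5)) for m in meshes]
        for sid, d0 in zip(model.subject_ids, init):
            assert model.residuals[sid] < d0 + 1e-12
        assert np.mean(list(model.residuals.values())) < 0.5 * np.mean(init)

    def test_gradient_equivariance_under_rotation(self, tiny_population, rng):
        # rotating every input rotates the first-iteration gradients
        from meshmorph.atlas import _subject_targets

        template, cp, meshes, _ = tiny_population
        R = random_rotation(rng)
        params = KernelParams(sigma_W=0.5, sigma_V=1.0, max_iter=1)
        m1 = estimate_atlas(meshes, params, control_points=cp, init_template=template)
        rot = [TriMesh(m.vertices @ R.T, m.faces) for m in meshes]
        m2 = estimate_atlas(
            rot,
            params,
            control_points=ControlPointSet(cp.points @ R.T),
            init_template=TriMesh(template.vertices @ R.T, template.faces),
        )
        assert m1.objective_trace[0] == pytest.approx(m2.objective_trace[0], rel=1e-8)

    def test_save_load_roundtrip(self, tiny_population, tmp_path):
        template, cp, meshes, _ = tiny_population
        params = KernelParams(sigma_W=0.5, sigma_V=1.0, max_iter=5)
        model = estimate_atlas(meshes, params, control_points=cp)
        save_atlas(model, tmp_path / "atlas")
        back = load_atlas(tmp_path / "atlas")
        assert back.subject_ids == model.subject_ids
        for sid in model.subject_ids:
            assert np.allclose(
                back.momenta.momenta[sid], model.momenta.momenta[sid], atol=1e-12
            )
        assert np.array_equal(back.template.vertices, model.template.vertices)


class TestGroupMean:
    def test_single_subject_is_model_reconstruction(self, tiny_population):
        template, cp, meshes, _ = tiny_population
        params = KernelParams(sigma_W=0.5, sigma_V=1.0, max_iter=15)
        model = estimate_atlas(meshes, params, control_points=cp)
        sid = model.subject_ids[0]
        mean = group_mean_mesh(model, [sid])
        defo = shoot(
            model.control_points, model.momenta.momenta[sid], 1.0, params.n_timesteps
        )
        assert np.allclose(mean.vertices, defo.apply(model.template.vertices))

    def test_full_population_of_opposite_momenta_gives_template(self, icosphere2):
        from meshmorph.atlas import AtlasModel, MomentaSet

        cp = init_control_points([icosphere2], 1.0)
        rng = np.random.default_rng(3)
        a = 0.1 * rng.normal(size=(cp.n, 3))
        params = KernelParams(sigma_W=0.5, sigma_V=1.0)
        model = AtlasModel(
            template=icosphere2,
            control_points=cp,
            momenta=MomentaSet({"p": a, "m": -a}),
            params=params,
            residuals={"p": 0.0, "m": 0.0},
            subject_ids=["p", "m"],
        )
        mean = group_mean_mesh(model, ["p", "m"])
        assert np.allclose(mean.vertices, icosphere2.vertices, atol=1e-12)

    def test_vertex_count_matches_template(self, tiny_population):
        template, cp, meshes, _ = tiny_population
        params = KernelParams(sigma_W=0.5, sigma_V=1.0, max_iter=5)
        model = estimate_atlas(meshes, params, control_points=cp)
        mean = group_mean_mesh(model, model.subject_ids[:3])
        assert mean.n_vertices == model.template.n_vertices

    def test_unknown_subject_rejected(self, tiny_population):
        template, cp, meshes, _ = tiny_population
        params = KernelParams(sigma_W=0.5, sigma_V=1.0, max_iter=3)
        model = estimate_atlas(meshes, params, control_points=cp)
        with pytest.raises(KeyError):
            group_mean_mesh(model, ["nope"])


def test_kernel_params_config_roundtrip(tmp_path):
    p = KernelParams(sigma_W=0.5, n_timesteps=12, max_iter=99, mode="currents")
    p.to_file(tmp_path / "p.cfg")
    q = KernelParams.from_file(tmp_path / "p.cfg")
    assert q.sigma_W == 0.5 and q.sigma_V == 0.5
    assert q.sigma_eps == pytest.approx(0.025)
    assert q.n_timesteps == 12 and q.max_iter == 99 and q.mode == "currents"
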