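"""Unit and property tests for the multi-hop graph attention mathematics."""

import numpy as np
import pytest

from brainmga import mga


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def ck_multi_hop_oracle(E_tilde, m, beta):
    """Brute-force Chapman–Kolmogorov recursion over intermediate states.

    e^(j)_{ik} = sum_k' e_{ik'} e^(j-1)_{k'k}, summed as sum_j beta^{j-1} e^(j),
    with explicit Python loops — independent of matrix multiplication.
    """
    n = E_tilde.shape[0]
    hop = [[E_tilde[i][j] for j in range(n)] for i in range(n)]
    acc = [[beta**0 * hop[i][j] for j in range(n)] for i in range(n)]
    for j in range(2, m + 1):
        nxt = [[0.0] * n for _ in range(n)]
        for a in range(n):
            for b in range(n):
                s = 0.0
                for k in range(n):
                    s += E_tilde[a][k] * hop[k][b]
                nxt[a][b] = s
        hop = nxt
        for a in range(n):
            for b in range(n):
                acc[a][b] += beta ** (j - 1) * hop[a][b]
    return np.array(acc)


def enumerate_placements(extent, patch, stride):
    """Walk every candidate offset and keep the coverage-rule grid."""
    offs = []
    o = 0
    while o + patch <= extent:
        offs.append(o)
        o += stride
    if offs[-1] + patch < extent:
        offs.append(extent - patch)
    return offs


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "shape,gamma,patch_extent,stride,n_patches,patch_size",
    [
        ((1, 8, 8, 8), 2, (4, 4, 4), 4, 8, 64),
        ((1, 8, 8, 12), 2, (4, 4, 6), 4, 12, 96),
        ((3, 4, 4, 4), 4, (1, 1, 1), 1, 64, 3),
    ],
)
def test_extract_patches_geometry(shape, gamma, patch_extent, stride, n_patches,
                                  patch_size):
    fmap = np.arange(np.prod(shape), dtype=float).reshape(shape)
    ps = mga.extract_patches(fmap, gamma)
    g = ps.geometry
    assert g.patch_extent == patch_extent
    assert g.stride == stride
    assert g.n_patches == n_patches
    assert ps.patches.shape == (n_patches, patch_size)
    # brute-force placement enumeration under the coverage rule
    expected = [
        (oh, ow, od)
        for oh in enumerate_placements(shape[1], patch_extent[0], stride)
        for ow in enumerate_placements(shape[2], patch_extent[1], stride)
        for od in enumerate_placements(shape[3], patch_extent[2], stride)
    ]
    assert list(g.placements) == expected


def test_extract_patches_non_divisible_overlap_offsets():
    ps = mga.extract_patches(np.zeros((1, 8, 8, 12)), 2)
    d_offsets = sorted({od for (_, _, od) in ps.geometry.placements})
    assert d_offsets == [0, 4, 6]


def test_extract_patches_rejects_small_axis():
    with pytest.raises(mga.InvalidSplitError, match="axis D"):
        mga.extract_patches(np.zeros((1, 8, 8, 3)), 4)


def test_patch_vectorization_is_row_major_and_invertible(rng):
    fmap = rng.normal(size=(2, 6, 6, 6))
    ps = mga.extract_patches(fmap, 2)
    # first patch equals the raveled corner block
    assert np.array_equal(ps.patches[0], fmap[:, :3, :3, :3].reshape(-1))
    assert np.allclose(mga.reassemble(ps), fmap)


# ---------------------------------------------------------------------------
# nodes
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "patch,expected",
    [
        (np.full(10, 3.7), (3.7, 3.7)),
        (np.array([1.0, 2.0, 3.0, 4.0]), (2.5, 4.0)),
        (np.array([-1.0, 0.0, 1.0]), (0.0, 1.0)),
    ],
)
def test_aggregate_nodes_examples(patch, expected):
    nodes = mga.aggregate_nodes(patch[None, :])
    assert nodes.shape == (1, 2)
    assert np.allclose(nodes[0], expected)


def test_aggregate_nodes_max_dominates_mean(rng):
    ps = mga.extract_patches(rng.normal(size=(3, 8, 8, 8)), 2)
    nodes = mga.aggregate_nodes(ps)
    assert nodes.shape == (ps.geometry.n_patches, 2)
    assert np.all(nodes[:, 1] >= nodes[:, 0])


# ---------------------------------------------------------------------------
# edges
# ---------------------------------------------------------------------------


def test_edge_scores_self_similarity_and_symmetry(rng):
    for _ in range(20):
        nodes = rng.normal(0, 5, (7, 2))
        V = rng.normal(0, 2, (2, 2))
        E = mga.edge_scores(nodes, V)
        assert np.all(np.diag(E) == 1.0)
        assert np.array_equal(E, E.T)
        assert np.all(E > 0) and np.all(E <= 1)


def test_edge_scores_known_distance():
    nodes = np.array([[0.0, 0.0], [3.0, 4.0]])
    E = mga.edge_scores(nodes, np.eye(2))
    assert np.isclose(E[0, 1], np.exp(-5.0))


def test_edge_scores_zero_embedding_collapses_to_ones(rng):
    E = mga.edge_scores(rng.normal(size=(5, 2)), np.zeros((2, 2)))
    assert np.allclose(E, 1.0)


def test_edge_scores_rejects_nonfinite():
    with pytest.raises(ValueError):
        mga.edge_scores(np.array([[np.nan, 0.0]]), np.eye(2))


def test_row_normalize_examples_and_property(rng, random_nodes):
    assert np.allclose(mga.row_normalize(np.ones((2, 2))), 0.5)
    near_identity = np.eye(3) + 1e-12
    assert np.allclose(mga.row_normalize(near_identity), np.eye(3), atol=1e-9)
    E = mga.edge_scores(random_nodes, rng.normal(size=(2, 2)))
    Et = mga.row_normalize(E)
    assert np.allclose(Et.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(Et >= 0) and np.all(Et <= 1)


# ---------------------------------------------------------------------------
# multi-hop propagation
# ---------------------------------------------------------------------------


def test_multi_hop_idempotent_examples():
    Et = np.full((2, 2), 0.5)
    assert np.allclose(mga.multi_hop_edges(Et, 3, 1.0), 1.5)
    assert np.allclose(mga.multi_hop_edges(Et, 3, 0.8), 0.5 * (1 + 0.8 + 0.64))


def test_multi_hop_matches_chapman_kolmogorov_oracle(rng):
    for _ in range(10):
        n = int(rng.integers(2, 9))
        m = int(rng.integers(1, 6))
        beta = float(rng.uniform(0.2, 1.0))
        nodes = rng.normal(0, 2, (n, 2))
        Et = mga.row_normalize(mga.edge_scores(nodes, rng.normal(size=(2, 2))))
        oracle = ck_multi_hop_oracle(Et, m, beta)
        ours = mga.multi_hop_edges(Et, m, beta)
        assert np.allclose(ours, (oracle + oracle.T) / 2, atol=1e-9)
        # pre-symmetrization row sums follow the geometric closed form
        expected = m if beta == 1.0 else (1 - beta**m) / (1 - beta)
        assert np.allclose(oracle.sum(axis=1), expected, atol=1e-9)
        # stochastic closure of every power
        power = Et.copy()
        for _ in range(m):
            assert np.allclose(power.sum(axis=1), 1.0, atol=1e-9)
            power = power @ Et


def test_multi_hop_output_is_symmetric_and_rejects_bad_m(rng):
    Et = mga.row_normalize(mga.edge_scores(rng.normal(size=(5, 2)), np.eye(2)))
    Ea = mga.multi_hop_edges(Et, 4, 0.8)
    assert np.array_equal(Ea, Ea.T)
    assert np.all(Ea >= 0)
    with pytest.raises(mga.InvalidConfigError):
        mga.multi_hop_edges(Et, 0, 0.8)


def test_permutation_equivariance_up_to_threshold(rng):
    nodes = rng.normal(size=(8, 2))
    V = rng.normal(size=(2, 2))
    perm = rng.permutation(8)
    P = np.eye(8)[perm]
    E = mga.edge_scores(nodes, V)
    Ep = mga.edge_scores(nodes[perm], V)
    assert np.allclose(Ep, P @ E @ P.T)
    Et, Etp = mga.row_normalize(E), mga.row_normalize(Ep)
    assert np.allclose(Etp, P @ Et @ P.T)
    assert np.allclose(
        mga.multi_hop_edges(Etp, 3, 0.8), P @ mga.multi_hop_edges(Et, 3, 0.8) @ P.T
    )


# ---------------------------------------------------------------------------
# threshold and adjacency
# ---------------------------------------------------------------------------


def test_threshold_examples(rng):
    M = np.zeros((4, 4))
    M[np.arange(3), np.arange(1, 4)] = [0.2, 0.4, 0.6]
    assert np.isclose(mga.compute_threshold(M), 0.4)
    const = np.full((5, 5), 0.3)
    assert np.isclose(mga.compute_threshold(const), 0.3)
    R = rng.random((6, 6))
    brute = np.mean([R[i, i + 1] for i in range(5)])
    assert np.isclose(mga.compute_threshold(R), brute)
    assert mga.compute_threshold(np.ones((1, 1))) == 0.0


def test_threshold_edges_strict_comparison_and_self_loops(rng):
    uniform = np.full((3, 3), 0.7)
    A = mga.threshold_edges(uniform, 0.7)
    assert np.array_equal(A, np.eye(3))
    mixed = np.array([[0.1, 0.9], [0.9, 0.1]])
    assert np.array_equal(mga.threshold_edges(mixed, 0.5),
                          np.array([[1.0, 1.0], [1.0, 1.0]]))
    R = rng.random((5, 5))
    theta = 0.5
    expected = np.array(
        [[1.0 if (i == j or R[i, j] > theta) else 0.0 for j in range(5)]
         for i in range(5)]
    )
    assert np.array_equal(mga.threshold_edges(R, theta), expected)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------


def test_masked_attention_identity_and_uniform(rng):
    params = mga.init_params(rng)
    nodes = rng.normal(size=(4, 2))
    alpha = mga.masked_attention(nodes, np.eye(4), params)
    assert np.allclose(alpha, np.eye(4))
    same = np.tile(nodes[0], (5, 1))
    alpha = mga.masked_attention(same, np.ones((5, 5)), params)
    assert np.allclose(alpha, 0.2)


def test_masked_attention_matches_direct_softmax(rng):
    params = mga.init_params(rng)
    nodes = rng.normal(size=(4, 2))
    adj = np.array(
        [[1, 1, 0, 0], [1, 1, 1, 0], [0, 1, 1, 1], [0, 0, 1, 1]], dtype=float
    )
    alpha = mga.masked_attention(nodes, adj, params, leaky_slope=0.2)
    z = nodes @ params.V.T
    for i in range(4):
        logits = []
        nbrs = [j for j in range(4) if adj[i, j]]
        for j in nbrs:
            raw = params.a @ np.concatenate([z[i], z[j]])
            logits.append(raw if raw >= 0 else 0.2 * raw)
        ex = np.exp(logits)
        soft = ex / ex.sum()
        assert np.allclose(alpha[i, nbrs], soft, atol=1e-12)
        off = [j for j in range(4) if not adj[i, j]]
        assert np.all(alpha[i, off] == 0.0)
    assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# update and reassembly
# ---------------------------------------------------------------------------


def test_update_patches_convexity_and_shape_guard(rng):
    fmap = rng.normal(size=(1, 8, 8, 8))
    ps = mga.extract_patches(fmap, 2)
    n = ps.geometry.n_patches
    assert np.array_equal(mga.update_patches(ps, np.eye(n)).patches, ps.patches)
    two = mga.PatchSet(np.vstack([ps.patches[0], ps.patches[0]]), ps.geometry)
    alpha = rng.dirichlet(np.ones(2), size=2)
    upd = mga.update_patches(two, alpha)
    assert np.allclose(upd.patches, ps.patches[0])
    half = np.array([[0.5, 0.5], [0.5, 0.5]])
    pair = mga.PatchSet(ps.patches[:2], ps.geometry)
    assert np.allclose(mga.update_patches(pair, half).patches,
                       (ps.patches[0] + ps.patches[1]) / 2)
    with pytest.raises(ValueError):
        mga.update_patches(ps, np.eye(n + 1))


def test_reassemble_overlap_averaging():
    # two patches of constant a and b overlapping along D
    fmap = np.zeros((1, 4, 4, 6))
    ps = mga.extract_patches(fmap, 1)  # single patch == whole map
    assert np.allclose(mga.reassemble(ps), fmap)
    geom = mga.PatchGeometry(
        gamma=2, channels=1, map_extent=(4, 4, 6), patch_extent=(4, 4, 4),
        stride=4, placements=((0, 0, 0), (0, 0, 2)),
    )
    a, b = 2.0, 6.0
    patches = np.vstack([np.full(64, a), np.full(64, b)])
    out = mga.reassemble(mga.PatchSet(patches, geom))
    assert np.allclose(out[0, :, :, :2], a)
    assert np.allclose(out[0, :, :, 2:4], (a + b) / 2)
    assert np.allclose(out[0, :, :, 4:], b)


@pytest.mark.parametrize("shape,gamma", [((1, 8, 8, 8), 2), ((2, 8, 8, 12), 2),
                                         ((1, 9, 9, 9), 2), ((3, 6, 7, 9), 3)])
def test_round_trip_identity(rng, shape, gamma):
    fmap = rng.normal(size=shape)
    ps = mga.extract_patches(fmap, gamma)
    out = mga.reassemble(mga.update_patches(ps, np.eye(ps.geometry.n_patches)))
    assert np.allclose(out, fmap, atol=1e-9)


# ---------------------------------------------------------------------------
# full module
# ---------------------------------------------------------------------------


def test_mga_forward_preserves_shape_and_constants(rng):
    config = mga.MGAConfig()
    params = [mga.init_params(np.random.default_rng(s)) for s in (1, 2)]
    fmap = rng.normal(size=(2, 10, 12, 9))
    out = mga.mga_forward(fmap, config, params)
    assert out.shape == fmap.shape
    const = np.full((1, 8, 8, 8), 3.25)
    out = mga.mga_forward(const, config, params)
    assert np.allclose(out, 3.25)


def test_mga_forward_validates_params_and_drop_path(rng):
    config = mga.MGAConfig(drop_path_rate=0.5)
    params = [mga.init_params(rng) for _ in range(2)]
    with pytest.raises(mga.InvalidConfigError):
        mga.mga_forward(np.zeros((1, 8, 8, 8)), config, params[:1])

    class AlwaysDrop:
        def random(self):
            return 0.0

    fmap = rng.normal(size=(1, 8, 8, 8))
    out = mga.mga_forward(fmap, config, params, rng=AlwaysDrop(), training=True)
    assert np.array_equal(out, fmap)
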