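import numpy as np
import pytest

import fmridyn as fd
from fmridyn.indices import _zscore_mask


# ---------------------------------------------------------------- ALFF

def test_alff_on_bin_sinusoid_closed_form():
    """A sine of amplitude 2 on DFT bin 3 (0.046875 Hz at L=32, TR=2)
    contributes amplitude 2 to one of the 5 band bins: ALFF = 2/5."""
    L, tr = 32, 2.0
    t = np.arange(L) * tr
    seg = 2.0 * np.sin(2 * np.pi * 0.046875 * t)[None, :]
    assert fd.alff(seg, tr, (0.01, 0.08))[0] == pytest.approx(0.4, abs=1e-10)


def test_alff_zero_and_linearity(rng):
    seg = rng.standard_normal((6, 32))
    a1 = fd.alff(seg, 2.0, (0.01, 0.08))
    a2 = fd.alff(2.0 * seg, 2.0, (0.01, 0.08))
    np.testing.assert_allclose(a2, 2.0 * a1, rtol=1e-12)
    assert fd.alff(np.zeros((1, 32)), 2.0, (0.01, 0.08))[0] == 0.0
    assert (a1 >= 0).all()


def test_alff_empty_band_errors():
    with pytest.raises(ValueError, match="longer window"):
        fd.alff(np.zeros((1, 8)), 0.5, (0.01, 0.08))


# ---------------------------------------------------------------- ReHo

def test_reho_identical_series_is_one(rng):
    mask = np.ones((3, 3, 3), dtype=bool)
    tbl = fd.neighbor_table(mask, 27)
    seg = np.tile(rng.standard_normal(32), (27, 1))
    W = fd.reho(seg, tbl)
    np.testing.assert_allclose(W, 1.0, atol=1e-12)


def test_reho_white_noise_low(rng):
    mask = np.ones((3, 3, 3), dtype=bool)
    tbl = fd.neighbor_table(mask, 27)
    W = fd.reho(rng.standard_normal((27, 32)), tbl)
    assert W[13] < 0.2  # center voxel, full 27-neighborhood


def test_reho_rank_invariance_two_voxels(rng):
    mask = np.ones((2, 1, 1), dtype=bool)
    tbl = fd.neighbor_table(mask, 27)
    x = rng.standard_normal(20)
    seg = np.vstack([x, np.exp(2 * x)])  # monotone transform
    np.testing.assert_allclose(fd.reho(seg, tbl), 1.0, atol=1e-12)


def test_reho_matches_brute_force_oracle(rng, w_oracle):
    """Vectorized neighborhood W equals the loop-based W on tiny integer
    series for every voxel of a small fully-masked grid."""
    mask = np.ones((3, 1, 1), dtype=bool)  # K <= 3 in-mask neighbors
    tbl = fd.neighbor_table(mask, 27)
    seg = rng.integers(0, 4, size=(3, 6)).astype(float)
    seg += rng.normal(0, 1e-9, seg.shape)  # avoid fully-constant rows
    W = fd.reho(seg, tbl)
    for v in range(3):
        nbrs = tbl[v][tbl[v] >= 0]
        expected = w_oracle(seg[nbrs])
        assert W[v] == pytest.approx(expected, abs=1e-9)


def test_reho_affine_rescale_invariance(rng):
    mask = np.ones((3, 3, 3), dtype=bool)
    tbl = fd.neighbor_table(mask, 27)
    seg = rng.standard_normal((27, 30))
    scales = rng.uniform(0.5, 3.0, size=(27, 1))
    offsets = rng.normal(0, 5, size=(27, 1))
    np.testing.assert_allclose(
        fd.reho(seg, tbl), fd.reho(scales * seg + offsets, tbl), atol=1e-9
    )


def test_neighbor_table_sizes():
    mask = np.ones((5, 5, 5), dtype=bool)
    for k in (7, 19, 27):
        tbl = fd.neighbor_table(mask, k)
        assert tbl.shape[1] == k
        center = 2 * 25 + 2 * 5 + 2  # linear index of (2,2,2)
        assert (tbl[center] >= 0).all()  # interior voxel has full neighborhood
    corner = 0
    tbl = fd.neighbor_table(mask, 27)
    assert (tbl[corner] >= 0).sum() == 8


# ---------------------------------------------------------------- DC

def test_dc_constructed_degree(rng):
    latent = rng.standard_normal(60)
    seg = np.vstack(
        [latent + 0.3 * rng.standard_normal(60) for _ in range(4)]
        + [rng.standard_normal(60)]
    )
    raw = fd.degree_centrality(seg, 0.25, zscore=False)
    assert raw[0] == 3.0  # voxel A: 3 latent-sharing partners, not E


def test_dc_identical_voxels_guarded(rng):
    seg = np.tile(rng.standard_normal(30), (5, 1))
    z = fd.degree_centrality(seg, 0.25)
    np.testing.assert_allclose(z, 0.0)  # zero spread -> zeros, not NaN


def test_dc_zscore_mean_sd(rng):
    seg = rng.standard_normal((40, 30))
    z = fd.degree_centrality(seg, 0.25)
    assert np.nanmean(z) == pytest.approx(0.0, abs=1e-12)
    assert np.nanstd(z, ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_dc_zero_variance_voxel_nan(rng):
    seg = rng.standard_normal((5, 30))
    seg[2] = 4.0
    raw = fd.degree_centrality(seg, 0.25, zscore=False)
    assert np.isnan(raw[2])


# ---------------------------------------------------------------- VMHC

def _sym_mask(shape=(6, 4, 4)):
    return np.ones(shape, dtype=bool)


def test_vmhc_duplicated_halves_capped(rng):
    mask = _sym_mask()
    data = rng.standard_normal(mask.shape + (32,))
    data[3:] = data[:3][::-1]  # right half mirrors left half exactly
    seg = data[mask]
    z = fd.vmhc(seg, fd.mirror_pairs(mask))
    np.testing.assert_allclose(z, np.arctanh(1 - 1e-7), atol=1e-9)


def test_vmhc_symmetry_invariant(rng):
    mask = _sym_mask()
    seg = rng.standard_normal((mask.sum(), 32))
    mirrors = fd.mirror_pairs(mask)
    z = fd.vmhc(seg, mirrors)
    np.testing.assert_allclose(z, z[mirrors], atol=1e-12)


def test_vmhc_independent_halves_near_zero(rng):
    mask = _sym_mask((10, 8, 8))
    seg = rng.standard_normal((mask.sum(), 32))
    z = fd.vmhc(seg, fd.mirror_pairs(mask))
    assert abs(np.nanmean(z)) < 0.05


def test_vmhc_unpaired_voxel_nan(rng):
    mask = np.ones((4, 2, 2), dtype=bool)
    mask[0, 0, 0] = False  # its mirror (3,0,0) is unpaired
    seg = rng.standard_normal((mask.sum(), 20))
    z = fd.vmhc(seg, fd.mirror_pairs(mask))
    lin = np.full(mask.shape, -1)
    lin[mask] = np.arange(mask.sum())
    assert np.isnan(z[lin[3, 0, 0]])


def test_mirror_requires_even_first_dim():
    with pytest.raises(ValueError, match="even"):
        fd.mirror_pairs(np.ones((5, 4, 4), dtype=bool))


# ---------------------------------------------------------------- GSC

def test_gsc_identical_series_capped(rng):
    seg = np.tile(rng.standard_normal(30), (8, 1))
    z = fd.gsc(seg)
    np.testing.assert_allclose(z, np.arctanh(1 - 1e-7), atol=1e-9)


def test_gsc_orthogonal_voxel_zero(rng):
    """Construct (Gram-Schmidt) a voxel whose series is orthogonal to the
    resulting global mean; its GSC must vanish."""
    t = 40
    s = rng.standard_normal(t)
    s -= s.mean()
    s = 2.0 * s / np.linalg.norm(s)  # centered, norm 2
    w = rng.standard_normal(t)
    w -= w.mean()
    w -= (w @ s) / (s @ s) * s
    w /= np.linalg.norm(w)
    u = -s / np.linalg.norm(s) + w  # then <u, s + u> = -1 + 1 = 0
    # nine voxels summing to s, plus the engineered voxel u:
    # global mean = (s + u) / 10, orthogonal to u by construction
    seg = np.vstack([np.vstack([s / 9.0] * 9), u])
    z = fd.gsc(seg)
    assert z[-1] == pytest.approx(0.0, abs=1e-10)


def test_gsc_sign_antisymmetry(rng):
    # global signal dominated by a shared component, so flipping one
    # voxel's series leaves it essentially unchanged
    common = rng.standard_normal(32)
    seg = common[None, :] + 0.3 * rng.standard_normal((400, 32))
    z = fd.gsc(seg)
    flipped = seg.copy()
    flipped[0] = -flipped[0]
    z2 = fd.gsc(flipped)
    assert np.sign(z2[0]) == -np.sign(z[0])
    assert z2[0] == pytest.approx(-z[0], abs=0.02)


# ------------------------------------------------- dynamic stack

@pytest.fixture(scope="module")
def stack_setup():
    r = np.random.default_rng(5)
    mask = np.zeros((6, 6, 6), dtype=bool)
    mask[1:5, 1:5, 1:5] = True
    data = r.standard_normal((6, 6, 6, 80))
    series = fd.BoldSeries(data, [3, 3, 3], 2.0, mask)
    cfg = fd.AnalysisConfig(window_length=32, window_step=8, bandpass=False)
    plan = fd.plan_windows(80, 32, 8)
    return series, plan, cfg


def test_stack_shape_and_invariants(stack_setup):
    series, plan, cfg = stack_setup
    stack = fd.compute_dynamic_stack(series, plan, cfg)
    V = series.n_mask_voxels
    assert stack.values.shape == (5, plan.n_windows, V)
    alff_v = stack.index("ALFF")
    reho_v = stack.index("ReHo")
    dc_v = stack.index("DC")
    assert (alff_v[np.isfinite(alff_v)] >= 0).all()
    fin = reho_v[np.isfinite(reho_v)]
    assert (fin >= 0).all() and (fin <= 1).all()
    for w in range(plan.n_windows):
        assert np.nanmean(dc_v[w]) == pytest.approx(0.0, abs=1e-10)
        assert np.nanstd(dc_v[w], ddof=1) == pytest.approx(1.0, abs=1e-10)
    # VMHC/GSC finite (capped) everywhere in this nondegenerate data
    assert np.isfinite(stack.index("VMHC")).all()
    assert np.isfinite(stack.index("GSC")).all()


def test_single_window_stack_equals_static_indices(stack_setup):
    series, _, cfg = stack_setup
    plan = fd.plan_windows(80, 80, 4, taper="none")
    stack = fd.compute_dynamic_stack(series, plan, cfg)
    assert stack.n_windows == 1
    seg = fd.extract_window(series.masked(), plan, 0)
    np.testing.assert_allclose(
        stack.values[0, 0], fd.alff(seg, 2.0, cfg.alff_band), atol=1e-12
    )
    tbl = fd.neighbor_table(series.mask, cfg.reho_neighborhood)
    np.testing.assert_allclose(stack.values[1, 0], fd.reho(seg, tbl), atol=1e-12)
    np.testing.assert_allclose(stack.values[4, 0], fd.gsc(seg), atol=1e-12)


def test_zscore_mask_helper(rng):
    vals = rng.standard_normal(50)
    z = _zscore_mask(vals)
    assert z.mean() == pytest.approx(0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1, abs=1e-12)
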