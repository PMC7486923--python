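"""Transform algebra and exhaustive reference-free alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cryoprepro.align import (
    SearchEngine,
    SearchGrid,
    apply_transform,
    average_reference,
    compose_params,
    invert_params,
    reference_free_align,
    search_alignment,
    soft_circular_mask,
)
from cryoprepro.stack_io import ParamTable, ParticleStack


def _rms(a, b):
    return np.sqrt(np.mean((a - b) ** 2))


def test_identity_transform_is_bit_exact(smooth_image):
    out = apply_transform(smooth_image, 0.0, 0.0, 0.0)
    np.testing.assert_array_equal(out, smooth_image)


def test_quarter_turn_equals_array_rotation():
    rng = np.random.default_rng(0)
    img = rng.normal(size=(16, 16))
    np.testing.assert_allclose(apply_transform(img, 90.0), np.rot90(img, -1), atol=1e-6)
    np.testing.assert_allclose(apply_transform(img, 180.0), np.rot90(img, 2), atol=1e-6)


def test_non_finite_parameters_rejected(smooth_image):
    with pytest.raises(ValueError):
        apply_transform(smooth_image, np.nan, 0, 0)


def test_forward_inverse_round_trip_is_small(smooth_image):
    p = ParamTable([37.0], [1.3], [-2.1])
    pi = invert_params(p)
    fwd = apply_transform(smooth_image, 37.0, 1.3, -2.1, order=3)
    back = apply_transform(
        fwd, float(pi.psi[0]), float(pi.dx[0]), float(pi.dy[0]), order=3
    )
    dyn = smooth_image.max() - smooth_image.min()
    assert _rms(back, smooth_image) / dyn < 1e-2


def test_compose_identity_and_inverse_are_exact():
    p = ParamTable([25.0], [1.5], [-2.0])
    ident = ParamTable.identity(1)
    for left, right in ((ident, p), (p, ident)):
        c = compose_params(left, right)
        assert c.psi[0] == pytest.approx(25.0)
        assert (c.dx[0], c.dy[0]) == (pytest.approx(1.5), pytest.approx(-2.0))
    c = compose_params(p, invert_params(p))
    assert c.psi[0] == pytest.approx(0.0, abs=1e-12)
    assert abs(c.dx[0]) < 1e-12 and abs(c.dy[0]) < 1e-12


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    psi1=st.floats(0, 360, allow_nan=False),
    psi2=st.floats(0, 360, allow_nan=False),
    d=st.tuples(*[st.floats(-4, 4, allow_nan=False)] * 4),
)
def test_compose_is_associative_and_inverse_cancels(psi1, psi2, d):
    p1 = ParamTable([psi1], [d[0]], [d[1]])
    p2 = ParamTable([psi2], [d[2]], [d[3]])
    left = compose_params(compose_params(p1, p2), invert_params(p2))
    np.testing.assert_allclose(
        ((left.psi - p1.psi + 180) % 360) - 180, 0.0, atol=1e-9
    )
    np.testing.assert_allclose(left.dx, p1.dx, atol=1e-9)
    np.testing.assert_allclose(left.dy, p1.dy, atol=1e-9)


def test_sequential_application_matches_composed(smooth_image):
    p1 = ParamTable([40.0], [2.0], [1.0])
    p2 = ParamTable([75.0], [-1.0], [2.5])
    c = compose_params(p1, p2)
    seq = apply_transform(
        apply_transform(smooth_image, 40.0, 2.0, 1.0, order=3), 75.0, -1.0, 2.5, order=3
    )
    one = apply_transform(
        smooth_image, float(c.psi[0]), float(c.dx[0]), float(c.dy[0]), order=3
    )
    # single-interpolation error scale, measured by a forward/backward trip
    pi = invert_params(p1)
    interp = _rms(
        apply_transform(
            apply_transform(smooth_image, 40.0, 2.0, 1.0, order=3),
            float(pi.psi[0]), float(pi.dx[0]), float(pi.dy[0]), order=3,
        ),
        smooth_image,
    )
    assert _rms(seq, one) < 2 * max(interp, 1e-12)


def test_average_reference_identity_and_single(smooth_image):
    a = smooth_image
    b = np.roll(smooth_image, 3, axis=1)
    stack = ParticleStack(np.stack([a, b]).astype(np.float32))
    np.testing.assert_allclose(
        average_reference(stack), (a + b) / 2, atol=1e-6
    )
    single = ParticleStack(a[None].astype(np.float32))
    params = ParamTable([30.0], [1.0], [0.0])
    np.testing.assert_allclose(
        average_reference(single, params),
        apply_transform(a.astype(np.float32), 30.0, 1.0, 0.0),
        atol=1e-6,
    )


def test_average_reference_pose_cancellation(smooth_image):
    rng = np.random.default_rng(1)
    n = 8
    psis = rng.uniform(0, 360, n)
    dxs = rng.uniform(-2, 2, n)
    dys = rng.uniform(-2, 2, n)
    images = np.stack(
        [apply_transform(smooth_image, psis[i], dxs[i], dys[i], order=3) for i in range(n)]
    )
    stack = ParticleStack(images.astype(np.float32))
    inv = invert_params(ParamTable(psis, dxs, dys))
    ref = average_reference(stack, inv, order=3)
    dyn = smooth_image.max() - smooth_image.min()
    assert _rms(ref, smooth_image) / dyn < 1e-2


def test_search_self_is_identity_pose(smooth_image):
    grid = SearchGrid(max_shift=3, angular_step=15.0)
    psi, dx, dy, cc = search_alignment(smooth_image, smooth_image, grid)
    assert (psi, dx, dy) == (0.0, 0.0, 0.0)
    assert cc == pytest.approx(1.0, abs=1e-6)


def test_search_recovers_planted_grid_pose(smooth_image):
    grid = SearchGrid(max_shift=3, angular_step=15.0)
    ref = apply_transform(smooth_image, 30.0, 2.0, -1.0, order=1)
    psi, dx, dy, cc = search_alignment(smooth_image, ref, grid)
    assert (psi, dx, dy) == (30.0, 2.0, -1.0)
    assert cc > 0.99


def test_half_step_rotation_lands_on_flanking_angle(smooth_image):
    grid = SearchGrid(max_shift=1, angular_step=15.0)
    ref = apply_transform(smooth_image, 7.5, 0.0, 0.0, order=1)
    psi, _, _, _ = search_alignment(smooth_image, ref, grid)
    assert psi in (0.0, 15.0)


def test_search_invariant_to_affine_intensity_rescaling(smooth_image):
    rng = np.random.default_rng(2)
    img = smooth_image + rng.normal(0, 0.05, smooth_image.shape)
    ref = apply_transform(smooth_image, 45.0, 1.0, 1.0, order=1)
    grid = SearchGrid(max_shift=2, angular_step=45.0)
    base = search_alignment(img, ref, grid)
    scaled = search_alignment(3.7 * img - 11.0, ref, grid)
    assert base[:3] == scaled[:3]
    assert base[3] == pytest.approx(scaled[3], abs=1e-9)


def test_search_rejects_zero_variance():
    grid = SearchGrid(max_shift=2, angular_step=90.0)
    flat = np.zeros((16, 16))
    bumpy = np.zeros((16, 16))
    bumpy[8, 8] = 1.0
    with pytest.raises(ValueError):
        search_alignment(flat, bumpy, grid)
    with pytest.raises(ValueError):
        search_alignment(bumpy, flat, grid)


def test_mirror_search_detects_flipped_particle(smooth_image):
    grid = SearchGrid(max_shift=1, angular_step=30.0, mirror=True)
    ref = smooth_image[:, ::-1].copy()
    psi, dx, dy, cc, mirror = search_alignment(smooth_image, ref, grid)
    assert mirror and cc > 0.99
    same = search_alignment(smooth_image, smooth_image, grid)
    assert not same[4]


def test_soft_mask_shape():
    mask = soft_circular_mask(32, 10.0, falloff=2.0)
    c = (32 - 1) / 2
    yy, xx = np.mgrid[0:32, 0:32]
    rr = np.hypot(xx - c, yy - c)
    assert np.all(mask[rr >= 10.0] == 0.0)
    assert np.all(mask[rr <= 8.0] == 1.0)
    assert np.all((mask >= 0) & (mask <= 1))


def test_align_identical_images_is_identity_after_one_iteration(smooth_image):
    stack = ParticleStack(np.stack([smooth_image] * 5).astype(np.float32))
    res = reference_free_align(stack, 1, SearchGrid(max_shift=2, angular_step=30.0))
    np.testing.assert_array_equal(res.params.psi, 0.0)
    np.testing.assert_array_equal(res.params.dx, 0.0)
    np.testing.assert_array_equal(res.params.dy, 0.0)


def test_align_recovers_relative_poses_noiselessly():
    """Absolute pose is gauge-free; relative poses between particles must
    match the planted ones within one grid step."""
    from cryoprepro.evaluate import alignment_error, generative_to_aligning
    import pandas as pd
    from cryoprepro.simulate import make_phantom, project

    rng = np.random.default_rng(7)
    proj = project(make_phantom(48, seed=1))
    grid = SearchGrid(max_shift=3, angular_step=15.0)
    n = 20
    psis = rng.choice(np.arange(0, 360, 15.0), n)
    dxs = rng.integers(-2, 3, n).astype(float)
    dys = rng.integers(-2, 3, n).astype(float)
    images = np.stack(
        [apply_transform(proj, psis[i], dxs[i], dys[i], order=1) for i in range(n)]
    )
    res = reference_free_align(ParticleStack(images.astype(np.float32)), 3, grid)
    err = alignment_error(
        res.params, generative_to_aligning(pd.DataFrame({"psi": psis, "dx": dxs, "dy": dys}))
    )
    assert err["rotation_median_deg"] <= grid.angular_step + 1e-9
    assert err["shift_median_px"] <= 1.5  # one grid step + sub-pixel gauge slack
    assert res.mean_cc_per_iter == sorted(res.mean_cc_per_iter)


def test_iteration_split_reproduces_single_run():
    rng = np.random.default_rng(9)
    stack = ParticleStack(rng.normal(size=(10, 24, 24)).astype(np.float32))
    grid = SearchGrid(max_shift=2, angular_step=30.0)
    full = reference_free_align(stack, 5, grid)
    first = reference_free_align(stack, 3, grid)
    second = reference_free_align(stack, 2, grid, init_params=first.params)
    np.testing.assert_array_equal(full.params.psi, second.params.psi)
    np.testing.assert_array_equal(full.params.dx, second.params.dx)
    np.testing.assert_array_equal(full.params.dy, second.params.dy)


def test_mirror_grid_rejected_by_iterative_aligner(random_stack):
    with pytest.raises(NotImplementedError):
        reference_free_align(
            random_stack, 1, SearchGrid(max_shift=1, angular_step=90.0, mirror=True)
        )


def test_search_grid_validation():
    with pytest.raises(ValueError):
        SearchGrid(max_shift=-1)
    with pytest.raises(ValueError):
        SearchGrid(angular_step=7.0)  # does not divide 360
    with pytest.raises(ValueError):
        SearchGrid(shift_step=0)
    assert len(SearchGrid(max_shift=2, angular_step=45.0).angles) == 8
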