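"""Reference-free 2D alignment and in-plane transform algebra.

The aligner implements the classic two-stage scheme: average all particles
into a single reference, then exhaustively search each particle's in-plane
rotation and x/y shift against that reference by masked normalized
cross-correlation, keep the best pose, rebuild the reference from the
re-posed particles, and iterate.  No external template is ever used, so
the recovered poses carry one global gauge freedom (a common rotation and
shift applied to every particle leaves the objective unchanged).

Transform convention (SPIDER-style, used consistently everywhere): a pose
(psi, dx, dy) rotates the particle counter-clockwise by psi degrees about
the image center, then shifts the content by (dx, dy) pixels; stored
parameters map the particle into the reference frame.  Composition is
therefore psi = psi1 + psi2 (mod 360), d = R(psi2) d1 + d2.

The search enumerates every pose on the grid.  Rotations are resampled
explicitly at each grid angle; all shifts for one angle are scored at once
through FFT cross-correlation, which is exactly equivalent to transforming
and scoring each pose one by one because the scoring mask vanishes outside
radius H/2 - max_shift (no circular wrap-around can reach it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stack_io import ParamTable, ParticleStack

__all__ = [
    "SearchGrid",
    "AlignmentResult",
    "soft_circular_mask",
    "edge_mean",
    "apply_transform",
    "transform_stack",
    "compose_params",
    "invert_params",
    "average_reference",
    "search_alignment",
    "reference_free_align",
]

# Correlations closer than this are treated as exact ties so that the
# deterministic tie-break, not floating-point round-off, picks the pose.
TIE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class SearchGrid:
    """Exhaustive pose grid: all combinations of shift and rotation.

    ``angular_step`` must divide 360 so the rotation grid closes; the grid
    enumerates (2*max_shift/shift_step + 1)^2 * (360/angular_step) poses.
    """

    max_shift: int = 4
    shift_step: int = 1
    angular_step: float = 3.0
    mirror: bool = False  # also score the x-flipped candidate

    def __post_init__(self) -> None:
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")
        if self.shift_step < 1:
            raise ValueError("shift_step must be >= 1")
        if not (0 < self.angular_step <= 360) or abs(
            round(360 / self.angular_step) - 360 / self.angular_step
        ) > 1e-9:
            raise ValueError("angular_step must be positive and divide 360")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(0.0, 360.0, self.angular_step)

    @property
    def shifts(self) -> np.ndarray:
        return np.arange(-self.max_shift, self.max_shift + 1, self.shift_step)

    @classmethod
    def for_box(cls, box: int, angular_step: float = 3.0) -> "SearchGrid":
        """Default grid for a box size: max_shift = floor(0.1 * H)."""
        return cls(max_shift=int(0.1 * box), angular_step=angular_step)


@dataclass
class AlignmentResult:
    """Poses, per-particle peak correlations, and per-iteration diagnostics."""

    params: ParamTable
    peak_cc: np.ndarray
    mean_cc_per_iter: list = field(default_factory=list)
    references: list = field(default_factory=list)


def soft_circular_mask(box: int, radius: float, falloff: float = 2.0) -> np.ndarray:
    """Raised-cosine disc: 1 inside ``radius - falloff``, 0 outside ``radius``."""
    c = (box - 1) / 2.0
    yy, xx = np.mgrid[0:box, 0:box]
    rr = np.hypot(xx - c, yy - c)
    mask = np.zeros((box, box), dtype=np.float64)
    mask[rr <= radius - falloff] = 1.0
    edge = (rr > radius - falloff) & (rr < radius)
    mask[edge] = 0.5 * (1.0 + np.cos(np.pi * (rr[edge] - radius + falloff) / falloff))
    return mask


def edge_mean(image: np.ndarray) -> float:
    """Mean intensity of the one-pixel border (the out-of-field fill value)."""
    return float(
        np.concatenate([image[0], image[-1], image[1:-1, 0], image[1:-1, -1]]).mean()
    )


def _snap(coords: np.ndarray, decimals: int = 9) -> np.ndarray:
    """Round sampling coordinates to kill 1e-16-scale trigonometric noise.

    scipy's constant-mode interpolation yields cval for any coordinate even
    marginally outside the grid, so an exact boundary coordinate computed as
    -4e-16 would otherwise flip a whole pixel to the fill value at
    quarter-turn angles.
    """
    return np.round(coords, decimals)


def _sample_coords(box: int, psi_deg: np.ndarray, mirror: bool = False):
    """Input-pixel coordinates that realize a CCW rotation for each angle.

    Returns (in_y, in_x) arrays of shape (A, box, box) mapping output pixels
    back to input pixels (the inverse map interpolators need).
    """
    c = (box - 1) / 2.0
    yy, xx = np.mgrid[0:box, 0:box].astype(np.float64)
    t = np.deg2rad(np.atleast_1d(psi_deg))[:, None, None]
    dxg = xx[None] - c
    dyg = yy[None] - c
    # inverse rotation R(-psi) applied to output offsets
    in_x = np.cos(t) * dxg + np.sin(t) * dyg + c
    in_y = -np.sin(t) * dxg + np.cos(t) * dyg + c
    if mirror:
        in_x = (box - 1) - in_x
    return in_y, in_x


def apply_transform(
    image: np.ndarray,
    psi: float,
    dx: float = 0.0,
    dy: float = 0.0,
    mirror: bool = False,
    order: int = 1,
    cval: float | None = None,
) -> np.ndarray:
    """Mirror (optionally), rotate CCW by ``psi`` about the center, then shift.

    Out-of-field pixels take the image's edge-mean value (or ``cval``).
    The identity pose returns a bit-exact copy; the input is never modified.
    ``order`` selects the spline degree (1 = bilinear for search speed,
    3 = cubic for final output quality).
    """
    image = np.asarray(image)
    if not (np.isfinite(psi) and np.isfinite(dx) and np.isfinite(dy)):
        raise ValueError("non-finite transform parameters")
    if psi % 360 == 0 and dx == 0 and dy == 0 and not mirror:
        return image.astype(np.float64, copy=True)
    if cval is None:
        cval = edge_mean(image)
    box = image.shape[0]
    in_y, in_x = _sample_coords(box, np.array([psi]), mirror=mirror)
    # the shift acts in the output frame after the rotation, so it enters
    # the inverse sampling map rotated by R(-psi) (and mirrored if set)
    t = np.deg2rad(psi)
    dxr = np.cos(t) * dx + np.sin(t) * dy
    dyr = -np.sin(t) * dx + np.cos(t) * dy
    if mirror:
        dxr = -dxr
    out = ndimage.map_coordinates(
        image.astype(np.float64),
        [_snap(in_y[0] - dyr), _snap(in_x[0] - dxr)],
        order=order,
        mode="constant",
        cval=cval,
    )
    return out


def transform_stack(
    stack: ParticleStack, params: ParamTable, order: int = 1
) -> ParticleStack:
    """Apply one pose per particle; a new stack, the input untouched."""
    if len(params) != stack.n:
        raise ValueError("parameter rows do not match stack size")
    out = np.empty_like(stack.images, dtype=np.float32)
    for i in range(stack.n):
        psi, dx, dy, mirror = params.row(i)
        out[i] = apply_transform(stack.images[i], psi, dx, dy, mirror=mirror, order=order)
    return ParticleStack(out, stack.pixel_size,
                         None if stack.meta is None else stack.meta.copy())


def compose_params(first: ParamTable, second: ParamTable) -> ParamTable:
    """Single pose equivalent to applying ``first`` then ``second``.

    In the continuous model: psi = psi1 + psi2 mod 360 and
    d = R(psi2) d1 + d2, exactly (no resampling involved).
    """
    if np.any(first.mirror) or np.any(second.mirror):
        raise NotImplementedError("composition with mirror poses is not supported")
    rad = np.deg2rad(second.psi)
    cos, sin = np.cos(rad), np.sin(rad)
    return ParamTable(
        psi=first.psi + second.psi,
        dx=cos * first.dx - sin * first.dy + second.dx,
        dy=sin * first.dx + cos * first.dy + second.dy,
    )


def invert_params(params: ParamTable) -> ParamTable:
    """Group inverse: compose(p, invert_params(p)) is the identity pose."""
    if np.any(params.mirror):
        raise NotImplementedError("inversion of mirror poses is not supported")
    rad = np.deg2rad(-params.psi)
    cos, sin = np.cos(rad), np.sin(rad)
    return ParamTable(
        psi=-params.psi,
        dx=-(cos * params.dx - sin * params.dy),
        dy=-(sin * params.dx + cos * params.dy),
    )


def average_reference(
    stack: ParticleStack, params: ParamTable | None = None, order: int = 1
) -> np.ndarray:
    """Pixel-wise mean of the (re-posed) particles — the evolving template."""
    if params is None:
        params = ParamTable.identity(stack.n)
    if len(params) != stack.n:
        raise ValueError("parameter rows do not match stack size")
    acc = np.zeros(stack.images.shape[1:], dtype=np.float64)
    for i in range(stack.n):
        psi, dx, dy, mirror = params.row(i)
        acc += apply_transform(stack.images[i], psi, dx, dy, mirror=mirror, order=order)
    return acc / stack.n


# ---------------------------------------------------------------------------
# Exhaustive pose search
# ---------------------------------------------------------------------------

class SearchEngine:
    """Caches everything reusable for repeated pose searches on one box size.

    The masked normalized cross-correlation of a candidate pose with the
    reference is assembled from three FFT cross-correlations per rotation
    angle (candidate, candidate squared, both against the mask / the masked
    reference), giving every shift at once.
    """

    def __init__(self, box: int, grid: SearchGrid, order: int = 1):
        self.box = box
        self.grid = grid
        self.order = order
        radius = box / 2.0 - grid.max_shift
        if radius <= 1.0:
            raise ValueError("max_shift leaves no usable mask radius")
        self.mask = soft_circular_mask(box, radius)
        self.wsum = self.mask.sum()
        self._f_mask = np.fft.rfft2(self.mask)
        self._shift_idx = np.mod(grid.shifts, box)
        self.angles = grid.angles
        self._win = np.ix_(
            np.arange(len(self.angles)), self._shift_idx, self._shift_idx
        )
        self._coords = _sample_coords(box, self.angles)
        signed = np.mod(self.angles + 180.0, 360.0) - 180.0
        self._psi_signed = signed

    # -- candidate side -----------------------------------------------------

    def rotate_all(self, image: np.ndarray) -> np.ndarray:
        """The image resampled at every grid angle, shape (A, box, box)."""
        cval = edge_mean(image)
        flat = ndimage.map_coordinates(
            np.asarray(image, dtype=np.float64),
            [_snap(self._coords[0].ravel()), _snap(self._coords[1].ravel())],
            order=self.order,
            mode="constant",
            cval=cval,
        )
        rots = flat.reshape(len(self.angles), self.box, self.box)
        if self.order == 1:
            # bilinear at psi = 0 is the identity; enforce it bit-exactly
            rots[0] = np.asarray(image, dtype=np.float64)
        return rots

    def candidate_data(self, rotations_or_image: np.ndarray) -> dict:
        """Everything query-independent about one candidate particle.

        Accepts a raw image or a precomputed ``rotate_all`` result.  The
        returned dict holds the rotations' FFT plus the windowed mask
        correlations (per-pose masked sum and variance of the candidate),
        which can be reused against any number of references.
        """
        arr = np.asarray(rotations_or_image, dtype=np.float64)
        rots = self.rotate_all(arr) if arr.ndim == 2 else arr
        box = self.box
        f_rot = np.fft.rfft2(rots)
        f_rot2 = np.fft.rfft2(rots * rots)
        win = self._win
        s1 = np.fft.irfft2(self._f_mask * f_rot.conj(), s=(box, box))[win]
        s2 = np.fft.irfft2(self._f_mask * f_rot2.conj(), s=(box, box))[win]
        var_a = s2 - s1 * s1 / self.wsum
        bad = var_a <= 0
        return {
            "f_rot": f_rot,
            "s1": s1,
            "inv_sqrt_var": 1.0 / np.sqrt(np.where(bad, 1.0, var_a)),
            "bad": bad,
        }

    def refresh_fft(self, cand: dict, rotations: np.ndarray) -> dict:
        """Re-attach the rotations' FFT to a cached candidate record
        (used when the FFT was dropped to save memory)."""
        out = dict(cand)
        out["f_rot"] = np.fft.rfft2(np.asarray(rotations, dtype=np.float64))
        return out

    # -- reference side -----------------------------------------------------

    def prepare_reference(self, reference: np.ndarray):
        ref = np.asarray(reference, dtype=np.float64)
        mb = self.mask * ref
        sb1 = mb.sum()
        sb2 = (self.mask * ref * ref).sum()
        var_b = sb2 - sb1 * sb1 / self.wsum
        if var_b <= 0:
            raise ValueError("reference has zero variance under the mask")
        return {"f_mb": np.fft.rfft2(mb), "sb1": sb1, "var_b": var_b}

    # -- scoring ------------------------------------------------------------

    def scores(self, cand: dict, ref_data) -> np.ndarray:
        """cc[a, iy, ix] for every angle and (dy, dx) on the shift grid."""
        box = self.box
        x = np.fft.irfft2(ref_data["f_mb"] * cand["f_rot"].conj(), s=(box, box))[self._win]
        num = x - cand["s1"] * (ref_data["sb1"] / self.wsum)
        cc = num * cand["inv_sqrt_var"] / np.sqrt(ref_data["var_b"])
        cc[cand["bad"]] = -2.0  # degenerate poses never win
        return cc

    def best(self, cc: np.ndarray):
        """Deterministic argmax: ties (within TIE_TOLERANCE of the peak) go
        to the smallest |psi|, then the smallest shift norm, then
        lexicographic (psi, dx, dy)."""
        peak = cc.max()
        ties = np.argwhere(cc >= peak - TIE_TOLERANCE)
        shifts = self.grid.shifts
        best_key = None
        best_pose = None
        for a, iy, ix in ties:
            psi_s = self._psi_signed[a]
            dx = float(shifts[ix])
            dy = float(shifts[iy])
            key = (abs(psi_s), dx * dx + dy * dy, psi_s, dx, dy)
            if best_key is None or key < best_key:
                best_key = key
                best_pose = (float(self.angles[a]), dx, dy, float(cc[a, iy, ix]))
        return best_pose

    def search(self, image: np.ndarray, ref_data) -> tuple[float, float, float, float]:
        return self.best(self.scores(self.candidate_data(image), ref_data))


def search_alignment(
    image: np.ndarray,
    reference: np.ndarray,
    grid: SearchGrid,
    order: int = 1,
) -> tuple[float, float, float, float]:
    """Best (psi, dx, dy, cc) of ``image`` against ``reference`` on the grid.

    A soft circular mask of radius H/2 - max_shift is applied to both sides
    before scoring; cc is the masked normalized cross-correlation in
    [-1, 1].  Raises if either side has zero variance under the mask.
    """
    image = np.asarray(image, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if image.shape != reference.shape:
        raise ValueError("image and reference shapes differ")
    engine = SearchEngine(image.shape[0], grid, order=order)
    masked = engine.mask * image
    if (engine.mask * image * image).sum() - masked.sum() ** 2 / engine.wsum <= 0:
        raise ValueError("image has zero variance under the mask")
    ref_data = engine.prepare_reference(reference)
    pose = engine.search(image, ref_data)
    if not grid.mirror:
        return pose
    # mirror-then-rotate candidates: an exact x-flip of the array, so the
    # mirrored branch reuses the ordinary machinery
    pose_m = engine.search(np.ascontiguousarray(image[:, ::-1]), ref_data)
    if pose_m[3] > pose[3] + TIE_TOLERANCE:
        return (*pose_m[:3], pose_m[3], True)
    return (*pose[:3], pose[3], False)


def reference_free_align(
    stack: ParticleStack,
    n_iter: int,
    grid: SearchGrid | None = None,
    init_params: ParamTable | None = None,
    order: int = 1,
) -> AlignmentResult:
    """Iterative reference-free alignment of a whole stack.

    Each iteration rebuilds the reference as the average of the particles
    under the current poses (the plain unaligned average on iteration one,
    unless ``init_params`` seeds it), then re-searches every particle
    against it from the raw input images — poses are absolute, never
    accumulated, so the search grid bounds always hold.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if grid is None:
        grid = SearchGrid.for_box(stack.box)
    if grid.mirror:
        raise NotImplementedError(
            "mirror search is available for retrieval, not for the iterative aligner"
        )
    engine = SearchEngine(stack.box, grid, order=order)
    params = ParamTable.identity(stack.n) if init_params is None else init_params
    peak_cc = np.zeros(stack.n)
    mean_ccs: list[float] = []
    references: list[np.ndarray] = []
    # Rotations of the raw images and their mask statistics are
    # iteration-independent; cache the rotations in float32 when the stack
    # is small enough, else recompute everything per iteration.
    cache_bytes = stack.n * len(engine.angles) * stack.box**2 * 4
    rot_cache: list[np.ndarray] | None = None
    cand_cache: list[dict] | None = None
    if cache_bytes <= 600e6:
        rot_cache, cand_cache = [], []
        for i in range(stack.n):
            rots = engine.rotate_all(stack.images[i]).astype(np.float32)
            cd = engine.candidate_data(rots)
            del cd["f_rot"]  # recomputed per iteration: too large to keep
            rot_cache.append(rots)
            cand_cache.append(cd)
    for _ in range(n_iter):
        reference = average_reference(stack, params, order=order)
        references.append(reference)
        ref_data = engine.prepare_reference(reference)
        psi = np.zeros(stack.n)
        dx = np.zeros(stack.n)
        dy = np.zeros(stack.n)
        for i in range(stack.n):
            if cand_cache is not None:
                cand = engine.refresh_fft(cand_cache[i], rot_cache[i])
            else:
                cand = engine.candidate_data(stack.images[i])
            psi[i], dx[i], dy[i], peak_cc[i] = engine.best(
                engine.scores(cand, ref_data)
            )
        params = ParamTable(psi, dx, dy)
        mean_ccs.append(float(peak_cc.mean()))
    return AlignmentResult(params, peak_cc, mean_ccs, references)
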