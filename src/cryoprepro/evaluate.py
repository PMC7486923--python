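"""Quantitative evaluation: SNR bookkeeping, rotation/translation-invariant
particle retrieval with true-positive counting, aligned class averages, and
gauge-fixed alignment-error statistics.

Retrieval operationalizes "most resembling" as the highest masked
normalized cross-correlation over an exhaustive rotation/shift grid — the
same objective a fast rotational matcher optimizes, searched directly.
Because reference-free poses are only defined up to one global rotation
and shift, alignment errors are measured after fitting that single global
pose (the gauge) between the estimated and true parameter sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import SearchEngine, SearchGrid, apply_transform, invert_params
from .stack_io import ParamTable, ParticleStack

__all__ = [
    "RetrievalResult",
    "estimate_snr",
    "retrieve_knn",
    "retrieve_knn_all",
    "aligned_average",
    "true_positive_rate",
    "alignment_error",
    "generative_to_aligning",
]


@dataclass
class RetrievalResult:
    """The k best matches for one query particle.

    ``indices`` are stack indices ordered by descending score, excluding
    the query itself; ``params`` holds the best relative pose mapping each
    retrieved particle onto the query.
    """

    query: int
    indices: np.ndarray
    params: ParamTable
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.query in set(int(i) for i in self.indices):
            raise ValueError("retrieved indices must exclude the query")


def estimate_snr(noisy, signal) -> float:
    """Variance ratio var(signal) / var(noisy - signal), pooled over a stack.

    This is the working definition of SNR throughout: the noise is whatever
    separates the observed image from the known clean signal.  A zero
    signal gives 0; zero residual noise raises (effectively noiseless).
    """
    noisy = noisy.images if isinstance(noisy, ParticleStack) else np.asarray(noisy)
    signal = signal.images if isinstance(signal, ParticleStack) else np.asarray(signal)
    if noisy.shape != signal.shape:
        raise ValueError("noisy and signal shapes differ")
    sig_var = float(np.asarray(signal, dtype=np.float64).var())
    noise_var = float((np.asarray(noisy, np.float64) - np.asarray(signal, np.float64)).var())
    if sig_var == 0.0:
        return 0.0
    if noise_var == 0.0:
        raise ZeroDivisionError("zero noise variance: signals are effectively noiseless")
    return sig_var / noise_var


def retrieve_knn(
    query_index: int,
    stack: ParticleStack,
    k: int,
    grid: SearchGrid | None = None,
    engine: SearchEngine | None = None,
) -> RetrievalResult:
    """The k stack members best matching the query under optimal alignment.

    Every other particle is searched over the full pose grid against the
    query; the k highest peak correlations win.  Ordering among equal
    scores is by particle index (stable).
    """
    if grid is None and engine is None:
        grid = SearchGrid.for_box(stack.box)
    if engine is None:
        engine = SearchEngine(stack.box, grid)
    if not (0 < k < stack.n):
        raise ValueError(f"k must be in (0, n={stack.n})")
    return retrieve_knn_all([query_index], stack, k, engine=engine)[0]


def retrieve_knn_all(
    query_indices,
    stack: ParticleStack,
    k: int,
    grid: SearchGrid | None = None,
    engine: SearchEngine | None = None,
) -> list[RetrievalResult]:
    """Retrieval for several queries, sharing per-candidate work.

    Resampling each candidate at every grid angle and correlating it with
    the mask are query-independent and dominate the cost, so each
    candidate is processed once and scored against every query before
    moving on.
    """
    if engine is None:
        if grid is None:
            grid = SearchGrid.for_box(stack.box)
        engine = SearchEngine(stack.box, grid)
    queries = [int(q) for q in query_indices]
    if not (0 < k < stack.n):
        raise ValueError(f"k must be in (0, n={stack.n})")
    refs = {q: engine.prepare_reference(stack.images[q]) for q in queries}
    poses = np.zeros((len(queries), stack.n, 3))
    ccs = np.full((len(queries), stack.n), -np.inf)
    for i in range(stack.n):
        cand = engine.candidate_data(stack.images[i])
        for qi, q in enumerate(queries):
            if i == q:
                continue
            psi, dx, dy, cc = engine.best(engine.scores(cand, refs[q]))
            poses[qi, i] = (psi, dx, dy)
            ccs[qi, i] = cc
    results = []
    for qi, q in enumerate(queries):
        candidates = np.array([i for i in range(stack.n) if i != q])
        order = candidates[np.argsort(-ccs[qi, candidates], kind="stable")[:k]]
        results.append(
            RetrievalResult(
                query=q,
                indices=order,
                params=ParamTable(poses[qi, order, 0], poses[qi, order, 1],
                                  poses[qi, order, 2]),
                scores=ccs[qi, order],
            )
        )
    return results


def aligned_average(stack: ParticleStack, result: RetrievalResult, order: int = 3) -> np.ndarray:
    """Mean of the retrieved particles, each mapped onto the query's frame.

    The stack passed here chooses whose pixels are averaged: pass the
    original stack to average raw particles under poses found elsewhere
    (e.g. on denoised surrogates) — parameters from one stack, pixels from
    another.
    """
    imgs = []
    for j, i in enumerate(result.indices):
        psi, dx, dy, mirror = result.params.row(j)
        imgs.append(apply_transform(stack.images[int(i)], psi, dx, dy,
                                    mirror=mirror, order=order))
    if not imgs:
        raise ValueError("retrieval result holds no particles")
    return np.mean(imgs, axis=0)


def true_positive_rate(results, truth: pd.DataFrame) -> float:
    """Fraction of retrieved particles sharing the query's true view id.

    Pooled over all queries: TP count / total retrieved.
    """
    views = np.asarray(truth["view"])
    tp = 0
    total = 0
    for res in results:
        need = max(int(res.query), int(np.max(res.indices)) if len(res.indices) else 0)
        if need >= len(views):
            raise IndexError("ground truth does not cover all retrieved indices")
        qview = views[res.query]
        tp += int(np.sum(views[res.indices] == qview))
        total += len(res.indices)
    if total == 0:
        raise ValueError("no retrievals to score")
    return tp / total


def generative_to_aligning(truth: pd.DataFrame) -> pd.DataFrame:
    """Invert generative poses (projection -> particle) into aligning ones.

    The simulator records the pose that *produced* each particle; an
    aligner estimates the pose that maps the particle back.  Comparing the
    two requires inverting one side; this returns the inverted truth as a
    psi/dx/dy frame suitable for :func:`alignment_error`.
    """
    inv = invert_params(
        ParamTable(np.asarray(truth["psi"]), np.asarray(truth["dx"]),
                   np.asarray(truth["dy"]))
    )
    return pd.DataFrame({"psi": inv.psi, "dx": inv.dx, "dy": inv.dy})


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    rad = np.deg2rad(angles_deg)
    return float(np.rad2deg(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))))


def _wrap180(angles_deg: np.ndarray) -> np.ndarray:
    return np.mod(np.asarray(angles_deg) + 180.0, 360.0) - 180.0


def alignment_error(estimated: ParamTable, truth: pd.DataFrame) -> dict:
    """Residual rotation/shift statistics after fixing the global gauge.

    Fits the single pose g minimizing the residuals of
    compose(estimated_i, g) against the true poses (rotation by circular
    mean, shift by least squares given that rotation), then reports the
    per-particle rotation residual (deg, wrapped to [-180, 180)) and shift
    residual (Euclidean px) as median and RMS.
    """
    if len(estimated) != len(truth):
        raise ValueError("estimated and truth lengths differ")
    psi_t = np.asarray(truth["psi"], dtype=float)
    dx_t = np.asarray(truth["dx"], dtype=float)
    dy_t = np.asarray(truth["dy"], dtype=float)
    gauge_psi = _circular_mean_deg(psi_t - estimated.psi)
    rad = np.deg2rad(gauge_psi)
    cos, sin = np.cos(rad), np.sin(rad)
    rx = cos * estimated.dx - sin * estimated.dy
    ry = sin * estimated.dx + cos * estimated.dy
    gauge_dx = float(np.mean(dx_t - rx))
    gauge_dy = float(np.mean(dy_t - ry))
    rot_res = _wrap180(psi_t - (estimated.psi + gauge_psi))
    shift_res = np.hypot(dx_t - (rx + gauge_dx), dy_t - (ry + gauge_dy))
    return {
        "rotation_median_deg": float(np.median(np.abs(rot_res))),
        "rotation_rms_deg": float(np.sqrt(np.mean(rot_res**2))),
        "shift_median_px": float(np.median(shift_res)),
        "shift_rms_px": float(np.sqrt(np.mean(shift_res**2))),
        "gauge": (gauge_psi, gauge_dx, gauge_dy),
    }
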