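"""Membrane embedding: per-span and whole-protein estimates, frame transforms,
and score-driven optimization of the membrane placement.

The embedding of a span is the midpoint and direction of its two anchor CA
atoms; the protein embedding averages span centers and (sign-corrected) span
normals.  ``transform_into_membrane`` moves the protein so its estimated
embedding coincides with the membrane default frame; ``optimize_embedding``
instead moves the membrane, searching depth offset and two tilt angles for
the lowest total score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .core import (
    DegenerateGeometryError,
    MembraneGeometry,
    RigidTransform,
    Structure,
    apply_transform,
    rotation_about_axis,
)
from .topology import Span, SpanningTopology

__all__ = [
    "Embedding",
    "EmbeddingSearchConfig",
    "span_embedding",
    "protein_embedding",
    "set_membrane_position",
    "transform_into_membrane",
    "optimize_embedding",
]


@dataclass(frozen=True)
class Embedding:
    """A (center, normal) summary of position relative to the bilayer."""

    center: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "normal", np.asarray(self.normal, dtype=float))
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("embedding normal must be unit length")


def span_embedding(structure: Structure, span: Span) -> Embedding:
    """Embedding of one span: CA-midpoint center, CA start→end unit normal."""
    a = structure.residue(span.chain, span.start).ca
    b = structure.residue(span.chain, span.end).ca
    d = b - a
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise DegenerateGeometryError(f"span {span.start}-{span.end}: zero-length CA axis")
    return Embedding(0.5 * (a + b), d / n)


def protein_embedding(structure: Structure, topology: SpanningTopology) -> Embedding:
    """Whole-protein embedding: average of span centers and span normals.

    Antiparallel spans are sign-corrected before averaging: any span normal
    whose dot product with the first span's normal is negative is flipped.
    """
    if len(topology) == 0:
        raise ValueError("protein embedding requires at least one span")
    embeds = [span_embedding(structure, s) for s in topology.spans]
    center = np.mean([e.center for e in embeds], axis=0)
    ref = embeds[0].normal
    normals = [e.normal if np.dot(e.normal, ref) >= 0 else -e.normal for e in embeds]
    mean_normal = np.mean(normals, axis=0)
    n = np.linalg.norm(mean_normal)
    if n < 1e-9:
        raise DegenerateGeometryError("span normals cancel; protein normal undefined")
    return Embedding(center, mean_normal / n)


def set_membrane_position(
    geom: MembraneGeometry, center: np.ndarray, normal: np.ndarray
) -> MembraneGeometry:
    """Return a geometry with the given center and (normalized) normal."""
    normal = np.asarray(normal, dtype=float)
    n = np.linalg.norm(normal)
    if n < 1e-9:
        raise ValueError("membrane normal must be nonzero")
    return replace(geom, center=np.asarray(center, dtype=float), normal=normal / n)


def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    c = float(np.dot(a, b))
    axis = np.cross(a, b)
    if np.linalg.norm(axis) < 1e-12:
        if c > 0:
            return np.eye(3)
        # Antiparallel: rotate 180 degrees about any axis perpendicular to a.
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return rotation_about_axis(perp, np.pi)
    return rotation_about_axis(axis, float(np.arctan2(np.linalg.norm(axis), c)))


def transform_into_membrane(
    structure: Structure,
    topology: SpanningTopology,
    default_geom: MembraneGeometry | None = None,
) -> tuple[Structure, RigidTransform]:
    """Move the protein so its estimated embedding matches the membrane frame.

    The estimated embedding center maps to the membrane center and the
    embedding normal to the membrane normal (default: origin and +z).  The
    membrane itself stays fixed; the returned transform is the one applied to
    the structure.
    """
    geom = default_geom if default_geom is not None else MembraneGeometry()
    emb = protein_embedding(structure, topology)
    R = _rotation_aligning(emb.normal, geom.normal)
    t = geom.center - R @ emb.center
    transform = RigidTransform(R, t)
    return apply_transform(structure, transform), transform


@dataclass(frozen=True)
class EmbeddingSearchConfig:
    """Grid + local-refinement schedule for membrane placement search.

    The search moves the membrane: a depth offset along its own normal and
    two tilts of the normal about in-plane axes.  A coarse grid scan is
    followed by coordinate-wise quadratic refinement; the score never
    increases relative to the input placement.
    """

    z_range: float = 10.0
    z_step: float = 1.0
    tilt_range_deg: float = 30.0
    tilt_step_deg: float = 5.0
    refine_tol: float = 1e-3
    max_refine_iter: int = 40


def _perpendicular_axes(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def optimize_embedding(
    structure: Structure,
    geom: MembraneGeometry,
    topology: SpanningTopology,
    score_fn: Callable[[Structure, MembraneGeometry, SpanningTopology], "object"],
    search_cfg: EmbeddingSearchConfig | None = None,
):
    """Search membrane depth offset and tilts for the lowest total score.

    ``score_fn(structure, geom, topology)`` must return an object with a
    ``total`` attribute (a ScoreBreakdown).  Deterministic: fixed config and
    inputs give bit-identical output.  Returns ``(geometry, breakdown)`` with
    ``breakdown.total <=`` the input placement's total.
    """
    cfg = search_cfg if search_cfg is not None else EmbeddingSearchConfig()
    u_axis, v_axis = _perpendicular_axes(geom.normal)

    def place(params: np.ndarray) -> MembraneGeometry:
        dz, tu, tv = params
        R = rotation_about_axis(v_axis, np.radians(tv)) @ rotation_about_axis(
            u_axis, np.radians(tu)
        )
        normal = R @ geom.normal
        normal = normal / np.linalg.norm(normal)
        return replace(geom, center=geom.center + dz * geom.normal, normal=normal)

    cache: dict[tuple[float, float, float], float] = {}

    def evaluate(params: np.ndarray):
        key = (round(float(params[0]), 9), round(float(params[1]), 9), round(float(params[2]), 9))
        if key not in cache:
            cache[key] = float(score_fn(structure, place(params), topology).total)
        return cache[key]

    best = np.zeros(3)
    best_score = evaluate(best)

    zs = np.arange(-cfg.z_range, cfg.z_range + 0.5 * cfg.z_step, cfg.z_step)
    tilts = np.arange(
        -cfg.tilt_range_deg, cfg.tilt_range_deg + 0.5 * cfg.tilt_step_deg, cfg.tilt_step_deg
    )
    for dz in zs:
        for tu in tilts:
            for tv in tilts:
                params = np.array([dz, tu, tv])
                s = evaluate(params)
                if s < best_score - 1e-12:
                    best_score, best = s, params

    # Coordinate-wise quadratic refinement; accept only strict improvements.
    # A dimension whose search range is zero stays frozen.
    ranges = np.array([cfg.z_range, cfg.tilt_range_deg, cfg.tilt_range_deg])
    steps = np.minimum(
        np.array([cfg.z_step, cfg.tilt_step_deg, cfg.tilt_step_deg], dtype=float), ranges
    )
    for _ in range(cfg.max_refine_iter):
        moved = False
        for k in range(3):
            h = steps[k]
            if h < cfg.refine_tol:
                continue
            lo, hi = best.copy(), best.copy()
            lo[k] -= h
            hi[k] += h
            s_lo, s_mid, s_hi = evaluate(lo), best_score, evaluate(hi)
            denom = s_lo - 2.0 * s_mid + s_hi
            if denom > 1e-12:  # convex: jump to the parabola vertex
                delta = 0.5 * h * (s_lo - s_hi) / denom
                cand = best.copy()
                cand[k] += float(np.clip(delta, -h, h))
                s_cand = evaluate(cand)
                candidates = [(s_cand, cand), (s_lo, lo), (s_hi, hi)]
            else:
                candidates = [(s_lo, lo), (s_hi, hi)]
            s_new, p_new = min(candidates, key=lambda c: c[0])
            if s_new < best_score - 1e-12:
                best_score, best = s_new, p_new
                moved = True
            else:
                steps[k] = 0.5 * h
        if not moved and np.all(steps < cfg.refine_tol):
            break
    final_geom = place(best)
    return final_geom, score_fn(structure, final_geom, topology)
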