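"""Shared fixtures and independent brute-force oracles.

The oracles re-state the geometric definitions directly (double loops over
voxel centers, ray-casting point-in-polygon) so the vectorized library
implementations are checked against code that shares nothing with them.
"""

from __future__ import annotations

import numpy as np
import pytest

from hypotriage import Cohort, OverlapFeatures, PatientRecord
from hypotriage.geometry import _MARGIN_ATTR, _OPPOSITE, StructureMask


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_expand(ctv: StructureMask, margins) -> np.ndarray:
    """O(N * |CTV|) evaluation of the piecewise-ellipsoidal margin predicate.

    For every true CTV voxel center c, mark every voxel center p whose
    displacement d = p - c satisfies
    sum_axis (d_axis / margin(sign of d_axis))^2 <= 1.
    """
    centers = [ctv.axis_centers(axis) for axis in range(3)]
    out = np.zeros(ctv.shape, bool)
    for ci, cj, ck in np.argwhere(ctv.voxels):
        total = np.zeros(ctv.shape)
        for axis, c_index in enumerate((ci, cj, ck)):
            d = centers[axis] - centers[axis][c_index]
            positive = ctv.axis_labels[axis]
            m_pos = getattr(margins, _MARGIN_ATTR[positive])
            m_neg = getattr(margins, _MARGIN_ATTR[_OPPOSITE[positive]])
            term = np.zeros_like(d)
            for mask, m in ((d > 0, m_pos), (d < 0, m_neg)):
                term[mask] = (d[mask] / m) ** 2 if m > 0 else np.inf
            shape = [1, 1, 1]
            shape[axis] = d.size
            total = total + term.reshape(shape)
        out |= total <= 1.0 + 1e-9
    return out


def point_in_polygon(px: float, py: float, vertices: np.ndarray) -> bool:
    """Even-odd ray-casting test, written independently of shapely."""
    inside = False
    n = len(vertices)
    j = n - 1
    for i in range(n):
        xi, yi = vertices[i]
        xj, yj = vertices[j]
        if (yi > py) != (yj > py):
            x_cross = (xj - xi) * (py - yi) / (yj - yi) + xi
            if px < x_cross:
                inside = not inside
        j = i
    return inside


def brute_force_rasterize(stack, template: StructureMask) -> np.ndarray:
    """Per-voxel-center even-odd rasterization of a contour stack."""
    out = np.zeros(template.shape, bool)
    xs = template.axis_centers(0)
    ys = template.axis_centers(1)
    zs = template.axis_centers(2)
    dz = template.spacing[2]
    for z, polygons in stack.slices:
        plane = int(np.argmin(np.abs(zs - z)))
        if abs(zs[plane] - z) > dz / 2 + 1e-9:
            continue
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                if any(point_in_polygon(x, y, poly) for poly in polygons):
                    out[i, j, plane] = True
    return out


def sphere_mask(radius_mm, spacing=1.0, center=(0.0, 0.0, 0.0), pad_mm=2.0) -> StructureMask:
    """Digitized solid sphere by direct center sampling (no morphology)."""
    half = radius_mm + pad_mm
    n = int(2 * half / spacing) + 1
    origin = tuple(c - (n - 1) * spacing / 2.0 for c in center)
    axes = [origin[i] + spacing * np.arange(n) for i in range(3)]
    x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)
    voxels = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius_mm**2
    return StructureMask(voxels, (spacing,) * 3, origin)


def lens_volume(r1: float, r2: float, d: float) -> float:
    """Analytic intersection volume of two spheres (spherical caps)."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * np.pi * r**3
    return (
        np.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )


# ---------------------------------------------------------------------------
# Cohort builders
# ---------------------------------------------------------------------------

def cohort_from_metrics(metrics, eligible, ptv_volumes=None) -> Cohort:
    """Cohort with given overlap metrics, placed on the plane diagonal."""
    patients = []
    for i, (metric, label) in enumerate(zip(metrics, eligible)):
        component = float(metric) / np.sqrt(2.0)
        patients.append(
            PatientRecord(
                id=f"p{i:03d}",
                features=OverlapFeatures(component, component),
                ptv_volume_cc=None if ptv_volumes is None else float(ptv_volumes[i]),
                eligible=None if label is None else bool(label),
            )
        )
    return Cohort(patients)


@pytest.fixture
def separable_cohort() -> Cohort:
    """40 patients whose metric separates the classes with a 0.1 gap."""
    rng = np.random.default_rng(42)
    metrics = np.concatenate([rng.uniform(0.05, 0.25, 28), rng.uniform(0.35, 0.55, 12)])
    labels = np.concatenate([np.ones(28, bool), np.zeros(12, bool)])
    return cohort_from_metrics(metrics, labels)


@pytest.fixture
def noisy_cohort() -> Cohort:
    """Default synthetic 150-patient cohort (seeded)."""
    from hypotriage import generate_cohort

    return generate_cohort(seed=7)
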