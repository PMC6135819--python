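"""Validation of the reconstruction + morphometry path on analytic phantoms.

Runs the full surface-reconstruction and measurement pipeline on voxel
phantoms with known geometry and reports relative errors of volume and
surface area against their analytic references, plus the curvature
descriptors used for the qualitative shape-ordering checks.
"""
from __future__ import annotations

import pandas as pd

from .morphometry import compute_signature
from .phantoms import PhantomSpec, make_phantom
from .reconstruction import ReconstructionParams, reconstruct_surface
from .volumes import split_objects


def default_phantom_specs(grid: int = 128) -> dict[str, PhantomSpec]:
    """The standard validation phantoms: nucleus-scale smooth and faceted
    solids on a ``grid³`` voxel lattice."""
    g = (grid, grid, grid)
    return {
        "sphere": PhantomSpec("sphere", (20.0,), grid_shape=g),
        "ellipsoid": PhantomSpec("ellipsoid", (26.0, 20.0, 15.4), grid_shape=g),
        "cube": PhantomSpec("cube", (24.0,), grid_shape=g),
        "octahedron": PhantomSpec("octahedron", (20.0,), grid_shape=g),
        "overlapping_spheres": PhantomSpec("overlapping_spheres", (15.0, 20.0),
                                           grid_shape=g),
    }


def curvature_ordering_specs(grid: int = 80) -> dict[str, PhantomSpec]:
    """Shape trio for the qualitative curvature-ordering comparison.

    The sphere and the 2:1 prolate ellipsoid have equal volume, so size does
    not confound the shape comparison (for near-spherical triaxial
    ellipsoids the surface-averaged mean curvature is almost exactly the
    equal-volume sphere's 1/r; a 2:1 prolate gives a clear gap).  The
    overlapping spheres use smaller radii so that their high-curvature lobes
    dominate the negative-curvature neck creases.
    """
    g = (grid, grid, grid)
    a = 25.6
    return {
        "sphere": PhantomSpec("sphere", ((a * (a / 2) ** 2) ** (1 / 3),), grid_shape=g),
        "ellipsoid": PhantomSpec("ellipsoid", (a, a / 2, a / 2), grid_shape=g),
        "overlapping_spheres": PhantomSpec("overlapping_spheres", (11.0, 18.0),
                                           grid_shape=g),
    }


def measure_phantom(spec: PhantomSpec, params: ReconstructionParams | None = None):
    """Voxelize, reconstruct, and measure one phantom.

    Returns ``(signature, filled_spec)``.
    """
    params = params or ReconstructionParams()
    volume, filled = make_phantom(spec)
    objs = split_objects(volume, min_voxels=8)
    if len(objs) != 1:
        raise RuntimeError(f"phantom voxelized into {len(objs)} components")
    mesh = reconstruct_surface(objs[0], params)
    return compute_signature(mesh), filled


def validate_phantoms(
    specs: dict[str, PhantomSpec] | None = None,
    params: ReconstructionParams | None = None,
) -> pd.DataFrame:
    """Error-report table for a phantom suite: one row per shape with computed
    vs analytic volume and surface area (relative errors in %), and the mean
    curvature descriptors."""
    specs = specs or default_phantom_specs()
    rows = []
    for name, spec in specs.items():
        sig, filled = measure_phantom(spec, params)
        rows.append({
            "shape": name,
            "volume": sig.volume,
            "analytic_volume": filled.analytic_volume,
            "volume_error_pct": 100.0 * abs(sig.volume / filled.analytic_volume - 1.0),
            "surface_area": sig.surface_area,
            "analytic_surface_area": filled.analytic_surface_area,
            "surface_area_error_pct":
                100.0 * abs(sig.surface_area / filled.analytic_surface_area - 1.0),
            "mean_mc": sig.mean_mc,
            "mean_si": sig.mean_si,
            "mean_cv": sig.mean_cv,
            "fractal_dimension": sig.fractal_dimension,
        })
    return pd.DataFrame(rows)
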