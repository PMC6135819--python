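"""Robust genus-zero surface reconstruction from binary masks by iterative
Laplace-Beltrami eigen-projection with topology-preserving mask deformation.

The reconstruction loop:

1. **Boundary meshing.** A closed triangulated surface is extracted from the
   (cavity-filled, zero-padded) binary mask at the 0.5 iso-level.
2. **Eigen-projection.** The three vertex-coordinate functions are projected
   onto the span of the first ``k`` eigenfunctions of the mesh's
   Laplace-Beltrami operator.  Eigenvalue magnitude plays the role of
   frequency, so truncating the basis is a spectral low-pass filter on shape:
   voxelization staircase and spurious segmentation features are
   high-frequency and are suppressed, while the smooth anatomy is kept.
3. **Distortion localization.** The per-vertex metric distortion between the
   boundary and its projection (displacement in units of mean edge length)
   localizes spurious features: vertices the low-pass basis cannot represent
   move far.
4. **Mask deformation.** Boundary voxels whose vertices exceed a distortion
   threshold are flipped to background, but only where the flip is a *simple
   point* — i.e. preserves the topology of both foreground and background —
   so only spurious features are removed and the rest of the mask (and hence
   the enclosed volume) is kept intact.

Steps 1–4 iterate until no voxel is flipped; the final surface is the
eigen-projection of the final mask boundary.

The LB operator is discretized with the cotangent-weight stiffness matrix and
a lumped (barycentric) mass matrix; the generalized symmetric eigenproblem
``L φ = λ M φ`` is solved for the smallest eigenpairs by shift-invert
Lanczos (dense fallback for small meshes or near-complete bases).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import trimesh
from scipy import ndimage
from skimage import measure

from .meshes import TriangleMesh
from .volumes import ObjectMask

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReconstructionParams:
    """Controls for the iterative reconstruction.

    ``n_eigenfunctions`` is the spectral cutoff k (k=100 keeps roughly the
    spherical-harmonic content up to degree ~9 on a nucleus-like shape).
    ``distortion_threshold`` is scale-free (units of mean edge length); when
    None it is set once, on the first iteration, to 3x the median vertex
    displacement — a robust scale that flags only outlying features — but
    never below ``distortion_floor``: boundary meshes of binary masks carry
    an irreducible sub-edge-length staircase ripple (empirically < ~0.5 mean
    edge lengths on voxelized solids at any resolution) that the low-pass
    projection removes without any mask deformation, so only displacements
    clearly beyond that band indicate a spurious feature.
    """

    n_eigenfunctions: int = 100
    distortion_threshold: float | None = None
    distortion_floor: float = 0.75
    max_iterations: int = 10
    volume_tolerance: float = 0.05  # |mesh volume / voxel volume - 1| allowed

    def __post_init__(self) -> None:
        if self.n_eigenfunctions < 4:
            raise ValueError("n_eigenfunctions must be >= 4")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.distortion_threshold is not None and self.distortion_threshold <= 0:
            raise ValueError("distortion_threshold must be positive")


@dataclass
class ReconstructionReport:
    """Diagnostics from :func:`reconstruct_surface`."""

    n_iterations: int = 0
    flipped_per_iteration: list[int] = field(default_factory=list)
    above_threshold_per_iteration: list[int] = field(default_factory=list)
    threshold: float = float("nan")
    volume_ratio: float = float("nan")


# ---------------------------------------------------------------------------
# Boundary meshing

_MIN_MESHABLE_VOXELS = 8


def _repair_critical_configurations(vol: np.ndarray, max_passes: int = 20) -> np.ndarray:
    """Make a binary volume well-composed by adding foreground voxels.

    Critical configurations — a 2x2 axis-plane square with only a diagonal
    foreground pair, or a 2x2x2 cube whose foreground (or background) pair
    is antipodal — are the voxel patterns whose iso-surface is pinched
    (non-manifold or of the wrong genus).  Each is resolved by promoting a
    background voxel of the pattern to foreground (ties broken toward
    foreground), which perturbs the mask by isolated voxels only.
    """
    v = vol.astype(bool).copy()
    for _ in range(max_passes):
        changed = False
        # 2D diagonal checkerboards in the three axis planes
        for ax1, ax2 in ((1, 2), (0, 2), (0, 1)):
            sl = [slice(None)] * 3

            def w(d1, d2):
                s = list(sl)
                s[ax1] = slice(d1, v.shape[ax1] - 1 + d1)
                s[ax2] = slice(d2, v.shape[ax2] - 1 + d2)
                return tuple(s)

            a, b = v[w(0, 0)], v[w(0, 1)]
            c, d = v[w(1, 0)], v[w(1, 1)]
            diag1 = a & d & ~b & ~c
            diag2 = b & c & ~a & ~d
            if diag1.any():
                v[w(0, 1)] |= diag1
                changed = True
            if diag2.any():
                v[w(0, 0)] |= diag2
                changed = True
        # 2x2x2 antipodal pairs
        corners = {
            (dz, dy, dx): v[dz:v.shape[0] - 1 + dz, dy:v.shape[1] - 1 + dy,
                            dx:v.shape[2] - 1 + dx]
            for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)
        }
        total = sum(c.astype(np.int8) for c in corners.values())
        for c0 in ((0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1)):
            c1 = tuple(1 - i for i in c0)
            pair_fg = corners[c0] & corners[c1] & (total == 2)
            if pair_fg.any():
                fill = (c0[0], c0[1], 1 - c0[2])  # a face neighbor of c0
                corners[fill] |= pair_fg
                changed = True
            pair_bg = ~corners[c0] & ~corners[c1] & (total == 6)
            if pair_bg.any():
                corners[c0] |= pair_bg
                changed = True
        if not changed:
            return v
    log.warning("well-composedness repair did not converge in %d passes", max_passes)
    return v


def extract_boundary_mesh(mask: ObjectMask) -> TriangleMesh:
    """Extract the closed boundary surface of a binary mask at the 0.5 iso-level.

    Internal cavities are filled first and only the largest boundary
    component is kept, so the result has sphere topology (Euler
    characteristic 2).  The mask is zero-padded by one voxel so the surface
    is closed even at the subgrid border.  Vertices are in the physical
    coordinate frame of the parent volume, axis order (x, y, z).
    """
    if mask.n_voxels < _MIN_MESHABLE_VOXELS:
        raise ValueError(
            f"mask with {mask.n_voxels} voxels is too small to triangulate "
            f"(needs >= {_MIN_MESHABLE_VOXELS})"
        )
    filled = ndimage.binary_fill_holes(mask.voxels)
    repaired = _repair_critical_configurations(filled)
    if repaired is not filled and (repaired != filled).any():
        log.debug("object %s/%s: well-composedness repair added %d voxels",
                  mask.image_id, mask.object_id, int((repaired & ~filled).sum()))
        filled = ndimage.binary_fill_holes(repaired)
    padded = np.pad(filled, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    # physical frame: undo the pad, add the bounding-box offset, apply spacing
    verts = (verts - 1.0 + np.array(mask.offset)) * np.array(mask.spacing)
    # marching-cubes output is (z, y, x); meshes live in (x, y, z)
    verts = verts[:, ::-1]
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True, validate=True)
    if tm.body_count > 1:
        tm = max(tm.split(only_watertight=False), key=lambda b: len(b.faces))
    if tm.volume < 0:
        tm.invert()
    mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Laplace-Beltrami discretization and eigen-projection

def cotangent_laplacian(mesh: TriangleMesh) -> tuple[sp.csc_matrix, np.ndarray]:
    """Cotangent-weight stiffness matrix L and lumped barycentric mass vector m.

    L is symmetric positive semi-definite with L·1 = 0; m_i is one third of
    the total area of triangles incident to vertex i.
    """
    verts, faces = mesh.vertices, mesh.faces
    n = len(verts)
    tri = verts[faces]
    I, J, W = [], [], []
    for i in range(3):
        i1, i2 = (i + 1) % 3, (i + 2) % 3
        e1 = tri[:, i1] - tri[:, i]
        e2 = tri[:, i2] - tri[:, i]
        double_area = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = (e1 * e2).sum(axis=1) / np.maximum(double_area, 1e-300)
        # angle at corner i weights the edge (i1, i2) opposite to it
        I.extend([faces[:, i1], faces[:, i2]])
        J.extend([faces[:, i2], faces[:, i1]])
        W.extend([0.5 * cot, 0.5 * cot])
    Wm = sp.coo_matrix(
        (np.concatenate(W), (np.concatenate(I), np.concatenate(J))), shape=(n, n)
    ).tocsr()
    L = (sp.diags(np.asarray(Wm.sum(axis=1)).ravel()) - Wm).tocsc()
    tri_area = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    m = np.zeros(n)
    for i in range(3):
        np.add.at(m, faces[:, i], tri_area / 3.0)
    return L, m


def lb_eigenbasis(mesh: TriangleMesh, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First k Laplace-Beltrami eigenpairs of a mesh.

    Returns ``(eigenvalues, eigenfunctions, mass)`` with eigenvalues
    ascending and eigenfunctions M-orthonormal columns.
    """
    n = mesh.n_vertices
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_vertices ({n}), got {k}")
    L, m = cotangent_laplacian(mesh)
    if n <= 600 or k > n - 4:
        vals, vecs = scipy.linalg.eigh(L.toarray(), np.diag(m))
        return vals[:k], vecs[:, :k], m
    diag_ratio = L.diagonal() / m
    sigma = -1e-4 * float(np.median(diag_ratio))
    try:
        vals, vecs = spla.eigsh(L, k=k, M=sp.diags(m).tocsc(), sigma=sigma,
                                v0=np.ones(n))
    except (spla.ArpackNoConvergence, RuntimeError) as exc:
        raise RuntimeError(
            f"LB eigen-solver failed for k={k} on a mesh with {n} vertices: {exc}"
        ) from exc
    order = np.argsort(vals)
    return vals[order], vecs[:, order], m


def lb_eigenprojection(mesh: TriangleMesh, k: int) -> TriangleMesh:
    """Project the vertex coordinate functions onto the span of the first k
    LB eigenfunctions (a spectral low-pass filter on shape).

    Connectivity is unchanged; the projection is idempotent with respect to
    the basis of the *input* mesh.
    """
    _, basis, m = lb_eigenbasis(mesh, k)
    coeff = basis.T @ (mesh.vertices * m[:, None])
    return mesh.with_vertices(basis @ coeff)


def metric_distortion(original: TriangleMesh, projected: TriangleMesh) -> np.ndarray:
    """Per-vertex displacement between a mesh and its eigen-projection,
    normalized by the original mesh's mean edge length (scale-free)."""
    if original.faces.shape != projected.faces.shape or \
            (original.faces != projected.faces).any():
        raise ValueError("metric_distortion requires identical connectivity")
    disp = np.linalg.norm(projected.vertices - original.vertices, axis=1)
    return disp / original.mean_edge_length()


# ---------------------------------------------------------------------------
# Topology-preserving mask deformation

_S26 = ndimage.generate_binary_structure(3, 3)
_S6 = ndimage.generate_binary_structure(3, 1)
# the 18-neighborhood (face + edge neighbors) used for the background test
_N18 = _S26.copy()
_N18[0, 0, 0] = _N18[0, 0, 2] = _N18[0, 2, 0] = _N18[0, 2, 2] = False
_N18[2, 0, 0] = _N18[2, 0, 2] = _N18[2, 2, 0] = _N18[2, 2, 2] = False


def is_simple_point(patch: np.ndarray) -> bool:
    """Whether the center voxel of a 3x3x3 binary patch is a simple point
    under the 26-connected foreground / 6-connected background pairing.

    A flip of a simple point changes neither the connectivity of the
    foreground nor of the background (Bertrand's two topological numbers
    both equal 1).
    """
    fg = patch.astype(bool).copy()
    fg[1, 1, 1] = False
    if not fg.any():
        return False  # isolated voxel: removal deletes a component
    lab, n_fg = ndimage.label(fg, structure=_S26)
    if n_fg != 1:
        return False
    bg = ~patch.astype(bool)
    bg[1, 1, 1] = True
    bg &= _N18
    bg[1, 1, 1] = False
    lab, n_bg = ndimage.label(bg, structure=_S6)
    if n_bg == 0:
        return False
    # count only background components 6-adjacent to the center
    face_labels = {lab[0, 1, 1], lab[2, 1, 1], lab[1, 0, 1],
                   lab[1, 2, 1], lab[1, 1, 0], lab[1, 1, 2]} - {0}
    return len(face_labels) == 1


def _count_critical_configurations(patch: np.ndarray) -> int:
    """Count well-composedness violations inside a 3x3x3 binary patch.

    Critical configurations (Latecki): a 2x2 axis-aligned square whose two
    foreground voxels sit on a diagonal, and a 2x2x2 cube whose two
    foreground (or two background) voxels are antipodal.  Iso-surfacing such
    patterns can pinch the surface into tunnels, so mask deformation must
    not introduce new ones.
    """
    p = patch.astype(bool)
    n = 0
    # 2x2 squares in the three axis planes
    for ax in range(3):
        q = np.moveaxis(p, ax, 0)
        for i in range(3):
            sq = q[i]
            for dy in range(2):
                for dx in range(2):
                    s = sq[dy:dy + 2, dx:dx + 2]
                    if s[0, 0] == s[1, 1] and s[0, 1] == s[1, 0] and s[0, 0] != s[0, 1]:
                        n += 1
    # 2x2x2 cubes with an antipodal pair
    for dz in range(2):
        for dy in range(2):
            for dx in range(2):
                c = p[dz:dz + 2, dy:dy + 2, dx:dx + 2]
                for phase in (c, ~c):
                    if phase.sum() == 2:
                        idx = np.argwhere(phase)
                        if (idx[0] + idx[1] == 1).all():
                            n += 1
    return n


def deform_mask(
    mask: ObjectMask,
    mesh: TriangleMesh,
    distortion: np.ndarray,
    threshold: float,
) -> tuple[ObjectMask, int]:
    """Remove spurious boundary voxels flagged by eigen-projection distortion.

    Each mesh vertex is mapped to its nearest voxel center; a boundary voxel
    is a removal candidate only if the maximum distortion over its vertices
    exceeds ``threshold``.  Candidates are flipped to background in order of
    decreasing distortion; a flip is allowed only at a simple point (both
    foreground and background connectivity preserved, so the mask keeps a
    single genus-zero component) and only if it introduces no new critical
    configuration (keeping the deformation well-composed, so the iso-surface
    of the deformed mask stays a manifold of the same genus).  Voxels below
    threshold are never touched, preventing volume shrinkage.

    Returns the (possibly unchanged) mask and the number of flipped voxels.
    """
    if len(distortion) != mesh.n_vertices:
        raise ValueError("distortion field length does not match mesh vertex count")
    above = distortion > threshold
    if not above.any():
        return mask, 0
    spacing = np.array(mask.spacing)
    # vertex (x, y, z) physical -> parent (z, y, x) index -> local index
    idx = np.round(mesh.vertices[:, ::-1] / spacing).astype(int) - np.array(mask.offset)
    idx = np.clip(idx, 0, np.array(mask.voxels.shape) - 1)
    vox_distortion: dict[tuple[int, int, int], float] = {}
    for (z, y, x), d in zip(idx[above], distortion[above]):
        key = (int(z), int(y), int(x))
        vox_distortion[key] = max(vox_distortion.get(key, 0.0), float(d))
    new = np.pad(mask.voxels.copy(), 1)  # pad so 3x3x3 patches never clip
    flipped = 0
    for (z, y, x), _ in sorted(vox_distortion.items(), key=lambda kv: -kv[1]):
        pz, py, px = z + 1, y + 1, x + 1
        if not new[pz, py, px]:
            continue
        patch = new[pz - 1:pz + 2, py - 1:py + 2, px - 1:px + 2]
        if not is_simple_point(patch):
            continue
        after = patch.copy()
        after[1, 1, 1] = False
        if _count_critical_configurations(after) > _count_critical_configurations(patch):
            continue
        new[pz, py, px] = False
        flipped += 1
    if flipped == 0:
        return mask, 0
    return mask.with_voxels(new[1:-1, 1:-1, 1:-1]), flipped


# ---------------------------------------------------------------------------
# The iterative reconstruction driver

def reconstruct_surface(
    mask: ObjectMask,
    params: ReconstructionParams = ReconstructionParams(),
    full_output: bool = False,
) -> TriangleMesh | tuple[TriangleMesh, ReconstructionReport]:
    """Reconstruct a smooth, closed, genus-zero surface from a binary mask.

    Iterates boundary meshing → eigen-projection → distortion localization →
    topology-preserving deformation until no voxel is flipped (or
    ``max_iterations``), then returns the eigen-projection of the final mask
    boundary.  The output satisfies all mesh invariants and its enclosed
    volume stays within ``params.volume_tolerance`` of the mask voxel volume.
    """
    report = ReconstructionReport()
    current = mask
    threshold = params.distortion_threshold
    projected: TriangleMesh | None = None
    for it in range(params.max_iterations):
        mesh = extract_boundary_mesh(current)
        k = min(params.n_eigenfunctions, mesh.n_vertices - 4)
        projected = lb_eigenprojection(mesh, k)
        dist = metric_distortion(mesh, projected)
        if threshold is None:
            threshold = max(3.0 * float(np.median(dist)), params.distortion_floor)
            report.threshold = threshold
        report.above_threshold_per_iteration.append(int((dist > threshold).sum()))
        deformed, flipped = deform_mask(current, mesh, dist, threshold)
        if flipped:
            try:  # guard: deformation must leave the mask meshable
                extract_boundary_mesh(deformed)
            except (ValueError, RuntimeError):
                log.warning(
                    "object %s/%s: deformation at iteration %d broke the boundary "
                    "surface; reverting and stopping", mask.image_id, mask.object_id,
                    it + 1,
                )
                flipped = 0
                deformed = current
        current = deformed
        report.flipped_per_iteration.append(flipped)
        report.n_iterations = it + 1
        if flipped == 0:
            break
    else:
        # max_iterations reached with flips still occurring: project the final mask
        mesh = extract_boundary_mesh(current)
        k = min(params.n_eigenfunctions, mesh.n_vertices - 4)
        projected = lb_eigenprojection(mesh, k)
    assert projected is not None
    try:
        projected.validate()
    except ValueError as exc:
        raise RuntimeError(
            f"reconstruction failed to produce a valid genus-zero mesh after "
            f"{report.n_iterations} iterations "
            f"(residual above-threshold vertices: "
            f"{report.above_threshold_per_iteration[-1]}): {exc}"
        ) from exc
    vol_ratio = projected.signed_volume() / current.voxel_volume
    report.volume_ratio = vol_ratio
    if abs(vol_ratio - 1.0) > params.volume_tolerance:
        log.warning(
            "object %s/%s: reconstructed volume deviates %.1f%% from mask volume",
            mask.image_id, mask.object_id, 100 * abs(vol_ratio - 1.0),
        )
    if full_output:
        return projected, report
    return projected
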