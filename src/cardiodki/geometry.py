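"""Left-ventricular local wall coordinates and the helix / sheetlet angle maps.

For short-axis slices the LV long axis is taken as the slice normal.  At each
myocardial voxel an orthonormal right-handed triad is defined:

- r_hat: in-plane unit vector pointing outward from the slice's LV centre,
- z_hat: slice normal (toward base),
- c_hat = z_hat x r_hat: circumferential direction.

Helix angle (HA): project the primary eigenvector e1 onto the tangential
(c_hat-z_hat) plane; HA is the signed angle of that projection from c_hat,
positive toward +z_hat, in [-90, 90] deg.  The antipodal ambiguity of e1 is
removed by flipping e1 so its c_hat component is non-negative.

Secondary eigenvector angle (E2A): within the cross-myocyte plane (the plane
orthogonal to e1), the wall-tangent reference direction is t = e1 x r_hat
(orthogonal to both e1 and the radial direction); the sheet-normal-most
direction is s = e1 x t.  E2A is the signed angle of e2 from t toward s,
folded to (-90, 90] because e2 is also only defined up to sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["CardiacFrame", "build_frames", "helix_angle", "e2a_angle",
           "helix_angle_map", "e2a_angle_map"]


@dataclass
class CardiacFrame:
    """Per-voxel orthonormal triad over a stack of short-axis slices.

    Arrays are (n_slices, ny, nx, 3); defined (non-NaN) only inside the
    myocardial mask.  ``centers`` is (n_slices, 2) in (y, x) voxel units.
    """

    radial: np.ndarray
    circumferential: np.ndarray
    longitudinal: np.ndarray
    centers: np.ndarray
    mask: np.ndarray


def build_frames(mask: np.ndarray) -> CardiacFrame:
    """Wall coordinate triads from a per-slice annulus mask (slices, ny, nx).

    The LV centre of each slice is the mask centroid; the centroid must fall
    in the central cavity (i.e. outside the annulus) and the mask must be a
    single connected ring.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be (n_slices, ny, nx)")
    ns, ny, nx = mask.shape
    radial = np.full((ns, ny, nx, 3), np.nan)
    circ = np.full((ns, ny, nx, 3), np.nan)
    longi = np.full((ns, ny, nx, 3), np.nan)
    centers = np.zeros((ns, 2))
    for s in range(ns):
        m = mask[s]
        if not m.any():
            raise ValueError(f"slice {s}: empty myocardial mask")
        n_comp = ndimage.label(m)[1]
        if n_comp != 1:
            raise ValueError(f"slice {s}: mask has {n_comp} components, "
                             "expected one connected annulus")
        cy, cx = ndimage.center_of_mass(m)
        if m[int(round(cy)), int(round(cx))]:
            raise ValueError(f"slice {s}: centroid lies inside the wall; "
                             "mask is not an annulus around a cavity")
        centers[s] = (cy, cx)
        yy, xx = np.nonzero(m)
        dy = yy - cy
        dx = xx - cx
        r = np.hypot(dx, dy)
        if np.any(r < 1e-9):
            raise ValueError(f"slice {s}: voxel coincides with the LV centre")
        # image axes: x along columns, y along rows, z along slices
        radial[s, yy, xx, 0] = dx / r
        radial[s, yy, xx, 1] = dy / r
        radial[s, yy, xx, 2] = 0.0
        longi[s, yy, xx] = (0.0, 0.0, 1.0)
        circ[s, yy, xx] = np.cross([0.0, 0.0, 1.0], radial[s, yy, xx])
    return CardiacFrame(radial, circ, longi, centers, mask)


def _signed_plane_angle(v: np.ndarray, ref: np.ndarray, toward: np.ndarray,
                        min_proj: float = 1e-6):
    """Angle of v's projection onto span(ref, toward), measured from ref,
    positive toward *toward*; NaN where the projection is negligible."""
    a = np.sum(v * ref, axis=-1)
    b = np.sum(v * toward, axis=-1)
    norm = np.hypot(a, b)
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arctan2(b, a))
    return np.where(norm < min_proj, np.nan, ang)


def helix_angle(e1: np.ndarray, frame: CardiacFrame) -> np.ndarray:
    """Helix angle in degrees, [-90, 90]; NaN where e1 is (near) purely radial
    or outside the mask.  ``e1`` is (..., 3) matching the frame arrays."""
    c, z = frame.circumferential, frame.longitudinal
    # resolve antipodal ambiguity: make the circumferential component >= 0
    s = np.sign(np.sum(e1 * c, axis=-1))
    s = np.where(s == 0, 1.0, s)
    e1f = e1 * s[..., None]
    return _signed_plane_angle(e1f, c, z)


def e2a_angle(e2: np.ndarray, e1: np.ndarray, frame: CardiacFrame) -> np.ndarray:
    """Sheetlet (secondary eigenvector) angle in degrees, (-90, 90].

    NaN where the cross-myocyte tangent is undefined (e1 parallel to the
    radial direction) or outside the mask.
    """
    r = frame.radial
    t = np.cross(e1, r)
    tnorm = np.linalg.norm(t, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = t / tnorm
    sdir = np.cross(e1, t)
    ang = _signed_plane_angle(e2, t, sdir)
    # e2 sign ambiguity: fold to (-90, 90]
    ang = np.where(ang <= -90.0, ang + 180.0, ang)
    ang = np.where(ang > 90.0, ang - 180.0, ang)
    return np.where(tnorm[..., 0] < 1e-6, np.nan, ang)


def helix_angle_map(evecs: np.ndarray, frame: CardiacFrame) -> np.ndarray:
    """HA map from an eigenvector stack (..., 3, 3) (columns sorted by
    descending eigenvalue)."""
    return helix_angle(evecs[..., 0], frame)


def e2a_angle_map(evecs: np.ndarray, frame: CardiacFrame) -> np.ndarray:
    """E2A map from an eigenvector stack (..., 3, 3)."""
    return e2a_angle(evecs[..., 1], evecs[..., 0], frame)
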