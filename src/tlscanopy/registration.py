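"""Rigid registration of scans into the season-fixed sphere frame.

The white spherical targets keep constant world positions during the season
and define a fixed coordinate system.  Each scan observes the sphere centers
in its own instrument frame; a correspondence-based least-squares rigid
transform (Kabsch, via cross-covariance SVD) maps the scan into the fixed
frame.  The residual deviations of the transformed sphere centers are the
pipeline's quality-control metric: they bound the best achievable accuracy
of any height difference computed between scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io_formats import ScanPointCloud, SphereObservationSet

__all__ = [
    "RigidTransform",
    "ReferenceConstellation",
    "fit_sphere",
    "estimate_rigid_transform",
    "apply_transform",
    "sphere_deviations",
    "register_campaign",
]

_ORTHO_TOL = 1e-8
_COLLINEAR_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion p -> R p + t (no scaling, no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying `other` first, then `self`."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def to_array(self) -> np.ndarray:
        """Serialize as 12 numbers: row-major rotation then translation."""
        return np.concatenate([self.rotation.ravel(), self.translation])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "RigidTransform":
        arr = np.asarray(arr, dtype=float).ravel()
        if arr.size != 12:
            raise ValueError("expected 12 numbers (rotation row-major + translation)")
        return cls(arr[:9].reshape(3, 3), arr[9:])

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savetxt(path, self.to_array()[None, :], fmt="%.17g")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        return cls.from_array(np.loadtxt(path))


@dataclass
class ReferenceConstellation:
    """Fixed-frame sphere centers defining the season coordinate system."""

    centers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.centers = {str(k): np.asarray(v, dtype=float).reshape(3)
                        for k, v in self.centers.items()}
        if len(self.centers) < 3:
            raise ValueError("a reference constellation needs >= 3 spheres")
        pts = np.stack(list(self.centers.values()))
        if _is_collinear(pts):
            raise ValueError("reference sphere centers are collinear")

    @classmethod
    def from_observations(cls, obs: SphereObservationSet,
                          scan_id: str | None = None) -> "ReferenceConstellation":
        """Adopt one scan's observed centers as the fixed frame (default: first scan)."""
        if scan_id is None:
            scan_id = obs.scan_ids[0]
        return cls(obs.for_scan(scan_id).centers_by_id())

    @property
    def sphere_ids(self) -> list[str]:
        return list(self.centers)

    def as_array(self, sphere_ids: list[str]) -> np.ndarray:
        return np.stack([self.centers[s] for s in sphere_ids])


def _is_collinear(pts: np.ndarray) -> bool:
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return len(s) < 2 or s[1] <= _COLLINEAR_TOL * max(s[0], 1.0)


# ---------------------------------------------------------------------------
# sphere fitting (plumbing for starting from raw target patches)
# ---------------------------------------------------------------------------

def fit_sphere(points: np.ndarray, known_radius: float | None = None,
               refine: bool = True) -> tuple[np.ndarray, float, float]:
    """Least-squares sphere fit.

    Algebraic fit (linear in center and radius) optionally refined by
    geometric (orthogonal-distance) least squares.  With ``known_radius`` only
    the center is free.  Returns ``(center, radius, rms_residual)`` with the
    rms of geometric residuals |p - c| - r.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("need >= 4 points of shape (n, 3)")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[2] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("points are coplanar or collinear; sphere fit is degenerate")

    # algebraic: |p|^2 = 2 c.p + (r^2 - |c|^2)
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(max(sol[3] + center @ center, 0.0)))

    if known_radius is not None:
        radius = float(known_radius)

        def resid_c(c: np.ndarray) -> np.ndarray:
            return np.linalg.norm(pts - c, axis=1) - radius

        center = least_squares(resid_c, center).x
    elif refine:
        def resid(params: np.ndarray) -> np.ndarray:
            return np.linalg.norm(pts - params[:3], axis=1) - params[3]

        out = least_squares(resid, np.append(center, radius)).x
        center, radius = out[:3], float(out[3])

    res = np.linalg.norm(pts - center, axis=1) - radius
    return np.asarray(center), radius, float(np.sqrt(np.mean(res**2)))


# ---------------------------------------------------------------------------
# rigid transform estimation (Kabsch)
# ---------------------------------------------------------------------------

def estimate_rigid_transform(moving: SphereObservationSet | Mapping[str, np.ndarray],
                             reference: ReferenceConstellation,
                             ) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform taking one scan's sphere centers onto the
    reference constellation.

    Correspondence is by sphere_id only (targets are individually placed and
    identifiable), never nearest-neighbor.  The rotation comes from the SVD of
    the cross-covariance of the matched, centered point sets; a det = -1
    optimum is forced to a proper rotation by flipping the smallest singular
    direction.  Returns the transform and the rms residual over matched
    spheres (meters).
    """
    if isinstance(moving, SphereObservationSet):
        moving_centers = moving.centers_by_id()
    else:
        moving_centers = {k: np.asarray(v, dtype=float).reshape(3)
                          for k, v in moving.items()}
    common = sorted(set(moving_centers) & set(reference.centers))
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 matched spheres, found {len(common)}: {common}")
    src = np.stack([moving_centers[s] for s in common])
    dst = reference.as_array(common)
    if _is_collinear(src) or _is_collinear(dst):
        raise ValueError("matched sphere centers are collinear")

    src_mean = src.mean(axis=0)
    dst_mean = dst.mean(axis=0)
    H = (src - src_mean).T @ (dst - dst_mean)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = dst_mean - R @ src_mean
    transform = RigidTransform(R, t)
    rms = float(np.sqrt(np.mean(np.sum((transform.apply(src) - dst) ** 2, axis=1))))
    return transform, rms


def apply_transform(cloud: ScanPointCloud, transform: RigidTransform) -> ScanPointCloud:
    """Map a scanner-frame cloud into the fixed frame.

    Refuses clouds already in the fixed frame so a scan can never be
    transformed twice.
    """
    if cloud.frame != "scanner":
        raise ValueError(
            f"cloud {cloud.scan_id!r} is already in frame {cloud.frame!r}; "
            "refusing a double transform")
    return cloud.with_points(transform.apply(cloud.points), frame="fixed")


# ---------------------------------------------------------------------------
# deviation QC metric
# ---------------------------------------------------------------------------

def sphere_deviations(transformed: SphereObservationSet,
                      reference: ReferenceConstellation,
                      mode: str = "reference") -> pd.DataFrame:
    """Per-observation deviation of transformed sphere centers.

    ``mode="reference"`` measures each observation against the reference
    constellation position; ``mode="sphere_mean"`` against the per-sphere mean
    over all scans.  Returns a DataFrame with columns sphere_id, scan_id,
    dx, dy, dz, euclidean_deviation_m; its mean/sd summarize a campaign.
    """
    if mode not in ("reference", "sphere_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    tab = transformed.table
    unknown = set(tab["sphere_id"]) - set(reference.centers)
    if unknown:
        raise ValueError(f"observations reference unknown sphere ids: {sorted(unknown)}")
    obs = tab[["x", "y", "z"]].to_numpy(dtype=float)
    if mode == "reference":
        target = np.stack([reference.centers[s] for s in tab["sphere_id"]])
    else:
        means = tab.groupby("sphere_id")[["x", "y", "z"]].transform("mean")
        target = means.to_numpy(dtype=float)
    delta = obs - target
    report = tab[["sphere_id", "scan_id"]].copy()
    report[["dx", "dy", "dz"]] = delta
    report["euclidean_deviation_m"] = np.linalg.norm(delta, axis=1)
    return report


def summarize_deviations(report: pd.DataFrame) -> tuple[float, float, int]:
    """Campaign summary: (mean deviation m, sd, number of observations)."""
    d = report["euclidean_deviation_m"].to_numpy(dtype=float)
    return float(d.mean()), float(d.std(ddof=1)) if len(d) > 1 else 0.0, len(d)


def register_campaign(observations: SphereObservationSet,
                      reference: ReferenceConstellation | None = None,
                      self_consistent: bool = False,
                      ) -> tuple[dict[str, RigidTransform], pd.DataFrame]:
    """Estimate one transform per scan and the campaign deviation report.

    Without an explicit reference the first scan's frame defines the fixed
    coordinate system.  With ``self_consistent=True`` a second pass replaces
    the reference by the per-sphere mean of first-pass transformed centers and
    re-estimates all transforms against it.
    """
    if reference is None:
        reference = ReferenceConstellation.from_observations(observations)

    def _solve(ref: ReferenceConstellation):
        transforms: dict[str, RigidTransform] = {}
        rows = []
        for scan in observations.scan_ids:
            sub = observations.for_scan(scan)
            transform, _ = estimate_rigid_transform(sub, ref)
            transforms[scan] = transform
            moved = transform.apply(sub.table[["x", "y", "z"]].to_numpy(dtype=float))
            out = sub.table.copy()
            out[["x", "y", "z"]] = moved
            rows.append(out)
        return transforms, SphereObservationSet(pd.concat(rows, ignore_index=True))

    transforms, moved = _solve(reference)
    if self_consistent:
        mean_centers = (moved.table.groupby("sphere_id")[["x", "y", "z"]]
                        .mean())
        reference = ReferenceConstellation(
            {sid: row.to_numpy() for sid, row in mean_centers.iterrows()})
        transforms, moved = _solve(reference)
    report = sphere_deviations(moved, reference)
    return transforms, report
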