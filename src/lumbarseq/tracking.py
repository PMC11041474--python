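"""Vertebral tracking by rigid 2-D matching of normalized gradient fields.

Each vertebra is delineated once, by a polygon drawn on the median frame,
and followed through the stack by maximising an intensity-invariant
similarity between normalized gradient field (NGF) images: each pixel's
gradient is divided by sqrt(|grad I|^2 + eps^2), so edge *orientation*
drives the match while absolute brightness does not.  The similarity is
the mean squared inner product of the (rotated) reference NGF and the
moving frame's NGF over the transformed template region.

Tracking proceeds outward from the reference frame, frame by frame, each
search initialised at the neighbouring frame's pose and bounded (default
+-6 deg rotation and +-20 px translation per frame).  The best fit is found
coarse-to-fine on a 3-level x2 image pyramid: an exhaustive grid at the
coarsest level, a local grid at the middle level, and continuous
Nelder-Mead refinement at full resolution.  Ties on the coarse grid break
toward the smallest pose change from the previous frame.

Conventions: pixel coordinates are 0-based with the origin at the top-left;
angles are positive counter-clockwise in image coordinates; the rotation
pivot is the template polygon centroid; image resampling is bilinear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize
from shapely.geometry import Polygon as ShapelyPolygon
from skimage.draw import polygon as draw_polygon
from skimage.transform import downscale_local_mean

from .synth import ValidationError


@dataclass(frozen=True)
class TemplateArea:
    """A user-drawn polygon around one vertebra on the median frame."""

    vertebra_label: str
    polygon: tuple[tuple[float, float], ...]  # (x, y) pixel vertices
    reference_frame_index: int

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise ValidationError("template polygon needs >= 3 vertices")
        shp = ShapelyPolygon(self.polygon)
        if not shp.is_simple or shp.area <= 0:
            raise ValidationError("template polygon must be simple with positive area")

    @property
    def centroid(self) -> np.ndarray:
        c = ShapelyPolygon(self.polygon).centroid
        return np.array([c.x, c.y])

    def shifted(self, dx: float, dy: float) -> "TemplateArea":
        return TemplateArea(
            self.vertebra_label,
            tuple((x + dx, y + dy) for x, y in self.polygon),
            self.reference_frame_index,
        )


@dataclass
class VertebraPose:
    """Rigid 2-D pose of one vertebra in one frame, relative to the reference frame."""

    frame_index: int
    vertebra_label: str
    rotation_deg: float
    tx_px: float
    ty_px: float
    match_score: float
    valid: bool = True


@dataclass(frozen=True)
class SearchConfig:
    """Bounds and resolution of the per-frame pose search."""

    max_rotation_per_frame_deg: float = 6.0
    max_translation_per_frame_px: float = 20.0
    pyramid_levels: int = 3
    coarse_rotation_step_deg: float = 1.5
    coarse_translation_step_px: float = 1.0  # at the coarsest level
    epsilon: float | None = None  # None: 10% of median template gradient magnitude
    presmooth_sigma: float = 1.0  # image smoothing before gradients; the smoothed
    # central difference approximates a Gaussian derivative, which is far more
    # rotation-equivariant than the raw pixel stencil
    score_floor: float = 0.05


def normalized_gradient_field(image: np.ndarray, epsilon: float) -> np.ndarray:
    """Per-pixel gradient divided by sqrt(|grad I|^2 + eps^2).

    Returns an (H, W, 2) array of (gx, gy).  Output magnitudes are <= 1,
    tending to 0 in flat regions and to 1 where the gradient dominates eps.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError("normalized_gradient_field expects a 2-D image")
    if epsilon <= 0:
        raise ValidationError("epsilon must be > 0")
    gy, gx = np.gradient(image)
    norm = np.sqrt(gx**2 + gy**2 + epsilon**2)
    return np.stack([gx / norm, gy / norm], axis=-1)


def _rot_mat(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def _template_pixels(template: TemplateArea, shape: tuple[int, int]) -> np.ndarray:
    xs = [p[0] for p in template.polygon]
    ys = [p[1] for p in template.polygon]
    rr, cc = draw_polygon(ys, xs, shape=shape)
    if len(rr) == 0:
        raise ValidationError("template polygon covers no pixels")
    return np.column_stack([cc, rr]).astype(float)  # (N, 2) as (x, y)


def default_epsilon(image: np.ndarray, template: TemplateArea) -> float:
    """10% of the median gradient magnitude over the template region."""
    image = np.asarray(image, dtype=float)
    gy, gx = np.gradient(image)
    mag = np.sqrt(gx**2 + gy**2)
    pix = _template_pixels(template, image.shape)
    vals = mag[pix[:, 1].astype(int), pix[:, 0].astype(int)]
    med = float(np.median(vals))
    return max(0.1 * med, 1e-6)


class _LevelData:
    """Precomputed reference data for one pyramid level."""

    def __init__(self, ref_image: np.ndarray, template: TemplateArea, factor: int,
                 epsilon: float, presmooth_sigma: float = 0.0):
        self.factor = factor
        self.epsilon = epsilon / factor  # gradients shrink with downsampling
        self.presmooth_sigma = presmooth_sigma
        if factor > 1:
            self.ref = downscale_local_mean(ref_image, (factor, factor))
        else:
            self.ref = np.asarray(ref_image, dtype=float)
        if presmooth_sigma > 0:
            self.ref = ndimage.gaussian_filter(self.ref, presmooth_sigma)
        # rasterize the polygon on this level's grid so the pixel count
        # shrinks with the resolution
        xs = [p[0] / factor for p in template.polygon]
        ys = [p[1] / factor for p in template.polygon]
        rr, cc = draw_polygon(ys, xs, shape=self.ref.shape)
        if len(rr) == 0:
            raise ValidationError("template polygon covers no pixels at this level")
        self.pix = np.column_stack([cc, rr]).astype(float)
        self.centroid = template.centroid / factor
        ngf_ref = normalized_gradient_field(self.ref, self.epsilon)
        self.ref_vec = _sample_field(ngf_ref, self.pix)

    def frame_ngf(self, frame: np.ndarray) -> np.ndarray:
        img = (
            downscale_local_mean(frame, (self.factor, self.factor))
            if self.factor > 1
            else np.asarray(frame, dtype=float)
        )
        if self.presmooth_sigma > 0:
            img = ndimage.gaussian_filter(img, self.presmooth_sigma)
        return normalized_gradient_field(img, self.epsilon)


def _sample_field(field: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinear samples of a 2-vector field at (x, y) points -> (N, 2)."""
    coords = np.stack([points[:, 1], points[:, 0]])  # (row, col)
    fx = ndimage.map_coordinates(field[..., 0], coords, order=1, cval=0.0)
    fy = ndimage.map_coordinates(field[..., 1], coords, order=1, cval=0.0)
    return np.column_stack([fx, fy])


def _score_many(
    ngf: np.ndarray,
    pix: np.ndarray,
    centroid: np.ndarray,
    ref_vec: np.ndarray,
    poses: np.ndarray,
) -> np.ndarray:
    """NGF similarity for many candidate poses (K, 3) -> scores (K,).

    Pose = (rotation_deg, tx, ty) about the template centroid, in the
    level's pixel units.  All candidates are gathered into one bilinear
    sampling call.

    The similarity is the energy-normalised squared inner product of the
    rotated reference NGF and the sampled moving NGF,

        s = sum_i (r_i . m_i)^2 / sum_i |r_i|^2 |m_i|^2 ,

    which lies in [0, 1] by Cauchy-Schwarz and equals 1 only for pointwise
    parallel fields.  The energy normalisation cancels the attenuation that
    bilinear interpolation applies at sub-pixel sample positions; the plain
    mean squared inner product is biased toward integer-pixel poses.
    """
    k = len(poses)
    n = len(pix)
    rel = pix - centroid
    pts = np.empty((k, n, 2))
    rvec = np.empty((k, n, 2))
    for i, (ang, tx, ty) in enumerate(poses):
        r = _rot_mat(ang)
        pts[i] = rel @ r.T + centroid + (tx, ty)
        rvec[i] = ref_vec @ r.T  # gradient orientation rotates with the image
    flat = _sample_field(ngf, pts.reshape(-1, 2)).reshape(k, n, 2)
    dots = np.einsum("kni,kni->kn", rvec, flat)
    energy = np.einsum("kni,kni->kn", rvec, rvec) * np.einsum("kni,kni->kn", flat, flat)
    denom = energy.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (dots**2).sum(axis=1) / denom
    return np.where(denom > 0, s, 0.0)


def _polygon_in_bounds(template: TemplateArea, pose, shape) -> bool:
    ang, tx, ty = pose
    c = template.centroid
    verts = np.asarray(template.polygon, dtype=float)
    moved = (verts - c) @ _rot_mat(ang).T + c + (tx, ty)
    h, w = shape
    return bool(
        (moved[:, 0] >= 0).all()
        and (moved[:, 1] >= 0).all()
        and (moved[:, 0] <= w - 1).all()
        and (moved[:, 1] <= h - 1).all()
    )


@dataclass
class TrackingResult:
    """Poses for every frame plus the context needed for re-tracking."""

    template: TemplateArea
    poses: list[VertebraPose]
    config: SearchConfig
    audit_log: list[dict] = field(default_factory=list)

    @property
    def any_invalid(self) -> bool:
        return any(not p.valid for p in self.poses)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": [p.frame_index for p in self.poses],
                "vertebra": [p.vertebra_label for p in self.poses],
                "rotation_deg": [p.rotation_deg for p in self.poses],
                "tx_px": [p.tx_px for p in self.poses],
                "ty_px": [p.ty_px for p in self.poses],
                "match_score": [p.match_score for p in self.poses],
                "valid": [p.valid for p in self.poses],
            }
        )


class VertebraTracker:
    """Tracks one template through a frame stack.

    Heavy per-frame NGF pyramids can be shared between trackers via an
    external cache (see :func:`track_stack`).
    """

    def __init__(
        self,
        frames: np.ndarray,
        template: TemplateArea,
        config: SearchConfig | None = None,
        ngf_cache: dict | None = None,
    ):
        self.frames = np.asarray(frames)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a (n_frames, H, W) stack")
        if not 0 <= template.reference_frame_index < len(self.frames):
            raise ValidationError("reference frame index out of range")
        self.template = template
        self.config = config or SearchConfig()
        eps = self.config.epsilon
        ref_img = self.frames[template.reference_frame_index].astype(float)
        if eps is None:
            eps = default_epsilon(ref_img, template)
        self.epsilon = eps
        self.levels = [
            _LevelData(ref_img, template, 2**lev, eps, self.config.presmooth_sigma)
            for lev in range(self.config.pyramid_levels - 1, -1, -1)
        ]  # coarsest first
        self._ngf_cache = ngf_cache if ngf_cache is not None else {}

    def _ngf(self, frame_index: int, level: _LevelData) -> np.ndarray:
        key = (frame_index, level.factor, round(level.epsilon, 9))
        if key not in self._ngf_cache:
            self._ngf_cache[key] = level.frame_ngf(self.frames[frame_index].astype(float))
        return self._ngf_cache[key]

    def _grid_best(
        self,
        frame_index: int,
        level: _LevelData,
        center: np.ndarray,
        rot_offsets: np.ndarray,
        trans_offsets: np.ndarray,
        tie_break: bool = False,
    ) -> np.ndarray:
        """Best pose on a (rotation x tx x ty) grid around ``center`` (full-res units)."""
        dr, dtx, dty = np.meshgrid(rot_offsets, trans_offsets, trans_offsets, indexing="ij")
        deltas = np.column_stack([dr.ravel(), dtx.ravel(), dty.ravel()])
        cand = center + deltas
        cand_lvl = cand / (1.0, level.factor, level.factor)
        scores = _score_many(
            self._ngf(frame_index, level), level.pix, level.centroid,
            level.ref_vec, cand_lvl,
        )
        if tie_break:
            # prefer the smallest pose change from the previous frame
            change = np.abs(deltas).sum(axis=1)
            return cand[int(np.lexsort((change, -scores))[0])]
        return cand[int(np.argmax(scores))]

    def _search_frame(self, frame_index: int, init: np.ndarray) -> tuple[np.ndarray, float]:
        cfg = self.config
        rmax = cfg.max_rotation_per_frame_deg
        tmax = cfg.max_translation_per_frame_px
        coarse = self.levels[0]

        # coarse level: localize translation over the full search window
        # (small rotations are unresolvable at this scale)
        rots = np.arange(-rmax, rmax + 1e-9, cfg.coarse_rotation_step_deg)
        ts = np.arange(-tmax, tmax + 1e-9, cfg.coarse_translation_step_px * coarse.factor)
        best = self._grid_best(frame_index, coarse, init, rots, ts, tie_break=True)

        # mid level(s): consolidate translation at sub-pixel steps
        # (non-integer steps avoid the interpolation bias toward integer shifts)
        for level in self.levels[1:-1]:
            rr = np.arange(-1.5, 1.5 + 1e-9, 0.75)
            tt = np.arange(-3.0, 3.0 + 1e-9, 0.75)
            best = self._grid_best(frame_index, level, best, rr, tt)

        # full resolution: rotation is only resolvable here -- dense sweep of
        # the whole per-frame rotation range, then a sub-pixel local grid,
        # then continuous refinement
        fine = self.levels[-1]
        best = self._grid_best(
            frame_index, fine, best,
            np.arange(-rmax, rmax + 1e-9, 0.25),
            np.array([-0.6, 0.0, 0.6]),
        )
        best = self._grid_best(
            frame_index, fine, best,
            np.arange(-0.3, 0.3 + 1e-9, 0.05),
            np.arange(-0.6, 0.6 + 1e-9, 0.3),
        )
        ngf = self._ngf(frame_index, fine)

        def neg_score(pose):
            return -float(
                _score_many(ngf, fine.pix, fine.centroid, fine.ref_vec, pose[None, :])[0]
            )

        res = minimize(
            neg_score,
            best,
            method="Nelder-Mead",
            options={
                "xatol": 2e-3,
                "fatol": 1e-8,
                "maxiter": 100,
                "initial_simplex": best
                + np.vstack([np.zeros(3), np.diag([0.1, 0.3, 0.3])]),
            },
        )
        pose = res.x if -res.fun >= -neg_score(best) else best
        return pose, -neg_score(pose)

    def track(self) -> TrackingResult:
        n = len(self.frames)
        ref = self.template.reference_frame_index
        label = self.template.vertebra_label
        poses: list[VertebraPose | None] = [None] * n

        ref_pose = np.zeros(3)
        ref_score = float(
            _score_many(
                self._ngf(ref, self.levels[-1]),
                self.levels[-1].pix,
                self.levels[-1].centroid,
                self.levels[-1].ref_vec,
                ref_pose[None, :],
            )[0]
        )
        poses[ref] = self._make_pose(ref, ref_pose, ref_score)

        for direction in (1, -1):
            prev = ref_pose
            rng = range(ref + direction, n if direction == 1 else -1, direction)
            for i in rng:
                pose, score = self._search_frame(i, prev)
                poses[i] = self._make_pose(i, pose, score)
                prev = pose
        return TrackingResult(self.template, [p for p in poses], self.config)

    def _make_pose(self, frame_index: int, pose: np.ndarray, score: float) -> VertebraPose:
        in_bounds = _polygon_in_bounds(self.template, pose, self.frames.shape[1:])
        return VertebraPose(
            frame_index=frame_index,
            vertebra_label=self.template.vertebra_label,
            rotation_deg=float(pose[0]),
            tx_px=float(pose[1]),
            ty_px=float(pose[2]),
            match_score=float(score),
            valid=bool(in_bounds and score >= self.config.score_floor),
        )

    def retrack_from(self, result: TrackingResult, frame_index: int) -> TrackingResult:
        """Re-track frames beyond ``frame_index`` (outward from the reference)."""
        ref = self.template.reference_frame_index
        direction = 1 if frame_index >= ref else -1
        poses = list(result.poses)
        prev = np.array(
            [
                poses[frame_index].rotation_deg,
                poses[frame_index].tx_px,
                poses[frame_index].ty_px,
            ]
        )
        n = len(self.frames)
        rng = range(frame_index + direction, n if direction == 1 else -1, direction)
        for i in rng:
            pose, score = self._search_frame(i, prev)
            poses[i] = self._make_pose(i, pose, score)
            prev = pose
        return TrackingResult(self.template, poses, self.config, list(result.audit_log))


def track_vertebra(
    frames: np.ndarray,
    template: TemplateArea,
    config: SearchConfig | None = None,
    ngf_cache: dict | None = None,
) -> TrackingResult:
    """Best-fit rigid tracking of one vertebra through all frames."""
    return VertebraTracker(frames, template, config, ngf_cache).track()


def track_stack(
    frames: np.ndarray,
    templates: list[TemplateArea],
    config: SearchConfig | None = None,
) -> dict[str, TrackingResult]:
    """Track several vertebrae, sharing per-frame NGF pyramids."""
    cache: dict = {}
    out = {}
    for tpl in templates:
        out[tpl.vertebra_label] = track_vertebra(frames, tpl, config, ngf_cache=cache)
    return out


def manual_correction(
    result: TrackingResult,
    frames: np.ndarray,
    frame_index: int,
    corrected_pose: tuple[float, float, float],
) -> TrackingResult:
    """Replace one frame's pose and re-track the frames beyond it.

    The correction is recorded in the audit log.  A correction that jumps
    outside the configured per-frame search bounds relative to its
    neighbours is still applied, with a warning.
    """
    import warnings

    n = len(result.poses)
    if not 0 <= frame_index < n:
        raise ValidationError("frame_index out of range")
    old = result.poses[frame_index]
    ang, tx, ty = corrected_pose
    cfg = result.config
    for nb in (frame_index - 1, frame_index + 1):
        if 0 <= nb < n:
            p = result.poses[nb]
            if (
                abs(p.rotation_deg - ang) > cfg.max_rotation_per_frame_deg
                or abs(p.tx_px - tx) > cfg.max_translation_per_frame_px
                or abs(p.ty_px - ty) > cfg.max_translation_per_frame_px
            ):
                warnings.warn(
                    f"correction at frame {frame_index} is outside the search bounds "
                    f"of neighbour frame {nb}; applying anyway",
                    stacklevel=2,
                )
                break

    tracker = VertebraTracker(frames, result.template, result.config)
    score = float(
        _score_many(
            tracker._ngf(frame_index, tracker.levels[-1]),
            tracker.levels[-1].pix,
            tracker.levels[-1].centroid,
            tracker.levels[-1].ref_vec,
            np.array([[ang, tx, ty]]),
        )[0]
    )
    poses = list(result.poses)
    poses[frame_index] = tracker._make_pose(frame_index, np.array([ang, tx, ty]), score)
    interim = TrackingResult(result.template, poses, result.config, list(result.audit_log))
    out = tracker.retrack_from(interim, frame_index)
    out.audit_log.append(
        {
            "frame_index": frame_index,
            "old_pose": (old.rotation_deg, old.tx_px, old.ty_px),
            "new_pose": (float(ang), float(tx), float(ty)),
        }
    )
    return out


def templates_from_json(obj) -> list[TemplateArea]:
    """Build templates from the JSON structure written by the simulator."""
    return [
        TemplateArea(
            vertebra_label=t["vertebra_label"],
            polygon=tuple((float(x), float(y)) for x, y in t["polygon"]),
            reference_frame_index=int(t["reference_frame_index"]),
        )
        for t in obj
    ]
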