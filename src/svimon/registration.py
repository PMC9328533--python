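"""Affine registration of repeat photographs.

A sensed photograph is aligned to a reference image of the same site with a
2-D affine transform estimated from ORB keypoint matches under RANSAC.
Coordinates are 0-based with ``x`` = column and ``y`` = row; transforms act on
``(x, y)`` points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import ORB, match_descriptors
from skimage.transform import AffineTransform as _SkAffine
from skimage.transform import warp

from svimon.errors import ParameterError, RegistrationError

__all__ = [
    "AffineTransform",
    "MatchSet",
    "estimate_affine",
    "register_pair",
    "checkerboard_mosaic",
]

_MIN_DET = 1e-6


@dataclass(frozen=True)
class AffineTransform:
    """A 2x3 affine map sending ``(x, y)`` pixel coordinates to new coordinates.

    ``matrix`` holds ``[[a, b, tx], [c, d, ty]]`` so that a point ``p``
    maps to ``A @ (x, y, 1)``.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ParameterError(f"affine matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) <= _MIN_DET:
            raise ParameterError("affine linear part is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_params(
        cls,
        rotation_deg: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
        scale: float = 1.0,
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform":
        """Rotation/scale about ``center`` followed by a translation."""
        theta = np.deg2rad(rotation_deg)
        c, s = np.cos(theta), np.sin(theta)
        lin = scale * np.array([[c, -s], [s, c]])
        ctr = np.asarray(center, dtype=float)
        t = ctr - lin @ ctr + np.asarray(translation, dtype=float)
        return cls(np.column_stack([lin, t]))

    @classmethod
    def from_skimage(cls, tf: _SkAffine) -> "AffineTransform":
        return cls(np.asarray(tf.params)[:2, :])

    def to_skimage(self) -> _SkAffine:
        params = np.vstack([self.matrix, [0.0, 0.0, 1.0]])
        return _SkAffine(matrix=params)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    @property
    def inverse(self) -> "AffineTransform":
        lin_inv = np.linalg.inv(self.matrix[:, :2])
        t_inv = -lin_inv @ self.matrix[:, 2]
        return AffineTransform(np.column_stack([lin_inv, t_inv]))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        lin = self.matrix[:, :2] @ other.matrix[:, :2]
        t = self.matrix[:, :2] @ other.matrix[:, 2] + self.matrix[:, 2]
        return AffineTransform(np.column_stack([lin, t]))

    def corner_error(self, other: "AffineTransform", shape: tuple[int, int]) -> float:
        """Mean displacement (px) of the four image corners under self vs other."""
        h, w = shape[:2]
        corners = np.array(
            [[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float
        )
        return float(
            np.mean(np.linalg.norm(self.apply(corners) - other.apply(corners), axis=1))
        )

    def is_identity(self, shape: tuple[int, int], tol_px: float = 0.1) -> bool:
        return self.corner_error(AffineTransform.identity(), shape) <= tol_px


@dataclass
class MatchSet:
    """Matched point pairs between a reference and a sensed image."""

    reference: np.ndarray  # (N, 2) x, y
    sensed: np.ndarray  # (N, 2) x, y
    scores: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.reference = np.atleast_2d(np.asarray(self.reference, dtype=float))
        self.sensed = np.atleast_2d(np.asarray(self.sensed, dtype=float))
        if self.reference.shape != self.sensed.shape or self.reference.shape[1] != 2:
            raise ParameterError("reference and sensed point arrays must both be (N, 2)")
        if self.scores is None:
            self.scores = np.ones(len(self.reference))
        else:
            self.scores = np.asarray(self.scores, dtype=float)

    def __len__(self) -> int:
        return len(self.reference)

    def subset(self, idx: np.ndarray) -> "MatchSet":
        return MatchSet(self.reference[idx], self.sensed[idx], self.scores[idx])


def _collinear(points: np.ndarray, tol: float = 1e-6) -> bool:
    pts = points - points.mean(axis=0)
    # rank < 2 means all points lie on one line (or coincide)
    return np.linalg.matrix_rank(pts, tol=tol) < 2


def _lstsq_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    """Least-squares affine mapping src -> dst; raises on degenerate geometry."""
    if _collinear(src):
        raise RegistrationError("matched points are collinear; affine is underdetermined")
    a = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(a, dst, rcond=None)
    return AffineTransform(coef.T)


def estimate_affine(
    matches: MatchSet,
    ransac_threshold_px: float = 2.0,
    max_iters: int = 500,
    seed: int | None = 0,
) -> tuple[AffineTransform, np.ndarray]:
    """RANSAC + least-squares affine estimate from point matches.

    Returns the transform mapping sensed coordinates to reference coordinates
    and the boolean inlier mask of the consensus set. Deterministic for a
    fixed ``seed`` and match ordering; the final least-squares refit over the
    consensus set makes the result insensitive to match ordering whenever the
    same consensus is reached.
    """
    n = len(matches)
    if n < 3:
        raise RegistrationError(f"need at least 3 matches, got {n}")
    src = matches.sensed
    dst = matches.reference

    if n == 3:
        tf = _lstsq_affine(src, dst)
        return tf, np.ones(3, dtype=bool)

    rng = np.random.default_rng(seed)
    best_mask = None
    best_count = 0
    best_err = np.inf
    for _ in range(max_iters):
        idx = rng.choice(n, size=3, replace=False)
        if _collinear(src[idx]):
            continue
        try:
            cand = _lstsq_affine(src[idx], dst[idx])
        except RegistrationError:
            continue
        resid = np.linalg.norm(cand.apply(src) - dst, axis=1)
        mask = resid <= ransac_threshold_px
        count = int(mask.sum())
        err = float(resid[mask].sum())
        if count > best_count or (count == best_count and err < best_err):
            best_count, best_mask, best_err = count, mask, err
    if best_mask is None or best_count < 3 or _collinear(src[best_mask]):
        raise RegistrationError("no non-degenerate RANSAC consensus found")
    tf = _lstsq_affine(src[best_mask], dst[best_mask])
    # one re-weighted pass: refit on inliers of the refit
    resid = np.linalg.norm(tf.apply(src) - dst, axis=1)
    mask = resid <= ransac_threshold_px
    if mask.sum() >= 3 and not _collinear(src[mask]):
        tf = _lstsq_affine(src[mask], dst[mask])
        best_mask = mask
    return tf, best_mask


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        return rgb2gray(img)
    return img.astype(float) / 255.0 if img.dtype == np.uint8 else img.astype(float)


def _orb_features(gray: np.ndarray, n_keypoints: int):
    orb = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
    orb.detect_and_extract(gray)
    return orb.keypoints, orb.descriptors


def register_pair(
    reference: np.ndarray,
    sensed: np.ndarray,
    ransac_threshold_px: float = 2.0,
    seed: int | None = 0,
    n_keypoints: int = 800,
    min_inliers: int = 6,
) -> tuple[np.ndarray, AffineTransform, MatchSet]:
    """Align ``sensed`` to ``reference``; returns (registered, transform, inliers).

    The transform maps sensed pixel coordinates into the reference frame.
    Pixels with no source data are zero-filled. Raises
    :class:`RegistrationError` when fewer than ``min_inliers`` consistent
    matches survive RANSAC.
    """
    ref = np.asarray(reference)
    sen = np.asarray(sensed)
    if ref.size == 0 or sen.size == 0:
        raise ParameterError("empty image")
    try:
        kp_ref, desc_ref = _orb_features(_to_gray(ref), n_keypoints)
        kp_sen, desc_sen = _orb_features(_to_gray(sen), n_keypoints)
    except RuntimeError as exc:  # ORB raises when no keypoints are found
        raise RegistrationError(f"keypoint detection failed: {exc}") from exc
    if len(kp_ref) < 3 or len(kp_sen) < 3:
        raise RegistrationError("too few keypoints for registration")
    pairs = match_descriptors(desc_ref, desc_sen, cross_check=True)
    if len(pairs) < 3:
        raise RegistrationError(f"only {len(pairs)} descriptor matches")
    # skimage keypoints are (row, col); flip to (x, y)
    matches = MatchSet(kp_ref[pairs[:, 0]][:, ::-1], kp_sen[pairs[:, 1]][:, ::-1])
    tf, inlier_mask = estimate_affine(matches, ransac_threshold_px, seed=seed)
    if int(inlier_mask.sum()) < min_inliers:
        raise RegistrationError(
            f"only {int(inlier_mask.sum())} inlier matches (< {min_inliers})"
        )
    registered = warp_image(sen, tf, output_shape=ref.shape[:2], order=1)
    return registered, tf, matches.subset(inlier_mask)


def warp_image(
    image: np.ndarray,
    transform: AffineTransform,
    output_shape: tuple[int, int],
    order: int = 1,
) -> np.ndarray:
    """Resample ``image`` through ``transform`` (input -> output coords).

    ``order=0`` for class-id masks, ``order=1`` for intensity images. The
    dtype of the input is preserved; uncovered output pixels are zero.
    """
    img = np.asarray(image)
    out = warp(
        img,
        inverse_map=transform.inverse.to_skimage(),
        output_shape=output_shape,
        order=order,
        mode="constant",
        cval=0,
        preserve_range=True,
    )
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(img.dtype)


def checkerboard_mosaic(
    reference: np.ndarray, registered: np.ndarray, tiles: int = 8
) -> np.ndarray:
    """Alternate square tiles from two aligned images (registration QA view).

    Even-parity tiles (row+col of the tile grid even) come from the reference.
    """
    ref = np.asarray(reference)
    reg = np.asarray(registered)
    if ref.shape != reg.shape:
        raise ParameterError(f"shape mismatch: {ref.shape} vs {reg.shape}")
    if tiles < 2:
        raise ParameterError("tiles must be >= 2")
    h, w = ref.shape[:2]
    rows = np.minimum(np.arange(h) * tiles // h, tiles - 1)
    cols = np.minimum(np.arange(w) * tiles // w, tiles - 1)
    parity = (rows[:, None] + cols[None, :]) % 2
    if ref.ndim == 3:
        parity = parity[..., None]
    return np.where(parity == 0, ref, reg)
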