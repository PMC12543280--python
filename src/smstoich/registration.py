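"""Spot detection, channel registration from bead images, and colocalization.

Detection finds local maxima above a background threshold and refines them to
sub-pixel precision by background-subtracted centroid.  Registration between
the green and far-red channels is a pure translation estimated from a
TetraSpeck-style bead image pair.  Colocalization pairs mutual nearest
neighbors within a fixed distance (2 px by default) after applying the
registration shift to the far-red coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

__all__ = [
    "SpotDetection",
    "RegistrationTransform",
    "SpotPair",
    "InsufficientBeadsError",
    "spot_cap",
    "detect_spots",
    "estimate_registration",
    "colocalize",
    "DEFAULT_COLOC_DISTANCE",
]

#: Maximum registered-coordinate separation (pixels) for declaring a green
#: and a far-red spot the same complex.
DEFAULT_COLOC_DISTANCE = 2.0


@dataclass(frozen=True)
class SpotDetection:
    x: float
    y: float
    peak_intensity: float
    channel: str = "unknown"


@dataclass(frozen=True)
class RegistrationTransform:
    """Displacement of the far-red channel relative to green, in pixels.

    A structure at green-channel position (x, y) appears at
    (x + dx, y + dy) in the far-red channel; :meth:`apply` maps far-red
    coordinates back into the green frame.
    """

    dx: float
    dy: float

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, dtype=float) - np.array([self.dx, self.dy])

    def inverse(self) -> "RegistrationTransform":
        return RegistrationTransform(-self.dx, -self.dy)


@dataclass(frozen=True)
class SpotPair:
    green: SpotDetection
    farred: SpotDetection
    distance_after_registration: float


class InsufficientBeadsError(ValueError):
    """Fewer than 3 mutually matchable bead detections."""


def spot_cap(image_shape: tuple[int, int], cap_scale: float = 1.0) -> int:
    """Detection cap: floor(imgArea / 3e5 * cap_scale) candidate spots."""
    h, w = image_shape
    return int(math.floor(h * w / 3e5 * cap_scale))


def _refine_centroid(image: np.ndarray, cy: int, cx: int, r: int, background: float) -> tuple[float, float]:
    h, w = image.shape
    y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
    x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
    patch = np.clip(image[y0:y1, x0:x1] - background, 0.0, None)
    total = patch.sum()
    if total <= 0:
        return float(cx), float(cy)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return float((patch * xx).sum() / total), float((patch * yy).sum() / total)


def detect_spots(
    image: np.ndarray,
    k_sd: float = 5.0,
    max_spots: int | None = None,
    cap_scale: float = 1.0,
    min_distance: int = 3,
    channel: str = "unknown",
    refine_radius: int = 3,
) -> list[SpotDetection]:
    """Detect diffraction-limited spots in a single 2-D image.

    Candidates are local maxima exceeding ``background mean + k_sd * sd``;
    each is refined to sub-pixel coordinates by background-subtracted
    centroid.  When more candidates exist than the cap — ``max_spots`` if
    given, else ``floor(imgArea/3e5 * cap_scale)`` — only the brightest are
    kept.  A computed cap below 1 (image much smaller than the sensor the
    formula targets) disables the cap.  A zero-variance image yields an
    empty list.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("image is empty")
    if image.std() == 0:
        return []
    # robust background statistics: sparse bright spots must not inflate
    # the mean/sd, so use median and MAD-derived sd
    background = float(np.median(image))
    sd = float(np.median(np.abs(image - background)) / 0.6745)
    if sd == 0:
        sd = float(image.std())
    threshold = background + k_sd * sd
    peaks = peak_local_max(image, min_distance=min_distance, threshold_abs=threshold)
    if len(peaks) == 0:
        return []
    intensities = image[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(-intensities, kind="stable")
    cap = max_spots if max_spots is not None else spot_cap(image.shape, cap_scale)
    if max_spots is None and cap < 1:
        cap = len(order)
    order = order[:cap]
    out = []
    for i in order:
        cy, cx = int(peaks[i, 0]), int(peaks[i, 1])
        x, y = _refine_centroid(image, cy, cx, refine_radius, background)
        out.append(SpotDetection(x=x, y=y, peak_intensity=float(intensities[i]), channel=channel))
    return out


def _mutual_nn(a: np.ndarray, b: np.ndarray, max_dist: float) -> list[tuple[int, int, float]]:
    """Mutual nearest-neighbor pairs within ``max_dist`` (inclusive).

    Ties are broken deterministically toward the smallest index.
    """
    if len(a) == 0 or len(b) == 0:
        return []
    tree_a, tree_b = cKDTree(a), cKDTree(b)
    d_ab, nn_ab = tree_b.query(a)  # nearest b for each a
    d_ba, nn_ba = tree_a.query(b)  # nearest a for each b
    pairs = []
    for i in range(len(a)):
        j = int(nn_ab[i])
        if int(nn_ba[j]) == i and d_ab[i] <= max_dist:
            pairs.append((i, j, float(d_ab[i])))
    return pairs


def estimate_registration(
    bead_green: np.ndarray,
    bead_farred: np.ndarray,
    k_sd: float = 5.0,
    match_radius: float = 10.0,
    min_distance: int = 3,
) -> RegistrationTransform:
    """Estimate the green<->far-red translation from a bead image pair.

    Beads are detected in both channels, matched by mutual nearest neighbor
    within ``match_radius`` pixels, and the translation minimizing the mean
    squared distance between matched centroids (the mean displacement
    far-red minus green) is returned.  One refinement pass re-matches after
    applying the initial estimate.  Raises :class:`InsufficientBeadsError`
    with < 3 matches.
    """
    greens = detect_spots(bead_green, k_sd=k_sd, max_spots=10000, min_distance=min_distance, channel="green")
    fars = detect_spots(bead_farred, k_sd=k_sd, max_spots=10000, min_distance=min_distance, channel="farred")
    g = np.array([[s.x, s.y] for s in greens], dtype=float).reshape(-1, 2)
    f = np.array([[s.x, s.y] for s in fars], dtype=float).reshape(-1, 2)

    disp = np.zeros(2)  # far-red minus green
    for _ in range(2):  # initial match + one refinement pass
        pairs = _mutual_nn(g, f - disp, match_radius)
        if len(pairs) < 3:
            raise InsufficientBeadsError(
                f"only {len(pairs)} mutually matchable beads (need >= 3)"
            )
        gi = np.array([p[0] for p in pairs])
        fi = np.array([p[1] for p in pairs])
        disp = (f[fi] - g[gi]).mean(axis=0)
    return RegistrationTransform(dx=float(disp[0]), dy=float(disp[1]))


def colocalize(
    greens: list[SpotDetection],
    farreds: list[SpotDetection],
    transform: RegistrationTransform | None = None,
    coloc_distance: float = DEFAULT_COLOC_DISTANCE,
) -> list[SpotPair]:
    """Pair colocalized green and far-red spots.

    The registration transform is applied to far-red coordinates first;
    pairs are mutual nearest neighbors at distance <= ``coloc_distance``
    (inclusive boundary).  Each spot joins at most one pair.
    """
    if transform is None:
        transform = RegistrationTransform(0.0, 0.0)
    g = np.array([[s.x, s.y] for s in greens], dtype=float).reshape(-1, 2)
    f = np.array([[s.x, s.y] for s in farreds], dtype=float).reshape(-1, 2)
    if len(f):
        f = transform.apply(f)
    return [
        SpotPair(greens[i], farreds[j], d)
        for i, j, d in _mutual_nn(g, f, coloc_distance)
    ]
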