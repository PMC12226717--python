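"""Image normalization stack and gradient-boosted tabular imputation.

The image pipeline is order-fixed: resample (Lanczos) -> CLAHE ->
[polar transform, focused flow only] -> min-max normalization, so the
final pixel values always land in [0, 1].  The working resolution
defaults to 256x256.

Tabular imputation follows the multiple-imputation scheme: an
iterative per-column LightGBM regression repeated ``n_rounds`` (default
5) times with different stochastic seeds, the final value being the
mean of the rounds.  Observed cells are never altered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import exposure

from .core.types import FEATURE_ORDER, ClinicalRecord, ImageBundle

__all__ = [
    "PolarSpec",
    "resample_image",
    "apply_clahe",
    "normalize_minmax",
    "polar_transform",
    "inverse_polar_transform",
    "preprocess_image",
    "preprocess_bundle",
    "impute_tabular",
]

_IMPUTABLE = ("bcva", "iop", "cdr")


@dataclass(frozen=True)
class PolarSpec:
    """Geometry of the polar transform about the optic-disc centre.

    ``center`` is (row, col) in 0-based pixel-centre coordinates;
    ``output_size`` is (rings, angles).  Angle 0 points along +col and
    increases counter-clockwise (up in the standard image view).
    """

    center: tuple[float, float]
    radius: float
    output_size: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if min(self.output_size) < 1:
            raise ValueError("output_size entries must be >= 1")


def resample_image(img: np.ndarray, size: int) -> np.ndarray:
    """Resample to ``size`` x ``size`` with Lanczos (order-3 windowed sinc).

    Output values are clipped to the input's value range so the kernel's
    ringing cannot overshoot the admissible dynamic range.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image")
    if size < 8:
        raise ValueError("size must be >= 8")

    def _resample_plane(plane: np.ndarray) -> np.ndarray:
        pil = Image.fromarray(plane.astype(np.float32), mode="F")
        out = pil.resize((size, size), resample=Image.LANCZOS)
        return np.asarray(out, dtype=np.float64)

    if img.ndim == 2:
        out = _resample_plane(img)
    elif img.ndim == 3:
        out = np.stack([_resample_plane(img[..., c]) for c in range(img.shape[-1])], axis=-1)
    else:
        raise ValueError(f"expected 2-D or 3-D raster, got shape {img.shape}")

    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        return np.clip(np.round(out), info.min, info.max).astype(img.dtype)
    return np.clip(out, float(img.min()), float(img.max()))


def apply_clahe(img: np.ndarray, clip_limit: float = 2.0,
                tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    ``clip_limit`` is expressed as a multiple of the mean histogram bin
    height (2.0 by default) and converted internally to the fractional
    limit the backend expects.  RGB inputs are equalized per channel.
    Constant images are returned unchanged.
    """
    img = np.asarray(img)
    if clip_limit <= 0:
        raise ValueError("clip_limit must be > 0")
    if img.ndim == 3:
        return np.stack([apply_clahe(img[..., c], clip_limit, tile_grid)
                         for c in range(img.shape[-1])], axis=-1)
    if img.max() == img.min():
        return img.copy()

    integer_input = np.issubdtype(img.dtype, np.integer)
    if integer_input:
        info = np.iinfo(img.dtype)
        work = img.astype(np.float64) / info.max
    else:
        lo, hi = float(img.min()), float(img.max())
        work = (img.astype(np.float64) - lo) / (hi - lo)

    kernel = (max(1, img.shape[0] // tile_grid[0]), max(1, img.shape[1] // tile_grid[1]))
    out = exposure.equalize_adapthist(work, kernel_size=kernel,
                                      clip_limit=clip_limit / 256.0)
    if integer_input:
        return np.clip(np.round(out * info.max), info.min, info.max).astype(img.dtype)
    return lo + out * (hi - lo)


def normalize_minmax(img: np.ndarray) -> np.ndarray:
    """Scale pixel values to [0, 1]: (x - min) / (max - min).

    A constant image has no contrast to scale; by documented convention
    it maps to all zeros (with a warning) instead of raising.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        warnings.warn("constant image: min-max normalization returns zeros",
                      RuntimeWarning, stacklevel=2)
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def _check_center(img: np.ndarray, spec: PolarSpec) -> None:
    cr, cc = spec.center
    if not (0 <= cr <= img.shape[0] - 1 and 0 <= cc <= img.shape[1] - 1):
        raise ValueError(f"center {spec.center} outside image bounds {img.shape[:2]}")


def polar_transform(img: np.ndarray, spec: PolarSpec) -> np.ndarray:
    """Resample ``img`` onto a (rings x angles) polar grid about a centre.

    Output row ``r``, column ``a`` samples the input at radius
    ``(r / rings) * radius`` and angle ``2*pi*a / angles`` (bilinear;
    out-of-bounds reads 0).  The disc region is magnified into the
    low-``r`` rows.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("polar_transform expects a 2-D raster")
    _check_center(img, spec)
    rings, angles = spec.output_size
    cr, cc = spec.center
    r = np.arange(rings)[:, None] / rings * spec.radius
    theta = 2.0 * np.pi * np.arange(angles)[None, :] / angles
    rows = cr - r * np.sin(theta)
    cols = cc + r * np.cos(theta)
    return ndimage.map_coordinates(img, [rows, cols], order=1, mode="constant", cval=0.0)


def inverse_polar_transform(polar_img: np.ndarray, spec: PolarSpec,
                            out_shape: tuple[int, int]) -> np.ndarray:
    """Map a polar raster back onto the Cartesian grid (oracle inverse).

    Pixels outside the sampled disc read 0.  Bilinear interpolation with
    angular wrap-around.
    """
    polar_img = np.asarray(polar_img, dtype=np.float64)
    rings, angles = spec.output_size
    if polar_img.shape != (rings, angles):
        raise ValueError("polar image shape does not match spec.output_size")
    cr, cc = spec.center
    rows, cols = np.mgrid[0:out_shape[0], 0:out_shape[1]].astype(float)
    dy = -(rows - cr)  # +angle is counter-clockwise in view coordinates
    dx = cols - cc
    rho = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    r_idx = rho / spec.radius * rings
    a_idx = theta / (2.0 * np.pi) * angles

    inside = r_idx <= rings - 1
    # manual bilinear with wrap on the angle axis
    r0 = np.clip(np.floor(r_idx).astype(int), 0, rings - 1)
    r1 = np.clip(r0 + 1, 0, rings - 1)
    fr = np.clip(r_idx - r0, 0.0, 1.0)
    a0 = np.floor(a_idx).astype(int) % angles
    a1 = (a0 + 1) % angles
    fa = a_idx - np.floor(a_idx)
    out = ((1 - fr) * ((1 - fa) * polar_img[r0, a0] + fa * polar_img[r0, a1])
           + fr * ((1 - fa) * polar_img[r1, a0] + fa * polar_img[r1, a1]))
    out[~inside] = 0.0
    return out


def preprocess_image(img: np.ndarray, size: int = 256, clahe_clip: float = 2.0,
                     tile_grid: tuple[int, int] = (8, 8),
                     polar: PolarSpec | None = None) -> np.ndarray:
    """The order-fixed stack: resample -> CLAHE -> [polar] -> min-max."""
    out = resample_image(img, size)
    out = apply_clahe(out, clahe_clip, tile_grid)
    if polar is not None:
        out = polar_transform(out if out.ndim == 2 else out.mean(axis=-1), polar)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return normalize_minmax(out)


def preprocess_bundle(bundle: ImageBundle, size: int = 256, clahe_clip: float = 2.0,
                      tile_grid: tuple[int, int] = (8, 8)) -> ImageBundle:
    """Apply the normalization stack to every present modality."""
    out = ImageBundle()
    for modality in ("global", "focused", "rnfl"):
        img = bundle.get(modality)
        if img is not None:
            out.set(modality, preprocess_image(img, size, clahe_clip, tile_grid))
    return out


def impute_tabular(records: list[ClinicalRecord], n_rounds: int = 5,
                   seed: int = 0, max_sweeps: int = 10,
                   tol: float = 1e-4) -> list[ClinicalRecord]:
    """Fill missing bcva/iop/cdr cells by averaged iterative boosted imputation.

    Each of the ``n_rounds`` rounds initializes missing cells at the
    column mean, then cycles per-column LightGBM regressions (trained on
    rows where that column is observed, predicting the missing rows)
    until the largest cell change drops below ``tol`` or ``max_sweeps``
    sweeps.  The rounds differ only in their stochastic seed; their mean
    is the imputed value.  Observed cells are returned untouched.
    """
    import lightgbm as lgb

    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    X = np.stack([r.feature_vector() for r in records])  # n x 5, NaN = missing
    observed = ~np.isnan(X)
    target_cols = [FEATURE_ORDER.index(c) for c in _IMPUTABLE]
    for j in range(X.shape[1]):
        if not observed[:, j].any():
            raise ValueError(f"column {FEATURE_ORDER[j]!r} is entirely missing")
    if (observed.all(axis=0)).sum() < 2:
        raise ValueError("need at least 2 fully observed columns")
    bad = [FEATURE_ORDER[j] for j in range(X.shape[1])
           if not observed[:, j].all() and j not in target_cols]
    if bad:
        raise ValueError(f"missingness only supported in {_IMPUTABLE}, found in {bad}")
    if observed.all():
        return [ClinicalRecord(**r.__dict__) for r in records]

    col_means = np.nanmean(X, axis=0)
    fills = np.zeros((n_rounds,) + X.shape)
    for k in range(n_rounds):
        Xw = X.copy()
        for j in target_cols:
            Xw[~observed[:, j], j] = col_means[j]
        for sweep in range(max_sweeps):
            max_change = 0.0
            for j in target_cols:
                miss = ~observed[:, j]
                if not miss.any():
                    continue
                other = [c for c in range(X.shape[1]) if c != j]
                model = lgb.LGBMRegressor(
                    n_estimators=100, learning_rate=0.1, num_leaves=31,
                    min_child_samples=10, subsample=0.8, subsample_freq=1,
                    colsample_bytree=0.9, random_state=seed * 1000 + k,
                    verbose=-1, n_jobs=1,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    model.fit(Xw[observed[:, j]][:, other], Xw[observed[:, j], j])
                    pred = model.predict(Xw[miss][:, other])
                max_change = max(max_change, float(np.abs(pred - Xw[miss, j]).max()))
                Xw[miss, j] = pred
            if max_change < tol:
                break
        fills[k] = Xw
    Xfinal = fills.mean(axis=0)
    Xfinal[observed] = X[observed]  # observed cells are inviolate

    out = []
    for i, r in enumerate(records):
        kw = dict(r.__dict__)
        for name in _IMPUTABLE:
            j = FEATURE_ORDER.index(name)
            if not observed[i, j]:
                kw[name] = float(Xfinal[i, j])
        out.append(ClinicalRecord(**kw))
    return out
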