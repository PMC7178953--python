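"""Offline 10x and per-epoch online data augmentation.

Offline augmentation expands each training pair to exactly ten: the
original, a vertical flip, four random translations (horizontal and
vertical shifts drawn independently from [-32, 32] px), and four random
field-of-view scalings (a margin drawn from [10, 50] px, independently per
axis, cropped from the border and resampled back to the native size).

Online augmentation independently applies, each with probability 1/2,
rotation, shrinking, translation, additive Gaussian noise, and gamma
transformation, freshly drawn every epoch.  Geometric operations act
identically on the image and its mask; intensity operations (noise, gamma)
touch the image alone.  Masks are resampled nearest-neighbour so they stay
strictly binary; borders uncovered by a geometric operation are zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["AugmentSpec", "offline_augment", "online_augment"]


@dataclass(frozen=True)
class AugmentSpec:
    """Parameter ranges for both augmentation stages (pixels, degrees)."""

    # offline
    translation_range: int = 32          # per axis, independent draws
    scaling_range: tuple = (10, 50)      # cropped margin per axis
    n_translations: int = 4
    n_scalings: int = 4
    # online (each op applied with probability 1/2)
    online_rotation_deg: float = 10.0
    online_shrink_max: float = 0.10
    online_translation: int = 16
    online_noise_sigma: float = 5.0
    online_gamma_range: tuple = (0.7, 1.3)
    # offline geometric variant: 'scaling' per the parameter table, or
    # 'rotation' (the alternative wording of the protocol)
    offline_variant: str = "scaling"

    def __post_init__(self):
        if self.scaling_range[0] > self.scaling_range[1]:
            raise ValueError("scaling_range must be (lo, hi) with lo <= hi")
        if self.offline_variant not in ("scaling", "rotation"):
            raise ValueError("offline_variant must be 'scaling' or 'rotation'")


def _check_pair(img, mask):
    img = np.asarray(img)
    mask = np.asarray(mask).astype(bool)
    if img.shape != mask.shape:
        raise ValueError(f"image/mask shape mismatch: {img.shape} vs {mask.shape}")
    return img, mask


def _translate(img, mask, dr, dc):
    out_i = ndimage.shift(img.astype(np.float64), (dr, dc), order=1,
                          mode="constant", cval=0.0)
    out_m = ndimage.shift(mask.astype(np.uint8), (dr, dc), order=0,
                          mode="constant", cval=0) > 0
    return out_i, out_m


def _scale_crop(img, mask, margin_r, margin_c):
    """Crop a margin from every border and zoom back to the native size."""
    h, w = img.shape
    sub_i = img[margin_r:h - margin_r, margin_c:w - margin_c]
    sub_m = mask[margin_r:h - margin_r, margin_c:w - margin_c]
    zr, zc = h / sub_i.shape[0], w / sub_i.shape[1]
    out_i = ndimage.zoom(sub_i.astype(np.float64), (zr, zc), order=1,
                         grid_mode=True, mode="grid-constant")[:h, :w]
    out_m = ndimage.zoom(sub_m.astype(np.uint8), (zr, zc), order=0,
                         grid_mode=True, mode="grid-constant")[:h, :w] > 0
    return out_i, out_m


def _rotate(img, mask, angle_deg):
    out_i = ndimage.rotate(img.astype(np.float64), angle_deg, reshape=False,
                           order=1, mode="constant", cval=0.0)
    out_m = ndimage.rotate(mask.astype(np.uint8), angle_deg, reshape=False,
                           order=0, mode="constant", cval=0) > 0
    return out_i, out_m


def _shrink(img, mask, factor):
    """Shrink towards the image centre by ``factor`` (0-1), zero-filling."""
    h, w = img.shape
    nh, nw = max(1, int(round(h * (1 - factor)))), max(1, int(round(w * (1 - factor))))
    small_i = ndimage.zoom(img.astype(np.float64), (nh / h, nw / w), order=1,
                           grid_mode=True, mode="grid-constant")[:nh, :nw]
    small_m = ndimage.zoom(mask.astype(np.uint8), (nh / h, nw / w), order=0,
                           grid_mode=True, mode="grid-constant")[:nh, :nw] > 0
    out_i = np.zeros((h, w), dtype=np.float64)
    out_m = np.zeros((h, w), dtype=bool)
    r0, c0 = (h - nh) // 2, (w - nw) // 2
    out_i[r0:r0 + nh, c0:c0 + nw] = small_i
    out_m[r0:r0 + nh, c0:c0 + nw] = small_m
    return out_i, out_m


def _finalize(img, ref_dtype):
    if np.issubdtype(ref_dtype, np.integer):
        return np.clip(np.rint(img), 0, 255).astype(ref_dtype)
    return img.astype(np.float64)


def offline_augment(img, mask, rng_seed: int, spec: AugmentSpec = None):
    """Expand one (image, mask) pair into exactly ten augmented pairs.

    Returns ``(pairs, transforms)`` where ``pairs`` is a list of ten
    (image, mask) tuples — original, vertical flip, four translations, four
    scalings (or rotations if so configured) — and ``transforms`` logs the
    drawn parameters of each pair for reproducibility audits.
    """
    spec = spec if spec is not None else AugmentSpec()
    img, mask = _check_pair(img, mask)
    rng = np.random.default_rng(rng_seed)
    pairs = [(img.copy(), mask.copy())]
    transforms = [{"op": "identity"}]

    pairs.append((np.flipud(img).copy(), np.flipud(mask).copy()))
    transforms.append({"op": "flip", "axis": "vertical"})

    t = spec.translation_range
    for _ in range(spec.n_translations):
        dr = int(rng.integers(-t, t + 1))
        dc = int(rng.integers(-t, t + 1))
        out_i, out_m = _translate(img, mask, dr, dc)
        pairs.append((_finalize(out_i, img.dtype), out_m))
        transforms.append({"op": "translate", "dr": dr, "dc": dc})

    for _ in range(spec.n_scalings):
        if spec.offline_variant == "scaling":
            lo, hi = spec.scaling_range
            mr = int(rng.integers(lo, hi + 1))
            mc = int(rng.integers(lo, hi + 1))
            out_i, out_m = _scale_crop(img, mask, mr, mc)
            pairs.append((_finalize(out_i, img.dtype), out_m))
            transforms.append({"op": "scale", "margin_r": mr, "margin_c": mc})
        else:
            ang = float(rng.uniform(-spec.online_rotation_deg,
                                    spec.online_rotation_deg))
            out_i, out_m = _rotate(img, mask, ang)
            pairs.append((_finalize(out_i, img.dtype), out_m))
            transforms.append({"op": "rotate", "angle": ang})
    return pairs, transforms


def online_augment(img, mask, rng, spec: AugmentSpec = None):
    """Random per-epoch augmentation of one pair.

    Each of rotation, shrinking, translation, noise, and gamma is applied
    independently with probability 1/2.  Returns ``(image, mask, log)``;
    shapes are unchanged and the mask stays strictly binary.
    """
    spec = spec if spec is not None else AugmentSpec()
    img, mask = _check_pair(img, mask)
    ref_dtype = img.dtype
    scale = 255.0 if np.issubdtype(ref_dtype, np.integer) or img.max() > 1.5 else 1.0
    cur_i = img.astype(np.float64)
    cur_m = mask
    log = {}

    if rng.uniform() < 0.5:
        ang = float(rng.uniform(-spec.online_rotation_deg, spec.online_rotation_deg))
        cur_i, cur_m = _rotate(cur_i, cur_m, ang)
        log["rotate"] = ang
    if rng.uniform() < 0.5:
        f = float(rng.uniform(0.0, spec.online_shrink_max))
        cur_i, cur_m = _shrink(cur_i, cur_m, f)
        log["shrink"] = f
    if rng.uniform() < 0.5:
        dr = int(rng.integers(-spec.online_translation, spec.online_translation + 1))
        dc = int(rng.integers(-spec.online_translation, spec.online_translation + 1))
        cur_i, cur_m = _translate(cur_i, cur_m, dr, dc)
        log["translate"] = (dr, dc)
    if rng.uniform() < 0.5:
        sigma = spec.online_noise_sigma * scale / 255.0
        cur_i = cur_i + rng.normal(0.0, sigma, cur_i.shape)
        log["noise_sigma"] = sigma
    if rng.uniform() < 0.5:
        gamma = float(rng.uniform(*spec.online_gamma_range))
        cur_i = np.clip(cur_i / scale, 0.0, 1.0) ** gamma * scale
        log["gamma"] = gamma

    cur_i = np.clip(cur_i, 0.0, scale)
    return _finalize(cur_i, ref_dtype), cur_m, log
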