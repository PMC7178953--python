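"""Synthetic transverse finger-ultrasound phantoms.

A phantom emulates the anatomy seen in a transverse scan at the A1 pulley:
an elliptical hyperechoic tendon sitting above a bright volar-plate line,
surrounded by a hypoechoic synovial-sheath ring, on a textured background,
all degraded by multiplicative speckle (first-order Rayleigh model).  The
intensity step across the tendon's bottom boundary is an explicit control
(``bottom_contrast``): it drives the clear/fuzzy appearance of the boundary,
mirroring how real scans are split into clear and fuzzy groups by comparing
the mean intensities of two 15x15 windows above and below that boundary
(clear iff the window above is brighter by more than 30 intensity levels).

These phantoms reproduce the geometry and contrast structure the
segmentation pipeline depends on; they make no attempt at physically
realistic wave propagation or real-texture statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PhantomSpec", "generate_phantom", "classify_clear_fuzzy",
           "generate_dataset", "CLEAR_THRESHOLD"]

CLEAR_THRESHOLD = 30.0  # intensity-level difference separating clear from fuzzy


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast, and noise of one phantom image/mask pair.

    All lengths in pixels, intensities in 0-255 levels.  The default canvas
    is 192 rows x 384 columns, matching the network input; everything scales
    down proportionally for fast tests via :meth:`scaled`.
    """

    image_hw: tuple = (192, 384)
    tendon_center: tuple = (88.0, 192.0)      # (row, col)
    tendon_axes: tuple = (30.0, 62.0)         # (semi-row, semi-col)
    sheath_thickness: float = 14.0            # ring width around the tendon
    plate_offset: float = 28.0                # volar plate depth below tendon centre
    plate_thickness: float = 6.0
    plate_intensity: float = 225.0
    tendon_intensity: float = 150.0           # hyperechoic tendon
    sheath_intensity: float = 55.0            # hypoechoic ring
    background_intensity: float = 95.0
    speckle: float = 0.25                     # multiplicative speckle strength
    bottom_contrast: float = 60.0             # step across the bottom tendon boundary
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_hw
        cr, cc = self.tendon_center
        ar, ac = self.tendon_axes
        t = self.sheath_thickness
        if self.bottom_contrast < 0:
            raise ValueError("bottom_contrast must be >= 0")
        if not (ar + t <= cr <= h - 1 - ar - t and ac + t <= cc <= w - 1 - ac - t):
            raise ValueError(
                "sheath ring (tendon plus thickness) must lie inside the image")

    @property
    def intended_label(self) -> str:
        return "clear" if self.bottom_contrast > CLEAR_THRESHOLD else "fuzzy"

    def scaled(self, factor: float) -> "PhantomSpec":
        """Proportionally shrink the canvas and all geometry."""
        h, w = self.image_hw
        return replace(
            self,
            image_hw=(int(round(h * factor)), int(round(w * factor))),
            tendon_center=tuple(v * factor for v in self.tendon_center),
            tendon_axes=tuple(v * factor for v in self.tendon_axes),
            sheath_thickness=self.sheath_thickness * factor,
            plate_offset=self.plate_offset * factor,
            plate_thickness=max(1.0, self.plate_thickness * factor),
        )


def _ellipse_mask(hw, center, axes):
    rr, cc = np.mgrid[0:hw[0], 0:hw[1]]
    return (((rr - center[0]) / axes[0]) ** 2
            + ((cc - center[1]) / axes[1]) ** 2) <= 1.0


def generate_phantom(spec: PhantomSpec):
    """Render one phantom.

    Returns ``(image, tendon_mask, sheath_mask)``: the image as uint8
    (H, W), the tendon mask (filled ellipse) and the sheath mask (filled
    outer ellipse, enclosing the tendon) as boolean arrays.  Fully
    deterministic given the spec (including its seed).
    """
    h, w = spec.image_hw
    rng = np.random.default_rng(spec.seed)
    tendon = _ellipse_mask(spec.image_hw, spec.tendon_center,
                           spec.tendon_axes)
    outer = _ellipse_mask(spec.image_hw, spec.tendon_center,
                          (spec.tendon_axes[0] + spec.sheath_thickness,
                           spec.tendon_axes[1] + spec.sheath_thickness))
    ring = outer & ~tendon

    base = np.full((h, w), spec.background_intensity, dtype=np.float64)
    base += rng.normal(0.0, 6.0, size=(h, w))  # background tissue texture
    base[ring] = spec.sheath_intensity
    base[tendon] = spec.tendon_intensity

    # region below the tendon's bottom boundary, inside the ring: its
    # intensity sits bottom_contrast levels below the tendon, so the
    # boundary fades as the contrast shrinks
    rr, cc = np.mgrid[0:h, 0:w]
    below = ring & (rr > spec.tendon_center[0])
    base[below] = spec.tendon_intensity - spec.bottom_contrast

    # bright volar-plate curve below the sheath: a shallow parabola
    plate_row = (spec.tendon_center[0] + spec.tendon_axes[0]
                 + spec.sheath_thickness + spec.plate_offset * 0.25)
    curve = plate_row + 6.0 * ((cc - spec.tendon_center[1]) / (w / 2)) ** 2 * spec.plate_offset / 8.0
    plate = np.abs(rr - curve) <= spec.plate_thickness / 2.0
    plate &= ~outer
    base[plate] = spec.plate_intensity

    if spec.speckle > 0:
        # Rayleigh multiplicative speckle normalized to unit mean
        noise = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=(h, w))
        base = base * (1.0 + spec.speckle * (noise - 1.0))
    img = np.clip(base, 0, 255).astype(np.uint8)
    return img, tendon, outer


def classify_clear_fuzzy(img, tendon, offset: int = 8, window: int = 15,
                         threshold: float = CLEAR_THRESHOLD) -> str:
    """Label an image 'clear' or 'fuzzy' from its bottom tendon boundary.

    Two ``window`` x ``window`` windows are centred ``offset`` pixels above
    and below the bottom-most tendon boundary row, on the column centroid of
    that row's boundary pixels.  The image is clear iff the mean intensity
    above exceeds the mean below by strictly more than ``threshold``.
    """
    img = np.asarray(img, dtype=np.float64)
    tendon = np.asarray(tendon, dtype=bool)
    if not tendon.any():
        raise ValueError("tendon mask is empty")
    if img.shape != tendon.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {tendon.shape}")
    rows, cols = np.nonzero(tendon)
    r_bottom = rows.max()
    c_center = int(round(cols[rows == r_bottom].mean()))
    half = window // 2

    def window_mean(r_center):
        r0, r1 = r_center - half, r_center + half + 1
        c0, c1 = c_center - half, c_center + half + 1
        if r0 < 0 or c0 < 0 or r1 > img.shape[0] or c1 > img.shape[1]:
            raise ValueError(
                f"{window}x{window} window at ({r_center}, {c_center}) exceeds "
                f"image bounds {img.shape}")
        return img[r0:r1, c0:c1].mean()

    diff = window_mean(r_bottom - offset) - window_mean(r_bottom + offset)
    return "clear" if diff > threshold else "fuzzy"


def _random_spec(rng, image_hw, clear: bool, seed: int) -> PhantomSpec:
    h, w = image_hw
    scale = h / 192.0
    ar = rng.uniform(24, 36) * scale
    ac = rng.uniform(50, 74) * scale
    thick = rng.uniform(10, 18) * scale
    cr = rng.uniform(ar + thick + 2 * scale, 0.58 * h - 1)
    cc = rng.uniform(ac + thick + 2 * scale, w - 1 - ac - thick - 2 * scale)
    contrast = rng.uniform(45.0, 90.0) if clear else rng.uniform(0.0, 18.0)
    return PhantomSpec(image_hw=image_hw, tendon_center=(cr, cc),
                       tendon_axes=(ar, ac), sheath_thickness=thick,
                       bottom_contrast=contrast,
                       speckle=rng.uniform(0.15, 0.3), seed=seed)


def generate_dataset(n: int, clear_fraction: float = 0.5, seed: int = 0,
                     image_hw=(192, 384), series: bool = False):
    """Generate ``n`` phantoms with randomized geometry.

    Returns a list of ``(image, tendon_mask, sheath_mask, label)`` tuples,
    with labels verified through :func:`classify_clear_fuzzy`.  The bottom
    contrast is sampled from well-separated clear/fuzzy ranges so the
    realized clear fraction tracks ``clear_fraction``.  In ``series`` mode
    the phantoms vary smoothly from slice to slice, emulating one continuous
    acquisition group.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    # windows scale with the canvas (15x15 at the native 192-row height)
    scale = image_hw[0] / 192.0
    window = max(3, int(round(15 * scale)) | 1)
    offset = max(2, int(round(8 * scale)))
    out = []
    if series:
        base = _random_spec(rng, image_hw, rng.uniform() < clear_fraction,
                            seed=int(rng.integers(2 ** 31)))
        spec = base
        for i in range(n):
            img, tendon, sheath = generate_phantom(spec)
            label = classify_clear_fuzzy(img, tendon, offset=offset, window=window)
            out.append((img, tendon, sheath, label))
            # small random-walk perturbation: consecutive slices stay close
            spec = replace(
                spec,
                tendon_center=(spec.tendon_center[0] + rng.uniform(-1.5, 1.5),
                               spec.tendon_center[1] + rng.uniform(-1.5, 1.5)),
                tendon_axes=(np.clip(spec.tendon_axes[0] + rng.uniform(-1, 1),
                                     18, 40 * image_hw[0] / 192),
                             np.clip(spec.tendon_axes[1] + rng.uniform(-1, 1),
                                     40, 80 * image_hw[0] / 192)),
                seed=int(rng.integers(2 ** 31)))
        return out
    for i in range(n):
        clear = rng.uniform() < clear_fraction
        spec = _random_spec(rng, image_hw, clear, seed=int(rng.integers(2 ** 31)))
        img, tendon, sheath = generate_phantom(spec)
        label = classify_clear_fuzzy(img, tendon, offset=offset, window=window)
        out.append((img, tendon, sheath, label))
    return out
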