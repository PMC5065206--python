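"""Synthetic nucleus generator.

Produces binary masks, contours and rendered single-cell images emulating
the three cytologic classes:

* NILM  — near-circular/oval nuclei with smooth contours;
* LSIL  — moderate low-frequency boundary variability, occasional notch;
* HSIL  — convoluted boundaries with prominent notches/indentations.

A nucleus boundary is a star-shaped polar curve

    r(theta) = R * e(theta) + sum_h a_h cos(f_h theta + phi_h)
               - sum_n depth_n exp(-0.5 ((theta - angle_n) / width_n)^2)

(e(theta) is the ellipse radius normalized so e = 1 for ellipticity 1),
sampled at roughly 1-px arc resolution, rasterized with a polygon fill and
re-traced to an 8-connected pixel contour.  Rendered images frame the
nucleus with a small margin, as in cropped single-cell micrographs, with a
dark nucleus on a lighter background plus Gaussian noise.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon

from .errors import ParameterError
from .geometry import Contour, extract_contour

__all__ = [
    "Harmonic",
    "Notch",
    "ShapeSpec",
    "RenderParams",
    "CohortSpec",
    "SyntheticNucleus",
    "DEFAULT_CLASS_PARAMS",
    "make_contour",
    "render_image",
    "generate_cohort",
]


@dataclass(frozen=True)
class Harmonic:
    frequency: int
    amplitude: float  # px
    phase: float = 0.0  # rad


@dataclass(frozen=True)
class Notch:
    angle: float  # rad, center of the indentation
    depth: float  # px
    width: float = 0.25  # rad, Gaussian sigma of the dip


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one synthetic nucleus boundary."""

    base_radius: float = 50.0
    ellipticity: float = 1.0  # major/minor axis ratio, >= 1
    harmonics: tuple[Harmonic, ...] = ()
    notches: tuple[Notch, ...] = ()
    noise_sigma: float = 0.0  # radial jitter, px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius < 10:
            raise ParameterError("base_radius must be >= 10 px")
        if self.ellipticity < 1:
            raise ParameterError("ellipticity must be >= 1")
        budget = sum(abs(h.amplitude) for h in self.harmonics)
        budget += sum(abs(nt.depth) for nt in self.notches)
        if budget >= self.base_radius / self.ellipticity:
            raise ParameterError(
                "harmonic amplitudes + notch depths must stay below the "
                "minor radius (contour must remain star-shaped)"
            )

    def radial_function(self):
        """Analytic r(theta) of the noise-free boundary (oracle use)."""

        def r(theta: np.ndarray) -> np.ndarray:
            theta = np.asarray(theta, dtype=np.float64)
            a = self.base_radius
            b = self.base_radius / self.ellipticity
            rr = a * b / np.hypot(b * np.cos(theta), a * np.sin(theta))
            for h in self.harmonics:
                rr = rr + h.amplitude * np.cos(h.frequency * theta + h.phase)
            for nt in self.notches:
                delta = np.angle(np.exp(1j * (theta - nt.angle)))
                rr = rr - nt.depth * np.exp(-0.5 * (delta / nt.width) ** 2)
            return rr

        return r


@dataclass(frozen=True)
class RenderParams:
    """Rendering of a mask into a cropped single-cell style image.

    Beyond the two base intensities and sensor noise, a smooth random
    intensity field (``texture``/``texture_corr``) emulates chromatin and
    illumination inhomogeneity.  It matters for segmentation realism: a
    strictly two-level image has a degenerate histogram whose equalization
    amplifies sensor noise into gradients comparable to the nucleus edge;
    real micrographs have spread histograms and equalize gently.  The crop
    margin is small because the frames emulate micrographs cropped tightly
    around one nucleus, which also keeps the nucleus the dominant region
    for the largest-component rule.
    """

    foreground: int = 60  # nucleus intensity
    background: int = 180  # cytoplasm intensity
    noise_sigma: float = 5.0  # additive Gaussian sensor noise
    texture: float = 18.0  # std (gray levels) of the smooth intensity field
    texture_corr: float = 12.0  # correlation length (px) of that field
    margin_frac: float = 0.10  # frame margin / equivalent nucleus radius


@dataclass(frozen=True)
class SyntheticNucleus:
    spec: ShapeSpec
    contour: Contour
    mask: np.ndarray
    label: str | None = None
    item_id: str | None = None


def make_contour(spec: ShapeSpec) -> SyntheticNucleus:
    """Sample, rasterize and trace the boundary described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    r_fn = spec.radial_function()
    r_max = spec.base_radius + sum(abs(h.amplitude) for h in spec.harmonics)
    n_samples = max(64, int(np.ceil(2 * np.pi * r_max)))
    theta = np.linspace(0.0, 2 * np.pi, n_samples, endpoint=False)
    r = r_fn(theta)
    if spec.noise_sigma > 0:
        r = r + rng.normal(0.0, spec.noise_sigma, size=n_samples)
    if r.min() <= 2.0:
        raise ParameterError("shape spec collapses the boundary (r <= 2 px)")
    pad = 4
    c0 = float(np.ceil(r_max + spec.noise_sigma * 4)) + pad
    size = int(2 * c0) + 1
    rows = c0 + r * np.sin(theta)
    cols = c0 + r * np.cos(theta)
    rr, cc = polygon(rows, cols, shape=(size, size))
    mask = np.zeros((size, size), dtype=bool)
    mask[rr, cc] = True
    mask = ndimage.binary_fill_holes(mask)
    contour = extract_contour(mask)
    return SyntheticNucleus(spec=spec, contour=contour, mask=mask)


def render_image(
    nucleus: SyntheticNucleus,
    params: RenderParams = RenderParams(),
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a nucleus mask as a noisy RGB micrograph crop.

    Returns ``(image, mask)`` where the mask is cropped identically to the
    image (the ground truth for segmentation benchmarks).
    """
    mask = nucleus.mask
    ys, xs = np.nonzero(mask)
    r_eq = np.sqrt(mask.sum() / np.pi)
    margin = max(4, int(round(params.margin_frac * r_eq)))
    y0, y1 = ys.min() - margin, ys.max() + margin + 1
    x0, x1 = xs.min() - margin, xs.max() + margin + 1
    if y0 < 0 or x0 < 0 or y1 > mask.shape[0] or x1 > mask.shape[1]:
        padded = np.zeros(
            (mask.shape[0] + 2 * margin, mask.shape[1] + 2 * margin), dtype=bool
        )
        padded[margin:-margin, margin:-margin] = mask
        mask = padded
        y0, y1, x0, x1 = y0 + margin, y1 + margin, x0 + margin, x1 + margin
    crop = mask[y0:y1, x0:x1]
    rng = np.random.default_rng(nucleus.spec.seed if seed is None else seed)
    img = np.where(crop, float(params.foreground), float(params.background))
    if params.texture > 0:
        field = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, size=img.shape), params.texture_corr
        )
        img = img + field / field.std() * params.texture
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
    img8 = np.rint(img).clip(0, 255).astype(np.uint8)
    return np.dstack([img8, img8, img8]), crop


# Per-class distributions of ShapeSpec parameters.  Ranges are uniform
# draws; harmonic/notch counts are inclusive integer ranges.  The classes
# follow the Bethesda-system descriptions: NILM nuclei are smaller with
# smooth, near-round contours; LSIL and HSIL nuclei are enlarged
# (karyomegaly) with boundary waviness, mandatory notches (sharper and more
# numerous for HSIL) and fine-scale roughness.  The ranges overlap so the
# two dysplastic classes' score distributions overlap substantially while
# both separate from the smooth class.
DEFAULT_CLASS_PARAMS: dict[str, dict] = {
    "NILM": dict(
        radius=(35.0, 55.0), ellipticity=(1.0, 1.15),
        n_harmonics=(1, 2), freq=(2, 4), amp=(0.2, 1.0),
        n_notches=(0, 0), depth=(0.0, 0.0), width=(0.2, 0.3),
        radial_noise=(0.0, 0.1),
    ),
    "LSIL": dict(
        radius=(55.0, 80.0), ellipticity=(1.0, 1.3),
        n_harmonics=(2, 4), freq=(3, 8), amp=(1.5, 4.0),
        n_notches=(1, 3), depth=(4.0, 8.0), width=(0.08, 0.2),
        radial_noise=(0.1, 0.3),
    ),
    "HSIL": dict(
        radius=(60.0, 85.0), ellipticity=(1.0, 1.35),
        n_harmonics=(3, 5), freq=(5, 12), amp=(2.0, 4.5),
        n_notches=(2, 4), depth=(5.0, 9.0), width=(0.08, 0.25),
        radial_noise=(0.2, 0.45),
    ),
}


@dataclass(frozen=True)
class CohortSpec:
    """A labeled three-class cohort of synthetic nuclei."""

    n_per_class: int = 200
    class_params: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_PARAMS.items()}
    )
    render: RenderParams = RenderParams()
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ParameterError("n_per_class must be >= 1")


def _draw_shape_spec(params: dict, rng: np.random.Generator, seed: int) -> ShapeSpec:
    radius = rng.uniform(*params["radius"])
    ell = rng.uniform(*params["ellipticity"])
    nh = int(rng.integers(params["n_harmonics"][0], params["n_harmonics"][1] + 1))
    harmonics = tuple(
        Harmonic(
            frequency=int(rng.integers(params["freq"][0], params["freq"][1] + 1)),
            amplitude=float(rng.uniform(*params["amp"])),
            phase=float(rng.uniform(0, 2 * np.pi)),
        )
        for _ in range(nh)
    )
    nn = int(rng.integers(params["n_notches"][0], params["n_notches"][1] + 1))
    notches = tuple(
        Notch(
            angle=float(rng.uniform(0, 2 * np.pi)),
            depth=float(rng.uniform(*params["depth"])),
            width=float(rng.uniform(*params["width"])),
        )
        for _ in range(nn)
    )
    noise = float(rng.uniform(*params["radial_noise"]))
    return ShapeSpec(
        base_radius=float(radius), ellipticity=float(ell),
        harmonics=harmonics, notches=notches, noise_sigma=noise, seed=seed,
    )


def generate_cohort(
    spec: CohortSpec, classes: tuple[str, ...] = ("NILM", "LSIL", "HSIL")
) -> tuple[list[SyntheticNucleus], pd.DataFrame]:
    """Generate ``n_per_class`` nuclei per class, reproducibly.

    Returns the nuclei and a manifest with one row per item recording the
    drawn shape parameters.
    """
    rng = np.random.default_rng(spec.master_seed)
    items: list[SyntheticNucleus] = []
    rows = []
    for label in classes:
        params = spec.class_params[label]
        for i in range(spec.n_per_class):
            item_seed = int(rng.integers(0, 2**31 - 1))
            for attempt in range(20):  # redraw on invalid parameter combos
                try:
                    sspec = _draw_shape_spec(params, rng, seed=item_seed + attempt)
                    nucleus = make_contour(sspec)
                    break
                except ParameterError:
                    continue
            else:
                raise ParameterError(
                    "could not draw a valid shape for class %s" % label
                )
            item_id = "%s_%04d" % (label, i)
            nucleus = replace(nucleus, label=label, item_id=item_id)
            items.append(nucleus)
            rows.append(
                dict(
                    image_id=item_id, label=label,
                    base_radius=sspec.base_radius, ellipticity=sspec.ellipticity,
                    n_harmonics=len(sspec.harmonics),
                    harmonic_amp_total=sum(h.amplitude for h in sspec.harmonics),
                    n_notches=len(sspec.notches),
                    notch_depth_total=sum(nt.depth for nt in sspec.notches),
                    noise_sigma=sspec.noise_sigma, seed=sspec.seed,
                )
            )
    return items, pd.DataFrame(rows)
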