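"""Synthetic diffusion-weighted phantoms of breast lesions.

Each phantom is a single 2D slice acquired at three b-values (50, 750,
1500 s/mm^2 by default) containing one roughly circular lesion whose ADC
differs from the background.  The generator reproduces the statistical
structure the downstream stability analysis assumes:

* mono-exponential signal decay S(b) = S0 * exp(-b * ADC);
* a partial-volume-like transition rim: the ADC is exactly the lesion mean
  inside the true disk and relaxes smoothly to background over about an
  ``edge_width`` just outside it, as scanner point-spread and peritumoral
  tissue produce in vivo — so threshold perturbations move the segmentation
  boundary through the rim instead of carving the lesion interior;
* spatially correlated ADC texture over the whole slice (white Gaussian
  noise convolved with a Gaussian kernel of a configurable correlation
  length, scaled to a target standard deviation), so texture features see
  genuine heterogeneity and the background histogram has realistic spread —
  a strictly constant background would give Otsu's objective a flat plateau
  across the lesion/background gap, which no measured tissue produces;
* magnitude-MRI-like noise: independent additive Gaussian noise per b-value
  image, magnitude-rectified;
* a rough delineation, modelled as the true lesion disk dilated by two
  pixels, mimicking a generous manual outline.

All randomness flows from explicit integer seeds, so cohorts are pure
functions of their configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .adc import compute_adc


@dataclass
class PhantomConfig:
    """Parameters of one synthetic lesion slice.

    ADC values are in um^2/ms, lengths in mm, b-values in s/mm^2.
    ``noise_sigma`` is the noise standard deviation as a fraction of the
    b=50 (maximum) signal ``s0``.
    """

    image_size: int = 64
    pixel_spacing: float = 1.0
    b_values: tuple[float, ...] = (50.0, 750.0, 1500.0)
    background_adc_mean: float = 2.2
    lesion_adc_mean: float = 1.0
    lesion_radius: float = 6.0
    edge_width: float = 1.0
    texture_correlation_length: float = 2.0
    texture_sd: float = 0.08
    noise_sigma: float = 0.02
    s0: float = 1000.0
    #: relative proton-density/T2 weighting of the lesion vs background;
    #: > 1 models the T2 shine-through that keeps fluid lesions (cysts)
    #: bright on high-b images despite their elevated ADC
    lesion_s0_factor: float = 1.0
    seed: int = 0
    # cohort sampling: radii uniform over lesion_radius_range; a fraction of
    # lesions is cyst-like with elevated ADC and strong shine-through, the
    # rest solid with depressed ADC
    lesion_radius_range: tuple[float, float] = (2.05, 20.5)
    lesion_adc_range: tuple[float, float] = (0.6, 1.4)
    elevated_fraction: float = 0.25
    elevated_adc_range: tuple[float, float] = (2.5, 3.0)
    elevated_s0_factor: float = 6.0

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        for adc in (self.background_adc_mean, self.lesion_adc_mean):
            if not 0 < adc < 3.5:
                raise ValueError("ADC means must lie in (0, 3.5) um^2/ms")
        r_px = self.lesion_radius / self.pixel_spacing
        # lesion disk + 2-pixel delineation dilation + 2-pixel margin
        if r_px + 4 >= self.image_size / 2:
            raise ValueError(
                f"lesion of radius {self.lesion_radius} mm does not fit in a "
                f"{self.image_size}-pixel image with a 2-pixel margin"
            )
        if r_px < 1:
            raise ValueError("lesion radius below one pixel")


@dataclass
class PhantomCase:
    """One synthetic lesion: b-value images, rough delineation, ground truth."""

    images: dict[float, np.ndarray]
    delineation: np.ndarray
    true_adc: np.ndarray
    pixel_spacing: float
    case_id: str
    config: PhantomConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        shapes = {img.shape for img in self.images.values()}
        shapes.add(self.delineation.shape)
        shapes.add(self.true_adc.shape)
        if len(shapes) != 1:
            raise ValueError("all phantom arrays must share one shape")
        if self.delineation.sum() < 9:
            raise ValueError("delineation must contain at least 9 pixels")
        d = self.delineation
        if d[0, :].any() or d[-1, :].any() or d[:, 0].any() or d[:, -1].any():
            raise ValueError("delineation must keep a 1-pixel border margin")


def _correlated_field(
    shape: tuple[int, int],
    corr_length_px: float,
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian random field: white noise smoothed to ``corr_length_px`` and
    rescaled to standard deviation ``sd``."""
    white = rng.standard_normal(shape)
    if corr_length_px <= 0:
        return white * sd
    smooth = ndimage.gaussian_filter(white, sigma=corr_length_px)
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def generate_phantom(config: PhantomConfig, case_id: str = "case") -> PhantomCase:
    """Build one phantom slice; bit-reproducible given ``config.seed``."""
    config.validate()
    n = config.image_size
    rng = np.random.default_rng(config.seed)

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    center = (n - 1) / 2.0
    r_px = config.lesion_radius / config.pixel_spacing
    dist = np.sqrt((yy - center) ** 2 + (xx - center) ** 2)
    lesion = dist <= r_px

    # weight 1 on the true disk, Gaussian falloff over ~edge_width outside:
    # a partial-volume-like rim; the disk interior is exactly the lesion mean
    weight = np.ones((n, n))
    outside = dist > r_px
    edge_sigma = max(config.edge_width / config.pixel_spacing, 1e-6)
    weight[outside] = np.exp(-0.5 * ((dist[outside] - r_px) / edge_sigma) ** 2)
    true_adc = (
        config.background_adc_mean
        + (config.lesion_adc_mean - config.background_adc_mean) * weight
    )
    if config.texture_sd > 0:
        true_adc += _correlated_field(
            (n, n),
            config.texture_correlation_length / config.pixel_spacing,
            config.texture_sd,
            rng,
        )
    np.clip(true_adc, 1e-3, 3.499, out=true_adc)

    # proton-density/T2 weighting follows the same rim profile as the ADC
    s0_map = config.s0 * (1.0 + (config.lesion_s0_factor - 1.0) * weight)
    images: dict[float, np.ndarray] = {}
    for b in config.b_values:
        signal = s0_map * np.exp(-b * true_adc * 1e-3)
        if config.noise_sigma > 0:
            noise = rng.standard_normal((n, n)) * config.noise_sigma * config.s0
            signal = np.abs(signal + noise)
        images[float(b)] = signal

    delineation = ndimage.binary_dilation(lesion, iterations=2)
    return PhantomCase(
        images=images,
        delineation=delineation,
        true_adc=true_adc,
        pixel_spacing=config.pixel_spacing,
        case_id=case_id,
        config=config,
    )


def generate_cohort(
    n_lesions: int,
    base_config: PhantomConfig,
    seed: int,
) -> list[PhantomCase]:
    """Generate a cohort with lesion radii and ADC means drawn uniformly from
    the ranges in ``base_config``; per-case seeds derive from ``seed``."""
    if n_lesions < 1:
        raise ValueError("n_lesions must be >= 1")
    rng = np.random.default_rng(seed)
    case_seeds = np.random.SeedSequence(seed).generate_state(n_lesions) % (2**31)
    cases = []
    width = len(str(n_lesions))
    for i in range(n_lesions):
        radius = rng.uniform(*base_config.lesion_radius_range)
        cyst_like = rng.random() < base_config.elevated_fraction
        if cyst_like:
            adc = rng.uniform(*base_config.elevated_adc_range)
            s0_factor = base_config.elevated_s0_factor
        else:
            adc = rng.uniform(*base_config.lesion_adc_range)
            s0_factor = base_config.lesion_s0_factor
        cfg = replace(
            base_config,
            lesion_radius=float(radius),
            lesion_adc_mean=float(adc),
            lesion_s0_factor=float(s0_factor),
            seed=int(case_seeds[i]),
        )
        cases.append(generate_phantom(cfg, case_id=f"lesion{i + 1:0{width}d}"))
    return cases


def recovered_adc(case: PhantomCase):
    """ADC map fitted from the two lowest b-value images of a phantom."""
    bs = sorted(case.images)
    b_low, b_high = bs[0], bs[1]
    return compute_adc(case.images[b_low], b_low, case.images[b_high], b_high)
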