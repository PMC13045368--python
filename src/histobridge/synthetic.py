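"""Synthetic histology-like fixtures with measurable ground truth.

Every stage of the pipeline is exercised on images whose generative factors
are known and recoverable by simple estimators: categorical domains set the
background hue (standing in for stain/preparation identity), a binary
"gene" sets the count of dark nucleus-like blobs (standing in for
cellularity effects of a mutation), and a continuous "expression" value
sets background brightness linearly.  ``measure_attributes`` is the
independent oracle that closes the loop: generate -> measure recovers the
specified attributes within stated tolerances.

A slide generator produces large bright-background images with saturated
tissue regions and their ground-truth masks for the preprocessing front end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv
from skimage.filters import threshold_otsu

from .conditioning import ConditionBundle

__all__ = ["DomainSpec", "MutationGeneSpec", "ExpressionGeneSpec", "SyntheticSpec",
           "two_domain_spec", "generate_image", "measure_attributes",
           "circular_hue_difference", "SyntheticDataset", "generate_dataset",
           "generate_synthetic_slide"]

_MUT_ATTRS = {"blob_count", "blob_radius", "hue_shift"}
_EXPR_ATTRS = {"background_value", "blob_radius"}


@dataclass(frozen=True)
class DomainSpec:
    """Visual identity of a categorical domain."""
    hue: float                 # background hue in [0, 1)
    saturation: float = 0.55
    value: float = 0.85        # background brightness
    grain: float = 0.02        # per-pixel texture noise s.d.


@dataclass(frozen=True)
class MutationGeneSpec:
    """Binary gene bound to one visual attribute (WT vs mutant value)."""
    attribute: str
    wt: float
    mut: float

    def __post_init__(self):
        if self.attribute not in _MUT_ATTRS:
            raise ValueError(f"unknown mutation attribute {self.attribute!r}")


@dataclass(frozen=True)
class ExpressionGeneSpec:
    """Continuous gene: attribute shifts by slope * (t - 0.5) plus noise."""
    attribute: str
    slope: float
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.attribute not in _EXPR_ATTRS:
            raise ValueError(f"unknown expression attribute {self.attribute!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    resolution: int
    domains: dict[str, DomainSpec]
    genes: dict[str, MutationGeneSpec] = field(default_factory=dict)
    expression_genes: dict[str, ExpressionGeneSpec] = field(default_factory=dict)
    blob_radius: float = 2.2   # base radius when no gene controls it
    blob_hue: float = 0.75
    blob_saturation: float = 0.45
    blob_value: float = 0.25

    def __post_init__(self):
        bound = [g.attribute for g in self.genes.values()]
        bound += [g.attribute for g in self.expression_genes.values()]
        if len(set(bound)) != len(bound):
            raise ValueError("attribute bindings must be injective "
                             f"(one gene per attribute); got {bound}")

    @property
    def labels(self) -> list[str]:
        return list(self.domains)

    @property
    def gene_names(self) -> list[str]:
        return list(self.genes)

    @property
    def expression_gene_names(self) -> list[str]:
        return list(self.expression_genes)


def two_domain_spec(resolution: int = 32) -> SyntheticSpec:
    """The reference two-domain study: hue-separated domains, one blob-count
    mutation gene, one brightness expression gene."""
    return SyntheticSpec(
        resolution=resolution,
        # hues are deliberately non-antipodal so signed circular differences
        # between the two domains are unambiguous
        domains={"domain_a": DomainSpec(hue=0.08),
                 "domain_b": DomainSpec(hue=0.55)},
        genes={"GENE_BLOBS": MutationGeneSpec("blob_count", wt=3, mut=9)},
        expression_genes={"GENE_BRIGHT": ExpressionGeneSpec("background_value",
                                                            slope=0.15)},
    )


def _resolve_attributes(spec: SyntheticSpec, domain: str,
                        genomic: dict[str, bool] | None,
                        transcriptomic: dict[str, float] | None,
                        rng: np.random.Generator) -> dict[str, float]:
    if domain not in spec.domains:
        raise KeyError(f"unregistered domain {domain!r}")
    dom = spec.domains[domain]
    attrs = {"blob_count": 0.0, "blob_radius": spec.blob_radius,
             "hue_shift": 0.0, "background_value": dom.value, "hue": dom.hue}
    genomic = genomic or {}
    for g in genomic:
        if g not in spec.genes:
            raise KeyError(f"unregistered mutation gene {g!r}")
    for name, gene in spec.genes.items():
        bit = bool(genomic.get(name, False))
        attrs[gene.attribute] = gene.mut if bit else gene.wt
    transcriptomic = transcriptomic or {}
    for g in transcriptomic:
        if g not in spec.expression_genes:
            raise KeyError(f"unregistered expression gene {g!r}")
    for name, gene in spec.expression_genes.items():
        t = float(transcriptomic.get(name, 0.5))
        delta = gene.slope * (t - 0.5)
        if gene.noise_sd > 0:
            delta += rng.normal(0.0, gene.noise_sd)
        attrs[gene.attribute] = attrs[gene.attribute] + delta
    attrs["hue"] = (attrs["hue"] + attrs.pop("hue_shift")) % 1.0
    return attrs


def _place_blobs(n: int, radius: float, res: int, rng: np.random.Generator
                 ) -> list[tuple[float, float, float]]:
    """Non-overlapping blob centers via rejection sampling with jitter."""
    blobs: list[tuple[float, float, float]] = []
    margin = radius + 1.5
    min_sep = 2.0 * radius + 1.0
    for _ in range(n):
        for _attempt in range(200):
            cy = rng.uniform(margin, res - margin)
            cx = rng.uniform(margin, res - margin)
            if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep ** 2
                   for y, x, _r in blobs):
                blobs.append((cy, cx, radius * rng.uniform(0.85, 1.15)))
                break
    return blobs


def generate_image(spec: SyntheticSpec, domain: str,
                   genomic: dict[str, bool] | None = None,
                   transcriptomic: dict[str, float] | None = None,
                   seed: int = 0) -> tuple[np.ndarray, dict[str, float]]:
    """Render one HxWx3 image in [0, 1] plus its ground-truth attribute record.

    Identical arguments give bit-identical images.
    """
    rng = np.random.default_rng(seed)
    attrs = _resolve_attributes(spec, domain, genomic, transcriptomic, rng)
    res = spec.resolution
    dom = spec.domains[domain]
    hsv = np.empty((res, res, 3))
    hsv[..., 0] = attrs["hue"]
    hsv[..., 1] = dom.saturation
    hsv[..., 2] = np.clip(attrs["background_value"]
                          + rng.normal(0.0, dom.grain, (res, res)), 0.05, 1.0)
    img = hsv2rgb(hsv)

    n_blobs = int(round(attrs["blob_count"]))
    blobs = _place_blobs(n_blobs, attrs["blob_radius"], res, rng)
    if blobs:
        blob_rgb = hsv2rgb(np.array([[[spec.blob_hue, spec.blob_saturation,
                                       spec.blob_value]]]))[0, 0]
        yy, xx = np.mgrid[0:res, 0:res]
        for cy, cx, r in blobs:
            dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
            alpha = np.clip(r + 0.5 - dist, 0.0, 1.0)[..., None]  # 1-px soft edge
            img = img * (1 - alpha) + blob_rgb[None, None, :] * alpha
    attrs["blob_count"] = float(len(blobs))
    return np.clip(img, 0.0, 1.0), attrs


def measure_attributes(image: np.ndarray, spec: SyntheticSpec,
                       min_blob_area: int = 4) -> dict[str, float]:
    """Estimate blob count/radius, background hue and brightness of an image.

    Blobs are dark connected components under an Otsu split of luminance
    (components below `min_blob_area` pixels are noise and dropped); the
    split is only trusted when the luminance range is wide enough to contain
    blobs at all.  Hue is the circular mean over background pixels.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.shape[0] != spec.resolution or img.shape[1] != spec.resolution:
        raise ValueError(f"image resolution {img.shape[:2]} != spec "
                         f"resolution {spec.resolution}")
    lum = img.mean(axis=2)
    blob_mask = np.zeros(lum.shape, dtype=bool)
    if np.ptp(lum) > 0.25:  # blobs are ~0.6 darker than background
        blob_mask = lum < threshold_otsu(lum)
        if blob_mask.mean() > 0.5:  # degenerate split: "blobs" dominate
            blob_mask[:] = False
    labels, n_comp = ndimage.label(blob_mask)
    areas = ndimage.sum_labels(np.ones_like(lum), labels, np.arange(1, n_comp + 1))
    keep = areas >= min_blob_area
    count = int(keep.sum())
    mean_radius = float(np.sqrt(areas[keep] / np.pi).mean()) if count else 0.0

    bg = ~blob_mask
    if not bg.any():
        bg = np.ones_like(bg)
    hsv = rgb2hsv(img)
    ang = hsv[..., 0][bg] * 2.0 * np.pi
    mean_hue = (np.angle(np.exp(1j * ang).mean()) / (2.0 * np.pi)) % 1.0
    return {"blob_count": float(count), "blob_radius": mean_radius,
            "hue": float(mean_hue),
            "background_value": float(hsv[..., 2][bg].mean())}


def circular_hue_difference(h1: float, h2: float) -> float:
    """Signed shortest distance h1 - h2 on the hue circle, in (-0.5, 0.5]."""
    d = (h1 - h2) % 1.0
    return d - 1.0 if d > 0.5 else d


# -------------------------------------------------------------------- dataset
@dataclass
class SyntheticDataset:
    images: np.ndarray                 # N x H x W x 3 in [0, 1]
    bundles: list[ConditionBundle]
    truth: pd.DataFrame                # one row per image: domain, genes, attrs


def _default_omics_sampler(spec: SyntheticSpec, rng: np.random.Generator
                           ) -> tuple[dict[str, bool], dict[str, float]]:
    genomic = {g: bool(rng.random() < 0.5) for g in spec.gene_names}
    transcriptomic = {g: float(rng.uniform(0.05, 0.95))
                      for g in spec.expression_gene_names}
    return genomic, transcriptomic


def generate_dataset(spec: SyntheticSpec, n_per_domain: int,
                     omics_sampler=None, seed: int = 0) -> SyntheticDataset:
    """Class-balanced dataset over domains with per-image condition bundles."""
    if n_per_domain < 1:
        raise ValueError("n_per_domain must be >= 1")
    sampler = omics_sampler or _default_omics_sampler
    rng = np.random.default_rng(seed)
    images, bundles, rows = [], [], []
    for domain in spec.labels:
        for i in range(n_per_domain):
            genomic, transcriptomic = sampler(spec, rng)
            img_seed = int(rng.integers(0, 2 ** 31 - 1))
            img, attrs = generate_image(spec, domain, genomic, transcriptomic,
                                        seed=img_seed)
            images.append(img)
            bundles.append(ConditionBundle.make(domain, genomic, transcriptomic))
            row = {"domain": domain, "image_seed": img_seed}
            row.update({f"mut_{g}": v for g, v in genomic.items()})
            row.update({f"expr_{g}": v for g, v in transcriptomic.items()})
            row.update(attrs)
            rows.append(row)
    return SyntheticDataset(images=np.stack(images), bundles=bundles,
                            truth=pd.DataFrame(rows))


# ---------------------------------------------------------------------- slides
def generate_synthetic_slide(spec: SyntheticSpec,
                             tissue_shape: list[tuple[float, float, float, float]] | None = None,
                             size: tuple[int, int] = (256, 256),
                             seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Bright background plus saturated elliptical tissue regions.

    ``tissue_shape`` lists ellipses as (cy, cx, ry, rx) in fractional
    coordinates of the slide; ``None`` gives one centred ellipse, and an
    empty list a blank slide.  Returns (slide in [0, 1], ground-truth mask).
    """
    h, w = size
    if tissue_shape is None:
        tissue_shape = [(0.5, 0.5, 0.3, 0.35)]
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for cy, cx, ry, rx in tissue_shape:
        if not (0 < ry and 0 < rx and ry <= 0.5 and rx <= 0.5):
            raise ValueError("ellipse radii must fit within the slide")
        mask |= (((yy - cy * h) / (ry * h)) ** 2
                 + ((xx - cx * w) / (rx * w)) ** 2) <= 1.0
    dom = spec.domains[spec.labels[0]]
    hsv = np.empty((h, w, 3))
    hsv[..., 0] = dom.hue
    hsv[..., 1] = np.where(mask, dom.saturation, 0.02)
    texture = rng.normal(0.0, 0.04, (h, w))
    hsv[..., 2] = np.where(mask, np.clip(dom.value + texture, 0.3, 1.0),
                           np.clip(0.97 + rng.normal(0.0, 0.005, (h, w)), 0.9, 1.0))
    return np.clip(hsv2rgb(hsv), 0.0, 1.0), mask
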