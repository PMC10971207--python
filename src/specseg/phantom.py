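"""Synthetic oral-mucosa tissue phantoms with paired IR / darkfield rasters.

Each phantom section emulates a punch-biopsy cross-section on a 1 um ground
truth grid: a background (non-tissue) margin, an epithelial band whose lower
boundary undulates with rete-peg-like protrusions into the underlying stroma
(non-epithelium), and a single contiguous dysplastic focus within the
epithelium.  From the label geometry the generator renders

* three single-band IR absorbance images (1238, 1546, 1658 cm^-1) at
  2 um/pixel following A_b(x) = t(x) * mu_{class(x),b} * c_b(x) * (1 + eps),
  where t is a smooth multiplicative thickness/density field (log-normal,
  exactly shared across bands so the Amide-I ratio cancels it), c_b a
  class-conditional log-normal chemical heterogeneity field controlling the
  within-class spread of the band ratios, and eps additive detector noise;
* a darkfield visible raster at 0.5 um/pixel: per-class base scattering
  intensity plus Poisson-count nuclear speckle (denser in dysplastic than in
  non-dysplastic epithelium) blurred to a plausible point-spread width.

Default band-ratio medians encode the class orderings seen in real tissue:
the non-epithelium ratio at both 1238 and 1546 cm^-1 exceeds both epithelium
classes, dysplastic epithelium exceeds non-dysplastic at 1238 cm^-1 (higher
nuclear-acid content), and the 1546 cm^-1 spread is wider for non-dysplastic
than dysplastic epithelium.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocess import BandImage, LabelMap, ParameterError, write_band_tiff

__all__ = ["PhantomParams", "PhantomSection", "generate_phantom", "write_section", "read_section"]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, chemistry and noise settings of one synthetic section.

    Per-class tuples are indexed by tissue class (non-epithelium, dysplastic
    epithelium, non-dysplastic epithelium) unless noted; the darkfield base
    intensity tuple additionally includes background as its first entry.
    """

    image_height_px: int = 1024  # 1 um grid
    image_width_px: int = 1024
    tissue_fraction: float = 0.85
    epithelium_depth_frac: float = 0.35
    rete_peg_amplitude_px: float = 60.0
    rete_peg_period_px: float = 200.0
    dysplasia_extent_frac: float = 0.40
    # class-conditional band-ratio medians (A_b / A_1658), classes 1..3
    mu_ratio_1238: tuple[float, float, float] = (0.75, 0.60, 0.48)
    mu_ratio_1546: tuple[float, float, float] = (0.85, 0.55, 0.52)
    # log-normal sigma of the within-class ratio spread, classes 1..3
    sigma_ratio_1238: tuple[float, float, float] = (0.10, 0.05, 0.04)
    sigma_ratio_1546: tuple[float, float, float] = (0.12, 0.04, 0.07)
    # baseline Amide I absorbance (AU), classes 1..3
    mu_a1658: tuple[float, float, float] = (0.70, 0.60, 0.55)
    # multiplicative thickness/density field
    thickness_mean: float = 1.0
    thickness_corr_um: float = 100.0
    thickness_cov: float = 0.15
    # darkfield rendering: per-class base intensity, classes 0..3
    df_base_intensity: tuple[float, float, float, float] = (0.02, 0.25, 0.45, 0.45)
    # nuclear speckle events per um^2, classes 1..3 (dysplastic > non-dysplastic)
    nuclear_density_per_class: tuple[float, float, float] = (0.0005, 0.0040, 0.0030)
    nuclear_amplitude: float = 0.8
    df_psf_sigma_um: float = 0.7
    noise_sd: float = 0.01
    background_absorbance: float = 0.01
    ir_pixel_um: float = 2.0
    df_pixel_um: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        p = self
        if p.image_height_px % 4 or p.image_width_px % 4:
            raise ParameterError("frame dimensions must be multiples of 4 um")
        if not (0.0 < p.tissue_fraction <= 1.0):
            raise ParameterError("tissue_fraction must be in (0, 1]")
        if p.epithelium_depth_frac >= 1.0 or p.epithelium_depth_frac <= 0.0:
            raise ParameterError("epithelium_depth_frac must be in (0, 1)")
        if not (0.0 <= p.dysplasia_extent_frac <= 1.0):
            raise ParameterError("dysplasia_extent_frac must be in [0, 1]")
        epi_depth = p.epithelium_depth_frac * p.image_height_px
        tissue_h = p.tissue_fraction * p.image_height_px
        if epi_depth >= tissue_h:
            raise ParameterError("epithelium deeper than the tissue slab")
        # sinusoid + 30% low-frequency jitter must stay inside the epithelium
        # and inside the frame
        if 1.3 * p.rete_peg_amplitude_px >= min(epi_depth, tissue_h - epi_depth):
            raise ParameterError("rete peg amplitude exceeds epithelium depth")
        if p.rete_peg_period_px <= 0:
            raise ParameterError("rete_peg_period_px must be positive")
        m1238, m1546 = p.mu_ratio_1238, p.mu_ratio_1546
        if not (m1238[0] > m1238[1] > m1238[2]):
            raise ParameterError("mu_ratio_1238 must order non-epi > dysplastic > non-dysplastic")
        if not (m1546[0] > m1546[1] and m1546[0] > m1546[2]):
            raise ParameterError("mu_ratio_1546 must order non-epi above both epithelium classes")
        if not self._zero_spread():
            # spread-ordering constraints are vacuous in the noise-free limit
            if not (p.sigma_ratio_1238[0] > max(p.sigma_ratio_1238[1:])
                    and p.sigma_ratio_1546[0] > max(p.sigma_ratio_1546[1:])):
                raise ParameterError("non-epithelium ratio spread must be strictly largest")
            if not p.sigma_ratio_1546[2] > p.sigma_ratio_1546[1]:
                raise ParameterError("1546 spread must be larger for non-dysplastic than dysplastic")
        if not p.nuclear_density_per_class[1] > p.nuclear_density_per_class[2]:
            raise ParameterError("nuclear density must be higher in dysplastic epithelium")
        for name in ("mu_a1658", "df_base_intensity"):
            if any(v <= 0 for v in getattr(p, name)):
                raise ParameterError(f"{name} entries must be strictly positive")
        if p.thickness_mean <= 0 or p.background_absorbance <= 0:
            raise ParameterError("intensities must be strictly positive")
        if p.noise_sd < 0 or p.thickness_cov < 0:
            raise ParameterError("noise_sd and thickness_cov must be non-negative")

    def noise_free(self, thickness_cov: float | None = None) -> "PhantomParams":
        """Copy with detector noise and within-class chemical spread removed.

        The thickness field is kept (optionally with a new coefficient of
        variation): it is multiplicative and cancels exactly in the band
        ratios, which is the point of Amide I normalization.
        """
        return dataclasses.replace(
            self,
            noise_sd=0.0,
            sigma_ratio_1238=(0.0, 0.0, 0.0),
            sigma_ratio_1546=(0.0, 0.0, 0.0),
            thickness_cov=self.thickness_cov if thickness_cov is None else thickness_cov,
        )

    def _zero_spread(self) -> bool:
        return all(v == 0 for v in self.sigma_ratio_1238 + self.sigma_ratio_1546)


@dataclass
class PhantomSection:
    """A generated section: raw modality rasters plus ground-truth labels."""

    raw_band_images: dict[float, BandImage]  # wavenumber -> 2 um/px raster
    darkfield: np.ndarray  # 0.5 um/px raster
    darkfield_pixel_um: float
    labels: LabelMap  # 1 um/px ground truth
    params: PhantomParams
    section_id: str


def _smooth_unit_field(rng: np.random.Generator, shape, sigma_px: float) -> np.ndarray:
    """Smooth Gaussian random field renormalized to zero mean, unit variance."""
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px, mode="wrap")
    sd = g.std()
    return (g - g.mean()) / (sd if sd > 0 else 1.0)


def _boundary_profile(rng: np.random.Generator, params: PhantomParams) -> np.ndarray:
    """Row index of the epithelium->stroma boundary for every column."""
    w = params.image_width_px
    cols = np.arange(w)
    phase = rng.uniform(0, 2 * np.pi)
    base_row = (1.0 - params.tissue_fraction + params.epithelium_depth_frac) * params.image_height_px
    pegs = params.rete_peg_amplitude_px * np.sin(2 * np.pi * cols / params.rete_peg_period_px + phase)
    jitter = 0.3 * params.rete_peg_amplitude_px * _smooth_unit_field(
        rng, (w,), sigma_px=max(params.rete_peg_period_px / 2.0, 1.0)
    )
    return base_row + pegs + jitter


def _make_labels(rng: np.random.Generator, params: PhantomParams) -> np.ndarray:
    h, w = params.image_height_px, params.image_width_px
    tissue_top = int(round((1.0 - params.tissue_fraction) * h))
    boundary = _boundary_profile(rng, params)
    rows = np.arange(h)[:, None]
    labels = np.zeros((h, w), dtype=np.uint8)
    in_tissue = np.broadcast_to(rows >= tissue_top, (h, w))
    in_epi = in_tissue & (rows < boundary[None, :])
    labels[in_tissue] = 1  # stroma by default
    # one contiguous dysplastic focus along the width of the epithelium
    focus_w = int(round(params.dysplasia_extent_frac * w))
    start = int(rng.integers(0, max(w - focus_w, 0) + 1)) if focus_w < w else 0
    dys_cols = np.zeros(w, dtype=bool)
    dys_cols[start:start + focus_w] = True
    labels[in_epi & ~dys_cols[None, :]] = 3
    labels[in_epi & dys_cols[None, :]] = 2
    return labels


def _labels_on_grid(labels: np.ndarray, target_pixel_um: float) -> np.ndarray:
    """Nearest-neighbor label transfer from the 1 um grid to another pitch."""
    from .preprocess import resample

    return resample(labels, 1.0, target_pixel_um, mode="label")


def generate_phantom(params: PhantomParams, section_id: str | None = None) -> PhantomSection:
    """Render one synthetic section from its parameters (seeded, bit-stable)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    labels = _make_labels(rng, params)
    h2, w2 = params.image_height_px // 2, params.image_width_px // 2
    labels_ir = _labels_on_grid(labels, params.ir_pixel_um)

    # shared multiplicative thickness/density field on the IR grid
    if params.thickness_cov > 0:
        sigma_ln = float(np.sqrt(np.log1p(params.thickness_cov**2)))
        g = _smooth_unit_field(rng, (h2, w2), params.thickness_corr_um / params.ir_pixel_um)
        thickness = params.thickness_mean * np.exp(sigma_ln * g - 0.5 * sigma_ln**2)
    else:
        rng.standard_normal((h2, w2))  # keep the draw sequence stable across CoV settings
        thickness = np.full((h2, w2), params.thickness_mean)

    tissue_ir = labels_ir > 0
    cls_idx = np.clip(labels_ir.astype(np.int32) - 1, 0, 2)

    def _per_class(vals):
        return np.asarray(vals, dtype=np.float64)[cls_idx]

    a1658_mu = np.where(tissue_ir, _per_class(params.mu_a1658), params.background_absorbance)

    bands: dict[float, np.ndarray] = {}
    band_specs = [
        (1238.0, params.mu_ratio_1238, params.sigma_ratio_1238),
        (1546.0, params.mu_ratio_1546, params.sigma_ratio_1546),
    ]
    chem_sigma_px = 4.0 / params.ir_pixel_um  # ~4 um biochemical texture scale
    for wn, mu_ratio, sigma_ratio in band_specs:
        z = _smooth_unit_field(rng, (h2, w2), chem_sigma_px)
        chem = np.exp(_per_class(sigma_ratio) * z)  # median 1 per class
        a = a1658_mu * np.where(tissue_ir, _per_class(mu_ratio) * chem, 1.0)
        bands[wn] = a
    bands[1658.0] = a1658_mu.copy()

    for wn in (1238.0, 1546.0, 1658.0):
        a = bands[wn] * thickness
        if params.noise_sd > 0:
            a = a * 1.0 + params.noise_sd * rng.standard_normal((h2, w2))
        bands[wn] = np.clip(a, 0.0, None).astype(np.float32)

    darkfield = _render_darkfield(rng, labels, params)

    sid = section_id if section_id is not None else f"phantom-{params.seed:05d}"
    return PhantomSection(
        raw_band_images={
            wn: BandImage(bands[wn], wn, params.ir_pixel_um) for wn in (1238.0, 1546.0, 1658.0)
        },
        darkfield=darkfield,
        darkfield_pixel_um=params.df_pixel_um,
        labels=LabelMap(labels),
        params=params,
        section_id=sid,
    )


def _render_darkfield(
    rng: np.random.Generator, labels: np.ndarray, params: PhantomParams
) -> np.ndarray:
    labels_df = _labels_on_grid(labels, params.df_pixel_um)
    base = np.asarray(params.df_base_intensity, dtype=np.float64)[labels_df]
    px_area_um2 = params.df_pixel_um**2
    impulses = np.zeros(labels_df.shape, dtype=np.float64)
    flat = labels_df.ravel()
    for cls in (1, 2, 3):
        idx = np.flatnonzero(flat == cls)
        if idx.size == 0:
            continue
        lam = params.nuclear_density_per_class[cls - 1] * idx.size * px_area_um2
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        where = rng.choice(idx, size=n, replace=True)
        amp = params.nuclear_amplitude * rng.uniform(0.7, 1.3, size=n)
        np.add.at(impulses.ravel(), where, amp)
    sigma_px = params.df_psf_sigma_um / params.df_pixel_um
    # scale so one nucleus contributes ~nuclear_amplitude at its center post-blur
    speckle = ndimage.gaussian_filter(impulses, sigma_px) * (2.0 * np.pi * sigma_px**2)
    df = base + speckle
    if params.noise_sd > 0:
        df = df + params.noise_sd * rng.standard_normal(df.shape)
    return np.clip(df, 0.0, None).astype(np.float32)


# ---------------------------------------------------------------------------
# on-disk layout: float32 TIFF per channel, 8-bit label PNG, JSON sidecar
# ---------------------------------------------------------------------------

def write_section(section: PhantomSection, out_dir: str | Path) -> Path:
    import imageio.v3 as iio

    out = Path(out_dir) / section.section_id
    out.mkdir(parents=True, exist_ok=True)
    for wn, band in section.raw_band_images.items():
        write_band_tiff(out / f"ir_{int(wn)}.tif", band.pixels, band.pixel_size)
    write_band_tiff(out / "darkfield.tif", section.darkfield, section.darkfield_pixel_um)
    iio.imwrite(out / "labels.png", section.labels.labels)
    sidecar = {
        "section_id": section.section_id,
        "seed": section.params.seed,
        "params": dataclasses.asdict(section.params),
    }
    (out / "params.json").write_text(json.dumps(sidecar, indent=2))
    return out


def read_section(section_dir: str | Path) -> PhantomSection:
    import imageio.v3 as iio

    from .preprocess import read_band_tiff

    d = Path(section_dir)
    sidecar = json.loads((d / "params.json").read_text())
    pdict = sidecar["params"]
    for k, v in list(pdict.items()):
        if isinstance(v, list):
            pdict[k] = tuple(v)
    params = PhantomParams(**pdict)
    bands = {}
    for wn in (1238, 1546, 1658):
        px, px_um = read_band_tiff(d / f"ir_{wn}.tif")
        bands[float(wn)] = BandImage(px, float(wn), px_um)
    df, df_um = read_band_tiff(d / "darkfield.tif")
    labels = LabelMap(np.asarray(iio.imread(d / "labels.png")))
    return PhantomSection(
        raw_band_images=bands,
        darkfield=df,
        darkfield_pixel_um=df_um,
        labels=labels,
        params=params,
        section_id=sidecar["section_id"],
    )
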