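"""Synthetic study generator: trees, phylogenetic traits, climate
covariates, and band-limited pattern textures.

No raw study data are distributable, so every pipeline input is
emulated:

* pure-birth (Yule) phylogenies rescaled to unit depth, defaulting to
  the study's 17 taxa;
* Brownian-motion tip traits with a lambda-scaled covariance;
* a trait table in which each animal trait depends log-linearly on its
  background counterpart with a controllable slope, plus log-normal
  precipitation covariates (PDT, PWT) correlated with the background;
* sexes coupled through a shared phylogenetic field whose rate is
  scaled in males, so the expected male-on-female major-axis slope is
  sqrt(rate_ratio_male_female);
* isotropic band-limited textures with a known dominant wavelength for
  validating the granularity analysis.

Traits are generated multiplicatively (exponentials of Gaussian
phylogenetic fields): the natural-log analysis scale is then exactly
linear-Gaussian, and every trait column is strictly positive.
Everything is a pure function of its config and seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .colorimetry import ReflectanceImage
from .phylo import (
    Phylogeny,
    PhyloCovariance,
    lambda_transform,
    parse_newick,
    phylo_covariance,
)

COLOR_TRAITS = ("brightness", "saturation", "hue1", "hue2")
PATTERN_TRAITS = ("overall_contrast", "dominant_size_px", "diversity")
ALL_TRAITS = COLOR_TRAITS + PATTERN_TRAITS

# ln-scale baselines, loosely matching plausible magnitudes of each metric
_BASELINES = {
    "brightness": np.log(0.3),
    "saturation": np.log(1.2),
    "hue1": np.log(1.1),
    "hue2": np.log(2.5),
    "overall_contrast": np.log(0.02),
    "dominant_size_px": np.log(16.0),
    "diversity": np.log(0.3),
}


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for one synthetic study.

    Defaults mirror the study conditions: 17 taxa, moderate phylogenetic
    signal in the residuals, a unit animal-on-background slope, and
    equal male/female rates.
    """

    n_taxa: int = 17
    seed: int = 0
    lambda_true: float = 0.5
    slope_bg: float = 1.0
    sigma_bm: float = 0.5        # BM sd of ln background traits over unit depth
    sigma_resid: float = 0.15    # sd of the animal residual field
    rate_ratio_male_female: float = 1.0
    sigma_sex_noise: float = 0.05  # sd of each sex's independent deviation
    climate_effect: float = 0.5
    sigma_climate: float = 0.3
    dominant_wavelength_px: float = 16.0
    image_size: int = 256

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")
        for name in ("sigma_bm", "rate_ratio_male_female"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sigma_resid", "sigma_sex_noise", "sigma_climate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def sim_tree(n: int, seed: int) -> Phylogeny:
    """Pure-birth tree with n extant tips, rescaled to unit depth."""
    if n < 2:
        raise ValueError("need at least 2 tips")
    rng = random.Random(int(seed))
    dtree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n,
        rng=rng,
    )
    # the simulator stops at the n-th split (zero-length final cherry);
    # grow all pendant edges by the Exp(n * birth_rate) waiting time to
    # the next, uncounted speciation to complete the Yule sample
    extra = rng.expovariate(n * 1.0)
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = parse_newick(newick)
    return tree.rescale_depth(1.0)


def _bm_factor(cov: PhyloCovariance, lam: float) -> np.ndarray:
    """Matrix square root of the lambda-transformed covariance."""
    V = lambda_transform(cov, lam).V
    # V can be singular (e.g. zero-length branches); eigh is robust
    w, Q = np.linalg.eigh(V)
    w = np.clip(w, 0.0, None)
    return Q * np.sqrt(w)[None, :]


def sim_bm_trait(
    tree: "Phylogeny | PhyloCovariance",
    lam: float,
    sigma2: float,
    seed: "int | np.random.Generator",
) -> np.ndarray:
    """One Brownian-motion tip draw: N(0, sigma2 * V_lambda), tip order
    matching ``tree.tip_names``."""
    if not sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    cov = tree if isinstance(tree, PhyloCovariance) else phylo_covariance(tree)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = _bm_factor(cov, lam)
    return np.sqrt(sigma2) * (A @ rng.standard_normal(len(cov.taxa)))


def sim_study_traits(config: SimConfig) -> tuple[pd.DataFrame, Phylogeny]:
    """Full synthetic trait table (both sexes) plus its phylogeny.

    Per trait k the generative model on the ln scale is

        ln Bg_k   = mu_bg,k + B_k,                 B_k ~ BM(sigma_bm^2)
        ln A_sex,k = mu_a,k + slope_bg * ln Bg_k
                     + s_sex * D_k + eta_sex,k

    where D_k ~ BM-lambda(sigma_resid^2) is shared between the sexes,
    s_female = 1, s_male = sqrt(rate_ratio_male_female), and eta are
    small independent BM-lambda fields (sd sigma_sex_noise).  The
    background is shared between sexes (same localities).  PDT and PWT
    are log-normal with a climate_effect loading on the brightness
    background field.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tree = sim_tree(cfg.n_taxa, int(rng.integers(2**31 - 1)))
    cov = phylo_covariance(tree)
    taxa = list(cov.taxa)

    def bm(lam: float, sd: float) -> np.ndarray:
        if sd == 0.0:
            return np.zeros(len(taxa))
        return sim_bm_trait(cov, lam, sd**2, rng)

    s_male = np.sqrt(cfg.rate_ratio_male_female)
    rows: dict[str, dict[str, float]] = {
        ("F", t): {} for t in taxa
    } | {("M", t): {} for t in taxa}

    bg_fields = {}
    for k in ALL_TRAITS:
        B = bm(1.0, cfg.sigma_bm)
        bg_fields[k] = B
        D = bm(cfg.lambda_true, cfg.sigma_resid)
        ln_bg = _BASELINES[k] + B
        for sex, scale in (("F", 1.0), ("M", s_male)):
            eta = bm(cfg.lambda_true, cfg.sigma_sex_noise)
            ln_animal = (
                _BASELINES[k]
                + cfg.slope_bg * (ln_bg - _BASELINES[k])
                + scale * D
                + eta
            )
            for i, t in enumerate(taxa):
                rows[(sex, t)][k] = float(np.exp(ln_animal[i]))
                rows[(sex, t)][f"bg_{k}"] = float(np.exp(ln_bg[i]))

    # climate: log-normal, correlated with the brightness background field
    ln_pdt = np.log(40.0) + cfg.climate_effect * bg_fields["brightness"] + (
        cfg.sigma_climate * rng.standard_normal(len(taxa))
    )
    ln_pwt = np.log(600.0) + cfg.climate_effect * bg_fields["saturation"] + (
        cfg.sigma_climate * rng.standard_normal(len(taxa))
    )
    for i, t in enumerate(taxa):
        for sex in ("F", "M"):
            rows[(sex, t)]["PDT"] = float(np.exp(ln_pdt[i]))
            rows[(sex, t)]["PWT"] = float(np.exp(ln_pwt[i]))

    records = [
        {"taxon": t, "sex": sex, **vals} for (sex, t), vals in rows.items()
    ]
    table = pd.DataFrame.from_records(records).sort_values(
        ["sex", "taxon"], kind="stable"
    )
    return table.reset_index(drop=True), tree


def sim_pattern_image(
    size: int,
    wavelength_px: float,
    mean_rgb: tuple[float, float, float],
    amplitude: float,
    seed: int,
    *,
    px_per_mm: float = 30.0,
    rel_bandwidth: float = 0.10,
) -> ReflectanceImage:
    """Isotropic band-limited texture with a known dominant wavelength.

    A white-noise field is filtered to a narrow annulus of spatial
    frequencies centered on 1/wavelength_px, rescaled so its extreme
    value equals ``amplitude``, and added to mean R and G; B is held
    constant.  The full frame is both the "animal" and "background"
    mask.
    """
    if not 0 < wavelength_px < size:
        raise ValueError("wavelength must lie inside the image")
    mean_rgb = tuple(float(c) for c in mean_rgb)
    rng = np.random.default_rng(seed)
    if amplitude > 0:
        noise = rng.standard_normal((size, size))
        F = np.fft.fft2(noise)
        fv = np.fft.fftfreq(size)[:, None]
        fu = np.fft.fftfreq(size)[None, :]
        rho = np.hypot(fv, fu)
        f0 = 1.0 / wavelength_px
        annulus = np.abs(rho - f0) <= rel_bandwidth * f0
        if not annulus.any():
            raise ValueError("annulus empty; wavelength unresolvable at this size")
        fieldr = np.fft.ifft2(F * annulus).real
        peak = np.abs(fieldr).max()
        fieldr *= amplitude / peak
    else:
        fieldr = np.zeros((size, size))
    pix = np.empty((size, size, 3))
    pix[..., 0] = mean_rgb[0] + fieldr
    pix[..., 1] = mean_rgb[1] + fieldr
    pix[..., 2] = mean_rgb[2]
    if pix.min() < 0.0 or pix.max() > 1.0:
        raise ValueError(
            "amplitude pushes reflectance out of [0, 1]; reduce amplitude"
        )
    full = np.ones((size, size), dtype=bool)
    return ReflectanceImage(
        pixels=pix,
        px_per_mm=px_per_mm,
        masks={"animal": full, "background": full},
    )
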