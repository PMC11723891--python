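"""Study orchestration: images -> metrics -> trait table -> PGLS + MA tables.

``extract_metrics`` turns a manifest of calibrated photographs (image,
region masks, gray-standard patches, pixel scale) into per-individual
color and pattern metrics; ``aggregate_to_taxa`` reduces individuals to
taxon x sex means; ``run_study`` fits, per sex, one PGLS model per
response trait (its background counterpart plus ln PDT and ln PWT as
predictors, everything ln-transformed, BH-adjusted p-values pooled over
the run) and then quantifies male/female divergence per trait by a
major-axis regression of male on female independent contrasts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import MAFit, ma_fit
from .colorimetry import (
    GrayStandard,
    ReflectanceImage,
    calibrate_from_gray_standards,
    region_color_metrics,
)
from .granularity import (
    ScaleBank,
    build_scale_bank,
    check_pixel_scale,
    region_granularity,
)
from .pgls import ModelSpec, PGLSFit, adjust_family, pgls
from .phylo import Phylogeny, independent_contrasts, match_taxa
from .synthetic_data import ALL_TRAITS, PATTERN_TRAITS

REGIONS = ("animal", "background")


@dataclass
class Exclusion:
    record: str
    reason: str


@dataclass
class StudyOptions:
    fixed_lambda: float | None = None
    method: str = "REML"             # lambda profile: "REML" or "ML"
    ln_transform: bool = True
    outlier_threshold: float = 3.0
    aggregate: str = "mean"          # or "median"
    diversity: str = "of_total"
    energy: str = "power"


@dataclass
class StudyReport:
    pgls_rows: list[PGLSFit]
    ma_rows: dict[str, MAFit]
    exclusions: list[Exclusion]
    run_metadata: dict

    def pgls_table(self) -> pd.DataFrame:
        rows = []
        for fit in self.pgls_rows:
            sex, response = fit.response_name.split(":", 1)
            for term in fit.terms:
                rows.append(
                    {
                        "sex": sex,
                        "response": response,
                        "term": term.name,
                        "coefficient": term.coefficient,
                        "t": term.t,
                        "F": term.F,
                        "multiple_R2": fit.multiple_r2,
                        "P": term.p,
                        "adj_P": term.p_adjusted,
                        "lambda": fit.lambda_hat,
                        "df_model": fit.df_model,
                        "df_residual": fit.df_residual,
                    }
                )
        return pd.DataFrame(rows)

    def ma_table(self) -> pd.DataFrame:
        rows = []
        for trait, fit in self.ma_rows.items():
            rows.append(
                {
                    "trait": trait,
                    "beta": fit.beta,
                    "ucl": fit.ucl,
                    "lcl": fit.lcl,
                    "r2": fit.r2,
                    "r_w": fit.wald_r,
                    "df": fit.df,
                    "p": fit.p_slope1,
                    "n_used": fit.n_used,
                    "removed_indices": ";".join(map(str, fit.removed_indices)),
                    "degenerate_flag": (
                        "independent_evolution" if fit.degenerate else ""
                    ),
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pgls_table().to_csv(outdir / "pgls_models.csv", index=False)
        self.ma_table().to_csv(outdir / "ma_divergence.csv", index=False)
        meta = dict(self.run_metadata)
        meta["exclusions"] = [dataclasses.asdict(e) for e in self.exclusions]
        (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2))


def read_gray_standards(path: str | Path) -> list[GrayStandard]:
    """Gray-standard CSV: patch_id, mean_R, mean_G, mean_B, known_reflectance."""
    df = pd.read_csv(path)
    return [
        GrayStandard(
            (row["mean_R"], row["mean_G"], row["mean_B"]),
            row["known_reflectance"],
        )
        for _, row in df.iterrows()
    ]


def _read_raster(path: str | Path, *, assume_srgb: bool = False) -> np.ndarray:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path)).astype(float)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    arr = arr[..., :3]
    maxval = 65535.0 if arr.max() > 255 else 255.0
    arr = arr / maxval
    if assume_srgb:
        a = 0.055
        arr = np.where(
            arr <= 0.04045, arr / 12.92, ((arr + a) / (1 + a)) ** 2.4
        )
    return arr


def load_image_record(
    record: "pd.Series | dict", *, assume_srgb: bool = False
) -> ReflectanceImage:
    """Read one manifest record into a calibrated ReflectanceImage."""
    import imageio.v3 as iio

    raw = _read_raster(record["image_path"], assume_srgb=assume_srgb)
    masks = {
        "animal": np.asarray(iio.imread(record["animal_mask_path"])) > 0,
        "background": np.asarray(iio.imread(record["background_mask_path"])) > 0,
    }
    masks = {k: m[..., 0] if m.ndim == 3 else m for k, m in masks.items()}
    standards = read_gray_standards(record["standards_path"])
    return calibrate_from_gray_standards(
        raw,
        standards,
        px_per_mm=float(record["px_per_mm"]),
        masks=masks,
    )


def metrics_for_image(
    image: ReflectanceImage,
    bank: ScaleBank | None = None,
    *,
    options: StudyOptions | None = None,
) -> tuple[dict[str, float], list[str]]:
    """All 14 metric columns for one calibrated image.

    Color metrics always; pattern metrics only when the pixel-scale
    check passes and the region is non-constant.  Returns (metrics,
    exclusion reasons); excluded pattern columns are NaN.
    """
    options = options or StudyOptions()
    bank = bank or build_scale_bank()
    out: dict[str, float] = {}
    reasons: list[str] = []
    for region in REGIONS:
        prefix = "" if region == "animal" else "bg_"
        cm = region_color_metrics(image, region)
        for k, val in cm.as_dict().items():
            out[f"{prefix}{k}"] = val
        if not check_pixel_scale(image.px_per_mm):
            for k in PATTERN_TRAITS:
                out[f"{prefix}{k}"] = math.nan
            if region == "animal":
                reasons.append(
                    f"pixel scale {image.px_per_mm} px/mm below minimum; "
                    "pattern metrics omitted"
                )
            continue
        spec = region_granularity(
            image, region, bank,
            diversity=options.diversity, energy=options.energy,
        )
        if spec.undefined:
            reasons.append(f"constant {region} region; pattern descriptors undefined")
        for k, val in spec.as_dict().items():
            out[f"{prefix}{k}"] = val
    return out, reasons


def extract_metrics(
    manifest: pd.DataFrame,
    bank: ScaleBank | None = None,
    *,
    options: StudyOptions | None = None,
    assume_srgb: bool = False,
) -> tuple[pd.DataFrame, list[Exclusion]]:
    """Per-individual metric rows from an image manifest.

    Manifest columns: individual_id, taxon, sex, image_path,
    animal_mask_path, background_mask_path, standards_path, px_per_mm.
    Unreadable records are skipped with an exclusion entry; the run
    continues.
    """
    rows, exclusions = [], []
    for _, rec in manifest.iterrows():
        rid = str(rec.get("individual_id", rec.name))
        try:
            image = load_image_record(rec, assume_srgb=assume_srgb)
            metrics, reasons = metrics_for_image(image, bank, options=options)
        except Exception as exc:
            exclusions.append(Exclusion(rid, f"unreadable record: {exc}"))
            continue
        for reason in reasons:
            exclusions.append(Exclusion(rid, reason))
        rows.append(
            {"individual_id": rid, "taxon": rec["taxon"], "sex": rec["sex"],
             **metrics}
        )
    return pd.DataFrame(rows), exclusions


def aggregate_to_taxa(
    rows: pd.DataFrame, *, how: str = "mean"
) -> pd.DataFrame:
    """Reduce per-individual rows to one row per taxon x sex."""
    if how not in ("mean", "median"):
        raise ValueError(f"unknown aggregation {how!r}")
    if rows.empty:
        raise ValueError("no rows to aggregate")
    value_cols = [
        c for c in rows.columns if c not in ("individual_id", "taxon", "sex")
    ]
    grouped = rows.groupby(["taxon", "sex"], as_index=False)[value_cols]
    return (grouped.mean() if how == "mean" else grouped.median())


def validate_trait_table(table: pd.DataFrame, tree: Phylogeny) -> None:
    """Fail fast before any model runs: sexes, taxa, and positivity."""
    sexes = set(table["sex"].unique())
    missing_sex = {"F", "M"} - sexes
    if missing_sex:
        raise ValueError(f"trait table missing sex(es): {sorted(missing_sex)}")
    for sex in ("F", "M"):
        sub = table[table["sex"] == sex]
        match_taxa(tree, list(sub["taxon"]))
    numeric = table.drop(columns=["taxon", "sex"])
    finite = numeric.to_numpy(dtype=float)
    bad = ~(np.isfinite(finite) & (finite > 0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive or non-finite value in column "
            f"{numeric.columns[j]!r}, taxon {table['taxon'].iloc[i]!r}"
        )


def run_study(
    traits: pd.DataFrame,
    tree: Phylogeny,
    options: StudyOptions | None = None,
    *,
    traits_to_use: tuple[str, ...] = ALL_TRAITS,
    seed: int | None = None,
) -> StudyReport:
    """PGLS per sex x response, pooled BH adjustment, then MA divergence.

    Responses whose columns contain NaN pattern metrics are dropped per
    sex with an exclusion entry rather than failing the run.
    """
    options = options or StudyOptions()
    exclusions: list[Exclusion] = []
    usable_traits = []
    for trait in traits_to_use:
        cols = [trait, f"bg_{trait}"]
        if traits[cols].isna().any().any():
            exclusions.append(
                Exclusion(trait, "missing metric values; trait dropped")
            )
        else:
            usable_traits.append(trait)
    if not usable_traits:
        raise ValueError("no trait has complete data across all taxa")
    keep_cols = ["taxon", "sex", "PDT", "PWT"] + [
        c for t in usable_traits for c in (t, f"bg_{t}")
    ]
    usable = traits[keep_cols]
    validate_trait_table(usable, tree)

    fits: list[PGLSFit] = []
    for sex in ("F", "M"):
        sub = usable[usable["sex"] == sex].set_index("taxon")
        for response in usable_traits:
            spec = ModelSpec(
                response=response,
                predictors=(f"bg_{response}", "PDT", "PWT"),
                ln_transform=options.ln_transform,
            )
            fit = pgls(
                sub, spec, tree,
                fixed_lambda=options.fixed_lambda, method=options.method,
            )
            fits.append(
                dataclasses.replace(fit, response_name=f"{sex}:{response}")
            )
    fits = adjust_family(fits)

    ma_rows: dict[str, MAFit] = {}
    female = usable[usable["sex"] == "F"].set_index("taxon")
    male = usable[usable["sex"] == "M"].set_index("taxon")
    tips = [t.strip() for t in tree.tip_names]
    for trait in usable_traits:
        f_vals = np.log(female.loc[tips, trait].to_numpy(dtype=float))
        m_vals = np.log(male.loc[tips, trait].to_numpy(dtype=float))
        u = independent_contrasts(tree, f_vals).values
        v = independent_contrasts(tree, m_vals).values
        ma_rows[trait] = ma_fit(
            u, v, outlier_threshold=options.outlier_threshold
        )
        if ma_rows[trait].degenerate:
            exclusions.append(
                Exclusion(trait, "degenerate MA fit: independent evolution")
            )

    metadata = {
        "version": __version__,
        "seed": seed,
        "options": dataclasses.asdict(options),
        "n_taxa": tree.n_tips,
        "traits": list(usable_traits),
        "fdr_pooling": "all term-level p-values of this run",
    }
    return StudyReport(fits, ma_rows, exclusions, metadata)
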