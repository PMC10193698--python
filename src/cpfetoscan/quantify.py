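"""Volumetric particle loads: tissue segmentation, normalization, pooling.

Counts are converted to particles per mm^3 by dividing by the segmented
tissue area of each region and by the physical section thickness
(7 um).  Region loads are averaged per sample (fetus x organ) and then
per litter (dam), so the dam is the statistical unit for the group
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .image_io import TileScan, TissueMask

#: display scaling of organ/fetus weight ratios, per reporting convention
RATIO_SCALE = {"placenta": 10.0, "heart": 1e3, "kidney": 1e3, "liver": 1e2, "lung": 1e2}


@dataclass
class SampleQuant:
    """Per-sample (fetus x organ) volumetric particle load."""

    sample_id: str
    region_loads: list  # particles / mm^3 per valid region
    region_areas_mm2: list
    sample_load: float
    n_regions: int
    under_sampled: bool  # fewer than n_min valid regions


def segment_tissue(tile: TileScan, downsample: int = 2, smooth_sigma_px: float = 4.0) -> TissueMask:
    """Segment the tissue region from the broad (autofluorescence) channel.

    Automated stand-in for a manual area annotation: Gaussian-smoothed
    broad channel, global Otsu threshold, morphological closing, hole
    filling and small-object removal.  ``downsample`` trades boundary
    precision for speed (block-mean pooling before segmentation); the
    returned mask is upsampled back to the tile grid.
    """
    broad = tile.broad_channel.astype(np.float32)
    n_rows, n_cols = broad.shape
    ds = max(1, int(downsample))
    if ds > 1 and n_rows % ds == 0 and n_cols % ds == 0:
        broad = broad.reshape(n_rows // ds, ds, n_cols // ds, ds).mean(axis=(1, 3))
    else:
        ds = 1
    smoothed = ndimage.gaussian_filter(broad, smooth_sigma_px / ds)
    if smoothed.max() <= 0 or np.ptp(smoothed) < 1e-6:
        return TissueMask(np.zeros((n_rows, n_cols), dtype=bool), tile.pixel_size_um)
    # cap bright outliers (saturating particles) so the global threshold
    # separates background vs tissue, not tissue vs particles
    ceiling = np.quantile(smoothed, 0.90)
    capped = np.minimum(smoothed, ceiling)
    thr = threshold_otsu(capped)
    below = capped[capped < thr]
    above = capped[capped >= thr]
    if below.size == 0 or (above.size and below.mean() > 0.35 * above.mean()):
        # no genuine background class: the whole field is tissue
        thr = 0.1 * ceiling
    mask = smoothed > thr
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3), bool))
    # fill only small holes (smoothing artefacts); genuine enclosed
    # background regions stay excluded from the tissue area
    holes, n_holes = ndimage.label(~mask)
    if n_holes:
        hole_sizes = np.bincount(holes.ravel())
        small_hole = hole_sizes < max(9, mask.size // 4096)
        small_hole[0] = False
        mask[small_hole[holes]] = True
    labels, n_obj = ndimage.label(mask)
    if n_obj:
        sizes = np.bincount(labels.ravel())
        small = sizes < max(16, mask.size // 1024)
        small[0] = False
        mask[small[labels]] = False
    if ds > 1:
        mask = np.repeat(np.repeat(mask, ds, axis=0), ds, axis=1)
    return TissueMask(mask, tile.pixel_size_um)


def load_per_mm3(n_particles: int, area_mm2: float, thickness_um: float = 7.0) -> float:
    """Particles per mm^3: count / (tissue area x section thickness)."""
    if n_particles < 0:
        raise ValueError("negative count")
    if not area_mm2 > 0:
        raise ValueError("zero or negative tissue area — load undefined")
    if not thickness_um > 0:
        raise ValueError("non-positive thickness")
    return n_particles / (area_mm2 * thickness_um * 1e-3)


def aggregate_sample(
    region_loads: list,
    region_areas_mm2: list | None = None,
    n_min: int = 5,
    sample_id: str = "",
    pool_regions: bool = False,
    region_counts: list | None = None,
    thickness_um: float = 7.0,
) -> SampleQuant:
    """Aggregate region loads into one sample load.

    Default is the unweighted mean of region loads.  With
    ``pool_regions=True`` (requires ``region_counts`` and areas), the
    sample load is instead total count / total volume — the
    pooled-count alternative reading of per-sample averaging.  Samples
    with fewer than ``n_min`` valid regions are flagged under-sampled;
    zero-area regions are excluded with a warning.
    """
    loads = list(region_loads)
    areas = list(region_areas_mm2) if region_areas_mm2 is not None else [np.nan] * len(loads)
    if region_areas_mm2 is not None:
        valid = [a > 0 for a in areas]
        if not all(valid):
            warnings.warn(f"{sample_id}: {valid.count(False)} zero-area region(s) excluded", stacklevel=2)
        loads = [l for l, v in zip(loads, valid) if v]
        areas = [a for a, v in zip(areas, valid) if v]
        if region_counts is not None:
            region_counts = [c for c, v in zip(region_counts, valid) if v]
    if not loads:
        raise ValueError("no valid regions")

    if pool_regions:
        if region_counts is None or region_areas_mm2 is None:
            raise ValueError("pooled aggregation needs region counts and areas")
        sample_load = load_per_mm3(int(sum(region_counts)), float(sum(areas)), thickness_um)
    else:
        sample_load = float(np.mean(loads))
    return SampleQuant(
        sample_id=sample_id,
        region_loads=loads,
        region_areas_mm2=areas,
        sample_load=sample_load,
        n_regions=len(loads),
        under_sampled=len(loads) < n_min,
    )


def pool_by_dam(table: pd.DataFrame, value_cols: list | None = None) -> pd.DataFrame:
    """Pool fetus-level rows to litter means per dam x organ.

    Group tests downstream operate on these litter means (n = dams per
    group).  Pooling an already litter-level table (one fetus per dam)
    is the identity on the value columns.
    """
    if table.empty:
        raise ValueError("empty table")
    if value_cols is None:
        skip = {"dam_id", "group", "fetus_id", "sex", "organ"}
        value_cols = [c for c in table.columns if c not in skip and pd.api.types.is_numeric_dtype(table[c])]
    pooled = (
        table.groupby(["dam_id", "group", "organ"], sort=False, observed=True)[value_cols]
        .mean()
        .reset_index()
    )
    return pooled


def derive_biometry(table: pd.DataFrame) -> pd.DataFrame:
    """Add derived weight-ratio columns to a fetus-level long table.

    Placental efficiency = fetal weight / placental weight; the
    placenta/fetus weight ratio is displayed x10, heart and kidney
    ratios x10^3, liver and lung ratios x10^2.  By construction,
    placental efficiency x (unscaled placenta/fetus ratio) = 1.
    """
    out = table.copy()
    if (out["fetal_weight_g"] <= 0).any():
        raise ValueError("non-positive fetal weight")
    placenta = out[out["organ"] == "placenta"]
    if (placenta["organ_weight_g"] <= 0).any():
        raise ValueError("non-positive placental weight")

    scale = out["organ"].map(RATIO_SCALE)
    out["weight_ratio_scaled"] = scale * out["organ_weight_g"] / out["fetal_weight_g"]
    eff = placenta.set_index("fetus_id").apply(
        lambda r: r["fetal_weight_g"] / r["organ_weight_g"], axis=1
    )
    out["placental_efficiency"] = out["fetus_id"].map(eff)
    out["placenta_fetus_ratio_x10"] = out["fetus_id"].map(
        placenta.set_index("fetus_id").apply(lambda r: 10.0 * r["organ_weight_g"] / r["fetal_weight_g"], axis=1)
    )
    return out


def quantify_study(records, params=None, n_min: int = 5, pool_regions: bool = False, segment_downsample: int = 2) -> pd.DataFrame:
    """Run detection + segmentation + normalization over rendered regions.

    ``records`` is an iterable of objects with ``tile`` plus sample
    metadata (as yielded by ``SimulatedStudy.iter_tiles`` or assembled
    from files).  Returns one row per sample with its volumetric load.
    """
    from .detection import call_particles

    per_sample: dict[str, dict] = {}
    for rec in records:
        calls = call_particles(rec.tile, params)
        mask = segment_tissue(rec.tile, downsample=segment_downsample)
        entry = per_sample.setdefault(
            rec.sample_id,
            dict(
                dam_id=rec.dam_id, fetus_id=rec.fetus_id, group=rec.group,
                organ=rec.organ, loads=[], areas=[], counts=[],
            ),
        )
        area = mask.area_mm2
        entry["areas"].append(area)
        entry["counts"].append(calls.n_particles)
        entry["loads"].append(
            load_per_mm3(calls.n_particles, area, rec.tile.section_thickness_um) if area > 0 else 0.0
        )

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sid, e in per_sample.items():
            sq = aggregate_sample(
                e["loads"], e["areas"], n_min=n_min, sample_id=sid,
                pool_regions=pool_regions, region_counts=e["counts"],
            )
            rows.append(
                dict(
                    sample_id=sid, dam_id=e["dam_id"], fetus_id=e["fetus_id"],
                    group=e["group"], organ=e["organ"], cp_load=sq.sample_load,
                    n_regions=sq.n_regions, under_sampled=sq.under_sampled,
                )
            )
    return pd.DataFrame(rows)
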