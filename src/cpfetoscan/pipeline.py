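"""End-to-end driver: simulate -> detect -> quantify -> stats -> mfa.

A single seeded configuration fully determines every output; each stage
persists its intermediates so it can be re-run in isolation, and the
final machine-readable results JSON is byte-stable for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import DetectionParams
from .mfa import build_mfa_input, dimension_description, fit_mfa, supplementary_categories
from .quantify import derive_biometry, pool_by_dam, quantify_study
from .stats import fit_lmm, fold_changes, organ_deficits, spearman_matrix, summarize, within_litter_check
from .synthetic import ORGANS, ImagingConfig, OrganEffectProfile, StudyDesign, simulate_study


@dataclass
class RunConfig:
    """Serializable configuration of one reproducible run."""

    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    effects: OrganEffectProfile = field(default_factory=OrganEffectProfile)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    fold_stat: str = "mean"
    pool_regions: bool = False
    segment_downsample: int = 4
    lmm_responses: tuple = ("weight_ratio_scaled", "organ_weight_g", "fetal_weight_g")
    mfa_factors: tuple = ("group",)

    def __post_init__(self) -> None:
        self.design = dataclasses.replace(self.design, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key, typ in (
            ("design", StudyDesign),
            ("effects", OrganEffectProfile),
            ("imaging", ImagingConfig),
            ("detection", DetectionParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kwargs[key] = typ(**sub)
        for k in ("lmm_responses", "mfa_factors"):
            if k in kwargs and isinstance(kwargs[k], list):
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def analyse_study_table(study: pd.DataFrame, config: RunConfig) -> dict:
    """Run the statistics battery + MFA on a fetus-level study table."""
    litter = pool_by_dam(study, value_cols=["cp_load"])
    results: dict = {}

    wl = within_litter_check(study)
    results["within_litter"] = {
        "n_families": int(len(wl)),
        "all_pooling_permitted": bool(wl["pooling_permitted"].all()),
        "refused": wl.loc[~wl["pooling_permitted"], ["group", "organ"]].to_dict("records"),
    }

    fc = fold_changes(litter, stat=config.fold_stat)
    results["fold_changes"] = fc.set_index("organ")[["control_mean", "exposed_mean", "ratio", "p_value"]].to_dict("index")

    od = organ_deficits(litter)
    results["organ_deficits"] = od.set_index("organ")[["deficit", "p_value"]].to_dict("index")

    results["group_summaries"] = {
        organ: {
            grp: summarize(litter.loc[(litter["organ"] == organ) & (litter["group"] == grp), "cp_load"])
            for grp in ("C", "DE")
        }
        for organ in litter["organ"].unique()
    }

    try:
        results["spearman_exposed"] = spearman_matrix(litter).round(6).to_dict()
    except ValueError as exc:  # fewer than 3 dams, or constant loads
        results["spearman_exposed"] = {"error": str(exc)}

    lmm = {}
    study_b = derive_biometry(study) if "weight_ratio_scaled" not in study else study
    for organ in ORGANS:
        if organ == "gonad":
            continue  # no organ weight recorded for gonads
        try:
            fit = fit_lmm(study_b, "weight_ratio_scaled", organ)
            slope = fit.fixed_effects.set_index("term").loc["log10_load"]
            lmm[organ] = dict(
                estimate=float(slope["estimate"]),
                ci_low=float(slope["ci_low"]),
                ci_high=float(slope["ci_high"]),
                p=float(slope["p"]),
                random_slope=fit.random_slope,
                fallback=fit.fallback_intercept_only,
            )
        except (RuntimeError, ValueError) as exc:
            lmm[organ] = dict(error=str(exc))
    results["lmm_ratio_per_decade"] = lmm

    inp = build_mfa_input(study_b, factors=tuple(dict.fromkeys(("group",) + tuple(config.mfa_factors))))
    fit = fit_mfa(inp, n_dims=min(5, len(inp.data) - 1, sum(len(g) for g in inp.groups.values())))
    cats = supplementary_categories(fit, inp.factors["group"])
    dd = dimension_description(fit, inp.factors["group"])
    results["mfa"] = {
        "inertia_pct_dim12": float(fit.inertia_pct[:2].sum()),
        "eigenvalues": [float(e) for e in fit.eigenvalues[:5]],
        "n_individuals": fit.n_individuals,
        "categories": cats.set_index("level")[["coord_dim1", "vtest_dim1", "cos2_dim1", "vtest_dim2", "cos2_dim2"]].to_dict("index"),
        "dimension_r2": dd.set_index("dimension")[["r2", "p"]].to_dict("index"),
    }
    return results


def run_pipeline(config: RunConfig, outdir: str | Path | None = None, write_tiles: bool = False) -> dict:
    """Execute every stage and return (and optionally persist) the report.

    Any stage failure aborts with the stage name attached; partial
    outputs written up to that point are left in place.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        sim = simulate_study(config.design, config.effects, config.imaging)
        truth = sim.table
        if outdir is not None:
            truth.round(8).to_csv(outdir / "truth_table.csv", index=False)
        if write_tiles and outdir is not None:
            from .image_io import write_tile

            tiledir = outdir / "tiles"
            tiledir.mkdir(exist_ok=True)
            for rec in sim.iter_tiles():
                write_tile(tiledir / f"{rec.sample_id}_{rec.region_id}.tif", rec.tile)

        stage = "detect+quantify"
        quant = quantify_study(
            sim.iter_tiles(),
            config.detection,
            pool_regions=config.pool_regions,
            segment_downsample=config.segment_downsample,
        )
        study = quant.merge(
            truth,
            on=["dam_id", "fetus_id", "group", "organ"],
            how="left",
        )
        study = derive_biometry(study)
        if outdir is not None:
            study.round(8).to_csv(outdir / "study_table.csv", index=False)

        stage = "stats+mfa"
        results = analyse_study_table(study, config)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    from . import __version__ as pkg_version

    report = {
        "config": _round_floats(config.to_dict()),
        "versions": {"cpfetoscan": pkg_version, "numpy": np.__version__, "pandas": pd.__version__},
        "results": _round_floats(results),
    }
    if outdir is not None:
        (outdir / "results.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
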