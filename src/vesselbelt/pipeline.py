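"""Per-sample orchestration and cohort-level summaries.

``analyze_sample`` composes the stages: (optional) segmentation of an RGB
image, restriction of vessels to the tumor ROI, the distance-excess analysis
against every available reference region (both references share the same
Monte-Carlo control draws, halving null variance within a sample), and the
hotspot metrics.  ``cohort_summary`` aggregates samples into the group-level
outputs: mean +/- SD of excess mass and zone width, a two-tailed pooled-
variance Student's t-test between groups, the fraction of samples with a
significant positive excess, and the Pearson correlation between overall and
in-hotspot MVD.  ``waterfall_export`` orders per-sample excesses for the
waterfall representation, and ``count_validation`` reproduces the observer
agreement analysis for segmentation counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULTS, merge_config
from .errors import DegenerateInputError, LabelError, VesselBeltError
from .excess import ExcessProfile, excess_analysis
from .hotspots import HotspotSummary, hotspot_analysis
from .roi import ADJACENT, LUMEN, TUMOR, PointPattern, RoiSet
from .seeds import derive_rng, derive_seed
from .segmentation import VesselSet, segment_image
from .synthetic import sample_uniform_in_polygon

__all__ = [
    "SampleResult",
    "analyze_sample",
    "cohort_summary",
    "waterfall_export",
    "count_validation",
]

log = logging.getLogger("vesselbelt")

GROUPS = ("primary_untreated", "primary_neoadjuvant", "metastasis")
COHORTS = ("first", "validation")


@dataclass
class SampleResult:
    """All analysis outputs of one sample."""

    sample_id: str
    cohort: str = "first"
    group: str = "primary_untreated"
    lumen_excess: ExcessProfile | None = None
    adjacent_excess: ExcessProfile | None = None
    hotspots: HotspotSummary | None = None
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}")

    def excess_for(self, reference: str) -> ExcessProfile | None:
        return self.lumen_excess if reference == LUMEN else self.adjacent_excess

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "cohort": self.cohort,
            "group": self.group,
            "seed": self.seed,
            "lumen_excess": self.lumen_excess.to_dict() if self.lumen_excess else None,
            "adjacent_excess": self.adjacent_excess.to_dict() if self.adjacent_excess else None,
            "hotspots": self.hotspots.to_dict() if self.hotspots else None,
            "config": self.config,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _as_pattern(vessels, roi_set: RoiSet, config: dict) -> PointPattern:
    if isinstance(vessels, PointPattern):
        pattern = vessels
    elif isinstance(vessels, VesselSet):
        pattern = PointPattern(vessels.centroids_mm)
    elif isinstance(vessels, pd.DataFrame):
        if {"x_mm", "y_mm"} <= set(vessels.columns):
            pattern = PointPattern(vessels[["x_mm", "y_mm"]].to_numpy(dtype=float))
        else:
            pattern = PointPattern(
                vessels[["x_um", "y_um"]].to_numpy(dtype=float) / 1000.0
            )
    elif isinstance(vessels, np.ndarray) and vessels.ndim == 3:
        seg = config["segmentation"]
        vs = segment_image(
            vessels,
            seg["mpp"],
            close_radius=seg["close_radius"],
            min_area_um2=seg["min_area_um2"],
            max_area_um2=seg["max_area_um2"],
            min_od=seg["min_od"],
        )
        pattern = PointPattern(vs.centroids_mm)
    else:
        raise TypeError("vessels must be a PointPattern, VesselSet, DataFrame or RGB image")
    return roi_set.clip_pattern(pattern, TUMOR)


def analyze_sample(
    vessels,
    roi_set: RoiSet,
    *,
    sample_id: str = "sample",
    cohort: str = "first",
    group: str = "primary_untreated",
    config: dict | None = None,
    seed: int = 0,
) -> SampleResult:
    """Run every analysis stage on one sample.

    ``vessels`` may be a :class:`PointPattern` (mm), a :class:`VesselSet`,
    a vessel table (``x_mm/y_mm`` or ``x_um/y_um`` columns) or an RGB image
    to segment first.  The tumor ROI must be present and at least one of the
    two reference ROIs; missing references are tolerated and recorded as
    missing.  Fully determined by (inputs, config, seed).
    """
    cfg = merge_config(DEFAULTS, config)
    if TUMOR not in roi_set:
        raise LabelError("tumor ROI is required")
    references = [r for r in (LUMEN, ADJACENT) if r in roi_set]
    if not references:
        raise LabelError(
            f"no reference ROI (lumen or adjacent); available labels: {roi_set.labels}"
        )
    t0 = time.perf_counter()
    pattern = _as_pattern(vessels, roi_set, cfg)
    exc_cfg = cfg["excess"]
    tumor_geom = roi_set.geometry(TUMOR)

    # one set of null draws per sample, shared by both reference regions
    rng = derive_rng(seed, f"controls:{sample_id}")
    control_points = None
    if pattern.n_points >= exc_cfg["min_points"]:
        control_points = [
            sample_uniform_in_polygon(tumor_geom, pattern.n_points, rng)
            for _ in range(exc_cfg["n_controls"])
        ]

    profiles: dict[str, ExcessProfile | None] = {LUMEN: None, ADJACENT: None}
    for ref in references:
        try:
            profiles[ref] = excess_analysis(
                pattern,
                roi_set,
                ref,
                bin_width=exc_cfg["bin_width_mm"],
                n_controls=exc_cfg["n_controls"],
                control_points=control_points,
                ci_method=exc_cfg["ci_method"],
                significance_rule=exc_cfg["significance_rule"],
                min_points=exc_cfg["min_points"],
            )
        except DegenerateInputError as err:
            log.warning("sample %s not evaluable for %s: %s", sample_id, ref, err)

    kde = cfg["kde"]
    hotspots = None
    if pattern.n_points > 0:
        hotspots = hotspot_analysis(
            pattern,
            tumor_geom,
            bandwidth=kde["bandwidth_mm"],
            grid=kde["grid_mm"],
            n_reps=kde["n_reps"],
            alpha=kde["alpha"],
            seed=derive_seed(seed, f"kde:{sample_id}"),
        )
    log.info(
        "stage=analyze_sample sample_id=%s elapsed=%.2fs seed=%d n_vessels=%d",
        sample_id, time.perf_counter() - t0, seed, pattern.n_points,
    )
    return SampleResult(
        sample_id, cohort, group,
        profiles[LUMEN], profiles[ADJACENT], hotspots, seed, cfg,
    )


def cohort_table(results: list[SampleResult]) -> pd.DataFrame:
    """One row per (sample, reference) with excess and MVD metrics."""
    rows = []
    for res in results:
        for ref in (LUMEN, ADJACENT):
            prof = res.excess_for(ref)
            if prof is None:
                continue
            hs = res.hotspots
            rows.append(
                {
                    "sample_id": res.sample_id,
                    "cohort": res.cohort,
                    "group": res.group,
                    "reference": ref,
                    "A": prof.mass,
                    "A_corrected": prof.excess_corrected,
                    "ci_low": prof.ci[0],
                    "ci_high": prof.ci[1],
                    "significant": prof.significant,
                    "direction": prof.direction,
                    "x0_mm": prof.x0,
                    "bin_width_mm": prof.bin_width,
                    "n_vessels": prof.n_points,
                    "overall_mvd": hs.overall_mvd if hs else np.nan,
                    "in_hotspot_mvd": (
                        hs.in_hotspot_mvd if hs and hs.in_hotspot_mvd is not None else np.nan
                    ),
                    "hotspot_density": hs.hotspot_density if hs else np.nan,
                    "n_hotspots": hs.n_hotspots if hs else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _t_test(a: np.ndarray, b: np.ndarray, kind: str = "student"):
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        return None
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if np.mean(a) == np.mean(b):
            return {"t": 0.0, "p": 1.0, "df": len(a) + len(b) - 2}
        return None
    res = stats.ttest_ind(a, b, equal_var=(kind == "student"))
    df = len(a) + len(b) - 2 if kind == "student" else float(res.df)
    return {"t": float(res.statistic), "p": float(res.pvalue), "df": df}


def cohort_summary(results: list[SampleResult], config: dict | None = None):
    """Group-level statistics for a cohort of analyzed samples.

    Returns ``(table, summary)`` where ``table`` is the per-(sample,
    reference) table and ``summary`` holds per-group mean +/- SD of excess
    mass / zone width / MVD metrics, the fraction of significant positive
    excesses, Student's t-tests between primaries and metastases (excess
    mass at the invasion front, hotspot density, overall MVD) and the Pearson
    correlation between overall and in-hotspot MVD.
    """
    cfg = merge_config(DEFAULTS, config)["cohort"]
    table = cohort_table(results)
    summary: dict = {"groups": {}, "tests": {}, "correlations": {}}
    if table.empty:
        return table, summary

    for (group, ref), sub in table.groupby(["group", "reference"]):
        sig_pos = sub[sub["significant"] & (sub["direction"] == "positive")]
        summary["groups"][f"{group}:{ref}"] = {
            "n": int(len(sub)),
            "mean_A": float(sub["A"].mean()),
            "sd_A": float(sub["A"].std(ddof=1)) if len(sub) > 1 else 0.0,
            "mean_x0_mm": float(sub["x0_mm"].mean()),
            "sd_x0_mm": float(sub["x0_mm"].std(ddof=1)) if len(sub) > 1 else 0.0,
            "frac_significant_positive": float(len(sig_pos) / len(sub)),
            "mean_sig_pos_A": float(sig_pos["A"].mean()) if len(sig_pos) else None,
            "mean_sig_pos_x0_mm": float(sig_pos["x0_mm"].mean()) if len(sig_pos) else None,
        }

    per_sample = table.drop_duplicates("sample_id")
    for group, sub in per_sample.groupby("group"):
        summary["groups"].setdefault(f"{group}:mvd", {}).update(
            {
                "n": int(len(sub)),
                "mean_overall_mvd": float(sub["overall_mvd"].mean()),
                "sd_overall_mvd": float(sub["overall_mvd"].std(ddof=1)) if len(sub) > 1 else 0.0,
                "mean_hotspot_density": float(sub["hotspot_density"].mean()),
                "sd_hotspot_density": (
                    float(sub["hotspot_density"].std(ddof=1)) if len(sub) > 1 else 0.0
                ),
            }
        )

    prim = per_sample[per_sample["group"] == "primary_untreated"]
    met = per_sample[per_sample["group"] == "metastasis"]
    if len(prim) >= 2 and len(met) >= 2:
        for metric in ("overall_mvd", "hotspot_density"):
            test = _t_test(prim[metric].dropna(), met[metric].dropna(), cfg["t_test"])
            if test is not None:
                summary["tests"][f"primary_vs_metastasis:{metric}"] = test
        adj = table[table["reference"] == ADJACENT]
        test = _t_test(
            adj[adj["group"] == "primary_untreated"]["A"],
            adj[adj["group"] == "metastasis"]["A"],
            cfg["t_test"],
        )
        if test is not None:
            summary["tests"]["primary_vs_metastasis:adjacent_A"] = test

    mvd = per_sample[["overall_mvd", "in_hotspot_mvd"]].dropna()
    if len(mvd) >= 3 and mvd["overall_mvd"].std() > 0 and mvd["in_hotspot_mvd"].std() > 0:
        r, p = stats.pearsonr(mvd["overall_mvd"], mvd["in_hotspot_mvd"])
        summary["correlations"]["overall_vs_in_hotspot_mvd"] = {
            "r": float(r), "p": float(p), "n": int(len(mvd)),
        }
    return table, summary


def waterfall_export(table: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Rows for one reference region, sorted by excess mass descending within group.

    Non-significant rows keep ``significant == False`` (rendered as "ns").
    """
    if table.empty:
        raise ValueError("empty cohort table")
    sub = table[table["reference"] == reference]
    sub = sub.sort_values(["group", "A"], ascending=[True, False], kind="mergesort")
    cols = ["sample_id", "group", "A", "ci_low", "ci_high", "significant", "x0_mm"]
    return sub[cols].reset_index(drop=True)


def count_validation(auto_counts, observer_counts) -> pd.DataFrame:
    """Pairwise Pearson correlations between raters and the automatic counts.

    ``observer_counts`` is (n_patches, n_observers); the automatic counts are
    additionally compared with the mean over observers.  Zero-variance raters
    yield ``NaN`` for the affected pairs.
    """
    auto = np.asarray(auto_counts, dtype=float)
    obs = np.asarray(observer_counts, dtype=float)
    if obs.ndim != 2:
        raise ValueError("observer_counts must be (n_patches, n_observers)")
    if len(auto) != len(obs):
        raise ValueError("auto and observer counts must cover the same patches")
    if len(auto) < 3:
        raise ValueError("need at least 3 patches")

    def _r(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(stats.pearsonr(x, y)[0])

    rows = []
    n_obs = obs.shape[1]
    for i in range(n_obs):
        for j in range(i + 1, n_obs):
            rows.append(
                {"pair": f"observer_{i + 1}_vs_observer_{j + 1}", "r": _r(obs[:, i], obs[:, j])}
            )
    rows.append({"pair": "automatic_vs_observer_mean", "r": _r(auto, obs.mean(axis=1))})
    return pd.DataFrame(rows)
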