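"""Run configuration: defaults, YAML overrides and echo into results."""

from __future__ import annotations

import copy

import yaml

__all__ = ["DEFAULTS", "load_config", "merge_config"]

DEFAULTS: dict = {
    "segmentation": {
        "mpp": 0.5,              # um / pixel
        "close_radius": 1,       # px, dilation-erosion structuring disk
        "min_area_um2": 16.0,
        "max_area_um2": 1.0e5,
        "min_od": 0.15,          # DAB OD floor under the Otsu threshold
    },
    "excess": {
        "bin_width_mm": 0.1,
        "n_controls": 100,
        "ci_method": "percentile",        # or "t"
        "significance_rule": "mc_rank",   # or "ci" (interval excludes zero)
        "min_points": 10,
    },
    "kde": {
        "bandwidth_mm": 0.3,
        "grid_mm": 0.05,
        "n_reps": 50,
        "alpha": 0.05,
    },
    "cohort": {
        "t_test": "student",     # pooled-variance; "welch" available
        "alpha": 0.05,
    },
}


def merge_config(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Defaults, optionally overridden by a YAML file with the same sections."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(DEFAULTS, user)
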