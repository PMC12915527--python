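"""Run configuration: defaults, YAML loading, strict key validation.

Defaults are the thresholds the analysis is defined by: induced peaks at
L2FC > 2 and FDR < 0.01, persistence at L2FC >= 0 and FDR < 0.01, gene
induction at 5-fold, potentiation at 5-fold induction plus a 2-fold arm
difference at 2 contiguous timepoints (4-fold induction gate in the
ruxolitinib-conditioned design), basal split at L2FC 0.5, and linkage at
+/-20 kb of a TSS excluding +/-1 kb promoters.  Unknown keys are rejected so
a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["ConfigError", "default_config", "load_config", "merge_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration keys."""


def default_config() -> dict:
    return {
        "seed": 0,
        "paths": {
            "peaks_bed": None,
            "peak_counts": None,
            "peak_design": None,
            "gene_counts": None,
            "gene_design": None,
            "tss": None,
        },
        "conditions": {
            "unstim": "UNSTIM",
            "stims": ["IFNG_8H", "LPS_8H", "LPS_RUX_8H"],
            "washout": {
                "media": "WASH_MEDIA",
                "rux": "WASH_RUX",
                "anti_ifng": "WASH_AIFNG",
            },
            "gene_unstim": "UNSTIM",
            "gene_stim": "IFNG_8H",
            "gene_washout": {"media": "WASH_MEDIA", "rux": "WASH_RUX"},
            "restim_template": "{arm}_LPS_{t:g}H",
            "restim_arms": ["PBS", "IFNG", "PBS_RUX"],
            "restim_grid": [0, 1, 3, 6, 12],
        },
        "pseudocount": {"policy": "percentile_1_per_condition", "percentile": 1.0},
        "filter": {
            "percentile": 0.5,
            "acute_conditions": ["UNSTIM", "IFNG_8H", "LPS_8H"],
        },
        "differential": {"l2fc_min": 2.0, "fdr_max": 0.01, "shrinkage_weight": 0.7},
        "durability": {
            "k": 3,
            "seed": 0,
            "stim_condition": "IFNG_8H",
            "persistence": {"l2fc_min": 0.0, "fdr_max": 0.01},
        },
        "memory": {
            "fold_min": 5.0,
            "lps_fold_min": 5.0,
            "delta_fold_min": 2.0,
            "contiguous": 2,
            "basal_l2fc": 0.5,
            "reduction_fold_min": 2.0,
            "rux_induction_min": 4.0,
            "pbs_arm": "PBS",
            "ifng_arm": "IFNG",
            "rux_arm": "PBS_RUX",
        },
        "linkage": {"window": 20000, "promoter_window": 1000},
    }


def merge_config(base: dict, override: dict, _path: str = "") -> dict:
    """Deep-merge ``override`` into ``base``; unknown keys raise ConfigError."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{_path}.{key}" if _path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = merge_config(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config merged over the defaults (None -> pure defaults)."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return merge_config(cfg, user)
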