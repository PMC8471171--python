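"""Run configuration: study-default thresholds and YAML round-trip."""

from __future__ import annotations

import copy

import yaml

__all__ = ["DEFAULTS", "load_config", "dump_default_config"]

# stage parameters; the thresholds reproduce the study defaults
DEFAULTS: dict = {
    "seed": 0,
    "simulate": {
        "n_genes": 200,
        "n_cpg_per_promoter": 8,
        "n_per_group": 20,
        "delta_beta_effect": 0.3,
        "log2fc_effect": 1.5,
        "beta_noise_sd": 0.5,
        "expr_noise_sd": 0.5,
        "quadrant_proportions": {
            "hyper_up": 0.10, "hyper_down": 0.05,
            "hypo_up": 0.05, "hypo_down": 0.05,
        },
    },
    "knockdown": {
        "n_cell_lines": 3,
        "n_genes": 200,
        "n_down_consistent": 10,
        "per_line_extra_down": 5,
        "log2fc_effect": 1.5,
        "n_per_group": 5,
        "noise_sd": 0.3,
    },
    "methylation": {"p_adj": 0.05, "min_abs_delta_beta": 0.1},
    "expression": {"p_adj": 0.01, "min_abs_log2fc": 0.5},
    "tf_screen": {
        "sd_multiplier": 4.0,
        "ratio_cutoff": 2.0,
        "top_k": 15,
        "expression_floor": 1.0,
    },
    "motif": {"p_threshold": 1.0e-4, "granularity": 1.0e-3},
    "gsea": {
        "weight": 1.0, "n_perm": 1000,
        "min_nes": 1.0, "max_p": 0.05, "max_q": 0.25,
    },
    "fisher": {"p_adj": 0.05},
    "validation": {"conversion_pass_pct": 95.0, "replicate_combine": "mean"},
    "log_level": "INFO",
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown configuration key: {here!r}")
        if isinstance(base[key], dict) and isinstance(val, dict) \
                and key != "quadrant_proportions":
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid by a YAML file, overlaid by explicit overrides.

    Unknown keys are rejected so typos cannot silently revert a
    threshold to its default.
    """
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def dump_default_config(path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(DEFAULTS, fh, sort_keys=False)
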