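"""Declarative run configuration for the pipeline CLI.

Defaults encode the reference workflow settings: 1.5 kb promoters, motif
widths 6-10 with at most 10 motifs per width, the GGCWWW / SYGGRG selection
consensi, multi-site scan thresholds 6.2 (activator matrix) and 8.0
(repressor matrix), the 6.1-6.6 enrichment sweep, the 6.4 promoter-map
threshold, and the stringent genome-scan thresholds 6.6 / 9.2.  A resolved
copy of the config is written beside every run's outputs.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 1,
    "paths": {
        "genome": None,
        "annotation": None,
        "annotation_dialect": "tsv",
        "gene_lists": None,
        "category_map": None,
        "motifs": None,
    },
    "promoter_length": 1500,
    "discovery": {
        "width_min": 6,
        "width_max": 10,
        "n_motifs": 10,
        "seeds_per_width": 5,
        "max_iter": 100,
        "tol": 1.0e-6,
    },
    "consensus_patterns": {
        "activator": "GGCWWW",
        "repressor": "SYGGRG",
    },
    "matrix": {
        "window_start": 0,
        "window_end": None,  # null = full motif width
        "pseudocount": 0.25,
    },
    "thresholds": {
        "single": 6.2,
        "promoter_map": 6.4,
        "stringent": 6.6,
        "sweep": [6.1, 6.2, 6.3, 6.4, 6.5, 6.6],
    },
    "architecture": {
        "orientations": ["inverted", "everted"],
        "gap_min": 8,
        "gap_max": 30,
    },
    "bootstrap_B": 200,
    "simulate": {
        "n_fg": 50,
        "n_bg": 2000,
        "length": 1500,
        "consensus": "GGCTAAAT",
        "sharpness": 0.95,
        "orientation": "everted",
        "gap_min": 8,
        "gap_max": 30,
        "fg_rate": 0.6,
        "bg_rate": 0.1,
        "fixed_atg_start": None,
    },
}


def _deep_update(base: dict, extra: dict) -> dict:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a YAML file and dot-path overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        _deep_update(cfg, user)
    for dotted, value in (overrides or {}).items():
        node = cfg
        *parents, leaf = dotted.split(".")
        for p in parents:
            node = node.setdefault(p, {})
        node[leaf] = yaml.safe_load(value) if isinstance(value, str) else value
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
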