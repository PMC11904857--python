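"""End-to-end driver: simulate cohorts, analyze each cell, compare groups.

The run configuration is a plain mapping (typically loaded from YAML/JSON).
Unknown keys are rejected.  Outputs are deterministic under a fixed
(config, seed): the provenance manifest carries the package version, the
seed, and a hash of the canonicalized config, and contains no timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ap import ap_parameters
from .calcium import segment_and_average, transient_parameters
from .errors import CmquantError, ConfigError
from .morphometry import analyze_profile, extract_profile
from .presets import (APTargets, GatingPreset, StriationGeometry,
                      TransientTargets)
from .sodium import analyze_inact_family, analyze_na_family
from .stats import compare_groups
from .synth import MODALITIES, CohortVariability, make_cohort

__all__ = ["build_group_presets", "analyze_cell", "cohort_table",
           "run_pipeline", "config_hash"]

_TOP_KEYS = {"seed", "n_cells", "modalities", "groups", "noise_sd",
             "variability", "out_dir", "v_rev"}
_GROUP_KEYS = {"label", "gating", "ap", "ca", "image"}

# fixed per-modality seed offsets keep modalities statistically independent
_MODALITY_OFFSET = {m: 10_000 * (i + 1) for i, m in enumerate(MODALITIES)}

_DEFAULT_NOISE = {"na": 0.02, "inact": 0.02, "ap": 0.5, "ca": 0.02,
                  "image": 0.0}


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _merged(cls, overrides: dict | None, label: str):
    overrides = dict(overrides or {})
    overrides["label"] = label
    try:
        return cls(**overrides)
    except TypeError as exc:
        raise ConfigError(f"bad {cls.__name__} overrides: {exc}") from exc


def build_group_presets(group_cfg: dict, modality: str):
    """Materialize the generator preset of one group for one modality."""
    unknown = set(group_cfg) - _GROUP_KEYS
    if unknown:
        raise ConfigError(f"unknown group keys: {sorted(unknown)}")
    label = group_cfg.get("label")
    if not label:
        raise ConfigError("each group needs a label")
    if modality in ("na", "inact"):
        return _merged(GatingPreset, group_cfg.get("gating"), label)
    if modality == "ap":
        return _merged(APTargets, group_cfg.get("ap"), label)
    if modality == "ca":
        return _merged(TransientTargets, group_cfg.get("ca"), label)
    if modality == "image":
        geo = dict(group_cfg.get("image") or {})
        for key in ("image_size", "channel_gains", "channel_kinds",
                    "channel_labels"):
            if key in geo:
                geo[key] = tuple(geo[key])
        return _merged(StriationGeometry, geo, label)
    raise ConfigError(f"unknown modality {modality!r}")


def analyze_cell(recording, modality: str, v_rev: float | None = None) -> dict:
    """Dispatch one cell's recording to its analysis stage; flat dict out."""
    if modality == "na":
        return analyze_na_family(recording, v_rev=v_rev)
    if modality == "inact":
        return analyze_inact_family(recording)
    if modality == "ap":
        return ap_parameters(recording).to_dict()
    if modality == "ca":
        return transient_parameters(segment_and_average(recording)).to_dict()
    if modality == "image":
        rows = recording.channels.shape[1]
        cols = recording.channels.shape[2]
        line = ((rows // 2, 0), (rows // 2, cols - 1))
        profile = extract_profile(recording, line)
        res = analyze_profile(profile, image=recording)
        return res.to_dict()
    raise ConfigError(f"unknown modality {modality!r}")


def cohort_table(cohorts: list, modality: str,
                 v_rev: float | None = None) -> pd.DataFrame:
    """Per-cell analysis rows for a list of cohorts (one per group)."""
    rows = []
    for cohort in cohorts:
        for i, cell in enumerate(cohort.cells):
            row = {"cell_id": f"{cohort.group_label}_{i:03d}",
                   "group": cohort.group_label, "modality": modality}
            row.update(analyze_cell(cell, modality, v_rev=v_rev))
            rows.append(row)
    return pd.DataFrame(rows)


def _long_format(cells: pd.DataFrame) -> pd.DataFrame:
    skip = {"cell_id", "group", "modality", "flags", "censored",
            "n_beats_averaged", "n_periods_used"}
    value_cols = [c for c in cells.columns if c not in skip
                  and pd.api.types.is_numeric_dtype(cells[c])]
    return cells.melt(id_vars=["cell_id", "group"], value_vars=value_cols,
                      var_name="parameter", value_name="value")


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run simulate -> analyze -> compare for every configured modality.

    Returns {"cells": {modality: DataFrame}, "comparisons": {modality:
    DataFrame}, "manifest": dict, "errors": {modality: message}}.  When
    ``out_dir`` is given, per-modality CSVs and ``manifest.json`` are
    written there.
    """
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    modalities = config.get("modalities") or []
    if not modalities:
        raise ConfigError("config.modalities must be a non-empty list")
    groups = config.get("groups") or []
    if len(groups) < 2:
        raise ConfigError("config.groups needs at least two entries")
    seed = int(config.get("seed", 0))
    n_cells = int(config.get("n_cells", 10))
    noise = dict(_DEFAULT_NOISE, **(config.get("noise_sd") or {}))
    var_cfg = config.get("variability") or {}
    variability = CohortVariability(cv=float(var_cfg.get("cv", 0.05)),
                                    voltage_sd=float(var_cfg.get("voltage_sd",
                                                                 1.0)))
    v_rev = config.get("v_rev")

    out = Path(out_dir or config.get("out_dir") or ".")
    bundle = {"cells": {}, "comparisons": {}, "errors": {}}
    for modality in modalities:
        try:
            presets = [build_group_presets(g, modality) for g in groups]
            cohorts = make_cohort(presets, n_cells, modality,
                                  seed=seed + _MODALITY_OFFSET[modality],
                                  noise_sd=noise[modality],
                                  variability=variability)
            cells = cohort_table(cohorts, modality, v_rev=v_rev)
            comparisons = compare_groups(
                _long_format(cells),
                groups=(cohorts[0].group_label, cohorts[1].group_label))
            bundle["cells"][modality] = cells
            bundle["comparisons"][modality] = pd.DataFrame(
                [c.to_dict() for c in comparisons])
        except CmquantError as exc:
            bundle["errors"][modality] = f"{type(exc).__name__}: {exc}"

    manifest = {
        "software": "cmquant",
        "version": __version__,
        "seed": seed,
        "n_cells": n_cells,
        "modalities": list(modalities),
        "groups": [g.get("label") for g in groups],
        "config_hash": config_hash(config),
        "errors": bundle["errors"],
    }
    bundle["manifest"] = manifest

    if out_dir is not None or config.get("out_dir"):
        out.mkdir(parents=True, exist_ok=True)
        for modality, df in bundle["cells"].items():
            df.to_csv(out / f"cells_{modality}.csv", index=False,
                      float_format="%.8g")
        for modality, df in bundle["comparisons"].items():
            df.to_csv(out / f"comparisons_{modality}.csv", index=False,
                      float_format="%.8g")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return bundle
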