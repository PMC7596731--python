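"""Named scenario presets and reproducible scenario execution.

Each preset expands to a fully explicit configuration (topology, parameter
overrides, axes, observables).  ``run_scenario`` writes tidy CSV outputs and
a JSON manifest recording every parameter, the seed and the package version;
re-running a manifest of a deterministic scenario reproduces the CSV bytes.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np

from .network import build_network
from .observables import observable_table
from .params import ParameterSet
from .solver import sweep

__all__ = ["PRESETS", "expand_config", "run_scenario", "ConfigError"]


class ConfigError(ValueError):
    pass


_SUCC_GRID = list(np.round(np.geomspace(1.0, 5000.0, 60), 6))

#: figure-condition presets (axis values and overrides follow the study design)
PRESETS: dict[str, dict] = {
    "fig2_aa5": {
        "topology": "assembled_only",
        "overrides": {"CIIt": 235.0, "succ": 100.0, "kf29": 1.0},
        "axes": [{"axis": "AA5", "values": [0.0, 0.05, 0.1, 0.15, 0.25]}],
        "observables": ["vH2O2tot", "v20", "v22", "v28"],
    },
    "fig3_sites": {
        "topology": "assembled_only",
        "overrides": {"CIIt": 235.0, "kf29": 1.0},
        "axes": [
            {"axis": "succinate", "values": _SUCC_GRID, "at": {"aa5": a}}
            for a in (0.0, 0.05, 0.15, 0.25)
        ],
        "observables": ["v22", "v23", "v24", "v25", "v26", "vH2O2tot", "v20"],
    },
    "fig4_ciii": {
        "topology": "assembled_only",
        "overrides": {"CIIt": 97.0, "aa5": 0.0, "kf29": 0.005},
        "axes": [{"axis": "succinate", "values": _SUCC_GRID}],
        "observables": ["vH2O2tot", "v22", "v23", "v20"],
    },
    "fig5_flux": {
        "topology": "assembled_only",
        "overrides": {"CIIt": 235.0},
        "axes": [
            {"axis": "succinate", "values": _SUCC_GRID, "at": {"kf29": k}}
            for k in (1.0, 0.1, 0.01)
        ],
        "observables": ["v20", "v6", "v23"],
        "flux_splits": ["6", "23"],
    },
    "fig6_hemeb": {
        "topology": "assembled_only",
        "overrides": {"CIIt": 235.0},
        "axes": [
            {"axis": "succinate", "values": _SUCC_GRID, "at": {"em_b": em}}
            for em in (-185.0, 36.0)
        ],
        "observables": ["b_red", "v20", "vH2O2tot", "v8", "v16"],
    },
    "fig7_mixed": {
        "topology": "mixed",
        "overrides": {"CIIt": 100.0, "ABt": 135.0, "CDt": 135.0, "aa5": 0.0},
        "axes": [{"axis": "succinate", "values": _SUCC_GRID}],
        "observables": ["v22", "v22d", "v22total", "v23", "v23d", "v23total",
                        "v24", "v25", "v26", "vH2O2tot"],
    },
}

_ALLOWED_KEYS = {"preset", "topology", "overrides", "axes", "observables",
                 "flux_splits", "seed", "out_dir"}


def expand_config(config: dict) -> dict:
    """Expand a preset name into a fully explicit configuration."""
    unknown = set(config) - _ALLOWED_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    out = dict(config)
    preset = out.pop("preset", None)
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            )
        base = json.loads(json.dumps(PRESETS[preset]))  # deep copy
        base["overrides"] = {**base.get("overrides", {}),
                             **out.get("overrides", {})}
        for key in ("topology", "axes", "observables", "flux_splits",
                    "seed", "out_dir"):
            if key in out:
                base[key] = out[key]
        out = base
        out["preset"] = preset
    out.setdefault("topology", "assembled_only")
    out.setdefault("overrides", {})
    out.setdefault("observables", ["vH2O2tot", "v20"])
    if not out.get("axes"):
        raise ConfigError("configuration defines no sweep axes")
    for ax in out["axes"]:
        if not ax.get("values"):
            raise ConfigError(f"axis {ax.get('axis')!r} has an empty value list")
    return out


def run_scenario(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute a (possibly preset) scenario; returns the manifest dict."""
    cfg = expand_config(config)
    out = Path(out_dir or cfg.get("out_dir") or ".")
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:  # fail on unwritable output before any computation
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise ConfigError(f"output directory {out} is not writable: {exc}")

    params = ParameterSet(**cfg["overrides"])
    network = build_network(cfg["topology"], params)
    try:
        pkg_version = version("ciiros")
    except PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"
    manifest = {
        "config": cfg,
        "parameters": params.to_dict(),
        "seed": cfg.get("seed"),
        "version": pkg_version,
        "outputs": [],
    }
    base = cfg.get("preset", "scenario")
    for i, ax in enumerate(cfg["axes"]):
        p = params.copy(**ax.get("at", {}))
        sw = sweep(network, p, ax["axis"], ax["values"])
        table = observable_table(sw, cfg["observables"])
        for key, val in ax.get("at", {}).items():
            table.insert(1, key, val)
        fname = out / f"{base}_axis{i}_{ax['axis']}.csv"
        table.to_csv(fname, index=False)
        manifest["outputs"].append(str(fname))
    mpath = out / f"{base}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    manifest["manifest_path"] = str(mpath)
    return manifest
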