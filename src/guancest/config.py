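"""Pipeline configuration: one YAML document covering acquisition, effect
calibration, PLOF recipe, DFA protocol, cohort sizing and statistics options.

Every run writes the fully resolved configuration next to its outputs, so a
result file is always traceable to a (config, seed) pair.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from . import synthetic_data as sd
from .atlas import ALL_REGIONS
from .t1_mapping import DFAAcquisition
from .zspectrum_fitting import PLOFConfig


def default_config() -> dict:
    acq = sd.AcquisitionConfig()
    plof = PLOFConfig()
    dfa = DFAAcquisition()
    eff = sd.EffectConfig()
    return {
        "cohort": {"n_pwpd": 25, "n_hc": 24, "seed": 42},
        "acquisition": {
            "offsets_ppm": [float(o) for o in acq.offsets_ppm],
            "b1_uT": acq.b1_uT, "tsat_s": acq.tsat_s,
            "voxel_mm": list(acq.voxel_mm), "noise_sd": acq.noise_sd,
        },
        "effect": {
            "between_subject_sd_pct": eff.between_subject_sd_pct,
            "between_subject_sd_amide_pct": eff.between_subject_sd_amide_pct,
            "association_mode": eff.association_mode,
            "severity_center": eff.severity_center,
            "severity_scale": eff.severity_scale,
            "regions": {k: dataclasses.asdict(v) for k, v in eff.regions.items()},
        },
        "plof": {
            "fit_window_ppm": list(plof.fit_window_ppm),
            "peak_exclusion_bands_ppm": [list(b) for b in plof.peak_exclusion_bands_ppm],
            "poly_order": plof.poly_order,
            "guan_center_init": plof.guan_center_init,
            "guan_center_halfwidth": plof.guan_center_halfwidth,
            "amide_center_init": plof.amide_center_init,
            "amide_center_halfwidth": plof.amide_center_halfwidth,
            "guan_width_bounds_ppm": list(plof.guan_width_bounds_ppm),
            "amide_width_bounds_ppm": list(plof.amide_width_bounds_ppm),
            "max_amplitude": plof.max_amplitude,
        },
        "dfa": {"tr_ms": dfa.tr_ms, "flip_deg_low": dfa.flip_deg_low,
                "flip_deg_high": dfa.flip_deg_high},
        "phantom": {"regions": list(ALL_REGIONS), "blob_shape": [5, 6, 7]},
        "stats": {"alpha": 0.05, "fence_multiplier": 1.5, "fixed_age": 67.7,
                  "csf_threshold_fraction": 0.25},
    }


def _deep_update(base: dict, override: dict) -> dict:
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path=None) -> dict:
    """Defaults, overridden by an optional YAML file."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        _deep_update(cfg, user)
    return cfg


def dump_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


# --- resolution into typed objects -----------------------------------------

def make_acquisition(cfg: dict) -> sd.AcquisitionConfig:
    a = cfg["acquisition"]
    return sd.AcquisitionConfig(
        offsets_ppm=tuple(a["offsets_ppm"]), b1_uT=a["b1_uT"], tsat_s=a["tsat_s"],
        voxel_mm=tuple(a["voxel_mm"]), noise_sd=a["noise_sd"])


def make_effect(cfg: dict) -> sd.EffectConfig:
    e = cfg["effect"]
    regions = {name: sd.RegionEffect(**params) for name, params in e["regions"].items()}
    return sd.EffectConfig(
        regions=regions, between_subject_sd_pct=e["between_subject_sd_pct"],
        between_subject_sd_amide_pct=e["between_subject_sd_amide_pct"],
        association_mode=e["association_mode"], severity_center=e["severity_center"],
        severity_scale=e["severity_scale"])


def make_plof(cfg: dict) -> PLOFConfig:
    p = cfg["plof"]
    return PLOFConfig(
        fit_window_ppm=tuple(p["fit_window_ppm"]),
        peak_exclusion_bands_ppm=tuple(tuple(b) for b in p["peak_exclusion_bands_ppm"]),
        poly_order=p["poly_order"],
        guan_center_init=p["guan_center_init"],
        guan_center_halfwidth=p["guan_center_halfwidth"],
        amide_center_init=p["amide_center_init"],
        amide_center_halfwidth=p["amide_center_halfwidth"],
        guan_width_bounds_ppm=tuple(p["guan_width_bounds_ppm"]),
        amide_width_bounds_ppm=tuple(p["amide_width_bounds_ppm"]),
        max_amplitude=p["max_amplitude"])


def make_dfa(cfg: dict) -> DFAAcquisition:
    d = cfg["dfa"]
    return DFAAcquisition(tr_ms=d["tr_ms"], flip_deg_low=d["flip_deg_low"],
                          flip_deg_high=d["flip_deg_high"])
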