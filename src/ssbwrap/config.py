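"""Structured-text configuration for polymer, instrument and model defaults.

Configuration files are TOML with ``[dsdna]``, ``[ssdna]``, ``[instrument]``
and ``[landscape]`` sections; every key falls back to the package default,
so an empty file is valid.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict

from ssbwrap.landscape import EnergyLandscape
from ssbwrap.polymer import PolymerParams, SnakeLikeChain


class ConfigError(ValueError):
    """Malformed configuration; the message lists the offending keys."""


_DSDNA_KEYS = {"persistence_length_nm": "dsdna_persistence_length",
               "stretch_modulus_pn": "dsdna_stretch_modulus",
               "contour_per_bp_nm": "dsdna_contour_per_bp",
               "thermal_energy_pn_nm": "thermal_energy",
               "temperature_k": "temperature"}
_SSDNA_KEYS = {"anchor_force_pn": "anchor_force",
               "anchor_extension_nm_nt": "anchor_extension",
               "ref_force_pn": "ref_force",
               "ref_extension_nm_nt": "ref_extension",
               "crossover_force_pn": "crossover_force"}
_INSTRUMENT_DEFAULTS = {
    "native_rate_hz": 66000.0,
    "analysis_rate_hz": 10.0,
    "trap_stiffness_pn_nm": 0.3,
    "ramp_speed_nm_s": 65.0,
    "noise_sd_nm": 25.0,
}


def load_config(path=None) -> dict:
    """Parse a TOML config into polymer params, instrument dict and landscape.

    Returns ``{"params": PolymerParams, "instrument": dict,
    "landscape": EnergyLandscape}``.
    """
    raw = {}
    if path is not None:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)

    bad = []
    ss_kwargs = {}
    for key, val in raw.get("ssdna", {}).items():
        if key not in _SSDNA_KEYS:
            bad.append(f"ssdna.{key}")
        else:
            ss_kwargs[_SSDNA_KEYS[key]] = val
    poly_kwargs = {}
    for key, val in raw.get("dsdna", {}).items():
        if key not in _DSDNA_KEYS:
            bad.append(f"dsdna.{key}")
        else:
            poly_kwargs[_DSDNA_KEYS[key]] = val
    instrument = dict(_INSTRUMENT_DEFAULTS)
    for key, val in raw.get("instrument", {}).items():
        if key not in instrument:
            bad.append(f"instrument.{key}")
        else:
            instrument[key] = val
    known_landscape = {"states", "barriers_kbt", "barrier_x_nm", "k0_per_s", "x_ssb_nm"}
    for key in raw.get("landscape", {}):
        if key not in known_landscape:
            bad.append(f"landscape.{key}")
    for section in raw:
        if section not in ("dsdna", "ssdna", "instrument", "landscape"):
            bad.append(section)
    if bad:
        raise ConfigError("unknown configuration keys: " + ", ".join(sorted(bad)))

    params = PolymerParams(ssdna=SnakeLikeChain(**ss_kwargs), **poly_kwargs)
    ls_raw = raw.get("landscape", {})
    landscape = EnergyLandscape.reference(params)
    if "states" in ls_raw:
        landscape.energies = {int(k): float(v) for k, v in ls_raw["states"].items()}
    if "k0_per_s" in ls_raw:
        landscape.k0 = float(ls_raw["k0_per_s"])
    if "x_ssb_nm" in ls_raw:
        landscape.x_ssb = {int(k): float(v) for k, v in ls_raw["x_ssb_nm"].items()}
    if "barriers_kbt" in ls_raw:
        landscape.barriers = {tuple(int(x) for x in k.split("/")): float(v)
                              for k, v in ls_raw["barriers_kbt"].items()}
    if "barrier_x_nm" in ls_raw:
        landscape.barrier_x = {tuple(int(x) for x in k.split("/")): float(v)
                               for k, v in ls_raw["barrier_x_nm"].items()}
    return {"params": params, "instrument": instrument, "landscape": landscape}


def default_config_text() -> str:
    """Render the embedded defaults as a commented TOML snippet."""
    params = PolymerParams()
    lines = ["[dsdna]"]
    inv = {v: k for k, v in _DSDNA_KEYS.items()}
    for field_name, value in asdict(params).items():
        if field_name in inv:
            lines.append(f"{inv[field_name]} = {value}")
    lines.append("\n[ssdna]")
    inv_ss = {v: k for k, v in _SSDNA_KEYS.items()}
    for field_name, value in asdict(params.ssdna).items():
        if field_name in inv_ss:
            lines.append(f"{inv_ss[field_name]} = {value}")
    lines.append("\n[instrument]")
    for k, v in _INSTRUMENT_DEFAULTS.items():
        lines.append(f"{k} = {v}")
    return "\n".join(lines) + "\n"
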