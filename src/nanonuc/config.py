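"""Configuration files, unit handling, manifests and serialization.

Config files are flat key/value YAML with unit-suffixed keys (e.g.
``R20_nm: 140``).  Units are converted to SI at this boundary only — the
core modules are SI-only.  Unknown keys are a hard error.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import yaml

from . import eos, fieldmap, interfaces
from .constants import P_ATM
from .errors import ConfigError

#: key -> (SI conversion factor or None for pass-through, default, description)
SCHEMA: dict[str, tuple[float | None, object, str]] = {
    # droplet
    "R20_nm": (1e-9, 140.0, "initial droplet radius"),
    "sigma2_mN_per_m": (1e-3, 56.0, "droplet-tissue interfacial tension"),
    "T0_K": (1.0, 310.0, "working temperature"),
    "K2_GPa": (1e9, 2.2, "droplet bulk modulus"),
    "laplace_factor": (None, 1.0, "Laplace prefactor (1 = sigma2/R20)"),
    # tissue
    "K3_MPa": (1e6, 0.0, "tissue bulk modulus"),
    "G_MPa": (1e6, None, "tissue shear modulus (overrides K3 via K3 = 4G/3)"),
    "Pc_conf_kPa": (1e3, 0.0, "static confinement pressure"),
    # drive
    "f_MHz": (1e6, 5.0, "ultrasound frequency"),
    "tau_divisor": (None, 10.0, "nucleation window tau = 1/(tau_divisor*f)"),
    "include_gas": (None, True, "include dissolved-gas partial pressure"),
    "include_elastic_barrier": (None, True, "use the confined work barrier"),
    "P0_kPa": (1e3, P_ATM / 1e3, "ambient pressure"),
    # fluid overrides
    "Psat_kPa": (1e3, 135.0, "saturation vapor pressure at T0"),
    "Tc_K": (1.0, 420.0, "critical temperature"),
    "Pc_crit_MPa": (1e6, 2.045, "critical pressure"),
    "molar_mass_g_per_mol": (1e-3, 288.03, "molar mass"),
    # transducer / field grid
    "roc_mm": (1e-3, 60.0, "bowl radius of curvature"),
    "aperture_mm": (1e-3, 60.0, "bowl aperture diameter"),
    "source_pressure_MPa": (1e6, 0.1, "source surface pressure amplitude"),
    "sound_speed_m_per_s": (1.0, 1500.0, "medium sound speed"),
    "water_path_mm": (1e-3, 30.0, "water/tissue interface depth"),
    "alpha0_dB_cm_MHz": (None, 0.5, "tissue attenuation coefficient"),
    "attenuation_power": (None, 1.0, "attenuation frequency power"),
    "z_min_mm": (1e-3, 10.0, "field grid axial start"),
    "z_max_mm": (1e-3, 110.0, "field grid axial end"),
    "r_max_mm": (1e-3, 10.0, "field grid radial extent"),
    "dx_mm": (1e-3, 0.1, "field grid spacing"),
}


def load_config(path: str | Path | None) -> dict:
    """Read a YAML config; reject unknown keys; fill defaults (raw units)."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw = loaded
    unknown = sorted(set(raw) - set(SCHEMA))
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    resolved = {key: spec[1] for key, spec in SCHEMA.items()}
    resolved.update(raw)
    return resolved


def to_si(config: dict) -> dict:
    """Convert a resolved raw-unit config to SI values."""
    si = {}
    for key, value in config.items():
        factor = SCHEMA[key][0]
        si[key] = value if factor is None or value is None else value * factor
    return si


def build_scenario(config: dict):
    """Droplet, tissue and fluid objects from a resolved config."""
    si = to_si(config)
    droplet = interfaces.DropletConfig(
        R20=si["R20_nm"], sigma2=si["sigma2_mN_per_m"], T0=si["T0_K"],
        K2=si["K2_GPa"], laplace_factor=si["laplace_factor"])
    if si["G_MPa"] is not None:
        tissue = interfaces.TissueConfig.from_shear_modulus(
            si["G_MPa"], Pc_conf=si["Pc_conf_kPa"])
    else:
        tissue = interfaces.TissueConfig(K3=si["K3_MPa"], Pc_conf=si["Pc_conf_kPa"])
    fluid = eos.FluidProperties.pfp(
        Tc=si["Tc_K"], Pc_crit=si["Pc_crit_MPa"],
        molar_mass=si["molar_mass_g_per_mol"], Psat=si["Psat_kPa"])
    return droplet, tissue, fluid


def build_transducer(config: dict) -> fieldmap.TransducerConfig:
    si = to_si(config)
    return fieldmap.TransducerConfig(
        roc=si["roc_mm"], aperture_diameter=si["aperture_mm"], f=si["f_MHz"],
        source_pressure=si["source_pressure_MPa"],
        sound_speed=si["sound_speed_m_per_s"], water_path=si["water_path_mm"],
        alpha0=si["alpha0_dB_cm_MHz"], attenuation_power=si["attenuation_power"])


def write_csv(df, path: str | Path) -> None:
    """CSV with 9-significant-digit floats."""
    df.to_csv(path, index=False, float_format="%.9g")


def _json_default(obj):
    import numpy as np
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")


def write_json(data, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, default=_json_default)
        fh.write("\n")


def write_manifest(path: str | Path, config: dict, outputs: list[str]) -> None:
    """Run manifest: resolved config (raw units), version, outputs."""
    from . import __version__
    write_json({
        "package": "nanonuc",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config,
        "outputs": list(outputs),
    }, path)


def config_from_manifest(path: str | Path) -> dict:
    """Recover the resolved config from a manifest (round-trip identity)."""
    with open(path) as fh:
        manifest = json.load(fh)
    return manifest["config"]
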