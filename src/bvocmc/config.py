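"""Run configuration: sectioned key-value files, validation, seeding.

The on-disk format is INI-style ([section] headers, ``key = value`` lines,
``#`` comments).  Every key mirrors a field of the corresponding domain type;
unknown sections or keys are rejected with a diagnostic.  An empty file
yields the all-defaults configuration (the reference tables' values).
"""

from __future__ import annotations

import configparser
import io
from dataclasses import dataclass, field, fields as dc_fields, replace
from pathlib import Path

from .dispersion import Environment, SourceEvent, DispersionScheme, FieldOptions
from .uptake import ReceiverSphere, QuadratureSpec
from .interference import InterferenceGeometry, AttenuationParams
from .particle import ParticleSimConfig
from .link import FrameSpec, LinkConfig
from .testbed import FixtureSpec, CorrectionParams

__all__ = ["RunConfig", "load_config", "loads_config", "dump_config"]


@dataclass(frozen=True)
class RunConfig:
    """All module settings plus the master seed and output directory."""

    environment: Environment = field(default_factory=Environment)
    source: SourceEvent = field(default_factory=SourceEvent)
    receiver: ReceiverSphere = field(default_factory=ReceiverSphere)
    scheme: DispersionScheme = field(default_factory=DispersionScheme)
    options: FieldOptions = field(default_factory=FieldOptions)
    quadrature: QuadratureSpec = field(default_factory=QuadratureSpec)
    interference: InterferenceGeometry = field(
        default_factory=lambda: InterferenceGeometry(0.5, 0.5))
    attenuation: AttenuationParams = field(default_factory=AttenuationParams)
    simulation: ParticleSimConfig = field(default_factory=ParticleSimConfig)
    frame: FrameSpec = field(default_factory=FrameSpec)
    link: LinkConfig = field(default_factory=LinkConfig)
    fixture: FixtureSpec = field(default_factory=FixtureSpec)
    correction: CorrectionParams = field(default_factory=CorrectionParams)
    master_seed: int = 0
    output_dir: str = "."

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)


_SECTIONS = {
    "environment": ("environment", Environment),
    "source": ("source", SourceEvent),
    "receiver": ("receiver", ReceiverSphere),
    "scheme": ("scheme", DispersionScheme),
    "options": ("options", FieldOptions),
    "quadrature": ("quadrature", QuadratureSpec),
    "interference": ("interference", InterferenceGeometry),
    "attenuation": ("attenuation", AttenuationParams),
    "simulation": ("simulation", ParticleSimConfig),
    "frame": ("frame", FrameSpec),
    "link": ("link", LinkConfig),
    "fixture": ("fixture", FixtureSpec),
    "correction": ("correction", CorrectionParams),
}

# fields handled specially or not settable from text
_SKIP_FIELDS = {
    ("simulation", "receiver"),
    ("simulation", "geometry"),
    ("fixture", "true_params"),
}


def _parse_value(raw: str, annot: str, section: str, key: str):
    raw = raw.strip()
    try:
        if annot == "bool":
            low = raw.lower()
            if low in ("true", "1", "yes", "on"):
                return True
            if low in ("false", "0", "no", "off"):
                return False
            raise ValueError(raw)
        if annot == "int":
            return int(raw)
        if annot == "float":
            return float(raw)
        if annot == "str":
            return raw
        if annot == "tuple":
            return tuple(float(v) for v in raw.replace(",", " ").split())
        if annot == "tuple | int":
            parts = raw.replace(",", " ").split()
            return int(parts[0]) if len(parts) == 1 else tuple(
                int(v) for v in parts)
    except (TypeError, ValueError) as exc:
        raise ValueError(
            f"config [{section}] {key} = {raw!r}: cannot parse as {annot}"
        ) from exc
    raise ValueError(f"config [{section}] {key}: unsupported type {annot}")


def _build_section(section: str, cls, items: dict):
    known = {f.name: f for f in dc_fields(cls)
             if (section, f.name) not in _SKIP_FIELDS}
    kwargs = {}
    for key, raw in items.items():
        if key not in known:
            raise ValueError(f"unknown key {key!r} in section [{section}]; "
                             f"expected one of {sorted(known)}")
        annot = known[key].type
        kwargs[key] = _parse_value(raw, annot, section, key)
    try:
        return cls(**kwargs) if kwargs else cls()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"config section [{section}]: {exc}") from exc


def loads_config(text: str) -> RunConfig:
    """Parse configuration text; see :func:`load_config`."""
    cp = configparser.ConfigParser(inline_comment_prefixes=("#",))
    cp.optionxform = str  # case-sensitive keys
    cp.read_string(text)
    kwargs = {}
    for sect in cp.sections():
        if sect == "run":
            for key, raw in cp.items(sect):
                if key == "master_seed":
                    kwargs["master_seed"] = int(raw)
                elif key == "output_dir":
                    kwargs["output_dir"] = raw.strip()
                else:
                    raise ValueError(f"unknown key {key!r} in section [run]")
            continue
        if sect not in _SECTIONS:
            raise ValueError(f"unknown config section [{sect}]; expected one "
                             f"of {sorted(_SECTIONS) + ['run']}")
        attr, cls = _SECTIONS[sect]
        kwargs[attr] = _build_section(sect, cls, dict(cp.items(sect)))
    # keep the particle-sim receiver/geometry in sync with the scene sections
    cfg = RunConfig(**kwargs)
    sim = cfg.simulation.replace(receiver=cfg.receiver,
                                 geometry=cfg.interference,
                                 source_height=cfg.source.H,
                                 seed=cfg.master_seed)
    return cfg.replace(simulation=sim)


def load_config(path) -> RunConfig:
    """Load and validate a sectioned key-value config file.

    Missing file, unknown section/key or unparsable/invalid values raise
    descriptive errors; an empty file returns the all-defaults RunConfig.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    return loads_config(p.read_text())


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig back to config text (round-trips through
    :func:`loads_config`)."""
    out = io.StringIO()
    out.write("[run]\n")
    out.write(f"master_seed = {cfg.master_seed}\n")
    out.write(f"output_dir = {cfg.output_dir}\n\n")
    for sect, (attr, cls) in _SECTIONS.items():
        obj = getattr(cfg, attr)
        out.write(f"[{sect}]\n")
        for f in dc_fields(cls):
            if (sect, f.name) in _SKIP_FIELDS:
                continue
            val = getattr(obj, f.name)
            if isinstance(val, tuple):
                val = " ".join(str(v) for v in val)
            out.write(f"{f.name} = {val}\n")
        out.write("\n")
    return out.getvalue()
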