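"""Reading and writing parameter sets and experiment artifacts.

Parameter files are flat key-value mappings (JSON, YAML or TOML, chosen by
file extension) with keys exactly matching the dataclass field names, a
``kind`` discriminator and an optional ``_meta`` block carrying unit
annotations and provenance, which is preserved on round trips.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .params import (
    CircadianWaveform,
    ParameterError,
    PRParams,
    PRSwitchParams,
    TwoProcessParams,
)

__all__ = ["read_params", "write_params", "params_to_dict", "params_from_dict"]

_KINDS = {
    "two_process": TwoProcessParams,
    "pr": PRParams,
    "pr_switch": PRSwitchParams,
}

_UNITS = {
    "two_process": {
        "mu": "pressure", "lower": "pressure", "chi_w": "h", "chi_s": "h",
        "H0_plus": "pressure", "H0_minus": "pressure",
        "circadian.amplitude": "pressure",
    },
    "pr": {
        "Q_max": "1/s", "theta": "mV", "sigma": "mV", "nu_vm": "mV s",
        "nu_mv": "mV s", "nu_vh": "mV/pressure", "D0_v": "mV", "A": "mV",
        "chi": "h", "mu_h": "pressure s", "tau": "s",
        "circadian.amplitude": "mV",
    },
}
_UNITS["pr_switch"] = {**_UNITS["pr"], "Q_bar": "1/s", "V_th": "mV"}


def _kind_of(p) -> str:
    if isinstance(p, PRSwitchParams):
        return "pr_switch"
    if isinstance(p, PRParams):
        return "pr"
    if isinstance(p, TwoProcessParams):
        return "two_process"
    raise TypeError(f"unsupported parameter object: {type(p).__name__}")


def params_to_dict(p, meta: dict | None = None) -> dict:
    kind = _kind_of(p)
    out = {"kind": kind}
    for f in dataclasses.fields(p):
        v = getattr(p, f.name)
        if isinstance(v, CircadianWaveform):
            out[f.name] = {
                "amplitude": v.amplitude, "omega": v.omega, "alpha": v.alpha,
                "coefficients": list(v.coefficients),
            }
        else:
            out[f.name] = v
    out["_meta"] = {"units": _UNITS[kind], **(meta or {})}
    return out


def params_from_dict(d: dict):
    d = dict(d)
    d.pop("_meta", None)
    kind = d.pop("kind", None)
    if kind is None:
        # infer from discriminating fields
        kind = ("pr_switch" if "Q_bar" in d else
                "pr" if "Q_max" in d else
                "two_process" if "chi_w" in d else None)
    cls = _KINDS.get(kind)
    if cls is None:
        raise ParameterError("kind", f"unknown or missing parameter kind: {kind!r}")
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - field_names
    if unknown:
        raise ParameterError(sorted(unknown)[0], "unknown parameter key")
    missing = {f.name for f in dataclasses.fields(cls)
               if f.default is dataclasses.MISSING
               and f.default_factory is dataclasses.MISSING} - set(d)
    if missing:
        raise ParameterError(sorted(missing)[0], "required parameter missing")
    if "circadian" in d and isinstance(d["circadian"], dict):
        c = dict(d["circadian"])
        if "coefficients" in c:
            c["coefficients"] = tuple(c["coefficients"])
        d["circadian"] = CircadianWaveform(**c)
    return cls(**d)


def _json_load(fh):
    return json.load(fh)


def read_params(path, dialect: str | None = None):
    """Load a parameter set; dialect inferred from the extension by default."""
    path = Path(path)
    dialect = dialect or path.suffix.lstrip(".").lower()
    text = path.read_text()
    if dialect == "json":
        data = json.loads(text)
    elif dialect in ("yaml", "yml"):
        import yaml

        data = yaml.safe_load(text)
    elif dialect == "toml":
        import tomllib

        data = tomllib.loads(text)
    else:
        raise ValueError(f"unsupported parameter dialect: {dialect!r}")
    return params_from_dict(data)


def write_params(p, path, dialect: str | None = None, meta: dict | None = None):
    """Write a parameter set; round-trips to an equal object."""
    path = Path(path)
    dialect = dialect or path.suffix.lstrip(".").lower()
    data = params_to_dict(p, meta=meta)
    if dialect == "json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    elif dialect in ("yaml", "yml"):
        import yaml

        path.write_text(yaml.safe_dump(data, sort_keys=True))
    elif dialect == "toml":
        lines = []
        for k, v in data.items():
            if isinstance(v, dict) or v is None:  # TOML has no null
                continue
            lines.append(f"{k} = {json.dumps(v)}")
        for k, v in data.items():
            if isinstance(v, dict):
                lines.append(f"[{k}]")
                for kk, vv in v.items():
                    if isinstance(vv, dict):
                        continue
                    lines.append(f"{kk} = {json.dumps(vv)}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported parameter dialect: {dialect!r}")
    return path
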