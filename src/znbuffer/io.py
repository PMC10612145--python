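"""Configuration loading, model registry validation, and file I/O.

One unit convention everywhere: concentrations are molar inside the package;
config files may use suffixed strings ("2 uM", "0.5 mM"), normalized at
load time.  Binding constants are -log10 molar ("pkd") or explicit molar
``kd`` values.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .equilibria import (
    OneToOneChelator,
    OneToOneProbe,
    SteppedBindingModel,
    TwoToOneProbe,
)

__all__ = [
    "Registry",
    "ModelValidationError",
    "load_models",
    "bundled_registry",
    "parse_concentration",
    "fit_result_to_json",
]

_UNIT_SCALE = {
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "nm": 1e-9,
    "pm": 1e-12,
    "fm": 1e-15,
}


class ModelValidationError(ValueError):
    """Aggregated config validation failures, each with its field path."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("model config invalid:\n" + "\n".join(f"  - {e}" for e in errors))


def parse_concentration(value) -> float:
    """Molar concentration from a number or a suffixed string ('2 uM')."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    match = re.fullmatch(r"([-+0-9.eE]+)\s*([a-zA-Zµ]+)?", text)
    if not match:
        raise ValueError(f"cannot parse concentration {value!r}")
    number = float(match.group(1))
    unit = (match.group(2) or "M").lower()
    if unit not in _UNIT_SCALE:
        raise ValueError(f"unknown concentration unit {match.group(2)!r} in {value!r}")
    return number * _UNIT_SCALE[unit]


@dataclass(frozen=True)
class Registry:
    """Validated collections of proteins, chelators and probes."""

    proteins: Mapping[str, SteppedBindingModel]
    chelators: Mapping[str, OneToOneChelator]
    probes: Mapping[str, object]
    metadata: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)

    def protein_meta(self, name: str) -> Mapping[str, Any]:
        return self.metadata.get(name, {})


def _pkd_from_entry(entry: Mapping[str, Any], path: str, errors: list[str]) -> Optional[float]:
    if "pkd" in entry:
        try:
            return float(entry["pkd"])
        except (TypeError, ValueError):
            errors.append(f"{path}.pkd: not a number ({entry['pkd']!r})")
            return None
    if "kd" in entry:
        try:
            kd = float(entry["kd"])
        except (TypeError, ValueError):
            errors.append(f"{path}.kd: not a number ({entry['kd']!r})")
            return None
        if not kd > 0:
            errors.append(f"{path}.kd: must be > 0")
            return None
        return -math.log10(kd)
    errors.append(f"{path}: missing required field 'pkd' (or 'kd')")
    return None


def _build_protein(
    name: str, spec: Mapping[str, Any], errors: list[str]
) -> Optional[SteppedBindingModel]:
    path = f"proteins.{name}"
    steps: list[float] = []
    groups: dict[str, tuple[int, ...]] = {}
    if "pkd_steps" in spec:
        raw = spec["pkd_steps"]
        if not isinstance(raw, (list, tuple)) or not raw:
            errors.append(f"{path}.pkd_steps: must be a non-empty list")
            return None
        try:
            steps = [float(v) for v in raw]
        except (TypeError, ValueError):
            errors.append(f"{path}.pkd_steps: entries must be numbers")
            return None
    elif "sites" in spec:
        sites = spec["sites"]
        if not isinstance(sites, Mapping):
            errors.append(f"{path}.sites: must be a mapping of group -> constants")
            return None
        cursor = 1
        for label in ("tight", "moderate", "weak"):
            if label not in sites:
                continue
            entry = sites[label]
            if isinstance(entry, Mapping):  # {count: k, pkd: v} grouped form
                try:
                    count = int(entry["count"])
                    value = float(entry["pkd"])
                except (KeyError, TypeError, ValueError):
                    errors.append(f"{path}.sites.{label}: grouped form needs count and pkd")
                    continue
                values = [value] * count
            elif isinstance(entry, (list, tuple)):
                try:
                    values = [float(v) for v in entry]
                except (TypeError, ValueError):
                    errors.append(f"{path}.sites.{label}: entries must be numbers")
                    continue
            else:
                try:
                    values = [float(entry)]
                except (TypeError, ValueError):
                    errors.append(f"{path}.sites.{label}: unrecognized form {entry!r}")
                    continue
            steps.extend(values)
            groups[label] = tuple(range(cursor, cursor + len(values)))
            cursor += len(values)
    else:
        errors.append(f"{path}: missing 'pkd_steps' or 'sites'")
        return None

    declared = spec.get("n_sites")
    if declared is not None and int(declared) != len(steps):
        errors.append(
            f"{path}.n_sites: declares {declared} sites but {len(steps)} constants given"
        )
        return None
    try:
        return SteppedBindingModel(
            name=name,
            pkd_steps=tuple(steps),
            site_groups=groups or None,
            notes=str(spec.get("notes", "")),
        )
    except ValueError as err:
        errors.append(f"{path}: {err}")
        return None


def _as_named_mapping(section, section_name: str, errors: list[str]) -> dict[str, Mapping]:
    """Accept either {name: spec} or [{name: ..., **spec}]; detect duplicates."""
    out: dict[str, Mapping] = {}
    if section is None:
        return out
    if isinstance(section, Mapping):
        items = section.items()
    elif isinstance(section, list):
        items = []
        for k, entry in enumerate(section):
            if not isinstance(entry, Mapping) or "name" not in entry:
                errors.append(f"{section_name}[{k}]: list entries need a 'name' field")
                continue
            items.append((entry["name"], {k2: v for k2, v in entry.items() if k2 != "name"}))
    else:
        errors.append(f"{section_name}: must be a mapping or a list")
        return out
    for name, spec in items:
        if name in out:
            errors.append(f"{section_name}.{name}: duplicate name")
            continue
        out[name] = spec
    return out


def load_models(source) -> Registry:
    """Load and validate a protein/chelator/probe registry (YAML or JSON).

    ``source`` may be a path or an already-parsed mapping.  Every violation
    is collected with its field path and raised together.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        text = Path(source).read_text()
        doc = yaml.safe_load(text)  # YAML superset also parses JSON
    if not isinstance(doc, Mapping):
        raise ModelValidationError(["top level: expected a mapping"])

    errors: list[str] = []
    proteins: dict[str, SteppedBindingModel] = {}
    metadata: dict[str, dict] = {}
    for name, spec in _as_named_mapping(doc.get("proteins"), "proteins", errors).items():
        if not isinstance(spec, Mapping):
            errors.append(f"proteins.{name}: must be a mapping")
            continue
        model = _build_protein(name, spec, errors)
        if model is not None:
            proteins[name] = model
            metadata[name] = {
                k: v for k, v in spec.items() if k not in ("sites", "pkd_steps", "n_sites")
            }

    chelators: dict[str, OneToOneChelator] = {}
    for name, spec in _as_named_mapping(doc.get("chelators"), "chelators", errors).items():
        if not isinstance(spec, Mapping):
            errors.append(f"chelators.{name}: must be a mapping")
            continue
        pkd = _pkd_from_entry(spec, f"chelators.{name}", errors)
        if pkd is not None:
            chelators[name] = OneToOneChelator(name=name, pkd=pkd)

    probes: dict[str, object] = {}
    for name, spec in _as_named_mapping(doc.get("probes"), "probes", errors).items():
        if not isinstance(spec, Mapping):
            errors.append(f"probes.{name}: must be a mapping")
            continue
        stoich = str(spec.get("stoichiometry", "1:1"))
        if stoich == "2:1":
            try:
                probes[name] = TwoToOneProbe(
                    name=name,
                    kd12=float(spec["kd12"]),
                    epsilon_492=float(spec["epsilon_492"]),
                    path_length=float(spec.get("path_length_cm", 1.0)),
                )
            except (KeyError, TypeError, ValueError) as err:
                errors.append(f"probes.{name}: {err!r}")
        elif stoich == "1:1":
            pkd = _pkd_from_entry(spec, f"probes.{name}", errors)
            if pkd is not None:
                probes[name] = OneToOneProbe(name=name, pkd=pkd)
        else:
            errors.append(f"probes.{name}.stoichiometry: must be '1:1' or '2:1'")

    if errors:
        raise ModelValidationError(errors)
    return Registry(proteins=proteins, chelators=chelators, probes=probes, metadata=metadata)


def bundled_registry() -> Registry:
    """The packaged reference registry (10 metallothioneins, 6 chelators,
    both probes)."""
    with resources.files("znbuffer.data").joinpath("constants.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    return load_models(doc)


def fit_result_to_json(result, path=None) -> str:
    """Serialize a FitResult; writes to ``path`` if given."""
    payload = {
        "parameters": dict(result.parameters),
        "standard_errors": {
            k: (None if not math.isfinite(v) else v)
            for k, v in result.standard_errors.items()
        },
        "residual_norm": result.residual_norm,
        "converged": result.converged,
        "model_tag": result.model_tag,
        "flags": list(result.flags),
        "message": result.message,
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
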