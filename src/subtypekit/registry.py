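"""The method registry: descriptors for the ten supported classifiers."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .types import MethodDescriptor, ValidationError

CONVENTIONAL_TAG = "conventional"
ER_DEVIATED_TAG = "er_deviated"
SUBTYPE_SPECIFIC_TAG = "subtype_specific"


def load_registry(path: Optional[Union[str, Path]] = None) -> list[MethodDescriptor]:
    """Load method descriptors from a registry YAML (packaged default)."""
    if path is None:
        text = (
            resources.files("subtypekit") / "data" / "registry.yaml"
        ).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    payload = yaml.safe_load(text)
    entries = payload.get("methods", [])
    descriptors = []
    for entry in entries:
        descriptors.append(
            MethodDescriptor(
                name=entry["name"],
                family=entry["family"],
                centering_strategy=entry.get("centering"),
                correlation_kind=entry.get("correlation"),
                model_ref=entry.get("model", "centroid"),
                assumption_tags=frozenset(entry.get("tags", [])),
                gates=entry.get("gates", {}),
            )
        )
    names = [d.name for d in descriptors]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate method names in registry")
    return descriptors


def get_method(registry: list[MethodDescriptor], name: str) -> MethodDescriptor:
    for descriptor in registry:
        if descriptor.name == name:
            return descriptor
    raise KeyError(f"method not in registry: {name!r}")
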