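"""Structured clinical prompt templates (Entity + Quantification + Context).

A class prompt is the concatenation of three sentence fragments grounded in
WHO diagnostic criteria:

* **Entity** — the global semantic anchor naming the lesion category;
* **Quantification** — the histological criteria that discriminate it;
* **Context** — its clinical risk/behavior framing.

The bundled registry covers the three polyp classes; new labels can be
registered at run time, so the same E+Q+C meta-template transfers to other
diagnostic domains. A token-entropy diagnostic quantifies the information
density of each component and checks that the concatenated prompt's entropy
never exceeds the sum of its components'.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "PromptTemplate",
    "TemplateRegistry",
    "PromptDiagnostics",
    "default_registry",
    "build_prompt",
    "build_generic_prompt",
    "register_template",
    "prompt_entropy",
    "registry_diagnostics",
]


@dataclass(frozen=True)
class PromptTemplate:
    """The three clinical fragments for one class label."""

    label: str
    entity: str
    quantification: str
    context: str
    generic: str | None = None

    def __post_init__(self):
        for name in ("entity", "quantification", "context"):
            frag = getattr(self, name)
            if not frag or not frag.strip():
                raise ValueError(f"template fragment {name!r} must be non-empty")
            if frag.strip()[-1] not in ".!?":
                raise ValueError(
                    f"template fragment {name!r} must end with terminal punctuation"
                )

    @property
    def prompt(self) -> str:
        """Entity + Quantification + Context joined by single spaces."""
        return " ".join((self.entity, self.quantification, self.context))


class TemplateRegistry:
    """Mutable mapping from class label to its prompt template."""

    def __init__(self, templates: dict[str, PromptTemplate] | None = None):
        self._templates: dict[str, PromptTemplate] = dict(templates or {})

    def __contains__(self, label: str) -> bool:
        return label in self._templates

    def __getitem__(self, label: str) -> PromptTemplate:
        if label not in self._templates:
            raise KeyError(
                f"no template registered for {label!r}; "
                f"registered labels: {sorted(self._templates)}"
            )
        return self._templates[label]

    def labels(self) -> list[str]:
        return sorted(self._templates)

    def add(self, template: PromptTemplate) -> None:
        self._templates[template.label] = template

    @classmethod
    def from_json(cls, path: str | Path) -> "TemplateRegistry":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "TemplateRegistry":
        reg = cls()
        for label, frags in payload.items():
            reg.add(
                PromptTemplate(
                    label=label,
                    entity=frags["entity"],
                    quantification=frags["quantification"],
                    context=frags["context"],
                    generic=frags.get("generic"),
                )
            )
        return reg

    def to_json(self, path: str | Path) -> None:
        payload = {
            t.label: {
                "entity": t.entity,
                "quantification": t.quantification,
                "context": t.context,
                **({"generic": t.generic} if t.generic else {}),
            }
            for t in self._templates.values()
        }
        Path(path).write_text(
            json.dumps(payload, indent=2, ensure_ascii=False), encoding="utf-8"
        )


def default_registry() -> TemplateRegistry:
    """The bundled three-class clinical registry (loaded from package data)."""
    payload = json.loads(
        resources.files("polypclip").joinpath("data/scst_templates.json").read_text(
            encoding="utf-8"
        )
    )
    return TemplateRegistry._from_payload(payload)


def build_prompt(label: str, registry: TemplateRegistry) -> str:
    """The full structured clinical prompt for ``label`` (byte-stable)."""
    return registry[label].prompt


def build_generic_prompt(label: str, registry: TemplateRegistry) -> str:
    """The plain class-name prompt ("A photo of ..."), the ablation baseline."""
    template = registry[label]
    if template.generic:
        return template.generic
    return f"A photo of {label}."


def register_template(
    label: str,
    entity: str,
    quantification: str,
    context: str,
    registry: TemplateRegistry,
    generic: str | None = None,
) -> TemplateRegistry:
    """Add or overwrite a label's template; returns the registry."""
    registry.add(
        PromptTemplate(
            label=label,
            entity=entity,
            quantification=quantification,
            context=context,
            generic=generic,
        )
    )
    return registry


@dataclass(frozen=True)
class PromptDiagnostics:
    """Token-entropy (bits) of each component list and of the concatenations."""

    entity_bits: float
    quantification_bits: float
    context_bits: float
    prompt_bits: float

    @property
    def component_sum_bits(self) -> float:
        return self.entity_bits + self.quantification_bits + self.context_bits

    @property
    def subadditive(self) -> bool:
        return self.prompt_bits <= self.component_sum_bits + 1e-12


def prompt_entropy(texts: list[str]) -> float:
    """Shannon entropy (bits) of the pooled whitespace-token distribution."""
    if not texts:
        raise ValueError("texts must be non-empty")
    counts = Counter(tok for t in texts for tok in t.split())
    total = sum(counts.values())
    return -sum(
        (c / total) * math.log2(c / total) for c in counts.values() if c > 0
    )


def registry_diagnostics(registry: TemplateRegistry) -> PromptDiagnostics:
    """Entropy of each fragment list across all registered labels."""
    templates = [registry[lbl] for lbl in registry.labels()]
    return PromptDiagnostics(
        entity_bits=prompt_entropy([t.entity for t in templates]),
        quantification_bits=prompt_entropy([t.quantification for t in templates]),
        context_bits=prompt_entropy([t.context for t in templates]),
        prompt_bits=prompt_entropy([t.prompt for t in templates]),
    )
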