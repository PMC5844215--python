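"""Run configuration: keyword sets, marker lexicon, thresholds, backend.

Loaded from a YAML (or flat ``key = value``) file; every field has the
package default so an empty config is valid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .associations import DEFAULT_P_MARKERS
from .cohort import (
    DEFAULT_CONTROL_KEYWORDS,
    DEFAULT_MIN_NATIONALITY_LENGTH,
    DEFAULT_PATIENT_KEYWORDS,
)


@dataclass(frozen=True)
class Config:
    nlp_backend: str = "heuristic"            # or "rule_fallback"
    patient_keywords: tuple[str, ...] = DEFAULT_PATIENT_KEYWORDS
    control_keywords: tuple[str, ...] = DEFAULT_CONTROL_KEYWORDS
    min_nationality_length: int = DEFAULT_MIN_NATIONALITY_LENGTH
    p_marker_variants: tuple[str, ...] = DEFAULT_P_MARKERS
    value_rel_tol: float = 1e-6               # gold-match tolerance
    retmax: int = 3000                        # PMIDs fetched per query
    entrez_email: str | None = None
    entrez_tool: str = "snpminer"


_TUPLE_FIELDS = {"patient_keywords", "control_keywords", "p_marker_variants"}


def load_config(path: str | Path | None) -> Config:
    """Build a :class:`Config`, overriding defaults from ``path`` if given.

    Accepts YAML mappings; list-valued fields may also be given as
    comma-separated strings.  Unknown keys raise ``ValueError`` so typos
    do not silently fall back to defaults.
    """
    if path is None:
        return Config()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _TUPLE_FIELDS:
            if isinstance(value, str):
                value = [v.strip() for v in value.split(",") if v.strip()]
            value = tuple(value)
        kwargs[key] = value
    return Config(**kwargs)
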