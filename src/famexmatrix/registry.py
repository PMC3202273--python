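"""Organism registry.

Members of gene families carry an organism code; codes must be registered
before use so that typos in input tables fail loudly.  The default registry
covers the five model organisms the family resources are built for.
"""

from __future__ import annotations

from typing import Mapping

#: Default organism space: code -> species name.
DEFAULT_ORGANISMS: dict[str, str] = {
    "Hs": "Homo sapiens",
    "Mm": "Mus musculus",
    "Dm": "Drosophila melanogaster",
    "Ce": "Caenorhabditis elegans",
    "Sc": "Saccharomyces cerevisiae",
}


def check_organism(code: str, registry: Mapping[str, str] | None = None) -> str:
    """Validate an organism code against a registry (default: the five model
    organisms).  Returns the code unchanged; raises ``ValueError`` otherwise."""
    reg = DEFAULT_ORGANISMS if registry is None else registry
    if code not in reg:
        raise ValueError(
            f"unknown organism code {code!r}; registered codes: {sorted(reg)}"
        )
    return code
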