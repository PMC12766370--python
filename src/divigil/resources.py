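"""Loaders for the bundled dictionary files.

The package ships three small hand-curated text tables (stand-ins for the
licensed MedDRA, DrugBank and WHO-ATC resources): a preferred-term list,
a verbatim-to-ingredient synonym map and an ingredient-to-ATC-level-1 map.
All three use the same ``$``-delimited dialect as the quarterly tables.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

__all__ = [
    "load_pt_terms",
    "load_synonym_map",
    "load_atc_map",
    "TARGET_PT_CODE",
    "TARGET_PT_NAME",
]

#: MedDRA preferred-term code for diabetes insipidus, the target adverse event.
TARGET_PT_CODE = 10012599
TARGET_PT_NAME = "Diabetes insipidus"


def _iter_data_lines(path: str | Path | None, default_name: str):
    if path is None:
        text = resources.files("divigil.data").joinpath(default_name).read_text()
    else:
        text = Path(path).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        yield line.split("$")


def load_pt_terms(path: str | Path | None = None) -> dict[int, str]:
    """Return ``{pt_code: pt_name}`` from a two-column ``$``-delimited file."""
    out: dict[int, str] = {}
    for fields in _iter_data_lines(path, "pt_terms.txt"):
        if len(fields) != 2:
            raise ValueError(f"expected 2 fields in PT table, got {fields!r}")
        out[int(fields[0])] = fields[1]
    return out


def load_synonym_map(path: str | Path | None = None) -> dict[str, str]:
    """Return the normalized-verbatim -> standardized-ingredient map.

    Keys are stored pre-normalized (case-folded, whitespace-collapsed);
    values must be non-empty.
    """
    out: dict[str, str] = {}
    for fields in _iter_data_lines(path, "drug_synonyms.txt"):
        if len(fields) != 2:
            raise ValueError(f"expected 2 fields in synonym map, got {fields!r}")
        key, value = fields
        if not value:
            raise ValueError(f"empty ingredient for synonym key {key!r}")
        out[key] = value
    return out


ATC_MAIN_GROUPS = frozenset("ABCDGHJLMNPRSV")


def load_atc_map(path: str | Path | None = None) -> dict[str, tuple[str, str]]:
    """Return ``{ingredient: (atc_level1_code, class_label)}``."""
    out: dict[str, tuple[str, str]] = {}
    for fields in _iter_data_lines(path, "atc_classes.txt"):
        if len(fields) != 3:
            raise ValueError(f"expected 3 fields in ATC map, got {fields!r}")
        ingredient, code, label = fields
        if code not in ATC_MAIN_GROUPS:
            raise ValueError(f"{code!r} is not an ATC anatomical main group")
        out[ingredient] = (code, label)
    return out
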