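"""Host / agent / environment designation of factors from code prefixes.

The shipped default map is illustrative, not authoritative: disease and
symptom chapters resolve to host, transport / fall / strike external
causes to agent, and assault, abuse, complication-of-care, and social
circumstance codes to environment. Designation is domain judgment; the map
is an ordered first-match-wins prefix table and fully editable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .factors import FactorDefinition

__all__ = [
    "CATEGORIES",
    "FactorDesignation",
    "HaddonMap",
    "default_haddon_map",
    "designate_factor",
    "load_haddon_map",
    "save_haddon_map",
]

CATEGORIES = ("host", "agent", "environment")

# canonical rendering of every category combination
_LABELS = {
    frozenset({"host"}): "H",
    frozenset({"agent"}): "A",
    frozenset({"environment"}): "E",
    frozenset({"host", "agent"}): "H/A",
    frozenset({"host", "environment"}): "H/E",
    frozenset({"agent", "environment"}): "A/E",
    frozenset({"host", "agent", "environment"}): "H/A/E",
}


@dataclass(frozen=True)
class FactorDesignation:
    factor_id: str
    categories: frozenset[str]
    label: str


@dataclass
class HaddonMap:
    """Ordered (prefix, category) rules; first match wins, default is host."""

    entries: list[tuple[str, str]]
    default: str = "host"

    def __post_init__(self) -> None:
        for prefix, category in self.entries:
            if not 1 <= len(prefix) <= 3 or not prefix.isalnum():
                raise ValueError(f"bad prefix {prefix!r} (need 1-3 alphanumerics)")
            if category not in CATEGORIES:
                raise ValueError(f"unknown category {category!r}")
        if self.default not in CATEGORIES:
            raise ValueError(f"unknown default category {self.default!r}")

    def categorize(self, code: str) -> str:
        code = code.upper()
        for prefix, category in self.entries:
            if code.startswith(prefix):
                return category
        return self.default


def designate_factor(definition: FactorDefinition, haddon_map: HaddonMap) -> FactorDesignation:
    """Label a factor by the set of categories its member codes map to."""
    if not definition.code_ids:
        raise ValueError("factor has no codes")
    categories = frozenset(haddon_map.categorize(c) for c in definition.code_ids)
    return FactorDesignation(factor_id=definition.factor_id,
                             categories=categories,
                             label=_LABELS[categories])


def default_haddon_map() -> HaddonMap:
    entries: list[tuple[str, str]] = []
    # specific environment codes first so they beat the broad chapter rules
    entries.append(("T74", "environment"))                      # maltreatment
    entries += [(f"X{i}", "environment") for i in range(85, 100)]  # assault
    entries.append(("Y0", "environment"))                       # assault
    entries += [(f"Y{i}", "environment") for i in (4, 5, 6, 7)]  # care complications
    entries += [(f"Y8{i}", "environment") for i in range(5)]
    entries += [(f"Z{i}", "environment") for i in range(55, 66)]  # social circumstances
    # transport, falls, strikes and other mechanical external causes
    entries.append(("V", "agent"))
    entries.append(("W", "agent"))
    entries += [(f"X{i}", "agent") for i in range(6)]
    # everything else (disease and symptom chapters A-R, injuries S-T) -> host
    return HaddonMap(entries=entries, default="host")


def save_haddon_map(haddon_map: HaddonMap, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{prefix}: {category}" for prefix, category in haddon_map.entries]
    lines.append(f"default: {haddon_map.default}")
    path.write_text("\n".join(lines) + "\n")
    return path


def load_haddon_map(path: str | Path) -> HaddonMap:
    """Read an ordered ``prefix: category`` map file (``#`` comments allowed)."""
    path = Path(path)
    entries: list[tuple[str, str]] = []
    default = "host"
    lines = [ln for ln in path.read_text().splitlines()]
    meaningful = [ln for ln in lines if ln.strip() and not ln.strip().startswith("#")]
    if not meaningful:
        raise ValueError(f"{path}: empty map file")
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'prefix: category'")
        prefix, _, category = line.partition(":")
        prefix, category = prefix.strip(), category.strip().lower()
        if category not in CATEGORIES:
            raise ValueError(f"{path}:{lineno}: unknown category {category!r}")
        if prefix.lower() == "default":
            default = category
            continue
        if not 1 <= len(prefix) <= 3 or not prefix.isalnum():
            raise ValueError(f"{path}:{lineno}: malformed prefix {prefix!r}")
        entries.append((prefix.upper(), category))
    return HaddonMap(entries=entries, default=default)
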