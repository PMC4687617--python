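"""Delimited-text I/O for trait tables and result tables."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = ["TraitObservations", "read_trait_table", "write_trait_table"]


@dataclass(frozen=True)
class TraitObservations:
    """Tip-label → trait value map tagged with its measurement space."""

    values: dict[str, float]
    space: str = "arithmetic"  # "arithmetic" | "log"

    def __post_init__(self) -> None:
        if self.space not in ("arithmetic", "log"):
            raise ValueError(f"space must be 'arithmetic' or 'log', got {self.space!r}")

    def __getitem__(self, label: str) -> float:
        return self.values[label]

    def __contains__(self, label: str) -> bool:
        return label in self.values

    def keys(self):
        return self.values.keys()

    def items(self):
        return self.values.items()

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


def read_trait_table(path: str | Path, space: str = "arithmetic") -> TraitObservations:
    """Read a two-column (tip label, value) delimited file.

    Tab, comma and whitespace delimiters are accepted; lines starting with
    '#' are ignored.  A header line is detected by a non-numeric second
    field and skipped.
    """
    values: dict[str, float] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'label value', got {line!r}")
        label = parts[0]
        try:
            val = float(parts[1])
        except ValueError:
            if lineno == 1:  # header
                continue
            raise ValueError(f"{path}:{lineno}: non-numeric value {parts[1]!r}")
        if label in values:
            raise ValueError(f"{path}:{lineno}: duplicate tip label {label!r}")
        values[label] = val
    return TraitObservations(values=values, space=space)


def write_trait_table(tips: Mapping[str, float], path: str | Path) -> None:
    """Write a tab-delimited (tip label, value) table."""
    df = pd.DataFrame(sorted(tips.items()), columns=["tip", "value"])
    df.to_csv(path, sep="\t", index=False)
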