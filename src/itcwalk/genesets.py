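"""Gene-set containers and GMT I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique node identifiers."""

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            # silently uniquify while preserving order
            object.__setattr__(self, "members", tuple(dict.fromkeys(self.members)))

    def __len__(self) -> int:
        return len(self.members)

    def intersect(self, universe: Iterable[str]) -> "GeneSet":
        keep = set(universe)
        return GeneSet(self.name, tuple(m for m in self.members if m in keep),
                       self.description)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: name <tab> description <tab> member... per line."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need >=3 fields): {line[:80]!r}")
        sets.append(GeneSet(parts[0], tuple(m for m in parts[2:] if m), parts[1]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.members]) + "\n")
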