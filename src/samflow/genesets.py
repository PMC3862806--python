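"""Named probeset collections and the GMT file format.

GMT is one set per line: name, description, then tab-separated member IDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import SchemaError


@dataclass(frozen=True)
class GeneSet:
    """A named collection of probeset identifiers."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("gene set needs a non-empty name")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


def read_gmt(path) -> list[GeneSet]:
    path = Path(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise SchemaError(f"{path.name}:{lineno}: expected >=3 tab-separated fields")
        name, desc, *members = fields
        members = [m for m in members if m]
        sets.append(GeneSet(name, frozenset(members), desc))
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise SchemaError(f"{path.name}: duplicate set name {dup!r}")
    return sets


def write_gmt(sets, path) -> None:
    lines = []
    for s in sets:
        lines.append("\t".join([s.name, s.description, *sorted(s.members)]))
    Path(path).write_text("\n".join(lines) + "\n")
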