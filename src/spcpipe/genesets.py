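"""GMT gene-set collections: the tab-delimited carrier used by pathway
over-representation tools (set name, description, then member ids)."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Duplicate members within a line are deduplicated; duplicate set names
    across lines are rejected. Malformed lines (< 3 tab fields) raise with
    the 1-based line number.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT parse error at line {lineno}: expected >= 3 tab-separated fields")
            name, desc, *members = fields
            if name in seen:
                raise ValueError(f"GMT parse error at line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name=name, description=desc, members=frozenset(m for m in members if m)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def as_dict(sets: Iterable[GeneSet]) -> dict[str, frozenset[str]]:
    return {s.name: s.members for s in sets}
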