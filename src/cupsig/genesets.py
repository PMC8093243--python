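"""Gene sets and GMT (Broad dialect) I/O."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of unique gene identifiers."""

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection:
    """Ordered collection of gene sets with unique names."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets: list[GeneSet] = list(sets)
        names = [s.name for s in self.sets]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate set name(s): {', '.join(sorted(dup))}")
        self._by_name = {s.name: s for s in self.sets}

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB member TAB member ...

    Duplicate members within one line are de-duplicated (first occurrence
    wins) with a warning; a duplicate set name is an error.
    """
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) != len(members):
                warnings.warn(
                    f"{path}:{lineno}: de-duplicated repeated member(s) in set {name!r}",
                    stacklevel=2,
                )
            sets.append(GeneSet(name, tuple(uniq), desc))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection | Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")
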