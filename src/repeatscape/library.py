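"""Repeat libraries and the hierarchical transposable-element taxonomy.

A repeat library is a FASTA file whose headers carry the classification in
the dialect ``name#Class/Order/Superfamily/Family@species``; missing levels
are written as ``unknown`` and trailing unknown levels may be omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

UNKNOWN = "unknown"

CLASS_I_ORDERS = frozenset({"LTR", "LINE", "SINE", "DIRS", "PLE"})
CLASS_II_ORDERS = frozenset({"TIR", "Helitron"})
LTR_SUPERFAMILIES = frozenset({"Gypsy", "Copia"})


def order_to_class(order: str) -> str:
    if order in CLASS_I_ORDERS:
        return "I"
    if order in CLASS_II_ORDERS:
        return "II"
    return UNKNOWN


@dataclass(frozen=True)
class Classification:
    """Class/Order/Superfamily/family assignment with its evidence route.

    Class I elements transpose via an RNA intermediate (retrotransposons);
    Class II are DNA transposons. Gypsy and Copia are the two dominant LTR
    retrotransposon superfamilies.
    """

    class_: str = UNKNOWN
    order: str = UNKNOWN
    superfamily: str = UNKNOWN
    family: str | None = None
    evidence: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.superfamily in LTR_SUPERFAMILIES and self.order != "LTR":
            raise ValueError(
                f"superfamily {self.superfamily} implies order LTR, "
                f"got {self.order}"
            )
        if self.family is not None and self.class_ == UNKNOWN:
            raise ValueError("a family-level call requires a class call")

    @property
    def path(self) -> tuple[str, str, str, str]:
        return (self.class_, self.order, self.superfamily,
                self.family or UNKNOWN)

    def header_tag(self) -> str:
        return "/".join(self.path)

    @classmethod
    def from_header_tag(cls, tag: str, evidence: str = UNKNOWN) -> "Classification":
        parts = (tag.split("/") + [UNKNOWN] * 4)[:4]
        family = None if parts[3] in (UNKNOWN, "", "none") else parts[3]
        return cls(class_=parts[0] or UNKNOWN, order=parts[1] or UNKNOWN,
                   superfamily=parts[2] or UNKNOWN, family=family,
                   evidence=evidence)

    def is_unknown(self) -> bool:
        return (self.class_ == UNKNOWN and self.order == UNKNOWN
                and self.superfamily == UNKNOWN and self.family is None)


@dataclass
class RepeatLibraryEntry:
    """One curated repeat element with its classification."""

    name: str
    sequence: str
    classification: Classification = field(default_factory=Classification)
    source_species: str = UNKNOWN

    def __len__(self) -> int:
        return len(self.sequence)


class RepeatLibrary:
    """Uniquely named repeat elements, indexed by name."""

    def __init__(self, entries: list[RepeatLibraryEntry]):
        self.entries = entries
        self._index: dict[str, RepeatLibraryEntry] = {}
        for e in entries:
            if e.name in self._index:
                raise ValueError(f"duplicate library entry name: {e.name!r}")
            self._index[e.name] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RepeatLibraryEntry]:
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> RepeatLibraryEntry:
        if name not in self._index:
            raise KeyError(f"subject {name!r} not in library")
        return self._index[name]

    def sequences(self) -> dict[str, str]:
        return {e.name: e.sequence for e in self.entries}


def parse_library_header(header: str) -> tuple[str, Classification, str]:
    """Split ``name#Class/Order/Superfamily/Family@species``."""
    species = UNKNOWN
    if "@" in header:
        header, species = header.rsplit("@", 1)
    if "#" in header:
        name, tag = header.split("#", 1)
        cls = Classification.from_header_tag(tag)
    else:
        name, cls = header, Classification()
    return name, cls, species


def format_library_header(entry: RepeatLibraryEntry) -> str:
    header = f"{entry.name}#{entry.classification.header_tag()}"
    if entry.source_species != UNKNOWN:
        header += f"@{entry.source_species}"
    return header


def read_repeat_library(path: str | Path) -> RepeatLibrary:
    """Read a classified repeat library from FASTA."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, cls, species = parse_library_header(rec.id)
        entries.append(RepeatLibraryEntry(
            name=name, sequence=str(rec.seq).upper(),
            classification=cls, source_species=species,
        ))
    if not entries:
        raise ValueError(f"empty repeat library: {path}")
    return RepeatLibrary(entries)


def write_repeat_library(library: RepeatLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for entry in library:
            fh.write(f">{format_library_header(entry)}\n")
            seq = entry.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
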