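"""Named candidate gene lists and k-of-n membership queries.

Filter I can use prior knowledge in the form of several named lists of
candidate genes (e.g. embryonic-development GO terms, lethal/essential gene
catalogues, developmental-disorder genes, manually curated candidates).  A
variant's gene satisfies the list clause when it appears in at least
``min_list_membership`` of the loaded lists.

Symbols are matched by exact string comparison after upper-casing; no
alias or stable-ID resolution is attempted (that would require an external
nomenclature database and the curation is expected to happen upstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneListCollection:
    """Mapping of list name -> set of upper-cased gene symbols, with stable order."""

    lists: Mapping[str, frozenset[str]]
    order: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in self.order:
            if not self.lists[name]:
                raise ValueError(f"gene list {name!r} is empty")

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "GeneListCollection":
        lists = {name: frozenset(s.upper() for s in symbols) for name, symbols in d.items()}
        return cls(lists=lists, order=tuple(lists))

    @property
    def names(self) -> tuple[str, ...]:
        return self.order

    def __len__(self) -> int:
        return len(self.order)

    def membership_count(self, gene: str) -> int:
        """Number of lists containing ``gene`` (0 for unknown symbols)."""
        g = gene.upper()
        return sum(g in self.lists[name] for name in self.order)

    def union(self, selected: Sequence[str] | None = None) -> frozenset[str]:
        """Deduplicated union over the selected (default: all) lists."""
        if selected is None:
            selected = self.order
        out: set[str] = set()
        for name in selected:
            if name not in self.lists:
                raise KeyError(f"unknown gene list {name!r}")
            out |= self.lists[name]
        return frozenset(out)


def _read_symbols(path: str | Path) -> frozenset[str]:
    symbols: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        # one symbol per line; TSV accepted, first column used
        symbols.add(line.split("\t")[0].strip().upper())
    return frozenset(symbols)


def load_gene_lists(
    paths: Sequence[str | Path], names: Sequence[str]
) -> GeneListCollection:
    """Load named candidate gene lists from plain-text files.

    One name per path; '#' comment lines are skipped; duplicates within a
    list are collapsed and symbols upper-cased.  An empty file or a
    duplicate list name is an error.
    """
    if len(paths) != len(names):
        raise ValueError(f"{len(paths)} paths but {len(names)} names")
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate gene-list names in {list(names)}")
    lists: dict[str, frozenset[str]] = {}
    for name, path in zip(names, paths):
        symbols = _read_symbols(path)
        if not symbols:
            raise ValueError(f"gene list {name!r} ({path}) contains no symbols")
        lists[name] = symbols
        logger.info("gene list %s: %d symbols", name, len(symbols))
    return GeneListCollection(lists=lists, order=tuple(names))


def membership_count(gene: str, collection: GeneListCollection) -> int:
    """Number of lists in ``collection`` that contain ``gene``."""
    return collection.membership_count(gene)


def merge_candidate_compendium(
    collection: GeneListCollection, selected: Sequence[str] | None = None
) -> frozenset[str]:
    """Deduplicated union of the selected lists (the candidate compendium)."""
    return collection.union(selected)


def write_gene_list(symbols: Iterable[str], path: str | Path, name: str | None = None) -> None:
    """Write one gene list as plain text, one symbol per line, sorted."""
    lines = []
    if name:
        lines.append(f"# {name}")
    lines += sorted({s.upper() for s in symbols})
    Path(path).write_text("\n".join(lines) + "\n")
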