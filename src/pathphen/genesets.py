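"""Gene-set collections and GMT input/output.

A gene set collection maps pathway names to ordered, unique gene symbol
lists, read from the tab-separated GMT dialect (name, description,
members...).  Before use in enrichment statistics the collection is
intersected with the expression universe and size-filtered, so every
surviving set is guaranteed to have at least ``min_size`` members that are
actually measured.
"""

from __future__ import annotations

import logging
import warnings
from collections import OrderedDict
from collections.abc import Iterable, Iterator, Mapping

log = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 10


class GmtFormatError(ValueError):
    """Raised for a malformed GMT line; carries the 1-based line number."""


class GeneSetCollection(Mapping):
    """Named gene sets with deterministic iteration order.

    Gene symbols are case-normalized to upper case on construction.
    Behaves as a read-only mapping ``name -> tuple of genes``.
    """

    def __init__(self, sets: Mapping[str, Iterable[str]], source: str = "<memory>"):
        self._sets: "OrderedDict[str, tuple[str, ...]]" = OrderedDict()
        for name, genes in sets.items():
            seen: "OrderedDict[str, None]" = OrderedDict()
            dup = False
            for g in genes:
                g = str(g).upper()
                if g in seen:
                    dup = True
                else:
                    seen[g] = None
            if dup:
                warnings.warn(f"duplicate genes in set {name!r} were deduplicated")
            self._sets[name] = tuple(seen)
        self.source = source

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneSetCollection({len(self)} sets from {self.source!r})"

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def filtered(self, universe: Iterable[str], min_size: int = DEFAULT_MIN_SIZE) -> "GeneSetCollection":
        """Intersect every set with ``universe`` and drop sets below ``min_size``.

        Genes absent from the universe are removed *before* the size check.
        Raises ``ValueError`` if nothing survives.
        """
        uni = {str(g).upper() for g in universe}
        kept: "OrderedDict[str, tuple[str, ...]]" = OrderedDict()
        n_dropped = 0
        for name, genes in self._sets.items():
            present = tuple(g for g in genes if g in uni)
            if len(present) >= min_size:
                kept[name] = present
            else:
                n_dropped += 1
        if n_dropped:
            log.info("dropped %d gene sets below min_size=%d", n_dropped, min_size)
        if not kept:
            raise ValueError("no gene sets survive universe intersection and size filter")
        out = GeneSetCollection({}, source=self.source)
        out._sets = kept
        return out


def read_gmt(path, universe: Iterable[str] | None = None,
             min_size: int = DEFAULT_MIN_SIZE) -> GeneSetCollection:
    """Parse a GMT file; optionally filter against an expression universe.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.  A line
    with fewer than three fields raises :class:`GmtFormatError` with its
    line number.  When ``universe`` is given the collection is filtered
    with :meth:`GeneSetCollection.filtered`.
    """
    sets: "OrderedDict[str, list[str]]" = OrderedDict()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(f"{path}:{lineno}: expected name, description and "
                                     f"members, got {len(fields)} fields")
            name = fields[0]
            sets[name] = [g for g in fields[2:] if g]
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    coll = GeneSetCollection(sets, source=str(path))
    if universe is not None:
        coll = coll.filtered(universe, min_size=min_size)
    return coll


def write_gmt(collection: Mapping[str, Iterable[str]], path, description: str = "na") -> None:
    """Write a mapping of set name -> genes in the GMT dialect."""
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
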