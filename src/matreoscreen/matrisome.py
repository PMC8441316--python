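"""Matrisome gene-set registry: GMT I/O, category lookup, universe partition."""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from importlib import resources

MATRISOME_CATEGORIES = (
    "collagens",
    "glycoproteins",
    "proteoglycans",
    "ECM-regulators",
    "secreted-factors",
    "ECM-affiliated",
)

MASTER_SET = "matrisome"


class GmtParseError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Ordered gene sets plus a per-gene category map.

    ``sets`` maps set name -> ordered gene symbols (no duplicates within a
    set). ``categories`` maps gene -> category label for genes that belong
    to one of the recognized category sets. The master ``matrisome`` set is
    the union of all category sets, each gene counted once. ``universe``
    optionally lists all measurable symbols.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate symbols in set {name!r}")
            if any((not g) or (not isinstance(g, str)) for g in genes):
                raise ValueError(f"empty or non-string symbol in set {name!r}")

    @property
    def categories(self) -> dict[str, str]:
        cat: dict[str, str] = {}
        for name in MATRISOME_CATEGORIES:
            for g in self.sets.get(name, ()):
                cat.setdefault(g, name)
        return cat

    @property
    def matrisome(self) -> list[str]:
        """Master set: union of category sets (or an explicit set named so)."""
        if MASTER_SET in self.sets:
            return list(self.sets[MASTER_SET])
        seen: dict[str, None] = {}
        for name in MATRISOME_CATEGORIES:
            for g in self.sets.get(name, ()):
                seen.setdefault(g)
        return list(seen)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.matrisome)


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Parse a GMT file (one set per line: name, description, symbols...).

    Symbols are whitespace-trimmed and matched case-sensitively. A line
    with fewer than two tab-separated fields raises :class:`GmtParseError`
    naming the offending line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise GmtParseError(f"line {lineno}: expected >=2 tab-separated fields")
            name, desc, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(coll: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.sets.items():
            desc = coll.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def partition_universe(
    coll: GeneSetCollection, measured: list[str]
) -> tuple[list[str], list[str]]:
    """Split measured symbols into (matrisome members, background).

    Order of ``measured`` is preserved in both halves; the two lists are
    disjoint and their union is ``measured``. An empty matrisome
    intersection triggers a warning, not an error.
    """
    if not measured:
        raise ValueError("measured gene list is empty")
    members = set(coll.matrisome)
    inside = [g for g in measured if g in members]
    outside = [g for g in measured if g not in members]
    if not inside:
        warnings.warn("no measured genes are matrisome members", stacklevel=2)
    return inside, outside


def load_demo_matrisome() -> GeneSetCollection:
    """Packaged six-category demo GMT used by tests and the demo pipeline."""
    ref = resources.files("matreoscreen") / "data" / "matrisome_demo.gmt"
    with resources.as_file(ref) as p:
        return read_gmt(p)
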