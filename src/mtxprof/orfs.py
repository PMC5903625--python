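"""ORF catalogs: contig-anchored coding intervals with family and KO annotations.

The catalog is the universe over which all read counting and taxonomic /
functional stratification happens. Coordinates are held 0-based half-open
internally; GFF3 I/O converts to and from the standard's 1-based inclusive
convention (feature type ``CDS``, attributes carry ``family`` and ``ko``).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = ["Orf", "OrfCatalog", "CatalogError"]


class CatalogError(ValueError):
    """Raised for malformed ORF catalogs (bad intervals, duplicate ids)."""


@dataclass(frozen=True)
class Orf:
    """A predicted protein-coding interval on an assembled contig.

    ``start``/``end`` are 0-based half-open on the contig. ``family`` is the
    best-hit taxonomic family (or None if unannotated here); ``ko`` the KEGG
    orthology identifier, at most one per ORF.
    """

    orf_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    family: Optional[str] = None
    ko: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CatalogError(
                f"ORF {self.orf_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise CatalogError(f"ORF {self.orf_id!r}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


class OrfCatalog:
    """An ordered collection of :class:`Orf` with unique identifiers."""

    def __init__(self, orfs: Iterable[Orf]):
        self.orfs: list[Orf] = list(orfs)
        seen: set[str] = set()
        for o in self.orfs:
            if o.orf_id in seen:
                raise CatalogError(f"duplicate orf_id {o.orf_id!r}")
            seen.add(o.orf_id)
        self._by_contig: dict[str, list[Orf]] = defaultdict(list)
        for o in self.orfs:
            self._by_contig[o.contig_id].append(o)
        for lst in self._by_contig.values():
            lst.sort(key=lambda o: (o.start, o.end, o.orf_id))

    def __len__(self) -> int:
        return len(self.orfs)

    def __iter__(self) -> Iterator[Orf]:
        return iter(self.orfs)

    @property
    def orf_ids(self) -> list[str]:
        return [o.orf_id for o in self.orfs]

    @property
    def contig_ids(self) -> set[str]:
        return set(self._by_contig)

    def on_contig(self, contig_id: str) -> list[Orf]:
        """ORFs on one contig, sorted by start coordinate."""
        return self._by_contig.get(contig_id, [])

    def lengths(self) -> pd.Series:
        return pd.Series({o.orf_id: o.length for o in self.orfs}, name="length")

    def family_map(self) -> dict[str, str]:
        """orf_id -> family for ORFs that carry a family annotation."""
        return {o.orf_id: o.family for o in self.orfs if o.family is not None}

    def ko_map(self) -> dict[str, str]:
        """orf_id -> KO for ORFs that carry a KO annotation."""
        return {o.orf_id: o.ko for o in self.orfs if o.ko is not None}

    # ------------------------------------------------------------------ I/O

    def to_gff3(self, path) -> None:
        """Write as GFF3 (1-based inclusive, feature type CDS)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for o in self.orfs:
                attrs = [f"ID={o.orf_id}"]
                if o.family is not None:
                    attrs.append(f"family={o.family}")
                if o.ko is not None:
                    attrs.append(f"ko={o.ko}")
                fh.write(
                    "\t".join(
                        [
                            o.contig_id,
                            "mtxprof",
                            "CDS",
                            str(o.start + 1),
                            str(o.end),
                            ".",
                            o.strand,
                            "0",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def from_gff3(cls, path) -> "OrfCatalog":
        """Read CDS features from a GFF3 table (1-based inclusive coordinates)."""
        orfs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 9:
                    raise CatalogError(f"malformed GFF3 line: {line!r}")
                contig, _src, ftype, start1, end1, _score, strand, _frame, attrs = fields
                if ftype != "CDS":
                    continue
                adict = {}
                for item in attrs.split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        adict[k.strip()] = v.strip()
                if "ID" not in adict:
                    raise CatalogError(f"CDS feature without ID attribute: {line!r}")
                orfs.append(
                    Orf(
                        orf_id=adict["ID"],
                        contig_id=contig,
                        start=int(start1) - 1,
                        end=int(end1),
                        strand=strand if strand in ("+", "-") else "+",
                        family=adict.get("family"),
                        ko=adict.get("ko"),
                    )
                )
        return cls(orfs)
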