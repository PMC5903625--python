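"""KEGG-module catalogs: named KO sets forming functional units.

A module (e.g. M00196, multiple sugar transport system) is a curated set of
KEGG orthology identifiers. The bundled default catalog mirrors the shape of
the module table analysed in the pipeline (six modules: three sugar-related,
three protein-related) with synthetic KO memberships — KEGG's own definitions
are licensed data and are supplied by the user as a TSV when available.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["Module", "ModuleCatalog", "ModuleCatalogError"]


class ModuleCatalogError(ValueError):
    """Malformed module catalog or module/KO-pool inconsistency."""


@dataclass(frozen=True)
class Module:
    module_id: str
    description: str
    kos: frozenset

    def __post_init__(self) -> None:
        if not self.kos:
            raise ModuleCatalogError(f"module {self.module_id!r} has an empty KO set")


class ModuleCatalog:
    """Ordered mapping of module_id -> :class:`Module`."""

    def __init__(self, modules: Iterable[Module]):
        self.modules: dict[str, Module] = {}
        for m in modules:
            if m.module_id in self.modules:
                raise ModuleCatalogError(f"duplicate module id {m.module_id!r}")
            self.modules[m.module_id] = m

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules.values())

    def __contains__(self, module_id: str) -> bool:
        return module_id in self.modules

    def __getitem__(self, module_id: str) -> Module:
        return self.modules[module_id]

    @property
    def all_kos(self) -> frozenset:
        out: set = set()
        for m in self:
            out |= m.kos
        return frozenset(out)

    def validate_against_pool(self, ko_pool) -> None:
        """Every module KO must exist in the given KO pool."""
        pool = set(ko_pool)
        for m in self:
            extra = m.kos - pool
            if extra:
                raise ModuleCatalogError(
                    f"module {m.module_id} contains KOs outside the pool: {sorted(extra)}"
                )

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path) -> None:
        rows = [
            (m.module_id, m.description, ",".join(sorted(m.kos))) for m in self
        ]
        pd.DataFrame(rows, columns=["module_id", "description", "kos"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "ModuleCatalog":
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = {"module_id", "description", "kos"} - set(df.columns)
        if missing:
            raise ModuleCatalogError(f"module TSV missing columns: {sorted(missing)}")
        return cls(
            Module(
                module_id=str(r.module_id),
                description=str(r.description),
                kos=frozenset(k.strip() for k in str(r.kos).split(",") if k.strip()),
            )
            for r in df.itertuples(index=False)
        )

    @classmethod
    def default(cls) -> "ModuleCatalog":
        """The bundled synthetic six-module catalog."""
        with resources.files("mtxprof.data").joinpath("default_modules.tsv").open() as fh:
            import io

            return cls.from_tsv(io.StringIO(fh.read()))
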