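"""Study design: samples, diets and the 2×2 protein × fat factor structure.

Diets follow the NPLF / NPHF / HPLF / HPHF naming (normal/high protein ×
low/high fat); the protein level (NP vs HP) is the primary contrast for the
differential analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

__all__ = ["DIETS", "Sample", "StudyDesign", "protein_level", "fat_level"]

DIETS = ("NPLF", "NPHF", "HPLF", "HPHF")


def protein_level(diet: str) -> str:
    """'NP' or 'HP' for a diet code."""
    if diet not in DIETS:
        raise ValueError(f"unknown diet {diet!r}; expected one of {DIETS}")
    return diet[:2]


def fat_level(diet: str) -> str:
    """'LF' or 'HF' for a diet code."""
    if diet not in DIETS:
        raise ValueError(f"unknown diet {diet!r}; expected one of {DIETS}")
    return diet[2:]


@dataclass(frozen=True)
class Sample:
    sample_id: str
    diet: str
    mouse_weight: float = float("nan")

    def __post_init__(self) -> None:
        if self.diet not in DIETS:
            raise ValueError(f"sample {self.sample_id!r}: unknown diet {self.diet!r}")

    @property
    def protein_level(self) -> str:
        return protein_level(self.diet)

    @property
    def fat_level(self) -> str:
        return fat_level(self.diet)


class StudyDesign:
    """An ordered collection of samples with unique ids."""

    def __init__(self, samples: Iterable[Sample]):
        self.samples: list[Sample] = list(samples)
        seen: set[str] = set()
        dups: list[str] = []
        for s in self.samples:
            (dups if s.sample_id in seen else seen).append(s.sample_id) if False else None
            if s.sample_id in seen:
                dups.append(s.sample_id)
            seen.add(s.sample_id)
        if dups:
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def diet_of(self) -> dict[str, str]:
        return {s.sample_id: s.diet for s in self.samples}

    def factor(self, name: str) -> dict[str, str]:
        """sample_id -> level for factor 'diet', 'protein_level' or 'fat_level'."""
        if name == "diet":
            return {s.sample_id: s.diet for s in self.samples}
        if name == "protein_level":
            return {s.sample_id: s.protein_level for s in self.samples}
        if name == "fat_level":
            return {s.sample_id: s.fat_level for s in self.samples}
        raise ValueError(f"unknown factor {name!r}")

    def samples_with(self, **criteria: str) -> list[str]:
        out = []
        for s in self.samples:
            if all(getattr(s, k) == v for k, v in criteria.items()):
                out.append(s.sample_id)
        return out

    @classmethod
    def balanced(
        cls,
        replicates: int = 4,
        weights: Optional[dict] = None,
        nplf_replicates: Optional[int] = None,
    ) -> "StudyDesign":
        """A balanced 4-diet design (``nplf_replicates`` allows the 3-mouse
        NPLF group of the motivating study)."""
        samples = []
        for diet in DIETS:
            n = replicates
            if diet == "NPLF" and nplf_replicates is not None:
                n = nplf_replicates
            for i in range(1, n + 1):
                w = float("nan") if weights is None else weights.get(diet, float("nan"))
                samples.append(Sample(sample_id=f"{diet}_{i}", diet=diet, mouse_weight=w))
        return cls(samples)

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [(s.sample_id, s.diet, s.protein_level, s.fat_level, s.mouse_weight)
             for s in self.samples],
            columns=["sample_id", "diet", "protein_level", "fat_level", "mouse_weight"],
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StudyDesign":
        df = pd.read_csv(path, sep="\t")
        missing = {"sample_id", "diet"} - set(df.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        return cls(
            Sample(
                sample_id=str(r.sample_id),
                diet=str(r.diet),
                mouse_weight=float(getattr(r, "mouse_weight", float("nan"))),
            )
            for r in df.itertuples(index=False)
        )
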