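"""Taxonomic (best-hit family) and functional (KO category) annotation.

Family assignment follows the best-hit rule: an ORF inherits the taxonomic
family of its highest-scoring protein database hit. Function categories are
named KO sets (peptidases, amino-acid metabolism, amino-acid transporters,
SCFA production pathways); activity of a category is the summed normalized
expression of ORFs whose KO belongs to the set, optionally stratified by
family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd

from .quantify import ExpressionMatrix, aggregate_by

__all__ = [
    "HitRecord",
    "FunctionCategoryConfig",
    "UNCLASSIFIED",
    "assign_family_best_hit",
    "family_activity",
    "filter_families_for_plot",
    "category_activity",
    "read_hits_tsv",
    "write_hits_tsv",
]

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"

#: The three SCFA-production pathway KO sets, as published. Note K01895
#: (acetyl-CoA synthase) is a member of both the acetate and the propionate
#: pathway; the overlap is preserved deliberately.
SCFA_ACETATE_KOS = frozenset({"K00925", "K00625", "K01895", "K13788"})
SCFA_PROPIONATE_KOS = frozenset({"K01895", "K01026"})
SCFA_BUTYRATE_KOS = frozenset({"K01034", "K01035", "K01896", "K00929", "K00634"})


@dataclass(frozen=True)
class HitRecord:
    """One protein-database hit of a predicted ORF protein."""

    orf_id: str
    subject_id: str
    bit_score: float
    e_value: float
    subject_family: str = UNCLASSIFIED

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"hit {self.orf_id}->{self.subject_id}: e_value < 0")


@dataclass(frozen=True)
class FunctionCategoryConfig:
    """Named KO sets defining function categories."""

    categories: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        for name, kos in self.categories.items():
            if not kos:
                raise ValueError(f"category {name!r} has an empty KO set")

    def __getitem__(self, name: str) -> frozenset:
        return self.categories[name]

    def __iter__(self):
        return iter(self.categories)

    @classmethod
    def from_tsv(cls, path) -> "FunctionCategoryConfig":
        df = pd.read_csv(path, sep="\t", comment="#")
        cats = {
            str(r.category): frozenset(
                k.strip() for k in str(r.kos).split(",") if k.strip()
            )
            for r in df.itertuples(index=False)
        }
        return cls(categories=cats)

    def to_tsv(self, path) -> None:
        rows = [(name, ",".join(sorted(kos))) for name, kos in self.categories.items()]
        pd.DataFrame(rows, columns=["category", "kos"]).to_csv(path, sep="\t", index=False)

    @classmethod
    def default(cls) -> "FunctionCategoryConfig":
        """Bundled defaults: published SCFA pathway sets plus editable
        synthetic peptidase / AA metabolism / AA transporter sets."""
        with resources.files("mtxprof.data").joinpath("default_categories.tsv").open() as fh:
            import io

            cfg = cls.from_tsv(io.StringIO(fh.read()))
        assert cfg["scfa_acetate"] == SCFA_ACETATE_KOS
        assert cfg["scfa_propionate"] == SCFA_PROPIONATE_KOS
        assert cfg["scfa_butyrate"] == SCFA_BUTYRATE_KOS
        return cfg


# ------------------------------------------------------------- best-hit rule


def assign_family_best_hit(
    hits: Iterable[HitRecord],
    orf_ids: Optional[Iterable[str]] = None,
    max_e_value: Optional[float] = None,
) -> dict[str, str]:
    """Assign each ORF the family of its highest-similarity hit.

    Hits are ranked by descending bit score, ties broken by ascending
    e-value, then lexicographic subject id — a total order, so the result is
    invariant to input order. ORFs listed in ``orf_ids`` but lacking hits
    (or whose hits all exceed ``max_e_value``) are assigned ``unclassified``.
    """
    best: dict[str, HitRecord] = {}
    for h in hits:
        if max_e_value is not None and h.e_value > max_e_value:
            continue
        cur = best.get(h.orf_id)
        if cur is None or (-h.bit_score, h.e_value, h.subject_id) < (
            -cur.bit_score,
            cur.e_value,
            cur.subject_id,
        ):
            best[h.orf_id] = h
    out = {oid: h.subject_family for oid, h in best.items()}
    if orf_ids is not None:
        for oid in orf_ids:
            out.setdefault(oid, UNCLASSIFIED)
    return out


def read_hits_tsv(path) -> list[HitRecord]:
    """Read an outfmt-6-like hit table with an appended family column.

    Required columns: orf_id, subject_id, bit_score, e_value, family.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"orf_id", "subject_id", "bit_score", "e_value", "family"} - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return [
        HitRecord(
            orf_id=str(r.orf_id),
            subject_id=str(r.subject_id),
            bit_score=float(r.bit_score),
            e_value=float(r.e_value),
            subject_family=str(r.family),
        )
        for r in df.itertuples(index=False)
    ]


def write_hits_tsv(hits: Iterable[HitRecord], path) -> None:
    rows = [
        (h.orf_id, h.subject_id, h.bit_score, h.e_value, h.subject_family) for h in hits
    ]
    pd.DataFrame(
        rows, columns=["orf_id", "subject_id", "bit_score", "e_value", "family"]
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------- activity summaries


def family_activity(
    norm: ExpressionMatrix, family_map: Mapping[str, str]
) -> pd.DataFrame:
    """Family × sample relative activity (columns sum to 1)."""
    out = aggregate_by(norm, family_map, unassigned_label=UNCLASSIFIED)
    out.index.name = "family"
    return out

def filter_families_for_plot(
    family_matrix: pd.DataFrame,
    sample_groups: Mapping[str, str],
    threshold: float = 0.005,
) -> list[str]:
    """Families whose mean activity exceeds ``threshold`` in ≥1 condition.

    ``sample_groups`` maps sample id -> diet group; "conditions" are the
    diet-group means, so a family abundant in a single diet is retained.
    The default 0.5% is the conventional plotting cutoff.
    """
    if not (0 <= threshold < 1):
        raise ValueError("threshold must lie in [0, 1)")
    groups = pd.Series({s: sample_groups[s] for s in family_matrix.columns})
    group_means = family_matrix.T.groupby(groups).mean().T
    if threshold == 0:
        keep = (group_means > 0).any(axis=1)
    else:
        keep = (group_means > threshold).any(axis=1)
    return [f for f in family_matrix.index if keep[f]]


def category_activity(
    norm: ExpressionMatrix,
    ko_map: Mapping[str, str],
    categories: FunctionCategoryConfig,
    family_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-category (optionally per-family) summed activity per sample.

    Returns a DataFrame indexed by category, or by (category, family) when
    ``family_map`` is given. A category none of whose KOs are detected yields
    an explicit zero row and a logged warning. Because categories may share
    KOs (the acetate and propionate pathways both contain K01895), rows are
    computed independently and may double-count shared KOs, as published.
    """
    values = norm.values
    samples = values.columns
    rows = {}
    for name in categories:
        kos = categories[name]
        member_orfs = [oid for oid in values.index if ko_map.get(oid) in kos]
        if not member_orfs:
            logger.warning("category %r: no detected KOs; emitting zero row", name)
        if family_map is None:
            rows[name] = values.loc[member_orfs].sum(axis=0) if member_orfs else pd.Series(
                0.0, index=samples
            )
        else:
            families = sorted(set(family_map.values()) | {UNCLASSIFIED})
            sub = values.loc[member_orfs]
            fam_labels = pd.Series(
                [family_map.get(oid, UNCLASSIFIED) for oid in member_orfs],
                index=sub.index,
            )
            fam_sum = sub.groupby(fam_labels).sum() if member_orfs else pd.DataFrame(
                columns=samples
            )
            for fam in families:
                if fam in fam_sum.index:
                    rows[(name, fam)] = fam_sum.loc[fam]
                else:
                    rows[(name, fam)] = pd.Series(0.0, index=samples)
    out = pd.DataFrame(rows).T
    out.columns = samples
    if family_map is None:
        out.index.name = "category"
    else:
        out.index = pd.MultiIndex.from_tuples(out.index, names=["category", "family"])
    return out
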