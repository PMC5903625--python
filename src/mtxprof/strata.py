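"""Family-stratified functional profiles and pathway-map exports.

These operations decompose each function category's activity by the
taxonomic family of the contributing ORFs: which families express the
peptidases, amino-acid metabolism proteins and transporters, and which
families carry the acetate / propionate / butyrate production pathways.
Stratified profiles always sum over families to the unstratified category
activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .design import StudyDesign
from .quantify import ExpressionMatrix
from .taxfun import (
    UNCLASSIFIED,
    FunctionCategoryConfig,
    category_activity,
    filter_families_for_plot,
)

__all__ = [
    "FamilyFunctionProfile",
    "ScfaPathwayProfile",
    "build_family_function_profile",
    "build_scfa_pathway_profile",
    "single_ko_report",
    "ipath_width_export",
    "write_ipath_selection",
    "SCFA_PATHWAYS",
]

logger = logging.getLogger(__name__)

SCFA_PATHWAYS = ("acetate", "propionate", "butyrate")
_SCFA_CATEGORY = {p: f"scfa_{p}" for p in SCFA_PATHWAYS}


@dataclass
class FamilyFunctionProfile:
    """Tidy family × category × sample relative-activity table."""

    table: pd.DataFrame  # columns: family, category, sample, relative_activity

    def category_totals(self) -> pd.DataFrame:
        """category × sample totals (marginal over families)."""
        return self.table.pivot_table(
            index="category", columns="sample", values="relative_activity",
            aggfunc="sum", fill_value=0.0,
        )

    def display_subset(
        self, sample_groups: Mapping[str, str], threshold: float = 0.005
    ) -> pd.DataFrame:
        """Apply the plotting filter: keep families whose total activity
        exceeds ``threshold`` in at least one diet-group mean. The full
        table remains available unfiltered."""
        fam_matrix = self.table.pivot_table(
            index="family", columns="sample", values="relative_activity",
            aggfunc="sum", fill_value=0.0,
        )
        keep = set(filter_families_for_plot(fam_matrix, sample_groups, threshold))
        return self.table[self.table["family"].isin(keep)].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class ScfaPathwayProfile:
    """Per family × pathway × diet group mean and SD of pathway activity."""

    table: pd.DataFrame  # columns: family, pathway, diet, mean_activity, sd_activity

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def build_family_function_profile(
    norm: ExpressionMatrix,
    ko_map: Mapping[str, str],
    family_map: Mapping[str, str],
    categories: FunctionCategoryConfig,
) -> FamilyFunctionProfile:
    """Stratify each category's activity by contributing family.

    Every family × category combination is materialised (zero rows present,
    not missing), so downstream joins never silently drop absent strata.
    """
    strat = category_activity(norm, ko_map, categories, family_map=family_map)
    tidy = (
        strat.stack()
        .rename("relative_activity")
        .reset_index()
        .rename(columns={"level_2": "sample"})
    )
    tidy.columns = ["category", "family", "sample", "relative_activity"]
    tidy = tidy[["family", "category", "sample", "relative_activity"]]
    return FamilyFunctionProfile(
        table=tidy.sort_values(["family", "category", "sample"]).reset_index(drop=True)
    )


def build_scfa_pathway_profile(
    norm: ExpressionMatrix,
    ko_map: Mapping[str, str],
    family_map: Mapping[str, str],
    design: StudyDesign,
    scfa_config: Optional[FunctionCategoryConfig] = None,
    merge_shared_kos_to_acetate: bool = False,
    ddof: int = 1,
) -> ScfaPathwayProfile:
    """Family attribution of SCFA-production pathway activity, with group SDs.

    For each family × pathway, activity is summed over the pathway's KOs per
    sample, then averaged within each diet group (SD across the group's
    samples, ``ddof=1``). The default pathway KO sets share K01895 between
    acetate and propionate, preserved as published;
    ``merge_shared_kos_to_acetate=True`` instead credits shared KOs to
    acetate only.
    """
    if scfa_config is None:
        scfa_config = FunctionCategoryConfig.default()
    sets = {p: set(scfa_config[_SCFA_CATEGORY[p]]) for p in SCFA_PATHWAYS}
    if merge_shared_kos_to_acetate:
        sets["propionate"] -= sets["acetate"]
        sets["butyrate"] -= sets["acetate"]
    cfg = FunctionCategoryConfig(
        categories={p: frozenset(s) for p, s in sets.items() if s}
    )
    strat = category_activity(norm, ko_map, cfg, family_map=family_map)
    diets = design.diet_of()
    rows = []
    for (pathway, family), activity in strat.iterrows():
        for diet in dict.fromkeys(diets[s] for s in activity.index if s in diets):
            vals = activity[[s for s in activity.index if diets.get(s) == diet]]
            rows.append(
                {
                    "family": family,
                    "pathway": pathway,
                    "diet": diet,
                    "mean_activity": float(vals.mean()),
                    "sd_activity": float(vals.std(ddof=ddof)) if len(vals) > ddof else 0.0,
                }
            )
    table = pd.DataFrame(rows).sort_values(["pathway", "family", "diet"]).reset_index(drop=True)
    return ScfaPathwayProfile(table=table)


def single_ko_report(
    norm: ExpressionMatrix,
    ko_map: Mapping[str, str],
    family_map: Mapping[str, str],
    ko: str,
) -> pd.DataFrame:
    """Family × sample activity of a single KO (e.g. 6-phosphofructokinase).

    Unknown or undetected KOs yield an empty table plus a warning.
    """
    member_orfs = [oid for oid in norm.values.index if ko_map.get(oid) == ko]
    if not member_orfs:
        logger.warning("KO %r not detected in the expression matrix; empty report", ko)
        return pd.DataFrame(columns=norm.values.columns, index=pd.Index([], name="family"))
    sub = norm.values.loc[member_orfs]
    fam = pd.Series(
        [family_map.get(oid, UNCLASSIFIED) for oid in member_orfs], index=sub.index
    )
    out = sub.groupby(fam).sum()
    out.index.name = "family"
    return out


def ipath_width_export(
    ko_raw_counts: pd.DataFrame,
    group_samples: Sequence[str],
) -> pd.DataFrame:
    """Pathway-map line widths from raw per-KO read-nucleotide counts.

    width(KO) = log10(1 + Σ counts over the group's samples); KOs with zero
    group count are omitted. The +1 offset keeps single-count KOs visible
    and zero-count KOs undefined, matching the log10 read-count convention.
    """
    missing = [s for s in group_samples if s not in ko_raw_counts.columns]
    if missing:
        raise ValueError(f"samples not in count matrix: {missing}")
    totals = ko_raw_counts[list(group_samples)].sum(axis=1)
    totals = totals[totals > 0]
    widths = np.log10(1.0 + totals.to_numpy(float))
    return pd.DataFrame({"ko": totals.index, "width": widths}).reset_index(drop=True)


def write_ipath_selection(widths: pd.DataFrame, path) -> None:
    """Write an iPath-style selection file: one ``Kxxxxx Wwidth`` row per KO."""
    with open(path, "w") as fh:
        for r in widths.itertuples(index=False):
            fh.write(f"{r.ko} W{r.width:g}\n")
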