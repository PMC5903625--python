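"""Differential statistics: per-KO t-tests, module enrichment, SCFA and
category group tests.

The differential pipeline mirrors a two-stage design: (1) per-KO Welch
t-tests of normalized activity between protein-level groups (NP vs HP);
(2) significantly higher KOs of each direction pooled, and each KEGG module
scored by the one-sided hypergeometric tail probability of containing at
least the observed number of significant members, over the universe of
detected (expressed) KOs. Univariate group comparisons use Welch t-tests
(SCFA concentrations) or exact Wilcoxon rank-sum tests (function-category
activity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import StudyDesign
from .modules import ModuleCatalog

__all__ = [
    "KoDifferentialResult",
    "ModuleEnrichmentResult",
    "ko_ttest",
    "significant_ko_sets",
    "module_enrichment",
    "estimate_module_fold",
    "scfa_group_test",
    "wilcoxon_category_test",
    "bh_adjust",
    "SCFA_ACIDS",
    "DEFAULT_SCFA_PAIRINGS",
]

logger = logging.getLogger(__name__)

SCFA_ACIDS = (
    "acetate",
    "propionate",
    "butyrate",
    "valerate",
    "iso-butyrate",
    "iso-valerate",
)

#: Fig-1-style contrasts: protein level compared within matching fat level.
DEFAULT_SCFA_PAIRINGS = (("NPLF", "HPLF"), ("NPHF", "HPHF"))


@dataclass(frozen=True)
class KoDifferentialResult:
    ko_id: str
    mean_np: float
    mean_hp: float
    t_statistic: float
    p_value: float
    direction: str  # "NP-higher" | "HP-higher"
    degenerate: bool = False  # zero variance in both groups with equal means


@dataclass(frozen=True)
class ModuleEnrichmentResult:
    module_id: str
    description: str
    n_module_kos_total: int  # all KOs in the module definition
    n_module_kos_detected: int  # restricted to the detected-KO universe
    k_significant: int
    p_enrichment: float
    direction: str  # "NP" | "HP"

    @property
    def significant(self) -> bool:
        return self.p_enrichment < 0.05


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Welch t-test along the last axis."""
    t, p = stats.ttest_ind(a, b, axis=-1, equal_var=False)
    return np.asarray(t), np.asarray(p)


def ko_ttest(
    ko_matrix: pd.DataFrame,
    design: StudyDesign,
    factor: str = "protein_level",
) -> list[KoDifferentialResult]:
    """Per-KO two-sample Welch t-test between the two levels of ``factor``.

    ``ko_matrix`` is KO × sample normalized activity. Results are sorted by
    p-value. A KO with zero variance and equal means in both groups is
    degenerate: t = 0, p = 1, flagged.
    """
    levels = design.factor(factor)
    present = [s for s in ko_matrix.columns if s in levels]
    lvl_names = sorted(set(levels[s] for s in present))
    if len(lvl_names) != 2:
        raise ValueError(f"factor {factor!r} must have exactly 2 levels, got {lvl_names}")
    # convention: first group is the NP-like (alphabetically HP < NP, so fix order)
    if set(lvl_names) == {"NP", "HP"}:
        g1_name, g2_name = "NP", "HP"
    else:
        g1_name, g2_name = lvl_names
    g1 = [s for s in present if levels[s] == g1_name]
    g2 = [s for s in present if levels[s] == g2_name]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")
    a = ko_matrix[g1].to_numpy(float)
    b = ko_matrix[g2].to_numpy(float)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows produce a precision warning and nan; both handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = _welch(a, b)
    mean1 = a.mean(axis=1)
    mean2 = b.mean(axis=1)
    results = []
    for i, ko in enumerate(ko_matrix.index):
        ti, pi = float(t[i]), float(p[i])
        degenerate = False
        if not np.isfinite(ti) or not np.isfinite(pi):
            # zero variance in both groups
            if np.isclose(mean1[i], mean2[i]):
                ti, pi, degenerate = 0.0, 1.0, True
            else:
                # perfectly separated constant groups: infinitely strong evidence
                ti = float(np.sign(mean1[i] - mean2[i]) * np.inf)
                pi = 0.0
        direction = f"{g1_name}-higher" if mean1[i] >= mean2[i] else f"{g2_name}-higher"
        results.append(
            KoDifferentialResult(
                ko_id=str(ko),
                mean_np=float(mean1[i]),
                mean_hp=float(mean2[i]),
                t_statistic=ti,
                p_value=pi,
                direction=direction,
                degenerate=degenerate,
            )
        )
    if any(r.degenerate for r in results):
        logger.warning(
            "%d KO(s) with zero variance and equal means in both groups (p set to 1)",
            sum(r.degenerate for r in results),
        )
    results.sort(key=lambda r: (r.p_value, r.ko_id))
    return results


def significant_ko_sets(
    results: Iterable[KoDifferentialResult], alpha: float = 0.05
) -> dict[str, set]:
    """Split significant KOs by direction: {'NP': {...}, 'HP': {...}}."""
    out: dict[str, set] = {"NP": set(), "HP": set()}
    for r in results:
        if r.p_value < alpha:
            out[r.direction.split("-")[0]].add(r.ko_id)
    return out


def module_enrichment(
    significant_kos: set,
    detected_kos: set,
    modules: ModuleCatalog,
    alpha: float = 0.05,
    direction: str = "",
    method: str = "hypergeometric",
    bh: bool = False,
) -> list[ModuleEnrichmentResult]:
    """Score each module for over-representation of significant KOs.

    With ``N`` detected KOs of which ``S`` are significant, a module whose
    detected membership has size ``n`` and contains ``k`` significant KOs
    gets p = P[X ≥ k] for X ~ Hypergeom(N, S, n) (or Binomial(n, S/N) with
    ``method='binomial'``). All modules with n ≥ 1 are reported, sorted by
    p; modules with no detected KOs are skipped with a log notice.
    ``bh=True`` replaces raw p-values with Benjamini–Hochberg adjusted ones.
    """
    significant_kos = set(significant_kos)
    detected_kos = set(detected_kos)
    if not significant_kos <= detected_kos:
        raise ValueError("significant KOs must be a subset of detected KOs")
    if method not in ("hypergeometric", "binomial"):
        raise ValueError(f"unknown method {method!r}")
    N = len(detected_kos)
    S = len(significant_kos)
    results = []
    for m in modules:
        detected = m.kos & detected_kos
        n = len(detected)
        if n == 0:
            logger.info("module %s has no detected KOs; skipped", m.module_id)
            continue
        k = len(detected & significant_kos)
        if method == "hypergeometric":
            p = float(stats.hypergeom.sf(k - 1, N, S, n))
        else:
            p = float(stats.binom.sf(k - 1, n, S / N)) if N else 1.0
        results.append(
            ModuleEnrichmentResult(
                module_id=m.module_id,
                description=m.description,
                n_module_kos_total=len(m.kos),
                n_module_kos_detected=n,
                k_significant=k,
                p_enrichment=min(1.0, p),
                direction=direction,
            )
        )
    if bh and results:
        adj = bh_adjust([r.p_enrichment for r in results])
        results = [
            ModuleEnrichmentResult(
                module_id=r.module_id,
                description=r.description,
                n_module_kos_total=r.n_module_kos_total,
                n_module_kos_detected=r.n_module_kos_detected,
                k_significant=r.k_significant,
                p_enrichment=float(q),
                direction=r.direction,
            )
            for r, q in zip(results, adj)
        ]
    results.sort(key=lambda r: (r.p_enrichment, r.module_id))
    return results


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvalues, float), method="bh")


def estimate_module_fold(
    ko_matrix: pd.DataFrame,
    design: StudyDesign,
    module_kos: Iterable[str],
    factor: str = "protein_level",
) -> float:
    """Estimate a module's HP/NP activity ratio.

    Ratio of group means of the module's summed KO activity; a planted
    HP-enriched fold f is recovered as f, an NP-enriched fold as 1/f.
    """
    levels = design.factor(factor)
    kos = [k for k in module_kos if k in ko_matrix.index]
    if not kos:
        raise ValueError("none of the module KOs are present in the matrix")
    activity = ko_matrix.loc[kos].sum(axis=0)
    np_samples = [s for s in ko_matrix.columns if levels.get(s) == "NP"]
    hp_samples = [s for s in ko_matrix.columns if levels.get(s) == "HP"]
    mean_np = activity[np_samples].mean()
    mean_hp = activity[hp_samples].mean()
    if mean_np == 0:
        raise ValueError("module has zero NP-group activity; fold undefined")
    return float(mean_hp / mean_np)


# ------------------------------------------------------------ SCFA & category


def scfa_group_test(
    panel: pd.DataFrame,
    pairings: Sequence[tuple[str, str]] = DEFAULT_SCFA_PAIRINGS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-acid, per-pairing two-sample Welch t-tests of SCFA concentrations.

    ``panel`` is tidy with columns mouse_id, diet, acid, concentration
    (μmol/g). Returns a DataFrame with columns acid, diet_a, diet_b,
    mean_a, mean_b, t_statistic, p_value, significant.
    """
    required = {"mouse_id", "diet", "acid", "concentration"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"SCFA panel missing columns: {sorted(missing)}")
    rows = []
    for acid in panel["acid"].unique():
        sub = panel[panel["acid"] == acid]
        for diet_a, diet_b in pairings:
            a = sub.loc[sub["diet"] == diet_a, "concentration"].to_numpy(float)
            b = sub.loc[sub["diet"] == diet_b, "concentration"].to_numpy(float)
            if len(a) < 2 or len(b) < 2:
                raise ValueError(
                    f"acid {acid!r}, pairing {diet_a} vs {diet_b}: "
                    "each group needs at least 2 mice"
                )
            if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                {
                    "acid": acid,
                    "diet_a": diet_a,
                    "diet_b": diet_b,
                    "mean_a": a.mean(),
                    "mean_b": b.mean(),
                    "t_statistic": float(t),
                    "p_value": float(p),
                    "significant": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)


def wilcoxon_category_test(
    values: pd.Series,
    groups: Mapping[str, str],
    exact_max_n: int = 8,
) -> float:
    """Two-sided Wilcoxon rank-sum p-value for a category's activity.

    ``values`` is per-sample activity; ``groups`` maps sample -> one of two
    labels. The exact null distribution is used when both groups have at
    most ``exact_max_n`` samples and there are no ties; all-tied data give
    p = 1 by convention.
    """
    labels = sorted(set(groups[s] for s in values.index if s in groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    a = values[[s for s in values.index if groups.get(s) == labels[0]]].to_numpy(float)
    b = values[[s for s in values.index if groups.get(s) == labels[1]]].to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= exact_max_n and len(b) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(1.0, res.pvalue))
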