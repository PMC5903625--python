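"""Simulation studies: calibration and recovery experiments on synthetic data.

These drivers run the full analysis path (simulate → quantify → annotate →
test) over many replicate synthetic datasets to measure type-I error of the
module-enrichment procedure, power to recover planted module effects,
fold-change recovery accuracy, the reliability of the NP/HP clustering
split, and the null uniformity of the RDA permutation test. They are used by
the acceptance checks and are part of the public API for anyone validating
changes to the statistical machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import diffstats, multivariate, synthetic
from .design import StudyDesign, Sample
from .modules import ModuleCatalog
from .quantify import aggregate_by, normalize_per_sample
from .taxfun import UNCLASSIFIED

__all__ = [
    "SyntheticUniverse",
    "build_universe",
    "two_group_design",
    "null_module_rejection",
    "null_wilcoxon_rejection",
    "null_scfa_rejection",
    "module_recovery",
    "fold_recovery",
    "clustering_split_rate",
    "rda_null_rejection",
]


def _filler_kos(n: int) -> list[str]:
    return [f"K79{i:03d}" for i in range(1, n + 1)]


@dataclass
class SyntheticUniverse:
    """A fixed synthetic community reused across replicate simulations."""

    truth: synthetic.CommunityTruth
    design: StudyDesign
    modules: ModuleCatalog
    catalog: object
    ko_map: dict
    family_map: dict
    expected: pd.DataFrame


def two_group_design(replicates: int = 4) -> StudyDesign:
    """A minimal NP-vs-HP contrast: ``replicates`` NPLF and HPLF samples."""
    samples = [
        Sample(f"NPLF_{i}", "NPLF", 32.0) for i in range(1, replicates + 1)
    ] + [Sample(f"HPLF_{i}", "HPLF", 28.0) for i in range(1, replicates + 1)]
    return StudyDesign(samples)


def build_universe(
    seed: int,
    design: Optional[StudyDesign] = None,
    planted: bool = True,
    flat_family_fractions: bool = False,
    fold_change: float = 4.0,
    n_families: int = 4,
    orfs_per_family: int = 120,
    n_filler_kos: int = 64,
) -> SyntheticUniverse:
    """Generate the fixed community (catalog + annotations + expectations)."""
    modules = ModuleCatalog.default()
    truth = synthetic.default_truth(
        seed=seed,
        fold_change=fold_change,
        flat_family_fractions=flat_family_fractions,
        planted=planted,
    )
    if n_families != len(truth.families):
        # restrict family fractions to the first n families, renormalized
        fams = truth.families[:n_families]
        fractions = {}
        for diet, fr in truth.base_family_fraction.items():
            sub = {f: fr[f] for f in fams}
            total = sum(sub.values())
            sub = {f: v / total for f, v in sub.items()}
            # keep exact unit sum under fp
            first = fams[0]
            sub[first] += 1.0 - sum(sub.values())
            fractions[diet] = sub
        truth = synthetic.CommunityTruth(
            families=fams,
            base_family_fraction=fractions,
            planted_effects=truth.planted_effects,
            scfa_effects=truth.scfa_effects,
            seed=seed,
        )
    if design is None:
        design = synthetic.default_design(seed=seed)
    ko_pool = sorted(modules.all_kos) + _filler_kos(n_filler_kos)
    contigs, catalog, hits, ko_map = synthetic.generate_catalog(
        n_families=n_families,
        orfs_per_family=orfs_per_family,
        ko_pool=ko_pool,
        module_catalog=modules,
        seed=seed,
        families=list(truth.families),
    )
    expected = synthetic.expected_activity(truth, design, catalog, modules)
    return SyntheticUniverse(
        truth=truth,
        design=design,
        modules=modules,
        catalog=catalog,
        ko_map=ko_map,
        family_map=catalog.family_map(),
        expected=expected,
    )


def _ko_matrix(universe: SyntheticUniverse, seed: int, depth: int, dispersion: float) -> pd.DataFrame:
    """One replicate: simulate counts, normalize, aggregate to KO level."""
    expr = synthetic.simulate_expression(
        universe.truth,
        universe.design,
        universe.catalog,
        universe.modules,
        depth=depth,
        dispersion=dispersion,
        seed=seed,
        expected=universe.expected,
    )
    norm = normalize_per_sample(expr)
    ko_mat = aggregate_by(norm, universe.ko_map)
    return ko_mat.drop(index=UNCLASSIFIED, errors="ignore")


def _enrichment_pvalues(
    ko_mat: pd.DataFrame,
    universe: SyntheticUniverse,
    alpha: float = 0.05,
) -> list[diffstats.ModuleEnrichmentResult]:
    """Both direction blocks of the module-enrichment analysis."""
    detected = set(ko_mat.index[(ko_mat > 0).any(axis=1)])
    results = diffstats.ko_ttest(ko_mat.loc[sorted(detected)], universe.design)
    sig = diffstats.significant_ko_sets(results, alpha=alpha)
    out = []
    for direction in ("NP", "HP"):
        out.extend(
            diffstats.module_enrichment(
                sig[direction], detected, universe.modules, alpha=alpha, direction=direction
            )
        )
    return out


def null_module_rejection(
    n_datasets: int = 3000,
    seed: int = 0,
    dispersion: float = 0.3,
    replicates: int = 4,
    depth: int = 100_000,
    alpha: float = 0.05,
) -> float:
    """Type-I error of module enrichment under a no-effect community.

    Simulates ``n_datasets`` datasets with no planted module effects and
    diet-invariant family fractions, runs the two-stage KO t-test + module
    enrichment analysis, and returns the fraction of module tests (both
    direction blocks pooled) with p < alpha.
    """
    design = two_group_design(replicates)
    universe = build_universe(
        seed=seed, design=design, planted=False, flat_family_fractions=True
    )
    rng = np.random.default_rng(seed)
    n_tests = 0
    n_reject = 0
    for _ in range(n_datasets):
        ko_mat = _ko_matrix(universe, int(rng.integers(2**31)), depth, dispersion)
        for res in _enrichment_pvalues(ko_mat, universe, alpha=alpha):
            n_tests += 1
            n_reject += res.p_enrichment < alpha
    return n_reject / n_tests


def null_wilcoxon_rejection(
    n_datasets: int = 3000,
    n_per_group: int = 8,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the exact Wilcoxon category test on null data.

    Group size defaults to 8 vs 8, the pooled NP-vs-HP contrast of the
    four-diet design (at 4 vs 4 the exact rank-sum distribution has no
    attainable level near 0.05, so calibration is only meaningful at the
    pooled size).
    """
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(2 * n_per_group)]
    groups = {s: ("A" if i < n_per_group else "B") for i, s in enumerate(samples)}
    reject = 0
    for _ in range(n_datasets):
        values = pd.Series(rng.normal(size=2 * n_per_group), index=samples)
        reject += diffstats.wilcoxon_category_test(values, groups) < alpha
    return reject / n_datasets


def null_scfa_rejection(
    n_datasets: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the SCFA Welch t-tests with diet-invariant means."""
    base = synthetic.default_truth(seed=seed)
    null_scfa = {
        acid: synthetic.ScfaEffect(
            means={diet: eff.means["NPLF"] for diet in eff.means}, sd=eff.sd
        )
        for acid, eff in base.scfa_effects.items()
    }
    truth = synthetic.CommunityTruth(
        families=base.families,
        base_family_fraction=base.base_family_fraction,
        planted_effects=(),
        scfa_effects=null_scfa,
        seed=seed,
    )
    design = synthetic.default_design(seed=seed)
    rng = np.random.default_rng(seed)
    n_tests = 0
    n_reject = 0
    for _ in range(n_datasets):
        panel = synthetic.simulate_scfa_panel(truth, design, seed=int(rng.integers(2**31)))
        table = diffstats.scfa_group_test(panel, alpha=alpha)
        n_tests += len(table)
        n_reject += int(table["significant"].sum())
    return n_reject / n_tests


def module_recovery(
    n_sims: int = 200,
    seed: int = 0,
    fold_change: float = 4.0,
    dispersion: float = 0.2,
    replicates: int = 4,
    depth: int = 100_000,
    alpha: float = 0.05,
) -> dict:
    """Power to recover all planted modules with the correct direction.

    Returns a dict with the fraction of simulations recovering every planted
    module (p < alpha in its direction block) and per-module recovery rates.
    """
    design = two_group_design(replicates)
    universe = build_universe(
        seed=seed,
        design=design,
        planted=True,
        flat_family_fractions=True,
        fold_change=fold_change,
    )
    planted = {e.module_id: e.direction for e in universe.truth.planted_effects}
    rng = np.random.default_rng(seed)
    per_module = {m: 0 for m in planted}
    all_recovered = 0
    for _ in range(n_sims):
        ko_mat = _ko_matrix(universe, int(rng.integers(2**31)), depth, dispersion)
        hits = {
            res.module_id
            for res in _enrichment_pvalues(ko_mat, universe, alpha=alpha)
            if res.p_enrichment < alpha and planted.get(res.module_id) == res.direction
        }
        for m in planted:
            per_module[m] += m in hits
        all_recovered += len(hits) == len(planted)
    return {
        "all_modules_rate": all_recovered / n_sims,
        "per_module_rate": {m: c / n_sims for m, c in per_module.items()},
    }


def fold_recovery(
    seed: int = 0,
    fold_change: float = 4.0,
    depth: int = 1_000_000,
    replicates: int = 4,
) -> dict:
    """Re-estimate planted fold-changes at zero dispersion.

    Returns module -> (true fold, estimated fold) where the estimate is the
    HP/NP ratio of group-mean module activity (NP-enriched modules have true
    HP/NP fold 1/fold_change).
    """
    design = two_group_design(replicates)
    universe = build_universe(
        seed=seed,
        design=design,
        planted=True,
        flat_family_fractions=True,
        fold_change=fold_change,
    )
    ko_mat = _ko_matrix(universe, seed + 1, depth, dispersion=0.0)
    out = {}
    for eff in universe.truth.planted_effects:
        true_ratio = fold_change if eff.direction == "HP" else 1.0 / fold_change
        est = diffstats.estimate_module_fold(
            ko_mat, universe.design, universe.modules[eff.module_id].kos
        )
        out[eff.module_id] = (true_ratio, est)
    return out


def clustering_split_rate(
    n_sims: int = 100,
    seed: int = 0,
    fold_change: float = 4.0,
    dispersion: float = 0.2,
    depth: int = 100_000,
) -> float:
    """Fraction of simulations whose top-level Ward/Pearson cut is the exact
    NP/HP partition (adjusted Rand index 1) on the full 16-sample design."""
    design = synthetic.default_design(seed=seed)
    universe = build_universe(
        seed=seed, design=design, planted=True, fold_change=fold_change
    )
    protein = universe.design.factor("protein_level")
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_sims):
        ko_mat = _ko_matrix(universe, int(rng.integers(2**31)), depth, dispersion)
        logged = multivariate.log10_transform(ko_mat)
        tree = multivariate.pearson_ward_cluster(logged)
        cut = tree.cut(2)
        truth_labels = [protein[s] for s in universe.design.sample_ids]
        cut_labels = [cut[s] for s in universe.design.sample_ids]
        exact += adjusted_rand_score(truth_labels, cut_labels) == 1.0
    return exact / n_sims


def rda_null_rejection(
    n_datasets: int = 500,
    n_permutations: int = 999,
    seed: int = 0,
    n_features: int = 10,
    n_samples: int = 12,
    alpha: float = 0.05,
) -> float:
    """Null rejection rate of the RDA Monte Carlo permutation test.

    Response and explanatory data are independent Gaussians, so the p-value
    should be uniform and the rejection rate at ``alpha`` close to ``alpha``.
    """
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n_samples)]
    reject = 0
    for _ in range(n_datasets):
        response = pd.DataFrame(
            rng.normal(size=(n_features, n_samples)),
            index=[f"f{i}" for i in range(n_features)],
            columns=samples,
        )
        explanatory = pd.DataFrame(
            {
                "x1": rng.normal(size=n_samples),
                "x2": rng.normal(size=n_samples),
                "group": rng.choice(["a", "b"], size=n_samples),
            },
            index=samples,
        )
        p, _ = multivariate.rda_permutation_test(
            response, explanatory, n_permutations=n_permutations,
            seed=int(rng.integers(2**31)),
        )
        reject += p < alpha
    return reject / n_datasets
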