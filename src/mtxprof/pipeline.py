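"""Pipeline orchestration: validated configuration, staged execution,
plain-TSV checkpoints and a reproducible report bundle.

Stages run in order simulate → quantify → annotate → diff → strata →
ordinate. Every stage reads its inputs from, and writes its outputs to, the
output directory as plain text (TSV / FASTA / GFF3 / SAM / Newick), so any
stage can be rerun from the preceding checkpoints. The manifest records the
seeds, configuration hash and record counts needed to regenerate the bundle
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__, diffstats, multivariate, strata, synthetic, taxfun
from .design import StudyDesign
from .modules import ModuleCatalog
from .orfs import OrfCatalog
from .quantify import (
    ExpressionMatrix,
    aggregate_by,
    count_aligned_nucleotides,
    normalize_per_sample,
    read_alignment_tsv,
    read_sam,
)
from .taxfun import UNCLASSIFIED, FunctionCategoryConfig

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "annotate", "diff", "strata", "ordinate")


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists every violation."""


@dataclass
class PipelineConfig:
    outdir: Path
    mode: str = "synthetic"  # "synthetic" | "files"
    seed: int = 0
    alpha: float = 0.05
    n_permutations: int = 999
    alignment_format: str = "sam"  # "sam" | "tsv"
    # synthetic-mode generation block
    replicates: int = 4
    n_families: int = 6
    orfs_per_family: int = 80
    depth: int = 200_000
    dispersion: float = 0.2
    fold_change: float = 4.0
    read_length: int = 100
    # files-mode inputs
    orfs_gff: Optional[Path] = None
    hits_tsv: Optional[Path] = None
    ko_map_tsv: Optional[Path] = None
    alignments: tuple = ()
    metadata_tsv: Optional[Path] = None
    scfa_tsv: Optional[Path] = None
    # shared resources (defaults bundled)
    module_catalog_tsv: Optional[Path] = None
    categories_tsv: Optional[Path] = None
    single_ko: str = "K00850"  # 6-phosphofructokinase, pfkA

    def config_hash(self) -> str:
        # outdir is excluded: the hash identifies the analysis, not its location
        doc = {k: str(v) for k, v in sorted(self.__dict__.items()) if k != "outdir"}
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML config, reporting every violation at once."""
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    errors: list[str] = []
    known = set(PipelineConfig.__dataclass_fields__)
    for key in doc:
        if key not in known:
            errors.append(f"unknown config key: {key!r}")
    cfg_kwargs = {k: v for k, v in doc.items() if k in known}
    if "outdir" not in cfg_kwargs:
        errors.append("missing required key: 'outdir'")
        cfg_kwargs["outdir"] = "."
    cfg = PipelineConfig(**{**cfg_kwargs, "outdir": Path(cfg_kwargs["outdir"])})
    if cfg.mode not in ("synthetic", "files"):
        errors.append(f"mode must be 'synthetic' or 'files', got {cfg.mode!r}")
    if not (0 < cfg.alpha < 1):
        errors.append(f"alpha must lie in (0, 1), got {cfg.alpha}")
    if not isinstance(cfg.seed, int):
        errors.append(f"seed must be an integer, got {cfg.seed!r}")
    if cfg.n_permutations < 99:
        errors.append(f"n_permutations must be >= 99, got {cfg.n_permutations}")
    if cfg.alignment_format not in ("sam", "tsv"):
        errors.append(f"alignment_format must be 'sam' or 'tsv', got {cfg.alignment_format!r}")
    path_fields = [
        "orfs_gff", "hits_tsv", "ko_map_tsv", "metadata_tsv", "scfa_tsv",
        "module_catalog_tsv", "categories_tsv",
    ]
    for name in path_fields:
        value = getattr(cfg, name)
        if value is not None:
            setattr(cfg, name, Path(value))
            if not Path(value).is_file():
                errors.append(f"{name}: file not found: {value}")
    cfg.alignments = tuple(Path(p) for p in (cfg.alignments or ()))
    for p in cfg.alignments:
        if not p.is_file():
            errors.append(f"alignments: file not found: {p}")
    if cfg.mode == "files":
        for name in ("orfs_gff", "hits_tsv", "ko_map_tsv", "metadata_tsv"):
            if getattr(cfg, name) is None:
                errors.append(f"files mode requires {name}")
        if not cfg.alignments:
            errors.append("files mode requires at least one alignment file")
        if cfg.metadata_tsv is not None and Path(cfg.metadata_tsv).is_file():
            meta = pd.read_csv(cfg.metadata_tsv, sep="\t")
            dups = meta["sample_id"][meta["sample_id"].duplicated()].tolist()
            if dups:
                errors.append(f"duplicate sample ids in metadata: {sorted(set(dups))}")
    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


@dataclass
class ReportBundle:
    """Paths of every product of a pipeline run."""

    outdir: Path
    files: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _read_ko_map(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["orf_id"].astype(str), df["ko"].astype(str)))


def _stage_dir(cfg: PipelineConfig, stage: str) -> Path:
    d = cfg.outdir / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_pipeline(cfg: PipelineConfig, stages=STAGES) -> ReportBundle:
    """Execute the pipeline; any subset of consecutive stages may be given,
    provided earlier checkpoints already exist in the output directory."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(outdir=cfg.outdir)
    counts: dict = {}

    modules = (
        ModuleCatalog.from_tsv(cfg.module_catalog_tsv)
        if cfg.module_catalog_tsv
        else ModuleCatalog.default()
    )
    categories = (
        FunctionCategoryConfig.from_tsv(cfg.categories_tsv)
        if cfg.categories_tsv
        else FunctionCategoryConfig.default()
    )

    sim = _stage_dir(cfg, "simulate")
    if "simulate" in stages and cfg.mode == "synthetic":
        _run_simulate(cfg, modules, sim, counts)
    if cfg.mode == "synthetic":
        orfs_gff = sim / "orfs.gff3"
        hits_tsv = sim / "hits.tsv"
        ko_map_tsv = sim / "ko_map.tsv"
        metadata_tsv = sim / "metadata.tsv"
        scfa_tsv = sim / "scfa.tsv"
        suffix = "sam" if cfg.alignment_format == "sam" else "tsv"
        alignments = tuple(sorted(sim.glob(f"alignments/*.{suffix}")))
    else:
        orfs_gff, hits_tsv, ko_map_tsv = cfg.orfs_gff, cfg.hits_tsv, cfg.ko_map_tsv
        metadata_tsv, scfa_tsv = cfg.metadata_tsv, cfg.scfa_tsv
        alignments = cfg.alignments

    catalog = OrfCatalog.from_gff3(orfs_gff)
    design = StudyDesign.from_tsv(metadata_tsv)

    qdir = _stage_dir(cfg, "quantify")
    if "quantify" in stages:
        try:
            records = []
            for p in alignments:
                if cfg.alignment_format == "sam":
                    records.extend(read_sam(p))
                else:
                    records.extend(read_alignment_tsv(p))
            raw = count_aligned_nucleotides(records, catalog, samples=design.sample_ids)
            norm = normalize_per_sample(raw)
        except Exception as exc:
            raise RuntimeError(f"stage 'quantify' failed: {exc}") from exc
        raw.to_tsv(qdir / "raw_counts.tsv")
        norm.to_tsv(qdir / "normalized.tsv")
        counts["quantify"] = {"reads_counted": len(records), "orfs": len(catalog)}

    raw = ExpressionMatrix.from_tsv(qdir / "raw_counts.tsv", mode="raw")
    norm = ExpressionMatrix.from_tsv(qdir / "normalized.tsv", mode="normalized")
    hits = taxfun.read_hits_tsv(hits_tsv)
    family_map = taxfun.assign_family_best_hit(hits, orf_ids=catalog.orf_ids)
    ko_map = _read_ko_map(ko_map_tsv)

    adir = _stage_dir(cfg, "annotate")
    if "annotate" in stages:
        try:
            fam_act = taxfun.family_activity(norm, family_map)
            fam_act.to_csv(adir / "family_activity.tsv", sep="\t")
            retained = taxfun.filter_families_for_plot(fam_act, design.diet_of())
            (adir / "families_over_threshold.txt").write_text(
                "".join(f"{f}\n" for f in retained)
            )
            ko_act = aggregate_by(norm, ko_map)
            ko_act.to_csv(adir / "ko_activity.tsv", sep="\t")
            cat_act = taxfun.category_activity(norm, ko_map, categories)
            cat_act.to_csv(adir / "category_activity.tsv", sep="\t")
        except Exception as exc:
            raise RuntimeError(f"stage 'annotate' failed: {exc}") from exc
        counts["annotate"] = {
            "families_detected": int((fam_act.sum(axis=1) > 0).sum()),
            "kos_detected": int((ko_act.drop(index=UNCLASSIFIED, errors="ignore").sum(axis=1) > 0).sum()),
        }

    ko_act = pd.read_csv(adir / "ko_activity.tsv", sep="\t", index_col="group")
    ko_act = ko_act.drop(index=UNCLASSIFIED, errors="ignore")
    cat_act = pd.read_csv(adir / "category_activity.tsv", sep="\t", index_col="category")

    ddir = _stage_dir(cfg, "diff")
    if "diff" in stages:
        try:
            detected = set(ko_act.index[(ko_act > 0).any(axis=1)])
            ko_results = diffstats.ko_ttest(ko_act.loc[sorted(detected)], design)
            pd.DataFrame(
                [
                    (r.ko_id, r.mean_np, r.mean_hp, r.t_statistic, r.p_value, r.direction)
                    for r in ko_results
                ],
                columns=["ko_id", "mean_NP", "mean_HP", "t_statistic", "p_value", "direction"],
            ).to_csv(ddir / "ko_differential.tsv", sep="\t", index=False)
            sig = diffstats.significant_ko_sets(ko_results, alpha=cfg.alpha)
            enr_rows = []
            for direction in ("NP", "HP"):
                for r in diffstats.module_enrichment(
                    sig[direction], detected, modules, alpha=cfg.alpha, direction=direction
                ):
                    enr_rows.append(
                        (
                            direction,
                            r.module_id,
                            r.n_module_kos_total,
                            r.n_module_kos_detected,
                            r.k_significant,
                            r.p_enrichment,
                            r.description,
                        )
                    )
            pd.DataFrame(
                enr_rows,
                columns=[
                    "enriched_in", "module_id", "n_kos_in_module", "n_kos_detected",
                    "n_kos_found", "p_value", "description",
                ],
            ).to_csv(ddir / "module_enrichment.tsv", sep="\t", index=False)
            # Wilcoxon on each function category, NP vs HP
            protein = design.factor("protein_level")
            wil_rows = [
                (cat, diffstats.wilcoxon_category_test(cat_act.loc[cat], protein))
                for cat in cat_act.index
            ]
            pd.DataFrame(wil_rows, columns=["category", "wilcoxon_p"]).to_csv(
                ddir / "category_wilcoxon.tsv", sep="\t", index=False
            )
            if scfa_tsv is not None and Path(scfa_tsv).is_file():
                panel = pd.read_csv(scfa_tsv, sep="\t")
                diffstats.scfa_group_test(panel, alpha=cfg.alpha).to_csv(
                    ddir / "scfa_tests.tsv", sep="\t", index=False
                )
            else:
                logger.info("no SCFA panel supplied; SCFA tests skipped")
            counts["diff"] = {
                "kos_tested": len(ko_results),
                "modules_tested": len(enr_rows),
                "significant_np_kos": len(sig["NP"]),
                "significant_hp_kos": len(sig["HP"]),
            }
        except RuntimeError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage 'diff' failed: {exc}") from exc

    sdir = _stage_dir(cfg, "strata")
    if "strata" in stages:
        try:
            profile = strata.build_family_function_profile(norm, ko_map, family_map, categories)
            profile.to_tsv(sdir / "family_function_profile.tsv")
            profile.display_subset(design.diet_of()).to_csv(
                sdir / "family_function_profile_display.tsv", sep="\t", index=False
            )
            scfa_prof = strata.build_scfa_pathway_profile(
                norm, ko_map, family_map, design, scfa_config=categories
            )
            scfa_prof.to_tsv(sdir / "scfa_pathway_profile.tsv")
            strata.single_ko_report(norm, ko_map, family_map, cfg.single_ko).to_csv(
                sdir / f"single_ko_{cfg.single_ko}.tsv", sep="\t"
            )
            # pathway-map widths use raw counts aggregated to KO level
            labels = pd.Series({oid: ko_map.get(oid, UNCLASSIFIED) for oid in raw.values.index})
            ko_raw = raw.values.groupby(labels).sum().drop(index=UNCLASSIFIED, errors="ignore")
            for diet in sorted(set(design.diet_of().values())):
                widths = strata.ipath_width_export(ko_raw, design.samples_with(diet=diet))
                strata.write_ipath_selection(widths, sdir / f"ipath_{diet}.txt")
        except RuntimeError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage 'strata' failed: {exc}") from exc
        counts["strata"] = {"profile_rows": len(profile.table)}

    odir = _stage_dir(cfg, "ordinate")
    if "ordinate" in stages:
        try:
            logged = multivariate.log10_transform(ko_act)
            tree = multivariate.pearson_ward_cluster(logged)
            (odir / "cluster.nwk").write_text(tree.to_newick() + "\n")
            tree.to_tsv(odir / "cluster_merges.tsv")
            expl = pd.DataFrame(
                {
                    "diet": [s.diet for s in design],
                    "mouse_weight": [s.mouse_weight for s in design],
                },
                index=design.sample_ids,
            )
            if scfa_tsv is not None and Path(scfa_tsv).is_file():
                panel = pd.read_csv(scfa_tsv, sep="\t")
                wide = panel.pivot(index="mouse_id", columns="acid", values="concentration")
                expl = expl.join(wide.reindex(design.sample_ids))
            p, rda = multivariate.rda_permutation_test(
                logged, expl, n_permutations=cfg.n_permutations, seed=cfg.seed
            )
            rda.write_tsv_triptych(odir / "rda")
            kept = multivariate.species_axis_filter(rda)
            report = {
                "constrained_fraction": rda.constrained_fraction,
                "axis_fractions": [float(x) for x in rda.axis_fractions],
                "first_two_axes_fraction": float(rda.axis_fractions[:2].sum()),
                "permutation_p": p,
                "n_permutations": cfg.n_permutations,
                "features_majority_on_first_two_axes": [str(f) for f in kept],
            }
            (odir / "rda_report.json").write_text(json.dumps(report, indent=2) + "\n")
        except RuntimeError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage 'ordinate' failed: {exc}") from exc
        counts["ordinate"] = {"rda_constrained_fraction": rda.constrained_fraction}

    manifest = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "mode": cfg.mode,
        "stage_counts": counts,
    }
    (cfg.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    bundle.manifest = manifest
    bundle.files = {p.name: p for p in sorted(cfg.outdir.rglob("*")) if p.is_file()}
    return bundle


def _run_simulate(cfg: PipelineConfig, modules: ModuleCatalog, sim: Path, counts: dict) -> None:
    try:
        truth = synthetic.default_truth(seed=cfg.seed, fold_change=cfg.fold_change)
        design = synthetic.default_design(replicates=cfg.replicates, seed=cfg.seed)
        ko_pool = sorted(modules.all_kos) + [f"K79{i:03d}" for i in range(1, 61)] + [
            "K00850", "K00925", "K00625", "K01895", "K13788", "K01026",
            "K01034", "K01035", "K01896", "K00929", "K00634",
        ] + [f"K77{i:03d}" for i in list(range(1, 9)) + list(range(11, 19)) + list(range(21, 27))]
        contigs, catalog, hits, ko_map = synthetic.generate_catalog(
            n_families=cfg.n_families,
            orfs_per_family=cfg.orfs_per_family,
            ko_pool=ko_pool,
            module_catalog=modules,
            seed=cfg.seed,
        )
        expr = synthetic.simulate_expression(
            truth, design, catalog, modules,
            depth=cfg.depth, dispersion=cfg.dispersion, seed=cfg.seed,
        )
        records = synthetic.simulate_alignment_records(
            expr, catalog, read_length=cfg.read_length, seed=cfg.seed
        )
        synthetic.write_contigs_fasta(contigs, sim / "contigs.fasta")
        catalog.to_gff3(sim / "orfs.gff3")
        taxfun.write_hits_tsv(hits, sim / "hits.tsv")
        pd.DataFrame(sorted(ko_map.items()), columns=["orf_id", "ko"]).to_csv(
            sim / "ko_map.tsv", sep="\t", index=False
        )
        design.to_tsv(sim / "metadata.tsv")
        synthetic.simulate_scfa_panel(truth, design, seed=cfg.seed).to_csv(
            sim / "scfa.tsv", sep="\t", index=False
        )
        synthetic.write_truth(truth, sim / "truth.yaml")
        aln_dir = sim / "alignments"
        aln_dir.mkdir(exist_ok=True)
        by_sample: dict[str, list] = {}
        for r in records:
            by_sample.setdefault(r.sample_id, []).append(r)
        from .quantify import write_alignment_tsv

        for sample_id in design.sample_ids:
            recs = by_sample.get(sample_id, [])
            if cfg.alignment_format == "sam":
                synthetic.write_sam(recs, contigs, aln_dir / f"{sample_id}.sam")
            else:
                write_alignment_tsv(recs, aln_dir / f"{sample_id}.tsv")
        counts["simulate"] = {
            "orfs": len(catalog),
            "reads": len(records),
            "samples": len(design),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
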