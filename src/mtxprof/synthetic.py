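"""Synthetic metatranscriptome study generator with known ground truth.

Emulates a 4-diet (NPLF/NPHF/HPLF/HPHF), 4-replicate caecal metatranscriptome
study: a family-structured community of KO-annotated ORFs on contigs, read
alignments whose aligned-nucleotide totals reproduce a simulated expression
matrix, a per-mouse SCFA concentration panel (μmol/g), and a truth record of
every planted effect. Planted effects comprise (a) diet-dependent family
fractions (Erysipelotrichaceae up, Lachnospiraceae down under high protein)
and (b) module-level expression fold-changes (sugar modules favored under
normal protein, protein-metabolism modules under high protein).

Noise model: expected normalized activities are perturbed per ORF and sample
by a mean-one multiplicative log-normal factor (sigma = ``dispersion``), and
the sample's sequencing depth is allocated across ORFs by a single
multinomial draw. One parameter thus yields overdispersed compositional
counts with a closed-form expectation.

The planted module fold-changes are exact in expectation: a planted ORF's
normalized expected activity is its baseline probability times the fold, and
the complement (all non-planted ORFs) is rescaled to restore the unit sum.
The HP/NP ratio of a planted KO's expected normalized expression therefore
equals the fold exactly whenever family fractions are flat across diets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .design import DIETS, Sample, StudyDesign, protein_level
from .diffstats import SCFA_ACIDS
from .modules import ModuleCatalog
from .orfs import Orf, OrfCatalog
from .quantify import AlignmentRecord, ExpressionMatrix
from .taxfun import HitRecord

__all__ = [
    "SyntheticDataError",
    "PlantedEffect",
    "ScfaEffect",
    "CommunityTruth",
    "default_truth",
    "default_design",
    "generate_catalog",
    "expected_activity",
    "simulate_expression",
    "simulate_alignment_records",
    "simulate_scfa_panel",
    "write_sam",
    "write_contigs_fasta",
    "write_truth",
    "read_truth",
    "DEFAULT_FAMILIES",
]

_NT = np.array(list("ACGT"))

DEFAULT_FAMILIES = (
    "Lachnospiraceae",
    "Erysipelotrichaceae",
    "Clostridiaceae",
    "Ruminococcaceae",
    "Porphyromonadaceae",
    "Bacteroidaceae",
)


class SyntheticDataError(ValueError):
    """Invalid synthetic-study specification."""


@dataclass(frozen=True)
class PlantedEffect:
    """A module-level expression fold planted in one protein-level group."""

    module_id: str
    direction: str  # "NP" | "HP"
    fold_change: float

    def __post_init__(self) -> None:
        if self.direction not in ("NP", "HP"):
            raise SyntheticDataError(
                f"planted effect direction must be 'NP' or 'HP', got {self.direction!r}"
            )
        if not self.fold_change >= 1:
            raise SyntheticDataError("fold_change must be >= 1")


@dataclass(frozen=True)
class ScfaEffect:
    """Per-diet mean concentration (μmol/g) and Gaussian noise SD for one acid."""

    means: Mapping[str, float]  # diet -> mean
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise SyntheticDataError("SCFA noise SD must be non-negative")
        for diet, m in self.means.items():
            if m < 0:
                raise SyntheticDataError(f"SCFA mean for {diet} must be >= 0")


@dataclass
class CommunityTruth:
    """Ground truth of a synthetic study: the generative parameters."""

    families: tuple
    base_family_fraction: Mapping[str, Mapping[str, float]]  # diet -> family -> fraction
    planted_effects: tuple
    scfa_effects: Mapping[str, ScfaEffect]
    seed: int

    def __post_init__(self) -> None:
        for diet, fracs in self.base_family_fraction.items():
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-12:
                raise SyntheticDataError(
                    f"family fractions for diet {diet} sum to {total}, not 1"
                )
            if set(fracs) != set(self.families):
                raise SyntheticDataError(
                    f"family fractions for diet {diet} do not cover the family list"
                )

    def validate_modules(self, modules: ModuleCatalog) -> None:
        for eff in self.planted_effects:
            if eff.module_id not in modules:
                raise SyntheticDataError(
                    f"planted effect references unknown module {eff.module_id!r}"
                )


def default_truth(
    seed: int = 0,
    fold_change: float = 4.0,
    flat_family_fractions: bool = False,
    planted: bool = True,
) -> CommunityTruth:
    """The default study conditions.

    Family fractions shift with the protein level (Erysipelotrichaceae
    0.10→0.25, Lachnospiraceae 0.40→0.25 from NP to HP); three sugar modules
    are planted NP-enriched and three protein-metabolism modules HP-enriched
    at ``fold_change``. ``flat_family_fractions=True`` keeps the community
    composition diet-invariant (used for controlled fold-recovery
    experiments); ``planted=False`` removes the module effects (null
    simulations).
    """
    fams = DEFAULT_FAMILIES
    np_frac = {
        "Lachnospiraceae": 0.40,
        "Erysipelotrichaceae": 0.10,
        "Clostridiaceae": 0.20,
        "Ruminococcaceae": 0.15,
        "Porphyromonadaceae": 0.10,
        "Bacteroidaceae": 0.05,
    }
    hp_frac = {
        "Lachnospiraceae": 0.25,
        "Erysipelotrichaceae": 0.25,
        "Clostridiaceae": 0.20,
        "Ruminococcaceae": 0.12,
        "Porphyromonadaceae": 0.13,
        "Bacteroidaceae": 0.05,
    }
    if flat_family_fractions:
        hp_frac = dict(np_frac)
    fractions = {
        diet: dict(np_frac if protein_level(diet) == "NP" else hp_frac) for diet in DIETS
    }
    effects: tuple = ()
    if planted:
        effects = (
            PlantedEffect("M00377", "NP", fold_change),
            PlantedEffect("M00422", "NP", fold_change),
            PlantedEffect("M00196", "NP", fold_change),
            PlantedEffect("M00018", "HP", fold_change),
            PlantedEffect("M00299", "HP", fold_change),
            PlantedEffect("M00236", "HP", fold_change),
        )
    scfa = {
        "acetate": ScfaEffect({"NPLF": 55.0, "NPHF": 52.0, "HPLF": 62.0, "HPHF": 66.0}, 12.0),
        "propionate": ScfaEffect({"NPLF": 8.0, "NPHF": 8.0, "HPLF": 10.0, "HPHF": 10.5}, 2.5),
        "butyrate": ScfaEffect({"NPLF": 9.0, "NPHF": 9.0, "HPLF": 11.5, "HPHF": 12.0}, 3.0),
        "valerate": ScfaEffect({"NPLF": 0.30, "NPHF": 0.35, "HPLF": 0.90, "HPHF": 0.80}, 0.20),
        "iso-butyrate": ScfaEffect({"NPLF": 0.25, "NPHF": 0.25, "HPLF": 0.65, "HPHF": 0.75}, 0.15),
        "iso-valerate": ScfaEffect({"NPLF": 0.30, "NPHF": 0.30, "HPLF": 0.60, "HPHF": 0.65}, 0.18),
    }
    return CommunityTruth(
        families=fams,
        base_family_fraction=fractions,
        planted_effects=effects,
        scfa_effects=scfa,
        seed=seed,
    )


def default_design(
    replicates: int = 4, nplf_replicates: Optional[int] = None, seed: int = 0
) -> StudyDesign:
    """Balanced 4 × ``replicates`` design with diet-dependent mouse weights.

    High-protein diets reduce body weight; weights are N(mean, 2 g) draws.
    """
    rng = np.random.default_rng(seed)
    means = {"NPLF": 32.0, "NPHF": 38.0, "HPLF": 28.0, "HPHF": 30.0}
    samples = []
    for diet in DIETS:
        n = replicates if not (diet == "NPLF" and nplf_replicates) else nplf_replicates
        for i in range(1, n + 1):
            samples.append(
                Sample(
                    sample_id=f"{diet}_{i}",
                    diet=diet,
                    mouse_weight=float(np.round(rng.normal(means[diet], 2.0), 2)),
                )
            )
    return StudyDesign(samples)


# ------------------------------------------------------------------- catalog


def generate_catalog(
    n_families: int,
    orfs_per_family: int,
    ko_pool: Iterable[str],
    module_catalog: ModuleCatalog,
    seed: int,
    families: Optional[Sequence[str]] = None,
    orf_length_range: tuple[int, int] = (300, 3000),
    flank: int = 60,
    ko_assignment_rate: float = 0.8,
    decoy_hits: int = 2,
):
    """Generate contigs, an ORF catalog, a best-hit table and a KO map.

    Each ORF sits on its own contig with ``flank`` nt of random sequence on
    both sides, has a length that is a multiple of 3 inside
    ``orf_length_range``, exactly one family, and at most one KO. Every
    module KO is guaranteed to be carried by at least one ORF in each of at
    least two families; the hit table's best hit per ORF carries the true
    family, plus lower-scoring decoy hits from other families.

    Returns ``(contigs, catalog, hits, ko_map)`` where contigs is a dict
    contig_id -> sequence string.
    """
    ko_pool = sorted(set(ko_pool))
    if not ko_pool:
        raise SyntheticDataError("ko_pool must not be empty")
    if n_families < 2:
        raise SyntheticDataError("need at least 2 families")
    if orfs_per_family < 1:
        raise SyntheticDataError("orfs_per_family must be >= 1")
    module_catalog.validate_against_pool(ko_pool)
    module_kos = sorted(module_catalog.all_kos)
    if 2 * len(module_kos) > n_families * orfs_per_family:
        raise SyntheticDataError(
            "catalog too small to carry every module KO in two families: "
            f"{len(module_kos)} module KOs need {2 * len(module_kos)} ORFs, "
            f"have {n_families * orfs_per_family}"
        )
    if families is None:
        families = [
            DEFAULT_FAMILIES[i] if i < len(DEFAULT_FAMILIES) else f"Family{i+1:02d}"
            for i in range(n_families)
        ]
    families = list(families)[:n_families]
    if len(families) != n_families:
        raise SyntheticDataError("families list shorter than n_families")

    rng = np.random.default_rng(seed)
    lo, hi = orf_length_range
    orf_specs = []  # (orf_id, family)
    for fi, fam in enumerate(families):
        for j in range(orfs_per_family):
            orf_specs.append((f"orf_{fi:02d}_{j:04d}", fam))

    # KO assignment: each module KO goes to one ORF in each of two distinct
    # families (round robin), remaining ORFs draw from the pool at
    # ko_assignment_rate, or stay unannotated.
    ko_of: dict[str, Optional[str]] = {}
    by_family: dict[str, list[str]] = {fam: [] for fam in families}
    for oid, fam in orf_specs:
        by_family[fam].append(oid)
    cursor = {fam: 0 for fam in families}
    for i, ko in enumerate(module_kos):
        fam_a = families[i % n_families]
        fam_b = families[(i + 1) % n_families]
        for fam in (fam_a, fam_b):
            oid = by_family[fam][cursor[fam]]
            cursor[fam] += 1
            ko_of[oid] = ko
    # Background ORFs draw from the non-module portion of the pool (or stay
    # unannotated), so module expression is controlled exactly by the
    # guaranteed carriers above.
    background_pool = [k for k in ko_pool if k not in set(module_kos)]
    for oid, fam in orf_specs:
        if oid in ko_of:
            continue
        if background_pool and rng.random() < ko_assignment_rate:
            ko_of[oid] = str(rng.choice(background_pool))
        else:
            ko_of[oid] = None

    contigs: dict[str, str] = {}
    orfs: list[Orf] = []
    hits: list[HitRecord] = []
    other_families = {fam: [f for f in families if f != fam] for fam in families}
    for idx, (oid, fam) in enumerate(orf_specs):
        length = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        contig_id = f"contig_{idx:05d}"
        contig_len = length + 2 * flank
        seq = "".join(_NT[rng.integers(0, 4, size=contig_len)])
        contigs[contig_id] = seq
        strand = "+" if rng.random() < 0.5 else "-"
        orfs.append(
            Orf(
                orf_id=oid,
                contig_id=contig_id,
                start=flank,
                end=flank + length,
                strand=strand,
                family=fam,
                ko=ko_of[oid],
            )
        )
        best_bit = float(rng.uniform(150, 400))
        hits.append(
            HitRecord(
                orf_id=oid,
                subject_id=f"ref_{oid}_best",
                bit_score=round(best_bit, 1),
                e_value=float(10 ** -rng.uniform(20, 80)),
                subject_family=fam,
            )
        )
        for d in range(decoy_hits):
            decoy_fam = str(rng.choice(other_families[fam]))
            hits.append(
                HitRecord(
                    orf_id=oid,
                    subject_id=f"ref_{oid}_decoy{d}",
                    bit_score=round(float(rng.uniform(40, best_bit - 10)), 1),
                    e_value=float(10 ** -rng.uniform(3, 19)),
                    subject_family=decoy_fam,
                )
            )
    catalog = OrfCatalog(orfs)
    ko_map = {oid: ko for oid, ko in ko_of.items() if ko is not None}
    return contigs, catalog, hits, ko_map


# ---------------------------------------------------------------- expression


def expected_activity(
    truth: CommunityTruth,
    design: StudyDesign,
    catalog: OrfCatalog,
    module_catalog: ModuleCatalog,
) -> pd.DataFrame:
    """Expected normalized activity (ORF × sample); columns sum to 1.

    Baseline: an ORF's probability is its family's diet fraction times its
    length share within the family. Planted module folds multiply the
    baseline of carrier ORFs exactly; the non-planted complement is rescaled
    to restore the unit column sum.
    """
    truth.validate_modules(module_catalog)
    fam_of = catalog.family_map()
    ko_of = catalog.ko_map()
    missing = [o.orf_id for o in catalog if o.orf_id not in fam_of]
    if missing:
        raise SyntheticDataError(f"catalog ORFs without family annotation: {missing[:5]}")
    lengths = catalog.lengths()
    fam_length_total = lengths.groupby(pd.Series(fam_of)).sum()

    boosted_kos: dict[str, dict[str, float]] = {"NP": {}, "HP": {}}
    planted_module_kos: set = set()
    for eff in truth.planted_effects:
        kos = module_catalog[eff.module_id].kos
        planted_module_kos |= kos
        for ko in kos:
            prev = boosted_kos[eff.direction].get(ko, 1.0)
            boosted_kos[eff.direction][ko] = max(prev, eff.fold_change)

    cols = {}
    orf_ids = catalog.orf_ids
    base_cache: dict[str, np.ndarray] = {}
    for sample in design:
        diet = sample.diet
        level = protein_level(diet)
        if diet not in base_cache:
            fracs = truth.base_family_fraction[diet]
            base = np.array(
                [
                    fracs[fam_of[oid]] * lengths[oid] / fam_length_total[fam_of[oid]]
                    for oid in orf_ids
                ]
            )
            base_cache[diet] = base
        base = base_cache[diet]
        folds = np.array(
            [boosted_kos[level].get(ko_of.get(oid), 1.0) for oid in orf_ids]
        )
        # ORFs of any planted module (either direction) keep base × fold
        # exactly; only the pure background absorbs the compensation, so the
        # between-group expectation ratio of every planted KO equals its fold.
        protected = np.array(
            [ko_of.get(oid) in planted_module_kos for oid in orf_ids]
        )
        planted_mass = (base[protected] * folds[protected]).sum()
        background_mass = base[~protected].sum()
        if planted_mass >= 1.0 or background_mass <= 0.0:
            raise SyntheticDataError(
                f"planted effects absorb the whole sample (diet {diet}); "
                "reduce fold changes or planted-module coverage"
            )
        scale = (1.0 - planted_mass) / background_mass
        p = np.where(protected, base * folds, base * scale)
        cols[sample.sample_id] = p
    out = pd.DataFrame(cols, index=pd.Index(orf_ids, name="orf_id"))
    return out


def simulate_expression(
    truth: CommunityTruth,
    design: StudyDesign,
    catalog: OrfCatalog,
    module_catalog: ModuleCatalog,
    depth: int = 200_000,
    dispersion: float = 0.2,
    seed: Optional[int] = None,
    expected: Optional[pd.DataFrame] = None,
) -> ExpressionMatrix:
    """Draw a raw aligned-nucleotide count matrix (ORF × sample).

    Per sample: expected activities are multiplied by i.i.d. mean-one
    log-normal factors (sigma = ``dispersion``), renormalized, and ``depth``
    nucleotides are allocated by a multinomial draw, so every column sums to
    exactly ``depth``.
    """
    if depth <= 0:
        raise SyntheticDataError("depth must be positive")
    if dispersion < 0:
        raise SyntheticDataError("dispersion must be non-negative")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    if expected is None:
        expected = expected_activity(truth, design, catalog, module_catalog)
    counts = np.zeros(expected.shape, dtype=np.int64)
    for j, sample in enumerate(expected.columns):
        p = expected[sample].to_numpy(float)
        if dispersion > 0:
            factors = rng.lognormal(
                mean=-0.5 * dispersion**2, sigma=dispersion, size=p.shape
            )
            p = p * factors
            p = p / p.sum()
        counts[:, j] = rng.multinomial(depth, p)
    values = pd.DataFrame(counts, index=expected.index, columns=expected.columns)
    return ExpressionMatrix(values=values, mode="raw")


# ---------------------------------------------------------------- alignments


def simulate_alignment_records(
    expr: ExpressionMatrix,
    catalog: OrfCatalog,
    read_length: int = 100,
    seed: int = 0,
    boundary_reads: bool = False,
) -> list[AlignmentRecord]:
    """Place single-block reads realising the raw expression matrix.

    With ``boundary_reads=False`` every read lies fully inside its ORF, so
    re-counting aligned nucleotides reproduces ``expr`` exactly. With
    ``boundary_reads=True`` read start positions may hang over the ORF ends
    (clipped to the contig), so re-counts equal the per-base overlap with the
    ORF rather than the full read length.
    """
    if expr.mode != "raw":
        raise SyntheticDataError("alignment simulation needs a raw count matrix")
    rng = np.random.default_rng(seed)
    orf_of = {o.orf_id: o for o in catalog}
    records: list[AlignmentRecord] = []
    counter = 0
    for sample in expr.sample_ids:
        col = expr.values[sample]
        for oid, total in col.items():
            total = int(total)
            if total <= 0:
                continue
            orf = orf_of[oid]
            eff_len = min(read_length, orf.length)
            n_full, remainder = divmod(total, eff_len)
            pieces = [eff_len] * n_full + ([remainder] if remainder else [])
            for ln in pieces:
                if boundary_reads:
                    lo = max(0, orf.start - ln + 1)
                    hi = orf.end - 1  # last start still overlapping the ORF
                    start = int(rng.integers(lo, hi + 1))
                else:
                    start = int(rng.integers(orf.start, orf.end - ln + 1))
                records.append(
                    AlignmentRecord(
                        read_id=f"read_{sample}_{counter:08d}",
                        contig_id=orf.contig_id,
                        start=start,
                        aligned_blocks=((start, start + ln),),
                        sample_id=sample,
                    )
                )
                counter += 1
    return records


def write_sam(
    records: Iterable[AlignmentRecord],
    contigs: Mapping[str, str],
    path,
) -> None:
    """Write single-sample alignment records as SAM with all-M CIGARs."""
    contig_ids = sorted(contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": cid, "LN": len(contigs[cid])} for cid in contig_ids],
    }
    tid = {cid: i for i, cid in enumerate(contig_ids)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            (s, e), = rec.aligned_blocks
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.flag = 0
            a.reference_id = tid[rec.contig_id]
            a.reference_start = s
            a.mapping_quality = 60
            a.cigarstring = f"{e - s}M"
            a.query_sequence = contigs[rec.contig_id][s:e]
            out.write(a)


def write_contigs_fasta(contigs: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=cid, description="") for cid, seq in sorted(contigs.items())]
    seqio_write(recs, str(path), "fasta")


# ---------------------------------------------------------------------- SCFA


def simulate_scfa_panel(
    truth: CommunityTruth,
    design: StudyDesign,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """One row per mouse × acid: truncated-Gaussian concentrations (μmol/g).

    Draws N(diet mean, sd) per acid and clips at 0 (zero-truncation of the
    noise), so concentrations are never negative.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows = []
    for sample in design:
        for acid in SCFA_ACIDS:
            eff = truth.scfa_effects[acid]
            mean = eff.means[sample.diet]
            value = mean if eff.sd == 0 else max(0.0, float(rng.normal(mean, eff.sd)))
            rows.append(
                {
                    "mouse_id": sample.sample_id,
                    "diet": sample.diet,
                    "acid": acid,
                    "concentration": value,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- truth


def write_truth(truth: CommunityTruth, path) -> None:
    doc = {
        "seed": truth.seed,
        "families": list(truth.families),
        "base_family_fraction": {
            diet: dict(fracs) for diet, fracs in truth.base_family_fraction.items()
        },
        "planted_effects": [
            {"module_id": e.module_id, "direction": e.direction, "fold_change": e.fold_change}
            for e in truth.planted_effects
        ],
        "scfa_effects": {
            acid: {"means": dict(e.means), "sd": e.sd}
            for acid, e in truth.scfa_effects.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_truth(path) -> CommunityTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return CommunityTruth(
        families=tuple(doc["families"]),
        base_family_fraction=doc["base_family_fraction"],
        planted_effects=tuple(
            PlantedEffect(e["module_id"], e["direction"], float(e["fold_change"]))
            for e in doc["planted_effects"]
        ),
        scfa_effects={
            acid: ScfaEffect(means=e["means"], sd=float(e["sd"]))
            for acid, e in doc["scfa_effects"].items()
        },
        seed=int(doc["seed"]),
    )
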