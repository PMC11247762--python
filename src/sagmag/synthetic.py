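"""Synthetic community, genome-collection, gene-catalog, quality-report and
recruitment generators with known ground truth.

Every generator is a pure function of its parameters and a seed, so a fixed
seed reproduces its tables byte for byte.  The defaults emulate the
statistical structure of a tropical epipelagic prokaryoplankton survey
observed through four methods (randomised SAGs, MAGs, 16S amplicons,
shotgun reads): one underlying community, per-method sampling biases (MAG
recovery tempered toward rare lineages), SAG-like gene dropout, MAG-like
depletion of flexible genes, a small fraction of chimeric assemblies, and
occasional conflicting 16S copies.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import RankedTaxonomy


# --------------------------------------------------------------------------
# Specs and truth
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CommunitySpec:
    """Parameters of the simulated community and its observation methods.

    One true composition is drawn from a symmetric Dirichlet with
    *concentration* per lineage; each method observes it through an
    optional multiplicative bias vector and multinomial sampling at a
    per-sample depth drawn uniformly from *depth_range*.  A planted
    differential effect multiplies one lineage's final proportion by
    *fold* for a single method (other lineages renormalised), choosing the
    lineage whose true proportion is closest to *target_proportion* so the
    effect size is controlled.
    """

    n_lineages: int = 40
    concentration: float = 2.0
    n_samples: int = 20
    depth_range: tuple[int, int] = (50_000, 200_000)
    rank: str = "order"
    methods: tuple[str, ...] = ("SAG", "MAG", "AMPLICON", "SHOTGUN")
    method_bias: Mapping[str, Sequence[float]] | None = None
    planted_method: str | None = None
    planted_fold: float = 1.0
    planted_target_proportion: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lineages < 2:
            raise ValueError("need >= 2 lineages")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.planted_method is not None:
            if self.planted_method not in self.methods:
                raise ValueError("planted_method must be one of methods")
            if self.planted_fold <= 0:
                raise ValueError("planted_fold must be positive")
        if self.method_bias is not None:
            for m, bias in self.method_bias.items():
                if np.any(np.asarray(bias, dtype=float) <= 0):
                    raise ValueError(f"bias for {m} must be positive")


@dataclasses.dataclass
class TruthBundle:
    """Ground truth of a synthetic run; every item names emitted entities."""

    true_proportions: dict[str, float] = dataclasses.field(default_factory=dict)
    planted_differentials: list[dict] = dataclasses.field(default_factory=list)
    genome_lineages: dict[str, str] = dataclasses.field(default_factory=dict)
    gene_families: dict[str, str] = dataclasses.field(default_factory=dict)
    planted_module: dict = dataclasses.field(default_factory=dict)
    chimera_ids: list[str] = dataclasses.field(default_factory=list)
    conflicts_16s: list[dict] = dataclasses.field(default_factory=list)
    recruitment_coverage: dict[str, float] = dataclasses.field(
        default_factory=dict)

    def merge(self, other: "TruthBundle") -> "TruthBundle":
        for field in dataclasses.fields(self):
            mine = getattr(self, field.name)
            theirs = getattr(other, field.name)
            if isinstance(mine, dict):
                mine.update(theirs)
            else:
                mine.extend(theirs)
        return self

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _lineage_names(n: int, rank: str) -> list[str]:
    return [f"{rank}_{i:03d}" for i in range(n)]


# --------------------------------------------------------------------------
# Community counts
# --------------------------------------------------------------------------

def simulate_community_counts(
    spec: CommunitySpec,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Per-sample lineage count tables for the four observation methods."""
    rng = np.random.default_rng(spec.seed)
    lineages = _lineage_names(spec.n_lineages, spec.rank)
    truth = rng.dirichlet(np.full(spec.n_lineages, spec.concentration))

    planted_idx = None
    if spec.planted_method is not None and spec.planted_fold != 1.0:
        planted_idx = int(np.argmin(
            np.abs(truth - spec.planted_target_proportion)))

    bundle = TruthBundle(
        true_proportions=dict(zip(lineages, map(float, truth))))
    rows = []
    for method in spec.methods:
        props = truth.copy()
        if spec.method_bias and method in spec.method_bias:
            props = props * np.asarray(spec.method_bias[method], dtype=float)
            props /= props.sum()
        if planted_idx is not None and method == spec.planted_method:
            p = props[planted_idx]
            scaled = min(spec.planted_fold * p, 0.95)
            props = props * (1.0 - scaled) / (1.0 - p)
            props[planted_idx] = scaled
            bundle.planted_differentials.append({
                "lineage": lineages[planted_idx], "method": method,
                "fold": spec.planted_fold,
                "base_proportion": float(p),
                "shifted_proportion": float(scaled),
            })
        for s in range(spec.n_samples):
            depth = int(rng.integers(spec.depth_range[0],
                                     spec.depth_range[1] + 1))
            counts = rng.multinomial(depth, props)
            sample_id = f"{method}_s{s:02d}"
            for lineage, count in zip(lineages, counts):
                rows.append({"method": method, "sample_id": sample_id,
                             "rank": spec.rank, "lineage": lineage,
                             "count": int(count)})
    return pd.DataFrame(rows), bundle


# --------------------------------------------------------------------------
# Genome collections
# --------------------------------------------------------------------------

def _taxonomy_for(index: int) -> RankedTaxonomy:
    """Deterministic synthetic hierarchy: lineages nest 2:1 per rank."""
    return RankedTaxonomy(
        domain="Bacteria",
        phylum=f"phy{index // 16:02d}",
        class_=f"cls{index // 8:02d}",
        order=f"ord{index // 4:02d}",
        family=f"fam{index // 2:02d}",
        genus=f"gen{index:03d}",
        species=f"sp{index:03d}",
    )


def simulate_genome_collections(
    truth: TruthBundle,
    n_sag: int = 400,
    n_mag: int = 400,
    n_isolate: int = 15,
    tau: float = 0.3,
    sag_completeness: tuple[float, float] = (69.0, 8.0),
    mag_completeness: tuple[float, float] = (71.0, 8.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Genome metadata for SAG/MAG (and isolate) collections.

    SAG lineages track true abundance; MAG lineages are drawn from the
    abundance tempered to the power *tau* < 1, which enriches rare
    lineages (the recovery bias of assembly/binning).  Completeness is
    normal with the stated (mean, sd), clipped to [50, 99]; contamination
    is half-normal below the 10% prefilter.
    """
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    if n_sag < 1 or n_mag < 1:
        raise ValueError("need n_sag, n_mag >= 1")
    rng = np.random.default_rng(seed)
    lineages = list(truth.true_proportions)
    probs = np.array([truth.true_proportions[l] for l in lineages])
    probs = probs / probs.sum()
    tempered = probs ** tau
    tempered /= tempered.sum()

    out = TruthBundle(true_proportions=dict(truth.true_proportions))
    rows = []

    def emit(prefix: str, collection: str, n: int, lineage_p: np.ndarray,
             comp_mean: float, comp_sd: float) -> None:
        choices = rng.choice(len(lineages), size=n, p=lineage_p)
        comp = np.clip(rng.normal(comp_mean, comp_sd, size=n), 50.0, 99.0)
        cont = np.clip(np.abs(rng.normal(0.0, 3.0, size=n)), 0.0, 9.9)
        depth = rng.uniform(0.0, 100.0, size=n)
        lat = rng.uniform(-40.0, 40.0, size=n)
        for i in range(n):
            genome_id = f"{prefix}{i:04d}"
            lineage_idx = int(choices[i])
            rows.append({
                "genome_id": genome_id,
                "collection": collection,
                "taxonomy": _taxonomy_for(lineage_idx).to_string(),
                "completeness": float(comp[i]),
                "contamination": float(cont[i]),
                "sample_id": f"{collection}_s{i % 20:02d}",
                "depth_m": float(depth[i]),
                "latitude_deg": float(lat[i]),
                "region_flag": "open_ocean",
            })
            out.genome_lineages[genome_id] = lineages[lineage_idx]

    emit("SAG", "SAG", n_sag, probs, *sag_completeness)
    emit("MAG", "MAG", n_mag, tempered, *mag_completeness)
    if n_isolate:
        emit("ISO", "ISOLATE", n_isolate, probs, 97.0, 1.5)
    return pd.DataFrame(rows), out


# --------------------------------------------------------------------------
# Gene catalog with core/flexible structure and KO annotations
# --------------------------------------------------------------------------

def simulate_gene_catalog(
    genomes: pd.DataFrame,
    n_core: int = 300,
    n_flexible: int = 1200,
    gene_length: int = 300,
    sag_gene_dropout: float = 0.1,
    mag_flexible_dropout: float = 0.6,
    mutation_rate: float = 0.02,
    module_size: int = 8,
    n_modules: int = 30,
    planted_module_dropout: float | None = 0.6,
    sequence_genomes: int = 8,
    sequence_families: int = 40,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame, pd.DataFrame, TruthBundle]:
    """Ancestral gene families, per-genome gene content, KO annotations.

    A pool of ``n_core + n_flexible`` ancestral nucleotide genes is drawn;
    every genome carries core genes minus random dropout and flexible genes
    minus an elevated dropout in MAGs.  Isolate-labelled genomes keep
    everything (cultured references).  Each family maps to one KO; KOs are
    grouped into modules of *module_size* (consecutive, with every third
    module overlapping its predecessor to exercise category merging).  One
    module's genes are additionally dropped from MAGs with probability
    *planted_module_dropout* — the planted gene-content effect.

    Returns (FASTA records, annotations table, modules table, truth).  The
    FASTA is a toy window into the catalog — the first *sequence_families*
    families of the first *sequence_genomes* genomes — sized for
    alignment-based clustering in seconds; genome-wide family memberships
    are carried by the annotations.  FASTA descriptions carry a
    ``genome=<id>`` token.
    """
    for rate in (sag_gene_dropout, mag_flexible_dropout, mutation_rate):
        if not 0 <= rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_families = n_core + n_flexible
    bases = np.array(list("ACGT"))
    ancestral = ["".join(rng.choice(bases, size=gene_length))
                 for _ in range(n_families)]
    family_ids = [f"F{idx:05d}" for idx in range(n_families)]
    ko_ids = [f"K{idx:05d}" for idx in range(n_families)]
    is_core = np.arange(n_families) < n_core

    # modules over the core KOs; every third module shares most KOs with
    # its predecessor so that overlap merging has work to do
    module_rows = []
    cursor = 0
    for m in range(n_modules):
        mid = f"M{m:04d}"
        if m % 3 == 2 and module_rows:
            # overlap module: shares all but one KO with its predecessor
            prev_start = cursor - module_size
            kos = ko_ids[prev_start + 1:prev_start + module_size]
            kos = kos + [ko_ids[cursor % n_core]]
            cursor += 1
        else:
            if cursor + module_size > n_core:
                break  # modules are defined over core KOs only
            kos = ko_ids[cursor:cursor + module_size]
            cursor += module_size
        for ko in kos:
            module_rows.append({"module_id": mid, "ko_id": ko})
    modules = pd.DataFrame(module_rows).drop_duplicates(
        ).reset_index(drop=True)

    planted_module_id = None
    planted_kos: frozenset[str] = frozenset()
    if planted_module_dropout is not None and n_modules > 0:
        planted_module_id = "M0000"
        planted_kos = frozenset(
            modules.loc[modules["module_id"] == planted_module_id, "ko_id"])

    bundle = TruthBundle(
        gene_families=dict(zip(family_ids, ko_ids)),
        planted_module={
            "module_id": planted_module_id,
            "mag_dropout": planted_module_dropout,
            "ko_ids": sorted(planted_kos),
        } if planted_module_id else {},
    )

    ann_rows = []
    fasta: list[tuple[str, str, str]] = []
    genome_ids = list(genomes["genome_id"])
    collections = dict(zip(genomes["genome_id"], genomes["collection"]))
    for g_index, genome_id in enumerate(genome_ids):
        coll = collections[genome_id]
        keep = np.ones(n_families, dtype=bool)
        if coll != "ISOLATE":
            drop = rng.random(n_families)
            base_rate = np.full(n_families, sag_gene_dropout)
            if coll == "MAG":
                base_rate[~is_core] = mag_flexible_dropout
            keep = drop >= base_rate
        if coll == "MAG" and planted_kos:
            planted_mask = np.isin(np.array(ko_ids), list(planted_kos))
            extra = rng.random(n_families) < planted_module_dropout
            keep = keep & ~(planted_mask & extra)
        present = np.flatnonzero(keep)
        emit_seq = g_index < sequence_genomes
        for fam_idx in present:
            gene_id = f"{genome_id}_{family_ids[fam_idx]}"
            ann_rows.append({"genome_id": genome_id, "gene_id": gene_id,
                             "ko_id": ko_ids[fam_idx]})
            if emit_seq and fam_idx < sequence_families:
                seq = np.array(list(ancestral[fam_idx]))
                mutate = rng.random(gene_length) < mutation_rate
                if mutate.any():
                    # substitute with a uniformly different base
                    for pos in np.flatnonzero(mutate):
                        options = [b for b in "ACGT" if b != seq[pos]]
                        seq[pos] = options[int(rng.integers(3))]
                fasta.append((gene_id, f"{gene_id} genome={genome_id}",
                              "".join(seq)))
    annotations = pd.DataFrame(ann_rows)
    return fasta, annotations, modules, bundle


# --------------------------------------------------------------------------
# Quality reports with planted chimeras and 16S conflicts
# --------------------------------------------------------------------------

_ABOVE_GENUS = ("domain", "phylum", "class", "order", "family")
_ALL_RANKS = ("domain", "phylum", "class", "order", "family", "genus",
              "species")


def simulate_quality_reports(
    genomes: pd.DataFrame,
    chimera_fraction: float = 0.04,
    conflict_fraction: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthBundle]:
    """GUNC-like, MDMcleaner-like and 16S-assignment tables.

    Planted chimeras satisfy every consensus condition at one rank above
    genus (CSS 0.9-1.0, RRS 0.6-0.9, MDM fraction 0.12-0.45); every other
    genome is built to fail at least one condition (low CSS, low RRS, or
    MDM below 5%), some with deliberately high genus-level CSS or low-RRS
    high-CSS ranks so the default call and the consensus call differ.
    Planted 16S conflicts replace one 16S copy's domain (half) or phylum
    (half) with a foreign label.
    """
    if not 0 <= chimera_fraction <= 1 or not 0 <= conflict_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genome_ids = list(genomes["genome_id"])
    taxonomies = dict(zip(genomes["genome_id"], genomes["taxonomy"]))
    n = len(genome_ids)
    n_chimera = int(round(chimera_fraction * n))
    chimera_ids = sorted(rng.choice(genome_ids, size=n_chimera,
                                    replace=False)) if n_chimera else []
    chimera_set = set(chimera_ids)

    gunc_rows, mdm_rows = [], []
    for genome_id in genome_ids:
        if genome_id in chimera_set:
            evidence_rank = _ABOVE_GENUS[int(rng.integers(len(_ABOVE_GENUS)))]
            mdm_value = rng.uniform(0.12, 0.45)
            for rank in _ALL_RANKS:
                if rank == evidence_rank:
                    css = rng.uniform(0.90, 1.0)
                    rrs = rng.uniform(0.60, 0.90)
                    portion = rng.uniform(0.10, 0.45)
                else:
                    css = rng.uniform(0.0, 0.30)
                    rrs = rng.uniform(0.50, 1.0)
                    portion = rng.uniform(0.0, 0.05)
                gunc_rows.append({"genome_id": genome_id, "rank": rank,
                                  "css": css, "rrs": rrs,
                                  "contamination_portion": portion})
        else:
            # every clean genome fails >= 1 consensus condition: most have
            # low CSS everywhere; a few carry a high-CSS rank with poor
            # reference representation, or a strong GUNC signal with an
            # MDM fraction below 5%, or a genus-level distractor (rank not
            # above genus) -- cases where default and consensus calls differ
            mode = int(rng.choice([0, 1, 2], p=[0.90, 0.05, 0.05]))
            mdm_value = (rng.uniform(0.0, 0.049) if mode == 2
                         else rng.uniform(0.0, 0.30))
            special = _ABOVE_GENUS[int(rng.integers(len(_ABOVE_GENUS)))]
            distractor = mode == 0 and rng.random() < 0.05
            for rank in _ALL_RANKS:
                css = rng.uniform(0.0, 0.30)
                rrs = rng.uniform(0.40, 1.0)
                if mode == 1 and rank == special:
                    css = rng.uniform(0.50, 0.95)
                    rrs = rng.uniform(0.0, 0.39)
                elif mode == 2 and rank == special:
                    css = rng.uniform(0.85, 1.0)
                    rrs = rng.uniform(0.50, 1.0)
                elif distractor and rank == "genus":
                    css = rng.uniform(0.86, 0.99)
                    rrs = rng.uniform(0.60, 0.95)
                portion = rng.uniform(0.0, 0.10) * css
                gunc_rows.append({"genome_id": genome_id, "rank": rank,
                                  "css": css, "rrs": rrs,
                                  "contamination_portion": portion})
        mdm_rows.append({"genome_id": genome_id,
                         "contamination_fraction": mdm_value})

    # 16S assignments
    n_conflict = int(round(conflict_fraction * n))
    conflict_ids = sorted(rng.choice(genome_ids, size=n_conflict,
                                     replace=False)) if n_conflict else []
    conflict_set = set(conflict_ids)
    rrna_rows = []
    bundle = TruthBundle(chimera_ids=list(chimera_ids))
    for genome_id in genome_ids:
        n_copies = int(rng.choice([0, 1, 2], p=[0.3, 0.5, 0.2]))
        if genome_id in conflict_set and n_copies == 0:
            n_copies = 2
        own = RankedTaxonomy.from_string(taxonomies[genome_id])
        for c in range(n_copies):
            tax = own
            if genome_id in conflict_set and c == 0:
                if rng.random() < 0.5:
                    tax = dataclasses.replace(own, domain="Archaea"
                                              if own.domain != "Archaea"
                                              else "Bacteria")
                    level = "domain"
                else:
                    tax = dataclasses.replace(own, phylum="phyXX")
                    level = "phylum"
                bundle.conflicts_16s.append(
                    {"genome_id": genome_id, "rank": level})
            rrna_rows.append({"genome_id": genome_id,
                              "seq_id": f"{genome_id}_16S_{c}",
                              "taxonomy": tax.to_string()})
    gunc = pd.DataFrame(gunc_rows)
    mdm = pd.DataFrame(mdm_rows)
    rrna = pd.DataFrame(rrna_rows)
    return gunc, mdm, rrna, bundle


# --------------------------------------------------------------------------
# Recruitment summaries
# --------------------------------------------------------------------------

def simulate_recruitment(
    truth: TruthBundle,
    coverage: Mapping[str, float] | None = None,
    n_samples: int = 24,
    n_reads: int = 2000,
    identity_noise: float = 0.03,
    exact_identity_prob: float = 0.3,
    aln_length_mean: float = 150.0,
    aln_length_sd: float = 30.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Best-hit alignment summaries for SAG and MAG reference sets.

    Each reference set covers a random subset of lineages whose cumulative
    true abundance approximates its *coverage* (default 0.8 for both).
    Reads are drawn from the community; a read from a covered lineage gets
    ``best_identity = 1 - |N(0, identity_noise)|`` (with a point mass of
    perfect identity) and a normal alignment length whose lower tail dips
    below the 100 bp filter; uncovered reads yield no row.
    """
    coverage = dict(coverage or {"SAG": 0.8, "MAG": 0.8})
    for ref, cov in coverage.items():
        if not 0 <= cov <= 1:
            raise ValueError(f"coverage for {ref} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lineages = list(truth.true_proportions)
    probs = np.array([truth.true_proportions[l] for l in lineages])
    probs = probs / probs.sum()

    covered: dict[str, np.ndarray] = {}
    recruit_prob: dict[str, float] = {}
    for ref in ("SAG", "MAG"):
        target = coverage.get(ref, 0.8)
        order = rng.permutation(len(lineages))
        mask = np.zeros(len(lineages), dtype=bool)
        mass = 0.0
        for idx in order:
            if mass >= target:
                break
            mask[idx] = True
            mass += probs[idx]
        covered[ref] = mask
        # thin recruitment so the expected recruited fraction equals the
        # coverage target exactly; otherwise the random overshoot of the
        # covered mass would plant a spurious systematic SAG/MAG difference
        recruit_prob[ref] = min(1.0, target / mass) if mass > 0 else 0.0

    rows = []
    for s in range(n_samples):
        sample_id = f"meta_s{s:02d}"
        read_lineages = rng.choice(len(lineages), size=n_reads, p=probs)
        for ref in ("SAG", "MAG"):
            hit = (covered[ref][read_lineages]
                   & (rng.random(n_reads) < recruit_prob[ref]))
            n_hit = int(hit.sum())
            perfect = rng.random(n_hit) < exact_identity_prob
            noise = np.abs(rng.normal(0.0, identity_noise, size=n_hit))
            identity = np.clip(np.where(perfect, 1.0, 1.0 - noise), 0.0, 1.0)
            lengths = np.maximum(
                1, np.rint(rng.normal(aln_length_mean, aln_length_sd,
                                      size=n_hit)).astype(int))
            indices = np.flatnonzero(hit)
            for j in range(n_hit):
                rows.append({
                    "sample_id": sample_id, "reference_set": ref,
                    "read_id": f"{sample_id}_r{indices[j]:05d}",
                    "best_identity": float(identity[j]),
                    "aln_length": int(lengths[j]),
                    "sample_total_reads": n_reads,
                })
    bundle = TruthBundle(recruitment_coverage={
        ref: float(covered[ref].astype(float) @ probs) for ref in covered})
    return pd.DataFrame(rows), bundle
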