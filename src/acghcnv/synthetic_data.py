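"""Synthetic probe-level aCGH cohorts with planted CNV truth.

This module generates everything the downstream pipeline consumes, so the
whole analysis is testable without any external download:

* a jittered probe design tiling a genome model at a target mean spacing
  (the full-size preset emulates a ~410,739-probe array at 5.3 kb);
* a two-group patient cohort (default 39 + 10, mirroring a NASH / simple
  steatosis design) in which each sample carries each planted CNV with its
  group's frequency (independent Bernoulli draws);
* per-probe log2(test/reference) ratios: ``log2(copy_number / 2)`` inside
  carried intervals, 0 elsewhere, plus Gaussian probe noise and optional
  outliers;
* a reference CNV database engineered so that planted regions have exact
  0% / partial / 100% union coverage (novel / rare / common classes);
* gene annotation, gene sets (with one genuinely enriched planted term), a
  curated disease-gene list (70 symbols, a known fraction of them invalid)
  and the matching valid-symbol list;
* noisy TaqMan Ct replicates for the qPCR interpretation step.

The simulator emits already-normalised log2 ratios; dye bias, GC waves,
spatial artefacts, mosaicism and sex-chromosome dosage are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel, toy_genome

__all__ = [
    "ProbeDesign",
    "NoiseModel",
    "PlantedRegion",
    "CohortSpec",
    "TruthTable",
    "GeneResources",
    "SimulatedCohort",
    "design_probes",
    "plant_truth",
    "simulate_log2",
    "make_reference_db",
    "make_gene_resources",
    "simulate_qpcr_ct",
    "default_cohort_spec",
    "simulate_cohort",
    "write_cohort",
]

#: log2 ratio reported for homozygous deletions (log2(0/2) is -inf; real
#: arrays saturate, so copy number 0 is capped here).
LOG2_RATIO_FLOOR = -4.0


def copy_number_log2(copy_number: int) -> float:
    """Expected log2(test/reference) ratio of an integer copy state."""
    if copy_number < 0:
        raise ValueError("copy number must be non-negative")
    if copy_number == 0:
        return LOG2_RATIO_FLOOR
    return math.log2(copy_number / 2.0)


@dataclass(frozen=True)
class ProbeDesign:
    """Per-chromosome probe start positions (strictly increasing)."""

    starts: dict[str, np.ndarray]
    probe_length: int = 60
    target_spacing: int = 5300

    def __post_init__(self) -> None:
        for chrom, pos in self.starts.items():
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(f"probe positions on {chrom} must be strictly increasing")

    @property
    def n_probes(self) -> int:
        return sum(int(p.size) for p in self.starts.values())

    def mean_spacing(self, chrom: str) -> float:
        pos = self.starts[chrom]
        if pos.size < 2:
            return float("nan")
        return float((pos[-1] - pos[0]) / (pos.size - 1))

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for chrom, pos in self.starts.items():
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": pos,
                        "end": pos + self.probe_length,
                        "probe_id": [f"{chrom}_p{i + 1:06d}" for i in range(pos.size)],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def design_probes(
    genome_model: GenomeModel,
    target_spacing_bp: int,
    seed: int,
    jitter_frac: float = 0.2,
    probe_length: int = 60,
) -> ProbeDesign:
    """Tile every chromosome with jittered probes at a target mean spacing.

    Probes sit on a regular grid of pitch ``target_spacing_bp`` with each
    position independently perturbed by up to ``jitter_frac`` of the spacing
    (default +/-20%), which preserves strict ordering and keeps the probe
    count at exactly ``floor(length / spacing)`` per chromosome.  A
    chromosome shorter than the spacing receives a single central probe.
    Deterministic for a fixed seed.
    """
    if target_spacing_bp <= 0:
        raise ValueError("target spacing must be positive")
    if not 0.0 <= jitter_frac < 0.5:
        raise ValueError("jitter fraction must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    s = float(target_spacing_bp)
    starts: dict[str, np.ndarray] = {}
    for chrom in genome_model.chromosomes:
        k = chrom.length // target_spacing_bp
        if k == 0:
            pos = np.array([max(0, (chrom.length - probe_length) // 2)], dtype=np.int64)
        else:
            grid = np.arange(k, dtype=float) * s + s / 2.0
            jitter = rng.uniform(-jitter_frac * s, jitter_frac * s, size=k)
            pos = np.floor(grid + jitter).astype(np.int64)
            np.clip(pos, 0, chrom.length - 1, out=pos)
        starts[chrom.name] = pos
    return ProbeDesign(starts=starts, probe_length=probe_length, target_spacing=target_spacing_bp)


@dataclass(frozen=True)
class NoiseModel:
    """Per-probe measurement noise in log2 units."""

    sd: float = 0.15
    outlier_prob: float = 0.001
    outlier_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.sd < 0 or self.outlier_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.outlier_prob < 1.0:
            raise ValueError("outlier probability must lie in [0, 1)")


@dataclass(frozen=True)
class PlantedRegion:
    """A CNV to plant, with per-group carrier frequencies and DB coverage target."""

    name: str
    chrom: str
    start: int
    end: int
    copy_number: int
    frequencies: Mapping[str, float]
    db_coverage_pct: float = 100.0
    n_genes: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region {self.name!r}: start must be below end")
        if self.copy_number == 2:
            raise ValueError(f"region {self.name!r}: copy number 2 is not a CNV")
        for g, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"region {self.name!r}: frequency for {g!r} outside [0, 1]")
        if not 0.0 <= self.db_coverage_pct <= 100.0:
            raise ValueError(f"region {self.name!r}: coverage target outside [0, 100]")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def expected_log2(self) -> float:
        return copy_number_log2(self.copy_number)


@dataclass(frozen=True)
class CohortSpec:
    """Group sizes and planted regions of a simulated cohort."""

    groups: Mapping[str, int]
    regions: tuple[PlantedRegion, ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        for g, n in self.groups.items():
            if n <= 0:
                raise ValueError(f"group {g!r} must have a positive sample count")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{group}_{i + 1:02d}"
            for group, n in self.groups.items()
            for i in range(n)
        ]

    def group_of(self, sample: str) -> str:
        return sample.rsplit("_", 1)[0]


@dataclass(frozen=True)
class TruthTable:
    """Planted carrier truth: one row per (sample, carried region)."""

    samples: tuple[str, ...]
    groups: Mapping[str, tuple[str, ...]]
    rows: pd.DataFrame  # sample, group, region, chrom, start, end, copy_number

    def carriers(self, region_name: str) -> list[str]:
        r = self.rows
        return sorted(r.loc[r["region"] == region_name, "sample"])


def plant_truth(cohort_spec: CohortSpec, seed: int) -> TruthTable:
    """Draw carrier status for every sample x region (independent Bernoulli).

    Raises if a sample would carry two overlapping regions.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    groups: dict[str, tuple[str, ...]] = {}
    for group, n in cohort_spec.groups.items():
        ids = tuple(f"{group}_{i + 1:02d}" for i in range(n))
        groups[group] = ids
        for sample in ids:
            carried = []
            for region in cohort_spec.regions:
                freq = region.frequencies.get(group, 0.0)
                if rng.random() < freq:
                    carried.append(region)
            for a_idx, a in enumerate(carried):
                for b in carried[a_idx + 1 :]:
                    if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                        raise ValueError(
                            f"sample {sample} carries overlapping regions "
                            f"{a.name!r} and {b.name!r}"
                        )
            for region in carried:
                rows.append(
                    (
                        sample,
                        group,
                        region.name,
                        region.chrom,
                        region.start,
                        region.end,
                        region.copy_number,
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=["sample", "group", "region", "chrom", "start", "end", "copy_number"],
    )
    samples = tuple(s for ids in groups.values() for s in ids)
    return TruthTable(samples=samples, groups=groups, rows=df)


def simulate_log2(
    probe_design: ProbeDesign,
    truth_table: TruthTable,
    noise_model: NoiseModel,
    seed: int,
) -> pd.DataFrame:
    """Probe-level log2 ratio matrix: positions plus one column per sample.

    Probe value is ``log2(copy_number / 2)`` inside a carried interval and 0
    elsewhere, plus Gaussian noise of the given sd and, with the configured
    probability, an extra outlier deviate.
    """
    probed = set(probe_design.starts)
    bad = set(truth_table.rows["chrom"]) - probed
    if bad:
        raise ValueError(f"truth intervals on unprobed chromosomes: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    base = probe_design.to_frame()
    offsets = {}
    off = 0
    for chrom, pos in probe_design.starts.items():
        offsets[chrom] = off
        off += pos.size
    n_probes = off
    samples = list(truth_table.samples)
    values = np.zeros((n_probes, len(samples)))
    col = {s: j for j, s in enumerate(samples)}
    for r in truth_table.rows.itertuples():
        pos = probe_design.starts[r.chrom]
        lo = offsets[r.chrom] + int(np.searchsorted(pos, r.start, side="left"))
        hi = offsets[r.chrom] + int(np.searchsorted(pos, r.end, side="left"))
        values[lo:hi, col[r.sample]] = copy_number_log2(int(r.copy_number))
    if noise_model.sd > 0:
        values += rng.normal(0.0, noise_model.sd, size=values.shape)
    if noise_model.outlier_prob > 0:
        mask = rng.random(values.shape) < noise_model.outlier_prob
        values[mask] += rng.normal(0.0, noise_model.outlier_sd, size=int(mask.sum()))
    for j, s in enumerate(samples):
        base[s] = values[:, j]
    return base


def make_reference_db(
    regions: Sequence[PlantedRegion],
    coverage_targets: Optional[Sequence[float]] = None,
    seed: int = 0,
    genome_model: Optional[GenomeModel] = None,
    n_background: int = 60,
    clearance: int = 20_000,
) -> pd.DataFrame:
    """Engineer a reference CNV database with exact per-region union coverage.

    For each planted region a record is emitted so that the union coverage of
    the region equals its target percentage: no record for 0%, a record over
    the leading fraction of the region for partial targets, and a record
    containing the region (with padding) for 100%.  Unrelated background
    records are scattered over the genome, keeping ``clearance`` bp away from
    every planted region so the engineered coverages stay exact.
    """
    if coverage_targets is None:
        coverage_targets = [r.db_coverage_pct for r in regions]
    if len(coverage_targets) != len(regions):
        raise ValueError("one coverage target per region is required")
    records = []
    rid = 0
    for region, target in zip(regions, coverage_targets):
        if not 0.0 <= target <= 100.0:
            raise ValueError(f"coverage target {target} outside [0, 100]")
        if target == 0.0:
            continue
        rid += 1
        if target == 100.0:
            start = max(0, region.start - 5000)
            end = region.end + 5000
        else:
            start = region.start
            end = region.start + int(round(region.size * target / 100.0))
        records.append((region.chrom, start, end, f"nsv{rid:05d}"))
    if genome_model is not None and n_background > 0:
        rng = np.random.default_rng(seed)
        keep_out = [
            (r.chrom, r.start - clearance, r.end + clearance) for r in regions
        ]
        chroms = genome_model.chromosomes
        attempts = 0
        made = 0
        while made < n_background and attempts < 50 * n_background:
            attempts += 1
            c = chroms[int(rng.integers(len(chroms)))]
            size = int(rng.integers(5_000, 200_000))
            if c.length <= size:
                continue
            start = int(rng.integers(0, c.length - size))
            end = start + size
            if any(
                c.name == kc and start < ke and ks < end for kc, ks, ke in keep_out
            ):
                continue
            rid += 1
            made += 1
            records.append((c.name, start, end, f"nsv{rid:05d}"))
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start"], ignore_index=True)


@dataclass(frozen=True)
class GeneResources:
    """Gene annotation, gene sets and symbol lists for the annotation stage."""

    genes: pd.DataFrame  # chrom, start, end, name
    gene_sets: dict[str, tuple[str, list[str]]]  # GMT-shaped
    disease_genes: list[str]
    valid_symbols: list[str]
    region_genes: dict[str, list[str]]
    planted_term_id: str
    background: list[str]


def make_gene_resources(
    regions: Sequence[PlantedRegion],
    n_background_genes: int = 1000,
    seed: int = 0,
    genome_model: Optional[GenomeModel] = None,
    n_disease: int = 70,
    n_invalid: int = 2,
    planted_term_members: int = 30,
    planted_term_hits: int = 10,
    n_random_terms: int = 12,
) -> GeneResources:
    """Build gene annotation, gene sets and symbol lists around planted regions.

    Every planted region receives exactly its requested number of genes, laid
    out fully inside the region.  The curated disease list carries
    ``n_disease`` symbols of which ``n_invalid`` are deliberately absent from
    the valid-symbol list (emulating non-gene entities that symbol
    verification must remove).  One planted gene set is genuinely enriched in
    the union of region genes and valid disease genes, with an exactly
    recomputable hypergeometric p-value; the remaining terms are random.
    """
    if n_background_genes < 1:
        raise ValueError("need at least one background gene")
    rng = np.random.default_rng(seed)
    n_region_genes = sum(r.n_genes for r in regions)
    if n_background_genes < n_region_genes + n_disease:
        raise ValueError("background gene count too small for regions + disease list")
    symbols = [f"GENE{i + 1:06d}" for i in range(n_background_genes)]
    rows = []
    region_genes: dict[str, list[str]] = {}
    cursor = 0
    for region in regions:
        assigned = []
        slot = region.size / max(region.n_genes, 1)
        for g in range(region.n_genes):
            sym = symbols[cursor]
            cursor += 1
            gs = region.start + int(slot * (g + 0.2))
            ge = region.start + int(slot * (g + 0.8))
            rows.append((region.chrom, gs, max(ge, gs + 1), sym))
            assigned.append(sym)
        region_genes[region.name] = assigned
    filler = symbols[cursor:]
    keep_out = [(r.chrom, r.start - 10_000, r.end + 10_000) for r in regions]
    if genome_model is not None:
        chroms = genome_model.chromosomes
        for sym in filler:
            for _ in range(100):
                c = chroms[int(rng.integers(len(chroms)))]
                size = int(rng.integers(2_000, 50_000))
                if c.length <= size:
                    continue
                start = int(rng.integers(0, c.length - size))
                end = start + size
                if any(c.name == kc and start < ke and ks < end for kc, ks, ke in keep_out):
                    continue
                rows.append((c.name, start, end, sym))
                break
            else:
                raise RuntimeError("could not place a background gene off the planted regions")
    else:
        # no genome given: park fillers on an unplaced contig
        for i, sym in enumerate(filler):
            rows.append(("chrU", i * 10_000, i * 10_000 + 5_000, sym))
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    genes = genes.sort_values(["chrom", "start"], ignore_index=True)

    valid_disease = list(rng.choice(filler, size=n_disease - n_invalid, replace=False))
    invalid = [f"NONGENE{i + 1:02d}" for i in range(n_invalid)]
    disease = valid_disease + invalid
    rng.shuffle(disease)

    all_region_genes = [g for genes_ in region_genes.values() for g in genes_]
    target_pool = list(dict.fromkeys(all_region_genes + valid_disease))
    planted_hits = min(planted_term_hits, len(target_pool))
    hit_members = list(rng.choice(target_pool, size=planted_hits, replace=False))
    other_pool = [s for s in symbols if s not in set(target_pool)]
    n_rest = max(planted_term_members - planted_hits, 0)
    rest_members = list(rng.choice(other_pool, size=n_rest, replace=False))
    planted_term_id = "GO:SIM0001"
    gene_sets: dict[str, tuple[str, list[str]]] = {
        planted_term_id: ("planted enriched process", hit_members + rest_members)
    }
    for t in range(n_random_terms):
        size = int(rng.integers(20, 60))
        members = list(rng.choice(symbols, size=size, replace=False))
        gene_sets[f"GO:SIM{t + 2:04d}"] = (f"random process {t + 1}", members)

    return GeneResources(
        genes=genes,
        gene_sets=gene_sets,
        disease_genes=disease,
        valid_symbols=list(symbols),
        region_genes=region_genes,
        planted_term_id=planted_term_id,
        background=list(symbols),
    )


def simulate_qpcr_ct(
    copy_number: int,
    seed: int,
    ct_sd: float = 0.1,
    n_replicates: int = 4,
    reference_ct: float = 25.0,
    calibrator_delta_ct: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy duplex TaqMan Ct replicates for a sample with a known copy state.

    Target Ct shifts by ``-log2(cn / 2)`` relative to the diploid calibrator
    offset, so feeding the result to the ddCt estimator recovers ``cn`` up to
    Ct noise.  Returns ``(target_ct, reference_ct)`` replicate arrays.
    """
    if copy_number <= 0:
        raise ValueError("qPCR simulation needs a positive copy number")
    rng = np.random.default_rng(seed)
    ref = reference_ct + rng.normal(0.0, ct_sd, size=n_replicates)
    shift = -math.log2(copy_number / 2.0)
    tgt = (
        reference_ct
        + calibrator_delta_ct
        + shift
        + rng.normal(0.0, ct_sd, size=n_replicates)
    )
    return tgt, ref


def default_cohort_spec() -> CohortSpec:
    """Study-shaped default cohort: 39 NASH + 10 simple-steatosis samples.

    Planted regions mirror the frequency spectrum of the study tables on the
    toy genome: a few common high-frequency gains/losses shared by both
    groups, NASH-only regions around 33% and 10-13% frequency including two
    rare (partial DB coverage) and two novel (0% coverage) loci, and one
    sex-chromosome CNV exercising the autosome filter.  Gene counts on the
    four rare/novel regions are 1, 1, 5 and 2.
    """
    both = lambda n, s: {"NASH": n, "SS": s}  # noqa: E731
    regions = (
        PlantedRegion("common_gain_chr1", "chr1", 2_000_000, 2_130_000, 3, both(0.54, 0.5), 100.0, 3),
        PlantedRegion("common_loss_chr1", "chr1", 7_000_000, 7_090_000, 1, both(0.36, 0.4), 100.0, 2),
        PlantedRegion("common_gain_chr2", "chr2", 1_500_000, 1_600_000, 3, both(0.33, 0.0), 100.0, 1),
        PlantedRegion("rare_gain_chr2a", "chr2", 4_800_000, 4_880_000, 3, both(0.128, 0.0), 30.0, 1),
        PlantedRegion("rare_gain_chr2b", "chr2", 8_200_000, 8_270_000, 4, both(0.103, 0.0), 30.0, 1),
        PlantedRegion("novel_gain_chr3", "chr3", 2_500_000, 2_620_000, 3, both(0.103, 0.0), 0.0, 5),
        PlantedRegion("novel_loss_chr3", "chr3", 6_400_000, 6_460_000, 1, both(0.103, 0.0), 0.0, 2),
        PlantedRegion("common_loss_chrX", "chrX", 3_000_000, 3_100_000, 1, both(0.2, 0.2), 100.0, 1),
    )
    return CohortSpec(groups={"NASH": 39, "SS": 10}, regions=regions)


@dataclass(frozen=True)
class SimulatedCohort:
    """Everything one simulated study provides to the pipeline."""

    genome: GenomeModel
    spec: CohortSpec
    probe_design: ProbeDesign
    truth: TruthTable
    probes: pd.DataFrame
    reference_db: pd.DataFrame
    gene_resources: GeneResources
    noise: NoiseModel
    seed: int


def simulate_cohort(
    spec: Optional[CohortSpec] = None,
    genome_model: Optional[GenomeModel] = None,
    noise_model: Optional[NoiseModel] = None,
    target_spacing_bp: int = 5300,
    seed: int = 0,
) -> SimulatedCohort:
    """Generate one full synthetic study (probes, truth, DB, gene resources)."""
    spec = spec if spec is not None else default_cohort_spec()
    genome = genome_model if genome_model is not None else toy_genome()
    noise = noise_model if noise_model is not None else NoiseModel()
    ss = np.random.SeedSequence(seed)
    s_design, s_truth, s_log2, s_db, s_genes = (
        int(x % (2**31)) for x in ss.generate_state(5)
    )
    design = design_probes(genome, target_spacing_bp, s_design)
    truth = plant_truth(spec, s_truth)
    probes = simulate_log2(design, truth, noise, s_log2)
    refdb = make_reference_db(spec.regions, seed=s_db, genome_model=genome)
    resources = make_gene_resources(spec.regions, seed=s_genes, genome_model=genome)
    return SimulatedCohort(
        genome=genome,
        spec=spec,
        probe_design=design,
        truth=truth,
        probes=probes,
        reference_db=refdb,
        gene_resources=resources,
        noise=noise,
        seed=seed,
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, str]:
    """Write all cohort artefacts as plain text; returns path map."""
    import os

    from . import io as aio

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "probes": os.path.join(outdir, "probes.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "genome": os.path.join(outdir, "genome.tsv"),
        "samples": os.path.join(outdir, "samples.txt"),
        "reference_db": os.path.join(outdir, "reference_cnvs.bed"),
        "genes": os.path.join(outdir, "genes.bed"),
        "gene_sets": os.path.join(outdir, "gene_sets.gmt"),
        "disease_genes": os.path.join(outdir, "disease_genes.txt"),
        "valid_symbols": os.path.join(outdir, "valid_symbols.txt"),
    }
    aio.write_probe_matrix(cohort.probes, paths["probes"])
    cohort.truth.rows.to_csv(paths["truth"], sep="\t", index=False)
    cohort.genome.to_frame().to_csv(paths["genome"], sep="\t", index=False)
    aio.write_symbol_list(cohort.truth.samples, paths["samples"])
    aio.write_bed(cohort.reference_db, paths["reference_db"])
    aio.write_bed(cohort.gene_resources.genes, paths["genes"])
    aio.write_gmt(cohort.gene_resources.gene_sets, paths["gene_sets"])
    aio.write_symbol_list(cohort.gene_resources.disease_genes, paths["disease_genes"])
    aio.write_symbol_list(cohort.gene_resources.valid_symbols, paths["valid_symbols"])
    return paths
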