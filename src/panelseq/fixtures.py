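"""Seeded synthetic study generator for every pipeline input.

The generator emulates the study design end to end at 1/100 genome
scale: a five-chromosome reference, eight divergent inbred accessions
re-sequenced against it, five SNP callers with configurable
false-negative/false-positive rates, a self-resequencing control of the
reference line, and multiplexed amplicon read profiles for the eight
accessions plus an F1 hybrid of the reference and one accession.

Per-accession SNP densities default to realistic per-100-kb values for
divergent inbred accessions of a small grass genome; a subset of sites
("shared" SNPs) carries one identical alternate allele in every
accession and is the substrate of panel selection.  Everything is
reproducible from the seed: the same config yields byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .discovery import DiscoveryParams
from .genotyping import MarkerReadProfile
from .io_formats import (
    BASES,
    GenomeSequence,
    SiteAlleleCounts,
    VariantRecord,
    write_count_table,
    write_fasta,
    write_vcf_minimal,
)
from .saturation import ReadAllocation

DEFAULT_CHROM_LENGTHS = {
    # 1/100 of a 271-Mb five-chromosome grass genome
    "chr1": 748_000,
    "chr2": 593_000,
    "chr3": 599_000,
    "chr4": 486_000,
    "chr5": 284_000,
}

# SNPs per 100 kb vs the reference, per accession (genome-wide averages
# typical of divergent vs closely related inbred accessions).
DEFAULT_ACCESSION_DENSITY = {
    "acc1": 519.2,
    "acc2": 174.3,
    "acc3": 127.8,
    "acc4": 434.4,
    "acc5": 282.2,
    "acc6": 148.5,
    "acc7": 268.7,
    "acc8": 135.9,
}

DEFAULT_PANEL_TARGETS = {"chr1": 12, "chr2": 9, "chr3": 10, "chr4": 8, "chr5": 5}

DEFAULT_CALLERS = ("callerA", "callerB", "callerC", "callerD", "callerE")


@dataclass
class FixtureConfig:
    """All knobs of the synthetic study; the seed is mandatory."""

    seed: int
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    accession_density: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACCESSION_DENSITY)
    )
    reference_accession: str = "ref0"
    f1_parents: tuple[str, str] = ("ref0", "acc2")
    shared_snp_per_100kb: float = 25.0
    callers: tuple[str, ...] = DEFAULT_CALLERS
    caller_fn_rate: float = 0.05
    caller_fp_per_mb: float = 20.0
    depth_mean: float = 20.0  # per-caller reported depth, Poisson
    mq_mean: float = 50.0
    mq_sd: float = 5.0
    count_error: float = 0.01  # WGS per-read miscall fraction in count tables
    self_discordant_fraction: float = 0.02
    panel_targets: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_TARGETS)
    )
    # Amplicon sequencing model
    amplicon_total_reads: int = 65_000  # per sample, at 1/100 scale
    on_target_fraction: float = 0.45
    amplifiable_fraction: float = 400 / 443
    depth_sigma: float = 1.0  # log-normal per-marker amplification spread
    seq_error: float = 0.01  # amplicon per-read miscall fraction

    def __post_init__(self) -> None:
        for name, rate in [
            ("caller_fn_rate", self.caller_fn_rate),
            ("on_target_fraction", self.on_target_fraction),
            ("amplifiable_fraction", self.amplifiable_fraction),
            ("seq_error", self.seq_error),
            ("self_discordant_fraction", self.self_discordant_fraction),
        ]:
            if not (0 <= rate <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        total_kb100 = sum(self.chrom_lengths.values()) / 100_000
        n_shared = self.shared_snp_per_100kb * total_kb100
        for chrom, target in self.panel_targets.items():
            avail = self.shared_snp_per_100kb * self.chrom_lengths[chrom] / 100_000
            if target > avail:
                raise ValueError(
                    f"panel target {target} on {chrom} infeasible at "
                    f"{self.shared_snp_per_100kb} shared SNPs per 100 kb"
                )

    @property
    def accessions(self) -> list[str]:
        return list(self.accession_density)

    @property
    def samples(self) -> list[str]:
        """Reference + accessions + F1, the genotyped sample set."""
        return [self.reference_accession, *self.accessions, "f1"]

    def discovery_params(self) -> DiscoveryParams:
        return DiscoveryParams(
            required_callers=frozenset(self.callers),
            required_accessions=frozenset(self.accessions),
        )


@dataclass
class TrueSNP:
    chrom: str
    pos: int
    ref: str
    alt: str
    shared: bool


@dataclass
class StudyBundle:
    """In-memory synthetic study: all inputs plus the scoring truth."""

    config: FixtureConfig
    reference: GenomeSequence
    true_snps: dict[str, list[TrueSNP]]  # accession -> its SNPs vs reference
    shared_sites: list[TrueSNP]  # identical alt in every accession
    caller_records: dict[tuple[str, str], list[VariantRecord]]  # (accession, caller)
    count_tables: dict[str, list[SiteAlleleCounts]]  # accession -> counts
    self_counts: list[SiteAlleleCounts]  # reference line re-sequenced
    self_discordant_positions: set[tuple[str, int]]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def generate_reference(config: FixtureConfig, rng: np.random.Generator) -> GenomeSequence:
    names = list(config.chrom_lengths)
    sequences = {
        name: _random_sequence(rng, config.chrom_lengths[name]) for name in names
    }
    return GenomeSequence(chrom_names=names, sequences=sequences)


def _draw_positions(
    rng: np.random.Generator, length: int, n: int, taken: set[int]
) -> list[int]:
    """n distinct 1-based positions avoiding ``taken``."""
    out: list[int] = []
    while len(out) < n:
        draw = rng.integers(1, length + 1, size=(n - len(out)) * 2 + 10)
        for pos in draw:
            pos = int(pos)
            if pos not in taken:
                taken.add(pos)
                out.append(pos)
                if len(out) == n:
                    break
    return sorted(out)


def _alt_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in BASES if b != ref]
    return choices[int(rng.integers(0, 3))]


def generate_true_snps(
    config: FixtureConfig, reference: GenomeSequence, rng: np.random.Generator
) -> tuple[dict[str, list[TrueSNP]], list[TrueSNP]]:
    """Plant shared and accession-private SNPs at the configured densities."""
    shared: list[TrueSNP] = []
    taken: dict[str, set[int]] = {c: set() for c in reference.chrom_names}
    for chrom in reference.chrom_names:
        length = reference.lengths[chrom]
        n_shared = int(round(config.shared_snp_per_100kb * length / 100_000))
        for pos in _draw_positions(rng, length, n_shared, taken[chrom]):
            ref = reference.base_at(chrom, pos)
            shared.append(TrueSNP(chrom, pos, ref, _alt_base(rng, ref), shared=True))

    per_accession: dict[str, list[TrueSNP]] = {}
    for acc in config.accessions:
        snps = list(shared)
        acc_taken = {c: set(taken[c]) for c in reference.chrom_names}
        for chrom in reference.chrom_names:
            length = reference.lengths[chrom]
            n_total = int(round(config.accession_density[acc] * length / 100_000))
            n_private = max(0, n_total - sum(1 for s in shared if s.chrom == chrom))
            for pos in _draw_positions(rng, length, n_private, acc_taken[chrom]):
                ref = reference.base_at(chrom, pos)
                snps.append(TrueSNP(chrom, pos, ref, _alt_base(rng, ref), shared=False))
        snps.sort(key=lambda s: (s.chrom, s.pos))
        per_accession[acc] = snps
    return per_accession, shared


def generate_caller_records(
    config: FixtureConfig,
    true_snps: Mapping[str, list[TrueSNP]],
    reference: GenomeSequence,
    rng: np.random.Generator,
) -> dict[tuple[str, str], list[VariantRecord]]:
    """Per-caller call sets: true SNPs minus false negatives, plus false
    positives at random non-SNP positions."""
    out: dict[tuple[str, str], list[VariantRecord]] = {}
    genome_mb = sum(config.chrom_lengths.values()) / 1e6
    for acc in config.accessions:
        snps = true_snps[acc]
        snp_positions = {(s.chrom, s.pos) for s in snps}
        for caller in config.callers:
            records: list[VariantRecord] = []
            keep = rng.random(len(snps)) >= config.caller_fn_rate
            depths = rng.poisson(config.depth_mean, size=len(snps))
            mqs = np.clip(rng.normal(config.mq_mean, config.mq_sd, size=len(snps)), 0, None)
            for i, snp in enumerate(snps):
                if not keep[i]:
                    continue
                records.append(
                    VariantRecord(
                        snp.chrom,
                        snp.pos,
                        snp.ref,
                        snp.alt,
                        depth=int(depths[i]),
                        mapping_quality=round(float(mqs[i]), 1),
                        caller_id=caller,
                        accession_id=acc,
                    )
                )
            n_fp = rng.poisson(config.caller_fp_per_mb * genome_mb)
            for _ in range(int(n_fp)):
                chrom = reference.chrom_names[
                    int(rng.integers(0, len(reference.chrom_names)))
                ]
                pos = int(rng.integers(1, reference.lengths[chrom] + 1))
                if (chrom, pos) in snp_positions:
                    continue
                ref = reference.base_at(chrom, pos)
                records.append(
                    VariantRecord(
                        chrom,
                        pos,
                        ref,
                        _alt_base(rng, ref),
                        depth=int(rng.poisson(config.depth_mean)),
                        mapping_quality=round(
                            float(np.clip(rng.normal(config.mq_mean, config.mq_sd), 0, None)), 1
                        ),
                        caller_id=caller,
                        accession_id=acc,
                    )
                )
            records.sort(key=lambda r: (r.chrom, r.pos, r.alt_allele))
            out[(acc, caller)] = records
    return out


def _counts_for_base(
    rng: np.random.Generator, depth: int, true_base: str, error: float
) -> tuple[int, int, int, int]:
    """Multinomial per-base read counts with a uniform miscall model."""
    probs = np.full(4, error / 3)
    probs[BASES.index(true_base)] = 1.0 - error
    drawn = rng.multinomial(depth, probs)
    return tuple(int(x) for x in drawn)


def generate_count_tables(
    config: FixtureConfig,
    true_snps: Mapping[str, list[TrueSNP]],
    reference: GenomeSequence,
    rng: np.random.Generator,
) -> dict[str, list[SiteAlleleCounts]]:
    """Alignment allele counts at the union of all true SNP positions.

    Every accession's table covers the same position set, so the
    allele-fraction discovery route sees each site in all accessions.
    Accessions are homozygous: reads carry the accession's allele with a
    small uniform miscall rate.
    """
    union: dict[tuple[str, int], str] = {}
    for snps in true_snps.values():
        for s in snps:
            union[(s.chrom, s.pos)] = s.ref
    positions = sorted(union)

    tables: dict[str, list[SiteAlleleCounts]] = {}
    for acc in config.accessions:
        own = {(s.chrom, s.pos): s for s in true_snps[acc]}
        depths = rng.poisson(config.depth_mean, size=len(positions))
        rows = []
        for (chrom, pos), depth in zip(positions, depths):
            depth = max(int(depth), 1)
            snp = own.get((chrom, pos))
            true_base = snp.alt if snp is not None else union[(chrom, pos)]
            counts = _counts_for_base(rng, depth, true_base, config.count_error)
            rows.append(SiteAlleleCounts(chrom, pos, acc, counts))
        tables[acc] = rows
    return tables


def generate_self_counts(
    config: FixtureConfig,
    shared_sites: Sequence[TrueSNP],
    rng: np.random.Generator,
) -> tuple[list[SiteAlleleCounts], set[tuple[str, int]]]:
    """Self-resequencing of the reference line at the shared sites.

    Most sites agree with the assembly; a configured fraction are
    assembly/mapping artifacts with a high non-reference read fraction,
    which purification must remove.
    """
    discordant: set[tuple[str, int]] = set()
    rows = []
    acc = config.reference_accession
    for snp in shared_sites:
        depth = max(int(rng.poisson(config.depth_mean)), 1)
        if rng.random() < config.self_discordant_fraction:
            # artifact: 10-60 % of self reads disagree with the assembly
            frac = rng.uniform(0.10, 0.60)
            n_bad = max(int(round(frac * depth)), int(0.06 * depth) + 1)
            n_bad = min(n_bad, depth)
            counts = [0, 0, 0, 0]
            counts[BASES.index(snp.ref)] = depth - n_bad
            counts[BASES.index(snp.alt)] = n_bad
            discordant.add((snp.chrom, snp.pos))
            rows.append(SiteAlleleCounts(snp.chrom, snp.pos, acc, tuple(counts)))
        else:
            counts = _counts_for_base(rng, depth, snp.ref, config.count_error / 2)
            rows.append(SiteAlleleCounts(snp.chrom, snp.pos, acc, counts))
    return rows, discordant


def generate_study(config: FixtureConfig) -> StudyBundle:
    """Generate the full synthetic study, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    reference = generate_reference(config, rng)
    true_snps, shared_sites = generate_true_snps(config, reference, rng)
    caller_records = generate_caller_records(config, true_snps, reference, rng)
    count_tables = generate_count_tables(config, true_snps, reference, rng)
    self_counts, discordant = generate_self_counts(config, shared_sites, rng)
    return StudyBundle(
        config=config,
        reference=reference,
        true_snps=true_snps,
        shared_sites=shared_sites,
        caller_records=caller_records,
        count_tables=count_tables,
        self_counts=self_counts,
        self_discordant_positions=discordant,
    )


def discover_candidates(bundle: StudyBundle) -> list:
    """Run the full discovery stack on a synthetic study bundle.

    Caller intersection per accession, allele-fraction supplementation,
    per-accession union, biallelic shared-alternate selection, then
    purification against the self-resequencing control.
    """
    from . import discovery as disc

    cfg = bundle.config
    params = cfg.discovery_params()
    per_acc = {
        acc: disc.intersect_callers(
            {c: bundle.caller_records[(acc, c)] for c in cfg.callers}, params
        )
        for acc in cfg.accessions
    }
    supplement = disc.supplement_by_allele_fraction(
        bundle.count_tables, bundle.reference, params
    )
    per_acc = {
        acc: disc.merge_candidates(per_acc[acc], supplement) for acc in per_acc
    }
    shared = disc.select_biallelic_shared(per_acc, cfg.accessions)
    return disc.purify_against_self(shared, bundle.self_counts, params)


def theoretical_genotypes(
    config: FixtureConfig, marker_ids: Sequence[str]
) -> dict[str, dict[str, str]]:
    """sample -> marker -> expected class.

    The reference line is AA everywhere, each accession BB (panel markers
    carry the shared alternate), and the F1 hybrid AB.
    """
    out: dict[str, dict[str, str]] = {}
    out[config.reference_accession] = {m: "AA" for m in marker_ids}
    for acc in config.accessions:
        out[acc] = {m: "BB" for m in marker_ids}
    out["f1"] = {m: "AB" for m in marker_ids}
    return out


def _genotype_allele_probs(genotype: str, error: float) -> tuple[float, float, float]:
    """(p_ref, p_alt, p_other) for one amplicon read."""
    # a miscalled read lands on the alternate with prob error/3 and on
    # one of the two remaining bases otherwise
    if genotype == "AA":
        return 1.0 - error, error / 3, 2 * error / 3
    if genotype == "BB":
        return error / 3, 1.0 - error, 2 * error / 3
    if genotype == "AB":
        p_hit = (1.0 - error) / 2 + error / 6
        return p_hit, p_hit, 2 * error / 3
    raise ValueError(f"unknown genotype {genotype}")


def amplicon_allocation(
    marker_ids: Sequence[str],
    genotype_per_marker: Mapping[str, str],
    rng: np.random.Generator,
    total_reads: int,
    on_target_fraction: float,
    amplifiable_mask: np.ndarray,
    marker_weights: np.ndarray,
    seq_error: float,
    sample_id: str,
) -> ReadAllocation:
    """Full-data amplicon read allocation for one sample.

    On-target reads are spread over the amplifiable markers with fixed
    per-marker weights (shared across samples: amplification efficiency
    is a property of the primer pair), then each marker's reads are
    split ref/alt/other according to the sample's genotype and the
    per-read miscall rate.
    """
    n = len(marker_ids)
    n_on = int(round(total_reads * on_target_fraction))
    weights = np.where(amplifiable_mask, marker_weights, 0.0)
    if weights.sum() == 0:
        per_marker = np.zeros(n, dtype=np.int64)
    else:
        per_marker = rng.multinomial(n_on, weights / weights.sum())
    ref = np.zeros(n, dtype=np.int64)
    alt = np.zeros(n, dtype=np.int64)
    other = np.zeros(n, dtype=np.int64)
    for i, mid in enumerate(marker_ids):
        depth = int(per_marker[i])
        if depth == 0:
            continue
        p_ref, p_alt, p_other = _genotype_allele_probs(genotype_per_marker[mid], seq_error)
        drawn = rng.multinomial(depth, [p_ref, p_alt, p_other])
        ref[i], alt[i], other[i] = int(drawn[0]), int(drawn[1]), int(drawn[2])
    return ReadAllocation(
        marker_ids=list(marker_ids),
        ref=ref,
        alt=alt,
        other=other,
        off_target=total_reads - n_on,
        sample_id=sample_id,
    )


def default_saturation_fixture(
    seed: int,
    n_markers: int = 443,
    total_reads: int = 6_500_000,
    on_target_fraction: float = 0.45,
    n_amplifiable: int = 400,
    depth_sigma: float = 1.0,
    seq_error: float = 0.01,
    genotype: str = "BB",
) -> tuple[ReadAllocation, dict[str, str]]:
    """The default full-scale amplicon fixture for saturation analysis.

    One homozygous-alternate sample over a 443-marker panel of which 400
    amplify, an on-target read fraction of 0.45 of 6.5 million total
    reads, and log-normal per-marker amplification spread.  Returns the
    allocation and the per-marker theoretical class.
    """
    rng = np.random.default_rng(seed)
    marker_ids = [f"M{i + 1:04d}" for i in range(n_markers)]
    amplifiable = np.zeros(n_markers, dtype=bool)
    amplifiable[rng.permutation(n_markers)[:n_amplifiable]] = True
    weights = rng.lognormal(mean=0.0, sigma=depth_sigma, size=n_markers)
    truth = {mid: genotype for mid in marker_ids}
    allocation = amplicon_allocation(
        marker_ids,
        truth,
        rng,
        total_reads=total_reads,
        on_target_fraction=on_target_fraction,
        amplifiable_mask=amplifiable,
        marker_weights=weights,
        seq_error=seq_error,
        sample_id="sim",
    )
    return allocation, truth


def sample_profiles(
    bundle_config: FixtureConfig,
    marker_ids: Sequence[str],
    rng: np.random.Generator,
) -> tuple[dict[str, list[MarkerReadProfile]], dict[str, dict[str, str]]]:
    """Amplicon read profiles for every sample over a marker panel.

    Per-marker amplification weights and the amplifiable subset are
    drawn once and shared across samples.  Returns profiles per sample
    and the theoretical genotype truth.
    """
    cfg = bundle_config
    n = len(marker_ids)
    n_amp = int(round(cfg.amplifiable_fraction * n))
    amplifiable = np.zeros(n, dtype=bool)
    amplifiable[rng.permutation(n)[:n_amp]] = True
    weights = rng.lognormal(0.0, cfg.depth_sigma, size=n)
    truth = theoretical_genotypes(cfg, marker_ids)

    profiles: dict[str, list[MarkerReadProfile]] = {}
    for sample in cfg.samples:
        allocation = amplicon_allocation(
            marker_ids,
            truth[sample],
            rng,
            total_reads=cfg.amplicon_total_reads,
            on_target_fraction=cfg.on_target_fraction,
            amplifiable_mask=amplifiable,
            marker_weights=weights,
            seq_error=cfg.seq_error,
            sample_id=sample,
        )
        profiles[sample] = allocation.to_profiles()
    return profiles, truth


def write_study(bundle: StudyBundle, outdir: str | Path) -> dict[str, Path]:
    """Serialize a study bundle to disk in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ref_path = outdir / "reference.fasta"
    write_fasta(bundle.reference, ref_path)
    paths["reference"] = ref_path

    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for (acc, caller), records in bundle.caller_records.items():
        p = vcf_dir / f"{acc}.{caller}.vcf"
        write_vcf_minimal(records, p, bundle.reference.lengths)
        paths[f"vcf:{acc}:{caller}"] = p

    counts_dir = outdir / "counts"
    counts_dir.mkdir(exist_ok=True)
    for acc, rows in bundle.count_tables.items():
        p = counts_dir / f"{acc}.counts.tsv"
        write_count_table(rows, p)
        paths[f"counts:{acc}"] = p

    self_path = outdir / "self_resequencing.counts.tsv"
    write_count_table(bundle.self_counts, self_path)
    paths["self_counts"] = self_path
    return paths
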