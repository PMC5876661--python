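"""Candidate marker discovery from multi-caller variant calls.

The candidate set is built in four stages:

1. **Caller intersection** — a site/allele is a candidate only if every
   required caller reports the identical (chrom, pos, ref, alt) with
   read depth >= 5 and mapping quality >= 20.
2. **Allele-fraction supplementation** — sites the callers missed are
   recovered directly from alignment allele counts: depth >= 5 and
   >= 95 % of reads disagreeing with the reference, consistently in
   every required accession.
3. **Purification against self-resequencing** — candidates where reads
   of the reference line itself disagree with the reference assembly in
   more than 5 % of reads are removed as assembly/mapping artifacts.
4. **Biallelic shared-alternate filter** — for panel membership a site
   must carry one and the same alternate allele in every accession.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import BASES, GenomeSequence, SiteAlleleCounts, VariantRecord

logger = logging.getLogger(__name__)

Site = tuple[str, int, str, str]  # chrom, pos, ref, alt


@dataclass(frozen=True)
class CandidateSNP:
    """A biallelic candidate genotyping marker."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    source: str  # "consensus" | "allele_fraction"
    per_accession_support: tuple = ()  # ((accession, depth, alt_fraction), ...)

    def __post_init__(self) -> None:
        if self.source not in ("consensus", "allele_fraction"):
            raise ValueError(f"unknown discovery source {self.source!r}")

    @property
    def site(self) -> Site:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class DiscoveryParams:
    """Numeric thresholds of the discovery and purification filters."""

    min_depth: int = 5
    min_mq: float = 20.0
    min_alt_fraction: float = 0.95
    max_self_discordance: float = 0.05
    required_callers: frozenset[str] = frozenset()
    required_accessions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0 < self.min_alt_fraction <= 1):
            raise ValueError("min_alt_fraction must be in (0, 1]")
        if not (0 <= self.max_self_discordance < 1):
            raise ValueError("max_self_discordance must be in [0, 1)")
        if self.min_depth < 0 or self.min_mq < 0:
            raise ValueError("thresholds must be non-negative")
        self.required_callers = frozenset(self.required_callers)
        self.required_accessions = frozenset(self.required_accessions)


def intersect_callers(
    per_caller_records: Mapping[str, Sequence[VariantRecord]],
    params: DiscoveryParams,
) -> list[CandidateSNP]:
    """Intersect one accession's calls across all required callers.

    A site/allele is emitted iff every required caller reports the same
    (chrom, pos, ref, alt) and every caller's record passes the depth and
    mapping-quality filters.  Output sorted by (chrom, pos).
    """
    callers = params.required_callers or frozenset(per_caller_records)
    if not callers:
        raise ValueError("required_callers must be non-empty")

    accessions = {
        rec.accession_id for recs in per_caller_records.values() for rec in recs
    }
    if len(accessions) > 1:
        raise ValueError(f"records span multiple accessions: {sorted(accessions)}")
    accession = next(iter(accessions)) if accessions else None

    # Per caller: sites passing filters, with the caller's own reported depth.
    per_caller_sites: dict[str, dict[Site, int]] = {}
    for caller in callers:
        records = per_caller_records.get(caller, ())
        if not records:
            logger.warning("required caller %s has no records", caller)
        passing: dict[Site, int] = {}
        for rec in records:
            if rec.depth >= params.min_depth and rec.mapping_quality >= params.min_mq:
                passing[rec.site] = rec.depth
        per_caller_sites[caller] = passing

    shared = set.intersection(*(set(s) for s in per_caller_sites.values()))
    out = []
    for site in sorted(shared, key=lambda s: (s[0], s[1], s[3])):
        depth = min(per_caller_sites[c][site] for c in callers)
        support = ((accession, depth, None),) if accession else ()
        out.append(
            CandidateSNP(*site, source="consensus", per_accession_support=support)
        )
    return out


def supplement_by_allele_fraction(
    counts_per_accession: Mapping[str, Sequence[SiteAlleleCounts]],
    reference: GenomeSequence,
    params: DiscoveryParams,
    existing: Sequence[CandidateSNP] = (),
) -> list[CandidateSNP]:
    """Recover candidate sites directly from alignment allele counts.

    A site is emitted when, in *every* required accession, depth >=
    ``min_depth`` and the non-reference read fraction is >=
    ``min_alt_fraction``, and the majority non-reference base is one and
    the same single base everywhere.  Ties among non-reference bases
    disqualify the site.  Sites already present in ``existing`` are not
    duplicated.
    """
    accessions = params.required_accessions or frozenset(counts_per_accession)
    if not accessions:
        raise ValueError("required_accessions must be non-empty")

    indexed: dict[str, dict[tuple[str, int], SiteAlleleCounts]] = {
        acc: {(c.chrom, c.pos): c for c in counts_per_accession.get(acc, ())}
        for acc in accessions
    }
    # Eligible positions must be covered in all required accessions.
    positions = set.intersection(*(set(ix) for ix in indexed.values()))
    existing_pos = {(c.chrom, c.pos) for c in existing}

    out = []
    for chrom, pos in sorted(positions):
        if (chrom, pos) in existing_pos:
            continue
        if chrom not in reference.sequences or pos > len(reference.sequences[chrom]):
            raise ValueError(f"position {chrom}:{pos} absent from the reference")
        ref_base = reference.base_at(chrom, pos)
        if ref_base not in BASES:
            continue
        alt_base = None
        support = []
        ok = True
        for acc in sorted(accessions):
            site = indexed[acc][(chrom, pos)]
            depth = site.depth
            if depth < params.min_depth:
                ok = False
                break
            if site.nonref_fraction(ref_base) < params.min_alt_fraction:
                ok = False
                break
            nonref = [(site.count(b), b) for b in BASES if b != ref_base]
            top = max(c for c, _ in nonref)
            majors = [b for c, b in nonref if c == top]
            if len(majors) != 1:  # tie among non-reference bases
                ok = False
                break
            if alt_base is None:
                alt_base = majors[0]
            elif majors[0] != alt_base:
                ok = False
                break
            support.append((acc, depth, site.nonref_fraction(ref_base)))
        if ok and alt_base is not None:
            out.append(
                CandidateSNP(
                    chrom,
                    pos,
                    ref_base,
                    alt_base,
                    source="allele_fraction",
                    per_accession_support=tuple(support),
                )
            )
    return out


def merge_candidates(
    consensus: Sequence[CandidateSNP],
    supplement: Sequence[CandidateSNP],
) -> list[CandidateSNP]:
    """Union of the two discovery routes for one accession.

    Positions already in the consensus set keep their consensus entry;
    the result has no duplicated (chrom, pos) and is sorted.
    """
    seen = {(c.chrom, c.pos) for c in consensus}
    merged = list(consensus) + [
        s for s in supplement if (s.chrom, s.pos) not in seen
    ]
    return sorted(merged, key=lambda c: (c.chrom, c.pos, c.alt_allele))


def purify_against_self(
    candidates: Sequence[CandidateSNP],
    self_counts: Sequence[SiteAlleleCounts],
    params: DiscoveryParams,
) -> list[CandidateSNP]:
    """Drop candidates discordant with the reference line's own reads.

    A candidate is removed when the self-resequencing non-reference
    fraction at its position is *strictly greater* than
    ``max_self_discordance``.  Candidates without self coverage are
    retained: absence of evidence is not discordance.
    """
    by_pos = {(c.chrom, c.pos): c for c in self_counts}
    kept = []
    no_coverage = 0
    for cand in candidates:
        site = by_pos.get((cand.chrom, cand.pos))
        if site is None or site.depth == 0:
            no_coverage += 1
            kept.append(cand)
            continue
        if site.nonref_fraction(cand.ref_allele) <= params.max_self_discordance:
            kept.append(cand)
    if no_coverage:
        logger.info(
            "purify_against_self: %d candidates retained without self coverage",
            no_coverage,
        )
    return kept


def select_biallelic_shared(
    per_accession_candidates: Mapping[str, Sequence[CandidateSNP]],
    required_accessions: Sequence[str],
) -> list[CandidateSNP]:
    """Keep sites with one identical alternate allele in every accession.

    The reference carries the reference allele and all accessions the
    shared alternate; a site is excluded when any accession reports a
    conflicting alternate, or shows multi-allelic evidence (more than one
    alternate at the position).
    """
    if not required_accessions:
        raise ValueError("required_accessions must be non-empty")

    per_acc_sites: dict[str, dict[tuple[str, int], dict[Site, CandidateSNP]]] = {}
    for acc in required_accessions:
        sites: dict[tuple[str, int], dict[Site, CandidateSNP]] = {}
        for cand in per_accession_candidates.get(acc, ()):
            sites.setdefault((cand.chrom, cand.pos), {})[cand.site] = cand
        per_acc_sites[acc] = sites

    shared_pos = set.intersection(*(set(s) for s in per_acc_sites.values()))
    out = []
    for pos_key in sorted(shared_pos):
        site_sets = [per_acc_sites[acc][pos_key] for acc in required_accessions]
        if any(len(s) != 1 for s in site_sets):  # multi-allelic evidence
            continue
        unique = {next(iter(s)) for s in site_sets}
        if len(unique) != 1:  # conflicting alternates
            continue
        site = next(iter(unique))
        source = next(iter(site_sets[0].values())).source
        out.append(
            CandidateSNP(
                *site,
                source=source,
                per_accession_support=tuple(
                    (acc, 0, None) for acc in sorted(required_accessions)
                ),
            )
        )
    return out


def write_candidates(candidates: Sequence[CandidateSNP], path: str | Path) -> None:
    """Serialize a candidate set as TSV."""
    rows = [
        {
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref_allele,
            "alt": c.alt_allele,
            "source": c.source,
            "n_supporting_accessions": len(c.per_accession_support),
        }
        for c in candidates
    ]
    pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "source", "n_supporting_accessions"]
    ).to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> list[CandidateSNP]:
    df = pd.read_csv(path, sep="\t")
    return [
        CandidateSNP(str(r.chrom), int(r.pos), str(r.ref), str(r.alt), str(r.source))
        for r in df.itertuples()
    ]
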