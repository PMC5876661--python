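"""Consensus genotype calling from per-marker amplicon allele counts.

The caller emulates a pileup consensus caller (VarScan ``mpileup2cns``
defaults) with explicit frequency/count thresholds: a marker needs
``min_coverage`` reads for any call; the alternate-allele fraction then
splits calls into homozygous reference (AA), heterozygous (AB) and
homozygous alternate (BB), with ``min_reads2`` supporting reads required
for any alternate call and an NC (no-call) fallback for ambiguous
evidence.  Reads matching neither allele do not contribute to the
alternate fraction; a marker with more than ``max_other_fraction`` such
reads is forced NC as a contamination guard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

GENOTYPE_CLASSES = ("AA", "AB", "BB", "NC")


@dataclass(frozen=True)
class MarkerReadProfile:
    """Allele counts observed at one marker in one sample."""

    marker_id: str
    sample_id: str
    ref_count: int
    alt_count: int
    other_count: int = 0

    def __post_init__(self) -> None:
        if min(self.ref_count, self.alt_count, self.other_count) < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count + self.other_count


@dataclass(frozen=True)
class GenotypeCall:
    marker_id: str
    sample_id: str
    call: str  # AA | AB | BB | NC
    alt_fraction: float
    depth: int


@dataclass
class CallerParams:
    """Thresholds of the consensus genotype caller."""

    min_coverage: int = 8
    min_reads2: int = 2
    min_var_freq: float = 0.01
    min_freq_for_hom: float = 0.75
    min_het_freq: float = 0.20
    max_other_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.min_var_freq <= self.min_het_freq < self.min_freq_for_hom <= 1):
            raise ValueError(
                "need 0 < min_var_freq <= min_het_freq < min_freq_for_hom <= 1"
            )
        if self.min_coverage < 1 or self.min_reads2 < 0:
            raise ValueError("coverage thresholds invalid")


def call_genotype(
    profile: MarkerReadProfile, params: CallerParams | None = None
) -> GenotypeCall:
    """Call AA/AB/BB/NC for one marker from its read profile.

    Deterministic rule: NC below ``min_coverage`` or when third-allele
    reads exceed ``max_other_fraction``; otherwise with f = alt/depth —
    BB when f >= ``min_freq_for_hom``, AB when ``min_het_freq`` <= f <
    ``min_freq_for_hom`` (both requiring ``min_reads2`` alternate
    reads), AA when f < ``min_het_freq``, and NC when alternate evidence
    is intermediate but fails ``min_reads2``.
    """
    params = params or CallerParams()
    depth = profile.depth
    if depth == 0:
        return GenotypeCall(profile.marker_id, profile.sample_id, "NC", 0.0, 0)
    f = profile.alt_count / depth
    if depth < params.min_coverage:
        call = "NC"
    elif profile.other_count / depth > params.max_other_fraction:
        call = "NC"
    elif f >= params.min_freq_for_hom:
        call = "BB" if profile.alt_count >= params.min_reads2 else "NC"
    elif f >= params.min_het_freq:
        call = "AB" if profile.alt_count >= params.min_reads2 else "NC"
    else:
        call = "AA"
    return GenotypeCall(profile.marker_id, profile.sample_id, call, f, depth)


def call_panel(
    profiles: Iterable[MarkerReadProfile],
    panel_marker_ids: Sequence[str],
    sample_id: str,
    params: CallerParams | None = None,
) -> list[GenotypeCall]:
    """Exactly one call per panel marker; markers without reads are NC."""
    params = params or CallerParams()
    panel_set = set(panel_marker_ids)
    by_marker: dict[str, MarkerReadProfile] = {}
    for p in profiles:
        if p.sample_id != sample_id:
            continue
        if p.marker_id not in panel_set:
            logger.warning("profile for unknown marker %s ignored", p.marker_id)
            continue
        by_marker[p.marker_id] = p
    out = []
    for marker_id in panel_marker_ids:
        profile = by_marker.get(
            marker_id, MarkerReadProfile(marker_id, sample_id, 0, 0, 0)
        )
        out.append(call_genotype(profile, params))
    return out


def read_profiles(path: str | Path) -> list[MarkerReadProfile]:
    """Read a profile TSV: marker_id sample_id ref_count alt_count other_count."""
    df = pd.read_csv(path, sep="\t")
    return [
        MarkerReadProfile(
            str(r.marker_id),
            str(r.sample_id),
            int(r.ref_count),
            int(r.alt_count),
            int(r.other_count),
        )
        for r in df.itertuples()
    ]


def write_profiles(profiles: Sequence[MarkerReadProfile], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "marker_id": p.marker_id,
                "sample_id": p.sample_id,
                "ref_count": p.ref_count,
                "alt_count": p.alt_count,
                "other_count": p.other_count,
            }
            for p in profiles
        ]
    ).to_csv(path, sep="\t", index=False)


def write_calls(calls: Sequence[GenotypeCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "marker_id": c.marker_id,
                "sample_id": c.sample_id,
                "call": c.call,
                "alt_fraction": round(c.alt_fraction, 4),
                "depth": c.depth,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[GenotypeCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        GenotypeCall(
            str(r.marker_id),
            str(r.sample_id),
            str(r.call),
            float(r.alt_fraction),
            int(r.depth),
        )
        for r in df.itertuples()
    ]
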