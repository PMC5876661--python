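"""Even-spaced marker panel selection and spacing/density statistics.

The selection rule is deterministic: each chromosome [1, L] is split
into n equal bins and, bin by bin, the not-yet-selected candidate
nearest the bin midpoint is taken (ties broken toward the lower
coordinate).  Candidates closer than a configured minimum distance to an
already selected marker are ineligible, so amplicons never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .discovery import CandidateSNP
from .io_formats import write_bed


class PanelShortfallError(ValueError):
    """Not enough candidates on a chromosome to fill the request."""


@dataclass(frozen=True)
class Marker:
    marker_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str


@dataclass
class MarkerPanel:
    """Markers sorted by (chrom, pos), with per-chromosome tallies."""

    markers: list[Marker]
    min_distance: int = 200

    def __post_init__(self) -> None:
        self.markers = sorted(self.markers, key=lambda m: (m.chrom, m.pos))
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker_ids must be unique")
        keys = [(m.chrom, m.pos) for m in self.markers]
        if len(set(keys)) != len(keys):
            raise ValueError("(chrom, pos) must be unique")
        for a, b in zip(self.markers, self.markers[1:]):
            if a.chrom == b.chrom and b.pos - a.pos < self.min_distance:
                raise ValueError(
                    f"markers {a.marker_id} and {b.marker_id} closer than "
                    f"{self.min_distance} bp"
                )

    @property
    def per_chrom_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.markers:
            counts[m.chrom] = counts.get(m.chrom, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class SpacingStats:
    """Adjacent-marker distance summaries, in bases.

    Chromosomes with fewer than two markers get NaN statistics and are
    listed in ``undefined_chroms``.
    """

    per_chrom: pd.DataFrame  # index chrom; columns mean, sd, min, max, n_gaps
    genome_wide_mean: float
    undefined_chroms: list[str]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, matching common table formatting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def select_even_spaced(
    candidates: Sequence[CandidateSNP],
    per_chrom_targets: Mapping[str, int],
    chrom_lengths: Mapping[str, int],
    min_distance: int = 200,
) -> MarkerPanel:
    """Pick an almost-evenly spaced marker subset per chromosome.

    For each chromosome, [1, L] is partitioned into n equal bins and the
    candidate nearest each bin midpoint is selected (lower coordinate
    wins ties; candidates within ``min_distance`` of a selected marker
    are skipped).  Raises :class:`PanelShortfallError` naming the
    chromosome when candidates run out.
    """
    by_chrom: dict[str, list[CandidateSNP]] = {}
    for cand in candidates:
        by_chrom.setdefault(cand.chrom, []).append(cand)

    markers: list[Marker] = []
    idx = 1
    for chrom, n in per_chrom_targets.items():
        pool = sorted(by_chrom.get(chrom, []), key=lambda c: c.pos)
        if len(pool) < n:
            raise PanelShortfallError(
                f"chromosome {chrom}: requested {n} markers but only "
                f"{len(pool)} candidates available"
            )
        length = chrom_lengths[chrom]
        selected: list[CandidateSNP] = []
        chosen_pos: list[int] = []
        for k in range(n):
            midpoint = (k + 0.5) * length / n
            best = None
            best_key = None
            for cand in pool:
                if cand in selected:
                    continue
                if any(abs(cand.pos - p) < min_distance for p in chosen_pos):
                    continue
                key = (abs(cand.pos - midpoint), cand.pos)
                if best_key is None or key < best_key:
                    best, best_key = cand, key
            if best is None:
                raise PanelShortfallError(
                    f"chromosome {chrom}: could not fill bin {k + 1}/{n} "
                    f"(min_distance={min_distance} exhausted the candidates)"
                )
            selected.append(best)
            chosen_pos.append(best.pos)
        for cand in sorted(selected, key=lambda c: c.pos):
            markers.append(
                Marker(f"M{idx:04d}", chrom, cand.pos, cand.ref_allele, cand.alt_allele)
            )
            idx += 1
    return MarkerPanel(markers, min_distance=min_distance)


def spacing_stats(
    panel: MarkerPanel | Sequence[Marker],
    chrom_lengths: Mapping[str, int] | None = None,
) -> SpacingStats:
    """Mean/SD/min/max of adjacent-marker distances within chromosomes."""
    markers = panel.markers if isinstance(panel, MarkerPanel) else list(panel)
    by_chrom: dict[str, list[int]] = {}
    for m in markers:
        by_chrom.setdefault(m.chrom, []).append(m.pos)

    rows = {}
    undefined = []
    all_gaps: list[int] = []
    for chrom, positions in by_chrom.items():
        positions = sorted(positions)
        gaps = np.diff(positions)
        if len(gaps) == 0:
            undefined.append(chrom)
            rows[chrom] = dict(
                mean=np.nan, sd=np.nan, min=np.nan, max=np.nan, n_gaps=0
            )
            continue
        rows[chrom] = dict(
            mean=float(gaps.mean()),
            sd=float(gaps.std(ddof=1)) if len(gaps) > 1 else 0.0,
            min=float(gaps.min()),
            max=float(gaps.max()),
            n_gaps=len(gaps),
        )
        all_gaps.extend(gaps.tolist())
    per_chrom = pd.DataFrame.from_dict(rows, orient="index")
    genome_mean = float(np.mean(all_gaps)) if all_gaps else float("nan")
    return SpacingStats(per_chrom, genome_mean, undefined)


def snp_density(
    variant_counts: Mapping[str, int],
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """SNPs per 100 kb, per chromosome and in total, to one decimal.

    ``variant_counts`` maps chromosome -> number of SNPs; lengths are in
    bases.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        n = int(variant_counts.get(chrom, 0))
        rows.append(
            {
                "chrom": chrom,
                "n_snps": n,
                "length_bp": length,
                "snps_per_100kb": round_half_up(n / (length / 100_000), 1),
            }
        )
    total_n = sum(r["n_snps"] for r in rows)
    total_len = sum(r["length_bp"] for r in rows)
    rows.append(
        {
            "chrom": "total",
            "n_snps": total_n,
            "length_bp": total_len,
            "snps_per_100kb": round_half_up(total_n / (total_len / 100_000), 1),
        }
    )
    return pd.DataFrame(rows, columns=["chrom", "n_snps", "length_bp", "snps_per_100kb"])


def write_panel(panel: MarkerPanel, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "marker_id": m.marker_id,
                "chrom": m.chrom,
                "pos": m.pos,
                "ref": m.ref_allele,
                "alt": m.alt_allele,
            }
            for m in panel.markers
        ]
    ).to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path, min_distance: int = 200) -> MarkerPanel:
    df = pd.read_csv(path, sep="\t")
    markers = [
        Marker(str(r.marker_id), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]
    return MarkerPanel(markers, min_distance=min_distance)


def export_amplicon_bed(
    panel: MarkerPanel, path: str | Path, flank: int = 100
) -> None:
    """BED of amplicon target windows (marker +/- flank), 0-based half-open."""
    intervals = [
        (m.chrom, max(0, m.pos - 1 - flank), m.pos + flank, m.marker_id)
        for m in panel.markers
    ]
    write_bed(intervals, path)
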