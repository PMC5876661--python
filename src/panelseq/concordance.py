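"""Concordance of called genotypes with theoretical (pedigree) genotypes.

Theoretical genotypes follow from the study design: the reference
accession is AA at every panel marker, each divergent inbred accession
is BB (the panel carries the shared alternate allele), and the F1 hybrid
of reference x accession is AB everywhere.  The concordance matrix
tallies called classes per sample; accuracy is the percentage of markers
whose call equals the theoretical class (NC never matches).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .genotyping import GENOTYPE_CLASSES, GenotypeCall
from .panel import round_half_up


@dataclass
class ConcordanceRow:
    sample_id: str
    theoretical: str  # AA | AB | BB
    counts: dict[str, int]  # class -> count
    rates: dict[str, float]  # class -> percentage, one decimal
    accuracy: float  # percentage in the theoretical class's column

    @property
    def panel_size(self) -> int:
        return sum(self.counts.values())


@dataclass
class ConcordanceMatrix:
    rows: list[ConcordanceRow]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            rec = {"sample_id": r.sample_id, "theoretical": r.theoretical}
            for cls in GENOTYPE_CLASSES:
                rec[cls] = r.counts[cls]
                rec[f"{cls}_pct"] = r.rates[cls]
            rec["accuracy_pct"] = r.accuracy
            records.append(rec)
        return pd.DataFrame(records)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def tally_row(
    sample_id: str,
    theoretical: str,
    class_counts: Mapping[str, int],
    panel_size: int,
) -> ConcordanceRow:
    """Build one matrix row from per-class counts.

    Percentages are 100*count/panel_size rounded half-up to one decimal;
    accuracy is the percentage in the theoretical class's column.
    """
    if theoretical not in ("AA", "AB", "BB"):
        raise ValueError(f"theoretical genotype must be AA/AB/BB, got {theoretical}")
    counts = {cls: int(class_counts.get(cls, 0)) for cls in GENOTYPE_CLASSES}
    if sum(counts.values()) != panel_size:
        raise ValueError(
            f"{sample_id}: class counts sum to {sum(counts.values())}, "
            f"expected panel size {panel_size}"
        )
    rates = {
        cls: round_half_up(100.0 * counts[cls] / panel_size, 1)
        for cls in GENOTYPE_CLASSES
    }
    return ConcordanceRow(sample_id, theoretical, counts, rates, rates[theoretical])


def concordance_matrix(
    calls_per_sample: Mapping[str, Sequence[GenotypeCall]],
    theoretical: Mapping[str, str],
    panel_size: int,
) -> ConcordanceMatrix:
    """Tally calls per sample against the theoretical genotype."""
    rows = []
    for sample_id, calls in calls_per_sample.items():
        if len(calls) != panel_size:
            raise ValueError(
                f"{sample_id}: {len(calls)} calls for a panel of {panel_size}"
            )
        counts = {cls: 0 for cls in GENOTYPE_CLASSES}
        for call in calls:
            counts[call.call] += 1
        rows.append(tally_row(sample_id, theoretical[sample_id], counts, panel_size))
    return ConcordanceMatrix(rows)


def accuracy_fraction(
    calls: Sequence[GenotypeCall], truth: Mapping[str, str]
) -> float:
    """Unrounded percentage of calls matching the per-marker truth class."""
    if not calls:
        raise ValueError("no calls")
    hits = sum(1 for c in calls if c.call == truth[c.marker_id])
    return 100.0 * hits / len(calls)
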