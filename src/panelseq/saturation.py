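"""Read-subsampling saturation analysis of genotyping accuracy.

Reads are drawn without replacement (multivariate hypergeometric) from
the full post-mapping allocation — per-marker ref/alt/other read
buckets plus one off-target bucket — at a grid of total-read budgets,
the panel is re-genotyped from each subsample, and accuracy against the
theoretical genotypes is summarized as mean +/- SD over replicates.

Subsampling the post-mapping allocation, rather than raw reads followed
by re-alignment, is the emulation boundary of this module: alignment is
upstream of the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concordance import accuracy_fraction
from .genotyping import CallerParams, MarkerReadProfile, call_panel

# Budget grid used for the saturation curve (reads).
DEFAULT_BUDGETS = (
    10_000,
    20_000,
    40_000,
    70_000,
    100_000,
    150_000,
    200_000,
    400_000,
    700_000,
    1_000_000,
    2_000_000,
    3_000_000,
)


@dataclass
class ReadAllocation:
    """Full-data read counts: per-marker ref/alt/other plus off-target."""

    marker_ids: list[str]
    ref: np.ndarray  # int, per marker
    alt: np.ndarray
    other: np.ndarray
    off_target: int
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.other = np.asarray(self.other, dtype=np.int64)
        n = len(self.marker_ids)
        if not (len(self.ref) == len(self.alt) == len(self.other) == n):
            raise ValueError("per-marker arrays must match marker_ids length")
        if self.ref.min(initial=0) < 0 or self.alt.min(initial=0) < 0 or (
            self.other.min(initial=0) < 0
        ) or self.off_target < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.ref.sum() + self.alt.sum() + self.other.sum() + self.off_target)

    @property
    def on_target(self) -> int:
        return self.total - self.off_target

    def to_profiles(self) -> list[MarkerReadProfile]:
        return [
            MarkerReadProfile(
                mid,
                self.sample_id,
                int(self.ref[i]),
                int(self.alt[i]),
                int(self.other[i]),
            )
            for i, mid in enumerate(self.marker_ids)
        ]


@dataclass
class SaturationCurve:
    budgets: list[int]
    mean: list[float]  # accuracy %, per budget
    sd: list[float]
    replicate_accuracy: pd.DataFrame  # columns budget, replicate, accuracy
    n_replicates: int
    seed: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"budget": self.budgets, "mean": self.mean, "sd": self.sd}
        )

    def write(self, path: str | Path, summary_path: str | Path | None = None) -> None:
        self.replicate_accuracy.to_csv(path, sep="\t", index=False)
        if summary_path is not None:
            self.summary_frame().to_csv(summary_path, sep="\t", index=False)


def subsample_reads(
    allocation: ReadAllocation, n: int, seed: int | np.random.Generator
) -> ReadAllocation:
    """Draw n reads without replacement from all buckets jointly.

    A single multivariate-hypergeometric draw over every sub-bucket
    (each marker's ref/alt/other and the off-target pool) is equivalent
    to subsampling markers first and their allele composition second;
    totals are conserved exactly.  Deterministic given the seed.
    """
    total = allocation.total
    if not (0 <= n <= total):
        raise ValueError(f"subsample size {n} outside [0, {total}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    colors = np.concatenate(
        [allocation.ref, allocation.alt, allocation.other, [allocation.off_target]]
    )
    drawn = rng.multivariate_hypergeometric(colors, n, method="marginals")
    k = len(allocation.marker_ids)
    return ReadAllocation(
        marker_ids=list(allocation.marker_ids),
        ref=drawn[:k],
        alt=drawn[k : 2 * k],
        other=drawn[2 * k : 3 * k],
        off_target=int(drawn[3 * k]),
        sample_id=allocation.sample_id,
    )


def saturation_curve(
    allocation: ReadAllocation,
    truth: Mapping[str, str],  # marker_id -> theoretical class
    budgets: Sequence[int] = DEFAULT_BUDGETS,
    n_replicates: int = 5,
    seed: int = 0,
    caller_params: CallerParams | None = None,
) -> SaturationCurve:
    """Accuracy vs read budget, with replicates.

    For each budget and replicate the allocation is subsampled, marker
    read profiles are regenerated, the whole panel re-called, and
    accuracy against the theoretical genotypes computed.  Budgets above
    the allocation total are truncated to the total (a full, replicate-
    invariant draw).
    """
    budgets = list(budgets)
    if any(b2 <= b1 for b1, b2 in zip(budgets, budgets[1:])):
        raise ValueError("budgets must be strictly increasing")
    caller_params = caller_params or CallerParams()
    rng = np.random.default_rng(seed)
    marker_ids = allocation.marker_ids

    records = []
    for budget in budgets:
        n = min(budget, allocation.total)
        for rep in range(n_replicates):
            sub = subsample_reads(allocation, n, rng)
            calls = call_panel(
                sub.to_profiles(), marker_ids, allocation.sample_id, caller_params
            )
            acc = accuracy_fraction(calls, truth)
            records.append({"budget": budget, "replicate": rep, "accuracy": acc})
    df = pd.DataFrame(records)
    grouped = df.groupby("budget", sort=True)["accuracy"]
    means = grouped.mean()
    sds = grouped.std(ddof=1).fillna(0.0)
    return SaturationCurve(
        budgets=list(means.index),
        mean=[float(x) for x in means],
        sd=[float(x) for x in sds],
        replicate_accuracy=df,
        n_replicates=n_replicates,
        seed=seed if isinstance(seed, int) else -1,
    )


def plot_curve(curve: SaturationCurve, path: str | Path) -> None:
    """Accuracy-vs-budget plot with error bars (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(curve.budgets, curve.mean, yerr=curve.sd, fmt="o-", capsize=3)
    ax.set_xscale("log")
    ax.set_xlabel("Total reads sampled")
    ax.set_ylabel("Genotyping accuracy (%)")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
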