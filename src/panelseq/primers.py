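"""Primer-pair design on polymorphism-masked reference windows.

Every polymorphic position discovered by any caller in any accession is
masked to ``N`` before design, so primers anneal to sequence identical
across all accessions; the target marker position itself is left
unmasked because the amplicon must contain it (primers may never cover
it).  Candidate primers are enumerated exhaustively within the window
and a pair is chosen by a penalty that prefers the optimum length and
melting temperature and a small Tm difference between the two primers.

Melting temperatures come from the unified nearest-neighbor
thermodynamic parameter set (SantaLucia-style duplex energies) with a
monovalent-salt entropy correction; salt and primer concentrations are
configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Unified nearest-neighbor duplex parameters: (dH kcal/mol, dS cal/mol/K)
# for each stacked pair read 5'->3' on the top strand.
NN_PARAMS = {
    "AA": (-7.6, -21.3),
    "TT": (-7.6, -21.3),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
    "CC": (-8.0, -19.9),
}
NN_INITIATION = (0.2, -5.7)
NN_TERMINAL_AT = (2.2, 6.9)  # per A/T duplex end
GAS_CONSTANT = 1.987  # cal/mol/K


class MaskedSequenceError(ValueError):
    """Tm requested for a sequence containing masked (N) bases."""


@dataclass
class TmParams:
    """Solution conditions for the nearest-neighbor Tm calculation."""

    monovalent_mM: float = 50.0
    primer_nM: float = 250.0
    template_nM: float = 250.0


@dataclass
class PrimerConstraints:
    """Primer3-style acceptance ranges for a single primer pair."""

    len_min: int = 18
    len_opt: int = 25
    len_max: int = 32
    tm_min: float = 60.0
    tm_opt: float = 65.0
    tm_max: float = 72.0
    gc_min: float = 45.0
    gc_max: float = 65.0
    product_min: int = 150
    product_max: int = 200

    def __post_init__(self) -> None:
        if not (self.len_min <= self.len_opt <= self.len_max):
            raise ValueError("primer length min <= opt <= max violated")
        if not (self.tm_min <= self.tm_opt <= self.tm_max):
            raise ValueError("Tm min <= opt <= max violated")
        if not (0 <= self.gc_min <= self.gc_max <= 100):
            raise ValueError("GC range invalid")
        if not (0 < self.product_min <= self.product_max):
            raise ValueError("product size range invalid")


@dataclass
class PenaltyWeights:
    w_len: float = 1.0
    w_tm: float = 1.0
    w_pair: float = 1.0


@dataclass(frozen=True)
class PrimerPair:
    marker_id: str
    left_seq: str  # 5'->3' on the forward strand
    right_seq: str  # 5'->3' on the reverse strand
    left_start: int  # 1-based genomic
    right_end: int  # 1-based genomic
    product_size: int
    left_tm: float
    right_tm: float
    left_gc: float
    right_gc: float
    penalty: float


@dataclass(frozen=True)
class NoPair:
    """Structured design failure, naming the constraint that bound."""

    marker_id: str
    reason: str


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC percentage of a primer sequence."""
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def melting_temperature(seq: str, params: TmParams | None = None) -> float:
    """Nearest-neighbor duplex melting temperature in degrees Celsius.

    Total enthalpy/entropy are summed over stacked base pairs plus helix
    initiation and terminal-A/T penalties; the entropy is corrected for
    monovalent salt (0.368 * (N-1) * ln[Na+]) and the concentration term
    uses CT = [primer] - [template]/2 for a non-self-complementary
    duplex in excess primer.
    """
    params = params or TmParams()
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("sequence shorter than 8 bases")
    if "N" in seq:
        raise MaskedSequenceError("sequence contains masked (N) bases")
    if set(seq) - set("ACGT"):
        raise ValueError("sequence must be over {A,C,G,T}")

    dh, ds = NN_INITIATION
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh += NN_TERMINAL_AT[0]
            ds += NN_TERMINAL_AT[1]
    for i in range(len(seq) - 1):
        pair_dh, pair_ds = NN_PARAMS[seq[i : i + 2]]
        dh += pair_dh
        ds += pair_ds

    ds += 0.368 * (len(seq) - 1) * math.log(params.monovalent_mM / 1000.0)
    ct = (params.primer_nM - params.template_nM / 2.0) * 1e-9
    tm_kelvin = dh * 1000.0 / (ds + GAS_CONSTANT * math.log(ct))
    return tm_kelvin - 273.15


def mask_polymorphic(
    window_seq: str,
    window_coords: tuple[str, int, int],
    variants: Iterable[tuple[str, int]],
    target_pos: int | None = None,
) -> str:
    """Replace caller-discovered polymorphic positions with ``N``.

    ``window_coords`` is (chrom, start, end), 1-based inclusive;
    ``variants`` are (chrom, pos) pairs, positions outside the window
    ignored.  The target marker position itself is never masked — the
    amplicon must contain it.  Length is unchanged; idempotent.
    """
    chrom, start, end = window_coords
    if end - start + 1 != len(window_seq):
        raise ValueError("window coordinates do not match sequence length")
    seq = list(window_seq)
    for vchrom, vpos in variants:
        if vchrom != chrom or not (start <= vpos <= end):
            continue
        if target_pos is not None and vpos == target_pos:
            continue
        seq[vpos - start] = "N"
    return "".join(seq)


def _enumerate_primers(
    window: str,
    constraints: PrimerConstraints,
    tm_params: TmParams,
) -> list[tuple[int, int, float, float]]:
    """All N-free subsequences passing length/Tm/GC ranges.

    Returns (start_offset, length, tm, gc) with 0-based window offsets.
    """
    out = []
    n = len(window)
    for length in range(constraints.len_min, constraints.len_max + 1):
        for start in range(0, n - length + 1):
            sub = window[start : start + length]
            if "N" in sub:
                continue
            gc = gc_content(sub)
            if not (constraints.gc_min <= gc <= constraints.gc_max):
                continue
            tm = melting_temperature(sub, tm_params)
            if not (constraints.tm_min <= tm <= constraints.tm_max):
                continue
            out.append((start, length, tm, gc))
    return out


def pick_primer_pair(
    masked_window: str,
    marker_offset: int,
    constraints: PrimerConstraints | None = None,
    weights: PenaltyWeights | None = None,
    tm_params: TmParams | None = None,
    marker_id: str = "",
    window_start: int = 1,
) -> PrimerPair | NoPair:
    """Choose the best-penalty primer pair around a marker.

    ``marker_offset`` is the 0-based offset of the marker inside the
    window; ``window_start`` the 1-based genomic coordinate of the
    window's first base (for reporting).  The product must be
    ``product_min``..``product_max`` bp and contain the marker strictly
    between the two primers.  Penalty:
    ``w_len*(|len-opt|) + w_tm*(|Tm-opt|)`` summed over both primers,
    plus ``w_pair*|Tm_left - Tm_right|``; ties broken by leftmost start,
    then smallest product, then shortest left primer.
    """
    constraints = constraints or PrimerConstraints()
    weights = weights or PenaltyWeights()
    tm_params = tm_params or TmParams()

    if len(masked_window) < constraints.product_min:
        return NoPair(marker_id, "product_size")
    if not (0 <= marker_offset < len(masked_window)):
        raise ValueError("marker_offset outside window")

    candidates = _enumerate_primers(masked_window, constraints, tm_params)
    # Left primers end strictly before the marker, right primers start
    # strictly after it (the marker may not lie under a primer).
    lefts = [c for c in candidates if c[0] + c[1] - 1 < marker_offset]
    rights = [c for c in candidates if c[0] > marker_offset]
    if not lefts or not rights:
        return NoPair(marker_id, "tm_gc_length" if candidates else "no_candidates")

    rights_by_end: dict[int, list[tuple[int, int, float, float]]] = {}
    for c in rights:
        rights_by_end.setdefault(c[0] + c[1] - 1, []).append(c)

    best = None
    best_key = None
    for lstart, llen, ltm, lgc in lefts:
        for product in range(constraints.product_min, constraints.product_max + 1):
            rend = lstart + product - 1
            for rstart, rlen, rtm, rgc in rights_by_end.get(rend, ()):
                penalty = (
                    weights.w_len * (abs(llen - constraints.len_opt) + abs(rlen - constraints.len_opt))
                    + weights.w_tm * (abs(ltm - constraints.tm_opt) + abs(rtm - constraints.tm_opt))
                    + weights.w_pair * abs(ltm - rtm)
                )
                key = (penalty, lstart, product, llen)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (lstart, llen, ltm, lgc, rstart, rlen, rtm, rgc, product)
    if best is None:
        return NoPair(marker_id, "product_size")

    lstart, llen, ltm, lgc, rstart, rlen, rtm, rgc, product = best
    left_seq = masked_window[lstart : lstart + llen]
    right_fwd = masked_window[rstart : rstart + rlen]
    return PrimerPair(
        marker_id=marker_id,
        left_seq=left_seq,
        right_seq=reverse_complement(right_fwd),
        left_start=window_start + lstart,
        right_end=window_start + rstart + rlen - 1,
        product_size=product,
        left_tm=ltm,
        right_tm=rtm,
        left_gc=lgc,
        right_gc=rgc,
        penalty=best_key[0],
    )


# Library-amplification primers used downstream of the multiplex PCR;
# recorded as constants, not designed here.
LIBRARY_FORWARD_PRIMER = "ATCTCATCCCTGCGTGTCTCC"
LIBRARY_REVERSE_PRIMER = "TCCGCTTTCCTCTCTATGGGC"


def write_primer_table(
    results: Sequence[PrimerPair | NoPair], path: str | Path
) -> None:
    rows = []
    for r in results:
        if isinstance(r, NoPair):
            rows.append({"marker_id": r.marker_id, "status": f"no_pair:{r.reason}"})
            continue
        rows.append(
            {
                "marker_id": r.marker_id,
                "status": "ok",
                "left_seq": r.left_seq,
                "right_seq": r.right_seq,
                "left_start": r.left_start,
                "right_end": r.right_end,
                "product_size": r.product_size,
                "left_tm": round(r.left_tm, 2),
                "right_tm": round(r.right_tm, 2),
                "left_gc": round(r.left_gc, 2),
                "right_gc": round(r.right_gc, 2),
                "penalty": round(r.penalty, 4),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def export_boulder_io(
    marker_id: str,
    masked_window: str,
    marker_offset: int,
    constraints: PrimerConstraints,
    path: str | Path,
) -> None:
    """Boulder-IO record for cross-checking with an external Primer3."""
    lines = [
        f"SEQUENCE_ID={marker_id}",
        f"SEQUENCE_TEMPLATE={masked_window}",
        f"SEQUENCE_TARGET={marker_offset},1",
        f"PRIMER_OPT_SIZE={constraints.len_opt}",
        f"PRIMER_MIN_SIZE={constraints.len_min}",
        f"PRIMER_MAX_SIZE={constraints.len_max}",
        f"PRIMER_OPT_TM={constraints.tm_opt}",
        f"PRIMER_MIN_TM={constraints.tm_min}",
        f"PRIMER_MAX_TM={constraints.tm_max}",
        f"PRIMER_MIN_GC={constraints.gc_min}",
        f"PRIMER_MAX_GC={constraints.gc_max}",
        f"PRIMER_PRODUCT_SIZE_RANGE={constraints.product_min}-{constraints.product_max}",
        "=",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
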