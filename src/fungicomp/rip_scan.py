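"""RIP (repeat-induced point mutation) index scanning.

RIP is a fungal genome-defense process that mutates C→T in duplicated
sequences, preferentially at CpA dinucleotides (and, on the reverse strand,
TpG).  It leaves diagnostic "relics" in dinucleotide composition that two
ratios capture:

* **product index** ``TpA/ApT`` — elevated by RIP, since CpA→TpA creates TpA;
* **substrate index** ``(CpA+TpG)/(ApC+GpT)`` — depleted by RIP, since
  CpA/TpG are consumed.

A window is called RIP-positive when ``product ≥ 0.89`` and
``substrate ≤ 1.03`` (inclusive), the conventional thresholds.  Both indices
are reverse-complement symmetric, so scanning is strand-agnostic.

Dinucleotides are counted as overlapping pairs; any pair containing ``N`` is
excluded from numerator and denominator alike (positions still advance by
one), so assembly gaps do not bias the ratios.  A ratio with a zero
denominator is *undefined* (``None``) and can never satisfy a threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seq_features import Contig, FeaturePartition, Interval, extract_sequence

__all__ = [
    "DinucleotideCounts",
    "RipIndexValues",
    "RipWindow",
    "RipCallParameters",
    "count_dinucleotides",
    "rip_indices",
    "scan_windows",
    "scan_genome",
    "rip_region_fraction",
    "summarize_by_class",
    "windows_to_frame",
    "windows_to_bed",
]

_BASE_ORDER = "ACGTN"
_BASE_TO_CODE = {b: i for i, b in enumerate(_BASE_ORDER)}
_DINUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=2)]


@dataclass(frozen=True)
class DinucleotideCounts:
    """Counts of the 16 unambiguous overlapping dinucleotides.

    ``valid_pairs`` is the number of counted pairs (pairs containing N are
    excluded).  Mononucleotide counts of the unambiguous bases ride along so
    AT content is computable from the same pass.
    """

    counts: Mapping[str, int]
    valid_pairs: int
    base_counts: Mapping[str, int]

    def __add__(self, other: "DinucleotideCounts") -> "DinucleotideCounts":
        return DinucleotideCounts(
            counts={d: self.counts[d] + other.counts[d] for d in _DINUCLEOTIDES},
            valid_pairs=self.valid_pairs + other.valid_pairs,
            base_counts={b: self.base_counts[b] + other.base_counts[b] for b in "ACGT"},
        )


@dataclass(frozen=True)
class RipIndexValues:
    """AT content and the two RIP indices; ``None`` marks an undefined ratio."""

    product_index: float | None
    substrate_index: float | None
    at_content: float | None


@dataclass(frozen=True)
class RipWindow:
    interval: Interval
    indices: RipIndexValues
    rip_positive: bool


@dataclass(frozen=True)
class RipCallParameters:
    """Sliding-window and threshold settings for RIP calling.

    Defaults are the conventional ones: 200-bp windows with 100-bp shifts,
    product index ≥ 0.89 and substrate index ≤ 1.03 call a window positive.
    """

    window: int = 200
    shift: int = 100
    product_min: float = 0.89
    substrate_max: float = 1.03

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be at least 2 bp")
        if not (1 <= self.shift <= self.window):
            raise ValueError("shift must satisfy 1 <= shift <= window")
        if self.product_min <= 0 or self.substrate_max <= 0:
            raise ValueError("thresholds must be positive")


def _encode(seq: str) -> np.ndarray:
    try:
        return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    except UnicodeEncodeError as exc:  # pragma: no cover - guarded upstream
        raise ValueError("non-ASCII residue in sequence") from exc


_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_TO_CODE.items():
    _CODE_LUT[ord(_b)] = _i


def _codes(seq: str) -> np.ndarray:
    codes = _CODE_LUT[_encode(seq)]
    if (codes < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(codes < 0)[0][:5]})
        raise ValueError(f"invalid residues {bad!r}; expected A/C/G/T/N")
    return codes.astype(np.int64)


def count_dinucleotides(seq: str) -> DinucleotideCounts:
    """Count overlapping dinucleotides left to right, skipping pairs with N."""
    if len(seq) == 0:
        return _counts_from_arrays(np.zeros(25, dtype=np.int64), np.zeros(5, dtype=np.int64))
    codes = _codes(seq)
    base_hist = np.bincount(codes, minlength=5)
    if len(codes) < 2:
        return _counts_from_arrays(np.zeros(25, dtype=np.int64), base_hist)
    pair_codes = codes[:-1] * 5 + codes[1:]
    pair_hist = np.bincount(pair_codes, minlength=25)
    return _counts_from_arrays(pair_hist, base_hist)


def _counts_from_arrays(pair_hist: np.ndarray, base_hist: np.ndarray) -> DinucleotideCounts:
    counts = {
        a + b: int(pair_hist[_BASE_TO_CODE[a] * 5 + _BASE_TO_CODE[b]])
        for a in "ACGT"
        for b in "ACGT"
    }
    return DinucleotideCounts(
        counts=counts,
        valid_pairs=sum(counts.values()),
        base_counts={b: int(base_hist[_BASE_TO_CODE[b]]) for b in "ACGT"},
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def rip_indices(counts: DinucleotideCounts) -> RipIndexValues:
    """The two RIP indices and AT content from dinucleotide counts.

    ``product_index = TA/AT``; ``substrate_index = (CA+TG)/(AC+GT)``;
    ``at_content = (A+T)/(A+C+G+T)``.  Zero denominators yield ``None``.
    """
    c = counts.counts
    b = counts.base_counts
    unambiguous = b["A"] + b["C"] + b["G"] + b["T"]
    return RipIndexValues(
        product_index=_ratio(c["TA"], c["AT"]),
        substrate_index=_ratio(c["CA"] + c["TG"], c["AC"] + c["GT"]),
        at_content=(b["A"] + b["T"]) / unambiguous if unambiguous > 0 else None,
    )


def _is_positive(idx: RipIndexValues, params: RipCallParameters) -> bool:
    return (
        idx.product_index is not None
        and idx.substrate_index is not None
        and idx.product_index >= params.product_min
        and idx.substrate_index <= params.substrate_max
    )


def scan_windows(
    contig: Contig, params: RipCallParameters = RipCallParameters()
) -> list[RipWindow]:
    """Sliding-window RIP scan of one contig.

    Windows start at 0, shift, 2·shift, …; only full-length windows are
    scored (trailing partials are dropped).  A contig shorter than the window
    yields an empty list.
    """
    n = contig.length
    if n < params.window:
        return []
    codes = _codes(contig.residues)
    pair_codes = codes[:-1] * 5 + codes[1:]
    # Cumulative histograms let each window's counts be two-array differences.
    pair_onehot = np.zeros((25, len(pair_codes) + 1), dtype=np.int64)
    base_onehot = np.zeros((5, n + 1), dtype=np.int64)
    pair_onehot[pair_codes, np.arange(len(pair_codes)) + 1] = 1
    base_onehot[codes, np.arange(n) + 1] = 1
    pair_cum = np.cumsum(pair_onehot, axis=1)
    base_cum = np.cumsum(base_onehot, axis=1)

    windows: list[RipWindow] = []
    for start in range(0, n - params.window + 1, params.shift):
        end = start + params.window
        pair_hist = pair_cum[:, end - 1] - pair_cum[:, start]
        base_hist = base_cum[:, end] - base_cum[:, start]
        counts = _counts_from_arrays(pair_hist, base_hist)
        idx = rip_indices(counts)
        windows.append(
            RipWindow(
                interval=Interval(contig.id, start, end),
                indices=idx,
                rip_positive=_is_positive(idx, params),
            )
        )
    return windows


def scan_genome(
    contigs: Sequence[Contig], params: RipCallParameters = RipCallParameters()
) -> list[RipWindow]:
    """Scan every contig; windows never span contig junctions."""
    out: list[RipWindow] = []
    for contig in contigs:
        out.extend(scan_windows(contig, params))
    return out


def rip_region_fraction(
    windows: Iterable[RipWindow], total_bp: int, mode: str = "bases"
) -> float:
    """Fraction of sequence called RIP-positive.

    ``mode="bases"`` (default): bases covered by the union of positive
    windows divided by ``total_bp``.  ``mode="windows"``: positive windows
    divided by all windows (``total_bp`` ignored for the ratio but must be
    positive).
    """
    if total_bp <= 0:
        raise ValueError("total sequence length must be positive")
    windows = list(windows)
    if mode == "windows":
        return sum(w.rip_positive for w in windows) / len(windows) if windows else 0.0
    if mode != "bases":
        raise ValueError(f"unknown mode {mode!r}")
    from .seq_features import merge_intervals

    positive = [w.interval for w in windows if w.rip_positive]
    if not positive:
        return 0.0
    covered = sum(iv.length for iv in merge_intervals(positive))
    return covered / total_bp


def _pooled_counts(seqs: Iterable[str]) -> DinucleotideCounts:
    """Pool dinucleotide counts across sequences without junction pairs."""
    total = count_dinucleotides("")
    for seq in seqs:
        total = total + count_dinucleotides(seq)
    return total


_WINDOW_SETTINGS = ((500, 100), (200, 100))


def summarize_by_class(
    contigs: Sequence[Contig],
    partition: FeaturePartition,
    params: RipCallParameters = RipCallParameters(),
    window_settings: Sequence[tuple[int, int]] = _WINDOW_SETTINGS,
) -> pd.DataFrame:
    """Per-feature-class AT content, RIP indices, and window statistics.

    For each class the whole-class indices pool dinucleotide counts across
    the class's extracted sequences (no artificial junction dinucleotides),
    and window statistics (window count, mean of each defined index,
    RIP-positive fraction of windows) are reported for each
    ``(window, shift)`` setting.  Thresholds come from ``params``.
    """
    contig_by_id = {c.id: c for c in contigs}
    rows = []
    for label, intervals in partition.class_intervals.items():
        seqs = [
            extract_sequence(contig_by_id[iv.contig_id], iv)
            for iv in intervals
            if iv.contig_id in contig_by_id
        ]
        pooled = _pooled_counts(seqs)
        idx = rip_indices(pooled)
        row: dict[str, object] = {
            "feature_class": label,
            "total_bp": sum(len(s) for s in seqs),
            "at_content": idx.at_content,
            "product_index": idx.product_index,
            "substrate_index": idx.substrate_index,
        }
        for window, shift in window_settings:
            wparams = RipCallParameters(
                window=window,
                shift=shift,
                product_min=params.product_min,
                substrate_max=params.substrate_max,
            )
            windows: list[RipWindow] = []
            for iv, seq in zip(intervals, seqs):
                sub = Contig(id=iv.contig_id, residues=seq)
                for w in scan_windows(sub, wparams):
                    # re-anchor window coordinates onto the parent contig
                    anchored = Interval(
                        iv.contig_id, iv.start + w.interval.start, iv.start + w.interval.end
                    )
                    windows.append(RipWindow(anchored, w.indices, w.rip_positive))
            prods = [w.indices.product_index for w in windows if w.indices.product_index is not None]
            subs = [w.indices.substrate_index for w in windows if w.indices.substrate_index is not None]
            ats = [w.indices.at_content for w in windows if w.indices.at_content is not None]
            tag = f"w{window}s{shift}"
            row[f"{tag}_n_windows"] = len(windows)
            row[f"{tag}_mean_at"] = float(np.mean(ats)) if ats else math.nan
            row[f"{tag}_mean_product"] = float(np.mean(prods)) if prods else math.nan
            row[f"{tag}_mean_substrate"] = float(np.mean(subs)) if subs else math.nan
            row[f"{tag}_positive_fraction"] = (
                sum(w.rip_positive for w in windows) / len(windows) if windows else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def windows_to_frame(windows: Iterable[RipWindow]) -> pd.DataFrame:
    """Window scan as a tidy table (one row per window)."""
    return pd.DataFrame(
        {
            "contig": w.interval.contig_id,
            "start": w.interval.start,
            "end": w.interval.end,
            "at_content": w.indices.at_content,
            "product_index": w.indices.product_index,
            "substrate_index": w.indices.substrate_index,
            "rip_positive": w.rip_positive,
        }
        for w in windows
    )


def windows_to_bed(windows: Iterable[RipWindow], path: str) -> None:
    """Write windows as BED6: name = window ordinal, score = product×1000."""
    with open(path, "w") as handle:
        for i, w in enumerate(windows):
            score = (
                int(round(w.indices.product_index * 1000))
                if w.indices.product_index is not None
                else 0
            )
            handle.write(
                f"{w.interval.contig_id}\t{w.interval.start}\t{w.interval.end}"
                f"\twin{i}\t{score}\t.\n"
            )
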