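"""Aggregation-law statistics and transferability analysis.

Two analyses are provided over populations of scored peptide systems:

* **Aggregation laws** — partition normalized scores into the four ranges
  A = [0, 0.25), B = [0.25, 0.5), C = [0.5, 0.75), D = [0.75, 1.0] and
  tabulate amino-acid composition per range (overall or per position).
  Residues are grouped by their statistical contribution to aggregation:
  aromatics (1), aliphatic/thiol hydrophobics (2), polarizable (3), M/P (4),
  and charged/strongly-polar/side-chain-less (5).

* **Transferability** — compare the aggregation propensity of concatenated
  decapeptides (AP_deca) and equimolar pentapeptide mixtures (AP_mixpen)
  against the mean of their constituents (AP_avepen), including the
  opposite-charge pairing that drives Coulombic enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import ScoreError, ScoreSet
from .seqspace import ALPHABET, Peptide

RANGE_NAMES = ("A", "B", "C", "D")
RANGE_EDGES = (0.0, 0.25, 0.5, 0.75, 1.0)

#: Residue groups ordered by statistical contribution to aggregation.
RESIDUE_GROUPS: dict[str, int] = {
    **{r: 1 for r in "FYW"},
    **{r: 2 for r in "CILV"},
    **{r: 3 for r in "HST"},
    **{r: 4 for r in "MP"},
    **{r: 5 for r in "DEKRNQAG"},
}

POSITIVE_RESIDUES = frozenset("KR")
NEGATIVE_RESIDUES = frozenset("DE")


def net_side_chain_charge(peptide: Peptide | str) -> int:
    """Net side-chain charge at neutral pH: (#K + #R) - (#D + #E).

    His and the backbone termini contribute zero under this convention
    (used for charge-typing the pentapeptide subgroups of mixtures).
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    seq = peptide.residues
    pos = sum(seq.count(r) for r in POSITIVE_RESIDUES)
    neg = sum(seq.count(r) for r in NEGATIVE_RESIDUES)
    return pos - neg


@dataclass
class RangePartition:
    """Assignment of normalized scores to the quartile ranges A-D."""

    assignments: dict[str, str]  # system -> range name
    counts: dict[str, int]

    def members(self, range_name: str) -> list[str]:
        return [k for k, v in self.assignments.items() if v == range_name]


def _range_of(x: float) -> str:
    if x < 0.0 or x > 1.0:
        raise ScoreError(f"normalized score out of [0, 1]: {x}")
    # half-open [lo, hi) with D closed at 1.0; ties at edges go upward
    for name, lo, hi in zip(RANGE_NAMES, RANGE_EDGES[:-1], RANGE_EDGES[1:]):
        if lo <= x < hi:
            return name
    return "D"


def partition_ranges(scores: ScoreSet) -> RangePartition:
    """Partition a normalized score set into ranges A-D."""
    assignments = {k: _range_of(v) for k, v in scores.values.items()}
    counts = {name: 0 for name in RANGE_NAMES}
    for v in assignments.values():
        counts[v] += 1
    return RangePartition(assignments=assignments, counts=counts)


@dataclass
class CompositionTable:
    """Residue percentages per range, overall or per position.

    ``overall`` maps range -> {residue: % of residue occurrences}.
    ``per_position`` (optional) maps range -> DataFrame indexed by residue
    with one column per position; entries are % of sequences in the range
    carrying that residue at that position.
    """

    overall: dict[str, dict[str, float]]
    per_position: dict[str, pd.DataFrame] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.overall).reindex(list(ALPHABET)).fillna(0.0)


def composition_by_range(
    scores: ScoreSet,
    partition: RangePartition | None = None,
    per_position: bool = False,
) -> CompositionTable:
    """Amino-acid composition (percent) within each score range.

    All systems must be single peptides of equal length.  Overall
    percentages are residue-occurrence weighted (summed over positions);
    per-position percentages are fractions of sequences in the range.
    """
    if partition is None:
        partition = partition_ranges(scores)
    seqs: dict[str, list[str]] = {name: [] for name in RANGE_NAMES}
    length = None
    for key, rng_name in partition.assignments.items():
        if "+" in key:
            raise ScoreError("composition analysis requires single peptides")
        if length is None:
            length = len(key)
        elif len(key) != length:
            raise ScoreError("composition analysis requires equal lengths")
        seqs[rng_name].append(key)
    overall: dict[str, dict[str, float]] = {}
    per_pos: dict[str, pd.DataFrame] = {}
    for name in RANGE_NAMES:
        members = seqs[name]
        if not members:
            overall[name] = {r: 0.0 for r in ALPHABET}
            continue
        arr = np.array([list(s) for s in members])
        n_occ = arr.size
        overall[name] = {
            r: 100.0 * float((arr == r).sum()) / n_occ for r in ALPHABET
        }
        if per_position:
            n_seq = len(members)
            per_pos[name] = pd.DataFrame(
                {
                    p: {r: 100.0 * float((arr[:, p] == r).sum()) / n_seq for r in ALPHABET}
                    for p in range(arr.shape[1])
                }
            )
    return CompositionTable(
        overall=overall, per_position=per_pos if per_position else None
    )


@dataclass(frozen=True)
class TransferRecord:
    """One pentapeptide pair with its concatenated and mixed-system scores."""

    pen1: Peptide
    pen2: Peptide
    ap_pen1: float
    ap_pen2: float
    ap_deca: float
    ap_mixpen: float

    @property
    def ap_avepen(self) -> float:
        return (self.ap_pen1 + self.ap_pen2) / 2.0

    @property
    def delta_deca(self) -> float:
        return self.ap_deca - self.ap_avepen

    @property
    def delta_mix(self) -> float:
        return self.ap_mixpen - self.ap_avepen

    @property
    def charge1(self) -> int:
        return net_side_chain_charge(self.pen1)

    @property
    def charge2(self) -> int:
        return net_side_chain_charge(self.pen2)

    @property
    def opposite_charged(self) -> bool:
        return self.charge1 * self.charge2 < 0

    def as_row(self) -> dict:
        return {
            "pen1": self.pen1.residues,
            "pen2": self.pen2.residues,
            "ap_pen1": self.ap_pen1,
            "ap_pen2": self.ap_pen2,
            "ap_avepen": self.ap_avepen,
            "ap_deca": self.ap_deca,
            "ap_mixpen": self.ap_mixpen,
            "delta_deca": self.delta_deca,
            "delta_mix": self.delta_mix,
            "charge1": self.charge1,
            "charge2": self.charge2,
        }


def records_to_frame(records: Sequence[TransferRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records])


@dataclass
class TransferSummary:
    n: int
    frac_mix_gain: float
    median_delta_mix: float
    max_delta_mix: float
    max_delta_deca: float
    corr_deltas: float
    mae_deca_vs_avepen: float
    mae_mix_vs_avepen: float
    top_table: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "frac_mix_gain": self.frac_mix_gain,
            "median_delta_mix": self.median_delta_mix,
            "max_delta_mix": self.max_delta_mix,
            "max_delta_deca": self.max_delta_deca,
            "corr_deltas": self.corr_deltas,
            "mae_deca_vs_avepen": self.mae_deca_vs_avepen,
            "mae_mix_vs_avepen": self.mae_mix_vs_avepen,
        }


def transfer_analysis(
    records: Sequence[TransferRecord],
    min_deca: float = 1.5,
    min_delta: float = 0.4,
    top_k: int | None = None,
) -> TransferSummary:
    """Summarize transferability of AP from pentapeptides to composites.

    Reports the fraction of pairs whose mixture outperforms the constituent
    mean, delta statistics, the correlation between concatenation and
    mixing gains, and a filtered table of strong-gain candidates
    (``ap_deca > min_deca`` and ``delta_deca > min_delta``), ordered by
    descending delta with lexicographic tie-break.
    """
    if not records:
        raise ScoreError("transfer_analysis requires at least one record")
    df = records_to_frame(records)
    dmix = df["delta_mix"].to_numpy()
    ddeca = df["delta_deca"].to_numpy()
    if np.std(dmix) == 0 or np.std(ddeca) == 0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(ddeca, dmix)[0, 1])
    mask = (df["ap_deca"] > min_deca) & (df["delta_deca"] > min_delta)
    top = df[mask].copy()
    top = top.sort_values(
        ["delta_deca", "pen1", "pen2"], ascending=[False, True, True]
    ).reset_index(drop=True)
    if top_k is not None:
        top = top.head(top_k)
    return TransferSummary(
        n=len(df),
        frac_mix_gain=float((dmix > 0).mean()),
        median_delta_mix=float(np.median(dmix)),
        max_delta_mix=float(dmix.max()),
        max_delta_deca=float(ddeca.max()),
        corr_deltas=corr,
        mae_deca_vs_avepen=float(np.abs(ddeca).mean()),
        mae_mix_vs_avepen=float(np.abs(dmix).mean()),
        top_table=top,
    )
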