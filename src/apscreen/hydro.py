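"""Wimley-White whole-residue hydrophilicity (logP) and its 0-1 normalization.

The hydrophilicity of a peptide is scored as

    logP = sum_i dG_woct(residue_i)        [kcal/mol]

where dG_woct is the free energy of transferring a whole residue from water
to n-octanol on the Wimley-White whole-residue scale (charged side chains
for D, E, K, R; neutral His — the neutral-pH convention).  Higher logP means
a more hydrophilic peptide.

The normalized form logP' rescales a length-n peptide by the theoretical
extremes attainable at that length — homopolymers of the most hydrophobic
(W) and most hydrophilic (D) residues:

    logP' = (logP - n*min) / (n*(max - min))   in [0, 1]
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .seqspace import ALPHABET, Peptide


class ScaleError(ValueError):
    """Raised when a residue scale is incomplete or inconsistent."""


@dataclass(frozen=True)
class ResidueScale:
    """Per-residue dG_woct constants (kcal/mol), all 20 residues present."""

    values: dict[str, float]
    name: str = "wimley_white_octanol"

    def __post_init__(self) -> None:
        missing = sorted(set(ALPHABET) - set(self.values))
        if missing:
            raise ScaleError(f"scale missing residues: {''.join(missing)}")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise ScaleError(f"residue {residue!r} not in scale {self.name!r}")

    @property
    def min_residue(self) -> float:
        return min(self.values[r] for r in ALPHABET)

    @property
    def max_residue(self) -> float:
        return max(self.values[r] for r in ALPHABET)


def load_scale(path: str | None = None) -> ResidueScale:
    """Load the shipped Wimley-White octanol scale, or a CSV with columns
    ``residue, delta_g_woct_kcal_per_mol``."""
    if path is None:
        ref = resources.files("apscreen").joinpath("data/wimley_white_octanol.csv")
        with ref.open("r") as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    values = dict(zip(df["residue"].str.upper(), df["delta_g_woct_kcal_per_mol"]))
    return ResidueScale(values=values)


#: Module-level default scale (loaded once).
DEFAULT_SCALE = load_scale()


def logp(peptide: Peptide | str, scale: ResidueScale = DEFAULT_SCALE) -> float:
    """Sum of per-residue water-to-octanol transfer free energies, kcal/mol."""
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    return float(sum(scale[r] for r in peptide.residues))


def logp_bounds(length: int, scale: ResidueScale = DEFAULT_SCALE) -> tuple[float, float]:
    """Theoretical (min, max) logP attainable by a peptide of this length."""
    if length < 1:
        raise ScaleError("length must be >= 1")
    return length * scale.min_residue, length * scale.max_residue


def logp_normalized(
    peptide: Peptide | str, scale: ResidueScale = DEFAULT_SCALE
) -> float:
    """logP min-max normalized by the theoretical length-n extremes, in [0,1]."""
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    lo, hi = logp_bounds(peptide.n, scale)
    return (logp(peptide, scale) - lo) / (hi - lo)
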