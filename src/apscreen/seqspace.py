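"""Peptide sequence space: representation, enumeration, sampling, tokenization.

The screening target is the space of oligopeptides over the 20 proteinogenic
amino acids, either as single chains (length 1-10) or as equimolar
two-component mixtures written ``PEN1+PEN2``.  Mixtures are unordered:
``A+B`` and ``B+A`` denote the same physical system, and the canonical form
sorts the two components lexicographically.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Fixed alphabetical ordering of the 20 proteinogenic amino acids.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SET = frozenset(ALPHABET)

#: Token used to join the two components of a mixed system.
MIX_TOKEN = "+"
#: Blank placeholder that pads short sequences up to the model length.
PAD_TOKEN = "_"

#: Vocabulary order: 20 residues, then '+', then the blank placeholder.
VOCAB = tuple(ALPHABET) + (MIX_TOKEN, PAD_TOKEN)
TOKEN_TO_ID = {t: i for i, t in enumerate(VOCAB)}
PAD_ID = TOKEN_TO_ID[PAD_TOKEN]
MIX_ID = TOKEN_TO_ID[MIX_TOKEN]

MAX_LENGTH = 10


class SequenceError(ValueError):
    """Raised for invalid residues, lengths, or encodings."""


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence of 1-10 standard residues."""

    residues: str

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        if seq != self.residues:
            object.__setattr__(self, "residues", seq)
        n = len(seq)
        if not 1 <= n <= MAX_LENGTH:
            raise SequenceError(
                f"peptide length must be 1..{MAX_LENGTH}, got {n} ({seq!r})"
            )
        bad = sorted(set(seq) - ALPHABET_SET)
        if bad:
            raise SequenceError(
                f"invalid residue(s) {''.join(bad)!r} in sequence {seq!r}"
            )

    @property
    def n(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __add__(self, other: "Peptide") -> "Peptide":
        """Concatenation, e.g. two pentapeptides into a decapeptide."""
        return Peptide(self.residues + other.residues)


@dataclass(frozen=True)
class PeptideSystem:
    """A single peptide or an unordered two-peptide mixture."""

    components: tuple[Peptide, ...]

    def __post_init__(self) -> None:
        if len(self.components) not in (1, 2):
            raise SequenceError("a system has one or two components")

    @classmethod
    def single(cls, seq: str | Peptide) -> "PeptideSystem":
        pep = seq if isinstance(seq, Peptide) else Peptide(seq)
        return cls((pep,))

    @classmethod
    def mixed(cls, a: str | Peptide, b: str | Peptide) -> "PeptideSystem":
        pa = a if isinstance(a, Peptide) else Peptide(a)
        pb = b if isinstance(b, Peptide) else Peptide(b)
        return cls((pa, pb))

    @classmethod
    def parse(cls, text: str) -> "PeptideSystem":
        """Parse ``"NRMMR"`` or ``"NRMMR+DMGID"``."""
        parts = text.strip().upper().split(MIX_TOKEN)
        if len(parts) == 1:
            return cls.single(parts[0])
        if len(parts) == 2:
            return cls.mixed(parts[0], parts[1])
        raise SequenceError(f"at most one {MIX_TOKEN!r} allowed: {text!r}")

    @property
    def is_mixed(self) -> bool:
        return len(self.components) == 2

    @property
    def kind(self) -> str:
        return "mixed" if self.is_mixed else "single"

    def canonical(self) -> "PeptideSystem":
        """Order-insensitive canonical form (components sorted)."""
        if self.is_mixed:
            a, b = self.components
            if b.residues < a.residues:
                return PeptideSystem((b, a))
        return self

    def swapped(self) -> "PeptideSystem":
        if not self.is_mixed:
            raise SequenceError("cannot swap a single-peptide system")
        a, b = self.components
        return PeptideSystem((b, a))

    def __str__(self) -> str:
        return MIX_TOKEN.join(p.residues for p in self.components)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeptideSystem):
            return NotImplemented
        return (
            self.canonical().components == other.canonical().components
        )

    def __hash__(self) -> int:
        return hash(self.canonical().components)


def space_size(length: int, mixed: bool = False) -> int:
    """Number of sequences of a given length; for ``mixed``, the number of
    unordered pairs (including self-pairs) drawn from that single space.

    The full pentapeptide space holds 20**5 = 3.2 million sequences; the
    mixed-pentapeptide space holds N(N+1)/2 unordered pairs of those.
    """
    if not 1 <= length <= MAX_LENGTH:
        raise SequenceError(f"length must be 1..{MAX_LENGTH}, got {length}")
    n = 20**length
    if mixed:
        return n * (n + 1) // 2
    return n


@dataclass(frozen=True)
class SequenceSpace:
    """The complete sequence space at one peptide length."""

    length: int
    mixed: bool = False

    @property
    def alphabet(self) -> str:
        return ALPHABET

    @property
    def cardinality(self) -> int:
        return space_size(self.length, self.mixed)


def enumerate_space(length: int, limit: int | None = None) -> Iterator[Peptide]:
    """Stream all single peptides of one length in lexicographic order."""
    if not 1 <= length <= MAX_LENGTH:
        raise SequenceError(f"length must be 1..{MAX_LENGTH}, got {length}")
    it = itertools.product(ALPHABET, repeat=length)
    if limit is not None:
        it = itertools.islice(it, limit)
    for tup in it:
        yield Peptide("".join(tup))


def lhs_sample(
    length: int, n_samples: int, seed: int, warn_duplicates: bool = True
) -> list[Peptide]:
    """Latin Hypercube sample of the sequence space.

    Each sequence position is one LHS dimension.  [0,1) is divided into
    ``n_samples`` strata per dimension; one uniform point is drawn in each
    stratum and the strata are permuted independently across dimensions.
    A point ``u`` maps to residue index ``floor(20*u)`` over the fixed
    alphabetical ordering, so for ``n_samples`` divisible by 20 every
    residue appears exactly ``n_samples/20`` times at every position.

    Duplicate sequences are kept (the sample is a multiset) but counted in
    a log message, since collisions are possible once strata outnumber
    residues.
    """
    if n_samples < 1:
        raise SequenceError("n_samples must be >= 1")
    if not 1 <= length <= MAX_LENGTH:
        raise SequenceError(f"length must be 1..{MAX_LENGTH}, got {length}")
    rng = np.random.default_rng(seed)
    # u[j, p] = (perm_p(j) + jitter) / n  lies in stratum perm_p(j).
    cols = []
    for _ in range(length):
        perm = rng.permutation(n_samples)
        jitter = rng.random(n_samples)
        u = (perm + jitter) / n_samples
        cols.append(np.floor(20 * u).astype(np.int64))
    idx = np.stack(cols, axis=1)
    peptides = ["".join(ALPHABET[i] for i in row) for row in idx]
    if warn_duplicates:
        n_dup = len(peptides) - len(set(peptides))
        if n_dup:
            logger.info("LHS sample contains %d duplicate sequence(s)", n_dup)
    return [Peptide(p) for p in peptides]


def tokenize(system: PeptideSystem | str, model_length: int) -> np.ndarray:
    """Encode a system as integer token ids padded to ``model_length``.

    Single systems emit residue tokens followed by blank placeholders;
    mixed systems emit ``pen1 + pen2`` joined by the '+' token.  Raises if
    the encoded content does not fit the model length.
    """
    if isinstance(system, str):
        system = PeptideSystem.parse(system)
    text = str(system)
    if len(text) > model_length:
        raise SequenceError(
            f"encoded system {text!r} (length {len(text)}) exceeds "
            f"model length {model_length}"
        )
    ids = [TOKEN_TO_ID[c] for c in text]
    ids.extend([PAD_ID] * (model_length - len(ids)))
    return np.asarray(ids, dtype=np.int64)


def detokenize(tokens: Sequence[int]) -> PeptideSystem:
    """Inverse of :func:`tokenize` on the non-placeholder prefix."""
    chars = []
    for t in tokens:
        if t == PAD_ID:
            break
        chars.append(VOCAB[t])
    return PeptideSystem.parse("".join(chars))


def tokenize_batch(
    systems: Sequence[PeptideSystem | str], model_length: int
) -> np.ndarray:
    return np.stack([tokenize(s, model_length) for s in systems])


def augment_mixed(
    systems: Sequence[PeptideSystem],
    labels: Sequence[float] | None = None,
):
    """Swap augmentation for mixed systems: append B+A for every A+B.

    Self-pairs (A+A) are not duplicated.  When ``labels`` is given, each
    swapped copy carries its original label; returns ``(systems, labels)``.
    """
    for s in systems:
        if not s.is_mixed:
            raise SequenceError(f"augment_mixed requires mixed systems, got {s}")
    out: list[PeptideSystem] = list(systems)
    out_labels = list(labels) if labels is not None else None
    for i, s in enumerate(systems):
        a, b = s.components
        if a.residues != b.residues:
            out.append(s.swapped())
            if out_labels is not None:
                out_labels.append(labels[i])  # type: ignore[index]
    if labels is None:
        return out
    return out, out_labels


def min_mixed_model_length(length: int) -> int:
    """Token length needed for a mixture of two peptides of one length."""
    return 2 * length + 1


def required_space_for_ten_trillion() -> int:
    """Decapeptide space plus mixed-pentapeptide pairs (the screened space)."""
    return space_size(10) + space_size(5, mixed=True)
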