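"""Trinucleotide sequence-graph-transform (SGT) encoding.

A DNA sequence is represented by the 64 overlapping trinucleotides it
contains.  For every ordered trinucleotide pair (u, v) the encoder
records the mean exponentially decayed distance between occurrences of
u and later occurrences of v:

    psi_uv = ( sum over pairs (u at l, v at m, l < m) of exp(-kappa (m - l)) )
             / |Lambda_uv|

where |Lambda_uv| is the number of such ordered occurrence pairs and
kappa > 0 controls how fast long-range pairings are discounted.  The
result is a 64 x 64 "pattern matrix" that captures both the frequency
and the relative placement of trinucleotide pairs, and is the input to
the convolutional classifier.

Row/column order is lexicographic with A < C < G < T (AAA = 0 ...
TTT = 63), rows indexing the earlier trinucleotide.  This ordering is
frozen: trained classifier weights depend on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np

logger = logging.getLogger(__name__)

#: Lexicographic trinucleotide alphabet, A < C < G < T.
TRINUCLEOTIDES: tuple[str, ...] = tuple("".join(p) for p in product("ACGT", repeat=3))
TRINUCLEOTIDE_INDEX: dict[str, int] = {t: i for i, t in enumerate(TRINUCLEOTIDES)}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
# IUPAC nucleotide one-letter codes (T and U both accepted on input).
IUPAC_LETTERS = frozenset("ACGTUNRYSWKMBDHV")

#: Default decay constant used throughout the package when none is given.
DEFAULT_KAPPA = 1.0


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence; bases may be any IUPAC letters, any case."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord.id must be non-empty")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class TrinucleotideTrack:
    """Positions of the pure-ACGT trinucleotide windows of one sequence.

    ``codes[i]`` is the lexicographic index (0-63) of the window starting
    at 1-based offset ``positions[i]``; windows overlapping any non-ACGT
    letter are absent, so positions are strictly increasing but not
    necessarily consecutive.
    """

    codes: np.ndarray  # int64, values in 0..63
    positions: np.ndarray  # int64, 1-based, strictly increasing
    source_length: int

    @property
    def tokens(self) -> list[tuple[int, int]]:
        return list(zip(self.codes.tolist(), self.positions.tolist()))

    @property
    def labels(self) -> list[str]:
        return [TRINUCLEOTIDES[c] for c in self.codes]

    def __len__(self) -> int:
        return int(self.codes.size)


@dataclass(frozen=True)
class PatternMatrix:
    """64 x 64 grid of pair weights psi_uv for one sequence.

    Every entry lies in [0, exp(-kappa)] because each summand has
    distance >= 1 and psi is an average of summands.
    """

    weights: np.ndarray  # (64, 64) float64, >= 0
    kappa: float
    sequence_id: str


def tokenize_trinucleotides(seq: SequenceRecord) -> TrinucleotideTrack:
    """Extract every overlapping pure-ACGT trinucleotide with its position.

    Positions are 1-based start offsets in the original sequence, so two
    consecutive overlapping windows are at distance 1.  Windows containing
    a degenerate base (N, R, ...) are dropped; surviving windows keep
    their original offsets, preserving genomic spacing.

    Raises
    ------
    ValueError
        If the sequence contains a letter that is not an IUPAC
        nucleotide code; the message names the (1-based) position.
    """
    bases = seq.bases.upper()
    n = len(bases)
    for pos, ch in enumerate(bases, start=1):
        if ch not in IUPAC_LETTERS:
            raise ValueError(
                f"sequence {seq.id!r}: non-IUPAC character {ch!r} at position {pos}"
            )
    if n < 3:
        empty = np.empty(0, dtype=np.int64)
        return TrinucleotideTrack(codes=empty, positions=empty.copy(), source_length=n)

    code = np.array([_BASE_CODE.get(ch, -1) for ch in bases], dtype=np.int64)
    ok = code >= 0
    window_ok = ok[:-2] & ok[1:-1] & ok[2:]
    starts = np.nonzero(window_ok)[0]
    codes = 16 * code[starts] + 4 * code[starts + 1] + code[starts + 2]
    return TrinucleotideTrack(
        codes=codes, positions=starts + 1, source_length=n
    )


def sgt_matrix(track: TrinucleotideTrack, kappa: float = DEFAULT_KAPPA,
               sequence_id: str = "") -> PatternMatrix:
    """Pair-weight matrix of a token track (streaming, O(T * 64)).

    A single left-to-right pass maintains, for every trinucleotide u, the
    decayed sum ``W[u] = sum exp(-kappa (p - l))`` over occurrences of u
    seen so far (p = current position) together with the running
    occurrence count; each summand is rescaled by ``exp(-kappa * gap)``
    as the pass advances, which avoids the overflowing ``exp(+kappa l)``
    prefix sums of the textbook formulation.
    """
    if not kappa > 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    numer = np.zeros((64, 64), dtype=np.float64)
    npairs = np.zeros((64, 64), dtype=np.int64)
    decayed = np.zeros(64, dtype=np.float64)  # W[u] at the current position
    seen = np.zeros(64, dtype=np.int64)
    prev = None
    for c, p in zip(track.codes.tolist(), track.positions.tolist()):
        if prev is not None:
            decayed *= np.exp(-kappa * (p - prev))
        numer[:, c] += decayed
        npairs[:, c] += seen
        decayed[c] += 1.0
        seen[c] += 1
        prev = p
    with np.errstate(invalid="ignore"):
        weights = np.where(npairs > 0, numer / np.maximum(npairs, 1), 0.0)
    return PatternMatrix(weights=weights, kappa=float(kappa), sequence_id=sequence_id)


def sgt_matrix_bruteforce(track: TrinucleotideTrack, kappa: float = DEFAULT_KAPPA,
                          sequence_id: str = "") -> PatternMatrix:
    """Reference all-pairs evaluation of the pair-weight definition.

    Enumerates every ordered occurrence pair (l < m) explicitly and
    averages the decayed distances — O(T^2), kept as the independent
    check for the streaming implementation.
    """
    if not kappa > 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    numer = np.zeros((64, 64), dtype=np.float64)
    npairs = np.zeros((64, 64), dtype=np.int64)
    T = len(track)
    if T >= 2:
        i, j = np.triu_indices(T, k=1)
        u = track.codes[i]
        v = track.codes[j]
        w = np.exp(-kappa * (track.positions[j] - track.positions[i]).astype(np.float64))
        np.add.at(numer, (u, v), w)
        np.add.at(npairs, (u, v), 1)
    with np.errstate(invalid="ignore"):
        weights = np.where(npairs > 0, numer / np.maximum(npairs, 1), 0.0)
    return PatternMatrix(weights=weights, kappa=float(kappa), sequence_id=sequence_id)


def encode_batch(seqs: list[SequenceRecord], kappa: float = DEFAULT_KAPPA) -> list[PatternMatrix]:
    """Encode a batch of sequences, order preserved.

    Sequences with fewer than two usable trinucleotides carry no pair
    information and yield the all-zero matrix (with a logged warning).
    Tokenizer errors are re-raised with the sequence id attached.
    """
    out = []
    for seq in seqs:
        track = tokenize_trinucleotides(seq)
        if len(track) < 2:
            logger.warning(
                "sequence %r has %d usable trinucleotide(s); emitting all-zero matrix",
                seq.id, len(track),
            )
        out.append(sgt_matrix(track, kappa=kappa, sequence_id=seq.id))
    return out


def stack_weights(matrices: list[PatternMatrix]) -> np.ndarray:
    """(N, 64, 64) float32 array of the matrices' weights, for the classifier."""
    return np.stack([m.weights for m in matrices]).astype(np.float32)
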