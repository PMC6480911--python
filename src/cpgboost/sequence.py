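"""Sequence n-gram features around CpG sites.

Each site is described by the 1-, 2- and 3-mer composition of the 101-bp
window centered on the C of the CpG dinucleotide (50 bp of flank on either
side): 4 + 16 + 64 = 84 frequencies.  The frequency of an n-mer v is
N(v) / (L - (n - 1)) where N(v) counts overlapping occurrences in the window
of length L.

Windows overlapping ambiguous bases (N, chromosome-end padding) contribute
those positions to no n-mer: the numerator skips them while the denominator
keeps the nominal window length, so the feature scale is identical for every
site regardless of where it sits on the chromosome.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

_BASES = "ACGT"

#: fixed column order: A..T, then AA..TT, then AAA..TTT
NGRAM_NAMES: tuple[str, ...] = tuple(
    "".join(p) for n in (1, 2, 3) for p in product(_BASES, repeat=n)
)

N_SEQUENCE_FEATURES = len(NGRAM_NAMES)  # 84

# byte value -> base code (A=0 C=1 G=2 T=3, anything else -1)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class GenomeSequence:
    """Random access to upper-cased DNA windows of a genome.

    Wraps either a pyfaidx.Fasta handle or a plain mapping of chromosome
    name to sequence string (used by the simulator and tests).
    """

    def __init__(self, source):
        self._source = source
        self._is_mapping = isinstance(source, Mapping)

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        from pyfaidx import Fasta

        return cls(Fasta(str(path), as_raw=True, sequence_always_upper=True))

    def __contains__(self, chrom: str) -> bool:
        if self._is_mapping:
            return chrom in self._source
        return chrom in self._source.keys()

    def chrom_length(self, chrom: str) -> int:
        if chrom not in self:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        return len(self._source[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the 1-based closed interval [start, end], clipped to
        the chromosome; the caller pads."""
        if chrom not in self:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        length = self.chrom_length(chrom)
        lo = max(start, 1)
        hi = min(end, length)
        if hi < lo:
            return ""
        seq = self._source[chrom][lo - 1 : hi]
        return str(seq).upper()


def extract_window(
    genome: GenomeSequence, chrom: str, pos: int, flank: int = 50
) -> str:
    """The (2*flank+1)-bp window centered on a 1-based position.

    Near chromosome ends the window is padded with N so every site yields a
    string of identical length.
    """
    if pos < 1:
        raise ValueError(f"pos must be >= 1, got {pos}")
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    start, end = pos - flank, pos + flank
    core = genome.fetch(chrom, start, end)
    left_pad = max(0, 1 - start)
    width = 2 * flank + 1
    right_pad = width - left_pad - len(core)
    return "N" * left_pad + core + "N" * right_pad


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def ngram_features(seq: str, n_set: Iterable[int] = (1, 2, 3)) -> np.ndarray:
    """Overlapping n-mer frequencies of one window, in NGRAM_NAMES order.

    For each requested n the denominator is L-(n-1); windows containing an
    ambiguous base are skipped in the numerator only.
    """
    n_set = sorted(set(n_set))
    if not n_set or any(n not in (1, 2, 3) for n in n_set):
        raise ValueError("n_set must be a non-empty subset of {1, 2, 3}")
    L = len(seq)
    for n in n_set:
        if L - (n - 1) < 1:
            raise ValueError(f"sequence of length {L} too short for n={n}")
    codes = _encode(seq)
    out = np.zeros(N_SEQUENCE_FEATURES, dtype=np.float64)
    offset = 0
    for n in (1, 2, 3):
        size = 4**n
        if n in n_set:
            windows = np.lib.stride_tricks.sliding_window_view(codes, n)
            valid = (windows >= 0).all(axis=1)
            if valid.any():
                idx = windows[valid].astype(np.int64)
                key = np.zeros(len(idx), dtype=np.int64)
                for col in range(n):
                    key = key * 4 + idx[:, col]
                counts = np.bincount(key, minlength=size)
                out[offset : offset + size] = counts / (L - (n - 1))
        offset += size
    return out


def ngram_matrix(seqs: Sequence[str], n_set: Iterable[int] = (1, 2, 3)) -> np.ndarray:
    """Stacked :func:`ngram_features` for many windows."""
    return np.vstack([ngram_features(s, n_set) for s in seqs]) if len(seqs) else np.zeros((0, N_SEQUENCE_FEATURES))


def sequence_feature_names() -> list[str]:
    return [f"seq_{g}" for g in NGRAM_NAMES]
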