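"""Strand-specific overlapping k-mer counting for mid-length DNA words.

Words of length 8-14 bp are counted on one strand with overlap allowed;
reverse complements are kept as distinct words so that strand biases remain
visible. Windows containing any non-ACGT symbol (N or other IUPAC ambiguity
codes) are skipped and excluded from the usable-window denominator.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from dataclasses import dataclass

import numpy as np

K_MIN = 8
K_MAX = 14

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes (A=0, C=1, G=2, T=3, other=-1)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def encode_kmer(word: str) -> int:
    code = 0
    for ch in word:
        v = _CODE[ord(ch)]
        if v < 0:
            raise ValueError(f"non-ACGT character in word: {word!r}")
        code = (code << 2) | int(v)
    return code


def window_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all ambiguity-free length-k windows of an encoded
    sequence, in positional order. Windows touching a negative (ambiguous)
    code are dropped."""
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    m = n - k + 1
    codes = arr[:m].astype(np.int64)
    for j in range(1, k):
        codes <<= 2
        codes += arr[j : j + m]
    bad = (arr < 0).astype(np.int32)
    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad)))
        window_bad = cs[k:] - cs[:-k]
        return codes[window_bad == 0]
    return codes


def unique_window_counts(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(sorted distinct codes, counts) over ambiguity-free windows.

    Uses a dense bincount when the 4^k table is small enough, otherwise a
    sort-based tally, so k up to 14 stays within ordinary memory.
    """
    codes = window_codes(arr, k)
    if codes.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    if k <= 11:
        table = np.bincount(codes, minlength=4**k)
        present = np.flatnonzero(table)
        return present.astype(np.int64), table[present]
    return np.unique(codes, return_counts=True)


class _KmerCountMap(Mapping):
    """Read-only mapping oligomer -> count backed by sorted code arrays."""

    def __init__(self, codes: np.ndarray, counts: np.ndarray, k: int):
        self._codes = codes
        self._counts = counts
        self.k = k

    def __getitem__(self, word: str) -> int:
        if len(word) != self.k:
            raise KeyError(word)
        code = encode_kmer(word)
        idx = np.searchsorted(self._codes, code)
        if idx < self._codes.size and self._codes[idx] == code:
            return int(self._counts[idx])
        raise KeyError(word)

    def __iter__(self) -> Iterator[str]:
        for code in self._codes:
            yield decode_kmer(int(code), self.k)

    def __len__(self) -> int:
        return int(self._codes.size)

    def values(self):
        return [int(c) for c in self._counts]

    def total(self) -> int:
        return int(self._counts.sum())


@dataclass
class WordCountTable:
    """Overlapping word counts of one chromosome at a single k.

    ``usable_positions`` is the number of length-k windows free of ambiguity
    codes; it always equals the sum of all counts.
    """

    chromosome_id: str
    k: int
    counts: Mapping
    usable_positions: int

    def get(self, word: str, default: int = 0) -> int:
        return self.counts.get(word, default)


def count_words(sequence: str, k: int, chromosome_id: str = "") -> WordCountTable:
    """Tally every overlapping ambiguity-free window of length k.

    Counting is on the given strand only; the reverse complement is not
    added. Raises ``ValueError`` for k outside [8, 14] or a sequence shorter
    than k.
    """
    if not K_MIN <= k <= K_MAX:
        raise ValueError(f"k must be in [{K_MIN}, {K_MAX}], got {k}")
    if len(sequence) < k:
        raise ValueError("sequence too short")
    arr = encode_sequence(sequence)
    codes, counts = unique_window_counts(arr, k)
    return WordCountTable(
        chromosome_id=chromosome_id,
        k=k,
        counts=_KmerCountMap(codes, counts, k),
        usable_positions=int(counts.sum()),
    )


def word_positions(sequence: str, word: str) -> list[int]:
    """0-based start positions of every overlapping exact occurrence."""
    if not word:
        raise ValueError("empty word")
    positions = []
    start = sequence.find(word)
    while start != -1:
        positions.append(start)
        start = sequence.find(word, start + 1)
    return positions


def copies_per_mb(count: int, length_bp: int) -> float:
    """Normalize a raw count to occurrences per megabase of chromosome."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    return count * 1e6 / length_bp


def reverse_complement(word: str) -> str:
    """Watson-Crick reverse complement of an ACGT word."""
    if any(c not in "ACGT" for c in word):
        raise ValueError(f"non-ACGT character in {word!r}")
    return word.translate(_COMPLEMENT)[::-1]


_COMPLEMENT_IUPAC = str.maketrans(
    "ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB"
)


def reverse_complement_sequence(sequence: str) -> str:
    """Reverse complement of a chromosome-scale sequence; IUPAC ambiguity
    codes are complemented symbol-wise (N stays N)."""
    return sequence.translate(_COMPLEMENT_IUPAC)[::-1]
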