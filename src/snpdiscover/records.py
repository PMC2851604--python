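"""Core record types shared across pipeline stages.

Reads keep their bases uppercase internally; repeat state lives in a
separate boolean mask vector so that masking never edits sequence.  All
coordinates in the package are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# 2-bit base codes; N gets 4 and is excluded from any k-mer window.
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def encode_bases(bases: str) -> np.ndarray:
    """Map an uppercase DNA string to uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return _BASE_CODE[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]


def revcomp(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """A sequenced fragment with bases, qualities and soft-mask state.

    Parameters
    ----------
    id : str
        Unique identifier; downstream stages refer to reads only by id.
    bases : str
        Uppercase DNA over {A,C,G,T,N}.
    quals : np.ndarray
        Phred-scale integer qualities, one per base.
    set_id : int
        Which sequencing increment (lane/quadrant) the read arrived in.
    individual_id : str
        Sample label, used by the multi-individual cluster filter.
    mask : np.ndarray
        Boolean soft-mask, True = masked (repeat-derived).
    """

    id: str
    bases: str
    quals: np.ndarray
    set_id: int = 0
    individual_id: str = "ind0"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    fully_masked: bool = False

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if self.mask is None:
            self.mask = np.zeros(len(self.bases), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.bases) == len(self.quals) == len(self.mask)):
            raise ValueError(
                f"read {self.id!r}: bases/quals/mask lengths differ "
                f"({len(self.bases)}/{len(self.quals)}/{len(self.mask)})"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def codes(self) -> np.ndarray:
        """2-bit base codes, cached after first use."""
        c = getattr(self, "_codes", None)
        if c is None:
            c = encode_bases(self.bases)
            self._codes = c
        return c

    def invalidate_cache(self) -> None:
        self._codes = None


@dataclass(frozen=True)
class Cutoffs:
    """Masker parameters derived from a k-mer frequency spectrum.

    The four thresholds are percentile cutoffs of the ascending frequency
    array (90 / 99 / 99.5 / 99.8 percent), each plus one, so they satisfy
    T_low <= T_extend <= T_threshold <= T_high.
    """

    K: int
    T_low: int
    T_extend: int
    T_threshold: int
    T_high: int
    N_total: int
    C_unique: int

    def __post_init__(self) -> None:
        if not (self.T_low <= self.T_extend <= self.T_threshold <= self.T_high):
            raise ValueError("cutoff ordering violated")


@dataclass
class KmerSpectrum:
    """Canonical k-mer frequencies for one input set.

    ``codes`` holds the sorted distinct canonical k-mer integer codes and
    ``freqs`` the matching counts; ``sorted_freqs`` is the ascending array
    the percentile cutoffs index into.
    """

    K: int
    codes: np.ndarray
    freqs: np.ndarray

    @property
    def C_unique(self) -> int:
        return len(self.codes)

    @property
    def sorted_freqs(self) -> np.ndarray:
        return np.sort(self.freqs)

    @property
    def counts(self) -> dict:
        """Mapping canonical k-mer string -> frequency (small inputs only)."""
        out = {}
        for code, f in zip(self.codes.tolist(), self.freqs.tolist()):
            kmer = _decode_kmer(code, self.K)
            out[kmer] = int(f)
        return out

    def lookup(self, query_codes: np.ndarray) -> np.ndarray:
        """Frequencies for an array of canonical codes (0 where absent)."""
        idx = np.searchsorted(self.codes, query_codes)
        idx_c = np.clip(idx, 0, len(self.codes) - 1)
        hit = (idx < len(self.codes)) & (self.codes[idx_c] == query_codes)
        out = np.zeros(len(query_codes), dtype=np.int64)
        out[hit] = self.freqs[idx_c[hit]]
        return out


def _decode_kmer(code: int, K: int) -> str:
    out = []
    for _ in range(K):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


@dataclass(frozen=True)
class ScoreSet:
    """Alignment scoring and filter parameters for one technology.

    mismatch/gap numbers are penalty magnitudes (positive costs).
    """

    match: int
    mismatch: int
    gap_open: int
    gap_extend: int
    seed_len: int
    xdrop: int
    min_overlap: int
    min_identity: float
    band: int = 11

    def __post_init__(self) -> None:
        if self.match <= 0 or min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("match must be positive and penalties non-negative")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")


@dataclass
class Alignment:
    """A pairwise overlap between reads ``id_a`` and ``id_b``.

    ``differences`` lists substitutions as (a_pos, a_base, b_base, b_pos)
    plus gap records with '-' for the gapped side.  Coordinates are on
    read a's forward strand; for strand '-', b coordinates refer to the
    reverse complement of b.
    """

    id_a: str
    id_b: str
    strand: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    differences: list
    identity: float
    aligned_cols: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity out of range")
        for d in self.differences:
            if not (self.a_start <= d[0] < self.a_end):
                raise ValueError("difference outside alignment span")

    def substitutions(self) -> list:
        return [d for d in self.differences if d[1] != "-" and d[2] != "-"]
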