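"""Three-pass soft-masking of over-represented k-mers in read sets.

Without a reference there is no repeat library, so repeats are inferred
from the reads themselves: k-mers that occur far more often than the
genome-wide average betray high-copy sequence.  Pass 1 derives K and four
percentile cutoffs from the set's k-mer frequency spectrum; pass 2 masks
sliding 5-k-mer windows whose mean k-mer score exceeds T_threshold,
bridging intervals whose windows all exceed T_extend; pass 3 masks whole
reads dominated by a local (within-read) repeat and finally unmasks any
masked run shorter than 40 bp, so isolated high-frequency k-mers in
otherwise unique sequence do not block alignment seeding.
"""

from __future__ import annotations

import numpy as np

from snpdiscover.records import Cutoffs, KmerSpectrum, Read

__all__ = [
    "choose_k",
    "build_spectrum",
    "compute_cutoffs",
    "score_kmer",
    "mask_windows",
    "local_repeat_pass",
    "mask_set",
]

MIN_MASK_RUN = 40  # pass-3 unmasking: masked runs shorter than this revert
WINDOW_KMERS = 5


def choose_k(n_total: int) -> int:
    """Largest K with n_total / 4**K > 5 (K-mer size for the current set)."""
    if n_total <= 20:
        raise ValueError(f"set too small to choose K ({n_total} bases; need > 20)")
    k = 1
    while n_total / 4 ** (k + 1) > 5:
        k += 1
    return k


def _kmer_codes(read: Read, K: int) -> tuple[np.ndarray, np.ndarray]:
    """(canonical k-mer codes, validity) for every window of the read.

    Windows containing N are invalid and excluded everywhere.  Canonical
    means the lexicographic minimum of a k-mer and its reverse complement,
    so both sampled strands accumulate into one count.
    """
    codes = read.codes
    n = len(codes) - K + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, K).astype(np.int64)
    valid = ~(win == 4).any(axis=1)
    pw_f = 4 ** np.arange(K - 1, -1, -1, dtype=np.int64)
    pw_r = 4 ** np.arange(K, dtype=np.int64)
    fwd = win @ pw_f
    rev = (3 - win) @ pw_r
    return np.minimum(fwd, rev), valid


def build_spectrum(reads: list[Read], K: int) -> KmerSpectrum:
    """Count canonical k-mers over all reads of one set."""
    chunks = []
    for r in reads:
        codes, valid = _kmer_codes(r, K)
        if codes.size:
            chunks.append(codes[valid])
    if chunks:
        all_codes = np.concatenate(chunks)
        uniq, counts = np.unique(all_codes, return_counts=True)
    else:
        uniq = np.empty(0, dtype=np.int64)
        counts = np.empty(0, dtype=np.int64)
    return KmerSpectrum(K=K, codes=uniq, freqs=counts.astype(np.int64))


def compute_cutoffs(spectrum: KmerSpectrum, n_total: int) -> Cutoffs:
    """Percentile cutoffs from the ascending frequency array F.

    T_high, T_threshold, T_extend, T_low are F[int(q·C)] + 1 at
    q = 0.998, 0.995, 0.99 and 0.9 respectively (0-based indexing,
    truncating int).
    """
    c = spectrum.C_unique
    if c < 1:
        raise ValueError("empty k-mer spectrum")
    f = spectrum.sorted_freqs

    def at(q: float) -> int:
        return int(f[min(int(q * c), c - 1)]) + 1

    return Cutoffs(
        K=spectrum.K,
        T_low=at(0.9),
        T_extend=at(0.99),
        T_threshold=at(0.995),
        T_high=at(0.998),
        N_total=n_total,
        C_unique=c,
    )


def score_kmer(freq, cutoffs: Cutoffs):
    """Clamp a k-mer frequency into [T_low, T_high].

    Damps the influence of a few extremely frequent k-mers and removes
    the need to distinguish among rare ones; scalar or array input.
    """
    return np.clip(freq, cutoffs.T_low, cutoffs.T_high)


def _window_scores(read: Read, spectrum: KmerSpectrum, cutoffs: Cutoffs) -> np.ndarray:
    codes, valid = _kmer_codes(read, cutoffs.K)
    if codes.size < WINDOW_KMERS:
        return np.empty(0)
    freqs = spectrum.lookup(codes)
    scores = score_kmer(freqs, cutoffs).astype(np.float64)
    scores[~valid] = 0.0
    kernel = np.ones(WINDOW_KMERS) / WINDOW_KMERS
    return np.convolve(scores, kernel, mode="valid")


def mask_windows(read: Read, spectrum: KmerSpectrum, cutoffs: Cutoffs) -> Read:
    """Pass 2: window masking with the T_extend bridging rule.

    Windows hold 5 k-mers and advance one base (adjacent windows share 4);
    a window whose mean k-mer score exceeds T_threshold is masked over the
    K+4 bases it spans, and the interval between two masked windows is
    masked too when every window in between exceeds T_extend.
    """
    K = cutoffs.K
    w = _window_scores(read, spectrum, cutoffs)
    if w.size == 0:
        return read
    hot = w > cutoffs.T_threshold
    warm = w > cutoffs.T_extend
    to_mask = hot.copy()
    # bridge: inside each maximal warm run, mask between first & last hot
    if hot.any():
        idx = 0
        n = len(w)
        while idx < n:
            if not warm[idx]:
                idx += 1
                continue
            end = idx
            while end < n and warm[end]:
                end += 1
            hot_in = np.flatnonzero(hot[idx:end])
            if hot_in.size >= 2:
                to_mask[idx + hot_in[0] : idx + hot_in[-1] + 1] = True
            idx = end
    if to_mask.any():
        span = K + WINDOW_KMERS - 1
        delta = np.zeros(len(read) + 1, dtype=np.int32)
        starts = np.flatnonzero(to_mask)
        np.add.at(delta, starts, 1)
        np.add.at(delta, np.minimum(starts + span, len(read)), -1)
        read.mask |= np.cumsum(delta[:-1]) > 0
    return read


def local_repeat_pass(read: Read, K: int, cutoffs: Cutoffs) -> tuple[Read, bool]:
    """Pass 3: whole-read local-repeat masking, then short-run unmasking.

    If any k-mer occurs more than T_extend times within the read itself the
    whole read is masked and flagged; otherwise every maximal masked run
    shorter than 40 bp is unmasked.
    """
    codes, valid = _kmer_codes(read, K)
    fully = False
    if codes.size:
        _, counts = np.unique(codes[valid], return_counts=True)
        if counts.size and counts.max() > cutoffs.T_extend:
            read.mask[:] = True
            read.fully_masked = True
            return read, True
    # unmask short runs
    m = read.mask
    if m.any():
        padded = np.concatenate(([False], m, [False])).astype(np.int8)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            if e - s < MIN_MASK_RUN:
                m[s:e] = False
    return read, fully


def mask_set(reads: list[Read], K: int | None = None) -> tuple[Cutoffs, list[str]]:
    """Run all three passes over one set in place.

    Returns the derived cutoffs and the ids of fully-masked reads (local
    repeats), which the SNP caller later uses to exclude repeat-adjacent
    clusters.
    """
    n_total = sum(len(r) for r in reads)
    if K is None:
        K = choose_k(n_total)
    spectrum = build_spectrum(reads, K)
    cutoffs = compute_cutoffs(spectrum, n_total)
    fully_masked: list[str] = []
    for r in reads:
        if len(r) >= K + WINDOW_KMERS - 1:
            mask_windows(r, spectrum, cutoffs)
        _, fully = local_repeat_pass(r, K, cutoffs)
        if fully:
            fully_masked.append(r.id)
    return cutoffs, fully_masked
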