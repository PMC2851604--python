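"""Seed-and-extend overlap detection between masked reads.

Pairs of reads are anchored by perfect matches of at least ``seed_len``
unmasked bases (found through a sorted word-index join), then extended in
both directions with banded affine-gap dynamic programming that stops when
the score drops ``xdrop`` below the running maximum.  A pair is "aligned"
when the overlap spans at least ``min_overlap`` columns at
``min_identity`` or better; the observed substitutions and gaps feed the
cluster store downstream.
"""

from __future__ import annotations

import numpy as np

from snpdiscover._kernels import xdrop_extend_kernel
from snpdiscover.records import Alignment, Read, ScoreSet, encode_bases, revcomp

__all__ = ["preset_scores", "find_seeds", "extend_seed", "all_overlaps"]

PRESETS = {
    # Roche/454-style long reads: cheap gap opening (homopolymer indels),
    # overlap must reach 100 bp at 96% identity.
    "long_454": ScoreSet(match=1, mismatch=3, gap_open=1, gap_extend=3,
                         seed_len=40, xdrop=10, min_overlap=100, min_identity=0.96),
    # Illumina-style 75 bp reads: gaps strongly discouraged, 50 bp overlaps.
    # A 40 bp exact seed would miss valid 50 bp overlaps with a central
    # error, so the seed is shortened to 32 bp.
    "short_illumina": ScoreSet(match=1, mismatch=10, gap_open=10, gap_extend=10,
                               seed_len=32, xdrop=20, min_overlap=50, min_identity=0.96),
}


def preset_scores(technology: str) -> ScoreSet:
    """Alignment score set and overlap filters for a sequencing technology."""
    try:
        return PRESETS[technology]
    except KeyError:
        raise ValueError(
            f"unknown technology {technology!r}; choose from {sorted(PRESETS)}"
        ) from None


def _word_codes(bases_codes: np.ndarray, mask: np.ndarray, w: int):
    """(codes, positions) of every length-w window free of N and masking."""
    n = len(bases_codes) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(bases_codes, w).astype(np.int64)
    ok = ~(win == 4).any(axis=1)
    if mask.any():
        mwin = np.lib.stride_tricks.sliding_window_view(mask, w)
        ok &= ~mwin.any(axis=1)
    pw = 4 ** np.arange(w - 1, -1, -1, dtype=np.int64)
    codes = win @ pw
    pos = np.flatnonzero(ok)
    return codes[pos], pos


def _maximal_run(a: str, b: str, a_pos: int, b_pos: int) -> tuple[int, int, int]:
    """Maximal exact-match run through (a_pos, b_pos); returns (a0, b0, length)."""
    i, j = a_pos, b_pos
    while i > 0 and j > 0 and a[i - 1] == b[j - 1]:
        i -= 1
        j -= 1
    e_i, e_j = a_pos, b_pos
    la, lb = len(a), len(b)
    while e_i < la and e_j < lb and a[e_i] == b[e_j]:
        e_i += 1
        e_j += 1
    return i, j, e_i - i


def _has_unmasked_window(mask_a, mask_b, a0, b0, length, seed_len) -> bool:
    """True if the run holds seed_len consecutive columns unmasked in both."""
    if length < seed_len:
        return False
    comb = mask_a[a0 : a0 + length] | mask_b[b0 : b0 + length]
    run = 0
    for m in comb:
        run = 0 if m else run + 1
        if run >= seed_len:
            return True
    return False


def find_seeds(a: Read, b: Read, seed_len: int) -> list[tuple]:
    """Maximal exact matches >= seed_len between two reads, either strand.

    Masked letters cannot anchor: a run qualifies only if it contains
    seed_len consecutive columns unmasked in both reads.  Returns
    (a_pos, b_pos, length, strand) with b coordinates on the reverse
    complement for strand '-'.
    """
    out = []
    w = min(seed_len, 31)
    codes_a, pos_a = _word_codes(a.codes, a.mask, w)
    order = np.argsort(codes_a, kind="stable")
    codes_a, pos_a = codes_a[order], pos_a[order]
    for strand in "+-":
        if strand == "+":
            b_bases, b_mask = b.bases, b.mask
        else:
            b_bases, b_mask = revcomp(b.bases), b.mask[::-1]
        codes_b, pos_b = _word_codes(encode_bases(b_bases), b_mask, w)
        seen = set()
        lo = np.searchsorted(codes_a, codes_b, side="left")
        hi = np.searchsorted(codes_a, codes_b, side="right")
        for qi in range(len(codes_b)):
            for t in range(lo[qi], hi[qi]):
                ap, bp = int(pos_a[t]), int(pos_b[qi])
                a0, b0, length = _maximal_run(a.bases, b_bases, ap, bp)
                key = (a0, b0, strand)
                if key in seen:
                    continue
                seen.add(key)
                if _has_unmasked_window(a.mask, b_mask, a0, b0, length, seed_len):
                    out.append((a0, b0, length, strand))
    return sorted(out)


def _walk_ops(ops, a: str, b: str, a0: int, b0: int, left: bool):
    """Turn a traceback into (a_cols_consumed, b_cols, matches, diffs).

    ``left=True`` walks leftwards from (a0, b0) exclusive; otherwise
    rightwards from (a0, b0) inclusive.  Diff records are
    (a_pos, a_base, b_base, b_pos) with '-' marking a gap.
    """
    i = j = 0
    matches = 0
    diffs = []
    for op in ops[::-1]:  # kernel returns reversed traceback
        if left:
            ai, bi = a0 - i - 1, b0 - j - 1
        else:
            ai, bi = a0 + i, b0 + j
        if op == 0:
            if a[ai] == b[bi]:
                matches += 1
            else:
                diffs.append((ai, a[ai], b[bi], bi))
            i += 1
            j += 1
        elif op == 1:  # gap in a, consumes b
            gap_pos = ai if not left else ai + 1
            diffs.append((gap_pos, "-", b[bi], bi))
            j += 1
        else:  # gap in b, consumes a
            gap_b = bi if not left else bi + 1
            diffs.append((ai, a[ai], "-", gap_b))
            i += 1
    return i, j, matches, diffs


def extend_seed(a: Read, b: Read, seed: tuple, scores: ScoreSet) -> Alignment | None:
    """Gapped x-drop extension of one seed; None if the overlap fails filters.

    Endpoints are the maximum-score cells of each direction, so the
    overlap never ends on a mismatch or gap.  Coordinates for strand '-'
    refer to the reverse complement of b.
    """
    a_pos, b_pos, length, strand = seed
    b_bases = b.bases if strand == "+" else revcomp(b.bases)
    a_codes = a.codes
    b_codes = encode_bases(b_bases)
    bw = (scores.band - 1) // 2

    ri, rj, _, rops = xdrop_extend_kernel(
        a_codes[a_pos + length :], b_codes[b_pos + length :],
        scores.match, scores.mismatch, scores.gap_open, scores.gap_extend,
        scores.xdrop, bw,
    )
    li, lj, _, lops = xdrop_extend_kernel(
        a_codes[:a_pos][::-1].copy(), b_codes[:b_pos][::-1].copy(),
        scores.match, scores.mismatch, scores.gap_open, scores.gap_extend,
        scores.xdrop, bw,
    )
    la_cols, lb_cols, l_matches, l_diffs = _walk_ops(
        lops[::-1], a.bases, b_bases, a_pos, b_pos, left=True
    )
    ra_cols, rb_cols, r_matches, r_diffs = _walk_ops(
        rops, a.bases, b_bases, a_pos + length, b_pos + length, left=False
    )
    assert la_cols == li and ra_cols == ri and lb_cols == lj and rb_cols == rj

    cols = len(lops) + length + len(rops)
    matches = l_matches + length + r_matches
    identity = matches / cols if cols else 0.0
    if cols < scores.min_overlap or identity < scores.min_identity:
        return None
    return Alignment(
        id_a=a.id, id_b=b.id, strand=strand,
        a_start=a_pos - la_cols, a_end=a_pos + length + ra_cols,
        b_start=b_pos - lb_cols, b_end=b_pos + length + rb_cols,
        differences=sorted(l_diffs) + r_diffs,
        identity=identity, aligned_cols=cols,
    )


def best_seed(seeds: list[tuple]) -> tuple | None:
    """Extension anchor choice: longest seed, then leftmost in read a."""
    if not seeds:
        return None
    return max(seeds, key=lambda s: (s[2], -s[0], -s[1]))


def align_pair(a: Read, b: Read, scores: ScoreSet) -> Alignment | None:
    """Seed-and-extend one read pair (convenience for tests and step 3)."""
    seed = best_seed(find_seeds(a, b, scores.seed_len))
    if seed is None:
        return None
    return extend_seed(a, b, seed, scores)


def all_overlaps(new_set: list[Read], prior: list[Read], scores: ScoreSet) -> list[Alignment]:
    """Every qualifying overlap of new reads vs (prior ∪ earlier-new) reads.

    Each pair is reported once; within-set pairs of the new set are
    included so a single-set run can overlap with itself.  Read a of each
    alignment is the later-arriving read.
    """
    reads_all = list(prior) + list(new_set)
    n_prior = len(prior)
    w = min(scores.seed_len, 31)

    codes_parts, read_parts, pos_parts = [], [], []
    for idx, r in enumerate(reads_all):
        c, p = _word_codes(r.codes, r.mask, w)
        codes_parts.append(c)
        read_parts.append(np.full(len(c), idx, dtype=np.int64))
        pos_parts.append(p)
    if not codes_parts:
        return []
    idx_codes = np.concatenate(codes_parts)
    idx_read = np.concatenate(read_parts)
    idx_pos = np.concatenate(pos_parts)
    order = np.argsort(idx_codes, kind="stable")
    idx_codes, idx_read, idx_pos = idx_codes[order], idx_read[order], idx_pos[order]

    cand = {}  # (q_idx, i_idx, strand) -> {diag: (count, min_qpos)}
    for qi_local, q in enumerate(new_set):
        q_idx = n_prior + qi_local
        for strand in "+-":
            if strand == "+":
                qb, qm = q.bases, q.mask
            else:
                qb, qm = revcomp(q.bases), q.mask[::-1]
            qc, qp = _word_codes(encode_bases(qb), qm, w)
            if not len(qc):
                continue
            lo = np.searchsorted(idx_codes, qc, side="left")
            hi = np.searchsorted(idx_codes, qc, side="right")
            nh = hi - lo
            have = np.flatnonzero(nh)
            if not len(have):
                continue
            hit_q = np.repeat(qp[have], nh[have])
            hit_t = np.concatenate([np.arange(lo[t], hi[t]) for t in have])
            hit_read = idx_read[hit_t]
            hit_pos = idx_pos[hit_t]
            keep = hit_read < q_idx  # each unordered pair reported once
            hit_q, hit_read, hit_pos = hit_q[keep], hit_read[keep], hit_pos[keep]
            diag = hit_q - hit_pos
            for rd, dg, qpos in zip(hit_read.tolist(), diag.tolist(), hit_q.tolist()):
                key = (q_idx, rd, strand)
                dd = cand.setdefault(key, {})
                cnt, mn = dd.get(dg, (0, qpos))
                dd[dg] = (cnt + 1, min(mn, qpos))

    out = []
    done_pairs = set()
    for (q_idx, i_idx, strand), diags in sorted(cand.items()):
        pair = (q_idx, i_idx)
        if pair in done_pairs:
            continue
        q = reads_all[q_idx]
        t = reads_all[i_idx]
        t_bases = t.bases if strand == "+" else None
        # evaluate each diagonal's maximal run; keep longest valid seed
        seeds = []
        if strand == "+":
            tb, tm = t.bases, t.mask
        else:
            tb, tm = revcomp(t.bases), t.mask[::-1]
        for dg, (_, qpos) in diags.items():
            ipos = qpos - dg
            if strand == "+":
                qp_f, tp = qpos, ipos
            else:
                # hits were found on q's reverse complement vs t's forward
                # strand; re-express as q-forward vs t-reverse-complement
                qp_f = len(q) - w - qpos
                tp = len(t) - w - ipos
            a0, b0, length = _maximal_run(q.bases, tb, qp_f, tp)
            if _has_unmasked_window(q.mask, tm, a0, b0, length, scores.seed_len):
                seeds.append((a0, b0, length, strand))
        seed = best_seed(seeds)
        if seed is None:
            continue
        aln = extend_seed(q, t, seed, scores)
        if aln is not None:
            done_pairs.add(pair)
            out.append(aln)
    return out
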