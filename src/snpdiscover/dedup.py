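"""Collapse exact duplicate reads (PCR/optical clones) within one set.

Clones of the same fragment inflate apparent coverage and can fabricate
allele support, so each group of reads with identical base strings is
replaced by its first-encountered representative before masking.  An MD5
checksum serves as a prefilter; the full base strings are compared before
any collapse so hash collisions cannot merge distinct reads.
"""

from __future__ import annotations

import hashlib

from snpdiscover.records import Read

__all__ = ["collapse_duplicates"]


def collapse_duplicates(reads: list[Read]) -> tuple[list[Read], int, list[str]]:
    """Return (surviving reads in input order, #removed, removed ids).

    Duplicates are detected on the forward strand only — PCR and optical
    duplicates share orientation — and the representative keeps its own
    quality string.
    """
    by_digest: dict[bytes, list[Read]] = {}
    kept: list[Read] = []
    removed: list[str] = []
    for r in reads:
        digest = hashlib.md5(r.bases.encode("ascii")).digest()
        bucket = by_digest.setdefault(digest, [])
        if any(prev.bases == r.bases for prev in bucket):
            removed.append(r.id)
            continue
        bucket.append(r)
        kept.append(r)
    return kept, len(removed), removed
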