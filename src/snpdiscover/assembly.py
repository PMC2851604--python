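"""Layout-consensus micro-assembly of one cluster's reads.

Clusters are tiny — at most the pile-up cap's worth of reads from a
single locus — so a full assembler is unnecessary: members are laid out
against the seed read's forward strand using their overlap offsets and
the contig is the per-column quality-weighted majority base.  External
assemblies can be imported instead through the ACE reader in
:mod:`snpdiscover.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from snpdiscover.records import Alignment, Read, revcomp

__all__ = ["MicroAssembly", "AssemblyError", "micro_assemble", "build_from_layout"]

MAX_OFFSET_CONFLICT = 5


class AssemblyError(ValueError):
    pass


@dataclass
class MicroAssembly:
    """A contig plus the read layout and per-column support behind it.

    ``placements`` holds (read_id, contig_offset, strand); strand is the
    placement orientation relative to the contig.  ``column_support`` has
    one entry per contig column: a list of (base, quality, read_id) for
    every read overlapping that column, on the contig strand.
    """

    contig: str
    placements: list = field(default_factory=list)
    column_support: list = field(default_factory=list)

    def coverage(self) -> np.ndarray:
        return np.array([len(c) for c in self.column_support])


def _consensus(column: list) -> str:
    """Quality-weighted majority base; alphabetical tie-break; N excluded."""
    weights: dict[str, int] = {}
    for base, qual, _ in column:
        if base in "ACGT":
            weights[base] = weights.get(base, 0) + int(qual)
    if not weights:
        return "N"
    return min(weights, key=lambda b: (-weights[b], b))


def build_from_layout(contig: str | None, reads: list[Read], layout: list) -> MicroAssembly:
    """Assemble column support from explicit placements.

    ``layout`` is (read_id, offset, strand) with offsets on the contig;
    when ``contig`` is None the consensus is computed from the columns.
    Leading/trailing uncovered columns are trimmed.
    """
    by_id = {r.id: r for r in reads}
    ends = []
    for read_id, off, _ in layout:
        if read_id not in by_id:
            raise AssemblyError(f"placement references unknown read {read_id!r}")
        ends.append(off + len(by_id[read_id]))
    if not layout:
        raise AssemblyError("empty layout")
    lo = min(off for _, off, _ in layout)
    hi = max(ends)
    if contig is not None and (lo < 0 or hi > len(contig)):
        raise AssemblyError("read placed outside contig coordinates")
    n_cols = (len(contig) if contig is not None else hi - lo)
    shift = 0 if contig is not None else -lo
    columns: list[list] = [[] for _ in range(n_cols)]
    placements = []
    for read_id, off, strand in layout:
        r = by_id[read_id]
        bases = r.bases if strand == "+" else revcomp(r.bases)
        quals = r.quals if strand == "+" else r.quals[::-1]
        start = off + shift
        placements.append((read_id, start, strand))
        for k, b in enumerate(bases):
            columns[start + k].append((b, int(quals[k]), read_id))
    if contig is None:
        contig = "".join(_consensus(c) for c in columns)
    # trim uncovered flanks
    covered = [i for i, c in enumerate(columns) if c]
    if not covered:
        raise AssemblyError("no covered columns")
    a, b = covered[0], covered[-1] + 1
    contig = contig[a:b]
    columns = columns[a:b]
    placements = [(rid, off - a, s) for rid, off, s in placements]
    return MicroAssembly(contig=contig, placements=placements, column_support=columns)


def micro_assemble(reads: list[Read], anchors: list[Alignment]) -> MicroAssembly:
    """Assemble one cluster from its seed-frame overlap alignments.

    Every anchor must have the cluster's seed read as ``id_a``; member
    offsets follow from (a_start − b_start) in the seed frame, members on
    strand '-' are placed reverse-complemented.  A member whose repeated
    anchors disagree on its offset by more than 5 bp aborts the assembly
    (the cluster is skipped upstream).
    """
    if not anchors:
        if len(reads) != 1:
            raise AssemblyError("need anchors for multi-read clusters")
        return build_from_layout(None, reads, [(reads[0].id, 0, "+")])
    seed_ids = {a.id_a for a in anchors}
    if len(seed_ids) != 1:
        raise AssemblyError(f"anchors name several seeds: {sorted(seed_ids)}")
    seed_id = seed_ids.pop()
    offsets: dict[str, tuple[int, str]] = {seed_id: (0, "+")}
    for aln in anchors:
        off = aln.a_start - aln.b_start
        prev = offsets.get(aln.id_b)
        if prev is not None:
            if abs(prev[0] - off) > MAX_OFFSET_CONFLICT or prev[1] != aln.strand:
                raise AssemblyError(
                    f"conflicting placements for read {aln.id_b!r}: "
                    f"{prev} vs ({off}, {aln.strand!r})"
                )
            continue
        offsets[aln.id_b] = (off, aln.strand)
    layout = [(rid, off, strand) for rid, (off, strand) in offsets.items()]
    used = {r.id for r in reads} & set(offsets)
    layout = [pl for pl in layout if pl[0] in used]
    reads = [r for r in reads if r.id in used]
    return build_from_layout(None, reads, layout)
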