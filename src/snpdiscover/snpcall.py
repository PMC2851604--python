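"""SNP determination: cluster filtering, disjoint selection, repeat
exclusion, allele calling on micro-assemblies, and genotypability filters.

The guiding principle is conservatism at low coverage: each allele must
be seen in at least two reads of quality >= 20, clusters that look like
collapsed repeats (too many members, too many differences, differences
too close together) are discarded wholesale, and a read may support at
most one emitted SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from snpdiscover.assembly import MicroAssembly
from snpdiscover.clusters import Cluster, ClusterStore
from snpdiscover.overlap import align_pair
from snpdiscover.records import Read, ScoreSet

__all__ = [
    "SNPCall",
    "filter_clusters",
    "order_clusters",
    "select_disjoint",
    "exclude_repeat_adjacent",
    "call_alleles",
    "final_filters",
]

MIN_ALLELE_SUPPORT = 2
MAX_SUBSTITUTION_DIFFS = 3
MIN_DIFF_SPACING = 50
MIN_SITE_QUALITY = 20
HOMOPOLYMER_WINDOW = 13
MAX_HOMOPOLYMER = 4
FLANK_BY_TECH = {"long_454": 50, "short_illumina": 40}


@dataclass
class SNPCall:
    """An emitted SNP: contig context, alleles, quality-filtered support."""

    contig: str
    position: int
    allele_1: str
    allele_2: str
    support_1: int
    support_2: int
    individuals: dict = field(default_factory=dict)
    flank_left: int = 0
    flank_right: int = 0
    source_cluster: str = ""

    def __post_init__(self) -> None:
        if self.support_1 < MIN_ALLELE_SUPPORT or self.support_2 < MIN_ALLELE_SUPPORT:
            raise ValueError("each allele needs support from at least two reads")
        if self.allele_1 == self.allele_2 or {self.allele_1, self.allele_2} - set("ACGT"):
            raise ValueError("alleles must be two distinct bases in ACGT")


def _allele_support(cl: Cluster) -> dict[int, dict[str, int]]:
    """Per substitution position: read support per base, in seed frame.

    The seed allele's support at a position counts the seed itself plus
    every member whose alignment spans the position without a difference
    there.
    """
    positions: dict[int, dict[str, int]] = {}
    sub_diffs: dict[int, list] = {}
    for member_id, aln in cl.members:
        for d in aln.differences:
            if d[1] != "-" and d[2] != "-":
                sub_diffs.setdefault(d[0], []).append((member_id, d))
    for pos, hits in sub_diffs.items():
        support: dict[str, int] = {}
        seed_base = hits[0][1][1]
        support[seed_base] = 1  # the seed read itself
        for member_id, aln in cl.members:
            diff_here = next((d for d in aln.differences if d[0] == pos), None)
            if diff_here is not None:
                if diff_here[1] != "-" and diff_here[2] != "-":
                    b = diff_here[2]
                    support[b] = support.get(b, 0) + 1
            elif aln.a_start <= pos < aln.a_end:
                support[seed_base] = support.get(seed_base, 0) + 1
        positions[pos] = support
    return positions


def _qualifying_positions(support: dict[int, dict[str, int]]) -> list[int]:
    """Positions where the seed allele and one alternative each have >= 2 reads."""
    out = []
    for pos, sup in support.items():
        bases = sorted(sup, key=lambda b: -sup[b])
        if len(bases) >= 2 and sup[bases[0]] >= MIN_ALLELE_SUPPORT and sup[bases[1]] >= MIN_ALLELE_SUPPORT:
            out.append(pos)
    return sorted(out)


def filter_clusters(store: ClusterStore, multi_individual: bool = False) -> list[Cluster]:
    """Step 1: keep clusters with a credibly biallelic substitution.

    Requires at least one substitution position with two reads per
    allele; drops candidate repeats, clusters with more than 3
    substitution difference positions, and clusters where two qualifying
    positions lie within 50 bp of each other (in seed coordinates).
    With ``multi_individual``, at least two reads from each of at least
    two individuals are additionally required.
    """
    kept = []
    for cl in store.clusters.values():
        if cl.candidate_repeat or not cl.members:
            continue
        support = _allele_support(cl)
        if len(support) > MAX_SUBSTITUTION_DIFFS:
            continue
        qual_pos = _qualifying_positions(support)
        if not qual_pos:
            continue
        if any(b - a < MIN_DIFF_SPACING for a, b in zip(qual_pos, qual_pos[1:])):
            continue
        if multi_individual:
            counts: dict[str, int] = {}
            for rid in cl.read_ids():
                ind = store.read_individual.get(rid, "?")
                counts[ind] = counts.get(ind, 0) + 1
            if sum(1 for v in counts.values() if v >= 2) < 2:
                continue
        kept.append(cl)
    return kept


def order_clusters(clusters: list[Cluster]) -> list[Cluster]:
    """Deterministic processing order: best-supported first, then seed id."""

    def key(cl: Cluster):
        support = _allele_support(cl)
        best = 0
        for pos in _qualifying_positions(support):
            sup = sorted(support[pos].values(), reverse=True)
            best = max(best, sup[0] + sup[1])
        return (-best, cl.seed_id)

    return sorted(clusters, key=key)


def select_disjoint(clusters: list[Cluster]) -> list[Cluster]:
    """Step 2: greedy selection so each read supports at most one call."""
    used: set[str] = set()
    out = []
    for cl in clusters:
        ids = cl.read_ids()
        if ids & used:
            continue
        used |= ids
        out.append(cl)
    return out


def exclude_repeat_adjacent(
    selected: list[Cluster],
    fully_masked_reads: list[Read],
    repeat_cluster_ids: set,
    scores: ScoreSet,
    reads_by_id: dict[str, Read],
) -> list[Cluster]:
    """Step 3: drop repeat-adjacent clusters and excise repeat-seed members.

    A cluster is dropped when any of its reads aligns (same score set,
    masks ignored for this check) to a completely masked read.  Members
    whose own clusters are candidate repeats are removed from the
    remaining clusters; clusters that thereby lose two-per-allele support
    are dropped as well.
    """
    bare_masked = [
        Read(id=f"_bare_{r.id}", bases=r.bases, quals=r.quals) for r in fully_masked_reads
    ]
    aligns_to_repeat: dict[str, bool] = {}

    def hits_masked(read_id: str) -> bool:
        if read_id in aligns_to_repeat:
            return aligns_to_repeat[read_id]
        r = reads_by_id[read_id]
        bare = Read(id="_q", bases=r.bases, quals=r.quals)
        hit = any(align_pair(bare, m, scores) is not None for m in bare_masked)
        aligns_to_repeat[read_id] = hit
        return hit

    out = []
    for cl in selected:
        if bare_masked and any(hits_masked(rid) for rid in cl.read_ids()):
            continue
        trimmed = [
            (mid, aln) for mid, aln in cl.members if mid not in repeat_cluster_ids
        ]
        if len(trimmed) != len(cl.members):
            cl = Cluster(seed_id=cl.seed_id, members=trimmed)
            cl.recount()
            support = _allele_support(cl)
            if not _qualifying_positions(support):
                continue
        out.append(cl)
    return out


def call_alleles(assembly: MicroAssembly, min_qual: int = MIN_SITE_QUALITY) -> list[tuple]:
    """Step 5: columns showing exactly two alleles with >= 2 reads each.

    Reads with base quality below ``min_qual`` at the column are not
    counted (low-confidence observations cannot establish an allele).
    Columns where three or more bases reach support two are rejected as
    inconsistent with the biallelic assumption, and N never supports an
    allele.  Returns (position, allele_1, allele_2, support_1, support_2,
    reads_1, reads_2).
    """
    out = []
    for pos, column in enumerate(assembly.column_support):
        support: dict[str, list[str]] = {}
        for base, qual, read_id in column:
            if base in "ACGT" and qual >= min_qual:
                support.setdefault(base, []).append(read_id)
        strong = {b: ids for b, ids in support.items() if len(ids) >= MIN_ALLELE_SUPPORT}
        if len(strong) != 2:
            continue
        (b1, ids1), (b2, ids2) = sorted(
            strong.items(), key=lambda kv: (-len(kv[1]), kv[0])
        )
        out.append((pos, b1, b2, len(ids1), len(ids2), ids1, ids2))
    return out


def _homopolymer_run(contig: str, pos: int, base: str) -> int:
    """Length of the run of ``base`` through ``pos`` inside the 13-bp window."""
    half = HOMOPOLYMER_WINDOW // 2
    lo = max(0, pos - half)
    hi = min(len(contig), pos + half + 1)
    run = 1
    i = pos - 1
    while i >= lo and contig[i] == base:
        run += 1
        i -= 1
    i = pos + 1
    while i < hi and contig[i] == base:
        run += 1
        i += 1
    return run


def final_filters(
    candidates: list[tuple],
    contig: str,
    technology: str,
    source_cluster: str = "",
    read_individual: dict[str, str] | None = None,
) -> list[SNPCall]:
    """Step 6 filters (a)-(d) on one micro-assembled contig.

    (a) exactly one candidate in the contig; (b) flanks of at least
    50 bp (454) or 40 bp (Illumina) on both sides; (d) neither allele
    sits in a homopolymer longer than 4 bp within the 13-bp window
    centred on the SNP.  Filter (c), the quality threshold, is applied
    upstream in :func:`call_alleles`.
    """
    min_flank = FLANK_BY_TECH[technology]
    if len(candidates) != 1:
        return []
    pos, b1, b2, s1, s2, ids1, ids2 = candidates[0]
    flank_left = pos
    flank_right = len(contig) - pos - 1
    if flank_left < min_flank or flank_right < min_flank:
        return []
    if any(_homopolymer_run(contig, pos, b) > MAX_HOMOPOLYMER for b in (b1, b2)):
        return []
    individuals = {}
    if read_individual:
        individuals = {
            b1: {read_individual.get(r, "?") for r in ids1},
            b2: {read_individual.get(r, "?") for r in ids2},
        }
    return [
        SNPCall(
            contig=contig, position=pos, allele_1=b1, allele_2=b2,
            support_1=s1, support_2=s2, individuals=individuals,
            flank_left=flank_left, flank_right=flank_right,
            source_cluster=source_cluster,
        )
    ]
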