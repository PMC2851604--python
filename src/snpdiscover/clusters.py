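"""Cumulative per-read cluster store with pile-up and difference caps.

Every read seeds one cluster; an accepted overlap grows the clusters of
both reads involved.  A cluster whose member count exceeds the
Poisson-derived pile-up cap (C_threshold, the 99.5th percentile of the
coverage distribution at the current cumulative coverage) or whose count
of distinct difference positions exceeds D_threshold is marked a
candidate repeat and frozen — its read is almost certainly repetitive and
any "SNP" in it would be a paralogous difference.  The seed read of a
frozen cluster may still join other clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from snpdiscover.records import Alignment, Read
from snpdiscover.theory import c_threshold as _poisson_cap
from snpdiscover.theory import coverage_lambda

__all__ = ["Cluster", "RepeatThresholds", "ClusterStore", "add_alignment", "coverage_lambda", "c_threshold"]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}


def c_threshold(lam: float) -> int:
    """Pile-up cap: smallest c with Poisson-CDF(c; λ) >= 0.995."""
    return _poisson_cap(lam)


@dataclass
class RepeatThresholds:
    """Caps that decide when a cluster becomes a candidate repeat."""

    expected_genome_length: int
    D_threshold: int = 10
    transcriptome_mode: bool = False

    def __post_init__(self) -> None:
        if self.expected_genome_length <= 0:
            raise ValueError("expected genome length must be positive")
        if self.D_threshold < 1:
            raise ValueError("D_threshold must be >= 1")


@dataclass
class Cluster:
    """One seed read plus the reads aligning to it.

    ``members`` holds (member_id, alignment-in-seed-frame): a_* fields and
    difference a-positions of the stored alignment always refer to the
    seed read's forward strand.
    """

    seed_id: str
    members: list = field(default_factory=list)
    candidate_repeat: bool = False
    frozen: bool = False
    diff_positions: set = field(default_factory=set)

    @property
    def diff_count(self) -> int:
        return len(self.diff_positions)

    def member_ids(self) -> set:
        return {m for m, _ in self.members}

    def read_ids(self) -> set:
        return self.member_ids() | {self.seed_id}

    def recount(self) -> None:
        self.diff_positions = {
            d[0] for _, aln in self.members for d in aln.differences
        }


class StoreError(KeyError):
    pass


class ClusterStore:
    """Cluster collection, cumulative over sequencing increments."""

    def __init__(self, thresholds: RepeatThresholds):
        self.thresholds = thresholds
        self.clusters: dict[str, Cluster] = {}
        self.read_len: dict[str, int] = {}
        self.read_individual: dict[str, str] = {}
        self.total_bases = 0
        self._cap: int | None = None

    # -- increments ---------------------------------------------------------
    def register_reads(self, reads: list[Read]) -> None:
        """Open one (initially empty) cluster per new read and update λ."""
        for r in reads:
            if r.id in self.clusters:
                raise StoreError(f"read id {r.id!r} already registered")
            self.clusters[r.id] = Cluster(seed_id=r.id)
            self.read_len[r.id] = len(r)
            self.read_individual[r.id] = r.individual_id
            self.total_bases += len(r)
        self._cap = None

    @property
    def lam(self) -> float:
        return coverage_lambda(self.total_bases, self.thresholds.expected_genome_length)

    @property
    def C_threshold(self) -> int:
        """Pile-up cap at the current cumulative coverage (recomputed lazily)."""
        if self._cap is None:
            self._cap = c_threshold(self.lam)
        return self._cap

    # -- alignment insertion ------------------------------------------------
    def add_alignment(self, aln: Alignment) -> None:
        """Grow the clusters of both reads by one member each (unless frozen)."""
        if aln.id_a not in self.clusters or aln.id_b not in self.clusters:
            missing = aln.id_a if aln.id_a not in self.clusters else aln.id_b
            raise StoreError(f"alignment references unknown read {missing!r}")
        self._insert(self.clusters[aln.id_a], aln.id_b, aln)
        self._insert(self.clusters[aln.id_b], aln.id_a, self._project_onto_b(aln))

    def _insert(self, cl: Cluster, member_id: str, aln: Alignment) -> None:
        if cl.frozen:
            return
        cl.members.append((member_id, aln))
        cl.diff_positions.update(d[0] for d in aln.differences)
        over_members = (
            not self.thresholds.transcriptome_mode
            and len(cl.members) > self.C_threshold
        )
        if over_members or cl.diff_count > self.thresholds.D_threshold:
            cl.candidate_repeat = True
            cl.frozen = True

    def _project_onto_b(self, aln: Alignment) -> Alignment:
        """Re-express an alignment in read b's forward-strand frame."""
        len_b = self.read_len[aln.id_b]
        len_a = self.read_len[aln.id_a]
        if aln.strand == "+":
            diffs = [(bp, bb, ab, ap) for (ap, ab, bb, bp) in aln.differences]
            b_start, b_end = aln.b_start, aln.b_end
            m_start, m_end = aln.a_start, aln.a_end
        else:
            # seed-frame coords flip to b's forward strand; the member's own
            # coords flip to ITS reverse-complement frame (strand stays '-')
            diffs = [
                (len_b - 1 - bp, _COMP[bb], _COMP[ab], len_a - 1 - ap)
                for (ap, ab, bb, bp) in aln.differences
            ]
            b_start, b_end = len_b - aln.b_end, len_b - aln.b_start
            m_start, m_end = len_a - aln.a_end, len_a - aln.a_start
        diffs.sort()
        # clamp gap records that project onto the interval boundary
        diffs = [
            (min(max(p, b_start), b_end - 1), sb, ob, op)
            for (p, sb, ob, op) in diffs
        ]
        return Alignment(
            id_a=aln.id_b, id_b=aln.id_a, strand=aln.strand,
            a_start=b_start, a_end=b_end,
            b_start=m_start, b_end=m_end,
            differences=diffs, identity=aln.identity,
            aligned_cols=aln.aligned_cols,
        )

    # -- views --------------------------------------------------------------
    def candidate_repeat_ids(self) -> set:
        return {c.seed_id for c in self.clusters.values() if c.candidate_repeat}


def add_alignment(store: ClusterStore, alignment: Alignment,
                  thresholds: RepeatThresholds | None = None,
                  transcriptome_mode: bool | None = None) -> ClusterStore:
    """Functional wrapper over :meth:`ClusterStore.add_alignment`."""
    if transcriptome_mode is not None:
        store.thresholds.transcriptome_mode = transcriptome_mode
    store.add_alignment(alignment)
    return store
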