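"""Incremental pipeline orchestration: add-set → mask → overlap → call.

SNPs are (re)determined every time a sequencing increment is added, so a
project can stop sequencing as soon as the cumulative call count meets
its genotyping-array budget.  All thresholds actually used — K, the
masker cutoffs, C_threshold, D_threshold and the score set — are
recorded per set for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

from snpdiscover import dedup as dedup_mod
from snpdiscover import masker
from snpdiscover.assembly import AssemblyError, micro_assemble
from snpdiscover.clusters import ClusterStore, RepeatThresholds
from snpdiscover.overlap import all_overlaps, preset_scores
from snpdiscover.records import Read, ScoreSet
from snpdiscover.snpcall import (
    call_alleles,
    exclude_repeat_adjacent,
    filter_clusters,
    final_filters,
    order_clusters,
    select_disjoint,
)

__all__ = ["RunConfig", "SetReport", "Pipeline"]

MIN_UNMASKED_BP = 40  # reads below this unmasked length count as fully masked


@dataclass
class RunConfig:
    """Run-wide settings; defaults follow the pipeline's standard values."""

    technology: str = "long_454"
    expected_genome_length: int = 1_000_000
    D_threshold: int = 10
    transcriptome_mode: bool = False
    multi_individual: bool = False
    scores: ScoreSet | None = None

    def __post_init__(self) -> None:
        if self.expected_genome_length <= 0:
            raise ValueError("expected genome length must be positive")
        if self.scores is None:
            self.scores = preset_scores(self.technology)


@dataclass
class SetReport:
    """Result of one add-set increment."""

    set_id: int
    duplicates_removed: int
    cutoffs: object
    c_threshold: int
    lam: float
    calls: list = field(default_factory=list)
    candidates: list = field(default_factory=list)  # (seed_id, assembly, cand list)
    skipped_assemblies: list = field(default_factory=list)


class Pipeline:
    """Cumulative state of one discovery run."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.store = ClusterStore(
            RepeatThresholds(
                expected_genome_length=config.expected_genome_length,
                D_threshold=config.D_threshold,
                transcriptome_mode=config.transcriptome_mode,
            )
        )
        self.reads_by_id: dict[str, Read] = {}
        self.fully_masked: list[Read] = []
        self.reports: list[SetReport] = []
        self._digests: set[bytes] = set()  # bases seen in earlier sets

    # ------------------------------------------------------------------
    def add_set(self, reads: list[Read]) -> SetReport:
        """Run one increment end to end and return the cumulative report."""
        import hashlib

        set_id = len(self.reports)
        unique, n_dup, _ = dedup_mod.collapse_duplicates(reads)
        # clones can straddle set boundaries (a re-run library); drop reads
        # whose bases were already seen so support never comes from copies
        fresh = []
        for r in unique:
            d = hashlib.md5(r.bases.encode("ascii")).digest()
            if d in self._digests:
                n_dup += 1
            else:
                self._digests.add(d)
                fresh.append(r)
        unique = fresh
        if not unique:
            report = SetReport(set_id=set_id, duplicates_removed=n_dup,
                               cutoffs=None, c_threshold=self.store.C_threshold,
                               lam=self.store.lam)
            if self.reports:
                prev = self.reports[-1]
                report.calls = prev.calls
                report.candidates = prev.candidates
            self.reports.append(report)
            return report
        cutoffs, fully_ids = masker.mask_set(unique)
        fully_set = set(fully_ids)
        for r in unique:
            if len(r) - int(r.mask.sum()) < MIN_UNMASKED_BP and r.id not in fully_set:
                fully_set.add(r.id)
                r.fully_masked = True
        self.fully_masked.extend(r for r in unique if r.id in fully_set)

        prior = [
            r for r in self.reads_by_id.values() if not r.fully_masked
        ]
        self.store.register_reads(unique)
        for r in unique:
            self.reads_by_id[r.id] = r

        alignable = [r for r in unique if r.id not in fully_set]
        for aln in all_overlaps(alignable, prior, self.config.scores):
            self.store.add_alignment(aln)

        report = SetReport(
            set_id=set_id,
            duplicates_removed=n_dup,
            cutoffs=cutoffs,
            c_threshold=self.store.C_threshold,
            lam=self.store.lam,
        )
        self._determine_snps(report)
        self.reports.append(report)
        return report

    # ------------------------------------------------------------------
    def _determine_snps(self, report: SetReport) -> None:
        kept = filter_clusters(self.store, self.config.multi_individual)
        selected = select_disjoint(order_clusters(kept))
        selected = exclude_repeat_adjacent(
            selected,
            self.fully_masked,
            self.store.candidate_repeat_ids(),
            self.config.scores,
            self.reads_by_id,
        )
        for cl in selected:
            cluster_reads = [self.reads_by_id[i] for i in cl.read_ids()
                             if i in self.reads_by_id]
            anchors = [aln for _, aln in cl.members]
            try:
                asm = micro_assemble(cluster_reads, anchors)
            except AssemblyError as exc:
                report.skipped_assemblies.append((cl.seed_id, str(exc)))
                continue
            cands = call_alleles(asm)
            report.candidates.append((cl.seed_id, asm, cands))
            report.calls.extend(
                final_filters(
                    cands, asm.contig, self.config.technology,
                    source_cluster=cl.seed_id,
                    read_individual=self.store.read_individual,
                )
            )

    # ------------------------------------------------------------------
    def candidate_sites(self):
        """Pre-final-filter candidates of the latest increment.

        Yields lightweight (contig, position) records usable wherever a
        SNP call's sequence context is needed (e.g. truth matching).
        """
        if not self.reports:
            return []
        out = []
        for _, asm, cands in self.reports[-1].candidates:
            for c in cands:
                out.append(SimpleNamespace(contig=asm.contig, position=c[0]))
        return out


def write_report(calls, path) -> None:
    """Tab-separated SNP report: contig, offset, alleles, supports, individuals."""
    with open(path, "w") as fh:
        fh.write("contig\tposition\tallele_1\tallele_2\tsupport_1\tsupport_2\t"
                 "individuals_1\tindividuals_2\tsource_cluster\n")
        for c in calls:
            ind1 = ",".join(sorted(c.individuals.get(c.allele_1, set()))) or "-"
            ind2 = ",".join(sorted(c.individuals.get(c.allele_2, set()))) or "-"
            fh.write(
                f"{c.contig}\t{c.position}\t{c.allele_1}\t{c.allele_2}\t"
                f"{c.support_1}\t{c.support_2}\t{ind1}\t{ind2}\t{c.source_cluster}\n"
            )
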