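"""Synthetic genomes and read sets with the structure the pipeline assumes.

The generator emulates exactly what the detection model describes:
a diploid genome with planted heterozygous sites, optional low-copy
segmental duplications whose copies differ at a stated density, optional
high-copy interspersed repeats, reads dropped uniformly and independently
(so per-base coverage is Poisson), independent per-base substitution
errors, and PCR duplicates.  Base qualities are calibrated: correctly
called bases get Phred 40, miscalled bases get low qualities (below the
caller's quality threshold by default), with an optional fraction of
high-quality miscalls to exercise the quality filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from snpdiscover.records import Read, revcomp

__all__ = ["SimConfig", "Truth", "simulate_genome", "sample_reads",
           "sample_read_sets", "classify_call"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    ``dup_classes`` lists (t, total_length, divergence): t copies of a
    segment of ``total_length`` distinct bp, copies differing at the given
    per-bp density (star topology: each difference hits one copy).
    ``het_min_spacing`` keeps planted sites separated so that one cluster
    sees at most one SNP, matching the model's sparse-SNP assumption.
    """

    genome_length: int = 1_000_000
    het_density: float = 1e-3
    dup_classes: list = field(default_factory=list)
    interspersed_repeat: tuple | None = None  # (unit_length, copy_count)
    coverage: float = 1.0
    read_length: int = 200
    error_rate: float = 0.0
    pcr_dup_rate: float = 0.0
    seed: int = 0
    num_individuals: int = 1
    technology: str = "long_454"
    het_min_spacing: int = 0
    correct_quality: int = 40
    error_qual_low: tuple = (5, 19)   # inclusive range for miscall qualities
    error_qual_high_frac: float = 0.0  # fraction of miscalls at Phred >= 20

    def __post_init__(self) -> None:
        for rate in (self.het_density, self.error_rate, self.pcr_dup_rate,
                     self.error_qual_high_frac):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.genome_length < 10 * self.read_length:
            raise ValueError("genome must be at least 10 read lengths long")


@dataclass
class Truth:
    """Planted ground truth for one simulated genome."""

    reference: str
    haplotypes: list  # 2 * num_individuals strings
    het_positions: list  # (position, (allele_hap_even, allele_hap_odd), individual)
    dup_diff_positions: set  # genomic positions that are inter-copy differences
    dup_regions: list  # (start, end) of every placed duplication copy

    def het_sites(self) -> set:
        return {p for p, _, _ in self.het_positions}


def _random_dna(rng, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)].copy()


def _mutate(rng, base: int) -> int:
    choices = _BASES[_BASES != base]
    return int(rng.choice(choices))


def simulate_genome(config: SimConfig) -> Truth:
    """Build the reference, place duplications/repeats, plant het sites."""
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    genome = _random_dna(rng, L)

    # reserve non-overlapping intervals for duplication copies and repeats
    blocks = []  # (length, payload) to place
    dup_payloads = []
    total_reserved = 0
    for (t, seg_len, divergence) in config.dup_classes:
        source = _random_dna(rng, seg_len)
        n_diffs = rng.binomial(seg_len, divergence)
        diff_pos = rng.choice(seg_len, size=n_diffs, replace=False)
        copies = [source.copy() for _ in range(t)]
        diff_cols = []
        for p in diff_pos:
            hit = rng.integers(0, t)
            copies[hit][p] = _mutate(rng, copies[hit][p])
            diff_cols.append(int(p))
        dup_payloads.append((copies, diff_cols))
        total_reserved += t * seg_len
    if config.interspersed_repeat is not None:
        unit_len, n_copies = config.interspersed_repeat
        unit = _random_dna(rng, unit_len)
        total_reserved += unit_len * n_copies
    else:
        unit, n_copies, unit_len = None, 0, 0
    if total_reserved > L // 2:
        raise ValueError("duplications and repeats exceed half the genome")

    for (copies, diff_cols) in dup_payloads:
        for copy_seq in copies:
            blocks.append((copy_seq, diff_cols))
    for _ in range(n_copies):
        blocks.append((unit, None))

    taken: list[tuple[int, int]] = []
    dup_diff_positions: set[int] = set()
    dup_regions: list[tuple[int, int]] = []

    def place(length: int) -> int:
        for _ in range(1000):
            s = int(rng.integers(0, L - length))
            if all(e <= s or s + length <= b for b, e in taken):
                taken.append((s, s + length))
                return s
        raise ValueError("could not place duplication/repeat blocks; genome too full")

    for seq, diff_cols in blocks:
        s = place(len(seq))
        genome[s : s + len(seq)] = seq
        dup_regions.append((s, s + len(seq)))
        if diff_cols is not None:
            dup_diff_positions.update(s + p for p in diff_cols)

    reference = genome.tobytes().decode("ascii")

    # plant heterozygous sites outside duplicated/repeat sequence
    in_block = np.zeros(L, dtype=bool)
    for b, e in taken:
        in_block[b:e] = True
    candidates = np.flatnonzero(~in_block)
    n_het = rng.binomial(len(candidates), config.het_density)
    chosen = np.sort(rng.choice(candidates, size=n_het, replace=False))
    if config.het_min_spacing > 1 and len(chosen):
        spaced = [int(chosen[0])]
        for p in chosen[1:]:
            if p - spaced[-1] >= config.het_min_spacing:
                spaced.append(int(p))
        chosen = np.array(spaced)

    haplotypes = []
    het_positions = []
    per_ind = np.array_split(chosen, config.num_individuals)
    for ind in range(config.num_individuals):
        h0 = genome.copy()
        h1 = genome.copy()
        for p in per_ind[ind]:
            p = int(p)
            alt = _mutate(rng, genome[p])
            if rng.integers(0, 2):
                h1[p] = alt
            else:
                h0[p] = alt
            het_positions.append((p, (chr(h0[p]), chr(h1[p])), ind))
        haplotypes.append(h0.tobytes().decode("ascii"))
        haplotypes.append(h1.tobytes().decode("ascii"))

    return Truth(
        reference=reference,
        haplotypes=haplotypes,
        het_positions=sorted(het_positions),
        dup_diff_positions=dup_diff_positions,
        dup_regions=dup_regions,
    )


def sample_reads(truth: Truth, config: SimConfig, set_id: int = 0,
                 coverage: float | None = None,
                 rng: np.random.Generator | None = None) -> list[Read]:
    """Draw n = λ·L/l uniform reads with errors, qualities and PCR clones.

    Each read picks an individual, a haplotype and a strand uniformly.
    Per-base errors are independent Bernoulli(error_rate) substitutions;
    a fraction ``pcr_dup_rate`` of reads is followed by an exact clone.
    """
    if rng is None:
        rng = np.random.default_rng((config.seed, 7, set_id))
    lam = config.coverage if coverage is None else coverage
    L = config.genome_length
    l = config.read_length
    n = int(round(lam * L / l))
    reads: list[Read] = []
    lo, hi = config.error_qual_low
    for i in range(n):
        start = int(rng.integers(0, L - l + 1))
        hap = int(rng.integers(0, len(truth.haplotypes)))
        frag = truth.haplotypes[hap][start : start + l]
        if rng.integers(0, 2):
            frag = revcomp(frag)
        arr = np.frombuffer(frag.encode("ascii"), dtype=np.uint8).copy()
        quals = np.full(l, config.correct_quality, dtype=np.int16)
        if config.error_rate > 0:
            errs = np.flatnonzero(rng.random(l) < config.error_rate)
            for p in errs:
                arr[p] = _mutate(rng, arr[p])
            if len(errs):
                high = rng.random(len(errs)) < config.error_qual_high_frac
                q = rng.integers(lo, hi + 1, size=len(errs))
                q[high] = rng.integers(20, 31, size=int(high.sum()))
                quals[errs] = q
        read = Read(
            id=f"s{set_id}_r{i}",
            bases=arr.tobytes().decode("ascii"),
            quals=quals,
            set_id=set_id,
            individual_id=f"ind{hap // 2}",
        )
        reads.append(read)
        if config.pcr_dup_rate > 0 and rng.random() < config.pcr_dup_rate:
            reads.append(
                Read(id=f"s{set_id}_r{i}dup", bases=read.bases,
                     quals=quals.copy(), set_id=set_id,
                     individual_id=read.individual_id)
            )
    return reads


def sample_read_sets(truth: Truth, config: SimConfig, n_sets: int,
                     coverage_per_set: float) -> list[list[Read]]:
    """Independent sequencing increments of equal coverage."""
    return [
        sample_reads(truth, config, set_id=s, coverage=coverage_per_set)
        for s in range(n_sets)
    ]


def classify_call(call, truth: Truth, flank: int = 15) -> tuple[str, int | None]:
    """Locate an emitted SNP in the truth: ('het'|'dup'|'other', position).

    The contig context around the SNP (``flank`` bases each side) is
    searched in every haplotype on both strands; matching genomic centre
    positions are checked against the planted het sites, then against the
    duplication difference columns.
    """
    ctx_lo = max(0, call.position - flank)
    left = call.contig[ctx_lo : call.position]
    right = call.contig[call.position + 1 : call.position + 1 + flank]
    centres: set[int] = set()
    for hap in truth.haplotypes:
        for oriented_left, oriented_right, rc in (
            (left, right, False),
            (revcomp(right), revcomp(left), True),
        ):
            start = 0
            while True:
                idx = hap.find(oriented_left, start)
                if idx < 0:
                    break
                centre = idx + len(oriented_left)
                if hap[centre + 1 : centre + 1 + len(oriented_right)] == oriented_right:
                    centres.add(centre)
                start = idx + 1
    het = truth.het_sites()
    for c in centres:
        if c in het:
            return "het", c
    for c in centres:
        if c in truth.dup_diff_positions:
            return "dup", c
    return "other", (min(centres) if centres else None)
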