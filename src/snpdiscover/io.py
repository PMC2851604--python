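"""Sequence I/O: FASTA/FASTQ loading, soft-masked FASTA, ACE assemblies.

Soft-masking follows the usual convention — lowercase letters mark
repeat-derived positions — but internally bases stay uppercase and the
mask lives in a separate boolean vector, so a write/load round trip is
the identity on (bases, mask).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
from Bio import SeqIO

from snpdiscover.records import Read, revcomp

__all__ = [
    "load_set",
    "write_masked",
    "write_fastq",
    "read_ace",
    "write_cluster_store",
    "load_cluster_store",
]

DEFAULT_FASTA_QUALITY = 20


class ParseError(ValueError):
    pass


class IdentityError(ValueError):
    pass


def load_set(
    path,
    format: str,
    set_id: int,
    individual_id: str,
    default_quality: int = DEFAULT_FASTA_QUALITY,
    phred64: bool = False,
    known_ids: set | None = None,
) -> list[Read]:
    """Load one sequencing increment ("set") as a list of Reads.

    FASTA records receive ``default_quality`` at every base; lowercase
    letters in FASTA input are interpreted as soft-masked.  FASTQ
    qualities are Phred+33 unless ``phred64``.  ``known_ids`` holds ids
    from previously loaded sets; a collision raises IdentityError so that
    read identities stay unique across the whole run.
    """
    path = Path(path)
    if format not in ("fasta", "fastq"):
        raise ParseError(f"unknown format {format!r}")
    reads: list[Read] = []
    seen = set() if known_ids is None else known_ids
    offset = 64 if phred64 else 33
    try:
        records = list(SeqIO.parse(str(path), format))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for i, rec in enumerate(records):
        seq = str(rec.seq)
        if format == "fastq":
            phred = rec.letter_annotations.get("phred_quality")
            if phred is None or len(phred) != len(seq):
                raise ParseError(f"{path}: record {i} has mismatched quality length")
            quals = np.asarray(phred, dtype=np.int16)
            if phred64:
                quals = quals + 33 - 64
            mask = None
        else:
            quals = np.full(len(seq), default_quality, dtype=np.int16)
            mask = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) >= ord("a")
        if not seq:
            raise ParseError(f"{path}: record {i} is empty")
        if re.search(r"[^ACGTNacgtn]", seq):
            raise ParseError(f"{path}: record {i} contains non-ACGTN characters")
        if rec.id in seen:
            raise IdentityError(f"duplicate read id {rec.id!r} (record {i} of {path})")
        seen.add(rec.id)
        reads.append(
            Read(id=rec.id, bases=seq, quals=quals, set_id=set_id,
                 individual_id=individual_id, mask=mask)
        )
    return reads


def write_masked(reads: list[Read], path, width: int = 70) -> None:
    """Write reads as FASTA with soft-masked positions in lowercase."""
    with open(path, "w") as fh:
        for r in reads:
            arr = np.frombuffer(r.bases.encode("ascii"), dtype=np.uint8).copy()
            lower = r.mask & (arr >= ord("A")) & (arr <= ord("Z"))
            arr[lower] += 32
            seq = arr.tobytes().decode("ascii")
            fh.write(f">{r.id}\n")
            for j in range(0, len(seq), width):
                fh.write(seq[j : j + width] + "\n")


def write_fastq(reads: list[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            q = "".join(chr(int(v) + 33) for v in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{q}\n")


class AceError(ValueError):
    pass


def read_ace(path):
    """Parse a single-contig ACE assembly into a MicroAssembly.

    Supports the common subset of the format: one CO record, AF lines
    giving padded offsets and orientation, and RD records with padded
    read sequences ('*' pads).  Reverse-complemented placements are
    projected onto the contig strand before column support is counted.
    """
    from snpdiscover.assembly import MicroAssembly, build_from_layout

    text = Path(path).read_text()
    contigs = re.findall(r"^CO (\S+) (\d+) (\d+)", text, flags=re.M)
    if len(contigs) != 1:
        raise AceError(f"expected a single-contig ACE file, found {len(contigs)} contigs")

    lines = text.splitlines()
    i = 0
    contig_seq = []
    af = {}
    rd = {}
    while i < len(lines):
        line = lines[i]
        if line.startswith("CO "):
            i += 1
            while i < len(lines) and lines[i].strip():
                if lines[i].startswith(("BQ", "AF ", "BS ")):
                    break
                contig_seq.append(lines[i].strip())
                i += 1
            continue
        if line.startswith("AF "):
            _, name, ori, off = line.split()
            af[name] = (ori, int(off))
        elif line.startswith("RD "):
            name = line.split()[1]
            i += 1
            seq = []
            while i < len(lines) and lines[i].strip() and not lines[i].startswith(("QA", "DS")):
                seq.append(lines[i].strip())
                i += 1
            rd[name] = "".join(seq)
            continue
        i += 1

    contig = "".join(contig_seq).replace("*", "").upper()
    if not contig:
        raise AceError("contig sequence missing")

    placements = []
    for name, padded in rd.items():
        if name not in af:
            raise AceError(f"read {name!r} has no AF placement line")
        ori, off = af[name]
        bases = padded.replace("*", "").upper()
        if ori == "C":
            bases = revcomp(bases)
        start = off - 1  # ACE offsets are 1-based
        if start < 0 or start + len(bases) > len(contig):
            raise AceError(
                f"read {name!r} placed outside contig "
                f"(offset {off}, length {len(bases)}, contig {len(contig)})"
            )
        placements.append((name, start, "+" if ori == "U" else "-", bases))

    reads = [
        Read(id=name, bases=bases, quals=np.full(len(bases), DEFAULT_FASTA_QUALITY))
        for name, _, _, bases in placements
    ]
    layout = [(name, start, strand) for name, start, strand, _ in placements]
    return build_from_layout(contig, reads, layout)


# ---------------------------------------------------------------------------
# Cluster store text format: one block per cluster.
#   C <seed_id> <candidate_repeat:0|1> <frozen:0|1>
#   M <member_id> <strand> <a_start> <a_end> <b_start> <b_end> <identity> <cols>
#   D <a_pos> <a_base> <b_base> <b_pos>  (differences of the preceding member)
# Blocks are separated by blank lines.
# ---------------------------------------------------------------------------

def write_cluster_store(store, path) -> None:
    from snpdiscover.records import Alignment  # noqa: F401

    with open(path, "w") as fh:
        for cl in store.clusters.values():
            fh.write(f"C {cl.seed_id} {int(cl.candidate_repeat)} {int(cl.frozen)}\n")
            for member_id, aln in cl.members:
                fh.write(
                    f"M {member_id} {aln.strand} {aln.a_start} {aln.a_end} "
                    f"{aln.b_start} {aln.b_end} {aln.identity:.6f} {aln.aligned_cols}\n"
                )
                for (p, ab, bb, bp) in aln.differences:
                    fh.write(f"D {p} {ab} {bb} {bp}\n")
            fh.write("\n")


def load_cluster_store(path, thresholds):
    from snpdiscover.clusters import Cluster, ClusterStore
    from snpdiscover.records import Alignment

    store = ClusterStore(thresholds)
    cl = None
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            cl = None
            continue
        tag, rest = line.split(" ", 1)
        if tag == "C":
            seed_id, rep, frozen = rest.split()
            cl = Cluster(seed_id=seed_id)
            cl.candidate_repeat = bool(int(rep))
            cl.frozen = bool(int(frozen))
            store.clusters[seed_id] = cl
        elif tag == "M":
            f = rest.split()
            aln = Alignment(
                id_a=cl.seed_id, id_b=f[0], strand=f[1],
                a_start=int(f[2]), a_end=int(f[3]),
                b_start=int(f[4]), b_end=int(f[5]),
                differences=[], identity=float(f[6]), aligned_cols=int(f[7]),
            )
            cl.members.append((f[0], aln))
        elif tag == "D":
            p, ab, bb, bp = rest.split()
            cl.members[-1][1].differences.append((int(p), ab, bb, int(bp)))
    for cl in store.clusters.values():
        cl.recount()
    return store
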