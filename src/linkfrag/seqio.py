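"""Sequence/alignment containers, standard-format I/O, and small-scale alignment.

Coordinates are 0-based half-open everywhere inside the library; 1-based
coordinates appear only in human-facing reports.  Guide and linker intervals
are always stored on the forward reference strand; reverse-strand features
carry strand ``"-"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Genome",
    "Read",
    "AlignmentRecord",
    "VariantRecord",
    "FormatError",
    "CapabilityError",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "parse_alignments",
    "semiglobal_align",
    "overlap_align",
    "levenshtein_within_k",
]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (case preserved)."""
    return seq.translate(_RC)[::-1]


class FormatError(ValueError):
    """A file violates its declared format."""


class CapabilityError(ValueError):
    """An input lacks information a downstream consumer requires
    (e.g. a PAF record without per-base operations asked to serve a pileup)."""


@dataclass
class Genome:
    """A set of named contigs over {A,C,G,T,N}, uppercase."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        self.sequences = {name: seq.upper() for name, seq in self.sequences.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences

    def contigs(self) -> list[str]:
        return list(self.sequences)

    def length(self, contig: str) -> int:
        return len(self.sequences[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Substring of ``contig`` over the 0-based half-open ``[start, end)``."""
        if start < 0 or end > len(self.sequences[contig]) or start > end:
            raise IndexError(f"interval [{start},{end}) out of bounds on {contig}")
        return self.sequences[contig][start:end]


@dataclass
class Read:
    id: str
    bases: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise FormatError(
                f"read {self.id}: {len(self.qualities)} qualities for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


# Alignment edit operations: "=" match, "X" mismatch, "I" insertion (extra read
# bases), "D" deletion (missing read bases), "M" alignment match (base-level
# match/mismatch undistinguished, as in a SAM "M" CIGAR).
_REF_OPS = frozenset("=XMD")
_READ_OPS = frozenset("=XMI")


@dataclass
class AlignmentRecord:
    """One read-to-reference alignment with optional per-base operations.

    ``bases``/``qualities`` hold the read in reference-forward orientation
    (as SAM stores SEQ); ``read_start``/``read_end`` index into them.
    """

    read_id: str
    contig: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str = "+"
    ops: Optional[list[tuple[str, int]]] = None
    bases: Optional[str] = None
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.ops is not None:
            ref_span = sum(n for op, n in self.ops if op in _REF_OPS)
            read_span = sum(n for op, n in self.ops if op in _READ_OPS)
            if ref_span != self.ref_end - self.ref_start:
                raise FormatError(
                    f"{self.read_id}: CIGAR reference span {ref_span} != "
                    f"interval {self.ref_end - self.ref_start}"
                )
            if read_span != self.read_end - self.read_start:
                raise FormatError(
                    f"{self.read_id}: CIGAR read span {read_span} != "
                    f"interval {self.read_end - self.read_start}"
                )

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start

    def has_base_level(self) -> bool:
        return self.ops is not None and self.bases is not None

    def walk(self) -> Iterator[tuple[str, int, int, int]]:
        """Yield (op, length, ref_pos, read_pos) for each operation run."""
        if self.ops is None:
            raise CapabilityError(f"{self.read_id}: no per-base operations")
        rpos, qpos = self.ref_start, self.read_start
        for op, n in self.ops:
            yield op, n, rpos, qpos
            if op in _REF_OPS:
                rpos += n
            if op in _READ_OPS:
                qpos += n


@dataclass
class VariantRecord:
    """A called or known variant; ``position`` is 0-based on the reference."""

    contig: str
    position: int
    ref: str
    alt: str
    zygosity: str = "het"  # {het, hom}
    phase: Optional[int] = None  # haplotype carrying ``alt`` (1 or 2)

    def __post_init__(self) -> None:
        if not self.ref:
            raise ValueError("ref allele must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def ref_end(self) -> int:
        return self.position + len(self.ref)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    sequences: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            sequences[rec.id] = str(rec.seq).upper()
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not sequences:
        # Distinguish empty from malformed: a non-empty file with no records
        # almost certainly is not FASTA.
        text = Path(path).read_text()
        if text.strip():
            raise FormatError(f"{path}: no FASTA records found (missing '>' header?)")
    return Genome(sequences)


def write_fasta(genome: Genome | dict[str, str], path: str | Path, width: int = 80) -> None:
    seqs = genome.sequences if isinstance(genome, Genome) else genome
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(
                Read(
                    id=rec.id,
                    bases=str(rec.seq).upper(),
                    qualities=list(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            quals = read.qualities
            if quals is None:
                quals = [30] * len(read.bases)
            rec = SeqRecord(Seq(read.bases), id=read.id, description="")
            rec.letter_annotations["phred_quality"] = quals
            SeqIO.write(rec, fh, "fastq")


# ---------------------------------------------------------------------------
# SAM / PAF
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# pysam op codes -> our op letters (None = not part of the alignment proper)
_PYSAM_OPS = {0: "M", 1: "I", 2: "D", 3: "D", 7: "=", 8: "X"}


def parse_alignments(
    path: str | Path,
    dialect: str = "SAM",
    include_secondary: bool = False,
    require_base_level: bool = False,
) -> list[AlignmentRecord]:
    """Parse SAM or PAF alignments into :class:`AlignmentRecord` s.

    Duplicate, secondary and supplementary records are excluded by default.
    PAF records carry no read bases, so ``require_base_level`` rejects them.
    """
    dialect = dialect.upper()
    if dialect == "SAM":
        records = list(_parse_sam(path, include_secondary))
    elif dialect == "PAF":
        records = list(_parse_paf(path))
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    if require_base_level:
        for rec in records:
            if not rec.has_base_level():
                raise CapabilityError(
                    f"{rec.read_id}: alignment lacks per-base operations/bases "
                    "required by this analysis (provide SAM with CIGAR and SEQ)"
                )
    return records


def _parse_sam(path: str | Path, include_secondary: bool) -> Iterator[AlignmentRecord]:
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            if not include_secondary and (
                aln.is_secondary or aln.is_supplementary or aln.is_duplicate
            ):
                continue
            ops = None
            if aln.cigartuples:
                ops = []
                for code, n in aln.cigartuples:
                    if code in (4, 5, 6):  # soft/hard clip, padding: not aligned
                        continue
                    ops.append((_PYSAM_OPS[code], n))
            quals = list(aln.query_qualities) if aln.query_qualities is not None else None
            yield AlignmentRecord(
                read_id=aln.query_name,
                contig=aln.reference_name,
                ref_start=aln.reference_start,
                ref_end=aln.reference_end,
                read_start=aln.query_alignment_start,
                read_end=aln.query_alignment_end,
                strand="-" if aln.is_reverse else "+",
                ops=ops,
                bases=aln.query_sequence,
                qualities=quals,
            )


def _parse_paf(path: str | Path) -> Iterator[AlignmentRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: PAF line has {len(fields)} fields")
            tags = dict(
                (f.split(":", 2)[0], f.split(":", 2)[2]) for f in fields[12:] if ":" in f
            )
            tp = tags.get("tp")
            if tp in ("S", "I"):  # secondary / inversion
                continue
            ops = None
            if "cg" in tags:
                ops = [
                    (op if op != "N" else "D", int(n))
                    for n, op in _CIGAR_RE.findall(tags["cg"])
                    if op not in "SHP"
                ]
            read_len = int(fields[1])
            qstart, qend = int(fields[2]), int(fields[3])
            strand = fields[4]
            if strand == "-":
                # PAF query coordinates are on the original read; report the
                # reference-forward interval as SAM would.
                qstart, qend = read_len - qend, read_len - qstart
            yield AlignmentRecord(
                read_id=fields[0],
                contig=fields[5],
                ref_start=int(fields[7]),
                ref_end=int(fields[8]),
                read_start=qstart,
                read_end=qend,
                strand=strand,
                ops=ops,
                bases=None,
                qualities=None,
            )


def write_sam(
    records: Iterable[AlignmentRecord],
    genome: Genome,
    path: str | Path,
) -> None:
    """Write alignments as text SAM (minimal header from the genome)."""
    op_order = {"=": "=", "X": "X", "M": "M", "I": "I", "D": "D"}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name in genome.contigs():
            fh.write(f"@SQ\tSN:{name}\tLN:{genome.length(name)}\n")
        for rec in records:
            flag = 16 if rec.strand == "-" else 0
            cigar = ""
            if rec.read_start > 0:
                cigar += f"{rec.read_start}S"
            if rec.ops:
                cigar += "".join(f"{n}{op_order[op]}" for op, n in rec.ops)
            else:
                cigar = "*"
            if rec.bases is not None and rec.read_end < len(rec.bases) and rec.ops:
                cigar += f"{len(rec.bases) - rec.read_end}S"
            seq = rec.bases if rec.bases is not None else "*"
            if rec.qualities is not None:
                qual = "".join(chr(q + 33) for q in rec.qualities)
            else:
                qual = "*"
            fh.write(
                f"{rec.read_id}\t{flag}\t{rec.contig}\t{rec.ref_start + 1}\t60\t"
                f"{cigar}\t*\t0\t0\t{seq}\t{qual}\n"
            )


# ---------------------------------------------------------------------------
# Alignment primitives
# ---------------------------------------------------------------------------

# N never matches anything, including another N (conservative scoring).  edlib
# compares characters literally, so we map N to distinct sentinels per side.
_N_QUERY = str.maketrans("N", "\x01")
_N_TARGET = str.maketrans("N", "\x02")


def _sanitize(query: str, target: str) -> tuple[str, str]:
    return query.translate(_N_QUERY), target.translate(_N_TARGET)


def semiglobal_align(
    read: str,
    window: str,
    contig: str = "",
    window_offset: int = 0,
    read_id: str = "",
) -> AlignmentRecord:
    """Minimum-edit-cost alignment of the full ``read`` against any substring
    of ``window`` (free end gaps on the reference side).

    Deterministic: among optimal alignments the leftmost reference start
    reported by the engine is taken, and for desk-scale problems the
    operation order tie-break prefers match > mismatch > deletion > insertion.
    """
    if not read:
        raise ValueError("cannot align an empty read")
    if len(window) > 200_000:
        raise ValueError("reference window exceeds 200 kbp")
    q, t = _sanitize(read.upper(), window.upper())
    res = edlib.align(q, t, mode="HW", task="locations")
    start = min(loc[0] for loc in res["locations"])
    end = min(loc[1] for loc in res["locations"] if loc[0] == start) + 1
    sub = t[start:end]
    if len(q) * len(sub) <= 4_000_000:
        ops = _nw_ops(q, sub)
    else:
        path = edlib.align(q, sub, mode="NW", task="path")
        ops = [(op, int(n)) for n, op in _CIGAR_RE.findall(path["cigar"])]
    ops = _merge_ops(ops)
    return AlignmentRecord(
        read_id=read_id,
        contig=contig,
        ref_start=window_offset + start,
        ref_end=window_offset + end,
        read_start=0,
        read_end=len(read),
        strand="+",
        ops=ops,
        bases=read.upper(),
        qualities=None,
    )


def alignment_cost(rec: AlignmentRecord) -> int:
    """Unit edit cost of an alignment (mismatches + indel bases)."""
    return sum(n for op, n in rec.ops or [] if op in "XID")


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged


def _nw_ops(query: str, target: str) -> list[tuple[str, int]]:
    """Global unit-cost alignment with deterministic traceback preferring
    match > mismatch > deletion > insertion at equal cost."""
    n, m = len(query), len(target)
    dp = np.zeros((n + 1, m + 1), dtype=np.int32)
    dp[0, :] = np.arange(m + 1)
    dp[:, 0] = np.arange(n + 1)
    qarr = np.frombuffer(query.encode("latin1"), dtype=np.uint8)
    tarr = np.frombuffer(target.encode("latin1"), dtype=np.uint8)
    col = np.arange(m + 1)
    for i in range(1, n + 1):
        sub = dp[i - 1, :-1] + (qarr[i - 1] != tarr)
        row = np.minimum(sub, dp[i - 1, 1:] + 1)  # substitution / insertion
        # deletion chains resolve as a prefix-min over (candidate - column)
        vals = np.empty(m + 1, dtype=np.int32)
        vals[0] = dp[i, 0]
        vals[1:] = row
        dp[i] = np.minimum.accumulate(vals - col) + col
    ops: list[tuple[str, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = dp[i, j]
        if i > 0 and j > 0 and query[i - 1] == target[j - 1] and dp[i - 1, j - 1] == here:
            ops.append(("=", 1))
            i, j = i - 1, j - 1
        elif i > 0 and j > 0 and dp[i - 1, j - 1] + 1 == here:
            ops.append(("X", 1))
            i, j = i - 1, j - 1
        elif j > 0 and dp[i, j - 1] + 1 == here:
            ops.append(("D", 1))
            j -= 1
        else:
            ops.append(("I", 1))
            i -= 1
    ops.reverse()
    return _merge_ops(ops)


def overlap_align(
    read: str,
    window: str,
    contig: str = "",
    window_offset: int = 0,
    read_id: str = "",
    match_score: int = 1,
    mismatch: int = -1,
    gap: int = -1,
) -> AlignmentRecord:
    """Overlap (dovetail/containment) alignment: end gaps are free on BOTH
    sequences, so only the genuinely shared region is aligned and the
    overhangs are soft-clipped (``read_start``/``read_end`` mark the aligned
    part of the read).  Score-maximizing with unit match/mismatch/gap scores;
    N never matches."""
    if not read:
        raise ValueError("cannot align an empty read")
    q, t = _sanitize(read.upper(), window.upper())
    n, m = len(q), len(t)
    qarr = np.frombuffer(q.encode("latin1"), dtype=np.uint8)
    tarr = np.frombuffer(t.encode("latin1"), dtype=np.uint8)
    dp = np.zeros((n + 1, m + 1), dtype=np.int32)
    col = np.arange(m + 1)
    for i in range(1, n + 1):
        diag = dp[i - 1, :-1] + np.where(qarr[i - 1] == tarr, match_score, mismatch)
        up = dp[i - 1, 1:] + gap
        row = np.maximum(diag, up)
        vals = np.empty(m + 1, dtype=np.int32)
        vals[0] = 0
        vals[1:] = row
        dp[i] = np.maximum.accumulate(vals - gap * col) + gap * col
        dp[i, 0] = 0
    # best end cell on the last row or last column (free trailing gaps)
    j_best = int(np.argmax(dp[n]))
    i_best = int(np.argmax(dp[:, m]))
    if dp[n, j_best] >= dp[i_best, m]:
        i, j = n, j_best
    else:
        i, j = i_best, m
    read_end, ref_end = i, j
    ops: list[tuple[str, int]] = []
    while i > 0 and j > 0:
        sc = match_score if (qarr[i - 1] == tarr[j - 1]) else mismatch
        if dp[i, j] == dp[i - 1, j - 1] + sc:
            ops.append(("=" if sc == match_score else "X", 1))
            i, j = i - 1, j - 1
        elif dp[i, j] == dp[i, j - 1] + gap:
            ops.append(("D", 1))
            j -= 1
        else:
            ops.append(("I", 1))
            i -= 1
    ops.reverse()
    ops = _merge_ops(ops)
    return AlignmentRecord(
        read_id=read_id,
        contig=contig,
        ref_start=window_offset + j,
        ref_end=window_offset + ref_end,
        read_start=i,
        read_end=read_end,
        strand="+",
        ops=ops,
        bases=read.upper(),
        qualities=None,
    )


def levenshtein_within_k(a: str, b: str, k: int) -> Optional[int]:
    """Exact Levenshtein distance if it is ≤ k, else ``None``.

    The N-never-matches rule of the alignment scoring applies here too.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if abs(len(a) - len(b)) > k:
        return None
    qa, qb = _sanitize(a.upper(), b.upper())
    d = edlib.align(qa, qb, mode="NW", task="distance", k=k)["editDistance"]
    return None if d == -1 else d
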