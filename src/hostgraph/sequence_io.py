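"""Sequence and alignment-table I/O.

Reads and writes FASTA, splits genomes into fixed-length segments for the
convolutional encoder, calls open reading frames when no protein FASTA is
supplied, and parses 12-column BLAST-style tabular alignment files
("outfmt 6" dialect) produced either by external aligners or by the
built-in fallback aligner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError, ParameterError

Role = Literal["virus", "host", "protein"]

#: default segment length in bp fed to the CNN encoder
SEGMENT_LENGTH = 2000


@dataclass
class SeqRecord:
    """A named nucleotide or amino-acid sequence with its source role."""

    id: str
    sequence: str
    role: Role = "virus"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Segment:
    """A fixed-length window of a genome, possibly N-padded at the end."""

    parent_id: str
    index: int
    sequence: str


@dataclass
class AlignmentHit:
    """One row of a 12-column BLAST-tabular alignment file."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    mismatch: int = 0
    gapopen: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0
    evalue: float = 1.0
    bitscore: float = 0.0


def read_fasta(path: str | Path, role: Role = "virus") -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Sequences are uppercased and file order is preserved.  Duplicate ids
    raise :class:`FormatError`; an empty file returns an empty list with a
    warning.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(id=rec.id, sequence=str(rec.seq).upper(), role=role))
    if not records:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def segment_genome(record: SeqRecord, L: int = SEGMENT_LENGTH) -> list[Segment]:
    """Split a genome into consecutive segments of exactly ``L`` bp.

    Full windows are emitted first; a trailing remainder of length >= L/2
    is kept and N-padded to L, shorter remainders are dropped.  A whole
    sequence shorter than L yields a single N-padded segment.
    """
    seq = record.sequence
    if not seq:
        raise ParameterError(f"empty sequence for record {record.id!r}")
    segments: list[Segment] = []
    n_full = len(seq) // L
    for i in range(n_full):
        segments.append(Segment(record.id, i, seq[i * L : (i + 1) * L]))
    rem = seq[n_full * L :]
    if (n_full == 0 and rem) or len(rem) >= L / 2:
        segments.append(Segment(record.id, n_full, rem + "N" * (L - len(rem))))
    return segments


_STOPS = {"TAA", "TAG", "TGA"}


def _scan_frame(seq: str, offset: int, min_len_aa: int) -> list[tuple[int, str]]:
    """Find ATG->stop ORFs in one forward frame; returns (start_offset, protein)."""
    orfs: list[tuple[int, str]] = []
    i = offset
    n = len(seq)
    while i + 3 <= n:
        if seq[i : i + 3] == "ATG":
            j = i + 3
            while j + 3 <= n and seq[j : j + 3] not in _STOPS:
                j += 3
            if j + 3 <= n:  # stop codon found
                aa_len = (j - i) // 3
                if aa_len >= min_len_aa:
                    prot = str(Seq(seq[i:j]).translate())
                    orfs.append((i, prot))
                i = j + 3  # resume after the stop; nested ATGs are skipped
                continue
            else:
                break
        i += 3
    return orfs


def find_orfs(record: SeqRecord, min_len_aa: int = 60) -> list[SeqRecord]:
    """Naive six-frame ORF caller (ATG to stop, standard genetic code).

    A simplified stand-in for a trained gene finder: it scans all six
    reading frames for ATG-initiated ORFs of at least ``min_len_aa``
    residues (stop codon required) and returns the translated proteins as
    records named ``<parent>_<n>``, ordered by start position on the
    forward strand.
    """
    seq = record.sequence.upper()
    found: list[tuple[int, str]] = []  # (forward-strand start, protein)
    for off in range(3):
        for start, prot in _scan_frame(seq, off, min_len_aa):
            found.append((start, prot))
    rc = str(Seq(seq).reverse_complement())
    for off in range(3):
        for start, prot in _scan_frame(rc, off, min_len_aa):
            # leftmost base of the ORF on the forward strand
            fwd_start = len(seq) - (start + 3 * len(prot) + 3)
            found.append((fwd_start, prot))
    found.sort(key=lambda t: (t[0], t[1]))
    return [
        SeqRecord(id=f"{record.id}_{i}", sequence=prot, role="protein")
        for i, (_, prot) in enumerate(found)
    ]


_TABULAR_COLUMNS = 12


def parse_tabular_alignments(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column BLAST-tabular file; self-hits are dropped."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != _TABULAR_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_TABULAR_COLUMNS} columns, got {len(parts)}"
                )
            if parts[0] == parts[1]:
                continue
            try:
                hit = AlignmentHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    pct_identity=float(parts[2]),
                    align_len=int(parts[3]),
                    mismatch=int(parts[4]),
                    gapopen=int(parts[5]),
                    qstart=int(parts[6]),
                    qend=int(parts[7]),
                    sstart=int(parts[8]),
                    send=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if hit.evalue < 0:
                raise FormatError(f"{path}:{lineno}: negative E-value")
            if hit.align_len < 1:
                raise FormatError(f"{path}:{lineno}: alignment length < 1")
            hits.append(hit)
    return hits


def write_tabular_alignments(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.1f}\t{h.align_len}\t"
                f"{h.mismatch}\t{h.gapopen}\t{h.qstart}\t{h.qend}\t{h.sstart}\t{h.send}\t"
                f"{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )
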