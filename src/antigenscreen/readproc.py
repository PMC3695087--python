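"""FASTQ to per-sample peptide-count tables.

A sequenced phage-display read carries a 4-base sample barcode, fixed vector
flanks, and a 21-nt insert encoding the displayed 7-mer peptide. Processing:
demultiplex on the exact leading barcode, cut the insert window (1-based
inclusive, default bases 29-49), collapse identical 21-mer DNA inserts, then
translate each unique insert in frame 1 and sum synonymous-codon counts into
peptide counts. Heptapeptide libraries are propagated in amber-suppressor
hosts, so TAG translates to Q by default; TAA/TGA or any N-containing codon
rejects the read.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "RawRead",
    "BarcodeMap",
    "InsertWindow",
    "PeptideCountTable",
    "UNASSIGNED",
    "demultiplex",
    "extract_insert",
    "translate_insert",
    "collapse",
    "process_reads",
    "process_fastq",
    "read_sequences",
]

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)  # TAA, TAG, TGA


@dataclass(frozen=True)
class RawRead:
    identifier: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.identifier}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


class BarcodeMap:
    """Mapping of fixed-length DNA barcodes to sample names."""

    def __init__(self, entries: Mapping[str, str]):
        seen: dict[str, str] = {}
        for barcode, sample in entries.items():
            bc = barcode.upper()
            if bc in seen:
                raise ValueError(f"duplicate barcode {bc!r}")
            if sample == UNASSIGNED:
                raise ValueError(f"sample name {UNASSIGNED!r} is reserved")
            seen[bc] = sample
        lengths = {len(b) for b in seen}
        if len(lengths) > 1:
            raise ValueError(f"barcodes have mixed lengths: {sorted(lengths)}")
        self.entries: dict[str, str] = seen
        self.barcode_length: int = lengths.pop() if lengths else 0

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeMap":
        entries = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            barcode, sample = line.split("\t")[:2]
            entries[barcode] = sample
        return cls(entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class InsertWindow:
    """1-based inclusive window of the peptide-coding insert on the read."""

    start: int = 29
    end: int = 49

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError("window must satisfy 1 <= start <= end")
        if self.length % 3 != 0:
            raise ValueError(f"window length {self.length} is not a codon multiple")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PeptideCountTable:
    """Collapsed peptide repertoire of one sample."""

    sample: str
    counts: dict[str, int] = field(default_factory=dict)
    total_reads_in: int = 0
    total_reads_kept: int = 0

    def validate(self) -> None:
        for pep, c in self.counts.items():
            if c < 1:
                raise ValueError(f"non-positive count for {pep}")
        if sum(self.counts.values()) != self.total_reads_kept:
            raise ValueError("counts do not sum to total_reads_kept")
        if self.total_reads_kept > self.total_reads_in:
            raise ValueError("kept more reads than were input")

    def sorted_items(self) -> list[tuple[str, int]]:
        """Descending count, then lexicographic peptide — the on-disk order."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))


def demultiplex(
    reads: Iterable[RawRead], barcodes: BarcodeMap
) -> dict[str, list[RawRead]]:
    """Assign each read to a sample by exact match of its leading bases.

    Reads matching no barcode (or shorter than a barcode) land in the
    ``"unassigned"`` bin; bin sizes always sum to the input count.
    """
    bins: dict[str, list[RawRead]] = {s: [] for s in barcodes.entries.values()}
    bins[UNASSIGNED] = []
    k = barcodes.barcode_length
    for read in reads:
        sample = barcodes.entries.get(read.sequence[:k].upper()) if k else None
        bins[sample if sample is not None else UNASSIGNED].append(read)
    return bins


def extract_insert(read: RawRead, window: InsertWindow) -> str | None:
    """Bases at 1-based positions [start, end]; None (skip) if the read is short."""
    if len(read.sequence) < window.end:
        log.debug("read %s shorter than insert window, skipped", read.identifier)
        return None
    return read.sequence[window.start - 1 : window.end].upper()


def translate_insert(dna: str, amber_as_q: bool = True) -> str | None:
    """Frame-1 translation of the insert; None when the insert is rejected.

    TAG reads through as Q under amber suppression (default); TAA/TGA, or any
    codon containing a base other than A/C/G/T, rejects the insert.
    """
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise ValueError(f"insert length {len(dna)} is not a codon multiple")
    residues = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        if codon == "TAG" and amber_as_q:
            residues.append("Q")
            continue
        if codon in _STOP_CODONS:
            return None
        aa = _CODON_TABLE.get(codon)
        if aa is None:
            return None
        residues.append(aa)
    return "".join(residues)


def collapse(peptides: Iterable[str], sample: str = "") -> PeptideCountTable:
    """Collapse a peptide stream into a count table (order-independent)."""
    counts = Counter(peptides)
    total = sum(counts.values())
    return PeptideCountTable(
        sample=sample,
        counts=dict(counts),
        total_reads_in=total,
        total_reads_kept=total,
    )


def process_reads(
    reads: Iterable[RawRead],
    sample: str,
    window: InsertWindow | None = None,
    amber_as_q: bool = True,
    min_mean_quality: float | None = None,
) -> PeptideCountTable:
    """Insert extraction + DNA-level collapse + translation for one sample.

    Identical 21-mer DNA inserts are collapsed first, then translated;
    synonymous codon variants are summed into one peptide count. Reads are
    dropped when too short for the window, when the insert is rejected in
    translation, or (optionally) when mean Phred quality over the insert is
    below ``min_mean_quality``.
    """
    window = window or InsertWindow()
    dna_counts: Counter[str] = Counter()
    n_in = n_skipped = n_lowq = 0
    for read in reads:
        n_in += 1
        insert = extract_insert(read, window)
        if insert is None:
            n_skipped += 1
            continue
        if min_mean_quality is not None and read.quality is not None:
            phred = [ord(c) - 33 for c in read.quality[window.start - 1 : window.end]]
            if sum(phred) / len(phred) < min_mean_quality:
                n_lowq += 1
                continue
        dna_counts[insert] += 1

    pep_counts: Counter[str] = Counter()
    n_rejected = 0
    for dna, count in dna_counts.items():
        pep = translate_insert(dna, amber_as_q=amber_as_q)
        if pep is None:
            n_rejected += count
        else:
            pep_counts[pep] += count
    kept = sum(pep_counts.values())
    log.info(
        "sample %s: %d reads in, %d kept (%d short, %d low-quality, %d rejected)",
        sample, n_in, kept, n_skipped, n_lowq, n_rejected,
    )
    table = PeptideCountTable(
        sample=sample,
        counts=dict(pep_counts),
        total_reads_in=n_in,
        total_reads_kept=kept,
    )
    table.validate()
    return table


def read_sequences(path: str | Path) -> Iterator[RawRead]:
    """Stream RawReads from FASTQ or FASTA (gzip allowed, sniffed by suffix)."""
    from Bio import SeqIO

    path = Path(path)
    suffixes = path.suffixes
    opener = gzip.open if suffixes and suffixes[-1] == ".gz" else open
    stem = suffixes[-2] if suffixes and suffixes[-1] == ".gz" else (
        suffixes[-1] if suffixes else ""
    )
    fmt = "fastq" if stem.lower() in (".fastq", ".fq") else "fasta"
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            yield RawRead(rec.id, str(rec.seq), qual)


def process_fastq(
    path: str | Path,
    barcodes: BarcodeMap,
    window: InsertWindow | None = None,
    amber_as_q: bool = True,
    min_mean_quality: float | None = None,
) -> dict[str, PeptideCountTable]:
    """Demultiplex a FASTQ/FASTA file and build one count table per sample."""
    bins = demultiplex(read_sequences(path), barcodes)
    return {
        sample: process_reads(
            reads, sample, window=window, amber_as_q=amber_as_q,
            min_mean_quality=min_mean_quality,
        )
        for sample, reads in bins.items()
        if sample != UNASSIGNED
    }
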