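"""Readers and writers for the pipeline's on-disk formats.

Peptide tables and result tables are plain TSV; protein databases are FASTA
(accession = first whitespace-delimited header token). All coordinates in
TSV outputs are 1-based inclusive; the optional BED writer converts to
0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .epitopes import EpitopeSite, PositionProfile
from .pepalign import AlignmentHit, ProteinRecord
from .ranking import CandidateAntigen, format_final_score, format_initial_score
from .readproc import PeptideCountTable
from .selection import PeptideList

__all__ = [
    "read_fasta", "write_fasta",
    "read_count_table", "write_count_table",
    "read_peptide_list", "write_peptide_list",
    "write_hits", "write_candidates", "write_sites", "write_sites_bed",
    "write_profile",
]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                accession=rec.id,
                description=rec.description.partition(" ")[2],
                sequence=str(rec.seq).upper(),
            )
        )
    return records


def write_fasta(proteins: Sequence[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(p.sequence), id=p.accession, description=p.description)
         for p in proteins],
        str(path), "fasta",
    )


def write_count_table(table: PeptideCountTable, path: str | Path) -> None:
    """`peptide<TAB>count`, descending count then lexicographic peptide."""
    with open(path, "w") as fh:
        fh.write("peptide\tcount\n")
        for pep, count in table.sorted_items():
            fh.write(f"{pep}\t{count}\n")


def read_count_table(path: str | Path, sample: str | None = None) -> PeptideCountTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"peptide": str, "count": int})
    counts = dict(zip(df["peptide"], df["count"].astype(int)))
    total = int(sum(counts.values()))
    return PeptideCountTable(
        sample=sample or Path(path).stem,
        counts=counts,
        total_reads_in=total,
        total_reads_kept=total,
    )


def write_peptide_list(plist: PeptideList, path: str | Path,
                       controls: Sequence[str] = (), n: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# sample={plist.sample} role={plist.role} "
            f"controls={','.join(controls) or '-'} n={n if n is not None else len(plist)}\n"
        )
        fh.write("rank\tpeptide\tcount\n")
        for rank, (pep, count) in enumerate(plist.entries, start=1):
            fh.write(f"{rank}\t{pep}\t{count}\n")


def read_peptide_list(path: str | Path, role: str = "step2") -> PeptideList:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "peptide" not in df.columns:  # headerless rank/peptide/count
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["rank", "peptide", "count"])
    entries = [(str(p), int(c)) for p, c in zip(df["peptide"], df["count"])]
    return PeptideList(sample=Path(path).stem, entries=entries, role=role)


def write_hits(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\taccession\tpep_start\tpep_end\tprot_start\tprot_end"
                 "\traw_score\tbit_score\tevalue\n")
        for h in hits:
            fh.write(
                f"{h.peptide}\t{h.protein_accession}\t{h.pep_start}\t{h.pep_end}"
                f"\t{h.prot_start}\t{h.prot_end}\t{h.raw_score}"
                f"\t{h.bit_score:.4g}\t{h.evalue:.3g}\n"
            )


def write_candidates(candidates: Sequence[CandidateAntigen], path: str | Path) -> None:
    """Report table mirroring the screen's result layout, one row per candidate."""
    with open(path, "w") as fh:
        fh.write("rank\taccession\tdescription\tlength\tinitial_matches"
                 "\tinitial_score\tsum_overall_scores\tfinal_score"
                 "\tmajor_epitope_score\n")
        for rank, c in enumerate(candidates, start=1):
            fh.write(
                f"{rank}\t{c.accession}\t{c.description}\t{c.length}"
                f"\t{c.initial_matches}\t{format_initial_score(c.initial_score)}"
                f"\t{c.sum_overall_scores:.1f}\t{format_final_score(c.final_score)}"
                f"\t{c.major_epitope_score:.1f}\n"
            )


def write_sites(sites: Sequence[EpitopeSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tsite_start\tsite_end\tn_peptides\tcumulative_score\n")
        for s in sites:
            fh.write(f"{s.accession}\t{s.site_start}\t{s.site_end}"
                     f"\t{s.n_peptides}\t{s.cumulative_score:.1f}\n")


def write_sites_bed(sites: Sequence[EpitopeSite], path: str | Path) -> None:
    """BED6: 0-based half-open, score column = cumulative score."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.accession}\t{s.site_start - 1}\t{s.site_end}"
                     f"\tepitope_site\t{s.cumulative_score:.1f}\t+\n")


def write_profile(profile: PositionProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tposition\tvalue\n")
        for pos, val in enumerate(profile.values, start=1):
            fh.write(f"{profile.accession}\t{pos}\t{val:.4g}\n")
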