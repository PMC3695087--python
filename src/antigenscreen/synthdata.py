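"""Seeded generator of screen fixtures with known ground truth.

Emulates the data-generating setting of a serum-antibody phage-display
screen: a decoy proteome plus one target protein carrying designated linear
epitopes; a case peptide repertoire containing a heavy-tailed shared
background, some sample-private background, and a family of abundant
epitope-derived ("spiked") 7-mers; a matched control repertoire without the
spike; and FASTQ reads that encode each peptide behind a sample barcode and
fixed vector flanks, positioning the 21-nt insert at the configured window.

Every stage draws from its own seed stream derived from ``cfg.seed``, so each
artifact is deterministic under the seed regardless of call order.

What is deliberately not modelled: phage amplification bias, panning-round
kinetics, and sequencing errors — reads are error-free so that read
processing round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from .pepalign import ProteinRecord, ROBINSON_FREQUENCIES
from .readproc import PeptideCountTable

__all__ = ["SimulationConfig", "GroundTruth", "gen_proteome", "gen_repertoire",
           "gen_fastq", "write_fastq", "simulate_all"]

_AA = "ARNDCQEGHILKMFPSTWYV"
_AA_FREQS = np.array([ROBINSON_FREQUENCIES[a] for a in _AA])
_AA_FREQS = _AA_FREQS / _AA_FREQS.sum()

# NNK degenerate codons (third base G/T) cover all 20 residues; TAG is the
# NNK amber codon read through as Q in suppressor hosts.
_NNK_CODONS: dict[str, list[str]] = {}
_BASES = "ACGT"
from Bio.Data.CodonTable import standard_dna_table as _tbl

for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in "GT":
            _codon = _b1 + _b2 + _b3
            if _codon == "TAG":
                continue
            _aa = _tbl.forward_table.get(_codon)
            if _aa:
                _NNK_CODONS.setdefault(_aa, []).append(_codon)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults define the standard study conditions."""

    seed: int = 0
    n_decoys: int = 200
    decoy_length_range: tuple[int, int] = (350, 450)
    target_sequence: str | None = None
    target_length: int = 400
    epitope_positions: tuple[tuple[int, int], ...] = ((220, 227),)
    #: sequences planted at epitope_positions when the target is auto-generated.
    #: The default is a known detectable linear epitope (high-self-score 7-mer
    #: windows); None keeps the random target's own residues, which may yield
    #: an epitope the bit threshold cannot see — as for real antigens whose
    #: epitopes are conformational or low-complexity.
    epitope_sequences: tuple[str, ...] | None = ("NFTLPSWA",)
    n_background_peptides: int = 1000
    n_private_background: int = 50
    n_spiked_peptides: int = 40
    spike_mutation_rate: float = 0.10
    abundance_shape: float = 2.0
    barcodes: dict[str, str] = field(
        default_factory=lambda: {"case": "ACGT", "control": "TGCA"}
    )
    flank5: str = "GGTGACGTTCCTTTCTATTCTCAC"  # 24 nt: insert at bases 29-49
    flank3: str = "GGTGGAGGTTCG"
    amber_codons: bool = False  # include TAG among Q codons in reverse translation

    def __post_init__(self) -> None:
        if not 0.0 <= self.spike_mutation_rate <= 1.0:
            raise ValueError("spike_mutation_rate must be in [0, 1]")
        lo, hi = self.decoy_length_range
        if lo < 7 or hi < lo:
            raise ValueError("invalid decoy_length_range")
        for k, (start, end) in enumerate(self.epitope_positions):
            if start < 1 or end < start + 6:
                raise ValueError(
                    f"epitope ({start}, {end}) must span at least one 7-mer window"
                )
            if end > (len(self.target_sequence) if self.target_sequence
                      else self.target_length):
                raise ValueError(f"epitope ({start}, {end}) outside the target")
            if self.epitope_sequences is not None:
                if len(self.epitope_sequences) != len(self.epitope_positions):
                    raise ValueError(
                        "epitope_sequences must match epitope_positions one-to-one"
                    )
                if len(self.epitope_sequences[k]) != end - start + 1:
                    raise ValueError(
                        f"epitope sequence {self.epitope_sequences[k]!r} does not "
                        f"fit interval ({start}, {end})"
                    )
        for sample, bc in self.barcodes.items():
            if len(bc) != 4 or set(bc) - set(_BASES):
                raise ValueError(f"barcode {bc!r} for {sample!r} is not 4-base DNA")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent deterministic stream per generation stage."""
        stage_id = sum(ord(c) * (31 ** i) for i, c in enumerate(stage)) % (2 ** 31)
        return np.random.default_rng([self.seed % (2 ** 31), stage_id])


@dataclass
class GroundTruth:
    """What was planted, for asserting recovery downstream."""

    target_accession: str
    planted_epitopes: list[tuple[int, int]]
    epitope_sequences: list[str]
    spiked_peptides: set[str] = field(default_factory=set)
    planted_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["spiked_peptides"] = sorted(self.spiked_peptides)
        return json.dumps(d, indent=2)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_AA))[rng.choice(20, size=length, p=_AA_FREQS)])


def _epitope_kmers(epitope: str, k: int = 5) -> set[str]:
    return {epitope[i : i + k] for i in range(len(epitope) - k + 1)}


def gen_proteome(cfg: SimulationConfig) -> tuple[list[ProteinRecord], GroundTruth]:
    """Decoy proteome plus the epitope-bearing target, with ground truth.

    Decoys are i.i.d. Robinson-frequency sequences; any decoy containing an
    exact 5-mer of a planted epitope is resampled (bounded retries), so
    rank-1 recovery of the target is a test of the method rather than an
    accident of random homology.
    """
    rng = cfg.rng("proteome")
    if cfg.target_sequence:
        target_seq = cfg.target_sequence
    else:
        target_seq = _random_protein(rng, cfg.target_length)
        if cfg.epitope_sequences is not None:
            chars = list(target_seq)
            for (s, e), epi in zip(cfg.epitope_positions, cfg.epitope_sequences):
                chars[s - 1 : e] = list(epi)
            target_seq = "".join(chars)
    epitopes = [target_seq[s - 1 : e] for s, e in cfg.epitope_positions]
    forbidden = set().union(*(_epitope_kmers(e) for e in epitopes))

    proteins: list[ProteinRecord] = []
    lo, hi = cfg.decoy_length_range
    for i in range(cfg.n_decoys):
        for attempt in range(100):
            seq = _random_protein(rng, int(rng.integers(lo, hi + 1)))
            if not any(seq[j : j + 5] in forbidden for j in range(len(seq) - 4)):
                break
        else:
            raise RuntimeError(f"could not sanitize decoy {i} in 100 attempts")
        proteins.append(
            ProteinRecord(f"DECOY_{i:04d}", f"synthetic decoy protein {i}", seq)
        )
    truth = GroundTruth(
        target_accession="TARGET_1",
        planted_epitopes=[tuple(p) for p in cfg.epitope_positions],
        epitope_sequences=epitopes,
    )
    proteins.append(
        ProteinRecord("TARGET_1", "synthetic target antigen with planted epitopes",
                      target_seq)
    )
    return proteins, truth


def _random_peptides(rng: np.random.Generator, n: int, avoid: set[str]) -> list[str]:
    out: list[str] = []
    seen = set(avoid)
    while len(out) < n:
        pep = "".join(np.array(list(_AA))[rng.choice(20, size=7, p=_AA_FREQS)])
        if pep not in seen:
            seen.add(pep)
            out.append(pep)
    return out


def _heavy_tail_counts(rng: np.random.Generator, n: int, shape: float,
                       cap: int = 10 ** 6) -> np.ndarray:
    return np.minimum(rng.zipf(shape, size=n), cap)


def gen_repertoire(
    cfg: SimulationConfig, truth: GroundTruth
) -> tuple[PeptideCountTable, PeptideCountTable]:
    """Case and control peptide-count tables; fills in the spike ground truth.

    Background peptides (heavy-tailed counts) are shared by case and control
    so control exclusion removes them; each sample also carries private
    background. Spiked peptides are mutated 7-mer windows of the planted
    epitopes, private to the case sample, with counts drawn from the upper
    tail so they survive top-N selection.
    """
    rng = cfg.rng("repertoire")
    shared = _random_peptides(rng, cfg.n_background_peptides, set())
    shared_set = set(shared)
    case_priv = _random_peptides(rng, cfg.n_private_background, shared_set)
    ctrl_priv = _random_peptides(rng, cfg.n_private_background,
                                 shared_set | set(case_priv))

    spiked: list[str] = []
    aa = np.array(list(_AA))
    for _ in range(cfg.n_spiked_peptides):
        epi = truth.epitope_sequences[rng.integers(len(truth.epitope_sequences))]
        w = int(rng.integers(len(epi) - 6))
        pep = list(epi[w : w + 7])
        for i in range(7):
            if rng.random() < cfg.spike_mutation_rate:
                pep[i] = str(aa[rng.choice(20, p=_AA_FREQS)])
        spiked.append("".join(pep))

    def table(sample: str, peptides: Iterable[str], spike: list[str] | None
              ) -> PeptideCountTable:
        peptides = list(peptides)
        counts = dict(zip(peptides,
                          map(int, _heavy_tail_counts(rng, len(peptides),
                                                      cfg.abundance_shape))))
        if spike:
            # upper-tail counts: abundant enough to head the private list
            spike_counts = 100 + _heavy_tail_counts(rng, len(spike),
                                                    cfg.abundance_shape)
            for pep, c in zip(spike, map(int, spike_counts)):
                counts[pep] = counts.get(pep, 0) + c
        t = PeptideCountTable(sample=sample, counts=counts)
        t.total_reads_in = t.total_reads_kept = sum(counts.values())
        return t

    case = table("case", shared + case_priv, spiked)
    control = table("control", shared + ctrl_priv, None)
    truth.spiked_peptides = {p for p in spiked if p not in shared_set}
    truth.planted_counts = {
        "case": {p: case.counts[p] for p in truth.spiked_peptides},
        "control": {},
    }
    return case, control


def _reverse_translate(rng: np.random.Generator, peptide: str,
                       amber: bool) -> str:
    codons = []
    for aa in peptide:
        options = list(_NNK_CODONS[aa])
        if amber and aa == "Q":
            options.append("TAG")
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def gen_fastq(
    tables: dict[str, PeptideCountTable], cfg: SimulationConfig
) -> list[tuple[str, str, str]]:
    """FASTQ records (id, sequence, quality) encoding the given count tables.

    Each peptide is emitted ``count`` times as barcode + 5' flank + codons +
    3' flank with constant qualities; codons are drawn uniformly among
    NNK-compatible synonyms. Read processing on this output reproduces the
    input tables exactly.
    """
    if len(cfg.flank5) + 4 != 28:
        raise ValueError("flank5 must place the insert at base 29 "
                         "(barcode 4 + flank5 must span bases 1-28)")
    rng = cfg.rng("fastq")
    records: list[tuple[str, str, str]] = []
    for sample, tab in sorted(tables.items()):
        barcode = cfg.barcodes[sample]
        idx = 0
        for pep, count in tab.sorted_items():
            for _ in range(count):
                insert = _reverse_translate(rng, pep, cfg.amber_codons)
                seq = barcode + cfg.flank5 + insert + cfg.flank3
                records.append((f"{sample}:{idx}", seq, "I" * len(seq)))
                idx += 1
    return records


def write_fastq(records: list[tuple[str, str, str]], path: str | Path) -> None:
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def simulate_all(cfg: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Write proteins.fasta, case.tsv, control.tsv, reads.fastq.gz, truth.json."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteins, truth = gen_proteome(cfg)
    case, control = gen_repertoire(cfg, truth)
    _io.write_fasta(proteins, outdir / "proteins.fasta")
    _io.write_count_table(case, outdir / "case.tsv")
    _io.write_count_table(control, outdir / "control.tsv")
    write_fastq(gen_fastq({"case": case, "control": control}, cfg),
                outdir / "reads.fastq.gz")
    (outdir / "truth.json").write_text(truth.to_json())
    return truth
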