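"""Local alignment of short peptides against proteins with BLAST-style statistics.

Replaces a database blastp / bl2seq step with a self-contained exhaustive
aligner: for 7-mer queries against a desk-scale protein FASTA, word-seeding
heuristics buy nothing, and an exhaustive scan makes results independent of
external database versions and BLAST internals.

Scores follow the Karlin-Altschul framework for ungapped local alignment:
``bits = (lambda * S - ln K) / ln 2`` and the two-sequence expectation
``E = K * m' * n' * exp(-lambda * S)`` with edge-corrected effective lengths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "ProteinRecord",
    "ScoringScheme",
    "AlignmentHit",
    "best_local_hit",
    "evalue_two_seq",
    "screen_database",
    "compute_ungapped_lambda",
    "ROBINSON_FREQUENCIES",
]

#: Amino-acid background frequencies of Robinson & Robinson, the composition
#: NCBI BLAST assumes for its ideal ungapped statistics.
ROBINSON_FREQUENCIES: dict[str, float] = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

#: NCBI's published ungapped Karlin-Altschul parameters (lambda, K, H).
#: lambda and H are re-derivable from the matrix + Robinson frequencies
#: (see compute_ungapped_lambda); K is tabulated (no closed form).
_UNGAPPED_PARAMS: dict[str, tuple[float, float, float]] = {
    "BLOSUM62": (0.3176, 0.134, 0.4012),
    "PAM30": (0.3400, 0.2830, 1.7536),
}

_NEG_INF = -(10 ** 9)


@dataclass(frozen=True)
class ProteinRecord:
    """One entry of the protein database being screened."""

    accession: str
    description: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus the Karlin-Altschul constants that go with it.

    Parameters
    ----------
    matrix_name
        ``"BLOSUM62"`` (default) or ``"PAM30"`` (NCBI's short-query choice);
        any matrix known to :mod:`Bio.Align.substitution_matrices` works if
        lambda/K/H are supplied explicitly.
    gapless
        Ungapped local alignment (default). Gapped mode uses Biopython's
        PairwiseAligner with ``gap_open``/``gap_extend``; the caller must then
        supply statistics constants appropriate for the gapped regime.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    gapless: bool = True
    lambda_: float | None = None
    k_param: float | None = None
    h_param: float | None = None

    def __post_init__(self) -> None:
        if self.lambda_ is None or self.k_param is None or self.h_param is None:
            try:
                lam, k, h = _UNGAPPED_PARAMS[self.matrix_name]
            except KeyError:
                raise ValueError(
                    f"no built-in Karlin-Altschul constants for {self.matrix_name!r}; "
                    "pass lambda_, k_param and h_param explicitly"
                ) from None
            if self.lambda_ is None:
                object.__setattr__(self, "lambda_", lam)
            if self.k_param is None:
                object.__setattr__(self, "k_param", k)
            if self.h_param is None:
                object.__setattr__(self, "h_param", h)
        if self.lambda_ <= 0 or self.k_param <= 0 or self.h_param <= 0:
            raise ValueError("lambda, K and H must be positive")

    def bit_score(self, raw_score: float) -> float:
        return (self.lambda_ * raw_score - math.log(self.k_param)) / math.log(2)


@dataclass(frozen=True)
class AlignmentHit:
    """Best local match of one peptide on one protein (1-based inclusive coords)."""

    peptide: str
    protein_accession: str
    pep_start: int
    pep_end: int
    prot_start: int
    prot_end: int
    raw_score: int
    bit_score: float
    evalue: float

    @property
    def length(self) -> int:
        return self.pep_end - self.pep_start + 1


@lru_cache(maxsize=8)
def _matrix_tables(matrix_name: str) -> tuple[dict[str, int], np.ndarray]:
    """Residue->index map and dense integer score matrix for ``matrix_name``."""
    mat = substitution_matrices.load(matrix_name)
    letters = [c for c in mat.alphabet if c != "*"]
    index = {c: i for i, c in enumerate(letters)}
    dense = np.empty((len(letters), len(letters)), dtype=np.int64)
    for a, i in index.items():
        for b, j in index.items():
            dense[i, j] = int(mat[a, b])
    return index, dense


def _encode(seq: str, index: dict[str, int], what: str) -> np.ndarray:
    try:
        return np.fromiter((index[c] for c in seq.upper()), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {what} {seq!r}") from None


def compute_ungapped_lambda(
    matrix_name: str = "BLOSUM62",
    frequencies: dict[str, float] | None = None,
) -> tuple[float, float]:
    """Solve for the ungapped Karlin-Altschul (lambda, H) of a matrix.

    lambda is the unique positive root of ``sum_ij p_i p_j exp(lambda s_ij) = 1``;
    H is the relative entropy of the induced aligned-pair distribution. Used as
    an independent cross-check of the tabulated constants.
    """
    from scipy.optimize import brentq

    freqs = frequencies or ROBINSON_FREQUENCIES
    mat = substitution_matrices.load(matrix_name)
    letters = sorted(freqs)
    p = np.array([freqs[a] for a in letters])
    p = p / p.sum()
    s = np.array([[mat[a, b] for b in letters] for a in letters], dtype=float)

    def restrict(lam: float) -> float:
        return float((p[:, None] * p[None, :] * np.exp(lam * s)).sum() - 1.0)

    lam = brentq(restrict, 1e-6, 10.0)
    q = p[:, None] * p[None, :] * np.exp(lam * s)
    h = float((q * lam * s).sum())
    return lam, h


def evalue_two_seq(
    hit_raw_score: float, peptide_len: int, protein_len: int, scheme: ScoringScheme
) -> float:
    """Two-sequence expectation of a local alignment score.

    ``E = K * m' * n' * exp(-lambda * S)`` where the effective lengths m', n'
    subtract the expected HSP length ``ln(K m n) / H`` (edge correction),
    floored at 1.
    """
    if peptide_len <= 0 or protein_len <= 0:
        raise ValueError("sequence lengths must be positive")
    k, lam, h = scheme.k_param, scheme.lambda_, scheme.h_param
    expected_hsp = math.log(k * peptide_len * protein_len) / h
    m_eff = max(peptide_len - expected_hsp, 1.0)
    n_eff = max(protein_len - expected_hsp, 1.0)
    return k * m_eff * n_eff * math.exp(-lam * hit_raw_score)


def _best_gapless(pep: np.ndarray, prot: np.ndarray, dense: np.ndarray):
    """Max-scoring ungapped local alignment by per-diagonal Kadane scan.

    Returns (raw_score, pep_start0, pep_end0, prot_start0, prot_end0) or None.
    Ties: smallest protein start, then longest alignment, then smallest
    peptide start.
    """
    m, n = len(pep), len(prot)
    grid = dense[pep[:, None], prot[None, :]]  # grid[i, j] = s(pep[i], prot[j])
    # column d of `diags` holds the diagonal j - i = d - (m - 1)
    diags = np.full((m, n + m - 1), _NEG_INF, dtype=np.int64)
    for i in range(m):
        diags[i, m - 1 - i : m - 1 - i + n] = grid[i]
    run = diags[0].copy()
    best_per_col = run.copy()
    for i in range(1, m):
        np.maximum(run, 0, out=run)
        run += diags[i]
        np.maximum(best_per_col, run, out=best_per_col)
    best = int(best_per_col.max())
    if best <= 0:
        return None

    chosen = None
    for col in np.flatnonzero(best_per_col == best):
        d = int(col) - (m - 1)  # j - i
        i_lo, i_hi = max(0, -d), min(m, n - d)  # valid peptide rows
        # enumerate all O(m^2) windows on this diagonal for exact tie-breaking
        for start in range(i_lo, i_hi):
            run_s = 0
            for end in range(start, i_hi):
                run_s += int(grid[end, end + d])
                if run_s == best:
                    ps0 = start + d
                    key = (ps0, -(end - start), start)
                    if chosen is None or key < chosen[0]:
                        chosen = (key, (best, start, end, ps0, end + d))
    assert chosen is not None
    return chosen[1]


def _best_gapped(peptide: str, protein: str, scheme: ScoringScheme):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(scheme.matrix_name)
    aligner.open_gap_score = -float(scheme.gap_open)
    aligner.extend_gap_score = -float(scheme.gap_extend)
    score = aligner.score(peptide, protein)
    if score <= 0:
        return None
    aln = next(iter(aligner.align(peptide, protein)))
    (p0, p1) = aln.aligned[0][0][0], aln.aligned[0][-1][1]
    (t0, t1) = aln.aligned[1][0][0], aln.aligned[1][-1][1]
    return int(round(score)), p0, p1 - 1, t0, t1 - 1


def best_local_hit(
    peptide: str, protein: ProteinRecord, scheme: ScoringScheme
) -> AlignmentHit | None:
    """Best-scoring local alignment of ``peptide`` against ``protein``.

    Returns ``None`` when no alignment scores above zero. Ties are broken by
    smallest protein start, then longest alignment, so results are
    deterministic.
    """
    if not peptide or not protein.sequence:
        raise ValueError("peptide and protein must be non-empty")
    index, dense = _matrix_tables(scheme.matrix_name)
    pep = _encode(peptide, index, "peptide")
    prot = _encode(protein.sequence, index, "protein")
    if scheme.gapless:
        res = _best_gapless(pep, prot, dense)
    else:
        res = _best_gapped(peptide.upper(), protein.sequence.upper(), scheme)
    if res is None:
        return None
    raw, i0, i1, j0, j1 = res
    bits = scheme.bit_score(raw)
    ev = evalue_two_seq(raw, len(peptide), protein.length, scheme)
    return AlignmentHit(
        peptide=peptide.upper(),
        protein_accession=protein.accession,
        pep_start=i0 + 1,
        pep_end=i1 + 1,
        prot_start=j0 + 1,
        prot_end=j1 + 1,
        raw_score=int(raw),
        bit_score=bits,
        evalue=ev,
    )


def screen_database(
    peptides: Iterable[str],
    proteins: Sequence[ProteinRecord],
    scheme: ScoringScheme,
    bit_threshold: float,
) -> list[AlignmentHit]:
    """Best hit for every peptide x protein pair with bit score >= threshold.

    Exhaustive over all pairs; one hit (the best HSP) per pair. Output is
    sorted by (peptide, accession) for reproducibility.
    """
    proteins = list(proteins)
    if not proteins:
        warnings.warn("screen_database called with an empty protein database")
        return []
    hits: list[AlignmentHit] = []
    for pep in peptides:
        for prot in proteins:
            hit = best_local_hit(pep, prot, scheme)
            if hit is not None and hit.bit_score >= bit_threshold:
                hits.append(hit)
    hits.sort(key=lambda h: (h.peptide, h.protein_accession))
    return hits
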