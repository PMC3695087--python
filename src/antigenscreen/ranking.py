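"""Two-step candidate-antigen ranking.

A real antigen carrying linear epitopes collects matches from many distinct
selected peptides, while chance matches accrue in proportion to protein
length; both steps therefore normalize by length.

Step 1 (stringent shortlist): screen the most abundant peptides (default
120) against the whole database at a high bit-score threshold (default
18.5); keep proteins matched by at least two distinct peptides; rank by
initial score = distinct matching peptides / protein length; truncate to the
top 100.

Step 2 (exhaustive rescoring): align the full selected list (default 500)
against each shortlisted protein; sum the best-hit bit scores of all
peptides passing a permissive E-value cutoff (default 10); rank by final
score = summed bit scores / protein length. The major-epitope score (summed
bit scores at the single strongest clustered site) localizes the signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .epitopes import EpitopeSite, cluster_sites, major_epitope_score
from .pepalign import (
    AlignmentHit,
    ProteinRecord,
    ScoringScheme,
    best_local_hit,
    screen_database,
)
from .selection import PeptideList

__all__ = [
    "RankingParams",
    "CandidateAntigen",
    "step1_shortlist",
    "step2_final_rank",
    "format_initial_score",
    "format_final_score",
]


@dataclass(frozen=True)
class RankingParams:
    step1_bit_threshold: float = 18.5
    min_matches: int = 2
    top_candidates: int = 100
    step2_evalue_cutoff: float = 10.0
    n_step1: int = 120
    n_step2: int = 500

    def __post_init__(self) -> None:
        if self.top_candidates < 1:
            raise ValueError("top_candidates must be >= 1")


@dataclass
class CandidateAntigen:
    """Per-protein aggregate of the two-step screen (one report-table row)."""

    accession: str
    description: str
    length: int
    initial_matches: int = 0
    sum_overall_scores: float = 0.0
    major_epitope_score: float = 0.0
    matched_peptides: list[str] = field(default_factory=list)
    hits: list[AlignmentHit] = field(default_factory=list)
    sites: list[EpitopeSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.accession}: protein length must be positive")

    @property
    def initial_score(self) -> float:
        """Distinct step-1 matching peptides per residue of protein length."""
        return self.initial_matches / self.length

    @property
    def final_score(self) -> float:
        """Summed step-2 peptide match scores per residue of protein length."""
        return self.sum_overall_scores / self.length


def format_initial_score(value: float) -> str:
    """Initial score display: truncated (not rounded) to 4 decimals."""
    return f"{int(value * 10**4) / 10**4:.4f}"


def format_final_score(value: float) -> str:
    """Final score display: 7 significant figures, trailing zeros dropped."""
    return f"{value:.7g}"


def step1_shortlist(
    step1_peptides: PeptideList,
    proteins: Sequence[ProteinRecord],
    params: RankingParams,
    scheme: ScoringScheme,
) -> list[CandidateAntigen]:
    """Proteins hit above the bit threshold by >= min_matches distinct peptides.

    Ordered by descending initial score, then ascending accession; truncated
    to ``params.top_candidates``.
    """
    if not step1_peptides.entries:
        raise ValueError("step-1 peptide list is empty")
    hits = screen_database(
        step1_peptides.peptides, proteins, scheme, params.step1_bit_threshold
    )
    by_protein: dict[str, set[str]] = {}
    for hit in hits:
        by_protein.setdefault(hit.protein_accession, set()).add(hit.peptide)
    records = {p.accession: p for p in proteins}
    candidates = [
        CandidateAntigen(
            accession=acc,
            description=records[acc].description,
            length=records[acc].length,
            initial_matches=len(peps),
            matched_peptides=sorted(peps),
        )
        for acc, peps in by_protein.items()
        if len(peps) >= params.min_matches
    ]
    if not candidates:
        warnings.warn("no protein reached the step-1 match threshold")
    candidates.sort(key=lambda c: (-c.initial_score, c.accession))
    return candidates[: params.top_candidates]


def step2_final_rank(
    step2_peptides: PeptideList,
    shortlist: list[CandidateAntigen],
    proteins: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
    params: RankingParams,
    scheme: ScoringScheme,
) -> list[CandidateAntigen]:
    """Exhaustively rescore the shortlist against the full peptide list.

    For each candidate, every step-2 peptide's best local hit is included
    when its two-sequence E-value is at most ``params.step2_evalue_cutoff``;
    the final score is the summed bit scores divided by protein length.
    Epitope sites are clustered from the included hits and the major-epitope
    score populated. Ordered by descending final score, then ascending
    accession.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.accession: p for p in proteins}
    ranked: list[CandidateAntigen] = []
    for cand in shortlist:
        record = proteins[cand.accession]
        included: list[AlignmentHit] = []
        for pep in step2_peptides.peptides:
            hit = best_local_hit(pep, record, scheme)
            if hit is not None and hit.evalue <= params.step2_evalue_cutoff:
                included.append(hit)
        sites = cluster_sites(included)
        ranked.append(
            CandidateAntigen(
                accession=cand.accession,
                description=cand.description,
                length=cand.length,
                initial_matches=cand.initial_matches,
                sum_overall_scores=sum(h.bit_score for h in included),
                major_epitope_score=major_epitope_score(sites),
                matched_peptides=sorted({h.peptide for h in included}),
                hits=included,
                sites=sites,
            )
        )
    ranked.sort(key=lambda c: (-c.final_score, c.accession))
    return ranked
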