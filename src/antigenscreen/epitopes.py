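"""Epitope-site localization on candidate proteins.

Peptide hits that pile up on one stretch of a protein indicate a linear
epitope. Hits are clustered by single-linkage over their protein-coordinate
intervals (two hits join a site iff they share at least one residue;
adjacency is not overlap), each site accumulates the bit scores of its
member peptides, and the major-epitope score is the cumulative score of the
strongest site. Per-position profiles spread each hit's bit score uniformly
over its aligned residues, so the profile's total mass equals the summed bit
scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pepalign import AlignmentHit

__all__ = [
    "EpitopeSite",
    "PositionProfile",
    "cluster_sites",
    "major_epitope_score",
    "position_profile",
]


@dataclass
class EpitopeSite:
    """A maximal run of mutually overlapping peptide hits on one protein."""

    accession: str
    site_start: int
    site_end: int
    member_hits: list[AlignmentHit] = field(default_factory=list)

    @property
    def cumulative_score(self) -> float:
        return sum(h.bit_score for h in self.member_hits)

    @property
    def n_peptides(self) -> int:
        return len({h.peptide for h in self.member_hits})


@dataclass
class PositionProfile:
    accession: str
    values: np.ndarray

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())


def cluster_sites(hits: list[AlignmentHit]) -> list[EpitopeSite]:
    """Single-linkage clustering of hit intervals into non-overlapping sites.

    Two hits share a site iff their [prot_start, prot_end] intervals overlap
    by >= 1 residue, transitively closed. Sites are returned in descending
    cumulative score (ties: ascending start). Input order is irrelevant.
    """
    if not hits:
        return []
    accessions = {h.protein_accession for h in hits}
    if len(accessions) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(accessions)}")
    accession = accessions.pop()
    ordered = sorted(hits, key=lambda h: (h.prot_start, h.prot_end))
    sites: list[EpitopeSite] = []
    current = EpitopeSite(accession, ordered[0].prot_start, ordered[0].prot_end,
                          [ordered[0]])
    for hit in ordered[1:]:
        if hit.prot_start <= current.site_end:  # strict overlap, not adjacency
            current.member_hits.append(hit)
            current.site_end = max(current.site_end, hit.prot_end)
        else:
            sites.append(current)
            current = EpitopeSite(accession, hit.prot_start, hit.prot_end, [hit])
    sites.append(current)
    sites.sort(key=lambda s: (-s.cumulative_score, s.site_start))
    return sites


def major_epitope_score(sites: list[EpitopeSite]) -> float:
    """Cumulative score of the strongest site; 0 when there are no sites."""
    if not sites:
        return 0.0
    return max(s.cumulative_score for s in sites)


def position_profile(hits: list[AlignmentHit], protein_length: int) -> PositionProfile:
    """Per-residue score density: each hit spreads bit_score/length over its span.

    Conserves total score: the profile sums to the summed bit scores of the
    hits (to numeric precision).
    """
    values = np.zeros(protein_length, dtype=float)
    accession = hits[0].protein_accession if hits else ""
    for hit in hits:
        if hit.prot_start < 1 or hit.prot_end > protein_length:
            raise ValueError(
                f"hit [{hit.prot_start}, {hit.prot_end}] outside protein "
                f"of length {protein_length}"
            )
        span = hit.prot_end - hit.prot_start + 1
        values[hit.prot_start - 1 : hit.prot_end] += hit.bit_score / span
    return PositionProfile(accession, values)
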