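"""End-to-end convenience wrapper: count tables in, ranked candidates out."""

from __future__ import annotations

from typing import Sequence

from .pepalign import ProteinRecord, ScoringScheme
from .ranking import CandidateAntigen, RankingParams, step1_shortlist, step2_final_rank
from .readproc import PeptideCountTable
from .selection import SelectionSpec, select_private_top

__all__ = ["run_screen"]


def run_screen(
    sample_table: PeptideCountTable,
    control_tables: list[PeptideCountTable],
    proteins: Sequence[ProteinRecord],
    params: RankingParams | None = None,
    scheme: ScoringScheme | None = None,
) -> list[CandidateAntigen]:
    """Select private abundant peptides, shortlist, and rank candidate antigens.

    Runs the whole screen for one sample: control exclusion and top-N
    selection, step-1 stringent shortlisting against the database, step-2
    exhaustive rescoring with epitope-site localization. Returns the final
    ranked candidate list.
    """
    params = params or RankingParams()
    scheme = scheme or ScoringScheme()
    spec = SelectionSpec(
        sample=sample_table.sample,
        controls=tuple(t.sample for t in control_tables),
        n_step2=params.n_step2,
        n_step1=params.n_step1,
    )
    step2, step1 = select_private_top(sample_table, control_tables, spec)
    shortlist = step1_shortlist(step1, proteins, params, scheme)
    return step2_final_rank(step2, shortlist, proteins, params, scheme)
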