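"""Per-sample candidate peptide lists: abundant peptides private to a sample.

The screen compares an immunized/case sample against designated control
samples (other immunogens, naive animals, healthy donors) and keeps the most
abundant peptides that never occur in any control — presence in a control at
any count excludes a peptide. Two nested lists feed the downstream ranking:
the long list (default 500) for the exhaustive scoring step and its head
(default 120) for the stringent shortlisting step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .readproc import PeptideCountTable

__all__ = ["SelectionSpec", "PeptideList", "select_private_top"]


@dataclass(frozen=True)
class SelectionSpec:
    sample: str
    controls: tuple[str, ...] = ()
    n_step2: int = 500
    n_step1: int = 120

    def __post_init__(self) -> None:
        if self.n_step1 > self.n_step2:
            raise ValueError("n_step1 must not exceed n_step2")
        if self.n_step1 < 1:
            raise ValueError("list sizes must be positive")
        if self.sample in self.controls:
            raise ValueError(f"sample {self.sample!r} listed among its own controls")


@dataclass
class PeptideList:
    """Ranked (peptide, count) list; role 'step1' or 'step2'."""

    sample: str
    entries: list[tuple[str, int]] = field(default_factory=list)
    role: str = "step2"

    @property
    def peptides(self) -> list[str]:
        return [p for p, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def select_private_top(
    sample_table: PeptideCountTable,
    control_tables: list[PeptideCountTable],
    spec: SelectionSpec,
) -> tuple[PeptideList, PeptideList]:
    """Top-n peptides of a sample absent from every control table.

    Returns the (step2, step1) pair; the step-1 list is the head of the
    step-2 list. Ordering is descending count with lexicographic tie-break,
    so output is byte-reproducible. If fewer than ``n_step2`` peptides
    survive the control exclusion, all survivors are returned with a warning.
    """
    if not sample_table.counts:
        raise ValueError(f"sample table {sample_table.sample!r} is empty")
    excluded: set[str] = set()
    for ctrl in control_tables:
        excluded.update(ctrl.counts)
    survivors = [
        (pep, count)
        for pep, count in sample_table.counts.items()
        if pep not in excluded
    ]
    survivors.sort(key=lambda kv: (-kv[1], kv[0]))
    if len(survivors) < spec.n_step2:
        warnings.warn(
            f"sample {spec.sample!r}: only {len(survivors)} peptides survive "
            f"control exclusion (requested {spec.n_step2})"
        )
    step2 = PeptideList(spec.sample, survivors[: spec.n_step2], role="step2")
    step1 = PeptideList(spec.sample, step2.entries[: spec.n_step1], role="step1")
    return step2, step1
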