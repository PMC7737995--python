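"""Haplotype extraction from an aligned set of mtDNA sequences.

Identical sequences (exact string equality after normalisation) are
collapsed into haplotype classes H1, H2, ... numbered by first
appearance. From the collapsed set the polymorphic columns are
extracted, rendered in the conventional dot notation (a dot where a
haplotype matches the reference row), and tabulated per population or
per group.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .seqio import Alignment, AlignmentError, PopulationMap

__all__ = [
    "Haplotype",
    "HaplotypeSet",
    "VariableSiteTable",
    "collapse_haplotypes",
    "variable_sites",
    "dot_notation",
    "expand_dot_notation",
    "population_matrix",
    "haplotype_table",
]


def _round_pct(count: int, total: int) -> float:
    """Percentage 100*count/total, round-half-up to 2 decimals
    (55/120 → 45.83)."""
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class Haplotype:
    id: str
    sequence: str
    members: list[str]

    @property
    def hf(self) -> int:
        """Haplotype frequency: number of samples carrying it."""
        return len(self.members)


@dataclass
class HaplotypeSet:
    """Partition of the samples into identical-sequence classes."""

    haplotypes: list[Haplotype]
    n_samples: int

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    @property
    def ids(self) -> list[str]:
        return [h.id for h in self.haplotypes]

    @property
    def sequences(self) -> list[str]:
        return [h.sequence for h in self.haplotypes]

    def pct(self, hap_id: str) -> float:
        return _round_pct(self[hap_id].hf, self.n_samples)

    def __getitem__(self, hap_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.id == hap_id:
                return h
        raise KeyError(hap_id)

    def __iter__(self):
        return iter(self.haplotypes)

    def member_to_haplotype(self) -> dict[str, str]:
        return {m: h.id for h in self.haplotypes for m in h.members}


def collapse_haplotypes(al: Alignment) -> HaplotypeSet:
    """Collapse identical sequences into haplotypes.

    Membership is exact string equality; gaps and ambiguity codes are
    literal states, never wildcards, so the partition is well defined.
    Ids H1..Hk follow first appearance in input order.
    """
    classes: dict[str, Haplotype] = {}
    for label, seq in al.records():
        if seq not in classes:
            classes[seq] = Haplotype(
                id=f"H{len(classes) + 1}", sequence=seq, members=[]
            )
        classes[seq].members.append(label)
    return HaplotypeSet(haplotypes=list(classes.values()), n_samples=al.n)


@dataclass
class VariableSiteTable:
    """The polymorphic columns of a haplotype set.

    ``positions`` are 1-based site indices into the (post-trim)
    alignment, strictly increasing; ``states`` holds one row per
    haplotype restricted to those columns.
    """

    haplotype_ids: list[str]
    positions: list[int]
    states: list[str]

    @property
    def m(self) -> int:
        return len(self.positions)

    def row(self, hap_id: str) -> str:
        return self.states[self.haplotype_ids.index(hap_id)]


def variable_sites(hs: HaplotypeSet, acgt_only: bool = False) -> VariableSiteTable:
    """Extract the columns that vary among the haplotype sequences.

    A variable site is any column with >= 2 distinct characters across
    haplotypes; with ``acgt_only`` only differences among definite
    bases A/C/G/T count (gap and ambiguity-code variation is ignored).
    """
    if hs.k < 1:
        raise AlignmentError("empty haplotype set")
    seqs = hs.sequences
    L = len(seqs[0])
    positions: list[int] = []
    for col in range(L):
        states = {s[col] for s in seqs}
        if acgt_only:
            states &= set("ACGT")
        if len(states) >= 2:
            positions.append(col + 1)
    rows = ["".join(s[p - 1] for p in positions) for s in seqs]
    return VariableSiteTable(
        haplotype_ids=list(hs.ids), positions=positions, states=rows
    )


def dot_notation(vst: VariableSiteTable, reference_row: int = 0) -> list[str]:
    """Render the variable-site matrix with the reference row verbatim
    and a ``.`` wherever another row matches it. Invertible given the
    reference row (:func:`expand_dot_notation`)."""
    if not 0 <= reference_row < len(vst.states):
        raise IndexError(f"reference_row {reference_row} out of range")
    ref = vst.states[reference_row]
    out = []
    for i, row in enumerate(vst.states):
        if i == reference_row:
            out.append(row)
        else:
            out.append("".join("." if c == r else c for c, r in zip(row, ref)))
    return out


def expand_dot_notation(rows: list[str], reference: str) -> list[str]:
    """Invert :func:`dot_notation`: replace each dot with the reference
    character at that column."""
    out = []
    for row in rows:
        if len(row) != len(reference):
            raise AlignmentError("dot-notation row length differs from reference")
        out.append("".join(r if c == "." else c for c, r in zip(row, reference)))
    return out


def population_matrix(
    hs: HaplotypeSet, pm: PopulationMap, level: str = "population"
) -> pd.DataFrame:
    """Haplotype x category count matrix at ``level`` ("population" or
    "group"). Row sums equal hf; column sums equal category sizes."""
    if level not in ("population", "group"):
        raise ValueError(f"unknown level: {level!r}")
    cells: dict[str, dict[str, int]] = {}
    for h in hs:
        counts: dict[str, int] = {}
        for m in h.members:
            cat = pm.category_of(m, level)
            counts[cat] = counts.get(cat, 0) + 1
        cells[h.id] = counts
    columns = pm.populations if level == "population" else pm.groups
    df = pd.DataFrame(
        [[cells[h.id].get(c, 0) for c in columns] for h in hs],
        index=hs.ids,
        columns=columns,
        dtype=int,
    )
    return df


def haplotype_table(hs: HaplotypeSet, vst: VariableSiteTable) -> pd.DataFrame:
    """Summary table: one row per haplotype with its variable-site
    string, frequency, percentage and member list."""
    return pd.DataFrame(
        {
            "haplotype": hs.ids,
            "variable_sites": vst.states,
            "hf": [h.hf for h in hs],
            "pct": [_round_pct(h.hf, hs.n_samples) for h in hs],
            "members": [",".join(h.members) for h in hs],
        }
    ).set_index("haplotype")
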