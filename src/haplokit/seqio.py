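"""Aligned-FASTA input/output and sample-label bookkeeping.

The workflow's single input is an aligned (equal-length) multi-FASTA whose
record labels encode population membership as ``<Population><sep><number>``
with an underscore or space separator, e.g. ``Kumluca_6`` or
``Bayatbadem 24``. This module reads and validates that file, parses the
population (and optional group) structure out of the labels, and offers
end-trimming of gappy alignment flanks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import SeqIO

__all__ = [
    "Alignment",
    "PopulationMap",
    "AlignmentError",
    "read_fasta",
    "write_fasta",
    "parse_population",
    "build_population_map",
    "read_group_table",
    "trim_ends",
]

#: Characters accepted in aligned DNA: the four bases, gap, N and the
#: remaining IUPAC ambiguity codes.
DNA_ALPHABET = frozenset("ACGT-NRYSWKMBDHV")

_TRAILING_NUMBER = re.compile(r"[_ ]?[0-9]+$")


class AlignmentError(ValueError):
    """Raised for malformed alignments or unparseable labels."""


@dataclass
class Alignment:
    """An ordered, labelled, equal-length DNA alignment.

    Parameters
    ----------
    labels:
        Unique, non-empty record labels, in input order.
    sequences:
        Uppercase DNA strings, all of identical length.
    offset:
        Number of columns trimmed from the left of the original
        alignment; site positions reported elsewhere are 1-based in the
        *current* (post-trim) coordinate system.
    """

    labels: list[str]
    sequences: list[str]
    offset: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n(self) -> int:
        """Number of records."""
        return len(self.labels)

    @property
    def length(self) -> int:
        """Alignment length (number of sites)."""
        return len(self.sequences[0]) if self.sequences else 0

    def validate(self) -> None:
        if not self.labels:
            raise AlignmentError("alignment has no records")
        if len(self.labels) != len(self.sequences):
            raise AlignmentError("labels and sequences differ in number")
        if any(not lab for lab in self.labels):
            raise AlignmentError("empty record label")
        seen: dict[str, int] = {}
        for lab in self.labels:
            seen[lab] = seen.get(lab, 0) + 1
        dups = sorted(lab for lab, c in seen.items() if c > 1)
        if dups:
            raise AlignmentError(f"duplicate labels: {', '.join(dups)}")
        L = len(self.sequences[0])
        bad = [
            f"{lab} (length {len(seq)})"
            for lab, seq in zip(self.labels, self.sequences)
            if len(seq) != L
        ]
        if bad:
            raise AlignmentError(
                "sequences are not aligned to equal length: "
                f"expected {L}, offending records: {'; '.join(bad)}"
            )
        for lab, seq in zip(self.labels, self.sequences):
            extra = set(seq) - DNA_ALPHABET
            if extra:
                raise AlignmentError(
                    f"record {lab!r} contains non-DNA characters: {sorted(extra)}"
                )

    def records(self) -> Iterable[tuple[str, str]]:
        return zip(self.labels, self.sequences)

    def __len__(self) -> int:
        return self.n


def _normalize(seq: str) -> str:
    """Uppercase and map RNA U onto T so the pipeline sees one alphabet."""
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path, label_from: str = "header") -> Alignment:
    """Read an aligned multi-FASTA into an :class:`Alignment`.

    Sequences are uppercased and U is mapped to T. Record order is
    preserved. By default the label is the full header line minus the
    leading ``>`` (the dataset convention allows spaces inside labels,
    e.g. ``Bayatbadem 24``); pass ``label_from="first-token"`` to keep
    only the text before the first whitespace.
    """
    path = Path(path)
    if label_from not in ("header", "first-token"):
        raise ValueError(f"unknown label_from: {label_from!r}")
    labels, sequences = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = rec.id if label_from == "first-token" else rec.description
        labels.append(label.strip())
        sequences.append(_normalize(str(rec.seq)))
    if not labels:
        raise AlignmentError(f"no FASTA records found in {path}")
    return Alignment(labels=labels, sequences=sequences)


def write_fasta(al: Alignment, path: str | Path, width: int = 70) -> Path:
    """Write the alignment to FASTA; round-trips exactly through
    :func:`read_fasta` (labels may contain spaces, so the full header
    line is the label)."""
    path = Path(path)
    with open(path, "w") as fh:
        for label, seq in al.records():
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def parse_population(label: str) -> str:
    """Extract the population name from a sample label.

    Strips one trailing run of digits together with the single
    underscore or space immediately before it: ``"Kumluca_6"`` →
    ``"Kumluca"``, ``"Bayatbadem 24"`` → ``"Bayatbadem"``. A label with
    no trailing digits is returned unchanged. Idempotent by
    construction (the result never ends in a digit run preceded by a
    separator that the rule would strip again — stripping once removes
    the entire trailing digit run).
    """
    if not label:
        raise AlignmentError("empty sample label")
    name = _TRAILING_NUMBER.sub("", label)
    if not name:
        raise AlignmentError(
            f"label {label!r} has no population name left after removing "
            "the trailing sample number"
        )
    return name


@dataclass
class PopulationMap:
    """Sample → population assignment, with an optional population → group
    level on top (e.g. greenhouse / firm / nature provenance)."""

    sample_to_population: dict[str, str]
    population_to_group: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        if self.population_to_group is not None:
            missing = sorted(
                set(self.sample_to_population.values())
                - set(self.population_to_group)
            )
            if missing:
                raise AlignmentError(
                    f"group mapping missing populations: {', '.join(missing)}"
                )

    @property
    def populations(self) -> list[str]:
        """Population names, sorted."""
        return sorted(set(self.sample_to_population.values()))

    @property
    def groups(self) -> list[str]:
        if self.population_to_group is None:
            return []
        return sorted(set(self.population_to_group.values()))

    def population_of(self, label: str) -> str:
        try:
            return self.sample_to_population[label]
        except KeyError:
            raise AlignmentError(f"sample {label!r} has no population") from None

    def group_of(self, label: str) -> str:
        if self.population_to_group is None:
            raise AlignmentError("no group mapping attached")
        return self.population_to_group[self.population_of(label)]

    def category_of(self, label: str, level: str) -> str:
        """Dispatch on ``level``: the sample itself, its population, or
        its group."""
        if level == "individual":
            return label
        if level == "population":
            return self.population_of(label)
        if level == "group":
            return self.group_of(label)
        raise ValueError(f"unknown level: {level!r}")


def build_population_map(
    al: Alignment,
    groups: Optional[Mapping[str, str]] = None,
) -> PopulationMap:
    """Infer the population of every sample from its label and attach a
    population → group mapping verbatim when one is given."""
    s2p = {lab: parse_population(lab) for lab in al.labels}
    p2g = dict(groups) if groups is not None else None
    return PopulationMap(sample_to_population=s2p, population_to_group=p2g)


def read_group_table(path: str | Path) -> dict[str, str]:
    """Read a two-column ``population<TAB>group`` TSV."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise AlignmentError(f"malformed group-table line: {line!r}")
        mapping[parts[0]] = parts[1]
    return mapping


def trim_ends(al: Alignment, max_missing_fraction: float) -> Alignment:
    """Drop leading and trailing columns whose gap/N fraction exceeds
    ``max_missing_fraction``; interior columns are never touched and
    surviving characters are unaltered. The number of columns removed
    on the left is recorded as the new alignment's ``offset``."""
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")

    def missing_fraction(col: int) -> float:
        miss = sum(1 for seq in al.sequences if seq[col] in "-N")
        return miss / al.n

    lo, hi = 0, al.length
    while lo < hi and missing_fraction(lo) > max_missing_fraction:
        lo += 1
    while hi > lo and missing_fraction(hi - 1) > max_missing_fraction:
        hi -= 1
    if lo >= hi:
        raise AlignmentError("trimming removed every alignment column")
    if lo == 0 and hi == al.length:
        return al
    return Alignment(
        labels=list(al.labels),
        sequences=[seq[lo:hi] for seq in al.sequences],
        offset=al.offset + lo,
    )
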