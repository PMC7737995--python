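"""Bundled reference dataset and its synthetic reconstruction.

The package ships the published haplotype survey of 120 *Bombus
terrestris dalmatinus* mitochondrial cytochrome *b* sequences (373 bp,
8 populations of 15 bees from the Antalya region) as three small TSV
tables: the 20 haplotypes at their 41 variable sites in dot notation
with frequencies, the 20x20 pairwise Hamming distance matrix, and the
haplotype-by-population count matrix. These printed tables make the
distance/tree/network half of the workflow fully testable without the
original sequence file.

The original per-individual FASTA is not redistributed here;
:func:`synthetic_cytb_alignment` builds a *synthetic* stand-in for it
that is exact where the tables constrain it (haplotype strings at the
variable sites, per-population counts, 373 bp length) and arbitrary but
deterministic elsewhere (the monomorphic background and the genomic
positions of the variable sites).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .haplotype import HaplotypeSet, Haplotype, expand_dot_notation
from .seqio import Alignment

__all__ = [
    "POPULATIONS",
    "GROUPS",
    "reference_haplotype_table",
    "reference_haplotype_strings",
    "reference_hamming",
    "reference_population_counts",
    "reference_haplotype_set",
    "synthetic_cytb_alignment",
]

#: The eight sampled populations, alphabetical.
POPULATIONS = (
    "Aksu",
    "Bayatbadem",
    "Demre",
    "Firm",
    "Geyikbayir",
    "Kumluca",
    "Phaselis",
    "Termessos",
)

#: Provenance of each population: commercial greenhouses, a breeding
#: firm, or natural areas.
GROUPS = {
    "Aksu": "greenhouse",
    "Demre": "greenhouse",
    "Kumluca": "greenhouse",
    "Firm": "firm",
    "Bayatbadem": "nature",
    "Phaselis": "nature",
    "Geyikbayir": "nature",
    "Termessos": "nature",
}


def _data_path(name: str):
    return resources.files("haplokit.data").joinpath(name)


def reference_haplotype_table() -> pd.DataFrame:
    """The haplotype table as published: dot-notation variable-site
    strings (H1 is the reference row), frequency ``hf`` and percentage
    ``pct``."""
    with resources.as_file(_data_path("haplotype_table.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="haplotype")


def reference_haplotype_strings() -> dict[str, str]:
    """The 20 haplotypes as full 41-character variable-site strings
    (dots expanded against H1)."""
    tab = reference_haplotype_table()
    rows = list(tab["variable_sites"])
    expanded = expand_dot_notation(rows, rows[0])
    return dict(zip(tab.index, expanded))


def reference_hamming() -> DistanceMatrix:
    """The published 20x20 haplotype Hamming distance matrix (shipped
    in its lower-triangular layout)."""
    with resources.as_file(_data_path("hamming_reference.tsv")) as p:
        lines = p.read_text().splitlines()
    header = lines[0].split("\t")[1:]
    labels = [header[0]] + [row.split("\t")[0] for row in lines[1:]]
    k = len(labels)
    values = np.zeros((k, k))
    for i, row in enumerate(lines[1:], start=1):
        cells = row.split("\t")[1:]
        for j, v in enumerate(cells):
            values[i, j] = values[j, i] = int(v)
    return DistanceMatrix(labels=labels, values=values, metric="hamming")


def reference_population_counts() -> pd.DataFrame:
    """Haplotype x population count matrix for the reference dataset
    (rows sum to hf, every column sums to 15).

    Note: the Geyikbayir column as originally published is inconsistent
    with the haplotype frequencies (its entries for two rows are
    shifted); the bundled copy carries the reconciled assignment, the
    unique one consistent with both margins.
    """
    with resources.as_file(_data_path("population_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="haplotype")


def _member_labels() -> dict[str, list[str]]:
    """Deterministic per-haplotype member labels consistent with the
    population count matrix; individuals are numbered within each
    population."""
    counts = reference_population_counts()
    members: dict[str, list[str]] = {h: [] for h in counts.index}
    for pop in counts.columns:
        i = 0
        for h in counts.index:
            for _ in range(int(counts.loc[h, pop])):
                i += 1
                members[h].append(f"{pop}_{i}")
    return members


def reference_haplotype_set() -> HaplotypeSet:
    """The reference haplotypes as a :class:`HaplotypeSet` over their
    41-site strings, with synthetic member labels assigned per the
    population count matrix."""
    strings = reference_haplotype_strings()
    members = _member_labels()
    haps = [
        Haplotype(id=h, sequence=strings[h], members=members[h]) for h in strings
    ]
    n = sum(len(m) for m in members.values())
    return HaplotypeSet(haplotypes=haps, n_samples=n)


def synthetic_cytb_alignment(length: int = 373, background_seed: int = 373) -> Alignment:
    """Synthetic reconstruction of the 120-sequence cyt *b* alignment.

    The 41 variable sites are embedded at deterministic (seeded)
    positions in a ``length``-bp monomorphic background; each of the
    120 individuals carries the full-length sequence of its haplotype
    and a ``<Population>_<number>`` label per the population count
    matrix. Collapsing this alignment reproduces the published census
    exactly (20 haplotypes, modal hf 55, 41 polymorphic sites); the
    background and site positions are synthetic.
    """
    strings = reference_haplotype_strings()
    m = len(next(iter(strings.values())))
    if length < m:
        raise ValueError(f"length must be >= {m}")
    rng = np.random.default_rng(background_seed)
    background = rng.choice(list("ACGT"), size=length)
    var_pos = np.sort(rng.choice(length, size=m, replace=False))

    full: dict[str, str] = {}
    for h, s in strings.items():
        seq = background.copy()
        seq[var_pos] = list(s)
        full[h] = "".join(seq)

    members = _member_labels()
    records = sorted(
        ((lab, full[h]) for h, labs in members.items() for lab in labs),
        key=lambda r: (r[0].rsplit("_", 1)[0], int(r[0].rsplit("_", 1)[1])),
    )
    return Alignment(
        labels=[r[0] for r in records], sequences=[r[1] for r in records]
    )
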