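"""Seeded synthetic-data generator with known ground truth.

Emulates the structure of the study input: a set of planted haplotype
strings derived from a random ancestor by substitutions only (the
reference data are gapless), assigned to labelled populations with a
tunable degree of population structure — one dominant haplotype shared
across populations plus mostly-private minor haplotypes, the pattern
seen in the reference count matrix. The generator returns both the
labelled alignment and the ground truth, so every pipeline stage can be
checked against what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .seqio import Alignment

__all__ = ["SyntheticTruth", "generate_dataset", "DEFAULT_POPULATION_SIZES"]

#: Default sampling design: eight populations of 15 individuals, the
#: study's layout.
DEFAULT_POPULATION_SIZES: dict[str, int] = {
    "Aksu": 15,
    "Bayatbadem": 15,
    "Demre": 15,
    "Firm": 15,
    "Geyikbayir": 15,
    "Kumluca": 15,
    "Phaselis": 15,
    "Termessos": 15,
}

BASES = np.array(list("ACGT"))


@dataclass
class SyntheticTruth:
    """Everything the generator decided: planted haplotype strings,
    the realised haplotype x population assignment, the ancestor, the
    mutated positions per haplotype, and the seed."""

    ancestor: str
    haplotypes: list[str]
    assignment: pd.DataFrame  # haplotype index x population -> count
    mutation_positions: list[list[int]]
    seed: int

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    @property
    def counts(self) -> list[int]:
        return [int(c) for c in self.assignment.sum(axis=1)]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "ancestor": self.ancestor,
            "haplotypes": self.haplotypes,
            "mutation_positions": self.mutation_positions,
            "assignment": {
                pop: [int(v) for v in self.assignment[pop]]
                for pop in self.assignment.columns
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _plant_haplotypes(
    rng: np.random.Generator, k: int, length: int, divergence: tuple[int, int]
) -> tuple[str, list[str], list[list[int]]]:
    lo, hi = divergence
    if not 0 <= lo <= hi <= length:
        raise ValueError("divergence range must satisfy 0 <= lo <= hi <= length")
    if k > 4**length:
        raise ValueError(f"cannot plant {k} distinct haplotypes of length {length}")
    ancestor = "".join(rng.choice(BASES, size=length))
    haplotypes: list[str] = []
    positions: list[list[int]] = []
    seen = set()
    for j in range(k):
        for _attempt in range(1000):
            if j == 0:
                # first haplotype is the ancestor itself (the common type)
                seq, pos = ancestor, []
            else:
                m = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
                m = max(m, 1)  # non-first haplotypes must differ somewhere
                pos = sorted(int(p) for p in rng.choice(length, size=m, replace=False))
                chars = list(ancestor)
                for p in pos:
                    alts = [b for b in "ACGT" if b != chars[p]]
                    chars[p] = alts[int(rng.integers(0, 3))]
                seq = "".join(chars)
            if seq not in seen:
                break
        else:
            raise ValueError("could not plant distinct haplotypes; widen divergence")
        seen.add(seq)
        haplotypes.append(seq)
        positions.append(pos)
    return ancestor, haplotypes, positions


def _assign(
    rng: np.random.Generator,
    k: int,
    pop_sizes: Mapping[str, int],
    mixing: float,
) -> pd.DataFrame:
    """Draw a haplotype x population count matrix.

    ``mixing`` in [0, 1] is the expected share of individuals carrying
    the dominant (first) haplotype in every population; the remainder
    goes to a small population-private subset of the other haplotypes,
    mirroring the dominant-shared-plus-private structure of the
    reference data. Every haplotype is guaranteed at least one carrier.
    """
    if not 0.0 <= mixing <= 1.0:
        raise ValueError("mixing must lie in [0, 1]")
    pops = list(pop_sizes)
    counts = np.zeros((k, len(pops)), dtype=int)
    for pj, pop in enumerate(pops):
        weights = np.zeros(k)
        weights[0] = mixing if k > 1 else 1.0
        if k > 1:
            n_private = min(k - 1, max(1, int(np.ceil((k - 1) / len(pops)))) + 1)
            private = rng.choice(np.arange(1, k), size=n_private, replace=False)
            w = rng.dirichlet(np.ones(n_private))
            weights[private] = (1.0 - mixing) * w
        counts[:, pj] = rng.multinomial(pop_sizes[pop], weights / weights.sum())
    # guarantee every planted haplotype is observed at least once
    for h in range(k):
        if counts[h].sum() == 0:
            donor_h, donor_p = np.unravel_index(np.argmax(counts), counts.shape)
            counts[donor_h, donor_p] -= 1
            counts[h, donor_p] += 1
    return pd.DataFrame(counts, columns=pops)


def generate_dataset(
    k: int = 20,
    length: int = 373,
    population_sizes: Optional[Mapping[str, int]] = None,
    divergence: tuple[int, int] = (1, 25),
    mixing: float = 0.45,
    seed: int = 0,
) -> tuple[Alignment, SyntheticTruth]:
    """Generate a labelled aligned FASTA-ready dataset with known truth.

    Defaults mirror the study conditions: 20 haplotypes over 373 bp,
    eight populations of 15, per-haplotype divergence of 1–25
    substitutions from the ancestor, and a dominant haplotype carried
    by slightly under half the sample.

    Returns the alignment (labels ``<Population>_<i>``, numbered within
    population, ordered by population) and the ground truth.
    """
    if k < 1:
        raise ValueError("need k >= 1 haplotypes")
    pop_sizes = dict(population_sizes or DEFAULT_POPULATION_SIZES)
    n = sum(pop_sizes.values())
    if n < k:
        raise ValueError(f"total sample size {n} < k={k}")
    rng = np.random.default_rng(seed)
    ancestor, haplotypes, positions = _plant_haplotypes(rng, k, length, divergence)
    assignment = _assign(rng, k, pop_sizes, mixing)

    labels: list[str] = []
    sequences: list[str] = []
    for pop in pop_sizes:
        i = 0
        for h in range(k):
            for _ in range(int(assignment.loc[h, pop])):
                i += 1
                labels.append(f"{pop}_{i}")
                sequences.append(haplotypes[h])
    truth = SyntheticTruth(
        ancestor=ancestor,
        haplotypes=haplotypes,
        assignment=assignment,
        mutation_positions=positions,
        seed=seed,
    )
    return Alignment(labels=labels, sequences=sequences), truth
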