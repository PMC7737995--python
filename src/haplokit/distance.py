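"""Pairwise distance matrices: literal Hamming counts and Kimura
two-parameter (K80) model distances.

Hamming counts every position at which two equal-length strings differ,
comparing all characters literally (gaps and ambiguity codes included),
which is what the haplotype distance table and the network weights use.
K80 is a substitution model with separate transition (A<->G, C<->T) and
transversion rates,

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q),

with P and Q the observed transition and transversion proportions over
the usable sites; it needs definite bases, so non-ACGT characters are
excluded under the active deletion policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import Alignment

__all__ = [
    "DistanceMatrix",
    "UndefinedDistanceError",
    "hamming",
    "hamming_matrix",
    "k80_distance",
    "k80_pair",
    "k80_matrix",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class UndefinedDistanceError(ValueError):
    """K80 distance undefined: divergence too large for the model
    (log argument <= 0) or no usable sites for a pair."""


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix over labelled sequences or
    haplotypes; ``metric`` is ``"hamming"`` (integer-valued) or
    ``"k80"``."""

    labels: list[str]
    values: np.ndarray
    metric: str = "hamming"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def k(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path, fmt: str = "square") -> Path:
        """Write as TSV: ``square`` (full matrix) or ``lower``
        (strictly lower-triangular, one fewer row/column, matching the
        conventional published layout)."""
        path = Path(path)
        is_int = self.metric == "hamming"

        def cell(v: float) -> str:
            return str(int(round(v))) if is_int else f"{v:.6f}"

        with open(path, "w") as fh:
            if fmt == "square":
                fh.write("\t" + "\t".join(self.labels) + "\n")
                for i, lab in enumerate(self.labels):
                    fh.write(
                        lab + "\t" + "\t".join(cell(v) for v in self.values[i]) + "\n"
                    )
            elif fmt == "lower":
                fh.write("\t" + "\t".join(self.labels[:-1]) + "\n")
                for i in range(1, self.k):
                    row = [cell(self.values[i, j]) for j in range(i)]
                    fh.write(self.labels[i] + "\t" + "\t".join(row) + "\n")
            else:
                raise ValueError(f"unknown format: {fmt!r}")
        return path


def hamming(a: str, b: str) -> int:
    """Number of positions at which two equal-length strings differ."""
    if len(a) != len(b):
        raise ValueError("Hamming distance needs equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def _as_labelled_seqs(
    seqs: Alignment | Sequence[tuple[str, str]],
    labels: Sequence[str] | None,
) -> tuple[list[str], list[str]]:
    if isinstance(seqs, Alignment):
        return list(seqs.labels), list(seqs.sequences)
    if labels is not None:
        return list(labels), list(seqs)  # type: ignore[arg-type]
    labs, ss = zip(*seqs)
    return list(labs), list(ss)


def hamming_matrix(
    seqs: Alignment | Sequence[tuple[str, str]] | Sequence[str],
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Pairwise Hamming distance matrix over labelled equal-length
    strings. Accepts an :class:`Alignment`, an iterable of
    ``(label, sequence)`` pairs, or plain sequences plus ``labels``."""
    labs, ss = _as_labelled_seqs(seqs, labels)
    if len(ss) < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array([list(s) for s in ss])
    # broadcast character comparison over all pairs
    k = len(ss)
    values = np.zeros((k, k), dtype=float)
    for i in range(k):
        values[i] = (arr != arr[i]).sum(axis=1)
    return DistanceMatrix(labels=labs, values=values, metric="hamming")


def k80_distance(p: float, q: float) -> float:
    """K80 distance from transition proportion ``p`` and transversion
    proportion ``q``. Raises :class:`UndefinedDistanceError` where the
    model's logarithms are undefined rather than returning NaN."""
    if p < 0 or q < 0 or p + q > 1:
        raise ValueError("need p, q >= 0 and p + q <= 1")
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise UndefinedDistanceError(
            f"K80 undefined for p={p:.4g}, q={q:.4g} (saturated divergence)"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def _is_transition(x: str, y: str) -> bool:
    return (x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES)


def k80_pair(a: str, b: str) -> float:
    """K80 distance between two sequences with pairwise deletion of
    non-ACGT sites."""
    usable = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    if not usable:
        raise UndefinedDistanceError("no usable (definite-base) sites for pair")
    n = len(usable)
    ts = sum(1 for x, y in usable if x != y and _is_transition(x, y))
    tv = sum(1 for x, y in usable if x != y and not _is_transition(x, y))
    return k80_distance(ts / n, tv / n)


def k80_matrix(al: Alignment, site_policy: str = "global-deletion") -> DistanceMatrix:
    """Pairwise K80 distance matrix over an alignment.

    ``site_policy="global-deletion"`` (default) drops every column that
    contains a non-ACGT character in any sequence before all
    comparisons; ``"pairwise-deletion"`` drops such sites per pair.
    """
    if al.n < 2:
        raise ValueError("need at least 2 sequences")
    seqs = al.sequences
    if site_policy == "global-deletion":
        keep = [
            c
            for c in range(al.length)
            if all(s[c] in "ACGT" for s in seqs)
        ]
        seqs = ["".join(s[c] for c in keep) for s in seqs]
    elif site_policy != "pairwise-deletion":
        raise ValueError(f"unknown site_policy: {site_policy!r}")
    k = al.n
    values = np.zeros((k, k), dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                d = k80_pair(seqs[i], seqs[j])
            except UndefinedDistanceError as exc:
                raise UndefinedDistanceError(
                    f"pair ({al.labels[i]}, {al.labels[j]}): {exc}"
                ) from None
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=list(al.labels), values=values, metric="k80")
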