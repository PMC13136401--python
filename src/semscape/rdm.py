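"""Labeled representational dissimilarity matrices (RDMs).

An RDM is a symmetric, zero-diagonal matrix of pairwise dissimilarities over
a set of labeled entities (languages or participants).  Entries need not be
non-negative in general: the semantic distance convention used downstream
(``1 - atanh(r)``) can dip below zero for very strong correlations, which is
harmless because every RDM is standardized before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-8

#: serialization format for all tabular float output (10 significant digits)
FLOAT_FMT = "%.10g"


class RDMError(ValueError):
    """Malformed dissimilarity matrix (asymmetry, label mismatch, non-finite)."""


@dataclass
class RDM:
    labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise RDMError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise RDMError("duplicate labels in RDM")
        if not np.all(np.isfinite(self.values)):
            raise RDMError("non-finite entries in RDM")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise RDMError(f"matrix asymmetric beyond tolerance (max |a-a'| = {asym:g})")
        # exact symmetry internally
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries (excluding the diagonal), pair order (i<j)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def pairs(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n, k=1)
        return [(self.labels[i], self.labels[j]) for i, j in zip(*iu)]

    def subset(self, labels: list[str]) -> "RDM":
        idx = [self.labels.index(str(l)) for l in labels]
        return RDM([self.labels[i] for i in idx], self.values[np.ix_(idx, idx)])

    @classmethod
    def from_condensed(cls, labels, condensed) -> "RDM":
        n = len(labels)
        m = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        m[iu] = condensed
        m = m + m.T
        return cls(list(labels), m)


def read_rdm(path) -> RDM:
    """Read a labeled square CSV as an RDM.

    Rejects rather than repairs: asymmetry beyond ``SYMMETRY_TOL`` or a
    row/column label mismatch is an error.
    """
    df = pd.read_csv(path, index_col=0)
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        raise RDMError(f"row/column label mismatch in {path}")
    return RDM(rows, df.to_numpy(dtype=float))


def write_rdm(rdm: RDM, path) -> None:
    """Write an RDM as labeled CSV with the diagonal forced to exact zero."""
    values = rdm.values.copy()
    np.fill_diagonal(values, 0.0)
    pd.DataFrame(values, index=rdm.labels, columns=rdm.labels).to_csv(
        path, float_format=FLOAT_FMT
    )
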