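"""Expression-matrix container shared across the package.

Expression data are held as a plain samples-by-genes numeric matrix with
gene and sample identifiers.  The ``standardized`` flag records whether
columns have been centered and scaled to unit sample standard deviation,
which the regression machinery requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """A samples x genes expression matrix.

    Parameters
    ----------
    values
        Numeric array of shape ``(n_samples, n_genes)``.
    gene_ids
        Unique gene identifiers, one per column.
    sample_ids
        Sample identifiers, one per row; generated if omitted.
    standardized
        True when columns are centered with unit sample standard deviation.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...] = field(default=())
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D samples x genes array")
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        if len(self.gene_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers: {dupes}")
        if not self.sample_ids:
            self.sample_ids = tuple(f"sample_{i}" for i in range(self.values.shape[0]))
        else:
            self.sample_ids = tuple(str(s) for s in self.sample_ids)
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample id count does not match row count")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at sample {self.sample_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, standardized: bool = False) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=tuple(map(str, df.columns)),
            sample_ids=tuple(map(str, df.index)),
            standardized=standardized,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.sample_ids), columns=list(self.gene_ids)
        )

    def standardize(self, ddof: int = 1) -> "ExpressionMatrix":
        """Return a copy with centered columns scaled to unit sample sd."""
        sd = self.values.std(axis=0, ddof=ddof)
        if np.any(sd == 0):
            zero = [g for g, s in zip(self.gene_ids, sd) if s == 0]
            raise ValueError(f"constant expression column(s): {zero}")
        vals = (self.values - self.values.mean(axis=0)) / sd
        return ExpressionMatrix(
            values=vals,
            gene_ids=self.gene_ids,
            sample_ids=self.sample_ids,
            standardized=True,
        )

    def column(self, gene: str) -> np.ndarray:
        try:
            j = self.gene_ids.index(str(gene))
        except ValueError as exc:
            raise KeyError(f"unknown gene identifier {gene!r}") from exc
        return self.values[:, j]

    def subset_samples(self, rows) -> "ExpressionMatrix":
        rows = np.asarray(rows)
        return ExpressionMatrix(
            values=self.values[rows],
            gene_ids=self.gene_ids,
            sample_ids=tuple(self.sample_ids[i] for i in rows),
            standardized=self.standardized,
        )
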