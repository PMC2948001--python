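"""Gene-by-sample expression matrix container and plain-text I/O.

The matrix carries an explicit ``scale`` tag so downstream operations can
refuse inputs on the wrong scale (e.g. fold changes are undefined on a
gene-standardized matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised scale tags, in the order they are produced by preprocessing.
SCALES = ("raw", "log2", "log2_qnorm", "standardized")


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression values with a scale tag.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene id, columns by sample id; values numeric and
        finite. Raw-scale values must be strictly positive.
    scale : str
        One of :data:`SCALES`.
    """

    data: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}; expected one of {SCALES}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values.astype(float))):
            raise ValueError("expression matrix contains missing or non-finite values")
        if self.scale == "raw" and values.size and not (values > 0).all():
            raise ValueError("raw-scale expression values must be strictly positive")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.scale)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.scale)

    def filter_genes(self, allow_list) -> "ExpressionMatrix":
        """Keep only genes in ``allow_list`` (annotation-style id filter)."""
        allowed = set(allow_list)
        keep = [g for g in self.data.index if g in allowed]
        return ExpressionMatrix(self.data.loc[keep], self.scale)

    # -- plain-text I/O --------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write tab-separated text with a ``#scale=`` sidecar comment line."""
        with open(path, "w") as fh:
            fh.write(f"#scale={self.scale}\n")
            self.data.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def read_tsv(cls, path, scale: str | None = None) -> "ExpressionMatrix":
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#scale="):
                tag = first.strip().split("=", 1)[1]
            else:
                fh.seek(0)
                tag = "raw"
            frame = pd.read_csv(fh, sep="\t", index_col="gene_id")
        return cls(frame, scale if scale is not None else tag)

    @classmethod
    def read_series_matrix(cls, path, scale: str = "log2_qnorm") -> "ExpressionMatrix":
        """Read the table block of a GEO series-matrix file.

        Lines outside the ``!series_matrix_table_begin`` /
        ``!series_matrix_table_end`` delimiters are ignored.
        """
        rows: list[str] = []
        inside = False
        with open(path) as fh:
            for line in fh:
                if line.startswith("!series_matrix_table_begin"):
                    inside = True
                    continue
                if line.startswith("!series_matrix_table_end"):
                    break
                if inside:
                    rows.append(line)
        if not rows:
            raise ValueError(f"no series-matrix table block found in {path}")
        from io import StringIO

        frame = pd.read_csv(StringIO("".join(rows)), sep="\t", index_col=0)
        frame.index.name = "gene_id"
        frame.index = frame.index.astype(str)
        return cls(frame, scale)
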