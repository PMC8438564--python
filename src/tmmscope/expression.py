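"""Gene-by-sample expression matrix container and plain-text IO (TSV and GCT 1.2).

The pipeline is rank-based, so expression units are platform-agnostic; the only
hard requirements are uniqueness of gene symbols / sample ids and finite,
non-negative, non-missing values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


class ExpressionMatrix:
    """Immutable-ish wrapper around a genes x samples :class:`pandas.DataFrame`.

    Parameters
    ----------
    df
        DataFrame with gene symbols as the index and sample ids as columns.
        Values must be finite, non-negative reals with no missing entries.
    """

    def __init__(self, df: pd.DataFrame):
        if not isinstance(df, pd.DataFrame):
            raise TypeError("expression matrix must be a pandas DataFrame")
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError("expression matrix must have at least one gene and one sample")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate gene symbols: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate sample ids: {dup}")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite (no NaN/inf); impute or drop first")
        if (values < 0).any():
            raise ValueError("expression values must be non-negative")
        self._df = df.astype(float)
        self._df.index = self._df.index.astype(str).str.strip()
        self._df.columns = self._df.columns.astype(str).str.strip()
        self._df.index.name = None
        self._df.columns.name = None

    # -- basic accessors ---------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def genes(self) -> list[str]:
        return self._df.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self._df.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self._df.loc[:, list(sample_ids)])

    # -- IO ----------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        """Read a tab-delimited genes-in-rows matrix (first column = symbols).

        Lines starting with ``#`` are treated as comments.
        """
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(df)

    def write_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self._df.to_csv(fh, sep="\t", index_label="gene")

    @classmethod
    def read_gct(cls, path) -> "ExpressionMatrix":
        """Read a GCT 1.2 file (version line, dimension line, Name/Description header)."""
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ValueError(f"unsupported GCT version line: {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ValueError("malformed GCT dimension line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
        if df.shape != (n_genes, n_samples):
            raise ValueError(
                f"GCT dimension line says {(n_genes, n_samples)} but table is {df.shape}"
            )
        return cls(df)

    def write_gct(self, path) -> None:
        g, s = self.shape
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{g}\t{s}\n")
            out = self._df.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
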