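"""Ortholog abundance matrix container.

The abundance unit is the user's (gene counts, RPKM, spectral counts, ...):
the workflow is agnostic to it because presence calls depend only on
positivity and the rank-sum test depends only on order.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AbundanceMatrix", "AbundanceMatrixError"]


class AbundanceMatrixError(ValueError):
    """Invalid abundance matrix content."""


@dataclass
class AbundanceMatrix:
    """Non-negative ortholog × sample measurements.

    ``data`` is a pandas DataFrame indexed by ortholog identifier with one
    column per sample.  All values must be finite and ≥ 0; ortholog and
    sample identifiers must be unique non-empty strings.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise AbundanceMatrixError(f"duplicate ortholog identifiers: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise AbundanceMatrixError(f"duplicate sample identifiers: {dups[:5]}")
        for ident in list(df.index) + list(df.columns):
            if not isinstance(ident, str) or not ident or ident.strip() != ident or not ident.strip():
                raise AbundanceMatrixError(f"invalid identifier {ident!r}")
        values = df.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise AbundanceMatrixError("abundance values must be finite")
        if values.size and (values < 0).any():
            raise AbundanceMatrixError("abundance values must be non-negative")
        # normalise dtype so downstream arithmetic is float
        self.data = df.astype(float)

    @property
    def orthologs(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def sample_abundances(self, sample: str) -> dict[str, float]:
        """Ortholog → abundance mapping for one sample."""
        return self.data[sample].to_dict()

    @classmethod
    def from_tsv(cls, path_or_stream) -> "AbundanceMatrix":
        """Read the input TSV: header ``ortholog<TAB>sample1<TAB>...``.

        Ragged rows are a hard error naming the offending line number.
        """
        if hasattr(path_or_stream, "read"):
            text = path_or_stream.read()
            name = "<stream>"
        else:
            with open(path_or_stream, encoding="utf-8") as fh:
                text = fh.read()
            name = str(path_or_stream)
        lines = text.splitlines()
        if not lines:
            raise AbundanceMatrixError(f"{name}: empty abundance table")
        n_fields = len(lines[0].split("\t"))
        for i, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            if len(line.split("\t")) != n_fields:
                raise AbundanceMatrixError(
                    f"{name}: line {i}: expected {n_fields} tab-separated fields, "
                    f"got {len(line.split(chr(9)))}"
                )
        df = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0, dtype={0: str})
        df.index = df.index.astype(str)
        df.columns = [str(c) for c in df.columns]
        try:
            return cls(df)
        except AbundanceMatrixError as exc:
            raise AbundanceMatrixError(f"{name}: {exc}") from exc

    def to_tsv(self, path, float_fmt: str = "%.6g") -> None:
        """Write the matrix as a TSV with fixed float formatting."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("ortholog\t" + "\t".join(self.samples) + "\n")
            for orth in self.orthologs:
                row = self.data.loc[orth]
                fh.write(orth + "\t" + "\t".join(float_fmt % v for v in row) + "\n")
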