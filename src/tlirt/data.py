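"""Response-data container and CSV I/O."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ResponseData"]


@dataclass(frozen=True)
class ResponseData:
    """An N x n matrix of 0-based category codes.

    Missing responses are not supported: any negative or out-of-range code
    is a hard error at construction.
    """

    codes: np.ndarray
    K: int

    def __post_init__(self):
        codes = np.asarray(self.codes)
        if codes.ndim != 2:
            raise ValueError("response data must be a 2-D matrix")
        if not np.issubdtype(codes.dtype, np.integer):
            if not np.all(codes == np.asarray(codes, dtype=int)):
                raise ValueError("response codes must be integers")
            codes = codes.astype(int)
        if codes.size and (codes.min() < 0 or codes.max() >= self.K):
            bad = np.argwhere((codes < 0) | (codes >= self.K))[0]
            raise ValueError(
                f"response code {codes[bad[0], bad[1]]} out of range 0..{self.K - 1} "
                f"at row {bad[0] + 1}, column {bad[1] + 1}"
            )
        object.__setattr__(self, "codes", codes)

    @property
    def n_respondents(self) -> int:
        return self.codes.shape[0]

    @property
    def n_items(self) -> int:
        return self.codes.shape[1]

    def grouped(self):
        """Unique response patterns and their counts (counts sum to N)."""
        patterns, counts = np.unique(self.codes, axis=0, return_counts=True)
        return patterns, counts

    def category_counts(self) -> np.ndarray:
        """Per-item category counts, shape (n, K)."""
        out = np.zeros((self.n_items, self.K), dtype=int)
        for k in range(self.K):
            out[:, k] = (self.codes == k).sum(axis=0)
        return out

    @classmethod
    def from_grouped(cls, patterns: np.ndarray, counts: np.ndarray, K: int) -> "ResponseData":
        codes = np.repeat(np.asarray(patterns, dtype=int), np.asarray(counts, dtype=int), axis=0)
        return cls(codes=codes, K=K)

    def to_csv(self, path, item_names=None) -> None:
        names = item_names or [f"item{i + 1}" for i in range(self.n_items)]
        pd.DataFrame(self.codes, columns=names).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, K: int) -> "ResponseData":
        df = pd.read_csv(path)
        if "count" in df.columns:
            counts = df.pop("count").to_numpy(int)
            return cls.from_grouped(df.to_numpy(), counts, K)
        arr = df.to_numpy()
        if np.issubdtype(arr.dtype, np.floating) and np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValueError(f"missing response at row {r + 2} (line), column '{df.columns[c]}'")
        try:
            return cls(codes=arr, K=K)
        except ValueError as err:
            raise ValueError(f"{path}: {err}") from err
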