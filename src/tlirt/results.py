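"""Result containers shared by the full- and limited-information statistics."""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as _stats

__all__ = ["FitStatistics"]


@dataclass(frozen=True)
class FitStatistics:
    """A goodness-of-fit statistic referred to a chi-square distribution.

    Attributes
    ----------
    value : float
        Observed statistic.
    df : int
        Degrees of freedom of the reference chi-square.
    p : float
        Upper-tail probability.
    N : int
        Sample size (number of respondents).
    statistic_kind : str
        One of ``"M2"``, ``"G2"``, ``"X2"``.
    """

    value: float
    df: int
    p: float
    N: int
    statistic_kind: str

    def __post_init__(self):
        if self.df < 0:
            raise ValueError("degrees of freedom must be nonnegative")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")

    @classmethod
    def from_value(cls, value: float, df: int, N: int, statistic_kind: str) -> "FitStatistics":
        p = float(_stats.chi2.sf(value, df)) if df > 0 else float("nan")
        if df <= 0:
            p = 1.0 if value <= 0 else 0.0
        return cls(value=float(value), df=int(df), p=p, N=int(N), statistic_kind=statistic_kind)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic_kind,
            "value": self.value,
            "df": self.df,
            "p": self.p,
            "N": self.N,
        }
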