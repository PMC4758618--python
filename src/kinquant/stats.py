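"""Population summaries, significance testing, and copy-number arithmetic.

Genotype arms are summarized as mean +- sd of control-normalized values in
the legend style of the source experiments ("1.00+-0.25"); arms are compared
with a two-sided two-sample t test (Welch by default, since the arm
variances typically differ) and the significance convention is a single
three-star marker at p < 1e-4.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ConfigError

#: Significance threshold for the three-star convention.
STAR_P_THRESHOLD = 1e-4


@dataclass(frozen=True)
class GenotypeSummary:
    """mean +- sd summary of one genotype arm's normalized values."""

    label: str
    n: int
    mean: float
    sd: float

    @property
    def formatted(self) -> str:
        """Legend-style string, 2 decimal places: ``"1.00±0.25"``."""
        return f"{self.mean:.2f}±{self.sd:.2f}"


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample t test outcome with the three-star convention."""

    t: float
    df: float
    p: float

    @property
    def stars(self) -> str:
        return "***" if self.p < STAR_P_THRESHOLD else ""

    @property
    def significant(self) -> bool:
        return self.p < STAR_P_THRESHOLD


def summarize(values, label: str) -> GenotypeSummary:
    """Sample mean and sample s.d. (n-1 denominator) of one arm."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ConfigError(f"arm {label!r}: need n >= 2 to summarize, got {values.size}")
    return GenotypeSummary(label=label, n=int(values.size),
                           mean=float(values.mean()),
                           sd=float(values.std(ddof=1)))


def compare(reference, test, equal_var: bool = False) -> ComparisonResult:
    """Two-sided two-sample t test of ``test`` vs ``reference``.

    Welch's unequal-variance form by default; ``equal_var=True`` selects the
    pooled Student's variant.  The degenerate zero-variance/equal-means case
    returns t = 0, p = 1.
    """
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.size < 2 or test.size < 2:
        raise ConfigError("both populations need n >= 2 for a t test")
    if reference.var(ddof=1) == 0.0 and test.var(ddof=1) == 0.0:
        df = float(reference.size + test.size - 2)
        if reference.mean() == test.mean():
            return ComparisonResult(t=0.0, df=df, p=1.0)
        return ComparisonResult(t=math.copysign(math.inf, test.mean() - reference.mean()),
                                df=df, p=0.0)
    result = sps.ttest_ind(test, reference, equal_var=equal_var)
    return ComparisonResult(t=float(result.statistic), df=float(result.df),
                            p=float(result.pvalue))


def mind_copies(baseline_complexes: float = 6.5, relative_level: float = 1.0) -> int:
    """Additional MIND complexes per kinetochore implied by a fold-change.

    With ``baseline_complexes`` MIND complexes per anaphase kinetochore
    (default 6.5, midpoint of the 6-7 estimate for two Cse4 nucleosomal
    copies per centromere), a control-normalized level of ``relative_level``
    corresponds to ``round(baseline * (relative_level - 1))`` extra
    complexes; e.g. a ~30% increase of Mtw1/Dsn1 is ~2 additional complexes.
    Rounding is half-away-from-zero.
    """
    if baseline_complexes <= 0:
        raise ConfigError("baseline_complexes must be positive")
    if relative_level <= 0:
        raise ConfigError("relative_level must be positive")
    delta = baseline_complexes * (relative_level - 1.0)
    return int(math.copysign(math.floor(abs(delta) + 0.5), delta)) if delta else 0
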