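"""Transcription shut-off mRNA half-life estimation.

After a transcription inhibitor (thiolutin) is added, target abundance is
measured by qPCR before (t0) and after (t1, default 30 min) treatment,
normalized to a reference gene (GAPDH for decay assays, ACT1 for UPR time
courses).  With first-order decay X(t) = X(0) * 2^(-t/T), the two-point
estimator is

    T = (t1 - t0) / log2(X(t0) / X(t1))

i.e. the elapsed time divided by the number of halvings; a remaining
fraction of one half over 30 min gives T = 30 min exactly.  Series with
three or more timepoints are fitted by least squares of log2 X(t) on t with
T = -1/slope.  Remaining fractions at or above one (induction — thiolutin
itself triggers ER stress) are flagged non-decaying rather than producing
a negative half-life.

At steady state of first-order synthesis-decay, X* = k/delta with
delta = ln2/T, so the predicted abundance ratio between two strains is
(k1/k2) * (T1/T2): a two-fold stability change alone accounts for a
two-fold steady-state difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import QpcrRecord

__all__ = [
    "DecaySeries",
    "HalfLifeEstimate",
    "qpcr_normalize",
    "remaining_fraction",
    "RemainingFraction",
    "half_life_two_point",
    "half_life_fit",
    "half_life_ratio",
    "steady_state_ratio",
    "DecayModel",
    "DecayResults",
]


@dataclass
class DecaySeries:
    """Normalized abundance of one gene over a shut-off time course."""

    gene: str
    condition: str
    timepoints: tuple[float, ...]  # minutes, strictly increasing, t0 = 0
    abundances: tuple[float, ...]  # target/reference, dimensionless > 0

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        x = np.asarray(self.abundances, dtype=float)
        if t.size != x.size or t.size < 2:
            raise ValueError("need matching timepoints/abundances, at least 2 points")
        if t[0] != 0:
            raise ValueError("series must include the pre-treatment timepoint t0 = 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(x <= 0):
            raise ValueError("abundances must be strictly positive")


@dataclass
class HalfLifeEstimate:
    """A first-order decay half-life with its provenance."""

    half_life: float  # minutes; +inf when flagged non-decaying
    remaining_fraction: float
    method: Literal["two_point", "loglinear_fit"]
    stderr: float | None = None  # minutes, fit-based only
    non_decaying: bool = False
    gene: str = ""
    condition: str = ""

    def __float__(self) -> float:
        return float(self.half_life)

    def __str__(self) -> str:
        label = f"{self.gene}/{self.condition}".strip("/")
        if self.non_decaying:
            return f"{label}: non-decaying (remaining fraction {self.remaining_fraction:.3f})"
        se = f" +/- {self.stderr:.1f}" if self.stderr is not None else ""
        return f"{label}: T1/2 = {self.half_life:.1f}{se} min ({self.method})"


@dataclass(frozen=True)
class RemainingFraction:
    value: float
    non_decaying: bool

    def __float__(self) -> float:
        return self.value


def qpcr_normalize(record: QpcrRecord | None = None, value: float | None = None,
                   reference_value: float | None = None) -> float:
    """Reference-gene normalization: target abundance / reference abundance."""
    if record is not None:
        value, reference_value = record.value, record.reference_value
    if reference_value is None or reference_value <= 0:
        raise ValueError(f"reference abundance must be > 0, got {reference_value}")
    return float(value) / float(reference_value)


def remaining_fraction(treated: float, untreated: float) -> RemainingFraction:
    """Fraction of transcript remaining after shut-off, f = X(t1)/X(t0).

    Fractions at or above one indicate induction rather than decay and are
    flagged non-decaying.
    """
    if untreated <= 0:
        raise ValueError(f"untreated abundance must be > 0, got {untreated}")
    f = float(treated) / float(untreated)
    return RemainingFraction(value=f, non_decaying=f >= 1.0)


def half_life_two_point(
    t0: float, t1: float, f: float | RemainingFraction, gene: str = "", condition: str = ""
) -> HalfLifeEstimate:
    """Two-timepoint half-life, T = (t1 - t0) / log2(X(t0)/X(t1)).

    The printed form of this estimator divides by log2 of the remaining
    fraction itself, which is negative for decaying RNA; it is read here as
    a magnitude so decaying series yield positive half-lives.  f >= 1 gives
    a flagged non-decaying result; f <= 0 is a domain error.
    """
    f = float(f)
    if t1 <= t0:
        raise ValueError(f"need t1 > t0, got t0={t0}, t1={t1}")
    if f <= 0:
        raise ValueError(f"remaining fraction must be > 0, got {f}")
    if f >= 1:
        return HalfLifeEstimate(
            half_life=math.inf, remaining_fraction=f, method="two_point",
            non_decaying=True, gene=gene, condition=condition,
        )
    half_life = (t1 - t0) / math.log2(1.0 / f)
    return HalfLifeEstimate(
        half_life=half_life, remaining_fraction=f, method="two_point",
        gene=gene, condition=condition,
    )


def half_life_fit(
    series: DecaySeries | None = None,
    timepoints: Sequence[float] | None = None,
    abundances: Sequence[float] | None = None,
    gene: str = "",
    condition: str = "",
) -> HalfLifeEstimate:
    """Least-squares fit of log2 X(t) on t; T = -1/slope, stderr by delta method.

    Exactly two points reduce to the two-point estimator.  A non-negative
    slope returns a flagged non-decaying result.
    """
    if series is not None:
        timepoints, abundances = series.timepoints, series.abundances
        gene, condition = series.gene, series.condition
    t = np.asarray(timepoints, dtype=float)
    x = np.asarray(abundances, dtype=float)
    if np.any(x <= 0):
        raise ValueError("abundances must be strictly positive")
    f_end = float(x[-1] / x[0])
    if t.size == 2:
        return half_life_two_point(t[0], t[1], f_end, gene=gene, condition=condition)
    if t.size < 2:
        raise ValueError("need at least 2 timepoints")
    fit = stats.linregress(t, np.log2(x))
    if fit.slope >= 0:
        return HalfLifeEstimate(
            half_life=math.inf, remaining_fraction=f_end, method="loglinear_fit",
            non_decaying=True, gene=gene, condition=condition,
        )
    half_life = -1.0 / fit.slope
    stderr = fit.stderr / fit.slope**2 if fit.stderr is not None else None
    return HalfLifeEstimate(
        half_life=float(half_life), remaining_fraction=f_end, method="loglinear_fit",
        stderr=None if stderr is None else float(stderr),
        gene=gene, condition=condition,
    )


def half_life_ratio(a: HalfLifeEstimate | float, b: HalfLifeEstimate | float) -> float:
    """Stabilization factor T_a / T_b (e.g. mutant over wild type)."""
    ta = a.half_life if isinstance(a, HalfLifeEstimate) else float(a)
    tb = b.half_life if isinstance(b, HalfLifeEstimate) else float(b)
    ta, tb = float(ta), float(tb)
    if ta <= 0 or tb <= 0:
        raise ValueError("half-lives must be positive")
    return ta / tb


def steady_state_ratio(
    t_half_1: float, t_half_2: float, synthesis_ratio: float = 1.0
) -> float:
    """Predicted steady-state abundance ratio, (k1/k2) * (T1/T2).

    From X* = k/delta with delta = ln2/T; homogeneous of degree zero in the
    two half-lives.
    """
    if t_half_1 <= 0 or t_half_2 <= 0:
        raise ValueError("half-lives must be positive")
    return float(synthesis_ratio) * t_half_1 / t_half_2


class DecayModel:
    """Half-life estimation over a qPCR shut-off table.

    ``data`` columns: gene, condition, timepoint_min, value, reference_value
    [, replicate].  Replicate normalized abundances are averaged per
    timepoint before estimation (per-replicate estimates are also kept).

    method "two_point" uses t0 and the last timepoint; "loglinear_fit" uses
    all timepoints (automatic fallback to two_point at 2 timepoints).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        reference_gene: str = "GAPDH",
        method: Literal["two_point", "loglinear_fit"] = "two_point",
    ) -> None:
        required = {"gene", "condition", "timepoint_min", "value", "reference_value"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"qPCR table missing column(s) {sorted(missing)}")
        self.data = data.copy()
        if "replicate" not in self.data.columns:
            self.data["replicate"] = 1
        self.reference_gene = reference_gene
        self.method = method

    def fit(self) -> "DecayResults":
        df = self.data[self.data["gene"] != self.reference_gene].copy()
        df["normalized"] = df["value"] / df["reference_value"]
        estimates: list[HalfLifeEstimate] = []
        per_replicate: list[HalfLifeEstimate] = []
        for (gene, condition), grp in df.groupby(["gene", "condition"], sort=True):
            mean_x = grp.groupby("timepoint_min", sort=True)["normalized"].mean()
            estimates.append(self._estimate(mean_x, gene, condition))
            for rep, rep_grp in grp.groupby("replicate", sort=True):
                rep_x = rep_grp.groupby("timepoint_min", sort=True)["normalized"].mean()
                if len(rep_x) >= 2:
                    est = self._estimate(rep_x, gene, f"{condition}/rep{rep}")
                    per_replicate.append(est)
        return DecayResults(model=self, estimates=estimates, per_replicate=per_replicate)

    def _estimate(self, x_by_t: pd.Series, gene: str, condition: str) -> HalfLifeEstimate:
        t = x_by_t.index.to_numpy(float)
        x = x_by_t.to_numpy(float)
        if self.method == "two_point" or t.size == 2:
            frac = remaining_fraction(x[-1], x[0])
            return half_life_two_point(t[0], t[-1], frac, gene=gene, condition=condition)
        return half_life_fit(timepoints=t, abundances=x, gene=gene, condition=condition)


@dataclass
class DecayResults:
    """Per gene/condition half-life estimates from a shut-off experiment."""

    model: DecayModel
    estimates: list[HalfLifeEstimate]
    per_replicate: list[HalfLifeEstimate] = field(default_factory=list)

    def __getitem__(self, key: tuple[str, str]) -> HalfLifeEstimate:
        gene, condition = key
        for est in self.estimates:
            if est.gene == gene and est.condition == condition:
                return est
        raise KeyError(key)

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "gene": e.gene,
                "condition": e.condition,
                "half_life_min": e.half_life,
                "remaining_fraction": e.remaining_fraction,
                "method": e.method,
                "stderr_min": e.stderr,
                "non_decaying": e.non_decaying,
            }
            for e in self.estimates
        ]
        return pd.DataFrame(rows)

    def ratio(self, numerator: tuple[str, str], denominator: tuple[str, str]) -> float:
        """Stabilization factor between two (gene, condition) estimates."""
        return half_life_ratio(self[numerator], self[denominator])

    def summary(self) -> str:
        lines = [
            "Transcription shut-off half-lives",
            "=================================",
            f"reference gene: {self.model.reference_gene}",
            f"method: {self.model.method}",
            "",
        ]
        lines += [str(e) for e in self.estimates]
        return "\n".join(lines)
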