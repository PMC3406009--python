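"""Protein-microarray RNA-binding screen statistic.

The screen hybridizes a labeled query RNA against labeled total mRNA
("Reference") on a proteome array, in six replicates: three with the query
in one dye and three dye-swapped.  Per array, proteins whose foreground
signal does not exceed ``k`` times background in both channels are filtered
out; the remaining log2(query/reference) ratios are centered (median by
default), z-scored over the array, and converted to one-sided upper-tail
Gaussian p-values.  Each dye set's three replicate p-values are combined by
their product, and a protein is called a high-confidence interactor when
both dye sets' combined values fall below ``alpha`` (1e-4 by default).

The product of three p-values is an uncalibrated score, not itself a
p-value; under the null of independent uniforms its CDF is
``x * sum_{j<3} (-ln x)^j / j!`` (:func:`product_null_cdf`).  A Fisher
chi-square calibrated p-value is also reported but plays no role in
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ArrayScan, ExperimentSet

__all__ = [
    "ScreenReplicate",
    "BindingScreenModel",
    "BindingScreenResults",
    "background_filter",
    "centered_log_ratio",
    "zscore",
    "gaussian_p",
    "combine_p",
    "fisher_p",
    "product_null_cdf",
    "dual_set_null_rate",
    "classify_binders",
]

BackgroundMode = Literal["all_channels", "any_channel"]


def background_filter(
    scan: ArrayScan, k: float = 1.5, mode: BackgroundMode = "all_channels"
) -> pd.Series:
    """Boolean pass mask: foreground detectable above ``k`` x background.

    ``all_channels`` (screen default) requires f > k*b in both channels;
    ``any_channel`` (RIP-ChIP presence rule) in at least one.
    """
    if k <= 0:
        raise ValueError(f"background factor k must be > 0, got {k}")
    if mode not in ("all_channels", "any_channel"):
        raise ValueError(f"unknown background mode {mode!r}")
    if len(scan.features) == 0:
        raise ValueError(f"array {scan.array_id!r} has no features")
    f1, b1 = scan.channel_intensities("ch1")
    f2, b2 = scan.channel_intensities("ch2")
    pass1, pass2 = f1 > k * b1, f2 > k * b2
    return (pass1 & pass2) if mode == "all_channels" else (pass1 | pass2)


@dataclass
class ScreenReplicate:
    """Centered log2 query/reference ratios for one array."""

    array_id: str
    dye_set: str
    ratios: pd.Series  # indexed by feature_id, passing features only
    pass_mask: pd.Series
    center: float  # the subtracted centering statistic
    dropped: list[str] = field(default_factory=list)  # nonpositive intensities


def centered_log_ratio(
    scan: ArrayScan,
    center: Literal["median", "mean"] = "median",
    pass_mask: pd.Series | None = None,
    k: float = 1.5,
    bg_mode: BackgroundMode = "all_channels",
    subtract_background: bool = False,
) -> ScreenReplicate:
    """Per-protein centered log2(query/reference) for one scan.

    Orientation follows the sample roles, so a dye-swapped scan of the same
    samples yields identically signed ratios.  Background is used for
    filtering only, unless ``subtract_background`` is set.  Proteins whose
    intensity is non-positive after background handling are dropped (listed
    in ``dropped``), not errors.
    """
    if center not in ("median", "mean"):
        raise ValueError(f"unknown centering statistic {center!r}")
    if pass_mask is None:
        pass_mask = background_filter(scan, k=k, mode=bg_mode)
    fq, bq = scan.channel_intensities(scan.query_channel)
    fr, br = scan.channel_intensities(scan.reference_channel)
    if subtract_background:
        fq, fr = fq - bq, fr - br
    usable = pass_mask & (fq > 0) & (fr > 0)
    dropped = sorted(pass_mask.index[pass_mask & ~usable])
    ratios = np.log2(fq[usable] / fr[usable])
    stat = float(ratios.median() if center == "median" else ratios.mean())
    return ScreenReplicate(
        array_id=scan.array_id,
        dye_set=str(scan.dye_set),
        ratios=ratios - stat,
        pass_mask=pass_mask,
        center=stat,
        dropped=list(dropped),
    )


def zscore(values: pd.Series | np.ndarray, ddof: int = 0) -> pd.Series | np.ndarray:
    """Standardize to mean 0, SD 1 over the supplied population.

    Population SD (ddof=0) by default: per-array z-scores run over
    thousands of proteins, where the n vs n-1 distinction is negligible.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to z-score")
    if not np.all(np.isfinite(arr)):
        raise ValueError("z-score input must be finite")
    sd = arr.std(ddof=ddof)
    if sd == 0:
        raise ValueError("zero variance: cannot z-score a constant vector")
    z = (arr - arr.mean()) / sd
    if isinstance(values, pd.Series):
        return pd.Series(z, index=values.index)
    return z


def gaussian_p(z: float | np.ndarray | pd.Series) -> float | np.ndarray | pd.Series:
    """One-sided upper-tail standard-normal p-value, P(Z >= z)."""
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("z-score must be finite")
    p = stats.norm.sf(arr)
    if isinstance(z, pd.Series):
        return pd.Series(p, index=z.index)
    return p if arr.ndim else float(p)


def combine_p(p_values: Sequence[float]) -> float:
    """Product of one dye set's three replicate p-values.

    The product is an uncalibrated evidence score (smaller = stronger); see
    :func:`product_null_cdf` for its null distribution and :func:`fisher_p`
    for a calibrated alternative.
    """
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size != 3 or not np.all(np.isfinite(arr)):
        raise ValueError(
            "a dye set combines exactly three replicate p-values; a protein "
            "must pass the background filter in all three replicates to be scored"
        )
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(arr.prod())


def fisher_p(p_values: Sequence[float]) -> float:
    """Fisher chi-square calibration of a product of independent p-values."""
    arr = np.asarray(list(p_values), dtype=float)
    return float(stats.chi2.sf(-2.0 * np.log(arr).sum(), df=2 * arr.size))


def product_null_cdf(x: float | np.ndarray, k: int = 3) -> float | np.ndarray:
    """P(product of ``k`` iid Uniform(0,1) <= x) = x * sum_{j<k} (-ln x)^j / j!."""
    x = np.asarray(x, dtype=float)
    lx = -np.log(x)
    out = x * sum(lx**j / factorial(j) for j in range(k))
    return out if out.ndim else float(out)


def dual_set_null_rate(alpha: float = 1e-4, k: int = 3) -> float:
    """Null probability that both dye sets' products fall below ``alpha``."""
    return float(product_null_cdf(alpha, k=k)) ** 2


def classify_binders(
    combined_a: pd.Series, combined_b: pd.Series, alpha: float = 1e-4
) -> pd.DataFrame:
    """Dual dye-set classification and ranking.

    A protein is classified iff both combined values are below ``alpha``;
    proteins are ranked by max(P_A, P_B) ascending (worst set first), ties
    broken lexicographically by protein id.  Only proteins scorable in both
    sets are classifiable.
    """
    df = pd.DataFrame({"combined_A": combined_a, "combined_B": combined_b})
    scorable = df.notna().all(axis=1)
    worst = df.max(axis=1)
    df["classified"] = scorable & (df["combined_A"] < alpha) & (df["combined_B"] < alpha)
    order = pd.DataFrame({"worst": worst[scorable]}).sort_index().sort_values(
        "worst", kind="mergesort"
    )
    df["rank"] = pd.Series(
        np.arange(1, len(order) + 1, dtype=float), index=order.index
    ).reindex(df.index)
    return df


class BindingScreenModel:
    """Dye-swap RNA-binding screen over a six-replicate experiment set.

    Parameters
    ----------
    data : ExperimentSet with design "screen"; dye set "A" and "B" scans.
    alpha : dual-set classification threshold on the combined products.
    bg_factor, bg_mode : background detectability filter settings.
    center : "median" (default) or "mean" log-ratio centering; the two
        differ by a constant that downstream z-scoring absorbs.
    subtract_background : form ratios from background-subtracted foreground.
    """

    def __init__(
        self,
        data: ExperimentSet,
        alpha: float = 1e-4,
        bg_factor: float = 1.5,
        bg_mode: BackgroundMode = "all_channels",
        center: Literal["median", "mean"] = "median",
        subtract_background: bool = False,
    ) -> None:
        if not data.scans:
            raise ValueError("empty experiment set")
        self.data = data
        self.alpha = float(alpha)
        self.bg_factor = float(bg_factor)
        self.bg_mode = bg_mode
        self.center = center
        self.subtract_background = subtract_background

    @classmethod
    def from_scans(cls, scans: Iterable[ArrayScan], **kwargs) -> "BindingScreenModel":
        return cls(ExperimentSet(scans=list(scans), design="screen"), **kwargs)

    def fit(self) -> "BindingScreenResults":
        universe = self.data.feature_universe
        per_rep: dict[str, pd.Series] = {}  # column label -> p-values
        zcols: dict[str, pd.Series] = {}
        reps_by_set: dict[str, list[str]] = {"A": [], "B": []}
        replicates: list[ScreenReplicate] = []
        for scan in self.data.scans:
            rep = centered_log_ratio(
                scan,
                center=self.center,
                k=self.bg_factor,
                bg_mode=self.bg_mode,
                subtract_background=self.subtract_background,
            )
            replicates.append(rep)
            z = zscore(rep.ratios)
            label = f"{rep.dye_set}{scan.replicate_id}"
            zcols[f"z_{label}"] = z.reindex(universe)
            per_rep[label] = gaussian_p(z).reindex(universe)
            reps_by_set.setdefault(rep.dye_set, []).append(label)
        combined: dict[str, pd.Series] = {}
        for dye_set in ("A", "B"):
            labels = reps_by_set.get(dye_set, [])
            if len(labels) == 0:
                raise ValueError(f"no replicates for dye set {dye_set!r}")
            ps = pd.DataFrame({lab: per_rep[lab] for lab in labels})
            scored = ps.notna().all(axis=1)  # must pass filter in all reps of the set
            comb = pd.Series(np.nan, index=universe)
            comb.loc[scored] = ps.loc[scored].prod(axis=1)
            combined[dye_set] = comb
        cls_df = classify_binders(combined["A"], combined["B"], alpha=self.alpha)
        table = pd.DataFrame(index=universe)
        table.index.name = "protein"
        for col, series in zcols.items():
            table[col] = series
        for lab, series in sorted(per_rep.items()):
            table[f"p_{lab}"] = series
        table["combined_A"] = cls_df["combined_A"]
        table["combined_B"] = cls_df["combined_B"]
        scorable = table[["combined_A", "combined_B"]].notna().all(axis=1)
        logp = np.log(
            table.loc[scorable, [f"p_{lab}" for labs in reps_by_set.values() for lab in labs]]
        )
        table["fisher_p"] = np.nan
        table.loc[scorable, "fisher_p"] = stats.chi2.sf(
            -2.0 * logp.sum(axis=1), df=2 * logp.shape[1]
        )
        table["classified"] = cls_df["classified"]
        table["rank"] = cls_df["rank"]
        return BindingScreenResults(model=self, table=table, replicates=replicates)


@dataclass
class BindingScreenResults:
    """Fitted screen: per-protein z, p, combined products and classification."""

    model: BindingScreenModel
    table: pd.DataFrame
    replicates: list[ScreenReplicate]

    @property
    def classified(self) -> list[str]:
        """Protein ids called high-confidence interactors, by rank."""
        hits = self.table[self.table["classified"]]
        return list(hits.sort_values("rank").index)

    @property
    def n_scored(self) -> int:
        return int(self.table[["combined_A", "combined_B"]].notna().all(axis=1).sum())

    def expected_null_calls(self) -> float:
        """Expected number of classified proteins under the global null."""
        return self.n_scored * dual_set_null_rate(self.model.alpha)

    def summary(self) -> str:
        lines = [
            "Dye-swap RNA-binding screen",
            "===========================",
            f"proteins on array:      {len(self.table)}",
            f"scorable in both sets:  {self.n_scored}",
            f"alpha (per dye set):    {self.model.alpha:g}",
            f"classified interactors: {len(self.classified)}",
            f"expected under null:    {self.expected_null_calls():.3g}",
        ]
        if self.classified:
            lines.append("")
            lines.append("rank  protein          combined_A   combined_B")
            for pid in self.classified[:20]:
                row = self.table.loc[pid]
                lines.append(
                    f"{int(row['rank']):>4}  {pid:<15s}  {row['combined_A']:.3e}  "
                    f"{row['combined_B']:.3e}"
                )
        return "\n".join(lines)
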