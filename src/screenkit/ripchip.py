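"""RIP-ChIP enrichment analysis with mock-IP correction.

An immunopurification (IP) of a tagged protein is hybridized against the
depleted supernatant on a two-channel array; "Mock" IPs from the untagged
parental strain control for non-specific recovery.  Per array, log2
(IP-channel / reference-channel) ratios are median-centered; mock-corrected
IP enrichment is then the gene-wise difference between each IP replicate
and the mean over mock replicates.  Genes must be detectable (foreground >
1.5x background in either channel) in a minimum number of experiments —
9 of 12 for the full design, strictly more than half otherwise.

Cross-condition comparisons use a simplified SAM (significance analysis of
microarrays): a moderated difference statistic d = (meanA - meanB)/(s + s0)
with s the pooled standard error and s0 fixed at the median of the per-gene
s values, and a permutation-based FDR (q-value) from group-label
reshuffling.  The full Tusher-style s0 percentile search is deliberately
not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ArrayScan, ExperimentSet, HAC1_PROBE_CLASSES
from .screen import background_filter, centered_log_ratio

__all__ = [
    "median_center",
    "mock_correct",
    "presence_filter",
    "default_min_count",
    "enrichment_ttest",
    "sam_two_class",
    "SamResult",
    "rank_genes",
    "summarize_hac1_probes",
    "ProbeClassSummary",
    "RipChipModel",
    "RipChipResults",
]


def median_center(values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Subtract the median over present (finite) entries of one array."""
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if not finite.any():
        raise ValueError("cannot median-center an all-missing array")
    centered = arr - np.median(arr[finite])
    if isinstance(values, pd.Series):
        return pd.Series(centered, index=values.index)
    return centered


def mock_correct(
    ip: pd.DataFrame, mocks: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene-wise mock correction: E[g, r] = IP[g, r] - mean_mocks(Mock[g, .]).

    ``ip`` and ``mocks`` are gene x replicate frames of centered log-ratios
    (NaN where a gene is absent from an array).  Genes absent from every
    mock get a mock term of 0 and are flagged in the returned Series.
    """
    if mocks.shape[1] == 0:
        raise ValueError("mock correction requires at least one mock experiment")
    genes = ip.index.union(mocks.index)
    ip = ip.reindex(genes)
    mock_mean = mocks.reindex(genes).mean(axis=1)
    no_mock = mock_mean.isna()
    enrichment = ip.sub(mock_mean.fillna(0.0), axis=0)
    return enrichment, no_mock


def default_min_count(n_experiments: int) -> int:
    """Presence threshold: 9 of 12 for the full design, else >50% of arrays."""
    if n_experiments == 12:
        return 9
    return n_experiments // 2 + 1


def presence_filter(
    es: ExperimentSet,
    k: float = 1.5,
    min_count: int | None = None,
    mode: Literal["any_channel", "all_channels"] = "any_channel",
) -> pd.Series:
    """Genes detectable above background in at least ``min_count`` arrays."""
    n = len(es.scans)
    if min_count is None:
        min_count = default_min_count(n)
    if min_count <= 0:
        raise ValueError(f"min_count must be positive, got {min_count}")
    if min_count > n:
        raise ValueError(f"min_count={min_count} exceeds {n} experiments")
    universe = es.feature_universe
    counts = pd.Series(0, index=universe, dtype=int)
    for scan in es.scans:
        mask = background_filter(scan, k=k, mode=mode)
        counts = counts.add(mask.reindex(universe).fillna(False).astype(int), fill_value=0)
    return counts >= min_count


def enrichment_ttest(
    values: Sequence[float] | pd.Series,
    alternative: Literal["greater", "less"] = "greater",
    group_b: Sequence[float] | pd.Series | None = None,
    equal_var: bool = False,
) -> tuple[float, float]:
    """One-tailed t-test of enrichment values.

    One-sample against 0 by default, or unpaired two-sample (Welch unless
    ``equal_var``) when ``group_b`` is given.  Returns (t, p).
    """
    a = np.asarray(values, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < 3:
        raise ValueError(f"need >= 3 finite replicates, got {a.size}")
    if alternative not in ("greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if group_b is None:
        if np.allclose(a.std(ddof=1), 0):
            raise ValueError("zero variance across replicates")
        res = stats.ttest_1samp(a, 0.0, alternative=alternative)
    else:
        b = np.asarray(group_b, dtype=float)
        b = b[np.isfinite(b)]
        if b.size < 3:
            raise ValueError(f"need >= 3 finite replicates in group B, got {b.size}")
        res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def _d_statistic(
    X: np.ndarray, a_cols: np.ndarray, b_cols: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """SAM moderated difference for one labeling; returns (d, s)."""
    A, B = X[:, a_cols], X[:, b_cols]
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    ss = ((A - ma[:, None]) ** 2).sum(axis=1) + ((B - mb[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) * ss / (na + nb - 2))
    return (ma - mb) / (s + s0), s


@dataclass
class SamResult:
    """Simplified SAM two-class comparison."""

    d: pd.Series  # moderated difference statistic per gene
    q: pd.Series  # permutation FDR at each gene's |d| cutoff
    s0: float
    n_perm: int
    seed: int

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"d": self.d, "q": self.q})


def sam_two_class(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    s0: float | Literal["median"] = "median",
) -> SamResult:
    """Simplified SAM: moderated d-scores and permutation q-values.

    ``group_a``/``group_b`` are gene x replicate matrices on a shared gene
    index.  d = (meanA - meanB)/(s + s0), s the pooled standard error and
    s0 the median of s by default.  The null is built from group-label
    permutations (all distinct assignments when there are at most
    ``n_perm``, otherwise a seeded sample); each gene's q-value is the
    median number of permuted |d| exceeding its |d|, divided by the
    observed count, clipped to [0, 1] and made monotone in |d|.
    """
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValueError("each group needs at least 2 replicates")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    genes = group_a.index
    if not genes.equals(group_b.index):
        raise ValueError("groups must share one gene index")
    X = np.hstack([group_a.to_numpy(float), group_b.to_numpy(float)])
    na, nb = group_a.shape[1], group_b.shape[1]
    n = na + nb
    obs_a = np.arange(na)
    obs_b = np.arange(na, n)
    _, s = _d_statistic(X, obs_a, obs_b, 0.0)
    s0_val = float(np.median(s)) if s0 == "median" else float(s0)
    d_obs, _ = _d_statistic(X, obs_a, obs_b, s0_val)

    total = comb(n, na)
    if total <= n_perm:
        assignments = [np.array(c) for c in combinations(range(n), na)]
    else:
        rng = np.random.default_rng(seed)
        assignments = [rng.permutation(n)[:na] for _ in range(n_perm)]
    all_cols = np.arange(n)

    abs_obs = np.abs(d_obs)
    order = np.argsort(abs_obs)[::-1]  # descending |d|
    thresholds = abs_obs[order]
    # observed exceedance counts at each gene's own cutoff (ties counted >=)
    sorted_asc = np.sort(abs_obs)
    r_obs = len(abs_obs) - np.searchsorted(sorted_asc, thresholds, side="left")

    exceed = np.empty((len(assignments), len(thresholds)), dtype=np.int32)
    for i, a_cols in enumerate(assignments):
        mask = np.zeros(n, dtype=bool)
        mask[a_cols] = True
        d_perm, _ = _d_statistic(X, all_cols[mask], all_cols[~mask], s0_val)
        perm_sorted = np.sort(np.abs(d_perm))
        exceed[i] = len(d_perm) - np.searchsorted(perm_sorted, thresholds, side="left")
    v_med = np.median(exceed, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.clip(v_med / r_obs, 0.0, 1.0)
    # monotone: a larger |d| never carries a larger q
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return SamResult(
        d=pd.Series(d_obs, index=genes),
        q=pd.Series(q, index=genes),
        s0=s0_val,
        n_perm=len(assignments),
        seed=seed,
    )


def rank_genes(
    enrichment: pd.DataFrame, presence: pd.Series | None = None
) -> pd.DataFrame:
    """Rank genes by mean enrichment over present replicates, descending.

    Ties break lexicographically by gene id; rank is invariant to
    experiment (column) order.
    """
    mean = enrichment.mean(axis=1)
    if presence is not None:
        mean = mean[presence.reindex(mean.index).fillna(False)]
    out = pd.DataFrame({"mean_enrichment": mean, "n_present": enrichment.notna().sum(axis=1)})
    out = out.sort_index().sort_values("mean_enrichment", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class ProbeClassSummary:
    """Mean enrichment per HAC1 probe class, plus isoform aggregates."""

    per_class: pd.DataFrame  # index probe class; columns mean_enrichment, n
    unspliced_mean: float  # unspliced junctions + intron probes
    spliced_mean: float  # spliced junction probe

    def __str__(self) -> str:
        lines = ["HAC1 probe-class enrichment"]
        for cls, row in self.per_class.iterrows():
            mean = row["mean_enrichment"]
            shown = "missing" if np.isnan(mean) else f"{mean:+.3f} (n={int(row['n'])})"
            lines.append(f"  {cls:<16s} {shown}")
        lines.append(f"  unspliced isoform mean {self.unspliced_mean:+.3f}")
        lines.append(f"  spliced isoform mean   {self.spliced_mean:+.3f}")
        return "\n".join(lines)


def summarize_hac1_probes(
    enrichment: pd.DataFrame, annotation: Mapping[str, str] | pd.Series
) -> ProbeClassSummary:
    """Summarize enrichment per annotated HAC1 probe class.

    ``annotation`` maps feature_id -> probe class (one of
    ``HAC1_PROBE_CLASSES``).  The unspliced-isoform aggregate averages the
    unspliced-junction and intron probes; the spliced aggregate is the
    spliced-junction probe.  Empty classes are reported as missing.
    """
    ann = pd.Series(dict(annotation)) if not isinstance(annotation, pd.Series) else annotation
    ann = ann[ann.isin(HAC1_PROBE_CLASSES)]
    if ann.empty:
        raise ValueError("annotation maps no feature to a HAC1 probe class")
    rows = {}
    class_values: dict[str, np.ndarray] = {}
    for cls in HAC1_PROBE_CLASSES:
        feats = ann.index[ann == cls]
        vals = enrichment.reindex(feats).to_numpy(float).ravel()
        vals = vals[np.isfinite(vals)]
        class_values[cls] = vals
        rows[cls] = {
            "mean_enrichment": vals.mean() if vals.size else np.nan,
            "n": vals.size,
        }
    unspliced = np.concatenate(
        [class_values[c] for c in ("unspliced_jxn_1", "unspliced_jxn_2", "intron")]
    )
    spliced = class_values["spliced_jxn"]
    return ProbeClassSummary(
        per_class=pd.DataFrame.from_dict(rows, orient="index"),
        unspliced_mean=float(unspliced.mean()) if unspliced.size else float("nan"),
        spliced_mean=float(spliced.mean()) if spliced.size else float("nan"),
    )


class RipChipModel:
    """Mock-corrected IP enrichment over an IP/Mock experiment set.

    Each scan is a two-channel array with the IP (or mock-IP) sample as the
    query against the depleted-supernatant reference; ``data.groups`` labels
    every array "IP" or "Mock".
    """

    def __init__(
        self,
        data: ExperimentSet,
        bg_factor: float = 1.5,
        min_present: int | None = None,
        center: Literal["median", "mean"] = "median",
        alternative: Literal["greater", "less"] = "greater",
    ) -> None:
        self.data = data
        self.bg_factor = float(bg_factor)
        self.min_present = min_present
        self.center = center
        self.alternative = alternative
        ip = [s for s in data.scans if data.group_of(s.array_id) == "IP"]
        mock = [s for s in data.scans if data.group_of(s.array_id) == "Mock"]
        if not ip:
            raise ValueError("no arrays labeled 'IP' in experiment set groups")
        if not mock:
            raise ValueError("mock correction requires arrays labeled 'Mock'")
        self.ip_scans, self.mock_scans = ip, mock

    def centered_ratios(self, scans: list[ArrayScan]) -> pd.DataFrame:
        cols = {}
        for scan in scans:
            rep = centered_log_ratio(
                scan, center=self.center, k=self.bg_factor, bg_mode="any_channel"
            )
            cols[scan.array_id] = rep.ratios
        return pd.DataFrame(cols)

    def fit(self, ttest_min_n: int = 3) -> "RipChipResults":
        presence = presence_filter(
            self.data, k=self.bg_factor, min_count=self.min_present, mode="any_channel"
        )
        ip = self.centered_ratios(self.ip_scans)
        mock = self.centered_ratios(self.mock_scans)
        enrichment, no_mock = mock_correct(ip, mock)
        keep = presence.reindex(enrichment.index).fillna(False)
        enrichment = enrichment[keep]
        ranking = rank_genes(enrichment)
        t_vals, p_vals, flagged = {}, {}, []
        for gene, row in enrichment.iterrows():
            vals = row.to_numpy(float)
            vals = vals[np.isfinite(vals)]
            if vals.size < ttest_min_n or np.allclose(vals.std(ddof=1), 0):
                flagged.append(gene)
                continue
            t_vals[gene], p_vals[gene] = enrichment_ttest(vals, self.alternative)
        table = ranking.copy()
        table["t"] = pd.Series(t_vals).reindex(table.index)
        table["p_one_tailed"] = pd.Series(p_vals).reindex(table.index)
        return RipChipResults(
            model=self,
            enrichment=enrichment,
            mock_ratios=mock,
            presence=presence,
            no_mock_flag=no_mock.reindex(enrichment.index).fillna(False),
            table=table,
            skipped=flagged,
        )


@dataclass
class RipChipResults:
    """Mock-corrected enrichment matrix plus ranking and per-gene tests."""

    model: RipChipModel
    enrichment: pd.DataFrame  # genes x IP replicates, presence-filtered
    mock_ratios: pd.DataFrame
    presence: pd.Series
    no_mock_flag: pd.Series
    table: pd.DataFrame  # gene, mean_enrichment, n_present, rank, t, p
    skipped: list[str] = field(default_factory=list)

    def compare(
        self, other: "RipChipResults", n_perm: int = 1000, seed: int = 0
    ) -> SamResult:
        """SAM-style comparison of this condition's enrichment vs another's."""
        genes = self.enrichment.index.intersection(other.enrichment.index)
        return sam_two_class(
            self.enrichment.loc[genes], other.enrichment.loc[genes], n_perm=n_perm, seed=seed
        )

    def hac1_summary(
        self, annotation: Mapping[str, str] | pd.Series | None = None
    ) -> ProbeClassSummary:
        if annotation is None:
            ann = self.model.data.annotation()["probe_class"]
            annotation = ann[ann.isin(HAC1_PROBE_CLASSES)]
        return summarize_hac1_probes(self.enrichment, annotation)

    def summary(self, top: int = 10) -> str:
        lines = [
            "Mock-corrected RIP-ChIP enrichment",
            "==================================",
            f"arrays: {len(self.model.ip_scans)} IP, {len(self.model.mock_scans)} Mock",
            f"genes passing presence filter: {len(self.enrichment)} "
            f"of {len(self.presence)}",
            "",
            "rank  gene             mean_enrich  t        p(one-tailed)",
        ]
        for gene, row in self.table.head(top).iterrows():
            t = "  --  " if np.isnan(row.get("t", np.nan)) else f"{row['t']:6.2f}"
            p = " -- " if np.isnan(row.get("p_one_tailed", np.nan)) else f"{row['p_one_tailed']:.2e}"
            lines.append(
                f"{int(row['rank']):>4}  {str(gene):<15s} {row['mean_enrichment']:+10.3f}  {t}  {p}"
            )
        return "\n".join(lines)
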