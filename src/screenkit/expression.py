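"""Knockdown-vs-wild-type expression profiling.

Two-channel arrays compare a hypomorphic (DAmP) knockdown strain against
its isogenic wild type.  Per replicate, median-centered log2(knockdown/WT)
ratios and per-array z-scores are computed; replicate-averaged ratios feed
(i) a target-set shift test — do annotated UPR target genes shift relative
to the rest of the transcriptome? — and (ii) per-gene fold-change tests,
including the HAC1 probe classes (unspliced junctions vs spliced junction).

The set test compares set members to non-members (disjoint groups) by
unpaired t-test; an inclusive "set vs all genes" variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExperimentSet, HAC1_PROBE_CLASSES
from .screen import centered_log_ratio, zscore

__all__ = [
    "GeneSet",
    "knockdown_ratios",
    "target_set_shift",
    "ShiftTest",
    "gene_level_change",
    "GeneChange",
    "KnockdownModel",
    "KnockdownResults",
    "EXAMPLE_UPR_TARGETS",
]

#: Small illustrative UPR target set (canonical targets named in the field);
#: real analyses should supply the full annotated list as a GeneSet file.
EXAMPLE_UPR_TARGETS = ("KAR2", "ERO1", "PDI1", "HAC1")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids (e.g. annotated UPR targets)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_iterable(cls, name: str, members: Iterable[str]) -> "GeneSet":
        return cls(name=name, members=frozenset(str(m) for m in members))

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "GeneSet":
        """One gene id per line; '#' starts a comment."""
        path = Path(path)
        members = []
        for line in path.read_text().splitlines():
            entry = line.split("#", 1)[0].strip()
            if entry:
                members.append(entry)
        return cls.from_iterable(name or path.stem, members)

    def intersect(self, genes: Iterable[str]) -> frozenset[str]:
        return self.members & set(genes)


def knockdown_ratios(
    data: ExperimentSet,
    center: Literal["median", "mean"] = "median",
    bg_factor: float = 1.5,
) -> pd.DataFrame:
    """Per-gene centered log2(knockdown/WT) per replicate, plus the average.

    Requires every scan to carry a knockdown-role query against a WT
    reference; orientation is role-based, so dye-swapped replicates yield
    identically signed ratios.  Returns a feature x replicate frame with a
    final ``mean`` column (the replicate average the profiling reports).
    """
    if not data.scans:
        raise ValueError("empty experiment set")
    cols = {}
    for scan in data.scans:
        rep = centered_log_ratio(scan, center=center, k=bg_factor, bg_mode="any_channel")
        cols[f"rep{scan.replicate_id}"] = rep.ratios
    profile = pd.DataFrame(cols)
    profile["mean"] = profile.mean(axis=1)
    return profile


@dataclass
class ShiftTest:
    """Target-set shift relative to the rest of the profiled genes."""

    set_name: str
    shift: float  # difference of means (set - comparison group), log2 units
    t: float
    p: float
    n_set: int
    n_comparison: int
    alternative: str
    missing: tuple[str, ...] = ()

    def __str__(self) -> str:
        return (
            f"{self.set_name}: shift={self.shift:+.4f} log2 "
            f"(n={self.n_set} vs {self.n_comparison}), t={self.t:.3f}, "
            f"p={self.p:.3g} ({self.alternative})"
        )


def target_set_shift(
    profile: pd.Series | pd.DataFrame,
    gene_set: GeneSet,
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
    inclusive: bool = False,
    equal_var: bool = False,
) -> ShiftTest:
    """Unpaired t-test of target-set log-ratios against the other genes.

    ``profile`` is the replicate-averaged log2(knockdown/WT) Series (a
    profile frame's ``mean`` column is used when a frame is passed).  With
    ``inclusive`` the comparison group is all genes including the set;
    default compares to the disjoint complement.  The shift estimate is
    invariant to adding a constant to all genes.
    """
    if isinstance(profile, pd.DataFrame):
        profile = profile["mean"]
    profile = profile.dropna()
    in_set = profile.index.isin(gene_set.members)
    missing = tuple(sorted(gene_set.members - set(profile.index)))
    if not in_set.any():
        raise ValueError(
            f"gene set {gene_set.name!r} has no overlap with the profile; "
            f"missing: {missing[:10]}"
        )
    set_vals = profile[in_set].to_numpy(float)
    comp_vals = profile.to_numpy(float) if inclusive else profile[~in_set].to_numpy(float)
    if set_vals.size < 3 or comp_vals.size < 3:
        raise ValueError("need >= 3 genes in the set and in the comparison group")
    res = stats.ttest_ind(set_vals, comp_vals, equal_var=equal_var, alternative=alternative)
    return ShiftTest(
        set_name=gene_set.name,
        shift=float(set_vals.mean() - comp_vals.mean()),
        t=float(res.statistic),
        p=float(res.pvalue),
        n_set=int(set_vals.size),
        n_comparison=int(comp_vals.size),
        alternative=alternative,
        missing=missing,
    )


@dataclass
class GeneChange:
    """Replicate-level change for one gene or HAC1 probe class."""

    target: str
    mean_log2: float
    fold_change: float
    t: float
    p: float
    n: int

    def __str__(self) -> str:
        return (
            f"{self.target}: {self.fold_change:.2f}-fold "
            f"(log2={self.mean_log2:+.3f}, t={self.t:.3f}, p={self.p:.3g}, n={self.n})"
        )


def gene_level_change(
    profile: pd.DataFrame,
    target: str,
    annotation: pd.Series | None = None,
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
) -> GeneChange:
    """Fold-change and across-replicate t-test for a gene or probe class.

    ``target`` is a feature id, or (with ``annotation`` mapping feature ->
    probe class) one of the HAC1 probe classes, whose probes' replicate
    values are pooled.
    """
    rep_cols = [c for c in profile.columns if c != "mean"]
    if annotation is not None and target in HAC1_PROBE_CLASSES:
        feats = annotation.index[annotation == target]
        if len(feats) == 0:
            raise KeyError(f"no probes annotated with class {target!r}")
        vals = profile.loc[profile.index.intersection(feats), rep_cols].to_numpy(float).ravel()
    else:
        if target not in profile.index:
            raise KeyError(f"gene {target!r} absent from the expression profile")
        vals = profile.loc[target, rep_cols].to_numpy(float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError(f"need >= 2 replicate values for {target!r}, got {vals.size}")
    mean = float(vals.mean())
    if np.allclose(vals.std(ddof=1), 0):
        t, p = (0.0, 1.0) if np.allclose(mean, 0) else (np.inf, 0.0)
    else:
        res = stats.ttest_1samp(vals, 0.0, alternative=alternative)
        t, p = float(res.statistic), float(res.pvalue)
    return GeneChange(
        target=target, mean_log2=mean, fold_change=float(2.0**mean), t=t, p=p, n=vals.size
    )


class KnockdownModel:
    """Knockdown-vs-WT expression profile over replicate two-channel arrays."""

    def __init__(
        self,
        data: ExperimentSet,
        center: Literal["median", "mean"] = "median",
        bg_factor: float = 1.5,
    ) -> None:
        if not data.scans:
            raise ValueError("empty experiment set")
        self.data = data
        self.center = center
        self.bg_factor = float(bg_factor)

    def fit(self) -> "KnockdownResults":
        profile = knockdown_ratios(self.data, center=self.center, bg_factor=self.bg_factor)
        rep_cols = [c for c in profile.columns if c != "mean"]
        zscores = pd.DataFrame(
            {c: zscore(profile[c].dropna()).reindex(profile.index) for c in rep_cols}
        )
        return KnockdownResults(model=self, profile=profile, zscores=zscores)


@dataclass
class KnockdownResults:
    model: KnockdownModel
    profile: pd.DataFrame  # per-replicate centered log2 ratios + mean
    zscores: pd.DataFrame

    def target_set_shift(self, gene_set: GeneSet, **kwargs) -> ShiftTest:
        return target_set_shift(self.profile, gene_set, **kwargs)

    def gene_level_change(self, target: str, **kwargs) -> GeneChange:
        annotation = self.model.data.annotation()["probe_class"]
        return gene_level_change(self.profile, target, annotation=annotation, **kwargs)

    @property
    def table(self) -> pd.DataFrame:
        out = self.profile.copy()
        out.index.name = "gene"
        return out

    def summary(self, gene_set: GeneSet | None = None) -> str:
        lines = [
            "Knockdown expression profile",
            "============================",
            f"replicates: {len(self.model.data.scans)}",
            f"profiled genes: {self.profile['mean'].notna().sum()}",
            f"log2-ratio SD (averaged): {self.profile['mean'].std():.3f}",
        ]
        if gene_set is not None:
            lines.append(str(self.target_set_shift(gene_set)))
        return "\n".join(lines)
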