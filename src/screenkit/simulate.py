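"""Seeded synthetic-data generators for every pipeline input class.

Each generator emulates the statistical structure its downstream analysis
assumes — not array physics.  Log-ratios carry additive Gaussian noise on
the log2 scale; qPCR abundances carry multiplicative log-normal noise.
Intensities are back-transformed from log-ratios around a log-normal
baseline with additive background so background filtering is exercisable.
Dye bias is a per-array constant offset (removed by centering) whose sign
follows which dye carries the query, plus per-array random offsets, so
dye-swap handling is non-trivial.

Every generator returns its data together with a :class:`SyntheticTruth`
carrying the ground truth (truth sets, effect sizes, true half-lives) for
recovery tests; the truth never leaks into the analyzed columns.  A single
root seed derives fixed per-stream child seeds, so outputs are reproducible
and modules are independently testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ArrayScan, ExperimentSet, HAC1_PROBE_CLASSES

__all__ = [
    "SyntheticTruth",
    "stream_rng",
    "simulate_screen",
    "simulate_ripchip",
    "simulate_knockdown",
    "simulate_decay",
]

_STREAMS = {"screen": 1, "ripchip": 2, "expression": 3, "decay": 4}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-stream generator derived from one root seed."""
    if stream not in _STREAMS:
        raise ValueError(f"unknown stream {stream!r}; choose from {sorted(_STREAMS)}")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth carried alongside generated data."""

    seed: int
    truth_set: tuple[str, ...]
    effect_size: float | Mapping
    noise_sd: float
    params: Mapping = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id": t, "effect": self.effect_size if np.isscalar(self.effect_size)
                 else dict(self.effect_size).get(t)} for t in self.truth_set]
        return pd.DataFrame(rows, columns=["id", "effect"])


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _intensities_from_ratios(
    rng: np.random.Generator,
    log_ratios: np.ndarray,
    background: float,
    baseline_log2: float,
    baseline_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Back-transform log2(query/reference) into (query, reference) foregrounds.

    The reference signal follows a log-normal baseline; the query signal is
    the reference scaled by 2**ratio; both get the additive background.
    """
    ref_signal = 2.0 ** (baseline_log2 + baseline_sd * rng.standard_normal(log_ratios.size))
    query_signal = ref_signal * 2.0**log_ratios
    return query_signal + background, ref_signal + background


def _make_scan(
    array_id: str,
    feature_ids: Sequence[str],
    query_fg: np.ndarray,
    ref_fg: np.ndarray,
    background: float,
    query_label: str,
    reference_label: str,
    dye_set: str,
    replicate_id: int,
    genes: Sequence[str] | None = None,
    probe_classes: Sequence[str] | None = None,
) -> ArrayScan:
    """Assemble a scan; dye set A puts the query in ch1, B in ch2."""
    if dye_set == "A":
        f1, f2 = query_fg, ref_fg
        assignment = {"ch1": query_label, "ch2": reference_label}
    else:
        f1, f2 = ref_fg, query_fg
        assignment = {"ch1": reference_label, "ch2": query_label}
    features = pd.DataFrame(
        {
            "feature_id": list(feature_ids),
            "gene": list(genes) if genes is not None else list(feature_ids),
            "probe_class": list(probe_classes) if probe_classes is not None else "na",
            "f_ch1": f1,
            "b_ch1": np.full(len(feature_ids), background),
            "f_ch2": f2,
            "b_ch2": np.full(len(feature_ids), background),
        }
    )
    return ArrayScan(
        array_id=array_id,
        features=features,
        channel_assignment=assignment,
        query=query_label,
        replicate_id=replicate_id,
        dye_set=dye_set,
    )


def simulate_screen(
    n_proteins: int = 2000,
    truth_set: Sequence[str] | int = (),
    effect: float = 4.0,
    noise_sd: float = 1.0,
    n_replicates: int = 6,
    background: float = 100.0,
    dye_bias: float = 0.0,
    baseline_log2: float = 13.0,
    baseline_sd: float = 1.0,
    array_offset_sd: float = 0.1,
    seed: int = 0,
) -> tuple[ExperimentSet, SyntheticTruth]:
    """Six-replicate dye-swap binding screen with a spiked truth set.

    ``truth_set`` is a list of protein ids (or an integer count, spiking the
    first k proteins); truth members get an additive ``effect`` on their
    log2 query/reference ratio in every replicate.  Half the replicates are
    dye-swapped (set "B").
    """
    if n_replicates % 2 or n_replicates < 2:
        raise ValueError("n_replicates must be even (half per dye set)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = stream_rng(seed, "screen")
    proteins = _ids("P", n_proteins)
    if isinstance(truth_set, int):
        truth_set = proteins[:truth_set]
    truth = [str(t) for t in truth_set]
    unknown = set(truth) - set(proteins)
    if unknown:
        raise ValueError(f"truth ids not on the array: {sorted(unknown)[:5]}")
    effect_vec = np.where(np.isin(proteins, truth), float(effect), 0.0)

    scans = []
    for r in range(n_replicates):
        dye_set = "A" if r < n_replicates // 2 else "B"
        rep_id = r % (n_replicates // 2) + 1
        # dye bias follows the dye carrying the query, so swaps flip its sign
        bias = dye_bias if dye_set == "A" else -dye_bias
        offset = array_offset_sd * rng.standard_normal()
        ratios = effect_vec + noise_sd * rng.standard_normal(n_proteins) + bias + offset
        qf, rf = _intensities_from_ratios(rng, ratios, background, baseline_log2, baseline_sd)
        scans.append(
            _make_scan(
                f"screen_{dye_set}{rep_id}", proteins, qf, rf, background,
                query_label="HAC1", reference_label="Reference",
                dye_set=dye_set, replicate_id=rep_id,
            )
        )
    es = ExperimentSet(scans=scans, design="screen")
    truth_obj = SyntheticTruth(
        seed=seed, truth_set=tuple(truth), effect_size=float(effect), noise_sd=float(noise_sd),
        params={
            "n_proteins": n_proteins, "n_replicates": n_replicates,
            "background": background, "dye_bias": dye_bias,
            "baseline_log2": baseline_log2, "baseline_sd": baseline_sd,
        },
    )
    return es, truth_obj


def simulate_ripchip(
    n_genes: int = 2000,
    enriched_set: Sequence[str] | int = (),
    effect: float = 2.0,
    n_ip: int = 6,
    n_mock: int = 6,
    noise_sd: float = 0.5,
    dropout_rate: float = 0.0,
    background: float = 100.0,
    baseline_log2: float = 13.0,
    baseline_sd: float = 1.0,
    array_offset_sd: float = 0.1,
    hac1_probe_effects: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[ExperimentSet, SyntheticTruth]:
    """Paired IP/Mock two-channel experiments with selectively enriched RNAs.

    IP arrays carry ``effect`` log2 units of enrichment on ``enriched_set``;
    mock arrays carry none.  With ``dropout_rate`` > 0, random gene/array
    cells are set below background in both channels, exercising the
    presence filter.  ``hac1_probe_effects`` adds the five HAC1 probes
    (gene "HAC1") with per-probe-class IP enrichment.
    """
    if n_ip + n_mock < 2:
        raise ValueError("need at least 2 arrays in total")
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must lie in [0, 1)")
    rng = stream_rng(seed, "ripchip")
    genes = _ids("G", n_genes)
    feature_ids = list(genes)
    gene_col = list(genes)
    classes = ["na"] * n_genes
    if isinstance(enriched_set, int):
        enriched_set = genes[:enriched_set]
    enriched = [str(g) for g in enriched_set]
    unknown = set(enriched) - set(genes)
    if unknown:
        raise ValueError(f"enriched ids not on the array: {sorted(unknown)[:5]}")
    effect_vec = np.where(np.isin(genes, enriched), float(effect), 0.0)
    if hac1_probe_effects:
        for cls in HAC1_PROBE_CLASSES:
            feature_ids.append(f"HAC1_{cls}")
            gene_col.append("HAC1")
            classes.append(cls)
            effect_vec = np.append(effect_vec, float(hac1_probe_effects.get(cls, 0.0)))
    n_feat = len(feature_ids)

    scans, groups = [], {}
    layout = [("IP", i + 1) for i in range(n_ip)] + [("Mock", i + 1) for i in range(n_mock)]
    for group, rep_id in layout:
        offset = array_offset_sd * rng.standard_normal()
        ratios = noise_sd * rng.standard_normal(n_feat) + offset
        if group == "IP":
            ratios = ratios + effect_vec
        qf, rf = _intensities_from_ratios(rng, ratios, background, baseline_log2, baseline_sd)
        if dropout_rate > 0:
            drop = rng.random(n_feat) < dropout_rate
            qf = np.where(drop, background, qf)
            rf = np.where(drop, background, rf)
        array_id = f"{group.lower()}_{rep_id}"
        scans.append(
            _make_scan(
                array_id, feature_ids, qf, rf, background,
                query_label=group, reference_label="Reference",
                dye_set="A", replicate_id=rep_id,
                genes=gene_col, probe_classes=classes,
            )
        )
        groups[array_id] = group
    es = ExperimentSet(scans=scans, design="ripchip", groups=groups)
    truth_obj = SyntheticTruth(
        seed=seed, truth_set=tuple(enriched), effect_size=float(effect), noise_sd=float(noise_sd),
        params={
            "n_genes": n_genes, "n_ip": n_ip, "n_mock": n_mock,
            "dropout_rate": dropout_rate, "background": background,
            "hac1_probe_effects": dict(hac1_probe_effects or {}),
        },
    )
    return es, truth_obj


def simulate_knockdown(
    n_genes: int = 2000,
    effects: Mapping[str, float] | Sequence[float] | None = None,
    target_set: Sequence[str] | int = (),
    shift: float = 0.0,
    n_replicates: int = 2,
    noise_sd: float = 0.2,
    background: float = 100.0,
    baseline_log2: float = 13.0,
    baseline_sd: float = 1.0,
    array_offset_sd: float = 0.1,
    hac1_probe_effects: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[ExperimentSet, SyntheticTruth]:
    """Knockdown-vs-WT expression ratios with a shifted target gene set.

    log2(knockdown/WT) = per-gene effect + ``shift`` on target-set members
    + noise.  ``hac1_probe_effects`` adds HAC1 probes with probe-class
    specific effects (unspliced vs spliced readouts).
    """
    rng = stream_rng(seed, "expression")
    genes = _ids("G", n_genes)
    feature_ids, gene_col, classes = list(genes), list(genes), ["na"] * n_genes
    if isinstance(target_set, int):
        target_set = genes[:target_set]
    targets = [str(g) for g in target_set]
    unknown = set(targets) - set(genes)
    if unknown:
        raise ValueError(f"target ids not on the array: {sorted(unknown)[:5]}")
    if effects is None:
        effect_vec = np.zeros(n_genes)
    elif isinstance(effects, Mapping):
        unknown = set(effects) - set(genes)
        if unknown:
            raise ValueError(f"effect ids not on the array: {sorted(unknown)[:5]}")
        effect_vec = np.array([float(effects.get(g, 0.0)) for g in genes])
    else:
        effect_vec = np.asarray(effects, dtype=float)
        if effect_vec.size != n_genes:
            raise ValueError("effect vector length must equal n_genes")
    effect_vec = effect_vec + float(shift) * np.isin(genes, targets)
    if hac1_probe_effects:
        for cls in HAC1_PROBE_CLASSES:
            feature_ids.append(f"HAC1_{cls}")
            gene_col.append("HAC1")
            classes.append(cls)
            effect_vec = np.append(effect_vec, float(hac1_probe_effects.get(cls, 0.0)))
    n_feat = len(feature_ids)

    scans = []
    for rep_id in range(1, n_replicates + 1):
        offset = array_offset_sd * rng.standard_normal()
        ratios = effect_vec + noise_sd * rng.standard_normal(n_feat) + offset
        qf, rf = _intensities_from_ratios(rng, ratios, background, baseline_log2, baseline_sd)
        scans.append(
            _make_scan(
                f"kd_{rep_id}", feature_ids, qf, rf, background,
                query_label="knockdown", reference_label="WT",
                dye_set="A", replicate_id=rep_id,
                genes=gene_col, probe_classes=classes,
            )
        )
    es = ExperimentSet(scans=scans, design="expression")
    truth_obj = SyntheticTruth(
        seed=seed, truth_set=tuple(targets), effect_size=float(shift), noise_sd=float(noise_sd),
        params={
            "n_genes": n_genes, "n_replicates": n_replicates,
            "effects": dict(zip(feature_ids, effect_vec)),
            "hac1_probe_effects": dict(hac1_probe_effects or {}),
        },
    )
    return es, truth_obj


def simulate_decay(
    half_lives: Mapping[str, float],
    timepoints: Sequence[float] = (0.0, 30.0),
    noise_cv: float = 0.05,
    reference_gene: str = "GAPDH",
    condition: str = "WT",
    n_replicates: int = 3,
    initial_abundance: float = 50.0,
    reference_abundance: float = 100.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """First-order decay qPCR time courses with reference normalization.

    Target abundance follows X(t) = X(0) * 2^(-t/T) with multiplicative
    log-normal noise of coefficient of variation ``noise_cv``; the
    reference gene is constant up to the same noise.  Emits one qPCR row
    per gene/replicate/timepoint with the matched reference measurement.
    """
    if not half_lives:
        raise ValueError("half_lives must name at least one gene")
    for gene, T in half_lives.items():
        if T <= 0:
            raise ValueError(f"half-life for {gene!r} must be > 0, got {T}")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    t = np.asarray(timepoints, dtype=float)
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must start at 0 and increase strictly")
    rng = stream_rng(seed, "decay")
    sigma = noise_cv  # log-normal scale parameter ~ CV for small CV
    rows = []
    for gene in sorted(half_lives):
        T = float(half_lives[gene])
        for rep in range(1, n_replicates + 1):
            for ti in t:
                x = initial_abundance * 2.0 ** (-ti / T)
                noise = np.exp(sigma * rng.standard_normal()) if sigma else 1.0
                ref = reference_abundance * (
                    np.exp(sigma * rng.standard_normal()) if sigma else 1.0
                )
                rows.append(
                    {
                        "gene": gene,
                        "condition": condition,
                        "timepoint_min": float(ti),
                        "value": float(x * noise),
                        "reference_value": float(ref),
                        "replicate": rep,
                    }
                )
    table = pd.DataFrame(rows)
    truth_obj = SyntheticTruth(
        seed=seed, truth_set=tuple(sorted(half_lives)), effect_size=dict(half_lives),
        noise_sd=float(noise_cv),
        params={
            "timepoints": tuple(float(x) for x in t), "condition": condition,
            "n_replicates": n_replicates, "reference_gene": reference_gene,
        },
    )
    return table, truth_obj
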