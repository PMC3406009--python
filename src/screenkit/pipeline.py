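"""Stage orchestration: config-driven runs and a reproduce-all entry point.

A :class:`RunConfig` names a stage, its input paths and parameters; every
parameter defaults to the study's analysis settings (1.5x background
factor, alpha = 1e-4, 9-of-12 presence, 30-min shut-off).  Outputs carry a
machine-readable provenance header (tool version, parameters, seed).
:func:`reproduce_all` generates all synthetic datasets, runs every stage,
and evaluates the package's acceptance targets into a pass/fail report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    ExperimentSet,
    read_array_table,
    read_qpcr_table,
    validate_experiment_set,
    write_results_table,
)
from .screen import BindingScreenModel, dual_set_null_rate
from .ripchip import RipChipModel, sam_two_class
from .expression import GeneSet, KnockdownModel
from .decay import (
    DecayModel,
    half_life_ratio,
    half_life_two_point,
    steady_state_ratio,
)
from .simulate import (
    simulate_decay,
    simulate_knockdown,
    simulate_ripchip,
    simulate_screen,
)

__all__ = ["RunConfig", "run_stage", "reproduce_all", "read_metadata_table"]

STAGES = ("screen", "ripchip", "expression", "decay", "simulate")

DEFAULT_PARAMS: dict[str, object] = {
    "alpha": 1e-4,
    "bg_factor": 1.5,
    "center": "median",
    "min_present": None,  # 9-of-12 / strict majority chosen from the design
    "n_perm": 1000,
    "reference_gene": "GAPDH",
    "method": "two_point",
}


@dataclass
class RunConfig:
    """One stage invocation: inputs, parameters, seed, output directory."""

    stage: str
    inputs: list[str] = field(default_factory=list)
    metadata: str | None = None  # per-array metadata TSV
    geneset: str | None = None
    params: dict = field(default_factory=dict)
    seed: int = 17
    out: str = "runs"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; choose from {STAGES}")
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def provenance(self) -> dict:
        flat = {k: v for k, v in self.params.items() if v is not None}
        return {
            "tool": f"screenkit {__version__}",
            "stage": self.stage,
            "seed": self.seed,
            **{f"param.{k}": v for k, v in flat.items()},
        }


def read_metadata_table(path: str | Path) -> dict[str, dict]:
    """Per-array metadata TSV: array_id, ch1, ch2, query[, replicate_id, dye_set, group]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"array_id", "ch1", "ch2", "query"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing column(s) {sorted(missing)}")
    meta: dict[str, dict] = {}
    for _, row in df.iterrows():
        meta[row["array_id"]] = {
            "channel_assignment": {"ch1": row["ch1"], "ch2": row["ch2"]},
            "query": row["query"],
            "replicate_id": int(row.get("replicate_id", 1) or 1),
            "dye_set": row.get("dye_set") or None,
            "group": row.get("group") or "",
        }
    return meta


def _load_experiment_set(config: RunConfig, design: str) -> ExperimentSet:
    meta = read_metadata_table(config.metadata) if config.metadata else None
    sets = [read_array_table(p, metadata=meta, design=design) for p in config.inputs]
    scans, groups = [], {}
    for es in sets:
        scans.extend(es.scans)
        groups.update(es.groups)
    merged = ExperimentSet(scans=scans, design=design, groups=groups)
    report = validate_experiment_set(merged)
    if not report.ok:
        raise ValueError(f"invalid experiment set:\n{report}")
    return merged


def run_stage(config: RunConfig) -> dict:
    """Run one configured stage; returns {"outputs": [paths], "log": [...]}.

    All preconditions (inputs exist, config valid) are checked before any
    computation; no partial outputs are left on failure.
    """
    log: list[str] = []
    for p in config.inputs:
        if not Path(p).exists():
            raise FileNotFoundError(f"input path does not exist: {p}")
    if config.metadata and not Path(config.metadata).exists():
        raise FileNotFoundError(f"metadata path does not exist: {config.metadata}")
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    outputs: list[Path] = []

    if config.stage == "screen":
        data = _load_experiment_set(config, "screen")
        model = BindingScreenModel(
            data,
            alpha=float(config.params["alpha"]),
            bg_factor=float(config.params["bg_factor"]),
            center=str(config.params["center"]),
        )
        res = model.fit()
        out = outdir / "screen_result.tsv"
        table = res.table.reset_index()
        write_results_table(table.rename(columns={"index": "protein"}), out, prov)
        outputs.append(out)
        log.append(f"classified {len(res.classified)} of {res.n_scored} scorable proteins")

    elif config.stage == "ripchip":
        data = _load_experiment_set(config, "ripchip")
        mp = config.params["min_present"]
        model = RipChipModel(
            data,
            bg_factor=float(config.params["bg_factor"]),
            min_present=None if mp is None else int(mp),
        )
        res = model.fit()
        out = outdir / "enrichment.tsv"
        table = res.table.reset_index(names="gene")
        write_results_table(table, out, prov)
        outputs.append(out)
        log.append(f"{len(res.enrichment)} genes passed the presence filter")

    elif config.stage == "expression":
        data = _load_experiment_set(config, "expression")
        model = KnockdownModel(
            data,
            center=str(config.params["center"]),
            bg_factor=float(config.params["bg_factor"]),
        )
        res = model.fit()
        out = outdir / "profile.tsv"
        write_results_table(res.table.reset_index(), out, prov)
        outputs.append(out)
        if config.geneset:
            gs = GeneSet.from_file(config.geneset)
            shift = res.target_set_shift(gs)
            log.append(str(shift))

    elif config.stage == "decay":
        tables = [read_qpcr_table(p) for p in config.inputs]
        data = pd.concat(tables, ignore_index=True)
        model = DecayModel(
            data,
            reference_gene=str(config.params["reference_gene"]),
            method=str(config.params["method"]),
        )
        res = model.fit()
        out = outdir / "halflives.tsv"
        write_results_table(res.table, out, prov)
        outputs.append(out)
        log.append(f"estimated {len(res.estimates)} half-lives")

    elif config.stage == "simulate":
        kind = str(config.params.get("kind", "screen"))
        gen = {
            "screen": simulate_screen,
            "ripchip": simulate_ripchip,
            "expression": simulate_knockdown,
            "decay": simulate_decay,
        }[kind]
        gen_params = dict(config.params.get("generator", {}))
        data, truth = gen(seed=config.seed, **gen_params)
        if kind == "decay":
            out = outdir / "qpcr.tsv"
            write_results_table(data, out, prov)
            outputs.append(out)
        else:
            frames = []
            for scan in data.scans:
                frames.append(scan.features.assign(array_id=scan.array_id))
            out = outdir / f"{kind}_arrays.tsv"
            write_results_table(pd.concat(frames, ignore_index=True), out, prov)
            outputs.append(out)
            meta_rows = []
            for scan in data.scans:
                meta_rows.append(
                    {
                        "array_id": scan.array_id,
                        "ch1": scan.channel_assignment["ch1"],
                        "ch2": scan.channel_assignment["ch2"],
                        "query": scan.query,
                        "replicate_id": scan.replicate_id,
                        "dye_set": scan.dye_set,
                        "group": data.group_of(scan.array_id),
                    }
                )
            meta_out = outdir / f"{kind}_metadata.tsv"
            write_results_table(pd.DataFrame(meta_rows), meta_out, prov)
            outputs.append(meta_out)
        truth_out = outdir / f"{kind}_truth.tsv"
        tf = truth.to_frame()
        if not tf.empty:
            write_results_table(tf, truth_out, prov)
            outputs.append(truth_out)
        log.append(f"simulated {kind} dataset with seed {config.seed}")

    return {"outputs": [str(p) for p in outputs], "log": log}


# ---------------------------------------------------------------------------
# reproduce-all: synthetic end-to-end evaluation of the acceptance targets


def simulate_stabilization_ratios(
    seed: int,
    half_life_wt: float = 19.0,
    stabilizations: Mapping[str, float] = {"ada5del": 1.6, "ire1del": 2.7},
    n_experiments: int = 30,
    noise_cv: float = 0.05,
    n_replicates: int = 3,
) -> tuple[float, ...]:
    """Mutant/WT half-life ratios recovered from simulated shut-off assays.

    Each seeded experiment simulates one 30-min thiolutin shut-off qPCR
    assay (``n_replicates`` replicates, multiplicative noise ``noise_cv``)
    per strain, estimates every half-life with the two-point formula on the
    replicate-mean fraction, and takes the mutant/WT ratio; the returned
    values are medians across experiments, in ``stabilizations`` order.
    """
    strains = {"WT": half_life_wt}
    strains.update({k: v * half_life_wt for k, v in stabilizations.items()})
    ratios: dict[str, list[float]] = {k: [] for k in stabilizations}
    for i in range(n_experiments):
        frames = []
        for j, (name, T) in enumerate(sorted(strains.items())):
            tbl, _ = simulate_decay(
                {"HAC1u": T}, noise_cv=noise_cv, condition=name,
                n_replicates=n_replicates, seed=seed + 100 * i + j,
            )
            frames.append(tbl)
        res = DecayModel(pd.concat(frames, ignore_index=True)).fit()
        for name in stabilizations:
            ratios[name].append(res.ratio(("HAC1u", name), ("HAC1u", "WT")))
    return tuple(float(np.median(ratios[name])) for name in stabilizations)


def _target(value: float, expected: float, tol: float, kind: str = "abs") -> dict:
    ok = abs(value - expected) <= tol if kind == "abs" else value >= expected
    return {"value": float(value), "expected": float(expected),
            "tolerance": float(tol), "pass": bool(ok)}


def reproduce_all(
    seed: int = 17,
    outdir: str | Path = "runs",
    n_null_runs: int = 40,
    n_spike_seeds: int = 20,
    n_sam_seeds: int = 10,
    n_perm: int = 300,
    n_decay_seeds: int = 30,
) -> dict:
    """Generate every synthetic input class, run all stages, check targets.

    Returns a report dict with a per-target computed value, tolerance and
    pass flag, and writes it as JSON under ``outdir``.  Problem sizes are
    the study's stated conditions (2,000 features, 6 dye-swap replicates,
    6 IP / 6 Mock, 3 qPCR replicates at 5% noise); run counts are
    adjustable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    seeds = root.generate_state(6, dtype=np.uint32) % (2**31 - 1)
    report: dict[str, dict] = {}

    # printed-fraction half-life arithmetic
    wt = half_life_two_point(0.0, 30.0, 0.3347)
    damp = half_life_two_point(0.0, 30.0, 0.5700)
    report["halflife_wt_min"] = _target(wt.half_life, 19.0, 0.05)
    report["halflife_ypt1damp_min"] = _target(damp.half_life, 37.0, 0.05)
    report["steady_state_fold"] = _target(steady_state_ratio(37.0, 19.0), 1.95, 0.05)

    # simulated shut-off series at the mutant stabilizations; each seeded
    # experiment is one 3-replicate qPCR assay, the estimate is the median
    # ratio across experiments
    ratio_ada5, ratio_ire1 = simulate_stabilization_ratios(int(seeds[0]))
    report["stabilization_fold_ada5"] = _target(ratio_ada5, 1.6, 0.25)
    report["stabilization_fold_ire1"] = _target(ratio_ire1, 2.7, 0.4)

    # screen global-null false-call calibration vs the product-null closed form
    n_prot, alpha = 2000, 1e-4
    calls = 0
    for i in range(n_null_runs):
        es, _ = simulate_screen(n_proteins=n_prot, seed=int(seeds[1]) + i)
        calls += len(BindingScreenModel(es, alpha=alpha).fit().classified)
    expected_rate = dual_set_null_rate(alpha)
    trials = n_null_runs * n_prot
    mc_sd = float(np.sqrt(expected_rate * (1 - expected_rate) / trials))
    report["screen_null_call_rate"] = _target(calls / trials, expected_rate, 3 * mc_sd)

    # spike-in recovery: all spiked classified above every null
    ok_runs = 0
    for i in range(n_spike_seeds):
        es, truth = simulate_screen(
            n_proteins=2000, truth_set=10, effect=4.0, noise_sd=1.0,
            seed=int(seeds[2]) + i,
        )
        fit = BindingScreenModel(es).fit()
        spiked = set(truth.truth_set)
        top = fit.table["rank"].nsmallest(len(spiked)).index
        if spiked <= set(fit.classified) and set(top) == spiked:
            ok_runs += 1
    report["screen_spike_recovery_rate"] = _target(
        ok_runs / n_spike_seeds, 0.95, 0.0, kind="ge"
    )

    # RIP-ChIP effect recovery
    est_effects = []
    for i in range(5):
        es, truth = simulate_ripchip(
            n_genes=2000, enriched_set=20, effect=2.0, noise_sd=0.5,
            seed=int(seeds[3]) + i,
        )
        fit = RipChipModel(es).fit()
        est = fit.table.loc[
            fit.table.index.intersection(truth.truth_set), "mean_enrichment"
        ].mean()
        est_effects.append(est)
    report["ripchip_spiked_enrichment_log2"] = _target(
        float(np.mean(est_effects)), 2.0, 0.2
    )

    # SAM null calibration: median q in the 5% tail near 1
    tail_meds = []
    for i in range(n_sam_seeds):
        es, _ = simulate_ripchip(n_genes=2000, seed=int(seeds[4]) + i)
        model = RipChipModel(es)
        ip = model.centered_ratios(model.ip_scans).dropna()
        mock = model.centered_ratios(model.mock_scans).reindex(ip.index).dropna()
        sam = sam_two_class(
            ip.loc[mock.index], mock, n_perm=n_perm, seed=int(seeds[4]) + i
        )
        top = sam.d.abs().nlargest(max(1, len(sam.d) // 20)).index
        tail_meds.append(float(sam.q[top].median()))
    report["sam_null_tail_median_q"] = _target(float(np.median(tail_meds)), 1.0, 0.5)

    # two-point round-trip identity on a grid
    grid_t = np.array([5.0, 10.0, 19.0, 37.0, 60.0, 120.0])
    grid_dt = np.array([10.0, 30.0, 45.0])
    err = max(
        abs(half_life_two_point(0.0, dt, 2.0 ** (-dt / T)).half_life - T) / T
        for T in grid_t
        for dt in grid_dt
    )
    report["halflife_roundtrip_max_rel_err"] = _target(err, 0.0, 1e-9)

    # decay parameter recovery at the study's replication
    worst = 0.0
    for T in (10.0, 19.0, 37.0, 60.0):
        ests = []
        for i in range(n_decay_seeds):
            tbl, _ = simulate_decay(
                {"g": T}, noise_cv=0.05, n_replicates=3, seed=int(seeds[5]) + i
            )
            ests.append(DecayModel(tbl).fit().estimates[0].half_life)
        worst = max(worst, abs(float(np.median(ests)) - T) / T)
    report["decay_recovery_worst_rel_err"] = _target(worst, 0.0, 0.15)

    report_path = outdir / "reproduce_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
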