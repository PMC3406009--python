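"""Data model and tab-delimited I/O for two-channel array experiments.

The native exchange format is plain TSV with one row per array feature and
the columns ``feature_id, gene, probe_class, f_ch1, b_ch1, f_ch2, b_ch2``
(foreground/background fluorescence per channel, arbitrary units).  A
minimal reader for the GenePix GPR dialect maps the standard
``F635 Median``/``B635 Median``/``F532 Median``/``B532 Median`` columns onto
the same schema.

Channel semantics are carried by sample-role metadata (which sample label is
the "query" and which the reference), never by dye identity, so dye-swap
replicates are handled uniformly: dye set "A" means the query sample is in
channel 1, "B" means it is in channel 2.
"""

from __future__ import annotations

import io as _io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMeasurement",
    "ArrayScan",
    "ExperimentSet",
    "QpcrRecord",
    "ValidationReport",
    "SchemaError",
    "ValidationError",
    "read_array_table",
    "read_gpr",
    "read_qpcr_table",
    "write_results_table",
    "validate_experiment_set",
]

REQUIRED_COLUMNS = ("feature_id", "f_ch1", "b_ch1", "f_ch2", "b_ch2")
INTENSITY_COLUMNS = ("f_ch1", "b_ch1", "f_ch2", "b_ch2")

#: HAC1 is tiled by five probes: two unspliced exon-intron junctions, the
#: intron, the ORF, and the spliced exon-exon junction.
HAC1_PROBE_CLASSES = (
    "unspliced_jxn_1",
    "unspliced_jxn_2",
    "intron",
    "ORF",
    "spliced_jxn",
)


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """An input value violates a data-model invariant."""


@dataclass(frozen=True)
class FeatureMeasurement:
    """One spotted feature on a two-channel array."""

    feature_id: str
    gene: str = ""
    probe_class: str = "na"
    f_ch1: float = 0.0
    f_ch2: float = 0.0
    b_ch1: float = 0.0
    b_ch2: float = 0.0

    def __post_init__(self) -> None:
        for name in INTENSITY_COLUMNS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"intensity {name}={v!r} for feature {self.feature_id!r} "
                    "must be finite and non-negative"
                )


@dataclass
class ArrayScan:
    """A single two-channel hybridization.

    Parameters
    ----------
    features : DataFrame with the native schema columns (one row per feature).
    channel_assignment : mapping {"ch1": label, "ch2": label} giving the
        sample hybridized in each channel (e.g. {"ch1": "HAC1",
        "ch2": "Reference"}).
    query : the sample label playing the "query" role (numerator of the
        log-ratio); the other channel is the reference/denominator.
    dye_set : "A" when the query is in channel 1, "B" when in channel 2.
        Inferred from ``channel_assignment`` when omitted.
    """

    array_id: str
    features: pd.DataFrame
    channel_assignment: Mapping[str, str]
    query: str
    replicate_id: int = 1
    dye_set: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.features.columns]
        if missing:
            raise SchemaError(f"array {self.array_id!r} missing column(s) {missing}")
        if "gene" not in self.features.columns:
            self.features = self.features.assign(gene=self.features["feature_id"])
        if "probe_class" not in self.features.columns:
            self.features = self.features.assign(probe_class="na")
        self.features = self.features.reset_index(drop=True)
        _check_intensities(self.features, self.array_id)
        ids = self.features["feature_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(
                f"array {self.array_id!r}: duplicate feature_id {dup!r}"
            )
        if self.dye_set is None:
            self.dye_set = "A" if self.query_channel == "ch1" else "B"

    @property
    def query_channel(self) -> str:
        matches = [ch for ch, lab in self.channel_assignment.items() if lab == self.query]
        if len(matches) != 1:
            raise ValidationError(
                f"array {self.array_id!r}: query role {self.query!r} must match "
                f"exactly one channel, got {matches}"
            )
        return matches[0]

    @property
    def reference_channel(self) -> str:
        return "ch2" if self.query_channel == "ch1" else "ch1"

    def channel_intensities(self, channel: str) -> tuple[pd.Series, pd.Series]:
        """Foreground and background series for ``channel`` ('ch1'|'ch2')."""
        fg = self.features[f"f_{channel}"].astype(float)
        bg = self.features[f"b_{channel}"].astype(float)
        fg.index = bg.index = self.features["feature_id"]
        return fg, bg

    @property
    def feature_ids(self) -> pd.Index:
        return pd.Index(self.features["feature_id"])


@dataclass
class ExperimentSet:
    """A collection of scans sharing a (possibly partial) feature universe."""

    scans: list[ArrayScan]
    design: str = "screen"  # "screen" | "ripchip" | "expression"
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for scan in self.scans:
            if scan.array_id in seen:
                raise ValidationError(f"duplicate array_id {scan.array_id!r}")
            seen.add(scan.array_id)

    @property
    def feature_universe(self) -> pd.Index:
        """Sorted outer join of every scan's feature ids."""
        ids: set[str] = set()
        for scan in self.scans:
            ids.update(scan.features["feature_id"])
        return pd.Index(sorted(ids))

    @property
    def presence_mask(self) -> pd.DataFrame:
        """Boolean feature x array membership table (outer-join tracking)."""
        universe = self.feature_universe
        cols = {}
        for scan in self.scans:
            cols[scan.array_id] = universe.isin(set(scan.features["feature_id"]))
        return pd.DataFrame(cols, index=universe)

    def annotation(self) -> pd.DataFrame:
        """gene / probe_class per feature, first occurrence wins."""
        frames = [
            scan.features[["feature_id", "gene", "probe_class"]] for scan in self.scans
        ]
        ann = pd.concat(frames).drop_duplicates("feature_id").set_index("feature_id")
        return ann.loc[self.feature_universe]

    def group_of(self, array_id: str) -> str:
        return self.groups.get(array_id, "")

    def subset(self, group: str) -> list[ArrayScan]:
        return [s for s in self.scans if self.group_of(s.array_id) == group]


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR measurement of a target gene against a normalization gene."""

    gene: str
    condition: str
    timepoint: float  # minutes
    value: float
    reference_value: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.timepoint < 0:
            raise ValidationError("timepoint must be >= 0 minutes")
        if self.value <= 0 or self.reference_value <= 0:
            raise ValidationError(
                f"qPCR abundances must be strictly positive "
                f"(gene={self.gene!r}, t={self.timepoint})"
            )


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff clean
        return self.ok

    def __str__(self) -> str:
        lines = [f"violation: {v}" for v in self.violations]
        lines += [f"note: {n}" for n in self.notes]
        return "\n".join(lines) if lines else "ok"


def _check_intensities(df: pd.DataFrame, array_id: str) -> None:
    for col in INTENSITY_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"array {array_id!r}: column {col!r} row {row} has invalid "
                f"intensity {df[col].iloc[row]!r} (must be finite and >= 0)"
            )


def read_array_table(
    path: str | Path,
    metadata: Mapping[str, Mapping] | Mapping | None = None,
    design: str = "screen",
) -> ExperimentSet:
    """Read a native TSV feature table into an :class:`ExperimentSet`.

    The file holds one or more scans; multiple scans are distinguished by an
    ``array_id`` column.  ``metadata`` supplies per-array annotations as a
    mapping ``array_id -> {channel_assignment, query, replicate_id, dye_set,
    group}`` (or a single such mapping when the file holds one unlabeled
    scan).  Unknown columns are preserved on ``scan.features``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"feature_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    default_meta = {
        "channel_assignment": {"ch1": "query", "ch2": "Reference"},
        "query": "query",
        "replicate_id": 1,
        "dye_set": None,
        "group": "",
    }
    per_array: dict[str, dict]
    if "array_id" in df.columns:
        array_ids = list(dict.fromkeys(df["array_id"].astype(str)))
        tables = {aid: g.drop(columns="array_id") for aid, g in df.groupby("array_id", sort=False)}
    else:
        array_ids = [path.stem]
        tables = {path.stem: df}
    if metadata is None:
        per_array = {aid: dict(default_meta) for aid in array_ids}
    elif all(aid in metadata for aid in array_ids):
        per_array = {aid: {**default_meta, **dict(metadata[aid])} for aid in array_ids}
    else:  # a single scan's metadata applied to every array in the file
        per_array = {aid: {**default_meta, **dict(metadata)} for aid in array_ids}

    scans, groups = [], {}
    for aid in array_ids:
        meta = per_array[aid]
        scan = ArrayScan(
            array_id=str(aid),
            features=tables[aid].reset_index(drop=True),
            channel_assignment=meta["channel_assignment"],
            query=meta["query"],
            replicate_id=int(meta["replicate_id"]),
            dye_set=meta["dye_set"],
        )
        scans.append(scan)
        if meta.get("group"):
            groups[str(aid)] = meta["group"]
    return ExperimentSet(scans=scans, design=design, groups=groups)


_GPR_COLUMN_MAP = {
    "F635 Median": "f_ch1",
    "B635 Median": "b_ch1",
    "F532 Median": "f_ch2",
    "B532 Median": "b_ch2",
}


def read_gpr(
    path: str | Path,
    metadata: Mapping | None = None,
    design: str = "screen",
) -> ExperimentSet:
    """Minimal GenePix GPR reader mapped onto the native schema.

    Parses the ATF-style header block then the data table; channel 1 is the
    635 nm (Cy5) scan and channel 2 the 532 nm (Cy3) scan.  Only median
    foreground/background intensities are used.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    # ATF header: "ATF\t1.0" then "<n_optional>\t<n_fields>" then n_optional
    # quoted "key=value" records, then the column header line.
    if not lines or not lines[0].startswith("ATF"):
        raise SchemaError(f"{path}: not an ATF/GPR file")
    n_optional = int(lines[1].split("\t")[0])
    table_text = "\n".join(lines[2 + n_optional:])
    df = pd.read_csv(_io.StringIO(table_text), sep="\t")
    df.columns = [re.sub(r'^"|"$', "", c) for c in df.columns]
    missing = [c for c in _GPR_COLUMN_MAP if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing GPR column(s) {missing}")
    out = pd.DataFrame(
        {
            "feature_id": df.get("ID", df.get("Name")).astype(str),
            "gene": df.get("Name", df.get("ID")).astype(str),
        }
    )
    for src, dst in _GPR_COLUMN_MAP.items():
        out[dst] = df[src].astype(float).clip(lower=0.0)
    meta = dict(metadata or {})
    meta.setdefault("channel_assignment", {"ch1": "query", "ch2": "Reference"})
    meta.setdefault("query", "query")
    scan = ArrayScan(
        array_id=str(meta.get("array_id", path.stem)),
        features=out,
        channel_assignment=meta["channel_assignment"],
        query=meta["query"],
        replicate_id=int(meta.get("replicate_id", 1)),
        dye_set=meta.get("dye_set"),
    )
    es = ExperimentSet(scans=[scan], design=design)
    if meta.get("group"):
        es.groups[scan.array_id] = meta["group"]
    return es


QPCR_COLUMNS = ("gene", "condition", "timepoint_min", "value", "reference_value")


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR abundance table (gene, condition, timepoint_min, value,
    reference_value[, replicate])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing qPCR column(s) {missing}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    if (df["value"] <= 0).any() or (df["reference_value"] <= 0).any():
        row = int(np.flatnonzero((df["value"] <= 0) | (df["reference_value"] <= 0))[0])
        raise ValidationError(f"{path}: non-positive abundance at row {row}")
    return df


_SORT_PRIORITY = ("feature_id", "protein", "gene", "condition", "replicate_id", "replicate")


def write_results_table(
    result: pd.DataFrame,
    path: str | Path,
    provenance: Mapping | None = None,
) -> None:
    """Write any tabular stage output as deterministic TSV.

    Rows are sorted by id-like columns (feature/protein/gene, then
    replicate), floats carry 8 significant digits, and two writes of the
    same object are byte-identical.  ``provenance`` entries are emitted as
    leading ``# key=value`` comment lines (skipped on re-read).
    """
    if isinstance(result, pd.Series):
        result = result.to_frame()
    if not isinstance(result, pd.DataFrame):
        table = getattr(result, "table", None)
        result = table if isinstance(table, pd.DataFrame) else pd.DataFrame(result)
    if result.empty:
        raise ValueError("refusing to write an empty results table")
    df = result.reset_index() if result.index.name else result.copy()
    sort_cols = [c for c in _SORT_PRIORITY if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g", lineterminator="\n")


def validate_experiment_set(es: ExperimentSet) -> ValidationReport:
    """Report per-scan invariant violations; empty report iff all hold."""
    report = ValidationReport()
    if not es.scans:
        report.violations.append("experiment set contains no scans")
        return report
    for scan in es.scans:
        labels = list(scan.channel_assignment.values())
        if len(scan.channel_assignment) != 2:
            report.violations.append(
                f"{scan.array_id}: expected exactly 2 channels, got "
                f"{sorted(scan.channel_assignment)}"
            )
            continue
        n_query = sum(lab == scan.query for lab in labels)
        if n_query != 1:
            report.violations.append(
                f"{scan.array_id}: query role {scan.query!r} assigned to "
                f"{n_query} channels (need exactly 1)"
            )
            continue
        expected_set = "A" if scan.query_channel == "ch1" else "B"
        if scan.dye_set not in ("A", "B"):
            report.violations.append(
                f"{scan.array_id}: dye_set {scan.dye_set!r} not in {{'A','B'}}"
            )
        elif scan.dye_set != expected_set:
            report.violations.append(
                f"{scan.array_id}: dye_set {scan.dye_set!r} inconsistent with "
                f"query in {scan.query_channel}"
            )
    mask = es.presence_mask
    if len(es.scans) > 1 and not mask.all().all():
        n_partial = int((~mask.all(axis=1)).sum())
        report.notes.append(
            f"feature universes differ across scans: {n_partial} feature(s) "
            "absent from at least one scan (tracked by presence mask)"
        )
    return report
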