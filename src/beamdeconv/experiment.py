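"""End-to-end deconvolution protocol: split, train, evaluate, tabulate.

The protocol mirrors how chamber-specific deconvolution networks are
commissioned: a geometry grid of paired chamber/diode scans is split into
a training/validation subset (four field sizes at three depths, 12 scans on
the default 7 x 4 grid) and a held-out test subset (the remaining 16); a
network is trained per beam condition (energy, modality, chamber) — or one
combined network on several conditions pooled — and judged by the penumbra
width difference (PWD) of its output against the diode reference, before
and after deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ann import SlidingWindowANN, ANNResults
from .profiles import normalize_cax, pwd, mse
from .synthetic import GeometryEntry, SyntheticConfig, build_dataset

__all__ = [
    "TRAIN_FIELD_SIZES_MM",
    "TRAIN_DEPTHS_MM",
    "DatasetSplit",
    "BeamCondition",
    "EvaluationReport",
    "make_split",
    "make_condition",
    "run_separate",
    "run_combined",
    "report",
]

#: Field sizes (mm) and depths (mm) whose scans form the training/validation
#: subset; every other geometry is held out for testing.
TRAIN_FIELD_SIZES_MM = (20.0, 40.0, 60.0, 100.0)
TRAIN_DEPTHS_MM = (15.0, 100.0, 200.0)


@dataclass(frozen=True, eq=False)
class DatasetSplit:
    """Disjoint, exhaustive partition of a geometry collection."""

    train: list  # GeometryEntry
    test: list

    @property
    def n_train(self) -> int:
        return len(self.train)

    @property
    def n_test(self) -> int:
        return len(self.test)


def make_split(
    entries,
    train_field_sizes=TRAIN_FIELD_SIZES_MM,
    train_depths=TRAIN_DEPTHS_MM,
) -> DatasetSplit:
    """Rule-based train/test partition of a scan collection.

    A geometry goes to training/validation iff its field size AND depth are
    both in the training sets; on the default 7 x 4 grid this yields 12
    training and 16 test scans.  Applied to whatever geometries exist, so
    reduced grids partition consistently.
    """
    entries = list(entries)
    seen = set()
    for e in entries:
        key = (e.field_size_mm, e.depth_mm)
        if key in seen:
            raise ValueError(f"duplicate geometry {key}")
        seen.add(key)
    is_train = [
        e.field_size_mm in train_field_sizes and e.depth_mm in train_depths
        for e in entries
    ]
    train = [e for e, t in zip(entries, is_train) if t]
    test = [e for e, t in zip(entries, is_train) if not t]
    if not train:
        raise ValueError(
            "split rule selects no training geometries — cannot train; "
            "extend the grid to cover the training field sizes and depths"
        )
    return DatasetSplit(train=train, test=test)


@dataclass(frozen=True, eq=False)
class BeamCondition:
    """One (energy, modality, chamber) combination and its scan grid."""

    energy: str
    modality: str
    detector: str
    entries: list  # GeometryEntry

    @property
    def label(self) -> str:
        return f"{self.energy}{self.modality}_{self.detector}"

    def measured_of(self, entry: GeometryEntry):
        """The chamber scan of one geometry (the reference itself if the
        condition's detector does not blur)."""
        if self.detector in entry.measured:
            return entry.measured[self.detector]
        return entry.reference


def make_condition(
    config: SyntheticConfig, modality: str, detector: str
) -> BeamCondition:
    """Generate a synthetic beam condition for one chamber."""
    return BeamCondition(
        energy=config.energy,
        modality=modality,
        detector=detector,
        entries=build_dataset(config, modality=modality),
    )


@dataclass(frozen=True, eq=False)
class EvaluationReport:
    """Per-geometry PWD/MSE table plus training diagnostics for one condition."""

    condition: BeamCondition
    kind: str  # "separate" | "combined"
    rows: pd.DataFrame
    ann: ANNResults

    def _subset(self, subset: str) -> pd.DataFrame:
        return self.rows if subset == "all" else self.rows[self.rows.subset == subset]

    def mean_abs_pwd_before(self, subset: str = "all") -> float:
        return float(self._subset(subset).pwd_before.abs().mean())

    def mean_abs_pwd_after(self, subset: str = "all") -> float:
        return float(self._subset(subset).pwd_after.abs().mean())

    def sd_abs_pwd_after(self, subset: str = "all") -> float:
        return float(self._subset(subset).pwd_after.abs().std(ddof=1))

    def mean_abs_pwd_after_vs_true(self, subset: str = "all") -> float:
        return float(self._subset(subset).pwd_after_vs_true.abs().mean())

    def summary(self) -> str:
        lines = [
            f"Condition {self.condition.label} ({self.kind} network)",
            f"  geometries        {len(self.rows)} "
            f"({(self.rows.subset == 'train').sum()} train / "
            f"{(self.rows.subset == 'test').sum()} test)",
        ]
        for subset in ("train", "test", "all"):
            df = self._subset(subset)
            lines.append(
                f"  |PWD| {subset:5s}  before {df.pwd_before.abs().mean():5.2f} ± "
                f"{df.pwd_before.abs().std(ddof=1):4.2f} mm   after "
                f"{df.pwd_after.abs().mean():5.2f} ± "
                f"{df.pwd_after.abs().std(ddof=1):4.2f} mm"
            )
        return "\n".join(lines)


def _training_pairs(condition: BeamCondition, split: DatasetSplit):
    return [(condition.measured_of(e), e.reference) for e in split.train]


def _evaluate(condition: BeamCondition, ann: ANNResults, kind: str) -> EvaluationReport:
    split = make_split(condition.entries)
    train_keys = {(e.field_size_mm, e.depth_mm) for e in split.train}
    rows = []
    for e in condition.entries:
        measured = condition.measured_of(e)
        deconv = normalize_cax(ann.deconvolve(measured))
        rows.append(
            {
                "field_size_mm": e.field_size_mm,
                "depth_mm": e.depth_mm,
                "subset": "train"
                if (e.field_size_mm, e.depth_mm) in train_keys
                else "test",
                "pwd_before": pwd(measured, e.reference),
                "pwd_after": pwd(deconv, e.reference),
                "pwd_after_vs_true": pwd(deconv, e.true),
                "mse_before": mse(measured, e.reference),
                "mse_after": mse(deconv, e.reference),
            }
        )
    df = pd.DataFrame(rows).sort_values(["field_size_mm", "depth_mm"]).reset_index(drop=True)
    return EvaluationReport(condition=condition, kind=kind, rows=df, ann=ann)


def run_separate(
    condition: BeamCondition,
    restarts: int = 10,
    max_epochs: int = 400,
    seed: int = 0,
) -> EvaluationReport:
    """Train one network for a single beam condition and evaluate it.

    Windows are pooled from the condition's training geometries, split
    80/20 sample-wise into train/validation, and the lowest-validation-MSE
    restart is used to deconvolve every geometry of the condition.
    """
    split = make_split(condition.entries)
    model = SlidingWindowANN.from_profile_pairs(_training_pairs(condition, split))
    ann = model.fit(restarts=restarts, max_epochs=max_epochs, seed=seed)
    return _evaluate(condition, ann, kind="separate")


def run_combined(
    conditions,
    restarts: int = 10,
    max_epochs: int = 400,
    seed: int = 0,
) -> list:
    """Train one network on several pooled conditions; evaluate each.

    All conditions must share the same chamber — a combined network models
    one detector response across energies/modalities, not several chambers
    at once. No condition label enters the network input.
    """
    conditions = list(conditions)
    if len(conditions) < 2:
        raise ValueError("run_combined needs at least two conditions")
    detectors = {c.detector for c in conditions}
    if len(detectors) != 1:
        raise ValueError(
            f"combined training requires a single chamber, got {sorted(detectors)}"
        )
    pairs = []
    for c in conditions:
        pairs.extend(_training_pairs(c, make_split(c.entries)))
    model = SlidingWindowANN.from_profile_pairs(pairs)
    ann = model.fit(restarts=restarts, max_epochs=max_epochs, seed=seed)
    return [_evaluate(c, ann, kind="combined") for c in conditions]


def _fmt(mean, sd):
    return f"{mean:.2f} ± {sd:.2f}"


def report(reports, outdir, combined_reports=None) -> dict:
    """Write per-geometry PWD tables and a separate-vs-combined summary.

    One CSV per condition with the geometry-level PWD before/after, and a
    summary CSV of mean ± SD |PWD| per condition (chamber-measured,
    separate network, combined network; ``n/a`` where a condition was not
    run combined). Returns the written paths.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("report needs at least one evaluation")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for rep in reports:
        p = outdir / f"pwd_{rep.condition.label}.csv"
        rep.rows.to_csv(p, index=False)
        paths[rep.condition.label] = p

    combined_by_label = {
        r.condition.label: r for r in (combined_reports or [])
    }
    summary_rows = []
    for rep in reports:
        comb = combined_by_label.get(rep.condition.label)
        df = rep.rows
        summary_rows.append(
            {
                "condition": rep.condition.label,
                "detector": rep.condition.detector,
                "pwd_ic": _fmt(df.pwd_before.abs().mean(), df.pwd_before.abs().std(ddof=1)),
                "pwd_separate": _fmt(
                    df.pwd_after.abs().mean(), df.pwd_after.abs().std(ddof=1)
                ),
                "pwd_combined": _fmt(
                    comb.rows.pwd_after.abs().mean(),
                    comb.rows.pwd_after.abs().std(ddof=1),
                )
                if comb is not None
                else "n/a",
            }
        )
    summary = pd.DataFrame(summary_rows)
    spath = outdir / "summary.csv"
    summary.to_csv(spath, index=False)
    cols = list(summary.columns)
    md = [
        "| " + " | ".join(cols) + " |",
        "| " + " | ".join("---" for _ in cols) + " |",
    ]
    for _, row in summary.iterrows():
        md.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    (outdir / "summary.md").write_text("\n".join(md) + "\n")
    paths["summary"] = spath
    return paths
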