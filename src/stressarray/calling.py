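"""Fold-change response calling, p38-dependency classification, set
overlaps and timecourse dependency fractions.

Responsive genes are defined purely by linear fold-change thresholds on the
replicate-averaged gene-level log2 ratios (up: FC >= 2.5; down: FC <= 1/4 by
default; both inclusive). A responsive gene is p38-dependent when its
induction above baseline is reduced by at least 50% in the SB203580 arm or
in the p38a knockout; the reduction is evaluated on ``fc - 1`` by default
(``mode='induction'``), with ``mode='ratio'`` evaluating the raw
fold-change ratio instead. For down-regulated genes the rule is mirrored
through the reciprocal fold change. No statistical test is applied on fold
changes; thresholds are the calling rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .array_core import RatioMatrix
from .conditions import condition_label
from .errors import ClassificationError, DesignError, StressArrayError

#: absolute tolerance applied at every threshold boundary (inclusive rules)
BOUNDARY_EPS = 1e-9

DEFAULT_UP_FC = 2.5
DEFAULT_DOWN_FC = 4.0
DEFAULT_REDUCTION = 0.5


def _table(matrix: RatioMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.table if isinstance(matrix, RatioMatrix) else matrix


def _condition_column(table: pd.DataFrame, condition: str) -> pd.Series:
    if condition not in table.columns:
        raise DesignError(f"condition {condition!r} not present in the ratio matrix")
    return table[condition]


def call_up(matrix: RatioMatrix | pd.DataFrame, condition: str,
            up_threshold: float = DEFAULT_UP_FC) -> pd.DataFrame:
    """Genes with linear FC >= up_threshold (inclusive), sorted by gene_id."""
    if up_threshold <= 0:
        raise StressArrayError("up_threshold must be positive")
    col = _condition_column(_table(matrix), condition)
    thr = np.log2(up_threshold)
    hits = col[col >= thr - BOUNDARY_EPS].sort_index()
    return pd.DataFrame({
        "gene_id": hits.index,
        "condition": condition,
        "log2fc": hits.to_numpy(dtype=float),
        "status": "up",
    })


def call_down(matrix: RatioMatrix | pd.DataFrame, condition: str,
              down_threshold: float = DEFAULT_DOWN_FC) -> pd.DataFrame:
    """Genes with linear FC <= 1/down_threshold (inclusive)."""
    if down_threshold <= 0:
        raise StressArrayError("down_threshold must be positive")
    col = _condition_column(_table(matrix), condition)
    thr = -np.log2(down_threshold)
    hits = col[col <= thr + BOUNDARY_EPS].sort_index()
    return pd.DataFrame({
        "gene_id": hits.index,
        "condition": condition,
        "log2fc": hits.to_numpy(dtype=float),
        "status": "down",
    })


@dataclass(frozen=True)
class DependencyCall:
    """Per-gene dependency verdicts against the available perturbations.

    ``dependent_two`` is None ("not applicable") unless both perturbations
    were measured.
    """

    gene_id: str
    status: str
    fc_wt: float
    fc_sb: float | None = None
    fc_ko: float | None = None
    dependent_sb: bool | None = None
    dependent_ko: bool | None = None
    stimulus: str | None = None
    time_min: int | None = None

    @property
    def dependent_any(self) -> bool | None:
        flags = [f for f in (self.dependent_sb, self.dependent_ko) if f is not None]
        return any(flags) if flags else None

    @property
    def dependent_two(self) -> bool | None:
        if self.dependent_sb is None or self.dependent_ko is None:
            return None
        return self.dependent_sb and self.dependent_ko


def _reduced(fc_wt: float, fc_pert: float, reduction: float, mode: str,
             status: str) -> bool:
    if status == "down":
        # mirror through the reciprocal: repression depth attenuated
        fc_wt, fc_pert = 1.0 / fc_wt, 1.0 / fc_pert
    if mode == "induction":
        return (fc_pert - 1.0) <= (1.0 - reduction) * (fc_wt - 1.0) + BOUNDARY_EPS
    if mode == "ratio":
        return fc_pert <= (1.0 - reduction) * fc_wt + BOUNDARY_EPS
    raise ClassificationError(f"unknown dependency mode {mode!r}")


def classify_dependency(gene_id: str, fc_wt: float, fc_sb: float | None = None,
                        fc_ko: float | None = None, status: str = "up",
                        reduction: float = DEFAULT_REDUCTION, mode: str = "induction",
                        up_threshold: float = DEFAULT_UP_FC,
                        down_threshold: float = DEFAULT_DOWN_FC,
                        stimulus: str | None = None,
                        time_min: int | None = None) -> DependencyCall:
    """Apply the >=50%-reduction rule against the available perturbations."""
    if not (0.0 < reduction <= 1.0):
        raise ClassificationError("reduction must lie in (0, 1]")
    if status not in ("up", "down"):
        raise ClassificationError(f"status must be 'up' or 'down' (got {status!r})")
    if fc_sb is None and fc_ko is None:
        raise ClassificationError(f"gene {gene_id}: no perturbed measurement available")
    if status == "up" and fc_wt < up_threshold - BOUNDARY_EPS:
        raise ClassificationError(
            f"gene {gene_id}: wt fold change {fc_wt:.3g} below the up-calling threshold"
        )
    if status == "down" and fc_wt > 1.0 / down_threshold + BOUNDARY_EPS:
        raise ClassificationError(
            f"gene {gene_id}: wt fold change {fc_wt:.3g} above the down-calling threshold"
        )
    dep_sb = None if fc_sb is None else _reduced(fc_wt, fc_sb, reduction, mode, status)
    dep_ko = None if fc_ko is None else _reduced(fc_wt, fc_ko, reduction, mode, status)
    return DependencyCall(gene_id=gene_id, status=status, fc_wt=fc_wt,
                          fc_sb=fc_sb, fc_ko=fc_ko,
                          dependent_sb=dep_sb, dependent_ko=dep_ko,
                          stimulus=stimulus, time_min=time_min)


def dependency_calls(matrix: RatioMatrix | pd.DataFrame, stimulus: str, time_min: int,
                     direction: str = "up", up_threshold: float = DEFAULT_UP_FC,
                     down_threshold: float = DEFAULT_DOWN_FC,
                     reduction: float = DEFAULT_REDUCTION,
                     mode: str = "induction") -> list[DependencyCall]:
    """Dependency calls for every gene called responsive in the wt arm of a
    stress context, using whichever of the sb/ko arms the matrix contains.
    Genes whose perturbed values are all missing get all-None verdicts."""
    table = _table(matrix)
    wt = condition_label(stimulus, time_min, "wt")
    if wt not in table.columns:
        raise DesignError(f"wt condition {wt!r} not present in the ratio matrix")
    pert_cols = {arm: condition_label(stimulus, time_min, arm)
                 for arm in ("sb", "ko")
                 if condition_label(stimulus, time_min, arm) in table.columns}
    if not pert_cols:
        raise ClassificationError(
            f"no perturbed (sb/ko) condition for context ({stimulus}, {time_min})"
        )
    if direction == "up":
        called = call_up(table, wt, up_threshold)
    elif direction == "down":
        called = call_down(table, wt, down_threshold)
    else:
        raise ClassificationError(f"unknown direction {direction!r}")

    calls: list[DependencyCall] = []
    for gene, log2fc in zip(called["gene_id"], called["log2fc"]):
        fc_wt = float(2.0 ** log2fc)
        fcs: dict[str, float | None] = {}
        for arm, col in pert_cols.items():
            v = table.loc[gene, col]
            fcs[arm] = float(2.0 ** v) if pd.notna(v) else None
        if all(v is None for v in fcs.values()):
            calls.append(DependencyCall(gene_id=gene, status=direction, fc_wt=fc_wt,
                                        stimulus=stimulus, time_min=int(time_min)))
            continue
        calls.append(classify_dependency(
            gene, fc_wt, fc_sb=fcs.get("sb"), fc_ko=fcs.get("ko"), status=direction,
            reduction=reduction, mode=mode, up_threshold=up_threshold,
            down_threshold=down_threshold, stimulus=stimulus, time_min=int(time_min)))
    return calls


@dataclass(frozen=True)
class FractionResult:
    fraction: float
    n_dependent: int
    n_total: int
    n_missing: int = 0


def dependency_fraction(calls: Sequence[DependencyCall], mode: str = "any") -> FractionResult:
    """Dependent fraction over calls with a defined verdict for ``mode``
    (one of any/sb/ko/two); calls with a missing verdict are excluded and
    counted separately."""
    if not calls:
        raise ClassificationError("dependency fraction undefined for an empty call list")
    getter = {
        "any": lambda c: c.dependent_any,
        "sb": lambda c: c.dependent_sb,
        "ko": lambda c: c.dependent_ko,
        "two": lambda c: c.dependent_two,
    }.get(mode)
    if getter is None:
        raise ClassificationError(f"unknown dependency mode {mode!r}")
    flags = [getter(c) for c in calls]
    defined = [f for f in flags if f is not None]
    if not defined:
        raise ClassificationError(f"no call carries a defined {mode!r} verdict")
    n_dep = sum(defined)
    return FractionResult(fraction=n_dep / len(defined), n_dependent=int(n_dep),
                          n_total=len(defined), n_missing=len(flags) - len(defined))


@dataclass
class OverlapReport:
    """Full Venn partition of k named sets.

    ``members`` maps each non-empty label subset (as a tuple in label order)
    to the sorted genes belonging to exactly those sets; the regions are
    pairwise disjoint and their counts sum to the union size.
    """

    labels: tuple[str, ...]
    members: dict[tuple[str, ...], tuple[str, ...]]

    @property
    def counts(self) -> dict[tuple[str, ...], int]:
        return {region: len(m) for region, m in self.members.items()}

    @property
    def union_size(self) -> int:
        return sum(len(m) for m in self.members.values())

    def region(self, *labels: str) -> tuple[str, ...]:
        """Members of the exact region belonging to precisely these sets."""
        key = tuple(l for l in self.labels if l in labels)
        if len(key) != len(set(labels)):
            raise DesignError(f"unknown label(s) in {labels}")
        return self.members.get(key, ())

    def intersection(self, *labels: str) -> set[str]:
        """Members of every listed set (union of the covering regions)."""
        want = set(labels)
        out: set[str] = set()
        for region, m in self.members.items():
            if want <= set(region):
                out |= set(m)
        return out

    def validate(self) -> None:
        seen: set[str] = set()
        for region, m in self.members.items():
            if seen & set(m):
                raise StressArrayError("overlap regions are not disjoint")
            seen |= set(m)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "regions": {"&".join(r): sorted(m) for r, m in self.members.items()},
            "counts": {"&".join(r): len(m) for r, m in self.members.items()},
            "union_size": self.union_size,
        }


def overlap(sets: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]]
            ) -> OverlapReport:
    """Exact Venn partition (all 2^k - 1 regions) of k >= 2 named sets."""
    if isinstance(sets, Mapping):
        items = list(sets.items())
    else:
        items = list(sets)
        names = [n for n, _ in items]
        if len(names) != len(set(names)):
            raise DesignError("duplicate set names in overlap input")
    if len(items) < 2:
        raise DesignError("overlap needs at least two named sets")
    labels = tuple(n for n, _ in items)
    as_sets = {n: set(map(str, s)) for n, s in items}
    members: dict[tuple[str, ...], tuple[str, ...]] = {}
    for k in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, k):
            inside = set.intersection(*(as_sets[l] for l in combo))
            outside = set.union(set(), *(as_sets[l] for l in labels if l not in combo))
            members[combo] = tuple(sorted(inside - outside))
    report = OverlapReport(labels=labels, members=members)
    report.validate()
    return report


def common_core(up_sets: Mapping[str, Iterable[str]],
                dep_calls: Mapping[str, Mapping[str, DependencyCall]]) -> pd.DataFrame:
    """Genes up-regulated by every treatment, annotated with the
    two-perturbation dependency verdict per treatment.

    ``dep_calls`` maps treatment label -> gene -> DependencyCall. A core
    gene missing from a treatment's calls is flagged missing (None), never
    silently dropped.
    """
    if len(up_sets) < 3:
        raise DesignError("common core needs at least three treatment sets")
    sets = {k: set(map(str, v)) for k, v in up_sets.items()}
    core = sorted(set.intersection(*sets.values()))
    rows = []
    for gene in core:
        row: dict[str, object] = {"gene_id": gene}
        verdicts = []
        missing = False
        for treatment in up_sets:
            call = dep_calls.get(treatment, {}).get(gene)
            v = call.dependent_two if call is not None else None
            row[f"dependent_two_{treatment}"] = v
            if v is None:
                missing = True
            else:
                verdicts.append(v)
        row["dependent_two_any_treatment"] = any(verdicts) if verdicts else None
        row["missing_dependency_data"] = missing
        rows.append(row)
    cols = (["gene_id"] + [f"dependent_two_{t}" for t in up_sets]
            + ["dependent_two_any_treatment", "missing_dependency_data"])
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class TimecoursePoint:
    """Up-calls and SB-dependency at one timepoint, globally and restricted
    to a designated gene set (transcription-factor-activity surrogate)."""

    time_min: int
    n_up: int
    n_dependent: int
    dependency_fraction: float
    tf_n_up: int | None = None
    tf_n_dependent: int | None = None
    tf_dependency_fraction: float | None = None


def timecourse(matrix: RatioMatrix | pd.DataFrame, stimulus: str,
               timepoints: Sequence[int], tf_genes: Iterable[str] | None = None,
               up_threshold: float = DEFAULT_UP_FC,
               reduction: float = DEFAULT_REDUCTION,
               mode: str = "induction") -> tuple[list[TimecoursePoint], OverlapReport]:
    """Per-timepoint up-calls and SB-dependency fractions, plus the overlap
    partition of the up-sets across timepoints."""
    if len(timepoints) < 2:
        raise DesignError("timecourse needs at least two timepoints")
    table = _table(matrix)
    tf_set = set(map(str, tf_genes)) if tf_genes is not None else None

    points: list[TimecoursePoint] = []
    up_sets: dict[str, set[str]] = {}
    for t in timepoints:
        wt = condition_label(stimulus, t, "wt")
        sb = condition_label(stimulus, t, "sb")
        for col in (wt, sb):
            if col not in table.columns:
                raise DesignError(
                    f"timepoint {t} min: condition {col!r} missing from the ratio matrix"
                )
        calls = dependency_calls(table, stimulus, t, direction="up",
                                 up_threshold=up_threshold, reduction=reduction, mode=mode)
        up_sets[f"t{int(t)}"] = {c.gene_id for c in calls}
        if calls:
            frac = dependency_fraction(calls, mode="sb")
            n_up, n_dep, f = frac.n_total, frac.n_dependent, frac.fraction
        else:
            n_up, n_dep, f = 0, 0, float("nan")
        kwargs: dict = {}
        if tf_set is not None:
            tf_calls = [c for c in calls if c.gene_id in tf_set]
            kwargs["tf_n_up"] = len(tf_calls)
            if tf_calls:
                tf_frac = dependency_fraction(tf_calls, mode="sb")
                kwargs["tf_n_dependent"] = tf_frac.n_dependent
                kwargs["tf_dependency_fraction"] = tf_frac.fraction
            else:
                kwargs["tf_n_dependent"] = 0
                kwargs["tf_dependency_fraction"] = None
        points.append(TimecoursePoint(time_min=int(t), n_up=n_up, n_dependent=n_dep,
                                      dependency_fraction=f, **kwargs))
    return points, overlap(up_sets)


def calls_to_frame(calls: Sequence[DependencyCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "gene_id": c.gene_id,
            "stimulus": c.stimulus,
            "time_min": c.time_min,
            "status": c.status,
            "fc_wt": c.fc_wt,
            "fc_sb": c.fc_sb,
            "fc_ko": c.fc_ko,
            "dependent_sb": c.dependent_sb,
            "dependent_ko": c.dependent_ko,
            "dependent_any": c.dependent_any,
            "dependent_two": c.dependent_two,
        })
    return pd.DataFrame(rows, columns=["gene_id", "stimulus", "time_min", "status",
                                       "fc_wt", "fc_sb", "fc_ko", "dependent_sb",
                                       "dependent_ko", "dependent_any", "dependent_two"])
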