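"""Experimental design vocabulary for the reference-pool two-color layout.

Every hybridization compares one treated sample (Cy5, channel 2) against a
common pool of untreated wild-type cDNA (Cy3, channel 1), so a biological
condition is identified by (stimulus, time, arm) where *arm* is one of

``wt``  untreated genetics, no inhibitor (the stimulated wild type),
``sb``  wild type pre-treated with the p38 inhibitor SB203580,
``ko``  p38a knockout cells.

A design table maps each hybridization (``sample_id``) to its condition and
replicate index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import DesignError, ParseError

GENOTYPES = ("wt", "p38a_ko")
INHIBITORS = ("none", "SB203580")
ARMS = ("wt", "sb", "ko")

DESIGN_COLUMNS = ("sample_id", "genotype", "inhibitor", "stimulus", "time_min", "replicate")


@dataclass(frozen=True)
class ConditionDescriptor:
    """One hybridized sample: genotype/inhibitor/stimulus/time (+ replicate)."""

    genotype: str
    inhibitor: str
    stimulus: str
    time_min: int
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise DesignError(f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}")
        if self.inhibitor not in INHIBITORS:
            raise DesignError(f"unknown inhibitor {self.inhibitor!r}; expected one of {INHIBITORS}")
        if self.genotype == "p38a_ko" and self.inhibitor != "none":
            raise DesignError("knockout samples are never inhibitor-treated in this design")
        if self.time_min < 0:
            raise DesignError("time_min must be non-negative")
        if self.replicate is not None and self.replicate < 1:
            raise DesignError("replicate index starts at 1")

    @property
    def arm(self) -> str:
        if self.genotype == "p38a_ko":
            return "ko"
        if self.inhibitor != "none":
            return "sb"
        return "wt"

    @property
    def label(self) -> str:
        return condition_label(self.stimulus, self.time_min, self.arm)


def condition_label(stimulus: str, time_min: int, arm: str) -> str:
    """Canonical biological-condition label, replicates merged."""
    if arm not in ARMS:
        raise DesignError(f"unknown arm {arm!r}; expected one of {ARMS}")
    return f"{stimulus}_t{int(time_min)}_{arm}"


def descriptor_for_arm(stimulus: str, time_min: int, arm: str,
                       replicate: int | None = None) -> ConditionDescriptor:
    if arm == "ko":
        return ConditionDescriptor("p38a_ko", "none", stimulus, time_min, replicate)
    if arm == "sb":
        return ConditionDescriptor("wt", "SB203580", stimulus, time_min, replicate)
    if arm == "wt":
        return ConditionDescriptor("wt", "none", stimulus, time_min, replicate)
    raise DesignError(f"unknown arm {arm!r}")


def sample_id_for(stimulus: str, time_min: int, arm: str, replicate: int) -> str:
    return f"{condition_label(stimulus, time_min, arm)}_r{int(replicate)}"


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Type-check a design table and attach the derived ``label`` column."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ParseError(f"design table missing column(s): {', '.join(missing)}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"duplicate sample_id {dup!r} in design table")
    out = design.copy()
    out["time_min"] = out["time_min"].astype(int)
    out["replicate"] = out["replicate"].astype(int)
    labels = []
    for row in out.itertuples(index=False):
        desc = ConditionDescriptor(row.genotype, row.inhibitor, row.stimulus,
                                   row.time_min, row.replicate)
        labels.append(desc.label)
    out["label"] = labels
    return out


def read_design(source) -> pd.DataFrame:
    return validate_design(pd.read_csv(source, sep="\t", dtype={"sample_id": str}))


def write_design(design: pd.DataFrame, path) -> None:
    design.loc[:, list(DESIGN_COLUMNS)].to_csv(path, sep="\t", index=False)


def design_labels(design: pd.DataFrame) -> list[str]:
    """Biological-condition labels in first-appearance order."""
    seen: dict[str, None] = {}
    for lab in design["label"]:
        seen.setdefault(lab, None)
    return list(seen)


def contexts_in_design(design: pd.DataFrame) -> list[tuple[str, int]]:
    """Unique (stimulus, time_min) stress contexts in first-appearance order."""
    seen: dict[tuple[str, int], None] = {}
    for row in design.itertuples(index=False):
        seen.setdefault((row.stimulus, int(row.time_min)), None)
    return list(seen)


def arms_for_context(design: pd.DataFrame, stimulus: str, time_min: int) -> list[str]:
    sub = design[(design["stimulus"] == stimulus) & (design["time_min"] == int(time_min))]
    arms: dict[str, None] = {}
    for row in sub.itertuples(index=False):
        desc = ConditionDescriptor(row.genotype, row.inhibitor, row.stimulus,
                                   row.time_min, row.replicate)
        arms.setdefault(desc.arm, None)
    return list(arms)


def build_design(entries: Iterable[ConditionDescriptor]) -> pd.DataFrame:
    rows = []
    for desc in entries:
        if desc.replicate is None:
            raise DesignError("design entries need a replicate index")
        rows.append({
            "sample_id": sample_id_for(desc.stimulus, desc.time_min, desc.arm, desc.replicate),
            "genotype": desc.genotype,
            "inhibitor": desc.inhibitor,
            "stimulus": desc.stimulus,
            "time_min": desc.time_min,
            "replicate": desc.replicate,
        })
    return validate_design(pd.DataFrame(rows))
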