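"""Probe-level two-channel processing.

The chain mirrors standard two-color practice for a reference-pool design:

1. background subtraction per channel (negatives retained, not floored);
2. a generalized-log (glog) variance-stabilizing transform per sample and
   channel, ``glog2(x) = log2((x + sqrt(x^2 + c^2)) / 2)``, which is defined
   for non-positive intensities and converges to ``log2(x)`` for ``x >> c``;
3. per-probe log ratios ``M = ch2' - ch1'`` (treated minus reference) with
   ``A = (ch1' + ch2')/2`` kept for QC;
4. replicate QC via Pearson correlation of the stabilized channel signals;
5. arithmetic averaging of replicate M values per biological condition;
6. collapse of probes to unique gene-level values via a probe->gene map.

Replicate averaging happens before the probe collapse, and a full
maximum-likelihood variance-stabilization fit is deliberately not attempted:
the downstream statistics consume only log2 ratios, for which the glog with a
robust additive-noise scale estimate preserves the variance-stabilization
contract.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CorrelationError, DesignError, ParseError, ScaleEstimationError

PROBE_COLUMNS = ("probe_id", "sample_id", "ch1_fg", "ch1_bg", "ch2_fg", "ch2_bg")
INTENSITY_COLUMNS = ("ch1_fg", "ch1_bg", "ch2_fg", "ch2_bg")

#: default assumed multiplicative noise (log2 sd) used to convert the
#: estimated additive-noise scale into the glog parameter c.
DEFAULT_MULT_SD_LOG2 = 0.25


def validate_probe_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe table: columns, numeric non-negative finite
    intensities, unique (probe_id, sample_id) keys."""
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"probe table missing column(s): {', '.join(missing)}")
    out = df.loc[:, list(PROBE_COLUMNS)].copy()
    out["probe_id"] = out["probe_id"].astype(str)
    out["sample_id"] = out["sample_id"].astype(str)
    for col in INTENSITY_COLUMNS:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise ParseError(f"non-numeric or missing intensity in column {col!r}, row {bad[0]}")
        arr = vals.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            row = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise ParseError(f"non-finite intensity in column {col!r}, row {row}")
        if (arr < 0).any():
            row = int(np.flatnonzero(arr < 0)[0])
            raise ParseError(f"negative intensity in column {col!r}, row {row}")
        out[col] = arr
    dup = out.duplicated(subset=["probe_id", "sample_id"])
    if dup.any():
        row = out.loc[dup.idxmax()]
        raise ParseError(
            f"duplicate (probe_id, sample_id) key ({row['probe_id']!r}, {row['sample_id']!r})"
        )
    return out.reset_index(drop=True)


def read_probe_table(source) -> pd.DataFrame:
    """Read and validate a tab-separated probe table."""
    try:
        df = pd.read_csv(source, sep="\t", dtype={"probe_id": str, "sample_id": str})
    except (ValueError, pd.errors.ParserError) as exc:  # pragma: no cover - pandas detail
        raise ParseError(f"cannot parse probe table: {exc}") from exc
    return validate_probe_table(df)


def background_correct(probes: pd.DataFrame) -> pd.DataFrame:
    """Subtract per-channel background; negatives are retained (the glog
    transform handles them) and bg columns are zeroed."""
    out = probes.copy()
    out["ch1_fg"] = out["ch1_fg"] - out["ch1_bg"]
    out["ch2_fg"] = out["ch2_fg"] - out["ch2_bg"]
    out["ch1_bg"] = 0.0
    out["ch2_bg"] = 0.0
    return out


def glog2(x, c: float):
    """Generalized log2: ``log2((x + sqrt(x^2 + c^2)) / 2)``.

    Strictly monotone for c > 0; for c == 0 it degrades to plain log2 on
    positive values (non-positive values map to -inf).
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        return np.log2((x + np.sqrt(x * x + c * c)) / 2.0)


def estimate_glog_scale(values, mult_sd_log2: float = DEFAULT_MULT_SD_LOG2) -> float:
    """Estimate the glog parameter c for one channel of one sample.

    The additive-noise sd is taken as the root-mean-square of the
    non-positive background-corrected intensities (for a signal near zero,
    E[x^2 | x <= 0] equals the additive noise variance) and converted to the
    variance-balancing c = sigma_add / (ln2 * mult_sd_log2). With no
    non-positive values the additive component is judged negligible and c = 0.
    """
    if mult_sd_log2 <= 0:
        raise ScaleEstimationError("mult_sd_log2 must be positive")
    x = np.asarray(values, dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        raise ScaleEstimationError("cannot estimate glog scale from a constant channel")
    neg = x[x <= 0]
    if neg.size == 0:
        return 0.0
    sigma_add = math.sqrt(float(np.mean(neg * neg)))
    return sigma_add / (math.log(2.0) * mult_sd_log2)


def stabilize(probes: pd.DataFrame, mult_sd_log2: float = DEFAULT_MULT_SD_LOG2) -> pd.DataFrame:
    """Apply the glog transform per sample and channel.

    After this step the ``ch*_fg`` columns hold stabilized log2-scale values.
    """
    out = probes.copy()
    for _, idx in out.groupby("sample_id", sort=False).groups.items():
        for col in ("ch1_fg", "ch2_fg"):
            x = out.loc[idx, col].to_numpy(dtype=float)
            c = estimate_glog_scale(x, mult_sd_log2)
            out.loc[idx, col] = glog2(x, c)
    return out


def log_ratios(stabilized: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-probe, per-sample M = ch2' - ch1' and A = (ch1' + ch2')/2."""
    known = set(design["sample_id"])
    present = set(stabilized["sample_id"].unique())
    unknown = sorted(present - known)
    if unknown:
        raise DesignError(f"sample_id(s) absent from design: {', '.join(unknown[:5])}")
    out = stabilized.loc[:, ["probe_id", "sample_id"]].copy()
    out["M"] = stabilized["ch2_fg"] - stabilized["ch1_fg"]
    out["A"] = (stabilized["ch1_fg"] + stabilized["ch2_fg"]) / 2.0
    return out


def replicate_pcc(v1, v2) -> float:
    """Pearson correlation between two replicate probe vectors."""
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != b.shape:
        raise CorrelationError("replicate vectors differ in length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise CorrelationError("need at least 3 paired finite probe values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise CorrelationError("correlation undefined for a constant vector")
    return float(np.corrcoef(a, b)[0, 1])


def average_replicates(ratios: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Mean per-probe M over the replicates of each biological condition.

    Missing replicate values are skipped (mean of the remaining ones); a
    probe with no finite value in a condition stays missing.
    """
    if "label" not in design.columns:
        raise DesignError("design must carry a 'label' column (use validate_design)")
    merged = ratios.merge(design[["sample_id", "label"]], on="sample_id", how="left")
    wide = merged.pivot_table(index="probe_id", columns="label", values="M",
                              aggfunc="mean", dropna=False)
    # preserve the design's condition order
    from .conditions import design_labels

    cols = [c for c in design_labels(design) if c in wide.columns]
    return wide.loc[:, cols]


@dataclass
class RatioMatrix:
    """Gene x condition matrix of replicate-averaged log2 ratios.

    ``table`` is indexed by unique gene_id with one column per biological
    condition label; ``n_unmapped``/``n_ambiguous`` count dropped probes.
    """

    table: pd.DataFrame
    n_unmapped: int = 0
    n_ambiguous: int = 0


def validate_probe_gene_map(probe_gene_map: pd.DataFrame) -> pd.DataFrame:
    if probe_gene_map is None or len(probe_gene_map) == 0:
        raise DesignError("empty probe->gene map")
    for col in ("probe_id", "gene_id"):
        if col not in probe_gene_map.columns:
            raise ParseError(f"probe->gene map missing column {col!r}")
    out = probe_gene_map.loc[:, ["probe_id", "gene_id"]].copy()
    out["probe_id"] = out["probe_id"].astype(str)
    out["gene_id"] = out["gene_id"].astype(str)
    return out.drop_duplicates()


def collapse_to_genes(per_probe: pd.DataFrame, probe_gene_map: pd.DataFrame,
                      agg: str = "mean") -> RatioMatrix:
    """Collapse per-probe condition values to unique gene-level values.

    Probes absent from the map are dropped (counted); probes mapping to more
    than one gene are ambiguous and dropped from every gene (counted). The
    per-gene aggregate is ``mean`` by default (``median`` and ``max_abs``
    are available).
    """
    mapping = validate_probe_gene_map(probe_gene_map)
    counts = mapping.groupby("probe_id")["gene_id"].nunique()
    ambiguous = set(counts.index[counts > 1])
    clean = mapping[~mapping["probe_id"].isin(ambiguous)]
    probe_to_gene = clean.set_index("probe_id")["gene_id"]

    probes_present = per_probe.index.astype(str)
    n_ambiguous = int(probes_present.isin(ambiguous).sum())
    mapped_mask = probes_present.isin(probe_to_gene.index)
    n_unmapped = int((~mapped_mask).sum()) - n_ambiguous

    data = per_probe.loc[mapped_mask].copy()
    data.index = probe_to_gene.loc[data.index.astype(str)].to_numpy()
    data.index.name = "gene_id"
    grouped = data.groupby(level=0, sort=True)
    if agg == "mean":
        table = grouped.mean()
    elif agg == "median":
        table = grouped.median()
    elif agg == "max_abs":
        table = grouped.agg(lambda s: s.loc[s.abs().idxmax()] if s.notna().any() else np.nan)
    else:
        raise DesignError(f"unknown collapse aggregate {agg!r}")
    return RatioMatrix(table=table, n_unmapped=n_unmapped, n_ambiguous=n_ambiguous)


def write_ratio_matrix(matrix: RatioMatrix | pd.DataFrame, path) -> None:
    table = matrix.table if isinstance(matrix, RatioMatrix) else matrix
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_ratio_matrix(source) -> RatioMatrix:
    table = pd.read_csv(source, sep="\t", index_col="gene_id")
    return RatioMatrix(table=table)


@dataclass
class QCReport:
    """Numeric QC summaries (no graphics): per-sample MA/box/density
    summaries, per-condition replicate PCC, and threshold flags."""

    samples: dict = field(default_factory=dict)
    conditions: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    pcc_threshold: float = 0.9

    def to_dict(self) -> dict:
        return {
            "pcc_threshold": self.pcc_threshold,
            "samples": self.samples,
            "conditions": self.conditions,
            "flags": list(self.flags),
        }


def qc_report(ratios: pd.DataFrame, stabilized: pd.DataFrame, design: pd.DataFrame,
              pcc_threshold: float = 0.9, n_bins: int = 20) -> QCReport:
    """Numeric replicate/array QC.

    Per sample: median M, M-vs-A trend slope, intensity quartiles and an M
    histogram. Per condition: Pearson correlation between replicate pairs of
    the stabilized channel signals (treated Cy5 and reference Cy3), flagged
    when below ``pcc_threshold``.
    """
    report = QCReport(pcc_threshold=pcc_threshold)
    ch2 = stabilized.pivot_table(index="probe_id", columns="sample_id", values="ch2_fg")
    ch1 = stabilized.pivot_table(index="probe_id", columns="sample_id", values="ch1_fg")

    for sample, sub in ratios.groupby("sample_id", sort=False):
        m = sub["M"].to_numpy(dtype=float)
        a = sub["A"].to_numpy(dtype=float)
        keep = np.isfinite(m) & np.isfinite(a)
        m, a = m[keep], a[keep]
        slope = float(np.polyfit(a, m, 1)[0]) if np.ptp(a) > 0 else 0.0
        counts, edges = np.histogram(m, bins=n_bins)
        report.samples[sample] = {
            "median_M": float(np.median(m)),
            "ma_trend_slope": slope,
            "A_quartiles": [float(q) for q in np.percentile(a, [0, 25, 50, 75, 100])],
            "M_histogram": {
                "counts": [int(c) for c in counts],
                "edges": [float(e) for e in edges],
            },
        }

    for label, sub in design.groupby("label", sort=False):
        samples = list(sub.sort_values("replicate")["sample_id"])
        pccs = {}
        for s1, s2 in itertools.combinations(samples, 2):
            if s1 in ch2.columns and s2 in ch2.columns:
                pccs[f"{s1}|{s2}"] = {
                    "treated_channel": replicate_pcc(ch2[s1], ch2[s2]),
                    "reference_channel": replicate_pcc(ch1[s1], ch1[s2]),
                }
        entry = {"samples": samples, "replicate_pcc": pccs}
        if pccs:
            worst = min(v["treated_channel"] for v in pccs.values())
            entry["min_treated_pcc"] = worst
            if worst < pcc_threshold:
                report.flags.append(
                    f"condition {label}: replicate PCC {worst:.3f} below {pcc_threshold}"
                )
        report.conditions[label] = entry
    return report
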