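"""Synthetic two-color experiments with known ground truth.

The generator emulates the structure of the reference-pool MEF stress study:
a 44K-style array of 41,175 probes covering 19,261 unique genes (every gene
by at least two probes on average), two replicate hybridizations per
biological condition, per-context planted fractions of up/down-responsive
genes, per-gene p38-dependency flags with attenuated induction in the
inhibitor (SB203580) and knockout arms, a designated common core of genes
up-regulated by every stimulus, and a GO annotation with one category
planted enriched among the responsive genes.

Intensities follow baseline * 2^eps multiplicative noise (eps ~ N(0, sd) in
log2 units, per measurement) plus a constant additive background that is
recorded in the bg columns, so the downstream pipeline at zero noise
recovers every planted fold change exactly. All randomness flows through
seeded ``numpy.random.Generator`` streams derived from the config seed; no
global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import conditions as cond
from .enrichment import GOAnnotation
from .errors import ConfigurationError

#: array geometry of the emulated platform
DEFAULT_N_GENES = 19_261
DEFAULT_N_PROBES = 41_175


@dataclass(frozen=True)
class StressContext:
    """One stress context (stimulus at a time point) with its planted effect
    structure: responsive fractions, dependency probabilities and the arms
    that were hybridized."""

    stimulus: str
    time_min: int
    frac_up: float
    frac_down: float = 0.0
    dep_fraction: float = 0.8
    dep_fraction_down: float | None = None
    arms: tuple[str, ...] = ("wt", "sb", "ko")

    def __post_init__(self) -> None:
        for name in ("frac_up", "frac_down", "dep_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1] (got {v})")
        if self.dep_fraction_down is not None and not (0.0 <= self.dep_fraction_down <= 1.0):
            raise ConfigurationError("dep_fraction_down must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1.0:
            raise ConfigurationError("frac_up + frac_down must not exceed 1")
        if "wt" not in self.arms:
            raise ConfigurationError("every context needs a wt arm")
        for arm in self.arms:
            if arm not in cond.ARMS:
                raise ConfigurationError(f"unknown arm {arm!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.stimulus, int(self.time_min))

    @property
    def effective_dep_fraction_down(self) -> float:
        return self.dep_fraction if self.dep_fraction_down is None else self.dep_fraction_down


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a simulated study.

    Fold-change laws are uniform on the stated log2 ranges; attenuation laws
    are uniform residual-induction fractions whose supports sit strictly on
    either side of the 50%-reduction boundary, so the dependency rule is
    decidable at zero noise.
    """

    contexts: tuple[StressContext, ...]
    seed: int
    n_genes: int = DEFAULT_N_GENES
    n_probes: int = DEFAULT_N_PROBES
    n_replicates: int = 2
    fc_up_log2_range: tuple[float, float] = (1.5, 4.0)
    fc_down_log2_range: tuple[float, float] = (-4.2, -2.2)
    dep_attenuation_range: tuple[float, float] = (0.0, 0.4)
    indep_attenuation_range: tuple[float, float] = (0.6, 1.1)
    channel_noise_sd: float = 0.25
    background_mean: float = 40.0
    baseline_log2_mean: float = math.log2(1000.0)
    baseline_log2_sd: float = 1.5
    core_size: int = 0
    # GO annotation
    n_go_terms: int = 50
    go_term_size_range: tuple[int, int] = (20, 200)
    enriched_term: str = "GO:PLANTED"
    enriched_term_size: int = 60
    enrichment_factor: float = 5.0
    tf_term: str = "GO:TF_ACTIVITY"
    tf_term_size: int = 300
    tf_enrichment_factor: float = 5.0
    undersized_term_size: int | None = None

    # calling thresholds used only to validate that the planted laws are
    # decidable at zero noise
    up_threshold: float = 2.5
    down_threshold: float = 4.0

    def __post_init__(self) -> None:
        if not self.contexts:
            raise ConfigurationError("at least one stress context is required")
        keys = [c.key for c in self.contexts]
        if len(set(keys)) != len(keys):
            raise ConfigurationError("duplicate (stimulus, time) context")
        if self.n_genes < 1 or self.n_probes < self.n_genes:
            raise ConfigurationError("need n_probes >= n_genes >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("need at least one replicate")
        if self.channel_noise_sd < 0:
            raise ConfigurationError("channel_noise_sd must be non-negative")
        if self.background_mean < 0:
            raise ConfigurationError("background_mean must be non-negative")
        lo, hi = self.fc_up_log2_range
        if not (lo < hi) or 2.0 ** lo < self.up_threshold:
            raise ConfigurationError(
                "fc_up_log2_range support must lie strictly above the up-calling threshold"
            )
        lo, hi = self.fc_down_log2_range
        if not (lo < hi) or 2.0 ** hi > 1.0 / self.down_threshold:
            raise ConfigurationError(
                "fc_down_log2_range support must lie at or below 1/down_threshold"
            )
        lo, hi = self.dep_attenuation_range
        if not (0.0 <= lo <= hi < 0.5):
            raise ConfigurationError("dep_attenuation_range support must lie in [0, 0.5)")
        lo, hi = self.indep_attenuation_range
        if not (0.5 < lo <= hi <= 1.2):
            raise ConfigurationError("indep_attenuation_range support must lie in (0.5, 1.2]")
        if self.core_size < 0:
            raise ConfigurationError("core_size must be non-negative")
        for ctx in self.contexts:
            if self.core_size and round(ctx.frac_up * self.n_genes) < self.core_size:
                raise ConfigurationError(
                    f"context {ctx.key}: planted up count below core_size"
                )
        if self.enriched_term_size > self.n_genes or self.tf_term_size > self.n_genes:
            raise ConfigurationError("requested GO category larger than the gene universe")
        if self.enrichment_factor <= 0 or self.tf_enrichment_factor <= 0:
            raise ConfigurationError("enrichment factors must be positive")


def gene_ids(n_genes: int) -> np.ndarray:
    return np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)


def probe_ids(n_probes: int) -> np.ndarray:
    return np.array([f"P{i:06d}" for i in range(n_probes)], dtype=object)


@dataclass
class TruthTable:
    """Planted ground truth, one row per (gene, stress context)."""

    table: pd.DataFrame

    def context(self, stimulus: str, time_min: int) -> pd.DataFrame:
        sub = self.table[(self.table["stimulus"] == stimulus)
                         & (self.table["time_min"] == int(time_min))]
        if sub.empty:
            raise ConfigurationError(f"no planted context ({stimulus}, {time_min})")
        return sub

    def genes_with_status(self, stimulus: str, time_min: int, status: str) -> set[str]:
        sub = self.context(stimulus, time_min)
        return set(sub.loc[sub["status"] == status, "gene_id"])

    def dependent_flags(self, stimulus: str, time_min: int,
                        status: str = "up") -> pd.Series:
        """Boolean dependency flags indexed by gene, responsive genes only."""
        sub = self.context(stimulus, time_min)
        sub = sub[sub["status"] == status]
        return sub.set_index("gene_id")["dependent"].astype(bool)

    def expected_log2fc(self, stimulus: str, time_min: int, arm: str) -> pd.Series:
        """Planted gene-level log2 fold change for one arm of a context."""
        sub = self.context(stimulus, time_min).set_index("gene_id")
        fc = sub["true_fc"].to_numpy(dtype=float)
        if arm != "wt":
            fc = perturbed_fold_change(fc, sub["status"].to_numpy(),
                                       sub["attenuation"].to_numpy(dtype=float))
        return pd.Series(np.log2(fc), index=sub.index)


def perturbed_fold_change(true_fc, status, attenuation) -> np.ndarray:
    """Linear fold change in a perturbed (inhibitor or knockout) arm.

    Up genes keep a residual fraction ``a`` of their induction above
    baseline: fc' = 1 + a (fc - 1). Down genes are mirrored through the
    reciprocal: 1/fc' = 1 + a (1/fc - 1), so repression depth is attenuated
    symmetrically.
    """
    fc = np.asarray(true_fc, dtype=float)
    a = np.asarray(attenuation, dtype=float)
    status = np.asarray(status)
    out = np.ones_like(fc)
    up = status == "up"
    down = status == "down"
    out[up] = 1.0 + a[up] * (fc[up] - 1.0)
    out[down] = 1.0 / (1.0 + a[down] * (1.0 / fc[down] - 1.0))
    return out


def generate_truth(config: SyntheticConfig) -> TruthTable:
    """Plant the responsive/dependency structure.

    The designated core genes are up-regulated in every context; additional
    up genes are drawn per context, with membership capped at two non-core
    contexts per gene so that the all-context intersection equals the core
    exactly. Dependency is Bernoulli(dep_fraction) per responsive gene, with
    attenuation drawn from the dependent or independent law accordingly.
    """
    rng = np.random.default_rng([config.seed, 0])
    genes = gene_ids(config.n_genes)
    n = config.n_genes

    core_idx = np.array([], dtype=int)
    if config.core_size:
        core_idx = np.sort(rng.choice(n, size=config.core_size, replace=False))
    core_mask = np.zeros(n, dtype=bool)
    core_mask[core_idx] = True
    up_count = np.zeros(n, dtype=int)

    frames = []
    for ctx in config.contexts:
        n_up = round(ctx.frac_up * n)
        n_down = round(ctx.frac_down * n)
        n_extra = n_up - len(core_idx)
        eligible = np.flatnonzero((up_count < 2) & ~core_mask)
        if n_extra > len(eligible):
            raise ConfigurationError(
                f"context {ctx.key}: not enough genes left to plant {n_extra} up genes"
            )
        extra = rng.choice(eligible, size=n_extra, replace=False) if n_extra else np.array([], dtype=int)
        up_idx = np.concatenate([core_idx, extra]).astype(int)
        up_count[extra] += 1

        up_mask = np.zeros(n, dtype=bool)
        up_mask[up_idx] = True
        down_pool = np.flatnonzero(~up_mask & ~core_mask)
        down_idx = (rng.choice(down_pool, size=n_down, replace=False)
                    if n_down else np.array([], dtype=int))

        status = np.full(n, "none", dtype=object)
        status[up_idx] = "up"
        status[down_idx] = "down"

        true_fc = np.ones(n)
        true_fc[up_idx] = 2.0 ** rng.uniform(*config.fc_up_log2_range, size=len(up_idx))
        true_fc[down_idx] = 2.0 ** rng.uniform(*config.fc_down_log2_range, size=len(down_idx))

        dependent = np.zeros(n, dtype=bool)
        dependent[up_idx] = rng.random(len(up_idx)) < ctx.dep_fraction
        dependent[down_idx] = rng.random(len(down_idx)) < ctx.effective_dep_fraction_down

        attenuation = np.ones(n)
        responsive = np.concatenate([up_idx, down_idx]).astype(int)
        dep_r = responsive[dependent[responsive]]
        ind_r = responsive[~dependent[responsive]]
        attenuation[dep_r] = rng.uniform(*config.dep_attenuation_range, size=len(dep_r))
        attenuation[ind_r] = rng.uniform(*config.indep_attenuation_range, size=len(ind_r))

        frames.append(pd.DataFrame({
            "gene_id": genes,
            "stimulus": ctx.stimulus,
            "time_min": int(ctx.time_min),
            "status": status,
            "true_fc": true_fc,
            "dependent": dependent,
            "attenuation": attenuation,
        }))
    return TruthTable(table=pd.concat(frames, ignore_index=True))


def build_probe_gene_map(config: SyntheticConfig) -> pd.DataFrame:
    """Deterministic probe->gene assignment: every gene gets
    ``n_probes // n_genes`` probes, the first ``n_probes % n_genes`` genes
    one more, in gene-index order (41,175 probes over 19,261 genes gives 2
    or 3 probes per gene)."""
    base = config.n_probes // config.n_genes
    rem = config.n_probes - base * config.n_genes
    per_gene = np.full(config.n_genes, base, dtype=int)
    per_gene[:rem] += 1
    gene_of_probe = np.repeat(np.arange(config.n_genes), per_gene)
    return pd.DataFrame({
        "probe_id": probe_ids(config.n_probes),
        "gene_id": gene_ids(config.n_genes)[gene_of_probe],
    })


def build_design(config: SyntheticConfig) -> pd.DataFrame:
    entries = []
    for ctx in config.contexts:
        for arm in ctx.arms:
            for rep in range(1, config.n_replicates + 1):
                entries.append(cond.descriptor_for_arm(ctx.stimulus, ctx.time_min, arm, rep))
    return cond.build_design(entries)


@dataclass
class SyntheticExperiment:
    """Probe table plus the bookkeeping emitted alongside it."""

    probes: pd.DataFrame
    probe_gene_map: pd.DataFrame
    design: pd.DataFrame
    truth: TruthTable


def generate_probe_table(truth: TruthTable, config: SyntheticConfig) -> SyntheticExperiment:
    """Simulate every hybridization of the design.

    Reference channel: baseline * 2^eps + background. Treated channel:
    baseline * fc_arm * 2^eps + background, where fc_arm applies the planted
    attenuation in the sb/ko arms. Per-probe baselines are drawn once and
    shared across hybridizations (probe affinity), so zero-noise replicates
    are identical.
    """
    rng = np.random.default_rng([config.seed, 1])
    pmap = build_probe_gene_map(config)
    design = build_design(config)
    gene_index = pd.Series(np.arange(config.n_genes), index=gene_ids(config.n_genes))
    probe_gene_idx = gene_index.loc[pmap["gene_id"]].to_numpy()

    baseline = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                                 size=config.n_probes)

    # per (context, arm) gene-level linear fold change
    fc_by_label: dict[str, np.ndarray] = {}
    for ctx in config.contexts:
        sub = truth.context(ctx.stimulus, ctx.time_min).set_index("gene_id")
        sub = sub.loc[gene_ids(config.n_genes)]
        wt_fc = sub["true_fc"].to_numpy(dtype=float)
        pert_fc = perturbed_fold_change(wt_fc, sub["status"].to_numpy(),
                                        sub["attenuation"].to_numpy(dtype=float))
        for arm in ctx.arms:
            label = cond.condition_label(ctx.stimulus, ctx.time_min, arm)
            fc_by_label[label] = wt_fc if arm == "wt" else pert_fc

    pid = pmap["probe_id"].to_numpy()
    frames = []
    for row in design.itertuples(index=False):
        fc_probe = fc_by_label[row.label][probe_gene_idx]
        eps1 = rng.normal(0.0, config.channel_noise_sd, size=config.n_probes)
        eps2 = rng.normal(0.0, config.channel_noise_sd, size=config.n_probes)
        ch1 = baseline * 2.0 ** eps1 + config.background_mean
        ch2 = baseline * fc_probe * 2.0 ** eps2 + config.background_mean
        frames.append(pd.DataFrame({
            "probe_id": pid,
            "sample_id": row.sample_id,
            "ch1_fg": ch1,
            "ch1_bg": config.background_mean,
            "ch2_fg": ch2,
            "ch2_bg": config.background_mean,
        }))
    probes = pd.concat(frames, ignore_index=True)
    return SyntheticExperiment(probes=probes, probe_gene_map=pmap,
                               design=design, truth=truth)


def _weighted_members(rng: np.random.Generator, universe: np.ndarray,
                      favored_mask: np.ndarray, size: int, factor: float) -> np.ndarray:
    """Sample ``size`` members without replacement so the favored subset is
    over-represented ``factor``-fold in expectation."""
    n_total = len(universe)
    n_fav = int(favored_mask.sum())
    if factor * n_fav >= n_total:
        raise ConfigurationError(
            "enrichment factor too large for the favored-set size"
        )
    w = factor * (n_total - n_fav) / (n_total - factor * n_fav)
    weights = np.where(favored_mask, w, 1.0).astype(float)
    weights /= weights.sum()
    return rng.choice(universe, size=size, replace=False, p=weights)


def generate_go_annotation(truth: TruthTable, config: SyntheticConfig) -> GOAnnotation:
    """Random flat GO annotation with one planted enriched category.

    Background terms draw members uniformly; the planted term (and the
    transcription-factor-activity surrogate used by the timecourse analysis)
    over-sample the responsive genes by the configured factor. With
    ``enrichment_factor = 1`` the planted term is indistinguishable from
    background. An optional undersized term exercises the size filter.
    """
    rng = np.random.default_rng([config.seed, 2])
    genes = gene_ids(config.n_genes)
    responsive = set()
    for ctx in config.contexts:
        responsive |= truth.genes_with_status(ctx.stimulus, ctx.time_min, "up")
    resp_mask = np.isin(genes, sorted(responsive))

    ann = GOAnnotation()
    onts = ["CC", "MF", "BP"]
    for i in range(config.n_go_terms):
        lo, hi = config.go_term_size_range
        size = int(rng.integers(lo, hi + 1))
        term = f"GO:{i:04d}"
        ann.terms[term] = frozenset(rng.choice(genes, size=size, replace=False))
        ann.ontology[term] = onts[i % 3]
        ann.names[term] = f"synthetic category {i}"

    ann.terms[config.enriched_term] = frozenset(_weighted_members(
        rng, genes, resp_mask, config.enriched_term_size, config.enrichment_factor))
    ann.ontology[config.enriched_term] = "MF"
    ann.names[config.enriched_term] = "planted enriched category"

    ann.terms[config.tf_term] = frozenset(_weighted_members(
        rng, genes, resp_mask, config.tf_term_size, config.tf_enrichment_factor))
    ann.ontology[config.tf_term] = "MF"
    ann.names[config.tf_term] = "transcription factor activity (surrogate)"

    if config.undersized_term_size is not None:
        if config.undersized_term_size > config.n_genes:
            raise ConfigurationError("undersized term larger than the gene universe")
        ann.terms["GO:SMALL"] = frozenset(
            rng.choice(genes, size=config.undersized_term_size, replace=False))
        ann.ontology["GO:SMALL"] = "MF"
        ann.names["GO:SMALL"] = "deliberately undersized category"
    return ann


def write_truth(truth: TruthTable, path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def read_truth(source) -> TruthTable:
    return TruthTable(table=pd.read_csv(source, sep="\t"))


def write_probe_table(probes: pd.DataFrame, path) -> None:
    probes.to_csv(path, sep="\t", index=False)


def write_probe_gene_map(pmap: pd.DataFrame, path) -> None:
    pmap.to_csv(path, sep="\t", index=False)


def read_probe_gene_map(source) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t", dtype=str)


# --- study-condition presets -------------------------------------------------

def treatment_contexts() -> tuple[StressContext, ...]:
    """The three-stimulus endpoint comparison: planted up/down counts match
    the study scale (144/146/178 up, 29/36/22 down) and the dependency
    fractions span the reported 60-88% range (down-gene dependency 1.0 for
    TNFa/anisomycin, 0.70 for NaCl)."""
    n = DEFAULT_N_GENES
    return (
        StressContext("TNFa", 45, frac_up=144 / n, frac_down=29 / n,
                      dep_fraction=0.60, dep_fraction_down=1.0),
        StressContext("anisomycin", 45, frac_up=146 / n, frac_down=36 / n,
                      dep_fraction=0.74, dep_fraction_down=1.0),
        StressContext("NaCl", 120, frac_up=178 / n, frac_down=22 / n,
                      dep_fraction=0.88, dep_fraction_down=0.70),
    )


def timecourse_contexts() -> tuple[StressContext, ...]:
    """The osmostress timecourse: 114/178/321 planted up genes at
    45 min/2 h/8 h with dependency 0.90/0.74/0.62, wt and SB arms only."""
    n = DEFAULT_N_GENES
    return (
        StressContext("NaCl", 45, frac_up=114 / n, dep_fraction=0.90, arms=("wt", "sb")),
        StressContext("NaCl", 120, frac_up=178 / n, dep_fraction=0.74, arms=("wt", "sb")),
        StressContext("NaCl", 480, frac_up=321 / n, dep_fraction=0.62, arms=("wt", "sb")),
    )


def treatment_config(seed: int, **overrides) -> SyntheticConfig:
    cfg = SyntheticConfig(contexts=treatment_contexts(), seed=seed, core_size=30)
    return replace(cfg, **overrides) if overrides else cfg


def timecourse_config(seed: int, **overrides) -> SyntheticConfig:
    cfg = SyntheticConfig(contexts=timecourse_contexts(), seed=seed, core_size=0)
    return replace(cfg, **overrides) if overrides else cfg
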