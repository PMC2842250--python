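"""End-to-end orchestration: simulate/read -> correct -> stabilize ->
ratios -> QC -> average -> collapse -> call -> classify -> overlap -> core
-> timecourse -> enrich -> report.

``process_experiment`` and ``run_synthetic`` are the library entry points
used by tests and scripts; ``run`` drives a whole configured analysis and
writes TSV/JSON artifacts plus a machine-readable, invariant-checked run
report. Scientific parameters come only from the config (environment
variables are never consulted) and all randomness flows from the config
seed, so a run is idempotent.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from . import array_core as ac
from . import calling as rc
from . import conditions as cond
from . import enrichment as en
from . import synthetic as syn
from .errors import ConfigurationError, ReportInvariantError

log = logging.getLogger(__name__)


@dataclass
class ProcessedRun:
    matrix: ac.RatioMatrix
    qc: ac.QCReport
    design: pd.DataFrame
    n_probe_rows: int


def process_experiment(probes: pd.DataFrame, probe_gene_map: pd.DataFrame,
                       design: pd.DataFrame, pcc_threshold: float = 0.9,
                       mult_sd_log2: float = ac.DEFAULT_MULT_SD_LOG2,
                       collapse_agg: str = "mean") -> ProcessedRun:
    """Probe table -> gene x condition log2-ratio matrix (+ QC report)."""
    probes = ac.validate_probe_table(probes)
    design = cond.validate_design(design)
    corrected = ac.background_correct(probes)
    stabilized = ac.stabilize(corrected, mult_sd_log2=mult_sd_log2)
    ratios = ac.log_ratios(stabilized, design)
    qc = ac.qc_report(ratios, stabilized, design, pcc_threshold=pcc_threshold)
    averaged = ac.average_replicates(ratios, design)
    matrix = ac.collapse_to_genes(averaged, probe_gene_map, agg=collapse_agg)
    if matrix.n_unmapped or matrix.n_ambiguous:
        log.info("collapse dropped %d unmapped and %d ambiguous probes",
                 matrix.n_unmapped, matrix.n_ambiguous)
    return ProcessedRun(matrix=matrix, qc=qc, design=design, n_probe_rows=len(probes))


@dataclass
class SyntheticRun:
    config: syn.SyntheticConfig
    truth: syn.TruthTable
    experiment: syn.SyntheticExperiment
    annotation: en.GOAnnotation
    processed: ProcessedRun

    @property
    def matrix(self) -> ac.RatioMatrix:
        return self.processed.matrix


def run_synthetic(config: syn.SyntheticConfig, pcc_threshold: float = 0.9,
                  with_annotation: bool = True) -> SyntheticRun:
    """Generate a synthetic study and push it through the full array chain."""
    truth = syn.generate_truth(config)
    experiment = syn.generate_probe_table(truth, config)
    annotation = (syn.generate_go_annotation(truth, config)
                  if with_annotation else en.GOAnnotation())
    processed = process_experiment(experiment.probes, experiment.probe_gene_map,
                                   experiment.design, pcc_threshold=pcc_threshold)
    return SyntheticRun(config=config, truth=truth, experiment=experiment,
                        annotation=annotation, processed=processed)


# --- run configuration -------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full pipeline run (TOML-loadable).

    Either ``simulate`` holds a SyntheticConfig, or the probe/map/design
    paths must all be set. Thresholds default to the study's rules: 2.5-fold
    up, 4-fold down, 50% reduction, 2-fold for cellular-component
    enrichment, categories >= 20 genes, alpha 0.05 nominal and FDR.
    """

    out_dir: str
    seed: int = 0
    simulate: syn.SyntheticConfig | None = None
    probes_path: str | None = None
    map_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    annotation_format: str = "tsv"
    up_fc: float = 2.5
    down_fc: float = 4.0
    cc_fc: float = 2.0
    reduction: float = 0.5
    min_category_size: int = 20
    nominal_alpha: float = 0.05
    fdr_alpha: float = 0.05
    pcc_flag: float = 0.9
    dependency_mode: str = "induction"
    enrichment_tail: str = "upper"
    enrichment_universe: str = "annotated"  # or "array"
    enrichment_strata: str = "ontology"
    run_enrichment: bool = True
    tf_term: str = "GO:TF_ACTIVITY"
    collapse_agg: str = "mean"

    def __post_init__(self) -> None:
        for name in ("up_fc", "down_fc", "cc_fc"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0.0 < self.reduction <= 1.0):
            raise ConfigurationError("reduction must lie in (0, 1]")
        if self.min_category_size < 0:
            raise ConfigurationError("min_category_size must be non-negative")
        if self.enrichment_universe not in ("annotated", "array"):
            raise ConfigurationError("enrichment_universe must be 'annotated' or 'array'")
        if self.simulate is None:
            missing = [n for n in ("probes_path", "map_path", "design_path")
                       if getattr(self, n) is None]
            if missing:
                raise ConfigurationError(
                    f"without [synthetic], these paths are required: {', '.join(missing)}"
                )
            if self.run_enrichment and self.annotation_path is None:
                raise ConfigurationError(
                    "enrichment enabled but no annotation path configured"
                )


def _contexts_from_toml(items: list[dict]) -> tuple[syn.StressContext, ...]:
    ctxs = []
    for item in items:
        ctxs.append(syn.StressContext(
            stimulus=item["stimulus"],
            time_min=int(item["time_min"]),
            frac_up=float(item.get("frac_up", 0.0)),
            frac_down=float(item.get("frac_down", 0.0)),
            dep_fraction=float(item.get("dep_fraction", 0.8)),
            dep_fraction_down=(float(item["dep_fraction_down"])
                               if "dep_fraction_down" in item else None),
            arms=tuple(item.get("arms", ["wt", "sb", "ko"])),
        ))
    return tuple(ctxs)


def load_run_config(path) -> RunConfig:
    """Parse a TOML run configuration.

    Top-level keys map onto RunConfig fields; an optional ``[synthetic]``
    table (with a ``[[synthetic.contexts]]`` array) configures simulation.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    synth = None
    if "synthetic" in raw:
        s = dict(raw.pop("synthetic"))
        preset = s.pop("preset", None)
        seed = int(s.pop("seed", raw.get("seed", 0)))
        if preset == "treatment":
            synth = syn.treatment_config(seed, **_synth_overrides(s))
        elif preset == "timecourse":
            synth = syn.timecourse_config(seed, **_synth_overrides(s))
        elif preset is None:
            ctxs = _contexts_from_toml(s.pop("contexts", []))
            synth = syn.SyntheticConfig(contexts=ctxs, seed=seed, **_synth_overrides(s))
        else:
            raise ConfigurationError(f"unknown synthetic preset {preset!r}")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(simulate=synth, **raw)


def _synth_overrides(s: dict) -> dict:
    out = dict(s)
    for key in ("fc_up_log2_range", "fc_down_log2_range", "dep_attenuation_range",
                "indep_attenuation_range", "go_term_size_range"):
        if key in out:
            out[key] = tuple(out[key])
    out.pop("contexts", None)
    return out


# --- run + report ------------------------------------------------------------

def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(payload: dict, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def validate_report(report: dict) -> None:
    """Internal-consistency trap; raises ReportInvariantError on violation."""
    for ov in report.get("overlaps", {}).values():
        if sum(ov["counts"].values()) != ov["union_size"]:
            raise ReportInvariantError("Venn region counts do not sum to the union size")
    for ctx in report.get("contexts", {}).values():
        for key in ("n_up", "n_down"):
            if ctx.get(key, 0) < 0:
                raise ReportInvariantError(f"negative count for {key}")
        for dep in ctx.get("dependency", {}).values():
            f = dep["fraction"]
            if not (0.0 <= f <= 1.0):
                raise ReportInvariantError("dependency fraction outside [0, 1]")
            if dep["n_dependent"] > dep["n_total"]:
                raise ReportInvariantError("dependent count exceeds total")
    for point in report.get("timecourse", {}).get("points", []):
        if point.get("tf_n_up") is not None and point["tf_n_up"] > point["n_up"]:
            raise ReportInvariantError("TF-subset count exceeds the global count")


def run(config: RunConfig) -> dict:
    """Execute the configured analysis end-to-end and write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    report: dict = {
        "software": {"name": "stressarray", "version": __version__},
        "seed": config.seed,
        "config": _config_echo(config),
    }

    def stage(name):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s ...", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    log.error("stage %s failed: %s", name, exc)
                return False

        return _T()

    annotation: en.GOAnnotation | None = None
    with stage("inputs"):
        if config.simulate is not None:
            truth = syn.generate_truth(config.simulate)
            experiment = syn.generate_probe_table(truth, config.simulate)
            annotation = syn.generate_go_annotation(truth, config.simulate)
            probes, pmap, design = (experiment.probes, experiment.probe_gene_map,
                                    experiment.design)
            syn.write_truth(truth, out / "truth.tsv")
        else:
            probes = ac.read_probe_table(config.probes_path)
            pmap = syn.read_probe_gene_map(config.map_path)
            design = cond.read_design(config.design_path)
            if config.annotation_path is not None:
                annotation = en.load_annotation(config.annotation_path,
                                                fmt=config.annotation_format)
    report["n_probe_rows"] = len(probes)
    report["n_samples"] = int(probes["sample_id"].nunique())

    with stage("process"):
        processed = process_experiment(probes, pmap, design,
                                       pcc_threshold=config.pcc_flag,
                                       collapse_agg=config.collapse_agg)
    matrix = processed.matrix
    ac.write_ratio_matrix(matrix, out / "matrix.tsv")
    write_json(processed.qc.to_dict(), out / "qc.json")
    report["n_genes"] = int(len(matrix.table))
    report["n_probes_unmapped"] = matrix.n_unmapped
    report["n_probes_ambiguous"] = matrix.n_ambiguous
    report["qc_flags"] = list(processed.qc.flags)

    contexts = cond.contexts_in_design(processed.design)
    report["contexts"] = {}
    up_sets: dict[str, set[str]] = {}
    dep_by_treatment: dict[str, dict[str, rc.DependencyCall]] = {}
    call_frames = []
    dep_frames = []
    with stage("call"):
        for stimulus, t in contexts:
            wt = cond.condition_label(stimulus, t, "wt")
            label = f"{stimulus}_t{t}"
            up = rc.call_up(matrix, wt, config.up_fc)
            down = rc.call_down(matrix, wt, config.down_fc)
            call_frames.extend([up, down])
            entry: dict = {"n_up": int(len(up)), "n_down": int(len(down)),
                           "dependency": {}}
            arms = cond.arms_for_context(processed.design, stimulus, t)
            if "sb" in arms or "ko" in arms:
                for direction, frame in (("up", up), ("down", down)):
                    if len(frame) == 0:
                        continue
                    calls = rc.dependency_calls(
                        matrix, stimulus, t, direction=direction,
                        up_threshold=config.up_fc, down_threshold=config.down_fc,
                        reduction=config.reduction, mode=config.dependency_mode)
                    dep_frames.append(rc.calls_to_frame(calls))
                    frac = rc.dependency_fraction(calls, mode="any")
                    entry["dependency"][direction] = {
                        "mode": "any",
                        "rule": config.dependency_mode,
                        "fraction": frac.fraction,
                        "n_dependent": frac.n_dependent,
                        "n_total": frac.n_total,
                    }
                    if direction == "up":
                        dep_by_treatment[label] = {c.gene_id: c for c in calls}
            up_sets[label] = set(up["gene_id"])
            report["contexts"][label] = entry
    if call_frames:
        pd.concat(call_frames, ignore_index=True).to_csv(
            out / "gene_calls.tsv", sep="\t", index=False)
    if dep_frames:
        pd.concat(dep_frames, ignore_index=True).to_csv(
            out / "dependency.tsv", sep="\t", index=False)

    report["overlaps"] = {}
    with stage("overlap"):
        stimuli = {s for s, _ in contexts}
        if len(up_sets) >= 2 and len(stimuli) >= 2:
            ov = rc.overlap(up_sets)
            report["overlaps"]["up_sets"] = ov.to_dict()
            write_json(ov.to_dict(), out / "overlap.json")
        if len(up_sets) >= 3 and len(stimuli) >= 3:
            core = rc.common_core(up_sets, dep_by_treatment)
            core.to_csv(out / "common_core.tsv", sep="\t", index=False)
            report["common_core"] = {
                "n_genes": int(len(core)),
                "n_dependent_two_any_treatment":
                    int(core["dependent_two_any_treatment"].fillna(False).sum()),
            }

    with stage("timecourse"):
        by_stim: dict[str, list[int]] = {}
        for stimulus, t in contexts:
            arms = cond.arms_for_context(processed.design, stimulus, t)
            if "sb" in arms:
                by_stim.setdefault(stimulus, []).append(t)
        tc_stim = next((s for s, ts in by_stim.items() if len(ts) >= 2), None)
        if tc_stim is not None:
            tf_genes = annotation.terms.get(config.tf_term) if annotation else None
            points, tc_overlap = rc.timecourse(
                matrix, tc_stim, sorted(by_stim[tc_stim]), tf_genes=tf_genes,
                up_threshold=config.up_fc, reduction=config.reduction,
                mode=config.dependency_mode)
            frame = pd.DataFrame([vars(p) for p in points])
            frame.to_csv(out / "timecourse.tsv", sep="\t", index=False)
            report["timecourse"] = {
                "stimulus": tc_stim,
                "points": [vars(p) for p in points],
            }
            report["overlaps"]["timecourse_up_sets"] = tc_overlap.to_dict()

    if config.run_enrichment and annotation is not None and annotation.terms:
        with stage("enrich"):
            _run_enrichment(config, matrix, annotation, contexts, out, report)

    report["timings_sec"] = {k: round(v, 3) for k, v in timings.items()}
    validate_report(report)
    write_json(report, out / "report.json")
    return report


def _run_enrichment(config: RunConfig, matrix: ac.RatioMatrix,
                    annotation: en.GOAnnotation, contexts, out: Path,
                    report: dict) -> None:
    """Per-context, per-ontology binomial enrichment of the up-sets.

    Cellular component uses the 2-fold up-set, molecular function and
    biological process the 2.5-fold up-set (the thresholds travel with the
    results). The universe is either every gene with an annotation in the
    ontology under test (default) or the whole array.
    """
    array_universe = set(matrix.table.index.astype(str))
    results_by_cond: dict[str, dict[str, pd.DataFrame]] = {"CC": {}, "MF": {}, "BP": {}}
    summary: dict[str, dict] = {}
    for stimulus, t in contexts:
        wt = cond.condition_label(stimulus, t, "wt")
        label = f"{stimulus}_t{t}"
        per_ont = {}
        for ont in en.ONTOLOGIES:
            fold = config.cc_fc if ont == "CC" else config.up_fc
            de = set(rc.call_up(matrix, wt, fold)["gene_id"])
            sub_ann = annotation.restrict(ont)
            universe = (set(sub_ann.genes()) & array_universe
                        if config.enrichment_universe == "annotated" else array_universe)
            if not universe:
                continue
            filtered = en.filter_min_size(sub_ann, config.min_category_size, universe)
            res = en.enrich(de & universe, universe, filtered, ontology=ont,
                            tail=config.enrichment_tail,
                            nominal_alpha=config.nominal_alpha,
                            fdr_alpha=config.fdr_alpha,
                            strata=config.enrichment_strata,
                            fold_threshold_used=fold)
            res.insert(0, "condition", label)
            res.to_csv(out / f"enrichment_{label}_{ont}.tsv", sep="\t", index=False)
            results_by_cond[ont][label] = res
            per_ont[ont] = {
                "n_terms": int(len(res)),
                "n_fdr": int((res["sig_class"] == "fdr").sum()),
                "n_nominal": int((res["sig_class"] == "nominal").sum()),
                "fold_threshold_used": fold,
                "universe_size": res.attrs["universe_size"],
                "tail": res.attrs["tail"],
            }
        summary[label] = per_ont
    report["enrichment"] = summary
    for ont, by_cond in results_by_cond.items():
        if not by_cond:
            continue
        hm = en.heatmap_matrix(by_cond)
        hm.to_long().to_csv(out / f"heatmap_{ont}.tsv", sep="\t", index=False)
        write_json({
            "ontology": ont,
            "terms": list(hm.pvalue.index),
            "conditions": list(hm.pvalue.columns),
            "pvalue": hm.pvalue.where(hm.pvalue.notna(), None).values.tolist(),
            "qvalue": hm.qvalue.where(hm.qvalue.notna(), None).values.tolist(),
            "sig_class": hm.sig_class.values.tolist(),
        }, out / f"heatmap_{ont}.json")


def _config_echo(config: RunConfig) -> dict:
    echo = {k: v for k, v in vars(config).items() if k != "simulate"}
    if config.simulate is not None:
        s = {k: v for k, v in vars(config.simulate).items() if k != "contexts"}
        s["contexts"] = [vars(c) for c in config.simulate.contexts]
        for key, val in list(s.items()):
            if isinstance(val, tuple):
                s[key] = list(val)
        s["contexts"] = [
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in c.items()}
            for c in s["contexts"]
        ]
        echo["synthetic"] = s
    return echo
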