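"""End-to-end orchestration: synthetic cohort (or recorded files) through
signal conditioning, feature extraction, cognitive grouping, stable
sparse classification per feature-subset model, and statistical
evaluation.  Every intermediate result is written as CSV or JSON into a
run directory together with a manifest of seeds and parameters."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cogindex import cluster_groups, compute_mdcog, fit_normative_model
from .config import RunConfig
from .enet import ElasticNetConfig
from .evaluation import baseline_classifiers, compare_model_aucs, \
    permutation_anova2
from .features import MODEL_TASKS, STGF_NAMES, assemble_feature_table, \
    compute_stgf, compute_stride_params, select_model_columns
from .signal import AccelerationRecording, detect_gait_events, \
    lowpass_filter, split_segments, tilt_correct
from .ssc import StableSparseClassifier
from .synth import CohortSpec, TASKS, cohort_frame, generate_acceleration, \
    generate_cohort, generate_cognitive_scores, generate_normative_scores, \
    subject_profiles

logger = logging.getLogger(__name__)


def process_recording(rec: AccelerationRecording, config: RunConfig):
    """Signal chain for one trial: tilt -> filter -> split -> events."""
    rec = tilt_correct(rec)
    rec = lowpass_filter(rec, cutoff=config.filter_cutoff,
                         order=config.filter_order)
    segments = split_segments(rec, trim=config.trim_seconds)
    out = []
    for seg in segments:
        events = detect_gait_events(seg,
                                    wavelet_scale=config.wavelet_scale)
        out.append((seg, events))
    return out


def extract_subject_features(recordings: dict[str, AccelerationRecording],
                             height: float, config: RunConfig,
                             provenance: dict | None = None):
    """Per-task, per-direction gait feature vectors for one subject.

    When ``provenance`` (a dict) is given, the number of strides behind
    each task/direction cell is recorded into it.
    """
    result: dict[str, dict[str, object]] = {}
    for task, rec in recordings.items():
        per_dir = {}
        for i, (seg, events) in enumerate(process_recording(rec, config)):
            intervals = compute_stride_params(events)
            per_dir[f"dir{i + 1}"] = compute_stgf(
                intervals, seg, height=height, events=events)
            if provenance is not None:
                provenance.setdefault(task, {})[f"dir{i + 1}"] = \
                    len(events.ic_times) - 1
        result[task] = per_dir
    return result


def simulate_cohort_features(config: RunConfig,
                             spec: CohortSpec | None = None,
                             run_dir: Path | None = None):
    """Generate the cohort, walk signals, and the 96-column feature table.

    Returns ``(cohort_df, feature_table)``; subjects whose signals fail
    any processing stage are dropped with a logged reason.
    """
    spec = spec or CohortSpec(seed=config.stage_int_seed("cohort"))
    cohort = generate_cohort(spec)
    cdf = cohort_frame(cohort)
    per_subject = {}
    strides: dict[str, dict] = {}
    for s in cohort:
        rng = np.random.default_rng(config.stage_seed("gait", s.id))
        profiles = subject_profiles(s.group, rng)
        recordings = {}
        for task in TASKS:
            rec, _ = generate_acceleration(
                profiles[task], task=task, distance=config.distance,
                sampling_rate=config.sampling_rate,
                seed=config.stage_seed("accel", s.id, task),
                subject_id=s.id, filter_cutoff=config.filter_cutoff)
            recordings[task] = rec
        try:
            prov: dict = {}
            per_subject[s.id] = extract_subject_features(
                recordings, height=s.height, config=config,
                provenance=prov)
            strides[s.id] = prov
        except Exception as exc:  # noqa: BLE001 - drop subject, keep run
            logger.warning("dropping subject %s: %s", s.id, exc)
    labels = cdf["group"]
    table = assemble_feature_table(per_subject, labels=labels)
    if run_dir is not None:
        from .features import STGF_UNITS

        cdf.to_csv(run_dir / "cohort.csv")
        table.to_csv(run_dir / "features.csv")
        meta = {"units": {**STGF_UNITS, "dtc": "%"},
                "strides_per_cell": strides}
        with open(run_dir / "features_meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)
    return cdf, table


def features_from_files(recording_paths: dict[str, dict[str, str]],
                        heights: dict[str, float], labels: pd.Series,
                        config: RunConfig) -> pd.DataFrame:
    """Feature table from recorded ``t,ax,ay,az`` delimited files.

    ``recording_paths`` maps subject -> task -> file path.
    """
    per_subject = {}
    for subject, tasks in recording_paths.items():
        recordings = {}
        for task, path in tasks.items():
            try:
                recordings[task] = AccelerationRecording.read_csv(
                    path, subject_id=subject, task=task)
            except Exception as exc:
                raise ValueError(f"malformed recording {path}: {exc}") \
                    from exc
        per_subject[subject] = extract_subject_features(
            recordings, height=heights[subject], config=config)
    return assemble_feature_table(per_subject, labels=labels)


def run_ssc_models(table: pd.DataFrame, config: RunConfig,
                   models: list[str] | None = None,
                   run_dir: Path | None = None) -> dict[str, dict]:
    """Fit the stable sparse classifier for each feature-subset model."""
    if models is None or models == ["__all__"]:
        models = list(MODEL_TASKS)
    neg, pos = config.comparison
    sub = table[table["label"].isin([neg, pos])]
    econf = config.enet_config()
    out = {}
    for model_id in models:
        cols = select_model_columns(sub, model_id)
        clf = StableSparseClassifier.from_dataframe(
            cols, positive=pos, config=econf, n_iter=config.ssc_n_iter,
            subject_fraction=config.subject_fraction,
            feature_fraction=config.feature_fraction,
            threshold=config.consistency_threshold,
            keep_fraction=config.screening_keep_fraction)
        sel = clf.fit(seed=config.stage_int_seed("ssc", model_id))
        val = sel.validate(n_iter=config.validation_n_iter,
                           seed=config.stage_int_seed("validate", model_id),
                           target_sensitivity=config.target_sensitivity)
        entry = {
            "model": model_id,
            "stable_features": sel.stable_features,
            "frequencies": {f: float(v) for f, v in
                            zip(sel.model.feature_names, sel.frequencies)},
            "median_auc": None if val.no_stable_biomarkers
            else float(val.median_auc),
            "auc_sample": val.aucs.tolist(),
            "no_stable_biomarkers": val.no_stable_biomarkers,
        }
        if not val.no_stable_biomarkers:
            op = val.operating_point(config.target_sensitivity)
            entry["operating_point"] = {
                "sensitivity": op.sensitivity, "specificity": op.specificity,
                "accuracy": op.accuracy, "target_met": op.target_met}
            entry["roc"] = {
                "fpr": val.fpr_grid.tolist(),
                "tpr_median": val.tpr_median.tolist(),
                "tpr_lower": val.tpr_lower.tolist(),
                "tpr_upper": val.tpr_upper.tolist()}
        out[model_id] = entry
        if run_dir is not None:
            with open(run_dir / f"ssc_{model_id.replace('+', '_')}.json",
                      "w") as fh:
                json.dump(entry, fh, indent=1)
    return out


def run_evaluation(table: pd.DataFrame, ssc_results: dict, config: RunConfig,
                   run_dir: Path | None = None) -> dict:
    """ANOVA per gait feature, model-rank comparison, and baselines."""
    out: dict = {}
    # permutation two-way ANOVA on each normal-walk STGF across tasks
    anova = {}
    for name in STGF_NAMES:
        wide = table[[f"{t}::{name}" for t in TASKS]]
        res = permutation_anova2(wide, table["label"], None,
                                 n_perm=config.n_permutations,
                                 seed=config.stage_int_seed("anova", name))
        anova[name] = {"f_group": res.f_group, "f_task": res.f_task,
                       "f_interaction": res.f_interaction,
                       "p_group": res.p_group, "p_task": res.p_task,
                       "p_interaction": res.p_interaction}
    out["anova"] = anova
    # rank-based AUC comparison across models, normal walk as reference
    samples = {m: np.asarray(r["auc_sample"]) for m, r in
               ssc_results.items()
               if r["auc_sample"] and not r["no_stable_biomarkers"]}
    if len(samples) >= 2 and "NormalW" in samples:
        n_min = min(len(v) for v in samples.values())
        comp = compare_model_aucs({m: v[:n_min] for m, v in samples.items()},
                                  reference="NormalW", alpha=config.alpha)
        out["model_comparison"] = comp.table.to_dict(orient="records")
    # SVM / shrinkage-LDA baselines on the same tables
    neg, pos = config.comparison
    sub = table[table["label"].isin([neg, pos])]
    baselines = {}
    for model_id in ssc_results:
        cols = select_model_columns(sub, model_id)
        X = cols.drop(columns=["label"]).to_numpy(float)
        y = (cols["label"] == pos).to_numpy(int)
        bl = baseline_classifiers(
            X, y, folds=config.baseline_folds, reps=config.baseline_reps,
            seed=config.stage_int_seed("baseline", model_id))
        baselines[model_id] = {c: {"auc_mean": float(bl.loc[c, "auc_mean"]),
                                   "auc_sd": float(bl.loc[c, "auc_sd"])}
                               for c in bl.index}
    out["baselines"] = baselines
    if run_dir is not None:
        with open(run_dir / "evaluation.json", "w") as fh:
            json.dump(out, fh, indent=1)
    return out


def run_pipeline(config: RunConfig, mode: str = "synthetic",
                 feature_table: pd.DataFrame | None = None,
                 cohort_spec: CohortSpec | None = None) -> Path:
    """Execute the full analysis and write artifacts to the run directory.

    ``mode='synthetic'`` simulates the cohort end to end; with
    ``mode='from-table'`` a prepared feature table (with a ``label``
    column) is analyzed directly.
    """
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    stage = "init"
    try:
        if mode == "synthetic":
            stage = "synth/cognitive"
            if cohort_spec is None:
                cohort_spec = CohortSpec(
                    seed=config.stage_int_seed("cohort"))
            cohort = generate_cohort(cohort_spec)
            scores = generate_cognitive_scores(
                cohort, seed=config.stage_int_seed("scores"))
            normative = generate_normative_scores(
                config.normative_n, seed=config.stage_int_seed("normative"))
            stage = "cogindex"
            norm_model = fit_normative_model(normative)
            mdcog = compute_mdcog(scores, norm_model)
            ages = pd.Series({s.id: s.age for s in cohort})
            grouping = cluster_groups(
                mdcog, ages[mdcog.index], repeats=config.kmeans_repeats,
                age_threshold=config.age_threshold,
                seed=config.stage_int_seed("kmeans"))
            pd.DataFrame({"MDCog": mdcog, "age": ages,
                          "group": grouping.labels}).to_csv(
                run_dir / "mdcog.csv")
            norm_model.to_json(run_dir / "normative_model.json")
            stage = "signal/features"
            _, table = simulate_cohort_features(config, spec=cohort_spec,
                                                run_dir=run_dir)
        elif mode == "from-table":
            if feature_table is None:
                raise ValueError("from-table mode needs a feature table")
            table = feature_table
            table.to_csv(run_dir / "features.csv")
        else:
            raise ValueError(f"unknown mode {mode!r}")
        stage = "ssc"
        ssc_results = run_ssc_models(table, config,
                                     models=config.models, run_dir=run_dir)
        stage = "evaluation"
        evaluation = run_evaluation(table, ssc_results, config,
                                    run_dir=run_dir)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") \
            from exc
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "mode": mode,
        "n_subjects": int(len(table)),
        "models": list(ssc_results),
        "median_auc": {m: r["median_auc"] for m, r in ssc_results.items()},
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return run_dir


def report(run_dir) -> str:
    """Human-readable summary of a completed (or partial) run."""
    run_dir = Path(run_dir)
    lines = [f"Run report: {run_dir}"]
    manifest = run_dir / "manifest.json"
    if manifest.exists():
        m = json.loads(manifest.read_text())
        lines.append(f"  version {m['version']}, seed {m['seed']}, "
                     f"config {m['config_digest']}, "
                     f"n={m['n_subjects']} subjects")
    else:
        lines.append("  [incomplete run: no manifest]")
    ssc_files = sorted(run_dir.glob("ssc_*.json"))
    if not ssc_files:
        lines.append("  [no classifier results]")
    for f in ssc_files:
        r = json.loads(f.read_text())
        if r.get("no_stable_biomarkers"):
            lines.append(f"  {r['model']:<18} no stable biomarkers")
            continue
        op = r.get("operating_point", {})
        lines.append(
            f"  {r['model']:<18} median AUC {r['median_auc']:.2f}  "
            f"sens {op.get('sensitivity', float('nan')):.2f} "
            f"spec {op.get('specificity', float('nan')):.2f} "
            f"acc {op.get('accuracy', float('nan')):.2f}")
        stable = sorted(((f_, v) for f_, v in r["frequencies"].items()
                         if f_ in r["stable_features"]),
                        key=lambda kv: -kv[1])
        for name, freq in stable:
            lines.append(f"      {name:<30} {freq:5.2f}")
    ev = run_dir / "evaluation.json"
    if ev.exists():
        e = json.loads(ev.read_text())
        sig = [k for k, v in e.get("anova", {}).items()
               if v["p_group"] < 0.001]
        lines.append(f"  ANOVA: GROUP p<0.001 for {len(sig)}/"
                     f"{len(e.get('anova', {}))} gait features")
    else:
        lines.append("  [no evaluation results]")
    return "\n".join(lines)
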