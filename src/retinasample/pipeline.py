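"""End-to-end orchestration: synthesize, detect, reconstruct, score, analyze.

The experiment grid crosses sampling sources (random / control / super
policies), spotlight sizes and identities within observers, mirroring a
blocked gaze-contingent learning phase: every observer views every identity
once per spotlight size for 5 s. All randomness flows from one root seed
through named SeedSequence branches, so reruns are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import controls, events, infometrics, mixed_models, retina, scoring, synth
from .geometry import default_geometry

SOURCES = ("random", "control", "super")


@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort run."""

    seed: int = 0
    n_identities: int = 20
    observers_per_source: int = 10
    image_size: int = 224
    spotlight_set: tuple = synth.SPOTLIGHT_SIZES
    targeting: tuple = (0.0, 0.3, 0.7)
    delta: float = 25.0
    edge_ramp_px: float = 0.0
    background: float = retina.BACKGROUND_VALUE
    duration_ms: float = 5000.0
    rate_hz: float = 120.0
    backend_grids: tuple = (7, 8, 14)
    include_yoked: bool = False
    max_trial_model_trials: int = 150
    fit_models: bool = True
    write_traces: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("spotlight_set", "targeting", "backend_grids"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def _trial_seed(root: int, *branch: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([root, *branch])


def _seed_int(root: int, *branch: int) -> int:
    return int(_trial_seed(root, *branch).generate_state(1)[0] % (2 ** 31))


def synthesize_cohort(cfg: RunConfig):
    """Identities, stimuli, region mask, geometry and observer policies."""
    identities, stimuli = synth.generate_identities(
        cfg.n_identities, image_size=cfg.image_size, seed=_seed_int(cfg.seed, 0))
    mask = synth.build_region_mask(cfg.image_size)
    geometry = default_geometry(cfg.image_size)
    policies = synth.default_policies(cfg.image_size, targeting=cfg.targeting)
    return identities, stimuli, mask, geometry, policies


def generate_cohort_traces(cfg: RunConfig, identities, stimuli, geometry,
                           policies) -> list[synth.GazeTrace]:
    """One learning trace per (source, observer, spotlight, identity)."""
    diag = {i.identity_id: i.diagnosticity_map for i in identities}
    traces = []
    for si, src in enumerate(SOURCES):
        for k in range(cfg.observers_per_source):
            pid = f"{src}{k:02d}"
            for pct in cfg.spotlight_set:
                for ii, ident in enumerate(identities):
                    stim = stimuli[(ident.identity_id, "neutral")]
                    tid = f"{pid}-s{pct}-{ident.identity_id}"
                    traces.append(synth.generate_gaze_trace(
                        policies[src], stim, geometry,
                        duration_ms=cfg.duration_ms, rate_hz=cfg.rate_hz,
                        seed=_seed_int(cfg.seed, 1, si, k, pct, ii),
                        diagnosticity_map=diag[ident.identity_id],
                        participant_id=pid, trial_id=tid, spotlight_pct=pct))
    return traces


def detect_cohort_fixations(traces, geometry,
                            params: events.DetectionParams | None = None) -> dict:
    """Rules (a)+(b) per trace, then the per-participant 3 SD rule (c)."""
    per_trial = {(tr.participant_id, tr.trial_id):
                 events.detect_fixations(tr, geometry, params) for tr in traces}
    return events.apply_duration_outlier_rule(per_trial, params)


def reconstruct_and_measure(cfg: RunConfig, traces, fixations_by_trial, stimuli,
                            mask=None, backends=None):
    """Composite each trial, measure information, embed probes and galleries.

    Returns (trial_records DataFrame, probe embedding dict, gallery embedding
    dict). Composite pixel arrays are not retained (only their measurements),
    so cohort-scale runs stay within memory.
    """
    backends = backends or [scoring.GridStatsBackend(g) for g in cfg.backend_grids]
    geometry = default_geometry(cfg.image_size)
    models: dict = {}
    gallery_vecs = {}
    for (iid, expr), stim in stimuli.items():
        for be in backends:
            gallery_vecs[(be.name, iid, expr)] = be.embed(stim.pixels)

    records, probe_vecs = [], {}
    n_skipped = 0
    for tr in traces:
        fixes = fixations_by_trial.get((tr.participant_id, tr.trial_id), [])
        if not fixes:
            # e.g. a single-fixation trial whose fixation fell to the 3 SD rule
            n_skipped += 1
            continue
        src = tr.participant_id.rstrip("0123456789")
        iid = tr.trial_id.split("-")[-1]
        expr = "neutral"
        key = (iid, expr, cfg.delta)
        if key not in models:
            models[key] = retina.FoveationModel(stimuli[(iid, expr)], geometry,
                                                delta=cfg.delta)
        comp = retina.reconstruct_trial(
            models[key], fixes, retina.ApertureSpec(tr.spotlight_pct),
            trial_id=tr.trial_id, source_label=src,
            background=cfg.background, edge_ramp_px=cfg.edge_ramp_px)
        stim = stimuli[(iid, expr)]
        info = infometrics.info_proportion(comp, stim.pixels, stim.face_bounds,
                                           trial_id=tr.trial_id)
        records.append({"trial_id": tr.trial_id, "participant_id": tr.participant_id,
                        "source_label": src, "spotlight_pct": tr.spotlight_pct,
                        "identity_id": iid, "expression": expr,
                        "n_fixations": len(fixes),
                        "ssim_term": info.ssim_term, "pixel_term": info.pixel_term,
                        "info_proportion": info.value})
        for be in backends:
            probe_vecs[(be.name, tr.trial_id)] = be.embed(comp.pixels)
    df = pd.DataFrame(records)
    df.attrs["n_skipped_trials"] = n_skipped
    return df, probe_vecs, gallery_vecs, backends


def score_pairs(cfg: RunConfig, trial_df: pd.DataFrame, probe_vecs, gallery_vecs,
                backends, identities) -> pd.DataFrame:
    """Build balanced pairs and per-backend normalized similarity scores."""
    probes = trial_df.to_dict("records")
    pairs = scoring.build_pairs(probes, identities, seed=_seed_int(cfg.seed, 2))
    frames = []
    for be in backends:
        dist = np.array([
            np.linalg.norm(probe_vecs[(be.name, p["trial_id"])]
                           - gallery_vecs[(be.name, p["gallery_identity"],
                                           p["gallery_expression"])])
            for p in pairs])
        sim = scoring.normalized_similarity(dist)
        is_match = np.array([p["is_match"] for p in pairs])
        frames.append(pd.DataFrame({
            "trial_id": [p["trial_id"] for p in pairs],
            "backend": be.name,
            "source_label": [p["source_label"] for p in pairs],
            "spotlight_pct": [p["spotlight_pct"] for p in pairs],
            "is_match": is_match,
            "distance": dist,
            "similarity": sim,
            "correctness": scoring.correctness(sim, is_match),
        }))
    return pd.concat(frames, ignore_index=True)


def trial_model_table(scores: pd.DataFrame, trial_df: pd.DataFrame,
                      max_trials: int, seed: int) -> pd.DataFrame:
    """Match-trial correctness joined with the information covariate.

    One row per (backend, trial); when the cohort exceeds ``max_trials`` a
    seeded trial subsample is taken, stratified by source, so the crossed
    random-effects fit stays tractable.
    """
    match = scores[scores["is_match"]].merge(
        trial_df[["trial_id", "info_proportion"]], on="trial_id")
    trial_ids = match["trial_id"].unique()
    if len(trial_ids) > max_trials:
        info = trial_df.set_index("trial_id").loc[trial_ids]
        rng = np.random.default_rng(seed)
        keep = []
        per_source = max_trials // info["source_label"].nunique()
        for _, g in info.groupby("source_label"):
            idx = rng.permutation(len(g))[:per_source]
            keep.extend(g.index[idx])
        match = match[match["trial_id"].isin(keep)]
    return match[["backend", "trial_id", "source_label", "spotlight_pct",
                  "info_proportion", "correctness"]].reset_index(drop=True)


def add_yoked_source(cfg: RunConfig, fixations_by_trial, mask, yoke_to="control"):
    """Optional stage: region-matched yoked-random fixations for human trials."""
    out = {}
    for n, ((pid, tid), fixes) in enumerate(fixations_by_trial.items()):
        if not pid.startswith(yoke_to) or not fixes:
            continue
        ytid = tid.replace(yoke_to, "yoked", 1)
        out[(pid.replace(yoke_to, "yoked", 1), ytid)] = controls.yoked_random_fixations(
            fixes, mask, seed=_seed_int(cfg.seed, 3, n))
    return out


def run_experiment(cfg: RunConfig) -> dict:
    """Execute the full pipeline in memory and return all stage outputs."""
    identities, stimuli, mask, geometry, policies = synthesize_cohort(cfg)
    traces = generate_cohort_traces(cfg, identities, stimuli, geometry, policies)
    fixations = detect_cohort_fixations(traces, geometry)
    trial_df, probe_vecs, gallery_vecs, backends = reconstruct_and_measure(
        cfg, traces, fixations, stimuli, mask)
    scores = score_pairs(cfg, trial_df, probe_vecs, gallery_vecs, backends,
                         identities)
    auc = scoring.auc_table(scores)
    out = {"config": cfg, "identities": identities, "region_mask": mask,
           "trials": trial_df, "scores": scores, "auc": auc,
           "n_traces": len(traces),
           "n_skipped_trials": trial_df.attrs.get("n_skipped_trials", 0)}
    if cfg.fit_models:
        fits = mixed_models.compare_condition_forms(auc)
        out["condition_fits"] = fits
        out["condition_terms"] = mixed_models.term_tests(fits["logit"])
        ttab = trial_model_table(scores, trial_df, cfg.max_trial_model_trials,
                                 _seed_int(cfg.seed, 4))
        out["trial_table"] = ttab
        out["trial_fit"] = mixed_models.fit_trial_model(ttab)
        out["trial_terms"] = mixed_models.term_tests(out["trial_fit"])
    return out


# ---------------------------------------------------------------------------
# file outputs

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def fit_to_dict(fit: mixed_models.ModelFit, terms: pd.DataFrame | None = None) -> dict:
    d = {"form": fit.form, "link": fit.link, "bic": fit.bic,
         "llf": fit.llf, "n_params": fit.n_params, "nobs": fit.nobs,
         "converged": fit.converged, "random_effects": fit.random_effects,
         "fixed_effects": fit.terms.to_dict("records")}
    if terms is not None:
        d["term_tests"] = terms.to_dict("records")
    return d


def run(cfg: RunConfig, out_dir) -> dict:
    """Run the pipeline and persist stage outputs plus a hashed manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = run_experiment(cfg)

    files = {}
    result["trials"].to_csv(out_dir / "trial_metrics.csv", index=False)
    files["trial_metrics"] = "trial_metrics.csv"
    result["scores"].to_csv(out_dir / "pair_scores.csv", index=False)
    files["pair_scores"] = "pair_scores.csv"
    result["auc"].to_csv(out_dir / "auc_table.csv", index=False)
    files["auc_table"] = "auc_table.csv"
    if "condition_fits" in result:
        report = {form: fit_to_dict(f) for form, f in result["condition_fits"].items()}
        report["logit"]["term_tests"] = result["condition_terms"].to_dict("records")
        (out_dir / "model_condition.json").write_text(json.dumps(report, indent=1))
        files["model_condition"] = "model_condition.json"
        (out_dir / "model_trial.json").write_text(json.dumps(
            fit_to_dict(result["trial_fit"], result["trial_terms"]), indent=1))
        files["model_trial"] = "model_trial.json"

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "files": {name: {"path": rel, "sha256": _sha256(out_dir / rel)}
                  for name, rel in files.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    result["manifest"] = manifest
    return result
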