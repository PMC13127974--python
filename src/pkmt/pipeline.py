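"""End-to-end orchestration: simulate/ingest -> preprocess -> embed -> select
-> train -> evaluate -> explain, plus the repeated-split stability protocol.

One global seed fans out to per-stage seeds through a counter scheme
(``numpy.random.SeedSequence(seed).spawn``), so any stage can be re-run in
isolation and the whole pipeline is reproducible bit for bit.  The test
partition's target values are brokered by a :class:`TargetGuard` that logs
every read; no fitting stage may read them, and the run log records that
zero test-target reads happened before evaluation.

Two built-in profiles: ``full_profile()`` mirrors the full study settings
(10,000 split candidates, 100 HPO trials, 5,000 selection iterations, up to
15,000 boosting rounds); ``tiny_profile()`` scales every loop down so a
complete run finishes in a minute or two on one CPU, and is the profile
exercised by the test suite.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as prep
from . import synthdata
from .descriptors import descriptor_matrix, render_images
from .embeddings import HPOBudget, train_embedder, extract_embeddings
from .evaluate import (dm_test, metrics_report, stratified_gmfe,
                       summarize_repeats)
from .feature_select import SelectionConfig, boruta_shap_select, union_features
from .interpret import kernel_shapley, summarize_attributions
from .mtgbm import BoostConfig, MultiTaskGBMRegressor, hpo_single_task

TARGETS = {"CL": "human_CL_mL_min_kg", "VD": "human_VDss_L_kg"}


@dataclass
class PipelineConfig:
    """Everything one run needs; see ``tiny_profile`` / ``full_profile``."""

    synth: synthdata.SynthConfig = field(default_factory=synthdata.SynthConfig)
    data_csv: str | None = None            # ingest instead of simulate
    split_method: str = "optimized"        # 'optimized' | 'random'
    split_candidates: int = 10000
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    image_size: int = 224
    cnn_channels: tuple[int, ...] = (16, 32, 64, 128, 256, 512)
    cnn_budget: HPOBudget = field(default_factory=HPOBudget)
    mlp_budget: HPOBudget = field(default_factory=HPOBudget)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    st_hpo_trials: int = 100
    st_max_rounds: int = 15000
    st_patience: int = 150
    mt_config: BoostConfig = field(default_factory=BoostConfig)
    explain_rows: int = 200
    explain_background: int = 30
    explain_budget: int = 2048
    run_explain: bool = True
    seed: int = 0

    def stage_seed(self, stage: int, offset: int = 0) -> int:
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(stage, offset))
        return int(ss.generate_state(1)[0] % (2**31 - 1))


def full_profile(seed: int = 0) -> PipelineConfig:
    """Full-scale settings of the study protocol."""
    return PipelineConfig(seed=seed)


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a validated PipelineConfig from a plain mapping (YAML/JSON).

    Nested sections (``synth``, ``cnn_budget``, ``mlp_budget``,
    ``selection``, ``mt_config``) are promoted to their dataclasses; any
    unknown key raises, so configs are schema-checked before a run starts.
    """
    kwargs = dict(data)
    nested = {"synth": synthdata.SynthConfig, "cnn_budget": HPOBudget,
              "mlp_budget": HPOBudget, "selection": SelectionConfig,
              "mt_config": BoostConfig}
    for key, cls in nested.items():
        if isinstance(kwargs.get(key), dict):
            kwargs[key] = cls(**kwargs[key])
    for key in ("ratios", "cnn_channels"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    for key, cls in nested.items():
        if key in kwargs and not isinstance(kwargs[key], cls):
            raise TypeError(f"config section '{key}' must be a mapping")
    cfg = PipelineConfig(**kwargs)
    cfg.synth.validate()
    cfg.mt_config.validate()
    cfg.selection.validate()
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from a YAML (or JSON) file."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return config_from_dict(data)


def tiny_profile(seed: int = 0, n_compounds: int = 300,
                 rho_shared: float = 0.6) -> PipelineConfig:
    """CPU-minutes-scale profile used by the test suite and examples."""
    return PipelineConfig(
        synth=synthdata.SynthConfig(n_compounds=n_compounds,
                                    rho_shared=rho_shared, seed=seed),
        split_candidates=200,
        image_size=32,
        cnn_channels=(8, 16, 32),
        cnn_budget=HPOBudget(n_trials=1, max_epochs=12, patience=4,
                             lr_range=(3e-4, 3e-3), seed=seed),
        mlp_budget=HPOBudget(n_trials=2, max_epochs=40, patience=6,
                             lr_range=(1e-4, 1e-2),
                             hidden_units_range=(32, 64), seed=seed),
        selection=SelectionConfig(n_iterations=25, shap_budget=96,
                                  importance_rows=16, background_rows=10),
        st_hpo_trials=3,
        st_max_rounds=250,
        st_patience=30,
        mt_config=BoostConfig(learning_rate=0.05, num_leaves=16, max_depth=6,
                              lambda_l1=0.1, lambda_l2=1.0,
                              min_child_samples=15, max_rounds=250,
                              patience=30),
        explain_rows=40,
        explain_background=15,
        explain_budget=512,
        seed=seed,
    )


class TargetGuard:
    """Brokered access to target values; logs which partition is read when.

    ``get(indices, stage)`` returns model-scale target columns for the given
    rows and records how many of those rows belong to the test partition.
    Fitting stages must show zero test reads.
    """

    def __init__(self, y_model: np.ndarray, test_idx: np.ndarray):
        self._y = y_model
        self._test = set(int(i) for i in test_idx)
        self.log: list[dict] = []

    def get(self, indices: np.ndarray, stage: str) -> np.ndarray:
        indices = np.asarray(indices, int)
        n_test = sum(1 for i in indices if int(i) in self._test)
        self.log.append({"stage": stage, "n_rows": int(indices.size),
                         "n_test_rows": int(n_test)})
        return self._y[indices]

    def test_reads_before(self, stage: str) -> int:
        total = 0
        for entry in self.log:
            if entry["stage"] == stage:
                break
            total += entry["n_test_rows"]
        return total


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


@dataclass
class RunArtifacts:
    out_dir: Path
    metrics: dict
    manifest: dict

    def path(self, rel: str) -> Path:
        return self.out_dir / rel


def load_or_generate(cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.data_csv is not None:
        return pd.read_csv(cfg.data_csv)
    return synthdata.generate_pk_dataset(cfg.synth).table


def prepare_inputs(cfg: PipelineConfig, table: pd.DataFrame):
    """Row filtering, feature winsorization, and per-molecule inputs that do
    not depend on the split (images, descriptor matrix)."""
    kept, n_removed = prep.filter_physiological(table)
    kept = prep.winsorize_features(kept)
    smiles = kept["smiles"].tolist()
    images = render_images(smiles, size=cfg.image_size)
    descriptors = descriptor_matrix(smiles)
    return kept, n_removed, images, descriptors


def _fit_split(cfg: PipelineConfig, table: pd.DataFrame, images: np.ndarray,
               descriptors: np.ndarray, split: prep.SplitPlan,
               stage_offset: int = 0, run_explain: bool | None = None,
               collect_artifacts: bool = True) -> dict:
    """Execute embedding, selection, training and evaluation for one split."""
    n = len(table)
    split.validate(n)
    tr, va, te = split.train_idx, split.val_idx, split.test_idx

    scaler = prep.PKColumnScaler()
    scaler.fit(table.iloc[tr])

    # model-scale targets, NaN marking missing
    y_model = np.column_stack([
        scaler.transform_column(TARGETS[t], table[TARGETS[t]].to_numpy(float))
        for t in ("CL", "VD")])
    guard = TargetGuard(y_model, te)

    # descriptor standardization on training statistics only
    mu = descriptors[tr].mean(axis=0)
    sd = descriptors[tr].std(axis=0)
    sd[sd == 0] = 1.0
    desc_std = (descriptors - mu) / sd

    feature_blocks: dict[str, np.ndarray] = {}
    embed_meta: dict[str, dict] = {}
    for ki, (kind, X_all) in enumerate((("cnn", images), ("mlp", desc_std))):
        for ti, tname in enumerate(("CL", "VD")):
            y_col = ti
            present = ~np.isnan(y_model[:, y_col])
            tr_rows = tr[present[tr]]
            va_rows = va[present[va]]
            budget = cfg.cnn_budget if kind == "cnn" else cfg.mlp_budget
            seed = cfg.stage_seed(2 + stage_offset, 10 * ki + ti)
            model = train_embedder(
                kind, tname, X_all[tr_rows],
                guard.get(tr_rows, f"embed_{kind}_{tname}")[:, y_col],
                X_all[va_rows],
                guard.get(va_rows, f"embed_{kind}_{tname}")[:, y_col],
                budget=budget, seed=seed, cnn_channels=cfg.cnn_channels)
            emb = extract_embeddings(model, X_all)
            for d in (0, 1):
                feature_blocks[model.column_names[d]] = emb[:, d]
            embed_meta[f"{kind}_{tname}"] = {
                "chosen": model.hpo_record["chosen"],
                "best_val_loss": model.hpo_record["best_val_loss"],
                "n_trials": model.hpo_record["n_trials"]}

    # candidate feature table: transformed animal PK + physchem + embeddings
    scaled = scaler.transform(table)
    candidates = {}
    for col in prep.ANIMAL_PK_COLUMNS + prep.PHYSCHEM_COLUMNS:
        if col in scaled.columns:
            candidates[col] = scaled[col].to_numpy(float)
    candidates.update(feature_blocks)
    feat = pd.DataFrame(candidates)
    if feat.isna().any().any():  # synthetic tables are complete; guard anyway
        feat = feat.fillna(feat.median(numeric_only=True))

    decisions = {}
    for ti, tname in enumerate(("CL", "VD")):
        present = ~np.isnan(y_model[:, ti])
        rows = tr[present[tr]]
        sel_cfg = SelectionConfig(**{**asdict(cfg.selection),
                                     "seed": cfg.stage_seed(3 + stage_offset, ti)})
        decisions[tname] = boruta_shap_select(
            feat.iloc[rows], guard.get(rows, f"select_{tname}")[:, ti], sel_cfg)
    union = union_features(decisions["CL"], decisions["VD"])
    if not union:
        warnings.warn("no features accepted by selection; using all candidates")
        union = list(feat.columns)

    X = feat.to_numpy(float)
    cols = list(feat.columns)
    uidx = [cols.index(c) for c in union]

    def target_frame(idx, stage):
        return guard.get(idx, stage)

    # multi-task model on the union feature set, fixed configuration
    mt = MultiTaskGBMRegressor(**asdict(cfg.mt_config))
    mt.fit(X[tr][:, uidx], target_frame(tr, "train_mt"),
           eval_set=(X[va][:, uidx], target_frame(va, "train_mt")))

    # single-task baselines on their own accepted features, tuned by GMFE
    st_models = {}
    st_feats = {}
    for ti, tname in enumerate(("CL", "VD")):
        accepted = decisions[tname].accepted or union
        fidx = [cols.index(c) for c in accepted]
        st_feats[tname] = accepted
        present = ~np.isnan(y_model[:, ti])
        tr_rows = tr[present[tr]]
        va_rows = va[present[va]]
        ytr = target_frame(tr_rows, f"train_st_{tname}")[:, ti]
        yva = target_frame(va_rows, f"train_st_{tname}")[:, ti]
        inverse = lambda v, c=TARGETS[tname]: scaler.inverse_column(c, v)
        if cfg.st_hpo_trials > 1:
            best = hpo_single_task(
                X[tr_rows][:, fidx], ytr.reshape(-1, 1),
                X[va_rows][:, fidx], yva.reshape(-1, 1), inverse,
                n_trials=cfg.st_hpo_trials, max_rounds=cfg.st_max_rounds,
                patience=cfg.st_patience,
                seed=cfg.stage_seed(4 + stage_offset, ti))
        else:
            best = BoostConfig(**{**asdict(cfg.mt_config), "n_tasks": 1,
                                  "max_rounds": cfg.st_max_rounds,
                                  "patience": cfg.st_patience})
        best.n_tasks = 1
        st = MultiTaskGBMRegressor(**asdict(best))
        st.fit(X[tr_rows][:, fidx], ytr.reshape(-1, 1),
               eval_set=(X[va_rows][:, fidx], yva.reshape(-1, 1)))
        st_models[tname] = (st, fidx)

    # ---- evaluation (first and only stage allowed to read test targets) ----
    leak_reads = guard.test_reads_before("evaluate")
    metrics: dict = {"targets": {}, "leakage_test_reads_before_eval": leak_reads}
    errors = {}
    preds_orig = {}
    for ti, tname in enumerate(("CL", "VD")):
        col = TARGETS[tname]
        y_te = guard.get(te, "evaluate")[:, ti]
        present = ~np.isnan(y_te)
        obs_orig = scaler.inverse_column(col, y_te[present])
        p_mt = mt.predict(X[te][:, uidx])[:, ti]
        st, fidx = st_models[tname]
        p_st = st.predict(X[te][:, fidx])
        mt_orig = np.maximum(scaler.inverse_column(col, p_mt[present]), 1e-9)
        st_orig = np.maximum(scaler.inverse_column(col, p_st[present]), 1e-9)
        preds_orig[tname] = {"mt": mt_orig, "st": st_orig, "obs": obs_orig}
        rep_mt = metrics_report(mt_orig, obs_orig)
        rep_st = metrics_report(st_orig, obs_orig)
        err_mt = np.log1p(mt_orig) - np.log1p(obs_orig)
        err_st = np.log1p(st_orig) - np.log1p(obs_orig)
        errors[tname] = (err_mt, err_st)
        dm = dm_test(err_st, err_mt)  # positive statistic: baseline worse
        metrics["targets"][tname] = {
            "mtgbm": rep_mt.to_dict(), "single_task": rep_st.to_dict(),
            "dm": dm.to_dict(),
            "selected_features": decisions[tname].accepted,
        }
    metrics["union_features"] = union
    vd = preds_orig["VD"]
    metrics["vd_stratified"] = stratified_gmfe(vd["mt"], vd["st"], vd["obs"]).to_dict()

    out = {
        "metrics": metrics,
        "split": split,
        "scaler": scaler,
        "embed_meta": embed_meta,
        "decisions": decisions,
        "union": union,
        "guard_log": guard.log,
    }
    if collect_artifacts:
        out.update({"mt_model": mt, "st_models": st_models,
                    "features": feat, "X": X, "cols": cols, "uidx": uidx})

    do_explain = cfg.run_explain if run_explain is None else run_explain
    if do_explain:
        modality = {}
        for c in cols:
            if c in prep.ANIMAL_PK_COLUMNS:
                modality[c] = "preclinical_pk"
            elif c in prep.PHYSCHEM_COLUMNS:
                modality[c] = "physicochemical"
            elif c.startswith("cnn_"):
                modality[c] = "embedding_cnn"
            else:
                modality[c] = "embedding_mlp"
        rng = np.random.default_rng(cfg.stage_seed(6 + stage_offset))
        rows = te[:min(cfg.explain_rows, te.size)]
        bg = X[tr][:, uidx][rng.choice(tr.size, size=min(cfg.explain_background,
                                                         tr.size), replace=False)]
        explanations = {}
        for ti, tname in enumerate(("CL", "VD")):
            attr = kernel_shapley(
                lambda mat, t=ti: mt.predict(mat)[:, t],
                X[rows][:, uidx], bg, budget=cfg.explain_budget,
                seed=cfg.stage_seed(7 + stage_offset, ti),
                feature_names=union)
            explanations[tname] = {
                "summary": summarize_attributions(
                    attr, {f: modality[f] for f in union}),
                "attr": attr,
            }
        out["explanations"] = explanations
        metrics["modality_shares"] = {
            t: explanations[t]["summary"]["modality_shares"] for t in explanations}
    return out


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> RunArtifacts:
    """One full run; writes the artifact tree and a content-hash manifest."""
    out_dir = Path(out_dir)
    table = load_or_generate(cfg)
    kept, n_removed, images, descriptors = prepare_inputs(cfg, table)

    split_seed = cfg.stage_seed(1)
    if cfg.split_method == "optimized":
        split = prep.optimize_split(kept, n_candidates=cfg.split_candidates,
                                    ratios=cfg.ratios, seed=split_seed)
    else:
        split = prep.random_split(kept, ratios=cfg.ratios, seed=split_seed)

    res = _fit_split(cfg, kept, images, descriptors, split)

    (out_dir / "data").mkdir(parents=True, exist_ok=True)
    kept.to_csv(out_dir / "data" / "preprocessed.csv", index=False)
    _write_json(out_dir / "splits" / "split.json", split.to_dict())
    (out_dir / "data" / "scaler.json").parent.mkdir(exist_ok=True)
    (out_dir / "data" / "scaler.json").write_text(res["scaler"].to_json())

    emb_cols = {c: res["features"][c].tolist()
                for c in res["features"].columns if "_vec" in c}
    _write_json(out_dir / "embeddings" / "embeddings.json",
                {"columns": emb_cols, "meta": res["embed_meta"]})
    for tname, dec in res["decisions"].items():
        (out_dir / "selection").mkdir(exist_ok=True)
        dec.to_frame().to_csv(out_dir / "selection" / f"decision_{tname}.csv",
                              index=False)
    _write_json(out_dir / "selection" / "union.json", res["union"])
    (out_dir / "models").mkdir(exist_ok=True)
    (out_dir / "models" / "mtgbm.json").write_text(res["mt_model"].to_json())
    for tname, (st, fidx) in res["st_models"].items():
        (out_dir / "models" / f"single_task_{tname}.json").write_text(st.to_json())
    _write_json(out_dir / "logs" / "run.json",
                {"guard_log": res["guard_log"],
                 "n_removed_physiological": n_removed,
                 "config_seed": cfg.seed})
    _write_json(out_dir / "metrics" / "metrics.json", res["metrics"])
    if "explanations" in res:
        for tname, ex in res["explanations"].items():
            _write_json(out_dir / "explanations" / f"summary_{tname}.json",
                        ex["summary"])
            pd.DataFrame(ex["attr"].values,
                         columns=ex["attr"].feature_names).to_csv(
                out_dir / "explanations" / f"shap_{tname}.csv", index=False)

    manifest = {}
    for p in sorted(out_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest[str(p.relative_to(out_dir))] = _sha256(p)
    _write_json(out_dir / "manifest.json", manifest)
    return RunArtifacts(out_dir=out_dir, metrics=res["metrics"], manifest=manifest)


def run_repeated(cfg: PipelineConfig, k: int = 10,
                 out_dir: str | Path | None = None) -> dict:
    """k independent random 60/20/20 splits, full pipeline per split, and
    win-rate / mean +- sd aggregation of test MSE for both targets."""
    if k < 2:
        raise ValueError("k must be >= 2")
    table = load_or_generate(cfg)
    kept, n_removed, images, descriptors = prepare_inputs(cfg, table)
    base_seed = cfg.stage_seed(1)
    plans = prep.repeated_splits(kept, k=k, ratios=cfg.ratios, base_seed=base_seed)
    per_run = []
    failures = []
    for i, plan in enumerate(plans):
        try:
            res = _fit_split(cfg, kept, images, descriptors, plan,
                             stage_offset=100 * (i + 1), run_explain=False,
                             collect_artifacts=False)
            row = {"run": i, "seed": plan.seed}
            for tname in ("CL", "VD"):
                m = res["metrics"]["targets"][tname]
                row[f"mse_mt_{tname}"] = m["mtgbm"]["mse_log"]
                row[f"mse_st_{tname}"] = m["single_task"]["mse_log"]
                row[f"gmfe_mt_{tname}"] = m["mtgbm"]["gmfe"]
                row[f"gmfe_st_{tname}"] = m["single_task"]["gmfe"]
            per_run.append(row)
        except Exception as exc:  # record and continue
            failures.append({"run": i, "error": repr(exc)})
    runs = pd.DataFrame(per_run)
    summary = {"k_requested": k, "k_completed": len(per_run),
               "failures": failures, "per_run": per_run}
    for tname in ("CL", "VD"):
        summary[tname] = summarize_repeats(
            runs[f"mse_mt_{tname}"], runs[f"mse_st_{tname}"]).to_dict()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        runs.to_csv(out_dir / "per_run_metrics.csv", index=False)
        _write_json(out_dir / "repeat_summary.json", summary)
    return summary
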