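"""End-to-end orchestration: simulate -> connectivity -> states -> stats -> predict.

Each stage is a function over an in-memory context that also writes its
outputs (TSV/CSV/JSON) under the configured output directory, so stages can
be run individually from the command line or chained by
:func:`run_pipeline`, which records a manifest (parameter hash, seeds,
per-stage outputs).  Reruns with the same configuration produce
byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import states as st
from .cognition import correlate_changes, paired_compare
from .containers import TimeCourseSet, pair_labels, pairs_to_matrix
from .errors import DegenerateDataError, InsufficientDataError, StageDependencyError
from .prediction import loocv_svr, permutation_pvalue
from .synth import CohortConfig, simulate_cognition, simulate_timecourses

logger = logging.getLogger(__name__)

STAGES = ("simulate", "gica", "connectivity", "states", "stats", "predict")


@dataclass
class PipelineConfig:
    """All stage parameters plus toggles and paths.

    Defaults are the emulated protocol's stated values where it states
    them: window length 30 TRs, Gaussian taper sigma 3 TRs, step 1 TR,
    k scanned over 2..10 with 150 clustering replicates, alpha 0.05
    uncorrected.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    window_length: int = 30
    window_sigma: float = 3.0
    step: int = 1
    window_fisher_z: bool = True
    despike_mad: float = 3.5
    lowpass_hz: float = 0.15
    k_min: int = 2
    k_max: int = 10
    n_replicates: int = 150
    metric: str = "cityblock"
    alpha: float = 0.05
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    max_features: int | None = None
    n_permutations: int = 0  # 0 disables the permutation guard
    run_gica: bool = False
    run_predict: bool = True
    run_stats: bool = True
    nifti_paths: dict[str, str] | None = None
    mask_path: str | None = None
    seed: int = 0
    outdir: str = "results/pipeline"

    def parameter_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir")
        d["cohort"]["state_covariances"] = [
            np.asarray(c).round(12).tolist() for c in self.cohort.state_covariances
        ]
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        d["cohort"]["state_covariances"] = None  # rebuilt from n_states/strength defaults
        d["cohort"]["labels"] = list(self.cohort.labels)
        d["cohort"]["treatment_effects"] = [
            [list(p), float(b)] for p, b in self.cohort.treatment_effects
        ]
        d["cohort"]["prediction_couplings"] = [
            [list(p), float(b)] for p, b in self.cohort.prediction_couplings
        ]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        cohort = d.pop("cohort", None)
        cfg_kwargs = dict(d)
        if cohort is not None:
            if cohort.get("labels") is not None:
                cohort["labels"] = tuple(cohort["labels"])
            for key in ("treatment_effects", "prediction_couplings"):
                if cohort.get(key):
                    cohort[key] = [(tuple(p), float(b)) for p, b in cohort[key]]
            cfg_kwargs["cohort"] = CohortConfig(**cohort)
        return cls(**cfg_kwargs)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format="%.10g")
    return path


def stage_simulate(config: PipelineConfig, ctx: dict) -> list[Path]:
    """Generate the synthetic cohort: time courses, cognition, ground truth."""
    out = Path(config.outdir)
    tcs, truth = simulate_timecourses(config.cohort)
    ctx["timecourses"] = tcs
    ctx["truth"] = truth
    paths = tcs.save(out / "timecourses")

    # baseline sFNC features drive the planted cognition couplings
    baseline = _sfnc_features(tcs, config, session="pre")
    cognition, cog_truth = simulate_cognition(config.cohort, baseline)
    ctx["cognition"] = cognition
    ctx["cognition_truth"] = cog_truth
    paths.append(_write_csv(cognition.reset_index(), out / "cognition.csv"))
    truth.planted_betas = cog_truth.planted_betas
    truth.true_deltas = cog_truth.true_deltas
    truth.to_json(out / "ground_truth.json")
    paths.append(out / "ground_truth.json")
    return paths


def stage_gica(config: PipelineConfig, ctx: dict) -> list[Path]:
    """Optional volumetric entry point: decompose NIfTI data to time courses."""
    from .gica import GicaConfig, load_nifti_dataset, run_gica

    if not config.nifti_paths or not config.mask_path:
        raise StageDependencyError("gica stage enabled but nifti_paths/mask_path not set")
    dataset = load_nifti_dataset(config.nifti_paths, config.mask_path)
    comps, tcs = run_gica(dataset, GicaConfig(seed=config.seed))
    ctx["timecourses"] = tcs
    out = Path(config.outdir)
    paths = tcs.save(out / "timecourses")
    stab = pd.DataFrame(
        {"component": range(comps.n_components), "stability": comps.stability}
    )
    paths.append(_write_csv(stab, out / "gica_stability.csv"))
    return paths


def _clean_all(tcs: TimeCourseSet, config: PipelineConfig) -> TimeCourseSet:
    return tcs.map(
        lambda tc: conn.clean_timecourses(
            tc, despike_mad=config.despike_mad, lowpass_hz=config.lowpass_hz
        )
    )


def _sfnc_features(
    tcs: TimeCourseSet, config: PipelineConfig, session: str | None = None
) -> pd.DataFrame:
    """Subjects x pair-name frame of Fisher-z sFNC values (one session)."""
    rows = {}
    labels = None
    for tc in tcs if session is None else tcs.filter(session=session):
        cleaned = conn.clean_timecourses(
            tc, despike_mad=config.despike_mad, lowpass_hz=config.lowpass_hz
        )
        s = conn.static_fnc(cleaned)
        labels = s.labels
        rows[tc.subject] = s.pair_vector()
    return pd.DataFrame.from_dict(rows, orient="index", columns=pair_labels(labels))


def stage_connectivity(config: PipelineConfig, ctx: dict) -> list[Path]:
    """Clean time courses; compute sFNC, windowed dFNC, and variability."""
    if "timecourses" not in ctx:
        raise StageDependencyError("connectivity stage needs the simulate (or gica) stage")
    out = Path(config.outdir)
    cleaned = _clean_all(ctx["timecourses"], config)
    ctx["cleaned"] = cleaned
    taper = conn.build_taper(config.window_length, config.window_sigma)
    paths: list[Path] = []
    sfnc_rows = []
    wfncs = []
    var_rows = []
    plabels = None
    for tc in cleaned:
        s = conn.static_fnc(tc)
        plabels = pair_labels(s.labels)
        sfnc_rows.append(
            {"subject": tc.subject, "session": tc.session} | dict(zip(plabels, s.pair_vector()))
        )
        wf = conn.windowed_fnc(tc, taper, step=config.step, fisher_z=config.window_fisher_z)
        wfncs.append(wf)
        var_rows.append(
            {"subject": tc.subject, "session": tc.session}
            | dict(zip(plabels, conn.fnc_variability(wf)))
        )
    ctx["sfnc"] = pd.DataFrame(sfnc_rows)
    ctx["wfncs"] = wfncs
    ctx["variability"] = pd.DataFrame(var_rows)
    paths.append(_write_csv(ctx["sfnc"], out / "sfnc_wide.csv"))
    long = ctx["sfnc"].melt(
        id_vars=["subject", "session"], var_name="pair", value_name="z"
    )
    long[["i", "j"]] = long.pop("pair").str.split("-", expand=True)
    paths.append(_write_csv(long[["subject", "session", "i", "j", "z"]],
                            out / "sfnc_long.csv"))
    for session in ("pre", "post"):
        mean_vec = _session_wide(ctx["sfnc"], session).mean(axis=0).to_numpy()
        labels = list(next(iter(cleaned.filter(session=session))).labels)
        square = pd.DataFrame(
            pairs_to_matrix(mean_vec, len(labels)), index=labels, columns=labels
        )
        paths.append(_write_csv(square, out / f"sfnc_mean_{session}.csv", index=True))
    paths.append(_write_csv(ctx["variability"], out / "fnc_variability.csv"))
    wdir = out / "windowed"
    wdir.mkdir(parents=True, exist_ok=True)
    for wf in wfncs:
        p = wdir / f"sub-{wf.subject}_ses-{wf.session}_dfnc.csv"
        wf.to_csv(p)
        paths.append(p)
    return paths


def stage_states(config: PipelineConfig, ctx: dict) -> list[Path]:
    """Exemplar selection, elbow-k clustering, assignment, state metrics."""
    if "wfncs" not in ctx:
        raise StageDependencyError("states stage needs the connectivity stage")
    out = Path(config.outdir)
    exemplars = st.select_exemplars(ctx["wfncs"])
    model = st.choose_k_elbow(
        exemplars,
        k_range=range(config.k_min, config.k_max + 1),
        n_replicates=config.n_replicates,
        metric=config.metric,
        seed=config.seed,
    )
    sequences = st.assign_windows(ctx["wfncs"], model)
    ctx["state_model"] = model
    ctx["sequences"] = sequences
    model.to_json(out / "state_model.json")
    seq_rows = []
    for seq in sequences:
        for w, s in zip(seq.window_starts, seq.states):
            seq_rows.append(
                {"subject": seq.subject, "session": seq.session,
                 "window_start": int(w), "state": int(s)}
            )
    paths = [out / "state_model.json"]
    paths.append(_write_csv(pd.DataFrame(seq_rows), out / "state_sequences.csv"))
    metrics = st.metrics_table(sequences, model.k)
    ctx["state_metrics"] = metrics
    paths.append(_write_csv(metrics, out / "state_metrics.csv"))
    ctx["state_fnc"] = st.state_mean_fnc(ctx["wfncs"], sequences, model.k)
    paths.append(_write_csv(ctx["state_fnc"], out / "state_mean_fnc.csv"))
    return paths


def _paired_report(pre: pd.DataFrame, post: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Per-feature paired t tests tolerating NaN (incomplete) pairs."""
    rows = []
    common = sorted(set(pre.index) & set(post.index))
    pre, post = pre.loc[common], post.loc[common]
    for col in pre.columns:
        pair = pd.DataFrame({"pre": pre[col], "post": post[col]}).dropna()
        if len(pair) < 3:
            continue
        try:
            res = paired_compare(pair["pre"].to_numpy(), pair["post"].to_numpy(), str(col))
        except DegenerateDataError:
            continue
        rows.append(
            {"feature": res.feature, "t": res.t, "p": res.p, "n": res.n,
             "significant": res.p < alpha}
        )
    return pd.DataFrame(rows)


def _session_wide(df: pd.DataFrame, session: str) -> pd.DataFrame:
    return (
        df[df["session"] == session]
        .drop(columns=["session"])
        .set_index("subject")
        .sort_index()
    )


def stage_stats(config: PipelineConfig, ctx: dict) -> list[Path]:
    """Pre/post paired tests per feature family and brain-behavior correlations."""
    for need in ("sfnc", "variability"):
        if need not in ctx:
            raise StageDependencyError("stats stage needs the connectivity stage")
    out = Path(config.outdir)
    reports = {}
    reports["sfnc"] = _paired_report(
        _session_wide(ctx["sfnc"], "pre"), _session_wide(ctx["sfnc"], "post"), config.alpha
    )
    reports["variability"] = _paired_report(
        _session_wide(ctx["variability"], "pre"),
        _session_wide(ctx["variability"], "post"),
        config.alpha,
    )
    if "state_fnc" in ctx:
        sf = ctx["state_fnc"]
        for state in sorted(sf["state"].unique()):
            sub = sf[sf["state"] == state].drop(columns=["state"])
            reports[f"state{state + 1}"] = _paired_report(
                _session_wide(sub, "pre"), _session_wide(sub, "post"), config.alpha
            )
    if "state_metrics" in ctx:
        sm = ctx["state_metrics"].copy()
        sm["feature"] = sm.apply(
            lambda r: f"{r['metric']}"
            + (f"_s{int(r['state_from']) + 1}" if pd.notna(r["state_from"]) else "")
            + (f"_to_s{int(r['state_to']) + 1}" if pd.notna(r["state_to"]) else ""),
            axis=1,
        )
        wide = sm.pivot_table(index=["subject", "session"], columns="feature", values="value")
        pre = wide.xs("pre", level="session")
        post = wide.xs("post", level="session")
        reports["state_metrics"] = _paired_report(pre, post, config.alpha)
    tables = []
    for family, rep in reports.items():
        rep = rep.copy()
        rep.insert(0, "family", family)
        tables.append(rep)
    report = pd.concat(tables, ignore_index=True)
    ctx["group_differences"] = report
    paths = [_write_csv(report, out / "group_differences.csv")]

    if "cognition" in ctx:
        cog = ctx["cognition"]
        delta_cols = [c for c in cog.columns if c.endswith("_delta")]
        corr_rows = []
        for family in ("sfnc", "variability"):
            df = ctx[family]
            pre = _session_wide(df, "pre")
            post = _session_wide(df, "post")
            common = sorted(set(pre.index) & set(post.index) & set(cog.index))
            delta_feat = post.loc[common] - pre.loc[common]
            for dc in delta_cols:
                dy = cog.loc[common, dc].to_numpy()
                for col in delta_feat.columns:
                    try:
                        r, p = correlate_changes(delta_feat[col].to_numpy(), dy)
                    except DegenerateDataError:
                        continue
                    corr_rows.append(
                        {"family": family, "feature": col, "cognition": dc,
                         "r": r, "p": p, "significant": p < config.alpha}
                    )
        corr = pd.DataFrame(corr_rows)
        ctx["brain_behavior"] = corr
        paths.append(_write_csv(corr, out / "brain_behavior_correlations.csv"))
    return paths


def build_feature_families(config: PipelineConfig, ctx: dict) -> dict[str, pd.DataFrame]:
    """Baseline (pre-session) feature matrices per family for prediction."""
    families: dict[str, pd.DataFrame] = {
        "sfnc": _session_wide(ctx["sfnc"], "pre"),
        "variability": _session_wide(ctx["variability"], "pre"),
    }
    if "state_fnc" in ctx:
        sf = ctx["state_fnc"]
        for state in sorted(sf["state"].unique()):
            sub = sf[(sf["state"] == state) & (sf["session"] == "pre")].drop(
                columns=["state", "session"]
            )
            families[f"state{state + 1}"] = sub.set_index("subject").sort_index()
    return families


def stage_predict(config: PipelineConfig, ctx: dict) -> list[Path]:
    """LOOCV-SVR prediction of the cognitive change score per feature family."""
    if "cognition" not in ctx:
        raise StageDependencyError("predict stage needs a cognition table")
    if "sfnc" not in ctx:
        raise StageDependencyError("predict stage needs the connectivity stage")
    out = Path(config.outdir)
    cog = ctx["cognition"]
    delta_col = next(c for c in cog.columns if c.endswith("_delta"))
    results = {}
    for family, feats in build_feature_families(config, ctx).items():
        common = sorted(set(feats.index) & set(cog.index))
        feats = feats.loc[common].dropna(axis=1, how="any")
        y = cog.loc[common, delta_col].to_numpy()
        if len(common) < 4 or feats.shape[1] == 0:
            logger.info("predict: skipping family %s (too few complete subjects)", family)
            continue
        kwargs = dict(
            max_features=config.max_features,
            alpha=config.alpha,
            C=config.svr_c,
            epsilon=config.svr_epsilon,
        )
        try:
            if config.n_permutations:
                _, res = permutation_pvalue(
                    feats, y, n_perm=config.n_permutations, seed=config.seed, **kwargs
                )
            else:
                res = loocv_svr(feats, y, **kwargs)
        except Exception as exc:  # a family without signal is reported, not fatal
            logger.info("predict: family %s failed (%s)", family, exc)
            continue
        results[family] = res
    ctx["predictions"] = results
    payload = {fam: res.to_json_dict() for fam, res in results.items()}
    p = out / "predictions.json"
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(payload, sort_keys=True, indent=1))
    return [p]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "gica": stage_gica,
    "connectivity": stage_connectivity,
    "states": stage_states,
    "stats": stage_stats,
    "predict": stage_predict,
}


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Run enabled stages in order and write a run manifest.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    The manifest is deterministic for a fixed configuration.
    """
    enabled = list(stages) if stages is not None else [
        s
        for s in STAGES
        if not (
            (s == "gica" and not config.run_gica)
            or (s == "stats" and not config.run_stats)
            or (s == "predict" and not config.run_predict)
        )
    ]
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ctx: dict = {}
    manifest: dict = {
        "parameter_hash": config.parameter_hash(),
        "seed": config.seed,
        "cohort_seed": config.cohort.seed,
        "stages": {},
        "skipped": [s for s in STAGES if s not in enabled],
    }
    for stage in enabled:
        t0 = time.monotonic()
        paths = _STAGE_FUNCS[stage](config, ctx)
        logger.info("stage %-12s %6.1f s, %d outputs", stage, time.monotonic() - t0, len(paths))
        manifest["stages"][stage] = sorted(str(p.relative_to(out)) for p in paths)
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
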