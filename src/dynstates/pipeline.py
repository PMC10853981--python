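"""End-to-end orchestration with reproducible configuration and artifacts.

Three stages mirror a typical study: ``simulate`` writes a synthetic cohort
(parcel recordings + ground truth + clinical table) to disk, ``fit`` runs the
conditioning chain and the HMM and persists the model and posteriors, and
``metrics_stats`` turns posteriors and the clinical table into metric and
statistics tables.  Outputs are CSV/JSON plus ``.npy`` arrays with JSON
sidecars; every run writes its resolved configuration and a manifest with
SHA-256 hashes next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import clinical, synthetic
from .characterize import temporal_metrics
from .hmm import TDEHMM
from .prep import ParcelTimeSeries

log = logging.getLogger("dynstates")

__all__ = ["RunConfig", "simulate_cohort", "fit_model", "metrics_stats"]


class CohortConfig(BaseModel):
    n_subjects: int = Field(5, ge=1)
    n_parcels: int = Field(8, ge=4)
    n_samples: int = Field(30_000, ge=1000)
    stickiness: float = Field(0.95, gt=0, lt=1)
    noise_sd: float = Field(0.5, ge=0)
    rho_target: float = Field(0.6, ge=-1, le=1)
    missing_week12_frac: float = Field(8 / 37, ge=0, le=1)


class PrepConfig(BaseModel):
    fs: float = Field(250.0, gt=0)
    band_lo: float = Field(1.0, gt=0)
    band_hi: float = Field(40.0, gt=0)
    target_fs: float | None = None
    n_lags: int = Field(15, ge=1)
    n_components: int | None = None  # default: 2 x parcel count
    orthogonalize: bool = True

    @field_validator("band_hi")
    @classmethod
    def _band_order(cls, v, info):
        if "band_lo" in info.data and v <= info.data["band_lo"]:
            raise ValueError("band_hi must exceed band_lo")
        return v


class HMMConfig(BaseModel):
    n_states: int = Field(2, ge=1)
    max_iter: int = Field(50, ge=1)
    tol: float = Field(1e-6, gt=0)
    reg: float = Field(1e-6, ge=0)
    n_restarts: int = Field(3, ge=1)


class MetricsConfig(BaseModel):
    edge_visits: str = "exclude"
    fo_source: str = "viterbi"


class StatsConfig(BaseModel):
    quartile_method: str = "tukey"
    wilcoxon_zero: str = "drop"
    alpha: float = Field(0.05, gt=0, le=1)
    n_comparisons: int = Field(1, ge=1)


class RunConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    cohort: CohortConfig = CohortConfig()
    prep: PrepConfig = PrepConfig()
    hmm: HMMConfig = HMMConfig()
    metrics: MetricsConfig = MetricsConfig()
    stats: StatsConfig = StatsConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path) -> None:
    files = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {str(p.relative_to(outdir)): _sha256(p) for p in files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _prepare_outdir(outdir: str | Path, force: bool) -> Path:
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def simulate_cohort(config: RunConfig, outdir: str | Path, force: bool = False) -> Path:
    """Write a synthetic cohort: recordings, ground truth, clinical table."""
    outdir = _prepare_outdir(outdir, force)
    c = config.cohort
    truth = synthetic.default_truth(
        n_parcels=c.n_parcels, stickiness=c.stickiness, noise_sd=c.noise_sd,
        fs=config.prep.fs, seed=config.seed,
    )
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * c.n_subjects + 1)]
    metric = np.empty(c.n_subjects)
    for i in range(c.n_subjects):
        path = synthetic.simulate_markov_chain(truth, c.n_samples, seed=seeds[2 * i])
        ts = synthetic.synthesize_parcel_signals(path, truth, seed=seeds[2 * i + 1])
        sid = f"s{i:02d}"
        np.save(outdir / f"{sid}_parcels.npy", ts.data)
        np.save(outdir / f"{sid}_truepath.npy", path.states)
        (outdir / f"{sid}_parcels.json").write_text(json.dumps({
            "fs": ts.fs, "parcel_labels": ts.parcel_labels, "subject_id": sid,
            "session": "rest-week3", "group": "stroke-R",
        }))
        m = temporal_metrics(path.states, truth.fs, n_states=truth.n_states)
        metric[i] = m.loc[m["state"] == 1, "life_time_ms"].iloc[0]
    scores = synthetic.generate_clinical_scores(
        max(c.n_subjects, 3), metric if c.n_subjects >= 3 else np.resize(metric, 3),
        c.rho_target, seed=seeds[-1], missing_week12_frac=c.missing_week12_frac,
    ).iloc[: c.n_subjects]
    scores = scores.assign(subject_id=[f"s{i:02d}" for i in range(len(scores))])
    scores.to_csv(outdir / "clinical.csv", index=False)
    (outdir / "ground_truth.json").write_text(json.dumps({
        "transition_matrix": truth.transition_matrix.tolist(),
        "initial_dist": truth.initial_dist.tolist(),
        "state_amplitudes": truth.state_amplitudes.tolist(),
        "state_freqs": truth.state_freqs.tolist(),
        "noise_sd": truth.noise_sd, "fs": truth.fs, "seed": config.seed,
    }, indent=2))
    config.write(outdir / "config.yaml")
    _write_manifest(outdir)
    log.info("simulated %d subjects into %s", c.n_subjects, outdir)
    return outdir


def _load_recordings(datadir: Path) -> list[ParcelTimeSeries]:
    out = []
    for sidecar in sorted(datadir.glob("*_parcels.json")):
        meta = json.loads(sidecar.read_text())
        data = np.load(sidecar.with_suffix(".npy"))
        out.append(ParcelTimeSeries(
            data=data, fs=meta["fs"], parcel_labels=meta["parcel_labels"],
            subject_id=meta["subject_id"], session=meta.get("session", "rest-week3"),
            group=meta.get("group", "control"),
        ))
    if not out:
        raise FileNotFoundError(f"no *_parcels.json recordings under {datadir}")
    return out


def fit_model(
    config: RunConfig, datadir: str | Path, outdir: str | Path, force: bool = False
) -> Path:
    """Condition, embed, reduce and fit the HMM; persist model + posteriors.

    If a persisted model already exists in ``outdir`` (and ``force`` is not
    set) fitting is skipped and the cached model is kept.
    """
    datadir, outdir = Path(datadir), Path(outdir)
    model_file = outdir / "model.npz"
    if model_file.exists() and not force:
        log.info("model cache hit at %s; skipping fit", model_file)
        return outdir
    outdir.mkdir(parents=True, exist_ok=True)
    ts_list = _load_recordings(datadir)
    p = config.prep
    if config.hmm.n_states == 1:
        log.warning("fitting with a single state: dynamics will be degenerate")
    from .prep import default_lag_set

    model = TDEHMM.from_parcels(
        ts_list,
        n_states=config.hmm.n_states,
        band=(p.band_lo, p.band_hi),
        target_fs=p.target_fs,
        orthogonalize=p.orthogonalize,
        lag_set=default_lag_set(p.n_lags),
        n_components=p.n_components,
    )
    res = model.fit(
        max_iter=config.hmm.max_iter, tol=config.hmm.tol, reg=config.hmm.reg,
        seed=config.seed, n_restarts=config.hmm.n_restarts,
    )
    np.savez(
        model_file,
        initial_dist=res.params.initial_dist,
        transition_matrix=res.params.transition_matrix,
        covariances=res.params.covariances,
        means=res.params.means,
        boundaries=np.asarray(model.boundaries),
        fs=np.asarray(model.fs if model.fs else config.prep.fs),
    )
    (outdir / "subjects.json").write_text(json.dumps(model.subject_ids))
    for sid in model.subject_ids:
        gamma, path = res.subject_posterior(sid)
        np.save(outdir / f"{sid}_gamma.npy", gamma)
        np.save(outdir / f"{sid}_viterbi.npy", path)
    pd.DataFrame({"iteration": np.arange(len(res.loglik_trace)),
                  "loglik": res.loglik_trace}).to_csv(outdir / "loglik_trace.csv", index=False)
    config.write(outdir / "config.yaml")
    (outdir / "summary.txt").write_text(res.summary())
    _write_manifest(outdir)
    return outdir


def metrics_stats(
    config: RunConfig,
    outdir: str | Path,
    modeldir: str | Path | None = None,
    clinical_csv: str | Path | None = None,
) -> Path:
    """Emit metric tables and clinical statistics.

    With only a clinical table: demographic, MCID and subgroup summaries.
    With a fitted model as well: the per-subject temporal metrics plus the
    metric-score correlation analyses.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics_df = None
    if modeldir is not None:
        modeldir = Path(modeldir)
        subject_ids = json.loads((modeldir / "subjects.json").read_text())
        fs = float(np.load(modeldir / "model.npz")["fs"])
        frames = []
        for sid in subject_ids:
            path = np.load(modeldir / f"{sid}_viterbi.npy")
            df = temporal_metrics(path, fs, edge_visits=config.metrics.edge_visits)
            if config.metrics.fo_source == "gamma":
                gamma = np.load(modeldir / f"{sid}_gamma.npy")
                df["fractional_occupancy"] = gamma.mean(axis=0)[: len(df)]
            df.insert(0, "subject_id", sid)
            frames.append(df)
        metrics_df = pd.concat(frames, ignore_index=True)
        metrics_df.to_csv(outdir / "state_metrics.csv", index=False)
    summary: dict = {}
    results = []
    if clinical_csv is not None:
        rows = clinical.validate_cohort(pd.read_csv(clinical_csv))
        demo = {}
        for col in ("age", "days_post_stroke", "nihss_day0", "arat_w3", "fmue_w3"):
            med, q1, q3 = clinical.median_iqr(rows[col], method=config.stats.quartile_method)
            demo[col] = {"median": med, "q1": q1, "q3": q3, "n": int(rows[col].notna().sum())}
        arat_n, fmue_n, n_pairs = clinical.mcid_counts(rows)
        nr, rec = clinical.recovery_subgroups(rows)
        summary["demographics"] = demo
        summary["mcid"] = {"arat": arat_n, "fmue": fmue_n, "n_pairs": n_pairs}
        summary["subgroups"] = {"not_recovered": len(nr), "recovered": len(rec)}
        if metrics_df is not None and "subject_id" in rows:
            merged = rows.merge(
                metrics_df[metrics_df["state"] == 1], on="subject_id", how="inner"
            )
            orphans = sorted(set(rows.get("subject_id", [])) - set(metrics_df["subject_id"]))
            if len(merged) == 0:
                raise ValueError(f"clinical/subject ID mismatch; orphans: {orphans}")
            if orphans:
                log.warning("clinical rows without model subjects: %s", orphans)
            if len(merged) >= 3:
                r = clinical.spearman(merged["life_time_ms"], merged["arat_w3"])
                r.name = "state-1 life-time vs week-3 ARAT"
                results.append(r)
    if results:
        clinical.results_table(results).to_csv(outdir / "test_results.csv", index=False)
        summary["tests"] = [t.to_dict() for t in results]
    (outdir / "results_summary.json").write_text(json.dumps(summary, indent=2, default=float))
    config.write(outdir / "config.yaml")
    _write_manifest(outdir)
    return outdir
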