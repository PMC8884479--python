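"""End-to-end orchestration: atlas -> preprocess -> connectivity -> stats.

A :class:`RunConfig` (YAML-serialisable, round-trippable) describes one run:
where the subjects come from (``synthetic``, ``roi_tables`` or ``nifti``),
which preprocessing steps to apply, which transforms feed which analysis
level, and the statistical parameters (permutations, seed, FDR level,
covariates).  :func:`run_pipeline` executes all three analysis levels and
writes per-level group-contrast tables, the exploratory clinical-regression
table, a cohort summary and a deterministic JSON manifest; per-stage wall
times go to a separate ``timings.json`` so the result files are
byte-reproducible under a fixed config and seed.
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
import yaml

from . import __version__
from .atlas import AtlasParcellation, load_parcellation
from .connectivity import build_feature_tables
from .preprocess import (SubjectTimeSeries, bandpass_filter, detrend_linear,
                         drop_initial_volumes, load_roi_table)
from .stats import (clinical_regression, permutation_correction,
                    ttest_from_summary)
from .synthetic import ScoreModel, SyntheticCohortSpec, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "describe_cohort", "PipelineError"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML round-trippable)."""

    mode: str = "synthetic"                  # synthetic | roi_tables | nifti
    seed: int = 0
    out_dir: str = "rsfcnet_out"
    parcellation: str | None = None          # None -> packaged AAL-90 table
    # preprocessing (applied to roi_tables / nifti inputs; synthetic cohorts
    # arrive at stage "cleaned" already)
    drop_volumes: int = 10
    detrend: bool = True
    bandpass: bool = True
    low_hz: float = 0.01
    high_hz: float = 0.08
    tr: float = 0.8
    # transforms
    conversion: str = "exp_shift"
    # statistics
    permutations: int = 5000
    q: float = 0.05
    covariates: tuple[str, ...] = ("age", "sex", "education")
    scheme: str = "freedman-lane"
    regression_levels: tuple[str, ...] = ("network",)
    scales: tuple[str, ...] = ("updrs3", "mmse", "moca", "hama", "hamd")
    # input locations (roi_tables / nifti modes)
    roi_dir: str | None = None
    nifti_dir: str | None = None             # <subject_id>.nii[.gz] volumes
    labels: str | None = None                # shared 3D label volume
    phenotypes: str | None = None
    # synthetic-mode overrides for SyntheticCohortSpec fields
    synthetic: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        d["regression_levels"] = list(self.regression_levels)
        d["scales"] = list(self.scales)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text)
        for key in ("covariates", "regression_levels", "scales"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _preprocess_subject(ts: SubjectTimeSeries, cfg: RunConfig) -> SubjectTimeSeries:
    if ts.stage == "cleaned":
        return ts
    ts = drop_initial_volumes(ts, cfg.drop_volumes)
    if cfg.detrend:
        ts = detrend_linear(ts)
    if cfg.bandpass:
        ts = bandpass_filter(ts, cfg.low_hz, cfg.high_hz)
    else:
        ts = dataclasses.replace(ts, stage="cleaned")
    return ts


def _load_subjects(cfg: RunConfig, parc: AtlasParcellation
                   ) -> tuple[list[SubjectTimeSeries], pd.DataFrame]:
    if cfg.mode == "synthetic":
        overrides = dict(cfg.synthetic)
        if "scores" in overrides:
            overrides["scores"] = {
                k: (v if isinstance(v, ScoreModel) else ScoreModel(**v))
                for k, v in overrides["scores"].items()}
        if "deltas" in overrides:
            overrides["deltas"] = {
                (tuple(k.split("|")) if "|" in k else k): v
                for k, v in overrides["deltas"].items()}
        spec = SyntheticCohortSpec(seed=cfg.seed, **overrides)
        return simulate_cohort(spec, parc)
    if cfg.mode == "roi_tables":
        if cfg.roi_dir is None or cfg.phenotypes is None:
            raise PipelineError("roi_tables mode needs roi_dir and phenotypes")
        pheno = pd.read_csv(cfg.phenotypes, sep="\t").set_index("subject_id")
        subjects = []
        for sid in pheno.index:
            path = Path(cfg.roi_dir) / f"{sid}.tsv"
            if not path.exists():
                raise PipelineError(f"missing ROI table for subject {sid}: {path}")
            subjects.append(load_roi_table(path, tr=cfg.tr, subject_id=sid))
        return subjects, pheno
    if cfg.mode == "nifti":
        import nibabel as nib

        from .preprocess import extract_roi_timeseries
        if cfg.nifti_dir is None or cfg.labels is None or cfg.phenotypes is None:
            raise PipelineError(
                "nifti mode needs nifti_dir, labels and phenotypes")
        pheno = pd.read_csv(cfg.phenotypes, sep="\t").set_index("subject_id")
        lab_img = nib.load(cfg.labels)
        subjects = []
        for sid in pheno.index:
            matches = [p for ext in (".nii", ".nii.gz")
                       if (p := Path(cfg.nifti_dir) / f"{sid}{ext}").exists()]
            if not matches:
                raise PipelineError(f"missing 4D volume for subject {sid}")
            subjects.append(extract_roi_timeseries(
                nib.load(matches[0]), lab_img, parc, subject_id=sid))
        return subjects, pheno
    raise PipelineError(f"unsupported mode '{cfg.mode}'")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all three analysis levels and write the results bundle.

    Returns ``{"integrity": ..., "network": ..., "edge": ...,
    "regressions": ..., "cohort": ..., "manifest": ...}``; the same content
    is written under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    def _mark(stage: str) -> None:
        nonlocal t0
        timings[stage] = round(time.perf_counter() - t0, 3)
        t0 = time.perf_counter()

    parc = load_parcellation(cfg.parcellation)
    _mark("atlas")

    try:
        subjects, pheno = _load_subjects(cfg, parc)
    except Exception as exc:
        raise PipelineError(f"stage 'load': {exc}") from exc
    _mark("load")

    try:
        subjects = [_preprocess_subject(ts, cfg) for ts in subjects]
    except Exception as exc:
        raise PipelineError(f"stage 'preprocess': {exc}") from exc
    _mark("preprocess")

    try:
        tables = build_feature_tables(subjects, parc, conversion=cfg.conversion)
    except Exception as exc:
        raise PipelineError(f"stage 'connectivity': {exc}") from exc
    _mark("connectivity")

    pheno = pheno.loc[[ts.subject_id for ts in subjects]]
    group = (pheno["group"] == "PD").to_numpy(dtype=float)
    cov = (pheno[list(cfg.covariates)].to_numpy(dtype=float)
           if cfg.covariates else None)

    results: dict[str, pd.DataFrame] = {}
    for level, feats in tables.items():
        try:
            res = permutation_correction(
                feats, group, cov, B=cfg.permutations, seed=cfg.seed,
                q=cfg.q, scheme=cfg.scheme)
        except Exception as exc:
            raise PipelineError(f"stage 'stats:{level}': {exc}") from exc
        results[level] = res
        res.reset_index(names="feature").to_csv(
            out / f"{level}_stats.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
    _mark("stats")

    # exploratory clinical regressions: patients only, altered features only
    pd_mask = pheno["group"] == "PD"
    reg_frames = []
    for level in cfg.regression_levels:
        sig = results[level].index[results[level]["significant"]]
        if len(sig) == 0:
            continue
        feats = tables[level].loc[pd_mask.to_numpy(), list(sig)]
        scales = pheno.loc[pd_mask, [s for s in cfg.scales if s in pheno]]
        cov_pd = (pheno.loc[pd_mask, list(cfg.covariates)]
                  .to_numpy(dtype=float) if cfg.covariates else None)
        reg = clinical_regression(feats, scales, cov_pd)
        reg.insert(0, "level", level)
        reg_frames.append(reg)
    regressions = (pd.concat(reg_frames, ignore_index=True) if reg_frames
                   else pd.DataFrame(columns=["level", "feature", "scale",
                                              "slope", "t", "p", "n", "low_n"]))
    regressions.to_csv(out / "clinical_regressions.tsv", sep="\t",
                       index=False, float_format=_FLOAT_FMT)
    _mark("regression")

    cohort = describe_cohort(pheno)
    cohort.to_csv(out / "cohort_summary.tsv", sep="\t",
                  float_format=_FLOAT_FMT)

    import scipy
    import statsmodels
    manifest = {
        "package": "rsfcnet",
        "version": __version__,
        "config": yaml.safe_load(cfg.to_yaml()),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_subjects": {"PD": int(pd_mask.sum()),
                       "HC": int((~pd_mask).sum())},
        "n_features": {lvl: int(tables[lvl].shape[1]) for lvl in tables},
        "n_significant": {lvl: int(results[lvl]["significant"].sum())
                          for lvl in results},
        "software": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__,
                     "statsmodels": statsmodels.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    (out / "timings.json").write_text(json.dumps(timings, indent=2) + "\n")

    return {**results, "regressions": regressions, "cohort": cohort,
            "manifest": manifest}


def describe_cohort(pheno: pd.DataFrame,
                    variables: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Cohort-description table: per-group mean (SD) and Welch p per variable.

    Sex is reported as male/female counts with a chi-square p.  Variables
    absent from the table are skipped with a warning; variables observed in
    one group only (e.g. disease duration) get no p value.
    """
    if "group" not in pheno:
        raise PipelineError("phenotype table needs a 'group' column")
    if variables is None:
        candidates = ("age", "education", "duration_months", "hy_stage",
                      "updrs3", "mmse", "moca", "hama", "hamd")
        variables = tuple(v for v in candidates if v in pheno.columns)
    g_pd = pheno[pheno["group"] == "PD"]
    g_hc = pheno[pheno["group"] == "HC"]
    rows = {}
    if "sex" in pheno.columns:
        from scipy.stats import chi2_contingency
        counts = np.array([
            [(g_pd["sex"] == 1).sum(), (g_pd["sex"] == 0).sum()],
            [(g_hc["sex"] == 1).sum(), (g_hc["sex"] == 0).sum()]])
        try:
            p_sex = float(chi2_contingency(counts)[1])
        except ValueError:
            p_sex = np.nan
        rows["sex (M/F)"] = {
            "PD": f"{counts[0, 0]}/{counts[0, 1]}",
            "HC": f"{counts[1, 0]}/{counts[1, 1]}", "p": p_sex}
    for var in variables:
        if var not in pheno.columns:
            log.warning("variable %s absent from phenotype table; omitted", var)
            continue
        a, b = g_pd[var].dropna(), g_hc[var].dropna()
        entry = {
            "PD": f"{a.mean():.2f} ({a.std(ddof=1):.2f})" if len(a) else "-",
            "HC": f"{b.mean():.2f} ({b.std(ddof=1):.2f})" if len(b) else "-",
            "p": np.nan}
        if len(a) >= 2 and len(b) >= 2:
            res = ttest_from_summary(a.mean(), a.std(ddof=1), len(a),
                                     b.mean(), b.std(ddof=1), len(b))
            entry["p"] = res["p"]
        rows[var] = entry
    return pd.DataFrame(rows).T[["PD", "HC", "p"]]
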