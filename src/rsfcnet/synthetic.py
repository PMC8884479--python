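"""Synthetic resting-state cohorts with known connectivity structure.

The generator emulates the statistical structure the analysis assumes, at the
scale of the motivating study design (47 patients / 50 controls, 373 time
points at TR = 0.8 s):

* each subject's ROI series is stationary correlated Gaussian noise whose
  target correlation matrix is network-block-structured (``rho_within`` inside
  a network, ``rho_between`` elsewhere);
* the patient group's target matrix is the control matrix minus per-block
  ``deltas`` — reductions concentrated by default in the somatomotor, limbic,
  deep-gray-matter and visual networks, mirroring the expected disease
  pattern;
* demographic covariates are drawn per group and clinical scales are linear
  in selected realized network-FC features plus Gaussian noise, so score ~
  connectivity links are recoverable by regression.

Series are emitted at stage ``cleaned``: the generator models
post-preprocessed BOLD.  An optional AR(1) temporal autocorrelation knob
exists for sensitivity analyses (it inflates correlation-estimate variance
without changing the target correlations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import AtlasParcellation, load_parcellation
from .connectivity import correlation_matrix, fisher_z, network_fc
from .preprocess import SubjectTimeSeries

__all__ = ["ScoreModel", "SyntheticCohortSpec", "build_group_covariance",
           "simulate_cohort", "make_nifti_fixture", "SyntheticError"]

log = logging.getLogger(__name__)


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreModel:
    """Linear link from network-FC features to one clinical scale.

    ``score = intercept + sum_k weights[k] * (feature_k - center_k) + noise``
    where ``center_k`` is the expected Fisher-z of the feature's block under
    the group's target matrix (so the intercept is the group's mean score).
    ``pd_only=True`` restricts the link (and the scale itself) to patients.
    """

    intercept_pd: float
    intercept_hc: float | None
    noise_sd: float
    weights: dict[str, float] = field(default_factory=dict)
    pd_only: bool = False


def _default_scores() -> dict[str, ScoreModel]:
    # Means/SDs follow the emulated cohort; the nonzero weights plant the
    # cognition<->DGN and mood<->{SMN, LBN, VAN, DGN} links the regressions
    # should recover.
    return {
        "updrs3": ScoreModel(25.28, None, 12.0, {}, pd_only=True),
        "mmse": ScoreModel(24.41, 25.58, 3.0, {"intra_DGN": 60.0}),
        "moca": ScoreModel(18.36, 23.56, 4.0,
                           {"intra_DGN": 150.0, "inter_VAN_DGN": 100.0}),
        "hama": ScoreModel(11.70, 4.68, 5.0,
                           {"intra_SMN": -120.0, "intra_LBN": -120.0,
                            "intra_DGN": -120.0}),
        "hamd": ScoreModel(11.40, 4.84, 5.0,
                           {"intra_SMN": -120.0, "intra_VAN": -120.0,
                            "intra_DGN": -120.0}),
    }


def _default_deltas() -> dict[object, float]:
    return {
        "SMN": 0.12, "LBN": 0.12, "DGN": 0.15, "VSN": 0.08,
        ("VSN", "SMN"): 0.06, ("VSN", "LBN"): 0.06, ("VAN", "DGN"): 0.06,
    }


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of one synthetic cohort draw.

    Defaults mirror the emulated study: 47 patients, 50 controls, 373 time
    points at TR = 0.8 s, moderate within-network coupling, and connectivity
    reductions concentrated in SMN/LBN/DGN/VSN for the patient group.
    ``deltas`` maps a network name (intra block) or a pair of names (inter
    block) to the correlation reduction applied to patients.
    """

    n_pd: int = 47
    n_hc: int = 50
    n_timepoints: int = 373
    tr: float = 0.8
    rho_within: float = 0.4
    rho_between: float = 0.1
    deltas: dict = field(default_factory=_default_deltas)
    ar_coeff: float = 0.0
    age_pd: tuple[float, float] = (62.34, 11.41)
    age_hc: tuple[float, float] = (61.32, 5.60)
    male_prop_pd: float = 18 / 47
    male_prop_hc: float = 19 / 50
    education_pd: tuple[float, float] = (9.83, 3.44)
    education_hc: tuple[float, float] = (10.92, 3.18)
    duration_months: tuple[float, float] = (16.72, 12.08)
    hy_stage: tuple[float, float] = (1.60, 0.43)
    scores: dict[str, ScoreModel] = field(default_factory=_default_scores)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho_between <= self.rho_within < 1):
            raise SyntheticError(
                "need 0 <= rho_between <= rho_within < 1, got "
                f"({self.rho_between}, {self.rho_within})")
        if self.n_pd < 0 or self.n_hc < 0 or self.n_pd + self.n_hc < 1 \
                or self.n_timepoints < 2:
            raise SyntheticError("invalid cohort sizes")
        if not (0 <= self.ar_coeff < 1):
            raise SyntheticError("ar_coeff must be in [0, 1)")


def _block_value(spec: SyntheticCohortSpec, a: str, b: str) -> float:
    return spec.rho_within if a == b else spec.rho_between


def _delta_for(spec: SyntheticCohortSpec, a: str, b: str) -> float:
    if a == b:
        return float(spec.deltas.get(a, 0.0))
    for key in ((a, b), (b, a)):
        if key in spec.deltas:
            return float(spec.deltas[key])
    return 0.0


def build_group_covariance(spec: SyntheticCohortSpec, parc: AtlasParcellation,
                           group: str) -> np.ndarray:
    """Target correlation matrix for ``group`` ("PD" or "HC").

    Block-constant: ``rho_within`` inside each network, ``rho_between``
    elsewhere; the PD matrix subtracts ``spec.deltas`` from the named blocks.
    The result is repaired to the nearest positive semidefinite correlation
    matrix by eigenvalue clipping when needed; a repair that moves any entry
    by more than 0.05 is an error.
    """
    if group not in ("PD", "HC"):
        raise SyntheticError(f"group must be PD or HC, got {group!r}")
    labels = parc.table["network"].to_numpy()
    n = parc.n_nodes
    R = np.empty((n, n))
    nets = parc.networks
    idx = {net: np.flatnonzero(labels == net) for net in nets}
    for a in nets:
        for b in nets:
            val = _block_value(spec, a, b)
            if group == "PD":
                val -= _delta_for(spec, a, b)
            if not -1 < val < 1:
                raise SyntheticError(
                    f"delta on block ({a}, {b}) pushes correlation to {val}")
            R[np.ix_(idx[a], idx[b])] = val
    np.fill_diagonal(R, 1.0)

    w = np.linalg.eigvalsh(R)
    if w[0] < -1e-10:
        R_rep = _nearest_psd_correlation(R)
        dist = np.abs(R_rep - R).max()
        if dist > 0.05:
            raise SyntheticError(
                f"requested block structure is too far from PSD "
                f"(repair moved an entry by {dist:.3f} > 0.05)")
        log.info("PSD repair applied to %s target (max entry change %.2e)",
                 group, dist)
        R = R_rep
    return R


def _nearest_psd_correlation(R: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(R)
    R2 = (V * np.maximum(w, 0.0)) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2


def _mixing_root(R: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(R)
    return V * np.sqrt(np.maximum(w, 0.0))


def _draw_series(rng: np.random.Generator, T: int, L: np.ndarray,
                 ar: float) -> np.ndarray:
    n = L.shape[0]
    G = rng.standard_normal((T, n))
    if ar > 0:
        from scipy.signal import lfilter
        G = lfilter([np.sqrt(1 - ar ** 2)], [1.0, -ar], G, axis=0)
    return G @ L.T


def simulate_cohort(spec: SyntheticCohortSpec,
                    parc: AtlasParcellation | None = None,
                    ) -> tuple[list[SubjectTimeSeries], pd.DataFrame]:
    """Draw a full cohort: time series (stage ``cleaned``) + phenotype table.

    Bit-reproducible for a fixed ``spec.seed``.  Clinical scales are linear
    in each subject's realized network-FC features per ``spec.scores``.
    """
    parc = parc if parc is not None else load_parcellation()
    rng = np.random.default_rng(spec.seed)
    roots = {g: _mixing_root(build_group_covariance(spec, parc, g))
             for g in ("PD", "HC")}
    centers = {g: _expected_network_z(build_group_covariance(spec, parc, g),
                                      parc) for g in ("PD", "HC")}

    subjects: list[SubjectTimeSeries] = []
    pheno_rows: list[dict] = []
    groups = [("PD", spec.n_pd), ("HC", spec.n_hc)]
    for gname, count in groups:
        for i in range(count):
            sid = f"{gname.lower()}_{i + 1:03d}"
            data = _draw_series(rng, spec.n_timepoints, roots[gname],
                                spec.ar_coeff)
            ts = SubjectTimeSeries(subject_id=sid, data=data, tr=spec.tr,
                                   stage="cleaned", steps=("synthetic",))
            subjects.append(ts)

            if gname == "PD":
                age_m, age_s = spec.age_pd
                edu_m, edu_s = spec.education_pd
                male_p = spec.male_prop_pd
            else:
                age_m, age_s = spec.age_hc
                edu_m, edu_s = spec.education_hc
                male_p = spec.male_prop_hc
            row = {
                "subject_id": sid, "group": gname,
                "age": rng.normal(age_m, age_s),
                "sex": int(rng.random() < male_p),
                "education": max(0.0, rng.normal(edu_m, edu_s)),
            }
            if gname == "PD":
                row["duration_months"] = max(1.0, rng.normal(*spec.duration_months))
                row["hy_stage"] = float(np.clip(rng.normal(*spec.hy_stage), 1.0, 2.5))
            else:
                row["duration_months"] = np.nan
                row["hy_stage"] = np.nan

            needs_fc = any(
                m.weights and not (m.pd_only and gname == "HC")
                for m in spec.scores.values())
            feats = (network_fc(fisher_z(correlation_matrix(ts)), parc)
                     if needs_fc else None)
            for scale, model in spec.scores.items():
                if model.pd_only and gname == "HC":
                    row[scale] = np.nan
                    continue
                intercept = (model.intercept_pd if gname == "PD"
                             else model.intercept_hc)
                if intercept is None:
                    row[scale] = np.nan
                    continue
                val = intercept + rng.normal(0.0, model.noise_sd)
                for feat, wgt in model.weights.items():
                    val += wgt * (feats[feat] - centers[gname][feat])
                row[scale] = val
            pheno_rows.append(row)

    pheno = pd.DataFrame(pheno_rows).set_index("subject_id")
    return subjects, pheno


def _expected_network_z(R: np.ndarray, parc: AtlasParcellation) -> pd.Series:
    """Block means of atanh(R): the expected network features (noise-free)."""
    from .connectivity import ZMatrix, network_fc as _nfc
    z = np.arctanh(np.clip(R, -0.999999, 0.999999))
    np.fill_diagonal(z, 0.0)
    return _nfc(ZMatrix(subject_id="target", z=z, clip_r=0.999999), parc)


def make_nifti_fixture(parc: AtlasParcellation, T: int = 20,
                       voxels_per_roi: int = 1, noise_sd: float = 0.0,
                       tr: float = 0.8, seed: int = 0):
    """Tiny 4D NIfTI + label volume + ground-truth ROI series for round trips.

    Each region occupies ``voxels_per_roi`` voxels whose values equal the
    ground-truth series plus optional iid voxel noise; with ``noise_sd=0``
    extraction reproduces the truth exactly.
    """
    import nibabel as nib

    n = parc.n_nodes
    needed = n * voxels_per_roi
    if needed > 1000:
        raise SyntheticError(
            f"{needed} voxels needed but the fixture grid is capped at "
            "10 x 10 x 10")
    side = int(np.ceil(needed ** (1.0 / 3.0)))
    shape = (min(10, max(side, 2)),) * 3
    while int(np.prod(shape)) < needed:
        shape = tuple(min(10, s + 1) for s in shape)

    rng = np.random.default_rng(seed)
    truth = rng.standard_normal((T, n))
    labels = np.zeros(shape, dtype=np.int16)
    vol = np.zeros(shape + (T,))
    flat_idx = np.arange(int(np.prod(shape)))
    for j, node_id in enumerate(parc.node_ids):
        vox = flat_idx[j * voxels_per_roi:(j + 1) * voxels_per_roi]
        coords = np.unravel_index(vox, shape)
        labels[coords] = node_id
        series = truth[:, j][None, :] + rng.normal(
            0.0, noise_sd, size=(voxels_per_roi, T))
        vol[coords[0], coords[1], coords[2], :] = series

    affine = np.eye(4)
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((1.0, 1.0, 1.0, tr))
    lab_img = nib.Nifti1Image(labels, affine)
    return img, lab_img, truth
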