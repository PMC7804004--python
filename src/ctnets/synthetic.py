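"""Synthetic two-group regional cortical-thickness cohorts.

Generates subjects-by-regions thickness tables with a known interregional
correlation topology (equicorrelated modules, homolog coupling across
hemispheres, optional hub regions) and realistic nuisance structure (age,
sex, age-by-sex effects, a subject-level multiplicative global-thickness
factor, and Gaussian measurement noise).  The generative family is a
latent-Gaussian model: region values are drawn from a multivariate normal
with a prescribed correlation matrix and mapped onto the millimetre scale
of FreeSurfer cortical-thickness exports (regional means around 2.23 mm).

Because the downstream pipeline estimates Pearson correlations, the latent
correlation matrix is the ground truth every recovery test compares
against.  Measurement noise attenuates observed correlations by the factor
``sd^2 / (sd^2 + noise_sd^2)``; recovery tests either use a small
``noise_sd`` or account for the attenuation explicitly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, make_atlas, write_atlas

__all__ = [
    "CovarianceSpec",
    "CovariateModel",
    "ThicknessDataset",
    "build_target_correlation",
    "simulate_group",
    "simulate_study",
    "write_dataset",
    "read_dataset",
]

log = logging.getLogger(__name__)

#: Marginal scale of regional mean thickness (mm), matching typical
#: FreeSurfer Destrieux exports in elderly cohorts.
MEAN_THICKNESS_MM = 2.23
SD_THICKNESS_MM = 0.13

AGE_RANGE = (55.0, 90.0)
P_MALE = 0.63  # fraction of male subjects in the emulated cohort


@dataclass(frozen=True)
class CovarianceSpec:
    """Target interregional correlation structure.

    ``rho_within``/``rho_between`` set the equicorrelation inside/between
    ground-truth modules; homolog pairs get at least ``rho_homolog``; the
    optional ``hub_regions`` rows/columns get at least ``rho_hub``
    (elevated diffuse coupling, the covariance analogue of a connector
    hub).

    ``rho_diffuse`` scales a fixed signed random-factor layer
    (``rho_diffuse * U U^T`` with hemisphere-mirrored Gaussian loadings
    ``U``; see :func:`diffuse_loadings`).  It gives every region pair a
    distinct latent correlation, signed and zero-mean, emulating the
    continuous spread of empirical thickness covariance.  Because it is
    orthogonal to the global mean on average it survives mean-thickness
    regression, which is what keeps a realistic share of the residual
    correlations positive; a purely nonnegative equicorrelation model
    loses its common component to the mean-CT regressor.
    """

    n_regions: int = 148
    rho_within: float = 0.40
    rho_between: float = 0.10
    rho_homolog: float = 0.50
    module_sizes: tuple[int, ...] = (30, 33, 39, 22, 24)
    hub_regions: tuple[int, ...] = ()
    rho_hub: float = 0.0
    rho_diffuse: float = 0.35

    def __post_init__(self) -> None:
        for name in (
            "rho_within",
            "rho_between",
            "rho_homolog",
            "rho_hub",
            "rho_diffuse",
        ):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name}={v} must be in [0, 1)")
        if sum(self.module_sizes) != self.n_regions:
            raise ValueError("module_sizes must sum to n_regions")


@dataclass(frozen=True)
class CovariateModel:
    """Nuisance-effect model applied on top of the latent signal.

    Units: ``beta_age`` mm per year, ``beta_sex`` mm (offset for male
    subjects), ``beta_interaction`` mm per year for males; the global
    factor multiplies each subject's whole cortex and has the given mean
    and standard deviation; ``noise_sd`` is additive measurement noise in
    mm.
    """

    beta_age: float = -0.004
    beta_sex: float = 0.03
    beta_interaction: float = 0.0008
    global_scale_mean: float = 1.0
    global_scale_sd: float = 0.04
    noise_sd: float = 0.06

    def __post_init__(self) -> None:
        vals = asdict(self)
        if not all(np.isfinite(list(vals.values()))):
            raise ValueError("covariate parameters must be finite")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class ThicknessDataset:
    """Subjects-by-regions thickness matrix plus per-subject covariates."""

    thickness: np.ndarray  # (M, N) mm, strictly positive
    age: np.ndarray  # (M,) years
    sex: np.ndarray  # (M,) 0 = female, 1 = male
    group: np.ndarray  # (M,) group labels
    atlas: RegionAtlas
    subject_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        m, n = self.thickness.shape
        if self.subject_id is None:
            self.subject_id = np.array([f"sub-{i:04d}" for i in range(m)])
        if n != self.atlas.n_regions:
            raise ValueError("thickness column count must equal atlas size")
        if m < 3:
            raise ValueError("need at least 3 subjects")
        if not np.all(np.isfinite(self.thickness)):
            raise ValueError("thickness contains non-finite values")
        if np.any(self.thickness <= 0):
            raise ValueError("thickness must be strictly positive")

    @property
    def n_subjects(self) -> int:
        return self.thickness.shape[0]

    @property
    def n_regions(self) -> int:
        return self.thickness.shape[1]

    def subset(self, idx: np.ndarray, relabel: bool = True) -> "ThicknessDataset":
        """Row subset/resample; used by the bootstrap."""
        sid = self.subject_id[idx]
        return ThicknessDataset(
            thickness=self.thickness[idx],
            age=self.age[idx],
            sex=self.sex[idx],
            group=self.group[idx],
            atlas=self.atlas,
            subject_id=sid,
        )


#: Internal seed for the diffuse-loading pattern.  Fixed: the pattern is a
#: property of the generative family (like the block layout), not of any
#: particular simulated cohort, and must be identical across groups so it
#: can never masquerade as a group difference.
_DIFFUSE_SEED = 404733

def diffuse_loadings(atlas: RegionAtlas, n_factors: int = 8) -> np.ndarray:
    """Hemisphere-mirrored signed factor loadings, (N, n_factors).

    A fixed random Gaussian loading pattern (unit-variance rows in
    expectation, deterministic seed) emulating the diffuse, signed,
    continuously-varying part of empirical thickness covariance: every
    region pair receives a distinct latent correlation rather than one of
    a few equicorrelation levels.  Homolog regions share loadings, so the
    factors also feed left-right homolog coupling; the loadings are
    zero-mean, so this structure largely survives mean-thickness
    regression (unlike any uniform positive background).
    """
    half = atlas.n_regions // 2
    rng = np.random.default_rng(_DIFFUSE_SEED)
    base = rng.standard_normal((half, n_factors))
    base /= np.linalg.norm(base, axis=1, keepdims=True)  # unit rows
    u = np.empty((atlas.n_regions, n_factors))
    left = atlas.hemisphere == "left"
    u[left] = base
    u[~left] = base
    return u


def build_target_correlation(
    spec: CovarianceSpec, atlas: RegionAtlas
) -> np.ndarray:
    """Assemble the target correlation matrix and repair it to PSD.

    Entries are ``rho_within`` inside a ground-truth module and
    ``rho_between`` elsewhere, plus the signed gradient mode; homolog
    pairs and hub rows/columns are raised (never lowered) to
    ``rho_homolog`` / ``rho_hub``.  The result is projected to the
    nearest positive semi-definite matrix by clipping negative
    eigenvalues at zero and renormalizing the diagonal to one.  The
    maximum entry change caused by the projection is logged, with a
    warning when it exceeds 0.1.
    """
    n = spec.n_regions
    if atlas.n_regions != n:
        raise ValueError("atlas size must match spec.n_regions")
    mod = atlas.true_module
    same = mod[:, None] == mod[None, :]
    r = np.where(same, spec.rho_within, spec.rho_between).astype(float)
    if spec.rho_diffuse > 0:
        # unit-norm rows: adds exactly rho_diffuse to the diagonal, so the
        # assembled matrix is PSD with unit diagonal whenever
        # rho_within + rho_diffuse <= 1 (before the homolog/hub overrides)
        u = diffuse_loadings(atlas)
        r = r + spec.rho_diffuse * (u @ u.T)
    # homolog coupling: raise, never lower
    pairs = atlas.homolog_pairs
    for i, j in pairs:
        v = max(r[i, j], spec.rho_homolog)
        r[i, j] = r[j, i] = v
    if spec.hub_regions and spec.rho_hub > 0:
        # additive rank-1 hub factor (PSD-safe): hubs load 1, the rest 0.4,
        # so hub rows gain diffuse coupling to the whole cortex
        v = np.full(n, 0.4)
        v[np.asarray(spec.hub_regions, dtype=int)] = 1.0
        r = r + spec.rho_hub * (np.outer(v, v) - np.diag(v**2))
    np.clip(r, -0.99, 0.99, out=r)
    np.fill_diagonal(r, 1.0)

    w, v = np.linalg.eigh(r)
    if w.min() >= -1e-12:
        return r
    w_clip = np.clip(w, 0.0, None)
    repaired = (v * w_clip) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    dev = np.abs(repaired - r).max()
    if dev > 0.1:
        log.warning("PSD projection changed entries by up to %.3f", dev)
    else:
        log.info("PSD projection deviation %.2e", dev)
    return repaired


def _correlation_factor(r: np.ndarray) -> np.ndarray:
    """Factor L with L L^T = r, tolerant of semi-definite inputs."""
    w, v = np.linalg.eigh(r)
    if w.min() < -1e-8:
        raise ValueError("target correlation matrix is not PSD after projection")
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_group(
    spec: CovarianceSpec,
    cov_model: CovariateModel,
    m_subjects: int,
    seed: int,
    atlas: RegionAtlas | None = None,
    group: str = "group",
) -> ThicknessDataset:
    """Draw one group's thickness table.

    Per subject ``s`` and region ``r``::

        T[s, r] = (mu + sd * Z[s, r] + b_age*age_s + b_sex*sex_s
                   + b_int*age_s*sex_s) * g_s + eps[s, r]

    with ``Z`` multivariate normal under the target correlation, ``g_s``
    the subject's global-thickness factor and ``eps`` measurement noise.
    ``mu`` absorbs an offset so the realized grand mean sits at 2.23 mm
    despite the age effect.  Deterministic given ``seed``.
    """
    if m_subjects < 3:
        raise ValueError("need at least 3 subjects")
    if atlas is None:
        atlas = make_atlas(spec.n_regions, list(spec.module_sizes))
    target = build_target_correlation(spec, atlas)
    L = _correlation_factor(target)

    rng = np.random.default_rng(seed)
    age = rng.uniform(*AGE_RANGE, size=m_subjects)
    sex = (rng.random(m_subjects) < P_MALE).astype(int)
    z = rng.standard_normal((m_subjects, spec.n_regions)) @ L.T
    g = rng.normal(
        cov_model.global_scale_mean, cov_model.global_scale_sd, m_subjects
    )
    eps = rng.normal(0.0, cov_model.noise_sd, (m_subjects, spec.n_regions))

    mean_age = sum(AGE_RANGE) / 2.0
    mu = MEAN_THICKNESS_MM - cov_model.beta_age * mean_age
    covar = (
        cov_model.beta_age * age
        + cov_model.beta_sex * sex
        + cov_model.beta_interaction * age * sex
    )
    thickness = (mu + SD_THICKNESS_MM * z + covar[:, None]) * g[:, None] + eps
    return ThicknessDataset(
        thickness=thickness,
        age=age,
        sex=sex,
        group=np.full(m_subjects, group, dtype=object),
        atlas=atlas,
    )


def simulate_study(
    spec_a: CovarianceSpec,
    spec_b: CovarianceSpec,
    cov_model: CovariateModel,
    m_a: int,
    m_b: int,
    seed: int,
    labels: tuple[str, str] = ("carrier", "noncarrier"),
) -> ThicknessDataset:
    """Two-group cohort in one table (groups share the atlas and model)."""
    if spec_a.n_regions != spec_b.n_regions:
        raise ValueError("groups must share the region count")
    if spec_a.module_sizes != spec_b.module_sizes:
        raise ValueError("groups must share the module layout")
    atlas = make_atlas(spec_a.n_regions, list(spec_a.module_sizes))
    ss = np.random.SeedSequence(seed)
    s_a, s_b = ss.spawn(2)
    da = simulate_group(
        spec_a, cov_model, m_a, _sub_seed(s_a), atlas=atlas, group=labels[0]
    )
    db = simulate_group(
        spec_b, cov_model, m_b, _sub_seed(s_b), atlas=atlas, group=labels[1]
    )
    return ThicknessDataset(
        thickness=np.vstack([da.thickness, db.thickness]),
        age=np.concatenate([da.age, db.age]),
        sex=np.concatenate([da.sex, db.sex]),
        group=np.concatenate([da.group, db.group]),
        atlas=atlas,
        subject_id=np.array(
            [f"sub-{i:04d}" for i in range(m_a + m_b)], dtype=object
        ),
    )


def _sub_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0])


# ---------------------------------------------------------------------------
# On-disk formats: TSV dataset, CSV atlas, JSON ground truth.

def write_dataset(
    data: ThicknessDataset,
    dataset_path,
    atlas_path=None,
    truth_path=None,
    truth: dict | None = None,
) -> None:
    """Write the cohort as a tab-separated table (plus atlas/truth files).

    Columns: ``subject_id, age, sex, group, <region names...>``.
    """
    df = pd.DataFrame(
        {
            "subject_id": data.subject_id,
            "age": data.age,
            "sex": data.sex,
            "group": data.group,
        }
    )
    thick = pd.DataFrame(data.thickness, columns=list(data.atlas.names))
    pd.concat([df, thick], axis=1).to_csv(
        dataset_path, sep="\t", index=False, float_format="%.6f"
    )
    if atlas_path is not None:
        write_atlas(data.atlas, atlas_path)
    if truth_path is not None and truth is not None:
        Path(truth_path).write_text(json.dumps(truth, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray, tuple)):
        return list(o)
    raise TypeError(type(o).__name__)


def read_dataset(dataset_path, atlas: RegionAtlas) -> ThicknessDataset:
    """Read a TSV cohort written by :func:`write_dataset`.

    Region columns are taken in atlas order; a missing region column is an
    error.
    """
    df = pd.read_csv(dataset_path, sep="\t")
    missing = [n for n in atlas.names if n not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing region columns: {missing[:5]} ...")
    return ThicknessDataset(
        thickness=df[list(atlas.names)].to_numpy(dtype=float),
        age=df["age"].to_numpy(dtype=float),
        sex=df["sex"].to_numpy(dtype=int),
        group=df["group"].to_numpy(dtype=object),
        atlas=atlas,
        subject_id=df["subject_id"].to_numpy(dtype=object),
    )
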