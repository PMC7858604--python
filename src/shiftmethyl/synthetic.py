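"""Synthetic paired methylome cohorts with known ground truth.

Every generator is deterministic given its seed.  Randomness is organised by
stream splitting: one root ``numpy.random.SeedSequence`` is spawned into
named child streams (``cohort``, ``methylome``, ``symptoms``,
``annotation``), so each generator draws from an independent, reproducible
sub-stream.  :func:`simulate_dataset` wires the streams together from a
single root seed; the individual generators also accept a plain integer
seed when used stand-alone.

The planted data-generating process mirrors the analysis model: per-probe
group baselines, a vacation-minus-work effect planted in a configurable
fraction of probes per group (predominantly positive, i.e. methylation
gained on vacation), optional nuisance-covariate effects, an optional
per-subject random intercept, and iid Gaussian noise.  Designated "recovery
probes" additionally receive a subject-specific vacation shift proportional
to a latent recovery degree, which also drives the questionnaire answers so
that symptom change and methylation change are correlated with a
configurable strength.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .pathways import GeneSetLibrary

__all__ = [
    "CohortConfig",
    "EffectConfig",
    "LibraryConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_methylome",
    "generate_symptoms",
    "generate_annotation_and_gmt",
    "simulate_dataset",
]

#: M-value shift per unit of latent recovery degree at designated probes.
RECOVERY_LINK_SCALE = 1.0

#: Linear scale from the latent symptom target to the Likert change score.
_SYMPTOM_SCALE = 2.0

_STREAMS = ("cohort", "methylome", "symptoms", "annotation")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition; defaults mirror a 21 SWD + 11 control design."""

    n_swd: int = 21
    n_control: int = 11
    age_mean_swd: float = 41.0
    age_sd_swd: float = 8.9
    age_mean_ctrl: float = 49.2
    age_sd_ctrl: float = 9.1
    frac_female: float = 0.22
    n_plates: int = 2
    frac_smokers: float = 0.3
    frac_alcohol: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_swd < 1 or self.n_control < 1:
            raise ConfigurationError("n_swd and n_control must be >= 1")
        if self.n_plates < 1:
            raise ConfigurationError("n_plates must be >= 1")
        for name in ("frac_female", "frac_smokers", "frac_alcohol"):
            _check_fraction(name, getattr(self, name))


@dataclass(frozen=True)
class EffectConfig:
    """Planted vacation effects and noise structure of the methylome."""

    n_probes: int = 1000
    frac_affected_swd: float = 0.1
    frac_affected_ctrl: float = 0.0
    frac_positive_swd: float = 0.78
    frac_positive_ctrl: float = 0.5
    effect_size_mean: float = 1.0
    effect_size_sd: float = 0.2
    noise_sd: float = 0.5
    subject_intercept_sd: float = 0.0
    covariate_effect_scale: float = 0.0
    recovery_probe_ids: tuple = ()
    recovery_link_strength: float = 0.0
    affected_probes_swd: tuple | None = None  # explicit override of the random draw
    affected_probes_ctrl: tuple | None = None

    def __post_init__(self):
        if self.n_probes < 1:
            raise ConfigurationError("n_probes must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.subject_intercept_sd < 0 or self.covariate_effect_scale < 0:
            raise ConfigurationError("scale parameters must be >= 0")
        for name in (
            "frac_affected_swd", "frac_affected_ctrl",
            "frac_positive_swd", "frac_positive_ctrl",
            "recovery_link_strength",
        ):
            _check_fraction(name, getattr(self, name))


@dataclass(frozen=True)
class LibraryConfig:
    """Shape of the synthetic probe annotation and gene-set library."""

    n_genes: int = 100
    n_pathways: int = 10
    probes_per_gene: int = 5
    genes_per_pathway: int = 15

    def __post_init__(self):
        for name in ("n_genes", "n_pathways", "probes_per_gene", "genes_per_pathway"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth written by :func:`generate_methylome`."""

    probe_ids: np.ndarray
    beta_vacation_swd: np.ndarray
    beta_vacation_ctrl: np.ndarray
    affected_swd: np.ndarray
    affected_ctrl: np.ndarray
    recovery_degree: "pd.Series"  # per subject
    recovery_probe_ids: tuple

    def to_dict(self) -> dict:
        return {
            "probe_ids": [str(p) for p in self.probe_ids],
            "beta_vacation_swd": [float(b) for b in self.beta_vacation_swd],
            "beta_vacation_ctrl": [float(b) for b in self.beta_vacation_ctrl],
            "affected_swd": [bool(a) for a in self.affected_swd],
            "affected_ctrl": [bool(a) for a in self.affected_ctrl],
            "recovery_degree": {str(k): float(v) for k, v in self.recovery_degree.items()},
            "recovery_probe_ids": [str(p) for p in self.recovery_probe_ids],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SyntheticTruth":
        return cls(
            probe_ids=np.asarray(payload["probe_ids"], dtype=object),
            beta_vacation_swd=np.asarray(payload["beta_vacation_swd"], dtype=float),
            beta_vacation_ctrl=np.asarray(payload["beta_vacation_ctrl"], dtype=float),
            affected_swd=np.asarray(payload["affected_swd"], dtype=bool),
            affected_ctrl=np.asarray(payload["affected_ctrl"], dtype=bool),
            recovery_degree=pd.Series(payload["recovery_degree"], dtype=float),
            recovery_probe_ids=tuple(payload["recovery_probe_ids"]),
        )


def probe_id(index: int) -> str:
    """Deterministic synthetic probe identifier for a 0-based probe index."""
    return f"cg{index:08d}"


def split_streams(seed: int) -> dict:
    """Spawn the named child generators from one root seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate a paired sample sheet: two rows (work, vacation) per subject.

    Columns: ``sample_id, subject, group, period, age, sex, plate, alcohol,
    smoking, answer_a, answer_b`` — the questionnaire answers are left
    missing until :func:`generate_symptoms` fills them in.  Subject counts,
    age distributions and covariate frequencies follow the config.  Exact
    covariate counts use the floor rule ``floor(frac * n)`` so they are
    testable.
    """
    rng = rng if rng is not None else split_streams(config.seed)["cohort"]
    rows = []
    specs = (
        ("swd", config.n_swd, config.age_mean_swd, config.age_sd_swd, "SWD"),
        ("control", config.n_control, config.age_mean_ctrl, config.age_sd_ctrl, "CTRL"),
    )
    n_total = config.n_swd + config.n_control

    def _flag_vector(frac: float) -> np.ndarray:
        n_true = math.floor(frac * n_total)
        flags = np.zeros(n_total, dtype=bool)
        flags[rng.choice(n_total, size=n_true, replace=False)] = True
        return flags

    female = _flag_vector(config.frac_female)
    smoker = _flag_vector(config.frac_smokers)
    alcohol = _flag_vector(config.frac_alcohol)

    i = 0
    for group, n, age_mean, age_sd, prefix in specs:
        ages = rng.normal(age_mean, age_sd, size=n)
        for k in range(n):
            subject = f"{prefix}{k + 1:03d}"
            sex = "F" if female[i] else "M"
            subj_smoking = int(smoker[i])
            subj_alcohol = int(alcohol[i])
            for period in ("work", "vacation"):
                # plate may differ between the two draws of a subject
                plate = f"P{rng.integers(config.n_plates) + 1}"
                rows.append({
                    "sample_id": f"{subject}_{period}",
                    "subject": subject,
                    "group": group,
                    "period": period,
                    "age": round(float(ages[k]), 1),
                    "sex": sex,
                    "plate": plate,
                    "alcohol": subj_alcohol,
                    "smoking": subj_smoking,
                    "answer_a": np.nan,
                    "answer_b": np.nan,
                })
            i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def _select_affected(
    rng: np.random.Generator,
    n_probes: int,
    frac: float,
    explicit: Sequence | None,
    probe_ids: np.ndarray,
) -> np.ndarray:
    flags = np.zeros(n_probes, dtype=bool)
    if explicit is not None:
        id_to_idx = {str(p): j for j, p in enumerate(probe_ids)}
        for item in explicit:
            idx = item if isinstance(item, (int, np.integer)) else id_to_idx.get(str(item))
            if idx is None or not 0 <= int(idx) < n_probes:
                raise ConfigurationError(f"unknown affected probe {item!r}")
            flags[int(idx)] = True
        return flags
    n_affected = math.floor(frac * n_probes)
    if n_affected:
        flags[rng.choice(n_probes, size=n_affected, replace=False)] = True
    return flags


def _planted_betas(
    rng: np.random.Generator,
    flags: np.ndarray,
    frac_positive: float,
    mean: float,
    sd: float,
) -> np.ndarray:
    beta = np.zeros(flags.size)
    affected = np.nonzero(flags)[0]
    if affected.size == 0:
        return beta
    order = rng.permutation(affected)
    n_pos = math.floor(frac_positive * affected.size)
    signs = np.empty(affected.size)
    signs[:n_pos] = 1.0
    signs[n_pos:] = -1.0
    magnitudes = rng.normal(mean, sd, size=affected.size)
    beta[order] = signs * magnitudes
    return beta


def generate_methylome(
    sheet: pd.DataFrame,
    effects: EffectConfig,
    seed: int | np.random.Generator = 0,
) -> tuple:
    """Generate an M-value matrix for a paired sample sheet, plus its truth.

    Returns ``(matrix, truth)`` where ``matrix`` is probes x samples with
    columns in sheet order.
    """
    rng = _rng(seed)
    n_probes = effects.n_probes
    probe_ids = np.array([probe_id(j) for j in range(n_probes)], dtype=object)
    subjects = list(dict.fromkeys(sheet["subject"]))
    n_subjects = len(subjects)
    subj_index = {s: k for k, s in enumerate(subjects)}

    baseline = rng.normal(0.0, 2.0, size=n_probes)
    affected_swd = _select_affected(
        rng, n_probes, effects.frac_affected_swd, effects.affected_probes_swd, probe_ids)
    affected_ctrl = _select_affected(
        rng, n_probes, effects.frac_affected_ctrl, effects.affected_probes_ctrl, probe_ids)
    beta_swd = _planted_betas(
        rng, affected_swd, effects.frac_positive_swd,
        effects.effect_size_mean, effects.effect_size_sd)
    beta_ctrl = _planted_betas(
        rng, affected_ctrl, effects.frac_positive_ctrl,
        effects.effect_size_mean, effects.effect_size_sd)

    recovery_degree = pd.Series(rng.normal(0.0, 1.0, size=n_subjects), index=subjects)
    recovery_idx = []
    id_to_idx = {str(p): j for j, p in enumerate(probe_ids)}
    for item in effects.recovery_probe_ids:
        idx = item if isinstance(item, (int, np.integer)) else id_to_idx.get(str(item))
        if idx is None or not 0 <= int(idx) < n_probes:
            raise ConfigurationError(f"unknown recovery probe {item!r}")
        recovery_idx.append(int(idx))

    cov_matrix = None
    cov_coefs = None
    if effects.covariate_effect_scale > 0:
        age = sheet["age"].to_numpy(dtype=float)
        cov_matrix = np.column_stack([
            age - age.mean(),
            (sheet["sex"].astype(str) == "M").to_numpy(dtype=float),
            pd.factorize(sheet["plate"].astype(str))[0].astype(float),
            sheet["alcohol"].to_numpy(dtype=float),
            sheet["smoking"].to_numpy(dtype=float),
        ])
        cov_coefs = rng.normal(0.0, effects.covariate_effect_scale,
                               size=(cov_matrix.shape[1], n_probes))

    subject_intercepts = None
    if effects.subject_intercept_sd > 0:
        subject_intercepts = rng.normal(
            0.0, effects.subject_intercept_sd, size=(n_subjects, n_probes))

    n_samples = sheet.shape[0]
    is_vacation = (sheet["period"].astype(str) == "vacation").to_numpy()
    is_control = (sheet["group"].astype(str) == "control").to_numpy()
    subj_of_sample = np.array([subj_index[s] for s in sheet["subject"]])

    Y = np.tile(baseline, (n_samples, 1))
    group_beta = np.where(is_control[:, None], beta_ctrl[None, :], beta_swd[None, :])
    Y += is_vacation[:, None] * group_beta
    if cov_matrix is not None:
        Y += cov_matrix @ cov_coefs
    if subject_intercepts is not None:
        Y += subject_intercepts[subj_of_sample]
    if recovery_idx:
        shift = RECOVERY_LINK_SCALE * recovery_degree.to_numpy()[subj_of_sample]
        for j in recovery_idx:
            Y[is_vacation, j] += shift[is_vacation]
    Y += rng.normal(0.0, effects.noise_sd, size=Y.shape)

    matrix = pd.DataFrame(
        Y.T, index=pd.Index(probe_ids, name="probe_id"),
        columns=sheet["sample_id"].astype(str).to_list(),
    )
    truth = SyntheticTruth(
        probe_ids=probe_ids,
        beta_vacation_swd=beta_swd,
        beta_vacation_ctrl=beta_ctrl,
        affected_swd=affected_swd,
        affected_ctrl=affected_ctrl,
        recovery_degree=recovery_degree,
        recovery_probe_ids=tuple(probe_ids[j] for j in recovery_idx),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# symptoms
# ---------------------------------------------------------------------------

def generate_symptoms(
    sheet: pd.DataFrame,
    truth: SyntheticTruth,
    effects: EffectConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Fill Likert answers A and B (1-5) into a copy of the sample sheet.

    The symptom-change score ``(A+B)_work - (A+B)_vacation`` is driven by the
    latent recovery degree with correlation ~ ``recovery_link_strength``;
    since the same degree shifts vacation methylation *up* at the designated
    probes, the methylation change (work - vacation) correlates negatively
    with the symptom change.  Answers are clamped to [1, 5] after the linear
    link, which mildly attenuates the correlation at extreme scores.
    """
    rng = _rng(seed)
    s = effects.recovery_link_strength
    degrees = truth.recovery_degree
    z = degrees - degrees.mean()
    sd = z.std(ddof=0)
    if sd > 0:
        z = z / sd
    out = sheet.copy()
    for subject in degrees.index:
        eps = rng.normal()
        target = s * float(z[subject]) + math.sqrt(max(0.0, 1.0 - s * s)) * eps
        change = int(np.rint(_SYMPTOM_SCALE * target))
        d_a = change // 2
        d_b = change - d_a
        a_vac, b_vac = 3, 3
        a_work = int(np.clip(a_vac + d_a, 1, 5))
        b_work = int(np.clip(b_vac + d_b, 1, 5))
        for period, a, b in (("work", a_work, b_work), ("vacation", a_vac, b_vac)):
            mask = (out["subject"] == subject) & (out["period"] == period)
            out.loc[mask, "answer_a"] = a
            out.loc[mask, "answer_b"] = b
    return out


# ---------------------------------------------------------------------------
# annotation and gene sets
# ---------------------------------------------------------------------------

def generate_annotation_and_gmt(
    n_probes: int,
    n_genes: int,
    n_pathways: int,
    probes_per_gene: int,
    genes_per_pathway: int,
    seed: int | np.random.Generator = 0,
) -> tuple:
    """Generate a probe annotation table and a matching gene-set library.

    Gene *g* covers ``probes_per_gene`` consecutive probes starting at
    ``g * probes_per_gene`` (wrapping around the probe axis, so probes may
    map to several genes when coverage exceeds the probe count); leftover
    probes map to no gene.  Pathways draw ``genes_per_pathway`` distinct
    genes at random.

    Returns ``(annotation, library)`` where ``annotation`` has columns
    ``probe_id, chr, pos_1based, gene_symbols`` (semicolon-joined).
    """
    for name, value in (
        ("n_probes", n_probes), ("n_genes", n_genes), ("n_pathways", n_pathways),
        ("probes_per_gene", probes_per_gene), ("genes_per_pathway", genes_per_pathway),
    ):
        if value < 1:
            raise ConfigurationError(f"{name} must be >= 1")
    if genes_per_pathway > n_genes:
        raise ConfigurationError("genes_per_pathway cannot exceed n_genes")
    rng = _rng(seed)
    genes = [f"GENE{g + 1:05d}" for g in range(n_genes)]
    probe_genes: list[list[str]] = [[] for _ in range(n_probes)]
    for g in range(n_genes):
        for k in range(probes_per_gene):
            j = (g * probes_per_gene + k) % n_probes
            if genes[g] not in probe_genes[j]:
                probe_genes[j].append(genes[g])
    annotation = pd.DataFrame({
        "probe_id": [probe_id(j) for j in range(n_probes)],
        "chr": [str((j % 22) + 1) for j in range(n_probes)],
        "pos_1based": [(j + 1) * 997 for j in range(n_probes)],
        "gene_symbols": [";".join(g) for g in probe_genes],
    })
    sets = {}
    for t in range(n_pathways):
        members = rng.choice(n_genes, size=genes_per_pathway, replace=False)
        sets[f"PATHWAY{t + 1:03d}"] = tuple(genes[g] for g in sorted(members))
    library = GeneSetLibrary.from_dict(sets, descriptions={k: "synthetic" for k in sets})
    return annotation, library


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

def simulate_dataset(
    cohort: CohortConfig,
    effects: EffectConfig,
    library: LibraryConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Generate a full cohort bundle from one root seed.

    Returns a dict with keys ``sheet``, ``matrix``, ``truth`` and, when a
    :class:`LibraryConfig` is given, ``annotation`` and ``library``.  The
    root seed defaults to ``cohort.seed``.
    """
    streams = split_streams(cohort.seed if seed is None else seed)
    sheet = generate_cohort(cohort, rng=streams["cohort"])
    matrix, truth = generate_methylome(sheet, effects, seed=streams["methylome"])
    sheet = generate_symptoms(sheet, truth, effects, seed=streams["symptoms"])
    bundle = {"sheet": sheet, "matrix": matrix, "truth": truth}
    if library is not None:
        annotation, gene_sets = generate_annotation_and_gmt(
            effects.n_probes, library.n_genes, library.n_pathways,
            library.probes_per_gene, library.genes_per_pathway,
            seed=streams["annotation"],
        )
        bundle["annotation"] = annotation
        bundle["library"] = gene_sets
    return bundle
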