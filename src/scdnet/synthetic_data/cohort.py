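"""Latent-variable cohort simulation with planted measurement structure.

Two groups of subjects are generated from a common structural blueprint:
mutually orthogonal standard-normal exogenous latents (an optional
correlation matrix is supported), a single endogenous target latent
("memory complaints") formed as sum(beta * exogenous) plus an independent
residual scaled so the target has unit variance, and reflective
indicators

    indicator = lambda * latent + noise_sd * sqrt(1 - lambda^2) * eps .

With ``noise_sd = 1`` indicators are unit-variance and their population
correlation with the latent equals the planted loading.  Raw-scale
calibration (e.g. questionnaire sum scores with reported group means and
SDs) is applied as a final affine transform per indicator, optionally per
group, so it never alters the standardized latent structure that the
recovery tests check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ConstructSpec", "CohortSpec", "CohortData", "generate_questionnaire_cohort",
           "study_cohort_spec", "write_cohort_csv"]


@dataclass(frozen=True)
class ConstructSpec:
    """One latent construct with its indicators and planted loadings."""

    name: str
    indicators: tuple[str, ...]
    loadings: tuple[float, ...]

    def __init__(self, name, indicators, loadings) -> None:
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "indicators", tuple(indicators))
        object.__setattr__(self, "loadings", tuple(float(x) for x in loadings))
        if len(self.indicators) != len(self.loadings):
            raise ValueError(f"{name}: one loading per indicator required")
        if len(self.indicators) == 0:
            raise ValueError(f"{name}: at least one indicator required")
        for lam in self.loadings:
            if not (0.0 <= lam <= 1.0):
                raise ValueError(f"{name}: loading {lam} outside [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a two-group questionnaire cohort.

    ``paths`` maps group label -> {exogenous construct -> path coefficient}
    toward the single endogenous target.  The implied residual variance
    1 - beta' Sigma beta must be positive for every group.
    """

    n_subjects_per_group: dict[str, int]
    constructs: tuple[ConstructSpec, ...]
    target: str
    paths: dict[str, dict[str, float]]
    noise_sd: float = 1.0
    latent_corr: np.ndarray | None = None  # over exogenous constructs, default identity
    indicator_scaling: dict | None = None  # indicator -> (mean, sd) | {group: (mean, sd)}
    target_group_means: dict[str, float] | None = None  # target latent mean per group
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c.name for c in self.constructs]
        if len(set(names)) != len(names):
            raise ValueError("construct names must be unique")
        if self.target not in names:
            raise ValueError(f"target construct {self.target!r} not defined")
        all_inds = [i for c in self.constructs for i in c.indicators]
        if len(set(all_inds)) != len(all_inds):
            raise ValueError("each indicator must belong to exactly one construct")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        exo = self.exogenous_names
        sigma = self.latent_sigma
        for group, pmap in self.paths.items():
            for src in pmap:
                if src not in exo:
                    raise ValueError(
                        f"path source {src!r} in group {group!r} is not exogenous"
                    )
            beta = np.array([pmap.get(e, 0.0) for e in exo])
            if np.any(np.abs(beta) > 1):
                raise ValueError("path coefficients must lie in [-1, 1]")
            explained = float(beta @ sigma @ beta)
            if explained >= 1.0:
                raise ValueError(
                    f"group {group!r}: implied residual variance "
                    f"{1 - explained:.3f} is not positive"
                )
        for group in self.n_subjects_per_group:
            if group not in self.paths:
                raise ValueError(f"no path map for group {group!r}")

    @property
    def exogenous_names(self) -> list[str]:
        return [c.name for c in self.constructs if c.name != self.target]

    @property
    def latent_sigma(self) -> np.ndarray:
        k = len(self.exogenous_names)
        if self.latent_corr is None:
            return np.eye(k)
        sigma = np.asarray(self.latent_corr, dtype=float)
        if sigma.shape != (k, k):
            raise ValueError("latent_corr must be square over exogenous constructs")
        if not np.allclose(sigma, sigma.T):
            raise ValueError("latent_corr must be symmetric")
        if np.any(np.linalg.eigvalsh(sigma) < -1e-10):
            raise ValueError("latent_corr must be positive semi-definite")
        return sigma

    @property
    def indicator_map(self) -> dict[str, str]:
        return {i: c.name for c in self.constructs for i in c.indicators}


@dataclass
class CohortData:
    """Generated cohort: indicator table plus the hidden ground truth."""

    indicators: pd.DataFrame  # subject_id, group, one column per indicator
    latents: pd.DataFrame  # subject_id, group, one column per construct
    construct_map: pd.DataFrame  # indicator, construct
    spec: CohortSpec


def generate_questionnaire_cohort(spec: CohortSpec) -> CohortData:
    """Draw a reproducible two-group cohort from a :class:`CohortSpec`."""
    rng = np.random.default_rng(spec.seed)
    exo = spec.exogenous_names
    sigma = spec.latent_sigma
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(len(exo))) if exo else None

    frames_x, frames_l = [], []
    offset = 0
    for group in spec.n_subjects_per_group:  # dict order = group order
        n = spec.n_subjects_per_group[group]
        beta = np.array([spec.paths[group].get(e, 0.0) for e in exo])
        z = rng.standard_normal((n, len(exo)))
        if chol is not None:
            z = z @ chol.T
        explained = float(beta @ sigma @ beta)
        resid = rng.standard_normal(n) * np.sqrt(1.0 - explained)
        mu_target = (spec.target_group_means or {}).get(group, 0.0)
        target = mu_target + z @ beta + resid  # within-group variance stays 1

        latents = {}
        for i, e in enumerate(exo):
            latents[e] = z[:, i]
        latents[spec.target] = target

        data = {}
        for c in spec.constructs:
            latent = latents[c.name]
            mu_c = mu_target if c.name == spec.target else 0.0
            for ind, lam in zip(c.indicators, c.loadings):
                eps = rng.standard_normal(n)
                x = lam * latent + spec.noise_sd * np.sqrt(1.0 - lam**2) * eps
                data[ind] = _rescale(x, ind, group, spec, lam=lam, latent_mean=mu_c)
        ids = [f"S{offset + i:03d}" for i in range(n)]
        offset += n
        fx = pd.DataFrame(data)
        fx.insert(0, "group", group)
        fx.insert(0, "subject_id", ids)
        fl = pd.DataFrame({c: latents[c] for c in [*exo, spec.target]})
        fl.insert(0, "group", group)
        fl.insert(0, "subject_id", ids)
        frames_x.append(fx)
        frames_l.append(fl)

    cmap = pd.DataFrame(
        {"indicator": list(spec.indicator_map), "construct": list(spec.indicator_map.values())}
    )
    return CohortData(
        indicators=pd.concat(frames_x, ignore_index=True),
        latents=pd.concat(frames_l, ignore_index=True),
        construct_map=cmap,
        spec=spec,
    )


def _rescale(
    x: np.ndarray,
    indicator: str,
    group: str,
    spec: CohortSpec,
    lam: float,
    latent_mean: float,
) -> np.ndarray:
    if not spec.indicator_scaling or indicator not in spec.indicator_scaling:
        return x
    entry = spec.indicator_scaling[indicator]
    if isinstance(entry, dict):
        if group not in entry:
            return x
        mean, sd = entry[group]
    else:
        mean, sd = entry
    # standardize by the theoretical within-group moments (keeps sampling
    # noise realistic while hitting the calibration targets in expectation)
    mu_x = lam * latent_mean
    sd_x = np.sqrt(lam**2 + spec.noise_sd**2 * (1.0 - lam**2))
    return mean + sd * (x - mu_x) / sd_x


def write_cohort_csv(cohort: CohortData, indicators_path, construct_map_path) -> None:
    cohort.indicators.to_csv(indicators_path, index=False)
    cohort.construct_map.to_csv(construct_map_path, index=False)


# ----------------------------------------------------------------------
# study-shaped default cohort


def study_cohort_spec(
    seed: int = 0,
    n_non_scd: int = 45,
    n_scd: int = 50,
) -> CohortSpec:
    """Cohort spec mirroring the study conditions.

    Five reflective constructs (memory complaints with 10 indicators,
    neuropsychological tests with 3, emotional distress with 3,
    metacognitive beliefs with 5, personality factors with 4) with
    loadings set to the reported outer loadings of the final measurement
    model.  Planted structural paths follow the per-group pattern:
    emotional distress and metacognitive beliefs predict memory
    complaints in both groups (0.33 non-SCD, 0.35 SCD) and personality
    carries a negative path (-0.38) in the SCD group only.  The
    memory-complaints latent is shifted between groups (SCD higher) and
    the CCI-S memory indicator is calibrated per group to the reported
    raw-scale means and SDs (16.31 +- 3.41 vs 32.34 +- 5.03).
    """
    constructs = (
        ConstructSpec(
            "memory_complaints",
            (
                "CDS", "CCIS_memory", "CCIS_executive", "CCIS_language",
                "PRMQ_prospective", "PRMQ_retrospective", "PRMQ_short_term",
                "PRMQ_long_term", "PRMQ_self_cued", "PRMQ_env_cued",
            ),
            (0.88, 0.81, 0.74, 0.74, 0.93, 0.91, 0.93, 0.94, 0.93, 0.91),
        ),
        ConstructSpec(
            "neuropsych",
            ("RLRI_free_recall", "fluency_category", "fluency_letter"),
            (0.85, 0.75, 0.62),
        ),
        ConstructSpec(
            "emotional_distress",
            ("GDS", "STAI_YA", "STAI_YB"),
            (0.82, 0.84, 0.88),
        ),
        ConstructSpec(
            "metacognitive_beliefs",
            (
                "MCQ30_positive", "MCQ30_uncontrollability", "MCQ30_confidence",
                "MCQ30_punishment", "MCQ30_self_consciousness",
            ),
            (0.63, 0.75, 0.77, 0.76, 0.50),
        ),
        ConstructSpec(
            "personality",
            ("SES", "CD_RISC", "BFI10_conscientiousness", "BFI10_emotional_stability"),
            (0.86, 0.71, 0.64, 0.72),
        ),
    )
    paths = {
        "non-SCD": {
            "emotional_distress": 0.33,
            "metacognitive_beliefs": 0.33,
            "neuropsych": 0.0,
            "personality": 0.0,
        },
        "SCD": {
            "emotional_distress": 0.35,
            "metacognitive_beliefs": 0.35,
            "neuropsych": 0.0,
            "personality": -0.38,
        },
    }
    scaling = {
        "CCIS_memory": {
            "non-SCD": (16.31, 3.41),
            "SCD": (32.34, 5.03),
        }
    }
    return CohortSpec(
        n_subjects_per_group={"non-SCD": n_non_scd, "SCD": n_scd},
        constructs=constructs,
        target="memory_complaints",
        paths=paths,
        noise_sd=1.0,
        indicator_scaling=scaling,
        # SCD reports substantially more complaints: the target latent is
        # shifted by group (pooled mean ~0, within-group variance 1),
        # mirroring the reported composite-score separation
        target_group_means={"non-SCD": -0.9, "SCD": 0.8},
        seed=seed,
    )
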