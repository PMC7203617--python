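"""Cohort generation.

Each synthetic participant carries two latent per-frame propensities — a
probability of gazing at a distractor and a probability of being off-task
("nowhere in particular") — plus a 7x7 row-stochastic emotion-confusion
profile.  Group-level distraction parameters default to the study's printed
per-participant distraction-ratio moments (ASD mean 0.0433, SD 0.0911; NC
mean 0.0139, SD 0.0215); propensities are drawn from moment-matched Beta
distributions so they stay in [0, 1] even for the high-variance ASD group.

Clinical questionnaire scores (SCQ, SRS, ABIQ) are generated as inert
metadata in realistic group-specific ranges; the analysis never uses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gazephen import EMOTIONS

GROUPS = ("ASD", "NC")


@dataclass(frozen=True)
class GroupParams:
    """Per-group generator settings."""

    distraction_mean: float
    distraction_sd: float
    offtask_mean: float
    offtask_sd: float
    confusion_accuracy: float  # diagonal mass of the confusion profile
    age_range: tuple[int, int]
    male_fraction: float
    scq_mean: float
    scq_sd: float
    srs_mean: float
    srs_sd: float
    abiq_mean: float
    abiq_sd: float


DEFAULT_GROUP_PARAMS: dict[str, GroupParams] = {
    "ASD": GroupParams(
        distraction_mean=0.0433,
        distraction_sd=0.0911,
        offtask_mean=0.10,
        offtask_sd=0.05,
        confusion_accuracy=0.65,
        age_range=(6, 17),
        male_fraction=13 / 16,
        scq_mean=18.86,
        scq_sd=6.43,
        srs_mean=78.85,
        srs_sd=11.13,
        abiq_mean=102.75,
        abiq_sd=19.54,
    ),
    "NC": GroupParams(
        distraction_mean=0.0139,
        distraction_sd=0.0215,
        offtask_mean=0.05,
        offtask_sd=0.03,
        confusion_accuracy=0.80,
        age_range=(8, 17),
        male_fraction=9 / 17,
        scq_mean=1.82,
        scq_sd=1.07,
        srs_mean=44.41,
        srs_sd=8.11,
        abiq_mean=108.94,
        abiq_sd=9.58,
    ),
}


@dataclass
class Participant:
    participant_id: str
    group: str
    age: int
    gender: str  # "male" | "female"
    latent_distraction: float
    latent_offtask: float
    confusion_profile: np.ndarray
    clinical: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not 0 <= self.latent_distraction <= 1:
            raise ValueError("latent_distraction outside [0, 1]")
        if self.latent_distraction + self.latent_offtask > 1 + 1e-12:
            raise ValueError("latent_distraction + latent_offtask > 1")
        cp = np.asarray(self.confusion_profile, dtype=float)
        if cp.shape != (len(EMOTIONS), len(EMOTIONS)):
            raise ValueError("confusion_profile must be 7x7")
        if not np.allclose(cp.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion_profile rows must sum to 1")


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta(a, b) parameters matched to a mean and SD on (0, 1).

    Raises ``ValueError`` when the SD is too large for the mean (the method
    of moments would give non-positive shape parameters).
    """
    if not 0 < mean < 1:
        raise ValueError(f"mean {mean} outside (0, 1)")
    var = sd**2
    if var >= mean * (1 - mean):
        raise ValueError(
            f"SD {sd} too large for mean {mean}: no Beta distribution has "
            "these moments"
        )
    nu = mean * (1 - mean) / var - 1
    return mean * nu, (1 - mean) * nu


def uniform_confusion_profile(accuracy: float) -> np.ndarray:
    """Row-stochastic profile: ``accuracy`` on the diagonal, rest uniform."""
    k = len(EMOTIONS)
    profile = np.full((k, k), (1 - accuracy) / (k - 1))
    np.fill_diagonal(profile, accuracy)
    return profile


def _draw_propensity(rng: np.random.Generator, mean: float, sd: float,
                     group: str, what: str) -> float:
    if sd == 0:
        return mean
    try:
        a, b = beta_from_moments(mean, sd)
    except ValueError as exc:
        raise ValueError(f"{what} parameters infeasible for group {group}: {exc}")
    return float(rng.beta(a, b))


def make_cohort(
    n_asd: int,
    n_nc: int,
    seed: int,
    distraction_params: dict[str, tuple[float, float]] | None = None,
    confusion_params: dict[str, float] | None = None,
    offtask_params: dict[str, tuple[float, float]] | None = None,
    group_params: dict[str, GroupParams] | None = None,
) -> list[Participant]:
    """Draw a two-group cohort; deterministic given ``seed``.

    ``distraction_params``/``offtask_params`` map group name to (mean, SD)
    overrides; ``confusion_params`` maps group name to a diagonal accuracy
    override.  Defaults reproduce the study cohort structure (16 ASD / 17 NC,
    printed distraction moments, Table-1 gender splits and age ranges).
    """
    if n_asd < 1 or n_nc < 1:
        raise ValueError("each group needs at least one participant")
    params = dict(group_params or DEFAULT_GROUP_PARAMS)
    rng = np.random.default_rng(seed)
    cohort: list[Participant] = []
    counters = {"ASD": n_asd, "NC": n_nc}
    for group in GROUPS:
        gp = params[group]
        d_mean, d_sd = (distraction_params or {}).get(
            group, (gp.distraction_mean, gp.distraction_sd)
        )
        o_mean, o_sd = (offtask_params or {}).get(
            group, (gp.offtask_mean, gp.offtask_sd)
        )
        accuracy = (confusion_params or {}).get(group, gp.confusion_accuracy)
        profile = uniform_confusion_profile(accuracy)
        for i in range(counters[group]):
            distraction = _draw_propensity(rng, d_mean, d_sd, group, "distraction")
            offtask = _draw_propensity(rng, o_mean, o_sd, group, "offtask")
            offtask = min(offtask, 1 - distraction)
            lo, hi = gp.age_range
            age = int(rng.integers(lo, hi + 1))
            gender = "male" if rng.random() < gp.male_fraction else "female"
            clinical = {
                "scq": float(np.clip(rng.normal(gp.scq_mean, gp.scq_sd), 0, 39)),
                "srs": float(np.clip(rng.normal(gp.srs_mean, gp.srs_sd), 30, 90)),
                "abiq": float(np.clip(rng.normal(gp.abiq_mean, gp.abiq_sd), 47, 160)),
            }
            cohort.append(
                Participant(
                    participant_id=f"{group.lower()}{i + 1:02d}",
                    group=group,
                    age=age,
                    gender=gender,
                    latent_distraction=distraction,
                    latent_offtask=offtask,
                    confusion_profile=profile,
                    clinical=clinical,
                )
            )
    return cohort
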