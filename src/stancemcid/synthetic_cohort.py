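"""Seed-reproducible synthetic stance-platform cohorts.

The generator emulates a cohort of dogs with bilateral hip
osteoarthritis measured on a four-quadrant stance platform at baseline
(T0) and a 15-day follow-up (D15), with a per-dog anchor-question
response at each timepoint.  Its purpose is to give every downstream
stage a realistic, fully reproducible input whose ground truth is
known, so parameter recovery can be asserted.

Generative model (all randomness from a single seeded generator):

1. *Severity.*  Each dog draws a hind-limb off-loading severity
   ``u ~ Gamma`` with mean ``20 − baseline_hind_mean`` percent points
   and SD ``baseline_between_dog_sd``.  The dog's two hind limbs share
   a total off-load of ``2u``.
2. *Asymmetry.*  The total off-load is split between limbs as
   ``2uc`` / ``2u(1−c)`` with ``c ~ Beta(b, b)`` (``asymmetry_beta``).
   Small ``b`` concentrates the off-load on one limb, driving the
   symmetry index while leaving the expected per-limb deviation equal
   to the mean severity exactly.
3. *Response.*  Responder status is drawn with marginal probability
   ``p_responder`` through a logistic link in severity (worse dogs are
   more likely to report improvement); responders recover a fraction
   ``effect_better`` of each limb's baseline deviation, non-responders
   ``effect_same``, each perturbed per dog by ``effect_sd`` and clipped
   to [0, 1].  Fractional recovery shrinks deviation and symmetry index
   together, as treated cohorts show.
4. *Trials.*  Hind loads are ``20 − deviation``; the two forelimbs
   absorb the complement so each trial sums to exactly 100.  Per-trial
   noise is drawn per limb and projected onto the sum-zero subspace, so
   conservation is exact; loads are truncated (and counted) at [0, 100].
5. *Anchor.*  All dogs start at ``anchor_base_level``; responders move
   up exactly one level at D15.  An optional ``anchor_noise``
   probability flips a dog's recorded transition, to study estimator
   degradation under anchor misclassification.

The generator-true per-limb deviations and per-dog symmetry indices
(noise-free) travel with the cohort in a truth record that is never fed
to the estimators.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort_anchor import GROUP_BETTER, GROUP_SAME
from .exceptions import EstimationError, ValidationError
from .stance_metrics import NORMAL_HIND_LOAD

#: Beta(b, b) concentration of the left/right severity split, tuned once
#: so the default cohort's baseline symmetry-index mean lands on the
#: observed cohort value (~28); see docs/methods.md for the calibration.
DEFAULT_ASYMMETRY_BETA = 0.57

#: Logistic scale (percent points of severity) linking severity to the
#: odds of being a responder; tuned once against the observed baseline
#: separation of the two anchor groups.
DEFAULT_RESPONDER_SELECTIVITY = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    """All distributional parameters and the seed of a synthetic cohort.

    Defaults describe the emulated cohort: 80 dogs / 160 pelvic limbs,
    20 platform trials per limb per session, mean baseline hind load
    16.5% (deviation 3.5 points below the 20% norm), and a 37.5%
    responder fraction whose anchor response improves one level.
    """

    n_dogs: int = 80
    n_trials: int = 20
    seed: int = 0
    #: Mean baseline hind-limb load (percent body weight).
    baseline_hind_mean: float = 16.5
    #: Between-dog SD of the severity draw (percent points).
    baseline_between_dog_sd: float = 1.8
    #: Beta(b, b) concentration of the left/right severity split.
    asymmetry_beta: float = DEFAULT_ASYMMETRY_BETA
    #: Per-trial, per-limb measurement noise SD (percent points).
    trial_noise_sd: float = 1.0
    #: Fractional recovery of baseline deviation, non-responders.
    effect_same: float = 0.50
    #: Fractional recovery of baseline deviation, responders.
    effect_better: float = 0.65
    #: Between-dog SD of the recovery fraction.
    effect_sd: float = 0.12
    #: Marginal probability a dog's anchor response improves one level.
    p_responder: float = 0.375
    #: Logistic scale of the severity -> responder link (percent points);
    #: larger values decouple response from severity.
    responder_selectivity: float = DEFAULT_RESPONDER_SELECTIVITY
    #: Anchor level every dog reports at T0 (1=Poor .. 5=Excellent).
    anchor_base_level: int = 3
    #: Probability a dog's recorded transition is flipped (responder
    #: recorded as unchanged and vice versa).
    anchor_noise: float = 0.0

    def validate(self) -> None:
        if self.n_dogs < 1:
            raise ValidationError("n_dogs must be >= 1")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        for name in (
            "baseline_between_dog_sd",
            "trial_noise_sd",
            "effect_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.asymmetry_beta <= 0:
            raise ValidationError("asymmetry_beta must be > 0")
        if self.responder_selectivity <= 0:
            raise ValidationError("responder_selectivity must be > 0")
        for name in ("p_responder", "anchor_noise"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in ("effect_same", "effect_better"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(
                    f"{name} is a recovery fraction and must be in [0, 1]"
                )
        if not 0.0 <= self.baseline_hind_mean <= NORMAL_HIND_LOAD:
            raise ValidationError(
                "baseline_hind_mean must be in [0, 20]: hind limbs off-load "
                "below the 20% norm in this cohort model"
            )
        fore_mean = (100.0 - 2.0 * self.baseline_hind_mean) / 2.0
        if not 0.0 <= fore_mean <= 100.0:
            raise ValidationError("implied mean forelimb load outside [0, 100]")
        if not 1 <= self.anchor_base_level <= 5:
            raise ValidationError("anchor_base_level must be in 1..5")
        if self.p_responder > 0 and self.anchor_base_level >= 5:
            raise ValidationError(
                "responders must be able to move one anchor level up; "
                "anchor_base_level must be <= 4 when p_responder > 0"
            )


@dataclass(frozen=True)
class TruthRecord:
    """Generator-true latent state, carried alongside the data.

    ``latent`` holds one row per dog: severity ``u``, split ``c``,
    responder flag, recovery fraction ``rho``, noise-free per-limb
    deviations and per-dog symmetry indices at both timepoints.
    """

    latent: pd.DataFrame
    n_truncated_trials: int


@dataclass
class SyntheticCohort:
    trials: pd.DataFrame
    anchors: pd.DataFrame
    truth: Optional[TruthRecord]
    config: GeneratorConfig

    def strip_truth(self) -> "SyntheticCohort":
        """A copy without the truth record (estimators never see truth)."""
        return SyntheticCohort(self.trials, self.anchors, None, self.config)


def _solve_responder_threshold(u: np.ndarray, p: float, scale: float) -> float:
    """Logistic intercept giving a realized marginal responder rate p."""
    lo = float(u.min() - 40.0 * scale - 1.0)
    hi = float(u.max() + 40.0 * scale + 1.0)
    return brentq(lambda tau: expit((u - tau) / scale).mean() - p, lo, hi)


def _latent_si(dev_left: np.ndarray, dev_right: np.ndarray) -> np.ndarray:
    load_l = NORMAL_HIND_LOAD - dev_left
    load_r = NORMAL_HIND_LOAD - dev_right
    return np.abs(load_r - load_l) / ((load_r + load_l) * 0.5) * 100.0


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate one synthetic cohort.

    Identical ``(seed, config)`` yield byte-identical trial and anchor
    tables.  Returns a :class:`SyntheticCohort` whose ``trials`` and
    ``anchors`` frames match the CSV schemas consumed by the analysis
    stages, with the truth record attached.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_dogs

    mean_sev = NORMAL_HIND_LOAD - config.baseline_hind_mean
    sd_sev = config.baseline_between_dog_sd
    if mean_sev == 0 or sd_sev == 0:
        u = np.full(n, mean_sev)
        rng.random(n)  # keep the draw budget stable across configs
    else:
        shape = (mean_sev / sd_sev) ** 2
        scale = sd_sev**2 / mean_sev
        u = rng.gamma(shape, scale, size=n)
    c = rng.beta(config.asymmetry_beta, config.asymmetry_beta, size=n)

    dev_l0 = 2.0 * u * c
    dev_r0 = 2.0 * u * (1.0 - c)
    # keep latent hind loads physical; truncation here is counted below
    dev_l0 = np.minimum(dev_l0, NORMAL_HIND_LOAD)
    dev_r0 = np.minimum(dev_r0, NORMAL_HIND_LOAD)

    if config.p_responder <= 0.0:
        responder = np.zeros(n, dtype=bool)
        rng.random(n)
    elif config.p_responder >= 1.0:
        responder = np.ones(n, dtype=bool)
        rng.random(n)
    else:
        tau = _solve_responder_threshold(
            u, config.p_responder, config.responder_selectivity
        )
        p_i = expit((u - tau) / config.responder_selectivity)
        responder = rng.random(n) < p_i

    rho_mean = np.where(responder, config.effect_better, config.effect_same)
    rho = np.clip(rng.normal(rho_mean, config.effect_sd), 0.0, 1.0)

    dev_l1 = (1.0 - rho) * dev_l0
    dev_r1 = (1.0 - rho) * dev_r0

    # latent limb loads per dog x timepoint, limb order (lf, rf, lh, rh)
    latent_loads = np.empty((n, 2, 4))
    for t, (dl, dr) in enumerate([(dev_l0, dev_r0), (dev_l1, dev_r1)]):
        lh = NORMAL_HIND_LOAD - dl
        rh = NORMAL_HIND_LOAD - dr
        fore = (100.0 - lh - rh) / 2.0
        latent_loads[:, t, 0] = fore
        latent_loads[:, t, 1] = fore
        latent_loads[:, t, 2] = lh
        latent_loads[:, t, 3] = rh

    noise = rng.normal(0.0, config.trial_noise_sd, size=(n, 2, config.n_trials, 4))
    noise -= noise.mean(axis=-1, keepdims=True)  # sum-preserving
    loads = latent_loads[:, :, None, :] + noise
    n_truncated = int(np.sum((loads < 0.0) | (loads > 100.0)))
    loads = np.clip(loads, 0.0, 100.0)
    # clipping a near-zero hind load breaks the 100% sum; the forelimbs
    # (always far from the bounds) absorb the residual
    residual = 100.0 - loads.sum(axis=-1)
    loads[..., 0] += residual / 2.0
    loads[..., 1] += residual / 2.0

    dog_ids = np.array([f"dog{i:04d}" for i in range(1, n + 1)])
    timepoints = np.array(["T0", "D15"])
    idx_dog, idx_tp, idx_trial = np.meshgrid(
        np.arange(n), np.arange(2), np.arange(config.n_trials), indexing="ij"
    )
    trials = pd.DataFrame(
        {
            "dog_id": dog_ids[idx_dog.ravel()],
            "timepoint": timepoints[idx_tp.ravel()],
            "trial_index": idx_trial.ravel() + 1,
            "wb_lf": loads[..., 0].ravel(),
            "wb_rf": loads[..., 1].ravel(),
            "wb_lh": loads[..., 2].ravel(),
            "wb_rh": loads[..., 3].ravel(),
        }
    )

    observed_up = responder.copy()
    if config.anchor_noise > 0.0:
        flip = rng.random(n) < config.anchor_noise
        observed_up = observed_up ^ flip
    level_t0 = np.full(n, config.anchor_base_level)
    level_d15 = np.clip(level_t0 + observed_up.astype(int), 1, 5)
    anchors = pd.DataFrame(
        {
            "dog_id": dog_ids,
            "anchor_t0": level_t0,
            "anchor_d15": level_d15,
        }
    )

    latent = pd.DataFrame(
        {
            "dog_id": dog_ids,
            "severity": u,
            "split": c,
            "responder": responder,
            "recovery_fraction": rho,
            "dev_left_t0": dev_l0,
            "dev_right_t0": dev_r0,
            "dev_left_d15": dev_l1,
            "dev_right_d15": dev_r1,
            "si_t0": _latent_si(dev_l0, dev_r0),
            "si_d15": _latent_si(dev_l1, dev_r1),
        }
    )
    truth = TruthRecord(latent=latent, n_truncated_trials=n_truncated)
    return SyntheticCohort(trials=trials, anchors=anchors, truth=truth, config=config)


def true_parameters(cohort: SyntheticCohort) -> dict:
    """Generator-true per-group mean changes for recovery assertions.

    Returns ``{"deviation": {group: mean limb-deviation change},
    "si": {group: mean symmetry-index change}}`` computed from the
    noise-free latent state, with each dog contributing two limbs to
    the deviation means (matching the limb-level analysis table).
    """
    if cohort.truth is None:
        raise EstimationError("truth record was stripped from this cohort")
    lat = cohort.truth.latent
    out: dict[str, dict[str, float]] = {"deviation": {}, "si": {}}
    group = np.where(lat["responder"], GROUP_BETTER, GROUP_SAME)
    dev_change = np.concatenate(
        [
            lat["dev_left_d15"] - lat["dev_left_t0"],
            lat["dev_right_d15"] - lat["dev_right_t0"],
        ]
    )
    dev_group = np.concatenate([group, group])
    si_change = (lat["si_d15"] - lat["si_t0"]).to_numpy()
    for g in (GROUP_SAME, GROUP_BETTER):
        if np.any(group == g):
            out["deviation"][g] = float(dev_change[dev_group == g].mean())
            out["si"][g] = float(si_change[group == g].mean())
    return out


def config_to_dict(config: GeneratorConfig) -> dict:
    return asdict(config)


def config_with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    return replace(config, seed=seed)
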