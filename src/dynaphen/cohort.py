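"""Synthetic longitudinal cohort with retained ground truth.

The generator emulates the study design end to end: unconstrained
phenotype trajectories composed from a participant baseline, a plateauing
power-law practice term, valence/arousal state terms and Gaussian session
noise; trial-level task data simulated from the constrained trajectories
under the printed task designs; survey items generated from the two latent
affective factors; and configurable session missingness. Every generative
term is stored separately in :class:`CohortTruth` so recovery tests have
an exact oracle.

Latent affective states follow a per-participant AR(1) week-to-week
process (mood persistence); this is generator-only structure — the
statistical models make no assumption about state dynamics.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import TASKS, SurveyTable, TrialTable
from .tasks import constrain_theta, get_model, simulate_task

__all__ = [
    "ParamConfig",
    "SurveyConfig",
    "CohortConfig",
    "CohortTruth",
    "generate_trajectories",
    "generate_survey_items",
    "generate_cohort",
    "default_param_configs",
]

_B_LO, _B_HI = np.exp(-2.0), np.exp(1.0)


@dataclasses.dataclass
class ParamConfig:
    """Population settings of one phenotype entry (unconstrained space)."""

    loc: float  # group mean mu_g
    eta: float  # between-participant s.d. eta_g
    sigma: float  # session-level s.d.


# per-task (eta, sigma) pairs; locs come from each task module's PRIOR_LOC.
# The session-level sigma is calibrated against each parameter's published
# test-retest stability: with ICC ~ eta^2 / (eta^2 + sigma^2),
# sigma = eta * sqrt(1/ICC - 1) reproduces the study's weekly stability
# profile (e.g. lapse rate unstable at 0.45, reward/punishment effect size
# nearly frozen at 0.99).
_SCALES = {
    # b 0.66, pi 0.48, eps 0.90, rho_rp 0.99, rho_neut 0.65, xi 0.45
    "gng": [(0.3, 0.215), (0.3, 0.312), (0.4, 0.133), (0.4, 0.040),
            (0.4, 0.293), (0.4, 0.442)],
    # sigma/theta (and slopes) ~0.96
    "cd": [(0.4, 0.082), (0.4, 0.082), (0.3, 0.061), (0.3, 0.061)],
    # alpha 0.56, tau 0.68, delta 0.73
    "rdm": [(0.3, 0.266), (0.25, 0.171), (0.3, 0.182)],
    # rho 0.95, beta 0.90
    "lt": [(0.35, 0.080), (0.4, 0.133)],
    # k 0.93, beta 0.91
    "itc": [(0.6, 0.165), (0.4, 0.126)],
    # w_V 0.49, w_RU 0.61, w_sTU 0.62
    "tab": [(0.06, 0.061), (0.06, 0.048), (0.8, 0.626)],
    # w 0.81
    "nc": [(0.4, 0.194)],
}


def default_param_configs(task: str) -> dict[str, ParamConfig]:
    m = get_model(task)
    return {
        name: ParamConfig(loc=float(loc), eta=e, sigma=s)
        for name, loc, (e, s) in zip(m.PARAM_NAMES, m.PRIOR_LOC, _SCALES[task])
    }


@dataclasses.dataclass
class SurveyConfig:
    """Item map of the synthetic 35-item survey (item 34 is free text)."""

    noise_sd: float = 0.6
    day_noise_sd: float = 0.3
    n_days: int = 3
    scale_min: int = 1
    scale_max: int = 7
    #: optional explicit item_id -> (valence, arousal) loading override
    loadings: dict | None = None
    #: keep raw real-valued responses instead of ordinal binning
    continuous: bool = False

    def item_loadings(self) -> dict[int, tuple]:
        """item_id -> (valence loading, arousal loading)."""
        if self.loadings is not None:
            return dict(self.loadings)
        ids = [i for i in range(1, 37) if i != 34]
        loads = {}
        for i in ids:
            if i <= 8:
                loads[i] = (1.0, 0.0)  # positive-emotion items
            elif i <= 16:
                loads[i] = (-1.0, 0.0)  # negative-emotion items
            elif i <= 24:
                loads[i] = (0.0, 1.0)  # affect-intensity items
            elif i <= 30:
                loads[i] = (0.5, 0.5)  # mixed mood/energy items
            else:
                loads[i] = (0.2, 0.2)  # habits with weak affect loading
        return loads


@dataclasses.dataclass
class CohortConfig:
    n_participants: int = 20
    n_weeks: int = 8
    tasks: tuple = TASKS
    # population dynamic-effect fractions delta_i in (-1, 1), shared across
    # all parameters of the selected tasks
    delta_p: float = 0.0
    delta_v: float = 0.0
    delta_a: float = 0.0
    b_z_sd: float = 0.7  # spread of the raw practice-exponent score
    state_ar: float = 0.5  # AR(1) coefficient of weekly latent states
    missing_rate: float = 0.0
    ensure_included: bool = False
    survey: SurveyConfig = dataclasses.field(default_factory=SurveyConfig)
    param_overrides: dict = dataclasses.field(default_factory=dict)
    designs: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def full_scale(cls, **kw) -> "CohortConfig":
        """The published design: 90 participants x 12 weeks."""
        return cls(n_participants=90, n_weeks=12, **kw)

    def params_for(self, task: str) -> dict[str, ParamConfig]:
        cfg = default_param_configs(task)
        for (t, p), pc in self.param_overrides.items():
            if t == task:
                cfg[p] = pc
        return cfg

    def validate(self):
        for d in (self.delta_p, self.delta_v, self.delta_a):
            if not -1.0 < d < 1.0:
                raise ValueError("population fractions must lie in (-1, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclasses.dataclass
class CohortTruth:
    """Ground-truth trajectories, latent states and generator settings."""

    config: CohortConfig
    participants: list
    latent_valence: np.ndarray  # (S, T) raw AR(1) states
    latent_arousal: np.ndarray
    v_norm: np.ndarray  # (S, T) normalized to [-1, 1] within participant
    a_norm: np.ndarray
    mask: np.ndarray  # (S, T) True where the week was attended
    params: dict  # task -> param -> dict of arrays (mu_s, b, delta_*_s, terms, y)
    seed: int = 0

    def y(self, task: str, param: str) -> np.ndarray:
        return self.params[task][param]["y"]

    def to_json(self, path: str | Path) -> None:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        payload = dict(
            config=dataclasses.asdict(self.config),
            participants=self.participants,
            latent_valence=self.latent_valence,
            latent_arousal=self.latent_arousal,
            v_norm=self.v_norm,
            a_norm=self.a_norm,
            mask=self.mask.astype(int),
            params=self.params,
            seed=self.seed,
        )
        Path(path).write_text(json.dumps(payload, default=enc))


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    rng = hi - lo
    out = np.where(rng > 1e-12, 2.0 * (x - lo) / np.where(rng > 0, rng, 1.0) - 1.0, 0.0)
    return out


def _ar1(rng, S, T, phi):
    x = np.empty((S, T))
    x[:, 0] = rng.standard_normal(S)
    innov_sd = np.sqrt(1.0 - phi**2)
    for t in range(1, T):
        x[:, t] = phi * x[:, t - 1] + innov_sd * rng.standard_normal(S)
    return x


def generate_trajectories(config: CohortConfig, seed: int = 0) -> CohortTruth:
    """Draw phenotype trajectories from the dynamic generative model."""
    config.validate()
    S, T = config.n_participants, config.n_weeks
    rng = np.random.default_rng([seed, 1])
    participants = [f"p{i:03d}" for i in range(S)]

    lat_v = _ar1(rng, S, T, config.state_ar)
    lat_a = _ar1(rng, S, T, config.state_ar)
    v_norm = _normalize_rows(lat_v)
    a_norm = _normalize_rows(lat_a)

    mask_rng = np.random.default_rng([seed, 2])
    mask = _draw_mask(mask_rng, S, T, config)

    t_idx = np.arange(1, T + 1, dtype=float)[None, :]
    params: dict = {}
    for task in config.tasks:
        cfgs = config.params_for(task)
        params[task] = {}
        for pname, pc in cfgs.items():
            mu_s = pc.loc + pc.eta * rng.standard_normal(S)
            bz = config.b_z_sd * rng.standard_normal(S)
            b = np.exp(-2.0 + 3.0 / (1.0 + np.exp(-bz)))
            dp_s = config.delta_p * mu_s
            dv_s = config.delta_v * mu_s
            da_s = config.delta_a * mu_s
            practice = dp_s[:, None] * (1.0 - t_idx ** (-b[:, None]))
            valence = dv_s[:, None] * v_norm
            arousal = da_s[:, None] * a_norm
            noise = pc.sigma * rng.standard_normal((S, T))
            y = mu_s[:, None] + practice + valence + arousal + noise
            params[task][pname] = dict(
                mu_s=mu_s, b=b, delta_p_s=dp_s, delta_v_s=dv_s, delta_a_s=da_s,
                practice=practice, valence=valence, arousal=arousal,
                noise=noise, y=y,
            )
    return CohortTruth(
        config=config, participants=participants, latent_valence=lat_v,
        latent_arousal=lat_a, v_norm=v_norm, a_norm=a_norm, mask=mask,
        params=params, seed=seed,
    )


def _draw_mask(rng, S, T, config: CohortConfig) -> np.ndarray:
    from .inclusion import MAX_CONSECUTIVE_MISSING, MIN_WEEKS

    mask = np.ones((S, T), dtype=bool)
    if config.missing_rate <= 0:
        return mask
    for s in range(S):
        for _ in range(100):
            row = rng.random(T) >= config.missing_rate
            if not config.ensure_included:
                break
            weeks = set(np.where(row)[0] + 1)
            if len(weeks) >= min(MIN_WEEKS, T):
                runs, run = [], 0
                for w in range(min(weeks), max(weeks) + 1):
                    run = 0 if w in weeks else run + 1
                    runs.append(run)
                if max(runs, default=0) <= MAX_CONSECUTIVE_MISSING:
                    break
        mask[s] = row
    return mask


def generate_survey_items(
    truth: CohortTruth, item_spec: SurveyConfig | None = None, seed: int = 0
) -> SurveyTable:
    """Ordinal survey responses from the two latent affective factors."""
    spec = item_spec or truth.config.survey
    loads = spec.item_loadings()
    if all(lv == 0 and la == 0 for lv, la in loads.values()):
        raise ValueError("degenerate all-zero item loadings")
    rng = np.random.default_rng([seed, 3])
    rows = []
    S, T = truth.latent_valence.shape
    mid = 0.5 * (spec.scale_min + spec.scale_max)
    half = 0.5 * (spec.scale_max - spec.scale_min)
    for s in range(S):
        pid = truth.participants[s]
        for t in range(T):
            if not truth.mask[s, t]:
                continue
            for day in range(1, spec.n_days + 1):
                v = truth.latent_valence[s, t] + spec.day_noise_sd * rng.standard_normal()
                a = truth.latent_arousal[s, t] + spec.day_noise_sd * rng.standard_normal()
                for item, (lv, la) in loads.items():
                    raw = lv * v + la * a + spec.noise_sd * rng.standard_normal()
                    scaled = mid + half * raw / 2.5
                    if spec.continuous:
                        resp = float(scaled)
                    else:
                        resp = int(np.clip(np.round(scaled), spec.scale_min, spec.scale_max))
                    rows.append((pid, t + 1, day, item, resp))
    return SurveyTable(
        df=pd.DataFrame(
            rows, columns=["participant_id", "week", "day", "item_id", "response"]
        )
    )


def generate_cohort(config: CohortConfig, seed: int = 0) -> dict:
    """Full synthetic study: trials per task, survey, and ground truth."""
    truth = generate_trajectories(config, seed)
    survey = generate_survey_items(truth, config.survey, seed)
    trials = {}
    for k, task in enumerate(config.tasks):
        m = get_model(task)
        design = config.designs.get(task) or m.default_design()
        frames = []
        for s in range(config.n_participants):
            for t in range(config.n_weeks):
                if not truth.mask[s, t]:
                    continue
                u = np.array(
                    [truth.params[task][p]["y"][s, t] for p in m.PARAM_NAMES]
                )
                theta = constrain_theta(task, u)
                frames.append(
                    simulate_task(
                        task, theta, design=design,
                        seed=np.random.default_rng([seed, 4 + k, s, t]),
                        participant_id=truth.participants[s], week=t + 1,
                    )
                )
        trials[task] = TrialTable(task=task, df=pd.concat(frames, ignore_index=True))
    return dict(trials=trials, survey=survey, truth=truth)
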