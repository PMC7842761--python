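"""Synthetic cohorts with the statistical structure the analysis assumes.

The study design is a 2 x 2 factorial — estrous-cycle phase (early
proestrus / high E2 vs estrus / low E2) crossed with acute multi-stressor
exposure (control vs MAS) — with 6-7 mice per condition and fos+ cell
counts in 11 brain regions per mouse.  No per-animal raw data are
published, so every downstream stage is exercised on generated cohorts.

Regional counts are drawn with a Gaussian copula: per condition, latent
multivariate-normal vectors with a planted correlation structure are
pushed through the standard-normal CDF and the inverse CDF of each
region's count marginal (Poisson or negative-binomial).  The latent
Pearson matrix is calibrated from the target Spearman matrix via
rho = 2 sin(pi rho_s / 6), the exact Spearman-to-Pearson relation for
bivariate normals, so the generated data hit the requested rank
correlations up to discreteness attenuation (negligible for count means
>= 50).

Behavioral sessions, vaginal-smear compositions (Dirichlet on the 3-cell
simplex), and detection-limit-censored serum estradiol are generated with
the same cohort structure.  One global seed fans out into independent
per-stream sub-seeds (fos, behavior, smears, hormones) so adding draws to
one stream never perturbs another.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import behavior as bhv
from . import cytology as cyt
from .network import CYCLE_LEVELS, DEFAULT_REGIONS, STRESS_LEVELS, validate_fos_table

ALL_CONDITIONS = tuple(itertools.product(CYCLE_LEVELS, STRESS_LEVELS))
_STREAMS = ("fos", "behavior", "smears", "hormones")


def stream_rngs(seed: int) -> dict:
    """Expand one global seed into named independent generator streams."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


# ---------------------------------------------------------------------------
# copula calibration


def spearman_to_latent_pearson(rho_s):
    """Latent Pearson correlation giving Spearman ``rho_s`` under a
    Gaussian copula: rho = 2 sin(pi rho_s / 6).

    Odd and monotone on [-1, 1] with |rho| >= |rho_s|; fixed points at
    -1, 0, 1.
    """
    arr = np.asarray(rho_s, dtype=float)
    if np.any(np.abs(arr) > 1):
        raise ValueError("|rho_s| must be <= 1")
    out = 2.0 * np.sin(np.pi * arr / 6.0)
    return float(out) if np.isscalar(rho_s) else out


def nearest_psd_correlation(mat: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues to ``eig_floor`` and rescale back to unit
    diagonal.  Elementwise-valid target matrices can be jointly infeasible;
    this repair keeps them usable as latent covariances."""
    mat = np.asarray(mat, dtype=float)
    w, v = np.linalg.eigh((mat + mat.T) / 2.0)
    if w.min() >= eig_floor:
        return mat
    fixed = (v * np.maximum(w, eig_floor)) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


# ---------------------------------------------------------------------------
# fos cohort


@dataclass(frozen=True)
class MarginalSpec:
    """Count distribution of one region's fos+ cell number."""

    region: str
    family: str = "poisson"  # "poisson" | "negative-binomial"
    mean: float = 100.0
    dispersion: float | None = None  # nbinom size parameter; larger = less overdispersed

    def __post_init__(self):
        if self.family not in ("poisson", "negative-binomial"):
            raise ValueError(f"unknown marginal family {self.family!r}")
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.family == "negative-binomial" and (
            self.dispersion is None or self.dispersion <= 0
        ):
            raise ValueError("negative-binomial marginal needs dispersion > 0")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.family == "poisson":
            return stats.poisson.ppf(u, self.mean)
        size = self.dispersion
        return stats.nbinom.ppf(u, size, size / (size + self.mean))


@dataclass(frozen=True)
class ConditionCovSpec:
    """Target Spearman structure of one condition's regional coactivation."""

    condition: tuple[str, str]
    target_spearman: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.target_spearman, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("target_spearman must be square")
        if not np.allclose(m, m.T):
            raise ValueError("target_spearman must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("target_spearman must have unit diagonal")
        if np.abs(m).max() > 1:
            raise ValueError("target_spearman entries must lie in [-1, 1]")
        object.__setattr__(self, "target_spearman", m)

    def latent_pearson(self) -> np.ndarray:
        return nearest_psd_correlation(spearman_to_latent_pearson(self.target_spearman))


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full specification of a synthetic fos cohort."""

    regions: tuple = DEFAULT_REGIONS
    n_per_condition: int = 7
    marginals: tuple = ()
    covariances: tuple = ()
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_condition < 4:
            raise ValueError("n_per_condition must be >= 4 (Fisher variance needs n > 3)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        marginals = self.marginals or tuple(MarginalSpec(r) for r in self.regions)
        if sorted(m.region for m in marginals) != sorted(self.regions):
            raise ValueError("marginals must cover every region exactly once")
        covs = self.covariances or tuple(
            ConditionCovSpec(c, np.eye(len(self.regions))) for c in ALL_CONDITIONS
        )
        if sorted(c.condition for c in covs) != sorted(ALL_CONDITIONS):
            raise ValueError(f"covariances must cover all conditions {ALL_CONDITIONS}")
        for c in covs:
            if c.target_spearman.shape[0] != len(self.regions):
                raise ValueError(
                    f"covariance for {c.condition} has wrong dimension"
                )
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "marginals", tuple(marginals))
        object.__setattr__(self, "covariances", tuple(covs))

    def marginal_for(self, region: str) -> MarginalSpec:
        return next(m for m in self.marginals if m.region == region)

    # -- YAML / dict round trip ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "regions": list(self.regions),
            "n_per_condition": self.n_per_condition,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
            "marginals": [
                {"region": m.region, "family": m.family, "mean": m.mean,
                 **({"dispersion": m.dispersion} if m.dispersion is not None else {})}
                for m in self.marginals
            ],
            "covariances": [
                {"cycle": c.condition[0], "stress": c.condition[1],
                 "target_spearman": c.target_spearman.tolist()}
                for c in self.covariances
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCohortConfig":
        return cls(
            regions=tuple(d.get("regions", DEFAULT_REGIONS)),
            n_per_condition=d.get("n_per_condition", 7),
            marginals=tuple(MarginalSpec(**m) for m in d.get("marginals", ())),
            covariances=tuple(
                ConditionCovSpec((c["cycle"], c["stress"]),
                                 np.asarray(c["target_spearman"]))
                for c in d.get("covariances", ())
            ),
            missing_rate=d.get("missing_rate", 0.0),
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def sample_condition_counts(
    n: int,
    marginals: Sequence[MarginalSpec],
    target_spearman: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n copula-coupled count vectors with the planted rank structure."""
    spec = ConditionCovSpec(ALL_CONDITIONS[0], np.asarray(target_spearman))
    latent = spec.latent_pearson()
    try:
        chol = np.linalg.cholesky(latent + 1e-12 * np.eye(len(latent)))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - repaired upstream
        raise ValueError("latent correlation matrix is not PSD after repair") from exc
    z = rng.standard_normal((n, len(marginals))) @ chol.T
    u = stats.norm.cdf(z)
    counts = np.column_stack([m.ppf(u[:, j]) for j, m in enumerate(marginals)])
    return counts


def generate_fos_cohort(config: SyntheticCohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate a per-animal regional fos-count table for all 4 conditions.

    Returns a DataFrame with columns animal_id, cycle, stress and one column
    per region; missing measurements are NaN.  Bit-reproducible for a fixed
    config/seed.
    """
    rng = stream_rngs(config.seed if seed is None else seed)["fos"]
    marginals = [config.marginal_for(r) for r in config.regions]
    frames = []
    short = {"highE2": "hE2", "lowE2": "lE2", "control": "ctl", "MAS": "mas"}
    for cov in sorted(config.covariances, key=lambda c: ALL_CONDITIONS.index(c.condition)):
        cycle, stress = cov.condition
        counts = sample_condition_counts(config.n_per_condition, marginals,
                                         cov.target_spearman, rng)
        if config.missing_rate > 0:
            mask = rng.random(counts.shape) < config.missing_rate
            # every animal must keep >= 1 measured region
            for i in np.nonzero(mask.all(axis=1))[0]:
                mask[i, rng.integers(mask.shape[1])] = False
            counts = np.where(mask, np.nan, counts)
        df = pd.DataFrame(counts, columns=list(config.regions))
        df.insert(0, "animal_id", [
            f"{short[cycle]}-{short[stress]}-{i + 1:02d}"
            for i in range(config.n_per_condition)
        ])
        df.insert(1, "cycle", cycle)
        df.insert(2, "stress", stress)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return validate_fos_table(table)


# ---------------------------------------------------------------------------
# behavioral cohort


@dataclass(frozen=True)
class BehavioralGroupParams:
    """Moments of one condition's behavioral measures."""

    training_total_mean_s: float = 22.0
    training_total_sd_s: float = 5.0
    testing_total_mean_s: float = 15.0
    testing_total_sd_s: float = 4.0
    preference_ratio: float = 1.6
    p_first_entry_novel: float = 0.8
    mean_arm_entries: float = 40.0
    mean_distance_cm: float = 2200.0

    def __post_init__(self):
        if min(self.training_total_mean_s, self.testing_total_mean_s,
               self.preference_ratio, self.mean_arm_entries,
               self.mean_distance_cm) <= 0:
            raise ValueError("means and the preference ratio must be positive")
        if not 0 <= self.p_first_entry_novel <= 1:
            raise ValueError("p_first_entry_novel must lie in [0, 1]")


@dataclass(frozen=True)
class BehavioralEffectSpec:
    """Per-condition behavioral parameters.

    The defaults mirror the study's reported group structure: intact
    spatial memory (preference for the displaced object / novel arm) in
    both control groups and in stressed low-E2 mice, abolished preference
    (ratio 1, first-entry-novel below chance) in stressed high-E2 mice,
    with matched exploration totals and locomotion across groups.
    """

    groups: dict = field(default_factory=lambda: {
        ("highE2", "control"): BehavioralGroupParams(
            training_total_mean_s=24.4, testing_total_mean_s=16.3,
            preference_ratio=1.6, p_first_entry_novel=0.75,
            mean_arm_entries=40.3, mean_distance_cm=2235.0),
        ("lowE2", "control"): BehavioralGroupParams(
            training_total_mean_s=21.5, testing_total_mean_s=12.6,
            preference_ratio=1.6, p_first_entry_novel=0.875,
            mean_arm_entries=34.4, mean_distance_cm=2014.0),
        ("highE2", "MAS"): BehavioralGroupParams(
            training_total_mean_s=20.7, testing_total_mean_s=14.7,
            preference_ratio=1.0, p_first_entry_novel=0.333,
            mean_arm_entries=43.2, mean_distance_cm=2165.0),
        ("lowE2", "MAS"): BehavioralGroupParams(
            training_total_mean_s=23.7, testing_total_mean_s=15.1,
            preference_ratio=1.6, p_first_entry_novel=0.714,
            mean_arm_entries=49.7, mean_distance_cm=2358.0),
    })

    def __post_init__(self):
        if sorted(self.groups) != sorted(ALL_CONDITIONS):
            raise ValueError(f"groups must cover all conditions {ALL_CONDITIONS}")


def _lognormal(rng, mean, sd, size):
    """Log-normal draws with the given arithmetic mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _arm_walk(rng, n_entries: int, arms: tuple, first: str) -> tuple:
    """First-order walk over maze arms starting from the home arm: each
    entry moves to a uniformly chosen different arm."""
    seq = [first]
    current = first
    for _ in range(n_entries - 1):
        options = [a for a in arms if a != current]
        current = options[rng.integers(len(options))]
        seq.append(current)
    return tuple(seq)


def generate_behavior_cohort(
    spec: BehavioralEffectSpec = None,
    n_per_group: int = 8,
    seed: int = 0,
) -> tuple[list, list]:
    """Generate matched OLM and Y-maze session lists for all conditions.

    Exploration totals are log-normal with the specified group moments; the
    testing total is split between displaced and unmoved objects around the
    group's planted preference ratio; Y-maze entry logs are first-order arm
    walks whose first testing entry is novel with the group's probability.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    spec = spec or BehavioralEffectSpec()
    rng = stream_rngs(seed)["behavior"]
    olm_sessions, ymaze_sessions = [], []
    for (cycle, stress) in ALL_CONDITIONS:
        g = spec.groups[(cycle, stress)]
        train_tot = _lognormal(rng, g.training_total_mean_s, g.training_total_sd_s,
                               n_per_group)
        test_tot = _lognormal(rng, g.testing_total_mean_s, g.testing_total_sd_s,
                              n_per_group)
        # fraction of testing time on the displaced object, jittered around
        # the planted ratio r -> r/(1+r)
        f_pref = np.clip(rng.normal(g.preference_ratio / (1 + g.preference_ratio),
                                    0.03, n_per_group), 0.05, 0.95)
        f_train = np.clip(rng.normal(0.5, 0.03, n_per_group), 0.05, 0.95)
        first_novel = rng.random(n_per_group) < g.p_first_entry_novel
        n_train_entries = 1 + rng.poisson(g.mean_arm_entries * 1.8, n_per_group)
        n_test_entries = 1 + rng.poisson(g.mean_arm_entries, n_per_group)
        dist_train = np.abs(rng.normal(g.mean_distance_cm * 1.6,
                                       g.mean_distance_cm * 0.1, n_per_group))
        dist_test = np.abs(rng.normal(g.mean_distance_cm,
                                      g.mean_distance_cm * 0.1, n_per_group))
        for i in range(n_per_group):
            aid = f"{cycle}-{stress}-{i + 1:02d}"
            displaced = "A" if i % 2 == 0 else "B"  # counterbalanced
            t_move = train_tot[i] * f_train[i]
            t_stay = train_tot[i] - t_move
            a, b = (t_move, t_stay) if displaced == "A" else (t_stay, t_move)
            olm_sessions.append(bhv.OLMSession(
                aid, cycle, stress, a, b, displaced,
                test_tot[i] * f_pref[i], test_tot[i] * (1 - f_pref[i])))
            first = "novel" if first_novel[i] else "familiar"
            testing = (_arm_walk(rng, int(n_test_entries[i]), bhv.TESTING_ARMS, first)
                       )
            training = _arm_walk(
                rng, int(n_train_entries[i]), bhv.TRAINING_ARMS,
                "familiar")
            ymaze_sessions.append(bhv.YMazeSession(
                aid, cycle, stress, training, testing,
                float(dist_train[i]), float(dist_test[i])))
    return olm_sessions, ymaze_sessions


# ---------------------------------------------------------------------------
# cytology and hormones


@dataclass(frozen=True)
class SmearSpec:
    """Dirichlet concentrations over (nucleated, cornified, leukocyte).

    Defaults reflect the phase-typical compositions: estrus smears
    predominantly cornified; early-proestrus smears nucleated-dominant with
    some leukocytes and cornified cells.
    """

    phase: str
    concentrations: tuple

    def __post_init__(self):
        if self.phase not in ("early_proestrus", "estrus"):
            raise ValueError("phase must be early_proestrus or estrus")
        if len(self.concentrations) != 3 or any(c <= 0 for c in self.concentrations):
            raise ValueError("need 3 positive concentration parameters")

    @classmethod
    def default(cls, phase: str) -> "SmearSpec":
        conc = {
            "estrus": (1.0, 15.0, 2.0),
            "early_proestrus": (10.0, 3.0, 5.0),
        }[phase]
        return cls(phase, conc)


def generate_smears(n: int, spec: SmearSpec, seed: int = 0,
                    start_day: int = 0) -> list:
    """n smear compositions on the 3-part simplex (percentages sum to 100)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = stream_rngs(seed)["smears"]
    comps = rng.dirichlet(spec.concentrations, size=n) * 100.0
    # exact closure against float drift
    comps[:, 2] = 100.0 - comps[:, 0] - comps[:, 1]
    return [
        cyt.Smear(f"{spec.phase}-{i + 1:03d}", start_day + i,
                  float(c[0]), float(c[1]), float(c[2]))
        for i, c in enumerate(comps)
    ]


def generate_estradiol(
    phase: str,
    n: int,
    detection_limit: float = cyt.DETECTION_LIMIT_PG_ML,
    seed: int = 0,
    median_pg_ml: float | None = None,
    log_sd: float = 0.5,
    animal_ids: Sequence[str] | None = None,
) -> list:
    """Phase-dependent serum estradiol with detection-limit flagging.

    Draws are log-normal around a phase-typical median (9 pg/ml in early
    proestrus, 1.8 pg/ml in estrus — the latter placing the majority of
    draws below a 3 pg/ml kit sensitivity, as observed for estrus sera).
    """
    if phase not in ("early_proestrus", "estrus"):
        raise ValueError("phase must be early_proestrus or estrus")
    if detection_limit < 0:
        raise ValueError("detection_limit must be nonnegative")
    if median_pg_ml is None:
        median_pg_ml = 9.0 if phase == "early_proestrus" else 1.8
    rng = stream_rngs(seed)["hormones"]
    values = rng.lognormal(np.log(median_pg_ml), log_sd, n)
    ids = list(animal_ids) if animal_ids is not None else [
        f"{phase}-{i + 1:03d}" for i in range(n)
    ]
    return [
        cyt.HormoneSample(aid, float(v), detection_limit)
        for aid, v in zip(ids, values)
    ]


def generate_hormone_cytology_cohort(
    n_per_phase: int = 15, seed: int = 0
) -> tuple[list, list]:
    """Matched (hormone samples, smears) across both phases, one pair per
    animal — the input shape of the estradiol-vs-cytology correlation."""
    samples, smears = [], []
    for k, phase in enumerate(("early_proestrus", "estrus")):
        sm = generate_smears(n_per_phase, SmearSpec.default(phase), seed=seed + k)
        hs = generate_estradiol(phase, n_per_phase, seed=seed + k,
                                animal_ids=[s.animal_id for s in sm])
        smears.extend(sm)
        samples.extend(hs)
    return samples, smears


def generate_phase_series(
    animal_id: str, n_cycles: int, cycle_length: int = 5, seed: int = 0
) -> cyt.PhaseSeries:
    """Periodic daily phase series: one proestrus day then one estrus day
    per cycle, the rest indeterminate — the ~5-day mouse cycle in miniature."""
    if cycle_length < 3:
        raise ValueError("cycle_length must be >= 3")
    phases = []
    for _ in range(n_cycles):
        phases += ["early_proestrus", "estrus"] + ["indeterminate"] * (cycle_length - 2)
    phases.append("early_proestrus")  # closing onset so every cycle is measurable
    return cyt.PhaseSeries(animal_id, tuple(range(len(phases))), tuple(phases))
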