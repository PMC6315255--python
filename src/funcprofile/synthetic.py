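"""Synthetic cohorts with the statistical structure the pipeline assumes.

Each subject carries a latent physical-function score phi ~ N(0, 1).
Days are semi-Markov sequences of activity bouts: a bout's intensity
class is drawn with probability proportional to

    exp(base_weight_c + effect_size * phi * rank_c),

where rank_c is the class's centered intensity rank in [-1, 1], so
higher-functioning subjects tilt toward higher-intensity classes.  Bout
lengths are geometric (minimum 2 minutes) and within-bout counts are
conditionally independent draws from the class's Normal(mean, SD^2),
rounded and clipped at zero.  Nonwear appears as all-zero blocks longer
than 90 minutes (optionally salted with 1-2-minute sub-100 interruptions
to exercise the wear-time rule); daily wear time falls in a configured
10-14 h range, so every generated day is valid.

Capacity measures are monotone in phi — the 400-m walk time decreasing,
the 20-m pace and sit-stand rate increasing — plus Gaussian noise,
clipped positive.  Covariate distributions echo a knee-osteoarthritis
cohort (BMI 28.52 +/- 4.87, ~45% male, incidence-heavy subcohort mix)
and are independent of phi, so any held-out predictive gain of the
profile over the covariates is attributable to the activity data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DAY_MINUTES = 1440

#: (mean, SD) counts/min per intensity class, sedentary to vigorous,
#: including a low-SD moderate class around 3150 counts/min.
DEFAULT_TEMPLATES = (
    (50.0, 30.0),
    (400.0, 200.0),
    (1100.0, 500.0),
    (2000.0, 800.0),
    (3150.0, 350.0),
    (4500.0, 1000.0),
)
#: Log dwell weights favoring sedentary/light classes.
DEFAULT_BASE_WEIGHTS = (2.2, 1.2, 0.4, -0.4, -1.0, -1.8)

#: Capacity models: value = intercept + slope_phi*phi
#: + age_coef*(age-65) + bmi_coef*(BMI-28.5) + sex_coef*[male] + noise.
#: Age and BMI worsen every measure (longer 400-m time, slower pace,
#: slower sit-stands), mirroring the covariate signal a clinical
#: baseline model exploits; units are seconds, m/s, and reps/s.
DEFAULT_CAPACITY = {
    "walk400_time": {
        "intercept": 310.0, "slope_phi": -35.0, "age_coef": 1.6,
        "bmi_coef": 2.2, "sex_coef": -8.0, "noise_sd": 18.0,
    },
    "walk20_pace": {
        "intercept": 1.30, "slope_phi": 0.15, "age_coef": -0.007,
        "bmi_coef": -0.009, "sex_coef": 0.04, "noise_sd": 0.07,
    },
    "sitstand_rate": {
        "intercept": 0.45, "slope_phi": 0.08, "age_coef": -0.004,
        "bmi_coef": -0.005, "sex_coef": 0.02, "noise_sd": 0.04,
    },
}


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 150
    n_days: int = 7
    class_templates: tuple = DEFAULT_TEMPLATES
    base_weights: tuple = DEFAULT_BASE_WEIGHTS
    effect_size: float = 0.8          # latent-score -> dwell-weight tilt
    mean_bout_minutes: float = 20.0   # geometric bout length, min 2
    wear_minutes_range: tuple = (600, 840)   # 10-14 h
    midday_nonwear_prob: float = 0.25
    midday_nonwear_mean_extra: float = 30.0  # beyond the 91-min floor
    nonwear_interruptions: bool = False      # adversarial sub-100 blips
    capacity_params: dict = field(default_factory=lambda: dict(DEFAULT_CAPACITY))
    bmi_mean: float = 28.52
    bmi_sd: float = 4.87
    age_mean: float = 65.0
    age_sd: float = 9.0
    male_fraction: float = 0.4453
    subcohort_probs: tuple = (0.0030, 0.7446, 0.2524)  # control/incidence/progression
    seed: int = 0

    def __post_init__(self):
        if len(self.class_templates) != len(self.base_weights):
            raise ValueError("one base weight per class template")
        for m, s in self.class_templates:
            if m < 0 or s < 0:
                raise ValueError("class means and SDs must be nonnegative")
        lo, hi = self.wear_minutes_range
        if not (0 < lo <= hi <= DAY_MINUTES):
            raise ValueError("wear_minutes_range must fit in a day")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")


@dataclass
class SimulatedCohort:
    """Generated cohort plus the ground truth the generator knows."""

    epochs: pd.DataFrame
    covariates: pd.DataFrame
    capacity: pd.DataFrame
    ground_truth: pd.DataFrame
    config: SimulationConfig


def null_config(**overrides) -> SimulationConfig:
    """Zero-effect preset: activity independent of the latent score."""
    return SimulationConfig(effect_size=0.0, **overrides)


def adversarial_config(**overrides) -> SimulationConfig:
    """Nonwear blocks salted with short sub-100 interruptions."""
    return SimulationConfig(nonwear_interruptions=True, **overrides)


def width_scaled_config(scale: float = 700.0, **overrides) -> SimulationConfig:
    """Classes whose latent-score information lives at grid scale w*.

    Two mean levels (bin centers 0.5*w* and 2.5*w*) each host a low-SD
    and a high-SD class (0.21*w* and 1.21*w*: distinct SD bins at
    width w*, one bin at coarser widths).  Ranks follow template order,
    and the base weights cancel each mean level's first-order dwell
    response to the latent score, so the score is carried almost
    entirely by the within-level split that only a width-w* grid (or
    finer) resolves: coarser grids merge the SD pairs and lose it,
    finer grids pay fragmentation noise.  Longer bouts (30 min) keep
    segment-SD estimates inside their bins.  Used by the width-tuning
    self-consistency check.
    """
    ln3 = float(np.log(3.0))
    return SimulationConfig(
        class_templates=(
            (0.5 * scale, 150.0 / 700.0 * scale),
            (2.5 * scale, 150.0 / 700.0 * scale),
            (0.5 * scale, 850.0 / 700.0 * scale),
            (2.5 * scale, 850.0 / 700.0 * scale),
        ),
        base_weights=(0.0, ln3, ln3, 0.0),
        mean_bout_minutes=30.0,
        **overrides,
    )


def class_ranks(n_classes: int) -> np.ndarray:
    """Centered intensity ranks in [-1, 1]."""
    if n_classes == 1:
        return np.zeros(1)
    return np.linspace(-1.0, 1.0, n_classes)


def dwell_probabilities(phi: float, config: SimulationConfig) -> np.ndarray:
    """Softmax class-dwell probabilities for a subject."""
    logits = np.asarray(config.base_weights) + config.effect_size * phi * class_ranks(
        len(config.class_templates)
    )
    logits = logits - logits.max()
    w = np.exp(logits)
    return w / w.sum()


def simulate_subject_day(
    phi: float, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """One full 1440-minute day of counts for a subject."""
    lo, hi = config.wear_minutes_range
    wear_total = int(rng.integers(lo, hi + 1))
    slack = DAY_MINUTES - wear_total
    midday = 0
    if slack >= 2 * 91 and rng.random() < config.midday_nonwear_prob:
        midday = 91 + int(rng.geometric(1.0 / config.midday_nonwear_mean_extra))
        midday = min(midday, slack - 91)
    leading_max = slack - midday
    leading = int(rng.integers(91, leading_max + 1)) if leading_max > 91 else leading_max
    trailing = slack - midday - leading
    if 0 < trailing <= 90:  # avoid unflaggable short zero tails
        leading += trailing
        trailing = 0

    probs = dwell_probabilities(phi, config)
    p_geom = 1.0 / max(config.mean_bout_minutes - 1.0, 1.0)
    chunks = []
    total = 0
    while total < wear_total:
        c = int(rng.choice(len(probs), p=probs))
        mean, sd = config.class_templates[c]
        length = 1 + int(rng.geometric(p_geom))
        length = min(length, wear_total - total) if wear_total - total >= 2 else (
            wear_total - total
        )
        vals = np.clip(np.round(rng.normal(mean, sd, length)), 0, None) if sd > 0 else (
            np.full(length, round(mean))
        )
        chunks.append(vals.astype(np.int64))
        total += length
    wear = np.concatenate(chunks)[:wear_total]

    def nonwear_block(length):
        block = np.zeros(length, dtype=np.int64)
        if config.nonwear_interruptions and length > 20:
            for _ in range(int(rng.integers(1, 3))):
                pos = int(rng.integers(5, length - 7))
                k = int(rng.integers(1, 3))
                block[pos : pos + k] = rng.integers(1, 100, k)
        return block

    parts = [nonwear_block(leading)] if leading else []
    if midday:
        cut = int(rng.integers(1, wear_total))
        parts.extend([wear[:cut], nonwear_block(midday), wear[cut:]])
    else:
        parts.append(wear)
    if trailing:
        parts.append(nonwear_block(trailing))
    day = np.concatenate(parts)
    assert day.shape[0] == DAY_MINUTES
    return day


def _capacity_mean(phi: float, params: dict, covariates: dict | None) -> float:
    v = params["intercept"] + params["slope_phi"] * phi
    if covariates is not None:
        v += params.get("age_coef", 0.0) * (covariates["age"] - 65.0)
        v += params.get("bmi_coef", 0.0) * (covariates["bmi"] - 28.5)
        v += params.get("sex_coef", 0.0) * (1.0 if covariates["sex"] == "M" else 0.0)
    return v


def simulate_capacity(
    phi: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    covariates: dict | None = None,
) -> dict[str, float]:
    """Noisy capacity measures, monotone in phi, for one subject.

    When a covariate record is given, age/BMI/sex effects are added so
    a covariates-only baseline model has genuine signal to find.
    """
    out = {}
    for name, params in config.capacity_params.items():
        v = _capacity_mean(phi, params, covariates)
        sd = params.get("noise_sd", 0.0)
        if sd:
            v += rng.normal(0.0, sd)
        out[name] = float(max(v, 1e-3))
    return out


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full cohort: epoch traces, covariates, capacity, ground truth.

    Deterministic in config.seed; per-subject streams are derived from
    the master seed, so the cohort is reproducible byte for byte.
    """
    master = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(master.spawn(1)[0])
    n = config.n_subjects
    phis = cohort_rng.standard_normal(n)
    subject_ids = [f"S{i:04d}" for i in range(n)]
    base_date = pd.Timestamp("2020-03-02")

    epoch_frames = []
    cov_rows = []
    cap_rows = []
    gt_rows = []
    n_classes = len(config.class_templates)
    for i, (sid, phi) in enumerate(zip(subject_ids, phis)):
        srng = np.random.default_rng(np.random.SeedSequence([config.seed, 1000 + i]))
        counts = np.concatenate(
            [simulate_subject_day(phi, config, srng) for _ in range(config.n_days)]
        )
        stamps = pd.date_range(base_date, periods=config.n_days * DAY_MINUTES, freq="min")
        epoch_frames.append(
            pd.DataFrame({"subject_id": sid, "timestamp": stamps, "count": counts})
        )
        sex = "M" if srng.random() < config.male_fraction else "F"
        height = srng.normal(175.0, 7.0) if sex == "M" else srng.normal(162.0, 6.5)
        cov_rows.append(
            {
                "subject_id": sid,
                "bmi": max(float(srng.normal(config.bmi_mean, config.bmi_sd)), 14.0),
                "age": float(np.clip(srng.normal(config.age_mean, config.age_sd), 45, 90)),
                "sex": sex,
                "height": float(np.clip(height, 140, 205)),
                "oa_subcohort": ["control", "incidence", "progression"][
                    int(srng.choice(3, p=np.asarray(config.subcohort_probs)
                                    / np.sum(config.subcohort_probs)))
                ],
            }
        )
        cov = cov_rows[-1]
        cap = simulate_capacity(phi, config, srng, covariates=cov)
        cap_rows.append({"subject_id": sid, **cap})
        probs = dwell_probabilities(phi, config)
        gt = {"subject_id": sid, "phi": float(phi)}
        for j in range(n_classes):
            gt[f"dwell_prob_{j}"] = float(probs[j])
        for name, params in config.capacity_params.items():
            gt[f"noiseless_{name}"] = float(_capacity_mean(phi, params, cov))
        gt_rows.append(gt)

    epochs = pd.concat(epoch_frames, ignore_index=True)
    epochs["day"] = epochs["timestamp"].dt.normalize()
    epochs = epochs[["subject_id", "timestamp", "day", "count"]]
    covariates = pd.DataFrame(cov_rows)
    covariates["sex"] = pd.Categorical(covariates["sex"], categories=("F", "M"))
    covariates["oa_subcohort"] = pd.Categorical(
        covariates["oa_subcohort"],
        categories=("control", "incidence", "progression"),
    )
    capacity = pd.DataFrame(cap_rows)
    ground_truth = pd.DataFrame(gt_rows)
    # true ordinal categories via the pipeline's own quartile rule on
    # the noiseless capacity values
    from funcprofile.evaluation import quartile_categorize

    for name in config.capacity_params:
        vals = ground_truth[f"noiseless_{name}"].to_numpy()
        ground_truth[f"true_category_{name}"] = quartile_categorize(vals, vals)
    return SimulatedCohort(epochs, covariates, capacity, ground_truth, config)
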