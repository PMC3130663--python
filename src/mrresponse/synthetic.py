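"""Synthetic voxel-level MR signals and longitudinal xenograft cohorts.

Two layers of simulation:

* **Voxel level** — diffusion-weighted signal stacks following the
  mono-exponential decay model and DCE concentration time series following the
  Tofts model, with optional Gaussian or Rician noise.  These exercise the ADC
  and Ktrans estimators against known ground truth.

* **Animal level** — four treatment arms (untreated control, single-dose
  radiotherapy, androgen deprivation by castration, and the combination) of
  androgen-sensitive prostate-carcinoma xenografts.  Each animal carries
  tumor volume, serum PSA, ROI-mean ADC and ROI-mean Ktrans at days 0, 1 and
  9, and a day-30 endpoint volume.  Group-mean day-30 relative volume changes
  default to +940%, +60%, -40% and -64% with standard deviations 91%, 25%, 9%
  and 5% — the calibration anchors of the simulated experiment.

The generative link between early biomarker changes and the day-30 outcome is
a per-animal latent "resistance" structure: two independent standard-normal
latents drive the ADC and the Ktrans channels, and volume/PSA load partially
on their shared component.  The same latents (weighted, plus independent
outcome noise) drive the day-30 volume, so early functional-imaging changes
are genuinely — and complementarily — predictive of outcome.  The default
outcome-noise level makes the correlation between the noise-free generative
score and the realized within-group outcome equal to 0.90.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import AnimalRecord, Cohort, BIOMARKERS, GROUPS
from .dce import ConcentrationSeries, ToftsParams, VIFParams, tofts_forward_closed
from .dwi import DWStack

__all__ = [
    "GeneratorConfig",
    "NoiseModel",
    "simulate_cohort",
    "simulate_dw_stack",
    "simulate_dce_series",
    "oracle_correlation",
]

#: Day-30 relative volume change (V30/V0 - 1): group means and SDs.
DEFAULT_DAY30_MEAN = {"control": 9.40, "rt": 0.60, "adt": -0.40, "adt_rt": -0.64}
DEFAULT_DAY30_SD = {"control": 0.91, "rt": 0.25, "adt": 0.09, "adt_rt": 0.05}

#: Group-mean multiplicative biomarker changes, (day 1, day 9) relative to
#: day 0.  Effective therapy raises ADC (cell kill lowers restriction) and
#: lowers Ktrans (anti-vascular effect); androgen deprivation collapses PSA.
DEFAULT_BIOMARKER_EFFECT = {
    "adc": {
        "control": (1.00, 1.00),
        "rt": (1.05, 1.15),
        "adt": (1.08, 1.20),
        "adt_rt": (1.10, 1.25),
    },
    "ktrans": {
        "control": (1.00, 1.05),
        "rt": (0.90, 0.75),
        "adt": (0.85, 0.70),
        "adt_rt": (0.80, 0.60),
    },
    "volume": {
        "control": (1.10, 1.60),
        "rt": (1.05, 1.25),
        "adt": (0.97, 0.80),
        "adt_rt": (0.95, 0.75),
    },
    "psa": {
        "control": (1.10, 1.50),
        "rt": (1.00, 1.10),
        "adt": (0.70, 0.40),
        "adt_rt": (0.65, 0.35),
    },
}

#: Weights of the biomarker latents in the outcome score.  The two imaging
#: channels dominate; early volume/PSA changes track response only weakly.
DEFAULT_LATENT_WEIGHTS = {"adc": 1.0, "ktrans": 1.0, "volume": 0.15, "psa": 0.15}

#: Outcome noise SD on the standardized latent-score scale; 0.4843 makes the
#: generative-oracle correlation 1/sqrt(1 + sd^2) = 0.90.
DEFAULT_OUTCOME_NOISE_SD = 0.4843

#: Baseline (day 0) distributions: tumors enter at ~8 mm shortest diameter,
#: i.e. caliper volume near (8*8*8)/2 = 256 mm^3.
DEFAULT_BASELINES = {
    "volume": {"median": 256.0, "sigma_log": 0.25},
    "psa": {"median": 10.0, "sigma_log": 0.30},
    "adc": {"median": 1.0e-3, "sigma_log": 0.05},
    "ktrans": {"median": 5.0e-3, "sigma_log": 0.20},
}


@dataclass
class NoiseModel:
    """Measurement noise: ``none``, additive ``gaussian`` or magnitude
    ``rician`` (envelope of a complex Gaussian; output always non-negative).

    ``sigma`` is in the units of the signal it corrupts.  Rician noise is only
    meaningful for magnitude signals; Gaussian noise on a diffusion signal can
    produce non-positive values, which downstream ADC mapping flags invalid.
    """

    kind: str = "none"
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def apply(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        signal = np.asarray(signal, dtype=float)
        if self.kind == "none" or self.sigma == 0.0:
            return signal.copy()
        if self.kind == "gaussian":
            return signal + rng.normal(0.0, self.sigma, signal.shape)
        re = signal + rng.normal(0.0, self.sigma, signal.shape)
        im = rng.normal(0.0, self.sigma, signal.shape)
        return np.hypot(re, im)


#: The six diffusion-gradient directions of the acquisition protocol.
DEFAULT_DIRECTIONS = np.array(
    [[1, 0, 1], [-1, 0, 1], [0, 1, 1], [0, 1, -1], [1, 1, 0], [-1, 1, 0]], dtype=float
)


def _check_positive(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")


@dataclass
class GeneratorConfig:
    """Everything that defines a simulated cohort; defaults are the study
    conditions the package is calibrated to."""

    n_per_group: int = 8
    group_names: tuple[str, ...] = GROUPS
    day30_mean_relchange: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DAY30_MEAN)
    )
    day30_sd_relchange: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DAY30_SD)
    )
    biomarker_effect: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BIOMARKER_EFFECT.items()}
    )
    latent_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_WEIGHTS)
    )
    outcome_noise_sd: float = DEFAULT_OUTCOME_NOISE_SD
    #: loading of volume/PSA deviations on the shared (ADC+Ktrans) component
    shared_loading: float = 0.3
    #: latent-to-log-ratio coupling at day 1 and day 9
    latent_coupling: tuple[float, float] = (0.08, 0.20)
    #: lognormal measurement jitter SD on every observed ratio
    measurement_noise_sd: float = 0.02
    baselines: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BASELINES.items()}
    )
    #: relative volume change is floored here to keep volumes positive
    relchange_floor: float = -0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if len(self.group_names) != 4:
            raise ValueError("exactly 4 treatment groups are required")
        for g in self.group_names:
            if g not in self.day30_mean_relchange:
                raise ValueError(f"day30_mean_relchange missing group {g!r}")
            _check_positive("day30_sd_relchange", self.day30_sd_relchange[g])
        _check_positive("outcome_noise_sd", self.outcome_noise_sd)
        _check_positive("measurement_noise_sd", self.measurement_noise_sd)
        if not 0 <= self.shared_loading <= 1:
            raise ValueError("shared_loading must lie in [0, 1]")
        for name in BIOMARKERS:
            if name not in self.biomarker_effect:
                raise ValueError(f"biomarker_effect missing {name!r}")
            if name not in self.latent_weights:
                raise ValueError(f"latent_weights missing {name!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_names"] = list(self.group_names)
        d["latent_coupling"] = list(self.latent_coupling)
        d["biomarker_effect"] = {
            k: {g: list(v) for g, v in grp.items()}
            for k, grp in self.biomarker_effect.items()
        }
        return d


#: sign of the latent's effect on each observed biomarker ratio: a more
#: resistant tumor shows a smaller ADC rise and larger Ktrans/V/PSA.
_LATENT_SIGN = {"adc": -1.0, "ktrans": 1.0, "volume": 1.0, "psa": 1.0}


def _latent_score_sd(config: GeneratorConfig) -> float:
    """Population SD of the weighted latent score, from the analytic
    covariance of the biomarker deviations."""
    rho = config.shared_loading
    w = np.array([config.latent_weights[b] for b in BIOMARKERS])
    # deviations: adc = z_a, ktrans = z_k, volume/psa = rho*z_s + sqrt(1-rho^2)*eps
    # with z_s = (z_a + z_k)/sqrt(2).  All have unit variance.
    c_as = rho / math.sqrt(2.0)  # cov(z_a, dev_v) = cov(z_k, dev_v) etc.
    cov = np.array(
        [
            [1.0, 0.0, c_as, c_as],
            [0.0, 1.0, c_as, c_as],
            [c_as, c_as, 1.0, rho * rho],
            [c_as, c_as, rho * rho, 1.0],
        ]
    )
    return float(math.sqrt(w @ cov @ w))


def oracle_correlation(config: GeneratorConfig) -> float:
    """Correlation between the noise-free generative score and the realized
    standardized outcome: 1/sqrt(1 + outcome_noise_sd^2) when the latent
    weights are not all zero."""
    if _latent_score_sd(config) == 0.0:
        return 0.0
    return 1.0 / math.sqrt(1.0 + config.outcome_noise_sd**2)


def simulate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a full four-arm cohort; deterministic given ``config.seed``.

    Per animal: baseline values are lognormal; two independent latents (ADC
    channel, Ktrans channel) plus partially shared volume/PSA deviations
    perturb the group-mean multiplicative biomarker changes on the log scale;
    the day-30 relative volume change is the group mean plus the group SD
    times the standardized (latent score + noise), floored at
    ``relchange_floor``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2024]))
    rho = config.shared_loading
    score_sd = _latent_score_sd(config)
    noise_sd = config.outcome_noise_sd
    denom = math.sqrt(1.0 + noise_sd**2)

    animals: list[AnimalRecord] = []
    for group in config.group_names:
        mu_g = config.day30_mean_relchange[group]
        sd_g = config.day30_sd_relchange[group]
        for i in range(config.n_per_group):
            z_a, z_k, e_v, e_p, e_out = rng.normal(size=5)
            z_s = (z_a + z_k) / math.sqrt(2.0)
            dev = {
                "adc": z_a,
                "ktrans": z_k,
                "volume": rho * z_s + math.sqrt(1.0 - rho * rho) * e_v,
                "psa": rho * z_s + math.sqrt(1.0 - rho * rho) * e_p,
            }
            traj: dict[str, dict[int, float]] = {}
            for name in BIOMARKERS:
                base_cfg = config.baselines[name]
                v0 = base_cfg["median"] * math.exp(
                    base_cfg["sigma_log"] * rng.normal()
                )
                m1, m9 = config.biomarker_effect[name][group]
                values = {0: v0}
                for day, mean_ratio, coupling in (
                    (1, m1, config.latent_coupling[0]),
                    (9, m9, config.latent_coupling[1]),
                ):
                    log_ratio = (
                        math.log(mean_ratio)
                        + _LATENT_SIGN[name] * coupling * dev[name]
                        + config.measurement_noise_sd * rng.normal()
                    )
                    values[day] = v0 * math.exp(log_ratio)
                traj[name] = values

            score = config.outcome_noise_sd * e_out
            if score_sd > 0:
                score += sum(
                    config.latent_weights[b] * dev[b] for b in BIOMARKERS
                ) / score_sd
            relchange = mu_g + sd_g * score / denom
            relchange = max(relchange, config.relchange_floor)
            v30 = traj["volume"][0] * (1.0 + relchange)
            animals.append(
                AnimalRecord(
                    id=f"{group}_{i:04d}",
                    group=group,
                    volume=traj["volume"],
                    psa=traj["psa"],
                    adc=traj["adc"],
                    ktrans=traj["ktrans"],
                    v30=v30,
                )
            )
    return Cohort(animals=animals, config_snapshot=config.to_dict(), seed=config.seed)


def simulate_dw_stack(
    adc_true,
    s0,
    b_values=(0.0, 100.0),
    n_directions: int = 6,
    noise: NoiseModel = NoiseModel(),
    rng: np.random.Generator | int | None = None,
) -> DWStack:
    """Diffusion-weighted stack ``S(b, dir) = s0 * exp(-b * ADC)`` per voxel.

    Ground truth is isotropic (every direction decays identically); noise is
    drawn independently per (voxel, b, direction) measurement.  The b = 0 row
    is replicated across the direction axis as repeated acquisitions.
    """
    adc_true = np.atleast_1d(np.asarray(adc_true, dtype=float))
    s0 = np.broadcast_to(np.asarray(s0, dtype=float), adc_true.shape)
    b = np.asarray(b_values, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative b-value")
    if np.any(adc_true < 0):
        raise ValueError("adc_true must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    clean = s0[:, None] * np.exp(-b[None, :] * adc_true[:, None])
    stack = np.repeat(clean[:, :, None], n_directions, axis=2)
    noisy = noise.apply(stack, rng)
    directions = DEFAULT_DIRECTIONS[:n_directions] if n_directions <= 6 else None
    return DWStack(signals=noisy, b_values=b, directions=directions)


def simulate_dce_series(
    params: ToftsParams,
    vif: VIFParams = VIFParams(),
    times=None,
    noise: NoiseModel = NoiseModel(),
    rng: np.random.Generator | int | None = None,
) -> ConcentrationSeries:
    """Tissue concentration curve from the closed-form Tofts model plus
    pointwise noise.  Default grid: 12 s frames over 20 minutes."""
    if times is None:
        times = np.arange(0.0, 1200.0 + 1e-9, 12.0)
    clean = tofts_forward_closed(params, vif, times)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return ConcentrationSeries(times=clean.times, conc=noise.apply(clean.conc, rng))
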