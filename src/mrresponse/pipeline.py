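"""End-to-end treatment-response prediction.

Features are the day-1 and day-9 measurements of each selected biomarker
(ADC, Ktrans, tumor volume, PSA) normalized to the animal's own baseline
(day 0), plus four one-hot treatment-group codes.  The prediction target is
the baseline-normalized day-30 volume V30/V0.  Three input sets mirror the
study design: ADC + volume + PSA, Ktrans + volume + PSA, and all four
biomarkers together.

For each repeat, the cohort is split 50/25/25 into train/validation/test
(stratified by treatment arm), the target is standardized on the training
set, a back-propagation network is trained with validation-based early
stopping, and the Pearson correlation between predicted and measured
V30/V0 is computed on the held-out test animals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from . import bpnn, dce, dwi, synthetic
from .cohort import GROUPS, Cohort

__all__ = [
    "INPUT_SETS",
    "FeatureMatrix",
    "PredictionResult",
    "SimulationSpec",
    "StudyConfig",
    "build_features",
    "caliper_volume",
    "pearson",
    "run_simulation",
    "apply_imaging_path",
    "reproduce_study",
]

#: Biomarkers entering each named input set (canonical order preserved).
INPUT_SETS = {
    "adc": ("adc", "volume", "psa"),
    "ktrans": ("ktrans", "volume", "psa"),
    "all": ("adc", "ktrans", "volume", "psa"),
}


@dataclass
class FeatureMatrix:
    """Baseline-normalized features, one-hot group codes and the target."""

    x: pd.DataFrame
    y: np.ndarray
    animal_ids: list[str]
    groups: list[str]
    input_set: str

    @property
    def columns(self) -> list[str]:
        return list(self.x.columns)

    def __len__(self) -> int:
        return len(self.animal_ids)


@dataclass
class PredictionResult:
    """Aggregated prediction performance for one input set."""

    input_set: str
    per_repeat_r: list[float]
    per_repeat_p: list[float]
    pooled_r: float
    pooled_p: float
    predictions: pd.DataFrame
    seed: int

    @property
    def median_r(self) -> float:
        return float(np.median(self.per_repeat_r))

    @property
    def iqr_r(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.per_repeat_r, [25, 75])
        return float(lo), float(hi)


@dataclass
class SimulationSpec:
    """One prediction experiment: input set, network, splits and repeats."""

    input_set: str = "all"
    network: bpnn.NetworkConfig | None = None
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    n_repeats: int = 25
    seed: int = 0
    include_day0: bool = False

    def __post_init__(self) -> None:
        if self.input_set not in INPUT_SETS:
            raise ValueError(f"input_set must be one of {sorted(INPUT_SETS)}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be positive")


def build_features(
    cohort: Cohort, input_set: str = "all", include_day0: bool = False
) -> FeatureMatrix:
    """Assemble the feature matrix for one input set.

    Per biomarker the columns are ``<name>_d1`` and ``<name>_d9`` (ratios to
    day 0); the day-0 self-ratio is identically 1 and dropped unless
    ``include_day0``.  Four one-hot group columns follow.  Target: V30/V0.
    """
    params = INPUT_SETS[input_set]
    rows, targets, ids, groups = [], [], [], []
    for a in cohort.animals:
        row: dict[str, float] = {}
        for name in params:
            traj = a.trajectory(name)
            if not traj[0] > 0:
                raise ValueError(
                    f"animal {a.id}: non-positive day-0 {name} "
                    "(baseline normalization impossible)"
                )
            if include_day0:
                row[f"{name}_d0"] = 1.0
            row[f"{name}_d1"] = traj[1] / traj[0]
            row[f"{name}_d9"] = traj[9] / traj[0]
        for g in GROUPS:
            row[f"group_{g}"] = 1.0 if a.group == g else 0.0
        rows.append(row)
        targets.append(a.v30 / a.volume[0])
        ids.append(a.id)
        groups.append(a.group)
    x = pd.DataFrame(rows)
    return FeatureMatrix(
        x=x, y=np.asarray(targets), animal_ids=ids, groups=groups, input_set=input_set
    )


def caliper_volume(length: float, width: float) -> float:
    """Tumor volume (mm^3) from two caliper diameters: length^2 * width / 2,
    with length the longest diameter.  Swapped arguments are corrected with a
    warning."""
    if length <= 0 or width <= 0:
        raise ValueError("diameters must be positive")
    if width > length:
        warnings.warn("width exceeds length; swapping to enforce convention")
        length, width = width, length
    return length * length * width / 2.0


def pearson(pred, meas) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p-value from the t transform with
    n - 2 degrees of freedom."""
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if pred.size != meas.size:
        raise ValueError("length mismatch")
    n = pred.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(meas))):
        raise ValueError("non-finite values")
    dx = pred - pred.mean()
    dy = meas - meas.mean()
    sxx, syy = float(dx @ dx), float(dy @ dy)
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance")
    r = float(dx @ dy) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(_sstats.t.sf(abs(t), n - 2))
    return r, p


def _train_and_predict(
    features: FeatureMatrix,
    split: bpnn.SplitIndices,
    config: bpnn.NetworkConfig,
) -> tuple[np.ndarray, np.ndarray, bpnn.TrainingTrace]:
    """Rescale on the training set, train, predict the test set on the
    original scale.

    Inputs are standardized to the training mean/SD.  With a bounded (tanh)
    output unit the target is affinely mapped so the training range becomes
    [-0.8, 0.8]; with an identity output it is standardized instead.  The
    inverse map is applied to the predictions before evaluation.
    """
    x = features.x.to_numpy(dtype=float)
    y = features.y
    mu_x = x[split.train].mean(axis=0)
    sd_x = x[split.train].std(axis=0)
    sd_x[sd_x == 0] = 1.0
    xs = (x - mu_x) / sd_x
    if config.output_activation == "tanh":
        lo, hi = y[split.train].min(), y[split.train].max()
        offset = 0.5 * (hi + lo)
        scale = (hi - lo) / 1.6 or 1.0
    else:
        offset, scale = y[split.train].mean(), y[split.train].std() or 1.0
    y_t = (y - offset) / scale
    state, trace = bpnn.train(
        config,
        (xs[split.train], y_t[split.train]),
        (xs[split.validation], y_t[split.validation]),
    )
    pred = bpnn.forward(state, xs[split.test])[:, 0] * scale + offset
    return pred, y[split.test], trace


def run_simulation(cohort: Cohort, spec: SimulationSpec) -> PredictionResult:
    """Run one input-set experiment over ``n_repeats`` resampled splits.

    Each repeat draws a fresh stratified split and a fresh weight
    initialization (both derived from ``spec.seed``).  Pearson r is computed
    per repeat on the test animals (the headline statistic is the per-repeat
    median) and once on the pooled predictions of all repeats.
    """
    if len(cohort) < 8:
        raise ValueError("cohort too small for a 50/25/25 split")
    features = build_features(cohort, spec.input_set, spec.include_day0)
    base_net = spec.network or bpnn.NetworkConfig()
    groups = np.asarray(features.groups)

    per_r, per_p, frames = [], [], []
    for rep in range(spec.n_repeats):
        rep_seed = int(
            np.random.SeedSequence([spec.seed, rep]).generate_state(1, np.uint32)[0]
            % (2**31)
        )
        split = bpnn.split_data(
            len(features), spec.fractions, seed=rep_seed, groups=groups
        )
        config = replace(base_net, n_inputs=features.x.shape[1], seed=rep_seed)
        pred, meas, _ = _train_and_predict(features, split, config)
        if np.asarray(meas).std() == 0:
            raise ValueError("degenerate test set: zero variance in measured outcome")
        r, p = pearson(pred, meas)
        per_r.append(r)
        per_p.append(p)
        frames.append(
            pd.DataFrame(
                {
                    "repeat": rep,
                    "animal_id": [features.animal_ids[i] for i in split.test],
                    "group": groups[split.test],
                    "predicted": pred,
                    "measured": meas,
                }
            )
        )
    predictions = pd.concat(frames, ignore_index=True)
    pooled_r, pooled_p = pearson(predictions["predicted"], predictions["measured"])
    return PredictionResult(
        input_set=spec.input_set,
        per_repeat_r=per_r,
        per_repeat_p=per_p,
        pooled_r=pooled_r,
        pooled_p=pooled_p,
        predictions=predictions,
        seed=spec.seed,
    )


@dataclass
class StudyConfig:
    """Configuration of a full study reproduction."""

    generator: synthetic.GeneratorConfig = field(default_factory=synthetic.GeneratorConfig)
    network: bpnn.NetworkConfig | None = None
    input_sets: tuple[str, ...] = ("adc", "ktrans", "all")
    n_repeats: int = 25
    single_split: bool = False
    bypass_imaging: bool = True
    imaging_noise_dwi: float = 0.0
    imaging_noise_dce: float = 0.0
    n_voxels_dwi: int = 64
    n_voxels_dce: int = 8
    seed: int = 0


def apply_imaging_path(
    cohort: Cohort,
    seed: int = 0,
    n_voxels_dwi: int = 64,
    n_voxels_dce: int = 8,
    noise_dwi_sigma: float = 0.0,
    noise_dce_sigma: float = 0.0,
    ve: float = 0.3,
    s0: float = 1000.0,
) -> Cohort:
    """Replace each animal's ADC and Ktrans with imaging-derived estimates.

    Per animal and day, a voxel stack is simulated at the animal's true value
    (uniform over the ROI), the corresponding estimator is run and the
    ROI-mean estimate substitutes the ground truth — so biomarkers enter the
    features through the same estimation chain a real study would use.
    DW noise is Rician on the magnitude signal; DCE noise is Gaussian on
    concentration.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    vif = dce.VIFParams()
    times = np.arange(0.0, 1200.0 + 1e-9, 12.0)
    dwi_noise = synthetic.NoiseModel(
        kind="rician" if noise_dwi_sigma > 0 else "none", sigma=noise_dwi_sigma
    )
    dce_noise = synthetic.NoiseModel(
        kind="gaussian" if noise_dce_sigma > 0 else "none", sigma=noise_dce_sigma
    )

    new_animals = []
    for a in cohort.animals:
        adc_est, ktrans_est = {}, {}
        for day in (0, 1, 9):
            stack = synthetic.simulate_dw_stack(
                np.full(n_voxels_dwi, a.adc[day]), s0, (0.0, 100.0), 6, dwi_noise, rng
            )
            amap = dwi.compute_adc_map(stack)
            adc_est[day] = dwi.roi_mean(amap, dwi.ROIMask(np.arange(n_voxels_dwi))).mean

            params = dce.ToftsParams(ktrans=a.ktrans[day], ve=ve)
            conc = np.vstack(
                [
                    synthetic.simulate_dce_series(params, vif, times, dce_noise, rng).conc
                    for _ in range(n_voxels_dce)
                ]
            )
            results, _ = dce.fit_tofts_batch(conc, times, vif)
            ktrans_est[day] = dce.roi_mean_ktrans(
                results, np.arange(n_voxels_dce)
            ).mean
        new_animals.append(
            type(a)(
                id=a.id,
                group=a.group,
                volume=dict(a.volume),
                psa=dict(a.psa),
                adc=adc_est,
                ktrans=ktrans_est,
                v30=a.v30,
            )
        )
    return Cohort(
        animals=new_animals, config_snapshot=cohort.config_snapshot, seed=cohort.seed
    )


def reproduce_study(config: StudyConfig) -> dict:
    """Simulate a cohort and run the three input-set experiments.

    Returns a JSON-serializable report: per input set the per-repeat and
    pooled Pearson correlations, plus the resolved configuration and seeds.
    Deterministic given ``config.seed``.
    """
    gen = replace(config.generator, seed=config.seed)
    cohort = synthetic.simulate_cohort(gen)
    if not config.bypass_imaging:
        cohort = apply_imaging_path(
            cohort,
            seed=config.seed,
            n_voxels_dwi=config.n_voxels_dwi,
            n_voxels_dce=config.n_voxels_dce,
            noise_dwi_sigma=config.imaging_noise_dwi,
            noise_dce_sigma=config.imaging_noise_dce,
        )
    n_repeats = 1 if config.single_split else config.n_repeats
    report: dict = {
        "seed": config.seed,
        "n_animals": len(cohort),
        "bypass_imaging": config.bypass_imaging,
        "n_repeats": n_repeats,
        "generator_config": gen.to_dict(),
        "results": {},
    }
    for input_set in config.input_sets:
        spec = SimulationSpec(
            input_set=input_set,
            network=config.network,
            n_repeats=n_repeats,
            seed=config.seed,
        )
        res = run_simulation(cohort, spec)
        report["results"][input_set] = {
            "median_r": res.median_r,
            "iqr_r": list(res.iqr_r),
            "per_repeat_r": res.per_repeat_r,
            "pooled_r": res.pooled_r,
            "pooled_p": res.pooled_p,
        }
    return report
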