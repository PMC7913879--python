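"""Synthetic phantoms and cohorts.

Real paraspinal PDFF maps are not publicly distributable, so this module
generates volumetric stand-ins that exercise every pipeline stage:

* **Phantoms** — each muscle is an elliptic cylinder (axial ellipse
  extruded cranio-caudally) filled with a truncated-normal base PDFF
  field; fatty infiltration is modeled as high-PDFF prolate ellipsoids
  ("streaks") elongated along the cranio-caudal axis and placed at random
  in-mask positions.  More/brighter streaks mean a more heterogeneous
  fat distribution at a given mean fat content.
* **Cohorts** — subjects with sex, age and BMI drawn from the default
  healthy-adult distributions; four muscle phantoms each (erector spinae
  and psoas, both sides) with subject-specific heterogeneity; features
  extracted through the real pipeline; strength outcomes generated from a
  declared linear model on texture features and BMI plus Gaussian noise.
  The generating coefficients are returned as ground truth so recovery by
  the cohort statistics can be tested.

Defaults are calibrated so that cohort-mean PDFF lands near 10.5 % for
erector spinae and 4.8 % for psoas (females somewhat higher than males),
and generated torques span roughly 100-340 Nm.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .cohort_features import (
    SubjectRecord,
    bilateral_average,
    build_cohort_table,
)
from .exceptions import DomainError, PhantomConfigError, ToleranceError
from .preprocess import TextureConfig
from .texture_features import texture_profile
from .volume_io import MUSCLES, RoiMask, SIDES, VolumeGrid

__all__ = [
    "MuscleSpec",
    "PhantomConfig",
    "CohortConfig",
    "OutcomeModel",
    "default_phantom_config",
    "generate_phantom",
    "phantom_signals",
    "match_mean",
    "generate_cohort",
    "generate_cohort_table",
]


@dataclass(frozen=True)
class MuscleSpec:
    """Geometry and composition of one muscle's phantom.

    Lengths are in voxels; PDFF parameters in percent.
    """

    muscle: str
    side: str
    center: tuple[float, float]        # axial ellipse center (x, y)
    semi_axes: tuple[float, float]     # axial ellipse semi-axes (ax, ay)
    z_range: tuple[int, int]           # slices [z0, z1)
    base_pdff_mean: float = 10.0
    base_pdff_sd: float = 2.5
    n_streaks: int = 0
    streak_pdff_mean: float = 70.0
    streak_pdff_sd: float = 10.0
    streak_radius: float = 1.5         # in-plane semi-axis, voxels
    streak_halflength: float = 3.0     # cranio-caudal semi-axis, voxels

    def __post_init__(self) -> None:
        if not 0.0 <= self.streak_pdff_mean <= 100.0:
            raise PhantomConfigError(
                f"streak PDFF must be in [0, 100], got {self.streak_pdff_mean}")
        # base_pdff_mean is the *location* of a [0, 100]-truncated normal;
        # a location slightly outside the range is legitimate, the drawn
        # values are always within [0, 100]
        if not -50.0 <= self.base_pdff_mean <= 150.0:
            raise PhantomConfigError(
                f"base PDFF location out of range, got {self.base_pdff_mean}")
        if self.n_streaks < 0:
            raise PhantomConfigError("n_streaks must be >= 0")


@dataclass(frozen=True)
class PhantomConfig:
    """A full phantom: grid, spacing, muscle specs and the random seed."""

    shape: tuple[int, int, int] = (64, 44, 20)
    spacing: tuple[float, float, float] = (3.2, 2.0, 4.0)
    muscles: tuple[MuscleSpec, ...] = ()
    seed: int = 0


#: Muscle layouts: realistic-extent default and a reduced grid for
#: Monte-Carlo work.  (center, semi_axes) in voxels; z spans the grid.
_LAYOUTS = {
    "default": dict(
        shape=(64, 44, 20),
        es=dict(centers={"right": (20.0, 30.0), "left": (44.0, 30.0)},
                semi_axes=(8.0, 6.0), streak_radius=1.5, streak_halflength=3.0),
        ps=dict(centers={"right": (26.0, 14.0), "left": (38.0, 14.0)},
                semi_axes=(5.0, 4.0), streak_radius=1.0, streak_halflength=2.0),
    ),
    "small": dict(
        shape=(36, 26, 10),
        es=dict(centers={"right": (10.0, 17.0), "left": (26.0, 17.0)},
                semi_axes=(5.0, 4.0), streak_radius=1.0, streak_halflength=1.5),
        ps=dict(centers={"right": (14.0, 8.0), "left": (22.0, 8.0)},
                semi_axes=(3.2, 2.8), streak_radius=0.9, streak_halflength=1.5),
    ),
}


def default_phantom_config(seed: int = 0, layout: str = "default",
                           es_base_mean: float = 9.0, es_base_sd: float = 2.5,
                           ps_base_mean: float = 3.5, ps_base_sd: float = 1.5,
                           es_n_streaks: int = 2, ps_n_streaks: int = 3,
                           streak_pdff_mean: float = 70.0,
                           es_streak_pdff_mean: float | None = None,
                           ps_streak_pdff_mean: float | None = None,
                           streak_pdff_sd: float = 10.0) -> PhantomConfig:
    """Four-muscle phantom config (bilateral ES and PS) on a named layout."""
    lay = _LAYOUTS[layout]
    shape = lay["shape"]
    muscles = []
    streak_means = {"es": streak_pdff_mean if es_streak_pdff_mean is None
                    else es_streak_pdff_mean,
                    "ps": streak_pdff_mean if ps_streak_pdff_mean is None
                    else ps_streak_pdff_mean}
    for mkey, base_mean, base_sd, n_str in (
            ("es", es_base_mean, es_base_sd, es_n_streaks),
            ("ps", ps_base_mean, ps_base_sd, ps_n_streaks)):
        geo = lay[mkey]
        for side in SIDES:
            muscles.append(MuscleSpec(
                muscle=mkey.upper(), side=side,
                center=geo["centers"][side], semi_axes=geo["semi_axes"],
                z_range=(0, shape[2]),
                base_pdff_mean=base_mean, base_pdff_sd=base_sd,
                n_streaks=n_str,
                streak_pdff_mean=streak_means[mkey],
                streak_pdff_sd=streak_pdff_sd,
                streak_radius=geo["streak_radius"],
                streak_halflength=geo["streak_halflength"]))
    return PhantomConfig(shape=shape, muscles=tuple(muscles), seed=seed)


def _truncnorm_draw(rng, mean, sd, size, lo=0.0, hi=100.0):
    if sd <= 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _ellipse_mask(shape, spec: MuscleSpec) -> np.ndarray:
    cx, cy = spec.center
    ax, ay = spec.semi_axes
    x = np.arange(shape[0])[:, None]
    y = np.arange(shape[1])[None, :]
    inplane = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    z0, z1 = spec.z_range
    mask[:, :, z0:z1] = inplane[:, :, None]
    return mask


def generate_phantom(config: PhantomConfig
                     ) -> tuple[VolumeGrid, dict[tuple[str, str], RoiMask]]:
    """Generate the PDFF volume and per-muscle masks for one phantom.

    Deterministic given ``config.seed``.  Background (out-of-mask) voxels
    are 0 %.  Raises :class:`PhantomConfigError` if a streak does not fit
    inside its muscle.
    """
    rng = np.random.default_rng(config.seed)
    values = np.zeros(config.shape, dtype=np.float64)
    masks: dict[tuple[str, str], RoiMask] = {}
    for spec in config.muscles:
        fg = _ellipse_mask(config.shape, spec)
        if not fg.any():
            raise PhantomConfigError(
                f"{spec.muscle}/{spec.side}: ellipse produced an empty mask")
        n_fg = int(fg.sum())
        values[fg] = _truncnorm_draw(rng, spec.base_pdff_mean,
                                     spec.base_pdff_sd, n_fg)
        if spec.n_streaks > 0:
            z0, z1 = spec.z_range
            if (spec.streak_radius > min(spec.semi_axes)
                    or 2 * spec.streak_halflength > (z1 - z0)):
                raise PhantomConfigError(
                    f"{spec.muscle}/{spec.side}: streak larger than the muscle")
            fg_idx = np.argwhere(fg)
            xs = np.arange(config.shape[0])[:, None, None]
            ys = np.arange(config.shape[1])[None, :, None]
            zs = np.arange(config.shape[2])[None, None, :]
            for _ in range(spec.n_streaks):
                cx, cy, cz = fg_idx[rng.integers(len(fg_idx))]
                ell = (((xs - cx) / spec.streak_radius) ** 2
                       + ((ys - cy) / spec.streak_radius) ** 2
                       + ((zs - cz) / spec.streak_halflength) ** 2) <= 1.0
                hit = ell & fg
                values[hit] = _truncnorm_draw(rng, spec.streak_pdff_mean,
                                              spec.streak_pdff_sd,
                                              int(hit.sum()))
        masks[(spec.muscle, spec.side)] = RoiMask(
            values=fg, spacing=config.spacing,
            muscle=spec.muscle, side=spec.side)
    grid = VolumeGrid(values=values, spacing=config.spacing)
    return grid, masks


def phantom_signals(pdff: VolumeGrid) -> tuple[VolumeGrid, VolumeGrid]:
    """Consistent fat/water signal magnitudes for a PDFF map.

    With total signal fixed at 100 a.u., fat = PDFF and water = 100 - PDFF,
    so recomputing fat/(fat+water) recovers the map exactly.
    """
    fat = VolumeGrid(values=pdff.values.copy(), spacing=pdff.spacing,
                     origin=pdff.origin)
    water = VolumeGrid(values=100.0 - pdff.values, spacing=pdff.spacing,
                       origin=pdff.origin)
    return fat, water


def _realized_mean(config: PhantomConfig) -> float:
    grid, masks = generate_phantom(config)
    fg = np.zeros(config.shape, dtype=bool)
    for m in masks.values():
        fg |= m.values
    return float(grid.values[fg].mean())


def match_mean(config_a: PhantomConfig, config_b: PhantomConfig,
               tol: float = 0.1, max_iter: int = 20
               ) -> tuple[PhantomConfig, PhantomConfig]:
    """Adjust the more heterogeneous config so both realized means agree.

    The config with more total streaks has its base PDFF means lowered
    iteratively until the realized in-mask mean PDFF of the two phantoms
    differs by at most ``tol`` percentage points.  Lets one build pairs of
    phantoms that differ in fat *pattern* but not fat *content*.
    """
    n_a = sum(m.n_streaks for m in config_a.muscles)
    n_b = sum(m.n_streaks for m in config_b.muscles)
    streaky, other = (config_a, config_b) if n_a >= n_b else (config_b, config_a)
    target = _realized_mean(other)
    for _ in range(max_iter):
        diff = _realized_mean(streaky) - target
        if abs(diff) <= tol:
            out = (streaky, other) if n_a >= n_b else (other, streaky)
            return out
        muscles = tuple(
            dataclasses.replace(
                m, base_pdff_mean=float(np.clip(m.base_pdff_mean - diff, 0.0, 100.0)))
            for m in streaky.muscles)
        streaky = dataclasses.replace(streaky, muscles=muscles)
    raise ToleranceError(
        f"mean matching did not converge to {tol} % in {max_iter} iterations")


@dataclass(frozen=True)
class OutcomeModel:
    """Declared linear model generating one torque outcome (Nm)."""

    intercept: float
    coefficients: dict[str, float]   # cohort-table column -> coefficient
    noise_sd: float


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults for the synthetic cohort.

    Covariate distributions follow the healthy-adult cohort the package
    emulates: n = 26 with 15 females, age 30.27 +- 6.12 years, BMI
    27.01 +- 2.69 kg/m^2.  Sex shifts the erector-spinae base fat level
    (females higher).  Heterogeneity varies between subjects through the
    per-muscle streak count (uniform integers) and the subject's streak
    PDFF level (uniform 55-85 %).  Extension torque is generated from
    erector-spinae histogram kurtosis and BMI; flexion torque from psoas
    histogram variance and skewness.
    """

    n_subjects: int = 26
    female_fraction: float = 15 / 26
    age_mean: float = 30.27
    age_sd: float = 6.12
    bmi_mean: float = 27.01
    bmi_sd: float = 2.69
    layout: str = "default"
    # Per-sex target muscle-mean PDFF (percent) and its between-subject SD.
    # The generator compensates the base level for the expected streak
    # contribution, so a subject's realized mean PDFF tracks these targets
    # regardless of how heterogeneous the fat pattern is — fat content and
    # fat pattern vary independently across subjects.
    es_mean_male: float = 8.93
    es_mean_female: float = 11.65
    es_between_sd: float = 2.0
    es_within_sd: float = 2.5
    # Table 2 reports a significant sex difference only for erector spinae;
    # psoas means are pooled across sexes.
    ps_mean_male: float = 4.83
    ps_mean_female: float = 4.83
    ps_between_sd: float = 1.2
    ps_within_sd: float = 1.2
    es_max_streaks: int = 5
    ps_max_streaks: int = 3
    # Per-subject, per-muscle streak PDFF level, drawn uniformly.  The
    # independent variation of streak count (contamination fraction) and
    # streak level (contamination intensity) gives histogram variance and
    # skewness separate axes of variation.  Psoas streaks are weaker than
    # erector-spinae streaks, so that even the leanest psoas can host the
    # drawn contamination without its base level collapsing.
    es_streak_pdff_range: tuple[float, float] = (25.0, 70.0)
    ps_streak_pdff_range: tuple[float, float] = (12.0, 32.0)
    streak_pdff_sd: float = 10.0
    # Torque noise reflects dynamometer test-retest repeatability (a few
    # percent of typical MVIC values).
    extension_model: OutcomeModel = OutcomeModel(
        intercept=10.0,
        coefficients={"kurtosis_global_es": 1.5, "bmi": 6.0},
        noise_sd=8.0)
    flexion_model: OutcomeModel = OutcomeModel(
        intercept=100.0,
        coefficients={"variance_global_ps": 3.0, "skewness_global_ps": 12.0},
        noise_sd=8.0)
    seed: int = 0


@lru_cache(maxsize=None)
def _lattice_streak_volume(radius: float, halflength: float) -> int:
    """Voxel count of a discrete axis-aligned prolate ellipsoid."""
    rr, hh = int(math.floor(radius)), int(math.floor(halflength))
    count = 0
    for dx in range(-rr, rr + 1):
        for dy in range(-rr, rr + 1):
            for dz in range(-hh, hh + 1):
                if ((dx / radius) ** 2 + (dy / radius) ** 2
                        + (dz / halflength) ** 2) <= 1.0:
                    count += 1
    return count


@lru_cache(maxsize=None)
def _lattice_muscle_volume(layout: str, mkey: str) -> int:
    """Voxel count of a muscle's discrete elliptic cylinder."""
    lay = _LAYOUTS[layout]
    geo = lay[mkey]
    cx, cy = geo["centers"]["right"]
    ax, ay = geo["semi_axes"]
    nx, ny, nz = lay["shape"]
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    inplane = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0
    return int(inplane.sum()) * nz


def _streak_fraction_per_streak(layout: str, mkey: str) -> float:
    geo = _LAYOUTS[layout][mkey]
    return (_lattice_streak_volume(geo["streak_radius"], geo["streak_halflength"])
            / _lattice_muscle_volume(layout, mkey))


def _loc_for_truncated_mean(target: float, sd: float,
                            lo: float = 0.0, hi: float = 100.0) -> float:
    """Location parameter whose [lo, hi]-truncated normal has mean ``target``."""
    if sd <= 0 or (lo + 4 * sd) <= target <= (hi - 4 * sd):
        return target

    def gap(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - target

    return float(brentq(gap, lo - 12 * sd, hi + 12 * sd, xtol=1e-8))


def _subject_phantom(cfg: CohortConfig, rng, sex: str, seed: int) -> PhantomConfig:
    es_target = cfg.es_mean_female if sex == "female" else cfg.es_mean_male
    ps_target = cfg.ps_mean_female if sex == "female" else cfg.ps_mean_male
    es_target = float(np.clip(rng.normal(es_target, cfg.es_between_sd), 1.0, 40.0))
    ps_target = float(np.clip(rng.normal(ps_target, cfg.ps_between_sd), 1.0, 40.0))
    levels = {"es": float(rng.uniform(*cfg.es_streak_pdff_range)),
              "ps": float(rng.uniform(*cfg.ps_streak_pdff_range))}
    wanted = {"es": int(rng.integers(0, cfg.es_max_streaks + 1)),
              "ps": int(rng.integers(0, cfg.ps_max_streaks + 1))}
    # Solve target = (1 - f) * base + f * streak_level for the base level,
    # with f the streak volume fraction: the realized subject-mean PDFF then
    # tracks the target independently of the streak content.  If a lean
    # muscle cannot accommodate the drawn contamination (base level would
    # collapse), the streak count is reduced to the feasible maximum.
    base_locs, counts, sds = {}, {}, {}
    for mkey, target in (("es", es_target), ("ps", ps_target)):
        f1 = _streak_fraction_per_streak(cfg.layout, mkey)
        n = wanted[mkey]
        base_target = target
        while n > 0:
            f = n * f1
            base_target = (target - f * levels[mkey]) / (1.0 - f)
            if base_target >= 0.3:
                break
            n -= 1
        else:
            base_target = target
        counts[mkey] = n
        sds[mkey] = cfg.es_within_sd if mkey == "es" else cfg.ps_within_sd
        base_locs[mkey] = _loc_for_truncated_mean(float(base_target), sds[mkey])
    return default_phantom_config(
        seed=seed, layout=cfg.layout,
        es_base_mean=base_locs["es"], es_base_sd=sds["es"],
        ps_base_mean=base_locs["ps"], ps_base_sd=sds["ps"],
        es_n_streaks=counts["es"], ps_n_streaks=counts["ps"],
        es_streak_pdff_mean=levels["es"], ps_streak_pdff_mean=levels["ps"],
        streak_pdff_sd=cfg.streak_pdff_sd)


def generate_cohort(config: CohortConfig,
                    texture_config: TextureConfig = TextureConfig()
                    ) -> tuple[list[SubjectRecord], dict]:
    """Generate subjects end to end through the real feature pipeline.

    Returns the records and a ground-truth dict holding the declared
    outcome models and each subject's generating parameters, for recovery
    testing.  Deterministic given ``config.seed``.
    """
    if config.n_subjects < 10:
        raise DomainError("a synthetic cohort needs at least 10 subjects")
    master = np.random.default_rng(config.seed)
    n_female = int(round(config.female_fraction * config.n_subjects))
    sexes = ["female"] * n_female + ["male"] * (config.n_subjects - n_female)
    records: list[SubjectRecord] = []
    truth_subjects = []
    for i in range(config.n_subjects):
        sex = sexes[i]
        age = float(np.clip(master.normal(config.age_mean, config.age_sd), 20, 45))
        bmi = float(np.clip(master.normal(config.bmi_mean, config.bmi_sd), 20, 33))
        pseed = int(master.integers(0, 2 ** 31 - 1))
        pconfig = _subject_phantom(config, master, sex, pseed)
        grid, masks = generate_phantom(pconfig)
        sides = {}
        for muscle in MUSCLES:
            sides[muscle] = bilateral_average(
                texture_profile(grid, masks[(muscle, "right")], texture_config),
                texture_profile(grid, masks[(muscle, "left")], texture_config))
        row = {"bmi": bmi, "age": age}
        for m, fs in (("es", sides["ES"]), ("ps", sides["PS"])):
            for feat, val in fs.features.items():
                row[f"{feat}_{m}"] = val
        torques = {}
        for name, model in (("mvic_ext", config.extension_model),
                            ("mvic_flex", config.flexion_model)):
            mu = model.intercept + sum(c * row[k]
                                       for k, c in model.coefficients.items())
            torques[name] = max(float(mu + master.normal(0.0, model.noise_sd)), 5.0)
        records.append(SubjectRecord(
            subject_id=f"S{i + 1:03d}", sex=sex, age=age, bmi=bmi,
            es=sides["ES"], ps=sides["PS"],
            mvic_ext=torques["mvic_ext"], mvic_flex=torques["mvic_flex"]))
        truth_subjects.append({
            "subject_id": f"S{i + 1:03d}", "sex": sex,
            "phantom_seed": pseed,
            "es_n_streaks": pconfig.muscles[0].n_streaks,
            "ps_n_streaks": pconfig.muscles[2].n_streaks,
            "streak_pdff_mean": pconfig.muscles[0].streak_pdff_mean,
            "phantom_config": dataclasses.asdict(pconfig)})
    truth = {
        "extension": dataclasses.asdict(config.extension_model),
        "flexion": dataclasses.asdict(config.flexion_model),
        "subjects": truth_subjects,
    }
    return records, truth


def phantom_config_from_dict(d: dict) -> PhantomConfig:
    """Rebuild a :class:`PhantomConfig` from its ``dataclasses.asdict`` form."""
    muscles = tuple(
        MuscleSpec(**{**m,
                      "center": tuple(m["center"]),
                      "semi_axes": tuple(m["semi_axes"]),
                      "z_range": tuple(m["z_range"])})
        for m in d["muscles"])
    return PhantomConfig(shape=tuple(d["shape"]),
                         spacing=tuple(d["spacing"]),
                         muscles=muscles, seed=d["seed"])


def generate_cohort_table(config: CohortConfig,
                          texture_config: TextureConfig = TextureConfig()):
    """Cohort table (DataFrame) plus ground truth; see :func:`generate_cohort`."""
    records, truth = generate_cohort(config, texture_config)
    return build_cohort_table(records), truth
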