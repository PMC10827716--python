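"""Synthetic cohort generator with analytic ground truth.

Emulates the data of a rat photothrombotic-stroke stimulation-safety
experiment at the level the quantification pipeline consumes:

* serial coronal sections, two grayscale channels per anterior-posterior
  (AP) position — a degeneration-stain-like channel carrying a bright
  lesion disc, and a microglial-marker-like channel with Gaussian baseline
  plus perilesional, dose-dependent and tile-wise activation structure;
* behavioral logs — item-level mNSS scores per timepoint and
  pasta-handling trial records — whose group means default to the printed
  group trajectories of the study the pipeline models;
* a per-animal ground-truth record (analytic lesion volume, caudal lesion
  border, injected activated-tile fraction, behavioral targets), so tests
  can measure recovery rather than eyeball plausibility.

The lesion is modelled as a sphere of the illumination radius: each
section at AP offset ``d`` from the lesion center shows a disc of radius
``sqrt(R^2 - d^2)``, and the analytic volume is ``4/3*pi*R^3``. Everything
is driven by a single seed, fanned out per animal through stable
sub-seeding so that adding animals never perturbs existing ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .behavior import (ATYPICAL_BEHAVIORS, MNSS_ITEM_RANGES, MNSSItems,
                       PastaTrial)
from .dosimetry import STANDARD_DENSITIES
from .imaging import SectionImage
from .randomize import stratified_assign

ARM_LABELS = tuple(f"{d:.1f}" for d in STANDARD_DENSITIES)

#: Baseline exceedance of the mean + 1.5 SD rule on Gaussian tiles,
#: P(Z > 1.5); an activated-tile fraction f on top of it yields an
#: expected ipsi-contra ratio difference of f * (1 - P0).
P0_EXCEEDANCE = 0.066807


# --------------------------------------------------------------------------
# specs and ground truth


@dataclass
class LesionSpec:
    """Spherical lesion: stereotaxic center, radius and peak intensity.

    ``center_ap`` is mm from bregma (positive rostral); ``center_ml`` mm
    lateral of the midline on ``side``. Defaults follow the 5-mm-diameter
    illumination field centered at AP +1.5 / ML 3.5 on the left.
    """

    center_ap: float = 1.5
    center_ml: float = 3.5
    radius: float = 2.5
    peak_intensity: float = 180.0
    side: str = "left"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("lesion radius must be positive")
        if not (0 <= self.peak_intensity <= 255):
            raise ValueError("peak intensity outside the 8-bit dynamic range")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    def section_radius_mm(self, ap_mm: float) -> float:
        d = ap_mm - self.center_ap
        if abs(d) >= self.radius:
            return 0.0
        return math.sqrt(self.radius ** 2 - d ** 2)

    @property
    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius ** 3

    @property
    def caudal_border_mm(self) -> float:
        return self.center_ap - self.radius


@dataclass
class ReactivitySpec:
    """Microglial-channel structure: Gaussian baseline plus elevations.

    ``activated_tile_fraction`` is the fraction of ipsilesional analysis
    tiles elevated by ``activation_gain`` gray values (well above the
    mean + 1.5 SD classification threshold); ``dose_gain`` adds
    ``dose_gain * current_density`` over the whole ipsilesional
    hemisphere; perilesional elevation covers an annulus of
    ``perilesional_width`` mm outside the lesion rim.
    """

    baseline_mean: float = 60.0
    baseline_sd: float = 8.0
    perilesional_gain: float = 15.0
    perilesional_width: float = 0.3
    dose_gain: float = 0.0
    activated_tile_fraction: float = 0.0
    activation_gain: float = 8.0
    tile_um: float = 200.0

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")
        for g in (self.perilesional_gain, self.dose_gain, self.activation_gain):
            if g < 0:
                raise ValueError("gains must be non-negative")
        if not (0 <= self.activated_tile_fraction <= 1):
            raise ValueError("activated_tile_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually put into one animal's data."""

    true_volume_mm3: float
    true_caudal_border_mm: float | None
    true_activated_fraction: dict[str, float]
    group_effects: dict
    lesion_clipped: bool = False
    clipped_ap_mm: list[float] = field(default_factory=list)


# --------------------------------------------------------------------------
# image synthesis


def _disc_center_px(lesion: LesionSpec, midline_col: int, um_per_px: float,
                    n_rows: int) -> tuple[float, float]:
    ml_px = lesion.center_ml * 1000.0 / um_per_px
    col = midline_col + ml_px if lesion.side == "right" else midline_col - ml_px
    return n_rows / 2.0, col


def generate_section_stack(lesion: LesionSpec | None,
                           react: ReactivitySpec,
                           ap_positions: Sequence[float],
                           image_shape: tuple[int, int] = (600, 1200),
                           um_per_px: float = 10.0,
                           seed: int | np.random.Generator = 0,
                           current_density: float = 0.0,
                           animal_id: str = "A0",
                           midline_col: int | None = None,
                           lesion_side: str | None = None,
                           ) -> tuple[list[SectionImage], GroundTruth]:
    """Generate a two-channel serial-section stack plus its ground truth.

    Returns one ``fjc`` and one ``iba1`` :class:`SectionImage` per AP
    position (in that order per position). ``lesion=None`` produces a
    lesion-free animal; ``lesion_side`` defaults to the lesion's side (or
    "left" without a lesion). A lesion disc extending past the image
    border is clipped with a warning and recorded in the ground truth.
    """
    aps = [float(a) for a in ap_positions]
    if len(aps) == 0:
        raise ValueError("need at least one AP position")
    diffs = np.diff(aps)
    if len(aps) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("ap_positions must be strictly monotone")
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_rows, n_cols = image_shape
    midline = n_cols // 2 if midline_col is None else midline_col
    side = lesion_side or (lesion.side if lesion is not None else "left")

    rows_idx, cols_idx = np.mgrid[0:n_rows, 0:n_cols]
    ipsi_cols = (cols_idx >= midline) if side == "right" else (cols_idx < midline)
    tile_px = max(1, int(round(react.tile_um / um_per_px)))
    n_lat = min(midline, n_cols - midline) // tile_px
    n_tile_rows = n_rows // tile_px

    sections: list[SectionImage] = []
    clipped_aps: list[float] = []
    for ap in aps:
        meta = dict(ap_mm=ap, um_per_px=um_per_px, midline_col=midline,
                    lesion_side=side, animal_id=animal_id)

        # --- degeneration channel: background + lesion disc -------------
        fjc = rng.normal(20.0, 5.0, size=image_shape)
        disc = None
        if lesion is not None:
            r_mm = lesion.section_radius_mm(ap)
            if r_mm > 0:
                r_px = r_mm * 1000.0 / um_per_px
                cr, cc = _disc_center_px(lesion, midline, um_per_px, n_rows)
                disc = ((rows_idx - cr) ** 2 + (cols_idx - cc) ** 2) <= r_px ** 2
                if (cr - r_px < 0 or cr + r_px > n_rows
                        or cc - r_px < 0 or cc + r_px > n_cols):
                    clipped_aps.append(ap)
                fjc[disc] = lesion.peak_intensity + rng.normal(
                    0.0, 5.0, size=int(disc.sum()))
        sections.append(SectionImage(fjc, channel="fjc", **meta))

        # --- microglial channel: baseline + structured elevations --------
        iba = rng.normal(react.baseline_mean, react.baseline_sd,
                         size=image_shape)
        if lesion is not None and disc is not None:
            r_px = lesion.section_radius_mm(ap) * 1000.0 / um_per_px
            w_px = react.perilesional_width * 1000.0 / um_per_px
            cr, cc = _disc_center_px(lesion, midline, um_per_px, n_rows)
            dist2 = (rows_idx - cr) ** 2 + (cols_idx - cc) ** 2
            rim = (dist2 > r_px ** 2) & (dist2 <= (r_px + w_px) ** 2)
            iba[rim] += react.perilesional_gain
            iba[disc] += react.perilesional_gain  # core also reactive
        if react.dose_gain > 0 and current_density > 0:
            iba[ipsi_cols] += react.dose_gain * current_density
        if react.activated_tile_fraction > 0 and n_lat > 0 and n_tile_rows > 0:
            n_tiles = n_lat * n_tile_rows
            k = int(round(react.activated_tile_fraction * n_tiles))
            chosen = rng.choice(n_tiles, size=k, replace=False)
            for t in chosen:
                r, lat = divmod(int(t), n_lat)
                if side == "right":
                    c0 = midline + lat * tile_px
                else:
                    c0 = midline - (lat + 1) * tile_px
                iba[r * tile_px:(r + 1) * tile_px,
                    c0:c0 + tile_px] += react.activation_gain
        sections.append(SectionImage(iba, channel="iba1", **meta))

    if clipped_aps:
        warnings.warn(
            f"lesion disc clipped at the image border on {len(clipped_aps)} "
            "section(s); recorded in GroundTruth", stacklevel=2)
    truth = GroundTruth(
        true_volume_mm3=lesion.volume_mm3 if lesion is not None else 0.0,
        true_caudal_border_mm=(lesion.caudal_border_mm
                               if lesion is not None else None),
        true_activated_fraction={r: react.activated_tile_fraction
                                 for r in ("D", "E", "F")},
        group_effects={"current_density": current_density,
                       "dose_gain": react.dose_gain,
                       "activated_tile_fraction": react.activated_tile_fraction},
        lesion_clipped=bool(clipped_aps),
        clipped_ap_mm=clipped_aps,
    )
    return sections, truth


def lesion_exclusion_mask(lesion: LesionSpec | None, ap_mm: float,
                          image_shape: tuple[int, int] = (600, 1200),
                          um_per_px: float = 10.0,
                          midline_col: int | None = None,
                          margin_mm: float = 0.1) -> np.ndarray:
    """Binary exclusion mask covering the lesion core (plus a safety
    margin) on one section — the synthetic stand-in for the study's manual
    exclusion of the stroke area from tile analysis."""
    n_rows, n_cols = image_shape
    midline = n_cols // 2 if midline_col is None else midline_col
    mask = np.zeros(image_shape, dtype=bool)
    if lesion is None:
        return mask
    r_mm = lesion.section_radius_mm(ap_mm)
    if r_mm == 0:
        return mask
    r_px = (r_mm + margin_mm) * 1000.0 / um_per_px
    cr, cc = _disc_center_px(lesion, midline, um_per_px, n_rows)
    rows_idx, cols_idx = np.mgrid[0:n_rows, 0:n_cols]
    mask[(rows_idx - cr) ** 2 + (cols_idx - cc) ** 2 <= r_px ** 2] = True
    return mask


# --------------------------------------------------------------------------
# behavioral synthesis

# Per-arm mNSS target totals (mean, SD across animals) by timepoint.
# Post-stroke / post-stimulation defaults follow the printed group
# trajectories (SD = SEM * sqrt(n) with the histology group sizes
# 6/5/8/7); baseline sits near the floor.
MNSS_GROUP_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    "baseline": {a: (0.5, 0.5) for a in ARM_LABELS},
    "post_stroke": {"0.0": (7.56, 2.08), "0.8": (7.66, 3.00),
                    "31.8": (8.04, 1.50), "47.8": (8.14, 0.64)},
    "post_tdcs": {"0.0": (6.11, 2.96), "0.8": (5.60, 3.26),
                  "31.8": (5.74, 2.40), "47.8": (6.86, 0.42)},
}

MNSS_TIMEPOINTS = tuple(MNSS_GROUP_DEFAULTS)


@dataclass(frozen=True)
class PastaArmParams:
    """Targets for one arm x timepoint cell of the pasta task.

    Means/SDs are per-animal session means (SD = SEM * sqrt(n) with the
    pasta group sizes 5/4/4/5); trial-to-trial scatter inside a session is
    governed by ``duration_within_sd`` and the count distributions.
    """

    duration_mean: float
    duration_sd: float
    grasps_ipsi_mean: float
    grasps_ipsi_sd: float
    grasps_contra_mean: float
    grasps_contra_sd: float
    atypical_mean: float
    atypical_sd: float
    p_no_performance: float = 0.02
    p_break: float = 0.05
    duration_within_sd: float = 6.0


PASTA_GROUP_DEFAULTS: dict[str, dict[str, PastaArmParams]] = {
    "baseline": {
        "0.0": PastaArmParams(38.67, 19.3, 17.40, 5.4, 13.96, 6.5, 0.25, 0.31),
        "0.8": PastaArmParams(38.76, 3.7, 16.75, 8.2, 13.13, 3.0, 0.31, 0.38),
        "31.8": PastaArmParams(32.61, 8.2, 15.38, 10.9, 12.69, 9.1, 0.75, 0.36),
        "47.8": PastaArmParams(42.81, 14.2, 12.65, 6.4, 10.96, 6.6, 0.80, 0.58),
    },
    "day2": {
        "0.0": PastaArmParams(52.01, 19.8, 27.76, 6.1, 3.35, 3.7, 3.58, 0.89),
        "0.8": PastaArmParams(54.94, 16.2, 34.52, 11.7, 4.75, 4.5, 3.13, 1.78),
        "31.8": PastaArmParams(64.32, 36.0, 33.63, 21.6, 7.75, 6.2, 4.50, 0.40,
                               p_no_performance=0.15),
        "47.8": PastaArmParams(67.85, 22.4, 35.20, 13.7, 1.20, 1.3, 5.48, 1.43,
                               p_no_performance=0.10),
    },
}

PASTA_TIMEPOINTS = tuple(PASTA_GROUP_DEFAULTS)

# Per-arm injected activated-tile fractions. Chosen so the expected
# ipsi-contra high-tile ratio difference f*(1-P0) reproduces the printed
# per-arm group means (0.14 / 0.11 / 0.08 / 0.34): the stroke itself
# activates microglia in every arm, and only the highest stimulation
# intensity adds to it.
ACTIVATED_FRACTION_DEFAULTS: dict[str, float] = {
    "0.0": 0.150, "0.8": 0.118, "31.8": 0.086, "47.8": 0.364,
}
ACTIVATED_FRACTION_ANIMAL_SD = 0.06


def _allocate_items(total: float, rng: np.random.Generator) -> MNSSItems:
    """Distribute a target total into legal mNSS item scores.

    The total is quantized to thirds (the beam-balance item is a mean of
    three integer repetitions, so totals live on a 1/3 grid); whole points
    go to randomly ordered items with remaining capacity and the
    fractional remainder to the beam item.
    """
    total = float(np.clip(total, 0.0, 18.0))
    q = round(total * 3) / 3.0
    frac = q - math.floor(q)
    units = int(math.floor(q))
    caps = dict(MNSS_ITEM_RANGES)
    scores: dict[str, float] = {name: 0 for name in caps}
    if frac > 0:
        scores["beam_balance"] = frac
        caps["beam_balance"] -= 1  # leave room: int part + frac <= 6
    order = list(caps)
    while units > 0:
        rng.shuffle(order)
        placed = False
        for name in order:
            if scores[name] + 1 <= (caps[name] + (frac if name == "beam_balance" else 0)):
                scores[name] += 1
                units -= 1
                placed = True
                if units == 0:
                    break
        if not placed:  # all items saturated (total == 18)
            break
    # integer fields
    items = {k: (v if k == "beam_balance" else int(v))
             for k, v in scores.items()}
    beam = items["beam_balance"]
    reps = _beam_repetitions(beam)
    return MNSSItems(beam_repetitions=reps, **items)


def _beam_repetitions(beam_mean: float) -> tuple[int, int, int]:
    """Three integer 0-6 repetition scores averaging to ``beam_mean``
    (which lives on the 1/3 grid)."""
    total = round(beam_mean * 3)
    reps = [total // 3] * 3
    for i in range(total - 3 * (total // 3)):
        reps[i] += 1
    return tuple(int(r) for r in reps)  # type: ignore[return-value]


def generate_mnss_items(arm: str, timepoint: str,
                        group_params: dict | None = None,
                        seed: int | np.random.Generator = 0) -> MNSSItems:
    """Draw one animal-timepoint item set whose expected total matches the
    arm's configured trajectory (printed group means by default)."""
    if timepoint not in MNSS_TIMEPOINTS:
        raise ValueError(f"timepoint must be one of {MNSS_TIMEPOINTS}")
    params = group_params or MNSS_GROUP_DEFAULTS
    mu, sd = params[timepoint][arm]
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    total = mu if sd == 0 else rng.normal(mu, sd)
    return _allocate_items(total, rng)


def _between_sd(target_sd: float, within_var: float,
                n_trials: float = 4.0) -> float:
    """Animal-level SD that, combined with per-trial scatter averaged over
    ``n_trials`` trials, yields the target SD of animal means."""
    return math.sqrt(max(target_sd ** 2 - within_var / n_trials, 1e-4))


def generate_pasta_log(arm: str, timepoint: str,
                       group_params: dict | None = None,
                       seed: int | np.random.Generator = 0,
                       ) -> list[PastaTrial]:
    """Generate one animal's pasta session (the presented trials, in order).

    Presentation stops after the fourth valid trial or the fifth piece,
    mimicking the live stop rule, so the log holds at most five trials of
    which at most four are valid. Invalid trials occur with the configured
    no-performance / pasta-break probabilities.
    """
    if timepoint not in PASTA_TIMEPOINTS:
        raise ValueError(f"timepoint must be one of {PASTA_TIMEPOINTS}")
    params = (group_params or PASTA_GROUP_DEFAULTS)[timepoint][arm]
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    # animal-level latent session means
    dur_mu = max(5.0, rng.normal(params.duration_mean,
                                 _between_sd(params.duration_sd,
                                             params.duration_within_sd ** 2)))
    gi_mu = max(0.0, rng.normal(params.grasps_ipsi_mean,
                                _between_sd(params.grasps_ipsi_sd,
                                            params.grasps_ipsi_mean)))
    gc_mu = max(0.0, rng.normal(params.grasps_contra_mean,
                                _between_sd(params.grasps_contra_sd,
                                            params.grasps_contra_mean)))
    at_rate = float(np.clip(
        rng.normal(params.atypical_mean,
                   _between_sd(params.atypical_sd,
                               params.atypical_mean *
                               (1 - params.atypical_mean / 9.0))),
        0.0, 9.0))

    trials: list[PastaTrial] = []
    n_valid = 0
    for _ in range(5):
        u = rng.random()
        if u < params.p_no_performance:
            trials.append(PastaTrial(status="no_performance"))
        elif u < params.p_no_performance + params.p_break:
            trials.append(PastaTrial(status="pasta_break"))
        else:
            flags = {name: bool(rng.random() < at_rate / 9.0)
                     for name in ATYPICAL_BEHAVIORS}
            trials.append(PastaTrial(
                duration_s=max(1.0, rng.normal(dur_mu,
                                               params.duration_within_sd)),
                grasps_ipsi=int(rng.poisson(gi_mu)),
                grasps_contra=int(rng.poisson(gc_mu)),
                atypicals=flags,
                status="valid",
            ))
            n_valid += 1
        if n_valid == 4:
            break
    return trials


# --------------------------------------------------------------------------
# cohort assembly


@dataclass
class AnimalRecord:
    """One synthetic animal: arm, sub-seed, specs, behavior and truth.

    Section images are generated on demand (:meth:`sections`) so a cohort
    of full stacks never has to be resident in memory at once.
    """

    animal_id: str
    arm: str
    current_density: float
    seed_key: tuple[int, int]
    lesion: LesionSpec | None
    react: ReactivitySpec
    ap_positions: list[float]
    image_shape: tuple[int, int]
    um_per_px: float
    ground_truth: GroundTruth
    mnss: dict[str, MNSSItems]
    pasta: dict[str, list[PastaTrial]]

    def sections(self) -> list[SectionImage]:
        master, index = self.seed_key
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=master, spawn_key=(3, index)))
        sections, _ = generate_section_stack(
            self.lesion, self.react, self.ap_positions,
            image_shape=self.image_shape, um_per_px=self.um_per_px,
            seed=rng, current_density=self.current_density,
            animal_id=self.animal_id)
        return sections

    def exclusion_mask(self, ap_mm: float) -> np.ndarray:
        return lesion_exclusion_mask(self.lesion, ap_mm, self.image_shape,
                                     self.um_per_px)


def default_ap_positions() -> list[float]:
    """Default analyzed AP positions: a 0.3-mm volumetry ladder spanning
    the lesion plus three sections in each reactivity region window."""
    ladder = [round(-1.4 + 0.3 * i, 10) for i in range(20)]  # -1.4 .. +4.3
    regions = [-2.0, -1.85, -1.7, -0.1, 0.05, 0.2, 3.8, 4.15, 4.5]
    return sorted(set(ladder + regions))


@dataclass
class CohortConfig:
    """Everything the generator needs for one cohort.

    Per-arm sample sizes default to the study's final histology group
    sizes; behavioral and reactivity targets default to the printed group
    trajectories.
    """

    seed: int = 0
    arm_sizes: dict[str, int] = field(
        default_factory=lambda: {"0.0": 6, "0.8": 5, "31.8": 8, "47.8": 7})
    lesion: LesionSpec = field(default_factory=LesionSpec)
    # radius scatter implied by the printed volume dispersion
    # (SD_vol ~ 9 mm**3 => SD_r = SD_vol / (4*pi*r**2) ~ 0.1 mm)
    lesion_radius_sd: float = 0.1
    react: ReactivitySpec = field(default_factory=ReactivitySpec)
    activated_fraction_by_arm: dict[str, float] = field(
        default_factory=lambda: dict(ACTIVATED_FRACTION_DEFAULTS))
    activated_fraction_sd: float = ACTIVATED_FRACTION_ANIMAL_SD
    image_shape: tuple[int, int] = (600, 1200)
    um_per_px: float = 10.0
    ap_positions: list[float] = field(default_factory=default_ap_positions)
    mnss_params: dict = field(
        default_factory=lambda: {t: dict(d)
                                 for t, d in MNSS_GROUP_DEFAULTS.items()})
    pasta_params: dict = field(
        default_factory=lambda: {t: dict(d)
                                 for t, d in PASTA_GROUP_DEFAULTS.items()})
    mnss_timepoint_correlation: float = 0.7


@dataclass
class CohortDataset:
    """A generated cohort: animals plus the config echo."""

    animals: list[AnimalRecord]
    seed: int
    config: CohortConfig

    def manifest(self) -> list[dict]:
        return [{"animal_id": a.animal_id, "arm": a.arm,
                 "current_density": a.current_density,
                 "seed_key": list(a.seed_key)} for a in self.animals]


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> CohortDataset:
    """Generate a full cohort with stratified arm assignment.

    Animals 'arrive' in a seeded random order with a post-stroke mNSS
    drawn from the pooled severity distribution; each is assigned on
    arrival to the arm minimizing the arm-mean imbalance (the stratified
    step-by-step randomization), constrained to the configured per-arm
    sample sizes. Baseline and post-stimulation scores, the pasta
    sessions and the reactivity injection then follow the assigned arm's
    targets, correlated with the animal's post-stroke severity.
    """
    config = config or CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    master = config.seed
    arm_order = list(config.arm_sizes)
    n_total = sum(config.arm_sizes.values())
    if n_total < 1 or any(n < 1 for n in config.arm_sizes.values()):
        raise ValueError("every arm needs at least one animal")

    # pooled post-stroke severity: weighted mean/SD of the arm targets
    ps = config.mnss_params["post_stroke"]
    weights = np.array([config.arm_sizes[a] for a in arm_order], float)
    mus = np.array([ps[a][0] for a in arm_order])
    sds = np.array([ps[a][1] for a in arm_order])
    pooled_mu = float(np.average(mus, weights=weights))
    pooled_sd = float(np.average(sds, weights=weights))

    # separate streams for severity draws, assignment tie-breaks and the
    # per-animal data, so none shifts when the cohort grows
    latent_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=master, spawn_key=(1,)))
    assign_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=master, spawn_key=(2,)))
    z = latent_rng.standard_normal(n_total)
    post_stroke_targets = np.clip(pooled_mu + pooled_sd * z, 0, 18)

    labels = _capped_stratified_assign(post_stroke_targets, arm_order,
                                       config.arm_sizes, assign_rng)

    rho = config.mnss_timepoint_correlation
    animals: list[AnimalRecord] = []
    for i in range(n_total):
        arm = labels[i]
        density = float(arm)
        seed_key = (master, i)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=master, spawn_key=(3, i)))

        # behavioral scores: post-stroke from the pooled draw, the other
        # timepoints from arm targets, sharing the animal's latent severity
        mnss: dict[str, MNSSItems] = {}
        mnss["post_stroke"] = _allocate_items(post_stroke_targets[i], rng)
        for tp in ("baseline", "post_tdcs"):
            mu, sd = config.mnss_params[tp][arm]
            eps = rng.standard_normal()
            total = mu + sd * (rho * z[i] + math.sqrt(1 - rho ** 2) * eps)
            mnss[tp] = _allocate_items(total, rng)

        pasta = {tp: generate_pasta_log(arm, tp, config.pasta_params, rng)
                 for tp in PASTA_TIMEPOINTS}

        radius = max(0.5, rng.normal(config.lesion.radius,
                                     config.lesion_radius_sd))
        lesion = replace(config.lesion, radius=radius)
        f_arm = config.activated_fraction_by_arm.get(arm, 0.0)
        f = float(np.clip(rng.normal(f_arm, config.activated_fraction_sd),
                          0.0, 1.0))
        react = replace(config.react, activated_tile_fraction=f)

        truth = GroundTruth(
            true_volume_mm3=lesion.volume_mm3,
            true_caudal_border_mm=lesion.caudal_border_mm,
            true_activated_fraction={r: f for r in ("D", "E", "F")},
            group_effects={
                "arm": arm, "current_density": density,
                "activated_tile_fraction": f,
                "mnss_targets": {tp: config.mnss_params[tp][arm]
                                 for tp in MNSS_TIMEPOINTS},
            },
        )
        animals.append(AnimalRecord(
            animal_id=f"A{i:02d}", arm=arm, current_density=density,
            seed_key=seed_key, lesion=lesion, react=react,
            ap_positions=list(config.ap_positions),
            image_shape=config.image_shape, um_per_px=config.um_per_px,
            ground_truth=truth, mnss=mnss, pasta=pasta))
    return CohortDataset(animals=animals, seed=master, config=config)


def _capped_stratified_assign(scores: Sequence[float], arm_order: list[str],
                              arm_sizes: dict[str, int],
                              rng: np.random.Generator) -> list[str]:
    """Stratified sequential assignment under fixed per-arm capacities.

    Uses the same balance objective as :func:`~strokequant.randomize.
    stratified_assign` but never overfills an arm; with equal capacities
    it reduces to that function's behavior.
    """
    n_arms = len(arm_order)
    sums = np.zeros(n_arms)
    counts = np.zeros(n_arms, dtype=int)
    caps = np.array([arm_sizes[a] for a in arm_order])
    out: list[str] = []
    for s in scores:
        best_key, best = None, []
        for a in range(n_arms):
            if counts[a] >= caps[a]:
                continue
            sums[a] += s
            counts[a] += 1
            means = sums[counts > 0] / counts[counts > 0]
            fill = counts / caps
            key = (round(float(fill.max() - fill.min()), 12),
                   round(float(means.max() - means.min()), 12))
            sums[a] -= s
            counts[a] -= 1
            if best_key is None or key < best_key:
                best_key, best = key, [a]
            elif key == best_key:
                best.append(a)
        choice = best[rng.integers(len(best))]
        sums[choice] += s
        counts[choice] += 1
        out.append(arm_order[choice])
    return out
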