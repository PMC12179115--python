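"""Synthetic TSPO-PET cohorts with known ground-truth hemispheric asymmetry.

Generates subjects from two PET centres with per-region SRTM parameters,
reference and target time-activity curves on realistic frame schedules, and a
configurable right-minus-left DVR difference, so every downstream stage
(fitting, asymmetry metrics, inference) can be validated against known truth.

Conventions
-----------
* The injected asymmetry is applied on the DVR scale:
  ``DVR_side = DVR_bilateral * (1 +/- rel_diff/200)`` so the configured
  relative difference is exact in expectation on the scale reported.
* The reference (bilateral cerebellar grey matter) curve is a bi-exponential
  surge ``amp * (exp(-lam1 t) - exp(-lam2 t))`` — the simplest shape with a
  realistic peak-then-washout and a closed-form peak time for testing.
* Frame noise is Gaussian with variance proportional to value/duration on the
  decay-corrected data (no decay factor, since simulated TACs are defined as
  decay-corrected).
* One RNG stream per subject, spawned from the master seed and the subject
  index, so cohorts are extensible without reshuffling earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .kinetics import (
    FrameSchedule,
    PiecewiseLinearCurve,
    SRTMParams,
    TimeActivityCurve,
    manchester_schedule,
    srtm_forward,
    turku_schedule,
)

__all__ = [
    "REGIONS",
    "REFERENCE_REGION",
    "CohortConfig",
    "SubjectRecord",
    "GroundTruth",
    "generate_cohort",
    "simulate_reference_tac",
    "simulate_subject_tacs",
    "add_noise",
    "generate_phantom_image",
    "cohort_to_frame",
    "schedule_for_centre",
    "NOISE_FLOOR",
]

#: Bilateral regions analysed for asymmetry (six ROIs plus hemispheric composites).
REGIONS = (
    "thalamus",
    "putamen",
    "temporal",
    "frontal",
    "occipital",
    "parietal",
    "grey_matter",
    "brain_gmwm",
)

#: Bilateral cerebellar grey matter, used as pseudoreference tissue.
REFERENCE_REGION = "cerebellum_gm"

#: Small positive floor (kBq/mL) in the frame-noise variance model.
NOISE_FLOOR = 0.05

_SIDES = ("left", "right")


def _default_baseline_dvr() -> dict[str, float]:
    # bilateral means consistent with healthy-cohort PK11195 medians
    return {
        "thalamus": 1.18,
        "putamen": 1.10,
        "temporal": 1.03,
        "frontal": 1.10,
        "occipital": 1.10,
        "parietal": 1.10,
        "grey_matter": 1.08,
        "brain_gmwm": 1.08,
    }


def _default_asym() -> dict[str, float]:
    # signed right-minus-left relative differences (%), positive = right > left
    return {
        "thalamus": 3.09,
        "putamen": 3.55,
        "temporal": 2.78,
        "frontal": 1.96,
        "occipital": 0.76,
        "parietal": 1.66,
        "grey_matter": 1.87,
        "brain_gmwm": 1.90,
    }


def _default_volume_ml() -> dict[str, float]:
    # per-side volumes (mL), order-of-magnitude realistic
    return {
        "thalamus": 7.0,
        "putamen": 5.0,
        "temporal": 90.0,
        "frontal": 120.0,
        "occipital": 50.0,
        "parietal": 70.0,
        "grey_matter": 600.0,
        "brain_gmwm": 1100.0,
    }


def _default_volume_asym() -> dict[str, float]:
    # signed volume asymmetry (%): subcortical leftward, cortical rightward,
    # parietal null — matching the qualitative pattern in healthy cohorts
    return {
        "thalamus": -2.0,
        "putamen": -2.0,
        "temporal": 2.0,
        "frontal": 2.0,
        "occipital": 2.0,
        "parietal": 0.0,
        "grey_matter": 1.5,
        "brain_gmwm": 1.5,
    }


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic two-centre cohort.

    Defaults emulate the 76-subject reference cohort (50 Manchester, 26 Turku)
    with a ~1.9% rightward grey-matter DVR difference; ``pair_sd`` and
    ``noise_alpha`` are calibrated so the paired Cohen's d of fitted
    grey-matter DVRs lands near 1.1.
    """

    n_per_centre: Mapping[str, int] = field(
        default_factory=lambda: {"Manchester": 50, "Turku": 26}
    )
    baseline_dvr: Mapping[str, float] = field(default_factory=_default_baseline_dvr)
    asym_rel_diff_pct: Mapping[str, float] = field(default_factory=_default_asym)
    subject_sd: float = 0.04
    pair_sd: float = 0.015
    r1_mean: float = 1.0
    r1_sd: float = 0.05
    k2_ref: float = 0.15
    age_range: tuple[float, float] = (22.0, 62.0)
    sex_female_prop: Mapping[str, float] = field(
        default_factory=lambda: {"Manchester": 20 / 50, "Turku": 18 / 26}
    )
    handedness_props: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "Manchester": (44 / 50, 5 / 50, 1 / 50),
            "Turku": (15 / 26, 3 / 26, 8 / 26),
        }
    )
    injected_activity_mbq: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"Manchester": (650.0, 110.0), "Turku": (495.0, 15.0)}
    )
    body_weight_kg: tuple[float, float] = (75.0, 12.0)
    volume_ml: Mapping[str, float] = field(default_factory=_default_volume_ml)
    vol_asym_rel_diff_pct: Mapping[str, float] = field(default_factory=_default_volume_asym)
    vol_pair_sd_pct: float = 2.0
    suv_rel_diff_pct: float = 1.9
    amp_per_dose: float = 6.0  # kBq/mL per MBq/kg of injected dose
    lam1: float = 0.05  # reference washout rate, 1/min
    lam2: float = 0.5  # reference uptake rate, 1/min
    noise_alpha: float = 0.13
    seed: int = 0

    def __post_init__(self) -> None:
        for centre, n in self.n_per_centre.items():
            if n < 0:
                raise ValueError(f"negative subject count for centre {centre!r}")
        total = sum(self.n_per_centre.values())
        if total == 0 and any(v != 0 for v in self.asym_rel_diff_pct.values()):
            raise ValueError("empty cohort cannot carry a non-zero asymmetry")
        for region, dvr in self.baseline_dvr.items():
            if dvr <= 0:
                raise ValueError(f"baseline DVR for {region!r} must be positive")
        for region, a in self.asym_rel_diff_pct.items():
            if abs(a) >= 200:
                raise ValueError(f"|relative difference| must be < 200% ({region!r})")
        if self.pair_sd < 0 or self.subject_sd < 0:
            raise ValueError("pair_sd and subject_sd must be non-negative")
        if self.noise_alpha < 0:
            raise ValueError("noise_alpha must be non-negative")
        if not self.lam2 > self.lam1 > 0:
            raise ValueError("need lam2 > lam1 > 0 for a surge-shaped reference")
        for centre, p in self.sex_female_prop.items():
            if not 0 <= p <= 1:
                raise ValueError(f"female proportion for {centre!r} outside [0, 1]")
        for centre, props in self.handedness_props.items():
            if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-6:
                raise ValueError(
                    f"handedness proportions for {centre!r} must sum to 1"
                )

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.baseline_dvr)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    centre: str
    age: float
    sex: str
    handedness: str
    injected_activity_mbq: float
    body_weight_kg: float

    def __post_init__(self) -> None:
        if self.age <= 0 or self.injected_activity_mbq <= 0 or self.body_weight_kg <= 0:
            raise ValueError("age, injected activity and body weight must be positive")


@dataclass
class GroundTruth:
    """True simulation parameters: the recovery-test oracle.

    ``params`` has one row per subject x region x side (R1, k2, BP_ND, DVR);
    ``volumes`` the true per-side volumes (mL); ``intercepts`` the per-subject
    global DVR intercept draws; ``cerebellum_scale`` per-side multiplicative
    scales of the reference curve used for the cerebellar SUV asymmetry.
    """

    params: pd.DataFrame
    volumes: pd.DataFrame
    intercepts: pd.DataFrame
    cerebellum_scale: pd.DataFrame

    def subject_params(self, subject_id: str) -> pd.DataFrame:
        return self.params[self.params.subject_id == subject_id]


def _subject_rng(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


def schedule_for_centre(centre: str) -> FrameSchedule:
    if centre == "Manchester":
        return manchester_schedule()
    if centre == "Turku":
        return turku_schedule()
    raise ValueError(f"unknown centre {centre!r}")


def generate_cohort(config: CohortConfig) -> tuple[list[SubjectRecord], GroundTruth]:
    """Draw a deterministic cohort of subjects plus their ground truth."""
    subjects: list[SubjectRecord] = []
    param_rows: list[dict] = []
    vol_rows: list[dict] = []
    intercept_rows: list[dict] = []
    cereb_rows: list[dict] = []
    index = 0
    for centre, count in config.n_per_centre.items():
        p_female = config.sex_female_prop.get(centre, 0.5)
        hand_p = config.handedness_props.get(centre, (1.0, 0.0, 0.0))
        act_mean, act_sd = config.injected_activity_mbq.get(centre, (550.0, 100.0))
        for _ in range(count):
            rng = _subject_rng(config.seed, index)
            sid = f"{centre[:3].upper()}{index:03d}"
            age = float(rng.uniform(*config.age_range))
            sex = "female" if rng.random() < p_female else "male"
            handedness = str(rng.choice(["right", "left", "unknown"], p=hand_p))
            activity = float(np.clip(rng.normal(act_mean, act_sd), 100.0, None))
            weight = float(np.clip(rng.normal(*config.body_weight_kg), 45.0, None))
            subjects.append(
                SubjectRecord(sid, centre, age, sex, handedness, activity, weight)
            )
            intercept = float(rng.normal(0.0, config.subject_sd)) if config.subject_sd else 0.0
            intercept_rows.append({"subject_id": sid, "intercept": intercept})
            for region in config.regions:
                dvr_bilat = config.baseline_dvr[region] + intercept
                rel = config.asym_rel_diff_pct.get(region, 0.0) / 100.0
                pair_noise = float(rng.normal(0.0, config.pair_sd)) if config.pair_sd else 0.0
                dvr_right = dvr_bilat * (1.0 + rel / 2.0) + pair_noise / 2.0
                dvr_left = dvr_bilat * (1.0 - rel / 2.0) - pair_noise / 2.0
                vol = config.volume_ml.get(region, 50.0)
                vrel = config.vol_asym_rel_diff_pct.get(region, 0.0) / 100.0
                vnoise = float(rng.normal(0.0, config.vol_pair_sd_pct / 100.0 * vol))
                for side, dvr_side, vol_side in (
                    ("left", dvr_left, vol * (1 - vrel / 2) - vnoise / 2),
                    ("right", dvr_right, vol * (1 + vrel / 2) + vnoise / 2),
                ):
                    r1 = float(rng.normal(config.r1_mean, config.r1_sd))
                    k2 = r1 * config.k2_ref
                    param_rows.append(
                        {
                            "subject_id": sid,
                            "centre": centre,
                            "region": region,
                            "side": side,
                            "R1": r1,
                            "k2": k2,
                            "BP_ND": dvr_side - 1.0,
                            "DVR": dvr_side,
                        }
                    )
                    vol_rows.append(
                        {
                            "subject_id": sid,
                            "region": region,
                            "side": side,
                            "volume_ml": max(vol_side, 0.1),
                        }
                    )
            srel = config.suv_rel_diff_pct / 100.0
            snoise = float(rng.normal(0.0, config.pair_sd)) if config.pair_sd else 0.0
            cereb_rows.append(
                {
                    "subject_id": sid,
                    "scale_left": 1.0 - srel / 2.0 - snoise / 2.0,
                    "scale_right": 1.0 + srel / 2.0 + snoise / 2.0,
                }
            )
            index += 1
    truth = GroundTruth(
        params=pd.DataFrame(
            param_rows,
            columns=["subject_id", "centre", "region", "side", "R1", "k2", "BP_ND", "DVR"],
        ),
        volumes=pd.DataFrame(vol_rows, columns=["subject_id", "region", "side", "volume_ml"]),
        intercepts=pd.DataFrame(intercept_rows, columns=["subject_id", "intercept"]),
        cerebellum_scale=pd.DataFrame(
            cereb_rows, columns=["subject_id", "scale_left", "scale_right"]
        ),
    )
    return subjects, truth


def cohort_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Subject metadata as a tidy table (one row per subject)."""
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "centre": s.centre,
                "age": s.age,
                "sex": s.sex,
                "handedness": s.handedness,
                "injected_activity_MBq": s.injected_activity_mbq,
                "body_weight_kg": s.body_weight_kg,
            }
            for s in subjects
        ]
    )


def simulate_reference_tac(
    schedule: FrameSchedule, amp: float, lam1: float, lam2: float
) -> TimeActivityCurve:
    """Frame-averaged bi-exponential reference curve.

    Continuous model ``C_R(t) = amp (exp(-lam1 t) - exp(-lam2 t))`` for t >= 0,
    zero before injection; frame values are exact analytic averages
    (integral over the frame / duration).
    """
    if not lam2 > lam1 > 0:
        raise ValueError("need lam2 > lam1 > 0 (surge shape)")
    if amp <= 0:
        raise ValueError("amplitude must be positive")
    a = np.maximum(schedule.start_array, 0.0)
    b = np.maximum(schedule.end_array, 0.0)
    with np.errstate(over="ignore"):
        integral = amp * (
            (np.exp(-lam1 * a) - np.exp(-lam1 * b)) / lam1
            - (np.exp(-lam2 * a) - np.exp(-lam2 * b)) / lam2
        )
    width = b - a
    vals = np.where(width > 0, integral / np.where(width > 0, width, 1.0), 0.0)
    return TimeActivityCurve(schedule, np.maximum(vals, 0.0), label=REFERENCE_REGION)


def reference_amplitude(config: CohortConfig, subject: SubjectRecord) -> float:
    """Reference-curve amplitude scaled to the subject's injected dose per kg."""
    return config.amp_per_dose * subject.injected_activity_mbq / subject.body_weight_kg


def simulate_subject_tacs(
    subject: SubjectRecord,
    truth: GroundTruth,
    schedule: FrameSchedule,
    ref: TimeActivityCurve,
) -> dict[tuple[str, str], TimeActivityCurve]:
    """Noiseless SRTM forward TACs for every region x side of one subject.

    The bilateral cerebellum entry equals the reference curve itself.
    """
    rows = truth.subject_params(subject.subject_id)
    if rows.empty:
        raise KeyError(f"no ground truth for subject {subject.subject_id!r}")
    out: dict[tuple[str, str], TimeActivityCurve] = {}
    for row in rows.itertuples():
        params = SRTMParams(r1=row.R1, k2=row.k2, bp_nd=row.BP_ND)
        tac = srtm_forward(params, ref, schedule)
        out[(row.region, row.side)] = TimeActivityCurve(
            schedule, tac.values, label=f"{row.region}_{row.side}"
        )
    out[(REFERENCE_REGION, "bilateral")] = TimeActivityCurve(
        schedule, ref.values.copy(), label=REFERENCE_REGION
    )
    return out


def require_regions(
    tacs: Mapping[tuple[str, str], TimeActivityCurve], regions: tuple[str, ...]
) -> None:
    """Validate that every requested bilateral region is present."""
    for region in regions:
        for side in _SIDES:
            if (region, side) not in tacs:
                raise KeyError(f"missing TAC for region {region!r} side {side!r}")


def add_noise(
    tac: TimeActivityCurve, alpha: float, seed: int
) -> TimeActivityCurve:
    """Frame noise: value + N(0, alpha * sqrt(max(value, floor) / duration)).

    Deterministic given the seed; negative outputs are allowed, as in real
    decay-corrected PET data.
    """
    if alpha < 0:
        raise ValueError("noise scale must be non-negative")
    if alpha == 0:
        return TimeActivityCurve(tac.schedule, tac.values.copy(), tac.label)
    rng = np.random.default_rng(seed)
    sigma = alpha * np.sqrt(
        np.maximum(tac.values, NOISE_FLOOR) / tac.schedule.durations
    )
    noisy = tac.values + rng.normal(0.0, 1.0, size=tac.values.size) * sigma
    return TimeActivityCurve(tac.schedule, noisy, tac.label)


# ----------------------------------------------------------------------------
# digital phantom (image-mode exercise)
# ----------------------------------------------------------------------------

_PHANTOM_REGIONS = ("thalamus", "putamen", "temporal", "frontal", "occipital", "parietal")
_CORTICAL = {"temporal", "frontal", "occipital", "parietal"}


def _phantom_layout(shape: tuple[int, int, int]) -> dict[tuple[str, str], tuple]:
    """Mirror-placed 2x2x2 blobs for each region x side plus cerebellum."""
    nx, ny, nz = shape
    if nx < 16 or ny < 16 or nz < 10:
        raise ValueError("phantom grid too small to hold the paired region blobs")
    blobs: dict[tuple[str, str], tuple] = {}
    names = list(_PHANTOM_REGIONS) + [REFERENCE_REGION]
    for i, region in enumerate(names):
        y = 2 + (2 * i) % (ny - 4)
        z = 2 + 2 * ((2 * i) // (ny - 4))
        left = (slice(2, 4), slice(y, y + 2), slice(z, z + 2))
        right = (slice(nx - 4, nx - 2), slice(y, y + 2), slice(z, z + 2))
        blobs[(region, "left")] = left
        blobs[(region, "right")] = right
    return blobs


def generate_phantom_image(
    config: CohortConfig,
    shape: tuple[int, int, int] = (24, 24, 16),
    voxel_size_mm: float = 4.0,
    shell_value: float = 0.49,
    noise_alpha: float = 0.0,
):
    """Build a 4D dynamic phantom plus label volume and GM probability map.

    Each labelled blob carries the forward-model TAC of one region x side of
    the first simulated subject; left/right blobs are mirror-placed across the
    midline.  Cortical blobs have GM probability 1 with a one-voxel boundary
    shell at ``shell_value`` (straddling the 0.5 threshold by choice of value).

    Returns ``(image4d, labels, gm_probability, legend, truth_tacs, schedule)``
    where ``legend`` maps label id -> (region, side).
    """
    subjects, truth = generate_cohort(config)
    if not subjects:
        raise ValueError("phantom generation needs at least one subject")
    subject = subjects[0]
    schedule = schedule_for_centre(subject.centre)
    ref = simulate_reference_tac(
        schedule, reference_amplitude(config, subject), config.lam1, config.lam2
    )
    tacs = simulate_subject_tacs(subject, truth, schedule, ref)
    blobs = _phantom_layout(shape)

    n_frames = schedule.n_frames
    image = np.zeros(shape + (n_frames,), dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    pmap = np.zeros(shape, dtype=float)
    legend: dict[int, tuple[str, str]] = {}
    rng = np.random.default_rng(config.seed + 7_777)
    for lbl, ((region, side), sl) in enumerate(blobs.items(), start=1):
        if region == REFERENCE_REGION:
            tac = tacs[(REFERENCE_REGION, "bilateral")]
        else:
            tac = tacs[(region, side)]
        vals = tac.values
        if noise_alpha > 0:
            vals = add_noise(tac, noise_alpha, int(rng.integers(2**31))).values
        image[sl] = vals
        labels[sl] = lbl
        legend[lbl] = (region, side)
        if region in _CORTICAL or region == REFERENCE_REGION:
            pmap[sl] = 1.0
            shell = tuple(
                slice(max(s.start - 1, 0), min(s.stop + 1, dim))
                for s, dim in zip(sl, shape)
            )
            shell_mask = np.zeros(shape, dtype=bool)
            shell_mask[shell] = True
            shell_mask[sl] = False
            pmap[shell_mask & (pmap < 0.5)] = shell_value
    return image, labels, pmap, legend, tacs, schedule
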