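"""Synthetic longitudinal cohort generator.

Emulates a four-cohort, four-timepoint mental-training design: two 9-month
training cohorts that traverse three 3-month modules in mirrored orders, one
single-module active-control cohort, and an untrained retest cohort.  Known
ground-truth effects (standardized subfield volume shifts per module, a latent
coupling between volume change and diurnal cortisol output change, planted
seed-connectivity networks) are injected so that every downstream stage of the
pipeline can be validated by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "COHORTS",
    "TIMEPOINTS",
    "INTERVALS",
    "SUBFIELDS",
    "MODULES",
    "RETEST",
    "SALIVA_OFFSETS",
    "SimulationConfig",
    "ScanRecord",
    "CohortDataset",
    "module_schedule",
    "simulate_cohort",
    "inject_missingness",
]

COHORTS = ("TC1", "TC2", "TC3", "RCC")
TIMEPOINTS = ("T0", "T1", "T2", "T3")
INTERVALS = (("T0", "T1"), ("T1", "T2"), ("T2", "T3"))
SUBFIELDS = ("L_SUB", "R_SUB", "L_CA1-3", "R_CA1-3", "L_CA4-DG", "R_CA4-DG")
MODULES = ("Presence", "Affect", "Perspective")
RETEST = "retest"

#: designed saliva sampling occasions, minutes after awakening
SALIVA_OFFSETS = (0, 30, 60, 240, 360, 480, 600)

_SCHEDULE: dict[str, dict[tuple[str, str], str | None]] = {
    "TC1": {
        ("T0", "T1"): "Presence",
        ("T1", "T2"): "Affect",
        ("T2", "T3"): "Perspective",
    },
    "TC2": {
        ("T0", "T1"): "Presence",
        ("T1", "T2"): "Perspective",
        ("T2", "T3"): "Affect",
    },
    "TC3": {
        ("T0", "T1"): "Affect",
        ("T1", "T2"): None,
        ("T2", "T3"): None,
    },
    "RCC": {iv: RETEST for iv in INTERVALS},
}

N_PARCELS = 400
N_PARCELS_PER_HEMI = 200


def module_schedule(cohort: str, interval: tuple[str, str]) -> str | None:
    """Return the training module a cohort undergoes during an interval.

    ``interval`` must be a consecutive timepoint pair.  Returns the module
    label, ``"retest"`` for the untrained cohort, or ``None`` where the
    cohort has no scheduled activity (the single-module cohort after its
    training block).
    """
    if cohort not in _SCHEDULE:
        raise ValueError(f"unknown cohort: {cohort!r}")
    interval = tuple(interval)  # type: ignore[assignment]
    if interval not in _SCHEDULE[cohort]:
        raise ValueError(
            f"interval {interval!r} is not a consecutive timepoint pair "
            f"among {TIMEPOINTS}"
        )
    return _SCHEDULE[cohort][interval]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_n_per_cohort() -> dict[str, int]:
    return {"TC1": 80, "TC2": 81, "TC3": 81, "RCC": 90}


def _default_volume_means() -> dict[str, float]:
    # template-space subfield volumes, mm^3 (plausible magnitudes)
    return {
        "L_SUB": 650.0, "R_SUB": 650.0,
        "L_CA1-3": 1700.0, "R_CA1-3": 1700.0,
        "L_CA4-DG": 750.0, "R_CA4-DG": 750.0,
    }


def _default_module_effects() -> dict[tuple[str, str], float]:
    # standardized volume-change shift per (module, subfield); "CA1-3"
    # without a hemisphere prefix applies bilaterally
    return {("Affect", "CA1-3"): 0.35}


@dataclass
class SimulationConfig:
    """All generating parameters of a synthetic cohort.

    Defaults reproduce the study design sizes (TC1=80, TC2=81, TC3=81,
    RCC=90) and the headline ground truth: a standardized Affect effect of
    0.35 on bilateral CA1-3 volume change and a latent correlation of
    -0.23 between CA1-3 volume change and diurnal cortisol output change.
    """

    n_per_cohort: dict[str, int] = field(default_factory=_default_n_per_cohort)
    age_mean: float = 40.7
    age_sd: float = 9.2
    age_range: tuple[float, float] = (20.0, 55.0)
    sex_ratio: float = 197.0 / 332.0  # fraction female
    timepoints: tuple[str, ...] = TIMEPOINTS

    # volumes (mm^3)
    volume_baseline_mean: dict[str, float] = field(default_factory=_default_volume_means)
    volume_baseline_sd: float = 120.0
    volume_change_sd: float = 160.0
    module_effects: dict[tuple[str, str], float] = field(default_factory=_default_module_effects)

    # diurnal cortisol, log-nmol/l scale
    cortisol_level: float = 2.2
    cortisol_level_between_sd: float = 0.25
    car_amplitude: float = 0.8
    car_peak_min: float = 40.0
    decay_rate: float = 0.0028  # log-units per minute
    cortisol_noise_sd: float = 0.12
    aucg_shift_sd: float = 0.18  # per-interval latent level shift, log units
    sample_jitter_min: float = 15.0

    # couplings (latent correlations with CA1-3 volume change)
    brain_cortisol_coupling: float = -0.23
    hair_coupling: float = -0.20

    # hair steroids, log pg/mg
    hair_level: float = 1.6
    hair_between_sd: float = 0.35
    hair_shift_sd: float = 0.25
    hair_noise_sd: float = 0.10
    cortisone_offset: float = 1.0

    # fMRI
    with_fmri: bool = True
    n_timepoints_fmri: int = 210
    network_size: int = 20
    seed_signal_weight: float = 0.9
    network_weight: float = 0.6
    background_weight: float = 0.0
    netfc_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    netfc_weight_sd: float = 0.05

    # head motion
    fd_mean: float = 0.15
    fd_sd: float = 0.05
    fd_spike_rate: float = 0.01
    fd_spike_scale: float = 0.6

    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for cohort, n in self.n_per_cohort.items():
            if cohort not in COHORTS:
                raise ValueError(f"unknown cohort in n_per_cohort: {cohort!r}")
            if n <= 0:
                raise ValueError(f"cohort count must be > 0, got {cohort}={n}")
        for name in ("age_sd", "volume_baseline_sd", "volume_change_sd",
                     "cortisol_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("brain_cortisol_coupling", "hair_coupling"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"|{name}| must be < 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 < self.sex_ratio < 1:
            raise ValueError("sex_ratio must be in (0, 1)")
        if self.n_timepoints_fmri < 30:
            raise ValueError("n_timepoints_fmri must be >= 30")
        missing = set(SUBFIELDS) - set(self.volume_baseline_mean)
        if missing:
            raise ValueError(f"volume_baseline_mean missing subfields: {missing}")

    def effect_for(self, module: str | None, subfield: str) -> float:
        """Ground-truth standardized volume shift for (module, subfield)."""
        if module is None or module == RETEST:
            return 0.0
        if (module, subfield) in self.module_effects:
            return self.module_effects[(module, subfield)]
        bare = subfield.split("_", 1)[1] if "_" in subfield else subfield
        return self.module_effects.get((module, bare), 0.0)

    def netfc_effect_for(self, module: str | None, subfield: str) -> float:
        if module is None or module == RETEST:
            return 0.0
        if (module, subfield) in self.netfc_effects:
            return self.netfc_effects[(module, subfield)]
        bare = subfield.split("_", 1)[1] if "_" in subfield else subfield
        return self.netfc_effects.get((module, bare), 0.0)


# ---------------------------------------------------------------------------
# dataset containers
# ---------------------------------------------------------------------------

@dataclass
class ScanRecord:
    """One resting-state scan: parcel time series, seed series, motion."""

    subject_id: str
    timepoint: str
    parcel_ts: np.ndarray  # T x 400
    seed_ts: dict[str, np.ndarray]  # subfield -> length-T series
    motion: np.ndarray  # T x 6 (translations mm, rotations rad)


@dataclass
class CohortDataset:
    subjects: pd.DataFrame  # subject_id, cohort, age, sex
    volumes: pd.DataFrame  # subject_id, timepoint, subfield, volume_mm3
    saliva: pd.DataFrame  # subject_id, timepoint, day, offset_min, actual_min, nmol_l
    hair: pd.DataFrame  # subject_id, segment, cortisol_pg_mg, cortisone_pg_mg
    fmri: dict[tuple[str, str], ScanRecord]
    truth: dict

    def write(self, out_dir: str | Path, write_fmri: bool = True) -> None:
        """Write the tabular data as TSV and scans as plain-text matrices."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = dict(sep="\t", index=False, float_format="%.10g")
        self.subjects.to_csv(out / "subjects.tsv", **fmt)
        self.volumes.to_csv(out / "volumes.tsv", **fmt)
        self.saliva.to_csv(out / "saliva.tsv", **fmt)
        self.hair.to_csv(out / "hair.tsv", **fmt)
        if write_fmri and self.fmri:
            scan_dir = out / "fmri"
            scan_dir.mkdir(exist_ok=True)
            for (sid, tp), scan in sorted(self.fmri.items()):
                stem = f"{sid}_{tp}"
                np.savetxt(scan_dir / f"{stem}_parcels.txt", scan.parcel_ts, fmt="%.8g")
                np.savetxt(scan_dir / f"{stem}_motion.txt", scan.motion, fmt="%.8g")
                seeds = np.column_stack([scan.seed_ts[s] for s in SUBFIELDS])
                np.savetxt(scan_dir / f"{stem}_seeds.txt", seeds, fmt="%.8g",
                           header="\t".join(SUBFIELDS))


def planted_networks(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Ground-truth network membership (0-based parcel indices) per subfield.

    Disjoint contiguous blocks within the ipsilateral hemisphere, fixed by
    design rather than drawn at random so recovery tests have a stable key.
    """
    nets: dict[str, np.ndarray] = {}
    per_hemi_order = ("SUB", "CA1-3", "CA4-DG")
    k = config.network_size
    for hemi, base in (("L", 0), ("R", N_PARCELS_PER_HEMI)):
        for j, bare in enumerate(per_hemi_order):
            nets[f"{hemi}_{bare}"] = np.arange(base + j * k, base + (j + 1) * k)
    return nets


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sub_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _car_bump(t: np.ndarray | float, peak: float) -> np.ndarray | float:
    """Unimodal awakening-response shape: 0 at t=0, max 1 at t=peak."""
    x = np.asarray(t, dtype=float) / peak
    return x * np.exp(1.0 - x)


def expected_log_saliva(config: SimulationConfig, level: float,
                        offsets: Iterable[float]) -> np.ndarray:
    """Noise-free log concentration at the given awakening-relative minutes."""
    t = np.asarray(list(offsets), dtype=float)
    return level + config.car_amplitude * _car_bump(t, config.car_peak_min) \
        - config.decay_rate * t


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate a full synthetic dataset from a validated config.

    The latent model: for every subject i and consecutive interval k a shared
    standard-normal factor ``z[i, k]`` feeds (a) the standardized CA1-3 volume
    change, (b) the diurnal log-cortisol level shift, and (c) the hair
    log-steroid shift, with mixing weights chosen so that the pairwise
    correlations equal the configured couplings.  Volume changes for all
    subfields additionally receive the module-specific standardized effect.
    Identical seeds produce identical datasets.
    """
    config.validate()
    rng_subj, rng_vol, rng_sal, rng_hair, rng_fmri, rng_miss = _sub_rngs(config.seed, 6)

    # --- subjects -----------------------------------------------------------
    rows = []
    idx = 0
    for cohort in COHORTS:
        for _ in range(config.n_per_cohort.get(cohort, 0)):
            idx += 1
            age = float(np.clip(rng_subj.normal(config.age_mean, config.age_sd),
                                *config.age_range))
            sex = "F" if rng_subj.random() < config.sex_ratio else "M"
            rows.append((f"S{idx:04d}", cohort, round(age, 1), sex))
    subjects = pd.DataFrame(rows, columns=["subject_id", "cohort", "age", "sex"])
    n_subj = len(subjects)
    tps = list(config.timepoints)
    n_iv = len(tps) - 1

    # --- shared latent factors ---------------------------------------------
    z = rng_vol.standard_normal((n_subj, n_iv))
    r_bc = config.brain_cortisol_coupling
    r_h = config.hair_coupling
    a = math.sqrt(abs(r_bc))  # brain-side mixing weight
    # cortisol side: sign carried here so corr(brain, cortisol) = r_bc
    b = math.copysign(math.sqrt(abs(r_bc)), r_bc) if r_bc != 0 else 0.0
    # hair side mixed against the same latent: corr(brain, hair) = a * h
    h = (r_h / a) if a > 0 else 0.0
    if abs(h) > 1:
        raise ValueError(
            "hair_coupling incompatible with brain_cortisol_coupling: "
            f"requires |{r_h}/{a:.3f}| <= 1"
        )

    modules_by_row = np.empty((n_subj, n_iv), dtype=object)
    for i, cohort in enumerate(subjects["cohort"]):
        for k, iv in enumerate(zip(tps[:-1], tps[1:])):
            modules_by_row[i, k] = module_schedule(cohort, iv)

    # --- volumes ------------------------------------------------------------
    vol_rows = []
    std_changes = {}  # truth: (subject, subfield) -> per-interval std change
    for s in SUBFIELDS:
        base = rng_vol.normal(config.volume_baseline_mean[s],
                              config.volume_baseline_sd, n_subj)
        eps = rng_vol.standard_normal((n_subj, n_iv))
        is_ca13 = s.endswith("CA1-3")
        if is_ca13 and a > 0:
            noise = a * z + math.sqrt(1 - a * a) * eps
        else:
            noise = eps
        d = np.empty((n_subj, n_iv))
        for i in range(n_subj):
            for k in range(n_iv):
                d[i, k] = config.effect_for(modules_by_row[i, k], s)
        std = d + noise
        std_changes[s] = std
        v = np.empty((n_subj, n_iv + 1))
        v[:, 0] = base
        for k in range(n_iv):
            v[:, k + 1] = v[:, k] + std[:, k] * config.volume_change_sd
        v = np.maximum(v, 1.0)  # volumes strictly positive
        for i, sid in enumerate(subjects["subject_id"]):
            for t, tp in enumerate(tps):
                vol_rows.append((sid, tp, s, round(v[i, t], 4)))
    volumes = pd.DataFrame(
        vol_rows, columns=["subject_id", "timepoint", "subfield", "volume_mm3"]
    )

    # --- diurnal saliva -----------------------------------------------------
    # per-interval level shift on the log scale; a constant shift of the whole
    # diurnal curve moves AUCg by 600*shift and leaves CAR and slope unchanged
    e_c = rng_sal.standard_normal((n_subj, n_iv))
    cort_shift = config.aucg_shift_sd * (
        b * z + math.sqrt(max(0.0, 1 - b * b)) * e_c
    )
    subj_level = config.cortisol_level + rng_sal.normal(
        0.0, config.cortisol_level_between_sd, n_subj
    )
    offsets = np.array(SALIVA_OFFSETS, dtype=float)
    sal_rows = []
    for i, sid in enumerate(subjects["subject_id"]):
        level_t = subj_level[i] + np.concatenate(
            [[0.0], np.cumsum(cort_shift[i])]
        )
        for t, tp in enumerate(tps):
            mean_log = expected_log_saliva(config, level_t[t], offsets)
            for day in (1, 2):
                logged = mean_log + rng_sal.normal(0, config.cortisol_noise_sd,
                                                   len(offsets))
                jit = rng_sal.uniform(-config.sample_jitter_min,
                                      config.sample_jitter_min, len(offsets))
                jit[0] = 0.0  # awakening sample is not scheduled
                for j, off in enumerate(SALIVA_OFFSETS):
                    sal_rows.append((
                        sid, tp, day, off,
                        round(off + jit[j], 1),
                        round(float(np.exp(logged[j])), 6),
                    ))
    saliva = pd.DataFrame(
        sal_rows,
        columns=["subject_id", "timepoint", "day", "offset_min", "actual_min", "nmol_l"],
    )

    # --- hair steroids ------------------------------------------------------
    e_h = rng_hair.standard_normal((n_subj, n_iv))
    hair_shift = config.hair_shift_sd * (
        h * z + math.sqrt(max(0.0, 1 - h * h)) * e_h
    )
    hair_base = config.hair_level + rng_hair.normal(0, config.hair_between_sd, n_subj)
    hair_rows = []
    for i, sid in enumerate(subjects["subject_id"]):
        lv = hair_base[i] + np.concatenate([[0.0], np.cumsum(hair_shift[i])])
        for t, tp in enumerate(tps):
            lc = lv[t] + rng_hair.normal(0, config.hair_noise_sd)
            ln = lv[t] + config.cortisone_offset + rng_hair.normal(0, config.hair_noise_sd)
            hair_rows.append((sid, tp, round(float(np.exp(lc)), 6),
                              round(float(np.exp(ln)), 6)))
    hair = pd.DataFrame(
        hair_rows, columns=["subject_id", "segment", "cortisol_pg_mg", "cortisone_pg_mg"]
    )

    # --- resting-state scans ------------------------------------------------
    fmri: dict[tuple[str, str], ScanRecord] = {}
    nets = planted_networks(config)
    if config.with_fmri:
        T = config.n_timepoints_fmri
        for i, sid in enumerate(subjects["subject_id"]):
            for t, tp in enumerate(tps):
                parcel_ts = rng_fmri.standard_normal((T, N_PARCELS))
                seed_ts: dict[str, np.ndarray] = {}
                for s in SUBFIELDS:
                    g = rng_fmri.standard_normal(T)
                    w = config.network_weight
                    for k in range(t):  # accumulate trained-interval shifts
                        eff = config.netfc_effect_for(modules_by_row[i, k], s)
                        w += eff * config.netfc_weight_sd
                    w = float(np.clip(w, 0.0, 0.95))
                    members = nets[s]
                    parcel_ts[:, members] = (
                        w * g[:, None]
                        + math.sqrt(1 - w * w) * rng_fmri.standard_normal((T, len(members)))
                    )
                    aw = config.seed_signal_weight
                    seed_ts[s] = aw * g + math.sqrt(1 - aw * aw) * rng_fmri.standard_normal(T)
                fmri[(sid, tp)] = ScanRecord(
                    subject_id=sid, timepoint=tp,
                    parcel_ts=parcel_ts, seed_ts=seed_ts,
                    motion=_simulate_motion(rng_fmri, T, config),
                )

    truth = {
        "config": dataclasses.replace(config),
        "latent": z,
        "std_changes": std_changes,
        "cort_shift": cort_shift,
        "hair_shift": hair_shift,
        "networks": nets,
        "modules_by_row": modules_by_row,
    }
    dataset = CohortDataset(subjects=subjects, volumes=volumes, saliva=saliva,
                            hair=hair, fmri=fmri, truth=truth)
    if config.missing_rate > 0:
        dataset = inject_missingness(dataset, config.missing_rate,
                                     rng=rng_miss)
    return dataset


def _simulate_motion(rng: np.random.Generator, T: int,
                     config: SimulationConfig) -> np.ndarray:
    """Motion parameters whose Power framewise displacement tracks config."""
    fd = np.abs(rng.normal(config.fd_mean, config.fd_sd, T))
    spikes = rng.random(T) < config.fd_spike_rate
    fd = fd + spikes * rng.exponential(config.fd_spike_scale, T)
    fd[0] = 0.0
    # split each frame's FD budget equally over 6 parameters; rotations are
    # expressed in radians and contribute 50 mm * |delta| to FD
    signs = rng.choice([-1.0, 1.0], size=(T, 6))
    deltas = np.empty((T, 6))
    deltas[:, :3] = (fd / 6.0)[:, None] * signs[:, :3]
    deltas[:, 3:] = (fd / 6.0 / 50.0)[:, None] * signs[:, 3:]
    deltas[0] = 0.0
    return np.cumsum(deltas, axis=0)


def inject_missingness(
    dataset: CohortDataset,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CohortDataset:
    """Delete whole subject-timepoint records at random (MCAR).

    Deterministic under ``seed``; never removes every timepoint of a subject.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return dataset
    if rng is None:
        rng = np.random.default_rng(seed)

    keys = sorted(
        set(map(tuple, dataset.volumes[["subject_id", "timepoint"]].values))
    )
    drop = [k for k in keys if rng.random() < rate]
    # never orphan a subject completely
    drop_set = set(drop)
    by_subject: dict[str, list[tuple[str, str]]] = {}
    for k in keys:
        by_subject.setdefault(k[0], []).append(k)
    for sid, ks in by_subject.items():
        if all(k in drop_set for k in ks):
            drop_set.remove(ks[int(rng.integers(len(ks)))])

    def _filter(df: pd.DataFrame, tp_col: str) -> pd.DataFrame:
        mask = [
            (s, t) not in drop_set
            for s, t in zip(df["subject_id"], df[tp_col])
        ]
        return df.loc[mask].reset_index(drop=True)

    fmri = {k: v for k, v in dataset.fmri.items() if k not in drop_set}
    truth = dict(dataset.truth)
    truth["dropped_records"] = sorted(drop_set)
    return CohortDataset(
        subjects=dataset.subjects.copy(),
        volumes=_filter(dataset.volumes, "timepoint"),
        saliva=_filter(dataset.saliva, "timepoint"),
        hair=_filter(dataset.hair, "segment"),
        fmri=fmri,
        truth=truth,
    )
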