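"""Seed-based connectivity profiles, motion QC, and functional networks.

Parcel convention: 400 cortical parcels, 0-based indices 0-199 left
hemisphere, 200-399 right hemisphere.  A subfield's hemisphere is taken from
its ``L_``/``R_`` name prefix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import N_PARCELS, N_PARCELS_PER_HEMI, SUBFIELDS, ScanRecord

__all__ = [
    "framewise_displacement",
    "censor_flags",
    "scrub",
    "exclude_high_motion",
    "seed_profile",
    "ConnectivityProfile",
    "NetworkDefinition",
    "define_network",
    "network_mean_fc",
    "region_change_table",
    "compute_profiles",
]

logger = logging.getLogger(__name__)

ROTATION_RADIUS_MM = 50.0
Z_CLIP = 1.0 - 1e-7


def framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """Power-convention framewise displacement from T x 6 motion parameters.

    FD_1 = 0; FD_t = sum |d translation| + 50 mm * sum |d rotation (rad)|.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a T x 6 matrix")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def censor_flags(fd: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Boolean mask of frames to censor: FD >= threshold plus both neighbours."""
    fd = np.asarray(fd, dtype=float)
    hit = fd >= threshold
    flags = hit.copy()
    flags[:-1] |= hit[1:]
    flags[1:] |= hit[:-1]
    return flags


def scrub(
    parcel_ts: np.ndarray,
    seed_ts: dict[str, np.ndarray],
    fd: np.ndarray,
    threshold: float = 0.5,
):
    """Remove censored frames from all series before correlation.

    Returns ``(parcel_ts, seed_ts, frac_censored)``.  Raises if every frame
    is censored.
    """
    T = len(fd)
    if parcel_ts.shape[0] != T or any(len(v) != T for v in seed_ts.values()):
        raise ValueError("series lengths do not match the FD series")
    flags = censor_flags(fd, threshold)
    if flags.all():
        raise ValueError("all frames censored")
    keep = ~flags
    return (
        parcel_ts[keep],
        {k: np.asarray(v)[keep] for k, v in seed_ts.items()},
        float(flags.sum()) / T,
    )


def exclude_high_motion(
    fd_by_scan: dict[tuple[str, str], np.ndarray],
    mean_fd_limit: float = 0.3,
):
    """Split scans into retained keys and an exclusion log by mean FD."""
    retained, excluded = [], []
    for key in sorted(fd_by_scan):
        mean_fd = float(np.mean(fd_by_scan[key]))
        if mean_fd > mean_fd_limit:
            excluded.append({"subject_id": key[0], "timepoint": key[1],
                             "mean_fd": mean_fd})
        else:
            retained.append(key)
    log = pd.DataFrame(excluded, columns=["subject_id", "timepoint", "mean_fd"])
    return retained, log


@dataclass
class ConnectivityProfile:
    subject_id: str
    timepoint: str
    subfield: str
    values: np.ndarray  # 400-vector rescaled to [0, 1]
    raw_z: np.ndarray  # 400-vector of Fisher z (nan for undefined parcels)


def seed_profile(
    parcel_ts: np.ndarray,
    seed_ts: np.ndarray,
    subject_id: str = "",
    timepoint: str = "",
    subfield: str = "",
) -> ConnectivityProfile:
    """Correlate a seed series with every parcel, Fisher-transform, rescale.

    r is clipped to +/-(1 - 1e-7) before atanh.  Zero-variance parcels get an
    undefined correlation: they are excluded from the min/max used for the
    rescale and imputed at the profile minimum (0 after rescaling).
    """
    seed = np.asarray(seed_ts, dtype=float)
    X = np.asarray(parcel_ts, dtype=float)
    if seed.std() == 0:
        raise ValueError("seed series has zero variance")
    sc = seed - seed.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc ** 2).sum(axis=0)) * math.sqrt((sc ** 2).sum())
    dead = denom == 0
    if dead.any():
        logger.warning("%d zero-variance parcel(s); imputed at profile minimum",
                       int(dead.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * sc[:, None]).sum(axis=0) / denom
    z = np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))
    z[dead] = np.nan
    ok = ~dead
    zmin, zmax = np.nanmin(z[ok]), np.nanmax(z[ok])
    if zmax == zmin:
        raise ValueError("degenerate profile: all finite z identical")
    values = (z - zmin) / (zmax - zmin)
    values[dead] = 0.0
    return ConnectivityProfile(subject_id, timepoint, subfield, values, z)


@dataclass
class NetworkDefinition:
    subfield: str
    hemisphere: str
    parcel_ids: np.ndarray  # 0-based, sorted


def _hemisphere(subfield: str) -> str:
    if subfield.startswith("L_"):
        return "L"
    if subfield.startswith("R_"):
        return "R"
    raise ValueError(f"subfield {subfield!r} has no L_/R_ hemisphere prefix")


def define_network(
    baseline_profiles: list[ConnectivityProfile],
    fraction: float = 0.10,
    ipsilateral: bool = True,
    use_raw_z: bool = False,
) -> NetworkDefinition:
    """Top-fraction parcels of the group-mean baseline profile.

    Candidates are the subfield's ipsilateral hemisphere parcels (200) unless
    ``ipsilateral=False`` selects over all 400.  ceil(fraction * n_candidates)
    parcels are chosen; ties break toward the lower parcel index.  The result
    is frozen: later timepoints never alter it.
    """
    if len(baseline_profiles) < 2:
        raise ValueError("need >= 2 baseline profiles")
    subfield = baseline_profiles[0].subfield
    if any(p.subfield != subfield for p in baseline_profiles):
        raise ValueError("profiles mix subfields")
    attr = "raw_z" if use_raw_z else "values"
    mean_profile = np.nanmean(
        np.stack([getattr(p, attr) for p in baseline_profiles]), axis=0
    )
    hemi = _hemisphere(subfield)
    if ipsilateral:
        base = 0 if hemi == "L" else N_PARCELS_PER_HEMI
        candidates = np.arange(base, base + N_PARCELS_PER_HEMI)
    else:
        candidates = np.arange(N_PARCELS)
    if len(candidates) == 0:
        raise ValueError("empty candidate set")
    k = math.ceil(fraction * len(candidates))
    vals = mean_profile[candidates]
    order = np.argsort(-vals, kind="stable")  # ties -> lower parcel index
    members = np.sort(candidates[order[:k]])
    return NetworkDefinition(subfield=subfield, hemisphere=hemi, parcel_ids=members)


def network_mean_fc(profile: ConnectivityProfile, network: NetworkDefinition) -> float:
    """Mean rescaled connectivity over the network's parcels."""
    return float(profile.values[network.parcel_ids].mean())


def region_change_table(
    profiles: dict[tuple[str, str], ConnectivityProfile],
    network: NetworkDefinition,
    interval: tuple[str, str],
) -> pd.DataFrame:
    """Per-parcel connectivity change over an interval for each subject.

    ``profiles`` maps (subject_id, timepoint) to the subfield's profile.
    Subjects missing either timepoint are skipped (logged).  Returns a long
    table ``subject_id, parcel_id, delta``.
    """
    ta, tb = interval
    subjects = sorted({sid for sid, _ in profiles})
    rows = []
    for sid in subjects:
        pa, pb = profiles.get((sid, ta)), profiles.get((sid, tb))
        if pa is None or pb is None:
            logger.debug("skipping %s: missing %s", sid, ta if pa is None else tb)
            continue
        delta = pb.values[network.parcel_ids] - pa.values[network.parcel_ids]
        rows.extend((sid, int(p), float(d))
                    for p, d in zip(network.parcel_ids, delta))
    return pd.DataFrame(rows, columns=["subject_id", "parcel_id", "delta"])


def compute_profiles(
    scans: dict[tuple[str, str], ScanRecord],
    fd_scrub_threshold: float = 0.5,
    fd_exclude_mean: float = 0.3,
    network_fraction: float = 0.10,
    baseline_timepoint: str = "T0",
    subfields: tuple[str, ...] = SUBFIELDS,
):
    """Scan-level QC + profiles + frozen baseline networks + network FC table.

    Returns a dict with keys ``profiles`` (map (subject, timepoint, subfield)
    -> ConnectivityProfile), ``networks`` (subfield -> NetworkDefinition),
    ``network_fc`` (long DataFrame), ``exclusions`` (DataFrame) and
    ``n_input``/``n_retained`` scan counts.
    """
    fd_by_scan = {k: framewise_displacement(s.motion) for k, s in scans.items()}
    retained, exclusions = exclude_high_motion(fd_by_scan, fd_exclude_mean)

    profiles: dict[tuple[str, str, str], ConnectivityProfile] = {}
    for key in retained:
        scan = scans[key]
        p_ts, s_ts, _frac = scrub(scan.parcel_ts, scan.seed_ts,
                                  fd_by_scan[key], fd_scrub_threshold)
        for sf in subfields:
            profiles[key + (sf,)] = seed_profile(
                p_ts, s_ts[sf], scan.subject_id, scan.timepoint, sf
            )

    networks: dict[str, NetworkDefinition] = {}
    for sf in subfields:
        base = [p for k, p in profiles.items()
                if k[1] == baseline_timepoint and k[2] == sf]
        if len(base) >= 2:
            networks[sf] = define_network(base, fraction=network_fraction)

    fc_rows = [
        (sid, tp, sf, network_mean_fc(prof, networks[sf]))
        for (sid, tp, sf), prof in sorted(profiles.items())
        if sf in networks
    ]
    network_fc = pd.DataFrame(
        fc_rows, columns=["subject_id", "timepoint", "subfield", "netfc"]
    )
    return {
        "profiles": profiles,
        "networks": networks,
        "network_fc": network_fc,
        "exclusions": exclusions,
        "n_input": len(scans),
        "n_retained": len(retained),
    }
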