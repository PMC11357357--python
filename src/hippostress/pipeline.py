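"""End-to-end orchestration: simulate -> cortisol -> connectivity ->
change scores -> contrasts/associations -> PLS, with record accounting and a
deterministic JSON report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import connectivity as conn
from . import contrasts as ct
from . import cortisol as cort
from . import pls as plsmod
from . import synth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "build_pls_inputs", "measures_from_tables"]

VOLUME_MEASURES = tuple(f"volume:{s}" for s in synth.SUBFIELDS)
NETFC_MEASURES = tuple(f"netfc:{s}" for s in synth.SUBFIELDS)
CORTISOL_MEASURES = ("cortisol:CAR", "cortisol:slope", "cortisol:AUCg")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run_out"
    # stage toggles
    with_fmri: bool = True
    run_contrasts: bool = True
    run_associations: bool = True
    run_pls: bool = True
    # stage parameters
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    winsorize: bool = True
    sd_limit: float = 3.0
    use_actual_times: bool = False
    hair_log: bool = True
    fd_scrub_threshold: float = 0.5
    fd_exclude_mean: float = 0.3
    network_fraction: float = 0.10
    correction: str = "bh"
    pls_model: str = "ca13"
    n_perm: int = 1000
    n_boot: int = 100
    within_group_perm: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sim_config(self) -> synth.SimulationConfig:
        cfg = synth.SimulationConfig(seed=self.seed, with_fmri=self.with_fmri)
        for key, value in self.sim.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown sim config field: {key}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and value and isinstance(value, dict):
                # YAML maps keyed "module,subfield" -> effect
                parsed = {}
                for k, v in value.items():
                    parsed[tuple(k.split(",")) if isinstance(k, str) and "," in k
                           else k] = v
                value = parsed
            setattr(cfg, key, value)
        return cfg


def measures_from_tables(
    volumes: pd.DataFrame,
    indices: pd.DataFrame | None = None,
    network_fc: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stack per-timepoint measures into the long (measure, value) format."""
    parts = []
    v = volumes.rename(columns={"volume_mm3": "value"}).copy()
    v["measure"] = "volume:" + v["subfield"]
    parts.append(v[["subject_id", "timepoint", "measure", "value"]])
    if indices is not None and not indices.empty:
        for name, col in (("CAR", "car"), ("slope", "slope"), ("AUCg", "aucg")):
            part = indices[["subject_id", "timepoint", col]].rename(
                columns={col: "value"}
            )
            part["measure"] = f"cortisol:{name}"
            parts.append(part[["subject_id", "timepoint", "measure", "value"]])
    if network_fc is not None and not network_fc.empty:
        f = network_fc.rename(columns={"netfc": "value"}).copy()
        f["measure"] = "netfc:" + f["subfield"]
        parts.append(f[["subject_id", "timepoint", "measure", "value"]])
    return pd.concat(parts, ignore_index=True)


def build_pls_inputs(
    records: pd.DataFrame,
    model: str = "ca13",
    include_netfc: bool = True,
):
    """Complete-case PLS matrices from a change-record table.

    Rows are subject x trained interval (training modules only).  Returns
    (X, Y, meta) where meta carries module, subject_id, age, sex per row and
    the column names.
    """
    if model == "ca13":
        brain_cols = ["volume:L_CA1-3", "volume:R_CA1-3"]
        if include_netfc:
            brain_cols += ["netfc:L_CA1-3", "netfc:R_CA1-3"]
    elif model == "all":
        brain_cols = list(VOLUME_MEASURES)
        if include_netfc:
            brain_cols += list(NETFC_MEASURES)
    else:
        raise ValueError(f"unknown PLS model: {model!r}")
    behavior_cols = list(CORTISOL_MEASURES)

    df = records[records["module"].isin(synth.MODULES)]
    wide = df.pivot_table(
        index=["subject_id", "interval_start", "module", "age", "sex"],
        columns="measure", values="delta", aggfunc="first",
    ).reset_index()
    needed = brain_cols + behavior_cols
    missing_cols = [c for c in needed if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"measures absent from records: {missing_cols}")
    wide = wide.dropna(subset=needed).sort_values(
        ["subject_id", "interval_start"]
    ).reset_index(drop=True)
    X = wide[brain_cols].to_numpy(float)
    Y = wide[behavior_cols].to_numpy(float)
    meta = {
        "module": wide["module"].to_numpy(),
        "subject_id": wide["subject_id"].to_numpy(),
        "age": wide["age"].to_numpy(float),
        "sex": wide["sex"].to_numpy(),
        "brain_cols": brain_cols,
        "behavior_cols": behavior_cols,
    }
    return X, Y, meta


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    return obj


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Execute the enabled stages in order and return the run report.

    Identical seed + config yield an identical report.  All stage outputs and
    ``report.json`` are written under ``config.out_dir`` when ``write``.
    """
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }
    out = Path(config.out_dir)

    # --- stage: simulate ----------------------------------------------------
    sim_cfg = config.sim_config()
    try:
        dataset = synth.simulate_cohort(sim_cfg)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    n_records = dataset.volumes[["subject_id", "timepoint"]].drop_duplicates().shape[0]
    report["stages"]["simulate"] = {
        "n_subjects": int(len(dataset.subjects)),
        "n_subject_timepoints": int(n_records),
        "n_scans": len(dataset.fmri),
        "n_dropped_records": len(dataset.truth.get("dropped_records", [])),
    }

    # --- stage: cortisol ----------------------------------------------------
    indices = cort.diurnal_indices(
        dataset.saliva, winsorize=config.winsorize, sd_limit=config.sd_limit,
        use_actual_times=config.use_actual_times,
    )
    hair_changes = cort.hair_change(dataset.hair, log=config.hair_log)
    report["stages"]["cortisol"] = {
        "n_profiles_in": int(
            dataset.saliva[["subject_id", "timepoint"]].drop_duplicates().shape[0]
        ),
        "n_index_rows": int(len(indices)),
        "n_aucg_defined": int(indices["aucg"].notna().sum()),
        "n_hair_changes": int(len(hair_changes)),
    }

    # --- stage: connectivity ------------------------------------------------
    network_fc = None
    conn_result = None
    if config.with_fmri and dataset.fmri:
        try:
            conn_result = conn.compute_profiles(
                dataset.fmri,
                fd_scrub_threshold=config.fd_scrub_threshold,
                fd_exclude_mean=config.fd_exclude_mean,
                network_fraction=config.network_fraction,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'connectivity' failed: {exc}") from exc
        network_fc = conn_result["network_fc"]
        report["stages"]["connectivity"] = {
            "n_scans_in": conn_result["n_input"],
            "n_scans_retained": conn_result["n_retained"],
            "n_scans_excluded": int(len(conn_result["exclusions"])),
            "networks": {
                sf: conn_result["networks"][sf].parcel_ids.tolist()
                for sf in sorted(conn_result["networks"])
            },
        }
        assert (report["stages"]["connectivity"]["n_scans_retained"]
                + report["stages"]["connectivity"]["n_scans_excluded"]
                == report["stages"]["connectivity"]["n_scans_in"])

    # --- stage: change records ---------------------------------------------
    measures = measures_from_tables(dataset.volumes, indices, network_fc)
    records = ct.build_change_records(measures, dataset.subjects)
    if not hair_changes.empty:
        hc = hair_changes.rename(columns={"d_cortisol": "delta"}).merge(
            dataset.subjects, on="subject_id"
        )
        hc["module"] = [
            synth.module_schedule(c, (a, b)) if (a, b) in synth.INTERVALS else None
            for c, a, b in zip(hc["cohort"], hc["interval_start"], hc["interval_end"])
        ]
        hc = hc.dropna(subset=["module"])
        hc["measure"] = "hair:cortisol"
        records = pd.concat(
            [records, hc[records.columns]], ignore_index=True
        )
    report["stages"]["changes"] = {
        "n_records": int(len(records)),
        "n_by_module": {
            str(k): int(v) for k, v in
            records["module"].value_counts().sort_index().items()
        },
    }

    # --- stage: contrasts ---------------------------------------------------
    if config.run_contrasts:
        fams = {"volume": VOLUME_MEASURES}
        if network_fc is not None:
            fams["netfc"] = NETFC_MEASURES
        contrast_rows = []
        for family, meas_list in fams.items():
            for arms in (("Affect", "Perspective"), ("Presence", "Affect")):
                fits = []
                for m in meas_list:
                    sub = records[records["measure"] == m]
                    if arms == ("Presence", "Affect"):
                        # between-cohort active control: Presence (TC1/TC2,
                        # T0-T1) vs the single-module cohort's Affect block
                        sub = sub[
                            ((sub["module"] == "Presence"))
                            | ((sub["module"] == "Affect") & (sub["cohort"] == "TC3"))
                        ]
                    try:
                        fits.append((m, ct.fit_contrast(sub, *arms)))
                    except ValueError as exc:
                        logger.info("contrast %s on %s skipped: %s", arms, m, exc)
                if not fits:
                    continue
                qs = ct.correct_multiplicity(
                    [f.p for _, f in fits], method=config.correction
                )
                for (m, f), q in zip(fits, qs):
                    f.q = float(q)
                    row = f.as_dict()
                    row.update({"measure": m, "family": family,
                                "arms": " vs ".join(arms)})
                    contrast_rows.append(row)
        report["stages"]["contrasts"] = {"results": contrast_rows,
                                         "n_tests": len(contrast_rows)}

    # --- stage: associations ------------------------------------------------
    if config.run_associations:
        assoc_rows = []
        pairs = [
            (b, c)
            for b in ("volume:L_CA1-3", "volume:R_CA1-3")
            for c in CORTISOL_MEASURES
        ]
        fits = []
        for b, c in pairs:
            try:
                fits.append(ct.associate_change(records, records, b, c,
                                                modules=["Affect"]))
            except ValueError as exc:
                logger.info("association %s~%s skipped: %s", b, c, exc)
        if fits:
            qs = ct.correct_multiplicity([f.p for f in fits],
                                         method=config.correction)
            for f, q in zip(fits, qs):
                f.q = float(q)
                row = f.as_dict()
                row.update(f.extra)
                assoc_rows.append(row)
        report["stages"]["associations"] = {"results": assoc_rows}

    # --- stage: PLS ---------------------------------------------------------
    if config.run_pls:
        try:
            X, Y, meta = build_pls_inputs(
                records, model=config.pls_model,
                include_netfc=network_fc is not None,
            )
        except ValueError as exc:
            raise RuntimeError(f"stage 'pls' failed: {exc}") from exc
        Xr = plsmod.residualize_brain(X, meta["age"], meta["sex"],
                                      meta["subject_id"])
        Xn = plsmod.normalize_within_group(Xr, meta["module"])
        Yn = plsmod.normalize_within_group(Y, meta["module"])
        result = plsmod.pls_fit(Xn, Yn)
        groups = meta["module"] if config.within_group_perm else None
        result.perm_p, result.perm_q = plsmod.permutation_test(
            Xn, Yn, n_perm=config.n_perm, seed=config.seed, groups=groups,
            blocks=None if config.within_group_perm else meta["subject_id"],
        )
        cis = plsmod.bootstrap_loadings(
            Xn, Yn, n_boot=config.n_boot, seed=config.seed,
            subject_ids=meta["subject_id"],
        )
        expression = plsmod.per_group_expression(result, meta["module"])
        report["stages"]["pls"] = {
            "model": config.pls_model,
            "n_rows": int(X.shape[0]),
            "brain_cols": meta["brain_cols"],
            "behavior_cols": meta["behavior_cols"],
            "singular_values": result.singular_values.tolist(),
            "covexp_pct": result.covexp.tolist(),
            "perm_p": result.perm_p.tolist(),
            "perm_q": result.perm_q.tolist(),
            "brain_loadings_lc1": result.brain_loadings[:, 0].tolist(),
            "behavior_loadings_lc1": result.behavior_loadings[:, 0].tolist(),
            "loading_ci_brain_lc1": [
                cis["brain"][0][:, 0].tolist(), cis["brain"][1][:, 0].tolist()
            ],
            "loading_ci_behavior_lc1": [
                cis["behavior"][0][:, 0].tolist(), cis["behavior"][1][:, 0].tolist()
            ],
            "expression_r": expression,
        }

    report = _round_floats(report)
    if write:
        out.mkdir(parents=True, exist_ok=True)
        dataset.write(out / "data", write_fmri=False)
        fmt = dict(sep="\t", index=False, float_format="%.10g")
        indices.to_csv(out / "cortisol_indices.tsv", **fmt)
        records.to_csv(out / "changes.tsv", **fmt)
        if conn_result is not None:
            conn_result["network_fc"].to_csv(out / "network_fc.tsv", **fmt)
            with open(out / "networks.json", "w") as fh:
                json.dump({sf: nd.parcel_ids.tolist()
                           for sf, nd in conn_result["networks"].items()},
                          fh, sort_keys=True, indent=1)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=1)
        _write_summary(out / "summary.txt", report)
    return report


def _write_summary(path: Path, report: dict) -> None:
    lines = [f"hippostress {report['version']}  (config {report['config_hash'][:12]})"]
    for stage, rec in report["stages"].items():
        lines.append(f"[{stage}]")
        for key, val in rec.items():
            if isinstance(val, (int, float, str)):
                lines.append(f"  {key}: {val}")
    path.write_text("\n".join(lines) + "\n")
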