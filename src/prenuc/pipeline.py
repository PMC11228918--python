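"""End-to-end study orchestration: sizes → occupancy/regime → CNT → correlations.

``run_pipeline`` consumes a :class:`StudyConfig` (typically parsed from
YAML) and writes a bundle of CSV reports: per-condition size/NSMC/
regime tables, a clustering-and-nucleation summary (S, 72-h cluster
size, critical nucleus diameter per condition), a target-saturation
comparison table (interpolated cluster size vs critical nucleus), and
a descriptive correlation summary.  Measured quantities are never
recomputed and always carry a ``provenance`` column distinguishing
``measured`` from ``computed`` values.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data as packaged
from .cnt import CNTParameters, SolventRecord, critical_diameter, linear_correlation
from .growth import (
    MolecularConstants,
    RegimeThresholds,
    SizeSeries,
    SolutionSpec,
    interpolate_size,
    nsmc,
    regime_statistics,
)

__all__ = ["StudyConfig", "run_pipeline", "reproduce_tables", "read_size_series_csv"]

log = logging.getLogger("prenuc")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

SIZE_SERIES_COLUMNS = [
    "solvent",
    "temperature_K",
    "x_mol_L",
    "x_star_mol_L",
    "time_h",
    "diameter_nm",
]


def read_size_series_csv(path) -> list[SizeSeries]:
    """Read one or more size series from a flat CSV.

    Expected columns: ``solvent, temperature_K, x_mol_L, x_star_mol_L,
    time_h, diameter_nm[, sd_nm]``; rows are grouped into series by the
    (solvent, x) condition.
    """
    df = pd.read_csv(path)
    missing = [c for c in SIZE_SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"size series CSV {path} missing columns: {missing}")
    out = []
    for (solvent, x), grp in df.groupby(["solvent", "x_mol_L"], sort=False):
        grp = grp.sort_values("time_h")
        solution = SolutionSpec(
            solvent=str(solvent),
            x_mol_l=float(x),
            x_star_mol_l=float(grp["x_star_mol_L"].iloc[0]),
            temperature_K=float(grp["temperature_K"].iloc[0]),
        )
        sd = grp["sd_nm"].to_numpy() if "sd_nm" in grp.columns else None
        out.append(
            SizeSeries(
                solution=solution,
                times_h=grp["time_h"].to_numpy(),
                diameters_nm=grp["diameter_nm"].to_numpy(),
                sd_nm=sd,
            )
        )
    return out


@dataclass
class StudyConfig:
    """Everything one study run needs, resolvable from a YAML mapping."""

    output_dir: Path
    solvent_records: dict[str, SolventRecord]
    measured_sizes: dict[str, list[tuple[float, float]]]
    series_files: list[Path] = field(default_factory=list)
    temperature_K: float = packaged.STUDY_TEMPERATURE_K
    molar_volume_m3_mol: float = packaged.MOLECULAR_CONSTANTS.molar_volume_m3_mol
    molecular_volume_nm3: float = packaged.MOLECULAR_CONSTANTS.molecular_volume_nm3
    target_s: float = packaged.INTERPOLATION_TARGET_S
    regime_thresholds: RegimeThresholds = field(default_factory=RegimeThresholds)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        records = {}
        measured = {}
        for entry in raw.get("solvents", []):
            name = entry["name"]
            records[name] = SolventRecord(
                solvent=name,
                gamma_mj_m2=float(entry["gamma_mJ_m2"]),
                driving_force_2000s_J_mol=float(entry.get("driving_force_J_mol", np.nan)),
                g_solv_kJ_mol=float(entry.get("g_solv_kJ_mol", np.nan)),
                carbonyl_peak_cm1=float(entry.get("carbonyl_cm1", np.nan)),
            )
            measured[name] = [tuple(p) for p in entry.get("measured_sizes", [])]
        series_files = [Path(p) for p in raw.get("series_files", [])]
        for p in series_files:
            if not p.exists():
                raise FileNotFoundError(f"series file listed in config does not exist: {p}")
        thr = raw.get("regime", {})
        return cls(
            output_dir=Path(raw.get("output_dir", "prenuc_out")),
            solvent_records=records,
            measured_sizes=measured,
            series_files=series_files,
            temperature_K=float(raw.get("temperature_K", packaged.STUDY_TEMPERATURE_K)),
            molar_volume_m3_mol=float(
                raw.get("molar_volume_m3_mol", packaged.MOLECULAR_CONSTANTS.molar_volume_m3_mol)
            ),
            molecular_volume_nm3=float(
                raw.get("molecular_volume_nm3", packaged.MOLECULAR_CONSTANTS.molecular_volume_nm3)
            ),
            target_s=float(raw.get("target_S", packaged.INTERPOLATION_TARGET_S)),
            regime_thresholds=RegimeThresholds(
                flat_threshold=float(thr.get("threshold", 0.25)),
                margin=float(thr.get("margin", 0.10)),
            ),
        )

    @classmethod
    def packaged_demo(cls, output_dir="prenuc_out") -> "StudyConfig":
        """The packaged study constants, ready to reproduce the summary tables."""
        return cls(
            output_dir=Path(output_dir),
            solvent_records=dict(packaged.SOLVENT_RECORDS),
            measured_sizes={k: list(v) for k, v in packaged.MEASURED_SIZES.items()},
        )


def _cnt_params(config: StudyConfig, gamma: float) -> CNTParameters:
    return CNTParameters(
        gamma_mj_m2=gamma,
        molar_volume_m3_mol=config.molar_volume_m3_mol,
        temperature_K=config.temperature_K,
    )


def clustering_nucleation_table(config: StudyConfig) -> pd.DataFrame:
    """Summary per (solvent, supersaturation): measured D_s and computed D_c."""
    rows = []
    for name, rec in config.solvent_records.items():
        points = config.measured_sizes.get(name, [])
        if not points:
            raise ValueError(f"no measured sizes for solvent {name!r}")
        for s, d_s in points:
            d_c = (
                critical_diameter(_cnt_params(config, rec.gamma_mj_m2), s)
                if s > 1
                else np.nan
            )
            rows.append(
                {
                    "solvent": name,
                    "driving_force_2000s_J_mol": rec.driving_force_2000s_J_mol,
                    "gamma_mJ_m2": rec.gamma_mj_m2,
                    "supersaturation": s,
                    "D_s_72h_nm": d_s,
                    "D_s_provenance": "measured",
                    "D_c_nm": round(d_c, 2) if np.isfinite(d_c) else d_c,
                    "D_c_provenance": "computed",
                }
            )
    return pd.DataFrame(rows)


def target_saturation_table(config: StudyConfig) -> pd.DataFrame:
    """Interpolated cluster size vs critical nucleus at the target S."""
    rows = []
    for name, rec in config.solvent_records.items():
        points = config.measured_sizes.get(name, [])
        d_s, extrapolated = interpolate_size(points, config.target_s)
        d_c = critical_diameter(_cnt_params(config, rec.gamma_mj_m2), config.target_s)
        rows.append(
            {
                "solvent": name,
                "target_S": config.target_s,
                "D_s_interp_nm": round(d_s, 1),
                "D_s_provenance": "computed (linear interpolation of measured points)",
                "extrapolated": extrapolated,
                "D_c_nm": round(d_c, 2),
                "D_c_provenance": "computed",
            }
        )
    return pd.DataFrame(rows)


def correlation_summary(config: StudyConfig) -> pd.DataFrame:
    """Descriptive OLS correlations across solvents (n = 3: no p-values)."""
    t4 = target_saturation_table(config)
    recs = [config.solvent_records[s] for s in t4["solvent"]]
    d_s = t4["D_s_interp_nm"].to_numpy(dtype=float)
    d_c = t4["D_c_nm"].to_numpy(dtype=float)
    gammas = np.array([r.gamma_mj_m2 for r in recs])
    dfrc = np.array([r.driving_force_2000s_J_mol for r in recs])
    gsolv = np.array([r.g_solv_kJ_mol for r in recs])
    ir = np.array([r.carbonyl_peak_cm1 for r in recs])

    pairs = [
        ("D_s_vs_driving_force", dfrc, d_s),
        ("D_s_vs_gamma", gammas, d_s),
        ("D_s_vs_D_c", d_c, d_s),
        ("gamma_vs_G_solv", gsolv, gammas),
        ("gamma_vs_carbonyl_peak", ir, gammas),
    ]
    rows = []
    for label, xs, ys in pairs:
        if not (np.all(np.isfinite(xs)) and np.all(np.isfinite(ys))):
            continue
        slope, intercept, r = linear_correlation(xs, ys)
        rows.append(
            {"relation": label, "slope": slope, "intercept": intercept, "pearson_r": r}
        )
    return pd.DataFrame(rows)


def run_pipeline(config: StudyConfig) -> dict[str, pd.DataFrame]:
    """Run all stages and write the report bundle under ``config.output_dir``.

    Returns the tables keyed by report name.  Re-running with the same
    config is idempotent (outputs are rewritten byte-identically).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    constants = MolecularConstants(
        molecular_volume_nm3=config.molecular_volume_nm3,
        molar_volume_m3_mol=config.molar_volume_m3_mol,
    )
    log.info(
        "run: T=%.2f K, target S=%.3f, regime thresholds flat<%.2f margin=%.2f",
        config.temperature_K,
        config.target_s,
        config.regime_thresholds.flat_threshold,
        config.regime_thresholds.margin,
    )

    reports: dict[str, pd.DataFrame] = {}

    # per-condition series analysis
    series_rows = []
    for path in config.series_files:
        for series in read_size_series_csv(path):
            if series.solution.solvent not in config.solvent_records:
                raise ValueError(
                    f"series file {path} references solvent "
                    f"{series.solution.solvent!r} missing from config"
                )
            n = nsmc(series.diameters_nm, constants)
            regime = regime_statistics(series, constants, config.regime_thresholds)
            s = series.solution.saturation
            for t, d, occ in zip(series.times_h, series.diameters_nm, n):
                series_rows.append(
                    {
                        "solvent": series.solution.solvent,
                        "saturation": s,
                        "time_h": t,
                        "diameter_nm": d,
                        "nsmc": occ,
                        "regime": regime.classification,
                        "trend_diff": regime.trend_diff,
                        "trend_int": regime.trend_int,
                    }
                )
            log.info(
                "series %s S=%.3f -> %s (trend_diff=%.3f, trend_int=%.3f)",
                series.solution.solvent,
                s,
                regime.classification,
                regime.trend_diff,
                regime.trend_int,
            )
    if series_rows:
        reports["series_analysis"] = pd.DataFrame(series_rows)

    reports["clustering_nucleation"] = clustering_nucleation_table(config)
    reports["target_saturation"] = target_saturation_table(config)
    reports["correlations"] = correlation_summary(config)

    for name, df in reports.items():
        df.to_csv(out / f"{name}.csv", index=False)
    log.info("wrote %d reports to %s", len(reports), out)
    return reports


def reproduce_tables(output_dir=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute the packaged study's summary tables from printed inputs.

    Critical diameters are recomputed from (γ, ϑ_m, T, S); measured
    cluster sizes are echoed with ``measured`` provenance, never
    recomputed.  Optionally writes both tables as CSV.
    """
    config = StudyConfig.packaged_demo()
    t3 = clustering_nucleation_table(config)
    t4 = target_saturation_table(config)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        t3.to_csv(out / "clustering_nucleation.csv", index=False)
        t4.to_csv(out / "target_saturation.csv", index=False)
    return t3, t4
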