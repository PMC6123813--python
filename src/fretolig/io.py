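"""CSV/JSON readers and writers for the pipeline's artifacts.

Tabular data are RFC-4180 CSV (UTF-8, '.' decimal); fit reports are JSON.
The canonical measurement schema has columns ``cell_id``, ``region_id``,
``donor_per_um2``, ``acceptor_per_um2``, ``fret_eff``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import SchemaError
from .fitting import FitResult, MeasurementSet
from .proximity import ProximityConfig, ProximityTable

__all__ = [
    "MEASUREMENT_COLUMNS",
    "read_measurements",
    "write_measurements",
    "read_proximity_table",
    "write_proximity_table",
    "write_fit_report",
    "read_fit_report",
]

log = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = (
    "cell_id",
    "region_id",
    "donor_per_um2",
    "acceptor_per_um2",
    "fret_eff",
)

# measured efficiencies slightly outside [0,1] are instrument noise and are
# clamped; beyond this window the row is rejected as invalid
_E_TOLERANCE = 0.05


def read_measurements(
    path: Union[str, Path],
    condition: str = "",
    n_experiments=None,
) -> MeasurementSet:
    """Read and validate a measurement CSV.

    Rows with negative concentrations or efficiencies outside
    ``[-0.05, 1.05]`` are rejected (with counts logged); surviving
    efficiencies are clamped to ``[0, 1]``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty") from None
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} lacks required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise SchemaError(f"{path} contains a header but no data rows")

    bad_conc = (df["donor_per_um2"] < 0) | (df["acceptor_per_um2"] < 0)
    bad_eff = (df["fret_eff"] < -_E_TOLERANCE) | (df["fret_eff"] > 1 + _E_TOLERANCE)
    bad = bad_conc | bad_eff
    if bad.any():
        log.warning(
            "%s: rejected %d row(s) (%d negative concentration, %d efficiency "
            "outside [-%.2f, %.2f])",
            path,
            int(bad.sum()),
            int(bad_conc.sum()),
            int(bad_eff.sum()),
            _E_TOLERANCE,
            1 + _E_TOLERANCE,
        )
        df = df[~bad]
    if len(df) == 0:
        raise SchemaError(f"{path}: no valid rows after validation")

    out = pd.DataFrame(
        {
            "cell_id": df["cell_id"].astype(str),
            "region_id": df["region_id"],
            "donor_conc": df["donor_per_um2"].astype(float),
            "acceptor_conc": df["acceptor_per_um2"].astype(float),
            "fret_efficiency": df["fret_eff"].astype(float).clip(0.0, 1.0),
        }
    )
    if "ratio" in df.columns:
        out["ratio"] = df["ratio"].astype(str).values
    return MeasurementSet(out.reset_index(drop=True), condition=condition, n_experiments=n_experiments)


def write_measurements(ms: MeasurementSet, path: Union[str, Path]) -> None:
    """Write a measurement set in the canonical CSV schema."""
    df = pd.DataFrame(
        {
            "cell_id": ms.data["cell_id"],
            "region_id": ms.data["region_id"],
            "donor_per_um2": ms.data["donor_conc"],
            "acceptor_per_um2": ms.data["acceptor_conc"],
            "fret_eff": ms.data["fret_efficiency"],
        }
    )
    if "ratio" in ms.data.columns:
        df["ratio"] = ms.data["ratio"]
    df.to_csv(path, index=False, lineterminator="\n")


def write_proximity_table(table: ProximityTable, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "density_per_um2": table.densities,
            "efficiency": table.efficiencies,
            "stderr": table.stderr,
        }
    ).to_csv(path, index=False, lineterminator="\n")


def read_proximity_table(path: Union[str, Path]) -> ProximityTable:
    df = pd.read_csv(path)
    missing = [c for c in ("density_per_um2", "efficiency", "stderr") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} lacks required column(s): {', '.join(missing)}")
    return ProximityTable(
        df["density_per_um2"].to_numpy(float),
        df["efficiency"].to_numpy(float),
        df["stderr"].to_numpy(float),
    )


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("Infinity" if obj > 0 else "-Infinity")
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_fit_report(fit: FitResult, path: Union[str, Path], extra: dict | None = None) -> None:
    """Serialise a fit result (plus optional provenance) as JSON."""
    payload = fit.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n")


def read_fit_report(path: Union[str, Path]) -> FitResult:
    """Reload a fit report written by :func:`write_fit_report`."""
    d = json.loads(Path(path).read_text())

    def _pair(key):
        lo, hi = d[key]
        return (
            -np.inf if lo is None else float(lo),
            np.inf if hi in (None, "Infinity") else float(hi),
        )

    return FitResult(
        mse_by_n={int(k): v for k, v in d["mse_by_n"].items()},
        best_n=int(d["best_n"]),
        classification=d["classification"],
        e_tilde=float(d["e_tilde"]),
        e_tilde_ci=_pair("e_tilde_ci95"),
        assoc_const=float(d["assoc_const"]),
        kdiss=float(d["kdiss"]),
        kdiss_ci=_pair("kdiss_ci95"),
        delta_g=float(d["delta_g_kcal_mol"]),
        delta_g_ci=_pair("delta_g_ci95"),
        refined_mse=float(d["refined_mse"]),
        n_points=int(d["n_points"]),
        n_experiments=d.get("n_experiments"),
        condition=d.get("condition", ""),
        temperature=float(d.get("temperature_K", 298.15)),
        wide_kdiss_ci=bool(d.get("wide_kdiss_ci", False)),
    )
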