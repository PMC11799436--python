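"""Reading and writing parameter sets, fit results and protocol configs.

Parameter series round-trip through two plain-text forms: a key-value JSON
document (shared block + one block per temperature) and a flat CSV table
with columns (parameter, pool, temperature, value, ci95) mirroring the
published summary table layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pools import FourPoolParams, TemperatureSeries
from .synthetic import params_from_table, params_to_table

__all__ = [
    "save_series_json",
    "load_series_json",
    "save_series_csv",
    "load_series_csv",
    "fit_result_to_json",
    "save_fit_result",
]

_FIELDS = [f.name for f in FourPoolParams.__dataclass_fields__.values()
           if f.name not in ("lineshape_NM", "lineshape_M")]
_SHARED = ("A_IEW", "A_MW", "A_NM", "A_M", "A_BW", "f_b1")


def save_series_json(series: TemperatureSeries, path) -> None:
    doc = {
        "temperatures_c": list(series.temperatures_c),
        "shared": {n: getattr(series.entries[0], n) for n in _SHARED},
        "per_temperature": {
            f"{t:g}": {n: getattr(p, n) for n in _FIELDS if n not in _SHARED}
            for t, p in series
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_series_json(path) -> TemperatureSeries:
    doc = json.loads(Path(path).read_text())
    pairs = []
    for t in doc["temperatures_c"]:
        per = doc["per_temperature"][f"{t:g}"]
        pairs.append((t, FourPoolParams(**doc["shared"], **per)))
    return TemperatureSeries.from_pairs(pairs, shared=True)


def save_series_csv(series: TemperatureSeries, path, ci=None) -> None:
    params_to_table(series, ci).to_csv(path, index=False)


def load_series_csv(path) -> TemperatureSeries:
    table = pd.read_csv(path, keep_default_na=False,
                        dtype={"temperature": str})
    table["temperature"] = table["temperature"].replace("", np.nan)
    return params_from_table(table)


def fit_result_to_json(result) -> dict:
    """JSON-serializable view of a FitResult (estimates, CIs, correlations)."""
    return {
        "model": result.model,
        "param_names": list(result.param_names),
        "estimates": [float(v) for v in result.x],
        "ci95": [float(v) for v in result.ci95],
        "correlation": np.asarray(result.corr).tolist(),
        "residual_mean": result.resid_mean,
        "residual_sd": result.resid_sd,
        "cost": result.cost,
        "success": result.success,
        "nfev": result.nfev,
    }


def save_fit_result(result, path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_json(result), indent=2))
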