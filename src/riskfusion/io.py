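"""On-disk formats: datasets as Parquet/CSV with a JSON sidecar schema,
result tables as tidy CSV with a JSON run manifest."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .lodo import ExperimentConfig, results_to_frame
from .simdata import LabelledDataset

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_results",
    "read_results",
]

_AGE_COLUMN = "age_years"
_LABEL_PREFIX = "label_"


def _to_table(ds: LabelledDataset) -> pd.DataFrame:
    out = ds.features.copy()
    out[_AGE_COLUMN] = ds.age_years
    for outcome, y in ds.labels.items():
        out[_LABEL_PREFIX + outcome] = y
    return out


def write_dataset(ds: LabelledDataset, path, fmt: str = "parquet") -> Path:
    """Write one database plus a sidecar schema; returns the data path."""
    path = Path(path)
    table = _to_table(ds)
    if fmt == "parquet":
        data_path = path.with_suffix(".parquet")
        table.to_parquet(data_path, index=False)
    elif fmt == "csv":
        data_path = path.with_suffix(".csv")
        table.to_csv(data_path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    schema = {
        "db_id": ds.db_id,
        "feature_columns": list(ds.features.columns),
        "age_column": _AGE_COLUMN,
        "label_columns": {o: _LABEL_PREFIX + o for o in ds.labels},
    }
    path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=1))
    return data_path


def read_dataset(data_path) -> LabelledDataset:
    data_path = Path(data_path)
    schema = json.loads(data_path.with_suffix("").with_suffix(".schema.json").read_text())
    if data_path.suffix == ".parquet":
        table = pd.read_parquet(data_path)
    else:
        table = pd.read_csv(data_path)
    return LabelledDataset(
        db_id=schema["db_id"],
        features=table[schema["feature_columns"]].astype(np.uint8),
        age_years=table[schema["age_column"]].to_numpy(dtype=float),
        labels={
            o: table[c].to_numpy(dtype=np.uint8)
            for o, c in schema["label_columns"].items()
        },
    )


def write_results(results, config: ExperimentConfig, out_dir) -> Path:
    """Tidy result CSV plus a JSON manifest of the configuration."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    csv_path = out_dir / "transport_results.csv"
    df.to_csv(csv_path, index=False)
    manifest = {
        "seed": config.seed,
        "outcomes": list(config.outcomes) if config.outcomes else None,
        "methods": list(config.methods),
        "stacking_budgets": [b for b in config.stacking_budgets],
        "test_fraction": config.test_fraction,
        "cv_folds": config.cv_folds,
        "n_calibration_bins": config.n_calibration_bins,
        "stacking_eval_on_complement": config.stacking_eval_on_complement,
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return csv_path


def read_results(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path, keep_default_na=False, na_values=[""])
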