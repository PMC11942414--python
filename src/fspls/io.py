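"""Reading and writing the formats the command-line tools speak.

Count matrices come in as dense CSV/TSV (samples in rows by default, first
column = sample ids, header = feature ids) or as MatrixMarket triplets with
sidecar row/column id files.  Phenotypes are TSV with columns
``sample_id``, ``outcome`` and optionally ``weight``.  Models are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import io as spio

from .core import Outcome
from .normalize import NormalizationModel
from .selection import FsplsModel

__all__ = [
    "read_counts",
    "read_phenotype",
    "outcome_from_phenotype",
    "save_model",
    "load_model",
    "write_predictions",
]


def read_counts(
    path: str | Path,
    samples_in: str = "rows",
    row_ids: Optional[str | Path] = None,
    col_ids: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Load a counts/intensity matrix as a samples x features DataFrame."""
    path = Path(path)
    if samples_in not in ("rows", "columns"):
        raise ValueError("samples_in must be 'rows' or 'columns'")
    if path.suffix == ".mtx":
        mat = np.asarray(spio.mmread(path).todense(), dtype=float)
        rows = _read_ids(row_ids) if row_ids else [f"r{i}" for i in range(mat.shape[0])]
        cols = _read_ids(col_ids) if col_ids else [f"c{i}" for i in range(mat.shape[1])]
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
    if samples_in == "columns":
        df = df.T
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return df.astype(float)


def _read_ids(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def read_phenotype(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "outcome" not in df.columns:
        raise ValueError(
            "phenotype table needs 'sample_id' and 'outcome' columns; "
            f"found {list(df.columns)}"
        )
    df["sample_id"] = df["sample_id"].map(str)
    return df


def outcome_from_phenotype(
    pheno: pd.DataFrame, family: str, sample_ids: list[str]
) -> Outcome:
    """Align a phenotype table to the count matrix's sample order."""
    table = pheno.set_index("sample_id")
    missing = [s for s in sample_ids if s not in table.index]
    if missing:
        raise ValueError(f"phenotype missing sample(s): {', '.join(missing[:5])}")
    sub = table.loc[sample_ids]
    values = sub["outcome"].to_numpy()
    if family in ("binomial", "multinomial"):
        classes = sorted(pd.unique(values))
        values = np.array([classes.index(v) for v in values], dtype=float)
    weights = sub["weight"].to_numpy(dtype=float) if "weight" in sub.columns else None
    return Outcome(np.asarray(values, dtype=float), family, weights=weights)


def save_model(
    model: FsplsModel | NormalizationModel, path: str | Path, prune: bool = True
) -> None:
    if isinstance(model, NormalizationModel):
        doc = json.loads(model.inner.to_json(prune=prune))
        doc["normalization"] = {"pseudocount": model.pseudocount}
        Path(path).write_text(json.dumps(doc, indent=1))
    else:
        Path(path).write_text(model.to_json(prune=prune))


def load_model(path: str | Path) -> FsplsModel | NormalizationModel:
    text = Path(path).read_text()
    doc = json.loads(text)
    inner = FsplsModel.from_json(text)
    if "normalization" in doc:
        return NormalizationModel(
            inner=inner, pseudocount=doc["normalization"]["pseudocount"]
        )
    return inner


def write_predictions(
    path: str | Path,
    sample_ids: list[str],
    predictions: np.ndarray,
    family: str,
) -> None:
    predictions = np.asarray(predictions)
    if family == "multinomial":
        cols = {f"prob_{c}": predictions[:, c] for c in range(predictions.shape[1])}
        df = pd.DataFrame({"sample_id": sample_ids, **cols})
        df["predicted_class"] = predictions.argmax(axis=1)
    elif family == "binomial":
        df = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "probability": predictions,
                "predicted_class": (predictions > 0.5).astype(int),
            }
        )
    else:
        df = pd.DataFrame({"sample_id": sample_ids, "prediction": predictions})
    df.to_csv(path, sep="\t", index=False)
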