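"""CSV / JSON input and output.

Data CSVs carry a header row, a first column of subject IDs and one column
per biomarker; empty cells or the tokens NA / NaN / nan mark missing values.
Floating-point output uses 17 significant digits so values round-trip
bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import DataMatrix, SubjectPosterior, SubtypeModel

__all__ = [
    "read_data_csv",
    "write_data_csv",
    "write_assignments",
    "write_positional_variance",
    "write_mcmc_trace",
    "write_manifest",
]

_NA_TOKENS = ["", "NA", "NaN", "nan"]
_FLOAT_FMT = "%.17g"


def read_data_csv(path) -> tuple:
    """Read a Z-score matrix; returns (DataMatrix, biomarker names).

    Column order defines biomarker order.  Duplicate subject IDs and
    non-numeric cells are rejected with the offending location named.
    """
    df = pd.read_csv(path, index_col=0, na_values=_NA_TOKENS,
                     keep_default_na=False, dtype=str)
    ids = [str(i) for i in df.index]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject IDs: {dupes}")
    values = np.full(df.shape, np.nan)
    for col_idx, col in enumerate(df.columns):
        for row_idx, cell in enumerate(df[col]):
            if pd.isna(cell):
                continue
            try:
                values[row_idx, col_idx] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell at row {ids[row_idx]!r}, "
                    f"column {col!r}: {cell!r}") from None
    data = DataMatrix(values=values, subject_ids=tuple(ids))
    return data, list(df.columns)


def write_data_csv(data: DataMatrix, names, path) -> None:
    """Write a data matrix; missing cells become empty strings."""
    df = pd.DataFrame(data.values, index=list(data.subject_ids), columns=list(names))
    df.index.name = "subject_id"
    df.to_csv(path, float_format=_FLOAT_FMT, na_rep="")


def write_assignments(posteriors: SubjectPosterior, model: SubtypeModel,
                      path, mass: float = 0.95) -> None:
    """Per-subject assignment table.

    Columns: subject ID, ML subtype (1-based, or ``normal_appearing`` for
    ML-stage-0 subjects), ML stage, per-subtype marginal probabilities, the
    probability of the ML subtype, and the 95% credible-set size.
    """
    marg = posteriors.subtype_marginals()
    sets = posteriors.credible_sets(mass)
    rows = []
    for j, sid in enumerate(posteriors.subject_ids):
        sub = int(posteriors.ml_subtype[j])
        row = {
            "subject_id": sid,
            "ml_subtype": "normal_appearing" if posteriors.normal_appearing[j]
                          else str(sub + 1),
            "ml_stage": int(posteriors.ml_stage[j]),
            **{f"p_subtype_{c + 1}": marg[j, c] for c in range(model.n_subtypes)},
            "p_ml_subtype": marg[j, sub],
            "credible_set_size": len(sets[j]),
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_positional_variance(result, config, out_dir, prefix="positional_variance") -> list:
    """One CSV per subtype: rows = events (config order), cols = positions."""
    out_dir = Path(out_dir)
    paths = []
    labels = config.event_labels()
    for c, pv in enumerate(result.positional_variance or []):
        df = pd.DataFrame(pv, index=labels,
                          columns=[f"position_{p + 1}" for p in range(pv.shape[1])])
        df.index.name = "event"
        p = out_dir / f"{prefix}_subtype{c + 1}.csv"
        df.to_csv(p, float_format=_FLOAT_FMT)
        paths.append(p)
    return paths


def write_mcmc_trace(result, path) -> None:
    """MCMC trace CSV: iteration, log-likelihood, fractions."""
    if result.ll_samples is None:
        raise ValueError("fit result carries no MCMC samples")
    C = result.frac_samples.shape[1]
    df = pd.DataFrame({
        "iteration": np.arange(result.ll_samples.size),
        "log_likelihood": result.ll_samples,
        **{f"fraction_{c + 1}": result.frac_samples[:, c] for c in range(C)},
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seed, inputs=()) -> None:
    """Record everything needed to re-run a result."""
    from . import __version__

    manifest = {
        "config": config,
        "seed": seed,
        "mdsustain_version": __version__,
        "numpy_version": np.__version__,
        "input_checksums": {str(p): file_checksum(p) for p in inputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
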