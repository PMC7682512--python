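"""TSV/JSON input and output for panels and criteria reports.

Panel TSV dialect: tab-separated, UTF-8, '.' decimal; header with an ``id``
column, paired ``D_<name>`` (0/1) and ``r_<name>`` (risk in [0, 1]) columns,
and an optional ``sampling_prob`` column.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .panel import OutcomePanel, PanelValidationError, validate_panel
from .records import SENSES, CriteriaRecord

__all__ = ["read_panel", "write_panel", "panel_from_dataframe", "write_report"]


def panel_from_dataframe(df: pd.DataFrame, thresholds, importance_weights=None) -> OutcomePanel:
    """Assemble a panel from a frame with paired D_/r_ columns."""
    d_cols = [c for c in df.columns if c.startswith("D_")]
    r_cols = [c for c in df.columns if c.startswith("r_")]
    d_names = [c[2:] for c in d_cols]
    r_names = [c[2:] for c in r_cols]
    missing_r = sorted(set(d_names) - set(r_names))
    missing_d = sorted(set(r_names) - set(d_names))
    if missing_r or missing_d:
        raise PanelValidationError(
            f"unpaired outcome columns: missing risks for {missing_r}, "
            f"missing outcomes for {missing_d}"
        )
    if not d_names:
        raise PanelValidationError("no D_<name>/r_<name> column pairs found")
    if "id" in df.columns and df["id"].duplicated().any():
        raise PanelValidationError("duplicated id values")
    names = d_names  # keep file column order
    try:
        outcomes = df[[f"D_{n}" for n in names]].to_numpy(dtype=float)
        risks = df[[f"r_{n}" for n in names]].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise PanelValidationError(f"non-numeric cell: {exc}") from None
    sampling = df["sampling_prob"].to_numpy(dtype=float) if "sampling_prob" in df else None
    return validate_panel(
        outcomes,
        risks,
        thresholds,
        importance_weights=importance_weights,
        sampling_probs=sampling,
        outcome_names=names,
    )


def read_panel(path, thresholds, importance_weights=None) -> OutcomePanel:
    """Read a panel TSV (see module docstring for the dialect)."""
    df = pd.read_csv(path, sep="\t")
    return panel_from_dataframe(df, thresholds, importance_weights=importance_weights)


def write_panel(panel: OutcomePanel, path) -> None:
    data = {"id": np.arange(1, panel.n_individuals + 1)}
    for j, name in enumerate(panel.outcome_names):
        data[f"D_{name}"] = panel.outcomes[:, j]
    for j, name in enumerate(panel.outcome_names):
        data[f"r_{name}"] = panel.risks[:, j]
    if not np.all(panel.sampling_probs == 1.0):
        data["sampling_prob"] = panel.sampling_probs
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def _records_frame(records: dict) -> pd.DataFrame:
    rows = []
    for sense in SENSES:
        if sense not in records:
            continue
        rec = records[sense]
        for crit in ("sensitivity", "specificity", "c_index", "relative_utility", "ppv", "npv"):
            v = getattr(rec, crit)
            se = getattr(rec, f"{crit}_se", None)
            rows.append(
                {
                    "sense": sense,
                    "criterion": crit,
                    "value": v,
                    "se": se,
                    "display": None if v is None else f"{v:.4f}",
                    "note": rec.undefined.get(crit, ""),
                }
            )
    return pd.DataFrame(rows)


def write_report(records: dict, path, fmt: str = "json") -> None:
    """Write criteria records as TSV (flat) or JSON (nested).

    Undefined criteria appear as explicit nulls with the reason string.
    """
    if fmt == "tsv":
        _records_frame(records).to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        payload = {}
        for sense, rec in records.items():
            payload[sense] = rec.to_dict() if isinstance(rec, CriteriaRecord) else rec
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError("fmt must be 'tsv' or 'json'")
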