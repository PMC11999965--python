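"""Readers and writers for the tabular twin-data formats.

Trial-level CSV schema: ``family_id, zygosity, individual_id[, condition][,
trial], y`` — one row per trial. Aggregated CSV schema: ``family_id,
zygosity, individual_id[, condition], mean_y, var_y, n_trials`` — one row
per individual. Zygosity labels are case-insensitive {MZ, DZ}; anything else
is an error. Families with more than two individuals are truncated to the
first two (with a logged warning); single-twin families are retained —
they inform variance estimates but carry no within-family correlation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .errors import SchemaError

__all__ = [
    "read_trial_csv",
    "write_trial_csv",
    "read_aggregated_csv",
    "write_aggregated_csv",
    "fit_result_to_json",
]

logger = logging.getLogger("twinhlm")

_REQUIRED_TRIAL = ["family_id", "zygosity", "individual_id", "y"]
_REQUIRED_AGG = ["family_id", "zygosity", "individual_id", "mean_y", "n_trials"]


def _lines(index) -> str:
    """CSV line numbers (1-based, header = line 1) for an index of bad rows."""
    nums = [int(i) + 2 for i in list(index)[:10]]
    suffix = ", ..." if len(index) > 10 else ""
    return ", ".join(map(str, nums)) + suffix


def _validate_common(df: pd.DataFrame, required: list[str], path) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df.copy()
    df["zygosity"] = df["zygosity"].astype(str).str.strip().str.upper()
    bad = df.index[~df["zygosity"].isin(["MZ", "DZ"])]
    if len(bad):
        raise SchemaError(
            f"{path}: unknown zygosity label(s) at line(s) {_lines(bad)}; expected MZ or DZ"
        )
    # zygosity must be constant within a family
    mixed = df.groupby("family_id", observed=True)["zygosity"].nunique()
    mixed = mixed[mixed > 1]
    if len(mixed):
        raise SchemaError(
            f"{path}: zygosity varies within family id(s) {list(mixed.index[:10])}"
        )
    return df


def _truncate_families(df: pd.DataFrame, path) -> pd.DataFrame:
    """Keep at most the first two individuals per family; log what happened."""
    per_fam = df.groupby("family_id", observed=True)["individual_id"].nunique()
    too_big = per_fam[per_fam > 2]
    n_truncated = 0
    if len(too_big):
        keep_rows = []
        for fam in too_big.index:
            ids = sorted(df.loc[df["family_id"] == fam, "individual_id"].unique())
            keep_rows.append(
                df[(df["family_id"] == fam) & (df["individual_id"].isin(ids[:2]))]
            )
            n_truncated += 1
        rest = df[~df["family_id"].isin(too_big.index)]
        df = pd.concat([rest] + keep_rows, ignore_index=True)
        logger.warning(
            "%s: %d families with >2 individuals truncated to their first two twins",
            path, n_truncated,
        )
    singletons = int((per_fam == 1).sum())
    if singletons:
        logger.info(
            "%s: %d single-twin families retained (no within-family correlation "
            "contribution)", path, singletons,
        )
    df.attrs["exclusions"] = {
        "families_truncated": n_truncated,
        "singleton_families": singletons,
    }
    return df


def read_trial_csv(path) -> pd.DataFrame:
    """Read and validate a trial-level twin CSV.

    Enforces the column schema, normalizes zygosity labels, coerces the
    trait column to numeric (with line-numbered errors), rejects duplicate
    (family, individual, condition, trial) keys, truncates >2-twin families
    and logs an exclusion summary.
    """
    df = pd.read_csv(path)
    df = _validate_common(df, _REQUIRED_TRIAL, path)
    y = pd.to_numeric(df["y"], errors="coerce")
    bad = df.index[y.isna()]
    if len(bad):
        raise SchemaError(f"{path}: non-numeric trait value(s) at line(s) {_lines(bad)}")
    df["y"] = y
    keys = ["family_id", "zygosity", "individual_id"]
    for optional in ("condition", "trial"):
        if optional in df.columns:
            keys.append(optional)
    dup = df.index[df.duplicated(subset=keys, keep=False)]
    if len(dup):
        raise SchemaError(
            f"{path}: duplicate ({', '.join(keys)}) key(s) at line(s) {_lines(dup)}"
        )
    df = _truncate_families(df, path)
    logger.info("%s: read %d trial rows", path, len(df))
    return df


def write_trial_csv(table: pd.DataFrame, path) -> None:
    cols = [c for c in ("family_id", "zygosity", "individual_id", "condition", "trial", "y")
            if c in table.columns]
    table[cols].to_csv(path, index=False)


def read_aggregated_csv(path) -> pd.DataFrame:
    """Read and validate an aggregated (per-individual) twin CSV.

    ``n_trials`` is required — the measurement-error adjustment needs the
    trial count. ``var_y`` may be absent only when every individual has a
    single trial; otherwise its absence makes the trial-variance estimate
    (and hence the adjustment) unavailable and is an error.
    """
    df = pd.read_csv(path)
    df = _validate_common(df, _REQUIRED_AGG, path)
    for col in ("mean_y", "n_trials"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric {col} at line(s) {_lines(bad)}")
        df[col] = vals
    multi = df["n_trials"] >= 2
    if "var_y" not in df.columns:
        if multi.any():
            raise SchemaError(
                f"{path}: var_y column missing while n_trials >= 2: the cross-trial "
                "variance estimate omega0_hat^2 (and the attenuation adjustment) "
                "would be unavailable"
            )
        df["var_y"] = float("nan")
    else:
        df["var_y"] = pd.to_numeric(df["var_y"], errors="coerce")
        bad = df.index[multi & df["var_y"].isna()]
        if len(bad):
            raise SchemaError(
                f"{path}: missing var_y with n_trials >= 2 at line(s) {_lines(bad)}: "
                "the attenuation adjustment needs the cross-trial variances"
            )
    keys = ["family_id", "zygosity", "individual_id"]
    if "condition" in df.columns:
        keys.append("condition")
    dup = df.index[df.duplicated(subset=keys, keep=False)]
    if len(dup):
        raise SchemaError(
            f"{path}: duplicate ({', '.join(keys)}) key(s) at line(s) {_lines(dup)}"
        )
    df = _truncate_families(df, path)
    logger.info("%s: read %d aggregated rows", path, len(df))
    return df


def write_aggregated_csv(agg: pd.DataFrame, path) -> None:
    cols = [c for c in ("family_id", "zygosity", "individual_id", "condition",
                        "mean_y", "var_y", "n_trials") if c in agg.columns]
    agg[cols].to_csv(path, index=False)


def fit_result_to_json(fit, path, *, provenance: dict | None = None) -> None:
    """Serialize a fit (with optional provenance: version, seed, options) to JSON."""
    from . import __version__

    payload = fit.to_dict() if hasattr(fit, "to_dict") else fit
    doc = {"package": "twinhlm", "version": __version__, "result": payload}
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=float))
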