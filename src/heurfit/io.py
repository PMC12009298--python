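"""On-disk formats: choices and reports as CSV, fits and truth as JSON.

Choice data use a K-agnostic long CSV (one row per trial × attribute, the
chosen option repeated along the trial); self-reports use a wide CSV with K
columns per report format. JSON artifacts carry a ``schema_version`` and the
seed/config hash that produced them, and serialize floats at full precision
so reruns can be diffed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import ModelFit, ParticipantFit
from .models import ChoiceDataset, ChoiceModelSpec
from .simulate import CohortTruth, DeciderTruth, SelfReport

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "write_choices",
    "read_choices",
    "write_reports",
    "read_reports",
    "write_truth",
    "read_truth",
    "write_participant_fit",
    "read_participant_fit",
    "config_hash",
]

SCHEMA_VERSION = "1.0"

CHOICE_COLUMNS = ["participant_id", "trial", "attribute", "value_A", "value_B", "choice"]


class SchemaError(ValueError):
    """Raised for malformed or out-of-range on-disk data."""


def config_hash(obj) -> str:
    """Short stable hash of a (nested dataclass / dict) configuration."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))

    blob = json.dumps(obj, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# choices
# ---------------------------------------------------------------------------


def write_choices(datasets: list[ChoiceDataset], path: str | Path) -> None:
    """Write datasets in long CSV format (one row per trial × attribute)."""
    frames = []
    for ds in datasets:
        t_idx = np.repeat(np.arange(1, ds.n_trials + 1), ds.k)
        a_idx = np.tile(np.arange(1, ds.k + 1), ds.n_trials)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": ds.participant_id,
                    "trial": t_idx,
                    "attribute": a_idx,
                    "value_A": ds.x_a.ravel(),
                    "value_B": ds.x_b.ravel(),
                    "choice": np.repeat(
                        np.where(ds.choices == 0, "A", "B"), ds.k
                    ),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_choices(path: str | Path) -> list[ChoiceDataset]:
    """Read and validate long-format choice CSV into per-participant datasets."""
    df = pd.read_csv(path, comment="#")
    missing = set(CHOICE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"choice file is missing columns: {sorted(missing)}")
    for col in ("value_A", "value_B"):
        bad = df.index[(df[col] < 0) | (df[col] > 1) | df[col].isna()]
        if len(bad):
            raise SchemaError(
                f"{col} outside [0, 1] at data row {int(bad[0]) + 2} of {path}"
            )
    bad = df.index[~df["choice"].isin(["A", "B"])]
    if len(bad):
        raise SchemaError(f"choice must be A or B at data row {int(bad[0]) + 2}")

    datasets = []
    for pid, g in df.groupby("participant_id", sort=False):
        counts = g.groupby("trial")["attribute"].count()
        if counts.nunique() != 1:
            raise SchemaError(
                f"participant {pid!r} has inconsistent attribute counts across trials"
            )
        k = int(counts.iloc[0])
        g = g.sort_values(["trial", "attribute"])
        if not np.array_equal(
            g["attribute"].to_numpy().reshape(-1, k), np.tile(np.arange(1, k + 1), (len(counts), 1))
        ):
            raise SchemaError(f"participant {pid!r} has malformed attribute indices")
        per_trial_choice = g.groupby("trial")["choice"].nunique()
        if (per_trial_choice != 1).any():
            raise SchemaError(f"participant {pid!r} has conflicting choices in a trial")
        choices = (g.groupby("trial")["choice"].first() == "B").astype(int).to_numpy()
        datasets.append(
            ChoiceDataset(
                participant_id=str(pid),
                x_a=g["value_A"].to_numpy().reshape(-1, k),
                x_b=g["value_B"].to_numpy().reshape(-1, k),
                choices=choices,
            )
        )
    return datasets


# ---------------------------------------------------------------------------
# self-reports
# ---------------------------------------------------------------------------


def write_reports(reports: list[SelfReport], path: str | Path) -> None:
    """Write reports as wide CSV: K columns per format plus three extents."""
    rows = []
    for r in reports:
        k = len(r.graded)
        row: dict = {"participant_id": r.participant_id}
        row.update({f"graded_{i + 1}": r.graded[i] for i in range(k)})
        row.update({f"binary_{i + 1}": r.binary[i] for i in range(k)})
        row.update({f"single_{i + 1}": r.single[i] for i in range(k)})
        row["extent_single_attribute"] = r.extents[0]
        row["extent_binary_weights"] = r.extents[1]
        row["extent_binary_values"] = r.extents[2]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_reports(path: str | Path) -> list[SelfReport]:
    """Read and validate the wide self-report CSV."""
    df = pd.read_csv(path, comment="#")
    graded_cols = sorted(
        (c for c in df.columns if c.startswith("graded_")),
        key=lambda c: int(c.split("_")[1]),
    )
    k = len(graded_cols)
    if k == 0 or "participant_id" not in df.columns:
        raise SchemaError("report file needs participant_id and graded_1..K columns")
    reports = []
    for row_i, row in df.iterrows():
        try:
            reports.append(
                SelfReport(
                    participant_id=str(row["participant_id"]),
                    graded=np.array([row[f"graded_{i + 1}"] for i in range(k)]),
                    binary=np.array([row[f"binary_{i + 1}"] for i in range(k)]),
                    single=np.array([row[f"single_{i + 1}"] for i in range(k)]),
                    extents=np.array(
                        [
                            row["extent_single_attribute"],
                            row["extent_binary_weights"],
                            row["extent_binary_values"],
                        ]
                    ),
                )
            )
        except (ValueError, KeyError) as exc:
            raise SchemaError(
                f"invalid self-report at data row {int(row_i) + 2} of {path}: {exc}"
            ) from exc
    return reports


# ---------------------------------------------------------------------------
# truth / fits (JSON)
# ---------------------------------------------------------------------------


def _check_version(payload: dict, path) -> None:
    ver = str(payload.get("schema_version", ""))
    if ver.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise SchemaError(f"unsupported schema version {ver!r} in {path}")


def write_truth(truth: CohortTruth, path: str | Path, seed: int | None = None) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "records": [
            {
                "participant_id": r.participant_id,
                "model_id": r.model_id,
                "w": np.asarray(r.w).tolist(),
                "beta": float(r.beta),
                "report_noise": float(r.report_noise),
            }
            for r in truth.records
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> CohortTruth:
    payload = json.loads(Path(path).read_text())
    _check_version(payload, path)
    return CohortTruth(
        records=[
            DeciderTruth(
                participant_id=r["participant_id"],
                model_id=int(r["model_id"]),
                w=np.array(r["w"], dtype=float),
                beta=float(r["beta"]),
                report_noise=float(r.get("report_noise", 0.0)),
            )
            for r in payload["records"]
        ]
    )


def write_participant_fit(
    fit: ParticipantFit, path: str | Path, config_digest: str | None = None
) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "participant_id": fit.participant_id,
        "seed": fit.seed,
        "config_hash": config_digest,
        "model_probs": fit.model_probs.tolist(),
        "family_probs": fit.family_probs.tolist(),
        "averaged_w": fit.averaged_w.tolist(),
        "averaged_reported_w": (
            None if fit.averaged_reported_w is None else fit.averaged_reported_w.tolist()
        ),
        "fits": [
            {
                "model_id": f.spec.model_id,
                "map_w": f.map_w.tolist(),
                "map_beta": f.map_beta,
                "log_posterior": f.log_posterior,
                "log_marginal": f.log_marginal,
                "diagnostics": f.diagnostics,
            }
            for f in fit.fits
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_participant_fit(path: str | Path) -> ParticipantFit:
    payload = json.loads(Path(path).read_text())
    _check_version(payload, path)
    fits = [
        ModelFit(
            spec=ChoiceModelSpec.from_id(f["model_id"]),
            map_w=np.array(f["map_w"], dtype=float),
            map_beta=float(f["map_beta"]),
            log_posterior=float(f["log_posterior"]),
            log_marginal=float(f["log_marginal"]),
            diagnostics=f.get("diagnostics", {}),
        )
        for f in payload["fits"]
    ]
    avg_rw = payload.get("averaged_reported_w")
    return ParticipantFit(
        participant_id=payload["participant_id"],
        fits=fits,
        model_probs=np.array(payload["model_probs"], dtype=float),
        family_probs=np.array(payload["family_probs"], dtype=float),
        averaged_w=np.array(payload["averaged_w"], dtype=float),
        averaged_reported_w=None if avg_rw is None else np.array(avg_rw, dtype=float),
        seed=int(payload.get("seed", 0)),
    )
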