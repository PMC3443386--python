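"""Joint dataset container and delimited-text I/O.

The normative on-disk representation is a pair of CSV files:

* longitudinal: columns ``id,time,y`` — one row per measurement;
* survival: columns ``id,time,event`` — one row per subject.

An optional truth file (``id,u1,u2[,u3],true_time``) carries the simulated
random effects and latent failure times alongside simulator output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["JointData", "ValidationError", "read_joint_dataset"]

LONG_COLUMNS = ["id", "time", "y"]
SURV_COLUMNS = ["id", "time", "event"]


class ValidationError(ValueError):
    """Raised when a joint dataset violates its invariants.

    ``errors`` lists every violation found, not only the first.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid joint dataset:\n" +
                         "\n".join(f"  - {e}" for e in self.errors))


@dataclass
class JointData:
    """Validated long-format longitudinal table + per-subject survival table.

    ``longitudinal`` has columns ``id,time,y`` and ``survival`` has columns
    ``id,time,event``; both are kept sorted by subject (and time).
    """

    longitudinal: pd.DataFrame
    survival: pd.DataFrame

    def __post_init__(self):
        self.longitudinal = self.longitudinal[LONG_COLUMNS].copy()
        self.survival = self.survival[SURV_COLUMNS].copy()
        self.longitudinal.sort_values(["id", "time"], inplace=True,
                                      kind="stable", ignore_index=True)
        self.survival.sort_values("id", inplace=True, kind="stable",
                                  ignore_index=True)
        self.validate()

    def validate(self):
        errors = []
        lon, sur = self.longitudinal, self.survival
        if sur["id"].duplicated().any():
            dup = sur.loc[sur["id"].duplicated(), "id"].tolist()
            errors.append(f"duplicate survival ids: {dup}")
        long_ids = set(lon["id"])
        surv_ids = set(sur["id"])
        for sid in sorted(surv_ids - long_ids, key=str):
            errors.append(f"survival id {sid!r} has no longitudinal records")
        for sid in sorted(long_ids - surv_ids, key=str):
            errors.append(f"longitudinal id {sid!r} has no survival record")
        for col, df, name in (("time", lon, "longitudinal"),
                              ("y", lon, "longitudinal"),
                              ("time", sur, "survival")):
            bad = ~np.isfinite(df[col].to_numpy(dtype=float))
            if bad.any():
                errors.append(f"non-finite {col!r} in {name} table")
        if (lon["time"] < 0).any():
            errors.append("negative longitudinal times")
        if (sur["time"] <= 0).any():
            bad = sur.loc[sur["time"] <= 0, "id"].tolist()
            errors.append(f"non-positive observed times for ids {bad}")
        if not sur["event"].isin([0, 1]).all():
            errors.append("event indicator must be 0 or 1")
        # within-subject strictly increasing times
        g = lon.groupby("id", sort=False)["time"]
        nondec = g.apply(lambda s: np.any(np.diff(s.to_numpy()) <= 0))
        for sid in nondec[nondec].index:
            errors.append(f"times not strictly increasing for id {sid!r}")
        # no measurement after the observed time
        last = g.max()
        obs = sur.set_index("id")["time"]
        common = last.index.intersection(obs.index)
        late = common[last.loc[common] > obs.loc[common] + 1e-12]
        for sid in late:
            errors.append(f"id {sid!r} has a measurement after its "
                          f"observed time")
        if errors:
            raise ValidationError(errors)

    @property
    def n_subjects(self) -> int:
        return len(self.survival)

    @property
    def n_events(self) -> int:
        return int(self.survival["event"].sum())

    @property
    def person_years(self) -> float:
        return float(self.survival["time"].sum())

    def subject_ids(self):
        return self.survival["id"].to_numpy()

    def write(self, outdir, prefix=""):
        """Write the two normative CSVs into ``outdir``; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lp = outdir / f"{prefix}longitudinal.csv"
        sp = outdir / f"{prefix}survival.csv"
        self.longitudinal.to_csv(lp, index=False)
        self.survival.to_csv(sp, index=False)
        return lp, sp


def _read_csv(path, columns):
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError([f"{path}: {exc}"]) from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError([f"{path}: missing columns {missing}"])
    for col in columns[1:]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()  # header + 1-based
            raise ValidationError(
                [f"{path}: malformed {col!r} on line(s) {lines}"])
        df[col] = coerced
    return df


def read_joint_dataset(long_path, surv_path) -> JointData:
    """Read and validate the (id,time,y) / (id,time,event) CSV pair."""
    lon = _read_csv(long_path, LONG_COLUMNS)
    sur = _read_csv(surv_path, SURV_COLUMNS)
    return JointData(longitudinal=lon, survival=sur)
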