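"""Spike-in threshold calibration and per-spot present/absent/saturated calls.

Each array x PMT scan is calibrated independently: the three spike-in
species with the lowest median replicate SI define the detection
threshold as ``mean + 2 * sample SD`` over their pooled replicate
intensities.  A spot at or below the threshold is absent, one at or above
the saturation level (65,000 by default, below the 16-bit scanner
ceiling) is saturated/flagged, anything between is present.  Spot calls
are then tallied per probe into a call matrix whose denominators count
every spot instance — duplicate-fill features included, giving the 4/8/16
measurement denominators of a two-PMT, four-array study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hybsim import SpikeInSet

SATURATION_LEVEL = 65000.0


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationResult:
    array_id: str
    pmt: int
    threshold: float
    lowest_spike_ids: tuple[str, str, str]
    saturation_level: float = SATURATION_LEVEL
    min_spike_median: float = float("nan")

    def __post_init__(self) -> None:
        if self.saturation_level <= self.threshold:
            raise CalibrationError("saturation level must exceed the threshold")


def calibrate_threshold(
    spike_spots: pd.DataFrame,
    spikes: SpikeInSet,
    saturation_level: float = SATURATION_LEVEL,
) -> CalibrationResult:
    """Threshold for one array x PMT from its spike-in replicate blocks.

    The three species with the lowest median replicate SI are selected by
    signal (not by nominal concentration, so calibration works when
    concentrations are unknown); the threshold is the mean plus twice the
    sample standard deviation (n-1 denominator) of their pooled replicate
    SIs.
    """
    arrays = spike_spots["array_id"].unique()
    pmts = spike_spots["pmt"].unique()
    if len(arrays) != 1 or len(pmts) != 1:
        raise CalibrationError("calibrate one array x PMT at a time")
    present = [sid for sid in spikes.probe_ids if (spike_spots["probe_id"] == sid).any()]
    if len(present) < 3:
        raise CalibrationError(f"need >= 3 spike species, found {len(present)}")
    grouped = spike_spots[spike_spots["probe_id"].isin(present)].groupby("probe_id")["si"]
    counts = grouped.count()
    if (counts < 2).any():
        raise CalibrationError("need >= 2 replicate spots per spike species")
    medians = grouped.median().sort_values(kind="mergesort")
    lowest = tuple(medians.index[:3])
    pooled = spike_spots[spike_spots["probe_id"].isin(lowest)]["si"].to_numpy()
    threshold = float(pooled.mean() + 2.0 * pooled.std(ddof=1))
    return CalibrationResult(
        array_id=str(arrays[0]),
        pmt=int(pmts[0]),
        threshold=threshold,
        lowest_spike_ids=lowest,  # type: ignore[arg-type]
        saturation_level=saturation_level,
        min_spike_median=float(medians.iloc[0]),
    )


def calibrate_all(
    spots: pd.DataFrame, spikes: SpikeInSet, saturation_level: float = SATURATION_LEVEL
) -> dict[tuple[str, int], CalibrationResult]:
    """One :class:`CalibrationResult` per (array, PMT) in a spot table."""
    spike_mask = spots["probe_id"].isin(spikes.probe_ids)
    out: dict[tuple[str, int], CalibrationResult] = {}
    for (array_id, pmt), grp in spots[spike_mask].groupby(["array_id", "pmt"], sort=True):
        out[(str(array_id), int(pmt))] = calibrate_threshold(grp, spikes, saturation_level)
    return out


def call_spot(si: float, cal: CalibrationResult) -> str:
    """'saturated' at/above the saturation level, else 'absent' at/below the
    threshold (boundary resolved conservatively toward absent), else
    'present'."""
    if si >= cal.saturation_level:
        return "saturated"
    if si <= cal.threshold:
        return "absent"
    return "present"


@dataclass
class NegativeControlReport:
    passed: bool
    offending: pd.DataFrame  # spots whose SI exceeds the lowest spike median


def check_negative_controls(
    control_spots: pd.DataFrame,
    calibrations: Mapping[tuple[str, int], CalibrationResult],
) -> NegativeControlReport:
    """Negative-control SIs must not exceed the lowest spike-in median."""
    if control_spots.empty:
        warnings.warn("no negative-control spots to check; vacuous pass")
        return NegativeControlReport(True, control_spots)
    bad_idx = []
    for idx, row in control_spots.iterrows():
        cal = calibrations[(row["array_id"], int(row["pmt"]))]
        if row["si"] > cal.min_spike_median:
            bad_idx.append(idx)
    offending = control_spots.loc[bad_idx]
    return NegativeControlReport(offending.empty, offending)


def tabulate_calls(
    spots: pd.DataFrame,
    calibrations: Mapping[tuple[str, int], CalibrationResult],
    probe_universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-probe call matrix over all non-control spot instances.

    Each spot instance (duplicate-fill replicates included) is one
    measurement: present -> positive, saturated -> flagged, absent ->
    neither.  ``mean_si``/``cv_si`` are computed over non-flagged
    measurements (CV uses sample SD).  Probes in ``probe_universe`` with
    no spots get an all-zero row with a warning.
    """
    feats = spots[~spots["is_control"]].copy()
    thr = {k: c.threshold for k, c in calibrations.items()}
    sat = {k: c.saturation_level for k, c in calibrations.items()}
    keys = list(zip(feats["array_id"], feats["pmt"].astype(int)))
    missing = sorted({k for k in keys if k not in thr})
    if missing:
        raise KeyError(f"no calibration for array x PMT {missing}")
    feats["_thr"] = [thr[k] for k in keys]
    feats["_sat"] = [sat[k] for k in keys]
    feats["_flagged"] = feats["si"] >= feats["_sat"]
    feats["_positive"] = (~feats["_flagged"]) & (feats["si"] > feats["_thr"])

    def _agg(g: pd.DataFrame) -> pd.Series:
        ok = g.loc[~g["_flagged"], "si"]
        mean = float(ok.mean()) if len(ok) else float("nan")
        cv = float(ok.std(ddof=1) / mean) if len(ok) > 1 and mean else float("nan")
        return pd.Series(
            {
                "n_measurements": len(g),
                "n_positive": int(g["_positive"].sum()),
                "n_flagged": int(g["_flagged"].sum()),
                "mean_si": mean,
                "cv_si": cv,
            }
        )

    matrix = feats.groupby("probe_id", sort=True).apply(_agg, include_groups=False)
    matrix[["n_measurements", "n_positive", "n_flagged"]] = matrix[
        ["n_measurements", "n_positive", "n_flagged"]
    ].astype(int)
    if probe_universe is not None:
        absent = [p for p in probe_universe if p not in matrix.index]
        if absent:
            warnings.warn(f"{len(absent)} probes have no spots; zero rows emitted")
            zeros = pd.DataFrame(
                {
                    "n_measurements": 0,
                    "n_positive": 0,
                    "n_flagged": 0,
                    "mean_si": float("nan"),
                    "cv_si": float("nan"),
                },
                index=pd.Index(absent, name="probe_id"),
            )
            matrix = pd.concat([matrix, zeros]).sort_index()
    return matrix


def calibration_tsv(calibrations: Mapping[tuple[str, int], CalibrationResult]) -> str:
    lines = ["array_id\tpmt\tthreshold\tlowest_spikes\tsaturation_level"]
    for (array_id, pmt), c in sorted(calibrations.items()):
        lines.append(
            f"{array_id}\t{pmt}\t{c.threshold:.4f}\t{','.join(c.lowest_spike_ids)}\t{c.saturation_level:.0f}"
        )
    return "\n".join(lines) + "\n"
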