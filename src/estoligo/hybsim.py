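"""Synthetic transcriptomes, fragmented ESTs and one-color array
hybridization with spike-in calibration blocks.

This generator is the test bed for the whole pipeline: it draws a truth
table (which targets are expressed, in which orientation, how abundantly),
then produces per-spot background-subtracted median signal intensities
(SI) for every feature of an array design across multiple arrays and two
photomultiplier (PMT) gain settings.

Signal model per spot instance (probe p, array a, PMT g, replicate r):

* matching orientation of an expressed target:
  ``SI = gain(g) * abundance(target) * affinity(p) * exp(N(0, noise_sd))``
* otherwise a background draw ``gain(g) * N(bg_mean, bg_sd)`` (may be
  negative, as real background-subtracted data can be);
* probes sharing a >=95%/50-base window with a signal-bearing probe
  additionally receive ``cross_hyb_factor`` times that probe's signal;
* ten spike-in species at geometrically increasing nominal concentration
  hybridize on every array proportionally to concentration;
* everything is clipped at the 16-bit scanner ceiling (65,535), which is
  deliberately distinct from the downstream saturation call at 65,000.

Probe affinity is drawn once per probe and reused across arrays, so
probe-level consistency across the 8 measurements is realistic.  All
draws derive from a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aligner import DEFAULT_WORD_SIZE, similar_pairs
from .probe_design import ArrayDesign, ProbeCandidate
from .seqcore import SequenceRecord

GPR_COLUMNS = ["probe_id", "array_id", "pmt", "replicate", "si", "is_control"]
SCANNER_CEILING = 65535


@dataclass(frozen=True)
class TruthConfig:
    """Generative parameters for one simulated hybridization study."""

    n_targets: int = 500
    expressed_fraction: float = 0.5
    abundance_mu: float = 8.3  # log-scale; exp(mu) ~ 4,000 SI units at unit gain
    abundance_sigma: float = 0.6
    affinity_sigma: float = 0.3
    noise_sigma: float = 0.2
    background_mean: float = 50.0
    background_sd: float = 20.0
    gain: Mapping[int, float] = field(default_factory=lambda: {400: 1.0, 500: 1.6})
    saturation_ceiling: int = SCANNER_CEILING
    cross_hyb_factor: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.expressed_fraction <= 1.0):
            raise ValueError("expressed_fraction must be in [0, 1]")
        pmts = sorted(self.gain)
        gains = [self.gain[p] for p in pmts]
        if any(g <= 0 for g in gains) or gains != sorted(gains):
            raise ValueError("gain factors must be positive and monotone in PMT")


@dataclass(frozen=True)
class SpikeInSet:
    """Spike-in species of strictly increasing nominal concentration.

    Concentrations default to a geometric series (1, 2, 4, ... 512) on an
    arbitrary nominal scale; ``signal_per_unit`` converts concentration to
    expected SI at unit gain, placing the lowest species just above
    background so the calibrated threshold lands between background and
    true signal.
    """

    concentrations: tuple[float, ...] = tuple(float(2**k) for k in range(10))
    probe_ids: tuple[str, ...] = tuple(f"SPIKE_{k + 1:02d}" for k in range(10))
    replicates: int = 60
    signal_per_unit: float = 50.0

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.probe_ids):
            raise ValueError("one probe id per spike species")
        if list(self.concentrations) != sorted(set(self.concentrations)):
            raise ValueError("concentrations must be strictly increasing")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per spike species")
        if len(self.concentrations) < 3:
            raise ValueError("need >= 3 spike species for calibration")


def simulate_transcriptome(
    n: int,
    length_range: tuple[int, int] = (70, 250),
    seed: int = 0,
    prefix: str = "T",
    shared_blocks: Sequence[tuple[int, int, int]] = (),
) -> tuple[list[SequenceRecord], list[dict]]:
    """Uniform-random toy transcripts, optionally with planted shared blocks.

    ``shared_blocks`` entries ``(i, j, block_len)`` copy a block from
    record i into record j at random positions; plant positions are
    returned as truth for assembly-QC fixtures.
    """
    lo, hi = length_range
    if lo < 40:
        raise ValueError("minimum transcript length is 40")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    records = []
    for k in range(n):
        L = int(rng.integers(lo, hi + 1))
        records.append(
            SequenceRecord(f"{prefix}{k:05d}", "".join(rng.choice(bases, size=L)))
        )
    truth = []
    for i, j, blen in shared_blocks:
        src, dst = records[i], records[j]
        if blen > min(src.length, dst.length):
            raise ValueError("shared block longer than a participant")
        ps = int(rng.integers(0, src.length - blen + 1))
        pd_ = int(rng.integers(0, dst.length - blen + 1))
        block = src.seq[ps : ps + blen]
        new = dst.seq[:pd_] + block + dst.seq[pd_ + blen :]
        records[j] = SequenceRecord(dst.id, new, dst.source)
        truth.append({"src": src.id, "dst": dst.id, "src_pos": ps, "dst_pos": pd_, "len": blen})
    return records, truth


def fragment_ests(
    transcripts: Sequence[SequenceRecord],
    n_fragments: int,
    length_range: tuple[int, int] = (60, 200),
    seed: int = 0,
) -> list[SequenceRecord]:
    """Overlapping random fragments of the given transcripts (toy ESTs)."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_fragments):
        t = transcripts[int(rng.integers(0, len(transcripts)))]
        L = int(rng.integers(length_range[0], min(length_range[1], t.length) + 1))
        s = int(rng.integers(0, t.length - L + 1))
        out.append(SequenceRecord(f"EST{k:05d}", t.seq[s : s + L], "singleton"))
    return out


def draw_truth(targets: Sequence[SequenceRecord], cfg: TruthConfig) -> pd.DataFrame:
    """Expression state, true orientation and abundance per target."""
    rng = np.random.default_rng(cfg.seed)
    n = len(targets)
    expressed = rng.random(n) < cfg.expressed_fraction
    orientation = np.where(rng.random(n) < 0.5, "sense", "antisense")
    abundance = np.exp(rng.normal(cfg.abundance_mu, cfg.abundance_sigma, n))
    return pd.DataFrame(
        {
            "target_id": [t.id for t in targets],
            "expressed": expressed,
            "orientation": orientation,
            "abundance": abundance,
        }
    )


def simulate_hybridization(
    design: ArrayDesign,
    probes: Sequence[ProbeCandidate],
    truth: pd.DataFrame,
    cfg: TruthConfig,
    spikes: SpikeInSet | None = None,
    n_arrays: int = 4,
    pmts: Sequence[int] = (400, 500),
    n_negative_controls: int = 100,
) -> pd.DataFrame:
    """Per-spot SI tables for ``n_arrays`` arrays scanned at each PMT gain.

    Every feature of ``design`` (including duplicate fill) yields one spot
    per array x PMT; control spots comprise the spike-in replicate blocks
    and negative controls.  Output columns follow :data:`GPR_COLUMNS`.
    """
    spikes = spikes or SpikeInSet()
    by_id = {p.probe_id: p for p in probes}
    for pid, _ in design.features:
        if pid not in by_id:
            raise ValueError(f"feature probe id {pid!r} missing from manifest")
    for pmt in pmts:
        if pmt not in cfg.gain:
            raise ValueError(f"no gain factor configured for PMT {pmt}")
    tr = truth.set_index("target_id")

    rng = np.random.default_rng(cfg.seed + 1)
    probe_ids = sorted(by_id)
    affinity = dict(
        zip(probe_ids, np.exp(rng.normal(0.0, cfg.affinity_sigma, len(probe_ids))))
    )

    def base_signal(p: ProbeCandidate) -> float:
        """Unit-gain expected signal; 0 when the probe sees no target."""
        row = tr.loc[p.target_id]
        if bool(row["expressed"]) and p.orientation == row["orientation"]:
            return float(row["abundance"]) * affinity[p.probe_id]
        return 0.0

    base = {pid: base_signal(by_id[pid]) for pid in probe_ids}

    # cross-hybridization: similar probe pairs share signal at a discount
    cross = {pid: 0.0 for pid in probe_ids}
    if cfg.cross_hyb_factor > 0:
        seqs = [by_id[pid].seq for pid in probe_ids]
        for i, j in similar_pairs(seqs, 50, 0.95, DEFAULT_WORD_SIZE):
            a, b = probe_ids[i], probe_ids[j]
            cross[a] += cfg.cross_hyb_factor * base[b]
            cross[b] += cfg.cross_hyb_factor * base[a]

    rows: list[tuple] = []
    ceiling = float(cfg.saturation_ceiling)
    for a_idx in range(n_arrays):
        array_id = f"ARRAY_{a_idx + 1}"
        # one physical hybridization per array: shared multiplicative noise
        # across the two scans of the same spot
        spot_noise = {
            (pid, rep): float(np.exp(rng.normal(0.0, cfg.noise_sigma)))
            for pid, rep in design.features
        }
        bg_draw = {
            (pid, rep): float(rng.normal(cfg.background_mean, cfg.background_sd))
            for pid, rep in design.features
        }
        spike_noise = {
            (sid, r): float(np.exp(rng.normal(0.0, cfg.noise_sigma)))
            for sid in spikes.probe_ids
            for r in range(spikes.replicates)
        }
        neg_draw = [
            float(rng.normal(cfg.background_mean, cfg.background_sd))
            for _ in range(n_negative_controls)
        ]
        for pmt in pmts:
            g = cfg.gain[pmt]
            for pid, rep in design.features:
                signal = base[pid] + cross[pid]
                if signal > 0.0:
                    si = g * signal * spot_noise[(pid, rep)]
                else:
                    si = g * bg_draw[(pid, rep)]
                rows.append((pid, array_id, pmt, rep, min(si, ceiling), False))
            for sid, conc in zip(spikes.probe_ids, spikes.concentrations):
                expect = conc * spikes.signal_per_unit
                for r in range(spikes.replicates):
                    si = g * expect * spike_noise[(sid, r)]
                    rows.append((sid, array_id, pmt, r, min(si, ceiling), True))
            for r, draw in enumerate(neg_draw):
                rows.append((f"NEG_{r + 1:03d}", array_id, pmt, r, min(g * draw, ceiling), True))
    return pd.DataFrame(rows, columns=GPR_COLUMNS)


def write_gpr_like(measurements: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated spot table; SI written with 2 decimals (documented)."""
    df = measurements[GPR_COLUMNS].copy()
    df["si"] = df["si"].map(lambda v: f"{v:.2f}")
    df["is_control"] = df["is_control"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_gpr_like(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "array_id": str})
    missing = [c for c in GPR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot table missing columns {missing}")
    df["is_control"] = df["is_control"].astype(bool)
    df["si"] = df["si"].astype(float)
    return df[GPR_COLUMNS]


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
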