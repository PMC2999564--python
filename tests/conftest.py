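from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import estoligo as eo


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20261)


def run_study(
    seed: int,
    n_targets: int = 500,
    expressed_fraction: float = 0.5,
    length_range: tuple[int, int] = (70, 250),
    n_arrays: int = 4,
    noise: bool = True,
    n_negative_controls: int = 100,
    duplicate_fill: int = 50,
):
    """One full simulated hybridization study: transcriptome -> probes ->
    layout -> spots -> calibration -> call matrices -> selection inputs.

    Returns a dict of every intermediate the tests need.
    """
    kwargs = {} if noise else {"noise_sigma": 0.0, "background_sd": 0.0}
    cfg = eo.TruthConfig(
        n_targets=n_targets, expressed_fraction=expressed_fraction, seed=seed, **kwargs
    )
    targets, _ = eo.simulate_transcriptome(n_targets, length_range, seed=seed)
    probes = []
    for rec in targets:
        rule = eo.classify_target(rec.length)
        if rule is None:
            continue
        for o in ("sense", "antisense"):
            probes.extend(eo.design_probes(rec, rule, o))
    spikes = eo.SpikeInSet()
    controls = spikes.replicates * len(spikes.probe_ids) + n_negative_controls
    layout = eo.build_layout(
        probes, total_spots=len(probes) + controls + duplicate_fill, control_spots=controls
    )
    truth = eo.draw_truth(targets, cfg)
    spots = eo.simulate_hybridization(layout, probes, truth, cfg, spikes, n_arrays)
    cals = eo.calibrate_all(spots, spikes)
    matrix = eo.tabulate_calls(spots, cals)
    retained, flag_removed = eo.filter_flagged(matrix)
    pos = eo.call_positive(retained)
    tseq = {t.id: t.seq for t in targets}
    rows = [
        dict(
            probe_id=p.probe_id,
            target_id=p.target_id,
            orientation=p.orientation,
            probe_length=p.length,
            probe_seq=p.seq,
            target_seq=tseq[p.target_id],
            mean_si=pos.loc[p.probe_id, "mean_si"],
            cv_si=pos.loc[p.probe_id, "cv_si"],
        )
        for p in probes
        if p.probe_id in pos.index
    ]
    positives = pd.DataFrame(
        rows,
        columns=[
            "probe_id", "target_id", "orientation", "probe_length",
            "probe_seq", "target_seq", "mean_si", "cv_si",
        ],
    )
    return {
        "cfg": cfg,
        "targets": targets,
        "probes": probes,
        "layout": layout,
        "truth": truth,
        "spots": spots,
        "calibrations": cals,
        "matrix": matrix,
        "flag_removed": flag_removed,
        "positives": positives,
        "spikes": spikes,
    }


@pytest.fixture(scope="session")
def full_study():
    """The fixed-seed study at default conditions (500 targets, 50%
    expressed, 4 arrays x 2 PMTs), shared across selection tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(seed=1)


@pytest.fixture(scope="session")
def full_selection(full_study):
    return eo.select_unique(full_study["positives"])


@pytest.fixture(scope="session")
def small_study():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(seed=7, n_targets=40, n_negative_controls=20, duplicate_fill=10)
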