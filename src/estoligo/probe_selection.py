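"""Positivity calling and the six-step reduction to one unique, validated
probe per unique target.

After per-probe call matrices are tabulated, selection proceeds:

1. remove probes flagged (saturated) in more than 25% of their
   measurements (>=2/4, 3/8 or 5/16);
   a probe is then *positive* when at least 75% of its measurements are
   present;
2. remove redundant (identical-sequence) probes within each assumed
   target orientation;
3. remove redundant target sequences — and their probes — within each
   orientation, keeping one best probe per distinct target sequence;
4. remove redundant probes/targets across orientations;
5. remove highly similar probes (>=95% identity over >=50 consecutive
   bases on either strand) to curb cross-hybridization;
6. at every conflict in steps 2-5 the probe with the higher mean SI
   survives (ties broken by lexicographic probe id).

The provenance log records every removal with its step, so input probes
are conserved: each ends up either in the validated set or in the log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .aligner import DEFAULT_WORD_SIZE, SimilarityIndex

ENTRY_COLUMNS = [
    "probe_id",
    "target_id",
    "orientation",
    "probe_length",
    "probe_seq",
    "target_seq",
    "mean_si",
    "cv_si",
]
LOG_COLUMNS = ["probe_id", "step", "reason", "kept_probe_id"]


@dataclass(frozen=True)
class SelectionConfig:
    max_flag_fraction: float = 0.25  # strict >
    min_positive_fraction: float = 0.75  # >=
    similarity_min_overlap: int = 50
    similarity_min_identity: float = 0.95
    word_size: int = DEFAULT_WORD_SIZE

    def __post_init__(self) -> None:
        for f in (self.max_flag_fraction, self.min_positive_fraction, self.similarity_min_identity):
            if not (0.0 < f <= 1.0):
                raise ValueError("selection fractions must be in (0, 1]")
        if self.similarity_min_overlap < 1:
            raise ValueError("similarity overlap must be >= 1")


@dataclass
class ValidatedProbeSet:
    entries: pd.DataFrame  # ENTRY_COLUMNS
    provenance: pd.DataFrame  # LOG_COLUMNS


def filter_flagged(matrix: pd.DataFrame, cfg: SelectionConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Step 1: drop probes flagged in more than ``max_flag_fraction`` of
    their measurements.  Returns (retained matrix, removed matrix)."""
    cfg = cfg or SelectionConfig()
    if (matrix["n_measurements"] < 1).any():
        raise ValueError("every probe needs >= 1 measurement")
    frac = matrix["n_flagged"] / matrix["n_measurements"]
    removed = matrix[frac > cfg.max_flag_fraction]
    return matrix[frac <= cfg.max_flag_fraction], removed


def call_positive(matrix: pd.DataFrame, cfg: SelectionConfig | None = None) -> pd.DataFrame:
    """Positive probes: >= ``min_positive_fraction`` of measurements present."""
    cfg = cfg or SelectionConfig()
    frac = matrix["n_positive"] / matrix["n_measurements"]
    return matrix[frac >= cfg.min_positive_fraction]


def _keep_best(group: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Survivor by (higher mean_si, then lexicographic probe_id)."""
    ordered = group.sort_values(["mean_si", "probe_id"], ascending=[False, True], kind="mergesort")
    return ordered.iloc[0], ordered.iloc[1:]


def select_unique(positives: pd.DataFrame, cfg: SelectionConfig | None = None) -> ValidatedProbeSet:
    """Steps 2-6: reduce positive probes to a unique validated set.

    ``positives`` must carry :data:`ENTRY_COLUMNS`.  Dedup conflicts and
    similarity conflicts are resolved by higher mean SI (step 6), ties by
    probe id.  The similarity filter is greedy in descending mean SI with
    exact window verification, so the final set is pairwise dissimilar at
    the configured thresholds and every removal names its keeper.
    """
    cfg = cfg or SelectionConfig()
    missing = [c for c in ENTRY_COLUMNS if c not in positives.columns]
    if missing:
        raise ValueError(f"positives table missing columns {missing}")
    if positives[["probe_seq", "mean_si"]].isna().any().any():
        raise ValueError("every positive probe needs a sequence and mean SI")
    log_rows: list[tuple[str, int, str, str]] = []
    current = positives.copy()

    def dedup(df: pd.DataFrame, key_cols: list[str], step: int, reason: str) -> pd.DataFrame:
        kept = []
        for _, group in df.groupby(key_cols, sort=True):
            best, losers = _keep_best(group)
            kept.append(best)
            for _, row in losers.iterrows():
                log_rows.append((row["probe_id"], step, reason, best["probe_id"]))
        return pd.DataFrame(kept).reset_index(drop=True)

    # step 2: identical probe sequence within orientation
    current = dedup(current, ["orientation", "probe_seq"], 2, "redundant probe within orientation")
    # step 3: identical target sequence within orientation -> one probe per
    # target-sequence group (covers multi-probe targets and duplicate targets)
    current = dedup(current, ["orientation", "target_seq"], 3, "redundant target within orientation")
    # step 4: identical probes, then shared targets, across orientations
    current = dedup(current, ["probe_seq"], 4, "redundant probe across orientations")
    current = dedup(current, ["target_id"], 4, "redundant target across orientations")
    current = dedup(current, ["target_seq"], 4, "redundant target sequence across orientations")

    # step 5: cross-hybridization similarity, greedy by descending mean SI
    current = current.sort_values(["mean_si", "probe_id"], ascending=[False, True], kind="mergesort")
    index = SimilarityIndex(cfg.similarity_min_overlap, cfg.similarity_min_identity, cfg.word_size)
    kept_rows = []
    for _, row in current.iterrows():
        winner = index.find_similar(row["probe_seq"])
        if winner is None:
            index.add(row["probe_id"], row["probe_seq"])
            kept_rows.append(row)
        else:
            log_rows.append((row["probe_id"], 5, "highly similar probe", str(winner)))

    entries = (
        pd.DataFrame(kept_rows, columns=positives.columns)[ENTRY_COLUMNS]
        .sort_values("probe_id", kind="mergesort")
        .reset_index(drop=True)
    )
    provenance = pd.DataFrame(log_rows, columns=LOG_COLUMNS)
    return ValidatedProbeSet(entries=entries, provenance=provenance)


@dataclass
class SelectionSummary:
    n_total: int
    counts_by_orientation: dict[str, int]
    counts_by_length: dict[int, int]
    sense_share_pct: float
    antisense_share_pct: float
    targeted_bases: int
    genome_coverage_pct: float | None = None


def share_percentages(counts: dict[str, int]) -> dict[str, float]:
    """Orientation shares as percentages rounded to 1 decimal."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: round(100.0 * v / total, 1) for k, v in counts.items()}


def coverage_pct(targeted_bases: float, genome_size_bases: float) -> float:
    """Targeted fraction of the genome, as a percentage to 1 decimal."""
    if genome_size_bases <= 0:
        raise ValueError("genome size must be positive")
    return round(100.0 * targeted_bases / genome_size_bases, 1)


def summarize(vset: ValidatedProbeSet, genome_size_bases: float | None = None) -> SelectionSummary:
    """Counts by orientation and probe length, orientation shares, total
    targeted bases and optional genome-coverage percentage."""
    e = vset.entries
    by_orient = e["orientation"].value_counts().to_dict() if len(e) else {}
    by_len = e["probe_length"].value_counts().to_dict() if len(e) else {}
    shares = share_percentages(
        {"sense": by_orient.get("sense", 0), "antisense": by_orient.get("antisense", 0)}
    )
    targeted = int(e["target_seq"].str.len().sum()) if len(e) else 0
    cov = coverage_pct(targeted, genome_size_bases) if genome_size_bases else None
    return SelectionSummary(
        n_total=len(e),
        counts_by_orientation={k: int(v) for k, v in by_orient.items()},
        counts_by_length={int(k): int(v) for k, v in by_len.items()},
        sense_share_pct=shares["sense"],
        antisense_share_pct=shares["antisense"],
        targeted_bases=targeted,
        genome_coverage_pct=cov,
    )
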