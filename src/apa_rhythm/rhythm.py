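"""Consensus rhythm detection over replicate-slotted trials.

The circadian design has 6 timepoints (ZT2..ZT22) x 5 replicates.  A trial
places exactly one replicate in each timepoint slot; 5 trials are built
either by a deterministic Latin-square rotation (default) or by seeded
random per-slot permutations.  Each trial series is scored by the three
detectors, integrated by Fisher's method, and a PAC is a consensus hit only
when all 5 trial meta-p values fall below the significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .detectors import (
    circular_mean,
    cosinor_matrix,
    fisher_matrix,
    jtk_matrix,
    lomb_scargle_matrix,
)
from .pas_calling import SampleInfo

__all__ = [
    "RhythmParams",
    "CIRCADIAN_CONDITIONS",
    "condition_hours",
    "build_trials",
    "consensus_rhythm",
    "phase_bin",
]

CIRCADIAN_CONDITIONS = ("ZT2", "ZT6", "ZT10", "ZT14", "ZT18", "ZT22")

#: hours after light onset for every condition label; recovery groups map to
#: their collection clock time (R0 collected at ZT6, R2 at ZT8, ...)
_CONDITION_HOURS = {
    "ZT2": 2.0, "ZT6": 6.0, "ZT8": 8.0, "ZT10": 10.0, "ZT14": 14.0,
    "ZT18": 18.0, "ZT22": 22.0, "R0": 6.0, "R2": 8.0, "R4": 10.0, "R8": 14.0,
}


def condition_hours(condition: str) -> float:
    return _CONDITION_HOURS[condition]


@dataclass
class RhythmParams:
    alpha: float = 0.05
    scheme: str = "rotation"  # or "seeded_random"
    seed: int = 0
    n_trials: int = 5
    phase_grid_h: tuple | None = None  # JTK lag grid; None = sampling step


def build_trials(
    matrix: pd.DataFrame,
    samples: list[SampleInfo],
    scheme: str = "rotation",
    seed: int = 0,
    conditions: tuple[str, ...] = CIRCADIAN_CONDITIONS,
    n_trials: int = 5,
) -> list[tuple[np.ndarray, pd.DataFrame]]:
    """Build replicate-slotted trial matrices.

    Returns ``n_trials`` pairs ``(times, trial_matrix)`` where ``times`` are
    the timepoint hours and ``trial_matrix`` has one column per timepoint
    (a single replicate's counts), rows aligned with ``matrix``.

    ``rotation`` (default): timepoint index ``i`` (1-based) in trial ``j``
    gets replicate ``((i + j - 2) mod R) + 1`` — a Latin square, so every
    replicate serves each slot exactly once across the R trials.
    ``seeded_random``: an independent seeded permutation per slot per trial.
    """
    by_slot: dict[tuple[str, int], str] = {}
    for s in samples:
        if s.condition in conditions:
            by_slot[(s.condition, s.replicate)] = s.sample_id
    replicates = sorted({r for (_, r) in by_slot})
    n_rep = len(replicates)
    times = np.array([condition_hours(c) for c in conditions])
    order = np.argsort(times)
    conditions = tuple(conditions[k] for k in order)
    times = times[order]

    for cond in conditions:
        for rep in replicates:
            if (cond, rep) not in by_slot:
                raise ValueError(f"missing replicate {rep} for timepoint {cond}")

    rng = np.random.default_rng(seed)
    trials = []
    for j in range(1, n_trials + 1):
        chosen: list[str] = []
        if scheme == "rotation":
            for i in range(1, len(conditions) + 1):
                rep = replicates[(i + j - 2) % n_rep]
                chosen.append(by_slot[(conditions[i - 1], rep)])
        elif scheme == "seeded_random":
            for cond in conditions:
                rep = replicates[rng.integers(0, n_rep)]
                chosen.append(by_slot[(cond, rep)])
        else:
            raise ValueError(f"unknown trial scheme {scheme!r}")
        trials.append((times, matrix[chosen]))
    return trials


def _circ_mean_rows(phases: np.ndarray, period: float) -> np.ndarray:
    ang = 2.0 * np.pi * phases / period
    mean_ang = np.arctan2(np.sin(ang).mean(axis=1), np.cos(ang).mean(axis=1))
    out = (mean_ang * period / (2.0 * np.pi)) % period
    return np.where(out < period, out, 0.0)


def consensus_rhythm(
    matrix: pd.DataFrame,
    samples: list[SampleInfo],
    period_h: float = 24.0,
    params: RhythmParams | None = None,
) -> pd.DataFrame:
    """Run the 3-detector, 5-trial consensus screen on a (PAC x sample) matrix.

    Per PAC and trial the three detector p-values are combined by Fisher's
    method; ``mean_p`` is the arithmetic mean of the 5 trial meta-p values,
    ``mean_fdr`` the mean of their within-trial BH adjustments, ``mean_phase_h``
    the circular mean of trial phases, and ``consensus`` requires every trial
    meta-p < alpha.  All-zero (constant) PACs get p = 1 and stay in the BH
    denominators.
    """
    params = params or RhythmParams()
    trials = build_trials(matrix, samples, params.scheme, params.seed,
                          n_trials=params.n_trials)
    n_pac = matrix.shape[0]
    trial_p = np.empty((n_pac, len(trials)))
    trial_fdr = np.empty_like(trial_p)
    trial_phase = np.empty_like(trial_p)
    trial_amp = np.empty_like(trial_p)
    for k, (times, tm) in enumerate(trials):
        Y = tm.to_numpy(dtype=float)
        cos = cosinor_matrix(times, Y, period_h)
        ls = lomb_scargle_matrix(times, Y, period_h)
        jtk = jtk_matrix(times, Y, period_h, params.phase_grid_h)
        meta_p = fisher_matrix(np.column_stack([ls["p"], jtk["p"], cos["p"]]))
        phases = np.column_stack([ls["phase"], jtk["phase"], cos["phase"]])
        trial_p[:, k] = meta_p
        trial_fdr[:, k] = stats.false_discovery_control(meta_p, method="bh")
        trial_phase[:, k] = _circ_mean_rows(phases, period_h)
        trial_amp[:, k] = cos["amplitude"]

    out = pd.DataFrame({"pac_id": matrix.index})
    out["period_h"] = period_h
    for k in range(trial_p.shape[1]):
        out[f"trial_p_{k + 1}"] = trial_p[:, k]
    out["mean_p"] = trial_p.mean(axis=1)
    out["mean_fdr"] = trial_fdr.mean(axis=1)
    out["mean_phase_h"] = _circ_mean_rows(trial_phase, period_h)
    out["mean_amplitude"] = trial_amp.mean(axis=1)
    out["consensus"] = (trial_p < params.alpha).all(axis=1)
    return out


def phase_bin(
    results: pd.DataFrame,
    centers_h: tuple[float, ...] = (2, 6, 10, 14, 18, 22),
    halfwidth_h: float = 2.5,
    day_h: float = 24.0,
) -> dict[float, list[str]]:
    """Group consensus PACs into sliding circular phase windows.

    A PAC joins every window ``[center - halfwidth, center + halfwidth]``
    (mod ``day_h``) containing its mean phase; adjacent 5-h windows at 4-h
    centers overlap by 1 h, so dual membership is expected.  Only consensus
    rows are binned when a ``consensus`` column is present.
    """
    if "consensus" in results.columns:
        results = results[results["consensus"]]
    phases = results["mean_phase_h"].to_numpy(dtype=float) % day_h
    bins: dict[float, list[str]] = {}
    for center in centers_h:
        delta = np.abs((phases - center + day_h / 2.0) % day_h - day_h / 2.0)
        members = results["pac_id"].to_numpy()[delta <= halfwidth_h]
        bins[float(center)] = list(members)
    return bins


def write_rhythm_tsv(results: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# phases in ZT hours of fitted peak; p-values are 3-detector Fisher meta-p\n")
        results.to_csv(fh, sep="\t", index=False)
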