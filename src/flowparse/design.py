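"""Event-related scan design: balanced trial sequences and accounting.

One scan of the train experiment presents 15 movie trials of each of
the five conditions (Offboard, Onboard, Joint, Disjoint, Static) plus 5
target trials for the one-back task — 80 trials of 3 s shown back to
back, with a 10 s fixation period after every set of 10 trials, for a
total of 320 s (160 volumes at TR = 2 s).

The 75 non-target trials are first-order counterbalanced: every ordered
pair of conditions precedes/follows equally often.  With 74 real
transitions and 25 ordered pairs an exact count of 3 each is impossible
by one transition, so the construction (an Eulerian circuit on the
complete 5-node digraph with self-loops, 3 parallel edges per arc)
guarantees every pair count is 2 or 3 — the closest realisable balance.
Target trials are exact duplicates of their predecessor (the one-back
"same movie twice" event), inserted roughly once per minute, and are
excluded from the balance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from flowparse.stimuli import CONDITIONS

TRIAL_DURATION_S = 3.0
FIXATION_DURATION_S = 10.0
TRIALS_PER_CONDITION = 15
N_TARGETS = 5
TRIALS_PER_FIXATION = 10
MIN_TRIALS_BETWEEN_TARGETS = 12  # "approximately once per minute"
TRANSITION_MULTIPLICITY = 3  # each ordered condition pair occurs 3x


@dataclass
class Trial:
    onset: float
    duration: float
    trial_type: str
    movie_id: str
    is_target: bool = False


@dataclass
class ScanDesign:
    trials: list[Trial]
    fixation_blocks: list[tuple[float, float]]  # (onset, duration)
    scan_duration: float

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def condition_counts(self, include_targets: bool = False) -> dict[str, int]:
        counts = {c: 0 for c in CONDITIONS}
        for t in self.trials:
            if t.is_target and not include_targets:
                continue
            counts[t.trial_type] += 1
        return counts


@dataclass
class SessionPlan:
    """Scan bookkeeping for the full study."""

    n_subjects: int = 14
    n_mt_subjects: int = 8
    train_scans_per_subject: int = 6
    v6_localizer_scans: int = 2
    ppa_rsc_localizer_scans: int = 2
    mt_localizer_scans: int = 2
    train_volumes_per_scan: int = 160
    tr: float = 2.0


def _eulerian_condition_sequence(rng: np.random.Generator) -> list[str]:
    """Condition order for the 75 non-target trials.

    Hierholzer's algorithm on the complete digraph over the five
    conditions (self-loops included) with 3 parallel edges per arc: the
    circuit's 75 edges visit each condition 15 times; dropping the
    closing wrap leaves 74 transitions, every ordered pair counted 3
    times except the single wrapped pair (2).
    """
    k = len(CONDITIONS)
    # adjacency: for each node, a shuffled multiset of successors
    adjacency = {
        i: list(rng.permutation(np.repeat(np.arange(k), TRANSITION_MULTIPLICITY)))
        for i in range(k)
    }
    start = int(rng.integers(k))
    stack, circuit = [start], []
    while stack:
        v = stack[-1]
        if adjacency[v]:
            stack.append(int(adjacency[v].pop()))
        else:
            circuit.append(stack.pop())
    circuit.reverse()  # closed walk of 76 nodes (first == last)
    nodes = circuit[:-1]  # 75 trials
    return [CONDITIONS[i] for i in nodes]


def _target_positions(rng: np.random.Generator, n_trials: int) -> list[int]:
    """Positions (in the pre-insertion sequence) after which to duplicate."""
    while True:
        pos = np.sort(rng.choice(np.arange(1, n_trials), size=N_TARGETS, replace=False))
        if np.all(np.diff(pos) >= MIN_TRIALS_BETWEEN_TARGETS):
            return [int(p) for p in pos]


def build_scan_sequence(seed: int) -> ScanDesign:
    """Generate one train-experiment scan design.

    Deterministic in ``seed``.  Produces 75 counterbalanced non-target
    trials (15 per condition), inserts 5 one-back target duplicates with
    at least 12 trials between them, schedules a 10 s fixation block
    after every 10 trials, and assigns onsets with zero intertrial
    interval.
    """
    rng = np.random.default_rng(seed)
    sequence = _eulerian_condition_sequence(rng)

    # unique movie identities per non-target trial
    counters = {c: 0 for c in CONDITIONS}
    base: list[tuple[str, str]] = []
    for cond in sequence:
        base.append((cond, f"{cond}_{counters[cond]:02d}"))
        counters[cond] += 1

    # one-back targets: duplicate the trial at each chosen position
    full: list[tuple[str, str, bool]] = []
    positions = set(_target_positions(rng, len(base)))
    for i, (cond, movie_id) in enumerate(base):
        full.append((cond, movie_id, False))
        if i in positions:
            full.append((cond, movie_id, True))

    trials: list[Trial] = []
    fixations: list[tuple[float, float]] = []
    t = 0.0
    for i, (cond, movie_id, is_target) in enumerate(full):
        trials.append(Trial(t, TRIAL_DURATION_S, cond, movie_id, is_target))
        t += TRIAL_DURATION_S
        if (i + 1) % TRIALS_PER_FIXATION == 0:
            fixations.append((t, FIXATION_DURATION_S))
            t += FIXATION_DURATION_S
    return ScanDesign(trials, fixations, scan_duration=t)


def transition_balance_report(design: ScanDesign) -> tuple[pd.DataFrame, int]:
    """First-order transition counts over non-target trials.

    Returns the 5x5 matrix of ordered (previous condition -> current
    condition) counts and the imbalance score max - min.
    """
    seq = [t.trial_type for t in design.trials if not t.is_target]
    matrix = pd.DataFrame(
        np.zeros((len(CONDITIONS), len(CONDITIONS)), dtype=int),
        index=list(CONDITIONS),
        columns=list(CONDITIONS),
    )
    for prev, cur in zip(seq, seq[1:]):
        matrix.loc[prev, cur] += 1
    values = matrix.to_numpy()
    imbalance = int(values.max() - values.min()) if seq else 0
    return matrix, imbalance


def session_accounting(plan: SessionPlan) -> pd.DataFrame:
    """Per-experiment and total scan counts for the study."""
    train = plan.n_subjects * plan.train_scans_per_subject
    localizer = plan.n_subjects * (
        plan.v6_localizer_scans + plan.ppa_rsc_localizer_scans
    ) + plan.n_mt_subjects * plan.mt_localizer_scans
    return pd.DataFrame(
        {
            "experiment": ["train", "localizer", "total"],
            "n_scans": [train, localizer, train + localizer],
        }
    )


def expected_volumes(design: ScanDesign, tr: float) -> int:
    """Number of volumes needed to cover the scan at repetition time tr."""
    if tr <= 0:
        raise ValueError("TR must be positive")
    return int(np.ceil(design.scan_duration / tr))


EVENT_COLUMNS = [
    "onset", "duration", "trial_type", "movie_id", "is_target",
    "QoM", "SoM", "SMS", "OMS",
]


def write_events(
    design: ScanDesign, modulators: pd.DataFrame, path: str | Path
) -> pd.DataFrame:
    """Write a BIDS-style events TSV with per-trial modulator values.

    ``modulators`` must be indexed (or indexable) by movie_id with
    columns QoM, SoM and, where defined for the condition, SMS and OMS;
    missing modulator rows raise an error naming the offending movies.
    Returns the events table that was written.
    """
    mods = modulators.set_index("movie_id") if "movie_id" in modulators else modulators
    missing = sorted(
        {t.movie_id for t in design.trials if t.trial_type != "Static"}
        - set(mods.index)
    )
    if missing:
        raise KeyError(f"no modulator values for movie_ids: {missing}")
    rows = []
    for t in design.trials:
        rec: dict = {
            "onset": t.onset,
            "duration": t.duration,
            "trial_type": t.trial_type,
            "movie_id": t.movie_id,
            "is_target": int(t.is_target),
            "QoM": np.nan, "SoM": np.nan, "SMS": np.nan, "OMS": np.nan,
        }
        if t.movie_id in mods.index:
            for col in ("QoM", "SoM", "SMS", "OMS"):
                if col in mods.columns:
                    rec[col] = mods.loc[t.movie_id, col]
        rows.append(rec)
    table = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    table.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return table


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an events TSV written by :func:`write_events`."""
    return pd.read_csv(path, sep="\t", na_values="n/a")


def design_from_events(events: pd.DataFrame) -> ScanDesign:
    """Reconstruct a ScanDesign from an events table.

    Fixation blocks are inferred from the gaps between trials (the
    design leaves no other silence), so write -> read -> reconstruct is
    lossless for generated designs.
    """
    trials = [
        Trial(
            float(r.onset), float(r.duration), str(r.trial_type),
            str(r.movie_id), bool(r.is_target),
        )
        for r in events.itertuples()
    ]
    fixations = []
    for a, b in zip(trials, trials[1:]):
        gap = b.onset - (a.onset + a.duration)
        if gap > 1e-9:
            fixations.append((a.onset + a.duration, gap))
    last_end = trials[-1].onset + trials[-1].duration if trials else 0.0
    # the final fixation block closes the scan
    fixations.append((last_end, FIXATION_DURATION_S))
    return ScanDesign(trials, fixations, scan_duration=last_end + FIXATION_DURATION_S)
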