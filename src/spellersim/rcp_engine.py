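"""Row-column stimulation engine.

A *sequence* is one round in which each of the 7 rows (stimulus ids 0-6)
and 7 columns (ids 7-13) flashes exactly once in pseudo-random order.  A
selection accumulates classifier scores over ``n_sequences`` such rounds
and picks the cell at the intersection of the best-scoring row and column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_ROWS = 7
N_COLS = 7
N_STIMULI = N_ROWS + N_COLS
GRID_ITEMS = N_ROWS * N_COLS  # 49 selectable cells, dummies included


@dataclass(frozen=True)
class FlashSchedule:
    """Ordered stimulus ids over ``n_sequences`` complete rounds."""

    stimulus_ids: tuple[int, ...]
    n_sequences: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if len(self.stimulus_ids) != N_STIMULI * self.n_sequences:
            raise ValueError("schedule length must be 14 x n_sequences")
        for block in range(self.n_sequences):
            chunk = self.stimulus_ids[block * N_STIMULI:(block + 1) * N_STIMULI]
            if sorted(chunk) != list(range(N_STIMULI)):
                raise ValueError("each block of 14 must flash every stimulus once")

    def truncated(self, n_seq: int) -> "FlashSchedule":
        """First ``n_seq`` sequences of this schedule."""
        if not 1 <= n_seq <= self.n_sequences:
            raise ValueError("n_seq out of range for this schedule")
        return FlashSchedule(self.stimulus_ids[: N_STIMULI * n_seq], n_seq, self.seed)


@dataclass(frozen=True)
class MenuLayout:
    """A 7x7 menu: item identifiers plus a mask of no-effect dummy cells."""

    grid: tuple[tuple[str, ...], ...]
    dummy_mask: tuple[tuple[bool, ...], ...]

    def __post_init__(self) -> None:
        if len(self.grid) != N_ROWS or any(len(r) != N_COLS for r in self.grid):
            raise ValueError("grid must be 7x7")
        if len(self.dummy_mask) != N_ROWS or any(len(r) != N_COLS for r in self.dummy_mask):
            raise ValueError("dummy_mask must be 7x7")

    @property
    def n_dummies(self) -> int:
        return sum(sum(row) for row in self.dummy_mask)

    def item_at(self, position: tuple[int, int]) -> str:
        r, c = position
        return self.grid[r][c]

    def find(self, item: str) -> tuple[int, int] | None:
        """Position of ``item`` (case-insensitive), or None."""
        want = item.upper()
        for r in range(N_ROWS):
            for c in range(N_COLS):
                if self.grid[r][c].upper() == want and not self.dummy_mask[r][c]:
                    return (r, c)
        return None


def make_flash_schedule(n_seq: int, seed: int) -> FlashSchedule:
    """Concatenate ``n_seq`` independent uniform permutations of the 14 stimuli."""
    if n_seq < 1:
        raise ValueError("n_seq must be >= 1")
    rng = np.random.default_rng(seed)
    ids = np.concatenate([rng.permutation(N_STIMULI) for _ in range(n_seq)])
    return FlashSchedule(tuple(int(i) for i in ids), n_seq, int(seed))


def decide_item(scores, schedule: FlashSchedule) -> tuple[int, int]:
    """Pick the attended cell from per-flash classifier scores.

    Scores are summed per stimulus id; the decided row is the argmax over
    ids 0-6 and the decided column the argmax over ids 7-13.  Ties break
    toward the lowest id.
    """
    scores = np.asarray(scores, dtype=float)
    ids = np.asarray(schedule.stimulus_ids)
    if scores.shape != ids.shape:
        raise ValueError("one score per scheduled flash required")
    totals = np.bincount(ids, weights=scores, minlength=N_STIMULI)
    row = int(np.argmax(totals[:N_ROWS]))
    col = int(np.argmax(totals[N_ROWS:]))
    return row, col


def selection_duration(n_seq: int, timing) -> float:
    """Seconds per selection: 14 x n_seq flashes at the SOA, plus any pause."""
    if n_seq < 1:
        raise ValueError("n_seq must be >= 1")
    return N_STIMULI * n_seq * timing.soa_s + timing.inter_selection_pause_s


def export_event_log(events, scores, path) -> None:
    """CSV event log: onset, stimulus_id, score."""
    import pandas as pd

    pd.DataFrame({
        "onset_sample": [e.onset_sample for e in events],
        "stimulus_id": [e.stimulus_id for e in events],
        "score": np.asarray(scores, dtype=float),
    }).to_csv(path, index=False)
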