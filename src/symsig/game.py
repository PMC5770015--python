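"""Study design of the repeated graphical signalling game.

A pair of participants plays ``n_rounds`` rounds (default 8) of a
Pictionary-like guessing game over a shortlist of items (default 10 of 25),
alternating the signaller/receiver roles each round, so eight rounds make
four *turns* (a turn = two consecutive rounds in which each participant
signals every shortlist item once).  To separate item-specific novelty from
game-level fatigue, one shortlist item is replaced by a fresh pool item at
the start of every second round (rounds 3, 5, 7 by default), so every turn
after the first introduces exactly one novel item and removed items never
return.

This module builds seeded schedules, derives per-signal records with the
``time_seen`` covariate (number of distinct turns the pair has seen the
item, up to and including the signal's turn), and links each signal to its
most-resembling predecessor from the previous turn — the *familiarity
chain* against which familiarity is rated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError


@dataclass(frozen=True)
class ScheduleConfig:
    """Parameters of one game's schedule."""

    n_rounds: int = 8
    shortlist_size: int = 10
    replace_every: int = 2  # one item swapped at the start of every second round

    def replacement_rounds(self) -> list[int]:
        """Rounds at whose start one shortlist item is replaced (3, 5, 7 by default)."""
        return list(range(1 + self.replace_every, self.n_rounds + 1, self.replace_every))


@dataclass
class GameSchedule:
    """Fully resolved schedule for one pair."""

    pair_id: str
    participants: tuple[str, str]
    n_rounds: int
    round_rosters: list[list[str]]  # per round, ordered shortlist
    roles: list[tuple[str, str]]  # per round, (signaller_id, receiver_id)
    replacement_log: list[tuple[int, str, str]]  # (round, removed, added)

    def to_frame(self) -> pd.DataFrame:
        """Long-format schedule table: one row per (round, shortlist position)."""
        rows = []
        for r, roster in enumerate(self.round_rosters, start=1):
            sig, rec = self.roles[r - 1]
            for pos, item in enumerate(roster, start=1):
                rows.append(
                    {
                        "pair_id": self.pair_id,
                        "round": r,
                        "turn": turn_of_round(r),
                        "position": pos,
                        "item": item,
                        "signaller_id": sig,
                        "receiver_id": rec,
                    }
                )
        return pd.DataFrame(rows)


def turn_of_round(round_: int) -> int:
    """Turn index of a round: two consecutive rounds form one turn (``ceil(r/2)``)."""
    if round_ < 1:
        raise ValueError(f"round must be >= 1, got {round_}")
    return math.ceil(round_ / 2)


def build_schedule(
    item_pool: Sequence[str],
    config: ScheduleConfig = ScheduleConfig(),
    seed: int = 0,
    pair_id: str = "pair00",
    participants: tuple[str, str] | None = None,
) -> GameSchedule:
    """Build a seeded schedule for one pair.

    The shortlist is drawn uniformly without replacement from the pool, its
    order re-randomised before every round, and at each replacement round one
    current item (uniform) is swapped for an unused pool item (uniform).  A
    seeded coin toss decides who signals first; roles then alternate.

    Raises
    ------
    ConfigurationError
        If the pool cannot support the shortlist plus every replacement.
    """
    pool = list(item_pool)
    if len(set(pool)) != len(pool):
        raise ConfigurationError("item pool contains duplicates")
    n_repl = len(config.replacement_rounds())
    if config.shortlist_size >= len(pool):
        raise ConfigurationError(
            f"shortlist size {config.shortlist_size} must be smaller than the "
            f"pool ({len(pool)} items) so that replacement items exist"
        )
    if config.shortlist_size + n_repl > len(pool):
        raise ConfigurationError(
            f"pool of {len(pool)} items cannot supply a shortlist of "
            f"{config.shortlist_size} plus {n_repl} replacements"
        )

    rng = np.random.default_rng(seed)
    if participants is None:
        participants = (f"{pair_id}_a", f"{pair_id}_b")
    first_signaller = int(rng.integers(2))  # coin toss

    shortlist = [pool[i] for i in rng.choice(len(pool), config.shortlist_size, replace=False)]
    unused = [it for it in pool if it not in shortlist]
    retired: list[str] = []

    rosters: list[list[str]] = []
    roles: list[tuple[str, str]] = []
    replacement_log: list[tuple[int, str, str]] = []
    repl_rounds = set(config.replacement_rounds())

    for r in range(1, config.n_rounds + 1):
        if r in repl_rounds:
            removed = shortlist[int(rng.integers(len(shortlist)))]
            added = unused[int(rng.integers(len(unused)))]
            shortlist[shortlist.index(removed)] = added
            unused.remove(added)
            retired.append(removed)
            replacement_log.append((r, removed, added))
        order = rng.permutation(len(shortlist))
        rosters.append([shortlist[i] for i in order])
        sig = participants[(first_signaller + r - 1) % 2]
        rec = participants[(first_signaller + r) % 2]
        roles.append((sig, rec))

    return GameSchedule(
        pair_id=pair_id,
        participants=participants,
        n_rounds=config.n_rounds,
        round_rosters=rosters,
        roles=roles,
        replacement_log=replacement_log,
    )


def signal_records(schedule: GameSchedule) -> pd.DataFrame:
    """One row per drawing event, with first-exposure flags and time_seen.

    Columns: signal_id, pair_id, round, turn, item, signaller_id, receiver_id,
    is_first_exposure, time_seen.
    """
    df = schedule.to_frame().copy()
    df["signal_id"] = [
        f"{p}_r{r}_p{pos}" for p, r, pos in zip(df.pair_id, df["round"], df.position)
    ]
    order = df.sort_values(["round", "position"]).index
    seen_rounds: dict[str, list[int]] = {}
    first, tseen = {}, {}
    for idx in order:
        item = df.at[idx, "item"]
        r = int(df.at[idx, "round"])
        prev = seen_rounds.setdefault(item, [])
        first[idx] = len(prev) == 0
        prev.append(r)
        tseen[idx] = len({turn_of_round(x) for x in prev})
    df["is_first_exposure"] = pd.Series(first)
    df["time_seen"] = pd.Series(tseen)
    return df.drop(columns=["position"]).sort_values(["round", "signal_id"]).reset_index(drop=True)


def compute_time_seen(records: pd.DataFrame) -> pd.DataFrame:
    """Fill ``time_seen`` (and ``is_first_exposure``) on an existing record table.

    ``time_seen`` of a signal is the number of distinct turns in which its
    (pair, item) has appeared up to and including the signal's turn; it is
    monotone non-decreasing along a pair-item history.

    Raises
    ------
    DataIntegrityError
        On duplicate (pair, item, round, signaller) rows.
    """
    required = {"pair_id", "item", "round", "signaller_id"}
    missing = required - set(records.columns)
    if missing:
        raise DataIntegrityError(f"records missing columns: {sorted(missing)}")
    dup = records.duplicated(subset=["pair_id", "item", "round", "signaller_id"])
    if dup.any():
        bad = records.loc[dup, ["pair_id", "item", "round"]].iloc[0]
        raise DataIntegrityError(
            f"duplicate signal row for pair={bad.pair_id!r} item={bad.item!r} round={bad['round']}"
        )

    out = records.copy()
    out["turn"] = [turn_of_round(int(r)) for r in out["round"]]
    out = out.sort_values(["pair_id", "item", "round"], kind="mergesort")
    time_seen = []
    first_flag = []
    key = None
    turns_seen: set[int] = set()
    for pair, item, turn in zip(out.pair_id, out.item, out.turn):
        if (pair, item) != key:
            key = (pair, item)
            turns_seen = set()
            first_flag.append(True)
        else:
            first_flag.append(False)
        turns_seen.add(turn)
        time_seen.append(len(turns_seen))
    out["time_seen"] = time_seen
    out["is_first_exposure"] = first_flag
    return out.sort_index()


def link_familiarity_chain(
    signals: pd.DataFrame,
    resemblance: Callable[[str, str], float],
) -> dict[str, str | None]:
    """Map each signal of one (pair, item) history to its chain predecessor.

    The predecessor of a signal is the signal from the *previous turn* that it
    most resembles; within the item's first turn, the second-round signal links
    to the (only) first-round signal, and the very first signal links to
    nothing. Ties in resemblance break deterministically to the lower round,
    then the lexicographically smaller signal_id.

    Parameters
    ----------
    signals : DataFrame with columns signal_id, round (one pair-item history)
    resemblance : callable (signal_id, signal_id) -> similarity in [0, 1]
    """
    df = signals.sort_values("round")
    rounds = list(df["round"].astype(int))
    ids = list(df["signal_id"])
    turns = [turn_of_round(r) for r in rounds]
    first_turn = turns[0]

    out: dict[str, str | None] = {}
    for i, (sid, turn) in enumerate(zip(ids, turns)):
        if i == 0:
            out[sid] = None
            continue
        if turn == first_turn:
            # second signal of the item's first turn: forced link to the first
            out[sid] = ids[0]
            continue
        cands = [
            (ids[j], rounds[j])
            for j in range(len(ids))
            if turns[j] == turn - 1
        ]
        if not cands:  # item skipped a turn (real data); fall back to latest earlier signal
            cands = [(ids[j], rounds[j]) for j in range(i) if turns[j] < turn]
            cands = [max(cands, key=lambda c: c[1])]
        best = max(cands, key=lambda c: (resemblance(sid, c[0]), -c[1], _neg_str(c[0])))
        out[sid] = best[0]
    return out


class _neg_str:
    """Ordering helper: compares as the reverse of the wrapped string."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_neg_str") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_str) and self.s == other.s
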