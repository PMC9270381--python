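"""Data model and delimited-text I/O for career and team performance tables.

A *career* is the ordered sequence of non-negative integer scores of one
player in one format (ODI or Test) and one discipline (batting or bowling),
indexed by the rank of the game within the career. A *team series* pairs a
per-game team performance (the sum of the individual scores in that game)
with the game outcome (win / loss / other).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class Format(str, Enum):
    ODI = "ODI"
    TEST = "Test"


class Discipline(str, Enum):
    BATTING = "batting"
    BOWLING = "bowling"


class Outcome(str, Enum):
    WIN = "win"
    LOSS = "loss"
    OTHER = "other"


#: Default column names for career tables.
DEFAULT_CAREER_SCHEMA: dict[str, str] = {
    "player_id": "player_id",
    "format": "format",
    "discipline": "discipline",
    "order": "game_index",
    "score": "score",
}

#: Default column names for team match tables (one row per player-game).
DEFAULT_MATCH_SCHEMA: dict[str, str] = {
    "team": "team_id",
    "format": "format",
    "order": "game_index",
    "score": "score",
    "outcome": "outcome",
}

_OUTCOME_ALIASES = {
    "win": Outcome.WIN,
    "w": Outcome.WIN,
    "won": Outcome.WIN,
    "loss": Outcome.LOSS,
    "l": Outcome.LOSS,
    "lost": Outcome.LOSS,
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates an invariant (e.g. a negative score)."""


@dataclass(frozen=True)
class CareerRecord:
    """Ordered score sequence S(t), t = 1..tau, for one player/format/discipline."""

    player_id: str
    format: Format
    discipline: Discipline
    scores: np.ndarray  # non-negative ints, calendar order

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 1 or scores.size < 1:
            raise ValidationError(
                f"career {self.player_id!r}: scores must be a non-empty 1-d sequence"
            )
        if np.any(scores < 0):
            bad = int(np.argmax(scores < 0))
            raise ValidationError(
                f"career {self.player_id!r}: negative score at game {bad + 1}"
            )
        object.__setattr__(self, "scores", scores.astype(np.int64))

    @property
    def career_length(self) -> int:
        """tau: number of games in the career."""
        return int(self.scores.size)

    def with_scores(self, scores: Sequence[int] | np.ndarray) -> "CareerRecord":
        return CareerRecord(self.player_id, self.format, self.discipline, np.asarray(scores))


@dataclass(frozen=True)
class TeamSeries:
    """Per-game team performance and outcome sequence for one team/format."""

    team_id: str
    format: Format
    performances: np.ndarray
    outcomes: tuple[Outcome, ...] = field(default=())

    def __post_init__(self) -> None:
        perf = np.asarray(self.performances, dtype=float)
        if perf.ndim != 1 or perf.size < 1:
            raise ValidationError(f"team {self.team_id!r}: performances must be non-empty")
        if np.any(perf < 0):
            raise ValidationError(f"team {self.team_id!r}: negative performance")
        outcomes = tuple(self.outcomes)
        if outcomes and len(outcomes) != perf.size:
            raise ValidationError(
                f"team {self.team_id!r}: {len(outcomes)} outcomes for {perf.size} games"
            )
        object.__setattr__(self, "performances", perf)
        object.__setattr__(self, "outcomes", outcomes)

    def as_career(self, round_scores: bool = True) -> CareerRecord:
        """View the team performance series as a pseudo-career so the individual
        evaluation pipeline applies unchanged (team scores are sums of integer
        scores, hence integers already in the usual case)."""
        scores = np.round(self.performances).astype(np.int64) if round_scores else self.performances
        return CareerRecord(self.team_id, self.format, Discipline.BATTING, scores)


def _parse_enum(value: str, enum: type[Enum], what: str, row: int):
    try:
        if enum is Format:
            return Format.ODI if str(value).strip().upper() == "ODI" else Format(str(value).strip().title())
        return enum(str(value).strip().lower())
    except ValueError as exc:
        raise ValidationError(f"row {row}: unrecognized {what} {value!r}") from exc


def _parse_outcome(value: str) -> Outcome:
    return _OUTCOME_ALIASES.get(str(value).strip().lower(), Outcome.OTHER)


def _require_columns(df: pd.DataFrame, schema: Mapping[str, str], keys: Iterable[str]) -> None:
    missing = [schema[k] for k in keys if schema[k] not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


def load_careers(
    path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[CareerRecord]:
    """Read a delimited career table into one :class:`CareerRecord` per
    (player, format, discipline), games sorted by the order-index column.

    Malformed rows raise :class:`ValidationError` naming the offending row
    (1-based, excluding the header).
    """
    schema = dict(DEFAULT_CAREER_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, sep=delimiter)
    _require_columns(df, schema, ["player_id", "format", "discipline", "order", "score"])
    if df.empty:
        logger.warning("career table %s is empty", path)
        return []

    scores = pd.to_numeric(df[schema["score"]], errors="coerce")
    bad = np.flatnonzero(scores.isna() | (scores < 0))
    if bad.size:
        raise ValidationError(
            f"row {bad[0] + 1}: score {df[schema['score']].iloc[bad[0]]!r} "
            "is negative or non-numeric"
        )

    records: list[CareerRecord] = []
    grouped = df.groupby(
        [schema["player_id"], schema["format"], schema["discipline"]], sort=True
    )
    for (pid, fmt, disc), grp in grouped:
        grp = grp.sort_values(schema["order"], kind="stable")
        row0 = int(grp.index[0]) + 1
        records.append(
            CareerRecord(
                player_id=str(pid),
                format=_parse_enum(fmt, Format, "format", row0),
                discipline=_parse_enum(disc, Discipline, "discipline", row0),
                scores=grp[schema["score"]].to_numpy(dtype=np.int64),
            )
        )
    logger.info("loaded %d careers from %s", len(records), path)
    return records


def write_careers(
    careers: Iterable[CareerRecord],
    path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> None:
    """Inverse of :func:`load_careers` (same schema, game index 1..tau)."""
    schema = dict(DEFAULT_CAREER_SCHEMA, **(schema or {}))
    rows = []
    for c in careers:
        for t, s in enumerate(c.scores, start=1):
            rows.append(
                {
                    schema["player_id"]: c.player_id,
                    schema["format"]: c.format.value,
                    schema["discipline"]: c.discipline.value,
                    schema["order"]: t,
                    schema["score"]: int(s),
                }
            )
    pd.DataFrame(
        rows,
        columns=[schema[k] for k in ("player_id", "format", "discipline", "order", "score")],
    ).to_csv(path, sep=delimiter, index=False)


def filter_min_games(
    careers: Iterable[CareerRecord], min_games: int = 30
) -> list[CareerRecord]:
    """Keep careers with at least ``min_games`` games (inclusive threshold)."""
    if min_games < 1:
        raise ValueError("min_games must be >= 1")
    careers = list(careers)
    kept = [c for c in careers if c.career_length >= min_games]
    logger.info(
        "min-games filter (>=%d): retained %d / dropped %d",
        min_games, len(kept), len(careers) - len(kept),
    )
    return kept


def team_performance_series(
    match_table: pd.DataFrame,
    schema: Mapping[str, str] | None = None,
) -> list[TeamSeries]:
    """Aggregate a per-player match table into one :class:`TeamSeries` per
    (team, format): per-game performance is the sum of that game's individual
    scores; the outcome is carried through and must be unique within a game.
    """
    schema = dict(DEFAULT_MATCH_SCHEMA, **(schema or {}))
    _require_columns(match_table, schema, ["team", "order", "score", "outcome"])
    fmt_col = schema["format"] if schema["format"] in match_table.columns else None

    series: list[TeamSeries] = []
    team_keys = [schema["team"]] + ([fmt_col] if fmt_col else [])
    for key, tgrp in match_table.groupby(team_keys, sort=True):
        team_id = str(key[0] if isinstance(key, tuple) else key)
        fmt = (
            _parse_enum(key[1], Format, "format", 0)
            if fmt_col and isinstance(key, tuple)
            else Format.ODI
        )
        perfs, outs = [], []
        for game, ggrp in tgrp.groupby(schema["order"], sort=True):
            uniq = ggrp[schema["outcome"]].astype(str).str.strip().str.lower().unique()
            if len(uniq) > 1:
                raise ValidationError(
                    f"team {team_id!r} game {game}: conflicting outcomes {sorted(uniq)}"
                )
            perfs.append(float(ggrp[schema["score"]].sum()))
            outs.append(_parse_outcome(uniq[0]))
        series.append(TeamSeries(team_id, fmt, np.asarray(perfs), tuple(outs)))
    return series
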