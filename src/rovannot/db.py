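"""Relational persistence for the survey: movies, sites, species choices,
annotation subjects, aggregated annotations and model annotations, in a
single-file SQLite database with enforced foreign keys — plus export of
machine observation periods as Darwin Core occurrence records.

The schema has exactly seven interconnected tables::

    sites <- movies <- subjects <- agg_annotations_clip
    species ------------^      ^-- agg_annotations_frame
    movies <- model_annotations

The schema version is stored in SQLite's ``user_version`` pragma so a file
created by an incompatible release is rejected rather than silently
misread.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import ReferentialError, SchemaMismatchError, ValidationError
from .yolo import ObservationPeriod

SCHEMA_VERSION = 1

TABLES = (
    "movies",
    "sites",
    "species",
    "subjects",
    "agg_annotations_clip",
    "agg_annotations_frame",
    "model_annotations",
)

_SCHEMA_SQL = """
CREATE TABLE IF NOT EXISTS sites (
    site_id TEXT PRIMARY KEY,
    name TEXT NOT NULL,
    decimal_latitude REAL CHECK (decimal_latitude BETWEEN -90 AND 90),
    decimal_longitude REAL CHECK (decimal_longitude BETWEEN -180 AND 180),
    grid_square_id TEXT
);
CREATE TABLE IF NOT EXISTS movies (
    movie_id TEXT PRIMARY KEY,
    site_id TEXT NOT NULL REFERENCES sites(site_id),
    fps REAL NOT NULL CHECK (fps > 0),
    duration_s REAL NOT NULL CHECK (duration_s >= 0),
    recorded_date TEXT
);
CREATE TABLE IF NOT EXISTS species (
    choice_id TEXT PRIMARY KEY,
    label TEXT NOT NULL UNIQUE,
    scientific_name TEXT
);
CREATE TABLE IF NOT EXISTS subjects (
    subject_id TEXT PRIMARY KEY,
    kind TEXT NOT NULL CHECK (kind IN ('clip', 'frame')),
    movie_id TEXT NOT NULL REFERENCES movies(movie_id),
    clip_start_s REAL,
    clip_len_s REAL,
    frame_no INTEGER CHECK (frame_no IS NULL OR frame_no >= 0),
    CHECK (kind != 'clip' OR clip_len_s IS NOT NULL),
    CHECK (kind != 'frame' OR frame_no IS NOT NULL)
);
CREATE TABLE IF NOT EXISTS agg_annotations_clip (
    subject_id TEXT NOT NULL REFERENCES subjects(subject_id),
    choice_id TEXT NOT NULL REFERENCES species(choice_id),
    n_support INTEGER NOT NULL,
    n_annotators INTEGER NOT NULL,
    mean_first_seen_s REAL,
    consensus_count INTEGER,
    PRIMARY KEY (subject_id, choice_id)
);
CREATE TABLE IF NOT EXISTS agg_annotations_frame (
    subject_id TEXT NOT NULL REFERENCES subjects(subject_id),
    choice_id TEXT NOT NULL REFERENCES species(choice_id),
    x REAL NOT NULL, y REAL NOT NULL, w REAL NOT NULL, h REAL NOT NULL,
    support INTEGER NOT NULL,
    n_annotators INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS model_annotations (
    movie_id TEXT NOT NULL REFERENCES movies(movie_id),
    frame_no_start INTEGER NOT NULL,
    frame_no_end INTEGER NOT NULL,
    max_conf REAL NOT NULL,
    x REAL NOT NULL, y REAL NOT NULL, w REAL NOT NULL, h REAL NOT NULL,
    CHECK (frame_no_start <= frame_no_end)
);
"""

DWC_HEADER = [
    "occurrenceID",
    "scientificName",
    "individualCount",
    "eventDate",
    "decimalLatitude",
    "decimalLongitude",
    "basisOfRecord",
    "associatedMedia",
]


@dataclass(frozen=True)
class Movie:
    movie_id: str
    site_id: str
    fps: float
    duration_s: float
    recorded_date: Optional[str] = None


@dataclass(frozen=True)
class Site:
    site_id: str
    name: str
    decimal_latitude: Optional[float] = None
    decimal_longitude: Optional[float] = None
    grid_square_id: Optional[str] = None


@dataclass(frozen=True)
class OccurrenceRecord:
    """A Darwin Core occurrence-core record for one observation period."""

    occurrence_id: str
    scientific_name: str
    individual_count: int
    event_date: str
    decimal_latitude: Optional[float]
    decimal_longitude: Optional[float]
    basis_of_record: str
    associated_media: str


def create_schema(db_path: Union[str, Path]) -> sqlite3.Connection:
    """Create (or re-open) the seven-table survey database.

    Idempotent: calling twice on the same path is a no-op.  A file carrying
    a different schema version (or foreign tables) raises
    :class:`SchemaMismatchError`.
    """
    conn = sqlite3.connect(str(db_path))
    conn.execute("PRAGMA foreign_keys = ON")
    existing = {
        r[0]
        for r in conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' "
            "AND name NOT LIKE 'sqlite_%'"
        )
    }
    version = conn.execute("PRAGMA user_version").fetchone()[0]
    if existing:
        if existing != set(TABLES) or version != SCHEMA_VERSION:
            conn.close()
            raise SchemaMismatchError(
                f"{db_path} holds an incompatible schema "
                f"(tables={sorted(existing)}, version={version})"
            )
        return conn
    conn.executescript(_SCHEMA_SQL)
    conn.execute(f"PRAGMA user_version = {SCHEMA_VERSION}")
    conn.commit()
    return conn


def list_tables(conn: sqlite3.Connection) -> list[str]:
    return sorted(
        r[0]
        for r in conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' "
            "AND name NOT LIKE 'sqlite_%'"
        )
    )


def insert_sites(conn: sqlite3.Connection, sites: Iterable[Site]) -> None:
    conn.executemany(
        "INSERT INTO sites VALUES (?,?,?,?,?)",
        [
            (s.site_id, s.name, s.decimal_latitude, s.decimal_longitude, s.grid_square_id)
            for s in sites
        ],
    )
    conn.commit()


def insert_movies(conn: sqlite3.Connection, movies: Iterable[Movie]) -> None:
    conn.executemany(
        "INSERT INTO movies VALUES (?,?,?,?,?)",
        [(m.movie_id, m.site_id, m.fps, m.duration_s, m.recorded_date) for m in movies],
    )
    conn.commit()


def insert_periods(
    conn: sqlite3.Connection, periods: Iterable[ObservationPeriod]
) -> None:
    conn.executemany(
        "INSERT INTO model_annotations VALUES (?,?,?,?,?,?,?,?)",
        [
            (
                p.movie_id,
                p.frame_no_start,
                p.frame_no_end,
                p.max_conf,
                p.best_bbox.x,
                p.best_bbox.y,
                p.best_bbox.w,
                p.best_bbox.h,
            )
            for p in periods
        ],
    )
    conn.commit()


def export_darwin_core(
    periods: Sequence[ObservationPeriod],
    movies: Sequence[Movie],
    sites: Sequence[Site],
    species_label: str,
) -> list[OccurrenceRecord]:
    """Convert machine observation periods into Darwin Core occurrences.

    One record per period, ``basisOfRecord = MachineObservation``; the site
    coordinates of the period's movie are carried over when present, and a
    movie without a recorded date yields an empty ``eventDate`` rather than
    a fabricated one.
    """
    movie_by_id = {m.movie_id: m for m in movies}
    site_by_id = {s.site_id: s for s in sites}
    missing = sorted({p.movie_id for p in periods} - set(movie_by_id))
    if missing:
        raise ReferentialError(
            f"observation periods reference unknown movies: {missing}"
        )
    records = []
    for i, p in enumerate(periods):
        movie = movie_by_id[p.movie_id]
        site = site_by_id.get(movie.site_id)
        if site is None:
            raise ReferentialError(
                f"movie {movie.movie_id} references unknown site {movie.site_id}"
            )
        records.append(
            OccurrenceRecord(
                occurrence_id=f"{p.movie_id}:{p.frame_no_start}-{p.frame_no_end}:{i}",
                scientific_name=species_label,
                individual_count=1,
                event_date=movie.recorded_date or "",
                decimal_latitude=site.decimal_latitude,
                decimal_longitude=site.decimal_longitude,
                basis_of_record="MachineObservation",
                associated_media=(
                    f"{p.movie_id} frames {p.frame_no_start}-{p.frame_no_end}"
                ),
            )
        )
    return records


def write_darwin_core_csv(
    records: Sequence[OccurrenceRecord], path: Union[str, Path]
) -> None:
    rows = [
        {
            "occurrenceID": r.occurrence_id,
            "scientificName": r.scientific_name,
            "individualCount": r.individual_count,
            "eventDate": r.event_date,
            "decimalLatitude": r.decimal_latitude,
            "decimalLongitude": r.decimal_longitude,
            "basisOfRecord": r.basis_of_record,
            "associatedMedia": r.associated_media,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=DWC_HEADER).to_csv(path, index=False)


def audit_referential_closure(conn: sqlite3.Connection) -> dict[str, int]:
    """Count aggregated annotations whose subject is missing (full-join audit).

    Returns per-table orphan counts; all zero after a healthy pipeline run.
    """
    out = {}
    for table in ("agg_annotations_clip", "agg_annotations_frame"):
        (n,) = conn.execute(
            f"SELECT COUNT(*) FROM {table} a LEFT JOIN subjects s "
            "ON a.subject_id = s.subject_id WHERE s.subject_id IS NULL"
        ).fetchone()
        out[table] = n
    return out
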