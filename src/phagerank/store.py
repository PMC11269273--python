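"""SQLite persistence for count tables, patterns and evaluations.

One single-file database holds a campaign: one table per selection round
(named ``round_<sanitized selection name>``), a ``rounds`` registry with
per-round metadata, a ``patterns`` table of saved anchor pairs, and an
optional ``evaluation`` table with the ranked, filtered results.  Round
tables are never touched by evaluation, so the original extracted data
survive any re-filtering.

The schema is plain SQL (documented in the README) so any SQLite client
can query it directly.
"""

from __future__ import annotations

import re
import sqlite3
from pathlib import Path

from .extraction import SearchPattern
from .quantify import CountRow, CountTable
from .scoring import ScoredRecord


class StoreError(RuntimeError):
    pass


class NotFoundError(StoreError):
    pass


class ConflictError(StoreError):
    pass


def sanitize_table_name(selection_name: str) -> str:
    """Map a selection name onto a valid SQL identifier.

    Non-alphanumeric characters become underscores; the ``round_`` prefix
    avoids collisions with the fixed tables and leading digits.
    """
    return "round_" + re.sub(r"[^A-Za-z0-9]", "_", selection_name)


_SCHEMA = """
CREATE TABLE IF NOT EXISTS rounds (
    selection_name TEXT PRIMARY KEY,
    table_name     TEXT NOT NULL UNIQUE,
    user           TEXT NOT NULL,
    total_counted  INTEGER NOT NULL,
    frame_fail_count INTEGER NOT NULL,
    processed_date TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS patterns (
    label        TEXT PRIMARY KEY,
    left_anchor  TEXT NOT NULL,
    right_anchor TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS evaluation (
    rank             INTEGER PRIMARY KEY,
    dna              TEXT NOT NULL,
    peptide          TEXT NOT NULL,
    empty_score      REAL NOT NULL,
    enrichment_score REAL NOT NULL,
    target3_ppm      REAL NOT NULL,
    target2_ppm      REAL,
    target1_ppm      REAL,
    library_ppm      REAL NOT NULL,
    empty3_ppm       REAL NOT NULL,
    direct_control_ppm   REAL,
    direct_control_ratio REAL
);
"""


class CampaignDb:
    """A campaign database at *db_path* (created on first use)."""

    def __init__(self, db_path: str | Path):
        self.db_path = Path(db_path)

    def _connect(self) -> sqlite3.Connection:
        conn = sqlite3.connect(self.db_path)
        conn.executescript(_SCHEMA)
        return conn

    # -- rounds ---------------------------------------------------------

    def store_round(self, table: CountTable, overwrite: bool = False) -> int:
        """Persist one round; returns the number of sequence rows written.

        Re-storing an existing ``selection_name`` requires *overwrite* and
        replaces the round atomically.
        """
        table_name = sanitize_table_name(table.selection_name)
        with self._connect() as conn:
            exists = conn.execute(
                "SELECT 1 FROM rounds WHERE selection_name = ?",
                (table.selection_name,),
            ).fetchone()
            if exists and not overwrite:
                raise ConflictError(
                    f"round {table.selection_name!r} already stored; "
                    "pass overwrite to replace it"
                )
            conn.execute(f'DROP TABLE IF EXISTS "{table_name}"')
            conn.execute(
                f'CREATE TABLE "{table_name}" ('
                "dna TEXT PRIMARY KEY, peptide TEXT NOT NULL, "
                "raw_count INTEGER NOT NULL, ppm REAL NOT NULL)"
            )
            conn.executemany(
                f'INSERT INTO "{table_name}" VALUES (?, ?, ?, ?)',
                [
                    (dna, row.peptide, row.raw_count, row.ppm)
                    for dna, row in table.rows.items()
                ],
            )
            conn.execute(
                "INSERT OR REPLACE INTO rounds VALUES (?, ?, ?, ?, ?, ?)",
                (
                    table.selection_name,
                    table_name,
                    table.user,
                    table.total_counted,
                    table.frame_fail_count,
                    table.processed_date,
                ),
            )
        return len(table.rows)

    def load_round(self, selection_name: str) -> CountTable:
        with self._connect() as conn:
            meta = conn.execute(
                "SELECT table_name, user, total_counted, frame_fail_count, "
                "processed_date FROM rounds WHERE selection_name = ?",
                (selection_name,),
            ).fetchone()
            if meta is None:
                raise NotFoundError(f"no stored round {selection_name!r}")
            table_name, user, total, frame_fails, date = meta
            rows = {
                dna: CountRow(peptide, raw_count, ppm)
                for dna, peptide, raw_count, ppm in conn.execute(
                    f'SELECT dna, peptide, raw_count, ppm FROM "{table_name}"'
                )
            }
        return CountTable(
            selection_name=selection_name,
            rows=rows,
            total_counted=total,
            frame_fail_count=frame_fails,
            user=user,
            processed_date=date,
        )

    def list_rounds(self) -> list[str]:
        with self._connect() as conn:
            return [
                name
                for (name,) in conn.execute(
                    "SELECT selection_name FROM rounds ORDER BY selection_name"
                )
            ]

    # -- evaluation -----------------------------------------------------

    def store_evaluation(self, records: list[ScoredRecord]) -> int:
        """Persist the ranked evaluation (replacing any previous one)."""
        with self._connect() as conn:
            conn.execute("DELETE FROM evaluation")
            conn.executemany(
                "INSERT INTO evaluation VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                [
                    (
                        rank,
                        r.dna,
                        r.peptide,
                        r.empty_score,
                        r.enrichment_score,
                        r.target3_ppm,
                        r.target2_ppm,
                        r.target1_ppm,
                        r.library_ppm,
                        r.empty3_ppm,
                        r.direct_control_ppm,
                        r.direct_control_ratio,
                    )
                    for rank, r in enumerate(records, start=1)
                ],
            )
        return len(records)

    def load_evaluation(self) -> list[ScoredRecord]:
        with self._connect() as conn:
            rows = conn.execute(
                "SELECT dna, peptide, empty_score, enrichment_score, "
                "target3_ppm, target2_ppm, target1_ppm, library_ppm, "
                "empty3_ppm, direct_control_ppm, direct_control_ratio "
                "FROM evaluation ORDER BY rank"
            ).fetchall()
        return [
            ScoredRecord(
                dna=dna,
                peptide=peptide,
                target3_ppm=t3,
                library_ppm=lib,
                empty3_ppm=e3,
                enrichment_score=enr,
                empty_score=emp,
                direct_control_ppm=dppm,
                direct_control_ratio=dratio,
                target1_ppm=t1,
                target2_ppm=t2,
            )
            for dna, peptide, emp, enr, t3, t2, t1, lib, e3, dppm, dratio in rows
        ]

    # -- patterns -------------------------------------------------------

    def store_pattern(
        self, pattern: SearchPattern, overwrite: bool = False
    ) -> None:
        if not pattern.label:
            raise StoreError("pattern must carry a label to be stored")
        with self._connect() as conn:
            exists = conn.execute(
                "SELECT 1 FROM patterns WHERE label = ?", (pattern.label,)
            ).fetchone()
            if exists and not overwrite:
                raise ConflictError(
                    f"pattern {pattern.label!r} already stored"
                )
            conn.execute(
                "INSERT OR REPLACE INTO patterns VALUES (?, ?, ?)",
                (pattern.label, pattern.left_anchor, pattern.right_anchor),
            )

    def load_pattern(self, label: str) -> SearchPattern:
        with self._connect() as conn:
            row = conn.execute(
                "SELECT left_anchor, right_anchor FROM patterns "
                "WHERE label = ?",
                (label,),
            ).fetchone()
        if row is None:
            raise NotFoundError(f"no stored pattern {label!r}")
        return SearchPattern(row[0], row[1], label)

    def list_patterns(self) -> list[str]:
        with self._connect() as conn:
            return [
                label
                for (label,) in conn.execute(
                    "SELECT label FROM patterns ORDER BY label"
                )
            ]

    # -- integrity ------------------------------------------------------

    def round_checksum(self, selection_name: str) -> tuple[int, int]:
        """Cheap integrity fingerprint (row count, summed raw counts)."""
        table_name = sanitize_table_name(selection_name)
        with self._connect() as conn:
            row = conn.execute(
                f'SELECT COUNT(*), COALESCE(SUM(raw_count), 0) FROM "{table_name}"'
            ).fetchone()
        return (row[0], row[1])
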