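"""Relational store for raw and derived tables.

A thin contract over an embedded single-file SQL database (sqlite3).  The
four raw tables mirror their source DSV files row for row — GEDM, ANNO,
HGNC, LABELS — and the derived term2probeset / probeset2gene tables built
during local data integration are persisted here too, so every mapping the
pipeline uses can be queried after the run.
"""

from __future__ import annotations

import sqlite3
from typing import Iterable

import numpy as np

from .errors import GosigError
from .io import AnnotationTable, ExpressionMatrix, GeneNameTable, LabelVector


class RelationalStore:
    """Queryable store of raw input tables and derived mapping tables."""

    def __init__(self, path: str = ":memory:") -> None:
        try:
            self._conn = sqlite3.connect(path)
        except sqlite3.Error as exc:  # pragma: no cover
            raise GosigError(f"cannot open relational store at {path}: {exc}") from exc
        self.path = path

    def close(self) -> None:
        self._conn.close()

    # -- loading ------------------------------------------------------------

    def load_raw_tables(
        self,
        gedm: ExpressionMatrix,
        anno: AnnotationTable,
        hgnc: GeneNameTable,
        labels: LabelVector,
    ) -> None:
        """Populate the four raw tables from validated in-memory inputs."""
        cur = self._conn.cursor()
        cur.execute("DROP TABLE IF EXISTS GEDM")
        sample_cols = ", ".join(f'"{s}" REAL' for s in gedm.sample_ids)
        cur.execute(f'CREATE TABLE GEDM (probeset_id TEXT PRIMARY KEY, {sample_cols})')
        placeholders = ", ".join("?" * (gedm.n_samples + 1))
        cur.executemany(
            f"INSERT INTO GEDM VALUES ({placeholders})",
            ((pid, *map(float, row)) for pid, row in zip(gedm.probeset_ids, gedm.values)),
        )

        cur.execute("DROP TABLE IF EXISTS ANNO")
        cur.execute(
            "CREATE TABLE ANNO (probeset_id TEXT PRIMARY KEY, gene_symbol TEXT, "
            "go_terms TEXT, entrez_id TEXT, genbank_id TEXT)"
        )
        cur.executemany(
            "INSERT INTO ANNO VALUES (?, ?, ?, ?, ?)",
            (
                (r.probeset_id, r.gene_symbol, ";".join(sorted(r.go_term_ids)),
                 r.entrez_id, r.genbank_id)
                for r in anno.records
            ),
        )

        cur.execute("DROP TABLE IF EXISTS HGNC")
        cur.execute(
            "CREATE TABLE HGNC (approved_symbol TEXT, previous_symbols TEXT, "
            "aliases TEXT, status TEXT)"
        )
        cur.executemany(
            "INSERT INTO HGNC VALUES (?, ?, ?, ?)",
            (
                (r.approved_symbol, "|".join(sorted(r.previous_symbols)),
                 "|".join(sorted(r.aliases)), r.status)
                for r in hgnc.records
            ),
        )

        cur.execute("DROP TABLE IF EXISTS LABELS")
        cur.execute("CREATE TABLE LABELS (sample_id TEXT PRIMARY KEY, label INTEGER)")
        cur.executemany(
            "INSERT INTO LABELS VALUES (?, ?)", sorted(labels.assignments.items())
        )
        self._conn.commit()
        self._gedm_samples = list(gedm.sample_ids)

    def save_term_to_probeset(self, pairs: Iterable[tuple[str, str]]) -> None:
        """Persist the derived term2probeset table (one row per pair)."""
        cur = self._conn.cursor()
        cur.execute("DROP TABLE IF EXISTS term2probeset")
        cur.execute("CREATE TABLE term2probeset (term_id TEXT, probeset_id TEXT)")
        cur.executemany("INSERT INTO term2probeset VALUES (?, ?)", sorted(pairs))
        cur.execute("CREATE INDEX t2p_term ON term2probeset (term_id)")
        cur.execute("CREATE INDEX t2p_probeset ON term2probeset (probeset_id)")
        self._conn.commit()

    def save_probeset_to_gene(
        self, rows: Iterable[tuple[str, str, str, str | None, str | None]]
    ) -> None:
        """Persist probeset2gene: (probeset, symbol, status, entrez, genbank)."""
        cur = self._conn.cursor()
        cur.execute("DROP TABLE IF EXISTS probeset2gene")
        cur.execute(
            "CREATE TABLE probeset2gene (probeset_id TEXT PRIMARY KEY, "
            "resolved_symbol TEXT, resolution_status TEXT, entrez_id TEXT, genbank_id TEXT)"
        )
        cur.executemany("INSERT INTO probeset2gene VALUES (?, ?, ?, ?, ?)", sorted(rows))
        self._conn.commit()

    # -- queries ------------------------------------------------------------

    def table_row_count(self, table: str) -> int:
        if not table.replace("2", "").isalnum():
            raise GosigError(f"bad table name {table!r}")
        return self._conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]

    def expression_row(self, probeset_id: str) -> np.ndarray | None:
        """Expression values of one probeset in sample order, or None."""
        row = self._conn.execute(
            "SELECT * FROM GEDM WHERE probeset_id = ?", (probeset_id,)
        ).fetchone()
        if row is None:
            return None
        return np.array(row[1:], dtype=float)

    def sample_label(self, sample_id: str) -> int | None:
        row = self._conn.execute(
            "SELECT label FROM LABELS WHERE sample_id = ?", (sample_id,)
        ).fetchone()
        return None if row is None else int(row[0])

    def probesets_for_symbol(self, gene_symbol: str) -> list[str]:
        rows = self._conn.execute(
            "SELECT probeset_id FROM ANNO WHERE gene_symbol = ? ORDER BY probeset_id",
            (gene_symbol,),
        ).fetchall()
        return [r[0] for r in rows]

    def probesets_for_term(self, term_id: str) -> list[str]:
        rows = self._conn.execute(
            "SELECT probeset_id FROM term2probeset WHERE term_id = ? ORDER BY probeset_id",
            (term_id,),
        ).fetchall()
        return [r[0] for r in rows]

    def terms_for_probeset(self, probeset_id: str) -> list[str]:
        rows = self._conn.execute(
            "SELECT term_id FROM term2probeset WHERE probeset_id = ? ORDER BY term_id",
            (probeset_id,),
        ).fetchall()
        return [r[0] for r in rows]
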