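"""Metric store, percentile ranks and the combined score.

Each validated ligand yields four scored metrics: the direct-map
correlation cc_direct (higher is better), the difference-map
correlation cc_diff (nearer zero is better: either sign indicates
mismodelling), the geometry |Z-worst| (lower is better) and the
bad-contact count n_bad (lower is better).  Against a reference corpus
each metric becomes a percentile rank in [0, 100] using the mid-rank
convention rank = 100 * (n_worse + 0.5 * n_equal) / N, and the four
ranks combine into

    S = (R_dir^2 + R_diff^2 + R_mogul^2 + R_bumps^2) / 400

which spreads out the top end of the scale compared with linear
addition.  S is finally expressed as an overall percentile against the
S values of the whole corpus.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MetricSet",
    "RankReport",
    "MetricStore",
    "percentile_of",
    "combined_score",
    "ORIENTATIONS",
]

Orientation = Literal["higher-better", "lower-better", "nearer-zero-better"]

#: Default orientation of each scored metric.
ORIENTATIONS: dict[str, Orientation] = {
    "cc_direct": "higher-better",
    "cc_diff": "nearer-zero-better",
    "z_worst": "lower-better",
    "n_bad": "lower-better",
}

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE IF NOT EXISTS ligands (
    accession TEXT NOT NULL,
    comp_id TEXT NOT NULL,
    chain TEXT NOT NULL DEFAULT '',
    seq_id INTEGER NOT NULL DEFAULT 0,
    cc_direct REAL NOT NULL,
    cc_diff REAL NOT NULL,
    z_worst REAL NOT NULL,
    z_worst_signed REAL,
    n_bad INTEGER NOT NULL,
    r_eff REAL,
    r_nom REAL,
    deposition_date TEXT,
    PRIMARY KEY (accession, comp_id, chain, seq_id)
);
"""


@dataclass
class MetricSet:
    """The scored metrics for one ligand instance."""

    accession: str
    comp_id: str
    cc_direct: float
    cc_diff: float
    z_worst: float  # absolute value
    n_bad: int
    chain: str = ""
    seq_id: int = 0
    z_worst_signed: float | None = None
    r_eff: float | None = None
    r_nom: float | None = None
    deposition_date: str | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.cc_direct <= 1.0:
            raise ValueError(f"cc_direct {self.cc_direct} outside [-1, 1]")
        if not -1.0 <= self.cc_diff <= 1.0:
            raise ValueError(f"cc_diff {self.cc_diff} outside [-1, 1]")
        if self.z_worst < 0:
            raise ValueError("z_worst stores the absolute value and must be >= 0")
        if self.n_bad < 0 or int(self.n_bad) != self.n_bad:
            raise ValueError("n_bad must be a non-negative integer")
        self.n_bad = int(self.n_bad)


@dataclass
class RankReport:
    """Per-metric percentile ranks and the combined score."""

    R_dir: float
    R_diff: float
    R_mogul: float
    R_bumps: float
    S: float
    overall_percentile: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RankReport":
        return cls(**json.loads(text))


def _orient(values: np.ndarray, orientation: Orientation) -> np.ndarray:
    """Transform so that larger oriented value = better."""
    if orientation == "higher-better":
        return values
    if orientation == "lower-better":
        return -values
    if orientation == "nearer-zero-better":
        return -np.abs(values)
    raise ValueError(f"unknown orientation {orientation!r}")


def percentile_of(values: Sequence[float], value: float, orientation: Orientation) -> float:
    """Mid-rank percentile of ``value`` within ``values``:
    100 * (n_worse + 0.5 * n_equal) / N after orienting."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty reference distribution")
    ov = _orient(arr, orientation)
    x = float(_orient(np.array([value], dtype=float), orientation)[0])
    n_worse = int(np.sum(ov < x))
    n_equal = int(np.sum(ov == x))
    return 100.0 * (n_worse + 0.5 * n_equal) / arr.size


def combined_score(R_dir: float, R_diff: float, R_mogul: float, R_bumps: float) -> float:
    """Combined score S = (sum of squared ranks) / 400, in [0, 100];
    strictly increasing in each rank and super-linear at the top end."""
    ranks = (R_dir, R_diff, R_mogul, R_bumps)
    for r in ranks:
        if not 0.0 <= r <= 100.0:
            raise ValueError(f"rank {r} outside [0, 100]")
    return sum(r * r for r in ranks) / 400.0


class MetricStore:
    """SQLite-backed store of per-ligand metric records.

    ``path`` may be ':memory:' for an ephemeral store.  Mirrors the
    build-database / percentile-lookup pair of command-line tools.
    """

    COLUMNS = [
        "accession", "comp_id", "chain", "seq_id", "cc_direct", "cc_diff",
        "z_worst", "z_worst_signed", "n_bad", "r_eff", "r_nom", "deposition_date",
    ]

    def __init__(self, path: str | Path = ":memory:") -> None:
        self.path = str(path)
        self._con = sqlite3.connect(self.path)
        self._con.executescript(_SCHEMA)
        self._con.execute(
            "INSERT OR IGNORE INTO meta VALUES ('schema_version', ?)", (str(SCHEMA_VERSION),)
        )
        self._con.commit()

    def close(self) -> None:
        self._con.close()

    def __enter__(self) -> "MetricStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def __len__(self) -> int:
        return self._con.execute("SELECT COUNT(*) FROM ligands").fetchone()[0]

    # --- writing ----------------------------------------------------
    def store_metrics(self, m: MetricSet) -> None:
        key = (m.accession, m.comp_id, m.chain, m.seq_id)
        exists = self._con.execute(
            "SELECT 1 FROM ligands WHERE accession=? AND comp_id=? AND chain=? AND seq_id=?", key
        ).fetchone()
        if exists:
            import warnings

            warnings.warn(f"replacing existing record {key}")
        self._con.execute(
            "INSERT OR REPLACE INTO ligands VALUES (?,?,?,?,?,?,?,?,?,?,?,?)",
            (
                m.accession, m.comp_id, m.chain, m.seq_id, m.cc_direct, m.cc_diff,
                m.z_worst, m.z_worst_signed, m.n_bad, m.r_eff, m.r_nom, m.deposition_date,
            ),
        )
        self._con.commit()

    def store_many(self, metrics: Iterable[MetricSet]) -> None:
        self._con.executemany(
            "INSERT OR REPLACE INTO ligands VALUES (?,?,?,?,?,?,?,?,?,?,?,?)",
            [
                (
                    m.accession, m.comp_id, m.chain, m.seq_id, m.cc_direct, m.cc_diff,
                    m.z_worst, m.z_worst_signed, m.n_bad, m.r_eff, m.r_nom, m.deposition_date,
                )
                for m in metrics
            ],
        )
        self._con.commit()

    # --- reading ----------------------------------------------------
    def get(self, accession: str, comp_id: str | None = None) -> list[MetricSet]:
        q = "SELECT * FROM ligands WHERE accession=?"
        args: list = [accession]
        if comp_id is not None:
            q += " AND comp_id=?"
            args.append(comp_id)
        out = []
        for row in self._con.execute(q, args):
            d = dict(zip(self.COLUMNS, row))
            out.append(MetricSet(**d))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.read_sql_query("SELECT * FROM ligands", self._con)

    def metric_values(self, metric: str) -> np.ndarray:
        if metric not in ("cc_direct", "cc_diff", "z_worst", "n_bad"):
            raise ValueError(f"unknown metric {metric!r}")
        rows = self._con.execute(f"SELECT {metric} FROM ligands").fetchall()
        if not rows:
            raise ValueError("store is empty")
        return np.array([r[0] for r in rows], dtype=float)

    def median(self, metric: str) -> float:
        return float(np.median(self.metric_values(metric)))

    # --- csv round trip ---------------------------------------------
    def export_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, csv_path: str | Path, store_path: str | Path = ":memory:") -> "MetricStore":
        df = pd.read_csv(csv_path)
        store = cls(store_path)
        records = []
        for _, row in df.iterrows():
            d = {k: row[k] for k in cls.COLUMNS if k in df.columns}
            for opt in ("z_worst_signed", "r_eff", "r_nom"):
                if opt in d and pd.isna(d[opt]):
                    d[opt] = None
            if "deposition_date" in d and pd.isna(d["deposition_date"]):
                d["deposition_date"] = None
            records.append(MetricSet(**d))
        store.store_many(records)
        return store

    # --- ranking ----------------------------------------------------
    def percentile_rank(
        self, metric: str, value: float, orientation: Orientation | None = None
    ) -> float:
        orientation = orientation or ORIENTATIONS[metric]
        return percentile_of(self.metric_values(metric), value, orientation)

    def _all_scores(self, orientations: dict[str, Orientation]) -> np.ndarray:
        """Combined score S for every stored record, each ranked against
        the whole store (mid-rank, self included)."""
        from scipy.stats import rankdata

        n = len(self)
        s = np.zeros(n)
        for metric in ("cc_direct", "cc_diff", "z_worst", "n_bad"):
            vals = _orient(self.metric_values(metric), orientations[metric])
            # mid-rank of a member against the store: n_worse + 0.5*n_eq = rank - 0.5
            ranks = 100.0 * (rankdata(vals, method="average") - 0.5) / n
            s += ranks**2
        return s / 400.0

    def rank_report(
        self, m: MetricSet, orientations: dict[str, Orientation] | None = None
    ) -> RankReport:
        """Percentile ranks for one ligand's metrics, the combined score
        S and its overall percentile against the stored corpus."""
        ori = dict(ORIENTATIONS)
        if orientations:
            ori.update(orientations)
        r_dir = self.percentile_rank("cc_direct", m.cc_direct, ori["cc_direct"])
        r_diff = self.percentile_rank("cc_diff", m.cc_diff, ori["cc_diff"])
        r_mogul = self.percentile_rank("z_worst", m.z_worst, ori["z_worst"])
        r_bumps = self.percentile_rank("n_bad", m.n_bad, ori["n_bad"])
        s = combined_score(r_dir, r_diff, r_mogul, r_bumps)
        all_s = self._all_scores(ori)
        overall = 100.0 * (np.sum(all_s < s) + 0.5 * np.sum(all_s == s)) / all_s.size
        return RankReport(r_dir, r_diff, r_mogul, r_bumps, s, float(overall))

    def resolution_histogram(self, bin_edges: Sequence[float]) -> dict[str, int]:
        """Partition records by nominal resolution; bin counts plus an
        'unknown' bucket sum to the store size."""
        df = self.to_dataframe()
        out: dict[str, int] = {}
        known = df["r_nom"].dropna()
        counts, _ = np.histogram(known, bins=np.asarray(bin_edges, dtype=float))
        for i, c in enumerate(counts):
            out[f"{bin_edges[i]:.2f}-{bin_edges[i + 1]:.2f}"] = int(c)
        below = int(np.sum(known < bin_edges[0]))
        above = int(np.sum(known >= bin_edges[-1]))
        out["outside"] = below + above
        out["unknown"] = int(df["r_nom"].isna().sum())
        return out
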