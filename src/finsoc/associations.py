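"""From raw sighting records to half-weight association indices.

A *sighting table* is a tidy :class:`pandas.DataFrame` with one row per
(survey day, group, individual):

======== ============== ==========================================
column   dtype          meaning
======== ============== ==========================================
date     str/date       survey day (the sampling period)
group_id str            group label, unique within a day
x_m      float          group easting, projected meters
y_m      float          group northing, projected meters
individual_id str       photo-identified individual
est_group_size int      field estimate of total group size
======== ============== ==========================================

Two individuals seen in the same group on a day are associated for that
day.  The half-weight index (HWI) for a dyad is

    HWI = x / (x + yAB + (yA + yB) / 2)

where over sampling days: ``x`` = days together in a group, ``yA``/``yB`` =
days only one of the two was seen, and ``yAB`` = days both were seen but in
different groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dyadmatrix import DyadMatrix

__all__ = [
    "SIGHTING_COLUMNS",
    "DyadCounts",
    "validate_sightings",
    "filter_sightings",
    "dyad_counts",
    "hwi",
    "gregariousness_predictor",
    "dyad_sightings_predictor",
    "sighting_days",
]

logger = logging.getLogger(__name__)

SIGHTING_COLUMNS = ("date", "group_id", "x_m", "y_m", "individual_id", "est_group_size")


def validate_sightings(records: pd.DataFrame) -> pd.DataFrame:
    """Check schema and basic invariants; returns a normalized copy.

    Raises ``ValueError`` on a malformed table (missing columns, duplicate
    (day, group, individual) rows, group smaller than its identified count).
    """
    missing = [c for c in SIGHTING_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"sighting table missing columns: {missing}")
    rec = records.copy()
    rec["date"] = rec["date"].astype(str)
    rec["group_id"] = rec["group_id"].astype(str)
    rec["individual_id"] = rec["individual_id"].astype(str)
    dup = rec.duplicated(subset=["date", "group_id", "individual_id"])
    if dup.any():
        bad = rec.loc[dup, ["date", "group_id", "individual_id"]].iloc[0]
        raise ValueError(
            f"duplicate (day, group, individual) row: {tuple(bad)}"
        )
    sizes = rec.groupby(["date", "group_id"])["individual_id"].transform("size")
    if (rec["est_group_size"] < sizes).any():
        raise ValueError("est_group_size smaller than number of identified members")
    return rec


def filter_sightings(
    records: pd.DataFrame,
    min_identified_fraction: float = 0.75,
    min_sightings: int = 11,
    sexed_females: set | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Apply the study's inclusion filters to a sighting table.

    Filters, in order:

    1. drop groups with fewer than ``min_identified_fraction`` of the
       estimated group size photo-identified;
    2. keep only each individual's first group per day (this also removes
       identical groups resighted within a day, whose members have all
       been seen earlier that day);
    3. restrict to ``sexed_females`` if given;
    4. keep individuals seen on *strictly more than* ``min_sightings`` days.

    Returns the filtered table (rows of retained individuals only) and the
    retained id list in first-appearance order.
    """
    rec = validate_sightings(records)
    rec = rec.reset_index(drop=True)

    # 1. group photo-identification quality, judged on all identified members
    grp = rec.groupby(["date", "group_id"])
    identified = grp["individual_id"].transform("size")
    frac = identified / rec["est_group_size"]
    rec = rec[frac >= min_identified_fraction]

    # 2. first sighting of each individual per day (row order = time order)
    rec = rec.drop_duplicates(subset=["date", "individual_id"], keep="first")

    # 3. sex restriction
    if sexed_females is not None:
        females = {str(i) for i in sexed_females}
        rec = rec[rec["individual_id"].isin(females)]

    # 4. minimum sighting days, strictly greater than the threshold
    days_seen = rec.groupby("individual_id")["date"].transform("nunique")
    rec = rec[days_seen > min_sightings]

    if rec.empty:
        raise ValueError("no individuals retained after filtering")
    ids = list(dict.fromkeys(rec["individual_id"]))
    logger.info(
        "filter_sightings: retained %d individuals in %d groups over %d days",
        len(ids), rec.groupby(["date", "group_id"]).ngroups, rec["date"].nunique(),
    )
    return rec.reset_index(drop=True), ids


@dataclass
class DyadCounts:
    """Per-dyad daily tallies underlying the HWI and the GAI regression.

    ``x``, ``yab`` are symmetric arrays; ``alone[i, j]`` counts days ``i``
    was seen on a day ``j`` was not (so ``yA = alone[i, j]``,
    ``yB = alone[j, i]``).
    """

    ids: list[str]
    x: np.ndarray
    yab: np.ndarray
    alone: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def denominator(self) -> np.ndarray:
        """HWI denominator d = x + yAB + (yA + yB) / 2."""
        return self.x + self.yab + (self.alone + self.alone.T) / 2.0

    def dyad(self, i, j) -> dict:
        ids = [str(k) for k in self.ids]
        a, b = ids.index(str(i)), ids.index(str(j))
        return {
            "x": int(self.x[a, b]),
            "yA": int(self.alone[a, b]),
            "yB": int(self.alone[b, a]),
            "yAB": int(self.yab[a, b]),
            "d": float(self.denominator[a, b]),
        }


def dyad_counts(records: pd.DataFrame, ids: list | None = None) -> DyadCounts:
    """Tally x / yA / yB / yAB per dyad with the day as sampling period.

    A day counts toward ``x`` if the two individuals share *any* group that
    day; toward ``yAB`` if both were seen that day but never together.
    """
    rec = validate_sightings(records)
    if ids is None:
        ids = list(dict.fromkeys(rec["individual_id"]))
    ids = [str(i) for i in ids]
    known = set(rec["individual_id"])
    for i in ids:
        if i not in known:
            raise ValueError(f"individual absent from records: {i!r}")
    rec = rec[rec["individual_id"].isin(set(ids))]
    n = len(ids)
    pos = {ind: k for k, ind in enumerate(ids)}

    x = np.zeros((n, n), dtype=np.int64)
    yab = np.zeros((n, n), dtype=np.int64)
    alone = np.zeros((n, n), dtype=np.int64)
    for _, day in rec.groupby("date"):
        seen = np.zeros(n, dtype=bool)
        together = np.zeros((n, n), dtype=bool)
        for _, g in day.groupby("group_id"):
            members = np.array([pos[i] for i in g["individual_id"]], dtype=int)
            seen[members] = True
            together[np.ix_(members, members)] = True
        np.fill_diagonal(together, False)
        both = np.outer(seen, seen)
        np.fill_diagonal(both, False)
        x += together
        yab += both & ~together
        alone += np.outer(seen, ~seen)
    return DyadCounts(ids=ids, x=x, yab=yab, alone=alone)


def hwi(counts: DyadCounts) -> DyadMatrix:
    """Half-weight association index matrix; 0 where the denominator is 0."""
    d = counts.denominator
    degenerate = d == 0
    np.fill_diagonal(degenerate, False)
    if degenerate.any():
        logger.warning("hwi: %d dyads with zero denominator set to 0", int(degenerate.sum()) // 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(d > 0, counts.x / np.where(d > 0, d, 1.0), 0.0)
    return DyadMatrix(counts.ids, out)


def gregariousness_predictor(hwi_matrix: DyadMatrix) -> DyadMatrix:
    """Dyadic gregariousness predictor log(g_i * g_j).

    ``g_i`` is individual ``i``'s summed association strength; for each
    dyad, that dyad's own HWI is excluded from both sums so the predictor
    carries no direct information about the response dyad.  Dyads where
    either exclusive sum is 0 are flagged and assigned (matrix minimum - 1).
    """
    if hwi_matrix.n < 2:
        raise ValueError("gregariousness needs at least two individuals")
    w = hwi_matrix.values
    g = w.sum(axis=1)  # diagonal already zero
    gi = g[:, None] - w  # g_i excluding dyad (i, j)
    gj = g[None, :] - w
    prod = gi * gj
    off = ~np.eye(len(g), dtype=bool)
    valid = (prod > 0) & off
    out = np.zeros_like(prod)
    out[valid] = np.log(prod[valid])
    flagged = off & ~valid
    if flagged.any():
        fill = out[valid].min() - 1.0 if valid.any() else -1.0
        out[flagged] = fill
        logger.warning(
            "gregariousness: %d dyads with zero exclusive strength flagged",
            int(flagged.sum()) // 2,
        )
    return DyadMatrix(hwi_matrix.ids, out)


def sighting_days(records: pd.DataFrame, ids: list) -> pd.Series:
    """Days each individual was seen, indexed by id."""
    rec = validate_sightings(records)
    counts = rec.groupby("individual_id")["date"].nunique()
    return counts.reindex([str(i) for i in ids], fill_value=0)


def dyad_sightings_predictor(records: pd.DataFrame, ids: list) -> DyadMatrix:
    """Cumulative dyad exposure: sighting-day count of i plus that of j."""
    n_days = sighting_days(records, ids).to_numpy(dtype=float)
    return DyadMatrix([str(i) for i in ids], n_days[:, None] + n_days[None, :])
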