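"""Ring-width series to growth response: dbh reconstruction, BAI, EPS.

Increment cores are measured as annual ring widths (mm).  Two cores per tree
are averaged, historical diameter at breast height (dbh, cm) is reconstructed
backwards from the field-measured dbh, and yearly growth is expressed as the
basal area increment

    BAI_y = pi * (dbh_y / 2)^2 - pi * (dbh_{y-1} / 2)^2   [cm^2]

A per-tree standardized copy of the BAI series (``BAIS``) serves as the
one-year-lag autocorrelation covariate in the growth model, and the expressed
population signal (EPS) summarizes chronology reliability.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RingSeries",
    "read_rwl",
    "write_rwl",
    "average_cores",
    "reconstruct_dbh",
    "compute_bai",
    "standardize_bai",
    "compute_eps",
    "assemble_growth_table",
]

#: trailing single letter (North/South or A/B core) after the tree id
DEFAULT_CORE_PATTERN = r"^(?P<tree>.+?)(?P<core>[NSABnsab])$"


@dataclass
class RingSeries:
    """Annual ring widths for one increment core.

    Attributes
    ----------
    core_id : str
        Identifier of the physical core (e.g. ``"T01N"``).
    tree_id : str
        Identifier of the tree the core was extracted from.
    years : np.ndarray
        Strictly consecutive calendar years, one per ring.
    widths : np.ndarray
        Ring widths in mm, non-negative, same length as ``years``.
    """

    core_id: str
    tree_id: str
    years: np.ndarray = field(repr=False)
    widths: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.years.size != self.widths.size:
            raise ValueError("years and widths must have equal length")
        if self.years.size < 2:
            raise ValueError(f"series {self.core_id}: need at least 2 years")
        if np.any(np.diff(self.years) != 1):
            raise ValueError(f"series {self.core_id}: years must be consecutive")
        if np.any(self.widths < 0):
            raise ValueError(f"series {self.core_id}: negative ring width")

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        return int(self.years[-1])


def tree_id_from_core(core_id: str, pattern: str = DEFAULT_CORE_PATTERN) -> str:
    """Derive the tree id from a core id (trailing core letter stripped)."""
    m = re.match(pattern, core_id)
    return m.group("tree") if m else core_id


# ---------------------------------------------------------------------------
# Tucson (decadal) format
#
# Each line: series id (cols 1-8), decade year, then up to 10 integer widths.
# Stop marker 999 means the file is in 0.01 mm units, -9999 means 0.001 mm.
# We always write 0.001 mm with the -9999 stop marker.
# ---------------------------------------------------------------------------


def read_rwl(path, core_pattern: str = DEFAULT_CORE_PATTERN) -> list[RingSeries]:
    """Read a Tucson-format ring width file into a list of :class:`RingSeries`.

    Both stop-marker dialects are accepted: ``999`` (units 0.01 mm) and
    ``-9999`` (units 0.001 mm).  An empty file yields an empty list with a
    logged warning.
    """
    raw: dict[str, dict[int, float]] = {}
    units: dict[str, float] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        logger.warning("read_rwl: %s is empty", path)
        return []
    for ln in lines:
        sid = ln[:8].strip()
        rest = ln[8:].split()
        if not sid or len(rest) < 2:
            raise ValueError(f"malformed Tucson line: {ln!r}")
        try:
            decade = int(rest[0])
            vals = [int(v) for v in rest[1:]]
        except ValueError as exc:
            raise ValueError(f"non-numeric field in line: {ln!r}") from exc
        series = raw.setdefault(sid, {})
        for i, v in enumerate(vals):
            if v == 999:
                units[sid] = 0.01
                break
            if v == -9999:
                units[sid] = 0.001
                break
            year = decade + i
            if year in series:
                raise ValueError(f"series {sid}: duplicate year {year}")
            series[year] = v
    out = []
    for sid, vals_by_year in raw.items():
        years = np.array(sorted(vals_by_year), dtype=int)
        scale = units.get(sid, 0.001)
        widths = np.array([vals_by_year[y] for y in years], dtype=float) * scale
        out.append(
            RingSeries(
                core_id=sid,
                tree_id=tree_id_from_core(sid, core_pattern),
                years=years,
                widths=widths,
            )
        )
    return out


def write_rwl(series: list[RingSeries], path) -> None:
    """Write ring series in Tucson decadal format (0.001 mm, -9999 stop)."""
    with open(path, "w") as fh:
        for s in series:
            vals = {int(y): int(round(w * 1000)) for y, w in zip(s.years, s.widths)}
            first, last = s.first_year, s.last_year
            year = first
            while year <= last:
                decade_end = (year // 10) * 10 + 9
                stop = min(decade_end, last)
                row = [vals[y] for y in range(year, stop + 1)]
                if stop == last:
                    row.append(-9999)
                fh.write(f"{s.core_id:<8}{year:>4}" + "".join(f"{v:>6}" for v in row) + "\n")
                year = stop + 1


# ---------------------------------------------------------------------------
# Core averaging, dbh reconstruction, BAI
# ---------------------------------------------------------------------------


def average_cores(series: list[RingSeries]) -> RingSeries:
    """Average 1-2 cores of one tree into a per-tree width series.

    Years are the union of the cores' years; a year covered by only one core
    uses that core alone.
    """
    if not 1 <= len(series) <= 2:
        raise ValueError("average_cores expects 1 or 2 cores")
    tree_ids = {s.tree_id for s in series}
    if len(tree_ids) != 1:
        raise ValueError(f"cores from different trees: {sorted(tree_ids)}")
    (tree_id,) = tree_ids
    if len(series) == 1:
        s = series[0]
        return RingSeries(core_id=tree_id, tree_id=tree_id, years=s.years, widths=s.widths)
    years = np.arange(
        min(s.first_year for s in series), max(s.last_year for s in series) + 1
    )
    total = np.zeros(years.size)
    count = np.zeros(years.size)
    for s in series:
        idx = s.years - years[0]
        total[idx] += s.widths
        count[idx] += 1
    if np.any(count == 0):
        raise ValueError(f"tree {tree_id}: interior year covered by no core")
    return RingSeries(core_id=tree_id, tree_id=tree_id, years=years, widths=total / count)


def reconstruct_dbh(tree_widths: RingSeries, dbh_final: float, final_year: int) -> pd.Series:
    """Reconstruct the historical dbh trajectory (cm), anchored at the final year.

    Each ring adds one width on each of the two radii, so
    ``dbh_{y-1} = dbh_y - 2 * w_y / 10`` (widths are mm, dbh cm).  The returned
    series is indexed by year and includes the pre-series anchor year
    ``first_year - 1`` (the diameter before the first recorded ring formed).
    """
    if final_year != tree_widths.last_year:
        raise ValueError(
            f"final_year {final_year} does not match last ring year {tree_widths.last_year}"
        )
    w = tree_widths.widths
    years = np.arange(tree_widths.first_year - 1, final_year + 1)
    # cumulative diameter growth from each year forward to the end
    decrement = 2.0 * np.concatenate([[np.sum(w)], np.sum(w) - np.cumsum(w)]) / 10.0
    dbh = dbh_final - decrement
    bad = np.nonzero(dbh <= 0)[0]
    if bad.size:
        raise ValueError(
            f"tree {tree_widths.tree_id}: reconstructed dbh <= 0 in year {years[bad[0]]}"
        )
    return pd.Series(dbh, index=years, name="dbh")


def compute_bai(dbh: pd.Series) -> pd.Series:
    """Basal area increment (cm^2) from a yearly dbh series (cm).

    Output is indexed by the year of each increment (input length minus one);
    the increments telescope to the total basal area change.
    """
    d = np.asarray(dbh, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 dbh values")
    if np.any(d <= 0):
        raise ValueError("dbh must be strictly positive")
    area = np.pi * (d / 2.0) ** 2
    return pd.Series(np.diff(area), index=dbh.index[1:], name="bai")


def standardize_bai(bai: pd.Series) -> pd.Series:
    """Per-tree z-score of a BAI series (sample SD, ddof=1).

    A zero-variance series maps to all zeros with a warning.
    """
    x = np.asarray(bai, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 years of BAI to standardize")
    sd = np.std(x, ddof=1)
    if sd == 0:
        logger.warning("standardize_bai: zero-variance series, returning zeros")
        return pd.Series(np.zeros_like(x), index=bai.index, name="bais")
    return pd.Series((x - np.mean(x)) / sd, index=bai.index, name="bais")


def compute_eps(width_matrix: pd.DataFrame) -> float:
    """Expressed population signal of a trees x years width matrix.

    EPS = n*rbar / (n*rbar + (1 - rbar)) where rbar is the mean pairwise
    Pearson correlation over common years and n the number of series.  Raw
    widths are correlated (no detrending).
    """
    m = width_matrix.to_numpy(dtype=float)
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least 2 series")
    rs = []
    for i, j in itertools.combinations(range(n), 2):
        ok = ~(np.isnan(m[i]) | np.isnan(m[j]))
        if ok.sum() < 2:
            continue
        rs.append(np.corrcoef(m[i, ok], m[j, ok])[0, 1])
    if not rs:
        raise ValueError("no pair of series with >= 2 overlapping years")
    rbar = float(np.mean(rs))
    return n * rbar / (n * rbar + (1.0 - rbar))


# ---------------------------------------------------------------------------
# Growth table assembly
# ---------------------------------------------------------------------------


def assemble_growth_table(
    series: list[RingSeries],
    meta: pd.DataFrame,
    climate: pd.DataFrame,
    start_year: int = 1981,
    end_year: int = 2021,
) -> pd.DataFrame:
    """Build the tree x year growth table from cores, metadata and climate.

    Parameters
    ----------
    series : list of RingSeries
        All cores; grouped by ``tree_id``.
    meta : DataFrame indexed by tree_id
        Columns ``dbh_final`` (cm, measured in the final year), ``age_final``
        (tree age in the final ring year), ``species``, ``location``,
        ``nmin`` (net N mineralization, assay units), plus any neighborhood
        basal-area columns (passed through).
    climate : DataFrame
        Columns ``location``, ``year``, ``min_may_t`` (deg C).
    start_year, end_year : int
        Analysis window applied after dbh reconstruction.

    Returns
    -------
    DataFrame with one row per (tree_id, year) holding ``dbh`` (end-of-year),
    ``dbh_prev`` (start-of-year), ``bai``, ``bais`` (per-tree standardized
    BAI), ``age`` and the per-tree covariates.
    """
    by_tree: dict[str, list[RingSeries]] = {}
    for s in series:
        by_tree.setdefault(s.tree_id, []).append(s)
    missing = sorted(set(by_tree) - set(meta.index.astype(str)))
    if missing:
        raise ValueError(f"trees missing from metadata: {missing}")
    clim = climate.set_index(["location", "year"])["min_may_t"]
    rows = []
    for tree_id, cores in sorted(by_tree.items()):
        tree_w = average_cores(cores)
        info = meta.loc[tree_id]
        dbh = reconstruct_dbh(tree_w, float(info["dbh_final"]), tree_w.last_year)
        bai = compute_bai(dbh)
        keep = (bai.index >= start_year) & (bai.index <= end_year)
        bai = bai[keep]
        if bai.size < 3:
            raise ValueError(f"tree {tree_id}: fewer than 3 years inside window")
        bais = standardize_bai(bai)
        final_ring_year = tree_w.last_year
        extra = {
            c: info[c]
            for c in meta.columns
            if c not in ("dbh_final", "age_final", "species", "location", "nmin")
        }
        for y in bai.index:
            rows.append(
                {
                    "tree_id": tree_id,
                    "year": int(y),
                    "location": info["location"],
                    "species": info["species"],
                    "dbh": dbh.loc[y],
                    "dbh_prev": dbh.loc[y - 1],
                    "bai": bai.loc[y],
                    "bais": bais.loc[y],
                    "age": float(info["age_final"]) - (final_ring_year - int(y)),
                    "nmin": float(info["nmin"]),
                    "min_may_t": float(clim.loc[(info["location"], int(y))]),
                    **extra,
                }
            )
    return pd.DataFrame(rows).sort_values(["tree_id", "year"]).reset_index(drop=True)
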