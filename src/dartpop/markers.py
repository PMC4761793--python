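"""Dominant binary marker matrices: data model, TSV/CSV I/O and marker filtering.

The central container is :class:`MarkerMatrix`: an individuals x markers table of
band presence (1), absence (0) or missing calls, with per-individual group labels
at up to two nested hierarchy levels (e.g. breeding program or country; region)
and optional per-marker metadata (quality score, chromosome, map position).

Individuals are assumed to be fully inbred lines, so band-presence frequency is
interpreted directly as allele frequency throughout the package.

The filter chain mirrors common DArT pre-processing and is applied in the fixed
order quality -> missingness -> minor allele frequency -> correlation thinning;
each step returns a :class:`FilterReport` whose counts always reconcile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "FilterReport",
    "read_marker_matrix",
    "write_marker_matrix",
    "filter_quality",
    "filter_missing",
    "filter_maf",
    "thin_correlated",
    "apply_filter_chain",
]


@dataclass
class FilterReport:
    """Book-keeping for one marker-filtering step.

    ``n_markers_in - total_removed == n_markers_out`` always holds; removed
    marker names are recorded per rule so a full chain can be audited.
    """

    rule: str
    n_markers_in: int
    n_markers_out: int
    removed_names: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed_names.values())

    def __post_init__(self) -> None:
        if self.n_markers_in - self.n_removed != self.n_markers_out:
            raise ValueError(
                f"filter report does not reconcile: {self.n_markers_in} in, "
                f"{self.n_removed} removed, {self.n_markers_out} out"
            )


class MarkerMatrix:
    """Individuals x markers matrix of dominant binary calls.

    Parameters
    ----------
    calls
        DataFrame indexed by individual identifier with marker names as
        columns.  Values are 0.0 (absent), 1.0 (present) or NaN (missing).
    group_labels
        Optional level-1 label (program / country) per individual.
    region_labels
        Optional level-2 label per individual.  When present the design must
        be nested: each level-1 group maps to exactly one region.
    marker_meta
        Optional per-marker metadata indexed by marker name; recognised
        columns are ``quality_q``, ``chromosome`` and ``position_cM``.
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        group_labels: pd.Series | None = None,
        region_labels: pd.Series | None = None,
        marker_meta: pd.DataFrame | None = None,
    ):
        calls = calls.astype(float)
        if calls.index.has_duplicates:
            dups = sorted(calls.index[calls.index.duplicated()].unique())
            raise ValueError(f"duplicate individual identifiers: {dups}")
        if calls.columns.has_duplicates:
            dups = sorted(calls.columns[calls.columns.duplicated()].unique())
            raise ValueError(f"duplicate marker names: {dups}")
        vals = calls.to_numpy()
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"call for individual {calls.index[i]!r}, marker "
                f"{calls.columns[j]!r} is {vals[i, j]!r}; expected 0, 1 or missing"
            )
        self.calls = calls
        self.group_labels = self._align_series(group_labels, "group_labels")
        self.region_labels = self._align_series(region_labels, "region_labels")
        if marker_meta is not None:
            missing = set(calls.columns) - set(marker_meta.index)
            if missing:
                raise ValueError(f"marker_meta lacks entries for markers: {sorted(missing)[:5]}")
            marker_meta = marker_meta.loc[calls.columns]
        self.marker_meta = marker_meta
        self._check_nesting()

    def _align_series(self, s: pd.Series | None, what: str) -> pd.Series | None:
        if s is None:
            return None
        missing = set(self.calls.index) - set(s.index)
        if missing:
            raise ValueError(f"{what} lacks entries for individuals: {sorted(missing)[:5]}")
        return s.loc[self.calls.index]

    def _check_nesting(self) -> None:
        if self.group_labels is None or self.region_labels is None:
            return
        mapping = pd.DataFrame({"g": self.group_labels, "r": self.region_labels})
        per_group = mapping.groupby("g")["r"].nunique()
        broken = per_group[per_group > 1]
        if len(broken):
            raise ValueError(
                f"non-nested design: groups {list(broken.index)} span multiple regions"
            )

    # -- basic accessors -------------------------------------------------

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.index)

    @property
    def markers(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def values(self) -> np.ndarray:
        """Calls as a float array with NaN for missing."""
        return self.calls.to_numpy()

    def presence_frequencies(self, subset: list[str] | None = None) -> pd.Series:
        """Per-marker band-presence frequency over non-missing calls.

        Markers with no scored call in the subset yield NaN.
        """
        df = self.calls if subset is None else self.calls.loc[list(subset)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return df.mean(axis=0, skipna=True)

    def select_markers(self, keep: list[str]) -> "MarkerMatrix":
        meta = None if self.marker_meta is None else self.marker_meta.loc[keep]
        return MarkerMatrix(self.calls[keep], self.group_labels, self.region_labels, meta)

    def select_individuals(self, keep: list[str]) -> "MarkerMatrix":
        keep = list(keep)
        return MarkerMatrix(
            self.calls.loc[keep],
            None if self.group_labels is None else self.group_labels.loc[keep],
            None if self.region_labels is None else self.region_labels.loc[keep],
            self.marker_meta,
        )

    def groups(self, level: str = "group") -> dict[str, list[str]]:
        """Map of label -> member individuals at ``level`` ('group' or 'region')."""
        labels = self.group_labels if level == "group" else self.region_labels
        if labels is None:
            raise ValueError(f"no labels available at level {level!r}")
        out: dict[str, list[str]] = {}
        for ind, lab in labels.items():
            out.setdefault(lab, []).append(ind)
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MarkerMatrix({self.n_individuals} individuals x {self.n_markers} markers)"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_marker_matrix(
    path,
    format: str = "wide_tsv",
    missing_token: str = "NA",
    groups_path=None,
    markers_path=None,
) -> MarkerMatrix:
    """Read a wide marker table (rows = individuals, columns = markers).

    The first column holds individual identifiers, the header row marker
    names.  Cell values must be 0, 1 or ``missing_token``.  Optional sidecar
    tables supply group/region labels (columns ``individual``, ``group``,
    ``region``) and marker metadata (``marker``, ``quality_q``,
    ``chromosome``, ``position_cM``).
    """
    sep = {"wide_tsv": "\t", "wide_csv": ","}.get(format)
    if sep is None:
        raise ValueError(f"unknown format {format!r}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dups = sorted(raw.index[raw.index.duplicated()].unique())
        raise ValueError(f"duplicate individual identifiers in {path}: {dups}")
    allowed = {"0": 0.0, "1": 1.0, missing_token: np.nan}
    calls = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        column = raw[col]
        unknown = set(column.unique()) - set(allowed)
        if unknown:
            row = column[~column.isin(allowed)].index[0]
            rownum = raw.index.get_loc(row) + 2  # header is line 1
            raise ValueError(
                f"unknown call token {sorted(unknown)[0]!r} at line {rownum}, "
                f"marker {col!r} (expected 0, 1 or {missing_token!r})"
            )
        calls[col] = column.map(allowed)

    groups = regions = None
    if groups_path is not None:
        gt = pd.read_csv(groups_path, sep="\t", dtype=str)
        gt = gt.set_index("individual")
        groups = gt["group"]
        if "region" in gt.columns and not gt["region"].isna().all():
            regions = gt["region"]
    meta = None
    if markers_path is not None:
        meta = pd.read_csv(markers_path, sep="\t").set_index("marker")
    return MarkerMatrix(calls, groups, regions, meta)


def write_marker_matrix(
    m: MarkerMatrix,
    path,
    format: str = "wide_tsv",
    missing_token: str = "NA",
    groups_path=None,
    markers_path=None,
) -> None:
    """Write a matrix in the same wide layout ``read_marker_matrix`` accepts.

    Original row/column order is preserved so a write/read round-trip is an
    identity.
    """
    sep = {"wide_tsv": "\t", "wide_csv": ","}.get(format)
    if sep is None:
        raise ValueError(f"unknown format {format!r}")
    out = m.calls.map(lambda v: missing_token if np.isnan(v) else str(int(v)))
    out.index.name = "individual"
    out.to_csv(path, sep=sep)
    if groups_path is not None and m.group_labels is not None:
        gt = pd.DataFrame({"individual": m.individuals, "group": m.group_labels.values})
        if m.region_labels is not None:
            gt["region"] = m.region_labels.values
        gt.to_csv(groups_path, sep="\t", index=False)
    if markers_path is not None and m.marker_meta is not None:
        mm = m.marker_meta.reset_index().rename(columns={"index": "marker"})
        mm.to_csv(markers_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_quality(m: MarkerMatrix, min_q: float = 80.0) -> tuple[MarkerMatrix, FilterReport]:
    """Retain markers whose quality score Q is strictly greater than ``min_q``.

    Requires ``quality_q`` in the marker metadata; raise otherwise so callers
    can skip the step explicitly rather than silently.
    """
    if m.marker_meta is None or "quality_q" not in m.marker_meta.columns:
        raise ValueError(
            "marker quality metadata (quality_q) not available; "
            "skip the quality filter for this dataset"
        )
    q = m.marker_meta["quality_q"].astype(float)
    keep = [mk for mk in m.markers if q[mk] > min_q]
    removed = [mk for mk in m.markers if not q[mk] > min_q]
    report = FilterReport("quality", m.n_markers, len(keep), {"quality": removed})
    return m.select_markers(keep), report


def filter_missing(m: MarkerMatrix, max_missing_frac: float = 0.10) -> tuple[MarkerMatrix, FilterReport]:
    """Remove markers whose missing-call fraction is >= ``max_missing_frac``."""
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = m.calls.isna().mean(axis=0)
    keep = [mk for mk in m.markers if frac[mk] < max_missing_frac]
    removed = [mk for mk in m.markers if mk not in set(keep)]
    report = FilterReport("missing", m.n_markers, len(keep), {"missing": removed})
    return m.select_markers(keep), report


def filter_maf(m: MarkerMatrix, min_maf: float = 0.05) -> tuple[MarkerMatrix, FilterReport]:
    """Remove markers with minor allele frequency below ``min_maf``.

    Frequency is the band-presence frequency over non-missing calls (inbred
    assumption); the boundary is inclusive — ``min(f, 1-f) == min_maf`` is
    retained.  Markers with every call missing cannot be assessed and are
    removed, reported under a separate ``all_missing`` key.
    """
    f = m.presence_frequencies()
    maf = np.minimum(f, 1.0 - f)
    all_missing = [mk for mk in m.markers if np.isnan(f[mk])]
    removed = [mk for mk in m.markers if not np.isnan(f[mk]) and maf[mk] < min_maf]
    dropset = set(all_missing) | set(removed)
    keep = [mk for mk in m.markers if mk not in dropset]
    report = FilterReport(
        "maf", m.n_markers, len(keep), {"maf": removed, "all_missing": all_missing}
    )
    return m.select_markers(keep), report


def thin_correlated(m: MarkerMatrix, max_abs_r: float = 0.95) -> tuple[MarkerMatrix, FilterReport]:
    """Greedy correlation thinning in marker order.

    A marker is dropped when its absolute Pearson correlation with any
    already-retained earlier marker exceeds ``max_abs_r`` (correlation over
    individuals scored for both).  Keeping the earlier marker makes the pass
    deterministic.  Zero-variance pairs have undefined correlation, treated
    as 0 with a warning.
    """
    vals = m.values()
    n_markers = m.n_markers
    obs = ~np.isnan(vals)
    kept_idx: list[int] = []
    removed: list[str] = []
    warned_zero_var = False
    for j in range(n_markers):
        drop = False
        for k in kept_idx:
            both = obs[:, j] & obs[:, k]
            if both.sum() < 2:
                continue
            x, y = vals[both, j], vals[both, k]
            sx, sy = x.std(), y.std()
            if sx == 0.0 or sy == 0.0:
                warned_zero_var = True
                continue  # r undefined -> treated as 0
            r = np.corrcoef(x, y)[0, 1]
            if abs(r) > max_abs_r:
                drop = True
                break
        if drop:
            removed.append(m.markers[j])
        else:
            kept_idx.append(j)
    if warned_zero_var:
        warnings.warn("zero-variance marker pair(s): correlation undefined, treated as 0")
    keep = [m.markers[j] for j in kept_idx]
    report = FilterReport("correlation", n_markers, len(keep), {"correlation": removed})
    return m.select_markers(keep), report


def apply_filter_chain(
    m: MarkerMatrix,
    min_q: float | None = 80.0,
    max_missing_frac: float = 0.10,
    min_maf: float = 0.05,
    max_abs_r: float = 0.95,
) -> tuple[MarkerMatrix, list[FilterReport]]:
    """Run the full chain in the fixed order quality -> missing -> MAF -> correlation.

    ``min_q=None`` skips the quality step (for datasets without Q scores).
    """
    reports: list[FilterReport] = []
    if min_q is not None:
        m, rep = filter_quality(m, min_q)
        reports.append(rep)
    m, rep = filter_missing(m, max_missing_frac)
    reports.append(rep)
    m, rep = filter_maf(m, min_maf)
    reports.append(rep)
    m, rep = thin_correlated(m, max_abs_r)
    reports.append(rep)
    return m, reports
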