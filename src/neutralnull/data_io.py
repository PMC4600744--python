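"""Tables, validation and T-RFLP fingerprint processing.

The containers here are thin, validated wrappers around numpy/pandas
objects: a sample x taxon :class:`CommunityMatrix`, a :class:`SiteTable`
with planar coordinates / soil layer / land use, a :class:`HabitatMatrix`
of edaphic variables, and a long-format :class:`PeakTable` of fragment
peaks.  Fingerprint processing follows the standard T-RFLP workflow:
size-window and fluorescence filters (:func:`filter_peaks`), alignment of
fragments into bins across samples (:func:`bin_fragments`) and conversion
of relative abundances to integer counts (:func:`to_counts`), which the
neutral-model likelihood requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LAND_USE_CLASSES = (
    "arable",
    "improved grassland",
    "semi-natural grassland",
    "woodland",
    "moorland",
    "bog",
)

SITE_COLUMNS = ("sample_id", "site_id", "x", "y", "layer", "land_use")
PEAK_COLUMNS = ("sample_id", "fragment_size", "height")


class ValidationError(ValueError):
    """A table violated one of its structural invariants."""


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class CommunityMatrix:
    """Samples x taxa abundance matrix.

    ``abundance`` holds non-negative reals (relative fluorescence) or
    integer counts; ``is_counts`` records which.  Every sample must retain
    at least one positive taxon.
    """

    sample_ids: list
    taxon_ids: list
    abundance: np.ndarray
    is_counts: bool = False

    def __post_init__(self):
        self.abundance = np.asarray(self.abundance, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if self.abundance.ndim != 2:
            raise ValidationError("abundance must be 2-D (samples x taxa)")
        if self.abundance.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"shape {self.abundance.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.all(np.isfinite(self.abundance)):
            raise ValidationError("non-finite abundance values")
        if np.any(self.abundance < 0):
            i, j = np.argwhere(self.abundance < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.taxon_ids, "taxon ids")
        empty = np.flatnonzero(self.abundance.sum(axis=1) == 0)
        if empty.size:
            raise ValidationError(
                f"samples with no positive taxa: "
                f"{[self.sample_ids[i] for i in empty[:5]]}"
            )
        if self.is_counts and not np.allclose(self.abundance, np.round(self.abundance)):
            raise ValidationError("is_counts=True but abundances are not integers")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundance, index=self.sample_ids, columns=self.taxon_ids)

    def presence(self) -> np.ndarray:
        return (self.abundance > 0).astype(float)

    def subset(self, sample_ids) -> "CommunityMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        sub = self.abundance[idx]
        keep = sub.sum(axis=0) > 0
        return CommunityMatrix(
            list(sample_ids),
            [t for t, k in zip(self.taxon_ids, keep) if k],
            sub[:, keep],
            is_counts=self.is_counts,
        )


@dataclass
class SiteTable:
    """Per-sample site metadata: planar coordinates (metres), soil layer
    1-4 and one of the six land-use classes."""

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SITE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"site table missing columns: {missing}")
        f = self.frame
        _check_unique(f["sample_id"], "sample ids")
        if not np.all(np.isfinite(f[["x", "y"]].to_numpy(dtype=float))):
            raise ValidationError("non-finite coordinates in site table")
        bad_layer = set(f["layer"]) - {1, 2, 3, 4}
        if bad_layer:
            raise ValidationError(f"layer values outside 1-4: {sorted(bad_layer)}")
        bad_lu = set(f["land_use"]) - set(LAND_USE_CLASSES)
        if bad_lu:
            raise ValidationError(f"unknown land-use classes: {sorted(bad_lu)}")

    @property
    def sample_ids(self) -> list:
        return [str(s) for s in self.frame["sample_id"]]

    def coords(self, sample_ids=None) -> np.ndarray:
        f = self.frame.set_index("sample_id")
        if sample_ids is None:
            sample_ids = self.sample_ids
        return f.loc[list(sample_ids), ["x", "y"]].to_numpy(dtype=float)

    def subset(self, sample_ids) -> "SiteTable":
        f = self.frame.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SiteTable(f)


@dataclass
class HabitatMatrix:
    """Samples x habitat-variable matrix (missing values allowed)."""

    sample_ids: list
    variable_names: list
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_names = [str(v) for v in self.variable_names]
        if self.values.shape != (len(self.sample_ids), len(self.variable_names)):
            raise ValidationError("habitat value shape does not match ids")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.variable_names, "variable names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.variable_names)

    def subset(self, sample_ids) -> "HabitatMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return HabitatMatrix(
            list(sample_ids), list(self.variable_names), self.values[idx],
            standardized=self.standardized,
        )


def standardize_habitat(hm: HabitatMatrix, ddof: int = 1) -> HabitatMatrix:
    """Column-wise z-scoring on complete (non-missing) entries.

    Zero-variance columns are dropped with a warning; they carry no
    information for Euclidean habitat distances.
    """
    vals = hm.values.copy()
    keep, names = [], []
    for j, name in enumerate(hm.variable_names):
        col = vals[:, j]
        ok = np.isfinite(col)
        if ok.sum() < 2 or np.nanstd(col) == 0:
            warnings.warn(f"dropping constant/empty habitat variable {name!r}")
            continue
        mu = np.nanmean(col)
        sd = np.nanstd(col, ddof=ddof)
        vals[:, j] = (col - mu) / sd
        keep.append(j)
        names.append(name)
    return HabitatMatrix(list(hm.sample_ids), names, vals[:, keep], standardized=True)


@dataclass
class PeakTable:
    """Long-format T-RFLP peaks: one row per (sample, fragment size, height)."""

    frame: pd.DataFrame
    flagged_samples: list = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in PEAK_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"peak table missing columns: {missing}")
        f = self.frame
        if len(f) and np.any(f["fragment_size"].to_numpy(dtype=float) <= 0):
            raise ValidationError("fragment_size must be positive")
        if len(f) and np.any(f["height"].to_numpy(dtype=float) < 0):
            raise ValidationError("peak height must be non-negative")

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_community_matrix(path, orientation: str = "samples_rows",
                          is_counts: bool | None = None) -> CommunityMatrix:
    """Read a delimited community table (TSV/CSV).

    First column holds sample ids (or taxon ids with
    ``orientation='taxa_rows'``), header row the other axis.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "taxa_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[np.flatnonzero(bad)[0]]
            raise ValidationError(
                f"malformed numeric cell at row {row!r}, column {col!r}"
            )
        df[col] = coerced
    values = df.to_numpy(dtype=float)
    if is_counts is None:
        is_counts = bool(np.allclose(values, np.round(values)))
    return CommunityMatrix(list(df.index), list(df.columns), values, is_counts=is_counts)


def write_community_matrix(cm: CommunityMatrix, path) -> None:
    path = Path(path)
    df = cm.to_frame()
    if cm.is_counts:
        df = df.astype(int)
    df.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_site_table(path) -> SiteTable:
    return SiteTable(pd.read_csv(Path(path), sep=_sep_for(path)))


def write_site_table(sites: SiteTable, path) -> None:
    sites.frame.to_csv(Path(path), sep=_sep_for(path), index=False)


def read_habitat_matrix(path, standardized: bool = False) -> HabitatMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return HabitatMatrix(list(df.index), list(df.columns),
                         df.to_numpy(dtype=float), standardized=standardized)


def write_habitat_matrix(hm: HabitatMatrix, path) -> None:
    hm.to_frame().to_csv(Path(path), sep=_sep_for(Path(path)), index_label="sample_id")


def read_peak_table(path) -> PeakTable:
    return PeakTable(pd.read_csv(Path(path), sep=_sep_for(path)))


def write_peak_table(peaks: PeakTable, path) -> None:
    peaks.frame.to_csv(Path(path), sep=_sep_for(Path(path)), index=False)


# ---------------------------------------------------------------------------
# fingerprint processing
# ---------------------------------------------------------------------------

def filter_peaks(peaks: PeakTable, min_size: float = 35, max_size: float = 550,
                 min_height: float = 50, min_frac: float = 0.02) -> PeakTable:
    """Apply the standard T-RFLP quality filters.

    Per sample, keep peaks whose fragment size lies in ``[min_size,
    max_size]`` and whose height is at least ``min_height`` fluorescence
    units; then drop peaks below ``min_frac`` of the sample's total peak
    height, where the total is computed *after* the size and
    absolute-height filters (sequential filtering).  Samples that lose all
    their peaks are recorded in ``flagged_samples`` rather than silently
    vanishing.
    """
    if not min_size < max_size:
        raise ValueError("min_size must be < max_size")
    if not 0 <= min_frac < 1:
        raise ValueError("min_frac must be in [0, 1)")
    f = peaks.frame
    if len(f) == 0:
        warnings.warn("filter_peaks: empty peak table")
        return PeakTable(f.copy())

    size = f["fragment_size"].to_numpy(dtype=float)
    height = f["height"].to_numpy(dtype=float)
    keep = (size >= min_size) & (size <= max_size) & (height >= min_height)

    out_parts = []
    flagged = []
    for sid, grp in f.assign(_keep=keep).groupby("sample_id", sort=False):
        surv = grp[grp["_keep"]]
        total = surv["height"].sum()
        surv = surv[surv["height"] >= min_frac * total]
        if len(surv) == 0:
            flagged.append(sid)
        else:
            out_parts.append(surv.drop(columns="_keep"))
    out = (pd.concat(out_parts, ignore_index=True) if out_parts
           else f.iloc[0:0].copy())
    return PeakTable(out, flagged_samples=flagged)


def bin_fragments(peaks: PeakTable, clustering_threshold: float = 0.99,
                  min_size: float = 35, max_size: float = 550) -> CommunityMatrix:
    """Align fragments across samples into shared bins (putative taxa).

    Greedy single-linkage clustering of fragment sizes: scanning sizes in
    ascending order, a fragment joins the current bin if it is within
    ``(1 - clustering_threshold) * size`` of the bin's previous member,
    otherwise it starts a new bin.  This approximates fingerprint-software
    alignment at a "0.99 clustering" setting.  Cells are relative heights
    within each sample, so rows sum to 1.
    """
    if not 0 < clustering_threshold <= 1:
        raise ValueError("clustering_threshold must be in (0, 1]")
    f = peaks.frame
    if len(f) == 0:
        return _empty_matrix()
    size = f["fragment_size"].to_numpy(dtype=float)
    if np.any((size < min_size) | (size > max_size)):
        raise ValidationError(
            "peak table contains fragments outside the size window; "
            "run filter_peaks first"
        )
    tol = 1.0 - clustering_threshold
    order = np.argsort(size, kind="stable")
    sorted_sizes = size[order]
    bin_of_sorted = np.empty(len(f), dtype=int)
    current = 0
    bin_of_sorted[0] = 0
    for k in range(1, len(f)):
        # single linkage: compare to the nearest (previous) member
        if sorted_sizes[k] - sorted_sizes[k - 1] > tol * sorted_sizes[k]:
            current += 1
        bin_of_sorted[k] = current
    bin_ids = np.empty(len(f), dtype=int)
    bin_ids[order] = bin_of_sorted
    n_bins = current + 1

    # bin label: smallest member size (ties broken toward the smaller fragment)
    labels = [f"TRF_{size[bin_ids == b].min():g}" for b in range(n_bins)]

    samples = list(dict.fromkeys(f["sample_id"]))
    mat = np.zeros((len(samples), n_bins))
    srow = {s: i for i, s in enumerate(samples)}
    heights = f["height"].to_numpy(dtype=float)
    for sid, b, h in zip(f["sample_id"], bin_ids, heights):
        mat[srow[sid], b] += h
    totals = mat.sum(axis=1, keepdims=True)
    mat = mat / totals
    return CommunityMatrix(samples, labels, mat, is_counts=False)


def _empty_matrix() -> CommunityMatrix:
    cm = object.__new__(CommunityMatrix)
    cm.sample_ids, cm.taxon_ids = [], []
    cm.abundance = np.zeros((0, 0))
    cm.is_counts = False
    return cm


def to_counts(cm: CommunityMatrix, total: int) -> CommunityMatrix:
    """Rescale each sample to integer counts summing to ``total``.

    Uses largest-remainder rounding; every taxon that was positive keeps at
    least one individual (the neutral likelihood conditions on species
    presence, so silently extinguishing taxa would change the data).
    """
    total = int(total)
    counts = np.zeros_like(cm.abundance)
    for i in range(cm.n_samples):
        row = cm.abundance[i]
        pos = row > 0
        n_pos = int(pos.sum())
        if total < n_pos:
            raise ValueError(
                f"total={total} too small to keep {n_pos} positive taxa in "
                f"sample {cm.sample_ids[i]!r}"
            )
        raw = row / row.sum() * total
        base = np.floor(raw)
        remainder = raw - base
        short = int(total - base.sum())
        if short:
            give = np.argsort(-remainder, kind="stable")[:short]
            base[give] += 1
        # restore positivity for taxa rounded to zero
        zeroed = np.flatnonzero(pos & (base == 0))
        for j in zeroed:
            donor = int(np.argmax(base))
            base[donor] -= 1
            base[j] = 1
        counts[i] = base
    return CommunityMatrix(list(cm.sample_ids), list(cm.taxon_ids), counts,
                           is_counts=True)
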