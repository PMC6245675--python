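"""Community and environment tables: loading, validation and preprocessing.

The analysis operates on two paired tables: a site-by-taxon abundance matrix
(valve counts or percentages) and a site-by-variable environment table.  The
preprocessing chain mirrors the conventional transfer-function workflow:
counts -> row percentages -> coverage-based taxon screening -> square-root
transform, with the environmental target (chloride, mg/l) log10-transformed.

Units move strictly forward (``counts`` -> ``percent`` -> ``sqrt_percent``);
each operation checks the unit of its input so that, for example, the
square-root transform cannot be applied twice by accident.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "EnvironmentTable",
    "HarmonizationReport",
    "load_study",
    "relative_abundance",
    "sqrt_transform",
    "coverage_filter",
    "transform_env",
    "harmonize_taxa",
    "one_per_site_subsample",
]

VALID_UNITS = ("counts", "percent", "sqrt_percent")
SEASONS = ("spring", "summer", "autumn")

#: column names in community CSVs that carry metadata rather than taxa
_META_COLUMNS = ("season", "location_id")


@dataclass
class CommunityTable:
    """Site-by-taxon nonnegative abundance matrix with optional metadata.

    Parameters
    ----------
    data
        DataFrame indexed by site id, one column per taxon, nonnegative.
    unit
        One of ``counts``, ``percent``, ``sqrt_percent``.
    season
        Optional per-site season label (``spring``/``summer``/``autumn``).
    location
        Optional per-site location label (several sites may share one
        location when the same spot was sampled in several seasons).
    """

    data: pd.DataFrame
    unit: str = "counts"
    season: pd.Series | None = None
    location: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate site_id(s): {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon id(s): {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("community table contains non-finite values")
        if (values < 0).any():
            bad = self.data.index[(values < 0).any(axis=1)].tolist()
            raise ValueError(f"negative abundance at site(s) {bad}")
        for name in ("season", "location"):
            labels = getattr(self, name)
            if labels is not None:
                labels = pd.Series(labels).reindex(self.data.index)
                if labels.isna().any():
                    missing = labels.index[labels.isna()].tolist()
                    raise ValueError(f"{name} labels missing for site(s) {missing}")
                object.__setattr__(self, name, labels)
        if self.season is not None:
            bad = sorted(set(self.season) - set(SEASONS))
            if bad:
                raise ValueError(f"unknown season label(s) {bad}; expected {SEASONS}")

    # -- convenience accessors -------------------------------------------------
    @property
    def site_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def taxon_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def subset_sites(self, site_ids) -> "CommunityTable":
        """Return a new table restricted to *site_ids* (original order kept)."""
        keep = [s for s in self.site_ids if s in set(site_ids)]
        return CommunityTable(
            self.data.loc[keep],
            unit=self.unit,
            season=None if self.season is None else self.season.loc[keep],
            location=None if self.location is None else self.location.loc[keep],
        )


@dataclass
class EnvironmentTable:
    """Site-by-variable numeric table with units and transform bookkeeping."""

    data: pd.DataFrame
    units: dict = field(default_factory=dict)
    transform_state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate site_id(s): {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("environment table contains non-finite values")
        state = dict(self.transform_state)
        for var in self.data.columns:
            state.setdefault(var, "raw")
            if state[var] not in ("raw", "log10"):
                raise ValueError(f"unknown transform state {state[var]!r} for {var!r}")
        self.transform_state = state

    @property
    def site_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def variables(self) -> list:
        return self.data.columns.tolist()

    def column(self, name: str) -> pd.Series:
        return self.data[name]

    def subset_sites(self, site_ids) -> "EnvironmentTable":
        keep = [s for s in self.site_ids if s in set(site_ids)]
        return EnvironmentTable(self.data.loc[keep], units=dict(self.units),
                                transform_state=dict(self.transform_state))


@dataclass
class HarmonizationReport:
    """Outcome of matching a new dataset's taxa against a model's taxa."""

    matched_taxa: list
    dropped_taxa: list
    matched_abundance_fraction: pd.Series  # per site, in [0, 1]


def load_study(community_path, environment_path, *, unit: str = "counts",
               env_units: dict | None = None):
    """Read and validate paired community and environment CSV files.

    The community CSV has a leading ``site_id`` column, optional ``season``
    and ``location_id`` columns, and one numeric column per taxon.  The
    environment CSV has ``site_id`` plus numeric variable columns.  Both
    files must describe exactly the same sites; the environment rows are
    reordered to the community order.
    """
    # lines starting with '#' carry provenance (config hash, seed) and are skipped
    com = pd.read_csv(community_path, comment="#")
    env = pd.read_csv(environment_path, comment="#")
    for frame, path in ((com, community_path), (env, environment_path)):
        if frame.shape[1] < 2:
            raise ValueError(f"{path}: expected a site_id column plus data columns")
    com = com.set_index(com.columns[0])
    env = env.set_index(env.columns[0])

    season = com.pop("season") if "season" in com.columns else None
    location = com.pop("location_id") if "location_id" in com.columns else None
    com = com.apply(pd.to_numeric)
    env = env.apply(pd.to_numeric)

    com_sites, env_sites = set(com.index), set(env.index)
    only_com = sorted(com_sites - env_sites)
    only_env = sorted(env_sites - com_sites)
    if only_com or only_env:
        parts = []
        if only_com:
            parts.append(f"missing from environment table: {only_com}")
        if only_env:
            parts.append(f"missing from community table: {only_env}")
        raise ValueError("site mismatch; " + "; ".join(parts))

    zero_rows = com.index[(com.to_numpy(dtype=float).sum(axis=1) == 0)].tolist()
    if zero_rows:
        raise ValueError(f"site(s) with all-zero abundance row: {zero_rows}")

    ct = CommunityTable(com, unit=unit, season=season, location=location)
    et = EnvironmentTable(env.loc[com.index], units=dict(env_units or {}))
    return ct, et


def relative_abundance(ct: CommunityTable) -> CommunityTable:
    """Convert counts to row percentages (each site row sums to 100)."""
    if ct.unit != "counts":
        raise ValueError(f"relative_abundance expects counts, got {ct.unit!r}")
    totals = ct.values.sum(axis=1)
    if (totals == 0).any():
        bad = ct.data.index[totals == 0].tolist()
        raise ValueError(f"site(s) with zero total count: {bad}")
    pct = ct.data.div(totals, axis=0) * 100.0
    return replace(ct, data=pct, unit="percent")


def sqrt_transform(ct: CommunityTable) -> CommunityTable:
    """Square-root transform percentages, down-weighting dominant taxa."""
    if ct.unit != "percent":
        raise ValueError(f"sqrt_transform expects percent, got {ct.unit!r}")
    return replace(ct, data=np.sqrt(ct.data), unit="sqrt_percent")


def coverage_filter(ct: CommunityTable, threshold: float = 0.98):
    """Keep the most abundant taxa jointly covering *threshold* of the total.

    Taxa are ranked by grand-total abundance (descending, ties broken by
    taxon id) and the shortest prefix whose cumulative share of the grand
    total reaches *threshold* is retained.  Returns the filtered table and
    the list of dropped taxa.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if ct.unit not in ("counts", "percent"):
        raise ValueError(f"coverage_filter expects counts or percent, got {ct.unit!r}")
    totals = ct.data.sum(axis=0)
    order = totals.to_frame("total").reset_index(names="taxon")
    order = order.sort_values(["total", "taxon"], ascending=[False, True])
    cumfrac = order["total"].cumsum() / order["total"].sum()
    # smallest prefix with cumulative fraction >= threshold (tiny slack for
    # float round-off on exact boundaries such as 98/100)
    n_keep = int(np.searchsorted(cumfrac.to_numpy(), threshold - 1e-12) + 1)
    n_keep = min(n_keep, len(order))
    kept = order["taxon"].iloc[:n_keep].tolist()
    dropped = order["taxon"].iloc[n_keep:].tolist()
    kept_in_original_order = [t for t in ct.taxon_ids if t in set(kept)]
    return replace(ct, data=ct.data[kept_in_original_order]), dropped


def transform_env(et: EnvironmentTable, spec: dict) -> EnvironmentTable:
    """Apply per-variable transforms (``raw`` or ``log10``) to the table."""
    unknown = sorted(set(spec) - set(et.variables))
    if unknown:
        raise ValueError(f"transform spec names unknown variable(s) {unknown}")
    data = et.data.copy()
    state = dict(et.transform_state)
    for var, how in spec.items():
        if how == "raw":
            continue
        if how != "log10":
            raise ValueError(f"unknown transform {how!r} for {var!r}")
        if state.get(var) == "log10":
            raise ValueError(f"{var!r} is already log10-transformed")
        col = data[var]
        bad = col.index[col <= 0].tolist()
        if bad:
            raise ValueError(f"log10 of non-positive {var!r} at site(s) {bad}")
        data[var] = np.log10(col)
        state[var] = "log10"
    return EnvironmentTable(data, units=dict(et.units), transform_state=state)


def harmonize_taxa(model_taxa, ct: CommunityTable):
    """Align a community table to a model's taxon list by exact name match.

    Taxon names are matched after whitespace trimming.  Taxa the model knows
    but the table lacks are filled with zeros; table taxa unknown to the
    model are dropped and reported.  The matched-abundance fraction (share of
    each site's total abundance carried by matched taxa, computed before
    dropping) quantifies how much signal survives harmonization.
    """
    model_taxa = [str(t).strip() for t in model_taxa]
    if len(set(model_taxa)) != len(model_taxa):
        raise ValueError("model taxon list contains duplicates")
    data = ct.data.copy()
    data.columns = [str(c).strip() for c in data.columns]
    model_set = set(model_taxa)
    matched = [t for t in data.columns if t in model_set]
    dropped = [t for t in data.columns if t not in model_set]

    totals = data.sum(axis=1)
    matched_totals = data[matched].sum(axis=1) if matched else pd.Series(0.0, index=data.index)
    with np.errstate(invalid="ignore"):
        fraction = (matched_totals / totals).fillna(0.0)
    zero_sites = fraction.index[fraction == 0].tolist()
    if zero_sites:
        raise ValueError(
            f"site(s) share no taxa with the model after harmonization: {zero_sites}")

    harmonized = data.reindex(columns=model_taxa, fill_value=0.0)
    out = replace(ct, data=harmonized)
    report = HarmonizationReport(matched_taxa=matched, dropped_taxa=dropped,
                                 matched_abundance_fraction=fraction)
    return out, report


def one_per_site_subsample(ct: CommunityTable, et: EnvironmentTable, seed: int):
    """Keep one randomly chosen season per sampling location.

    Used to check whether a pooled all-season model owes its performance to
    its larger sample count: the subsample has one sample per location, the
    same size as a single-season dataset.
    """
    if ct.season is None or ct.location is None:
        raise ValueError("one_per_site_subsample requires season and location metadata")
    rng = np.random.default_rng(seed)
    chosen = []
    for loc in sorted(pd.unique(ct.location)):
        sites = [s for s in ct.site_ids if ct.location.loc[s] == loc]
        chosen.append(sites[rng.integers(len(sites))])
    chosen_set = set(chosen)
    keep = [s for s in ct.site_ids if s in chosen_set]
    return ct.subset_sites(keep), et.subset_sites(keep)
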