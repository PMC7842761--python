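"""Differential brain-region coactivation networks from regional fos counts.

The analysis treats per-animal counts of fos+ cells in a set of brain
regions as a proxy for regional activation, and inter-region Spearman rank
correlations across the animals of one experimental condition as a proxy
for functional coactivation.  Two conditions are compared edge-by-edge by
Fisher-transforming the two correlation coefficients and forming the
standardized difference

    Z_obs = (atanh(r1) - atanh(r2)) / sqrt(1/(n1 - 3) + 1/(n2 - 3)),

whose sign gives the direction of the change (positive: the first group is
more strongly coactivated) and whose magnitude is an approximately
standard-normal effect size under the null of equal population
correlations.  Edges with |Z_obs| at or above a display threshold form the
differential network; per-region sums of retained edge magnitudes rank
candidate hub regions.

Missing regional measurements are handled pairwise-complete: each region
pair uses only the animals with both regions present, and that pair's
effective sample size enters the Z_obs denominator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

CYCLE_LEVELS = ("highE2", "lowE2")
STRESS_LEVELS = ("control", "MAS")
META_COLUMNS = ("animal_id", "cycle", "stress")

#: region panel analyzed in the study: thalamic/hypothalamic nuclei,
#: dorsal hippocampal subfields, amygdalar nuclei, extended amygdala, septum
DEFAULT_REGIONS = (
    "PVT", "PVN", "dCA1", "dCA2/3", "dDG",
    "CeA", "BLA", "MeA", "BNST", "LS", "MS",
)

#: four planned condition contrasts: cycle effect at baseline, stress effect
#: within each cycle phase, and cycle effect under stress
DEFAULT_COMPARISONS = (
    (("highE2", "control"), ("lowE2", "control")),
    (("highE2", "MAS"), ("highE2", "control")),
    (("lowE2", "MAS"), ("lowE2", "control")),
    (("highE2", "MAS"), ("lowE2", "MAS")),
)

R_CLAMP = 1.0 - 1e-7
MIN_PAIR_N = 4  # Fisher variance 1/(n-3) needs n > 3


class UndefinedCorrelationError(ValueError):
    """A correlation is undefined (zero variance in one input)."""


class RankCorrelation(NamedTuple):
    """Spearman coefficient with its effective sample size and status."""

    rho: float
    n: int
    status: str = "ok"  # "ok" | "insufficient_n" | "zero_variance"


def condition_key(cycle: str, stress: str) -> tuple[str, str]:
    """Validate and normalize a (cycle, stress) condition label."""
    if cycle not in CYCLE_LEVELS:
        raise ValueError(f"unknown cycle level {cycle!r}; expected one of {CYCLE_LEVELS}")
    if stress not in STRESS_LEVELS:
        raise ValueError(f"unknown stress level {stress!r}; expected one of {STRESS_LEVELS}")
    return (cycle, stress)


def _region_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def validate_fos_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a per-animal fos-count table: metadata columns, nonnegative
    counts where present, and at least one measured region per animal."""
    missing_meta = [c for c in META_COLUMNS if c not in table.columns]
    if missing_meta:
        raise ValueError(f"fos table lacks metadata columns {missing_meta}")
    regions = _region_columns(table)
    if not regions:
        raise ValueError("fos table has no region columns")
    if len(set(regions)) != len(regions):
        raise ValueError("duplicate region labels")
    values = table[regions].to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise ValueError("fos counts must be nonnegative")
    if np.all(np.isnan(values), axis=1).any():
        bad = table.loc[np.all(np.isnan(values), axis=1), "animal_id"].tolist()
        raise ValueError(f"animals with no measured region: {bad}")
    return table


# ---------------------------------------------------------------------------
# scaling


class FosScaler(BaseEstimator, TransformerMixin):
    """Mean-normalize counts per region: x' = (x - mean) / (max - min).

    Statistics are pooled over all animals and groups, matching the study's
    scaling of raw counts across all brain regions and groups before the
    correlation matrices.  A constant region (max == min) maps to zeros.
    Missing values are ignored when fitting and preserved by transform.
    Rank correlations are invariant to this (or any increasing affine)
    per-region map, so scaling is bookkeeping for display rather than a
    choice that can move downstream Z_obs values.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "FosScaler":
        X = self._check_frame(X)
        values = X.to_numpy(dtype=float)
        if np.all(np.isnan(values), axis=0).any():
            bad = [c for c, empty in zip(X.columns, np.all(np.isnan(values), axis=0)) if empty]
            raise ValueError(f"region(s) entirely missing: {bad}")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.mean_ = np.nanmean(values, axis=0)
        self.min_ = np.nanmin(values, axis=0)
        self.max_ = np.nanmax(values, axis=0)
        self.range_ = self.max_ - self.min_
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._check_frame(X)
        if list(X.columns) != list(self.feature_names_in_):
            raise ValueError("columns differ from those seen in fit")
        values = X.to_numpy(dtype=float)
        rng = np.where(self.range_ == 0, 1.0, self.range_)
        scaled = (values - self.mean_) / rng
        scaled[:, self.range_ == 0] = np.where(
            np.isnan(values[:, self.range_ == 0]), np.nan, 0.0
        )
        return pd.DataFrame(scaled, index=X.index, columns=X.columns)

    @staticmethod
    def _check_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        return X


def scale_counts(table: pd.DataFrame) -> tuple[pd.DataFrame, FosScaler]:
    """Mean-normalize a full fos-count table (metadata columns carried
    through unchanged); returns the scaled table and the fitted scaler."""
    validate_fos_table(table)
    regions = _region_columns(table)
    scaler = FosScaler().fit(table[regions])
    out = table.copy()
    out[regions] = scaler.transform(table[regions])
    return out, scaler


# ---------------------------------------------------------------------------
# rank correlation


def spearman(x: Sequence[float], y: Sequence[float]) -> RankCorrelation:
    """Spearman rank correlation with midranks for ties and pairwise
    deletion of missing values.

    Returns the coefficient together with the effective sample size (pairs
    with both values present).  Fewer than 4 complete pairs, or zero rank
    variance in either vector, yields ``rho = nan`` with an explicit status
    — never a silent 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    n = int(keep.sum())
    if n < MIN_PAIR_N:
        return RankCorrelation(np.nan, n, "insufficient_n")
    rx = stats.rankdata(x[keep])
    ry = stats.rankdata(y[keep])
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return RankCorrelation(np.nan, n, "zero_variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return RankCorrelation(rho, n, "ok")


def spearman_matrix(data: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """All pairwise Spearman coefficients of the columns of ``data``
    (pairwise-complete), with per-pair effective n and the list of
    unavailable pairs (insufficient data or zero variance)."""
    cols = list(data.columns)
    k = len(cols)
    r = np.eye(k)
    n_eff = np.zeros((k, k), dtype=int)
    values = data.to_numpy(dtype=float)
    n_eff[np.diag_indices(k)] = np.sum(~np.isnan(values), axis=0)
    unavailable = []
    for i in range(k):
        for j in range(i + 1, k):
            res = spearman(values[:, i], values[:, j])
            r[i, j] = r[j, i] = res.rho
            n_eff[i, j] = n_eff[j, i] = res.n
            if res.status != "ok":
                unavailable.append((cols[i], cols[j], res.status))
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(n_eff, index=cols, columns=cols),
        unavailable,
    )


@dataclass(frozen=True)
class CorrelationMatrix:
    """Per-condition Spearman coactivation matrix with per-pair sample sizes."""

    condition: tuple[str, str]
    r: pd.DataFrame
    n_eff: pd.DataFrame
    unavailable: tuple = ()

    def __post_init__(self):
        if not np.allclose(self.r.fillna(0.0), self.r.fillna(0.0).T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r.to_numpy()), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        off = self.r.to_numpy()[~np.eye(len(self.r), dtype=bool)]
        if np.nanmax(np.abs(off), initial=0.0) > 1 + 1e-12:
            raise ValueError("correlation coefficients must lie in [-1, 1]")

    @property
    def regions(self) -> list[str]:
        return list(self.r.columns)


def correlation_matrix(table: pd.DataFrame, condition: tuple[str, str]) -> CorrelationMatrix:
    """Spearman coactivation matrix for one condition's animals.

    ``table`` is a (scaled or raw) fos table; only rows matching the
    condition are used, pairwise-complete over missing regions.
    """
    cycle, stress = condition_key(*condition)
    sub = table[(table["cycle"] == cycle) & (table["stress"] == stress)]
    if sub.empty:
        raise ValueError(f"condition {condition} absent from table")
    if len(sub) < MIN_PAIR_N:
        raise ValueError(
            f"condition {condition} has {len(sub)} animals; need >= {MIN_PAIR_N}"
        )
    r, n_eff, unavailable = spearman_matrix(sub[_region_columns(table)])
    return CorrelationMatrix((cycle, stress), r, n_eff, tuple(unavailable))


# ---------------------------------------------------------------------------
# Fisher transform and the differential statistic


def fisher_z(r, clamp: bool = True):
    """Fisher r-to-z transform, z = atanh(r) = 0.5*ln((1+r)/(1-r)).

    Coefficients within 1e-7 of ±1 (degenerate perfect correlations at
    small n) are clamped to keep z finite; a warning is emitted.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1):
        raise ValueError("|r| must be <= 1")
    if clamp and np.any(np.abs(arr) >= R_CLAMP):
        warnings.warn("correlation(s) clamped to +/-(1 - 1e-7) before atanh", RuntimeWarning)
        arr = np.clip(arr, -R_CLAMP, R_CLAMP)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


def z_obs(r1: float, n1: int, r2: float, n2: int) -> float:
    """Standardized difference of two independent correlations.

    Z_obs = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); requires
    n > 3 in both groups for the Fisher variance to exist.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("z_obs requires n > 3 in both groups")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float((fisher_z(r1) - fisher_z(r2)) / se)


@dataclass(frozen=True)
class DifferentialEdge:
    """One region pair's correlation change between two conditions."""

    region_a: str
    region_b: str
    r1: float
    r2: float
    n1: int
    n2: int
    z_obs: float

    @property
    def z1(self) -> float:
        return fisher_z(self.r1)

    @property
    def z2(self) -> float:
        return fisher_z(self.r2)

    @property
    def magnitude(self) -> float:
        return abs(self.z_obs)

    @property
    def direction(self) -> str:
        return "increased" if self.z_obs >= 0 else "decreased"


@dataclass
class DifferentialNetwork:
    """Signed, thresholded differential coactivation graph.

    ``edges`` holds every available region pair; the retained set is the
    pairs whose |Z_obs| meets ``display_threshold`` (0 keeps everything).
    """

    group1: tuple[str, str]
    group2: tuple[str, str]
    edges: list[DifferentialEdge]
    display_threshold: float = 1.96
    excluded_pairs: list = field(default_factory=list)
    regions: list[str] = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{'-'.join(self.group1)}_vs_{'-'.join(self.group2)}"

    @property
    def retained(self) -> list[DifferentialEdge]:
        return [e for e in self.edges if e.magnitude >= self.display_threshold]

    def to_frame(self) -> pd.DataFrame:
        """Long-format edge table: one row per computed pair."""
        rows = [
            {
                "region_a": e.region_a,
                "region_b": e.region_b,
                "comparison": self.label,
                "r1": e.r1,
                "n1": e.n1,
                "r2": e.r2,
                "n2": e.n2,
                "z_obs": e.z_obs,
                "retained": e.magnitude >= self.display_threshold,
            }
            for e in self.edges
        ]
        return pd.DataFrame(
            rows,
            columns=["region_a", "region_b", "comparison", "r1", "n1", "r2", "n2",
                     "z_obs", "retained"],
        )

    def to_networkx(self, retained_only: bool = True) -> nx.Graph:
        g = nx.Graph(comparison=self.label, display_threshold=self.display_threshold)
        g.add_nodes_from(self.regions)
        for e in (self.retained if retained_only else self.edges):
            g.add_edge(e.region_a, e.region_b, z_obs=e.z_obs,
                       magnitude=e.magnitude, direction=e.direction)
        return g

    def to_node_link(self) -> dict:
        return nx.node_link_data(self.to_networkx(), edges="links")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_node_link(), fh, indent=2)


def differential_network(
    m1: CorrelationMatrix,
    m2: CorrelationMatrix,
    display_threshold: float = 1.96,
) -> DifferentialNetwork:
    """Edge-wise Z_obs network between two per-condition matrices.

    Pairs unavailable in either matrix are excluded and listed rather than
    imputed.  Swapping the two matrices negates every Z_obs.
    """
    if list(m1.regions) != list(m2.regions):
        raise ValueError("correlation matrices cover different region sets")
    if display_threshold < 0:
        raise ValueError("display_threshold must be nonnegative")
    regions = m1.regions
    edges: list[DifferentialEdge] = []
    excluded: list[tuple[str, str]] = []
    for i, a in enumerate(regions):
        for b in regions[i + 1:]:
            r1 = m1.r.loc[a, b]
            r2 = m2.r.loc[a, b]
            if np.isnan(r1) or np.isnan(r2):
                excluded.append((a, b))
                continue
            n1 = int(m1.n_eff.loc[a, b])
            n2 = int(m2.n_eff.loc[a, b])
            edges.append(DifferentialEdge(a, b, float(r1), float(r2), n1, n2,
                                          z_obs(r1, n1, r2, n2)))
    return DifferentialNetwork(m1.condition, m2.condition, edges,
                               display_threshold, excluded, list(regions))


def node_strength(net: DifferentialNetwork) -> pd.DataFrame:
    """Hub score per region: sum of |Z_obs| over retained incident edges,
    plus the retained degree.  Isolated regions score 0."""
    strength = {r: 0.0 for r in net.regions}
    degree = {r: 0 for r in net.regions}
    for e in net.retained:
        strength[e.region_a] += e.magnitude
        strength[e.region_b] += e.magnitude
        degree[e.region_a] += 1
        degree[e.region_b] += 1
    return pd.DataFrame(
        {"strength": pd.Series(strength), "degree": pd.Series(degree)}
    ).rename_axis("region")


# ---------------------------------------------------------------------------
# full pipeline


class DifferentialNetworkAnalysis(BaseEstimator):
    """End-to-end differential coactivation analysis over a fos-count table.

    Parameters
    ----------
    comparisons : sequence of ((cycle, stress), (cycle, stress)), optional
        Condition contrasts to compute; defaults to the four planned ones
        (cycle effect in controls, stress effect within each phase, cycle
        effect under stress).
    display_threshold : float, default 1.96
        |Z_obs| cutoff for retaining an edge; the two-sided 5% normal
        quantile by default, 0 shows every nonzero difference.
    fdr : bool, default False
        If True, additionally Benjamini-Hochberg-adjust the two-sided
        normal p-values of each comparison's edges (reported in
        ``zobs_table_`` as ``q_value``; retention is still threshold-based,
        matching the descriptive use of Z_obs).

    Attributes
    ----------
    scaler_ : FosScaler — per-region pooled scaling statistics
    matrices_ : dict mapping condition -> CorrelationMatrix
    networks_ : dict mapping comparison label -> DifferentialNetwork
    zobs_table_ : DataFrame — long-format pair x comparison Z_obs table
    """

    def __init__(self, comparisons=None, display_threshold: float = 1.96,
                 fdr: bool = False):
        self.comparisons = comparisons
        self.display_threshold = display_threshold
        self.fdr = fdr

    def fit(self, X: pd.DataFrame, y=None) -> "DifferentialNetworkAnalysis":
        table = validate_fos_table(X)
        comparisons = [
            (condition_key(*g1), condition_key(*g2))
            for g1, g2 in (self.comparisons or DEFAULT_COMPARISONS)
        ]
        scaled, self.scaler_ = scale_counts(table)
        conditions = {c for pair in comparisons for c in pair}
        self.matrices_ = {c: correlation_matrix(scaled, c) for c in sorted(conditions)}
        self.networks_ = {}
        frames = []
        for g1, g2 in comparisons:
            net = differential_network(self.matrices_[g1], self.matrices_[g2],
                                       self.display_threshold)
            self.networks_[net.label] = net
            frames.append(net.to_frame())
        self.zobs_table_ = pd.concat(frames, ignore_index=True)
        if self.fdr:
            p = 2 * stats.norm.sf(np.abs(self.zobs_table_["z_obs"]))
            q = np.empty_like(p)
            for label, idx in self.zobs_table_.groupby("comparison").groups.items():
                q[np.asarray(idx)] = stats.false_discovery_control(p[np.asarray(idx)])
            self.zobs_table_["q_value"] = q
        return self

    def node_strengths(self) -> pd.DataFrame:
        """Hub scores for every fitted comparison, long format."""
        frames = []
        for label, net in self.networks_.items():
            df = node_strength(net).reset_index()
            df.insert(0, "comparison", label)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@dataclass
class PipelineResult:
    scaled: pd.DataFrame
    scaler: FosScaler
    matrices: dict
    networks: dict
    zobs_table: pd.DataFrame


def run_pipeline(
    table: pd.DataFrame,
    comparisons: Iterable = None,
    display_threshold: float = 1.96,
) -> PipelineResult:
    """scale -> per-condition Spearman matrices -> differential networks.

    Thin functional wrapper over :class:`DifferentialNetworkAnalysis`.
    """
    est = DifferentialNetworkAnalysis(
        comparisons=list(comparisons) if comparisons is not None else None,
        display_threshold=display_threshold,
    ).fit(table)
    return PipelineResult(
        scaled=scale_counts(table)[0],
        scaler=est.scaler_,
        matrices=est.matrices_,
        networks=est.networks_,
        zobs_table=est.zobs_table_,
    )
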