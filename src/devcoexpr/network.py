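"""Hard-threshold Pearson co-expression networks with scale-free cutoff scan.

All C(m, 2) gene pairs among the DE genes are correlated across all
samples; each correlation gets an exact two-sided p-value from the t
transform ``t = r * sqrt((n - 2) / (1 - r^2))`` with n - 2 degrees of
freedom, and BH adjustment is pooled over all tested pairs.  The network
significance cutoff is then chosen by scanning a grid of cutoffs and
scoring each resulting network by how well its degree distribution fits a
power law (R^2 of an OLS line in log10-log10 space), keeping the most
lenient cutoff whose R^2 meets the configured requirement (0.88 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import benjamini_hochberg
from .io import get_logger
from .types import ValidationError

log = get_logger("devcoexpr.network")


@dataclass
class CorrelationTable:
    """One row per unordered pair of distinct selected genes.

    Columns: gene_a, gene_b (gene_a < gene_b lexicographically), r, n and,
    once filled, p and q.  Pairs where either gene has zero variance carry
    r = NaN and are excluded from testing.
    """

    pairs: pd.DataFrame

    @property
    def tested(self) -> pd.DataFrame:
        return self.pairs[self.pairs.r.notna()]


def pairwise_pcc(norm: pd.DataFrame, genes: list[str]) -> CorrelationTable:
    """Pearson correlation for every unordered pair of the selected genes."""
    n = norm.shape[1]
    if n < 3:
        raise ValidationError(f"need >= 3 samples for correlation, have {n}")
    missing = [g for g in genes if g not in norm.index]
    if missing:
        raise ValidationError(f"selected gene {missing[0]!r} not in matrix")
    x = norm.loc[genes].to_numpy(dtype=float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.clip(corr, -1.0, 1.0)
    zero_var = sd == 0
    corr[zero_var, :] = np.nan
    corr[:, zero_var] = np.nan
    iu, ju = np.triu_indices(len(genes), k=1)
    ga = np.asarray(genes, dtype=object)[iu]
    gb = np.asarray(genes, dtype=object)[ju]
    swap = ga > gb
    ga[swap], gb[swap] = gb[swap], ga[swap]
    table = pd.DataFrame(
        {
            "gene_a": ga,
            "gene_b": gb,
            "r": corr[iu, ju],
            "n": n,
            "p": np.nan,
            "q": np.nan,
        }
    )
    n_undef = int(table.r.isna().sum())
    if n_undef:
        log.warning("%d gene pairs have undefined correlation (zero variance)", n_undef)
    return CorrelationTable(table)


def pcc_pvalues(table: CorrelationTable) -> CorrelationTable:
    """Fill exact two-sided p-values via the t transform (df = n - 2)."""
    df = table.pairs
    r = df.r.to_numpy()
    n = df.n.to_numpy()
    if np.any(n[~np.isnan(r)] < 3):
        raise ValidationError("p-values require n >= 3 per pair")
    p = np.full(len(df), np.nan)
    ok = ~np.isnan(r)
    edge = ok & (np.abs(r) >= 1.0)
    p[edge] = 0.0
    mid = ok & ~edge
    t = r[mid] * np.sqrt((n[mid] - 2) / (1.0 - r[mid] ** 2))
    p[mid] = 2.0 * stats.t.sf(np.abs(t), n[mid] - 2)
    df = df.assign(p=p)
    return CorrelationTable(df)


def adjust_and_select(table: CorrelationTable, cutoff: float) -> pd.DataFrame:
    """Pooled BH over all tested pairs; rows with q <= cutoff survive."""
    df = table.pairs
    tested = df.p.notna()
    q = np.full(len(df), np.nan)
    if tested.any():
        q[tested.to_numpy()] = benjamini_hochberg(df.p[tested].to_numpy())
    df = df.assign(q=q)
    table.pairs = df
    return df[(df.q <= cutoff) & tested]


def build_network(table: CorrelationTable, cutoff: float) -> nx.Graph:
    """Simple graph whose nodes are genes incident to >= 1 surviving edge."""
    edges = adjust_and_select(table, cutoff)
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        if row.gene_a == row.gene_b:
            continue
        g.add_edge(row.gene_a, row.gene_b, r=float(row.r), q=float(row.q))
    return g


def degree_distribution(network: nx.Graph) -> dict[int, int]:
    """Histogram degree k -> node count, over nodes with k >= 1."""
    hist: dict[int, int] = {}
    for _, k in network.degree():
        if k >= 1:
            hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


def powerlaw_r2(hist: dict[int, int], bins_per_decade: int | None = 3) -> float | None:
    """R^2 of an OLS power-law fit to the degree histogram in log-log space.

    By default degrees are pooled into logarithmic bins (``bins_per_decade``
    bins per factor of ten) and the fit is of log10 bin density on log10
    bin center: per-degree counts in the sparse tail of a heavy-tailed
    histogram are almost all 1, and a single stray minimum-degree node can
    otherwise dominate the regression.  ``bins_per_decade=None`` fits the
    raw per-degree counts instead (log10 P(k) on log10 k over degrees with
    P(k) > 0).  Returns None (undefined) with fewer than 3 distinct
    degrees or bins.
    """
    ks = sorted(k for k, c in hist.items() if c > 0 and k >= 1)
    if len(ks) < 3:
        return None
    if bins_per_decade is None:
        x = np.log10(ks)
        y = np.log10([hist[k] for k in ks])
    else:
        karr = np.asarray(ks, dtype=float)
        carr = np.asarray([hist[k] for k in ks], dtype=float)
        span = np.log10(karr[-1]) - np.log10(karr[0])
        n_bins = max(3, int(np.ceil((span + 1e-9) * bins_per_decade)))
        edges = np.logspace(np.log10(karr[0]), np.log10(karr[-1]), n_bins + 1)
        edges[-1] *= 1.0000001
        xs, ys = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (karr >= lo) & (karr < hi)
            if not m.any():
                continue
            xs.append(np.sqrt(lo * hi))  # geometric bin center
            ys.append(carr[m].sum() / max(hi - lo, 1.0))  # count density
        if len(xs) < 3:
            return None
        x = np.log10(xs)
        y = np.log10(ys)
    if np.allclose(y, y[0]):
        # horizontal line: perfectly fit, but carries no power-law signal
        return 0.0
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2)


@dataclass
class ThresholdScan:
    """Scan of significance cutoffs against scale-free topology fit."""

    rows: pd.DataFrame  # columns: cutoff, n_nodes, n_edges, r2
    selected_cutoff: float
    qualified: bool  # True if selected cutoff met the R^2 requirement


def scan_cutoffs(
    table: CorrelationTable,
    grid,
    r2_requirement: float = 0.88,
) -> ThresholdScan:
    """Score every cutoff in the grid; select the most lenient qualifying one.

    The grid is evaluated from most lenient (largest) to most stringent.
    The selected cutoff is the most lenient one whose degree-distribution
    power-law R^2 meets ``r2_requirement``; if none qualifies the grid's
    best-R^2 cutoff is returned with ``qualified=False``.
    """
    grid = sorted({float(c) for c in grid}, reverse=True)
    if not grid:
        raise ValidationError("cutoff grid must be non-empty")
    records = []
    for cutoff in grid:
        g = build_network(table, cutoff)
        r2 = powerlaw_r2(degree_distribution(g))
        records.append(
            {
                "cutoff": cutoff,
                "n_nodes": g.number_of_nodes(),
                "n_edges": g.number_of_edges(),
                "r2": np.nan if r2 is None else r2,
            }
        )
    rows = pd.DataFrame(records)
    qualifying = rows[(rows.r2.notna()) & (rows.r2 >= r2_requirement)]
    if len(qualifying):
        selected = float(qualifying.iloc[0].cutoff)  # most lenient first
        qualified = True
    else:
        if rows.r2.notna().any():
            selected = float(rows.loc[rows.r2.idxmax()].cutoff)
        else:
            selected = grid[0]
        qualified = False
        log.warning(
            "no cutoff reached R^2 >= %.3f; falling back to best-R^2 cutoff %g",
            r2_requirement, selected,
        )
    return ThresholdScan(rows, selected, qualified)


def connected_components(network: nx.Graph) -> tuple[list[set], float | None]:
    """Components (largest first) and giant-component node fraction."""
    comps = sorted(nx.connected_components(network), key=len, reverse=True)
    if not comps:
        return [], None
    return comps, len(comps[0]) / network.number_of_nodes()


def average_degree(network: nx.Graph) -> float:
    """2|E| / |V|; the published worked example is 2*3655/682 = 10.7."""
    n = network.number_of_nodes()
    if n == 0:
        raise ValidationError("average degree is undefined for an empty network")
    return 2.0 * network.number_of_edges() / n
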