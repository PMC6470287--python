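"""Whole-brain functional connectivity and group network statistics.

Pipeline: per-run region x region Pearson correlation matrices, Fisher
z-transform, edgewise two-group comparison (BS vs SW) with subject indicator
covariates, Hedges' g effect sizes, family-wise-error control over connected
components of suprathreshold edges (the network-based statistic, NBS), and a
lobe-block analysis that asks whether the significant ("disrupted") edges
concentrate in particular lobe pairs beyond what their share of possible
edges predicts (standardized residual Z with a uniform-placement permutation
null).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse import csgraph

from ._glm import DesignError, check_full_rank, subject_dummies
from .preproc import BOLDRun


@dataclass
class FCMatrix:
    """Symmetric region x region connectivity matrix (Pearson r or Fisher z)."""

    values: np.ndarray
    region_labels: list[str]
    scale: str = "r"
    subject: str = ""
    group: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.region_labels)
        if self.values.shape != (p, p):
            raise ValueError("matrix shape must match region labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if self.scale not in ("r", "z"):
            raise ValueError("scale must be 'r' or 'z'")
        if self.scale == "r":
            if not np.allclose(np.diag(self.values), 1.0):
                raise ValueError("r-scale matrix must have unit diagonal")
            if np.any(np.abs(self.values) > 1 + 1e-12):
                raise ValueError("|r| must not exceed 1")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


@dataclass
class EdgeGroupStats:
    """Edgewise BS-vs-SW statistics with component-level (NBS) correction.

    All per-edge arrays follow the upper-triangle order of
    :func:`edge_index`.  ``component_labels`` is -1 for edges outside any
    suprathreshold component; ``component_pvalues`` maps component label to
    its family-wise-corrected permutation p-value.
    """

    region_labels: list[str]
    tstats: np.ndarray
    pvalues: np.ndarray
    hedges_g: np.ndarray
    direction: np.ndarray
    significant: np.ndarray
    component_labels: np.ndarray
    component_pvalues: dict[int, float]
    n_bs: int
    n_sw: int
    edge_alpha: float = 0.001
    cluster_alpha: float = 0.05
    n_perm: int = 0

    def significance_matrix(self) -> np.ndarray:
        """Square boolean matrix of NBS-significant edges."""
        p = len(self.region_labels)
        iu = np.triu_indices(p, 1)
        m = np.zeros((p, p), dtype=bool)
        m[iu] = self.significant
        return m | m.T

    def to_frame(self) -> pd.DataFrame:
        p = len(self.region_labels)
        i, j = np.triu_indices(p, 1)
        return pd.DataFrame(
            {
                "region_i": [self.region_labels[a] for a in i],
                "region_j": [self.region_labels[b] for b in j],
                "t": self.tstats,
                "p": self.pvalues,
                "hedges_g": self.hedges_g,
                "direction": self.direction,
                "significant": self.significant,
                "component": self.component_labels,
            }
        )


def edge_index(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i, j) indices defining the canonical edge order."""
    return np.triu_indices(n_regions, 1)


def fc_matrix(run: BOLDRun) -> FCMatrix:
    """Pearson correlation between all parcel pairs of a preprocessed run."""
    if run.n_volumes < 3:
        raise ValueError("need at least 3 volumes")
    sd = run.data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [run.region_labels[i] for i in dead]
        raise ValueError(f"zero-variance parcels: {names}")
    vals = np.corrcoef(run.data)
    np.fill_diagonal(vals, 1.0)
    return FCMatrix(
        values=vals,
        region_labels=list(run.region_labels),
        scale="r",
        subject=run.subject,
        group=run.group,
        run_id=run.run_id,
    )


def fisher_z(m: FCMatrix) -> FCMatrix:
    """Fisher z (atanh) variance-stabilizing transform; diagonal set to 0."""
    if m.scale != "r":
        raise ValueError("fisher_z expects an r-scale matrix")
    off = ~np.eye(m.n_regions, dtype=bool)
    if np.any(np.abs(m.values[off]) >= 1.0):
        i, j = np.where(off & (np.abs(m.values) >= 1.0))
        edge = (m.region_labels[i[0]], m.region_labels[j[0]])
        raise ValueError(f"|r| = 1 at edge {edge}: Fisher z is infinite")
    vals = np.arctanh(m.values * off)
    return FCMatrix(
        values=vals,
        region_labels=list(m.region_labels),
        scale="z",
        subject=m.subject,
        group=m.group,
        run_id=m.run_id,
    )


def hedges_g(x: np.ndarray, y: np.ndarray) -> float:
    """Hedges' g: bias-corrected standardized mean difference.

    ``g = J * (mean_x - mean_y) / s_pooled`` with
    ``J = 1 - 3 / (4 (n_x + n_y) - 9)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx_, ny_ = len(x), len(y)
    if nx_ < 2 or ny_ < 2:
        raise ValueError("both samples need at least 2 observations")
    s2 = ((nx_ - 1) * x.var(ddof=1) + (ny_ - 1) * y.var(ddof=1)) / (nx_ + ny_ - 2)
    if s2 == 0:
        raise ValueError("undefined effect size: zero pooled variance")
    j = 1.0 - 3.0 / (4.0 * (nx_ + ny_) - 9.0)
    return float(j * (x.mean() - y.mean()) / np.sqrt(s2))


def _stack_edges(matrices: list[FCMatrix]) -> tuple[np.ndarray, list[str]]:
    labels = matrices[0].region_labels
    for m in matrices:
        if m.region_labels != labels:
            raise ValueError("all matrices must share the same parcellation")
    i, j = edge_index(len(labels))
    Y = np.stack([m.values[i, j] for m in matrices])
    return Y, labels


def _group_design(groups: list[str], subjects: list[str]) -> np.ndarray:
    g = np.asarray([1.0 if x == "BS" else 0.0 for x in groups])
    dummies, names = subject_dummies(subjects)
    X = np.column_stack([np.ones(len(groups)), g, dummies])
    check_full_rank(X, ["intercept", "group", *names])
    return X

def _group_t(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """t statistic of the group column (index 1) for every edge column of Y."""
    n, k = X.shape
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - k)
    scale = np.einsum("ij,ij->j", Y, Y) / n
    sigma2 = np.where(sigma2 <= 1e-24 * (scale + 1.0), 0.0, sigma2)
    se = np.sqrt(xtx_inv[1, 1] * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(se > 0, beta[1] / se, 0.0)


def edgewise_group_stats(
    matrices: list[FCMatrix],
    groups: list[str] | None = None,
    subjects: list[str] | None = None,
) -> pd.DataFrame:
    """Per-edge BS-vs-SW regression with subject covariates, plus Hedges' g.

    The regression runs on Fisher-z values (matrices passed on the r scale are
    transformed); Hedges' g is computed on the raw correlation samples.
    Returns a long-format frame with one row per upper-triangle edge.
    """
    groups = groups if groups is not None else [m.group for m in matrices]
    subjects = subjects if subjects is not None else [m.subject for m in matrices]
    if len({*groups}) < 2:
        raise DesignError("both groups must be present")
    zmats = [fisher_z(m) if m.scale == "r" else m for m in matrices]
    rmats = [m if m.scale == "r" else None for m in matrices]
    Y, labels = _stack_edges(zmats)
    X = _group_design(groups, subjects)
    n, k = X.shape
    t = _group_t(X, Y)
    p = 2.0 * stats.t.sf(np.abs(t), n - k)
    is_bs = np.asarray([g == "BS" for g in groups])
    if all(r is not None for r in rmats):
        R, _ = _stack_edges(rmats)
    else:
        R = np.tanh(Y)
    g_vals = np.array(
        [hedges_g(R[is_bs, e], R[~is_bs, e]) if R[:, e].std() > 0 else 0.0
         for e in range(Y.shape[1])]
    )
    i, j = edge_index(len(labels))
    return pd.DataFrame(
        {
            "region_i": [labels[a] for a in i],
            "region_j": [labels[b] for b in j],
            "t": t,
            "p": p,
            "hedges_g": g_vals,
            "direction": np.sign(t).astype(int),
        }
    )


def _restricted_permutation(
    rng: np.random.Generator, groups: np.ndarray, subjects: np.ndarray
) -> np.ndarray:
    """Permute group labels within subject strata (covariate-respecting null)."""
    out = groups.copy()
    for s in np.unique(subjects):
        idx = np.flatnonzero(subjects == s)
        out[idx] = groups[idx[rng.permutation(idx.size)]]
    return out


def _max_component_and_labels(
    t: np.ndarray, thresh: float, n_regions: int
) -> tuple[int, np.ndarray, np.ndarray]:
    """Component structure of the suprathreshold |t| graph.

    Returns (max component edge count, per-edge component label (-1 outside),
    per-component edge counts indexed by label).
    """
    i, j = edge_index(n_regions)
    supra = np.abs(t) > thresh
    edge_labels = np.full(t.size, -1, dtype=int)
    if not supra.any():
        return 0, edge_labels, np.zeros(0, dtype=int)
    adj = sparse.coo_matrix(
        (np.ones(supra.sum()), (i[supra], j[supra])), shape=(n_regions, n_regions)
    )
    n_comp, node_labels = csgraph.connected_components(adj + adj.T, directed=False)
    comp_of_edge = node_labels[i[supra]]
    edge_labels[supra] = comp_of_edge
    counts = np.bincount(comp_of_edge, minlength=n_comp)
    return int(counts.max()), edge_labels, counts


def nbs_correction(
    matrices: list[FCMatrix],
    groups: list[str] | None = None,
    subjects: list[str] | None = None,
    edge_alpha: float = 0.001,
    cluster_alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
) -> EdgeGroupStats:
    """Network-based statistic: component-extent permutation correction.

    Edges with two-sided ``p < edge_alpha`` on the group coefficient form a
    graph; connected components are scored by edge count; the null for the
    maximal component size is rebuilt by permuting group labels within subject
    strata.  Component p-values use the (1 + exceedances) / (1 + n_perm)
    convention.  Edges in components with ``p < cluster_alpha`` are flagged,
    signed by the group coefficient.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    groups = groups if groups is not None else [m.group for m in matrices]
    subjects = subjects if subjects is not None else [m.subject for m in matrices]
    zmats = [fisher_z(m) if m.scale == "r" else m for m in matrices]
    Y, labels = _stack_edges(zmats)
    X = _group_design(groups, subjects)
    n, k = X.shape
    df = n - k
    thresh = stats.t.ppf(1 - edge_alpha / 2, df)
    t_obs = _group_t(X, Y)
    p_obs = 2.0 * stats.t.sf(np.abs(t_obs), df)
    n_regions = len(labels)
    _, edge_labels, comp_sizes = _max_component_and_labels(t_obs, thresh, n_regions)

    rng = np.random.default_rng(seed)
    g_arr = np.asarray(groups, dtype=object)
    s_arr = np.asarray(subjects, dtype=object)
    null_max = np.empty(n_perm)
    Xp = X.copy()
    for b in range(n_perm):
        gp = _restricted_permutation(rng, g_arr, s_arr)
        Xp[:, 1] = [1.0 if x == "BS" else 0.0 for x in gp]
        t_perm = _group_t(Xp, Y)
        null_max[b], _, _ = _max_component_and_labels(t_perm, thresh, n_regions)

    comp_p: dict[int, float] = {}
    for lab, size in enumerate(comp_sizes):
        if size > 0:
            comp_p[lab] = (1.0 + np.sum(null_max >= size)) / (1.0 + n_perm)
    sig_comps = {lab for lab, pv in comp_p.items() if pv < cluster_alpha}
    significant = np.isin(edge_labels, list(sig_comps)) if sig_comps else np.zeros(
        t_obs.size, dtype=bool
    )

    # Hedges' g on the raw correlation scale
    rvals = np.tanh(Y)
    is_bs = np.asarray([g == "BS" for g in groups])
    g_vals = np.array(
        [
            hedges_g(rvals[is_bs, e], rvals[~is_bs, e]) if rvals[:, e].std() > 0 else 0.0
            for e in range(Y.shape[1])
        ]
    )
    return EdgeGroupStats(
        region_labels=list(labels),
        tstats=t_obs,
        pvalues=p_obs,
        hedges_g=g_vals,
        direction=np.sign(t_obs).astype(int),
        significant=significant,
        component_labels=edge_labels,
        component_pvalues=comp_p,
        n_bs=int(is_bs.sum()),
        n_sw=int((~is_bs).sum()),
        edge_alpha=edge_alpha,
        cluster_alpha=cluster_alpha,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# lobe-block analysis of significant edges


def load_partition(path=None) -> pd.Series:
    """Region -> lobe mapping.

    With no path, loads the packaged 94-region table (a constructed,
    synthetic Regional-Map-style parcellation: 82 cortical + 12 subcortical
    labels grouped into nine lobes); any user table with ``region`` and
    ``lobe`` columns can substitute for it.
    """
    if path is None:
        ref = resources.files("bsfc") / "data" / "regions94_synthetic.tsv"
        with resources.as_file(ref) as f:
            df = pd.read_csv(f, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if df["region"].duplicated().any():
        raise ValueError("duplicate region labels in partition table")
    return df.set_index("region")["lobe"]


def _as_edge_mask(sig_mask: np.ndarray, n_regions: int) -> np.ndarray:
    sig_mask = np.asarray(sig_mask)
    if sig_mask.ndim == 2:
        if sig_mask.shape != (n_regions, n_regions):
            raise ValueError("mask shape must match the parcellation")
        i, j = edge_index(n_regions)
        return sig_mask[i, j].astype(bool)
    return sig_mask.astype(bool)


def _edge_blocks(region_labels: list[str], partition: pd.Series):
    """Block id per upper-triangle edge plus the block bookkeeping tables."""
    missing = [r for r in region_labels if r not in partition.index]
    if missing:
        raise ValueError(f"partition does not cover regions: {missing[:5]}")
    lobes = partition.loc[list(region_labels)].to_numpy()
    lobe_names = sorted(set(lobes))
    lobe_idx = {name: a for a, name in enumerate(lobe_names)}
    n_lobes = len(lobe_names)
    pair_id = {}
    pairs = []
    for a in range(n_lobes):
        for b in range(a, n_lobes):
            pair_id[(a, b)] = len(pairs)
            pairs.append((lobe_names[a], lobe_names[b]))
    i, j = edge_index(len(region_labels))
    li = np.array([lobe_idx[lobes[a]] for a in i])
    lj = np.array([lobe_idx[lobes[b]] for b in j])
    lo, hi = np.minimum(li, lj), np.maximum(li, lj)
    edge_block = np.array([pair_id[(a, b)] for a, b in zip(lo, hi)])
    m_b = np.bincount(edge_block, minlength=len(pairs))
    return edge_block, pairs, m_b


def lobe_block_residuals(
    sig_mask: np.ndarray, partition: pd.Series, region_labels: list[str]
) -> pd.DataFrame:
    """Observed vs expected significant-edge counts per lobe-pair block.

    For each unordered lobe pair (including within-lobe blocks), the observed
    count O of significant edges is compared with the expectation
    ``E = D * m_b / M`` under uniform placement of the D significant edges
    among the M possible edges, and standardized as ``Z = (O - E) / sqrt(E)``.
    """
    edge_mask = _as_edge_mask(sig_mask, len(region_labels))
    D = int(edge_mask.sum())
    if D == 0:
        raise ValueError("no disrupted edges: block residuals undefined")
    edge_block, pairs, m_b = _edge_blocks(region_labels, partition)
    M = edge_block.size
    O = np.bincount(edge_block[edge_mask], minlength=len(pairs)).astype(float)
    E = D * m_b / M
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(E > 0, (O - E) / np.sqrt(E), 0.0)
    return pd.DataFrame(
        {
            "lobe_i": [p[0] for p in pairs],
            "lobe_j": [p[1] for p in pairs],
            "observed": O,
            "expected": E,
            "z": Z,
            "possible_edges": m_b,
        }
    )


def lobe_block_permutation(
    sig_mask: np.ndarray,
    partition: pd.Series,
    region_labels: list[str],
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation p-values for the lobe-block standardized residuals.

    Each permutation re-places the D significant edges uniformly at random
    (without replacement) among all M possible edges and recomputes each
    block's Z.  ``p = #{perm Z >= observed Z} / n_perm`` (the literal
    exceedance percentage), Bonferroni-corrected over the number of blocks.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    res = lobe_block_residuals(sig_mask, partition, region_labels)
    edge_mask = _as_edge_mask(sig_mask, len(region_labels))
    D = int(edge_mask.sum())
    edge_block, pairs, m_b = _edge_blocks(region_labels, partition)
    M = edge_block.size
    if D > M:
        raise ValueError("more disrupted edges than possible edges")
    E = res["expected"].to_numpy()
    z_obs = res["z"].to_numpy()
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(pairs))
    sqrtE = np.where(E > 0, np.sqrt(E), 1.0)
    for _ in range(n_perm):
        placed = rng.choice(M, size=D, replace=False)
        O_perm = np.bincount(edge_block[placed], minlength=len(pairs))
        z_perm = np.where(E > 0, (O_perm - E) / sqrtE, 0.0)
        exceed += z_perm >= z_obs
    res = res.copy()
    res["p"] = exceed / n_perm
    res["significant"] = res["p"] < alpha / len(pairs)
    return res


def mean_offdiag_fc(matrices: list[FCMatrix]) -> float:
    """Mean upper-triangle correlation across a list of r-scale matrices."""
    Y, _ = _stack_edges(matrices)
    return float(Y.mean())


def component_graph(stats_: EdgeGroupStats) -> nx.Graph:
    """NetworkX graph of the NBS-significant edges (regions as nodes)."""
    g = nx.Graph()
    g.add_nodes_from(stats_.region_labels)
    i, j = edge_index(len(stats_.region_labels))
    for a, b, sig, t in zip(i, j, stats_.significant, stats_.tstats):
        if sig:
            g.add_edge(stats_.region_labels[a], stats_.region_labels[b], t=float(t))
    return g
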