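"""Least-squares admixture-graph fitting and greedy leaf addition.

The model: each leaf's allele frequency is the root frequency plus
independent increments on the drift edges its lineage traverses, an
admixture node routing the lineage to its first parent with probability
alpha. Expected f2 between leaves A and B is then

    E f2(A, B) = sum_e c_e (w_A(e) - w_B(e))^2

with w_X(e) the probability that X's lineage uses edge e and c_e the edge's
drift length in f2 units (the root heterozygosity scale is absorbed into
the c's). Drift lengths are bounded below by 0, mixing weights to [0, 1];
fitted zero-length branches are reported, not errors. A topology's score is
the number of observed statistics whose residual exceeds 2 standard errors
(fewer is better).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .fstats import AlleleCounts, BlockPartition, f2 as f2_stat
from .graph import AdmixtureGraph

__all__ = ["GraphFit", "fit_graph", "greedy_add_leaf", "observed_f2"]


def observed_f2(
    counts: AlleleCounts,
    pops: list[str],
    partition: BlockPartition,
    corrected: bool = True,
) -> tuple[dict, dict]:
    """f2 estimates and jackknife SEs for every unordered pair of pops."""
    est, se = {}, {}
    for a, b in itertools.combinations(pops, 2):
        r = f2_stat(counts, a, b, partition, corrected=corrected)
        est[(a, b)] = r.estimate
        se[(a, b)] = r.se
    return est, se


def _path_structure(graph: AdmixtureGraph):
    """Per leaf: all lineage paths as (admixture choices, drift edges).

    Choices are (admixture node, side) with side 0 = first parent (weight
    alpha); probabilities are left symbolic so alphas can vary during the
    fit.
    """
    structure = {}
    for leaf in graph.leaves:
        paths = []

        def walk(node, choices, edges_acc):
            if node == graph.root:
                paths.append((list(choices), list(edges_acc)))
                return
            if node in graph.admixtures:
                pa, pb, _ = graph.admixtures[node]
                walk(pa, choices + [(node, 0)], edges_acc)
                walk(pb, choices + [(node, 1)], edges_acc)
            else:
                parent, _ = graph.drift_parent(node)
                walk(parent, choices, edges_acc + [(parent, node)])

        walk(leaf, [], [])
        structure[leaf] = paths
    return structure


@dataclass
class GraphFit:
    graph: AdmixtureGraph  # topology with fitted drift lengths and weights
    edge_lengths: dict[tuple[str, str], float]
    admix_weights: dict[str, float]
    residual_z: dict[tuple[str, str], float]
    score: int  # count of |z| > 2
    resid_sum: float
    param_se: dict[str, float] = field(default_factory=dict)
    null_space_dim: int = 0
    label: str = ""

    @property
    def all_internal_positive(self) -> bool:
        leaves = set(self.graph.leaves)
        return all(
            c > 1e-8
            for (u, v), c in self.edge_lengths.items()
            if v not in leaves
        )


def fit_graph(
    topology: AdmixtureGraph,
    f2_obs: dict[tuple[str, str], float],
    f2_se: dict[tuple[str, str], float],
    seed: int = 0,
    n_restarts: int = 3,
) -> GraphFit:
    """Fit drift lengths and admixture weights to observed leaf-pair f2.

    Bounded nonlinear least squares of (expected - observed)/SE with a few
    restarts over mixing-weight starting points. Non-identifiable
    parameter combinations are reported through ``null_space_dim`` (the
    rank deficiency of the Jacobian at the solution), not raised.
    """
    edges = [(p, c) for p, c, _ in topology.edges]
    admix_nodes = sorted(topology.admixtures)
    structure = _path_structure(topology)
    leaves = topology.leaves
    pairs = [
        (a, b) for a, b in itertools.combinations(leaves, 2)
        if (a, b) in f2_obs or (b, a) in f2_obs
    ]
    if not pairs:
        raise ValueError("no observed f2 values match the topology's leaves")

    def key(a, b):
        return (a, b) if (a, b) in f2_obs else (b, a)

    obs = np.array([f2_obs[key(a, b)] for a, b in pairs])
    sigma = np.array([max(f2_se[key(a, b)], 1e-12) for a, b in pairs])

    ne, na = len(edges), len(admix_nodes)

    def usage_matrix(alphas):
        aw = dict(zip(admix_nodes, alphas))
        U = np.zeros((len(leaves), ne))
        eidx = {e: i for i, e in enumerate(edges)}
        for li, leaf in enumerate(leaves):
            for choices, path_edges in structure[leaf]:
                prob = 1.0
                for node, side in choices:
                    prob *= aw[node] if side == 0 else 1.0 - aw[node]
                for e in path_edges:
                    U[li, eidx[e]] += prob
        return U

    lidx = {l: i for i, l in enumerate(leaves)}

    def residuals(params):
        c = params[:ne]
        alphas = params[ne:]
        U = usage_matrix(alphas)
        exp = np.array(
            [((U[lidx[a]] - U[lidx[b]]) ** 2 @ c) for a, b in pairs]
        )
        return (exp - obs) / sigma

    scale = max(float(np.mean(np.abs(obs))), 1e-6)
    lb = np.concatenate([np.zeros(ne), np.zeros(na)])
    ub = np.concatenate([np.full(ne, np.inf), np.ones(na)])
    rng = np.random.default_rng(seed)
    best = None
    for t in range(max(1, n_restarts)):
        alpha0 = (
            np.full(na, 0.5) if t == 0 else rng.uniform(0.15, 0.85, size=na)
        )
        x0 = np.concatenate([np.full(ne, scale / 2), alpha0])
        res = least_squares(residuals, x0, bounds=(lb, ub), method="trf")
        if best is None or res.cost < best.cost:
            best = res
    res = best
    c_fit = dict(zip(edges, res.x[:ne]))
    a_fit = dict(zip(admix_nodes, res.x[ne:]))

    z = {}
    r = residuals(res.x)
    for (a, b), ri in zip(pairs, r):
        z[(a, b)] = float(-ri)  # (obs - exp)/se
    score = int(sum(abs(v) > 2 for v in z.values()))

    J = res.jac
    rank = np.linalg.matrix_rank(J, tol=1e-8)
    cov = np.linalg.pinv(J.T @ J)
    ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    param_se = {f"c:{p}->{cld}": float(s) for (p, cld), s in zip(edges, ses[:ne])}
    param_se.update(
        {f"alpha:{n}": float(s) for n, s in zip(admix_nodes, ses[ne:])}
    )

    fitted = AdmixtureGraph(
        [(p, cld, float(c_fit[(p, cld)])) for p, cld in edges],
        {
            n: (topology.admixtures[n][0], topology.admixtures[n][1],
                float(a_fit[n]))
            for n in admix_nodes
        },
    )
    return GraphFit(
        fitted, {e: float(v) for e, v in c_fit.items()},
        {n: float(v) for n, v in a_fit.items()},
        z, score, float(2 * res.cost), param_se,
        null_space_dim=int(J.shape[1] - rank),
    )


def _split_edge(edges, edge, mid):
    """Replace (u, v) by (u, mid), (mid, v), splitting its length."""
    out = []
    for p, c, d in edges:
        if (p, c) == edge:
            out.append((p, mid, d / 2))
            out.append((mid, c, d / 2))
        else:
            out.append((p, c, d))
    return out


def greedy_add_leaf(
    base: AdmixtureGraph,
    new_leaf: str,
    f2_obs: dict[tuple[str, str], float],
    f2_se: dict[tuple[str, str], float],
    seed: int = 0,
    init_drift: float = 0.005,
) -> list[GraphFit]:
    """All single-edge and two-edge (admixed) attachments of a new leaf,
    refit and ranked by (score, all-positive internal branches, number of
    admixture events, residual sum). The parsimony key keeps an admixed
    attachment from beating a plain one purely by absorbing noise with its
    extra parameters. The search is greedy: the outcome can depend on the
    order in which leaves are added.
    """
    if new_leaf in base.leaves:
        raise ValueError(f"{new_leaf!r} is already a leaf")
    candidates = []
    drift_edges = [(p, c) for p, c, _ in base.edges]

    for e in drift_edges:
        mid = f"split_{e[0]}_{e[1]}"
        edges = _split_edge(base.edges, e, mid)
        edges.append((mid, new_leaf, init_drift))
        g = AdmixtureGraph(edges, dict(base.admixtures))
        candidates.append((f"edge:{e[0]}->{e[1]}", g))

    for e1, e2 in itertools.combinations(drift_edges, 2):
        m1 = f"split1_{e1[0]}_{e1[1]}"
        m2 = f"split2_{e2[0]}_{e2[1]}"
        edges = _split_edge(base.edges, e1, m1)
        edges = _split_edge(edges, e2, m2)
        adm = f"adm_{new_leaf}"
        admixtures = dict(base.admixtures)
        admixtures[adm] = (m1, m2, 0.5)
        edges.append((adm, new_leaf, init_drift))
        g = AdmixtureGraph(edges, admixtures)
        candidates.append(
            (f"admix:{e1[0]}->{e1[1]}+{e2[0]}->{e2[1]}", g)
        )

    fits = []
    for label, g in candidates:
        fit = fit_graph(g, f2_obs, f2_se, seed=seed, n_restarts=2)
        fit.label = label
        fits.append(fit)
    fits.sort(
        key=lambda f: (
            f.score,
            not f.all_internal_positive,
            len(f.graph.admixtures),
            f.resid_sum,
        )
    )
    return fits
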