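"""Generalized mixed Yule-coalescent (GMYC) species delimitation.

The GMYC model explains an ultrametric single-locus gene tree as the mix of
two branching processes: a Yule-like diversification process among species
lineages and neutral coalescence within each delimited unit.  Ordering the
n-1 branching events by age partitions the tree into inter-event intervals;
during interval i the total branching rate is

    b_i = lambda_div * k_i**p_div
        + lambda_coal * sum_j (m_ij * (m_ij - 1))**p_coal

with k_i the number of species-level lineages crossing the interval and
m_ij the number of gene lineages inside delimited unit j.  Each interval of
duration x_i ending in an event contributes ln(b_i) - b_i * x_i to the log
likelihood (the waiting-time density of the pooled process, with the event
term taken at the total rate).  The null model is a single coalescent
process over all lineages, b_i = lambda * (n_i (n_i - 1))**p, which is the
labeling with no speciation node at all.

The single-threshold fit scans every age threshold (nodes older than the
threshold labeled speciation, younger coalescent), maximising the
likelihood over the four rate/exponent parameters at each candidate; the
branches crossing the best threshold delimit the units.  The
multiple-threshold fit relaxes the assumption that speciation predates all
coalescence: starting from the single-threshold labeling it hill-climbs by
relabeling single nodes (splitting a unit at a node, or fusing units by
demoting a speciation node) while any move strictly improves the
likelihood.  A likelihood-ratio test against the null uses a chi-square
reference with 3 degrees of freedom by default.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize
from scipy.stats import chi2

from .distance_delim import Partition
from .distances import DistMatrix

logger = logging.getLogger("barcodescope")

ULTRAMETRIC_TOL = 1e-9


class TreeError(ValueError):
    """Raised for invalid tree input."""


# ---------------------------------------------------------------------------
# Ultrametric trees
# ---------------------------------------------------------------------------

class TreeNode:
    """Node of a rooted ultrametric tree; tips have age 0."""

    __slots__ = ("age", "children", "parent", "label", "preorder")

    def __init__(self, age: float, children=None, label: str | None = None):
        self.age = float(age)
        self.children: list[TreeNode] = list(children or [])
        self.parent: TreeNode | None = None
        self.label = label
        self.preorder = -1

    @property
    def is_tip(self) -> bool:
        return not self.children


class UltraTree:
    """Rooted binary ultrametric tree with node ages (tips at age 0)."""

    def __init__(self, root: TreeNode, tol: float = 1e-6):
        self.root = root
        self._index(tol)

    def _index(self, tol: float) -> None:
        self.nodes: list[TreeNode] = []
        stack = [self.root]
        self.root.parent = None
        while stack:
            node = stack.pop()
            node.preorder = len(self.nodes)
            self.nodes.append(node)
            for child in reversed(node.children):
                child.parent = node
                stack.append(child)
        self.tips = [n for n in self.nodes if n.is_tip]
        self.internal = [n for n in self.nodes if not n.is_tip]
        for node in self.internal:
            if len(node.children) != 2:
                raise TreeError("tree must be strictly bifurcating")
            for child in node.children:
                if child.age > node.age + tol:
                    raise TreeError("node ages must not increase toward the tips")
        for tip in self.tips:
            if abs(tip.age) > tol:
                raise TreeError("tip ages must be 0 (ultrametric tree)")
            tip.age = 0.0
        labels = [t.label for t in self.tips]
        if None in labels or len(set(labels)) != len(labels):
            raise TreeError("tips must carry unique labels")
        if self.root.age <= 0:
            raise TreeError("root age must be positive")

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips]

    def events(self) -> list[TreeNode]:
        """Internal nodes sorted youngest-first, ties by preorder (stable)."""
        return sorted(self.internal, key=lambda n: (n.age, n.preorder))

    # -- Newick round-trip (node ages encoded as branch lengths) -----------

    def to_newick(self) -> str:
        def fmt(node: TreeNode, parent_age: float | None) -> str:
            if node.is_tip:
                body = node.label
            else:
                body = "(" + ",".join(fmt(c, node.age) for c in node.children) + ")"
            if parent_age is None:
                return body
            return f"{body}:{parent_age - node.age:.12g}"

        return fmt(self.root, None) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, newick: str, tol: float = 1e-6) -> "UltraTree":
        import dendropy

        dtree = dendropy.Tree.get(data=newick, schema="newick")
        depths = {}
        for dnode in dtree.preorder_node_iter():
            edge = dnode.edge.length or 0.0
            parent = dnode.parent_node
            depths[dnode] = (depths[parent] if parent is not None else 0.0) + edge
        tip_depths = [depths[leaf] for leaf in dtree.leaf_node_iter()]
        height = max(tip_depths)
        if height - min(tip_depths) > tol:
            raise TreeError(
                f"input tree is not ultrametric (tip depth spread "
                f"{height - min(tip_depths):g})"
            )

        def convert(dnode) -> TreeNode:
            children = [convert(c) for c in dnode.child_nodes()]
            label = None
            if not children:
                label = (
                    dnode.taxon.label if dnode.taxon is not None else dnode.label
                )
            return TreeNode(
                age=0.0 if not children else height - depths[dnode],
                children=children,
                label=label,
            )

        return cls(convert(dtree.seed_node), tol=tol)

    @classmethod
    def read(cls, path, tol: float = 1e-6) -> "UltraTree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), tol=tol)


def upgma_ultrametric(dm: DistMatrix) -> UltraTree:
    """Deterministic ultrametric tree by UPGMA; node age = merge height / 2."""
    values = dm.condensed()
    if not np.all(np.isfinite(values)):
        raise TreeError("distance matrix contains non-finite entries")
    n = len(dm.ids)
    if n < 2:
        raise TreeError("need at least two sequences for UPGMA")
    Z = linkage(values, method="average")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(age=0.0, label=dm.ids[i]) for i in range(n)
    }
    for k, (a, b, height, _) in enumerate(Z):
        nodes[n + k] = TreeNode(
            age=height / 2.0, children=[nodes[int(a)], nodes[int(b)]]
        )
    return UltraTree(nodes[n + len(Z) - 1])


# ---------------------------------------------------------------------------
# Labelings and likelihood
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GMYCParams:
    """Rates and scaling exponents of the two branching processes."""

    lambda_div: float
    p_div: float
    lambda_coal: float
    p_coal: float

    def __post_init__(self) -> None:
        if self.lambda_div <= 0 or self.lambda_coal <= 0:
            raise ValueError("rates must be positive")
        if not (math.isfinite(self.p_div) and math.isfinite(self.p_coal)):
            raise ValueError("exponents must be finite")


def check_labeling(tree: UltraTree, speciation: frozenset[TreeNode]) -> None:
    """A labeling is consistent when every ancestor of a speciation node is
    a speciation node."""
    for node in speciation:
        if node.is_tip:
            raise ValueError("tips cannot be speciation nodes")
        if node.parent is not None and node.parent not in speciation:
            raise ValueError("ancestor of a speciation node must be speciation")


def delimit_units(
    tree: UltraTree, speciation: frozenset[TreeNode]
) -> list[list[str]]:
    """Tip groups of the delimited units: maximal coalescent subtrees."""
    units: list[list[str]] = []

    def collect_tips(node: TreeNode) -> list[str]:
        if node.is_tip:
            return [node.label]
        out = []
        for c in node.children:
            out.extend(collect_tips(c))
        return out

    def walk(node: TreeNode) -> None:
        if node in speciation:
            for c in node.children:
                walk(c)
        else:
            units.append(collect_tips(node))

    walk(tree.root)
    return units


class _IntervalData:
    """Per-interval quantities of one labeling, precomputed for fast
    likelihood evaluation over parameters."""

    def __init__(self, tree: UltraTree, speciation: frozenset[TreeNode]):
        check_labeling(tree, speciation)
        self.has_speciation = bool(speciation)
        events = tree.events()
        n_events = len(events)

        # unit id of every node inside a coalescent subtree (unit root = the
        # highest non-speciation node on the path to the root)
        unit_of: dict[TreeNode, int] = {}

        def assign(node: TreeNode, unit: int | None) -> None:
            if node in speciation:
                for c in node.children:
                    assign(c, None)
            else:
                if unit is None:
                    unit = max(unit_of.values(), default=-1) + 1
                unit_of[node] = unit
                for c in node.children:
                    assign(c, unit)

        assign(tree.root, None)
        self.n_units = len(set(unit_of.values()))

        ages = np.array([e.age for e in events])
        self.x = np.diff(np.concatenate([[0.0], ages]))  # interval durations

        # species-level lineage count per interval: 1 + #speciation events at
        # this interval's closing position or later (event order, stable)
        spec_flags = np.array([e in speciation for e in events], dtype=bool)
        remaining_spec = np.cumsum(spec_flags[::-1])[::-1]
        self.k = 1.0 + remaining_spec

        # per-unit lineage counts, tips upward; store coalescent weights
        # v = m (m - 1) per interval as counts over distinct v values
        active: dict[int, int] = {}
        for tip in tree.tips:
            u = unit_of.get(tip)
            if u is not None:
                active[u] = active.get(u, 0) + 1
        v_rows: list[dict[int, int]] = []
        for event in events:
            row: dict[int, int] = {}
            for m in active.values():
                if m >= 2:
                    v = m * (m - 1)
                    row[v] = row.get(v, 0) + 1
            v_rows.append(row)
            u = unit_of.get(event)
            if u is not None:
                active[u] -= 1  # two child lineages merge into one

        v_values = sorted({v for row in v_rows for v in row})
        self.v = np.array(v_values, dtype=float)
        self.C = np.zeros((n_events, len(v_values)))
        v_index = {v: j for j, v in enumerate(v_values)}
        for i, row in enumerate(v_rows):
            for v, c in row.items():
                self.C[i, v_index[v]] = c
        self.log_v = np.log(self.v) if len(v_values) else self.v
        self.log_k = np.log(self.k)
        # which process produced each event (needed for the component-rate
        # variant of the event term)
        self.event_is_coal = np.array(
            [e not in speciation for e in events], dtype=bool
        )

    # -- log-likelihood and gradient over (log rates, exponents) ----------

    def loglik(self, params: GMYCParams, event_rate: str = "total") -> float:
        """Log-likelihood at fixed parameters.

        ``event_rate`` chooses the event term: "total" uses the pooled rate
        b_i (waiting-time density of the pooled process); "component" uses
        the rate of the process that actually branched at each event.
        """
        yule, coal = self._component_rates(params)
        b = yule + coal
        if np.any(b <= 0):
            return -np.inf
        if event_rate == "total":
            event = np.log(b)
        elif event_rate == "component":
            rate_at_event = np.where(self.event_is_coal, coal, yule)
            if np.any(rate_at_event <= 0):
                return -np.inf
            event = np.log(rate_at_event)
        else:
            raise ValueError(f"unknown event_rate {event_rate!r}")
        return float(np.sum(event) - np.sum(b * self.x))

    def _component_rates(self, params: GMYCParams):
        yule = np.zeros_like(self.x)
        coal = np.zeros_like(self.x)
        if self.has_speciation:
            yule = params.lambda_div * np.exp(params.p_div * self.log_k)
        if len(self.v):
            coal = params.lambda_coal * (self.C @ self.v ** params.p_coal)
        return yule, coal

    def _negloglik_grad(self, z: np.ndarray):
        """z = (log lambda_div, p_div, log lambda_coal, p_coal) or the last
        two alone for the pure-coalescent (null) labeling."""
        if self.has_speciation:
            ld, pd_, lc, pc = math.exp(z[0]), z[1], math.exp(z[2]), z[3]
            yule = ld * np.exp(pd_ * self.log_k)
        else:
            lc, pc = math.exp(z[0]), z[1]
            yule = 0.0
        if len(self.v):
            vp = self.v ** pc
            coal = lc * (self.C @ vp)
            dcoal_dpc = lc * (self.C @ (vp * self.log_v))
        else:
            coal = 0.0
            dcoal_dpc = 0.0
        b = yule + coal
        if np.any(b <= 0):
            return np.inf, np.zeros_like(z)
        resid = 1.0 / b - self.x       # d lnL / d b_i
        nll = -(np.sum(np.log(b)) - np.sum(b * self.x))
        if self.has_speciation:
            grad = -np.array(
                [
                    np.sum(resid * yule),
                    np.sum(resid * yule * self.log_k),
                    np.sum(resid * coal),
                    np.sum(resid * dcoal_dpc),
                ]
            )
        else:
            grad = -np.array([np.sum(resid * coal), np.sum(resid * dcoal_dpc)])
        return nll, grad


_EXP_BOUNDS = (0.0, 10.0)
_LOGRATE_BOUNDS = (-20.0, 20.0)


def _fit_params(
    data: _IntervalData, n_starts: int = 3, seed: int = 0, tol: float = 1e-8
) -> tuple[GMYCParams, float]:
    """Maximise the interval likelihood over rates and exponents.

    Rates are optimised on the log scale; three starts (one moment-based,
    two seeded perturbations) guard against local optima.
    """
    n_events = len(data.x)
    total_time = float(np.sum((data.k + (data.C @ data.v if len(data.v) else 0)) * data.x))
    base_rate = n_events / max(total_time, 1e-12)
    log_b = math.log(max(base_rate, 1e-12))
    rng = np.random.default_rng(seed)
    if data.has_speciation:
        starts = [np.array([log_b, 1.0, log_b, 1.0])]
        bounds = [_LOGRATE_BOUNDS, _EXP_BOUNDS, _LOGRATE_BOUNDS, _EXP_BOUNDS]
    else:
        starts = [np.array([log_b, 1.0])]
        bounds = [_LOGRATE_BOUNDS, _EXP_BOUNDS]
    for _ in range(n_starts - 1):
        jitter = rng.normal(scale=[1.5, 0.4] * (len(starts[0]) // 2))
        starts.append(starts[0] + jitter)

    best_z, best_nll = None, np.inf
    for z0 in starts:
        z0 = np.clip(z0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            data._negloglik_grad, z0, jac=True, method="L-BFGS-B",
            bounds=bounds, options={"ftol": tol, "gtol": 1e-10},
        )
        if res.fun < best_nll:
            best_nll, best_z = res.fun, res.x
    if best_z is None or not np.isfinite(best_nll):
        raise RuntimeError("parameter optimisation failed to converge")
    if data.has_speciation:
        params = GMYCParams(
            lambda_div=math.exp(best_z[0]), p_div=best_z[1],
            lambda_coal=math.exp(best_z[2]), p_coal=best_z[3],
        )
    else:
        params = GMYCParams(
            lambda_div=1.0, p_div=1.0,
            lambda_coal=math.exp(best_z[0]), p_coal=best_z[1],
        )
    return params, -best_nll


def gmyc_loglik(
    tree: UltraTree,
    speciation_nodes,
    params: GMYCParams,
    event_rate: str = "total",
) -> float:
    """Log-likelihood of a labeling (set of speciation nodes) at fixed
    parameters.  With no speciation node the model reduces to the single
    coalescent null and only the coalescent parameters act.  See
    :meth:`_IntervalData.loglik` for the ``event_rate`` variants."""
    data = _IntervalData(tree, frozenset(speciation_nodes))
    return data.loglik(params, event_rate=event_rate)


def fit_null(tree: UltraTree, seed: int = 0) -> tuple[GMYCParams, float]:
    """Single-coalescent null model fit (no speciation nodes)."""
    data = _IntervalData(tree, frozenset())
    return _fit_params(data, seed=seed)


@dataclass
class GMYCFit:
    """Result of a GMYC fit."""

    mode: str                      # "single" | "multiple" | "null"
    threshold: float | None       # threshold age (single-threshold mode)
    speciation_ids: tuple[int, ...]  # preorder indices of speciation nodes
    params: GMYCParams
    lnL_gmyc: float
    lnL_null: float
    entities: Partition
    clusters: Partition
    lr: float = field(init=False)
    p_value: float = field(init=False)
    df: int = 3

    def __post_init__(self) -> None:
        self.lr, self.p_value = gmyc_lr_test(self.lnL_null, self.lnL_gmyc, self.df)

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "threshold": self.threshold,
            "n_entities": self.n_entities,
            "n_clusters": len(self.clusters),
            "lnL_gmyc": self.lnL_gmyc,
            "lnL_null": self.lnL_null,
            "LR": self.lr,
            "p_value": self.p_value,
            "df": self.df,
            "params": {
                "lambda_div": self.params.lambda_div,
                "p_div": self.params.p_div,
                "lambda_coal": self.params.lambda_coal,
                "p_coal": self.params.p_coal,
            },
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _make_fit(
    tree: UltraTree,
    speciation: frozenset[TreeNode],
    params: GMYCParams,
    lnL: float,
    lnL_null: float,
    mode: str,
    threshold: float | None,
    df: int,
) -> GMYCFit:
    groups = delimit_units(tree, speciation)
    entities = Partition.from_groups(groups, method=f"gmyc-{mode}")
    clusters = Partition.from_groups(
        [g for g in groups if len(g) >= 2], method=f"gmyc-{mode}-clusters"
    )
    return GMYCFit(
        mode=mode,
        threshold=threshold,
        speciation_ids=tuple(sorted(n.preorder for n in speciation)),
        params=params,
        lnL_gmyc=lnL,
        lnL_null=lnL_null,
        entities=entities,
        clusters=clusters,
        df=df,
    )


def candidate_thresholds(tree: UltraTree) -> list[float]:
    """Midpoints between consecutive distinct node ages, plus one threshold
    below every node (all-speciation) and one above the root (the null)."""
    ages = sorted({n.age for n in tree.internal})
    grid = [0.0] + ages + [tree.root.age * 1.0 + 1.0]
    return [(a + b) / 2.0 for a, b in zip(grid, grid[1:])]


def fit_gmyc_single(
    tree: UltraTree, seed: int = 0, df: int = 3, n_starts: int = 3
) -> GMYCFit:
    """Exhaustive single-threshold GMYC fit.

    Every candidate threshold labels nodes older than it as speciation and
    younger as coalescent; the profile likelihood over the four parameters
    is maximised per candidate and the best threshold is returned.  The
    all-coalescent labeling (threshold above the root) is included among
    the candidates, so the fitted likelihood can never fall below the null.
    """
    if tree.n_tips < 3:
        raise TreeError("single-threshold fit needs at least 3 tips")
    null_params, lnL_null = fit_null(tree, seed=seed)

    best = (lnL_null, frozenset(), null_params, None)  # includes null candidate
    for t in candidate_thresholds(tree):
        speciation = frozenset(n for n in tree.internal if n.age > t)
        if not speciation:
            continue  # the null, already evaluated
        data = _IntervalData(tree, speciation)
        try:
            params, lnL = _fit_params(data, n_starts=n_starts, seed=seed)
        except RuntimeError as exc:
            logger.warning("fit_gmyc_single: threshold %.6g skipped (%s)", t, exc)
            continue
        if lnL > best[0]:
            best = (lnL, speciation, params, t)

    lnL, speciation, params, threshold = best
    fit = _make_fit(
        tree, speciation, params, lnL, lnL_null,
        mode="single", threshold=threshold, df=df,
    )
    logger.info(
        "fit_gmyc_single: %d tips -> %d entities (lnL %.4f vs null %.4f)",
        tree.n_tips, fit.n_entities, lnL, lnL_null,
    )
    return fit


def _neighbor_labelings(
    tree: UltraTree, speciation: frozenset[TreeNode]
) -> list[frozenset[TreeNode]]:
    """Consistent labelings one relabeling move away.

    Promoting a node to speciation also promotes its non-speciation
    ancestors (the minimal relabels keeping the labeling consistent);
    demoting a node also demotes its speciation descendants.  Each move
    therefore splits a unit at a node or fuses a clade back into one unit.
    """
    out = []
    for node in tree.internal:
        if node in speciation:
            drop = {node}
            stack = list(node.children)
            while stack:
                n = stack.pop()
                if n in speciation:
                    drop.add(n)
                    stack.extend(n.children)
            out.append(speciation - drop)
        else:
            add = set()
            n = node
            while n is not None and n not in speciation:
                add.add(n)
                n = n.parent
            out.append(speciation | add)
    return out


def fit_gmyc_multiple(
    tree: UltraTree,
    single_fit: GMYCFit | None = None,
    seed: int = 0,
    df: int = 3,
    n_starts: int = 3,
    improve_tol: float = 1e-6,
) -> GMYCFit:
    """Multiple-threshold GMYC by greedy hill-climbing over labelings.

    Starts from the single-threshold solution and repeatedly applies the
    best strictly improving single-node relabeling (splitting a unit at a
    node or fusing sibling units) until no move improves the likelihood.
    The result can therefore never have a lower likelihood than the
    single-threshold fit.
    """
    if single_fit is None:
        single_fit = fit_gmyc_single(tree, seed=seed, df=df, n_starts=n_starts)
    by_preorder = {n.preorder: n for n in tree.nodes}
    current = frozenset(by_preorder[i] for i in single_fit.speciation_ids)
    current_lnL = single_fit.lnL_gmyc
    current_params = single_fit.params

    improved = True
    while improved:
        improved = False
        best_move = None
        for neighbor in _neighbor_labelings(tree, current):
            data = _IntervalData(tree, neighbor)
            try:
                params, lnL = _fit_params(data, n_starts=n_starts, seed=seed)
            except RuntimeError:
                continue
            if lnL > current_lnL + improve_tol and (
                best_move is None or lnL > best_move[0]
            ):
                best_move = (lnL, neighbor, params)
        if best_move is not None:
            current_lnL, current, current_params = best_move
            improved = True

    fit = _make_fit(
        tree, current, current_params, current_lnL, single_fit.lnL_null,
        mode="multiple", threshold=None, df=df,
    )
    logger.info(
        "fit_gmyc_multiple: %d -> %d entities (lnL %.4f)",
        single_fit.n_entities, fit.n_entities, current_lnL,
    )
    return fit


def gmyc_lr_test(
    lnL_null: float, lnL_gmyc: float, df: int = 3
) -> tuple[float, float]:
    """Likelihood-ratio test of the mixed model against the coalescent null."""
    lr = 2.0 * (lnL_gmyc - lnL_null)
    if lr < -1e-8:
        raise ValueError(f"negative likelihood ratio ({lr:g}): nesting violated")
    lr = max(lr, 0.0)
    return lr, float(chi2.sf(lr, df))
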