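"""Distance-based species delimitation: barcode-gap partitioning and MOTUs.

Two classic single-locus approaches are implemented.

Barcode-gap discovery partitions a set of pairwise distances by locating
the "barcode gap" separating intra- from interspecific divergence.  A prior
``P_max`` on the maximum intraspecific divergence calibrates theta (the mean
of all distances below the prior); gaps below the limit L = -ln(0.05)*theta
— the distance below which a gap has a 5% risk of being intraspecific under
an exponential pairwise-coalescent approximation — are ignored.  The gap is
located from peak slopes of the ranked distances with a dynamic window, and
accepted only when its width exceeds X times the largest consecutive gap
among the sub-limit (putatively intraspecific) distances.  Groups are then
formed by single linkage below the gap, and the procedure recurses within
each group until nothing splits further.

MOTU clustering takes a raw base-pair difference cutoff and forms clusters
as connected components of the graph linking sequence pairs with at most
``cutoff_bp`` differences (single linkage), so that no member of one MOTU is
within the cutoff of any member of another.  Sweeping the cutoff yields a
monotone non-increasing MOTU count.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import DistMatrix, distance_matrix
from .seqio import AlignedSeqSet

logger = logging.getLogger("barcodescope")

#: -ln(0.05): quantile factor of the exponential coalescent approximation
#: behind the intraspecific-gap risk limit.
LIMIT_FACTOR = -math.log(0.05)


class GapError(ValueError):
    """Raised when a barcode-gap quantity is undefined for the input."""


@dataclass
class Partition:
    """Assignment of sequence ids to delimited units."""

    units: dict[str, tuple[str, ...]]   # unit id -> member ids
    method: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        members = [m for ms in self.units.values() for m in ms]
        if len(members) != len(set(members)):
            raise ValueError("partition blocks must be disjoint")

    def __len__(self) -> int:
        return len(self.units)

    @property
    def n_members(self) -> int:
        return sum(len(ms) for ms in self.units.values())

    def unit_of(self) -> dict[str, str]:
        return {m: u for u, ms in self.units.items() for m in ms}

    def blocks(self) -> list[frozenset[str]]:
        return [frozenset(ms) for ms in self.units.values()]

    def refines(self, other: "Partition") -> bool:
        """True when every block of self lies within a block of other."""
        containing = other.unit_of()
        for ms in self.units.values():
            if len({containing.get(m) for m in ms}) != 1:
                return False
        return True

    def same_blocks(self, other: "Partition") -> bool:
        return set(self.blocks()) == set(other.blocks())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": m, "unit": u} for u, ms in self.units.items() for m in ms
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_groups(cls, groups: list[list[str]], method: str = "", **params):
        return cls(
            units={f"U{k + 1}": tuple(g) for k, g in enumerate(groups)},
            method=method, params=params,
        )


@dataclass
class ABGDConfig:
    """Parameters of a barcode-gap partitioning run."""

    prior: float = 0.01          # P_max: maximum intraspecific divergence
    gap_width: float = 1.5       # X: minimum relative gap width
    model: str = "jc69"          # jc69 | k80
    ts_tv: float | None = None   # transition/transversion ratio for k80

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ValueError("prior must lie in (0, 1)")
        if self.gap_width < 0:
            raise ValueError("gap width X must be >= 0")


#: Default prior grid: 10 logarithmic steps between 0.005 and 0.05.
DEFAULT_PRIORS: tuple[float, ...] = tuple(
    float(p) for p in np.geomspace(0.005, 0.05, 10)
)
DEFAULT_GAP_WIDTHS: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)


@dataclass
class GapScan:
    """Result of one barcode-gap detection pass."""

    distances: np.ndarray            # sorted ascending
    theta: float
    limit: float
    window: int
    slopes: np.ndarray
    gap_position: float | None       # distance value, or None
    gap_width: float | None
    baseline: float | None           # max consecutive intraspecific gap
    reason: str = ""


def abgd_theta_and_limit(distances, prior: float) -> tuple[float, float]:
    """Theta (mean distance below the prior) and the gap risk limit L.

    L = -ln(0.05) * theta, the 95% quantile of an exponential with mean
    theta: gaps at distances <= L carry more than a 5% risk of being
    intraspecific and are ignored downstream.
    """
    d = np.asarray(sorted(distances), dtype=float)
    if d.size == 0:
        raise GapError("empty distance set")
    below = d[d < prior]
    if below.size == 0:
        raise GapError(f"no distance below prior {prior}; theta undefined")
    theta = float(below.mean())
    return theta, LIMIT_FACTOR * theta


def detect_barcode_gap(
    distances, theta: float, limit: float, gap_width: float
) -> GapScan:
    """Locate the barcode gap in a ranked distance list.

    Slopes s_i = (d[i+w] - d[i]) / w are computed with a dynamic window
    w = max(10, ceil(0.01 m)); the peak-slope window among those reaching
    above the limit L marks the candidate region.  Within it, the largest
    single consecutive jump whose midpoint exceeds L is the candidate gap;
    it is accepted only when its width exceeds ``gap_width`` (X) times the
    largest consecutive jump among the sub-limit distances (the
    intraspecific baseline).  Returns a GapScan with ``gap_position`` None
    when no acceptable gap exists.
    """
    d = np.asarray(sorted(distances), dtype=float)
    m = d.size
    if m < 2:
        return GapScan(d, theta, limit, 0, np.empty(0), None, None, None,
                       reason="fewer than two distances")
    w = max(10, math.ceil(0.01 * m))
    if m < 2 * w:
        w = max(1, m // 2)
        logger.warning("detect_barcode_gap: window shrunk to %d (m=%d)", w, m)
    slopes = (d[w:] - d[:-w]) / w

    below = d[d < limit]
    if below.size < 2:
        return GapScan(d, theta, limit, w, slopes, None, None, None,
                       reason="no intraspecific baseline below limit")
    baseline = float(np.max(np.diff(below)))

    # windows whose top reaches above the limit can contain a usable gap
    candidates = np.flatnonzero(d[w:] > limit)
    if candidates.size == 0:
        return GapScan(d, theta, limit, w, slopes, None, None, baseline,
                       reason="no ranked-distance window reaches above limit")
    i_star = int(candidates[np.argmax(slopes[candidates])])

    # largest consecutive jump in the peak window with midpoint above L
    jumps = np.diff(d[i_star : i_star + w + 1])
    mids = 0.5 * (d[i_star : i_star + w] + d[i_star + 1 : i_star + w + 1])
    usable = np.flatnonzero(mids > limit)
    if usable.size == 0:
        return GapScan(d, theta, limit, w, slopes, None, None, baseline,
                       reason="gap entirely below limit")
    j = int(usable[np.argmax(jumps[usable])])
    width = float(jumps[j])
    position = float(mids[j])

    if baseline <= 0 or width <= gap_width * baseline:
        return GapScan(d, theta, limit, w, slopes, None, width, baseline,
                       reason="gap width below X times intraspecific baseline")
    return GapScan(d, theta, limit, w, slopes, position, width, baseline)


def _single_linkage_groups(
    ids: list[str], dm: DistMatrix, threshold: float
) -> list[list[str]]:
    """Connected components linking pairs with distance < threshold."""
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in itertools.combinations(ids, 2):
        if dm.get(a, b) < threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: ids.index(g[0]))


def abgd_partition(
    dm: DistMatrix, cfg: ABGDConfig
) -> tuple[Partition, Partition]:
    """Initial and recursive barcode-gap partitions of a distance matrix.

    The initial partition applies gap detection once to all pairwise
    distances and single-links below the gap.  The recursive partition
    re-runs detection inside every group (recomputing theta and the limit
    from that group's own distances, same prior) until no group splits.
    """
    ids = list(dm.ids)

    def split_once(group: list[str]) -> list[list[str]] | None:
        if len(group) < 3:
            return None
        sub = dm.subset(group)
        dists = sub.condensed()
        try:
            theta, limit = abgd_theta_and_limit(dists, cfg.prior)
        except GapError:
            return None
        scan = detect_barcode_gap(dists, theta, limit, cfg.gap_width)
        if scan.gap_position is None:
            return None
        parts = _single_linkage_groups(group, sub, scan.gap_position)
        return parts if len(parts) > 1 else None

    top = split_once(ids)
    initial_groups = top if top is not None else [ids]
    initial = Partition.from_groups(
        initial_groups, method="barcode-gap-initial",
        prior=cfg.prior, X=cfg.gap_width, model=cfg.model,
    )

    work = [list(g) for g in initial_groups]
    final: list[list[str]] = []
    while work:
        group = work.pop(0)
        parts = split_once(group)
        if parts is None:
            final.append(group)
        else:
            work = parts + work
    final.sort(key=lambda g: ids.index(g[0]))
    recursive = Partition.from_groups(
        final, method="barcode-gap-recursive",
        prior=cfg.prior, X=cfg.gap_width, model=cfg.model,
    )
    logger.info(
        "abgd_partition: prior=%.6f X=%.1f model=%s -> initial %d, recursive %d",
        cfg.prior, cfg.gap_width, cfg.model, len(initial), len(recursive),
    )
    return initial, recursive


def abgd_grid(
    aln: AlignedSeqSet,
    priors=DEFAULT_PRIORS,
    gap_widths=DEFAULT_GAP_WIDTHS,
    models=(("jc69", None), ("k80", 2.0), ("k80", 4.0)),
) -> pd.DataFrame:
    """Initial/recursive group counts over a (prior, X, model) grid.

    ``models`` is a list of (model, ts_tv) pairs.  Failures in individual
    cells are recorded as NA with the reason logged.
    """
    dms = {}
    for model, ts_tv in models:
        dms[(model, ts_tv)] = distance_matrix(aln, model=model, ts_tv=ts_tv)
    rows = []
    for prior, x, (model, ts_tv) in itertools.product(priors, gap_widths, models):
        cfg = ABGDConfig(prior=prior, gap_width=x, model=model, ts_tv=ts_tv)
        try:
            initial, recursive = abgd_partition(dms[(model, ts_tv)], cfg)
            n_init, n_rec = len(initial), len(recursive)
        except GapError as exc:
            logger.warning("abgd_grid cell failed (%s): %s", cfg, exc)
            n_init = n_rec = None
        rows.append(
            {
                "prior": prior,
                "X": x,
                "model": model,
                "ts_tv": ts_tv,
                "initial": n_init,
                "recursive": n_rec,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MOTU clustering on raw base-pair differences
# ---------------------------------------------------------------------------

def _informative_length(seq: str) -> int:
    return sum(1 for c in seq if c in "ACGT")


def bp_differences(seq_a: str, seq_b: str) -> tuple[int, int]:
    """(differences, overlap) over sites where both sequences have a base."""
    diff = overlap = 0
    for x, y in zip(seq_a, seq_b):
        if x in "ACGT" and y in "ACGT":
            overlap += 1
            if x != y:
                diff += 1
    return diff, overlap


def motu_cluster(
    aln: AlignedSeqSet,
    cutoff_bp: int,
    min_len: int = 500,
    overlap_frac: float = 0.90,
) -> Partition:
    """Single-linkage MOTUs at a raw base-pair difference cutoff.

    Sequences shorter than ``min_len`` informative bases are excluded.
    A pair is compared only when its mutual overlap covers at least
    ``overlap_frac`` of the shorter sequence; distance is the exact count of
    differing bases over mutually unambiguous sites (no substitution
    model).  Clusters are the connected components of the graph with an
    edge wherever differences <= cutoff, so no member of one MOTU is within
    the cutoff of any member of another.
    """
    kept: list[str] = []
    for sid, seq in aln:
        if _informative_length(seq) > min_len:
            kept.append(sid)
        else:
            logger.info("motu_cluster: %s excluded (< %d informative bp)", sid, min_len)
    idx = {sid: aln.get(sid) for sid in kept}
    parent = {i: i for i in kept}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in itertools.combinations(kept, 2):
        diff, overlap = bp_differences(idx[a], idx[b])
        shorter = min(_informative_length(idx[a]), _informative_length(idx[b]))
        if shorter == 0 or overlap < overlap_frac * shorter:
            continue
        if diff <= cutoff_bp:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    groups: dict[str, list[str]] = {}
    for i in kept:
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(groups.values(), key=lambda g: kept.index(g[0]))
    return Partition.from_groups(
        ordered, method="motu-single-linkage",
        cutoff_bp=cutoff_bp, min_len=min_len, overlap_frac=overlap_frac,
    )


def motu_sweep(
    aln: AlignedSeqSet,
    cutoffs=range(3, 24),
    min_len: int = 500,
    overlap_frac: float = 0.90,
) -> pd.DataFrame:
    """MOTU counts over a range of base-pair cutoffs (columns cutoff_bp, motus)."""
    rows = [
        {
            "cutoff_bp": int(c),
            "motus": len(motu_cluster(aln, int(c), min_len, overlap_frac)),
        }
        for c in cutoffs
    ]
    return pd.DataFrame(rows)
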