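"""Synthetic data with the statistical structure the analyses assume.

Three generators cover the pipeline's inputs end to end, with no external
data: (i) multi-species ultrametric gene trees built from a Yule species
tree with an independent constant-size coalescent genealogy grafted within
each species, so that speciation events are older than coalescent events
unless deliberately violated; (ii) nucleotide alignments evolved down such
trees under the Kimura two-parameter substitution process with a chosen
transition/transversion bias; (iii) specimen geography in which southern
(Iberian) populations carry haplotypes from deeper-diverged lineages than
matched-distance northern pairs, emulating the refugial concentration of
genetic diversity in southern Europe.  A fourth constructor plants an
exact barcode gap (all intraspecific distances below, all interspecific
distances above) for testing gap-based delimitation.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .gmyc import TreeNode, UltraTree
from .seqio import AlignedSeqSet, SpecimenRecord

logger = logging.getLogger("barcodescope")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    partition: dict[str, tuple[str, ...]]   # true species -> tip ids
    split_ages: tuple[float, ...]
    theta: float
    seed: int
    pop_regions: dict[str, str] = field(default_factory=dict)
    pop_coords: dict[str, tuple[float, float]] = field(default_factory=dict)
    lineages: dict[str, str] = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.partition)

    def partition_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"id": tip, "unit": sp}
                for sp, tips in self.partition.items()
                for tip in tips
            ]
        )


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _yule_species_times(
    n_species: int, rate: float, rng, min_split_age: float = 0.0
) -> tuple[list, float]:
    """Forward Yule split times and the observation time.

    ``min_split_age`` inserts a guard interval between the last speciation
    and the present, so every split age is at least that old.
    """
    times = []
    t = 0.0
    for k in range(1, n_species):
        t += rng.exponential(1.0 / (rate * k))
        times.append(t)
    t_present = t + min_split_age + rng.exponential(1.0 / (rate * n_species))
    return times, t_present


def _coalescent_subtree(
    labels: list[str], theta: float, rng, max_age: float | None = None
) -> TreeNode:
    """Constant-size coalescent genealogy over the given samples.

    ``theta`` is the expected coalescence time of a pair (mean pairwise
    depth).  If the MRCA would exceed ``max_age`` the whole genealogy is
    shrunk proportionally to fit below it, preserving topology.
    """
    active = [TreeNode(age=0.0, label=lab) for lab in labels]
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(theta / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        node = TreeNode(age=t, children=[active[i], active[j]])
        active = [a for idx, a in enumerate(active) if idx not in (i, j)]
        active.append(node)
    root = active[0]
    if max_age is not None and root.age >= max_age:
        factor = 0.95 * max_age / root.age

        def rescale(node: TreeNode) -> None:
            node.age *= factor
            for c in node.children:
                rescale(c)

        rescale(root)
    return root


def simulate_species_tree(
    n_species: int,
    lambda_spec: float = 1.0,
    theta: float = 0.05,
    n_per_species: int = 4,
    seed: int = 0,
    violate_threshold: float = 1.0,
    min_split_age: float = 0.5,
) -> tuple[UltraTree, SimTruth]:
    """Yule species tree with coalescent genealogies grafted at the tips.

    ``theta`` sets the mean pairwise coalescent depth within species (time
    units of the species tree); ``min_split_age`` guards the present so
    every speciation is at least that old, keeping speciations well above
    the coalescences whenever theta is small against it.
    ``violate_threshold`` > 1 multiplies the first species' theta,
    deepening its coalescences to break the single-threshold assumption
    that all speciations predate all coalescences.  Genealogies that would
    outgrow their species stem are shrunk to fit, keeping the tree valid
    and ultrametric.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if n_per_species < 1:
        raise ValueError("need at least 1 sample per species")
    if lambda_spec <= 0 or theta <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    split_times, t_present = _yule_species_times(
        n_species, lambda_spec, rng, min_split_age=min_split_age
    )

    root_slot = TreeNode(age=0.0)
    root_slot.parent = None
    active = [root_slot]
    for s in split_times:
        j = int(rng.integers(len(active)))
        slot = active.pop(j)
        slot.age = t_present - s
        slot.children = [TreeNode(age=0.0), TreeNode(age=0.0)]
        for child in slot.children:
            child.parent = slot
        active.extend(slot.children)

    partition: dict[str, tuple[str, ...]] = {}
    for idx, slot in enumerate(active):
        species = f"sp{idx + 1}"
        labels = [f"{species}_{i + 1}" for i in range(n_per_species)]
        partition[species] = tuple(labels)
        stem_age = slot.parent.age if slot.parent is not None else t_present
        sp_theta = theta * (violate_threshold if idx == 0 else 1.0)
        if n_per_species == 1:
            slot.label = labels[0]
            continue
        sub = _coalescent_subtree(labels, sp_theta, rng, max_age=stem_age)
        slot.age = sub.age
        slot.children = sub.children
        slot.label = None

    tree = UltraTree(root_slot)
    truth = SimTruth(
        partition=partition,
        split_ages=tuple(sorted(t_present - s for s in split_times)),
        theta=theta,
        seed=seed,
    )
    return tree, truth


# ---------------------------------------------------------------------------
# Sequence evolution (K2P process)
# ---------------------------------------------------------------------------

_BASES = np.array(list("AGCT"))   # purines first: transition partner = i ^ 1


def _k2p_branch_probs(t: float, rate: float, kappa: float):
    """(p_same, p_transition, p_each_transversion) after time t."""
    beta = rate / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return 1.0 - p_ts - 2.0 * p_tv, p_ts, p_tv


def evolve_alignment(
    tree: UltraTree,
    length_bp: int = 658,
    rate: float = 1.0,
    kappa: float = 4.0,
    seed: int = 0,
) -> AlignedSeqSet:
    """Evolve site-independent sequences down the tree under the K2P model.

    ``rate`` is the total substitution rate per site per unit branch time;
    ``kappa`` the instantaneous transition/transversion rate ratio
    alpha/beta (expected transition:transversion count ratio kappa/2 at low
    divergence).  Base frequencies are uniform, as the model assumes.
    """
    if length_bp <= 0 or rate < 0 or kappa <= 0:
        raise ValueError("length must be positive, rate >= 0, kappa > 0")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length_bp)

    out: dict[str, str] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        if node.is_tip:
            out[node.label] = "".join(_BASES[seq])
            return
        for child in node.children:
            t = node.age - child.age
            if t <= 0 or rate == 0:
                descend(child, seq)
                continue
            p_same, p_ts, p_tv = _k2p_branch_probs(t, rate, kappa)
            u = rng.random(length_bp)
            tv_bit = rng.integers(0, 2, size=length_bp)
            child_seq = np.where(
                u < p_same,
                seq,
                np.where(u < p_same + p_ts, seq ^ 1, (seq ^ 2) ^ tv_bit),
            )
            descend(child, child_seq)

    descend(tree.root, root_seq)
    labels = tree.tip_labels()
    return AlignedSeqSet(ids=tuple(labels), seqs=tuple(out[l] for l in labels))


# ---------------------------------------------------------------------------
# Geography with a refugial south
# ---------------------------------------------------------------------------

#: Disjoint bounding boxes (lat_min, lat_max, lon_min, lon_max) per region.
DEFAULT_REGION_BOXES: dict[str, tuple[float, float, float, float]] = {
    "EU": (46.0, 60.0, -5.0, 25.0),
    "IB": (36.0, 43.5, -9.0, 2.0),
    "IT": (37.0, 44.0, 7.0, 18.0),
}


def simulate_geography(
    pops_per_region: dict[str, int],
    refugium_effect: float = 1.0,
    boxes: dict[str, tuple[float, float, float, float]] = DEFAULT_REGION_BOXES,
    seed: int = 0,
    n_per_pop: int = 3,
    species: str = "sp1",
):
    """Populations placed in their region's box, with refugial lineages.

    Every population receives between 1 and 2*``n_per_pop`` - 1 specimens
    (uniform, mean ``n_per_pop``) at its coordinates.  Each population is
    assigned a haplotype lineage: all EU and IT populations draw from the
    'shallow' lineage, while Iberian populations split between 'deep' and
    'shallow' (at least one of each when two or more exist and
    ``refugium_effect`` > 0), so that Iberian pairs span the deep
    divergence that matched-distance northern pairs lack.

    Returns (specimens, pop_assignments) where ``pop_assignments`` maps
    population id to a dict with keys region, lineage, coords, ids.
    """
    for ra, rb in [("EU", "IB"), ("EU", "IT"), ("IB", "IT")]:
        if ra in boxes and rb in boxes:
            a, b = boxes[ra], boxes[rb]
            lat_overlap = a[0] < b[1] and b[0] < a[1]
            lon_overlap = a[2] < b[3] and b[2] < a[3]
            if lat_overlap and lon_overlap:
                raise ValueError(f"region boxes {ra} and {rb} overlap")
    if any(n < 1 for n in pops_per_region.values()):
        raise ValueError("population counts must be >= 1")
    rng = np.random.default_rng(seed)
    specimens: list[SpecimenRecord] = []
    assignments: dict[str, dict] = {}
    for region in sorted(pops_per_region):
        n_pops = pops_per_region[region]
        lo_lat, hi_lat, lo_lon, hi_lon = boxes[region]
        if region == "IB" and refugium_effect > 0:
            lineage_draw = rng.random(n_pops) < 0.5
            if n_pops >= 2 and len(set(lineage_draw)) == 1:
                lineage_draw[0] = not lineage_draw[0]
        else:
            lineage_draw = np.zeros(n_pops, dtype=bool)
        for p in range(n_pops):
            pop_id = f"{region.lower()}{p + 1}"
            lat = float(rng.uniform(lo_lat, hi_lat))
            lon = float(rng.uniform(lo_lon, hi_lon))
            n_samples = int(rng.integers(1, 2 * n_per_pop))
            ids = [f"{species}_{pop_id}_{i + 1}" for i in range(n_samples)]
            assignments[pop_id] = {
                "region": region,
                "lineage": "deep" if lineage_draw[p] else "shallow",
                "coords": (lat, lon),
                "ids": ids,
            }
            for sid in ids:
                specimens.append(
                    SpecimenRecord(
                        seq_id=sid,
                        species=species,
                        site_name=f"{species}_{pop_id}",
                        country={"EU": "Germany", "IB": "Spain", "IT": "Italy"}[region],
                        region=region,
                        lat=lat,
                        lon=lon,
                    )
                )
    return specimens, assignments


def _refugium_gene_tree(
    assignments: dict[str, dict],
    theta: float,
    base_depth: float,
    refugium_effect: float,
    rng,
) -> UltraTree:
    """Gene tree for one species under the two-lineage refugium model.

    Populations of the same lineage coalesce below ``base_depth``; the
    'deep' and 'shallow' lineages join at ``base_depth + refugium_effect``.
    Within-population genealogies are constant-size coalescents with mean
    pairwise depth ``theta``.
    """
    by_lineage: dict[str, list[TreeNode]] = {"shallow": [], "deep": []}
    for pop_id in sorted(assignments):
        info = assignments[pop_id]
        labels = info["ids"]
        if len(labels) == 1:
            sub = TreeNode(age=0.0, label=labels[0])
        else:
            sub = _coalescent_subtree(labels, theta, rng, max_age=0.4 * base_depth)
        by_lineage[info["lineage"]].append(sub)

    def join_clade(subs: list[TreeNode], top_age: float) -> TreeNode:
        # sequentially join population subtrees at increasing ages below top_age
        subs = list(subs)
        n_joins = len(subs) - 1
        if n_joins == 0:
            return subs[0]
        ages = np.sort(rng.uniform(0.5 * top_age, top_age, size=n_joins))
        current = subs[0]
        for j, nxt in enumerate(subs[1:]):
            current = TreeNode(age=float(ages[j]), children=[current, nxt])
        return current

    shallow = join_clade(by_lineage["shallow"], base_depth) if by_lineage["shallow"] else None
    deep = join_clade(by_lineage["deep"], base_depth) if by_lineage["deep"] else None
    if shallow is not None and deep is not None:
        root = TreeNode(
            age=base_depth + refugium_effect, children=[shallow, deep]
        )
    else:
        root = shallow if shallow is not None else deep
    if root.is_tip or root.age <= 0:
        raise ValueError("refugium gene tree needs at least two populations")
    return root


def simulate_refugium_dataset(
    n_species: int = 6,
    pops_per_region: dict[str, int] | None = None,
    n_per_pop: int = 3,
    refugium_effect: float = 1.0,
    base_depth: float = 1.0,
    theta: float = 0.1,
    rate: float = 0.01,
    kappa: float = 4.0,
    length_bp: int = 658,
    seed: int = 0,
):
    """End-to-end refugium simulation over several species.

    Each species carries its own population geography and two-lineage gene
    tree; the species subtrees are joined into one gene tree by a
    caterpillar backbone of deep splits (2.5-4x the deepest within-species
    divergence), and a single pooled alignment is evolved down it, so
    between-species divergence is realistic and finite under K2P.

    Returns (alignment, specimens, truth): the pooled alignment, the
    pooled specimen table, and a SimTruth whose ``partition`` holds the
    true species and whose ``lineages`` maps each population to its
    lineage.  With ``refugium_effect`` > 0 the expected maximum divergence
    of Iberia-Iberia population pairs exceeds that of Europe-Europe pairs
    at matched geographic distance, the pattern the divergence mixed model
    is designed to detect.
    """
    if pops_per_region is None:
        pops_per_region = {"EU": 6, "IB": 4, "IT": 2}
    rng = np.random.default_rng(seed)
    specimens: list[SpecimenRecord] = []
    partition: dict[str, tuple[str, ...]] = {}
    lineages: dict[str, str] = {}
    pop_regions: dict[str, str] = {}
    pop_coords: dict[str, tuple[float, float]] = {}
    species_roots: list[TreeNode] = []
    for s in range(n_species):
        species = f"sp{s + 1}"
        sub_seed = int(rng.integers(2**31 - 1))
        specs, assignments = simulate_geography(
            pops_per_region,
            refugium_effect=refugium_effect,
            seed=sub_seed,
            n_per_pop=n_per_pop,
            species=species,
        )
        species_roots.append(
            _refugium_gene_tree(
                assignments, theta, base_depth,
                refugium_effect, np.random.default_rng(sub_seed + 1),
            )
        )
        specimens.extend(specs)
        partition[species] = tuple(r.seq_id for r in specs)
        for pop_id, info in assignments.items():
            lineages[f"{species}_{pop_id}"] = info["lineage"]
            pop_regions[f"{species}_{pop_id}"] = info["region"]
            pop_coords[f"{species}_{pop_id}"] = info["coords"]

    max_depth = base_depth + refugium_effect
    if n_species > 1:
        join_ages = np.sort(
            rng.uniform(2.5 * max_depth, 4.0 * max_depth, size=n_species - 1)
        )
        root = species_roots[0]
        for j, nxt in enumerate(species_roots[1:]):
            root = TreeNode(age=float(join_ages[j]), children=[root, nxt])
    else:
        root = species_roots[0]
    tree = UltraTree(root)
    alignment = evolve_alignment(
        tree, length_bp=length_bp, rate=rate, kappa=kappa,
        seed=int(rng.integers(2**31 - 1)),
    )
    truth = SimTruth(
        partition=partition,
        split_ages=tuple(float(a) for a in (join_ages if n_species > 1 else ())),
        theta=theta,
        seed=seed,
        pop_regions=pop_regions,
        pop_coords=pop_coords,
        lineages=lineages,
    )
    return alignment, specimens, truth


# ---------------------------------------------------------------------------
# Planted barcode gap
# ---------------------------------------------------------------------------

def make_gap_dataset(
    n_species: int = 3,
    intra_max: float = 0.005,
    inter_min: float = 0.10,
    n_per: int = 5,
    length_bp: int = 658,
    seed: int = 0,
) -> tuple[AlignedSeqSet, SimTruth]:
    """Alignment with an exact planted barcode gap.

    All within-species pairwise distances (raw and model-corrected) fall
    strictly below ``intra_max`` and all between-species distances strictly
    above ``inter_min``.  Construction: each species flips a private block
    of sites away from a common backbone (guaranteeing interspecific
    differences), and each individual additionally flips a small private
    set of sites (bounding intraspecific differences).  Raises when the
    alignment is too short for the requested margins.
    """
    if inter_min <= intra_max:
        raise ValueError("inter_min must exceed intra_max")
    rng = np.random.default_rng(seed)
    k_inter = math.ceil(inter_min * length_bp / 2.0) + 2
    f_intra = max(1, math.floor(0.4 * intra_max * length_bp))
    need = n_species * k_inter + n_species * max(0, n_per - 1) * f_intra
    if need > length_bp:
        raise ValueError(
            f"gap construction infeasible: needs {need} sites, have {length_bp}"
        )
    positions = rng.permutation(length_bp)
    backbone = rng.integers(0, 4, size=length_bp)

    cursor = 0
    ids: list[str] = []
    seqs: list[str] = []
    partition: dict[str, tuple[str, ...]] = {}
    for s in range(n_species):
        species = f"sp{s + 1}"
        block = positions[cursor : cursor + k_inter]
        cursor += k_inter
        centroid = backbone.copy()
        centroid[block] = (centroid[block] + 1) % 4
        members = []
        for i in range(n_per):
            seq = centroid.copy()
            if i > 0:
                own = positions[cursor : cursor + f_intra]
                cursor += f_intra
                seq[own] = (seq[own] + 1) % 4
            sid = f"{species}_{i + 1}"
            members.append(sid)
            ids.append(sid)
            seqs.append("".join(_BASES[seq]))
        partition[species] = tuple(members)

    aln = AlignedSeqSet(ids=tuple(ids), seqs=tuple(seqs))
    _verify_gap(aln, partition, intra_max, inter_min)
    truth = SimTruth(
        partition=partition, split_ages=(), theta=intra_max, seed=seed
    )
    return aln, truth


def _verify_gap(aln, partition, intra_max, inter_min) -> None:
    from .distances import distance_matrix

    dm = distance_matrix(aln, model="jc69")
    species_of = {m: sp for sp, ms in partition.items() for m in ms}
    for i, a in enumerate(aln.ids):
        for b in aln.ids[i + 1 :]:
            d = dm.get(a, b)
            same = species_of[a] == species_of[b]
            if same and d >= intra_max:
                raise ValueError("gap construction failed: intra distance too large")
            if not same and d <= inter_min:
                raise ValueError("gap construction failed: inter distance too small")
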