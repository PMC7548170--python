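"""Pairwise genetic distances, geographic distances, populations, contrasts.

Genetic divergence is measured with the Kimura two-parameter (K2P) model,
which corrects the observed proportions of transitions (P) and
transversions (Q) for multiple hits:

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Specimens are grouped into populations by collection site: two specimens
belong to the same population when their site names match or their
collection points lie within a linking radius (5 km by default), closed
under single linkage so that population membership is an equivalence
relation.  For every species and unordered pair of populations, the
contrast table records the maximum K2P% divergence over all cross-population
specimen pairs, the great-circle distance between population centroids, the
contrast class of the region pair (EUEU, EUIB, EUIT, IBIB), and the larger
of the two sample sizes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import AlignedSeqSet, SpecimenRecord

logger = logging.getLogger("barcodescope")

EARTH_RADIUS_KM = 6371.0

_ACGT = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """K2P correction undefined: observed divergence beyond model saturation."""


class UndefinedDistanceError(ValueError):
    """No comparable sites remain for a sequence pair."""


# ---------------------------------------------------------------------------
# Genetic distances
# ---------------------------------------------------------------------------

def count_site_patterns(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """(compared sites, transitions, transversions) over unambiguous sites.

    Only columns where both symbols are in {A,C,G,T} are compared (pairwise
    deletion of gaps and ambiguity codes).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    n = ts = tv = 0
    for x, y in zip(seq_a, seq_b):
        if x not in _ACGT or y not in _ACGT:
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def k2p_from_pq(p: float, q: float) -> float:
    """Kimura (1980) two-parameter distance from transition/transversion
    proportions P and Q."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P undefined for P={p:.4f}, Q={q:.4f}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """K2P distance (proportion) between two aligned sequences."""
    n, ts, tv = count_site_patterns(seq_a, seq_b)
    if n == 0:
        raise UndefinedDistanceError("no comparable sites between sequences")
    return k2p_from_pq(ts / n, tv / n)


def jc69_from_p(p: float) -> float:
    """Jukes-Cantor distance from the proportion of differing sites."""
    w = 1.0 - 4.0 * p / 3.0
    if w <= 0.0:
        raise SaturationError(f"JC69 undefined for p={p:.4f}")
    return -0.75 * math.log(w)


def k80_fixed_kappa_from_p(p: float, ts_tv: float) -> float:
    """K80 correction of a raw difference proportion at a fixed ts/tv ratio.

    The observed difference proportion p is partitioned into transition and
    transversion proportions according to the supplied ratio, then the K2P
    formula is applied.  This is the correction used when a transition bias
    is imposed rather than estimated per pair.
    """
    ts = p * ts_tv / (ts_tv + 1.0)
    tv = p / (ts_tv + 1.0)
    return k2p_from_pq(ts, tv)


@dataclass
class DistMatrix:
    """Symmetric pairwise divergence matrix with provenance tags."""

    ids: tuple[str, ...]
    values: np.ndarray
    model: str = "k2p"          # k2p | jc69 | k80 | p | bp
    deletion: str = "pairwise"  # pairwise | complete
    scale: str = "proportion"   # proportion | percent | bp

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def subset(self, keep_ids) -> "DistMatrix":
        keep = [i for i in self.ids if i in set(keep_ids)]
        idx = [self.ids.index(i) for i in keep]
        return DistMatrix(
            ids=tuple(keep),
            values=self.values[np.ix_(idx, idx)],
            model=self.model, deletion=self.deletion, scale=self.scale,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, **tags) -> "DistMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=tuple(df.index.astype(str)), values=df.values, **tags)

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                row = " ".join(f"{v:.8f}" for v in self.values[i])
                fh.write(f"{sid}  {row}\n")


def _complete_deletion_mask(aln: AlignedSeqSet) -> np.ndarray:
    """Columns where every sequence has an unambiguous base."""
    arr = np.array([list(s) for s in aln.seqs])
    return np.all(np.isin(arr, list("ACGT")), axis=0)


def distance_matrix(
    aln: AlignedSeqSet,
    model: str = "k2p",
    deletion: str = "pairwise",
    scale: str = "proportion",
    ts_tv: float | None = None,
) -> DistMatrix:
    """All-pairs distance matrix under the chosen model and deletion policy.

    Models: ``k2p`` (P, Q estimated per pair), ``jc69``, ``k80`` (K2P at the
    fixed ``ts_tv`` ratio), ``p`` (raw proportion), ``bp`` (integer base
    differences).  ``pairwise`` deletion drops gap/ambiguous sites per pair;
    ``complete`` drops any column that is gapped or ambiguous in any
    sequence.  Scale ``percent`` multiplies model distances by 100; model
    ``bp`` always reports integer counts.
    """
    if len(aln) < 2:
        raise ValueError("need at least two sequences")
    if model == "k80" and ts_tv is None:
        raise ValueError("model 'k80' requires ts_tv")
    seqs = list(aln.seqs)
    if deletion == "complete":
        mask = _complete_deletion_mask(aln)
        cols = np.flatnonzero(mask)
        seqs = ["".join(s[c] for c in cols) for s in seqs]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion policy {deletion!r}")

    # integer encoding: A,G=purines 0,1; C,T=pyrimidines 2,3; other = 4
    lut = np.full(256, 4, dtype=np.int8)
    for k, base in enumerate("AGCT"):
        lut[ord(base)] = k
    enc = lut[
        np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    ]

    n = len(seqs)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = enc[i], enc[j]
        comparable = (a < 4) & (b < 4)
        m = int(comparable.sum())
        diff = comparable & (a != b)
        ts = int((diff & ((a >> 1) == (b >> 1))).sum())
        tv = int(diff.sum()) - ts
        if m == 0:
            raise UndefinedDistanceError(
                f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
            )
        try:
            if model == "k2p":
                d = k2p_from_pq(ts / m, tv / m)
            elif model == "jc69":
                d = jc69_from_p((ts + tv) / m)
            elif model == "k80":
                d = k80_fixed_kappa_from_p((ts + tv) / m, ts_tv)
            elif model == "p":
                d = (ts + tv) / m
            elif model == "bp":
                d = float(ts + tv)
            else:
                raise ValueError(f"unknown model {model!r}")
        except SaturationError as exc:
            raise SaturationError(
                f"{exc} (pair {aln.ids[i]!r} vs {aln.ids[j]!r})"
            ) from exc
        values[i, j] = values[j, i] = d
    if scale == "percent" and model != "bp":
        values *= 100.0
    elif scale not in ("proportion", "percent", "bp"):
        raise ValueError(f"unknown scale {scale!r}")
    return DistMatrix(
        ids=aln.ids, values=values,
        model=model, deletion=deletion,
        scale="bp" if model == "bp" else scale,
    )


# ---------------------------------------------------------------------------
# Geographic distance and populations
# ---------------------------------------------------------------------------

def haversine_km(
    a: tuple[float, float], b: tuple[float, float], radius_km: float = EARTH_RADIUS_KM
) -> float:
    """Great-circle distance in km between (lat, lon) points in degrees."""
    if any(v is None for v in (*a, *b)):
        raise ValueError("haversine_km requires both coordinates")
    phi1, lam1 = math.radians(a[0]), math.radians(a[1])
    phi2, lam2 = math.radians(b[0]), math.radians(b[1])
    s = math.sin((phi2 - phi1) / 2.0) ** 2 + (
        math.cos(phi1) * math.cos(phi2) * math.sin((lam2 - lam1) / 2.0) ** 2
    )
    return 2.0 * radius_km * math.asin(min(1.0, math.sqrt(s)))


@dataclass
class Population:
    pop_id: str
    member_ids: tuple[str, ...]
    centroid: tuple[float, float]   # (lat, lon)
    region: str
    site_names: tuple[str, ...]


@dataclass
class PopulationMap:
    populations: list[Population]
    excluded_ids: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.populations)

    def population_of(self, seq_id: str) -> Population | None:
        for pop in self.populations:
            if seq_id in pop.member_ids:
                return pop
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pop in self.populations:
            for sid in pop.member_ids:
                rows.append(
                    {
                        "population": pop.pop_id,
                        "seq_id": sid,
                        "region": pop.region,
                        "centroid_lat": pop.centroid[0],
                        "centroid_lon": pop.centroid[1],
                    }
                )
        return pd.DataFrame(rows)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def assign_populations(
    specimens: list[SpecimenRecord],
    radius_km: float = 5.0,
    single_linkage: bool = True,
) -> PopulationMap:
    """Group specimens into populations by shared site or proximity.

    Two specimens are linked when their site names are identical or both are
    located within ``radius_km`` (strict ``<``) of each other.  With
    ``single_linkage`` (default) links are closed transitively so that a
    chain of nearby sites forms one population; with strict pairwise mode a
    site joins a population only if it is within the radius of every current
    member (documented alternative).  Unlocated specimens with a site name
    are grouped by name; specimens with neither coordinates nor site name
    are excluded with a warning.
    """
    usable = [r for r in specimens if r.located or r.site_name]
    excluded = tuple(r.seq_id for r in specimens if not (r.located or r.site_name))
    if excluded:
        logger.warning(
            "assign_populations: %d unlocated specimens excluded", len(excluded)
        )
    n = len(usable)
    uf = _UnionFind(n)
    for i, j in itertools.combinations(range(n), 2):
        a, b = usable[i], usable[j]
        if a.site_name and a.site_name == b.site_name:
            uf.union(i, j)
        elif a.located and b.located:
            if haversine_km((a.lat, a.lon), (b.lat, b.lon)) < radius_km:
                uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    if not single_linkage:
        # strict pairwise: split closure groups into maximal cliques greedily
        # by insertion order (deterministic)
        refined: list[list[int]] = []
        for idx in groups.values():
            cliques: list[list[int]] = []
            for i in idx:
                placed = False
                for clique in cliques:
                    ok = all(_linked(usable[i], usable[j], radius_km) for j in clique)
                    if ok:
                        clique.append(i)
                        placed = True
                        break
                if not placed:
                    cliques.append([i])
            refined.extend(cliques)
        groups = dict(enumerate(refined))

    populations: list[Population] = []
    # deterministic ordering: by smallest member index
    for k, idx in enumerate(sorted(groups.values(), key=min)):
        members = [usable[i] for i in idx]
        located = [m for m in members if m.located]
        if located:
            centroid = (
                float(np.mean([m.lat for m in located])),
                float(np.mean([m.lon for m in located])),
            )
        else:
            centroid = (math.nan, math.nan)
        regions = sorted({m.region for m in members})
        if len(regions) > 1:
            logger.warning(
                "assign_populations: population P%d spans regions %s", k + 1, regions
            )
        populations.append(
            Population(
                pop_id=f"P{k + 1}",
                member_ids=tuple(m.seq_id for m in members),
                centroid=centroid,
                region=regions[0],
                site_names=tuple(sorted({m.site_name for m in members if m.site_name})),
            )
        )
    logger.info(
        "assign_populations: %d specimens -> %d populations (radius %.1f km)",
        n, len(populations), radius_km,
    )
    return PopulationMap(populations=populations, excluded_ids=excluded)


def _linked(a: SpecimenRecord, b: SpecimenRecord, radius_km: float) -> bool:
    if a.site_name and a.site_name == b.site_name:
        return True
    if a.located and b.located:
        return haversine_km((a.lat, a.lon), (b.lat, b.lon)) < radius_km
    return False


# ---------------------------------------------------------------------------
# Contrast table
# ---------------------------------------------------------------------------

#: Region pairs (unordered) mapped to contrast class; pairs involving only
#: Italy, or Iberia with Italy, are excluded from the models.
CONTRAST_OF_REGIONS = {
    frozenset(("EU",)): "EUEU",
    frozenset(("EU", "IB")): "EUIB",
    frozenset(("EU", "IT")): "EUIT",
    frozenset(("IB",)): "IBIB",
}


@dataclass
class ContrastRow:
    species: str
    pop_a: str
    pop_b: str
    contrast: str
    max_div: float      # percent K2P
    geo_km: float
    n_max: int


def contrast_label(region_a: str, region_b: str) -> str:
    """Contrast class of an unordered region pair ('other' when excluded)."""
    return CONTRAST_OF_REGIONS.get(frozenset((region_a, region_b)), "other")


def contrast_table(
    dms: dict[str, DistMatrix],
    pops: PopulationMap,
    specimens: list[SpecimenRecord],
) -> list[ContrastRow]:
    """Per-species, per-population-pair maximum divergence contrasts.

    ``dms`` maps species to a per-species distance matrix on K2P% scale (a
    single pooled matrix may be passed under the key '*').  One row is
    produced for every species and unordered pair of populations both
    holding at least one sequence of that species; ``max_div`` is the
    maximum distance over all cross-population pairs of individuals.
    """
    species_of = {r.seq_id: r.species for r in specimens}
    rows: list[ContrastRow] = []
    all_species = sorted({r.species for r in specimens})
    for species in all_species:
        dm = dms.get(species, dms.get("*"))
        if dm is None:
            continue
        dm_ids = set(dm.ids)
        pop_members = []
        for pop in pops.populations:
            ids = [
                sid for sid in pop.member_ids
                if species_of.get(sid) == species and sid in dm_ids
            ]
            if ids:
                pop_members.append((pop, ids))
        for (pa, ids_a), (pb, ids_b) in itertools.combinations(pop_members, 2):
            max_div = max(dm.get(i, j) for i in ids_a for j in ids_b)
            if any(math.isnan(c) for c in (*pa.centroid, *pb.centroid)):
                geo = math.nan
            else:
                geo = haversine_km(pa.centroid, pb.centroid)
            rows.append(
                ContrastRow(
                    species=species,
                    pop_a=pa.pop_id,
                    pop_b=pb.pop_id,
                    contrast=contrast_label(pa.region, pb.region),
                    max_div=max_div,
                    geo_km=geo,
                    n_max=max(len(ids_a), len(ids_b)),
                )
            )
    logger.info("contrast_table: %d rows over %d species", len(rows), len(all_species))
    return rows


def contrasts_to_frame(rows: list[ContrastRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [r.species for r in rows],
            "pop_a": [r.pop_a for r in rows],
            "pop_b": [r.pop_b for r in rows],
            "contrast": [r.contrast for r in rows],
            "max_div_pct": [r.max_div for r in rows],
            "geo_km": [r.geo_km for r in rows],
            "n_max": [r.n_max for r in rows],
        }
    )


def max_divergence_summary(rows: list[ContrastRow]) -> pd.DataFrame:
    """Species x contrast table of maximum K2P% divergence (NA when absent)."""
    df = contrasts_to_frame(rows)
    df = df[df["contrast"] != "other"]
    if df.empty:
        return pd.DataFrame(columns=["EUEU", "EUIB", "EUIT", "IBIB"])
    out = df.pivot_table(
        index="species", columns="contrast", values="max_div_pct", aggfunc="max"
    )
    return out.reindex(columns=["EUEU", "EUIB", "EUIT", "IBIB"])
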