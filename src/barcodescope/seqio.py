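"""Alignment and specimen-metadata I/O, haplotype collapsing, numt screening.

The analyses downstream all start from an aligned set of COI barcode
sequences plus a per-specimen metadata table (species, collection site,
country, coordinates).  This module reads and validates both, collapses
sequences into unique haplotypes, and screens for nuclear mitochondrial
insertions (numts) by translating every sequence in the three forward
reading frames and looking for internal stop codons: the mitochondrial COI
gene is intronless, so a genuine mitochondrial barcode must have at least
one stop-free frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("barcodescope")

#: IUPAC nucleotide symbols accepted in alignments (plus the gap symbol).
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

#: Default mapping from country to biogeographic region used in the
#: population contrasts: Iberia (IB), Italy (IT), everything else in Europe
#: (EU).  Balkan countries are deliberately left in EU.
DEFAULT_COUNTRY_REGIONS: dict[str, str] = {
    "Spain": "IB",
    "Portugal": "IB",
    "Italy": "IT",
}

VALID_REGIONS = ("IB", "IT", "EU")


class AlignmentError(ValueError):
    """Raised for ragged, duplicated or out-of-alphabet alignment input."""


class MetadataError(ValueError):
    """Raised for invalid specimen metadata."""


@dataclass(frozen=True)
class AlignedSeqSet:
    """An alignment: equal-length uppercase nucleotide sequences with ids."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - IUPAC_ALPHABET
            if bad:
                raise AlignmentError(
                    f"sequence {sid!r} contains non-IUPAC symbols: {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        """Alignment length in bp (0 for an empty set)."""
        return len(self.seqs[0]) if self.seqs else 0

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.seqs))

    def get(self, seq_id: str) -> str:
        return self.seqs[self.ids.index(seq_id)]

    def subset(self, keep_ids) -> "AlignedSeqSet":
        keep = [i for i in self.ids if i in set(keep_ids)]
        idx = {i: k for k, i in enumerate(self.ids)}
        return AlignedSeqSet(
            ids=tuple(keep), seqs=tuple(self.seqs[idx[i]] for i in keep)
        )

    def crop(self, start: int, end: int) -> "AlignedSeqSet":
        """Crop all sequences to the half-open column range [start, end)."""
        if not (0 <= start < end <= self.length):
            raise AlignmentError(f"invalid crop range [{start}, {end})")
        return AlignedSeqSet(
            ids=self.ids, seqs=tuple(s[start:end] for s in self.seqs)
        )


@dataclass(frozen=True)
class SpecimenRecord:
    """Metadata for one sequenced specimen."""

    seq_id: str
    species: str
    site_name: str
    country: str
    region: str
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.region not in VALID_REGIONS:
            raise MetadataError(
                f"{self.seq_id}: region {self.region!r} not in {VALID_REGIONS}"
            )
        if (self.lat is None) != (self.lon is None):
            raise MetadataError(
                f"{self.seq_id}: lat and lon must both be present or both missing"
            )
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise MetadataError(f"{self.seq_id}: latitude {self.lat} out of range")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise MetadataError(f"{self.seq_id}: longitude {self.lon} out of range")

    @property
    def located(self) -> bool:
        return self.lat is not None


@dataclass
class HaplotypeTable:
    """Unique haplotypes with their member sequence ids.

    ``haplotypes`` is a list of ``(representative_seq, member_ids, count)``
    tuples; the representative is the first-seen member sequence.  When
    collapsing was done within species separately, ``per_species`` is True
    and ``species_of`` maps each haplotype index to its species.
    """

    haplotypes: list[tuple[str, tuple[str, ...], int]]
    per_species: bool = False
    species_of: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def total_members(self) -> int:
        return sum(count for _, _, count in self.haplotypes)

    def representative_ids(self) -> list[str]:
        return [members[0] for _, members, _ in self.haplotypes]

    def to_alignment(self) -> AlignedSeqSet:
        """Alignment of representatives, named after the first member."""
        return AlignedSeqSet(
            ids=tuple(self.representative_ids()),
            seqs=tuple(seq for seq, _, _ in self.haplotypes),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, (seq, members, count) in enumerate(self.haplotypes):
            rows.append(
                {
                    "haplotype": f"H{k + 1}",
                    "species": self.species_of[k] if self.per_species else "",
                    "representative": members[0],
                    "count": count,
                    "members": ";".join(members),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class NumtScreenReport:
    """Per-sequence stop-codon screen across the three forward frames."""

    seq_ids: list[str]
    frames: list[int]          # frame (0/1/2) minimising internal stops
    stop_counts: list[int]     # stop count in that frame
    flagged: list[bool]        # True iff every frame contains a stop
    skipped: list[str] = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return sum(self.flagged)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seq_id": self.seq_ids,
                "frame": self.frames,
                "stop_codons": self.stop_counts,
                "flagged": self.flagged,
            }
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_alignment(path) -> AlignedSeqSet:
    """Read a FASTA alignment, uppercasing and validating the records.

    Raises :class:`AlignmentError` on ragged lengths, duplicate ids or
    symbols outside the IUPAC nucleotide alphabet.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    aln = AlignedSeqSet(ids=tuple(ids), seqs=tuple(seqs))
    logger.info("read_alignment: %d records x %d bp from %s", len(aln), aln.length, path)
    return aln


def write_alignment(aln: AlignedSeqSet, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln
    ]
    SeqIO.write(records, str(path), "fasta")
    logger.info("write_alignment: %d records to %s", len(aln), path)


def read_specimens(
    path,
    country_region_map: dict[str, str] | None = None,
    alignment_ids=None,
) -> list[SpecimenRecord]:
    """Read the specimen metadata TSV (seq_id species site country [region] lat lon).

    The region column is optional; when absent it is filled from
    ``country_region_map`` (unmapped countries default to EU).  Records with
    missing coordinates are retained.  If ``alignment_ids`` is given, ids
    absent from the alignment trigger a cross-reference warning only.
    """
    cmap = dict(DEFAULT_COUNTRY_REGIONS)
    if country_region_map:
        cmap.update(country_region_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"seq_id", "species", "site", "country"}
    missing = required - set(df.columns)
    if missing:
        raise MetadataError(f"metadata missing required columns: {sorted(missing)}")
    records: list[SpecimenRecord] = []
    for _, row in df.iterrows():
        region = row.get("region")
        if pd.isna(region) or region in (None, ""):
            region = cmap.get(row["country"], "EU")
        lat = row.get("lat")
        lon = row.get("lon")
        lat = None if pd.isna(lat) or lat == "" else float(lat)
        lon = None if pd.isna(lon) or lon == "" else float(lon)
        records.append(
            SpecimenRecord(
                seq_id=row["seq_id"],
                species=row["species"],
                site_name=row["site"],
                country=row["country"],
                region=str(region),
                lat=lat,
                lon=lon,
            )
        )
    if alignment_ids is not None:
        unknown = [r.seq_id for r in records if r.seq_id not in set(alignment_ids)]
        if unknown:
            logger.warning(
                "read_specimens: %d metadata ids absent from alignment (e.g. %s)",
                len(unknown), unknown[:3],
            )
    logger.info("read_specimens: %d records from %s", len(records), path)
    return records


def specimens_to_frame(records: list[SpecimenRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq_id": [r.seq_id for r in records],
            "species": [r.species for r in records],
            "site": [r.site_name for r in records],
            "country": [r.country for r in records],
            "region": [r.region for r in records],
            "lat": [r.lat for r in records],
            "lon": [r.lon for r in records],
        }
    )


def write_specimens(records: list[SpecimenRecord], path) -> None:
    specimens_to_frame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------

def collapse_haplotypes(
    aln: AlignedSeqSet,
    specimens: list[SpecimenRecord] | None = None,
) -> HaplotypeTable:
    """Collapse identical sequences into unique haplotypes.

    Identity is exact string equality after uppercasing: gaps and ambiguity
    codes are distinct symbols, so two sequences differing only A vs N are
    two haplotypes.  With ``specimens`` given, collapsing is done within
    each species separately (two species sharing a string keep separate
    haplotypes); the representative is always the first-seen member.
    """
    if specimens is None:
        species_by_id = None
    else:
        species_by_id = {r.seq_id: r.species for r in specimens}

    order: list[tuple[str, str]] = []          # (key-group, sequence) first-seen order
    members: dict[tuple[str, str], list[str]] = {}
    for sid, seq in aln:
        group = species_by_id.get(sid, "?") if species_by_id else ""
        key = (group, seq)
        if key not in members:
            members[key] = []
            order.append(key)
        members[key].append(sid)

    haplotypes = [
        (seq, tuple(members[(group, seq)]), len(members[(group, seq)]))
        for group, seq in order
    ]
    table = HaplotypeTable(
        haplotypes=haplotypes,
        per_species=species_by_id is not None,
        species_of=[group for group, _ in order] if species_by_id else [],
    )
    logger.info(
        "collapse_haplotypes: %d sequences -> %d haplotypes%s",
        len(aln), len(table), " (per species)" if species_by_id else "",
    )
    return table


# ---------------------------------------------------------------------------
# Numt screen
# ---------------------------------------------------------------------------

def _stops_in_frame(seq: str, frame: int, stop_codons: frozenset[str]) -> int | None:
    """Stop codons in one forward frame, skipping gap/ambiguous codons.

    Gap columns are removed before framing.  Codons containing '-', 'N' or
    any ambiguity symbol are skipped rather than translated.  The barcode is
    an internal gene fragment, so every stop is an internal stop.  Returns
    None when no complete codon is available.
    """
    bases = seq.replace("-", "")
    codons = [bases[i : i + 3] for i in range(frame, len(bases) - 2, 3)]
    if not codons:
        return None
    return sum(1 for c in codons if set(c) <= set("ACGT") and c in stop_codons)


def screen_numts(
    aln: AlignedSeqSet,
    genetic_code: int = 5,
    check_reverse: bool = False,
) -> NumtScreenReport:
    """Screen each sequence for in-frame internal stop codons.

    Translation uses the invertebrate mitochondrial code (NCBI table 5) by
    default.  Each sequence is read in the three forward frames after
    dropping gap columns; the frame minimising internal stop codons is
    reported, and a sequence is flagged iff that minimum is positive (no
    stop-free frame exists — the expected numt signature).  With
    ``check_reverse`` the three reverse-complement frames are also tried.
    """
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    stop_codons = frozenset(table.stop_codons)

    seq_ids: list[str] = []
    frames: list[int] = []
    stop_counts: list[int] = []
    flagged: list[bool] = []
    skipped: list[str] = []
    for sid, seq in aln:
        candidates = [(frame, seq) for frame in range(3)]
        if check_reverse:
            rc = str(Seq(seq).reverse_complement())
            candidates += [(frame + 3, rc) for frame in range(3)]
        best_frame, best_stops = None, None
        for frame, s in candidates:
            stops = _stops_in_frame(s, frame % 3, stop_codons)
            if stops is None:
                continue
            if best_stops is None or stops < best_stops:
                best_frame, best_stops = frame, stops
        if best_stops is None:
            skipped.append(sid)
            logger.warning("screen_numts: %s too short to translate; skipped", sid)
            continue
        seq_ids.append(sid)
        frames.append(best_frame)
        stop_counts.append(best_stops)
        flagged.append(best_stops > 0)

    report = NumtScreenReport(
        seq_ids=seq_ids, frames=frames, stop_counts=stop_counts,
        flagged=flagged, skipped=skipped,
    )
    logger.info(
        "screen_numts: %d sequences screened, %d flagged", len(seq_ids), report.n_flagged
    )
    return report
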