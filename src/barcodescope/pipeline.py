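"""Config-driven orchestration of the whole analysis.

Reads an alignment and specimen metadata, screens for numts, collapses
haplotypes, computes per-species K2P distances, builds populations and the
divergence contrast table, delimits species by GMYC (on a supplied
ultrametric tree or a UPGMA tree built from the haplotypes), barcode-gap
partitioning and MOTU clustering, and fits the divergence mixed models.
Outputs are plain CSV/JSON files in the configured directory, each tagged
with the hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import distance_delim, distances, geostats, gmyc, seqio

logger = logging.getLogger("barcodescope")


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""


@dataclass
class PipelineConfig:
    alignment: str
    specimens: str
    outdir: str = "barcodescope_out"
    tree: str | None = None
    ranges: str | None = None
    region_map: dict = field(default_factory=dict)
    model: str = "k2p"
    deletion: str = "pairwise"
    radius_km: float = 5.0
    gmyc_mode: str = "both"            # single | multiple | both
    abgd_priors: list = field(default_factory=lambda: list(distance_delim.DEFAULT_PRIORS))
    abgd_gap_widths: list = field(default_factory=lambda: list(distance_delim.DEFAULT_GAP_WIDTHS))
    abgd_models: list = field(default_factory=lambda: [["jc69", None], ["k80", 2.0], ["k80", 4.0]])
    motu_cutoffs: list = field(default_factory=lambda: list(range(3, 24)))
    motu_min_len: int = 500
    motu_overlap: float = 0.90
    motu_crop: list | None = None      # [start, end) columns for MOTU input
    lmm_pairs: list = field(default_factory=lambda: [["EUEU", "EUIB"], ["EUEU", "EUIT"], ["EUEU", "IBIB"]])
    lmm_ibib_cap_km: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(c) <= 0 for c in self.motu_cutoffs):
            raise ValueError("MOTU cutoffs must be positive integers")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis settings (the output directory is not one)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _write_csv(df, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns a report dict (also written as JSON)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    report: dict = {"config_hash": chash}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("seqio")
        aln = seqio.read_alignment(cfg.alignment)
        specimens = seqio.read_specimens(
            cfg.specimens, country_region_map=cfg.region_map, alignment_ids=aln.ids
        )
        numt = seqio.screen_numts(aln)
        _write_csv(numt.to_frame(), outdir / "numt_report.csv", chash)
        haplos = seqio.collapse_haplotypes(aln, specimens)
        _write_csv(haplos.to_frame(), outdir / "haplotypes.csv", chash)
        report["n_sequences"] = len(aln)
        report["n_haplotypes"] = len(haplos)
        report["n_numt_flagged"] = numt.n_flagged
    except Exception as exc:
        raise StageError(f"seqio: {exc}") from exc

    try:
        stage("distances")
        species_of = {r.seq_id: r.species for r in specimens}
        dms = {}
        for species in sorted({r.species for r in specimens}):
            ids = [i for i in aln.ids if species_of.get(i) == species]
            if len(ids) >= 2:
                dms[species] = distances.distance_matrix(
                    aln.subset(ids), model=cfg.model,
                    deletion=cfg.deletion, scale="percent",
                )
        pops = distances.assign_populations(specimens, radius_km=cfg.radius_km)
        _write_csv(pops.to_frame(), outdir / "populations.csv", chash)
        rows = distances.contrast_table(dms, pops, specimens)
        _write_csv(distances.contrasts_to_frame(rows), outdir / "contrasts.csv", chash)
        maxdiv = distances.max_divergence_summary(rows).reset_index()
        _write_csv(maxdiv, outdir / "max_divergence_by_contrast.csv", chash)
        report["n_populations"] = len(pops)
        report["n_contrast_rows"] = len(rows)
    except Exception as exc:
        raise StageError(f"distances: {exc}") from exc

    try:
        stage("gmyc")
        hap_aln = haplos.to_alignment()
        if cfg.tree:
            tree = gmyc.UltraTree.read(cfg.tree)
        else:
            hap_dm = distances.distance_matrix(
                hap_aln, model=cfg.model, deletion=cfg.deletion
            )
            tree = gmyc.upgma_ultrametric(hap_dm)
        tree.write(outdir / "gmyc_input_tree.nwk")
        otu_totals = {}
        if cfg.gmyc_mode in ("single", "both"):
            fit_s = gmyc.fit_gmyc_single(tree, seed=cfg.seed)
            fit_s.write_json(outdir / "gmyc_single.json")
            _write_csv(fit_s.entities.to_frame(), outdir / "gmyc_single_entities.csv", chash)
            otu_totals["gmyc_single"] = fit_s.n_entities
            report["gmyc_single"] = fit_s.summary()
        if cfg.gmyc_mode in ("multiple", "both"):
            start = fit_s if cfg.gmyc_mode == "both" else None
            fit_m = gmyc.fit_gmyc_multiple(tree, single_fit=start, seed=cfg.seed)
            fit_m.write_json(outdir / "gmyc_multiple.json")
            _write_csv(fit_m.entities.to_frame(), outdir / "gmyc_multiple_entities.csv", chash)
            otu_totals["gmyc_multiple"] = fit_m.n_entities
            report["gmyc_multiple"] = fit_m.summary()
    except Exception as exc:
        raise StageError(f"gmyc: {exc}") from exc

    try:
        stage("distance_delim")
        grid = distance_delim.abgd_grid(
            hap_aln,
            priors=cfg.abgd_priors,
            gap_widths=cfg.abgd_gap_widths,
            models=[tuple(m) for m in cfg.abgd_models],
        )
        _write_csv(grid, outdir / "abgd_grid.csv", chash)
        default_cfg = distance_delim.ABGDConfig(prior=0.01, gap_width=1.5, model="jc69")
        dm_jc = distance_delim.distance_matrix(hap_aln, model="jc69")
        initial, recursive = distance_delim.abgd_partition(dm_jc, default_cfg)
        _write_csv(recursive.to_frame(), outdir / "abgd_partition.csv", chash)
        otu_totals["abgd"] = len(recursive)

        motu_aln = hap_aln
        if cfg.motu_crop:
            motu_aln = hap_aln.crop(int(cfg.motu_crop[0]), int(cfg.motu_crop[1]))
        sweep = distance_delim.motu_sweep(
            motu_aln, cutoffs=[int(c) for c in cfg.motu_cutoffs],
            min_len=cfg.motu_min_len, overlap_frac=cfg.motu_overlap,
        )
        _write_csv(sweep, outdir / "motu_sweep.csv", chash)
        otu_totals["motu_min_cutoff"] = int(sweep["motus"].iloc[0])
        otu_totals["motu_max_cutoff"] = int(sweep["motus"].iloc[-1])
        report["otu_totals"] = otu_totals
        import pandas as pd

        _write_csv(
            pd.DataFrame([otu_totals]), outdir / "otu_comparison.csv", chash
        )
    except Exception as exc:
        raise StageError(f"distance_delim: {exc}") from exc

    try:
        stage("geostats")
        lmm_results = {}
        for pair in cfg.lmm_pairs:
            pair = tuple(pair)
            cap = cfg.lmm_ibib_cap_km if set(pair) == {"EUEU", "IBIB"} else None
            try:
                fit = geostats.fit_divergence_lmm(rows, contrast_pair=pair, max_geo_km=cap)
                lmm_results["_vs_".join(pair)] = fit.to_dict()
            except ValueError as exc:
                logger.warning("LMM %s skipped: %s", pair, exc)
        report["lmm"] = lmm_results
        with open(outdir / "lmm_results.json", "w") as fh:
            json.dump(lmm_results, fh, indent=2)
        if cfg.ranges:
            ranges = geostats.read_range_limits(cfg.ranges)
            lats = sorted(
                set(
                    range(
                        int(ranges["south_lat"].min()),
                        int(ranges["north_lat"].max()) + 1,
                    )
                )
            )
            richness = geostats.richness_by_latitude(ranges, lats)
            _write_csv(richness, outdir / "richness_by_latitude.csv", chash)
            trend = geostats.fit_latitude_trend(
                richness["lat"], richness["n_species"], degree=1
            )
            report["richness_trend"] = trend.to_dict()
    except Exception as exc:
        raise StageError(f"geostats: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    logger.info("pipeline complete: outputs in %s", outdir)
    return report
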