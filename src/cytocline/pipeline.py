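"""End-to-end orchestration: simulate -> transect -> co-introgression scan
-> climate associations -> quantitative genetics -> chloroplast divergence.

Each stage reads and writes plain files under a single output directory,
records its status and wall time in a RunReport, and failures in one stage
skip only the stages that depend on its outputs. The report is fully
determined by (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import assoc, cointro, cpdiff, geometry, io_tables, quantgen, synthdata
from .cline import ClineData

logger = logging.getLogger(__name__)

_KNOWN_SECTIONS = {"seed", "output_dir", "simulate", "scan", "assoc", "quantgen", "cpdiff"}

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "output_dir": "cytocline_out",
    "simulate": {
        "enabled": True,
        "n_samples": 300,
        "n_genes": 100,
        "co_fraction": 0.1,
        "cp_center": 0.43,
        "cp_width": 0.05,
        "nuc_center": 0.5,
        "nuc_width": 0.3,
    },
    "scan": {"n_starts": 8},
    "assoc": {},
    "quantgen": {"trait_name": "PhiPSII"},
    "cpdiff": {},
}


class ConfigError(ValueError):
    pass


def validate_config(config: Mapping[str, Any]) -> dict[str, Any]:
    unknown = set(config) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in config.items():
        if isinstance(v, Mapping):
            merged[k].update(v)
        else:
            merged[k] = v
    if not isinstance(merged["seed"], int):
        raise ConfigError("seed must be an integer")
    return merged


def config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StageResult:
    status: str  # "ok", "failed", "skipped"
    seconds: float = 0.0
    error: str | None = None


@dataclass
class RunReport:
    config_hash: str
    seed: int
    stages: dict[str, StageResult] = field(default_factory=dict)
    summary: dict[str, Any] = field(default_factory=dict)

    @property
    def failed(self) -> bool:
        return any(s.status == "failed" for s in self.stages.values())

    def to_json(self) -> str:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": {k: dataclasses.asdict(v) for k, v in self.stages.items()},
            "summary": self.summary,
        }
        # wall times vary run to run; they are reported but not part of the
        # deterministic summary block
        return json.dumps(payload, indent=1, sort_keys=True, default=float)


def _stage(report: RunReport, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                report.stages[name] = StageResult("ok", dt)
                logger.info("stage %s ok (%.2fs)", name, dt)
                return True
            report.stages[name] = StageResult("failed", dt, f"{exc_type.__name__}: {exc}")
            logger.error("stage %s failed: %s", name, exc)
            return True  # swallow; downstream stages decide via status

    return _Ctx()


def run_all(config: Mapping[str, Any], force: bool = True) -> RunReport:
    """Run every stage in dependency order and return the RunReport.

    ``force=False`` skips a stage whose output files already exist.
    Stage failures are recorded; independent stages still run.
    """
    cfg = validate_config(config)
    seed = cfg["seed"]
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config_hash(cfg), seed=seed)

    paths = {
        "samples": out / "samples.tsv",
        "ancestry": out / "ancestry_matrix.tsv",
        "genes": out / "genes.gff3",
        "climate": out / "climate.tsv",
        "traits": out / "traits.tsv",
        "alignment": out / "cp_alignment.fasta",
        "cds": out / "cp_cds.gff3",
        "truth": out / "truth.json",
        "transect": out / "transect.tsv",
        "verdicts": out / "cointro_verdicts.tsv",
        "assoc": out / "climate_assoc.tsv",
        "quantgen": out / "quantgen.json",
        "cpdiff": out / "cpdiff.tsv",
        "report": out / "run_report.json",
    }

    if cfg["simulate"].get("enabled", True):
        sim_done = all(paths[k].exists() for k in
                       ("samples", "ancestry", "genes", "climate", "traits",
                        "alignment", "cds"))
        if sim_done and not force:
            report.stages["simulate"] = StageResult("skipped")
        else:
            with _stage(report, "simulate"):
                hz_kwargs = {k: v for k, v in cfg["simulate"].items() if k != "enabled"}
                hz = synthdata.HybridZoneConfig(**hz_kwargs)
                samples, matrix, genes, truth = synthdata.generate_hybrid_zone(hz, seed)
                climate, truth = synthdata.generate_climate(
                    synthdata.ClimateConfig(), seed, samples, truth.transect, truth)
                traits, truth = synthdata.generate_traits(
                    synthdata.TraitConfig(trait_name=cfg["quantgen"]["trait_name"]),
                    seed, samples, truth)
                aln, cds, aln_truth = synthdata.generate_cp_alignment(
                    synthdata.AlignmentConfig(), seed)
                truth.planted_fixed_diffs = aln_truth.planted_fixed_diffs
                io_tables.write_sample_table(samples, paths["samples"])
                io_tables.write_ancestry_matrix(matrix, paths["ancestry"])
                io_tables.write_gene_annotations(genes, paths["genes"])
                io_tables.write_results(climate, paths["climate"], "TSV")
                io_tables.write_results(traits, paths["traits"], "TSV")
                io_tables.write_fasta(aln, paths["alignment"])
                io_tables.write_gene_annotations(cds, paths["cds"], feature="CDS")
                with open(paths["truth"], "w") as fh:
                    json.dump(_truth_json(truth), fh, indent=1, sort_keys=True)

    samples = transect = None
    with _stage(report, "transect"):
        samples = io_tables.read_sample_table(paths["samples"])
        positions = []
        for zone in sorted({s.contact_zone for s in samples}):
            zs = [(s.sample_id, s.lat, s.lon) for s in samples if s.contact_zone == zone]
            positions += geometry.scale_transect(zs)
        io_tables.write_results(positions, paths["transect"], "TSV")
        transect = {p.sample_id: p.distance_scaled for p in positions}

    with _stage(report, "cointro"):
        if transect is None:
            raise RuntimeError("transect stage did not produce positions")
        matrix = io_tables.read_ancestry_matrix(paths["ancestry"])
        genes = io_tables.read_gene_annotations(paths["genes"], "GFF3")
        cp_x, cp_y = [], []
        for s in samples:
            if s.chlorotype in ("PB", "PT") and s.sample_id in transect:
                cp_x.append(transect[s.sample_id])
                cp_y.append(1.0 if s.chlorotype == "PT" else 0.0)
        cp_data = ClineData(np.array(cp_x), np.array(cp_y), "bernoulli")
        gene_data = {
            g.gene_id: cointro.gene_ancestry_data(matrix, g, transect) for g in genes
        }
        nuc_data = cointro.mean_nuclear_data(matrix, genes, transect)
        n_starts = cfg["scan"].get("n_starts", 8)
        cp_ref = cointro.build_reference(
            "chloroplast", cp_data, n_starts=n_starts, seed=seed)
        nuc_ref = cointro.build_reference(
            "nuclear_mean", nuc_data, n_starts=n_starts, seed=seed)
        verdicts, summary = cointro.scan(
            gene_data, cp_data, nuc_data, n_starts=n_starts, seed=seed,
            cp_ref=cp_ref, nuc_ref=nuc_ref)
        rows = [
            {
                "gene_id": v.gene_id,
                "classification": v.classification,
                "center": None if v.gene_fit is None else v.gene_fit.spec.center,
                "width": None if v.gene_fit is None else v.gene_fit.spec.width,
                "overlap_cp": v.overlap_cp,
                "overlap_nuc": v.overlap_nuc,
                "lrt_cp_stat": None if v.lrt_cp is None else v.lrt_cp[0],
                "lrt_cp_p": None if v.lrt_cp is None else v.lrt_cp[1],
                "lrt_nuc_stat": None if v.lrt_nuc is None else v.lrt_nuc[0],
                "lrt_nuc_p": None if v.lrt_nuc is None else v.lrt_nuc[1],
            }
            for v in verdicts
        ]
        io_tables.write_results(rows, paths["verdicts"], "TSV")
        report.summary["cointro"] = {
            "n_genes": summary.n_genes,
            "n_co_introgressing": summary.n_co_introgressing,
            "n_independent": summary.n_independent,
            "n_ambiguous": summary.n_ambiguous,
            "n_unevaluable": summary.n_unevaluable,
            "cp_center": round(cp_ref.fit.spec.center, 6),
            "cp_width": round(cp_ref.fit.spec.width, 6),
            "nuc_center": round(nuc_ref.fit.spec.center, 6),
            "nuc_width": round(nuc_ref.fit.spec.width, 6),
        }

    with _stage(report, "assoc"):
        climate = io_tables.read_climate_table(paths["climate"])
        fits = assoc.climate_scan(samples, climate)
        io_tables.write_results(fits, paths["assoc"], "TSV")
        report.summary["climate_slopes"] = {
            f"{f.contact_zone}:{f.variable}": (None if f.slope is None else round(f.slope, 6))
            for f in fits
        }

    with _stage(report, "quantgen"):
        traits = io_tables.read_trait_table(paths["traits"])
        anc = {s.genotype_id: (s.nuclear_q, s.chlorotype) for s in samples}
        trait_name = cfg["quantgen"]["trait_name"]
        h2 = {}
        for garden in sorted({t.garden for t in traits}):
            vc = quantgen.estimate_h2(traits, garden, trait_name)
            h2[garden] = round(vc.H2, 6)
        fit = quantgen.fit_cytonuclear(traits, anc, trait_name)
        payload = {
            "H2": h2,
            "beta": {k: round(v, 6) for k, v in fit.beta.items()},
            "wald_p": {k: round(v, 6) for k, v in fit.wald_p.items()},
            "r2_marginal": round(fit.r2_marginal, 6),
            "r2_conditional": round(fit.r2_conditional, 6),
        }
        with open(paths["quantgen"], "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        report.summary["quantgen"] = payload

    with _stage(report, "cpdiff"):
        aln = cpdiff.read_alignment(paths["alignment"])
        cds = io_tables.read_gene_annotations(paths["cds"], "GFF3")
        a_ids = sorted(k for k in aln if k.startswith("A"))
        b_ids = sorted(k for k in aln if k.startswith("B"))
        ref_seq = aln[a_ids[0]]
        diffs = cpdiff.find_fixed_differences(aln, a_ids, b_ids)
        diffs = cpdiff.classify_effects(diffs, cds, ref_seq)
        io_tables.write_results(diffs, paths["cpdiff"], "TSV")
        report.summary["cpdiff"] = {
            "n_fixed": len(diffs),
            "n_nonsynonymous": sum(d.effect == "nonsynonymous" for d in diffs),
            "n_synonymous": sum(d.effect == "synonymous" for d in diffs),
            "n_noncoding": sum(d.effect == "noncoding" for d in diffs),
        }

    with open(paths["report"], "w") as fh:
        fh.write(report.to_json())
    return report


def _truth_json(truth: synthdata.SyntheticTruth) -> dict:
    def spec_dict(s):
        return None if s is None else {
            "center": s.center, "width": s.width,
            "scaling": s.scaling, "tails": s.tails,
        }

    return {
        "seed": truth.seed,
        "transect": truth.transect,
        "cp_cline": spec_dict(truth.cp_cline),
        "nuclear_cline": spec_dict(truth.nuclear_cline),
        "gene_clines": {k: spec_dict(v) for k, v in truth.gene_clines.items()},
        "co_introgressing": truth.co_introgressing,
        "climate_slopes": truth.climate_slopes,
        "trait_betas": truth.trait_betas,
        "variance_components": truth.variance_components,
        "planted_fixed_diffs": truth.planted_fixed_diffs,
    }
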