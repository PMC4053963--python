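"""End-to-end orchestration: simulate (optional) -> call -> annotate ->
enrich -> quantify -> report.

A run is driven by a :class:`RunConfig` (usually loaded from YAML). Every
tabular output carries a header comment with the tool version, a hash of the
resolved configuration and the seed, so a rerun with the same config is
bit-identical for the deterministic stages. Stage failures raise
:class:`StageError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional

import yaml

from . import __version__
from .annotation import assign_promoters_to_vlincs, classify_promoter_repeats
from .caller import CallerParams, VlincRNA, call_from_contigs
from .enrichment import test_ltr_family_enrichment, test_promoter_overlap_stranded
from .expression import QuantParams, quantify
from .intervals import IntervalSet
from . import io as vio
from .synthetic import SimParams, Simulation, emit_contigs, simulate_annotation

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    simulate: Optional[Dict[str, Any]] = None  # SimParams overrides, or None
    inputs: Dict[str, Any] = field(default_factory=dict)
    caller: Dict[str, Any] = field(default_factory=dict)
    quant: Dict[str, Any] = field(default_factory=dict)
    enrichment: Dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict) or "outdir" not in raw:
            raise ConfigError("config must be a mapping with an 'outdir' key")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            required = ("chrom_sizes", "genes", "contigs", "promoters")
            missing = [k for k in required if k not in self.inputs]
            if missing:
                raise ConfigError(
                    f"no 'simulate' section and missing inputs: {missing}"
                )
            paths = [self.inputs["chrom_sizes"], self.inputs["genes"]]
            paths += list(self.inputs["contigs"].values())
            paths += list(self.inputs["promoters"].values())
            for extra in ("repeats", "blacklist"):
                if extra in self.inputs:
                    paths.append(self.inputs[extra])
            for p in paths:
                if not Path(p).exists():
                    raise ConfigError(f"input file not found: {p}")
        try:
            CallerParams(**self.caller)
            QuantParams(**self.quant)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def content_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        payload.pop("log_level", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return (
        f"vlincscan {__version__}\n"
        f"config_hash {config.content_hash()}\n"
        f"seed {config.seed}"
    )


def run_pipeline(config: RunConfig) -> Dict[str, Any]:
    """Execute the full pipeline; returns the machine-readable summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _header(config)
    summary: Dict[str, Any] = {
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": {},
    }

    # ---- stage: simulate / load ------------------------------------------
    stage = "simulate" if config.simulate is not None else "load"
    try:
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            sim = simulate_annotation(SimParams(**sim_kwargs))
            contigs_by_sample = emit_contigs(sim)
            genome = sim.genome
            genes = sim.gene_set
            promoters_by_line = sim.promoters_by_line
            repeats = sim.repeats
            blacklist = sim.blacklist
            groups = sim.params.groups
            write_simulation_inputs(sim, contigs_by_sample, outdir / "inputs")
        else:
            genome = vio.read_chrom_sizes(config.inputs["chrom_sizes"])
            genes = IntervalSet(vio.read_bed(config.inputs["genes"]))
            contigs_by_sample = {
                sample: vio.read_contig_bed(path)
                for sample, path in config.inputs["contigs"].items()
            }
            promoters_by_line = {
                line: vio.read_promoter_bed(path, line)
                for line, path in config.inputs["promoters"].items()
            }
            repeats = (
                vio.read_repeat_bed(config.inputs["repeats"])
                if "repeats" in config.inputs
                else []
            )
            blacklist = (
                IntervalSet(vio.read_bed(config.inputs["blacklist"]))
                if "blacklist" in config.inputs
                else IntervalSet()
            )
            groups = config.inputs.get("groups", {})
        summary["stages"][stage] = {
            "samples": len(contigs_by_sample),
            "genes": len(genes),
            "promoter_lines": len(promoters_by_line),
            "repeats": len(repeats),
        }
    except (ConfigError,):
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # ---- stage: call ------------------------------------------------------
    try:
        params = CallerParams(**config.caller)
        vlincs_by_sample: Dict[str, List[VlincRNA]] = {}
        for sample, contigs in contigs_by_sample.items():
            called = call_from_contigs(contigs, genes, params, sample=sample)
            vlincs_by_sample[sample] = called
            vio.write_bed(
                [v.interval for v in called],
                outdir / f"vlincs.{sample}.bed",
                names=[v.vlinc_id for v in called],
                header=header,
            )
        summary["stages"]["call"] = {
            s: len(v) for s, v in vlincs_by_sample.items()
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("call", exc) from exc

    # ---- stage: annotate --------------------------------------------------
    try:
        classified = {
            line: classify_promoter_repeats(proms, repeats)
            for line, proms in promoters_by_line.items()
        }
        assignment_rows = []
        ltr_flags: Dict[str, bool] = {}
        for sample, vlincs in vlincs_by_sample.items():
            proms = classified.get(sample)
            if proms is None:
                continue
            for v, a in zip(
                vlincs, assign_promoters_to_vlincs(vlincs, proms)
            ):
                ltr_flags[v.vlinc_id] = a.ltr_driven
                assignment_rows.append(
                    (
                        v.vlinc_id,
                        sample,
                        ",".join(sorted(a.categories)) or ".",
                        "LTR" if a.ltr_driven else "non-LTR",
                        len(a.promoter_indices),
                    )
                )
        with open(outdir / "assignments.tsv", "w") as fh:
            for line_ in header.splitlines():
                fh.write(f"#{line_}\n")
            fh.write("vlinc_id\tsample\tcategories\tpromoter_type\tn_promoters\n")
            for row in assignment_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        summary["stages"]["annotate"] = {
            "assigned": sum(1 for r in assignment_rows if r[4] > 0),
            "ltr_driven": sum(ltr_flags.values()),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("annotate", exc) from exc

    # ---- stage: enrich ----------------------------------------------------
    try:
        enrich_rows = []
        for sample, vlincs in vlincs_by_sample.items():
            proms = classified.get(sample)
            if proms is None or not vlincs:
                continue
            res = test_promoter_overlap_stranded(
                vlincs, proms, genes, blacklist, genome,
                **config.enrichment.get("promoter", {}),
            )
            enrich_rows.append(
                ("promoter_overlap", sample, res.N, res.n_observed,
                 res.m_expected, res.fold, res.p_value, res.log10_p)
            )
        n_tests = max(1, len(enrich_rows))
        with open(outdir / "enrichment.tsv", "w") as fh:
            for line_ in header.splitlines():
                fh.write(f"#{line_}\n")
            fh.write(
                "test\tsample\tN\tn\tm\tfold\tp_value\tlog10_p\tbonferroni\n"
            )
            for row in enrich_rows:
                bonf = min(1.0, row[6] * n_tests)
                fh.write(
                    "\t".join(
                        f"{x:.6g}" if isinstance(x, float) else str(x)
                        for x in row
                    )
                    + f"\t{bonf:.6g}\n"
                )
        summary["stages"]["enrich"] = {"tests": len(enrich_rows)}
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrich", exc) from exc

    # ---- stage: quantify --------------------------------------------------
    try:
        all_vlincs = [v for vs in vlincs_by_sample.values() for v in vs]
        if all_vlincs:
            matrix = quantify(
                contigs_by_sample,
                all_vlincs,
                QuantParams(**config.quant),
                groups={s: g for s, g in groups.items() if g},
            )
            with open(outdir / "matrix.tsv", "w") as fh:
                for line_ in header.splitlines():
                    fh.write(f"#{line_}\n")
                matrix.values.to_csv(fh, sep="\t", float_format="%.6g")
            summary["stages"]["quantify"] = {
                "vlincs": len(matrix.vlinc_ids),
                "samples": len(matrix.samples),
            }
        else:
            summary["stages"]["quantify"] = {"vlincs": 0, "samples": 0}
    except Exception as exc:  # noqa: BLE001
        raise StageError("quantify", exc) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def write_simulation_inputs(
    sim: Simulation,
    contigs_by_sample: Mapping[str, list],
    directory: Path,
) -> None:
    """Materialise a simulation as the on-disk input dialects."""
    directory.mkdir(parents=True, exist_ok=True)
    vio.write_chrom_sizes(sim.genome, directory / "chrom.sizes")
    vio.write_bed(sim.genes, directory / "genes.bed")
    for line, proms in sim.promoters_by_line.items():
        vio.write_promoter_bed(proms, directory / f"promoters.{line}.bed")
    vio.write_repeat_bed(sim.repeats, directory / "repeats.bed")
    vio.write_bed(list(sim.blacklist), directory / "blacklist.bed")
    for sample, contigs in contigs_by_sample.items():
        vio.write_contig_bed(contigs, directory / f"contigs.{sample}.bed")
    with open(directory / "truth.tsv", "w") as fh:
        fh.write(
            "vlinc_id\tchrom\tstart\tend\tstrand\tsource_sample"
            "\tltr_driven\texpression\n"
        )
        for p in sim.truth.planted:
            iv = p.vlinc.interval
            expr = ",".join(
                f"{s}={v:.6g}" for s, v in sorted(p.expression.items())
            )
            fh.write(
                f"{p.vlinc.vlinc_id}\t{iv.chrom}\t{iv.start}\t{iv.end}"
                f"\t{iv.strand}\t{p.source_sample}\t{int(p.ltr_driven)}\t{expr}\n"
            )
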