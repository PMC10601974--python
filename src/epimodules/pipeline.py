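"""End-to-end orchestration from a declarative YAML config.

A run either consumes real input files (``inputs:`` section) or generates a
synthetic study first (``simulate:`` section). Stages run in order —
differential expression, differential methylation, FEM integration — and
every defaulted parameter is echoed into the resolved config and the JSON
run manifest, so a run can be reproduced from its manifest alone.
Outputs are deterministic given config + inputs + seed.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, replace
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import io as omio
from . import __version__
from .expression import NegativeBinomialDE, call_degs
from .fem import FEMParams, FunctionalEpigeneticModules, hypergeometric_ora
from .methylation import DifferentialMethylation
from .simulate import SimulationConfig, write_dataset

log = logging.getLogger("epimodules")


class ConfigError(ValueError):
    """Invalid or malformed pipeline configuration (exit code 2)."""


class InputError(ValueError):
    """Missing or unreadable input file (exit code 3)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 4)."""


DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "promoter": {"upstream": 1500, "downstream": 500},
    "coverage": {"min_cov": 10, "max_percentile": 99.9, "collapse_strands": True},
    "dmp": {"q_max": 0.01, "min_diff": 0.25},
    "dmg": {"min_dmps": 5},
    "deg": {"padj_max": 0.05, "lfc_min": 1.0},
    "de": {"pseudo_mean": 0.5, "dispersion_floor": 1e-8},
    "ppi": {"min_score": 400},
    "concordance": {"convention": "anticorrelated"},
    "fem": {
        "n_seeds": 100,
        "max_module_size": 100,
        "min_module_size": 5,
        "gain_tolerance": 1.05,
        "n_permutations": 1000,
        "p_max": 0.05,
        "dedup_jaccard": 0.9,
        "level": "promoter",
        "score_multiplier": False,
    },
}

INPUT_KEYS = {
    "counts", "groups", "regions", "regions_format", "case_coverage",
    "ctrl_coverage", "ppi", "id_map", "gene_sets", "de_table", "dmp_table",
}
TOP_KEYS = {"inputs", "simulate", "params", "rng_seed", "log_level"}


def _merge_defaults(
    section: Mapping[str, Any] | None, defaults: Mapping[str, Any], path: str
) -> dict[str, Any]:
    section = dict(section or {})
    unknown = set(section) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown key(s) under {path}: {sorted(unknown)}")
    out = dict(defaults)
    out.update(section)
    return out


class PipelineConfig:
    """Schema-validated configuration with all defaults filled in."""

    def __init__(self, raw: Mapping[str, Any]) -> None:
        unknown = set(raw) - TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        self.rng_seed = int(raw.get("rng_seed", 0))
        self.log_level = str(raw.get("log_level", "INFO"))
        params = dict(raw.get("params") or {})
        unknown = set(params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ConfigError(f"unknown key(s) under params: {sorted(unknown)}")
        self.params = {
            name: _merge_defaults(params.get(name), defaults, f"params.{name}")
            for name, defaults in DEFAULT_PARAMS.items()
        }
        self.simulate: SimulationConfig | None = None
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            valid = set(SimulationConfig.__dataclass_fields__)
            unknown = set(sim) - valid
            if unknown:
                raise ConfigError(
                    f"unknown key(s) under simulate: {sorted(unknown)}"
                )
            if "module_size_range" in sim:
                sim["module_size_range"] = tuple(sim["module_size_range"])
            sim.setdefault("rng_seed", self.rng_seed)
            try:
                self.simulate = SimulationConfig(**sim)
            except ValueError as exc:
                raise ConfigError(str(exc)) from None
        self.inputs = dict(raw.get("inputs") or {})
        unknown = set(self.inputs) - INPUT_KEYS
        if unknown:
            raise ConfigError(f"unknown key(s) under inputs: {sorted(unknown)}")
        if self.simulate is None:
            required = {
                "counts", "groups", "regions", "case_coverage",
                "ctrl_coverage", "ppi",
            }
            missing = required - set(self.inputs)
            if missing:
                raise ConfigError(
                    f"missing required input key(s): {sorted(missing)}"
                )
        self.inputs.setdefault("regions_format", "bed")

    def set_seed(self, seed: int) -> None:
        self.rng_seed = int(seed)
        if self.simulate is not None:
            self.simulate = replace(self.simulate, rng_seed=int(seed))

    def resolved(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "rng_seed": self.rng_seed,
            "log_level": self.log_level,
            "params": self.params,
            "inputs": {
                k: v for k, v in self.inputs.items() if isinstance(v, str)
            },
        }
        if self.simulate is not None:
            sim = asdict(self.simulate)
            sim["module_size_range"] = list(sim["module_size_range"])
            out["simulate"] = sim
        return out

    def fem_params(self) -> FEMParams:
        return FEMParams(rng_seed=self.rng_seed, **self.params["fem"])


def validate_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: {exc}") from None
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")
    return PipelineConfig(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path_str: str, what: str) -> Path:
    path = Path(path_str)
    if not path.exists():
        raise InputError(f"{what} file not found: {path}")
    return path


def _load_groups(spec) -> dict[str, str]:
    if isinstance(spec, Mapping):
        return dict(spec)
    path = _require(str(spec), "groups")
    with path.open() as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _materialize_inputs(config: PipelineConfig, outdir: Path) -> dict:
    inputs = dict(config.inputs)
    if config.simulate is not None:
        log.info("simulating synthetic dataset (seed=%d)", config.rng_seed)
        sim_paths = write_dataset(config.simulate, outdir / "inputs")
        merged = dict(sim_paths)
        merged["regions_format"] = "bed"
        for k, v in inputs.items():
            if k not in sim_paths:
                merged[k] = v
        inputs = merged
    return inputs


def stage_de(config: PipelineConfig, inputs: Mapping, outdir: Path) -> Path:
    """Compute (or import) the per-gene DE table; write de_table.tsv."""
    p = config.params
    if inputs.get("de_table"):
        de_table = omio.read_de_table(_require(inputs["de_table"], "DE table"))
        log.info("imported DE table with %d genes", len(de_table))
    else:
        groups = _load_groups(inputs["groups"])
        matrix = omio.read_counts_table(
            _require(inputs["counts"], "counts"), groups
        )
        model = NegativeBinomialDE(
            matrix,
            pseudo_mean=p["de"]["pseudo_mean"],
            dispersion_floor=p["de"]["dispersion_floor"],
        )
        de_table = model.fit().table
    de_path = outdir / "de_table.tsv"
    omio.write_de_table(de_table, de_path)
    return de_path


def _read_regions(config: PipelineConfig, inputs: Mapping):
    p = config.params
    return omio.read_regions(
        _require(inputs["regions"], "regions"),
        format=inputs.get("regions_format", "bed"),
        promoter_upstream=p["promoter"]["upstream"],
        promoter_downstream=p["promoter"]["downstream"],
    )


def stage_dm(
    config: PipelineConfig, inputs: Mapping, outdir: Path
) -> tuple[Path, Path]:
    """Compute (or import) the per-CpG DMP table and the DMG table."""
    p = config.params
    if inputs.get("dmp_table"):
        dmp_table = omio.read_dmp_table(
            _require(inputs["dmp_table"], "DMP table")
        )
        log.info("imported DMP table with %d CpGs", len(dmp_table))
    else:
        collapse = p["coverage"]["collapse_strands"]
        case_sites = omio.read_methylation_coverage(
            _require(inputs["case_coverage"], "case coverage"), collapse
        )
        ctrl_sites = omio.read_methylation_coverage(
            _require(inputs["ctrl_coverage"], "control coverage"), collapse
        )
        dm = DifferentialMethylation(
            case_sites, ctrl_sites,
            min_cov=p["coverage"]["min_cov"],
            max_percentile=p["coverage"]["max_percentile"],
        )
        dmp_table = dm.fit(
            q_max=p["dmp"]["q_max"], min_diff=p["dmp"]["min_diff"]
        ).table
    dmp_path = outdir / "dmp_table.tsv"
    omio.write_dmp_table(dmp_table, dmp_path)

    from .methylation import call_dmgs, count_dmps_by_region

    regions = _read_regions(config, inputs)
    dmg_table = call_dmgs(
        count_dmps_by_region(dmp_table, regions),
        min_dmps=p["dmg"]["min_dmps"],
    )
    dmg_path = outdir / "dmg_table.tsv"
    dmg_table.to_csv(dmg_path, sep="\t", index=False, float_format="%.12g")
    return dmp_path, dmg_path


def stage_fem(
    config: PipelineConfig, inputs: Mapping, outdir: Path,
    de_path: Path, dmp_path: Path,
):
    """Integrate the DE and DMP tables on the PPI and detect modules."""
    p = config.params
    de_table = omio.read_de_table(de_path)
    dmp_table = omio.read_dmp_table(dmp_path)
    regions = _read_regions(config, inputs)

    id_map = None
    if inputs.get("id_map"):
        id_map_df = pd.read_csv(
            _require(inputs["id_map"], "id map"), sep="\t",
            names=["protein", "gene"], comment="#",
        )
        id_map = dict(zip(id_map_df["protein"], id_map_df["gene"]))
    graph = omio.read_ppi_edges(
        _require(inputs["ppi"], "PPI"), id_map=id_map,
        min_score=p["ppi"]["min_score"],
    )
    log.info(
        "PPI: %d genes, %d edges (%d unmappable edges dropped)",
        graph.number_of_nodes(), graph.number_of_edges(),
        graph.graph.get("n_unmapped_edges", 0),
    )
    fem = FunctionalEpigeneticModules(
        graph, de_table, dmp_table, regions,
        params=config.fem_params(),
        deg_padj_max=p["deg"]["padj_max"],
        deg_lfc_min=p["deg"]["lfc_min"],
        dmg_min_dmps=p["dmg"]["min_dmps"],
    )
    return graph, fem.fit()


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    seed: int | None = None,
    stage: str = "all",
) -> dict[str, Any]:
    """Execute the configured stages; returns the result bundle manifest.

    ``stage`` limits execution: "de", "dm", "fem", or "all". On stage
    failure, partially written outputs are removed and an error log is left
    in the output directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config.set_seed(seed)
    written: list[Path] = []
    try:
        return _run(config, outdir, written, stage)
    except (ConfigError, InputError):
        raise
    except Exception as exc:
        for path in written:
            if path.exists():
                path.unlink()
        (outdir / "error.log").write_text(f"{type(exc).__name__}: {exc}\n")
        raise StageError(str(exc)) from exc


def _run(config: PipelineConfig, outdir: Path, written: list[Path], stage: str):
    p = config.params
    inputs = _materialize_inputs(config, outdir)

    resolved_path = outdir / "resolved_config.yaml"
    resolved = config.resolved()
    resolved["inputs"] = {
        k: str(v) for k, v in inputs.items() if isinstance(v, (str, Path))
    }
    resolved_path.write_text(
        yaml.safe_dump(resolved, sort_keys=True, default_flow_style=False)
    )
    written.append(resolved_path)

    manifest: dict[str, Any] = {
        "package_version": __version__,
        "rng_seed": config.rng_seed,
        "stage": stage,
        "parameters": config.params,
        "inputs": {
            k: {"path": str(v), "sha256": _sha256(Path(v))}
            for k, v in inputs.items()
            if isinstance(v, (str, Path)) and Path(v).is_file()
        },
        "outputs": {},
        "stats": {},
    }

    de_path = dmp_path = None
    if stage in ("de", "all", "fem"):
        if stage == "fem" and not inputs.get("de_table"):
            existing = outdir / "de_table.tsv"
            if existing.exists():
                de_path = existing
        if de_path is None:
            de_path = stage_de(config, inputs, outdir)
            written.append(de_path)
        manifest["outputs"]["de_table"] = str(de_path)
        de_table = omio.read_de_table(de_path)
        deg_up, deg_down = call_degs(
            de_table, p["deg"]["padj_max"], p["deg"]["lfc_min"]
        )
        manifest["stats"]["n_deg_up"] = len(deg_up)
        manifest["stats"]["n_deg_down"] = len(deg_down)
        log.info("DEGs: %d up, %d down", len(deg_up), len(deg_down))

    if stage in ("dm", "all", "fem"):
        if stage == "fem" and not inputs.get("dmp_table"):
            existing = outdir / "dmp_table.tsv"
            if existing.exists():
                dmp_path = existing
        if dmp_path is None:
            dmp_path, dmg_path = stage_dm(config, inputs, outdir)
            written.extend([dmp_path, dmg_path])
            manifest["outputs"]["dmg_table"] = str(dmg_path)
        manifest["outputs"]["dmp_table"] = str(dmp_path)
        dmp_table = omio.read_dmp_table(dmp_path)
        manifest["stats"]["n_cpgs_tested"] = int(len(dmp_table))
        manifest["stats"]["n_dmps"] = int((dmp_table["status"] != "ns").sum())

    if stage in ("fem", "all"):
        graph, results = stage_fem(
            config, inputs, outdir, de_path, dmp_path
        )
        dmg_path = outdir / "dmg_table.tsv"
        results.dmg_table.to_csv(
            dmg_path, sep="\t", index=False, float_format="%.12g"
        )
        written.append(dmg_path)
        manifest["outputs"]["dmg_table"] = str(dmg_path)

        report_path = outdir / "module_report.tsv"
        results.module_report().to_csv(
            report_path, sep="\t", index=False, float_format="%.12g"
        )
        written.append(report_path)
        manifest["outputs"]["module_report"] = str(report_path)

        modules_path = outdir / "modules.json"
        if results.significant_modules:
            omio.write_module_graph(
                results.significant_modules, modules_path, format="json"
            )
            written.append(modules_path)
            manifest["outputs"]["modules_json"] = str(modules_path)

        conc_path = outdir / "concordant_genes.txt"
        concordant = sorted(
            results.concordant_genes(p["concordance"]["convention"])
        )
        conc_path.write_text("".join(f"{g}\n" for g in concordant))
        written.append(conc_path)
        manifest["outputs"]["concordant_genes"] = str(conc_path)

        if inputs.get("gene_sets"):
            gene_sets = omio.read_gmt(
                _require(inputs["gene_sets"], "gene sets")
            )
            background = set(graph.nodes)
            hub_genes = set().union(
                *(m.members for m in results.significant_modules)
            ) if results.significant_modules else set()
            ora = hypergeometric_ora(
                hub_genes & background, background, gene_sets
            )
            ora_path = outdir / "ora_table.tsv"
            ora.to_csv(ora_path, sep="\t", index=False, float_format="%.12g")
            written.append(ora_path)
            manifest["outputs"]["ora_table"] = str(ora_path)

        manifest["stats"].update(
            {
                "n_dmgs": int(results.dmg_table["gene_id"].nunique()),
                "n_modules": len(results.modules),
                "n_significant_modules": len(results.significant_modules),
                "n_concordant_genes": len(concordant),
            }
        )

    manifest_path = outdir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written.append(manifest_path)
    log.info("run complete: %s", manifest_path)
    return manifest
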