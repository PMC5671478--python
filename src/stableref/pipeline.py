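"""Pipeline orchestration: screen → recommend → qPCR stability → DE.

A single YAML config enables any subset of the three analysis stages; each
stage reads the io-layer file formats, writes TSV outputs with a
``#stableref`` header, and records its record counts in a JSON run manifest
together with SHA-256 digests of every input and output.  Inputs of every
enabled stage are validated before any computation starts, and reruns on
identical inputs reproduce byte-identical stage outputs (all tie-breaking
is deterministic and output headers carry no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from stableref import __version__
from stableref.io import (
    build_isoform_index,
    read_cq_table,
    read_efficiency_table,
    read_expression_matrix,
    read_sample_design,
)
from stableref.normalize import concordance, de_calls_from_table, relative_de
from stableref.qpcr import evaluate_panel
from stableref.screen import (
    ScreenConfig,
    recommend_references,
    select_stable,
    transcript_stats,
)

logger = logging.getLogger("stableref")

__all__ = ["PipelineConfigError", "run_pipeline"]

STAGES = ("screen", "qpcr", "normde")


class PipelineConfigError(ValueError):
    """Raised before any compute when a stage's configuration is unusable."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(cfg: dict, stage: str, key: str) -> str:
    if key not in cfg or cfg[key] in (None, ""):
        raise PipelineConfigError(f"stage {stage!r}: missing required key {key!r}")
    return cfg[key]


def _check_input(stage: str, path: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise PipelineConfigError(f"stage {stage!r}: input file not found: {p}")
    return p


def _write_tsv(frame: pd.DataFrame, path: Path, command: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#stableref {__version__} {command}\n")
        frame.to_csv(fh, sep="\t")


def run_pipeline(config: str | Path | dict) -> dict:
    """Execute the configured stages and return the run manifest.

    ``config`` is a YAML file path or an equivalent dict with any of the
    top-level keys ``screen``, ``qpcr`` and ``normde``.  Returns the
    manifest dict (also written next to the first stage output as
    ``manifest.json`` when the config sets ``manifest:``).
    """
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        if not config_path.exists():
            raise PipelineConfigError(f"config file not found: {config_path}")
        raw = config_path.read_text()
        cfg = yaml.safe_load(raw) or {}
        config_digest = hashlib.sha256(raw.encode()).hexdigest()
        command = f"run --config {config_path.name}"
    else:
        cfg = dict(config)
        config_digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()
        command = "run --config <dict>"

    enabled = [s for s in STAGES if s in cfg]
    if not enabled:
        raise PipelineConfigError(
            f"config enables no stage; expected one of {STAGES}"
        )

    # validate every enabled stage's inputs up front
    inputs: dict[str, Path] = {}
    for stage in enabled:
        scfg = cfg[stage] or {}
        if stage == "screen":
            inputs[f"{stage}.matrix"] = _check_input(stage, _require(scfg, stage, "matrix"))
            if scfg.get("design"):
                inputs[f"{stage}.design"] = _check_input(stage, scfg["design"])
            if scfg.get("gtf"):
                inputs[f"{stage}.gtf"] = _check_input(stage, scfg["gtf"])
            elif scfg.get("out_candidates") and scfg.get("require_unique_isoform", True):
                raise PipelineConfigError(
                    "stage 'screen': out_candidates requires a gtf for the "
                    "isoform-uniqueness filter (or require_unique_isoform: false)"
                )
        elif stage == "qpcr":
            inputs[f"{stage}.cq"] = _check_input(stage, _require(scfg, stage, "cq"))
            if scfg.get("design"):
                inputs[f"{stage}.design"] = _check_input(stage, scfg["design"])
            if scfg.get("efficiencies"):
                inputs[f"{stage}.efficiencies"] = _check_input(stage, scfg["efficiencies"])
        elif stage == "normde":
            inputs[f"{stage}.matrix"] = _check_input(stage, _require(scfg, stage, "matrix"))
            inputs[f"{stage}.design"] = _check_input(stage, _require(scfg, stage, "design"))
            _require(scfg, stage, "hk")
            _require(scfg, stage, "treat")
            _require(scfg, stage, "control")
            if scfg.get("compare"):
                inputs[f"{stage}.compare"] = _check_input(stage, scfg["compare"])

    manifest: dict = {
        "command": command,
        "version": __version__,
        "config_sha256": config_digest,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {k: _sha256(p) for k, p in inputs.items()},
        "stages": {},
        "outputs": {},
    }

    for stage in enabled:
        scfg = cfg[stage] or {}
        logger.info("[%s] starting", stage)
        if stage == "screen":
            _run_screen(scfg, manifest)
        elif stage == "qpcr":
            _run_qpcr(scfg, manifest)
        elif stage == "normde":
            _run_normde(scfg, manifest)
        logger.info("[%s] done", stage)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    if cfg.get("manifest"):
        out = Path(cfg["manifest"])
        out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _screen_config(scfg: dict) -> ScreenConfig:
    kwargs = {}
    for key in (
        "cv_max", "mfc_max", "logcv_max", "expr_min", "expr_max",
        "require_unique_isoform", "detect_threshold",
    ):
        if key in scfg:
            kwargs[key] = scfg[key]
    return ScreenConfig(**kwargs)


def _run_screen(scfg: dict, manifest: dict) -> None:
    matrix = read_expression_matrix(scfg["matrix"], dialect=scfg.get("dialect", "tsv"))
    config = _screen_config(scfg)
    stats = transcript_stats(matrix, detect_threshold=config.detect_threshold)
    kept, ledger = select_stable(stats, config)
    index = build_isoform_index(scfg["gtf"]) if scfg.get("gtf") else None
    counts = {
        "n_transcripts": int(stats.shape[0]),
        "n_constitutive": int(stats["constitutive"].sum()),
        "n_stable": len(kept),
    }
    report = stats.copy()
    report["isoform_count"] = [
        (index.count_for_transcript(str(t)) if index else None) for t in stats.index
    ]
    report["passed"] = ledger["passed"]
    report["pass_clause"] = ledger["pass_clause"]
    report.index.name = "transcript_id"
    if scfg.get("out_stats"):
        path = Path(scfg["out_stats"])
        _write_tsv(report, path, "screen stats")
        manifest["outputs"]["screen.stats"] = _sha256(path)
    if index is None and config.require_unique_isoform and scfg.get("out_candidates"):
        raise PipelineConfigError(
            "screen: out_candidates requires a gtf for the isoform-uniqueness "
            "filter (or set require_unique_isoform: false)"
        )
    if index is not None or not config.require_unique_isoform:
        rec = recommend_references(stats, config, index)
        counts["n_recommended"] = int(rec.shape[0])
        if scfg.get("out_candidates"):
            path = Path(scfg["out_candidates"])
            rec.index.name = "transcript_id"
            _write_tsv(rec, path, "screen candidates")
            manifest["outputs"]["screen.candidates"] = _sha256(path)
    manifest["stages"]["screen"] = counts
    logger.info(
        "[screen] %d transcripts -> %d constitutive -> %d stable",
        counts["n_transcripts"], counts["n_constitutive"], counts["n_stable"],
    )


def _run_qpcr(scfg: dict, manifest: dict) -> None:
    eff = {}
    if scfg.get("efficiencies"):
        eff, _ = read_efficiency_table(scfg["efficiencies"])
    cq = read_cq_table(scfg["cq"], layout=scfg.get("layout", "wide"), efficiency_of=eff)
    design = read_sample_design(scfg["design"]) if scfg.get("design") else None
    use_groups = bool(scfg.get("use_groups", True)) and design is not None
    report, gn = evaluate_panel(cq, design=design, use_groups=use_groups)
    manifest["stages"]["qpcr"] = {
        "n_genes": int(report.shape[0]),
        "n_samples": len(cq.sample_ids),
        "optimal_n": gn.optimal_n,
        "v_flag": gn.v_flag,
    }
    if scfg.get("out"):
        path = Path(scfg["out"])
        _write_tsv(report, path, "qpcr stability")
        manifest["outputs"]["qpcr.stability"] = _sha256(path)
    if scfg.get("vcurve"):
        path = Path(scfg["vcurve"])
        vc = pd.DataFrame(
            {"n": list(gn.v_curve), "v": list(gn.v_curve.values())}
        ).set_index("n")
        _write_tsv(vc, path, "qpcr vcurve")
        manifest["outputs"]["qpcr.vcurve"] = _sha256(path)


def _run_normde(scfg: dict, manifest: dict) -> None:
    matrix = read_expression_matrix(scfg["matrix"], dialect=scfg.get("dialect", "tsv"))
    design = read_sample_design(scfg["design"])
    hk = scfg["hk"]
    if isinstance(hk, str):
        hk = [g.strip() for g in hk.split(",") if g.strip()]
    calls = relative_de(
        matrix, design, hk,
        treat=scfg["treat"], control=scfg["control"],
        fc_threshold=float(scfg.get("fc_threshold", 2.0)),
    )
    counts = {
        "n_genes": len(calls.gene_ids),
        "n_up": int((calls.table["call"] == "up").sum()),
        "n_down": int((calls.table["call"] == "down").sum()),
    }
    if scfg.get("compare"):
        ext = pd.read_csv(scfg["compare"], sep="\t", comment="#", index_col=0)
        ext_calls = de_calls_from_table(
            ext,
            fc_threshold=float(scfg.get("fc_threshold", 2.0)),
            significant_col=scfg.get("significant_col"),
        )
        summary = concordance(calls, ext_calls)
        counts["n_same_call"] = summary.n_same_call
        counts["n_same_direction_diff_magnitude"] = (
            summary.n_same_direction_diff_magnitude
        )
        counts["n_discordant"] = summary.n_discordant
    manifest["stages"]["normde"] = counts
    if scfg.get("out"):
        path = Path(scfg["out"])
        out = calls.table.copy()
        out.index.name = "gene"
        _write_tsv(out, path, "normde")
        manifest["outputs"]["normde.calls"] = _sha256(path)
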