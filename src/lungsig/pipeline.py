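"""End-to-end orchestration of the analysis stages.

Each stage is a pure function of (inputs, config, seed); `run_pipeline`
chains them and writes a JSON manifest recording the config hash, seed
and every output, so a rerun with identical inputs produces an identical
manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hotspots import (
    PCFParams,
    call_hotspots,
    compute_imd,
    count_breakpoints,
    fit_background,
    hotspots_to_frame,
    normalize_features,
)
from .io_formats import (
    ReferenceContext,
    read_matrix_tsv,
    read_mutations_dir,
    read_rearrangements,
    write_matrix_tsv,
)
from .mutation_catalog import build_catalog
from .rearrangements import attribution_table, build_rearrangement_catalog
from .signatures import dominance_labels, extract_signatures

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Configuration or input-path problem detected before any stage runs."""


@dataclass
class PipelineConfig:
    reference: str | None = None
    vcf_dir: str | None = None
    bedpe: str | None = None
    features: str | None = None
    cohort: str | None = None
    reference_signatures: str | None = None
    out_dir: str = "lungsig_out"
    seed: int = 0
    nmf_rank: int = 3
    nmf_restarts: int = 20
    nmf_max_iter: int = 5000
    nmf_tol: float = 1e-8
    pcf_gamma: float = 8.0
    pcf_kmin: int = 8
    pcf_i: int = 2
    bin_size: int = 500_000
    stats_n_groups: int = 10
    dominance_threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self, stages: list[str]) -> None:
        need = {
            "catalog": ["reference", "vcf_dir"],
            "signatures": ["reference", "vcf_dir"],
            "rearr": ["bedpe"],
            "hotspots": ["bedpe", "features"],
            "stats": ["cohort"],
        }
        for stage in stages:
            for key in need.get(stage, []):
                val = getattr(self, key)
                if val is None:
                    raise ValidationError(f"stage {stage!r} requires config key {key!r}")
                if not Path(val).exists():
                    raise ValidationError(f"stage {stage!r}: path {val!r} does not exist")

    def digest(self) -> str:
        # out_dir is where results land, not part of the analysis identity
        payload = json.dumps(
            {f.name: getattr(self, f.name) for f in fields(self) if f.name != "out_dir"},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


ALL_STAGES = ["catalog", "signatures", "rearr", "hotspots", "stats"]


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages (default: all applicable) and return the
    manifest. Any stage failure raises with the stage name attached."""
    stages = stages or ALL_STAGES
    config.validate(stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "outputs": {},
        "timing_s": {},
    }
    state: dict = {}
    for stage in stages:
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](config, out, state, manifest)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["timing_s"][stage] = round(time.time() - t0, 3)
        logger.info("stage %s done in %.1fs", stage, manifest["timing_s"][stage])
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _stage_catalog(config: PipelineConfig, out: Path, state: dict, manifest: dict) -> None:
    mutations = read_mutations_dir(config.vcf_dir)
    reference = ReferenceContext(config.reference)
    catalog = build_catalog(mutations, reference)
    path = out / "mutation_catalog.tsv"
    catalog.to_tsv(path)
    state["catalog"] = catalog
    manifest["outputs"]["mutation_catalog"] = str(path)


def _stage_signatures(config: PipelineConfig, out: Path, state: dict, manifest: dict) -> None:
    catalog = state.get("catalog")
    if catalog is None:
        _stage_catalog(config, out, state, manifest)
        catalog = state["catalog"]
    model = extract_signatures(
        catalog.matrix, rank=config.nmf_rank, restarts=config.nmf_restarts,
        seed=config.seed, max_iter=config.nmf_max_iter, tol=config.nmf_tol,
        sample_ids=catalog.sample_ids,
    )
    model.signature_names = [f"MS{i + 1}" for i in range(model.rank)]
    p_path = out / "ms_profiles.tsv"
    e_path = out / "ms_exposures.tsv"
    d_path = out / "ms_dominance.tsv"
    write_matrix_tsv(model.profiles, catalog.channel_labels, model.signature_names,
                     p_path, index_name="channel")
    write_matrix_tsv(model.exposures, model.signature_names, catalog.sample_ids,
                     e_path, index_name="signature")
    dominance_labels(model, config.dominance_threshold).to_csv(d_path, sep="\t")
    state["ms_model"] = model
    manifest["outputs"].update(
        ms_profiles=str(p_path), ms_exposures=str(e_path), ms_dominance=str(d_path)
    )


def _stage_rearr(config: PipelineConfig, out: Path, state: dict, manifest: dict) -> None:
    records = read_rearrangements(config.bedpe)
    catalog = build_rearrangement_catalog(records)
    nonzero = catalog.counts.sum(axis=1) > 0
    ids = [s for s, ok in zip(catalog.sample_ids, nonzero) if ok]
    model = extract_signatures(
        catalog.matrix[:, nonzero], rank=min(config.nmf_rank, len(ids) - 1),
        restarts=config.nmf_restarts, seed=config.seed,
        max_iter=config.nmf_max_iter, tol=config.nmf_tol, sample_ids=ids,
    )
    model.signature_names = [f"RS{i + 1}" for i in range(model.rank)]
    c_path = out / "rearrangement_catalog.tsv"
    p_path = out / "rs_profiles.tsv"
    a_path = out / "rs_attribution.tsv"
    catalog.to_tsv(c_path)
    write_matrix_tsv(model.profiles, catalog.category_labels, model.signature_names,
                     p_path, index_name="category")
    attribution_table([r for r in records if r.sample_id in set(ids)], model).to_csv(
        a_path, sep="\t", index=False
    )
    state["rearr_records"] = records
    state["rs_model"] = model
    manifest["outputs"].update(
        rearrangement_catalog=str(c_path), rs_profiles=str(p_path),
        rs_attribution=str(a_path),
    )


def _stage_hotspots(config: PipelineConfig, out: Path, state: dict, manifest: dict) -> None:
    records = state.get("rearr_records") or read_rearrangements(config.bedpe)
    breakpoints = compute_imd(records)
    bins = pd.read_csv(config.features, sep="\t")
    feature_cols = [c for c in bins.columns if c not in ("chrom", "start", "end", "observed")]
    bins = normalize_features(bins, feature_cols)
    bins = count_breakpoints(bins, breakpoints)
    background = fit_background(bins, feature_cols)
    params = PCFParams(gamma=config.pcf_gamma, kmin=config.pcf_kmin, i=config.pcf_i)
    hotspots = call_hotspots(breakpoints, background, bins, params)
    frame = hotspots_to_frame(hotspots)
    h_path = out / "hotspots.tsv"
    bed_path = out / "hotspots.bed"
    frame.to_csv(h_path, sep="\t", index=False)
    with open(bed_path, "w") as fh:
        for h in hotspots:
            fh.write(f"{h.chrom}\t{h.start - 1}\t{h.end}\t{h.n_breakpoints}\n")
    manifest["outputs"].update(hotspots=str(h_path), hotspots_bed=str(bed_path))
    manifest["background_model"] = {
        "m": background.m, "w": list(background.w),
        "dispersion": background.dispersion, "family": background.family,
    }


def _stage_stats(config: PipelineConfig, out: Path, state: dict, manifest: dict) -> None:
    from .stats import association_report

    model = state.get("ms_model")
    if model is not None:
        contributions = model.contributions_frame()
    else:
        exposures = read_matrix_tsv(Path(config.out_dir) / "ms_exposures.tsv")
        contributions = exposures / exposures.sum(axis=0)
    cohort = pd.read_csv(config.cohort, sep="\t")
    report = association_report(contributions, cohort, n_groups=config.stats_n_groups)
    path = out / "associations.tsv"
    report.to_csv(path, sep="\t", index=False)
    manifest["outputs"]["associations"] = str(path)


_STAGE_FUNCS = {
    "catalog": _stage_catalog,
    "signatures": _stage_signatures,
    "rearr": _stage_rearr,
    "hotspots": _stage_hotspots,
    "stats": _stage_stats,
}
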