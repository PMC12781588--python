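"""End-to-end orchestration: simulate -> QC -> match -> discover -> score.

One YAML-serialisable :class:`RunConfig` drives the whole discovery run;
outputs land in an artifact directory with a manifest recording the
config hash, seed, per-stage counts and a content hash per file so a
re-run with identical config reproduces every hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io_qc, matching, simulate
from .classifier import (
    TrainingPool, hierarchical_order, loocv_discovery, mds_embedding,
    score_samples, train_mvp,
)
from .diffmeth import differential_analysis
from .errors import ConfigurationError
from .io_qc import BetaMatrix, ProbeBlocklist, SampleSheet
from .selection import SelectionParams, select_probes
from .variants import load_domain_model, read_variant_table, run_burden


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "episignkit_run"
    # either simulate or load
    simulate: dict[str, Any] | None = None
    beta_path: str | None = None
    detp_path: str | None = None
    sheet_path: str | None = None
    blocklist_dir: str | None = None
    match: dict[str, Any] = field(default_factory=dict)
    selection: dict[str, Any] = field(default_factory=dict)
    run_loocv: bool = False
    adjust_cells: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_discovery(config: RunConfig) -> Path:
    """Run the full episignature discovery pipeline and write artifacts.

    Returns the artifact directory.  Stage counts (probes and samples in
    and out of each filter, funnel stage sizes) are recorded in
    ``manifest.json`` together with a content hash per output file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, Any] = {}

    if config.simulate is not None:
        sim_cfg = simulate.SimulationConfig(**{**config.simulate, "seed": config.seed})
        cohort = simulate.generate_cohort(sim_cfg)
        beta, detp, sheet = cohort.beta, cohort.detection_p, cohort.samples
        (out / "truth_probes.txt").write_text("\n".join(sorted(cohort.truth_probes)) + "\n")
    elif config.beta_path and config.sheet_path:
        beta = io_qc.read_beta_matrix(config.beta_path)
        sheet = io_qc.read_sample_sheet(config.sheet_path)
        detp = (
            io_qc.read_detection_p(config.detp_path)
            if config.detp_path
            else beta.values * 0.0
        )
    else:
        raise ConfigurationError("config needs either a simulate block or beta+sheet paths")

    # Sample QC first so failing samples cannot drive probe removal.
    qc = io_qc.sample_qc(detp)
    keep_samples = list(qc.loc[~qc["excluded"], "sample_id"])
    counts["samples_input"] = len(qc)
    counts["samples_excluded"] = int(qc["excluded"].sum())
    beta = beta.subset_samples(keep_samples)
    detp = detp[keep_samples]
    sheet = sheet.subset(keep_samples)

    blocklist = (
        io_qc.read_blocklist_dir(config.blocklist_dir)
        if config.blocklist_dir
        else ProbeBlocklist()
    )
    beta, probe_counts = io_qc.filter_probes(beta, detp, blocklist)
    counts["probes"] = probe_counts

    case_ids = sheet.ids_in_group("case")
    spec = matching.MatchSpec(**config.match) if config.match else matching.MatchSpec()
    assignment = matching.match_controls(
        sheet.subset(case_ids),
        SampleSheet(sheet.data[sheet.data["group"] == "control"].reset_index(drop=True)),
        spec,
    )
    control_ids = list(dict.fromkeys(assignment["control_id"]))
    assignment.to_csv(out / "matching.csv", index=False)
    counts["matched_controls"] = len(control_ids)

    train_ids = case_ids + control_ids
    stats = differential_analysis(
        beta.subset_samples(train_ids), sheet.subset(train_ids),
        adjust_cells=config.adjust_cells,
    )
    stats.reset_index().to_csv(out / "probe_stats.tsv", sep="\t", index=False)

    params = SelectionParams(**config.selection) if config.selection else SelectionParams()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        episig = select_probes(stats, beta, case_ids, control_ids, params)
    episig.to_json(out / "episignature.json")
    (out / "episignature_probes.txt").write_text("\n".join(episig.probe_ids) + "\n")
    counts["funnel"] = episig.stage_counts

    database_ids = sheet.ids_in_group("database")
    pool = TrainingPool(case_ids, control_ids, database_ids)
    model = train_mvp(episig, beta, pool, seed=config.seed)
    scored = score_samples(model, beta, beta.sample_ids)
    scored.drop(columns="per_fold_scores").to_csv(out / "mvp_scores.csv", index=False)

    plot_ids = train_ids
    mds = mds_embedding(beta.subset_probes(episig.probe_ids), plot_ids)
    mds.to_csv(out / "mds.csv")
    _, leaf_order = hierarchical_order(beta.subset_probes(episig.probe_ids), plot_ids)
    (out / "dendrogram_leaf_order.txt").write_text("\n".join(leaf_order) + "\n")

    if config.run_loocv:
        loocv = loocv_discovery(beta, sheet, pool, params, seed=config.seed,
                                adjust_cells=config.adjust_cells)
        loocv.to_csv(out / "loocv.csv", index=False)

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_counts": counts,
        "files": {
            p.name: _hash_file(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def run_burden_from_files(
    variants_path: str | Path,
    n_cases: int,
    n_controls: int,
    domains_path: str | Path | None = None,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Variant burden analysis from TSV inputs; optionally writes results."""
    variants = read_variant_table(variants_path)
    model = load_domain_model(domains_path)
    if variants.empty:
        warnings.warn("empty variant table; burden results will be empty")
        results = pd.DataFrame(
            columns=["scenario", "carrier_cases", "carrier_controls", "p_raw",
                     "p_adj", "odds_ratio", "or_cmle", "ci_low", "ci_high",
                     "significant"]
        )
    else:
        results = run_burden(variants, model, n_cases, n_controls)
    if out_path is not None:
        results.to_csv(out_path, sep="\t", index=False)
    return results
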