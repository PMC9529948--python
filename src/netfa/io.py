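"""Readers, writers, run configuration and pipeline orchestration.

Tabular dialects: comma-separated CSV for edge lists and covariate tables,
tab-separated TSV for numeric matrices and result tables, UTF-8, "NA" as
the missing-value marker.  Every result file starts with comment lines
recording the seed and a hash of the run configuration; a JSON manifest
lists the inputs, config, package versions and a SHA-256 per output so a
run can be verified later.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import TractFeatureMatrix, qc_filter_tracts
from .graph import METRICS, build_graph, network_summary, position_profiles, \
    transform_metrics
from .importance import necessity_analysis, sufficiency_analysis
from .model import RidgeCVConfig, run_outcome_family
from .synthetic import SyntheticSpec, generate_dataset

log = logging.getLogger("netfa")

__all__ = [
    "read_edge_list",
    "build_cohort_graphs",
    "read_covariates",
    "read_feature_matrix",
    "RunConfig",
    "run_pipeline",
    "verify_run",
]

_FLOAT_FMT = "%.17g"
ALL_STAGES = ("simulate", "metrics", "predict", "necessity", "sufficiency")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_edge_list(path) -> pd.DataFrame:
    """Roster-survey edge list CSV with columns ego_id, alter_id, cohort."""
    df = pd.read_csv(path, comment="#", dtype=str)
    required = {"ego_id", "alter_id", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def build_cohort_graphs(edges: pd.DataFrame, rosters: dict | None = None) -> dict:
    """One DirectedCohortGraph per cohort present in the edge table."""
    graphs = {}
    for cohort in sorted(edges["cohort"].unique()):
        sub = edges[edges["cohort"] == cohort]
        records = list(zip(sub["ego_id"], sub["alter_id"]))
        roster = rosters.get(cohort) if rosters else None
        graphs[cohort] = build_graph(records, cohort, roster=roster)
    return graphs


def read_covariates(path) -> pd.DataFrame:
    """Subject covariate CSV (age, gender, handedness, cohort, extraversion)."""
    df = pd.read_csv(path, comment="#", na_values=["NA"])
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing 'subject_id' column")
    df = df.set_index("subject_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicated subject ids")
    if "extraversion" in df.columns and \
            not pd.api.types.is_numeric_dtype(df["extraversion"]):
        raise ValueError(f"{path}: extraversion must be numeric")
    return df


def read_feature_matrix(path) -> TractFeatureMatrix:
    """TSV feature table with subject_id plus network::tract columns."""
    return TractFeatureMatrix.from_tsv(path)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run.

    Exactly one input source: real input paths (edges/fa_matrix/covariates)
    or a synthetic spec.  ``analyses`` selects stages from
    ``simulate | metrics | predict | necessity | sufficiency``.
    """

    output_dir: str = "netfa-run"
    analyses: tuple = ("simulate", "metrics", "predict")
    edges: str | None = None
    fa_matrix: str | None = None
    covariates: str | None = None
    synthetic: SyntheticSpec | None = None
    ridge: RidgeCVConfig = dataclasses.field(default_factory=RidgeCVConfig)
    networks: tuple | None = None
    necessity_targets: tuple | None = None  # ((network, outcome), ...) or None=auto
    qc_max_missing_fraction: float = 0.5
    n_permutations: int | None = None
    seed: int = 0
    log_level: str = "INFO"
    force: bool = False

    def validate(self):
        has_paths = any([self.edges, self.fa_matrix, self.covariates])
        if has_paths and self.synthetic is not None:
            raise ValueError("supply input paths or a synthetic spec, not both")
        if not has_paths and self.synthetic is None:
            self.synthetic = SyntheticSpec(seed=self.seed)
        for stage in self.analyses:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown analysis stage {stage!r}")
        need_inputs = {"metrics": ("simulate", "edges"),
                       "predict": ("simulate", "fa_matrix")}
        if "simulate" not in self.analyses:
            if "metrics" in self.analyses and self.edges is None:
                raise ValueError("metrics stage needs an edge list or simulate")
            for stage in ("predict", "necessity", "sufficiency"):
                if stage in self.analyses and self.fa_matrix is None:
                    raise ValueError(f"{stage} stage needs a feature matrix or simulate")
        del need_inputs

    # -- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ridge"] = self.ridge.to_dict()
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        d["analyses"] = list(self.analyses)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("ridge"):
            d["ridge"] = RidgeCVConfig.from_dict(d["ridge"])
        if d.get("synthetic"):
            syn = dict(d["synthetic"])
            for key in ("cohort_sizes", "imaged_per_cohort", "target_mean_degree",
                        "target_reciprocity"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            d["synthetic"] = SyntheticSpec(**syn)
        if d.get("analyses"):
            d["analyses"] = tuple(d["analyses"])
        known = {k: v for k, v in d.items() if k in
                 {f.name for f in dataclasses.fields(cls)}}
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        # hash the scientific configuration only, not where it is written
        d = self.to_dict()
        for key in ("output_dir", "force", "log_level"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# output helpers
# ---------------------------------------------------------------------------

def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig, index=True):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# seed={cfg.seed} config_hash={cfg.config_hash()} "
                 f"netfa={__version__}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", float_format=_FLOAT_FMT,
                  index=index)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the requested stages in dependency order.

    Writes result tables, a config snapshot and a manifest into
    ``cfg.output_dir`` and returns that directory.  Re-running with the
    same seed and configuration reproduces every table byte for byte; an
    existing completed run is never overwritten unless ``cfg.force``.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not cfg.force:
        raise FileExistsError(
            f"{out} already holds a completed run (use force to overwrite)"
        )
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    stages = [s for s in ALL_STAGES if s in cfg.analyses]
    outputs: list[Path] = []
    dataset = None
    graphs = None
    features = None
    covariates = None
    metrics_transformed = None

    if "simulate" in stages:
        spec = cfg.synthetic or SyntheticSpec(seed=cfg.seed)
        log.info("simulating synthetic cohorts (seed=%s)", spec.seed)
        dataset = generate_dataset(spec)
        graphs = dataset.graphs
        features = dataset.features
        covariates = dataset.covariates
        metrics_transformed = dataset.metrics_transformed

        edges = pd.DataFrame(
            [(e, a, g.cohort_id) for g in graphs.values()
             for e, a in sorted(g.edges)],
            columns=["ego_id", "alter_id", "cohort"],
        )
        p = out / "edges.csv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write(f"# seed={cfg.seed} config_hash={cfg.config_hash()}\n")
            edges.to_csv(fh, index=False)
        outputs.append(p)
        p = out / "fa_matrix.tsv"
        features.to_tsv(p, header_lines=[f"seed={cfg.seed} "
                                         f"config_hash={cfg.config_hash()}"])
        outputs.append(p)
        p = out / "covariates.csv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write(f"# seed={cfg.seed} config_hash={cfg.config_hash()}\n")
            covariates.to_csv(fh, float_format=_FLOAT_FMT, na_rep="NA")
        outputs.append(p)
        p = out / "ground_truth.tsv"
        dataset.truth.to_tsv(p)
        outputs.append(p)
    else:
        if cfg.edges:
            graphs = build_cohort_graphs(read_edge_list(cfg.edges))
        if cfg.fa_matrix:
            features = read_feature_matrix(cfg.fa_matrix)
        if cfg.covariates:
            covariates = read_covariates(cfg.covariates)

    if features is not None:
        features, qc_report = qc_filter_tracts(
            features, cfg.qc_max_missing_fraction)
        if len(qc_report):
            _write_table(qc_report, out / "qc_exclusions.tsv", cfg, index=False)
            outputs.append(out / "qc_exclusions.tsv")

    if "metrics" in stages:
        if graphs is None:
            raise ValueError("metrics stage requires graphs (simulate or edges)")
        log.info("computing position metrics for %d cohort(s)", len(graphs))
        raw = pd.concat([position_profiles(g) for g in graphs.values()])
        if metrics_transformed is None:
            subjects = (features.subject_ids if features is not None
                        else list(raw.index))
            try:
                metrics_transformed = transform_metrics(raw.loc[subjects])
            except ValueError as err:
                # degenerate toy inputs (a constant metric) still get a raw
                # metrics table; modeling stages would need the transform
                log.warning("within-cohort transform unavailable: %s", err)
        if metrics_transformed is not None:
            merged = raw.join(metrics_transformed.drop(columns="cohort"),
                              rsuffix="_transformed", how="left")
        else:
            merged = raw
        _write_table(merged, out / "metrics.tsv", cfg)
        outputs.append(out / "metrics.tsv")

        summaries = pd.DataFrame(
            [{"cohort": cid, **network_summary(g)} for cid, g in graphs.items()]
        )
        _write_table(summaries, out / "network_summary.tsv", cfg, index=False)
        outputs.append(out / "network_summary.tsv")

    ridge = cfg.ridge.replace(seed=cfg.seed)
    fam = None
    if "predict" in stages:
        if features is None or metrics_transformed is None:
            raise ValueError("predict stage requires features and metrics")
        outcomes = metrics_transformed.loc[features.subject_ids, list(METRICS)]
        log.info("running outcome-family prediction on networks %s",
                 cfg.networks or features.networks)
        fam = run_outcome_family(
            features, outcomes, ridge, covariates=covariates,
            networks=cfg.networks, n_permutations=cfg.n_permutations,
        )
        _write_table(fam.to_frame(), out / "prediction_results.tsv", cfg,
                     index=False)
        outputs.append(out / "prediction_results.tsv")
        detail = {
            f"{r.network}/{r.outcome}": {
                "r": r.r_observed, "p_perm": r.p_perm, "p_fdr": r.p_fdr,
                "lambda_per_fold": [float(v) for v in r.lambda_per_fold],
                "null_r": [float(v) for v in r.null_r],
            } for r in fam.results
        }
        p = out / "prediction_detail.json"
        p.write_text(json.dumps(detail, indent=1, sort_keys=True))
        outputs.append(p)

    if "necessity" in stages:
        if features is None or metrics_transformed is None:
            raise ValueError("necessity stage requires features and metrics")
        targets = cfg.necessity_targets
        if targets is None:
            if fam is None:
                raise ValueError(
                    "necessity with automatic target selection requires the "
                    "predict stage (or explicit necessity_targets)"
                )
            targets = [(r.network, r.outcome) for r in fam.results
                       if r.p_fdr is not None and r.p_fdr < 0.05]
            log.info("necessity targets (significant after FDR): %s", targets)
        tables = []
        for network, outcome in targets:
            y = metrics_transformed.loc[features.subject_ids, outcome]
            t = necessity_analysis(features, y, ridge, covariates=covariates,
                                   network=network,
                                   n_permutations=cfg.n_permutations)
            t.insert(0, "outcome", outcome)
            t.insert(0, "network", network)
            tables.append(t)
        nec = (pd.concat(tables, ignore_index=True) if tables
               else pd.DataFrame(columns=["network", "outcome", "tract",
                                          "r_full", "r_loo", "delta_r",
                                          "p_perm"]))
        _write_table(nec, out / "necessity.tsv", cfg, index=False)
        outputs.append(out / "necessity.tsv")

    if "sufficiency" in stages:
        if features is None or metrics_transformed is None:
            raise ValueError("sufficiency stage requires features and metrics")
        outcomes = metrics_transformed.loc[features.subject_ids, list(METRICS)]
        suf = sufficiency_analysis(features, outcomes, ridge,
                                   covariates=covariates,
                                   n_permutations=cfg.n_permutations)
        _write_table(suf, out / "sufficiency.tsv", cfg, index=False)
        outputs.append(out / "sufficiency.tsv")

    cfg.to_yaml(out / "config.yaml")
    outputs.append(out / "config.yaml")
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "netfa_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "inputs": {k: getattr(cfg, k) for k in ("edges", "fa_matrix", "covariates")},
        "analyses": list(cfg.analyses),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("run complete: %s", out)
    return out


def verify_run(run_dir) -> bool:
    """Re-check a run directory against its manifest (SHA-256 per output)."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    ok = True
    for name, digest in manifest["outputs"].items():
        path = run_dir / name
        if not path.exists():
            log.error("missing output %s", name)
            ok = False
        elif _sha256(path) != digest:
            log.error("checksum mismatch for %s", name)
            ok = False
    return ok
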