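"""End-to-end orchestration: simulate -> predict -> screen -> prioritize ->
enrich, with self-describing outputs and a reproducible run manifest.

Each stage writes a CSV whose header comments record the conventions used
(variogram family, thresholds, SD divisor, percentile method), so a result
file can be interpreted without the config that produced it.  The manifest
carries the config hash, package and library versions, per-stage row
counts, and collected warnings; rerunning with an identical config and
inputs reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd
import yaml

import coexmap
from coexmap.errors import CoexmapError, FitError, NumericalError
from coexmap.geometry import DomainGeometry, SampleSet, TargetMap, require_same_geometry
from coexmap.kriging import (
    fit_samples,
    krige_predict,
    loocv,
)
from coexmap.prioritize import PrioritizationConfig, map_sd, sd_percentile_selection
from coexmap.screen import (
    GeneRecord,
    ScreenConfig,
    screen_genes,
    spearman_map_correlation,
)
from coexmap.synthetic import SyntheticConfig, generate_study

QC_COLUMNS = ["gene_id", "nugget", "partial_sill", "range", "rsv", "loocv_r", "n_wells"]
RECORD_COLUMNS = ["gene_id", "rsv", "sd", "rho_target", "rho_seed_mrna", "loocv_r"]


def analyze_gene(
    samples: SampleSet,
    target: TargetMap,
    geometry: DomainGeometry,
    family: str = "exponential",
    refit_per_fold: bool = True,
    n_bins: int = 15,
    seed_map_values: np.ndarray | None = None,
) -> tuple[GeneRecord, np.ndarray]:
    """Run the per-gene prediction and statistics chain.

    Fits the variogram, kriges the gene onto the geometry, runs LOOCV, and
    correlates the predicted map with the target (and optionally with a
    seed gene's predicted map).  Returns the gene's record plus its
    predicted per-site values (NaN outside the solvable mask).
    """
    require_same_geometry(target.geometry, geometry)
    model = fit_samples(samples, family=family, n_bins=n_bins)
    pred = krige_predict(samples, model, geometry)
    cv = loocv(samples, family=family, refit_per_fold=refit_per_fold,
               n_bins=n_bins, model=model)
    joint = pred.geometry.mask & target.geometry.mask
    rho = spearman_map_correlation(pred.values, target.values, mask=joint)
    rho_seed = np.nan
    if seed_map_values is not None:
        rho_seed = spearman_map_correlation(pred.values, seed_map_values, mask=joint)
    record = GeneRecord(
        gene_id=samples.gene_id,
        rho_target=float(np.clip(rho, -1, 1)) if np.isfinite(rho) else np.nan,
        loocv_r=cv.loocv_r,
        sd=map_sd(pred.values, mask=pred.geometry.mask),
        rsv=model.rsv,
        rho_seed_mrna=float(np.clip(rho_seed, -1, 1)) if np.isfinite(rho_seed) else np.nan,
    )
    return record, pred.values


def run_synthetic_pipeline(
    config: SyntheticConfig,
    screen_config: ScreenConfig | None = None,
    prioritization_config: PrioritizationConfig | None = None,
    family: str = "exponential",
    refit_per_fold: bool = True,
) -> SimpleNamespace:
    """Full in-memory pipeline on one synthetic study.

    Returns a namespace with the domain, target, ground-truth driver
    indices, per-gene records, screen audit, screened and prioritized
    lists, and the target map SD used for prioritization.
    """
    screen_config = screen_config or ScreenConfig()
    prioritization_config = prioritization_config or PrioritizationConfig()
    domain, fields, target, drivers, samples = generate_study(config)
    records = []
    predicted = {}
    for ss in samples:
        try:
            rec, values = analyze_gene(
                ss, target, domain, family=family, refit_per_fold=refit_per_fold
            )
        except (FitError, NumericalError) as exc:
            warnings.warn(f"gene {ss.gene_id} unfittable: {exc}", stacklevel=2)
            rec, values = GeneRecord(gene_id=ss.gene_id), None
        records.append(rec)
        predicted[ss.gene_id] = values
    screened, audit = screen_genes(records, screen_config)
    target_sd = map_sd(target.values, mask=target.geometry.mask,
                       sd_definition=prioritization_config.sd_definition)
    prioritized = (
        sd_percentile_selection(screened, target_sd, prioritization_config)
        if screened
        else []
    )
    driver_ids = {samples[d].gene_id for d in drivers}
    return SimpleNamespace(
        config=config,
        domain=domain,
        target=target,
        target_sd=target_sd,
        drivers=drivers,
        driver_ids=driver_ids,
        samples=samples,
        records=records,
        predicted=predicted,
        screened=screened,
        audit=audit,
        prioritized=prioritized,
    )


# ---------------------------------------------------------------------------
# file-based runs and provenance
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths and settings of one file-based pipeline run."""

    output_dir: str = "coexmap_out"
    geometry_path: str | None = None
    target_path: str | None = None
    wells_path: str | None = None
    annotations_path: str | None = None
    annotation_metadata_path: str | None = None
    family: str = "exponential"
    refit_per_fold: bool = True
    n_bins: int = 15
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    prioritization: PrioritizationConfig = field(default_factory=PrioritizationConfig)
    synthetic: SyntheticConfig | None = None
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if d.get("synthetic") and d["synthetic"].get("driver_weights") is not None:
            d["synthetic"]["driver_weights"] = [
                float(w) for w in d["synthetic"]["driver_weights"]
            ]
        return d

    def config_hash(self) -> str:
        # the hash covers the scientific configuration, not where results land
        d = self.to_dict()
        d.pop("output_dir", None)
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def provenance_header(config_hash: str, seed: int, notes: dict) -> str:
    """Comment block prepended to every stage CSV (self-describing output)."""
    lines = [f"# coexmap {coexmap.__version__}", f"# config_hash: {config_hash}",
             f"# seed: {seed}"]
    lines += [f"# {k}: {v}" for k, v in notes.items()]
    return "\n".join(lines) + "\n"


def write_stage_csv(path, df: pd.DataFrame, config_hash: str, seed: int, notes: dict):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(config_hash, seed, notes))
        df.to_csv(fh, index=False)


def read_stage_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def records_to_frame(records: list[GeneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "rsv": r.rsv,
                "sd": r.sd,
                "rho_target": r.rho_target,
                "rho_seed_mrna": r.rho_seed_mrna,
                "loocv_r": r.loocv_r,
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )


def frame_to_records(df: pd.DataFrame) -> list[GeneRecord]:
    recs = []
    for _, row in df.iterrows():
        recs.append(
            GeneRecord(
                gene_id=str(row["gene_id"]),
                rho_target=float(row.get("rho_target", np.nan)),
                loocv_r=float(row.get("loocv_r", np.nan)),
                sd=float(row.get("sd", np.nan)),
                rsv=float(row.get("rsv", np.nan)),
                rho_seed_mrna=float(row.get("rho_seed_mrna", np.nan)),
            )
        )
    return recs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and write a run manifest.

    In simulate mode (``config.synthetic`` set) the study is generated
    in memory; otherwise geometry/target/wells are read from the
    configured paths.  Returns the manifest dict (also written to
    ``output_dir/manifest.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    caught: list[str] = []
    stage_counts: dict[str, int] = {}

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        if config.synthetic is not None:
            result = run_synthetic_pipeline(
                config.synthetic,
                screen_config=config.screen,
                prioritization_config=config.prioritization,
                family=config.family,
                refit_per_fold=config.refit_per_fold,
            )
        else:
            result = _run_from_files(config)
        caught.extend(str(w.message) for w in wlist)

    notes = {
        "family": config.family,
        "refit_per_fold": config.refit_per_fold,
        "rho_threshold": config.screen.rho_threshold,
        "rho_comparison": config.screen.rho_comparison,
        "cv_threshold": config.screen.cv_threshold,
        "cv_comparison": config.screen.cv_comparison,
        "sd_definition": config.prioritization.sd_definition,
        "percentile": config.prioritization.percentile,
        "percentile_method": "linear",
        "target_sd": f"{result.target_sd:.6g}",
    }
    write_stage_csv(out / "records.csv", records_to_frame(result.records),
                    chash, config.seed, notes)
    write_stage_csv(out / "screen_audit.csv", result.audit, chash, config.seed, notes)
    write_stage_csv(out / "screened.csv", records_to_frame(result.screened),
                    chash, config.seed, notes)
    write_stage_csv(out / "prioritized.csv", records_to_frame(result.prioritized),
                    chash, config.seed, notes)
    stage_counts = {
        "genes": len(result.records),
        "screened": len(result.screened),
        "prioritized": len(result.prioritized),
    }

    if config.annotations_path:
        from coexmap.enrich import adjust_results, fisher_overrepresentation
        from coexmap.io import read_annotations

        catalogue = read_annotations(
            config.annotations_path, metadata_path=config.annotation_metadata_path
        )
        study = [g.gene_id for g in result.prioritized]
        enr = adjust_results(fisher_overrepresentation(study, catalogue))
        enr_df = pd.DataFrame(
            [
                {
                    "term_id": r.term_id, "term_name": r.term_name,
                    "category": r.category, "count": r.k, "K": r.K,
                    "n": r.n, "N": r.N, "p_value": r.p_value,
                    "q_value": r.q_value, "genes": ";".join(r.study_gene_ids),
                }
                for r in sorted(enr, key=lambda r: (r.q_value, r.term_id))
            ]
        )
        write_stage_csv(out / "enrichment.csv", enr_df, chash, config.seed,
                        {**notes, "alpha": config.alpha})
        stage_counts["terms_tested"] = len(enr)
        stage_counts["terms_significant"] = int(
            sum(r.q_value < config.alpha for r in enr)
        )

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "config": config.to_dict(),
        "versions": {
            "coexmap": coexmap.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stage_counts": stage_counts,
        "warnings": caught,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_from_files(config: PipelineConfig) -> SimpleNamespace:
    """Predict/screen/prioritize from on-disk geometry, target and wells."""
    from coexmap.io import geometry_from_nifti, read_dense_map, read_samples

    for name in ("geometry_path", "target_path", "wells_path"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise CoexmapError(f"stage predict: missing input {name}={p!r}")
    geometry = geometry_from_nifti(config.geometry_path)
    target = read_dense_map(config.target_path, geometry)
    samples = read_samples(config.wells_path)
    records, predicted = [], {}
    for ss in samples:
        if not ss.fittable:
            records.append(GeneRecord(gene_id=ss.gene_id))
            continue
        try:
            rec, values = analyze_gene(
                ss, target, target.geometry, family=config.family,
                refit_per_fold=config.refit_per_fold, n_bins=config.n_bins,
            )
        except (FitError, NumericalError) as exc:
            warnings.warn(f"gene {ss.gene_id} unfittable: {exc}", stacklevel=2)
            rec, values = GeneRecord(gene_id=ss.gene_id), None
        records.append(rec)
        predicted[ss.gene_id] = values
    screened, audit = screen_genes(records, config.screen)
    target_sd = map_sd(target.values, mask=target.geometry.mask,
                       sd_definition=config.prioritization.sd_definition)
    prioritized = (
        sd_percentile_selection(screened, target_sd, config.prioritization)
        if screened
        else []
    )
    return SimpleNamespace(
        target=target, target_sd=target_sd, records=records, predicted=predicted,
        screened=screened, audit=audit, prioritized=prioritized,
    )


def both_region_genes(screened_a: pd.DataFrame, screened_b: pd.DataFrame) -> list[str]:
    """Genes passing the screen in both of two analyses (e.g. cortical
    surface and subcortical volume), sorted by gene_id."""
    return sorted(set(screened_a["gene_id"]) & set(screened_b["gene_id"]))
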