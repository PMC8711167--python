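"""End-to-end pipeline orchestration.

Runs the configured stages in order — simulate -> (segment) -> vectors ->
fit -> classify -> heterogeneity -> stats -> score — with every stage reading
its inputs from files, so a run can resume from any prior stage's outputs.
A single global seed expands into per-stage seeds through a fixed counter
scheme (SeedSequence of ``[global_seed, stage_index]``), and every randomized
choice (dye order, per-patient cap, subsampling) is recorded in the run
manifest together with output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, heterogeneity, pathology, strainspace, synthetic
from .spectra import (
    DEFAULT_DYES,
    WavelengthGrid,
    cap_vectors_per_patient,
    composites_from_table,
    draw_dye_order,
    SpectralMatrix,
)

logger = logging.getLogger("strainspec")

STAGE_ORDER = (
    "simulate",
    "segment",
    "vectors",
    "fit",
    "classify",
    "heterogeneity",
    "stats",
    "score",
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and offending records."""


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    output_dir: str = "run"
    input_spectra: str | None = None  # long-format CSV; None -> simulate
    input_covariates: str | None = None
    input_counts: str | None = None
    input_stack_dir: str | None = None  # TIFF stack directory for `segment`
    # synthetic-data conditions
    n_archetypes: int = 3
    ds_unique_weight: float = 0.3
    patients_per_cohort: dict[str, int] = field(
        default_factory=lambda: {"DS": 10, "AD": 10, "ADNC": 10}
    )
    plaques_per_patient: tuple[int, int] = (10, 40)
    noise_sd: float = 0.05
    batch_shift_magnitude: float = 0.0
    # vector construction
    n_channels: int = 40
    span: tuple[float, float] = (385.0, 780.0)
    cap: int = 30
    # eigenspace / statistics
    eigenspace_components: tuple[int, ...] = (2, 3)
    rmsd_components: tuple[int, ...] = (2, 3, 4)
    kde_coverage: float = 0.995
    bandwidth_rule: str = "scott"
    bh_correct: bool = False
    seed: int = 0

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(n_channels=self.n_channels, span=tuple(self.span))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.plaques_per_patient, list):
            cfg.plaques_per_patient = tuple(cfg.plaques_per_patient)
        for name in ("eigenspace_components", "rmsd_components", "span"):
            val = getattr(cfg, name)
            if isinstance(val, list):
                setattr(cfg, name, tuple(val))
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence([global_seed, stage_index])."""
    idx = STAGE_ORDER.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    warnings: list = field(default_factory=list)

    def record(self, stage: str, outputs: list[Path], info: dict | None = None) -> None:
        self.stages[stage] = {
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            **(info or {}),
        }
        for p in outputs:
            self.outputs[str(p)] = _sha256(p)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


# ---------------------------------------------------------------------------
# input validation

REQUIRED_SPECTRA_COLS = [
    "plaque_id",
    "patient_id",
    "cohort",
    "dye",
    "wavelength_nm",
    "intensity",
]
REQUIRED_COUNTS_COLS = [
    "case_id",
    "field_id",
    "total_plaques",
    "dense_cored",
    "neuritic",
    "mature_nfts",
]


def validate_inputs(
    spectra_path=None,
    covariates_path=None,
    counts_path=None,
    n_channels: int = 40,
    n_dyes: int = 3,
) -> list[dict]:
    """Schema checks for the input tables; returns a machine-readable error list."""
    errors: list[dict] = []

    def err(file, kind, detail):
        errors.append({"file": str(file), "error": kind, "detail": detail})

    if spectra_path is not None:
        try:
            df = pd.read_csv(spectra_path)
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            err(spectra_path, "unreadable", str(exc))
            df = None
        if df is not None:
            missing = [c for c in REQUIRED_SPECTRA_COLS if c not in df.columns]
            if missing:
                err(spectra_path, "missing-columns", missing)
            else:
                if not pd.api.types.is_numeric_dtype(df["intensity"]):
                    err(spectra_path, "non-numeric", "intensity")
                counts = df.groupby(["plaque_id", "dye"]).size()
                bad = counts[counts != n_channels]
                for (plaque, dye), n in bad.items():
                    err(
                        spectra_path,
                        "channel-count",
                        f"plaque {plaque} dye {dye}: {n} channels, expected {n_channels}",
                    )
                dye_counts = df.groupby("plaque_id")["dye"].nunique()
                for plaque, nd in dye_counts[dye_counts != n_dyes].items():
                    err(
                        spectra_path,
                        "dye-count",
                        f"plaque {plaque}: {nd} dyes, expected {n_dyes}",
                    )
                dupes = df.duplicated(
                    subset=["plaque_id", "dye", "wavelength_nm"]
                )
                if dupes.any():
                    err(
                        spectra_path,
                        "duplicate-rows",
                        f"{int(dupes.sum())} duplicated (plaque, dye, wavelength) rows",
                    )
                owners = df.groupby("plaque_id")["patient_id"].nunique()
                for plaque in owners[owners > 1].index:
                    err(
                        spectra_path,
                        "uniqueness",
                        f"plaque {plaque} maps to multiple patients",
                    )
    if covariates_path is not None:
        try:
            cov = pd.read_csv(covariates_path)
        except Exception as exc:  # noqa: BLE001
            err(covariates_path, "unreadable", str(exc))
            cov = None
        if cov is not None:
            if "patient_id" not in cov.columns:
                err(covariates_path, "missing-columns", ["patient_id"])
            elif cov["patient_id"].duplicated().any():
                err(covariates_path, "uniqueness", "duplicate patient_id rows")
    if counts_path is not None:
        try:
            cnt = pd.read_csv(counts_path)
        except Exception as exc:  # noqa: BLE001
            err(counts_path, "unreadable", str(exc))
            cnt = None
        if cnt is not None:
            missing = [c for c in REQUIRED_COUNTS_COLS if c not in cnt.columns]
            if missing:
                err(counts_path, "missing-columns", missing)
    return errors


# ---------------------------------------------------------------------------
# stages

def _outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_simulate(config: RunConfig) -> list[Path]:
    """Generate the synthetic dataset (spectra, covariates, truth, counts)."""
    out = _outdir(config)
    seed = stage_seed(config.seed, "simulate")
    cohorts = sorted(config.patients_per_cohort)
    k = config.n_archetypes
    availability: list[frozenset[str] | None] = [None] * k
    mixture: dict[str, tuple[float, ...]] = {}
    if "DS" in cohorts and k >= 2 and config.ds_unique_weight > 0:
        # last archetype occurs only in DS at the configured weight
        availability[-1] = frozenset({"DS"})
        shared = (1.0 - config.ds_unique_weight) / (k - 1)
        for c in cohorts:
            if c == "DS":
                mixture[c] = tuple([shared] * (k - 1) + [config.ds_unique_weight])
            else:
                mixture[c] = tuple([1.0 / (k - 1)] * (k - 1) + [0.0])
    archetypes = synthetic.generate_archetypes(
        k, seed=seed, grid=config.grid, cohort_availability=availability
    )
    cohort_cfg = synthetic.CohortConfig(
        patients_per_cohort=dict(config.patients_per_cohort),
        plaques_per_patient=tuple(config.plaques_per_patient),
        archetype_mixture=mixture,
        noise_sd=config.noise_sd,
        batch_shift_magnitude=config.batch_shift_magnitude,
        seed=seed + 1,
    )
    ds = synthetic.generate_cohort_dataset(cohort_cfg, archetypes, grid=config.grid)
    spectra_path = out / "spectra.csv"
    covariates_path = out / "covariates.csv"
    truth_path = out / "truth_labels.csv"
    counts_path = out / "counts.csv"
    ds.spectra_table.to_csv(spectra_path, index=False)
    ds.patient_covariates.to_csv(covariates_path, index=False)
    ds.truth_labels.rename("archetype_id").to_csv(truth_path)
    rng = np.random.default_rng(seed + 2)
    rows = []
    for r in ds.patient_covariates.itertuples():
        counts = synthetic.generate_pathology_counts(
            int(rng.integers(0, 5)), int(r.x_tau_sim), seed=int(rng.integers(2**31))
        )
        rows.append(
            {
                "case_id": r.patient_id,
                "field_id": 1,
                "total_plaques": counts.total_plaques,
                "dense_cored": counts.dense_cored_plaques,
                "neuritic": counts.neuritic_plaques,
                "mature_nfts": counts.mature_nfts,
            }
        )
    pd.DataFrame(rows).to_csv(counts_path, index=False)
    return [spectra_path, covariates_path, truth_path, counts_path]


def run_segment(config: RunConfig) -> list[Path]:
    """Segment a TIFF lambda stack and emit the long-format spectra CSV."""
    from . import segmentation as seg

    if config.input_stack_dir is None:
        raise StageError("segment: no input_stack_dir configured")
    out = _outdir(config)
    stack = seg.read_lambda_stack(config.input_stack_dir)
    image = seg.project_total_intensity(stack)
    masks = seg.segment_plaques(image, seg.SegmentationParams())
    spectra = seg.extract_plaque_spectra(stack, masks)
    rows = []
    for lab, per_dye in spectra.items():
        for dye, spec in per_dye.items():
            for wl, inten in zip(spec.wavelengths, spec.intensities):
                rows.append(
                    {
                        "plaque_id": f"plq{lab:04d}",
                        "patient_id": "unknown",
                        "cohort": "unknown",
                        "dye": dye,
                        "wavelength_nm": wl,
                        "intensity": inten,
                    }
                )
    path = out / "segmented_spectra.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    label_path = out / "labels.tif"
    seg.write_label_tiff(masks, label_path)
    return [path, label_path]


def _load_matrix(config: RunConfig) -> SpectralMatrix:
    path = Path(config.output_dir) / "vectors.csv"
    if not path.exists():
        raise StageError(f"vectors output missing at {path}; run the vectors stage")
    return SpectralMatrix.from_csv(path, grid=config.grid)


def run_vectors(config: RunConfig) -> list[Path]:
    """Build capped composite vectors from the long-format spectra table."""
    out = _outdir(config)
    spectra_path = config.input_spectra or out / "spectra.csv"
    errors = validate_inputs(spectra_path=spectra_path, n_channels=config.n_channels)
    if errors:
        raise StageError(f"vectors: invalid spectra input: {errors[:5]}")
    table = pd.read_csv(spectra_path)
    seed = stage_seed(config.seed, "vectors")
    dye_order = draw_dye_order(seed)
    matrix = composites_from_table(table, dye_order=dye_order, grid=config.grid)
    matrix = cap_vectors_per_patient(matrix, cap=config.cap, seed=seed + 1)
    vectors_path = out / "vectors.csv"
    matrix.to_csv(vectors_path)
    manifest_path = out / "vectors_manifest.json"
    manifest_path.write_text(
        json.dumps(
            {
                "dye_order": list(dye_order),
                "cap": config.cap,
                "seed": seed,
                "n_rows": matrix.n_rows,
                "grid": {"n_channels": config.n_channels, "span": list(config.span)},
            },
            indent=2,
        )
    )
    return [vectors_path, manifest_path]


def run_fit(config: RunConfig) -> list[Path]:
    """Fit the PCA strain space; write scores, centroids, explained variance."""
    out = _outdir(config)
    matrix = _load_matrix(config)
    space = strainspace.fit_strain_space(matrix)
    retained = tuple(
        sorted(set(config.eigenspace_components) | set(config.rmsd_components))
    )
    scores = strainspace.project_scores(matrix, space, retained=retained)
    scores_path = out / "scores.csv"
    scores.to_frame().to_csv(scores_path, index=False)
    eig_scores = strainspace.project_scores(
        matrix, space, retained=tuple(config.eigenspace_components)
    )
    centroids = strainspace.patient_centroids(eig_scores)
    centroids_path = out / "centroids.csv"
    centroids.to_csv(centroids_path, index=False)
    ev_path = out / "explained_variance.json"
    ev_path.write_text(
        json.dumps(
            {
                "explained_variance_ratio": space.explained_variance_ratio_.tolist(),
                "retained": list(retained),
            },
            indent=2,
        )
    )
    np.save(out / "components.npy", space.components_)
    np.save(out / "mean_vector.npy", space.mean_)
    return [scores_path, centroids_path, ev_path]


def _load_scores(config: RunConfig, retained: tuple[int, ...]) -> strainspace.ScoreSet:
    path = Path(config.output_dir) / "scores.csv"
    if not path.exists():
        raise StageError(f"scores output missing at {path}; run the fit stage")
    df = pd.read_csv(path)
    cols = [f"pc{i}" for i in retained]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise StageError(f"scores file lacks columns {missing}")
    return strainspace.ScoreSet(
        coords=df[cols].to_numpy(dtype=float),
        retained=tuple(retained),
        meta=df[["plaque_id", "patient_id", "cohort"]].copy(),
    )


def run_classify(config: RunConfig) -> list[Path]:
    """Fit ADNC and AD coverage regions and label every plaque."""
    out = _outdir(config)
    scores = _load_scores(config, tuple(config.eigenspace_components))
    adnc = scores.subset((scores.meta["cohort"] == "ADNC").to_numpy())
    ad = scores.subset((scores.meta["cohort"] == "AD").to_numpy())
    if adnc.coords.shape[0] == 0 or ad.coords.shape[0] == 0:
        raise StageError("classify: need both ADNC and AD reference plaques")
    adnc_region = strainspace.fit_density_region(
        adnc, coverage=config.kde_coverage, bandwidth_rule=config.bandwidth_rule
    )
    ad_region = strainspace.fit_density_region(
        ad, coverage=config.kde_coverage, bandwidth_rule=config.bandwidth_rule
    )
    labels = strainspace.classify_membership(scores, adnc_region, ad_region)
    member_path = out / "membership.csv"
    frame = scores.meta.copy()
    frame["membership"] = labels.to_numpy()
    frame.to_csv(member_path, index=False)
    summary = strainspace.membership_summary(labels, scores.meta)
    summary_path = out / "membership_summary.csv"
    summary.to_csv(summary_path, index=False)
    return [member_path, summary_path]


def run_heterogeneity(config: RunConfig) -> list[Path]:
    """Per-patient and per-cohort weighted-RMSD reports (PCs 2-4 by default)."""
    out = _outdir(config)
    retained = tuple(config.rmsd_components)
    scores = _load_scores(config, retained)
    matrix = _load_matrix(config)
    space = strainspace.fit_strain_space(matrix)
    report = heterogeneity.compute_heterogeneity(scores, space)
    pat_path = out / "heterogeneity_patients.csv"
    coh_path = out / "heterogeneity_cohorts.csv"
    report.per_patient.to_csv(pat_path, index=False)
    report.per_cohort.to_csv(coh_path, index=False)
    outputs = [pat_path, coh_path]
    cov_path = config.input_covariates or Path(config.output_dir) / "covariates.csv"
    if Path(cov_path).exists():
        cov = pd.read_csv(cov_path)
        if "x_tau_sim" in cov.columns:
            strata = cov.set_index("patient_id")["x_tau_sim"]
            strat = heterogeneity.stratified_heterogeneity(report, strata)
            strat_path = out / "heterogeneity_strata.json"
            strat_path.write_text(
                json.dumps({str(k): v for k, v in strat.items()}, indent=2)
            )
            outputs.append(strat_path)
    return outputs


def run_stats(config: RunConfig) -> list[Path]:
    """Cohort MANOVA plus the centroid x covariate regression grid."""
    out = _outdir(config)
    centroids_path = Path(config.output_dir) / "centroids.csv"
    if not centroids_path.exists():
        raise StageError("stats: centroids missing; run the fit stage")
    centroids = pd.read_csv(centroids_path)
    result: dict = {}
    if centroids["cohort"].nunique() >= 2:
        mv = cohort_stats.manova_on_centroids(centroids)
        result["manova"] = dataclasses.asdict(mv)
    outputs = []
    cov_path = config.input_covariates or Path(config.output_dir) / "covariates.csv"
    if Path(cov_path).exists():
        cov = pd.read_csv(cov_path)
        grid = cohort_stats.regression_grid(
            centroids, cov, bh_correct=config.bh_correct
        )
        reg_path = out / "regressions.csv"
        grid.to_csv(reg_path, index=False)
        outputs.append(reg_path)
    stats_path = out / "stats.json"
    stats_path.write_text(json.dumps(result, indent=2))
    outputs.append(stats_path)
    return outputs


def run_score(config: RunConfig) -> list[Path]:
    """Grade per-case pathology counts by the scoring rules."""
    out = _outdir(config)
    counts_path = config.input_counts or Path(config.output_dir) / "counts.csv"
    errors = validate_inputs(counts_path=counts_path)
    if errors:
        raise StageError(f"score: invalid counts input: {errors[:5]}")
    table = pd.read_csv(counts_path)
    scored = pathology.score_table(table)
    path = out / "pathology_scores.csv"
    scored.to_csv(path, index=False)
    return [path]


STAGE_FUNCS = {
    "simulate": run_simulate,
    "segment": run_segment,
    "vectors": run_vectors,
    "fit": run_fit,
    "classify": run_classify,
    "heterogeneity": run_heterogeneity,
    "stats": run_stats,
    "score": run_score,
}


def run_pipeline(config: RunConfig, stages: tuple[str, ...] | None = None) -> RunManifest:
    """Run the configured stages in order and write the manifest.

    Default stage list: simulate (only when no input spectra are configured),
    vectors, fit, classify, heterogeneity, stats, and score (when counts are
    available).  Identical config and seed give byte-identical numeric outputs.
    """
    from importlib.metadata import version as pkg_version

    if stages is None:
        stages = tuple(
            s
            for s in STAGE_ORDER
            if s not in ("segment",)
            and not (s == "simulate" and config.input_spectra is not None)
            and not (
                s == "score"
                and config.input_counts is None
                and config.input_spectra is not None
            )
        )
    try:
        ver = pkg_version("strainspec")
    except Exception:  # noqa: BLE001 - not installed
        ver = "unknown"
    manifest = RunManifest(config=config.to_dict(), version=ver)
    for stage in stages:
        logger.info("running stage %s", stage)
        try:
            outputs = STAGE_FUNCS[stage](config)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage} failed: {exc}") from exc
        manifest.record(stage, outputs, {"seed": stage_seed(config.seed, stage)})
    manifest.write(Path(config.output_dir) / "manifest.json")
    return manifest
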