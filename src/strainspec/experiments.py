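"""Pre-configured synthetic study conditions and benchmark experiments.

Each function runs one end-to-end property experiment on synthetic data whose
conditions emulate the study design: three cohorts (DS / AD / ADNC), plaques
nested in patients, a strong microscope-calibration batch gain that dominates
PC1, subtle joint 3-dye strain signatures in PCs 2-4, a DS-only strain
archetype, and per-cohort differences in patient-level strain mixing.

The configurations here *are* the study conditions — they are fixed, not
tunable knobs; sizes are chosen so each experiment runs in seconds to a couple
of minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from . import segmentation as seg
from .cohort_stats import manova_on_centroids, wilks_lambda_manova
from .heterogeneity import compute_heterogeneity
from .spectra import cap_vectors_per_patient, composites_from_table
from .strainspace import (
    classify_membership,
    fit_density_region,
    fit_strain_space,
    patient_centroids,
    project_scores,
)
from .synthetic import (
    CohortConfig,
    SceneConfig,
    generate_archetypes,
    generate_cohort_dataset,
    generate_lambda_stack,
)

#: retained components for the synthetic analyses: PC1 carries the batch
#: artifact; with three strain-relevant axes (two shared-mixing directions
#: plus the DS-unique contrast) the strain space is PCs 2-4
RETAINED = (2, 3, 4)


def _build_matrix(dataset, seed: int, cap: int = 30):
    matrix = composites_from_table(dataset.spectra_table, seed=seed)
    return cap_vectors_per_patient(matrix, cap=cap, seed=seed)


def strain_recovery(seed: int) -> dict:
    """One replicate of the DS-unique strain-recovery experiment.

    Three cohorts of 14 patients; three strain archetypes of which the last
    occurs only in DS at mixture weight 0.3; a strong batch gain on PC1.
    Coverage regions (99.5%) are fitted on the ADNC and AD scores in PCs 2-4
    and every plaque is classified; returns the per-cohort outside-both rates
    and the cohort-separation MANOVA p-value on patient centroids.
    """
    availability = [None, None, frozenset({"DS"})]
    archetypes = generate_archetypes(
        3, seed=1000 + seed, cohort_availability=availability, peak_shift_nm=15.0
    )
    config = CohortConfig(
        patients_per_cohort={"DS": 14, "AD": 14, "ADNC": 14},
        plaques_per_patient=(15, 25),
        archetype_mixture={
            "DS": (0.35, 0.35, 0.3),
            "AD": (0.5, 0.5, 0.0),
            "ADNC": (0.5, 0.5, 0.0),
        },
        noise_sd=0.04,
        batch_shift_magnitude=1.2,
        seed=seed,
    )
    dataset = generate_cohort_dataset(config, archetypes)
    matrix = _build_matrix(dataset, seed)
    space = fit_strain_space(matrix)
    scores = project_scores(matrix, space, retained=RETAINED)
    adnc_ref = scores.subset((scores.meta["cohort"] == "ADNC").to_numpy())
    ad_ref = scores.subset((scores.meta["cohort"] == "AD").to_numpy())
    adnc_region = fit_density_region(adnc_ref, coverage=0.995)
    ad_region = fit_density_region(ad_ref, coverage=0.995)
    labels = classify_membership(scores, adnc_region, ad_region)
    frame = scores.meta.copy()
    frame["outside"] = (labels == "outside_both").to_numpy()
    rates = frame.groupby("cohort")["outside"].mean()
    manova = manova_on_centroids(patient_centroids(scores))
    return {
        "outside_rate_DS": float(rates["DS"]),
        "outside_rate_AD": float(rates["AD"]),
        "outside_rate_ADNC": float(rates["ADNC"]),
        "manova_p": manova.p_value,
        "truth_labels": dataset.truth_labels,
        "membership": labels,
        "meta": scores.meta,
    }


def heterogeneity_ordering(seed: int) -> dict:
    """One replicate of the cohort heterogeneity-ordering experiment.

    Four shared archetypes; patient-level strain mixing is most variable in
    DS (Dirichlet concentration 1), intermediate in AD (8), and absent in
    ADNC, giving ordered between-patient centroid dispersion DS > AD > ADNC.
    Returns per-cohort weighted RMSDs in PCs 2-4.
    """
    archetypes = generate_archetypes(4, seed=3000 + seed, peak_shift_nm=15.0)
    config = CohortConfig(
        patients_per_cohort={"DS": 20, "AD": 20, "ADNC": 20},
        plaques_per_patient=(25, 35),
        noise_sd=0.04,
        batch_shift_magnitude=1.2,
        mixture_concentration={"DS": 1.0, "AD": 8.0},
        seed=seed,
    )
    dataset = generate_cohort_dataset(config, archetypes)
    matrix = _build_matrix(dataset, seed)
    space = fit_strain_space(matrix)
    scores = project_scores(matrix, space, retained=RETAINED)
    report = compute_heterogeneity(scores, space)
    rmsd = report.per_cohort.set_index("cohort")["rmsd"]
    return {
        "rmsd_DS": float(rmsd["DS"]),
        "rmsd_AD": float(rmsd["AD"]),
        "rmsd_ADNC": float(rmsd["ADNC"]),
        "report": report,
    }


def batch_isolation(seed: int) -> dict:
    """One replicate of the batch-artifact isolation experiment.

    Archetype differences are made small (5-nm peak shifts) relative to a
    strong calibration gain (magnitude 1.5) — the regime in which the first
    principal component is expected to absorb the batch artifact while the
    strain signal survives in PCs 2-3.  Returns |Pearson r| between each of
    PCs 1-3 and the batch label, plus the strongest PC2/PC3 correlation with
    any strain-archetype indicator.
    """
    archetypes = generate_archetypes(3, seed=2000 + seed, peak_shift_nm=5.0)
    config = CohortConfig(
        patients_per_cohort={"DS": 10, "AD": 10, "ADNC": 10},
        plaques_per_patient=(15, 25),
        noise_sd=0.03,
        batch_shift_magnitude=1.5,
        seed=seed,
    )
    dataset = generate_cohort_dataset(config, archetypes)
    matrix = composites_from_table(dataset.spectra_table, seed=seed)
    space = fit_strain_space(matrix)
    full = space.transform(matrix.values)
    covariates = dataset.patient_covariates.set_index("patient_id")
    batch = (
        matrix.meta["patient_id"].map(covariates["batch"]).eq("B").to_numpy()
    ).astype(float)
    truth = matrix.meta["plaque_id"].map(dataset.truth_labels)
    r_batch = [
        float(abs(np.corrcoef(full[:, j], batch)[0, 1])) for j in range(3)
    ]
    r_strain = max(
        float(
            abs(
                np.corrcoef(full[:, j], (truth == a.archetype_id).to_numpy())[0, 1]
            )
        )
        for j in (1, 2)
        for a in archetypes
    )
    return {
        "r_pc1_batch": r_batch[0],
        "r_pc2_batch": r_batch[1],
        "r_pc3_batch": r_batch[2],
        "r_strain_pc23": r_strain,
    }


def manova_type_i_error(
    n_replicates: int = 2000,
    n_per_group: int = 30,
    n_dims: int = 2,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the Wilks'-lambda MANOVA under the null."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(["a", "b"], n_per_group)
    rejections = 0
    for _ in range(n_replicates):
        Y = rng.normal(size=(2 * n_per_group, n_dims))
        if wilks_lambda_manova(Y, groups).p_value < alpha:
            rejections += 1
    return rejections / n_replicates


def segmentation_benchmark(seed: int, iou_threshold: float = 0.5) -> dict:
    """Detection recall/precision of plaque segmentation on one synthetic scene.

    Seven disks (radius 8-16 px, disk SNR well above 5) on a 256x256 field
    with faint background autofluorescence and pixel noise; a detection
    counts when it overlaps a truth disk at IoU >= ``iou_threshold``.
    """
    archetypes = generate_archetypes(3, seed=4000 + seed, peak_shift_nm=15.0)
    scene = SceneConfig(
        shape=(256, 256),
        n_plaques=7,
        radius_range=(8.0, 16.0),
        background_level=0.02,
        pixel_noise_sd=0.05,
        seed=seed,
    )
    stack, truth, _meta = generate_lambda_stack(scene, archetypes)
    lam = seg.LambdaStack(
        per_dye_volumes=stack,
        channel_wavelengths=np.linspace(385.0, 780.0, 40),
    )
    image = seg.project_total_intensity(lam)
    masks = seg.segment_plaques(image, seg.SegmentationParams())
    matched_truth = 0
    used: set[int] = set()
    n_truth = int(truth.max())
    for t in range(1, n_truth + 1):
        truth_mask = truth == t
        best_iou, best_label = 0.0, None
        for lab in masks.labels:
            if lab in used:
                continue
            pred = masks.label_image == lab
            iou = np.count_nonzero(truth_mask & pred) / np.count_nonzero(
                truth_mask | pred
            )
            if iou > best_iou:
                best_iou, best_label = iou, lab
        if best_iou >= iou_threshold:
            matched_truth += 1
            used.add(best_label)
    return {
        "n_truth": n_truth,
        "n_predicted": masks.n_labels,
        "true_positives": matched_truth,
    }
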