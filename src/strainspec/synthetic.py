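"""Synthetic spectral datasets with known ground truth.

No public archive of the per-plaque dye spectra exists, so every downstream
stage is exercised on simulated data that emulates the study's structure:

* latent strain *archetypes* — joint 3-dye spectral signatures, each dye's
  profile a sum of 1-2 Gaussian peaks on the 40-channel 385-780 nm grid;
* plaques nested in patients nested in cohorts (DS / AD / ADNC), with
  archetypes mixed per cohort and optionally restricted to some cohorts;
* a smooth multiplicative batch gain (linear tilt in wavelength) applied to
  one microscope batch — a calibration artifact that survives per-dye
  max-normalization and is designed to dominate the first principal component;
* patient covariates (Abeta40, Abeta42, pTau, a simulated tau grade) linearly
  coupled to the patient's realized loading on a designated archetype;
* lambda-stack image scenes (disks with radial falloff) for the segmentation
  stage, with truth masks;
* per-field pathology counts constructed to score back to requested grades.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathology import FieldCounts
from .spectra import DEFAULT_DYES, WavelengthGrid

DEFAULT_COHORTS = ("DS", "AD", "ADNC")


@dataclass
class StrainArchetype:
    """A latent strain: one smooth nonnegative profile per dye on the grid."""

    archetype_id: str
    per_dye_profile: dict[str, np.ndarray]
    #: cohorts in which this archetype may occur; None means all
    cohort_availability: frozenset[str] | None = None

    def peak_channels(self) -> dict[str, int]:
        return {dye: int(np.argmax(p)) for dye, p in self.per_dye_profile.items()}

    def concatenated(self, dye_order: tuple[str, ...]) -> np.ndarray:
        return np.concatenate([self.per_dye_profile[d] for d in dye_order])


@dataclass
class CovariateCoupling:
    """Linear-with-Gaussian-noise link from a patient's latent archetype
    loading (realized fraction of plaques carrying ``archetype_index``) to
    simulated biochemistry (arbitrary concentration units)."""

    archetype_index: int = 0
    abeta40: tuple[float, float, float] = (12.0, 6.0, 1.5)  # baseline, slope, noise sd
    abeta42: tuple[float, float, float] = (4.0, 3.0, 0.8)
    ptau: tuple[float, float, float] = (1.0, 2.0, 0.4)
    #: latent tau-grade link: baseline, slope, noise sd (clipped/rounded to 0-4)
    x_tau: tuple[float, float, float] = (1.5, 2.5, 0.8)


@dataclass
class CohortConfig:
    """Cohort/patient/plaque structure and noise model for a synthetic run."""

    patients_per_cohort: dict[str, int] = field(
        default_factory=lambda: {"DS": 10, "AD": 10, "ADNC": 10}
    )
    plaques_per_patient: tuple[int, int] = (10, 40)
    archetype_mixture: dict[str, tuple[float, ...]] = field(default_factory=dict)
    noise_sd: float = 0.05
    batch_assignment: dict[str, str] | None = None
    batch_shift_magnitude: float = 0.0
    covariate_coupling: CovariateCoupling = field(default_factory=CovariateCoupling)
    brightness_sd: float = 0.3
    #: per-cohort Dirichlet concentration for patient-level mixture jitter;
    #: lower values give more between-patient strain heterogeneity (the paper's
    #: DS > AD > ADNC ordering is emulated by ordered concentrations); None or a
    #: missing cohort means no jitter (all patients share the cohort mixture)
    mixture_concentration: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if any(n < 0 for n in self.patients_per_cohort.values()):
            raise ValueError("patients_per_cohort values must be >= 0")
        for cohort, w in self.archetype_mixture.items():
            w = np.asarray(w, dtype=float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError(
                    f"mixture weights for {cohort} must be nonnegative and sum to 1"
                )


@dataclass
class SyntheticDataset:
    """Long-format spectra plus truth labels and patient covariates."""

    spectra_table: pd.DataFrame
    truth_labels: pd.Series  # plaque_id -> archetype_id
    patient_covariates: pd.DataFrame

    @property
    def n_plaques(self) -> int:
        return len(self.truth_labels)


@dataclass
class SceneConfig:
    """A single synthetic lambda-stack field of view."""

    shape: tuple[int, int] = (256, 256)
    n_plaques: int = 6
    radius_range: tuple[float, float] = (8.0, 16.0)
    archetype_assignment: tuple[int, ...] | None = None
    background_level: float = 0.0
    pixel_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range[0] <= 0:
            raise ValueError("plaque radii must be positive")


def _gaussian_profile(
    centers: np.ndarray, peaks: list[tuple[float, float, float]]
) -> np.ndarray:
    prof = np.zeros_like(centers)
    for mu, sigma, amp in peaks:
        prof += amp * np.exp(-0.5 * ((centers - mu) / sigma) ** 2)
    return prof


def generate_archetypes(
    k: int,
    seed: int,
    grid: WavelengthGrid | None = None,
    dyes: tuple[str, ...] = DEFAULT_DYES,
    cohort_availability: list[frozenset[str] | None] | None = None,
    peak_shift_nm: float = 35.0,
) -> list[StrainArchetype]:
    """Draw ``k`` strain archetypes with distinct joint peak signatures.

    Each dye has a shared base emission shape (1-2 Gaussian peaks with centers
    drawn on the grid interior); an archetype perturbs every base peak by an
    archetype-specific center shift of up to ``peak_shift_nm`` plus mild
    width/amplitude modulation.  Strain identity is thus a joint, subtle
    3-dye signature — conformation-sensitive dyes shift their emission
    modestly, so strain differences are small relative to, e.g., a microscope
    calibration change.  Redraws until every pair of archetypes differs in at
    least one dye's peak-channel index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    grid = grid or WavelengthGrid()
    centers = grid.centers
    rng = np.random.default_rng(seed)
    lo, hi = grid.span
    margin = 0.12 * (hi - lo)
    base: dict[str, list[tuple[float, float, float]]] = {}
    for dye in dyes:
        n_peaks = int(rng.integers(1, 3))
        base[dye] = [
            (
                float(rng.uniform(lo + margin, hi - margin)),
                float(rng.uniform(40.0, 80.0)),
                float(rng.uniform(0.6, 1.0)),
            )
            for _ in range(n_peaks)
        ]
    archetypes: list[StrainArchetype] = []
    for i in range(k):
        for _attempt in range(1000):
            profiles: dict[str, np.ndarray] = {}
            for dye in dyes:
                peaks = [
                    (
                        mu + float(rng.uniform(-peak_shift_nm, peak_shift_nm)),
                        sig * float(rng.uniform(0.85, 1.15)),
                        amp * float(rng.uniform(0.85, 1.15)),
                    )
                    for mu, sig, amp in base[dye]
                ]
                profiles[dye] = _gaussian_profile(centers, peaks)
            cand = StrainArchetype(
                archetype_id=f"arch{i}",
                per_dye_profile=profiles,
                cohort_availability=(
                    cohort_availability[i] if cohort_availability else None
                ),
            )
            if all(
                any(
                    cand.peak_channels()[d] != prev.peak_channels()[d] for d in dyes
                )
                for prev in archetypes
            ):
                archetypes.append(cand)
                break
        else:  # pragma: no cover - overwhelmingly unlikely at 40 channels
            raise RuntimeError("could not draw a distinct archetype")
    return archetypes


def batch_gain_curve(
    wavelengths: np.ndarray, magnitude: float, span: tuple[float, float]
) -> np.ndarray:
    """Smooth multiplicative gain for the shifted batch: a linear tilt in
    wavelength from (1 - magnitude) to (1 + magnitude), floored at 0.05.

    A wavelength-dependent gain changes spectral *shape*, so it survives
    per-dye max-normalization; a flat gain would be erased by it.
    """
    t = (wavelengths - span[0]) / (span[1] - span[0])
    return np.maximum(1.0 + magnitude * (2.0 * t - 1.0), 0.05)


def generate_cohort_dataset(
    config: CohortConfig,
    archetypes: list[StrainArchetype],
    grid: WavelengthGrid | None = None,
    dyes: tuple[str, ...] = DEFAULT_DYES,
) -> SyntheticDataset:
    """Simulate the full nested dataset (plaques in patients in cohorts).

    Per plaque and dye: spectrum = archetype profile x patient brightness
    (lognormal), times the batch gain for batch-B patients, plus additive
    Gaussian noise with sd = ``noise_sd`` x the profile's peak, clipped at 0.
    """
    if not archetypes:
        raise ValueError("at least one archetype is required")
    grid = grid or WavelengthGrid()
    centers = grid.centers
    rng = np.random.default_rng(config.seed)
    cohorts = sorted(config.patients_per_cohort)
    mixtures: dict[str, np.ndarray] = {}
    for cohort in cohorts:
        if cohort in config.archetype_mixture:
            w = np.asarray(config.archetype_mixture[cohort], dtype=float)
            if len(w) != len(archetypes):
                raise ValueError("mixture weight length must match archetype count")
        else:
            w = np.ones(len(archetypes)) / len(archetypes)
        for idx, a in enumerate(archetypes):
            if (
                w[idx] > 0
                and a.cohort_availability is not None
                and cohort not in a.cohort_availability
            ):
                raise ValueError(
                    f"archetype {a.archetype_id} not available to cohort {cohort}"
                )
        mixtures[cohort] = w

    gain = batch_gain_curve(centers, config.batch_shift_magnitude, grid.span)
    col_plaque: list[np.ndarray] = []
    col_patient: list[np.ndarray] = []
    col_cohort: list[np.ndarray] = []
    col_dye: list[np.ndarray] = []
    col_wl: list[np.ndarray] = []
    col_int: list[np.ndarray] = []
    truth: dict[str, str] = {}
    cov_rows: list[dict] = []
    coupling = config.covariate_coupling

    for cohort in cohorts:
        n_patients = config.patients_per_cohort[cohort]
        for p in range(n_patients):
            patient_id = f"{cohort}-{p + 1:03d}"
            if config.batch_assignment is not None:
                batch = config.batch_assignment.get(patient_id, "A")
            else:
                # alternate within cohort: balanced and uncorrelated with cohort
                batch = "B" if p % 2 else "A"
            brightness = float(rng.lognormal(0.0, config.brightness_sd))
            lo_n, hi_n = config.plaques_per_patient
            n_plaques = int(rng.integers(lo_n, hi_n + 1)) if hi_n >= lo_n else 0
            weights = mixtures[cohort]
            conc = (config.mixture_concentration or {}).get(cohort)
            if conc is not None:
                # patient-specific mixture; zero-weight archetypes stay zero
                nz = weights > 0
                jittered = np.zeros_like(weights)
                jittered[nz] = rng.dirichlet(conc * weights[nz])
                weights = jittered
            arch_idx = rng.choice(len(archetypes), size=n_plaques, p=weights)
            for j in range(n_plaques):
                plaque_id = f"{patient_id}-plq{j + 1:03d}"
                arch = archetypes[int(arch_idx[j])]
                truth[plaque_id] = arch.archetype_id
                for dye in dyes:
                    profile = arch.per_dye_profile[dye]
                    signal = profile * brightness
                    if batch == "B":
                        signal = signal * gain
                    noise = rng.normal(0.0, config.noise_sd * profile.max(), centers.size)
                    intensity = np.clip(signal + noise, 0.0, None)
                    nch = centers.size
                    col_plaque.append(np.full(nch, plaque_id, dtype=object))
                    col_patient.append(np.full(nch, patient_id, dtype=object))
                    col_cohort.append(np.full(nch, cohort, dtype=object))
                    col_dye.append(np.full(nch, dye, dtype=object))
                    col_wl.append(centers)
                    col_int.append(intensity)
            loading = (
                float(np.mean(arch_idx == coupling.archetype_index))
                if n_plaques
                else 0.0
            )
            b40, s40, n40 = coupling.abeta40
            b42, s42, n42 = coupling.abeta42
            bpt, spt, npt = coupling.ptau
            bxt, sxt, nxt = coupling.x_tau
            cov_rows.append(
                {
                    "patient_id": patient_id,
                    "cohort": cohort,
                    "batch": batch,
                    "n_plaques": n_plaques,
                    "archetype_loading": loading,
                    "abeta40": b40 + s40 * loading + rng.normal(0.0, n40),
                    "abeta42": b42 + s42 * loading + rng.normal(0.0, n42),
                    "ptau": bpt + spt * loading + rng.normal(0.0, npt),
                    "x_tau_sim": int(
                        np.clip(round(bxt + sxt * loading + rng.normal(0.0, nxt)), 0, 4)
                    ),
                }
            )

    if col_plaque:
        spectra = pd.DataFrame(
            {
                "plaque_id": np.concatenate(col_plaque),
                "patient_id": np.concatenate(col_patient),
                "cohort": np.concatenate(col_cohort),
                "dye": np.concatenate(col_dye),
                "wavelength_nm": np.concatenate(col_wl),
                "intensity": np.concatenate(col_int),
            }
        )
    else:
        spectra = pd.DataFrame(
            columns=[
                "plaque_id",
                "patient_id",
                "cohort",
                "dye",
                "wavelength_nm",
                "intensity",
            ]
        )
    labels = pd.Series(truth, name="archetype_id", dtype=object)
    labels.index.name = "plaque_id"
    covariates = pd.DataFrame(
        cov_rows,
        columns=[
            "patient_id",
            "cohort",
            "batch",
            "n_plaques",
            "archetype_loading",
            "abeta40",
            "abeta42",
            "ptau",
            "x_tau_sim",
        ],
    )
    return SyntheticDataset(
        spectra_table=spectra, truth_labels=labels, patient_covariates=covariates
    )


def generate_lambda_stack(
    scene: SceneConfig,
    archetypes: list[StrainArchetype],
    grid: WavelengthGrid | None = None,
    dyes: tuple[str, ...] = DEFAULT_DYES,
) -> tuple[dict[str, np.ndarray], np.ndarray, dict]:
    """Render a synthetic spectral field of view.

    Each plaque is a disk whose pixels carry its archetype spectrum scaled by
    a radial falloff ``1 - (d/r)^2``; the background carries a broad low-level
    autofluorescence hump.  Returns ``(stack, truth_masks, meta)`` where
    ``stack`` maps dye -> (n_channels, H, W), ``truth_masks`` labels plaques
    1..n (0 background, later plaques overwrite on overlap), and ``meta``
    records centers, radii, archetype assignment, and overlapping pairs.
    """
    grid = grid or WavelengthGrid()
    centers_nm = grid.centers
    h, w = scene.shape
    rng = np.random.default_rng(scene.seed)

    if scene.archetype_assignment is not None:
        assignment = list(scene.archetype_assignment)
        if len(assignment) != scene.n_plaques:
            raise ValueError("archetype_assignment length must equal plaque count")
    else:
        assignment = [i % len(archetypes) for i in range(scene.n_plaques)]

    rr, cc = np.mgrid[0:h, 0:w]
    truth = np.zeros((h, w), dtype=np.uint16)
    weight = np.zeros((h, w), dtype=float)  # per-pixel falloff of owning plaque
    plaque_meta = []
    for i in range(scene.n_plaques):
        r = float(rng.uniform(*scene.radius_range))
        cy = float(rng.uniform(r, h - 1 - r))
        cx = float(rng.uniform(r, w - 1 - r))
        d = np.hypot(rr - cy, cc - cx)
        inside = d <= r
        falloff = np.where(inside, 1.0 - (d / r) ** 2, 0.0)
        truth[inside] = i + 1
        weight[inside] = falloff[inside]
        plaque_meta.append(
            {"label": i + 1, "center": (cy, cx), "radius": r, "archetype": assignment[i]}
        )

    overlaps = []
    for i, mi in enumerate(plaque_meta):
        for mj in plaque_meta[i + 1 :]:
            dist = np.hypot(
                mi["center"][0] - mj["center"][0], mi["center"][1] - mj["center"][1]
            )
            if dist < mi["radius"] + mj["radius"]:
                overlaps.append((mi["label"], mj["label"]))

    # broad background autofluorescence hump centered mid-spectrum
    bg_spectrum = scene.background_level * np.exp(
        -0.5 * ((centers_nm - 520.0) / 140.0) ** 2
    )

    stack: dict[str, np.ndarray] = {}
    for dye in dyes:
        vol = np.empty((centers_nm.size, h, w), dtype=float)
        vol[:] = bg_spectrum[:, None, None]
        for m in plaque_meta:
            profile = archetypes[m["archetype"]].per_dye_profile[dye]
            mask = truth == m["label"]
            vol[:, mask] += profile[:, None] * weight[mask][None, :]
        if scene.pixel_noise_sd > 0:
            vol += rng.normal(0.0, scene.pixel_noise_sd, vol.shape)
        stack[dye] = np.clip(vol, 0.0, None)

    meta = {"plaques": plaque_meta, "overlapping_pairs": overlaps}
    return stack, truth, meta


# interior sampling windows for each grade's count interval; boundaries that
# adjacent rows share are avoided by a 0.2/mm^2 margin
_TAU_WINDOWS = {
    0: (0.0, 0.8),
    1: (1.2, 4.8),
    2: (5.2, 11.8),
    3: (12.2, 24.8),
    4: (25.2, 40.0),
}


def generate_pathology_counts(
    target_score_abeta: int, target_score_tau: int, seed: int = 0
) -> FieldCounts:
    """Per-mm^2 counts guaranteed by construction to score back to the
    requested (X_Abeta, X_tau) targets, drawn from interval interiors."""
    if not (0 <= target_score_abeta <= 4 and 0 <= target_score_tau <= 4):
        raise ValueError("target scores must be in 0..4")
    rng = np.random.default_rng(seed)
    nfts = float(rng.uniform(*_TAU_WINDOWS[target_score_tau]))
    a = target_score_abeta
    if a == 0:
        total, dc, neur = float(rng.uniform(0.0, 0.8)), 0.0, 0.0
    elif a == 1:
        dc = float(rng.uniform(0.0, 0.7))
        neur = float(rng.uniform(0.0, 1.5))
        total = dc + neur + float(rng.uniform(2.2, 8.0))
    elif a == 2:
        dc = float(rng.uniform(1.2, 4.5))
        neur = float(rng.uniform(0.0, 1.7))
        total = dc + neur + float(rng.uniform(0.5, 4.0))
    elif a == 3:
        dc = float(rng.uniform(5.2, 12.0))
        neur = float(rng.uniform(2.2, 14.5))
        total = dc + neur + float(rng.uniform(0.0, 4.0))
    else:
        dc = float(rng.uniform(5.0, 15.0))
        neur = float(rng.uniform(15.2, 30.0))
        total = dc + neur + float(rng.uniform(0.0, 4.0))
    return FieldCounts(
        total_plaques=total,
        dense_cored_plaques=dc,
        neuritic_plaques=neur,
        mature_nfts=nfts,
    )
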