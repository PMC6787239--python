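"""Synthetic phantoms and cohorts with known ground truth.

Two generators make the whole pipeline testable without any image archive:

* :func:`make_phantom` renders a digitised-film-like mammogram: a half-ellipse
  breast entering from the left edge over dark background, smooth low-frequency
  tissue texture, bright specks (0.1-1 mm Gaussian bumps), curvilinear ridge
  structures (vessel stand-ins), bright label boxes outside the breast, and
  mixed Poisson-Gaussian noise. The annotation stores true speck centres,
  their cluster memberships (specks grouped at 5 mm / 3-spot density, the same
  definition the grouping stage uses), the true breast mask and the clean
  image.

* :func:`make_cohort` draws case-control cohorts whose control covariate
  marginals are calibrated to a postmenopausal Swedish screening population
  (ages 50-74), with cluster counts from a zero-inflated (hurdle) count model
  — presence probability 0.27 at the mean age, rising with age — and case
  status from a logistic model with configurable log-odds effects, the
  per-cluster effect chief among them.

All randomness flows from the spec's single seed; equal specs give
bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .cluster import dbscan_points
from .types import BreastMask, MammogramImage, SubjectRecord

__all__ = [
    "Speck",
    "Ridge",
    "LabelBox",
    "PhantomSpec",
    "PhantomAnnotation",
    "make_phantom",
    "random_phantom",
    "CohortSpec",
    "make_cohort",
]


# ---------------------------------------------------------------------------
# Phantom images
# ---------------------------------------------------------------------------


@dataclass
class Speck:
    center_mm: tuple[float, float]  # (row, col)
    diameter_mm: float
    amplitude: float


@dataclass
class Ridge:
    points_mm: list[tuple[float, float]]
    width_mm: float
    amplitude: float


@dataclass
class LabelBox:
    top_mm: float
    left_mm: float
    height_mm: float
    width_mm: float
    amplitude: float


@dataclass
class PhantomSpec:
    """Parameters of one phantom image.

    The default 1024 x 768 px frame at 0.05 mm/px is a desk-scale stand-in
    for full film-digitiser geometry; physical speck sizes and clustering
    distances are unchanged. ``poisson_scale`` is counts per intensity unit
    (0 disables Poisson noise); ``gaussian_sd`` is additive read noise.
    """

    shape_px: tuple[int, int] = (1024, 768)
    spacing_mm: float = 0.05
    background_level: float = 500.0
    outside_level: float = 30.0
    texture_amplitude: float = 30.0
    texture_corr_mm: float = 2.0
    specks: list[Speck] = field(default_factory=list)
    ridges: list[Ridge] = field(default_factory=list)
    labels: list[LabelBox] = field(default_factory=list)
    poisson_scale: float = 1.0
    gaussian_sd: float = 5.0
    seed: int = 0
    # breast half-ellipse geometry, as fractions of the frame
    breast_semi_row_frac: float = 0.45
    breast_semi_col_frac: float = 0.70

    def __post_init__(self) -> None:
        for s in self.specks:
            if not 0.05 <= s.diameter_mm <= 2.0:
                raise ValueError("speck diameters must lie in [0.05, 2.0] mm")

    @property
    def noise_sd(self) -> float:
        """Noise sd on a flat breast-level region (Poisson + Gaussian)."""
        pvar = self.background_level / self.poisson_scale if self.poisson_scale > 0 else 0.0
        return float(np.sqrt(pvar + self.gaussian_sd**2))


@dataclass
class PhantomAnnotation:
    """Ground truth attached to a phantom."""

    breast_mask: BreastMask
    speck_centers_mm: np.ndarray  # (n, 2) (row, col) in mm
    speck_cluster_labels: np.ndarray  # DBSCAN labels on true centres, -1 = isolated
    cluster_centroids_mm: np.ndarray  # (k, 2)
    clean_pixels: np.ndarray
    noise_sd: float

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_centroids_mm.shape[0])


def _breast_ellipse_mask(spec: PhantomSpec) -> np.ndarray:
    rows, cols = spec.shape_px
    rr, cc = np.mgrid[0:rows, 0:cols]
    a = spec.breast_semi_row_frac * rows
    b = spec.breast_semi_col_frac * cols
    return ((rr - rows / 2.0) / a) ** 2 + (cc / b) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[MammogramImage, PhantomAnnotation]:
    """Render the phantom described by ``spec``; see the module docstring."""
    rows, cols = spec.shape_px
    sp = spec.spacing_mm
    rng = np.random.default_rng(spec.seed)
    mask = _breast_ellipse_mask(spec)

    clean = np.full((rows, cols), spec.outside_level, dtype=float)
    clean[mask] = spec.background_level
    if spec.texture_amplitude > 0:
        corr_px = spec.texture_corr_mm / sp
        tex = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), corr_px)
        tex_sd = tex.std()
        if tex_sd > 0:
            tex = tex / tex_sd * spec.texture_amplitude
        clean[mask] += tex[mask]

    for ridge in spec.ridges:
        canvas = np.zeros((rows, cols))
        pts_px = [(int(round(r / sp)), int(round(c / sp))) for r, c in ridge.points_mm]
        for (r0, c0), (r1, c1) in zip(pts_px[:-1], pts_px[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            keep = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
            canvas[rr[keep], cc[keep]] = 1.0
        sigma = max(ridge.width_mm / sp / 2.0, 0.5)
        canvas = ndimage.gaussian_filter(canvas, sigma)
        peak = canvas.max()
        if peak > 0:
            clean += np.where(mask, canvas / peak * ridge.amplitude, 0.0)

    centers = []
    for s in spec.specks:
        r_px, c_px = s.center_mm[0] / sp, s.center_mm[1] / sp
        ri, ci = int(round(r_px)), int(round(c_px))
        if not (0 <= ri < rows and 0 <= ci < cols) or not mask[ri, ci]:
            raise ValueError(f"speck at {s.center_mm} mm lies outside the breast")
        sigma = s.diameter_mm / sp / 4.0  # +/- 2 sigma spans the diameter
        half = int(np.ceil(4 * sigma)) + 1
        r0, r1 = max(ri - half, 0), min(ri + half + 1, rows)
        c0, c1 = max(ci - half, 0), min(ci + half + 1, cols)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        clean[r0:r1, c0:c1] += s.amplitude * np.exp(
            -((rr - r_px) ** 2 + (cc - c_px) ** 2) / (2 * sigma**2)
        )
        centers.append(s.center_mm)

    for box in spec.labels:
        r0 = int(round(box.top_mm / sp))
        c0 = int(round(box.left_mm / sp))
        r1 = min(r0 + int(round(box.height_mm / sp)), rows)
        c1 = min(c0 + int(round(box.width_mm / sp)), cols)
        clean[r0:r1, c0:c1] = np.maximum(clean[r0:r1, c0:c1], box.amplitude)

    clean = np.maximum(clean, 0.0)
    noisy = clean.copy()
    if spec.poisson_scale > 0:
        noisy = rng.poisson(noisy * spec.poisson_scale) / spec.poisson_scale
    if spec.gaussian_sd > 0:
        noisy = noisy + rng.normal(0.0, spec.gaussian_sd, noisy.shape)
    noisy = np.maximum(noisy, 0.0)

    centers_mm = np.array(centers, dtype=float).reshape(-1, 2)
    labels = dbscan_points(centers_mm, eps=5.0, min_pts=3)
    k = labels.max() + 1 if labels.size else 0
    centroids = np.array(
        [centers_mm[labels == j].mean(axis=0) for j in range(k)], dtype=float
    ).reshape(-1, 2)

    img = MammogramImage(pixels=noisy, spacing_mm=sp, bit_depth=16)
    ann = PhantomAnnotation(
        breast_mask=BreastMask(mask=mask),
        speck_centers_mm=centers_mm,
        speck_cluster_labels=labels,
        cluster_centroids_mm=centroids,
        clean_pixels=clean,
        noise_sd=spec.noise_sd,
    )
    return img, ann


def random_phantom(
    seed: int,
    n_clusters: int = 3,
    specks_per_cluster: int = 4,
    amplitude_x_noise: float = 6.0,
    n_ridges: int = 1,
    shape_px: tuple[int, int] = (1024, 768),
    cluster_radius_mm: float = 2.0,
    min_cluster_separation_mm: float = 14.0,
    with_label: bool = True,
) -> tuple[MammogramImage, PhantomAnnotation]:
    """Randomised phantom with ``n_clusters`` speck clusters at a fixed SNR.

    Cluster centres are rejection-sampled well inside the breast, mutually
    separated by ``min_cluster_separation_mm`` (so true clusters stay distinct
    at the 5 mm grouping radius) and away from ridge paths. Speck amplitudes
    are ``amplitude_x_noise`` times the flat-field noise sd.
    """
    base = PhantomSpec(shape_px=shape_px, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1]))
    rows, cols = shape_px
    sp = base.spacing_mm
    a = base.breast_semi_row_frac * rows
    b = base.breast_semi_col_frac * cols

    ridges = []
    ridge_pts_all: list[tuple[float, float]] = []
    for _ in range(n_ridges):
        c_frac = rng.uniform(0.12, 0.30)
        pts = []
        for t in np.linspace(0.25, 0.75, 7):
            r_mm = t * rows * sp
            c_mm = (c_frac + 0.05 * np.sin(4 * t + rng.uniform(0, np.pi))) * cols * sp
            pts.append((r_mm, c_mm))
        ridges.append(Ridge(points_mm=pts, width_mm=0.4, amplitude=3.0 * base.noise_sd))
        ridge_pts_all.extend(pts)

    def inside_safe(r_mm: float, c_mm: float) -> bool:
        r_px, c_px = r_mm / sp, c_mm / sp
        # stay within 80% of the ellipse (≈ several mm inside the skin line)
        if ((r_px - rows / 2.0) / a) ** 2 + (c_px / b) ** 2 > 0.8**2:
            return False
        return all(
            np.hypot(r_mm - pr, c_mm - pc) > 6.0 for pr, pc in ridge_pts_all
        )

    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_clusters:
        tries += 1
        if tries > 10_000:
            raise RuntimeError("could not place cluster centres")
        r_mm = rng.uniform(0, rows * sp)
        c_mm = rng.uniform(0, cols * sp)
        if not inside_safe(r_mm, c_mm):
            continue
        if any(np.hypot(r_mm - r0, c_mm - c0) < min_cluster_separation_mm for r0, c0 in centers):
            continue
        centers.append((r_mm, c_mm))

    def inside_breast(r_mm: float, c_mm: float) -> bool:
        r_px, c_px = r_mm / sp, c_mm / sp
        if not (0 <= r_px < rows and 0 <= c_px < cols):
            return False
        return ((r_px - rows / 2.0) / a) ** 2 + (c_px / b) ** 2 <= 0.95**2

    amp = amplitude_x_noise * base.noise_sd
    specks = []
    for r_mm, c_mm in centers:
        for _ in range(specks_per_cluster):
            while True:
                rad = cluster_radius_mm * np.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * np.pi)
                pos = (r_mm + rad * np.cos(theta), c_mm + rad * np.sin(theta))
                if inside_breast(*pos):
                    break
            specks.append(
                Speck(
                    center_mm=pos,
                    diameter_mm=rng.uniform(0.2, 0.5),
                    amplitude=amp,
                )
            )

    labels = []
    if with_label:
        labels.append(
            LabelBox(
                top_mm=2.0,
                left_mm=(cols - 90) * sp,
                height_mm=3.0,
                width_mm=4.0,
                amplitude=900.0,
            )
        )

    spec = PhantomSpec(
        shape_px=shape_px,
        seed=seed,
        specks=specks,
        ridges=ridges,
        labels=labels,
    )
    return make_phantom(spec)


# ---------------------------------------------------------------------------
# Case-control cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Generative model of a case-control cohort.

    Control covariate marginals default to a postmenopausal screening
    population: age ~ N(63.8, 6.1) (years at mammography), BMI ~ N(25.5,
    3.9), percent density gamma-distributed with mean 14.6 / sd 13.7, HRT
    never/past/current at 78.6/3.1/18.3%, 11.1% nulliparous with parous
    parity 1 + NB (mean 2.16, sd 1.44 overall), smoking-ever 40.4%, diabetes
    5.3%, age at menopause ~ N(50.2, 4.1); among parous women breastfeeding
    ever 93.9% with gamma durations (mean 11.7 / sd 10.3 months) and age at
    first birth ~ N(24.9, 4.7).

    Cluster counts follow a hurdle (zero-inflated) model: presence
    probability 0.27 at the mean age with a per-year log-odds slope
    ``mcc_age_log_or``; positive counts are zero-truncated Poisson(1).
    Case status follows a logistic model with the ``log_or`` effects (the
    per-cluster log-odds ln 1.306 by default); exactly ``n_cases`` cases and
    ``n_controls`` controls are sampled from a generated population pool.
    """

    n_cases: int = 253
    n_controls: int = 728
    seed: int = 0
    pool_factor: float = 14.0
    # covariate marginals (control calibration)
    age_mean: float = 63.78
    age_sd: float = 6.08
    bmi_mean: float = 25.51
    bmi_sd: float = 3.87
    pd_mean: float = 14.61
    pd_sd: float = 13.70
    hrt_probs: tuple[float, float, float] = (0.786, 0.031, 0.183)  # never, past, current
    p_nulliparous: float = 0.111
    parity_mean: float = 2.163
    parity_sd: float = 1.444
    smoking_ever: float = 0.404
    diabetes_yes: float = 0.053
    menopause_mean: float = 50.19
    menopause_sd: float = 4.06
    bf_ever: float = 0.939
    bf_missing_rate: float = 0.19
    bf_months_mean: float = 11.66
    bf_months_sd: float = 10.34
    bf_months_missing_rate: float = 0.02
    afb_mean: float = 24.93
    afb_sd: float = 4.74
    afb_missing_rate: float = 0.05
    # cluster-count model
    p_cluster: float = 0.27
    mcc_age_log_or: float = log(1.060)
    ztp_lambda: float = 1.0
    # case-status model (log odds ratios)
    log_or: dict = field(default_factory=lambda: {
        "mcc_total": log(1.306),
        "age_yr": log(0.982),
        "bmi_kg_m2": log(1.069),
        "pd_percent": log(1.022),
        "hrt_past": log(0.607),
        "hrt_current": log(2.274),
        "parity": log(0.859),
        "smoking_ever": log(1.425),
        "diabetes_yes": log(1.227),
        "age_menopause_yr": log(1.007),
    })
    pool_prevalence: float = 0.05

    def __post_init__(self) -> None:
        probs = list(self.hrt_probs) + [
            self.p_nulliparous, self.smoking_ever, self.diabetes_yes,
            self.bf_ever, self.bf_missing_rate, self.afb_missing_rate,
            self.p_cluster, self.pool_prevalence,
        ]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")


def _zero_truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    out = rng.poisson(lam, size)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.poisson(lam, int(zero.sum()))


def make_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a case-control cohort; see :class:`CohortSpec`."""
    rng = np.random.default_rng(spec.seed)
    n_pool = int(spec.pool_factor * (spec.n_cases + spec.n_controls))

    age = rng.normal(spec.age_mean, spec.age_sd, n_pool).clip(50, 74)
    bmi = rng.normal(spec.bmi_mean, spec.bmi_sd, n_pool).clip(16, 45)
    pd_shape = (spec.pd_mean / spec.pd_sd) ** 2
    pd_scale = spec.pd_sd**2 / spec.pd_mean
    pd = rng.gamma(pd_shape, pd_scale, n_pool).clip(0, 100)
    hrt = rng.choice(np.array(["never", "past", "current"]), size=n_pool, p=spec.hrt_probs)
    # parity: point mass at 0 plus shifted negative binomial for parous women,
    # solved so the overall mean/sd match the calibration targets
    q = 1.0 - spec.p_nulliparous
    m_parous = spec.parity_mean / q  # mean of 1 + X
    var_total = spec.parity_sd**2
    var_parous = (var_total - q * spec.p_nulliparous * m_parous**2) / q
    m_x = m_parous - 1.0
    var_x = max(var_parous, m_x + 1e-6)
    r_nb = m_x**2 / max(var_x - m_x, 1e-6)
    p_nb = r_nb / (r_nb + m_x)
    parous = rng.uniform(size=n_pool) >= spec.p_nulliparous
    parity = np.where(parous, 1 + rng.negative_binomial(r_nb, p_nb, n_pool), 0)
    smoking = np.where(rng.uniform(size=n_pool) < spec.smoking_ever, "ever", "never")
    diabetes = np.where(rng.uniform(size=n_pool) < spec.diabetes_yes, "yes", "no")
    menopause = rng.normal(spec.menopause_mean, spec.menopause_sd, n_pool).clip(35, 60)

    bf = np.where(rng.uniform(size=n_pool) < spec.bf_ever, "ever", "never")
    bf_missing = rng.uniform(size=n_pool) < spec.bf_missing_rate
    months_shape = (spec.bf_months_mean / spec.bf_months_sd) ** 2
    months_scale = spec.bf_months_sd**2 / spec.bf_months_mean
    bf_months = rng.gamma(months_shape, months_scale, n_pool)
    bf_months_missing = rng.uniform(size=n_pool) < spec.bf_months_missing_rate
    afb = rng.normal(spec.afb_mean, spec.afb_sd, n_pool).clip(16, 45)
    afb_missing = rng.uniform(size=n_pool) < spec.afb_missing_rate

    # hurdle cluster-count model with an age effect on presence
    base_logit = np.log(spec.p_cluster / (1 - spec.p_cluster))
    presence_p = 1.0 / (1.0 + np.exp(-(base_logit + spec.mcc_age_log_or * (age - spec.age_mean))))
    present = rng.uniform(size=n_pool) < presence_p
    mcc = np.zeros(n_pool, dtype=int)
    mcc[present] = _zero_truncated_poisson(rng, spec.ztp_lambda, int(present.sum()))
    mcc_left = rng.binomial(mcc, 0.5)
    mcc_right = mcc - mcc_left

    eff = spec.log_or
    lp = (
        eff.get("mcc_total", 0.0) * mcc
        + eff.get("age_yr", 0.0) * (age - spec.age_mean)
        + eff.get("bmi_kg_m2", 0.0) * (bmi - spec.bmi_mean)
        + eff.get("pd_percent", 0.0) * (pd - spec.pd_mean)
        + eff.get("hrt_past", 0.0) * (hrt == "past")
        + eff.get("hrt_current", 0.0) * (hrt == "current")
        + eff.get("parity", 0.0) * parity
        + eff.get("smoking_ever", 0.0) * (smoking == "ever")
        + eff.get("diabetes_yes", 0.0) * (diabetes == "yes")
        + eff.get("age_menopause_yr", 0.0) * (menopause - spec.menopause_mean)
    )
    intercept = np.log(spec.pool_prevalence / (1 - spec.pool_prevalence)) - lp.mean()
    p_case = 1.0 / (1.0 + np.exp(-(intercept + lp)))
    is_case = rng.uniform(size=n_pool) < p_case

    case_idx = np.flatnonzero(is_case)
    control_idx = np.flatnonzero(~is_case)
    if len(case_idx) < spec.n_cases or len(control_idx) < spec.n_controls:
        raise ValueError(
            "infeasible prevalence: pool produced "
            f"{len(case_idx)} cases / {len(control_idx)} controls, "
            f"need {spec.n_cases} / {spec.n_controls}"
        )
    chosen_cases = rng.choice(case_idx, spec.n_cases, replace=False)
    chosen_controls = rng.choice(control_idx, spec.n_controls, replace=False)
    chosen = np.concatenate([chosen_cases, chosen_controls])

    records: list[SubjectRecord] = []
    for k, i in enumerate(chosen):
        parous_i = parity[i] > 0
        bf_i: Optional[str] = None
        months_i: Optional[float] = None
        afb_i: Optional[float] = None
        if parous_i and not bf_missing[i]:
            bf_i = str(bf[i])
            if bf_i == "ever" and not bf_months_missing[i]:
                months_i = float(bf_months[i])
            elif bf_i == "never":
                months_i = 0.0
        if parous_i and not afb_missing[i]:
            afb_i = float(afb[i])
        records.append(
            SubjectRecord(
                subject_id=f"S{k:05d}",
                status="case" if is_case[i] else "control",
                age_yr=float(age[i]),
                bmi_kg_m2=float(bmi[i]),
                pd_percent=float(pd[i]),
                hrt=str(hrt[i]),
                parity=int(parity[i]),
                smoking=str(smoking[i]),
                diabetes=str(diabetes[i]),
                age_menopause_yr=float(menopause[i]),
                breastfeeding=bf_i,
                breastfeeding_months=months_i,
                age_first_birth_yr=afb_i,
                mcc_left=int(mcc_left[i]),
                mcc_right=int(mcc_right[i]),
            )
        )
    return records
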