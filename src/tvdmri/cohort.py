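"""Synthetic clinical cohorts for the FA-vs-uFA group analyses.

Each subject carries a latent white-matter *damage* score in [0, 1] that
increases with disease severity (group), age and lesion load.  Damage
shrinks the microscopic anisotropy of the subject's normal-appearing
white matter (NAWM) microdomains and grows an isotropic compartment, so
mean uFA falls monotonically with damage.  Clinical scores are coupled
to damage: EDSS (physical disability, ordinal 0-10 in half steps)
increases with it, SDMT (processing speed) decreases with it.

Conventional FA is additionally confounded by each subject's
*physiological* fibre orientation dispersion (the fraction of
crossing/fanning voxels), which is independent of disease.  This is the
mechanism that makes the FA group effect weaker than the uFA group
effect even though both are driven by the same damage latent.

Group marginals (sample sizes, age, SDMT, EDSS range, lesion load)
emulate a cohort of 27 healthy controls, 26 relapsing-remitting and 14
primary-progressive multiple sclerosis patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .dti import fa_from_eigenvalues
from .gamma import ufa_from_parameters
from .phantom import (
    D_PAR_WM,
    D_PERP_WM,
    D_ISO_LESION,
    MicroDomain,
    Phantom,
    VoxelEnvironment,
    canonical_environment,
    _ISO_PER_DAMAGE,
)

__all__ = [
    "SubjectRecord",
    "EffectConfig",
    "simulate_cohort",
    "cohort_dataframe",
    "closed_form_roi_table",
    "subject_phantom",
    "GROUPS",
    "ROIS",
]

GROUPS = ("HC", "RRMS", "PPMS")
ROIS = ("NAWM", "CING", "SLF", "CST")
HEMISPHERES = ("left", "right")

AGE_MEAN = {"HC": 43.5, "RRMS": 40.2, "PPMS": 57.7}
AGE_SD = {"HC": 12.0, "RRMS": 8.9, "PPMS": 5.0}
AGE_BOUNDS = (18.0, 80.0)
SDMT_MEAN = {"HC": 50.5, "RRMS": 57.2, "PPMS": 45.9}
SDMT_SD = {"HC": 7.5, "RRMS": 11.0, "PPMS": 9.8}
LESION_MEDIAN_ML = {"HC": 0.0, "RRMS": 6.5, "PPMS": 17.6}
LESION_SIGMA_LOG = {"HC": 0.0, "RRMS": 0.8, "PPMS": 0.75}
FEMALE_FRACTION = {"HC": 0.55, "RRMS": 0.65, "PPMS": 0.5}

# baseline fraction of crossing-fibre voxels per ROI (physiological
# dispersion; subject-specific jitter added on top)
ROI_CROSSING = {"NAWM": 0.40, "CING": 0.10, "SLF": 0.60, "CST": 0.50}


@dataclass
class EffectConfig:
    """Couplings of the cohort generator (all free parameters).

    ``group_damage_base`` sets the disease-severity contribution to the
    damage latent; ``age_slope`` and ``lesion_coupling`` add the age and
    lesion-load contributions.  ``*_noise_sd`` terms control how
    recoverable the clinical correlations are.
    """

    group_damage_base: dict = field(
        default_factory=lambda: {"HC": 0.05, "RRMS": 0.10, "PPMS": 0.12}
    )
    age_slope: float = 0.0025        # damage per year of age beyond 45
    lesion_coupling: float = 0.02    # damage per log1p(lesion load in ml)
    damage_sd: float = 0.035
    edss_scale: float = 18.0         # EDSS points per unit damage above offset
    edss_offset: float = 0.04
    edss_noise_sd: float = 1.0
    sdmt_slope: float = -40.0        # SDMT points per unit damage (centred)
    dispersion_sd: float = 0.12      # subject jitter of crossing fraction
    measurement_sd_ufa: float = 0.010
    measurement_sd_fa: float = 0.012

    @classmethod
    def null(cls) -> "EffectConfig":
        """Zero damage coupling: damage independent of group, age, lesions."""
        base = cls()
        return cls(
            group_damage_base={g: base.group_damage_base["HC"] for g in GROUPS},
            age_slope=0.0,
            lesion_coupling=0.0,
        )

    def expected_damage(self, group: str) -> float:
        """Mean damage implied by the config for a group (pre-clipping)."""
        lesion = np.log1p(LESION_MEDIAN_ML[group]) if self.lesion_coupling else 0.0
        return (
            self.group_damage_base[group]
            + self.age_slope * (AGE_MEAN[group] - 45.0)
            + self.lesion_coupling * lesion
        )


@dataclass
class SubjectRecord:
    """One simulated subject with clinical scores and latent parameters."""

    id: str
    group: str
    age: float
    sex: str
    edss: float | None
    sdmt: float
    lesion_load_ml: float
    damage: float
    crossing_jitter: float  # subject offset of physiological dispersion

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "HC" and (self.edss is not None or self.lesion_load_ml != 0):
            raise ValueError("healthy controls have no EDSS and zero lesion load")
        if not 0.0 <= self.damage <= 1.0:
            raise ValueError("damage must lie in [0, 1]")


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _simulate_subject(group: str, index: int, cfg: EffectConfig, seed: int) -> SubjectRecord:
    rng = np.random.default_rng(seed)
    age = float(_truncated_normal(rng, AGE_MEAN[group], AGE_SD[group], *AGE_BOUNDS))
    sex = "F" if rng.random() < FEMALE_FRACTION[group] else "M"
    if group == "HC":
        lesion = 0.0
    else:
        lesion = float(
            np.exp(np.log(LESION_MEDIAN_ML[group]) + LESION_SIGMA_LOG[group] * rng.normal())
        )
    damage = (
        cfg.group_damage_base[group]
        + cfg.age_slope * (age - 45.0)
        + cfg.lesion_coupling * np.log1p(lesion)
        + cfg.damage_sd * rng.normal()
    )
    damage = float(np.clip(damage, 0.0, 1.0))
    if group == "HC":
        edss = None
    else:
        raw = cfg.edss_scale * (damage - cfg.edss_offset) + cfg.edss_noise_sd * rng.normal()
        edss = float(np.clip(np.round(raw * 2.0) / 2.0, 0.0, 10.0))
    # SDMT: group marginal preserved, coupled to the centred damage latent
    resid_sd = np.sqrt(
        max(SDMT_SD[group] ** 2 - (cfg.sdmt_slope * cfg.damage_sd) ** 2, 1.0)
    )
    sdmt = float(
        SDMT_MEAN[group]
        + cfg.sdmt_slope * (damage - cfg.expected_damage(group))
        + resid_sd * rng.normal()
    )
    jitter = float(np.clip(cfg.dispersion_sd * rng.normal(), -0.35, 0.35))
    return SubjectRecord(
        id=f"{group.lower()}{index:03d}",
        group=group,
        age=age,
        sex=sex,
        edss=edss,
        sdmt=sdmt,
        lesion_load_ml=lesion,
        damage=damage,
        crossing_jitter=jitter,
    )


def simulate_cohort(
    n_hc: int = 27,
    n_rrms: int = 26,
    n_ppms: int = 14,
    effect_config: EffectConfig | None = None,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Simulate a cohort; per-subject seeds split from ``seed`` by counter."""
    cfg = effect_config or EffectConfig()
    ss = np.random.SeedSequence(seed)
    counts = {"HC": n_hc, "RRMS": n_rrms, "PPMS": n_ppms}
    subjects = []
    counter = 0
    for group in GROUPS:
        for i in range(counts[group]):
            child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(counter,))
            subjects.append(
                _simulate_subject(group, i, cfg, child.generate_state(1)[0])
            )
            counter += 1
    return subjects


def cohort_dataframe(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Tidy subject table (one row per subject)."""
    df = pd.DataFrame([asdict(s) for s in subjects])
    return df


# ----------------------------------------------------------------------
# closed-form tissue summaries (no image simulation)
# ----------------------------------------------------------------------

def damaged_domain(damage: float) -> tuple[MicroDomain, float]:
    """NAWM microdomain after damage plus the isotropic fraction it creates."""
    d_par = D_PERP_WM + (D_PAR_WM - D_PERP_WM) * (1.0 - damage)
    iso = _ISO_PER_DAMAGE * damage
    return MicroDomain(d_par, D_PERP_WM, np.array([1.0, 0.0, 0.0])), iso


def nawm_gamma_moments(damage: float) -> tuple[float, float, float]:
    """Exact (MD, mu2_lte, mu2_ste) of damaged NAWM tissue.

    The mixture distribution of apparent diffusivities has mean
    ``MD = sum f_i MD_i``, isotropic variance equal to the between-
    component variance of the MDs (what STE sees) and an additional
    within-component variance ``(4/45) dD_i^2`` per anisotropic domain
    (what LTE adds).  Orientation structure does not enter.
    """
    dom, iso = damaged_domain(damage)
    f = 1.0 - iso
    md = f * dom.md + iso * D_ISO_LESION
    v_iso = f * (dom.md - md) ** 2 + iso * (D_ISO_LESION - md) ** 2
    v_aniso = f * (4.0 / 45.0) * (dom.d_par - dom.d_perp) ** 2
    return md, v_iso + v_aniso, v_iso


def nawm_ufa(damage: float) -> float:
    """Closed-form uFA of damaged NAWM (dispersion-independent)."""
    md, mu2_lte, mu2_ste = nawm_gamma_moments(damage)
    return ufa_from_parameters(md, mu2_lte, mu2_ste)


def nawm_fa(damage: float, crossing_fraction: float) -> float:
    """Closed-form voxel-average FA of damaged NAWM with crossing fibres.

    ``crossing_fraction`` of the voxels hold two orthogonal populations,
    the rest a single coherent one; FA is the mean of the two voxel FAs.
    Unlike uFA this depends on the (physiological) dispersion.
    """
    dom, iso = damaged_domain(damage)
    f = 1.0 - iso
    iso_t = iso * D_ISO_LESION * np.eye(3)
    d_straight = f * dom.tensor + iso_t
    ey = np.array([0.0, 1.0, 0.0])
    dom_y = MicroDomain(dom.d_par, dom.d_perp, ey)
    d_cross = f * 0.5 * (dom.tensor + dom_y.tensor) + iso_t
    fa_s = fa_from_eigenvalues(*np.linalg.eigvalsh(d_straight)[::-1])
    fa_x = fa_from_eigenvalues(*np.linalg.eigvalsh(d_cross)[::-1])
    c = float(np.clip(crossing_fraction, 0.0, 1.0))
    return (1.0 - c) * fa_s + c * fa_x


def closed_form_roi_table(
    subjects: list[SubjectRecord],
    effect_config: EffectConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject, per-ROI, per-hemisphere FA/uFA means without imaging.

    Tissue values come from the closed-form expressions above plus
    independent measurement noise; this is the fast path used for
    large replicate counts (e.g. null calibration).
    """
    cfg = effect_config or EffectConfig()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0F0)).generate_state(1)[0])
    rows = []
    for s in subjects:
        ufa_tissue = nawm_ufa(s.damage)
        for roi in ROIS:
            c = ROI_CROSSING[roi] + s.crossing_jitter
            fa_tissue = nawm_fa(s.damage, c)
            for hemi in HEMISPHERES:
                rows.append(
                    {
                        "id": s.id,
                        "group": s.group,
                        "age": s.age,
                        "sex": s.sex,
                        "edss": s.edss,
                        "sdmt": s.sdmt,
                        "lesion_load_ml": s.lesion_load_ml,
                        "roi": roi,
                        "hemisphere": hemi,
                        "uFA": float(
                            np.clip(ufa_tissue + cfg.measurement_sd_ufa * rng.normal(), 0, 1)
                        ),
                        "FA": float(
                            np.clip(fa_tissue + cfg.measurement_sd_fa * rng.normal(), 0, 1)
                        ),
                        "n_voxels": 1,
                    }
                )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# per-subject imaging phantom
# ----------------------------------------------------------------------

def subject_phantom(
    subject: SubjectRecord,
    shape: tuple[int, int, int] = (8, 4, 1),
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 2.5),
) -> Phantom:
    """Compact labelled phantom for one subject.

    The grid is split into left (x < nx/2) and right hemispheres.  Rows in
    y index tract systems: y=0 CING (coherent), y=1 SLF (crossing), y=2
    CST (crossing), remaining rows generic NAWM with the subject's mix of
    straight/crossing/fanning voxels.  Patients get lesion voxels
    (environment F) in proportion to lesion load; lesions are excluded
    from the NAWM and tract masks.
    """
    nx, ny, nz = shape
    if nx < 2 or ny < 3:
        raise ValueError("phantom grid must be at least 2 x 3 in (x, y)")
    rng = np.random.default_rng(seed)
    dam = subject.damage
    grid = np.empty(shape, dtype=object)
    tract_of_row = {0: "CING", 1: "SLF", 2: "CST"}
    masks = {
        name: np.zeros(shape, dtype=bool)
        for name in ["NAWM", "lesions"]
        + [f"{t}_{h}" for t in ("CING", "SLF", "CST") for h in HEMISPHERES]
    }
    c_nawm = float(np.clip(ROI_CROSSING["NAWM"] + subject.crossing_jitter, 0.0, 1.0))
    for idx in np.ndindex(shape):
        x, y, z = idx
        hemi = "left" if x < nx // 2 else "right"
        tract = tract_of_row.get(y)
        if tract is not None:
            c = float(np.clip(ROI_CROSSING[tract] + subject.crossing_jitter, 0.0, 1.0))
        else:
            c = c_nawm
        u = rng.random()
        if u < c / 2:
            label = "E" if dam > 0 else "B"
        elif u < c:
            label = "C"
        else:
            label = "D" if dam > 0 else "A"
        grid[idx] = canonical_environment(label, damage=dam, seed=int(rng.integers(2**31)))
        masks["NAWM"][idx] = True
        if tract is not None:
            masks[f"{tract}_{hemi}"][idx] = True
    # lesions scale with load; replace NAWM voxels outside the tract rows
    n_lesion = int(np.clip(np.round(subject.lesion_load_ml / 8.0), 0, nx * (ny - 3) * nz // 2))
    free = [i for i in np.ndindex(shape) if i[1] >= 3]
    rng.shuffle(free)
    for idx in free[:n_lesion]:
        grid[idx] = canonical_environment("F", seed=int(rng.integers(2**31)))
        masks["NAWM"][idx] = False
        masks["lesions"][idx] = True
    return Phantom(grid, voxel_size, masks)
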