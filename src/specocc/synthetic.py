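"""Synthetic powder-spectra generator for the screening study design.

Generates Gaussian-band endmember spectra for an authentic material (almond
powder, two varieties) and two adulterants (apricot and peanut powder) whose
band patterns are similar to each other but distinct from almond in the
fingerprint region — the statistical structure the one-class analysis
assumes.  Samples are rendered as mass-fraction mixtures with multiplicative
scatter, baseline offset/drift and white noise artifacts:

    s = b * [(1 - c) * almond_variety + c * adulterant]
        + offset + slope * axis + noise,    b ~ N(1, scatter_slope_sd)

The study design mirrors a two-variety calibration of 100 pure samples,
a first validation set of 110 samples (10 pure + 5-50% in 5% steps, 10
replicates each) and a second-variety validation set of 50 samples (10 pure
+ 7/15/22/30%, 10 replicates each).

Two presets fix the study conditions: ``separable`` (full adulterant
contrast; every level >= 15% is trivially detectable) and ``hard`` (the
adulterant endmember pulled toward almond so that 5-7% adulteration sits on
the detection transition while higher levels remain fully detected).
Physics fidelity is out of scope — bands are Gaussian and amplitudes
uncalibrated; the generator exists to exercise the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .dataset import SampleMeta, SpectrumSet

MIR_GRID = (650.0, 4000.0, 4.0)      # 838 points
NIR_GRID = (4000.0, 10000.0, 8.0)    # 751 points

# Base band tables (center cm^-1, width cm^-1, amplitude).  Centers follow
# the usual organic-powder landscape: carbohydrate C-O near 1045, CH2/CH3
# bends 1230-1460, protein amide bands near 1530-1650, the triacylglyceride
# ester carbonyl near 1745, CH stretches near 2855/2925, the cis-olefinic
# CH at 3010 and a broad O-H around 3300 cm^-1.  The adulterant table
# differs from the authentic one mainly below 1800 cm^-1 (the fingerprint
# region); apricot and peanut share one table and differ from each other by
# small amplitude perturbations only.
_MIR_ALMOND = [
    (1045, 30, 0.90), (1160, 25, 0.50), (1240, 30, 0.35), (1378, 20, 0.30),
    (1460, 22, 0.45), (1530, 25, 0.50), (1650, 30, 0.60), (1745, 25, 1.00),
    (2855, 30, 0.70), (2925, 30, 1.00), (3010, 20, 0.25), (3300, 150, 0.50),
]
# constituent group of each almond band (drives the per-sample composition
# variability): carbohydrate C-O / CH bends, lipid ester + CH stretches,
# protein amides, and the O-H moisture band
_MIR_ALMOND_GROUPS = ["carb", "carb", "carb", "lipid", "lipid", "protein",
                      "protein", "lipid", "lipid", "lipid", "lipid", "moisture"]
_MIR_ADULTERANT = [
    (1025, 35, 1.10), (1105, 30, 0.65), (1265, 28, 0.50), (1415, 25, 0.42),
    (1550, 28, 0.32), (1655, 32, 0.48), (1742, 26, 0.78), (2855, 30, 0.58),
    (2925, 30, 0.88), (3290, 160, 0.60),
]
_NIR_ALMOND = [
    (4330, 60, 0.50), (4536, 70, 0.60), (4744, 60, 0.30), (4987, 80, 0.55),
    (5174, 90, 0.70), (5376, 80, 0.45), (5800, 120, 0.35), (6929, 200, 0.50),
    (8500, 300, 0.25),
]
_NIR_ALMOND_GROUPS = ["lipid", "lipid", "lipid", "carb", "carb", "carb",
                      "lipid", "protein", "moisture"]
_NIR_ADULTERANT = [
    (4300, 65, 0.62), (4560, 72, 0.48), (4760, 62, 0.40), (4960, 82, 0.42),
    (5150, 92, 0.82), (5400, 82, 0.35), (5850, 125, 0.45), (6890, 210, 0.40),
    (8400, 310, 0.32),
]


class SyntheticError(ValueError):
    pass


def _tnorm(rng: np.random.Generator, clip: float = 2.2) -> float:
    """Standard normal truncated at +-clip (rejection sampling).

    Composition and measurement artifacts of a controlled powder process
    are bounded; unbounded Gaussian tails would put arbitrarily extreme
    samples in the pure class.
    """
    while True:
        z = rng.standard_normal()
        if abs(z) <= clip:
            return float(z)


@dataclass(frozen=True)
class EndmemberSpec:
    """Gaussian-band description of one material's spectrum."""

    material: str
    name: str
    bands: tuple[tuple[float, float, float], ...]
    baseline_slope: float = 0.0

    def render(self, grid: np.ndarray) -> np.ndarray:
        s = np.zeros_like(grid, dtype=float)
        for center, width, amp in self.bands:
            s += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
        span = grid.max() - grid.min()
        s += self.baseline_slope * (grid - grid.min()) / span
        return s


@dataclass(frozen=True)
class Endmembers:
    """Endmember set for one spectral region plus the variety effect."""

    region: str
    grid: np.ndarray
    almond: EndmemberSpec
    apricot: EndmemberSpec
    peanut: EndmemberSpec
    variety_factors: np.ndarray   # multiplicative almond band-amplitude factors, variety 2
    almond_groups: tuple[str, ...] = ()   # constituent group per almond band

    def spec(self, material: str) -> EndmemberSpec:
        return {"almond": self.almond, "apricot": self.apricot, "peanut": self.peanut}[
            material
        ]

    def almond_variety(self, variety: int) -> EndmemberSpec:
        if variety == 1:
            return self.almond
        bands = tuple(
            (c, w, a * f)
            for (c, w, a), f in zip(self.almond.bands, self.variety_factors)
        )
        return replace(self.almond, name=f"almond_v{variety}", bands=bands)


def region_grid(region: str) -> np.ndarray:
    if region == "mir":
        low, high, step = MIR_GRID
    elif region == "nir":
        low, high, step = NIR_GRID
    else:
        raise SyntheticError(f"unknown region {region!r}")
    return np.arange(low, high + step / 2, step)


def make_endmembers(
    region: str = "mir", seed: int = 0, variety_shift: float = 0.05
) -> Endmembers:
    """Deterministic-for-seed endmember set.

    Band centers and amplitudes are jittered slightly around the base
    tables; peanut is derived from apricot by small amplitude shifts so the
    two adulterants stay mutually similar but distinct from almond.
    ``variety_shift`` scales the fixed almond band-amplitude perturbation
    that distinguishes the second variety.
    """
    grid = region_grid(region)
    rng = np.random.default_rng(np.random.SeedSequence([seed, {"mir": 0, "nir": 1}[region]]))
    almond_base, adult_base, groups = (
        (_MIR_ALMOND, _MIR_ADULTERANT, _MIR_ALMOND_GROUPS)
        if region == "mir"
        else (_NIR_ALMOND, _NIR_ADULTERANT, _NIR_ALMOND_GROUPS)
    )

    def jitter(bands):
        out = []
        for c, w, a in bands:
            out.append(
                (
                    c + rng.normal(0, 2.0),
                    w * (1 + rng.normal(0, 0.03)),
                    a * (1 + rng.normal(0, 0.03)),
                )
            )
        return tuple(out)

    almond = EndmemberSpec("almond", "almond_v1", jitter(almond_base))
    apricot = EndmemberSpec("apricot", "apricot", jitter(adult_base))
    # peanut: same band landscape as apricot, small amplitude shifts only
    peanut_bands = tuple(
        (c, w, a * (1 + rng.normal(0, 0.08))) for c, w, a in apricot.bands
    )
    peanut = EndmemberSpec("peanut", "peanut", peanut_bands)
    variety_factors = 1.0 + variety_shift * rng.standard_normal(len(almond.bands))
    return Endmembers(region, grid, almond, apricot, peanut, variety_factors,
                      tuple(groups))


@dataclass
class StudyDesign:
    """Design and artifact scales for one synthetic study realization."""

    region: str = "mir"
    adulterant: str = "apricot"
    n_cal_per_variety: int = 50
    validation1_levels: tuple[float, ...] = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50)
    validation2_levels: tuple[float, ...] = (7, 15, 22, 30)
    replicates: int = 10
    n_pure_val: int = 10
    noise_sd: float = 0.0005
    structured_noise_sd: float = 0.004
    noise_corr_cm: float = 120.0
    chem_var_sd: float = 0.03
    adulterant_contrast: float = 1.0
    scatter_slope_sd: float = 0.05
    offset_sd: float = 0.02
    drift_slope_sd: float = 0.01
    variety_shift: float = 0.05
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.adulterant not in {"apricot", "peanut"}:
            raise SyntheticError(f"unknown adulterant {self.adulterant!r}")
        levels = list(self.validation1_levels) + list(self.validation2_levels)
        if any(not 0 < lv <= 100 for lv in levels):
            raise SyntheticError("adulteration levels must lie in (0, 100]")


# Preset artifact scales (study conditions; see docs/methods.md).  The
# "hard" noise level puts 5-7% adulteration on the detection transition
# while levels >= 15% stay fully detected; "separable" keeps every level
# >= 15% trivially separable.
PRESETS = {
    "separable": dict(adulterant_contrast=1.0, name="separable"),
    "hard": dict(adulterant_contrast=0.7, name="hard"),
}


def preset_design(name: str, region: str = "mir", adulterant: str = "apricot",
                  seed: int = 0) -> StudyDesign:
    if name not in PRESETS:
        raise SyntheticError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return StudyDesign(region=region, adulterant=adulterant, seed=seed, **PRESETS[name])


def _smooth_noise(
    rng: np.random.Generator, grid: np.ndarray, sd: float, corr_cm: float
) -> np.ndarray:
    """Stationary Gaussian noise with ~``corr_cm`` spectral correlation length.

    White noise convolved with a unit-L2 Gaussian kernel, so the marginal
    standard deviation is ``sd`` while neighbouring channels co-vary the way
    baseline wiggle and detector drift do in averaged FT spectra.
    """
    step = abs(grid[1] - grid[0]) if grid.size > 1 else 1.0
    sigma_pts = max(corr_cm / step, 1e-6)
    halfwidth = max(int(np.ceil(4 * sigma_pts)), 1)
    kernel = np.exp(-0.5 * (np.arange(-halfwidth, halfwidth + 1) / sigma_pts) ** 2)
    kernel /= np.linalg.norm(kernel)
    white = rng.standard_normal(grid.size + 2 * halfwidth)
    return sd * np.convolve(white, kernel, mode="valid")


def render_sample(
    endmembers: Endmembers,
    concentration: float,
    variety: int = 1,
    adulterant: str = "apricot",
    rng: Optional[np.random.Generator] = None,
    noise_sd: float = 0.0,
    structured_noise_sd: float = 0.0,
    noise_corr_cm: float = 120.0,
    scatter_slope_sd: float = 0.0,
    offset_sd: float = 0.0,
    drift_slope_sd: float = 0.0,
    chem_var_sd: float = 0.0,
    adulterant_contrast: float = 1.0,
) -> np.ndarray:
    """Render one spectrum as a mass-fraction mixture with artifacts.

    ``chem_var_sd`` scales per-sample composition variability: each
    constituent group of the almond bands (lipid, protein, carbohydrate,
    moisture) gets an independent multiplicative amplitude factor
    ``N(1, chem_var_sd)``, giving the target class a few strong, stable
    within-class directions, as natural lots of a powder would.  Noise has a
    white component (``noise_sd``) and a spectrally smooth component
    (``structured_noise_sd`` with correlation length ``noise_corr_cm``), the
    latter mimicking the correlated baseline wiggle that dominates residual
    variation in scan-averaged FT spectra.  With all artifact scales at zero
    the output is exactly the convex combination of the variety's almond
    endmember and the adulterant endmember at ``concentration`` percent.
    """
    if not 0 <= concentration <= 100:
        raise SyntheticError(f"concentration {concentration} outside [0, 100]")
    grid = endmembers.grid
    c = concentration / 100.0
    if rng is None:
        rng = np.random.default_rng()
    almond = endmembers.almond_variety(variety)
    if chem_var_sd and endmembers.almond_groups:
        unique = sorted(set(endmembers.almond_groups))
        factor = {g: 1.0 + chem_var_sd * _tnorm(rng) for g in unique}
        bands = tuple(
            (ctr, w, a * factor[g])
            for (ctr, w, a), g in zip(almond.bands, endmembers.almond_groups)
        )
        almond = replace(almond, bands=bands)
    base = (1 - c) * almond.render(grid)
    if c > 0:
        # contrast < 1 pulls the adulterant endmember toward pure almond,
        # making low-level adulteration genuinely harder to detect
        adult = endmembers.spec(adulterant).render(grid)
        if adulterant_contrast != 1.0:
            pure_almond = endmembers.almond.render(grid)
            adult = pure_almond + adulterant_contrast * (adult - pure_almond)
        base = base + c * adult
    b = 1.0 + scatter_slope_sd * _tnorm(rng) if scatter_slope_sd else 1.0
    offset = offset_sd * _tnorm(rng) if offset_sd else 0.0
    slope = drift_slope_sd * _tnorm(rng) if drift_slope_sd else 0.0
    axis = (grid - grid.min()) / (grid.max() - grid.min())
    s = b * base + offset + slope * axis
    if noise_sd:
        s = s + noise_sd * rng.standard_normal(grid.size)
    if structured_noise_sd:
        s = s + _smooth_noise(rng, grid, structured_noise_sd, noise_corr_cm)
    return s


def _artifact_kwargs(design: StudyDesign) -> dict:
    return dict(
        noise_sd=design.noise_sd,
        structured_noise_sd=design.structured_noise_sd,
        noise_corr_cm=design.noise_corr_cm,
        chem_var_sd=design.chem_var_sd,
        adulterant_contrast=design.adulterant_contrast,
        scatter_slope_sd=design.scatter_slope_sd,
        offset_sd=design.offset_sd,
        drift_slope_sd=design.drift_slope_sd,
    )


def _render_block(
    endmembers: Endmembers,
    design: StudyDesign,
    plan: list[tuple[float, int]],
    rng: np.random.Generator,
    set_role: str,
    prefix: str,
) -> SpectrumSet:
    rows, meta = [], []
    for i, (conc, variety) in enumerate(plan):
        rows.append(
            render_sample(
                endmembers,
                conc,
                variety=variety,
                adulterant=design.adulterant,
                rng=rng,
                **_artifact_kwargs(design),
            )
        )
        pure = conc == 0
        meta.append(
            SampleMeta(
                sample_id=f"{prefix}{i:03d}",
                class_label="pure" if pure else "adulterated",
                adulterant="none" if pure else design.adulterant,
                concentration=float(conc),
                variety=variety,
                set_role=set_role,
            )
        )
    return SpectrumSet(endmembers.grid, np.vstack(rows), meta)


def generate_study(design: StudyDesign) -> dict[str, SpectrumSet]:
    """Generate the calibration and both validation sets for one adulterant.

    The calibration set (and the endmembers) depend only on ``design.seed``,
    the region and the variety shift — not on the adulterant — so the pure
    calibration is shared between adulterant runs at the same seed.
    Reproducible for a fixed design.
    """
    adix = 0 if design.adulterant == "apricot" else 1
    endmembers = make_endmembers(
        design.region, seed=design.seed, variety_shift=design.variety_shift
    )
    rng_cal = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    cal_plan = [(0.0, 1)] * design.n_cal_per_variety + [(0.0, 2)] * design.n_cal_per_variety
    calibration = _render_block(endmembers, design, cal_plan, rng_cal, "calibration", "cal")

    rng_val = np.random.default_rng(np.random.SeedSequence([design.seed, 2, adix]))
    v1_plan = [(0.0, 1)] * design.n_pure_val + [
        (lv, 1) for lv in design.validation1_levels for _ in range(design.replicates)
    ]
    validation1 = _render_block(endmembers, design, v1_plan, rng_val, "validation1", "v1_")

    rng_val2 = np.random.default_rng(np.random.SeedSequence([design.seed, 3, adix]))
    v2_plan = [(0.0, 2)] * design.n_pure_val + [
        (lv, 2) for lv in design.validation2_levels for _ in range(design.replicates)
    ]
    validation2 = _render_block(endmembers, design, v2_plan, rng_val2, "validation2", "v2_")

    return {
        "calibration": calibration,
        "validation1": validation1,
        "validation2": validation2,
    }


def generate_pure_test(
    design: StudyDesign, n: int = 200, seed_offset: int = 7
) -> SpectrumSet:
    """An independent pure test set from the same generator (both varieties)."""
    endmembers = make_endmembers(
        design.region, seed=design.seed, variety_shift=design.variety_shift
    )
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, seed_offset]))
    plan = [(0.0, 1 + (i % 2)) for i in range(n)]
    return _render_block(endmembers, design, plan, rng, "test", "pt_")
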