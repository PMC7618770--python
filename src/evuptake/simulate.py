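"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the study's data without any optics simulation: isolated
rod-shaped live cardiomyocytes (rotated rectangles with semicircular end caps)
and near-circular hypercontracted dead cells on a two-channel field; elongated
nuclei bright in the 405-nm Hoechst channel over weak cytoplasmic
autofluorescence; treatment-dependent NeonGreen2 signal in the 488-nm channel
with a tunable multiplicative texture (spatially correlated Gaussian random
field) so homogeneity responds monotonically to the heterogeneity amplitude;
heart-level random intercepts nesting cells within hearts; single-exponential
FRAP recovery traces; and dose/mass-structured organ luminescence tables.

Noise (Poisson-scaled shot noise and additive Gaussian read noise) is optional
and zero-able so exact tests are possible.  All randomness is driven by one
master seed; sub-streams are derived per (group, heart, field) so adding fields
never perturbs earlier ones.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .frap import FRAPTrace
from .segmentation import ImageField

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "Treatment",
    "ExperimentDesign",
    "ParticleTruth",
    "GroundTruth",
    "SectionConfig",
    "SectionImage",
    "SectionTruth",
    "simulate_myocyte_field",
    "simulate_experiment",
    "simulate_cell_values",
    "simulate_section",
    "simulate_frap_trace",
    "simulate_biodistribution",
]

LIVE = "live"
DEAD = "dead"


class ConfigError(ValueError):
    """Raised for impossible or inconsistent simulation configurations."""


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Independent sub-stream derived from the master seed and an integer key."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *key]))


# ---------------------------------------------------------------------------
# myocyte fields
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Geometry, intensity and noise parameters of one synthetic myocyte field.

    Lengths are in um; intensities in arbitrary units.  Defaults draw live
    cells whose long/short ratio passes the rod filter and dead cells whose
    near-unit ratio fails it while their area stays inside the cell-area
    window (so the rejection is attributed to shape, as for real
    hypercontracted cells).  Nucleus axis ranges straddle the 30-um^2 /
    ratio-3 criteria so both passing and failing nuclei occur.
    """

    field_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.5  # um / pixel
    n_live_cells: int = 5
    n_dead_cells: int = 2
    n_border_cells: int = 0  # extra live cells deliberately crossing the border
    live_length: tuple[float, float] = (90.0, 130.0)
    live_width: tuple[float, float] = (20.0, 28.0)
    dead_diameter: tuple[float, float] = (45.0, 60.0)
    nuclei_per_cell: tuple[int, int] = (1, 2)
    nucleus_major: tuple[float, float] = (10.0, 18.0)
    nucleus_minor: tuple[float, float] = (3.0, 4.5)
    background_level: float = 10.0
    autofluorescence_level: float = 30.0
    hoechst_nuclear_level: float = 200.0
    neon_mean: float = 20.0
    neon_nuclear_factor: float = 1.0
    heterogeneity_length: float = 5.0  # correlation length of the texture, um
    heterogeneity_amplitude: float = 0.3  # relative SD of the multiplicative texture
    read_noise_sd: float = 2.0
    shot_noise_scale: float = 0.1  # intensity units per photon; 0 disables shot noise
    max_placement_attempts: int = 200
    seed: int = 0

    def validate(self) -> None:
        for name in ("live_length", "live_width", "dead_diameter", "nucleus_major", "nucleus_minor"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must satisfy 0 < min <= max")
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")
        if min(self.field_shape) < 2:
            raise ConfigError("field_shape too small")
        extent = min(self.field_shape) * self.pixel_size
        if self.live_length[1] >= extent:
            raise ConfigError("cell longer than the field: impossible geometry")
        if self.live_length[0] <= self.live_width[1]:
            raise ConfigError("live cells must be elongated (min length > max width)")
        if any(
            v < 0
            for v in (
                self.background_level,
                self.autofluorescence_level,
                self.hoechst_nuclear_level,
                self.neon_mean,
                self.heterogeneity_amplitude,
                self.read_noise_sd,
                self.shot_noise_scale,
            )
        ):
            raise ConfigError("intensity and noise parameters must be non-negative")
        if min(self.n_live_cells, self.n_dead_cells, self.n_border_cells) < 0:
            raise ConfigError("cell counts must be non-negative")


@dataclass
class ParticleTruth:
    label: int
    kind: str  # "live" or "dead"
    neon_mean: float
    touches_border: bool
    center: tuple[float, float]  # (row, col) in pixels
    length_um: float
    width_um: float
    theta: float
    nucleus_labels: list[int] = dc_field(default_factory=list)


@dataclass
class GroundTruth:
    """Truth record paired with one simulated field.

    ``cell_labels`` and ``nucleus_labels`` are integer label grids (0 =
    background) that partition their layer; every labelled object maps to
    exactly one ``ParticleTruth``.  ``placement_failures`` counts requested
    cells that could not be placed without overlap.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    particles: list[ParticleTruth]
    placement_failures: int = 0

    def particle(self, label: int) -> ParticleTruth:
        for p in self.particles:
            if p.label == label:
                return p
        raise KeyError(label)


def _stadium_mask(shape, center, length_px, width_px, theta):
    """Rotated rectangle with semicircular end caps ('rod')."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = center
    ux, uy = math.cos(theta), math.sin(theta)
    half = max(length_px / 2.0 - width_px / 2.0, 0.0)
    vx = cols - cx
    vy = rows - cy
    t = np.clip(vx * ux + vy * uy, -half, half)
    d2 = (vx - t * ux) ** 2 + (vy - t * uy) ** 2
    return d2 <= (width_px / 2.0) ** 2


def _ellipse_mask(shape, center, major_px, minor_px, theta):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = center
    ux, uy = math.cos(theta), math.sin(theta)
    vx = cols - cx
    vy = rows - cy
    a = major_px / 2.0
    b = minor_px / 2.0
    p = vx * ux + vy * uy
    q = -vx * uy + vy * ux
    return (p / a) ** 2 + (q / b) ** 2 <= 1.0


def _texture_field(shape, corr_px, amplitude, rng):
    """Multiplicative texture: 1 + amplitude * unit-variance correlated field, floored at 0."""
    if amplitude == 0:
        return np.ones(shape)
    z = rng.standard_normal(shape)
    if corr_px > 0:
        z = ndimage.gaussian_filter(z, corr_px, mode="wrap")
        sd = z.std()
        if sd > 0:
            z /= sd
    return np.clip(1.0 + amplitude * z, 0.0, None)


def _apply_noise(img, cfg: SimulationConfig, rng) -> np.ndarray:
    out = img
    if cfg.shot_noise_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) / cfg.shot_noise_scale) * cfg.shot_noise_scale
        out = out.astype(float)
    if cfg.read_noise_sd > 0:
        out = out + rng.normal(0.0, cfg.read_noise_sd, size=img.shape)
    return np.clip(out, 0.0, None)


def simulate_myocyte_field(
    config: SimulationConfig,
    heart_id: str = "heart1",
    treatment: str = "sham",
    rng: np.random.Generator | None = None,
    live_neon_means: Sequence[float] | None = None,
    session_id: str = "",
) -> tuple[ImageField, GroundTruth]:
    """Render one two-channel field of live and dead cells with paired truth.

    Channel 1 (405 nm) is background + weak autofluorescence over cell bodies
    + bright nuclei + noise; channel 2 (488 nm) is background + per-cell
    NeonGreen2 level times a spatially correlated multiplicative texture +
    noise.  Cells are placed without overlap by rejection sampling; when
    ``n_border_cells`` > 0, that many extra live cells are centred on the
    field edge and flagged ``touches_border``.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    shape = tuple(config.field_shape)
    ps = config.pixel_size

    if live_neon_means is not None and len(live_neon_means) != config.n_live_cells:
        raise ConfigError("live_neon_means length must equal n_live_cells")

    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    particles: list[ParticleTruth] = []
    failures = 0
    next_label = 1
    next_nuc = 1

    plan = (
        [(LIVE, False)] * config.n_live_cells
        + [(DEAD, False)] * config.n_dead_cells
        + [(LIVE, True)] * config.n_border_cells
    )

    for idx, (kind, on_border) in enumerate(plan):
        placed = False
        for _ in range(config.max_placement_attempts):
            theta = rng.uniform(0, math.pi)
            if kind == LIVE:
                length = rng.uniform(*config.live_length) / ps
                width = rng.uniform(*config.live_width) / ps
            else:
                length = rng.uniform(*config.dead_diameter) / ps
                # near-unit axis ratio by construction
                width = length * rng.uniform(0.9, 1.0)
            margin = length / 2.0 + 1.0
            if on_border:
                edge = rng.integers(0, 4)
                along = rng.uniform(margin, shape[edge % 2] - margin)
                center = {
                    0: (0.0, along),
                    1: (shape[0] - 1.0, along),
                    2: (along, 0.0),
                    3: (along, shape[1] - 1.0),
                }[int(edge)]
            else:
                if shape[0] - margin <= margin or shape[1] - margin <= margin:
                    raise ConfigError("cell does not fit inside the field interior")
                center = (
                    rng.uniform(margin, shape[0] - margin),
                    rng.uniform(margin, shape[1] - margin),
                )
            if kind == LIVE:
                mask = _stadium_mask(shape, center, length, width, theta)
            else:
                mask = _ellipse_mask(shape, center, length, width, theta)
            if not mask.any() or (mask & occupied).any():
                continue
            placed = True
            break
        if not placed:
            failures += 1
            continue

        label = next_label
        next_label += 1
        cell_labels[mask] = label
        occupied |= ndimage.binary_dilation(mask, iterations=2)

        if kind == LIVE and live_neon_means is not None and idx < config.n_live_cells:
            neon = float(live_neon_means[idx])
        elif kind == LIVE:
            neon = config.neon_mean
        else:
            neon = config.neon_mean  # dead cells carry signal too; they fail shape QC

        truth = ParticleTruth(
            label=label,
            kind=kind,
            neon_mean=neon,
            touches_border=bool(
                mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
            ),
            center=center,
            length_um=length * ps,
            width_um=width * ps,
            theta=theta,
        )

        # nuclei: elongated ellipses along the cell axis for live cells,
        # a round blob for dead cells
        if kind == LIVE:
            n_nuc = int(rng.integers(config.nuclei_per_cell[0], config.nuclei_per_cell[1] + 1))
            offsets = [0.0] if n_nuc == 1 else np.linspace(-0.18, 0.18, n_nuc)
            for off in np.atleast_1d(offsets):
                major = rng.uniform(*config.nucleus_major) / ps
                minor = rng.uniform(*config.nucleus_minor) / ps
                ncy = center[0] + off * length * math.sin(theta)
                ncx = center[1] + off * length * math.cos(theta)
                ang = theta + rng.normal(0.0, 0.08)
                nmask = _ellipse_mask(shape, (ncy, ncx), major, minor, ang) & mask
                nmask &= nucleus_labels == 0
                if not nmask.any():
                    continue
                nucleus_labels[nmask] = next_nuc
                truth.nucleus_labels.append(next_nuc)
                next_nuc += 1
        else:
            d = 8.0 / ps
            nmask = _ellipse_mask(shape, center, d, d, 0.0) & mask & (nucleus_labels == 0)
            if nmask.any():
                nucleus_labels[nmask] = next_nuc
                truth.nucleus_labels.append(next_nuc)
                next_nuc += 1

        particles.append(truth)

    cell_body = cell_labels > 0
    nuc_body = nucleus_labels > 0

    ch405 = np.full(shape, config.background_level, dtype=float)
    ch405[cell_body] += config.autofluorescence_level
    ch405[nuc_body] += config.hoechst_nuclear_level

    texture = _texture_field(
        shape, config.heterogeneity_length / ps, config.heterogeneity_amplitude, rng
    )
    ch488 = np.full(shape, config.background_level, dtype=float)
    for p in particles:
        m = cell_labels == p.label
        ch488[m] = config.background_level + p.neon_mean * texture[m]
        if config.neon_nuclear_factor != 1.0:
            nm = m & nuc_body
            ch488[nm] = config.background_level + (
                config.neon_nuclear_factor * p.neon_mean * texture[nm]
            )

    ch405 = _apply_noise(ch405, config, rng)
    ch488 = _apply_noise(ch488, config, rng)

    field = ImageField(
        channel_405=ch405,
        channel_488=ch488,
        pixel_size=ps,
        heart_id=heart_id,
        treatment=treatment,
        session_id=session_id,
    )
    truth = GroundTruth(
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
        particles=particles,
        placement_failures=failures,
    )
    return field, truth


# ---------------------------------------------------------------------------
# hierarchical multi-heart experiments
# ---------------------------------------------------------------------------


@dataclass
class Treatment:
    """One treatment arm: its true 488-channel mean and texture amplitude."""

    label: str
    neon_mean: float
    heterogeneity_amplitude: float | None = None  # None -> config default


@dataclass
class ExperimentDesign:
    """Nested design: cells within hearts within treatment groups.

    Per-heart random intercepts (SD ``heart_sd``) are drawn once per heart;
    per-cell means add residual noise (SD ``cell_sd``).  Mirrors the study
    design of 3-4 animals per group with tens of myocytes per heart.
    """

    treatments: list[Treatment]
    hearts_per_group: int | Mapping[str, int] = 3
    cells_per_heart: int = 30
    heart_sd: float = 3.0
    cell_sd: float = 6.0
    seed: int = 0

    def n_hearts(self, label: str) -> int:
        if isinstance(self.hearts_per_group, Mapping):
            return int(self.hearts_per_group[label])
        return int(self.hearts_per_group)

    def validate(self) -> None:
        if not self.treatments:
            raise ConfigError("need at least one treatment")
        if self.heart_sd < 0 or self.cell_sd < 0:
            raise ConfigError("SDs must be non-negative")
        for t in self.treatments:
            if self.n_hearts(t.label) < 1:
                raise ConfigError("each group needs at least one heart")
        if self.cells_per_heart < 1:
            raise ConfigError("cells_per_heart must be >= 1")


def simulate_cell_values(
    design: ExperimentDesign, seed: int | None = None
) -> pd.DataFrame:
    """Per-cell readout values with the design's hierarchical structure (no images).

    value = treatment mean + heart intercept + cell noise.  Deterministic
    given the seed; per-heart sub-streams keep hearts independent.
    """
    design.validate()
    master = design.seed if seed is None else seed
    rows = []
    for gi, tr in enumerate(design.treatments):
        for hi in range(design.n_hearts(tr.label)):
            rng = child_rng(master, 1, gi, hi)
            intercept = rng.normal(0.0, design.heart_sd)
            vals = tr.neon_mean + intercept + rng.normal(0.0, design.cell_sd, design.cells_per_heart)
            for ci, v in enumerate(vals):
                rows.append(
                    {
                        "treatment": tr.label,
                        "heart_id": f"{tr.label}_h{hi + 1}",
                        "cell_id": ci + 1,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows)


def simulate_experiment(
    design: ExperimentDesign, config: SimulationConfig
) -> dict[tuple[str, str, int], tuple[ImageField, GroundTruth]]:
    """Render a full multi-heart imaging experiment.

    Returns fields keyed by (treatment label, heart id, field index).  Each
    heart's cells are split into fields of ``config.n_live_cells`` live cells;
    per-cell NeonGreen2 means follow the hierarchical model (clipped at 0 for
    rendering).  Sub-streams are derived per (group, heart, field).
    """
    design.validate()
    config.validate()
    out: dict[tuple[str, str, int], tuple[ImageField, GroundTruth]] = {}
    for gi, tr in enumerate(design.treatments):
        amp = (
            config.heterogeneity_amplitude
            if tr.heterogeneity_amplitude is None
            else tr.heterogeneity_amplitude
        )
        for hi in range(design.n_hearts(tr.label)):
            heart_id = f"{tr.label}_h{hi + 1}"
            heart_rng = child_rng(design.seed, 2, gi, hi)
            intercept = heart_rng.normal(0.0, design.heart_sd)
            cell_means = np.clip(
                tr.neon_mean
                + intercept
                + heart_rng.normal(0.0, design.cell_sd, design.cells_per_heart),
                0.0,
                None,
            )
            n_fields = math.ceil(design.cells_per_heart / config.n_live_cells)
            for fi in range(n_fields):
                chunk = cell_means[fi * config.n_live_cells : (fi + 1) * config.n_live_cells]
                field_cfg = dataclasses.replace(
                    config, n_live_cells=len(chunk), heterogeneity_amplitude=amp
                )
                rng = child_rng(design.seed, 3, gi, hi, fi)
                field, truth = simulate_myocyte_field(
                    field_cfg,
                    heart_id=heart_id,
                    treatment=tr.label,
                    rng=rng,
                    live_neon_means=list(chunk),
                )
                out[(tr.label, heart_id, fi)] = (field, truth)
    return out


# ---------------------------------------------------------------------------
# tissue sections
# ---------------------------------------------------------------------------


@dataclass
class SectionConfig:
    """Three-channel tissue-section image: DAPI (nuclei), actinin (cells), red (immunostain).

    ``fractions`` are target area fractions (extracellular, cytoplasmic,
    nuclear) and must sum to 1; ``red_means`` are the per-compartment mean red
    intensities in the same order.
    """

    shape: tuple[int, int] = (256, 256)
    fractions: tuple[float, float, float] = (0.5, 0.4, 0.1)
    red_means: tuple[float, float, float] = (10.0, 25.0, 45.0)
    red_sd: float = 3.0
    background_level: float = 5.0
    dapi_level: float = 150.0
    actinin_level: float = 80.0
    noise_sd: float = 2.0
    smooth_sigma_cells: float = 8.0  # px; blob scale of the cell regions
    smooth_sigma_nuclei: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-8:
            raise ConfigError("compartment fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ConfigError("fractions must be non-negative")
        if self.red_sd < 0 or self.noise_sd < 0:
            raise ConfigError("noise SDs must be non-negative")


@dataclass
class SectionImage:
    dapi: np.ndarray
    actinin: np.ndarray
    red: np.ndarray
    pixel_size: float = 0.5

    def stack(self) -> np.ndarray:
        return np.stack([self.dapi, self.actinin, self.red])


@dataclass
class SectionTruth:
    """Per-pixel compartment labels: 0 extracellular, 1 cytoplasmic, 2 nuclear."""

    compartment_labels: np.ndarray

    def mask(self, compartment: int) -> np.ndarray:
        return self.compartment_labels == compartment


def simulate_section(config: SectionConfig) -> tuple[SectionImage, SectionTruth]:
    """Blob-structured section with compartment area fractions hit by quantile thresholds."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    f_ext, f_cyt, f_nuc = config.fractions

    cell_field = ndimage.gaussian_filter(rng.standard_normal(shape), config.smooth_sigma_cells)
    cell_frac = f_cyt + f_nuc
    if cell_frac > 0:
        cells = cell_field >= np.quantile(cell_field, 1.0 - cell_frac)
    else:
        cells = np.zeros(shape, dtype=bool)

    labels = np.zeros(shape, dtype=np.int8)
    labels[cells] = 1
    if f_nuc > 0 and cells.any():
        nuc_field = ndimage.gaussian_filter(rng.standard_normal(shape), config.smooth_sigma_nuclei)
        inside = nuc_field[cells]
        thr = np.quantile(inside, 1.0 - f_nuc / cell_frac)
        nuclei = cells & (nuc_field >= thr)
        labels[nuclei] = 2

    dapi = np.full(shape, config.background_level)
    dapi[labels == 2] += config.dapi_level
    actinin = np.full(shape, config.background_level)
    actinin[labels >= 1] += config.actinin_level
    red = np.empty(shape)
    for comp, mean in zip((0, 1, 2), config.red_means):
        m = labels == comp
        red[m] = mean + (rng.normal(0.0, config.red_sd, int(m.sum())) if config.red_sd > 0 else 0.0)

    if config.noise_sd > 0:
        dapi = dapi + rng.normal(0.0, config.noise_sd, shape)
        actinin = actinin + rng.normal(0.0, config.noise_sd, shape)
    dapi = np.clip(dapi, 0.0, None)
    actinin = np.clip(actinin, 0.0, None)
    red = np.clip(red, 0.0, None)
    return SectionImage(dapi=dapi, actinin=actinin, red=red), SectionTruth(compartment_labels=labels)


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------


def simulate_frap_trace(
    tau: float,
    mobile_fraction: float,
    bleach_depth: float = 0.5,
    noise_sd: float = 0.0,
    times: np.ndarray | None = None,
    baseline: float = 100.0,
    n_prebleach: int = 10,
    seed: int | None = None,
) -> FRAPTrace:
    """Single-exponential recovery trace with a pre-bleach plateau.

    ``bleach_depth`` is the post-bleach intensity as a fraction of baseline
    (0.5 bleaches to 50% of baseline).  Post-bleach signal is
    F(t) = F_bleach + mobile_fraction*(baseline - F_bleach)*(1 - exp(-t/tau)).
    If ``times`` is omitted, samples run from -5 s to 60 s at 0.5-s intervals
    with the bleach at t = 0.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must lie in [0, 1]")
    if times is None:
        pre = np.arange(-n_prebleach, 0) * 0.5
        post = np.arange(0.0, 60.0 + 1e-9, 0.5)
        times = np.concatenate([pre, post])
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("time vector must be strictly increasing")
    bleach_index = int(np.searchsorted(times, 0.0))
    floor = bleach_depth * baseline
    intensity = np.where(
        times < 0,
        baseline,
        floor + mobile_fraction * (baseline - floor) * (1.0 - np.exp(-np.clip(times, 0, None) / tau)),
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, times.shape)
    return FRAPTrace(time=times, intensity=intensity, bleach_index=bleach_index)


# ---------------------------------------------------------------------------
# biodistribution
# ---------------------------------------------------------------------------


def simulate_biodistribution(
    fold_map: Mapping[str, Mapping[str, float]],
    n_per_group: int = 6,
    dose: float = 1.0e9,
    organ_base: Mapping[str, float] | float = 100.0,
    tissue_mass: Mapping[str, float] | float = 0.2,
    mass_cv: float = 0.1,
    noise_cv: float = 0.0,
    control_label: str = "control",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-animal organ luminescence table with known enrichment folds.

    ``fold_map`` maps each non-control group to organ->fold versus control;
    the control group (fold 1 everywhere) is added automatically.  Raw
    luminescence = fold x organ base level x dose x tissue mass x lognormal
    noise, so dose- and mass-normalization recovers the folds exactly when
    ``noise_cv`` = 0 (mass variation cancels by construction).  Sexes
    alternate within each group, mirroring balanced male/female cohorts.
    """
    if n_per_group < 1:
        raise ConfigError("n_per_group must be >= 1")
    organs = sorted({o for folds in fold_map.values() for o in folds})
    if not organs:
        raise ConfigError("fold_map must name at least one organ")
    for g, folds in fold_map.items():
        if any(f <= 0 for f in folds.values()):
            raise ConfigError("folds must be positive")
        if set(folds) != set(organs):
            raise ConfigError(f"group {g!r} is missing organs")
    rng = np.random.default_rng(seed)

    def base(o):
        return organ_base[o] if isinstance(organ_base, Mapping) else float(organ_base)

    def mass_mean(o):
        return tissue_mass[o] if isinstance(tissue_mass, Mapping) else float(tissue_mass)

    groups = {control_label: {o: 1.0 for o in organs}}
    groups.update({g: dict(f) for g, f in fold_map.items() if g != control_label})

    rows = []
    animal = 0
    for glabel, folds in groups.items():
        for i in range(n_per_group):
            animal += 1
            sex = "M" if i % 2 == 0 else "F"
            for o in organs:
                mass = mass_mean(o)
                if mass_cv > 0:
                    sigma = math.sqrt(math.log(1 + mass_cv**2))
                    mass *= rng.lognormal(-(sigma**2) / 2.0, sigma)
                raw = folds[o] * base(o) * dose * mass
                if noise_cv > 0:
                    sigma = math.sqrt(math.log(1 + noise_cv**2))
                    raw *= rng.lognormal(-(sigma**2) / 2.0, sigma)
                rows.append(
                    {
                        "animal_id": f"a{animal:03d}",
                        "sex": sex,
                        "group": glabel,
                        "organ": o,
                        "luminescence": raw,
                        "dose": dose,
                        "tissue_mass": mass,
                    }
                )
    return pd.DataFrame(rows)
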