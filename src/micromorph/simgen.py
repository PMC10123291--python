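"""Synthetic microglia images and multiplex cytokine experiments.

The generator emulates the two inputs of the analysis with known ground
truth so every downstream stage is verifiable without any real data:

* **Images** — label rasters of non-overlapping cells drawn from a mixture
  of three morphotypes (round/amoeboid, polarized/rod-like, ramified), with
  a paired nuclei-channel raster. The shape grammar is deliberately
  minimal: the soma is a noisy ellipse (elongation >= 3 for rods) and
  processes are tapered protrusions placed at angularly separated
  positions, so each construction forces the defining feature of its class.

* **Plates** — 96-well multiplex cytokine experiments for 10 analytes with
  6-point 10x serial-dilution duplicate standards, 1:2-diluted sample
  wells, two medium-only background wells, and a per analyte x genotype x
  treatment true fold-effect table. Well responses follow a forward 5PL
  with multiplicative lognormal noise; at zero noise the plate is exactly
  invertible by the calibration chain.

A third, parametric layer (:func:`generate_morphology_experiment`) draws
per-cell morphotypes and descriptor values directly from the same
class-conditional distributions the renderer targets, which makes repeated
whole-experiment simulations cheap.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .cytokines import forward_5pl
from .morphometry import MORPHOTYPES, POLARIZED, RAMIFIED, ROUND

__all__ = [
    "ShapeParams",
    "ROIImage",
    "PlateDesign",
    "MorphologyDesign",
    "SizingError",
    "PlacementError",
    "ANALYTES",
    "TREATMENTS",
    "GENOTYPES",
    "generate_cell_shape",
    "sample_shape_params",
    "sample_morphotypes",
    "generate_roi",
    "default_plate_design",
    "generate_cytokine_experiment",
    "default_morphology_design",
    "generate_morphology_experiment",
    "write_roi",
    "write_plate",
]

ANALYTES = ("TNFa", "IFNg", "IL-1b", "IL-2", "IL-4", "IL-6",
            "IL-10", "IL-12", "IL-17", "IL-27")
GENOTYPES = ("CTRL", "KO")
TREATMENTS = ("control", "BzATP", "LPS+BzATP", "JNJ-47965567", "A-804598")
STIMULATIONS = ("BzATP", "LPS+BzATP")
ANTAGONISTS = ("JNJ-47965567", "A-804598")


class SizingError(ValueError):
    """Requested raster cannot contain the shape."""


class PlacementError(RuntimeError):
    """Cell placement failed after bounded retries."""


# --------------------------------------------------------------------------
# single-cell shapes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeParams:
    """Generative parameters of one cell."""

    morphotype: str
    soma_radius_um: float = 10.0
    n_processes: int = 0
    process_length_um: float = 25.0
    process_width_um: float = 3.0
    elongation: float = 1.0  # soma major/minor axis ratio, >= 1
    boundary_noise: float = 0.04  # relative radial perturbation, >= 0

    def __post_init__(self):
        if self.morphotype not in MORPHOTYPES:
            raise ValueError(f"unknown morphotype {self.morphotype!r}")
        if self.soma_radius_um <= 0:
            raise ValueError("soma_radius_um must be > 0")
        if self.n_processes < 0:
            raise ValueError("n_processes must be >= 0")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")
        if self.boundary_noise < 0:
            raise ValueError("boundary_noise must be >= 0")
        # morphotype-consistent construction rules
        if self.morphotype == ROUND and self.n_processes != 0:
            raise ValueError("round/amoeboid cells have no processes")
        if self.morphotype == POLARIZED and self.elongation < 3:
            raise ValueError("polarized cells require elongation >= 3")
        if self.morphotype == RAMIFIED and self.n_processes < 3:
            raise ValueError("ramified cells require >= 3 processes")


def _soma_polygon(params: ShapeParams, rng: np.random.Generator,
                  px: float, orientation: float) -> tuple[np.ndarray, np.ndarray]:
    """Radial polygon of the soma (row, col offsets in px)."""
    r_px = params.soma_radius_um / px
    a = r_px * math.sqrt(params.elongation)
    b = r_px / math.sqrt(params.elongation)
    theta = np.linspace(0.0, 2.0 * math.pi, 360, endpoint=False)
    t = theta - orientation
    radius = a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
    if params.boundary_noise > 0:
        noise = np.zeros_like(theta)
        for k in range(2, 7):
            amp = rng.normal(0.0, params.boundary_noise / math.sqrt(k))
            noise += amp * np.cos(k * theta + rng.uniform(0, 2 * math.pi))
        radius = radius * np.clip(1.0 + noise, 0.4, None)
    radius = np.clip(radius, 1.5, None)
    return radius * np.sin(theta), radius * np.cos(theta), theta, radius


def generate_cell_shape(
    params: ShapeParams,
    seed: int,
    pixel_size_um: float = 1.0,
    canvas_px: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Render one cell as a connected binary mask, with its truth record.

    Deterministic for identical ``(params, seed)``. ``canvas_px`` forces a
    square canvas; a :class:`SizingError` is raised if the shape cannot fit.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    rng = np.random.default_rng(seed)
    px = float(pixel_size_um)
    orientation = rng.uniform(0, math.pi)

    dr, dc, theta, radius = _soma_polygon(params, rng, px, orientation)
    r_max = float(radius.max())
    proc_len_px = params.process_length_um / px if params.n_processes else 0.0
    reach = r_max + 1.25 * proc_len_px + max(3.0, params.process_width_um / px)
    needed = int(2 * math.ceil(reach) + 3)
    size = needed if canvas_px is None else int(canvas_px)
    if size < needed:
        raise SizingError(f"canvas {size}px cannot contain shape needing {needed}px")
    c0 = size // 2
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw_polygon(c0 + dr, c0 + dc, shape=mask.shape)
    mask[rr, cc] = True

    n = params.n_processes
    if n > 0:
        base = rng.uniform(0, 2 * math.pi)
        jitter = rng.uniform(-0.3, 0.3, size=n) * (2 * math.pi / n)
        angles = base + 2 * math.pi * np.arange(n) / n + jitter
        w0 = max(1.6, params.process_width_um / px)
        for ang in angles:
            idx = int(np.argmin(np.abs(((theta - ang) + math.pi) % (2 * math.pi) - math.pi)))
            r_start = float(radius[idx]) - 1.0
            length = proc_len_px * rng.uniform(0.8, 1.2)
            drift = rng.normal(0.0, 0.015)
            steps = max(int(length), 2)
            direction = ang
            r_cur = r_start
            pos_r, pos_c = c0 + r_start * math.sin(ang), c0 + r_start * math.cos(ang)
            for s in range(steps):
                f = s / steps
                width = max(0.8, 0.5 * w0 * (1.0 - 0.6 * f))
                rr, cc = draw_disk((pos_r, pos_c), width + 0.5, shape=mask.shape)
                mask[rr, cc] = True
                direction += drift
                pos_r += math.sin(direction)
                pos_c += math.cos(direction)

    truth = {
        "morphotype": params.morphotype,
        "n_processes": params.n_processes,
        "soma_radius_um": params.soma_radius_um,
        "elongation": params.elongation,
        "center": (c0, c0),
    }
    return mask, truth


def sample_shape_params(morphotype: str, rng: np.random.Generator) -> ShapeParams:
    """Draw class-conditional generative parameters.

    Per-morphotype size priors are artifact defaults (no per-class size
    distributions exist to copy); they are stated here, in config, and in
    the methods note.
    """
    if morphotype == ROUND:
        return ShapeParams(
            morphotype=ROUND,
            soma_radius_um=rng.uniform(9.0, 14.0),
            n_processes=0,
            elongation=rng.uniform(1.0, 1.6),
            boundary_noise=rng.uniform(0.02, 0.06),
        )
    if morphotype == POLARIZED:
        return ShapeParams(
            morphotype=POLARIZED,
            soma_radius_um=rng.uniform(7.0, 10.0),
            n_processes=0,
            elongation=rng.uniform(3.3, 4.5),
            boundary_noise=rng.uniform(0.02, 0.05),
        )
    if morphotype == RAMIFIED:
        return ShapeParams(
            morphotype=RAMIFIED,
            soma_radius_um=rng.uniform(6.5, 9.0),
            n_processes=int(rng.choice([3, 4, 5, 6], p=[0.25, 0.3, 0.3, 0.15])),
            process_length_um=rng.uniform(20.0, 32.0),
            process_width_um=rng.uniform(2.6, 3.4),
            elongation=rng.uniform(1.0, 1.4),
            boundary_noise=rng.uniform(0.02, 0.05),
        )
    raise ValueError(f"unknown morphotype {morphotype!r}")


def sample_morphotypes(mixture, n_cells: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_cells`` morphotype labels from a (round, polarized, ramified) mixture."""
    mixture = np.asarray(mixture, dtype=float)
    if mixture.shape != (3,) or np.any(mixture < 0) or not math.isclose(mixture.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("mixture must be three non-negative proportions summing to 1")
    return rng.choice(np.array(MORPHOTYPES, dtype=object), size=int(n_cells), p=mixture)


# --------------------------------------------------------------------------
# ROI images
# --------------------------------------------------------------------------

@dataclass
class ROIImage:
    """A simulated region of interest (~1 mm^2 by default)."""

    labels: np.ndarray  # uint16, 0 = background
    nuclei: np.ndarray  # uint16 intensity raster
    pixel_size_um: float
    truth: pd.DataFrame  # cell_id, morphotype, n_processes, n_nuclei, ...
    roi_id: str = "roi"

    @property
    def roi_area_um2(self) -> float:
        return float(self.labels.size) * self.pixel_size_um**2


def generate_roi(
    mixture=(0.6, 0.2, 0.2),
    n_cells: int = 100,
    pixel_size_um: float = 1.0,
    seed: int = 0,
    shape: tuple[int, int] = (1000, 1000),
    multinucleated_fraction: float = 0.05,
    nucleus_intensity: float = 1000.0,
    background_intensity: float = 100.0,
    max_tries: int = 400,
    roi_id: str = "roi",
) -> ROIImage:
    """Place non-overlapping cells of mixed morphotypes into a label raster.

    Each cell gets one nucleus blob at its soma centre;
    ``multinucleated_fraction`` of ROIs contain one binucleated cell.
    Raises :class:`PlacementError` when the requested density cannot be
    achieved without overlap within the retry budget.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    labels = np.zeros((H, W), dtype=np.uint16)
    nuclei = np.clip(
        rng.normal(background_intensity, 8.0, size=(H, W)), 0, None
    ).astype(np.uint16)
    morphs = sample_morphotypes(mixture, n_cells, rng)
    multi_roi = rng.random() < multinucleated_fraction and n_cells > 0
    multi_cell = int(rng.integers(1, n_cells + 1)) if multi_roi else -1

    rows = []
    for cell_id, morph in enumerate(morphs, start=1):
        params = sample_shape_params(str(morph), rng)
        cell_seed = int(rng.integers(0, 2**31 - 1))
        mask, truth = generate_cell_shape(params, cell_seed, pixel_size_um)
        h, w = mask.shape
        if h >= H - 2 or w >= W - 2:
            raise SizingError("ROI raster too small for generated cell")
        placed = False
        for _ in range(max_tries):
            top = int(rng.integers(1, H - h - 1))
            left = int(rng.integers(1, W - w - 1))
            window = labels[top - 1:top + h + 1, left - 1:left + w + 1]
            grown = np.zeros((h + 2, w + 2), dtype=bool)
            grown[1:-1, 1:-1] = mask
            # 1-px gap: check the dilated footprint against existing labels
            grown = (
                grown
                | np.roll(grown, 1, 0) | np.roll(grown, -1, 0)
                | np.roll(grown, 1, 1) | np.roll(grown, -1, 1)
            )
            if not (window[grown] > 0).any():
                labels[top:top + h, left:left + w][mask] = cell_id
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {cell_id}/{n_cells} after {max_tries} tries"
            )
        center = (top + truth["center"][0], left + truth["center"][1])
        n_nuclei = 2 if cell_id == multi_cell else 1
        nuc_r = max(2.0, 0.42 * params.soma_radius_um / pixel_size_um)
        offsets = [(0.0, 0.0)]
        if n_nuclei == 2:
            ang = rng.uniform(0, 2 * math.pi)
            d = 1.15 * nuc_r
            offsets = [(-d / 2 * math.sin(ang), -d / 2 * math.cos(ang)),
                       (d / 2 * math.sin(ang), d / 2 * math.cos(ang))]
        for orr, occ in offsets:
            rr, cc = draw_disk((center[0] + orr, center[1] + occ), nuc_r,
                               shape=nuclei.shape)
            nuclei[rr, cc] = np.clip(
                nucleus_intensity + rng.normal(0, 30.0, size=rr.size), 0, 65535
            ).astype(np.uint16)
        rows.append(
            {
                "cell_id": cell_id,
                "morphotype": truth["morphotype"],
                "n_processes": truth["n_processes"],
                "n_nuclei": n_nuclei,
                "soma_radius_um": params.soma_radius_um,
                "center_row": center[0],
                "center_col": center[1],
            }
        )
    truth_df = pd.DataFrame(
        rows,
        columns=["cell_id", "morphotype", "n_processes", "n_nuclei",
                 "soma_radius_um", "center_row", "center_col"],
    )
    return ROIImage(labels=labels, nuclei=nuclei, pixel_size_um=pixel_size_um,
                    truth=truth_df, roi_id=roi_id)


# --------------------------------------------------------------------------
# cytokine plates
# --------------------------------------------------------------------------

def _default_effects() -> dict[tuple[str, str, str], float]:
    """True fold-multiplier table (analyte, genotype, treatment).

    Encodes the qualitative effect directions of the study system:
    stimulation raises proinflammatory cytokines more in CTRL than KO,
    BzATP depresses IL-4 in both genotypes, antagonists lower
    proinflammatory cytokines and double IL-4 in CTRL only. Magnitudes are
    free artifact parameters, not claims.
    """
    eff: dict[tuple[str, str, str], float] = {}
    for a in ANALYTES:
        for g in GENOTYPES:
            for t in TREATMENTS:
                eff[(a, g, t)] = 1.0
    bz = {
        "CTRL": {"IL-1b": 1.6, "TNFa": 1.3, "IL-6": 1.3, "IL-27": 1.2,
                 "IL-4": 1 / 9, "IL-10": 0.6},
        "KO": {"IL-1b": 1.1, "TNFa": 1.1, "IL-6": 1.1, "IL-27": 1.1,
               "IL-4": 1 / 6, "IL-10": 0.75},
    }
    lps = {
        "CTRL": {"TNFa": 25.0, "IL-6": 20.0, "IL-1b": 6.0, "IL-27": 10.0,
                 "IFNg": 2.0, "IL-12": 1.5, "IL-17": 1.3, "IL-2": 1.2,
                 "IL-4": 0.6, "IL-10": 0.8},
        "KO": {"TNFa": 8.0, "IL-6": 7.0, "IL-1b": 2.5, "IL-27": 4.0,
               "IFNg": 1.4, "IL-12": 1.2, "IL-17": 1.1, "IL-2": 1.1,
               "IL-4": 0.9, "IL-10": 0.9},
    }
    antag = {
        "CTRL": {"TNFa": 0.6, "IFNg": 0.6, "IL-6": 0.75, "IL-1b": 0.8,
                 "IL-27": 0.9, "IL-4": 2.0, "IL-10": 1.2},
        "KO": {"TNFa": 0.7, "IFNg": 0.7, "IL-6": 0.8, "IL-1b": 0.85},
    }
    for g, table in bz.items():
        for a, m in table.items():
            eff[(a, g, "BzATP")] = m
    for g, table in lps.items():
        for a, m in table.items():
            eff[(a, g, "LPS+BzATP")] = m
    for g, table in antag.items():
        for a, m in table.items():
            for t in ANTAGONISTS:
                eff[(a, g, t)] = m
    return eff


_BASELINE_PG_ML = {
    "TNFa": 40.0, "IFNg": 10.0, "IL-1b": 30.0, "IL-2": 8.0, "IL-4": 20.0,
    "IL-6": 50.0, "IL-10": 15.0, "IL-12": 12.0, "IL-17": 6.0, "IL-27": 25.0,
}


def _true_5pl_params() -> dict[str, tuple[float, float, float, float, float]]:
    """Fixed per-analyte true curve parameters (A, D, C, B, g)."""
    params = {}
    for i, a in enumerate(ANALYTES):
        params[a] = (
            25.0 + 2.0 * i,             # A: lower asymptote
            24000.0 + 600.0 * i,        # D: upper asymptote
            120.0 * (1.3 ** i),         # C: inflection scale, log-spread
            0.95 + 0.02 * i,            # B: slope
            0.85 + 0.05 * i,            # g: asymmetry
        )
    return params


@dataclass
class PlateDesign:
    """Design of one synthetic multiplex cytokine experiment."""

    analytes: tuple[str, ...] = ANALYTES
    n_animals_per_genotype: int = 6
    treatments: tuple[str, ...] = TREATMENTS
    standard_top_pg_ml: float = 10000.0
    n_standards: int = 6
    dilution_step: float = 10.0
    standard_replicates: int = 2
    dilution_factor: float = 2.0
    n_background_wells: int = 2
    background_pg_ml: float = 2.0
    noise_cv: float = 0.08
    animal_cv: float = 0.25  # between-animal baseline secretion spread
    effect_cv: float = 0.10  # per-animal jitter on the true multiplier
    effects: dict = field(default_factory=_default_effects)
    baselines: dict = field(default_factory=lambda: dict(_BASELINE_PG_ML))
    true_params: dict = field(default_factory=_true_5pl_params)

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if any(m <= 0 for m in self.effects.values()):
            raise ValueError("effect multipliers must be > 0")

    def standard_concentrations(self) -> np.ndarray:
        return self.standard_top_pg_ml / self.dilution_step ** np.arange(self.n_standards)

    def animals(self) -> list[tuple[str, str]]:
        out = []
        for g in GENOTYPES:
            for i in range(self.n_animals_per_genotype):
                out.append((f"{g.lower()}{i + 1:02d}", g))
        return out


def default_plate_design(**overrides) -> PlateDesign:
    return PlateDesign(**overrides)


def _lognoise(rng: np.random.Generator, cv: float, size=None):
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=size)


def generate_cytokine_experiment(
    design: PlateDesign, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one plate: ``(standards, samples, truth)`` tables.

    Sample wells contain ``(secreted + medium background) / dilution``;
    responses follow the analyte's true forward 5PL with multiplicative
    lognormal noise of the design's CV. Truth records the realized per
    animal x analyte x treatment fold multiplier and secreted
    concentration, so downstream recovery can be scored exactly.
    """
    rng = np.random.default_rng(seed)
    std_rows, sample_rows, truth_rows = [], [], []
    animals = design.animals()
    # per-animal baseline secretion multiplier, shared across analytes' wells
    animal_base = {
        (animal, a): _lognoise(rng, design.animal_cv)
        for animal, _ in animals
        for a in design.analytes
    }
    well_counter = 0
    for a in design.analytes:
        A, D, C, B, g = design.true_params[a]
        for conc in design.standard_concentrations():
            for rep in range(design.standard_replicates):
                resp = forward_5pl(conc, A, D, C, B, g) * _lognoise(rng, design.noise_cv)
                std_rows.append(
                    {"well": f"STD-{a}-{conc:g}-{rep + 1}", "role": "standard",
                     "analyte": a, "concentration": conc, "response": float(resp),
                     "replicate": rep + 1}
                )
        for k in range(design.n_background_wells):
            resp = forward_5pl(design.background_pg_ml, A, D, C, B, g)
            resp *= _lognoise(rng, design.noise_cv)
            sample_rows.append(
                {"well": f"BG-{k + 1}", "role": "background", "analyte": a,
                 "response": float(resp), "animal": "", "genotype": "",
                 "treatment": "", "dilution": 1.0}
            )
        for animal, geno in animals:
            base = design.baselines[a] * animal_base[(animal, a)]
            for treatment in design.treatments:
                mult = design.effects[(a, geno, treatment)]
                realized = mult * _lognoise(rng, design.effect_cv)
                secreted = base * realized
                n_wells = 2 if treatment == "control" else 1
                for w in range(n_wells):
                    well_counter += 1
                    in_well = (secreted + design.background_pg_ml) / design.dilution_factor
                    resp = forward_5pl(in_well, A, D, C, B, g)
                    resp *= _lognoise(rng, design.noise_cv)
                    sample_rows.append(
                        {"well": f"W{well_counter:04d}",
                         "role": "control" if treatment == "control" else "treatment",
                         "analyte": a, "response": float(resp), "animal": animal,
                         "genotype": geno, "treatment": treatment,
                         "dilution": design.dilution_factor}
                    )
                truth_rows.append(
                    {"analyte": a, "animal": animal, "genotype": geno,
                     "treatment": treatment, "true_multiplier": mult,
                     "realized_multiplier": realized,
                     "secreted_pg_ml": secreted}
                )
    return (
        pd.DataFrame(std_rows),
        pd.DataFrame(sample_rows),
        pd.DataFrame(truth_rows),
    )


# --------------------------------------------------------------------------
# parametric morphology experiments
# --------------------------------------------------------------------------

_ROUND_FRACTION = {
    ("CTRL", "control"): 0.79,
    ("CTRL", "BzATP"): 0.90,
    ("CTRL", "LPS+BzATP"): 0.93,
    ("CTRL", "JNJ-47965567"): 0.67,
    ("CTRL", "A-804598"): 0.67,
    ("KO", "control"): 0.83,
    ("KO", "BzATP"): 0.87,
    ("KO", "LPS+BzATP"): 0.92,
    ("KO", "JNJ-47965567"): 0.835,
    ("KO", "A-804598"): 0.835,
}

# class-conditional descriptor distributions (mean, sd, lo, hi)
_DESCRIPTOR_PRIORS = {
    "roundness": {
        ROUND: (0.82, 0.07, 0.40, 0.999),
        POLARIZED: (0.26, 0.05, 0.05, 0.40),
        RAMIFIED: (0.45, 0.08, 0.10, 0.80),
    },
    "circularity": {
        ROUND: (0.80, 0.06, 0.30, 1.0),
        POLARIZED: (0.40, 0.08, 0.10, 0.90),
        RAMIFIED: (0.22, 0.06, 0.05, 0.70),
    },
    "solidity": {
        ROUND: (0.95, 0.03, 0.70, 1.0),
        POLARIZED: (0.85, 0.05, 0.55, 1.0),
        RAMIFIED: (0.55, 0.08, 0.25, 0.95),
    },
}
_AREA_LOG_MEAN = {ROUND: math.log(450.0), POLARIZED: math.log(380.0),
                  RAMIFIED: math.log(520.0)}
_AREA_LOG_SD = 0.35


@dataclass
class MorphologyDesign:
    """Design of a repeated whole-experiment morphology simulation."""

    n_animals_per_genotype: int = 8
    cells_per_animal: int = 300
    n_rois: int = 2
    treatments: tuple[str, ...] = TREATMENTS
    round_fraction: dict = field(default_factory=lambda: dict(_ROUND_FRACTION))
    polarized_share_of_rest: float = 0.6
    animal_logit_sd: float = 0.15  # shared per-animal shift of the round fraction

    def animals(self) -> list[tuple[str, str]]:
        out = []
        for g in GENOTYPES:
            for i in range(self.n_animals_per_genotype):
                out.append((f"{g.lower()}{i + 1:02d}", g))
        return out


def default_morphology_design(**overrides) -> MorphologyDesign:
    return MorphologyDesign(**overrides)


def _trunc_normal(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def generate_morphology_experiment(
    design: MorphologyDesign, seed: int = 0
) -> pd.DataFrame:
    """Draw a per-cell morphology table for a full experiment.

    Cells are drawn from genotype x treatment morphotype mixtures (with a
    per-animal logit shift shared across that animal's conditions, mimicking
    culture-level variability) and descriptor values from the
    class-conditional priors the image renderer targets. Columns: animal,
    genotype, treatment, roi, morphotype, roundness, aspect_ratio, area,
    perimeter, circularity, solidity, complexity.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for animal, geno in design.animals():
        shift = rng.normal(0.0, design.animal_logit_sd)
        for treatment in design.treatments:
            p_round = design.round_fraction[(geno, treatment)]
            logit = math.log(p_round / (1.0 - p_round)) + shift
            p_round = 1.0 / (1.0 + math.exp(-logit))
            rest = 1.0 - p_round
            mixture = (
                p_round,
                rest * design.polarized_share_of_rest,
                rest * (1.0 - design.polarized_share_of_rest),
            )
            morphs = sample_morphotypes(mixture, design.cells_per_animal, rng)
            n = len(morphs)
            roundness = np.empty(n)
            circ = np.empty(n)
            solidity = np.empty(n)
            area = np.empty(n)
            for m in MORPHOTYPES:
                idx = morphs == m
                k = int(idx.sum())
                if k == 0:
                    continue
                roundness[idx] = _trunc_normal(rng, *_DESCRIPTOR_PRIORS["roundness"][m], k)
                circ[idx] = _trunc_normal(rng, *_DESCRIPTOR_PRIORS["circularity"][m], k)
                solidity[idx] = _trunc_normal(rng, *_DESCRIPTOR_PRIORS["solidity"][m], k)
                area[idx] = rng.lognormal(_AREA_LOG_MEAN[m], _AREA_LOG_SD, size=k)
            perimeter = np.sqrt(4.0 * math.pi * area / circ)
            frames.append(
                pd.DataFrame(
                    {
                        "animal": animal,
                        "genotype": geno,
                        "treatment": treatment,
                        "roi": 1 + (np.arange(n) % design.n_rois),
                        "morphotype": morphs,
                        "roundness": roundness,
                        "aspect_ratio": 1.0 / roundness,
                        "area": area,
                        "perimeter": perimeter,
                        "circularity": circ,
                        "solidity": solidity,
                        "complexity": perimeter / area,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------

def write_roi(roi: ROIImage, outdir: str | Path) -> dict[str, Path]:
    """Write label/nuclei rasters as 16-bit TIFF and truth as JSON."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "labels": outdir / f"{roi.roi_id}_labels.tif",
        "nuclei": outdir / f"{roi.roi_id}_nuclei.tif",
        "truth": outdir / f"{roi.roi_id}_truth.json",
    }
    tifffile.imwrite(paths["labels"], roi.labels.astype(np.uint16))
    tifffile.imwrite(paths["nuclei"], roi.nuclei.astype(np.uint16))
    payload = {
        "roi_id": roi.roi_id,
        "pixel_size_um": roi.pixel_size_um,
        "roi_area_um2": roi.roi_area_um2,
        "cells": roi.truth.to_dict(orient="records"),
    }
    paths["truth"].write_text(json.dumps(payload, indent=2))
    return paths


def write_plate(
    standards: pd.DataFrame, samples: pd.DataFrame, outdir: str | Path,
    prefix: str = "plate",
) -> dict[str, Path]:
    """Write standard and sample well tables as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "standards": outdir / f"{prefix}_standards.csv",
        "samples": outdir / f"{prefix}_samples.csv",
    }
    standards.to_csv(paths["standards"], index=False)
    samples.to_csv(paths["samples"], index=False)
    return paths
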