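"""Synthetic two-channel fluorescence microscopy fields with known ground truth.

Emulates a transient-transfection localization experiment: adherent
epithelial cells imaged at 40x on a widefield/confocal system, a blue
DNA counterstain (Hoechst/DAPI channel) marking every nucleus, and a
green channel (FITC) carrying the GFP-fusion signal only in transfected
cells.  Each simulated cell has a ground-truth localization class:

* ``NUCLEAR``      -- green signal confined to the nucleus disk,
* ``CYTOPLASMIC``  -- green signal in the annulus between nucleus and
  cell boundary,
* ``BOTH``         -- green signal over the whole cell disk,
* ``UNLABELED``    -- untransfected; contributes nothing to the green
  channel.

Cells are disks (nucleus) nested inside larger disks (cell body), placed
by dart-throwing with a minimum centre separation of twice the largest
cell radius, so the ground-truth geometry of every cell is unambiguous.
A full multi-well experiment mirrors the standard design of such an
assay: several treatment groups (wildtype construct, variant construct,
a diffuse-GFP positive control, an untransfected negative control),
wells plated in triplicate per experiment across two plates, two
independent experiments, and a fixed number of image fields captured
per well.

All randomness flows from a single master seed through a documented
per-field schedule (see :func:`field_seed`), so any individual field can
be regenerated in isolation and a whole experiment is bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "CLASSES",
    "LABELED_CLASSES",
    "CellSpec",
    "NoiseModel",
    "FieldSpec",
    "FieldImage",
    "TreatmentSpec",
    "ExperimentDesign",
    "OverlapError",
    "PlacementError",
    "render_field",
    "sample_field_spec",
    "field_seed",
    "generate_experiment",
]

#: Localization classes a labeled (transfected) cell can have.
LABELED_CLASSES = ("NUCLEAR", "CYTOPLASMIC", "BOTH")
#: All ground-truth classes, including untransfected cells.
CLASSES = LABELED_CLASSES + ("UNLABELED",)

_UINT16_MAX = np.iinfo(np.uint16).max


class OverlapError(ValueError):
    """Raised when nucleus disks overlap beyond the configured tolerance."""


class PlacementError(RuntimeError):
    """Raised when dart-throwing cannot place the requested cell count."""


@dataclass(frozen=True)
class CellSpec:
    """Geometry, intensity and ground-truth class of one simulated cell.

    Parameters
    ----------
    center
        (row, col) pixel coordinates of the cell centre.
    nucleus_radius, cell_radius
        Disk radii in pixels; ``cell_radius`` must exceed
        ``nucleus_radius``.
    true_class
        One of :data:`CLASSES`.
    nuclear_intensity, gfp_intensity
        Signal amplitudes in arbitrary fluorescence units, added on top
        of the channel background.  ``UNLABELED`` cells contribute
        nothing to the green channel regardless of ``gfp_intensity``.
    """

    center: tuple[float, float]
    nucleus_radius: float
    cell_radius: float
    true_class: str
    nuclear_intensity: float = 2000.0
    gfp_intensity: float = 2000.0

    def __post_init__(self) -> None:
        if not (self.cell_radius > self.nucleus_radius > 0):
            raise ValueError(
                f"require cell_radius > nucleus_radius > 0, got "
                f"cell_radius={self.cell_radius}, nucleus_radius={self.nucleus_radius}"
            )
        if self.true_class not in CLASSES:
            raise ValueError(f"unknown class {self.true_class!r}; expected one of {CLASSES}")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian read noise and optional Poisson shot noise."""

    gaussian_sd: float = 20.0
    poisson: bool = False


@dataclass(frozen=True)
class FieldSpec:
    """Complete recipe for rendering one two-channel field."""

    shape: tuple[int, int] = (512, 512)
    cells: tuple[CellSpec, ...] = ()
    background_level: tuple[float, float] = (100.0, 100.0)
    noise: NoiseModel = NoiseModel()
    seed: int = 0
    overlap_tol: float = 0.0

    def __post_init__(self) -> None:
        h, w = self.shape
        for cell in self.cells:
            r, c = cell.center
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"cell centre {cell.center} outside image bounds {self.shape}")


@dataclass
class FieldImage:
    """One acquired (or simulated) two-channel field with provenance.

    ``blue`` is the nuclear counterstain channel, ``green`` the
    GFP/FITC channel; both are 2-D arrays of identical shape.
    """

    blue: np.ndarray
    green: np.ndarray
    pixel_size_um: float = 0.325
    experiment: int = 1
    plate: int = 1
    well: str = "well"
    treatment: str = ""
    field: int = 1

    @property
    def provenance(self) -> dict:
        return {
            "experiment": self.experiment,
            "plate": self.plate,
            "well": self.well,
            "treatment": self.treatment,
            "field": self.field,
        }

    def to_tiff(self, path: str | Path) -> None:
        """Write a 2-page 16-bit TIFF (page 0 = blue, page 1 = green).

        Provenance and pixel size go into the ImageDescription tag as
        JSON so a field is self-describing independent of its path.
        """
        meta = dict(self.provenance, pixel_size_um=self.pixel_size_um)
        stack = np.stack([self.blue, self.green]).astype(np.uint16)
        tifffile.imwrite(path, stack, description=json.dumps(meta, sort_keys=True))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "FieldImage":
        """Read a two-channel field written by :meth:`to_tiff`.

        Accepts any TIFF whose first axis (pages or channels) has
        length >= 2; extra channels are ignored.
        """
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            desc = tf.pages[0].description
        stack = np.asarray(stack)
        if stack.ndim == 2:
            raise ValueError(f"{path}: single-channel TIFF, need blue + green channels")
        if stack.ndim != 3 or stack.shape[0] < 2:
            raise ValueError(f"{path}: expected >=2 channel pages, got shape {stack.shape}")
        kwargs: dict = {}
        try:
            meta = json.loads(desc) if desc else {}
            if isinstance(meta, dict):
                for key in ("experiment", "plate", "well", "treatment", "field", "pixel_size_um"):
                    if key in meta:
                        kwargs[key] = meta[key]
        except (json.JSONDecodeError, TypeError):
            pass
        return cls(blue=stack[0], green=stack[1], **kwargs)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> tuple[slice, slice, np.ndarray]:
    """Boolean disk restricted to its bounding box (for fast stamping)."""
    h, w = shape
    r0 = max(int(math.floor(center[0] - radius)) - 1, 0)
    r1 = min(int(math.ceil(center[0] + radius)) + 2, h)
    c0 = max(int(math.floor(center[1] - radius)) - 1, 0)
    c1 = min(int(math.ceil(center[1] + radius)) + 2, w)
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    mask = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2
    return slice(r0, r1), slice(c0, c1), mask


def _check_overlaps(cells: Sequence[CellSpec], tol: float) -> None:
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            a, b = cells[i], cells[j]
            d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            min_d = a.nucleus_radius + b.nucleus_radius - tol
            if d < min_d:
                raise OverlapError(
                    f"nucleus disks of cells {i} and {j} overlap: centre distance "
                    f"{d:.2f}px < {min_d:.2f}px (radii {a.nucleus_radius:.2f} + "
                    f"{b.nucleus_radius:.2f}, tolerance {tol}); ground truth would be ambiguous"
                )


def render_field(spec: FieldSpec, **provenance) -> tuple[FieldImage, pd.DataFrame]:
    """Render one field and return it with its ground-truth table.

    The blue channel receives a disk of ``nuclear_intensity`` at every
    nucleus.  The green channel receives, per cell class: NUCLEAR ->
    signal inside the nucleus disk only; CYTOPLASMIC -> signal in the
    annulus between nucleus and cell boundary; BOTH -> signal over the
    full cell disk; UNLABELED -> nothing.  Background is added, then
    optional Poisson shot noise, then Gaussian read noise, and pixel
    values are clipped to the 16-bit non-negative range.

    Rendering is bit-reproducible for a fixed ``spec.seed``.

    Raises
    ------
    OverlapError
        If any two nucleus disks overlap by more than
        ``spec.overlap_tol`` pixels.
    """
    _check_overlaps(spec.cells, spec.overlap_tol)
    blue = np.zeros(spec.shape, dtype=np.float64)
    green = np.zeros(spec.shape, dtype=np.float64)
    rows = []
    for cell_id, cell in enumerate(spec.cells, start=1):
        rs, cs, nmask = _disk_mask(spec.shape, cell.center, cell.nucleus_radius)
        blue[rs, cs][nmask] += cell.nuclear_intensity
        if cell.true_class == "NUCLEAR":
            green[rs, cs][nmask] += cell.gfp_intensity
        elif cell.true_class in ("CYTOPLASMIC", "BOTH"):
            rs2, cs2, cmask = _disk_mask(spec.shape, cell.center, cell.cell_radius)
            if cell.true_class == "CYTOPLASMIC":
                sub = np.zeros_like(cmask)
                sub[rs.start - rs2.start : rs.stop - rs2.start,
                    cs.start - cs2.start : cs.stop - cs2.start] = nmask
                cmask = cmask & ~sub
            green[rs2, cs2][cmask] += cell.gfp_intensity
        rows.append(
            {
                "cell_id": cell_id,
                "row": cell.center[0],
                "col": cell.center[1],
                "nucleus_radius": cell.nucleus_radius,
                "cell_radius": cell.cell_radius,
                "true_class": cell.true_class,
            }
        )
    blue += spec.background_level[0]
    green += spec.background_level[1]
    rng = np.random.default_rng(spec.seed)
    if spec.noise.poisson:
        blue = rng.poisson(blue).astype(np.float64)
        green = rng.poisson(green).astype(np.float64)
    if spec.noise.gaussian_sd > 0:
        blue = blue + rng.normal(0.0, spec.noise.gaussian_sd, spec.shape)
        green = green + rng.normal(0.0, spec.noise.gaussian_sd, spec.shape)
    blue = np.clip(np.rint(blue), 0, _UINT16_MAX).astype(np.uint16)
    green = np.clip(np.rint(green), 0, _UINT16_MAX).astype(np.uint16)
    truth = pd.DataFrame(rows, columns=["cell_id", "row", "col", "nucleus_radius", "cell_radius", "true_class"])
    img = FieldImage(blue=blue, green=green, **provenance)
    return img, truth


# ---------------------------------------------------------------------------
# Field sampling


def _place_centers(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    min_sep: float,
    margin: float,
    max_attempts_per_cell: int = 500,
) -> list[tuple[float, float]]:
    """Dart-throwing placement with a hard minimum centre separation."""
    h, w = shape
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PlacementError(f"image {shape} too small for margin {margin}")
    centers: list[tuple[float, float]] = []
    attempts = 0
    budget = max_attempts_per_cell * max(n, 1)
    while len(centers) < n:
        if attempts >= budget:
            raise PlacementError(
                f"could only place {len(centers)} of {n} cells with separation "
                f"{min_sep:.1f}px in a {shape} field; reduce cell count or size"
            )
        attempts += 1
        cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if all(math.hypot(cand[0] - c[0], cand[1] - c[1]) >= min_sep for c in centers):
            centers.append(cand)
    return centers


def sample_field_spec(
    seed: int,
    n_cells: int = 30,
    shape: tuple[int, int] = (512, 512),
    class_mixture: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    transfection_rate: float = 0.4,
    nucleus_radius_range: tuple[float, float] = (8.0, 12.0),
    cell_scale: float = 1.8,
    nuclear_intensity_range: tuple[float, float] = (1500.0, 3000.0),
    gfp_intensity_range: tuple[float, float] = (1000.0, 3000.0),
    background_level: tuple[float, float] = (100.0, 100.0),
    noise: NoiseModel = NoiseModel(),
) -> FieldSpec:
    """Draw one random field recipe.

    Each cell is transfected (labeled) with probability
    ``transfection_rate``; labeled cells draw their localization class
    from ``class_mixture`` (NUCLEAR, CYTOPLASMIC, BOTH), so per-field
    realized class counts are multinomial.  Radii and intensities are
    uniform draws within the stated ranges.  Everything, including the
    render seed, derives from ``seed``.
    """
    mix = np.asarray(class_mixture, dtype=float)
    if mix.shape != (3,) or (mix < 0).any():
        raise ValueError("class_mixture must be three non-negative probabilities")
    if not math.isclose(mix.sum(), 1.0, abs_tol=2e-2):
        raise ValueError(f"class_mixture must sum to 1, got {mix.sum():.4f}")
    mix = mix / mix.sum()
    rng = np.random.default_rng(seed)
    max_cell_radius = nucleus_radius_range[1] * cell_scale
    centers = _place_centers(rng, shape, n_cells, min_sep=2 * max_cell_radius, margin=max_cell_radius + 2)
    cells = []
    for center in centers:
        nr = rng.uniform(*nucleus_radius_range)
        labeled = rng.uniform() < transfection_rate
        if labeled:
            true_class = LABELED_CLASSES[rng.choice(3, p=mix)]
        else:
            true_class = "UNLABELED"
        cells.append(
            CellSpec(
                center=center,
                nucleus_radius=nr,
                cell_radius=nr * cell_scale,
                true_class=true_class,
                nuclear_intensity=rng.uniform(*nuclear_intensity_range),
                gfp_intensity=rng.uniform(*gfp_intensity_range),
            )
        )
    render_seed = int(rng.integers(0, 2**31 - 1))
    return FieldSpec(
        shape=shape,
        cells=tuple(cells),
        background_level=background_level,
        noise=noise,
        seed=render_seed,
    )


# ---------------------------------------------------------------------------
# Experiment design


@dataclass(frozen=True)
class TreatmentSpec:
    """Ground-truth localization mixture for one treatment group.

    ``mixture`` gives the (NUCLEAR, CYTOPLASMIC, BOTH) probabilities for
    labeled cells; it is renormalized to sum exactly to 1 (printed
    summary tables are often rounded, so sums like 0.9989 are accepted).
    ``transfection_rate`` overrides the design-wide default when set;
    0 models the untransfected negative control.
    """

    mixture: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    transfection_rate: float | None = None

    def normalized_mixture(self) -> tuple[float, float, float]:
        mix = np.asarray(self.mixture, dtype=float)
        if (mix < 0).any() or (mix > 1).any():
            raise ValueError(f"mixture probabilities must be in [0, 1], got {self.mixture}")
        total = mix.sum()
        if not math.isclose(total, 1.0, abs_tol=2e-2):
            raise ValueError(f"mixture must sum to 1 (got {total:.4f}): {self.mixture}")
        mix = mix / total
        return (float(mix[0]), float(mix[1]), float(mix[2]))


@dataclass
class ExperimentDesign:
    """Multi-well, multi-plate, multi-experiment imaging design.

    Defaults reproduce the assay layout this package targets: four
    groups (wildtype construct, variant construct, diffuse-GFP positive
    control, untransfected negative control), 3 wells per treatment per
    experiment spread over 2 plates, 2 independent experiments (6 wells
    per treatment in total) and 15 fields imaged per well.
    """

    treatments: dict[str, TreatmentSpec] = dc_field(default_factory=dict)
    wells_per_treatment_per_experiment: int = 3
    n_experiments: int = 2
    n_plates_per_experiment: int = 2
    fields_per_well: int = 15
    cells_per_field: int = 30
    transfection_rate: float = 0.4
    shape: tuple[int, int] = (512, 512)
    background_level: tuple[float, float] = (100.0, 100.0)
    noise: NoiseModel = NoiseModel()
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.treatments:
            raise ValueError("design needs at least one treatment")
        for name, t in self.treatments.items():
            t.normalized_mixture()  # validates
        if not (0 <= self.transfection_rate <= 1):
            raise ValueError("transfection_rate must be in [0, 1]")

    @property
    def wells_per_treatment(self) -> int:
        return self.wells_per_treatment_per_experiment * self.n_experiments

    @classmethod
    def default(cls, master_seed: int = 0, **overrides) -> "ExperimentDesign":
        """The standard four-group design with plausible mixtures.

        WT and RISK mixtures are the observed group-level class
        fractions of the wildtype and variant constructs; the positive
        control is dominated by whole-cell (BOTH) localization as
        expected for free diffusible GFP; the negative control has
        transfection rate 0.
        """
        treatments = {
            "WT": TreatmentSpec(mixture=(0.0621, 0.4512, 0.4867)),
            "RISK": TreatmentSpec(mixture=(0.0386, 0.6729, 0.2874)),
            "POS_CTRL": TreatmentSpec(mixture=(0.05, 0.05, 0.90)),
            "NEG_CTRL": TreatmentSpec(mixture=(1 / 3, 1 / 3, 1 / 3), transfection_rate=0.0),
        }
        return cls(treatments=treatments, master_seed=master_seed, **overrides)

    # -- YAML round trip ----------------------------------------------------

    _SCALAR_KEYS = (
        "wells_per_treatment_per_experiment",
        "n_experiments",
        "n_plates_per_experiment",
        "fields_per_well",
        "cells_per_field",
        "transfection_rate",
        "master_seed",
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentDesign":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: design YAML must be a mapping")
        known = set(cls._SCALAR_KEYS) | {"treatments", "shape", "background_level", "noise"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown design keys {sorted(unknown)}")
        kwargs: dict = {k: raw[k] for k in cls._SCALAR_KEYS if k in raw}
        treatments = {}
        for name, tdef in (raw.get("treatments") or {}).items():
            tdef = tdef or {}
            t_unknown = set(tdef) - {"mixture", "transfection_rate"}
            if t_unknown:
                raise ValueError(f"{path}: unknown treatment keys {sorted(t_unknown)} for {name!r}")
            treatments[name] = TreatmentSpec(
                mixture=tuple(tdef.get("mixture", (1 / 3, 1 / 3, 1 / 3))),
                transfection_rate=tdef.get("transfection_rate"),
            )
        kwargs["treatments"] = treatments
        if "shape" in raw:
            kwargs["shape"] = tuple(raw["shape"])
        if "background_level" in raw:
            kwargs["background_level"] = tuple(raw["background_level"])
        if "noise" in raw:
            kwargs["noise"] = NoiseModel(**raw["noise"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data: dict = {k: getattr(self, k) for k in self._SCALAR_KEYS}
        data["shape"] = list(self.shape)
        data["background_level"] = list(self.background_level)
        data["noise"] = {"gaussian_sd": self.noise.gaussian_sd, "poisson": self.noise.poisson}
        data["treatments"] = {
            name: {
                "mixture": list(t.mixture),
                **({"transfection_rate": t.transfection_rate} if t.transfection_rate is not None else {}),
            }
            for name, t in self.treatments.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def field_seed(master_seed: int, experiment: int, treatment_index: int, well: int, field: int) -> int:
    """Per-field seed schedule.

    The tuple ``(master_seed, experiment, treatment_index, well, field)``
    (all 1-based indices except the master seed) feeds a
    ``numpy.random.SeedSequence``; the first generated state word,
    masked to 31 bits, is the field seed.  Any single field is thus
    regenerable in isolation.
    """
    ss = np.random.SeedSequence([master_seed, experiment, treatment_index, well, field])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def _plate_of_well(well_index: int, n_plates: int) -> int:
    """Round-robin well->plate assignment (wells 1,3,5.. -> plate 1, ...)."""
    return (well_index - 1) % n_plates + 1


def generate_experiment(design: ExperimentDesign, out_dir: str | Path) -> pd.DataFrame:
    """Generate every field of ``design`` as TIFF files plus a manifest.

    Layout: ``out_dir/exp{E}/plate{P}/{TREATMENT}_e{E}_w{W}/f{F:02d}.tif``.
    The returned manifest (also written to ``out_dir/manifest.csv``) has
    one row per generated cell with its ground-truth class and geometry.
    Identical ``design.master_seed`` yields byte-identical TIFFs and
    manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for t_idx, (treatment, tspec) in enumerate(sorted(design.treatments.items()), start=1):
        rate = design.transfection_rate if tspec.transfection_rate is None else tspec.transfection_rate
        mixture = tspec.normalized_mixture()
        for exp in range(1, design.n_experiments + 1):
            for w in range(1, design.wells_per_treatment_per_experiment + 1):
                plate = _plate_of_well(w, design.n_plates_per_experiment)
                well_id = f"{treatment}_e{exp}_w{w}"
                well_dir = out_dir / f"exp{exp}" / f"plate{plate}" / well_id
                well_dir.mkdir(parents=True, exist_ok=True)
                for f in range(1, design.fields_per_well + 1):
                    seed = field_seed(design.master_seed, exp, t_idx, w, f)
                    spec = sample_field_spec(
                        seed=seed,
                        n_cells=design.cells_per_field,
                        shape=design.shape,
                        class_mixture=mixture,
                        transfection_rate=rate,
                        background_level=design.background_level,
                        noise=design.noise,
                    )
                    img, truth = render_field(
                        spec,
                        experiment=exp,
                        plate=plate,
                        well=well_id,
                        treatment=treatment,
                        field=f,
                    )
                    img.to_tiff(well_dir / f"f{f:02d}.tif")
                    truth = truth.copy()
                    for key, val in [
                        ("experiment", exp),
                        ("plate", plate),
                        ("well", well_id),
                        ("treatment", treatment),
                        ("field", f),
                    ]:
                        truth[key] = val
                    frames.append(truth)
    manifest = pd.concat(frames, ignore_index=True)
    manifest = manifest[
        ["experiment", "plate", "well", "treatment", "field",
         "cell_id", "row", "col", "nucleus_radius", "cell_radius", "true_class"]
    ]
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
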