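"""Shared fixtures: small synthetic fields and a reusable experiment run."""

from __future__ import annotations

import numpy as np
import pytest

from nucyto.simulate import (
    CellSpec,
    ExperimentDesign,
    FieldSpec,
    NoiseModel,
    TreatmentSpec,
    render_field,
    sample_field_spec,
)

NO_NOISE = NoiseModel(gaussian_sd=0.0, poisson=False)


def make_grid_cells(classes, nucleus_radius=10.0, cell_scale=1.8, spacing=80.0, origin=60.0):
    """Deterministic cells on a grid, one per requested class."""
    cells = []
    for i, cls in enumerate(classes):
        row = origin + spacing * (i // 5)
        col = origin + spacing * (i % 5)
        cells.append(
            CellSpec(
                center=(row, col),
                nucleus_radius=nucleus_radius,
                cell_radius=nucleus_radius * cell_scale,
                true_class=cls,
            )
        )
    return tuple(cells)


@pytest.fixture
def noise_free_field():
    """Factory: render a noise-free field with the given true classes."""

    def _make(classes, **spec_kwargs):
        cells = make_grid_cells(classes)
        spec = FieldSpec(cells=cells, noise=NO_NOISE, seed=0, **spec_kwargs)
        return render_field(spec)

    return _make


@pytest.fixture
def default_noise_field():
    """Factory: one sampled field at the shipped default noise level."""

    def _make(seed=0, **kwargs):
        spec = sample_field_spec(seed=seed, **kwargs)
        return render_field(spec), spec

    return _make


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory):
    """A reduced two-group experiment generated once per test session.

    Uses the wildtype / variant class mixtures of the assay this
    package models, 6 wells per group (3 wells x 2 experiments) and 5
    fields per well — enough labeled cells per well (~60) for the
    recovery checks while keeping the session fast.
    """
    from nucyto.simulate import generate_experiment

    design = ExperimentDesign(
        treatments={
            "WT": TreatmentSpec(mixture=(0.0621, 0.4512, 0.4867)),
            "RISK": TreatmentSpec(mixture=(0.0386, 0.6729, 0.2874)),
        },
        fields_per_well=5,
        cells_per_field=30,
        master_seed=20240917,
    )
    out = tmp_path_factory.mktemp("experiment")
    manifest = generate_experiment(design, out)
    return design, out, manifest


@pytest.fixture(scope="session")
def small_experiment_quantified(small_experiment):
    """Per-cell records and well summaries for the session experiment."""
    from nucyto.classify import ClassificationParams, classify_field
    from nucyto.segment import SegmentationParams, segment_nuclei
    from nucyto.simulate import FieldImage
    from nucyto.stats import summarize_wells
    import pandas as pd

    design, out, manifest = small_experiment
    frames = []
    for path in sorted(out.rglob("*.tif")):
        field = FieldImage.from_tiff(path)
        label_map = segment_nuclei(field.blue, SegmentationParams())
        frames.append(classify_field(field, label_map, ClassificationParams()))
    cells = pd.concat(frames, ignore_index=True)
    wells = summarize_wells(cells)
    return cells, wells
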