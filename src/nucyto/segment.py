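"""Nuclear segmentation from the blue (Hoechst/DAPI) counterstain channel.

The nuclear compartment of every cell is defined as the area covered by
the blue DNA stain.  The pipeline is classical and fully deterministic:

    global Otsu threshold -> binary closing -> hole filling ->
    removal of small components -> connected-component labeling ->
    (optional) distance-transform watershed split of touching nuclei

A global Otsu threshold is the default because counterstained fields
are strongly bimodal (dark background vs bright chromatin); the
watershed split is off by default and only needed for dense fields
where nuclei touch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops_table
from skimage.morphology import closing, disk
from skimage.segmentation import relabel_sequential, watershed

__all__ = [
    "SegmentationParams",
    "NucleusLabelMap",
    "segment_nuclei",
    "match_to_ground_truth",
    "MatchResult",
    "DEFAULT_NUCLEUS_RADIUS",
]

#: Nominal nucleus radius (pixels) used to derive the default minimum area.
DEFAULT_NUCLEUS_RADIUS = 10.0


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of :func:`segment_nuclei`.

    min_area
        Smallest accepted nucleus, in pixels.  ``None`` -> 25% of the
        area of a nominal nucleus disk (``pi * DEFAULT_NUCLEUS_RADIUS**2``).
    closing_radius
        Structuring-element radius of the binary closing that bridges
        noise-induced pinholes in the mask; 0 disables closing.
    split_touching
        Run a distance-transform watershed to split touching nuclei.
        Off by default: sparse fields have disjoint nuclei and the
        split can over-segment irregular shapes.
    watershed_min_distance
        Minimum separation (pixels) between watershed seed peaks.
    """

    min_area: float | None = None
    closing_radius: int = 2
    split_touching: bool = False
    watershed_min_distance: int = 10

    def resolved_min_area(self) -> float:
        if self.min_area is not None:
            return self.min_area
        return 0.25 * math.pi * DEFAULT_NUCLEUS_RADIUS**2


@dataclass
class NucleusLabelMap:
    """Integer label image plus a per-nucleus geometry table.

    ``labels`` uses 0 for background and contiguous ids 1..n for the
    nuclei.  ``nuclei`` has one row per label with columns ``label``,
    ``centroid_row``, ``centroid_col``, ``area`` and ``touches_border``
    (nuclei clipped by the field of view are kept but flagged so that
    downstream cytoplasm measurements can exclude them).
    """

    labels: np.ndarray
    nuclei: pd.DataFrame

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)


_EMPTY_COLUMNS = ["label", "centroid_row", "centroid_col", "area", "touches_border"]


def _empty_map(shape: tuple[int, int]) -> NucleusLabelMap:
    return NucleusLabelMap(
        labels=np.zeros(shape, dtype=np.int32),
        nuclei=pd.DataFrame(columns=_EMPTY_COLUMNS).astype(
            {"label": int, "centroid_row": float, "centroid_col": float, "area": int, "touches_border": bool}
        ),
    )


def segment_nuclei(blue: np.ndarray, params: SegmentationParams = SegmentationParams()) -> NucleusLabelMap:
    """Segment nuclei from a 2-D counterstain intensity image.

    Deterministic for a fixed input and parameter set.  A contrast-free
    (constant) image produces an empty label map with a warning rather
    than an exception, so a failed acquisition does not abort a run.
    """
    blue = np.asarray(blue)
    if blue.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {blue.shape}")
    if np.issubdtype(blue.dtype, np.signedinteger) or np.issubdtype(blue.dtype, np.floating):
        if blue.size and blue.min() < 0:
            raise ValueError("intensity image must be non-negative")
    if blue.size == 0 or blue.min() == blue.max():
        warnings.warn("constant blue channel: no foreground/background contrast, returning empty label map")
        return _empty_map(blue.shape)

    thresh = threshold_otsu(blue)
    mask = blue > thresh
    if params.closing_radius > 0:
        mask = closing(mask, disk(params.closing_radius))
    mask = ndi.binary_fill_holes(mask)
    min_area = params.resolved_min_area()
    if not mask.any():
        return _empty_map(blue.shape)

    if params.split_touching:
        distance = ndi.distance_transform_edt(mask)
        peaks = peak_local_max(
            distance, min_distance=params.watershed_min_distance, labels=mask, exclude_border=False
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        # peak order from peak_local_max is deterministic; lower marker id
        # wins ties in the watershed flooding.
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        labels = watershed(-distance, markers, mask=mask)
    else:
        labels, _ = ndi.label(mask)

    # watershed fragments below min_area are dropped, then ids compacted
    sizes = np.bincount(labels.ravel())
    too_small = np.flatnonzero(sizes < min_area)
    if too_small.size:
        labels[np.isin(labels, too_small[too_small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    labels = labels.astype(np.int32)
    if not labels.any():
        return _empty_map(blue.shape)

    props = regionprops_table(labels, properties=("label", "centroid", "area"))
    nuclei = pd.DataFrame(
        {
            "label": props["label"].astype(int),
            "centroid_row": props["centroid-0"],
            "centroid_col": props["centroid-1"],
            "area": props["area"].astype(int),
        }
    )
    h, w = labels.shape
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    nuclei["touches_border"] = nuclei["label"].isin(border_labels[border_labels > 0])
    return NucleusLabelMap(labels=labels, nuclei=nuclei)


@dataclass
class MatchResult:
    """Greedy centroid assignment between segmentation and ground truth."""

    assignments: pd.DataFrame  # columns: cell_id, label, distance
    n_true: int
    n_detected: int

    @property
    def n_matched(self) -> int:
        return len(self.assignments)

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else 0.0

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else 0.0


def match_to_ground_truth(label_map: NucleusLabelMap, manifest: pd.DataFrame) -> MatchResult:
    """Match segmented nuclei to ground-truth cells of the same field.

    Greedy nearest-centroid matching: candidate (cell, label) pairs with
    centroid distance at most the cell's ``nucleus_radius`` are taken in
    order of increasing distance, each cell and label used at most once.
    Unmatched labels are false positives; unmatched manifest cells are
    false negatives.
    """
    needed = {"cell_id", "row", "col", "nucleus_radius"}
    missing = needed - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")
    cells = manifest.reset_index(drop=True)
    nuclei = label_map.nuclei
    pairs = []
    for _, cell in cells.iterrows():
        d = np.hypot(nuclei["centroid_row"] - cell["row"], nuclei["centroid_col"] - cell["col"])
        for label, dist in zip(nuclei["label"].to_numpy(), d.to_numpy()):
            if dist <= cell["nucleus_radius"]:
                pairs.append((float(dist), int(cell["cell_id"]), int(label)))
    pairs.sort()
    used_cells: set[int] = set()
    used_labels: set[int] = set()
    rows = []
    for dist, cell_id, label in pairs:
        if cell_id in used_cells or label in used_labels:
            continue
        used_cells.add(cell_id)
        used_labels.add(label)
        rows.append({"cell_id": cell_id, "label": label, "distance": dist})
    assignments = pd.DataFrame(rows, columns=["cell_id", "label", "distance"])
    return MatchResult(assignments=assignments, n_true=len(cells), n_detected=label_map.n_nuclei)
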