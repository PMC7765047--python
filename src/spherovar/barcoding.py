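"""Combinatorial metal barcoding and slice debarcoding.

Spheroids grown in individual wells are barcoded with a k-of-n metal scheme
(each well receives exactly ``k_on`` of ``n_channels`` metals), pooled into a
single plug, sectioned, and imaged together.  Debarcoding reads the per-cell
barcode-channel intensities back into codewords and assigns each sphere slice
to its well of origin by majority vote, with minimum-count and dominance
rules guarding against misassignment.  Two monoisotopic cisplatin labels
(Pt194 / Pt198) applied to pooled plates double the addressable capacity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "CodeSet",
    "SliceAssignment",
    "enumerate_codes",
    "binarize_channels",
    "assign_slice",
    "combine_cisplatin",
    "DEBARCODE_BORDER_UM",
    "MIN_CELLS_PER_BARCODE",
    "DOMINANCE_FACTOR",
]

# Eligibility and assignment defaults (1 px ≡ 1 µm at IMC resolution).
DEBARCODE_BORDER_UM = 30.0
MIN_CELLS_PER_BARCODE = 10
DOMINANCE_FACTOR = 2.0

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class CodeSet:
    """A k-of-n barcoding scheme.

    ``codewords`` holds all binary vectors of length ``n_channels`` with
    exactly ``k_on`` ones, in lexicographic order; ``well_map`` maps each
    codeword (as a bit tuple) to a well id.  Plate layouts typically use a
    subset of the code (e.g. 60 of the 70 words of the 8-choose-4 scheme);
    pass a layout-derived ``well_map`` to restrict assignment to used wells.
    """

    n_channels: int
    k_on: int
    codewords: tuple[tuple[int, ...], ...]
    well_map: dict[tuple[int, ...], int]

    def __len__(self) -> int:
        return len(self.codewords)

    @property
    def capacity(self) -> int:
        return len(self.well_map)


def enumerate_codes(
    n_channels: int,
    k_on: int,
    well_map: dict[tuple[int, ...], int] | None = None,
) -> CodeSet:
    """All weight-``k_on`` binary codewords of length ``n_channels``.

    Deterministic lexicographic order; C(n, k) codewords.  Any two distinct
    equal-weight words differ in at least two positions, so single-channel
    binarization errors never convert one valid word into another.
    """
    if not (0 <= k_on <= n_channels):
        raise ValueError(f"need 0 <= k_on <= n_channels, got {k_on}, {n_channels}")
    words = []
    for on in combinations(range(n_channels), k_on):
        w = [0] * n_channels
        for i in on:
            w[i] = 1
        words.append(tuple(w))
    words.sort()
    assert len(words) == comb(n_channels, k_on)
    if well_map is None:
        well_map = {w: i + 1 for i, w in enumerate(words)}
    else:
        unknown = set(well_map) - set(words)
        if unknown:
            raise ValueError(f"well_map contains invalid codewords: {sorted(unknown)}")
    return CodeSet(n_channels, k_on, tuple(words), dict(well_map))


def binarize_channels(
    intensities: pd.DataFrame,
    plug_ids: np.ndarray | pd.Series | None = None,
    border_distance: np.ndarray | pd.Series | None = None,
    max_border_distance: float = DEBARCODE_BORDER_UM,
) -> pd.DataFrame:
    """Threshold raw barcode-channel intensities into per-cell bits.

    Per plug (all images pooled from one embedding), each channel is
    binarized at its mean intensity over all eligible cells; a cell's bit is
    1 where its intensity exceeds that mean.  Only cells within
    ``max_border_distance`` µm of the outer spheroid border are eligible —
    barcode reagents penetrate from the surface, so interior cells carry
    unreliable signal.  Thresholds use raw (untransformed) intensities.

    Returns a 0/1 DataFrame indexed like ``intensities`` with an ``eligible``
    boolean column appended; ineligible rows keep their bits but are meant to
    be excluded from slice assignment.
    """
    if plug_ids is None:
        plug_ids = np.zeros(len(intensities), dtype=int)
    plug_ids = np.asarray(plug_ids)
    if border_distance is None:
        eligible = np.ones(len(intensities), dtype=bool)
    else:
        eligible = np.asarray(border_distance, dtype=float) <= max_border_distance

    bits = pd.DataFrame(
        np.zeros(intensities.shape, dtype=np.int8),
        index=intensities.index,
        columns=intensities.columns,
    )
    for plug in np.unique(plug_ids):
        in_plug = plug_ids == plug
        pool = in_plug & eligible
        if pool.sum() < 2:
            raise ValueError(f"plug {plug!r}: fewer than 2 eligible cells")
        thresholds = intensities.loc[pool].mean(axis=0)
        if (intensities.loc[pool].std(axis=0, ddof=0) == 0).any():
            import warnings

            warnings.warn(f"plug {plug!r}: constant barcode channel(s), bits all zero")
        bits.loc[in_plug] = (
            intensities.loc[in_plug].gt(thresholds, axis=1).astype(np.int8).values
        )
    out = bits.copy()
    out["eligible"] = eligible
    return out


@dataclass(frozen=True)
class SliceAssignment:
    """Debarcoding verdict for one sphere slice (image)."""

    image_id: object
    well: object  # well id or UNASSIGNED
    majority_count: int
    runner_up_count: int
    n_eligible: int
    reason: str = ""

    @property
    def assigned(self) -> bool:
        return self.well != UNASSIGNED


def assign_slice(
    cell_codes: np.ndarray | pd.DataFrame,
    code_set: CodeSet,
    image_id: object = None,
    min_cells: int = MIN_CELLS_PER_BARCODE,
    dominance: float = DOMINANCE_FACTOR,
) -> SliceAssignment:
    """Assign a slice to the well of its most frequent valid codeword.

    Bit vectors whose weight differs from ``k_on`` (or that are not in the
    code's well map) are discarded before counting.  The winner must reach
    ``min_cells`` cells and be at least ``dominance`` times as frequent as
    the runner-up; otherwise the slice stays UNASSIGNED.
    """
    codes = np.asarray(cell_codes, dtype=int)
    n_eligible = len(codes)
    counts: dict[tuple[int, ...], int] = {}
    for row in codes:
        w = tuple(row.tolist())
        if w in code_set.well_map:
            counts[w] = counts.get(w, 0) + 1
    if not counts:
        return SliceAssignment(image_id, UNASSIGNED, 0, 0, n_eligible, "no valid codewords")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top_word, top = ranked[0]
    second = ranked[1][1] if len(ranked) > 1 else 0
    if top < min_cells:
        return SliceAssignment(
            image_id, UNASSIGNED, top, second, n_eligible, f"majority {top} < {min_cells}"
        )
    if top < dominance * second:
        return SliceAssignment(
            image_id,
            UNASSIGNED,
            top,
            second,
            n_eligible,
            f"majority {top} < {dominance}x runner-up {second}",
        )
    return SliceAssignment(image_id, code_set.well_map[top_word], top, second, n_eligible)


def call_pt_label(
    pt194_positive_fraction: float,
    pt198_positive_fraction: float,
    dominant: float = 0.7,
    recessive: float = 0.3,
) -> str:
    """Call a slice's cisplatin plate-group label from positive-cell fractions.

    A slice is Pt194 when most eligible cells are Pt194-positive and few are
    Pt198-positive (and vice versa); anything else — including ties — is
    ambiguous.  Thresholds are configurable; the defaults demand a clear
    majority on one channel and a clear minority on the other.
    """
    if pt194_positive_fraction > dominant and pt198_positive_fraction < recessive:
        return "Pt194"
    if pt198_positive_fraction > dominant and pt194_positive_fraction < recessive:
        return "Pt198"
    return UNASSIGNED


def combine_cisplatin(
    assignment: SliceAssignment,
    pt_label: str,
    layout_size: int,
    pt_labels: tuple[str, ...] = ("Pt194", "Pt198"),
) -> object:
    """Fold the cisplatin plate-group label into a global well id.

    A ``layout_size``-well barcode layout pooled under ``len(pt_labels)``
    cisplatin labels addresses ``layout_size × len(pt_labels)`` wells; label
    ``i`` offsets the within-layout well id by ``i × layout_size``.
    Pt-ambiguous or unassigned slices stay UNASSIGNED.
    """
    if not assignment.assigned or pt_label == UNASSIGNED:
        return UNASSIGNED
    if pt_label not in pt_labels:
        raise ValueError(f"unknown cisplatin label {pt_label!r}")
    group = pt_labels.index(pt_label)
    return assignment.well + group * layout_size
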