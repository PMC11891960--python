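"""Digital physical disector on slice pairs of a binary volume.

Two parallel sections a known distance apart are compared: an *island*
is a profile on the look-up section with no counterpart on the reference
section, a *bridge* is a new connection merging previously separate
profiles. Summed over sampled pairs (both directions), the event balance
chi_stereol = sum(islands) - sum(bridges) estimates twice the Euler
number of the swept object, and the loop density follows as

    N_V = -chi_stereol / (2 * n_par * a_frame * h_dis)

with a_frame in um^2 and h_dis in um, converted to counts per mm^3.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from capnet.volio import VoxelVolume

__all__ = [
    "FrameSpec",
    "DisectorResult",
    "label_profiles",
    "count_events",
    "disector_estimate",
]

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)
UM3_PER_MM3 = 1.0e9


@dataclass(frozen=True)
class FrameSpec:
    """Counting frame on a slice.

    kind='full_slice' uses the whole slice. kind='guarded' crops
    `margin_px` on every side and, following unbiased counting-frame
    practice, discards an event whose generating look-up profile touches
    the frame's left or bottom exclusion edge.
    """

    kind: str = "full_slice"
    margin_px: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("full_slice", "guarded"):
            raise ValueError(f"unknown frame kind {self.kind!r}")
        if self.kind == "full_slice" and self.margin_px:
            raise ValueError("full_slice frame takes no margin")
        if self.margin_px < 0:
            raise ValueError("margin_px must be >= 0")

    def crop(self, sl: np.ndarray) -> np.ndarray:
        if self.kind == "full_slice" or self.margin_px == 0:
            if self.kind == "guarded" and 2 * self.margin_px >= min(sl.shape):
                raise ValueError("margin exceeds half the slice extent")
            return sl
        m = self.margin_px
        if 2 * m >= min(sl.shape):
            raise ValueError("margin exceeds half the slice extent")
        return sl[m:-m, m:-m]

    def area_um2(self, slice_shape, spacing_nm_yx) -> float:
        ny, nx = slice_shape
        if self.kind == "guarded":
            ny, nx = ny - 2 * self.margin_px, nx - 2 * self.margin_px
        sy, sx = (s / 1000.0 for s in spacing_nm_yx)  # nm -> um
        return ny * sy * nx * sx


@dataclass
class DisectorResult:
    sum_islands: int
    sum_bridges: int
    chi_stereol: int
    n_par: int
    a_frame_um2: float
    h_dis_um: float
    nv_stereol_per_mm3: float
    n_events: int
    count_holes: bool = False
    event_log: list[dict] = field(default_factory=list)

    def write_csv(self, path: str) -> None:
        cols = ["pair_index", "z_reference", "z_lookup", "direction", "islands", "bridges"]
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            for row in self.event_log:
                w.writerow({c: row[c] for c in cols})
            fh.write(
                f"# sum_islands={self.sum_islands} sum_bridges={self.sum_bridges} "
                f"chi_stereol={self.chi_stereol} n_par={self.n_par} "
                f"a_frame_um2={self.a_frame_um2:.6g} h_dis_um={self.h_dis_um:.6g} "
                f"nv_stereol_per_mm3={self.nv_stereol_per_mm3:.6g}\n"
            )


def label_profiles(slice_image: np.ndarray) -> np.ndarray:
    """Label 8-connected foreground profiles 1..k on a 2D binary slice."""
    sl = np.asarray(slice_image)
    if sl.ndim != 2:
        raise ValueError("expected a 2D slice")
    labels, _ = ndi.label(sl.astype(bool), structure=_STRUCT8)
    return labels


def count_events(
    reference: np.ndarray,
    lookup: np.ndarray,
    frame: FrameSpec | None = None,
    count_holes: bool = False,
):
    """Count islands and bridges between a reference and a look-up slice.

    islands: look-up profiles whose footprint overlaps no reference
    foreground. bridges: for each look-up profile overlapping k distinct
    reference profiles, max(0, k - 1) — each merge is one new connection,
    which makes islands - bridges additive in the change of profile
    count. With `count_holes`, newly enclosed background components
    inside a look-up profile each contribute one 'hole' event (an
    extension to the printed island/bridge balance, off by default).
    """
    reference = np.asarray(reference).astype(bool)
    lookup = np.asarray(lookup).astype(bool)
    if reference.shape != lookup.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {lookup.shape}")
    if frame is not None:
        reference = frame.crop(reference)
        lookup = frame.crop(lookup)
    ref_labels = label_profiles(reference)
    look_labels, n_look = ndi.label(lookup, structure=_STRUCT8)

    islands = 0
    bridges = 0
    excluded_edges = frame is not None and frame.kind == "guarded"
    for lab in range(1, n_look + 1):
        mask = look_labels == lab
        if excluded_edges:
            ys, xs = np.nonzero(mask)
            # exclusion edges: left column and bottom row of the frame
            if (xs == 0).any() or (ys == mask.shape[0] - 1).any():
                continue
        overlapped = np.unique(ref_labels[mask])
        overlapped = overlapped[overlapped > 0]
        if overlapped.size == 0:
            islands += 1
        else:
            bridges += overlapped.size - 1

    if count_holes:
        holes = 0
        ref_holes = _enclosed_background(reference)
        look_holes = _enclosed_background(lookup)
        # background phase uses 4-connectivity
        hole_labels, n_holes = ndi.label(look_holes)
        for lab in range(1, n_holes + 1):
            if not ref_holes[hole_labels == lab].any():
                holes += 1
        return islands, bridges, holes
    return islands, bridges


def _enclosed_background(sl: np.ndarray) -> np.ndarray:
    filled = ndi.binary_fill_holes(sl)
    return filled & ~sl


def disector_estimate(
    volume: VoxelVolume,
    h_dis_um: float = 1.0,
    frame: FrameSpec | None = None,
    sampling: str = "exhaustive",
    step: int | None = None,
    seed: int = 0,
    bidirectional: bool = True,
    count_holes: bool = False,
) -> DisectorResult:
    """Run the disector over slice pairs (z, z + delta) of a volume.

    delta = h_dis / spacing_z must be integral to within 1%. With
    `bidirectional` (the default) each pair is counted twice, each slice
    once as reference and once as look-up, and the density formula's
    division by two compensates. `sampling` is 'exhaustive' (every pair)
    or 'systematic' (every `step`-th pair starting at a seeded random
    offset in [0, step)). Warns when fewer than 100 events were counted.
    """
    fg = volume.require_binary()
    frame = frame or FrameSpec()
    spacing_z_um = volume.spacing_nm[0] / 1000.0
    delta_f = h_dis_um / spacing_z_um
    delta = int(round(delta_f))
    if delta < 1 or abs(delta_f - delta) > 0.01 * delta:
        raise ValueError(
            f"h_dis={h_dis_um} um is not an integer multiple of the z spacing "
            f"({spacing_z_um} um)"
        )
    nz = fg.shape[0]
    if nz <= delta:
        raise ValueError(f"volume has {nz} slices; need more than delta={delta}")
    pair_starts = list(range(nz - delta))
    if sampling == "systematic":
        if not step or step < 1:
            raise ValueError("systematic sampling requires step >= 1")
        rng = np.random.default_rng(seed)
        offset = int(rng.integers(0, step))
        pair_starts = pair_starts[offset::step]
    elif sampling != "exhaustive":
        raise ValueError(f"unknown sampling {sampling!r}")

    sum_islands = 0
    sum_bridges = 0
    sum_holes = 0
    log: list[dict] = []
    for i, z in enumerate(pair_starts):
        directions = [(z, z + delta, "up")]
        if bidirectional:
            directions.append((z + delta, z, "down"))
        for z_ref, z_look, tag in directions:
            res = count_events(fg[z_ref], fg[z_look], frame=frame, count_holes=count_holes)
            if count_holes:
                isl, brd, hol = res
                sum_holes += hol
            else:
                isl, brd = res
            sum_islands += isl
            sum_bridges += brd
            log.append(
                {
                    "pair_index": i,
                    "z_reference": z_ref,
                    "z_lookup": z_look,
                    "direction": tag,
                    "islands": isl,
                    "bridges": brd,
                }
            )

    chi = sum_islands - sum_bridges + sum_holes
    n_par = len(pair_starts)
    a_frame_um2 = frame.area_um2(fg.shape[1:], volume.spacing_nm[1:])
    denom_um3 = 2.0 * n_par * a_frame_um2 * h_dis_um
    nv_per_mm3 = (-chi / denom_um3) * UM3_PER_MM3 if denom_um3 > 0 else 0.0
    n_events = sum_islands + sum_bridges + sum_holes
    if n_events < 100:
        logger.warning(
            "disector registered only %d events (< 100); estimate may be unstable", n_events
        )
    return DisectorResult(
        sum_islands=sum_islands,
        sum_bridges=sum_bridges,
        chi_stereol=chi,
        n_par=n_par,
        a_frame_um2=a_frame_um2,
        h_dis_um=float(h_dis_um),
        nv_stereol_per_mm3=nv_per_mm3,
        n_events=n_events,
        count_holes=count_holes,
        event_log=log,
    )
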