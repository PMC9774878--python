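"""Synthetic Raman tissue phantoms: muscle with sectioned fat patterns.

A phantom is built in four steps: (1) partition a H x W canvas into
rectangular sections, each carrying a fat pattern (solid, stripes, or
randomly placed globules); (2) render the binary fat mask; (3) synthesise a
fat and a muscle endmember spectrum (sums of Lorentzian lines over a
baseline); (4) assign the fat spectrum to every fat pixel and the muscle
spectrum to every muscle pixel.  Exactly two distinct pixel spectra exist in
any phantom, so separating fat from muscle by spectrum alone is trivial —
the segmentation task is to tell the *patterns* apart, which requires
spatial context.

The default phantom is 240 x 240 with one solid, one striped and one globule
section and a ground-truth image labelling each section's footprint by its
pattern kind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk

from .core import HSICube, WavenumberAxis, make_wavenumber_axis

__all__ = [
    "SectionMap",
    "FatMask",
    "Endmember",
    "PatternParams",
    "make_section_layout",
    "render_fat_mask",
    "synth_endmember",
    "fat_endmember",
    "muscle_endmember",
    "assemble_hsi",
    "make_phantom",
    "DEFAULT_LAYOUT",
    "PATTERN_IDS",
]

PATTERN_KINDS = ("solid", "stripes", "globules")
#: Pattern-kind ground-truth ids (muscle background, when present, is 3).
PATTERN_IDS = {"solid": 0, "stripes": 1, "globules": 2, "muscle": 3}


@dataclass
class SectionMap:
    """Integer section-id image plus each section's pattern kind."""

    labels: np.ndarray  # (H, W) int, section id per pixel
    section_patterns: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        for sid, kind in self.section_patterns.items():
            if kind not in PATTERN_KINDS:
                raise ValueError(f"unknown pattern kind {kind!r} for section {sid}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class FatMask:
    """Binary tissue mask: 1 = fat, 0 = muscle."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("fat mask must be binary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class Endmember:
    """A pure-component reference spectrum on a wavenumber axis."""

    axis: WavenumberAxis
    intensity: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.axis),):
            raise ValueError("intensity length must equal axis count")
        if not np.isfinite(self.intensity).all():
            raise ValueError("endmember intensities must be finite")
        if (self.intensity < 0).any():
            raise ValueError("endmember intensities must be non-negative")


@dataclass
class PatternParams:
    """Geometry of the fat patterns.

    stripe_width / stripe_period are in pixels along the stripe normal;
    globule radii are drawn uniformly from [globule_r_min, globule_r_max]
    and disks are added until the section's fat fraction reaches
    globule_fill.
    """

    stripe_width: int = 10
    stripe_period: int = 20
    stripe_orientation: str = "horizontal"
    globule_r_min: float = 3.0
    globule_r_max: float = 8.0
    globule_fill: float = 0.3

    def __post_init__(self) -> None:
        if self.stripe_width <= 0 or self.stripe_period <= 0:
            raise ValueError("stripe width and period must be positive")
        if self.stripe_width > self.stripe_period:
            raise ValueError("stripe width cannot exceed the period")
        if not 0 < self.globule_fill < 1:
            raise ValueError("globule fill fraction must lie in (0, 1)")
        if self.globule_r_min <= 0 or self.globule_r_max < self.globule_r_min:
            raise ValueError("invalid globule radius range")
        if self.stripe_orientation not in ("horizontal", "vertical"):
            raise ValueError("stripe orientation must be horizontal or vertical")


def default_pattern_params(height: int, width: int) -> PatternParams:
    """Default pattern geometry, scaled down with the canvas so globules and
    stripes always fit inside a third-of-the-image section."""
    sec = min(height, width) // 3
    r_max = min(8.0, sec / 4)
    period = int(min(20, max(4, sec // 2)))
    return PatternParams(
        stripe_width=max(1, period // 2),
        stripe_period=period,
        globule_r_min=min(3.0, r_max / 2),
        globule_r_max=r_max,
    )


#: Three horizontal bands: solid on top, stripes in the middle, globules below.
DEFAULT_LAYOUT = [
    ((0, 0, 80, 240), "solid"),
    ((80, 0, 80, 240), "stripes"),
    ((160, 0, 80, 240), "globules"),
]


def make_section_layout(
    height: int,
    width: int,
    layout_spec: list[tuple[tuple[int, int, int, int], str]] | None = None,
    seed: int = 0,
) -> SectionMap:
    """Partition a canvas into rectangular sections with assigned patterns.

    ``layout_spec`` is a list of ``((row, col, h, w), kind)`` rectangles that
    must cover the canvas without overlap.  The default three-band layout
    scales to the requested size.
    """
    if layout_spec is None:
        layout_spec = _scaled_default_layout(height, width)
    labels = np.full((height, width), -1, dtype=np.int64)
    patterns: dict[int, str] = {}
    for sid, ((r, c, h, w), kind) in enumerate(layout_spec):
        if r < 0 or c < 0 or r + h > height or c + w > width:
            raise ValueError(f"section {sid} rectangle {(r, c, h, w)} out of bounds")
        block = labels[r : r + h, c : c + w]
        if (block != -1).any():
            raise ValueError(f"section {sid} overlaps a previous section")
        block[:] = sid
        patterns[sid] = kind
    if (labels == -1).any():
        raise ValueError("layout rectangles do not cover the canvas")
    return SectionMap(labels, patterns)


def _scaled_default_layout(height: int, width: int):
    h3 = height // 3
    return [
        ((0, 0, h3, width), "solid"),
        ((h3, 0, h3, width), "stripes"),
        ((2 * h3, 0, height - 2 * h3, width), "globules"),
    ]


def render_fat_mask(
    sections: SectionMap,
    params: PatternParams | None = None,
    seed: int = 0,
) -> FatMask:
    """Render the binary fat mask from a section layout.

    Solid sections are entirely fat.  Striped sections alternate fat bands of
    ``stripe_width`` rows (or columns) with period ``stripe_period``, phase 0
    at the section's own origin.  Globule sections receive hard fat disks
    with uniformly drawn radii and centres until the section's fat fraction
    reaches ``globule_fill``; overlap is allowed.  Deterministic per seed.
    """
    if params is None:
        params = PatternParams()
    rng = np.random.default_rng(seed)
    H, W = sections.shape
    mask = np.zeros((H, W), dtype=np.uint8)
    for sid, kind in sorted(sections.section_patterns.items()):
        footprint = sections.labels == sid
        if not footprint.any():
            continue
        rows = np.flatnonzero(footprint.any(axis=1))
        cols = np.flatnonzero(footprint.any(axis=0))
        r0, r1 = rows[0], rows[-1] + 1
        c0, c1 = cols[0], cols[-1] + 1
        if kind == "solid":
            mask[footprint] = 1
        elif kind == "stripes":
            if params.stripe_orientation == "horizontal":
                coord = np.arange(H)[:, None] - r0
            else:
                coord = np.arange(W)[None, :] - c0
            stripe = (coord % params.stripe_period) < params.stripe_width
            stripe = np.broadcast_to(stripe, (H, W))
            mask[footprint & stripe] = 1
        else:  # globules
            sec_h, sec_w = r1 - r0, c1 - c0
            if 2 * params.globule_r_max > min(sec_h, sec_w):
                raise ValueError(
                    f"globule diameter {2 * params.globule_r_max} exceeds section "
                    f"extent {(sec_h, sec_w)}"
                )
            area = int(footprint.sum())
            local = np.zeros((H, W), dtype=np.uint8)
            # add disks until the target fill fraction is reached
            for _ in range(100_000):
                if local[footprint].sum() / area >= params.globule_fill:
                    break
                radius = rng.uniform(params.globule_r_min, params.globule_r_max)
                cr = rng.uniform(r0 + radius, r1 - radius)
                cc = rng.uniform(c0 + radius, c1 - radius)
                rr, dd = disk((cr, cc), radius, shape=(H, W))
                local[rr, dd] = 1
            mask[footprint & (local == 1)] = 1
    return FatMask(mask)


def synth_endmember(
    peaks: list[tuple[float, float, float]],
    baseline: tuple[float, float],
    axis: WavenumberAxis,
    name: str = "",
) -> Endmember:
    """Synthesise a spectrum as a sum of Lorentzian lines over a linear baseline.

    Each peak is ``(center cm^-1, half-width cm^-1, amplitude)``; the line
    shape is ``a * w^2 / ((x - c)^2 + w^2)`` so the amplitude is attained at
    the centre.  The baseline is ``offset + slope * (x - x0)``.  Negative
    values are clipped at zero.  A peak centred far outside the axis raises a
    warning, not an error.
    """
    x = axis.values
    offset, slope = baseline
    y = offset + slope * (x - x[0])
    for center, width, amp in peaks:
        if width <= 0:
            raise ValueError(f"peak width must be positive, got {width}")
        if center < x[0] - 5 * width or center > x[-1] + 5 * width:
            warnings.warn(
                f"peak at {center} cm^-1 lies far outside the axis "
                f"[{x[0]}, {x[-1]}]",
                stacklevel=2,
            )
        y = y + amp * width**2 / ((x - center) ** 2 + width**2)
    return Endmember(axis, np.clip(y, 0.0, None), name=name)


# Lorentzian line lists loosely following the strong bands of adipose and
# muscle tissue Raman spectra: fat is dominated by acyl-chain CH2 modes
# (1301, 1440 cm^-1), the ester carbonyl (1746) and C=C stretch (1655);
# muscle by the amide I / III protein bands, the CH deformation near 1450
# and the sharp phenylalanine ring mode at 1004 cm^-1.
_FAT_PEAKS = [
    (1078.0, 12.0, 0.35),
    (1301.0, 10.0, 0.75),
    (1440.0, 12.0, 1.0),
    (1655.0, 10.0, 0.45),
    (1746.0, 9.0, 0.55),
]
_MUSCLE_PEAKS = [
    (1004.0, 5.0, 0.55),
    (1250.0, 18.0, 0.45),
    (1340.0, 14.0, 0.40),
    (1450.0, 14.0, 0.50),
    (1655.0, 14.0, 0.90),
]


def fat_endmember(axis: WavenumberAxis) -> Endmember:
    """Fat-like preset spectrum on the given axis."""
    return synth_endmember(_FAT_PEAKS, (0.10, 1.5e-4), axis, name="fat")


def muscle_endmember(axis: WavenumberAxis) -> Endmember:
    """Muscle-like preset spectrum on the given axis."""
    return synth_endmember(_MUSCLE_PEAKS, (0.15, 1.0e-4), axis, name="muscle")


def assemble_hsi(
    fat: FatMask,
    fat_spec: Endmember,
    muscle_spec: Endmember,
    sections: SectionMap | None = None,
    truth_mode: str = "pattern",
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> HSICube:
    """Assemble the cube: the fat spectrum at every fat pixel, muscle elsewhere.

    ``truth_mode="pattern"`` (default) labels each pixel by its section's
    pattern kind; ``"section"`` labels by section id.  Optional i.i.d.
    Gaussian noise of standard deviation ``noise_sigma`` can be added.
    """
    if fat_spec.axis != muscle_spec.axis:
        raise ValueError("fat and muscle endmembers must share one wavenumber axis")
    H, W = fat.shape
    B = len(fat_spec.axis)
    data = np.where(
        fat.mask[:, :, None].astype(bool),
        fat_spec.intensity[None, None, :],
        muscle_spec.intensity[None, None, :],
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = np.clip(data + rng.normal(0.0, noise_sigma, data.shape), 0.0, None)
    truth = None
    if sections is not None:
        if sections.shape != (H, W):
            raise ValueError("section map shape differs from the fat mask")
        if truth_mode == "pattern":
            truth = np.empty((H, W), dtype=np.int64)
            for sid, kind in sections.section_patterns.items():
                truth[sections.labels == sid] = PATTERN_IDS[kind]
        elif truth_mode == "section":
            truth = sections.labels.copy()
        else:
            raise ValueError(f"unknown truth_mode {truth_mode!r}")
    return HSICube(data.astype(np.float64), fat_spec.axis, truth=truth)


def make_phantom(
    height: int = 240,
    width: int = 240,
    n_bands: int = 800,
    layout_spec=None,
    params: PatternParams | None = None,
    truth_mode: str = "pattern",
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> HSICube:
    """One-call phantom builder: layout -> mask -> endmembers -> cube.

    The wavenumber axis keeps the instrument's start (444.2 cm^-1) and span
    and re-spaces it to ``n_bands`` points (step 1.98 cm^-1 at the full 800).
    """
    step = 1.98 * 800 / n_bands
    axis = make_wavenumber_axis(444.2, step, n_bands)
    if params is None and layout_spec is None:
        params = default_pattern_params(height, width)
    sections = make_section_layout(height, width, layout_spec, seed=seed)
    mask = render_fat_mask(sections, params, seed=seed)
    return assemble_hsi(
        mask,
        fat_endmember(axis),
        muscle_endmember(axis),
        sections=sections,
        truth_mode=truth_mode,
        noise_sigma=noise_sigma,
        seed=seed + 1,
    )
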